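"""Minimal genome model: named chromosomes with lengths, one flagged as X.

Stands in for a real assembly (e.g. mm10): every coordinate-bearing object in
the package is validated against one of these, and the synthetic-data
generators place peaks, genes and SNPs on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["SimGenome"]


@dataclass(frozen=True)
class SimGenome:
    """A toy genome: unique chromosome names, positive lengths, exactly one X.

    Parameters
    ----------
    chrom_names
        Chromosome identifiers, unique.
    chrom_lengths
        Length in base pairs per chromosome, same order as ``chrom_names``.
    x_chrom
        Name of the chromosome treated as the X; must be in ``chrom_names``.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    x_chrom: str = "chrX"

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom_names", tuple(self.chrom_names))
        object.__setattr__(self, "chrom_lengths", tuple(int(x) for x in self.chrom_lengths))
        if len(self.chrom_names) == 0:
            raise ValueError("genome must have at least one chromosome")
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValueError("chromosome names must be unique")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths length mismatch")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.x_chrom not in self.chrom_names:
            raise ValueError(f"x_chrom {self.x_chrom!r} not among chromosome names")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(c for c in self.chrom_names if c != self.x_chrom)

    def is_x(self, chrom: str) -> bool:
        return chrom == self.x_chrom

    def contains(self, chrom: str, start: int, end: int) -> bool:
        """Whether the half-open interval lies fully inside the genome."""
        length = self.lengths.get(chrom)
        return length is not None and 0 <= start < end <= length

    # -- interop with the two-column chrom.sizes convention -----------------

    @classmethod
    def from_chrom_sizes(cls, path_or_df, x_chrom: str = "chrX") -> "SimGenome":
        if isinstance(path_or_df, (str, Path)):
            df = pd.read_csv(path_or_df, sep="\t", header=None, names=["chrom", "length"])
        else:
            df = path_or_df
            if list(df.columns) != ["chrom", "length"]:
                df = df.copy()
                df.columns = ["chrom", "length"]
        if df.empty:
            raise ValueError("empty chrom.sizes table")
        return cls(tuple(df["chrom"]), tuple(int(x) for x in df["length"]), x_chrom=x_chrom)

    def to_chrom_sizes(self, path) -> None:
        pd.DataFrame({"chrom": self.chrom_names, "length": self.chrom_lengths}).to_csv(
            path, sep="\t", header=False, index=False
        )

    @classmethod
    def default(cls) -> "SimGenome":
        """Small three-chromosome genome used throughout the examples/tests."""
        return cls(("chr1", "chr2", "chrX"), (5_000_000, 4_000_000, 3_000_000))
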