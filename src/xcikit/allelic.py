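"""Feature-level allelic ratios from biallelic read counts.

In an F1 hybrid (e.g. BL6 × CAST) every SNP-covered read can be assigned to
one parental allele. This module orients strain-labelled counts into
maternal/paternal columns according to the cross direction, aggregates
SNP-level counts over features (genes or genomic windows), and reports the
allelic ratio r = maternal / (maternal + paternal): 1 means purely maternal
expression, 0.5 biallelic, 0 purely paternal. Features below a minimum total
read count are flagged ``filtered`` rather than dropped, so downstream
"informative in every sample" set logic stays reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .windows import make_windows

__all__ = [
    "CrossDesign",
    "orient_counts",
    "aggregate_feature_counts",
    "allelic_ratio",
    "window_allelic_ratios",
    "median_ratios",
]

TAU_HI = 0.7
TAU_LO = 0.3


@dataclass(frozen=True)
class CrossDesign:
    """Which strain is the mother in the F1 cross (named mother × father)."""

    maternal_strain: str
    paternal_strain: str

    def __post_init__(self) -> None:
        if self.maternal_strain == self.paternal_strain:
            raise ValueError("maternal and paternal strains must differ")

    @classmethod
    def from_string(cls, label: str) -> "CrossDesign":
        """Parse e.g. "BL6xCAST" (maternal strain first)."""
        parts = label.replace("×", "x").split("x")
        if len(parts) != 2:
            raise ValueError(f"cannot parse cross label {label!r}")
        return cls(parts[0], parts[1])


def orient_counts(table: pd.DataFrame, cross: CrossDesign) -> pd.DataFrame:
    """Map strain-named count columns to maternal_count / paternal_count.

    Expects columns ``count_<maternal_strain>`` and ``count_<paternal_strain>``.
    Counts are not modified, only relabelled.
    """
    mat_col = f"count_{cross.maternal_strain}"
    pat_col = f"count_{cross.paternal_strain}"
    for col in (mat_col, pat_col):
        if col not in table.columns:
            have = [c for c in table.columns if c.startswith("count_")]
            raise ValueError(f"strain column {col!r} not found (have {have})")
    out = table.copy()
    out["maternal_count"] = table[mat_col].to_numpy()
    out["paternal_count"] = table[pat_col].to_numpy()
    return out


def aggregate_feature_counts(
    snp_table: pd.DataFrame,
    annotation: pd.DataFrame,
    min_unit_coverage: int = 1,
    count_cols: tuple[str, str] = ("maternal_count", "paternal_count"),
    stranded: bool = False,
) -> pd.DataFrame:
    """Sum SNP-level allele counts over annotated features.

    A SNP contributes to a feature iff its total count is at least
    ``min_unit_coverage`` and its position (the ``start`` coordinate) lies in
    the feature's half-open interval. SNPs inside several overlapping features
    contribute to each and those features are flagged ``ambiguous_units``.
    With ``stranded=True`` (both tables carrying a ``strand`` column) SNPs are
    restricted to same-strand features.
    """
    c1, c2 = count_cols
    ann_chroms = set(annotation["chrom"])
    offenders = sorted(set(snp_table["chrom"]) - ann_chroms)
    if offenders:
        raise ValueError(f"count-table chromosomes absent from annotation: {offenders}")
    if annotation["feature_id"].duplicated().any():
        raise ValueError("feature_id values must be unique")

    trees: dict[str, IntervalTree] = {}
    for idx, row in enumerate(annotation.itertuples(index=False)):
        if row.end > row.start:
            trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, idx)

    n_feat = len(annotation)
    mat = np.zeros(n_feat, dtype=np.int64)
    pat = np.zeros(n_feat, dtype=np.int64)
    n_units = np.zeros(n_feat, dtype=np.int64)
    ambiguous = np.zeros(n_feat, dtype=bool)
    ann_strand = annotation["strand"].to_numpy() if "strand" in annotation.columns else None

    totals = snp_table[c1].to_numpy() + snp_table[c2].to_numpy()
    keep = totals >= min_unit_coverage
    snp_strand = snp_table["strand"].to_numpy() if "strand" in snp_table.columns else None
    for pos_i, (chrom, pos, m, p) in enumerate(
        zip(
            snp_table["chrom"].to_numpy(),
            snp_table["start"].to_numpy(),
            snp_table[c1].to_numpy(),
            snp_table[c2].to_numpy(),
        )
    ):
        if not keep[pos_i]:
            continue
        tree = trees.get(chrom)
        if tree is None:
            continue
        hits = [iv.data for iv in tree.at(pos)]
        if stranded and snp_strand is not None and ann_strand is not None:
            hits = [h for h in hits if ann_strand[h] == snp_strand[pos_i]]
        if len(hits) > 1:
            for h in hits:
                ambiguous[h] = True
        for h in hits:
            mat[h] += m
            pat[h] += p
            n_units[h] += 1

    out = annotation[["feature_id", "chrom", "start", "end"]].copy()
    out[c1] = mat
    out[c2] = pat
    out["total"] = mat + pat
    out["n_informative_units"] = n_units
    out["ambiguous_units"] = ambiguous
    return out


def allelic_ratio(
    maternal,
    paternal,
    min_total: int = 30,
    tau_hi: float = TAU_HI,
    tau_lo: float = TAU_LO,
) -> pd.DataFrame:
    """Allelic ratio and status call per feature.

    r = maternal / (maternal + paternal) when the total passes ``min_total``;
    status is ``maternal`` for r >= tau_hi, ``paternal`` for r <= tau_lo,
    ``biallelic`` in between, and ``filtered`` whenever total < min_total
    (the ratio is then NaN, never a division error).
    """
    m = np.atleast_1d(np.asarray(maternal, dtype=np.int64))
    p = np.atleast_1d(np.asarray(paternal, dtype=np.int64))
    if (m < 0).any() or (p < 0).any():
        raise ValueError("allele counts must be non-negative")
    total = m + p
    passing = total >= max(min_total, 1)
    ratio = np.full(total.shape, np.nan)
    np.divide(m, total, out=ratio, where=passing)
    status = np.full(total.shape, "filtered", dtype=object)
    status[passing & (ratio >= tau_hi)] = "maternal"
    status[passing & (ratio <= tau_lo)] = "paternal"
    status[passing & (ratio > tau_lo) & (ratio < tau_hi)] = "biallelic"
    return pd.DataFrame(
        {
            "maternal_count": m,
            "paternal_count": p,
            "total": total,
            "ratio": ratio,
            "status": status,
        }
    )


def window_allelic_ratios(
    atac_table: pd.DataFrame,
    genome,
    width: int = 50_000,
    step: int = 50_000,
    min_total: int = 50,
    count_cols: tuple[str, str] = ("maternal_count", "paternal_count"),
    tau_hi: float = TAU_HI,
    tau_lo: float = TAU_LO,
) -> pd.DataFrame:
    """Allelic ratios over a genomic window lattice (ATAC-style analysis).

    Composition of window annotation + SNP aggregation + ratio computation,
    with the window-level total-read filter (default 50).
    """
    windows = make_windows(genome, width=width, step=step)
    ann = windows.copy()
    ann.insert(
        0,
        "feature_id",
        windows["chrom"].astype(str)
        + ":"
        + windows["start"].astype(str)
        + "-"
        + windows["end"].astype(str),
    )
    agg = aggregate_feature_counts(atac_table, ann, count_cols=count_cols)
    ratios = allelic_ratio(
        agg[count_cols[0]], agg[count_cols[1]], min_total=min_total, tau_hi=tau_hi, tau_lo=tau_lo
    )
    return pd.concat(
        [
            agg[["feature_id", "chrom", "start", "end", "n_informative_units"]].reset_index(drop=True),
            ratios.reset_index(drop=True),
        ],
        axis=1,
    )


def median_ratios(results: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Per-feature median allelic ratio per group (heatmap-ready wide table).

    ``results`` is long-format with columns feature_id, group, replicate,
    ratio, status. Under ``strict`` mode a feature is kept only if it is
    unfiltered in every replicate of every group ("informative across all
    strains"); otherwise filtered replicates are just excluded from medians.
    """
    required = {"feature_id", "group", "ratio", "status"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results missing columns: {sorted(missing)}")
    if results.empty or results["group"].nunique() == 0:
        raise ValueError("no groups present")
    sizes = results.groupby("group").size()
    if (sizes == 0).any():
        raise ValueError("empty group present")
    df = results
    if strict:
        bad_features = set(df.loc[df["status"] == "filtered", "feature_id"])
        df = df[~df["feature_id"].isin(bad_features)]
    else:
        df = df[df["status"] != "filtered"]
    wide = (
        df.groupby(["feature_id", "group"])["ratio"].median().unstack("group")
    )
    return wide
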