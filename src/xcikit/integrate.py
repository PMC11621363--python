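"""Downstream arithmetic over differential-expression and phenotyping tables.

Takes externally fitted DE result tables (gene, chromosome, shrunk log2 fold
change, FDR), applies the significance rule FDR <= 0.01 and |log2FC| >= 1,
and computes the bookkeeping statistics reported across conditions: set
overlaps and direction concordance, fold ratios of set sizes,
autosome/X-chromosome partitions, TPM normalisation for display, and
phenotype-screen significance tallies (uncorrected p < 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "call_de",
    "overlap_and_concordance",
    "fold_ratio",
    "chrom_partition",
    "tpm",
    "log_mean_tpm",
    "summarize_phenotypes",
    "OverlapSummary",
]

DEFAULT_FDR = 0.01
DEFAULT_LFC = 1.0
PHENOTYPE_GROUPS = ("TKO", "female-specific", "male-specific")


def call_de(table: pd.DataFrame, alpha: float = DEFAULT_FDR, lfc: float = DEFAULT_LFC) -> pd.DataFrame:
    """Significant genes under FDR <= alpha and |log2fc| >= lfc (inclusive).

    Returns the subset with a ``direction`` column (sign of the fold change).
    """
    for col in ("gene_id", "log2fc", "fdr"):
        if col not in table.columns:
            raise ValueError(f"DE table missing column {col!r}")
    hit = (table["fdr"] <= alpha) & (table["log2fc"].abs() >= lfc)
    out = table.loc[hit].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out.reset_index(drop=True)


def fold_ratio(n_a: int, n_b: int) -> float:
    """Unrounded ratio of two set sizes; reciprocal under argument swap."""
    if n_b == 0:
        return np.inf if n_a > 0 else np.nan
    return n_a / n_b


@dataclass
class OverlapSummary:
    """Shared/concordant gene accounting across DE condition sets."""

    set_sizes: dict[str, int]
    pairwise: pd.DataFrame
    sharing_histogram: pd.Series  # index k (number of conditions), value gene count
    multiway_shared: int

    def to_dict(self) -> dict:
        return {
            "set_sizes": self.set_sizes,
            "pairwise": self.pairwise.to_dict(orient="records"),
            "sharing_histogram": {int(k): int(v) for k, v in self.sharing_histogram.items()},
            "multiway_shared": int(self.multiway_shared),
        }


def overlap_and_concordance(
    sets: dict[str, pd.DataFrame],
    reference: str = "smaller",
) -> OverlapSummary:
    """Overlap counts, direction concordance and fold ratios across DE sets.

    Each value of ``sets`` is a call_de output (gene_id + direction). Shared
    genes are intersections by gene_id; concordant genes additionally agree
    in direction. The concordance denominator is the smaller set by default
    (``reference``: "smaller", "larger", "first" or a condition name). Fold
    ratios of totals are reported rounded to one decimal, larger over
    smaller. The per-k histogram counts genes significant in exactly k
    conditions.
    """
    if len(sets) < 2:
        raise ValueError("need at least two DE sets")
    dirs = {
        name: dict(zip(df["gene_id"], df["direction"])) for name, df in sets.items()
    }
    sizes = {name: len(d) for name, d in dirs.items()}
    rows = []
    for a, b in combinations(sets.keys(), 2):
        shared = set(dirs[a]) & set(dirs[b])
        concordant = {g for g in shared if dirs[a][g] == dirs[b][g]}
        if reference == "smaller":
            ref_name = a if sizes[a] <= sizes[b] else b
        elif reference == "larger":
            ref_name = a if sizes[a] >= sizes[b] else b
        elif reference == "first":
            ref_name = a
        elif reference in sets:
            ref_name = reference if reference in (a, b) else (a if sizes[a] <= sizes[b] else b)
        else:
            raise ValueError(f"unknown reference rule {reference!r}")
        ref_n = sizes[ref_name]
        concordance_pct = round(100.0 * len(concordant) / ref_n, 2) if ref_n else np.nan
        big, small = max(sizes[a], sizes[b]), min(sizes[a], sizes[b])
        rows.append(
            {
                "set_a": a,
                "set_b": b,
                "n_a": sizes[a],
                "n_b": sizes[b],
                "shared_n": len(shared),
                "concordant_n": len(concordant),
                "reference": ref_name,
                "concordance_pct": concordance_pct,
                "fold_ratio": round(fold_ratio(big, small), 1),
            }
        )
    membership = pd.Series(
        [g for d in dirs.values() for g in d], dtype=object
    ).value_counts()
    histogram = membership.value_counts().sort_index()
    histogram.index.name = "k"
    multiway = int((membership == len(sets)).sum())
    return OverlapSummary(sizes, pd.DataFrame(rows), histogram, multiway)


def chrom_partition(sets: dict[str, pd.DataFrame], x_label: str = "chrX") -> pd.DataFrame:
    """Percentage of each DE set on autosomes vs the X, plus unweighted mean."""
    rows = []
    for name, df in sets.items():
        if "chrom" not in df.columns or df["chrom"].isna().any():
            bad = list(df.loc[df.get("chrom", pd.Series(dtype=object)).isna(), "gene_id"]) if "chrom" in df.columns else "all"
            raise ValueError(f"genes without chromosome in set {name!r}: {bad}")
        n = len(df)
        n_x = int((df["chrom"] == x_label).sum())
        pct_x = 100.0 * n_x / n if n else np.nan
        rows.append({"condition": name, "n": n, "pct_autosome": 100.0 - pct_x, "pct_x": pct_x})
    out = pd.DataFrame(rows)
    mean_row = {
        "condition": "mean",
        "n": int(out["n"].sum()),
        "pct_autosome": out["pct_autosome"].mean(),
        "pct_x": out["pct_x"].mean(),
    }
    return pd.concat([out, pd.DataFrame([mean_row])], ignore_index=True)


def tpm(counts, lengths) -> np.ndarray:
    """Transcripts per million: length-normalised counts scaled to 1e6.

    TPM_g = 1e6 * (c_g / L_g) / sum_j (c_j / L_j), per sample column. Columns
    sum to 1e6; an all-zero column stays zero with a warning.
    """
    c = np.asarray(counts, dtype=float)
    length = np.asarray(lengths, dtype=float)
    if (length <= 0).any():
        raise ValueError("gene lengths must be positive")
    squeeze = c.ndim == 1
    if squeeze:
        c = c[:, None]
    rate = c / length[:, None]
    denom = rate.sum(axis=0)
    if (denom == 0).any():
        warnings.warn("all-zero count column(s); TPM left at zero")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, 1e6 * rate / np.maximum(denom, 1e-300), 0.0)
    return out[:, 0] if squeeze else out


def log_mean_tpm(tpm_matrix, groups) -> pd.DataFrame:
    """log10(mean TPM + 1) per gene within each sample group (display scale)."""
    mat = np.asarray(tpm_matrix, dtype=float)
    groups = np.asarray(groups)
    cols = {}
    for g in pd.unique(groups):
        cols[g] = np.log10(mat[:, groups == g].mean(axis=1) + 1.0)
    return pd.DataFrame(cols)


def summarize_phenotypes(
    table: pd.DataFrame,
    alpha: float = 0.05,
    groups: tuple[str, ...] = PHENOTYPE_GROUPS,
) -> dict:
    """Tally significant phenotyping parameters (strict p < alpha) by group.

    Returns total count, per-group and per-category counts, and per-group
    percentages of the significant total rounded to two decimals.
    """
    for col in ("parameter", "category", "group", "p_value"):
        if col not in table.columns:
            raise ValueError(f"phenotype table missing column {col!r}")
    unknown = set(table["group"]) - set(groups)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    sig = table[table["p_value"] < alpha]
    total = int(len(sig))
    by_group = {g: int((sig["group"] == g).sum()) for g in groups}
    by_category = sig.groupby("category").size().astype(int).to_dict()
    pct = {
        g: (round(100.0 * n / total, 2) if total else None) for g, n in by_group.items()
    }
    return {
        "total_significant": total,
        "by_group": by_group,
        "pct_by_group": pct,
        "by_category": by_category,
    }
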