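"""Single-cell X-inactivation analysis on allele-resolved count matrices.

Each female F1-hybrid cell expresses X-linked genes almost exclusively from
its active X (Xa). Summing the two allele layers over X-linked genes gives a
chromosome-wide allelic ratio per cell; cells with ratio >= 0.7 carry the
strain-1 Xa, cells with ratio <= 0.3 the strain-2 Xa, and cells in between
apparently carry two active X's — in practice barcode doublets — and are
excluded from grouping. Cells with fewer than 10 allele-informative X reads
are too shallow to classify. Definite-state cells are aggregated to
genotype × Xa pseudobulks, where escape genes (expressed from Xi as well as
Xa) show biallelic ratios and Xist shows the Xi allele only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import allelic

__all__ = [
    "CellQCParams",
    "qc_filter",
    "call_xa_state",
    "skew_summary",
    "pseudobulk",
    "gene_allelic_profile",
    "PseudobulkGroup",
]

STATES = ("STRAIN1_Xa", "STRAIN2_Xa", "BIALLELIC_EXCLUDED", "LOW_COVERAGE")
DEFINITE_STATES = ("STRAIN1_Xa", "STRAIN2_Xa")


@dataclass(frozen=True)
class CellQCParams:
    """Cell/gene quality-control bounds; all inequalities are strict."""

    min_features: int = 500
    max_features: int = 5_000
    min_counts: int = 2_000
    max_counts: int = 20_000
    max_mito_pct: float = 10.0
    min_cells_per_gene: int = 10
    mito_chroms: tuple[str, ...] = ("chrM", "MT")

    def __post_init__(self) -> None:
        if not (self.min_features < self.max_features and self.min_counts < self.max_counts):
            raise ValueError("QC ranges must satisfy min < max")
        if not 0 <= self.max_mito_pct <= 100:
            raise ValueError("max_mito_pct must be a percentage")


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)


def _ensure_obs_metrics(adata: ad.AnnData, params: CellQCParams) -> pd.DataFrame:
    obs = adata.obs
    need = {"n_features", "n_counts", "mito_pct"} - set(obs.columns)
    if need:
        X = adata.X
        total = np.asarray(X.sum(axis=1)).ravel()
        n_feat = (
            np.asarray((X > 0).sum(axis=1)).ravel()
            if sp.issparse(X)
            else (np.asarray(X) > 0).sum(axis=1)
        )
        mito_mask = adata.var["chrom"].isin(params.mito_chroms).to_numpy()
        mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else np.zeros(adata.n_obs)
        obs = obs.copy()
        if "n_counts" not in obs:
            obs["n_counts"] = total
        if "n_features" not in obs:
            obs["n_features"] = n_feat
        if "mito_pct" not in obs:
            with np.errstate(invalid="ignore", divide="ignore"):
                obs["mito_pct"] = np.where(total > 0, 100.0 * mito / np.maximum(total, 1), 0.0)
    return obs


def qc_filter(adata: ad.AnnData, params: CellQCParams = CellQCParams()):
    """Filter cells by strict feature/count/mito bounds, then lowly seen genes.

    Returns (filtered AnnData, report). Genes are kept iff expressed (total
    count > 0) in strictly more than ``min_cells_per_gene`` cells *after* the
    cell filter. Raises if nothing survives, with the report attached.
    """
    obs = _ensure_obs_metrics(adata, params)
    nf = obs["n_features"].to_numpy()
    nc = obs["n_counts"].to_numpy()
    mito = obs["mito_pct"].to_numpy()
    ok_feat = (nf > params.min_features) & (nf < params.max_features)
    ok_count = (nc > params.min_counts) & (nc < params.max_counts)
    ok_mito = mito < params.max_mito_pct
    keep_cells = ok_feat & ok_count & ok_mito
    report = {
        "n_cells_in": int(adata.n_obs),
        "removed_features_range": int((~ok_feat).sum()),
        "removed_counts_range": int((~ok_count).sum()),
        "removed_mito": int((~ok_mito).sum()),
        "removed_cells_total": int((~keep_cells).sum()),
        "n_cells_kept": int(keep_cells.sum()),
    }
    filtered = adata[keep_cells]
    cells_per_gene = np.asarray((filtered.X > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene > params.min_cells_per_gene
    report["removed_genes"] = int((~keep_genes).sum())
    report["n_genes_kept"] = int(keep_genes.sum())
    if report["n_cells_kept"] == 0 or report["n_genes_kept"] == 0:
        raise ValueError(f"nothing left after QC filtering: {report}")
    out = filtered[:, keep_genes].copy()
    out.obs = _ensure_obs_metrics(out, params)
    return out, report


def call_xa_state(
    adata: ad.AnnData,
    x_chrom: str = "chrX",
    tau_hi: float = 0.7,
    tau_lo: float = 0.3,
    min_x_reads: int = 10,
) -> pd.DataFrame:
    """Per-cell active-X call from chromosome-wide allelic X reads.

    x_total sums both allele layers over X-linked genes; x_ratio is the
    strain-1 share. Thresholds are inclusive on both sides: ratio >= tau_hi
    gives STRAIN1_Xa, ratio <= tau_lo STRAIN2_Xa, anything between is
    BIALLELIC_EXCLUDED (two apparent Xa's, the doublet signature), and cells
    with x_total < min_x_reads are LOW_COVERAGE regardless of ratio.
    """
    x_mask = (adata.var["chrom"] == x_chrom).to_numpy()
    if not x_mask.any():
        raise ValueError(f"no genes on {x_chrom!r} in matrix")
    s1 = np.asarray(adata.layers["strain1"][:, x_mask].sum(axis=1)).ravel()
    s2 = np.asarray(adata.layers["strain2"][:, x_mask].sum(axis=1)).ravel()
    x_total = s1 + s2
    with np.errstate(invalid="ignore", divide="ignore"):
        x_ratio = np.where(x_total > 0, s1 / np.maximum(x_total, 1), np.nan)
    state = np.full(adata.n_obs, "BIALLELIC_EXCLUDED", dtype=object)
    state[x_ratio >= tau_hi] = "STRAIN1_Xa"
    state[x_ratio <= tau_lo] = "STRAIN2_Xa"
    state[x_total < min_x_reads] = "LOW_COVERAGE"
    return pd.DataFrame(
        {"x_total": x_total.astype(np.int64), "x_ratio": x_ratio, "state": state},
        index=adata.obs_names,
    )


def skew_summary(calls: pd.DataFrame, genotypes: pd.Series) -> pd.DataFrame:
    """Per-genotype state counts and percentages (XCI skewing summary).

    Percentages are over the genotype's non-LOW_COVERAGE cells and therefore
    sum to 100 across the three classifiable states; LOW_COVERAGE rows carry
    counts only.
    """
    df = calls.copy()
    df["genotype"] = genotypes.reindex(calls.index).to_numpy()
    rows = []
    for gt, grp in df.groupby("genotype", sort=True, observed=True):
        informative = (grp["state"] != "LOW_COVERAGE").sum()
        for state in STATES:
            n = int((grp["state"] == state).sum())
            pct = (
                100.0 * n / informative
                if state != "LOW_COVERAGE" and informative > 0
                else np.nan
            )
            rows.append({"genotype": gt, "state": state, "n": n, "pct": pct})
    return pd.DataFrame(rows)


@dataclass
class PseudobulkGroup:
    """Summed allele counts over all cells of one genotype × Xa state."""

    genotype: str
    xa_state: str
    counts: pd.DataFrame  # index gene_id, columns strain1/strain2
    n_cells: int

    @property
    def name(self) -> str:
        return f"{self.genotype}|{self.xa_state}"


def pseudobulk(
    adata: ad.AnnData,
    calls: pd.DataFrame,
    genotypes: pd.Series | None = None,
) -> dict[tuple[str, str], PseudobulkGroup]:
    """Aggregate definite-Xa cells to genotype × state pseudobulk counts.

    BIALLELIC_EXCLUDED and LOW_COVERAGE cells are dropped. Every
    genotype × definite-state combination is emitted; an empty combination
    yields a zero-count group with a warning.
    """
    import warnings

    if genotypes is None:
        genotypes = adata.obs["genotype"]
    genotypes = genotypes.reindex(adata.obs_names)
    calls = calls.reindex(adata.obs_names)
    groups: dict[tuple[str, str], PseudobulkGroup] = {}
    for gt in sorted(pd.unique(genotypes.astype(str))):
        for state in DEFINITE_STATES:
            member = (genotypes.astype(str).to_numpy() == gt) & (
                calls["state"].to_numpy() == state
            )
            n = int(member.sum())
            if n == 0:
                warnings.warn(f"empty pseudobulk group {gt}|{state}; emitting zeros")
                s1 = np.zeros(adata.n_vars, dtype=np.int64)
                s2 = np.zeros(adata.n_vars, dtype=np.int64)
            else:
                s1 = np.asarray(adata.layers["strain1"][member].sum(axis=0)).ravel().astype(np.int64)
                s2 = np.asarray(adata.layers["strain2"][member].sum(axis=0)).ravel().astype(np.int64)
            counts = pd.DataFrame({"strain1": s1, "strain2": s2}, index=adata.var_names)
            groups[(gt, state)] = PseudobulkGroup(gt, state, counts, n)
    return groups


def gene_allelic_profile(
    groups: dict[tuple[str, str], PseudobulkGroup],
    var: pd.DataFrame,
    x_chrom: str = "chrX",
    tau_hi: float = 0.7,
    tau_lo: float = 0.3,
    min_total: int = 30,
) -> pd.DataFrame:
    """Per-group gene allelic ratios and escape calls on pseudobulk counts.

    The ratio is the strain-1 share. For X-linked genes passing the total
    filter the call is relative to the group's Xa strain: ``xa_exclusive``
    when expression comes from the active X only (normal XCI), ``escaping``
    when biallelic (tau_lo < r < tau_hi), ``xi_exclusive`` when the inactive
    X dominates (the Xist pattern). Autosomal genes get no escape call.
    """
    frames = []
    chrom = var["chrom"]
    for (gt, state), grp in sorted(groups.items()):
        res = allelic.allelic_ratio(
            grp.counts["strain1"],
            grp.counts["strain2"],
            min_total=min_total,
            tau_hi=tau_hi,
            tau_lo=tau_lo,
        )
        res = res.rename(columns={"maternal_count": "strain1", "paternal_count": "strain2"})
        res.insert(0, "gene_id", grp.counts.index.to_numpy())
        res.insert(1, "chrom", chrom.reindex(grp.counts.index).to_numpy())
        res.insert(0, "xa_state", state)
        res.insert(0, "genotype", gt)
        is_x = res["chrom"] == x_chrom
        xa_is_strain1 = state == "STRAIN1_Xa"
        call = np.full(len(res), "", dtype=object)
        unfiltered = res["status"] != "filtered"
        hi = unfiltered & (res["ratio"] >= tau_hi)
        lo = unfiltered & (res["ratio"] <= tau_lo)
        mid = unfiltered & ~hi & ~lo
        call[is_x & mid] = "escaping"
        call[is_x & (hi if xa_is_strain1 else lo)] = "xa_exclusive"
        call[is_x & (lo if xa_is_strain1 else hi)] = "xi_exclusive"
        call[is_x & ~unfiltered] = "filtered"
        res["call"] = call
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
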