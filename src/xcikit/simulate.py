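"""Synthetic-data generators for every pipeline input, with ground truth.

Each generator emulates the statistical structure of one real input class —
sex-labelled ATAC peak sets with locally enriched female-specific windows,
F1-hybrid biallelic read counts with allelic-class structure, single-cell
allele-count matrices with skewed X inactivation, doublets and Xi-restricted
Xist, and differential-expression tables with controlled overlap — and emits
a SyntheticTruth record labelling every generated entity, so downstream
operations are testable without any external data. All generators are
deterministic given their config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from .allelic import CrossDesign
from .genome import SimGenome
from . import io as xio

__all__ = [
    "PeakSimConfig",
    "AlleleSimConfig",
    "ScSimConfig",
    "SyntheticTruth",
    "gen_peak_sets",
    "gen_bulk_allele_counts",
    "gen_sc_allele_counts",
    "gen_de_tables",
    "write_peak_dataset",
]

ALLELIC_CLASSES = ("biallelic", "X-silenced", "escaper", "imprinted-maternal", "Xist-like")
X_ONLY_CLASSES = ("X-silenced", "escaper", "Xist-like")


@dataclass
class SyntheticTruth:
    """Ground-truth labels emitted alongside every generated dataset."""

    windows: dict | None = None  # injected enrichment regions
    features: dict | None = None  # feature_id -> allelic class + expected fraction
    cells: dict | None = None  # barcode -> Xa state, doublet flag, QC violation
    de: dict | None = None  # condition -> gene -> true direction

    def to_json(self, path) -> None:
        xio.write_json({k: v for k, v in asdict(self).items() if v is not None}, path)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        return cls(**xio.read_json(path))


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _negbin(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    """Negative-binomial draws with var = mean + dispersion * mean^2."""
    if dispersion <= 0:
        return rng.poisson(mean, size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size)


# ===========================================================================
# peak sets
# ===========================================================================


@dataclass
class PeakSimConfig:
    """Sex-labelled peak-set simulation.

    ``baseline_rate`` is the expected number of peaks per 100 kb; inside each
    ``enriched_windows`` region (chrom, start, end, fold) the rate is
    multiplied by ``fold`` for female samples only. Replicates of an
    organ-sex group share one underlying peak set and differ by boundary
    jitter (and optional dropout), mimicking the high reproducibility of real
    replicate peak calls so that replicate-intersection consensus is
    non-trivial but not empty.
    """

    n_organs: int = 6
    replicates_per_sex: int = 2
    baseline_rate: float = 5.0
    enriched_windows: tuple = ()
    peak_width_range: tuple[int, int] = (500, 2000)
    replicate_jitter: int = 100
    replicate_dropout: float = 0.0
    seed: int = 0

    def validate(self, genome: SimGenome) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.n_organs < 1 or self.replicates_per_sex < 1:
            raise ValueError("need at least one organ and one replicate per sex")
        if not 0 <= self.replicate_dropout < 1:
            raise ValueError("replicate_dropout must be in [0, 1)")
        w0, w1 = self.peak_width_range
        if not 0 < w0 <= w1:
            raise ValueError("invalid peak_width_range")
        for chrom, start, end, fold in self.enriched_windows:
            if fold < 1:
                raise ValueError(f"enrichment fold must be >= 1, got {fold}")
            if not genome.contains(chrom, start, end):
                raise ValueError(
                    f"enriched window {chrom}:{start}-{end} outside genome bounds"
                )


def _chrom_segments(length: int, regions: list[tuple[int, int, float]]):
    """Partition [0, length) into (start, end, fold) segments."""
    segments = []
    pos = 0
    for start, end, fold in sorted(regions):
        if start > pos:
            segments.append((pos, start, 1.0))
        segments.append((start, end, fold))
        pos = end
    if pos < length:
        segments.append((pos, length, 1.0))
    return segments


def gen_peak_sets(genome: SimGenome, cfg: PeakSimConfig):
    """Simulate one peak table per (organ, sex, replicate) plus truth.

    Peak starts follow a Poisson process at ``baseline_rate`` per 100 kb
    (times ``fold`` inside enriched regions, females only); widths are
    uniform in ``peak_width_range`` and clipped at chromosome ends.
    Returns (dict keyed by (organ, sex, replicate), SyntheticTruth).
    """
    cfg.validate(genome)
    rng = _rng(cfg.seed)
    w0, w1 = cfg.peak_width_range
    by_chrom: dict[str, list] = {}
    for chrom, start, end, fold in cfg.enriched_windows:
        by_chrom.setdefault(chrom, []).append((int(start), int(end), float(fold)))

    organs = [f"organ{i + 1}" for i in range(cfg.n_organs)]
    out: dict[tuple[str, str, int], pd.DataFrame] = {}
    for organ in organs:
        for sex in ("female", "male"):
            rows = []
            for chrom, length in genome.lengths.items():
                regions = by_chrom.get(chrom, []) if sex == "female" else []
                for s, e, fold in _chrom_segments(length, regions):
                    lam = cfg.baseline_rate * fold * (e - s) / 100_000.0
                    n = rng.poisson(lam)
                    if n == 0:
                        continue
                    starts = np.sort(rng.integers(s, e, n))
                    widths = rng.integers(w0, w1 + 1, n)
                    ends = np.minimum(starts + widths, length)
                    rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
            base = (
                pd.concat(rows, ignore_index=True)
                if rows
                else pd.DataFrame(columns=["chrom", "start", "end"])
            )
            for rep in range(1, cfg.replicates_per_sex + 1):
                peaks = base.copy()
                if len(peaks) and cfg.replicate_jitter > 0:
                    j = cfg.replicate_jitter
                    lengths = peaks["chrom"].map(genome.lengths).to_numpy()
                    ds = rng.integers(-j, j + 1, len(peaks))
                    de = rng.integers(-j, j + 1, len(peaks))
                    new_start = np.clip(peaks["start"].to_numpy() + ds, 0, lengths - 1)
                    new_end = np.clip(peaks["end"].to_numpy() + de, 1, lengths)
                    ok = new_end > new_start
                    peaks["start"] = np.where(ok, new_start, peaks["start"])
                    peaks["end"] = np.where(ok, new_end, peaks["end"])
                if len(peaks) and cfg.replicate_dropout > 0:
                    peaks = peaks[rng.random(len(peaks)) >= cfg.replicate_dropout]
                peaks = peaks.reset_index(drop=True)
                peaks["name"] = [
                    f"{organ}_{sex}_rep{rep}_peak{i}" for i in range(len(peaks))
                ]
                out[(organ, sex, rep)] = peaks

    truth = SyntheticTruth(
        windows={
            "enriched": [
                {"chrom": c, "start": int(s), "end": int(e), "fold": float(f)}
                for c, s, e, f in cfg.enriched_windows
            ]
        }
    )
    return out, truth


def write_peak_dataset(peaks: dict, out_dir) -> Path:
    """Write BED files and a sample sheet; returns the sample-sheet path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for (organ, sex, rep), df in sorted(peaks.items()):
        name = f"{organ}_{sex}_rep{rep}"
        path = out / f"{name}.bed"
        xio.write_bed(df, path)
        rows.append(
            {"sample_id": name, "sex": sex, "organ": organ, "replicate": rep, "path": str(path)}
        )
    sheet = out / "sample_sheet.tsv"
    pd.DataFrame(rows).to_csv(sheet, sep="\t", index=False)
    return sheet


# ===========================================================================
# bulk allele counts
# ===========================================================================


@dataclass
class AlleleSimConfig:
    """Bulk F1 biallelic count simulation.

    ``class_fractions`` are target proportions over the whole gene universe;
    X-restricted classes (X-silenced, escaper, Xist-like) are placed on X
    genes (any X remainder defaults to X-silenced, the modal class) and
    imprinted-maternal genes on autosomes, the rest biallelic. Per-feature
    totals follow a negative binomial (var = mean + dispersion * mean^2) and
    ``noise_eps`` is the symmetric probability that a read is assigned to the
    wrong allele (binomial thinning), so a monoallelic maternal gene has
    expected maternal fraction 1 - noise_eps.
    """

    n_genes_autosomal: int = 2000
    n_genes_X: int = 200
    class_fractions: dict = field(
        default_factory=lambda: {
            "biallelic": 0.90,
            "imprinted-maternal": 0.015,
            "X-silenced": 0.07,
            "escaper": 0.012,
            "Xist-like": 0.003,
        }
    )
    depth_mean: float = 100.0
    depth_dispersion: float = 0.3
    noise_eps: float = 0.02
    cross: CrossDesign = field(default_factory=lambda: CrossDesign("BL6", "CAST"))
    escaper_range: tuple[float, float] = (0.35, 0.65)
    snps_per_feature: int = 0
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.class_fractions) - set(ALLELIC_CLASSES)
        if unknown:
            raise ValueError(f"unknown allelic classes: {sorted(unknown)}")
        tot = sum(self.class_fractions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {tot}")
        if not 0 <= self.noise_eps < 0.5:
            raise ValueError("noise_eps must be in [0, 0.5)")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        lo, hi = self.escaper_range
        if not 0.3 < lo <= hi < 0.7:
            raise ValueError("escaper_range must lie inside (0.3, 0.7)")


def _largest_remainder(fractions: dict, total: int) -> dict:
    raw = {k: v * total for k, v in fractions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = total - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _place_genes(genome: SimGenome, chroms, n: int, prefix: str, width: int = 2000):
    """Evenly spaced non-overlapping gene intervals across the given chroms."""
    if n == 0:
        return pd.DataFrame(columns=["feature_id", "chrom", "start", "end"])
    if not chroms:
        raise ValueError("no chromosomes available to place genes on")
    lengths = {c: genome.lengths[c] for c in chroms}
    total_len = sum(lengths.values())
    per_chrom = _largest_remainder({c: length / total_len for c, length in lengths.items()}, n)
    rows = []
    i = 0
    for chrom in chroms:
        k = per_chrom[chrom]
        if k == 0:
            continue
        spacing = lengths[chrom] / (k + 1)
        w = int(min(width, max(spacing / 2, 200)))
        for j in range(k):
            start = int((j + 1) * spacing)
            rows.append((f"{prefix}{i:05d}", chrom, start, min(start + w, lengths[chrom])))
            i += 1
    return pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end"])


def gen_bulk_allele_counts(genome: SimGenome, cfg: AlleleSimConfig):
    """Simulate a biallelic count table with class-determined maternal fractions.

    Expected maternal fraction per class (before misassignment noise):
    biallelic 0.5, X-silenced 1 (maternal-Xa convention), escaper drawn
    uniformly inside ``escaper_range``, imprinted-maternal 1, Xist-like 0.
    Returns (AlleleCountTable DataFrame, SyntheticTruth).
    """
    cfg.validate()
    rng = _rng(cfg.seed)
    n_total = cfg.n_genes_autosomal + cfg.n_genes_X
    if n_total == 0:
        warnings.warn("zero genes requested; returning empty table")
        cols = ["unit_id", "chrom", "start", "end", "strand"]
        cols += [f"count_{cfg.cross.maternal_strain}", f"count_{cfg.cross.paternal_strain}"]
        return pd.DataFrame(columns=cols), SyntheticTruth(features={})

    auto = _place_genes(genome, genome.autosomes, cfg.n_genes_autosomal, "gA")
    xdf = _place_genes(genome, (genome.x_chrom,), cfg.n_genes_X, "gX")
    counts_per_class = _largest_remainder(cfg.class_fractions, n_total)
    n_x_classes = sum(counts_per_class.get(c, 0) for c in X_ONLY_CLASSES)
    if n_x_classes > cfg.n_genes_X:
        raise ValueError(
            f"X-restricted classes need {n_x_classes} genes but only {cfg.n_genes_X} X genes exist"
        )

    x_classes = []
    for cls in X_ONLY_CLASSES:
        x_classes += [cls] * counts_per_class.get(cls, 0)
    x_classes += ["X-silenced"] * (cfg.n_genes_X - len(x_classes))
    x_classes = np.array(x_classes, dtype=object)
    rng.shuffle(x_classes)

    n_imprinted = min(counts_per_class.get("imprinted-maternal", 0), cfg.n_genes_autosomal)
    a_classes = np.array(
        ["imprinted-maternal"] * n_imprinted
        + ["biallelic"] * (cfg.n_genes_autosomal - n_imprinted),
        dtype=object,
    )
    rng.shuffle(a_classes)

    genes = pd.concat([auto, xdf], ignore_index=True)
    genes["class"] = np.concatenate([a_classes, x_classes]) if n_total else []

    p_true = np.empty(n_total)
    for cls, val in (
        ("biallelic", 0.5),
        ("X-silenced", 1.0),
        ("imprinted-maternal", 1.0),
        ("Xist-like", 0.0),
    ):
        p_true[genes["class"] == cls] = val
    esc = (genes["class"] == "escaper").to_numpy()
    p_true[esc] = rng.uniform(*cfg.escaper_range, esc.sum())
    eps = cfg.noise_eps
    p_eff = p_true * (1 - eps) + (1 - p_true) * eps

    totals = _negbin(rng, cfg.depth_mean, cfg.depth_dispersion, n_total)
    maternal = rng.binomial(totals, p_eff)
    paternal = totals - maternal

    mat_col = f"count_{cfg.cross.maternal_strain}"
    pat_col = f"count_{cfg.cross.paternal_strain}"
    if cfg.snps_per_feature > 0:
        k = cfg.snps_per_feature
        rows = []
        for i, g in enumerate(genes.itertuples(index=False)):
            span = max(g.end - g.start, k)
            positions = g.start + (np.arange(k) * span) // k
            m_split = rng.multinomial(maternal[i], np.full(k, 1.0 / k))
            p_split = rng.multinomial(paternal[i], np.full(k, 1.0 / k))
            for j in range(k):
                rows.append(
                    (f"{g.feature_id}_snp{j}", g.chrom, int(positions[j]), int(positions[j]) + 1,
                     "+", m_split[j], p_split[j])
                )
        table = pd.DataFrame(
            rows, columns=["unit_id", "chrom", "start", "end", "strand", mat_col, pat_col]
        )
    else:
        table = pd.DataFrame(
            {
                "unit_id": genes["feature_id"],
                "chrom": genes["chrom"],
                "start": genes["start"],
                "end": genes["end"],
                "strand": "+",
                mat_col: maternal,
                pat_col: paternal,
            }
        )

    truth = SyntheticTruth(
        features={
            fid: {"class": cls, "p_true": float(pt), "p_expected": float(pe)}
            for fid, cls, pt, pe in zip(genes["feature_id"], genes["class"], p_true, p_eff)
        }
    )
    return table, truth


# ===========================================================================
# single-cell allele counts
# ===========================================================================


@dataclass
class ScSimConfig:
    """Single-cell allele-count simulation with skewed XCI.

    ``skew`` is the probability that a cell's active X carries strain 1
    (a float, or a mapping per genotype; defaults follow the definite-state
    proportions observed in F1 spleen: mild skew in WT, strong in TKO-het).
    Doublets are additive mixtures of two independently drawn cells of the
    same genotype. ``qc_outlier_rate`` cells per genotype are constructed to
    violate one QC bound each (cycling through low/high depth, high
    mitochondrial fraction, low feature count) so QC filters are exercisable
    with known survivor counts.
    """

    n_cells_per_genotype: int = 2000
    genotypes: tuple[str, ...] = ("WT", "TKO-het")
    skew: float | dict = field(default_factory=lambda: {"WT": 0.68, "TKO-het": 0.85})
    doublet_rate: float = 0.03
    per_cell_depth: tuple[float, float] = (8000.0, 0.05)  # mean, dispersion
    n_genes_autosomal: int = 1500
    n_genes_x: int = 200
    n_mito_genes: int = 10
    escape_gene_ids: tuple[str, ...] | None = None
    xist_id: str = "Xist"
    qc_outlier_rate: float = 0.02
    noise_eps: float = 0.02
    mito_frac: float = 0.03
    seed: int = 0

    def skew_for(self, genotype: str) -> float:
        if isinstance(self.skew, dict):
            return float(self.skew[genotype])
        return float(self.skew)

    def x_gene_ids(self) -> list[str]:
        return [self.xist_id] + [f"gX{i:04d}" for i in range(1, self.n_genes_x)]

    def default_escape_ids(self) -> tuple[str, ...]:
        pool = [g for g in self.x_gene_ids() if g != self.xist_id]
        k = max(1, round(0.04 * self.n_genes_x))
        idx = np.linspace(0, len(pool) - 1, k).astype(int)
        return tuple(pool[i] for i in idx)

    def validate(self) -> None:
        for gt in self.genotypes:
            if not 0 <= self.skew_for(gt) <= 1:
                raise ValueError("skew must be in [0, 1]")
        if not 0 <= self.doublet_rate < 0.5:
            raise ValueError("doublet_rate must be in [0, 0.5)")
        if not 0 <= self.qc_outlier_rate < 1:
            raise ValueError("qc_outlier_rate must be in [0, 1)")
        if not 0 <= self.noise_eps < 0.5:
            raise ValueError("noise_eps must be in [0, 0.5)")
        if self.n_genes_x < 2:
            raise ValueError("need at least two X genes (Xist plus one)")
        x_set = set(self.x_gene_ids())
        escape = self.escape_gene_ids or self.default_escape_ids()
        bad = set(escape) - x_set
        if bad:
            raise ValueError(f"escape_gene_ids not on X: {sorted(bad)}")
        if self.xist_id not in x_set:
            raise ValueError("xist_id must be an X gene")


OUTLIER_TYPES = ("low_counts", "high_counts", "high_mito", "low_features")


def _draw_cells(
    rng: np.random.Generator,
    cfg: ScSimConfig,
    genome: SimGenome,
    n: int,
    skew: float,
    gene_info: dict,
    outlier_types: np.ndarray,
):
    """Draw n cells; returns (total, s1, s2 matrices over all genes, xa, metrics)."""
    n_nuc = gene_info["n_nuclear"]
    weights = gene_info["weights"]
    xa_strain1 = rng.random(n) < skew
    mean, disp = cfg.per_cell_depth
    depth = _negbin(rng, mean, disp, n).astype(np.int64)
    mito_frac = np.clip(rng.normal(cfg.mito_frac, 0.005, n), 0.0, 0.5)

    for i, typ in enumerate(outlier_types):
        if typ == "low_counts":
            depth[i] = rng.integers(500, 1800)
        elif typ == "high_counts":
            depth[i] = rng.integers(21_000, 28_000)
        elif typ == "high_mito":
            mito_frac[i] = rng.uniform(0.12, 0.25)

    mito_counts_tot = rng.binomial(depth, mito_frac)
    nuclear_depth = depth - mito_counts_tot

    counts = np.zeros((n, n_nuc), dtype=np.int64)
    restricted = outlier_types == "low_features"
    normal = ~restricted
    if normal.any():
        counts[normal] = rng.multinomial(nuclear_depth[normal], weights)
    if restricted.any():
        k = min(300, n_nuc)
        w = weights[:k] / weights[:k].sum()
        counts[np.ix_(restricted, np.arange(k))] = rng.multinomial(
            nuclear_depth[restricted], w
        )

    eps = cfg.noise_eps
    p1 = np.full((n, n_nuc), 0.5)
    x_cols = gene_info["x_cols"]
    esc_cols = gene_info["escape_cols"]
    xist_col = gene_info["xist_col"]
    xa_p = np.where(xa_strain1, 1 - eps, eps)
    silenced_cols = np.setdiff1d(x_cols, np.append(esc_cols, xist_col))
    p1[:, silenced_cols] = xa_p[:, None]
    p1[:, xist_col] = np.where(xa_strain1, eps, 1 - eps)
    # escape columns stay at 0.5 (expressed from both X's)
    s1 = rng.binomial(counts, p1)
    s2 = counts - s1

    n_mito = gene_info["n_mito"]
    mito_counts = (
        rng.multinomial(mito_counts_tot, np.full(n_mito, 1.0 / n_mito))
        if n_mito
        else np.zeros((n, 0), dtype=np.int64)
    )
    total = np.concatenate([counts, mito_counts], axis=1)
    z = np.zeros_like(mito_counts)
    return (
        total,
        np.concatenate([s1, z], axis=1),
        np.concatenate([s2, z], axis=1),
        xa_strain1,
    )


def gen_sc_allele_counts(genome: SimGenome, cfg: ScSimConfig):
    """Simulate a cell×gene two-layer allele-count matrix plus truth.

    X-linked counts concentrate on the Xa strain except for escape genes
    (~50/50) and Xist (Xi strain only). Doublet barcodes are sums of two
    independently drawn cells; per-cell totals, feature counts and
    mitochondrial fractions are emitted so QC filters are exercisable.
    Returns (AnnData with layers strain1/strain2, SyntheticTruth).
    """
    cfg.validate()
    rng = _rng(cfg.seed)
    escape_ids = tuple(cfg.escape_gene_ids or cfg.default_escape_ids())

    x_genes = cfg.x_gene_ids()
    autosomes = genome.autosomes or (genome.chrom_names[0],)
    a_genes = [f"gA{i:04d}" for i in range(cfg.n_genes_autosomal)]
    a_chroms = [autosomes[i % len(autosomes)] for i in range(cfg.n_genes_autosomal)]
    mito_genes = [f"mt-{i + 1}" for i in range(cfg.n_mito_genes)]
    gene_ids = a_genes + x_genes + mito_genes
    chroms = a_chroms + [genome.x_chrom] * len(x_genes) + ["chrM"] * len(mito_genes)
    n_nuc = len(a_genes) + len(x_genes)

    weights = rng.lognormal(0.0, 1.0, n_nuc)
    xist_col = n_nuc - len(x_genes) + x_genes.index(cfg.xist_id)
    weights[xist_col] *= 5.0  # Xist is highly expressed
    weights /= weights.sum()
    gene_info = {
        "n_nuclear": n_nuc,
        "n_mito": len(mito_genes),
        "weights": weights,
        "x_cols": np.arange(len(a_genes), n_nuc),
        "escape_cols": np.array([len(a_genes) + x_genes.index(g) for g in escape_ids]),
        "xist_col": xist_col,
    }

    blocks, obs_rows, truth_cells = [], [], {}
    for gt in cfg.genotypes:
        n = cfg.n_cells_per_genotype
        skew = cfg.skew_for(gt)
        n_out = int(round(cfg.qc_outlier_rate * n))
        outlier_types = np.full(n, "", dtype=object)
        out_idx = rng.choice(n, size=n_out, replace=False) if n_out else np.array([], int)
        for j, idx in enumerate(out_idx):
            outlier_types[idx] = OUTLIER_TYPES[j % len(OUTLIER_TYPES)]

        total, s1, s2, xa = _draw_cells(rng, cfg, genome, n, skew, gene_info, outlier_types)

        eligible = np.flatnonzero(outlier_types == "")
        is_doublet = np.zeros(n, dtype=bool)
        if cfg.doublet_rate > 0 and len(eligible):
            chosen = eligible[rng.random(len(eligible)) < cfg.doublet_rate]
            is_doublet[chosen] = True
        partner_xa = np.full(n, None, dtype=object)
        n_db = int(is_doublet.sum())
        if n_db:
            p_total, p_s1, p_s2, p_xa = _draw_cells(
                rng, cfg, genome, n_db, skew, gene_info, np.full(n_db, "", dtype=object)
            )
            total[is_doublet] += p_total
            s1[is_doublet] += p_s1
            s2[is_doublet] += p_s2
            partner_xa[is_doublet] = np.where(p_xa, "strain1", "strain2")

        barcodes = [f"{gt}_cell{i:05d}" for i in range(n)]
        n_counts = total.sum(axis=1)
        n_features = (total > 0).sum(axis=1)
        mito_cols = np.arange(n_nuc, total.shape[1])
        mito_pct = 100.0 * total[:, mito_cols].sum(axis=1) / np.maximum(n_counts, 1)
        for i, bc in enumerate(barcodes):
            xa_label = "strain1" if xa[i] else "strain2"
            truth_cells[bc] = {
                "genotype": gt,
                "xa": xa_label,
                "doublet": bool(is_doublet[i]),
                "partner_xa": partner_xa[i],
                "mixed_doublet": bool(is_doublet[i] and partner_xa[i] != xa_label),
                "qc_violation": outlier_types[i] or None,
            }
        obs_rows.append(
            pd.DataFrame(
                {
                    "genotype": gt,
                    "n_counts": n_counts,
                    "n_features": n_features,
                    "mito_pct": mito_pct,
                },
                index=barcodes,
            )
        )
        blocks.append((total, s1, s2))

    obs = pd.concat(obs_rows)
    obs["genotype"] = obs["genotype"].astype(str)
    adata = ad.AnnData(
        X=np.concatenate([b[0] for b in blocks]),
        obs=obs,
        var=pd.DataFrame({"chrom": chroms}, index=gene_ids),
        layers={
            "strain1": np.concatenate([b[1] for b in blocks]),
            "strain2": np.concatenate([b[2] for b in blocks]),
        },
    )
    adata.uns["escape_gene_ids"] = list(escape_ids)
    adata.uns["xist_id"] = cfg.xist_id
    return adata, SyntheticTruth(cells=truth_cells)


# ===========================================================================
# DE tables
# ===========================================================================


def gen_de_tables(
    n_genes: int = 2000,
    n_de=(200, 150),
    shared_fraction: float = 0.5,
    concordant_fraction: float = 0.8,
    effect_size: float = 2.0,
    seed: int = 0,
    condition_names=None,
    x_fraction: float = 0.05,
):
    """Simulate DE result tables with controlled overlap and concordance.

    ``shared_fraction`` of the smaller set is shared across all conditions;
    ``concordant_fraction`` of those shared genes agree in direction
    everywhere (the remainder flip sign outside the first condition). True DE
    genes get fdr <= 0.01 and |log2fc| >= 1 by construction; null genes fall
    outside both bounds. Returns (dict condition -> DeTable, SyntheticTruth).
    """
    if isinstance(n_de, int):
        n_de = (n_de, n_de)
    n_de = tuple(int(x) for x in n_de)
    if any(x > n_genes for x in n_de):
        raise ValueError("n_de cannot exceed n_genes")
    if not (0 <= shared_fraction <= 1 and 0 <= concordant_fraction <= 1):
        raise ValueError("fractions must be in [0, 1]")
    n_cond = len(n_de)
    if condition_names is None:
        condition_names = [f"cond{i + 1}" for i in range(n_cond)]
    rng = _rng(seed)

    n_shared = int(round(shared_fraction * min(n_de)))
    n_unique = [x - n_shared for x in n_de]
    if n_shared + sum(n_unique) > n_genes:
        raise ValueError("n_genes too small for the requested DE sets")

    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    n_x = int(round(x_fraction * n_genes))
    chrom_pool = ["chr1", "chr2", "chr3", "chr4", "chr5"]
    chroms = np.array(
        [chrom_pool[i % len(chrom_pool)] for i in range(n_genes - n_x)] + ["chrX"] * n_x,
        dtype=object,
    )
    perm = rng.permutation(n_genes)
    chroms = chroms[perm]

    shared = gene_ids[:n_shared]
    n_conc = int(round(concordant_fraction * n_shared))
    shared_dir = np.where(rng.random(n_shared) < 0.5, "up", "down")
    pos = n_shared
    uniques = []
    for k in range(n_cond):
        uniques.append(gene_ids[pos : pos + n_unique[k]])
        pos += n_unique[k]

    tables, truth_de = {}, {}
    for k, name in enumerate(condition_names):
        members = dict()
        for j, g in enumerate(shared):
            d = shared_dir[j]
            if k > 0 and j >= n_conc:  # discordant beyond the concordant block
                d = "down" if d == "up" else "up"
            members[g] = d
        for g in uniques[k]:
            members[g] = "up" if rng.random() < 0.5 else "down"
        lfc = rng.normal(0.0, 0.3, n_genes).clip(-0.99, 0.99)
        fdr = rng.uniform(0.02, 1.0, n_genes)
        table = pd.DataFrame(
            {"gene_id": gene_ids, "chrom": chroms, "log2fc": lfc, "fdr": fdr}
        )
        idx = {g: i for i, g in enumerate(gene_ids)}
        for g, d in members.items():
            i = idx[g]
            mag = max(effect_size * rng.uniform(0.75, 1.25), 1.0)
            table.loc[i, "log2fc"] = mag if d == "up" else -mag
            table.loc[i, "fdr"] = rng.uniform(0.0, 0.01)
        tables[name] = table
        truth_de[name] = members
    return tables, SyntheticTruth(de=truth_de)
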