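"""Genome-wide sex-specificity scan over sliding windows of peak counts.

The scan tiles every chromosome with overlapping windows (default 100 kb wide,
50 kb apart), counts chromatin-accessibility peaks per window separately for
female and male samples, and scores each window with a signed one-sided
binomial statistic: with f and m the (rounded) median per-organ peak counts,
the p-value is the upper tail P(X >= max(f, m)) of Binomial(f + m, 1/2) and
the score is -log10(p), signed positive when females have more peaks. Large
positive scores mark female-specific accessible loci (the Firre/Dxz4 class),
large negative ones male-specific loci.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .genome import SimGenome
from . import io as xio

__all__ = [
    "make_windows",
    "consensus_peaks",
    "count_peaks",
    "sex_score",
    "rank_windows",
    "scan_sample_sheet",
]


def _as_length_map(genome) -> dict[str, int]:
    if isinstance(genome, SimGenome):
        return genome.lengths
    if isinstance(genome, pd.DataFrame):
        return dict(zip(genome["chrom"], genome["length"].astype(int)))
    if isinstance(genome, Mapping):
        return {str(k): int(v) for k, v in genome.items()}
    raise TypeError("genome must be SimGenome, chrom.sizes DataFrame or mapping")


def make_windows(genome, width: int = 100_000, step: int = 50_000) -> pd.DataFrame:
    """Sliding-window lattice over every chromosome.

    Windows start at 0, step, 2*step, ... while start < chromosome length and
    are clipped at the chromosome end, so terminal loci stay scoreable and
    every base is covered by at least one window.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if not 0 < step <= width:
        raise ValueError("step must satisfy 0 < step <= width")
    lengths = _as_length_map(genome)
    if not lengths:
        raise ValueError("empty genome table")
    rows = []
    for chrom, length in lengths.items():
        starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + width, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    windows = pd.concat(rows, ignore_index=True)
    windows.attrs["width"] = width
    windows.attrs["step"] = step
    return windows


# -- consensus over replicates ----------------------------------------------


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union-merge overlapping intervals within each chromosome."""
    if df.empty:
        return df[["chrom", "start", "end"]].copy()
    out = []
    for chrom, grp in df.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        running_end = np.maximum.accumulate(ends)
        # a new block starts where the interval begins past everything before it
        new_block = np.ones(len(starts), dtype=bool)
        new_block[1:] = starts[1:] >= running_end[:-1]
        block = np.cumsum(new_block) - 1
        merged_start = pd.Series(starts).groupby(block).min().to_numpy()
        merged_end = pd.Series(running_end).groupby(block).max().to_numpy()
        out.append(pd.DataFrame({"chrom": chrom, "start": merged_start, "end": merged_end}))
    return pd.concat(out, ignore_index=True)


def _intersect_two(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Intersection spans of two merged interval sets."""
    rows = []
    b_by_chrom = {c: g for c, g in b.groupby("chrom")}
    for chrom, ga in a.groupby("chrom", sort=True):
        gb = b_by_chrom.get(chrom)
        if gb is None:
            continue
        bs = gb["start"].to_numpy()
        be = gb["end"].to_numpy()
        for s, e in zip(ga["start"].to_numpy(), ga["end"].to_numpy()):
            lo = np.searchsorted(be, s, side="right")
            hi = np.searchsorted(bs, e, side="left")
            for j in range(lo, hi):
                rows.append((chrom, max(s, bs[j]), min(e, be[j])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def consensus_peaks(
    replicates: Sequence[pd.DataFrame],
    mode: str = "intersection",
    chrom_sizes=None,
) -> pd.DataFrame:
    """Consensus peak set for one organ-sex group.

    ``intersection`` (default) keeps only spans covered in every replicate,
    merged to their intersection; ``union`` merges the pooled replicates. The
    two readings of replicate-consensus are both offered because either is
    defensible; intersection is the conservative default.
    """
    if len(replicates) == 0:
        raise ValueError("need at least one replicate")
    if mode not in {"intersection", "union"}:
        raise ValueError(f"unknown consensus mode {mode!r}")
    if chrom_sizes is not None:
        known = set(_as_length_map(chrom_sizes))
        for i, rep in enumerate(replicates):
            bad = set(rep["chrom"]) - known
            if bad:
                raise ValueError(f"replicate {i} has chromosomes absent from genome: {sorted(bad)}")
    merged = [_merge_intervals(r) for r in replicates]
    if mode == "union":
        return _merge_intervals(pd.concat(merged, ignore_index=True))
    result = merged[0]
    for other in merged[1:]:
        result = _intersect_two(result, other)
        if result.empty:
            break
    return result.reset_index(drop=True)


# -- counting ----------------------------------------------------------------


def count_peaks(windows: pd.DataFrame, peaks: pd.DataFrame, assign: str = "midpoint") -> np.ndarray:
    """Per-window peak counts, assigning each peak by midpoint containment.

    A peak is counted in every window containing floor((start+end)/2); with
    step = width/2 each midpoint lands in exactly two windows except near the
    chromosome start.
    """
    if assign != "midpoint":
        raise ValueError(f"unknown assignment rule {assign!r}")
    counts = np.zeros(len(windows), dtype=np.int64)
    if peaks.empty or windows.empty:
        return counts
    windows = windows.reset_index(drop=True)
    widths = (windows["end"] - windows["start"]).to_numpy()
    for chrom, wgrp in windows.groupby("chrom", sort=False):
        pk = peaks.loc[peaks["chrom"] == chrom]
        if pk.empty:
            continue
        starts = wgrp["start"].to_numpy()
        ends = wgrp["end"].to_numpy()
        base = wgrp.index.to_numpy()
        order = np.argsort(starts, kind="stable")
        starts, ends, base = starts[order], ends[order], base[order]
        mids = (pk["start"].to_numpy() + pk["end"].to_numpy()) // 2
        max_width = int(widths[wgrp.index].max())
        if len(starts) > 1:
            min_step = int(np.diff(starts).min())
            min_step = max(min_step, 1)
        else:
            min_step = max_width
        n_back = max_width // min_step + 1
        hi = np.searchsorted(starts, mids, side="right")
        for t in range(n_back):
            j = hi - 1 - t
            ok = j >= 0
            jj = j[ok]
            inside = (mids[ok] >= starts[jj]) & (mids[ok] < ends[jj])
            np.add.at(counts, base[jj[inside]], 1)
    return counts


# -- scoring -----------------------------------------------------------------


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


def sex_score(
    female_counts,
    male_counts,
    windows: pd.DataFrame | None = None,
    median_rounding: str = "half_up",
) -> pd.DataFrame:
    """Signed binomial sex-specificity score per window.

    Parameters
    ----------
    female_counts, male_counts
        2-D arrays (n_windows × n_organs) of per-organ consensus peak counts,
        or 1-D arrays of already-summarised counts.
    windows
        Optional window table to prepend coordinate columns.
    median_rounding
        How to integerise half-integer medians before the binomial test:
        "half_up" (default), "floor" or "ceil".
    """
    f = np.atleast_2d(np.asarray(female_counts, dtype=float).T).T
    m = np.atleast_2d(np.asarray(male_counts, dtype=float).T).T
    if (f < 0).any() or (m < 0).any():
        raise ValueError("negative peak counts")
    if f.shape[1] < 1 or m.shape[1] < 1:
        raise ValueError("need at least one organ per sex")
    f_med_raw = np.median(f, axis=1)
    m_med_raw = np.median(m, axis=1)
    rounder = {
        "half_up": _round_half_up,
        "floor": lambda x: np.floor(x).astype(np.int64),
        "ceil": lambda x: np.ceil(x).astype(np.int64),
    }[median_rounding]
    fi = rounder(f_med_raw)
    mi = rounder(m_med_raw)
    n = fi + mi
    k = np.maximum(fi, mi)
    # upper-tail P(X >= k | n, 1/2); sf(k-1) is that tail exactly
    with np.errstate(divide="ignore"):
        p = binom.sf(k - 1, np.maximum(n, 1), 0.5)
    p = np.where(n == 0, 1.0, p)
    sign = np.sign(fi - mi)
    score = np.where(sign == 0, 0.0, sign * -np.log10(p))
    out = pd.DataFrame(
        {
            "f_med": f_med_raw,
            "m_med": m_med_raw,
            "f": fi,
            "m": mi,
            "p": p,
            "score": score,
            "informative": n > 0,
        }
    )
    if windows is not None:
        out = pd.concat([windows[["chrom", "start", "end"]].reset_index(drop=True), out], axis=1)
    return out


def rank_windows(scores: pd.DataFrame, top: int | None = None):
    """Ranked female- and male-specific window tables.

    Female-specific windows sort by descending score, male-specific by
    ascending (most negative first); ties break on (chrom, start). Windows
    with score exactly 0 appear in neither list.
    """
    sort_cols = ["score", "chrom", "start"] if "chrom" in scores.columns else ["score"]
    female = scores[scores["score"] > 0].sort_values(
        sort_cols, ascending=[False] + [True] * (len(sort_cols) - 1), kind="mergesort"
    )
    male = scores[scores["score"] < 0].sort_values(sort_cols, ascending=True, kind="mergesort")
    female = female.reset_index(drop=True)
    male = male.reset_index(drop=True)
    female.insert(0, "rank", np.arange(1, len(female) + 1))
    male.insert(0, "rank", np.arange(1, len(male) + 1))
    if top is not None:
        female, male = female.head(top), male.head(top)
    return female, male


# -- pipeline over a sample sheet -------------------------------------------


def scan_sample_sheet(
    samples: pd.DataFrame,
    genome,
    width: int = 100_000,
    step: int = 50_000,
    consensus: str = "intersection",
    peak_tables: Mapping[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Full scan: consensus per organ-sex, count per window, score per window.

    ``samples`` follows the sample-sheet schema (sample_id, sex, organ,
    replicate, path). ``peak_tables`` may supply in-memory peak DataFrames
    keyed by sample_id instead of reading from ``path``.
    """
    windows = make_windows(genome, width=width, step=step)
    counts: dict[str, dict[str, np.ndarray]] = {"female": {}, "male": {}}
    for (organ, sex), grp in samples.groupby(["organ", "sex"]):
        reps = []
        for _, row in grp.iterrows():
            if peak_tables is not None and row["sample_id"] in peak_tables:
                reps.append(peak_tables[row["sample_id"]])
            else:
                reps.append(xio.read_bed(row["path"]))
        cons = consensus_peaks(reps, mode=consensus, chrom_sizes=genome)
        counts[sex][organ] = count_peaks(windows, cons)
    if not counts["female"] or not counts["male"]:
        raise ValueError("need at least one organ for each sex")
    f = np.column_stack([counts["female"][o] for o in sorted(counts["female"])])
    m = np.column_stack([counts["male"][o] for o in sorted(counts["male"])])
    return sex_score(f, m, windows=windows)
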