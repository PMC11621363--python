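# Methods and design notes

This note documents the statistical models behind each module, the defaults
and why they were chosen, what the synthetic data do and do not emulate, and
the places where the design was genuinely open.

## Sliding-window sex-specificity score

Peaks are counted in windows of width `W = 100 kb` placed every `s = 50 kb`
on each chromosome; window starts run `0, s, 2s, …` while `start < L` and
ends are clipped at the chromosome end, so terminal loci remain scoreable and
every base is covered by at least one window. A peak is assigned to every
window containing its midpoint `⌊(start + end)/2⌋`; with `s = W/2` each peak
therefore counts in exactly two windows except within the first `s` bases of
a chromosome. Midpoint assignment was chosen over any-overlap assignment
because it gives each peak a well-defined multiplicity independent of peak
width.

Replicate peak sets of one organ-sex group are reduced to a consensus before
counting. The default is the conservative reading — intersection spans
present in every replicate — with a union-merge mode behind a flag, since
either reading of "replicate consensus" is defensible.

Per window, `f` and `m` are the medians of the per-organ consensus counts for
females and males. Medians over an even number of organs can be
half-integers; they are rounded half-up before testing (configurable to
floor/ceil), because the binomial test needs integers. With
`n = f + m`, `k = max(f, m)`, the one-sided p-value is the upper binomial
tail `P(X ≥ k | n, ½)` and the score is `−log₁₀ p`, signed positive when
`f > m` and negative when `m > f`; windows with `f = m` score exactly 0 and
`f = m = 0` windows are additionally flagged uninformative. Raw p-values are
used as a ranking score without multiple-testing correction — the score is a
screening statistic, not an inferential one. Base-10 logarithms are used
throughout.

Useful closed forms: `score(3, 0) = −log₁₀(1/8) ≈ 0.903`, and
`score(21, 9) ≈ +1.67` (upper tail of Binomial(30, ½) at 21). The score is
antisymmetric under swapping the sexes, and for fixed `n` its magnitude is
non-decreasing in `|f − m|`.

## Allelic ratios

For a feature with maternal count `M` and paternal count `P`, the allelic
ratio is `r = M / (M + P)`; 1 is maternal-only, 0.5 biallelic, 0
paternal-only. The package always computes the ratio of summed counts — never
the mean of per-SNP ratios — so deep SNPs dominate shallow ones, which is the
behaviour that makes pooling useful.

Filters and thresholds:

* a SNP contributes iff its own total count ≥ 1 (configurable) and its
  position lies in the feature's half-open interval;
* features with total < 30 reads (genes) or < 50 reads (ATAC windows) are
  emitted with status `filtered` rather than dropped, so "informative in
  every sample" set logic stays reproducible downstream;
* status calls use τ_hi = 0.7 / τ_lo = 0.3 with inclusive boundaries. The
  same pair is used at gene level and at single-cell chromosome level, to
  keep one convention (exposed as parameters).

SNPs inside several overlapping features contribute to each, and such
features carry an `ambiguous_units` flag; a strand-aware mode restricts SNPs
to same-strand features when both tables carry strands. This matters for
overlapping sense/antisense pairs (e.g. *Tsix*/*Xist*), where unstranded
pooling can fabricate apparent biallelic signal.

Cross orientation is a column relabelling: the strain column named by the
cross's maternal strain becomes `maternal_count`. Swapping the cross
direction together with the count columns leaves every ratio invariant, and
`r(M, P) = 1 − r(P, M)` for all unfiltered features.

## Single-cell Xa classification and escape detection

Cell QC keeps cells with (strictly) 500 < features < 5000,
2000 < counts < 20 000 and mitochondrial percentage < 10, then keeps genes
expressed in strictly more than 10 remaining cells. The inequalities are
deliberately strict at both boundaries (a cell with exactly 5000 features is
removed). Mitochondrial genes are identified by a configurable chromosome
list (`chrM`/`MT`), since the matrix abstraction carries chromosome labels
rather than gene-name conventions.

The per-cell active-X call sums both allele layers over X-linked genes:
`x_ratio = strain1 / (strain1 + strain2)`. Cells with `x_total < 10` are
`LOW_COVERAGE`; `x_ratio ≥ 0.7` gives `STRAIN1_Xa`; `x_ratio ≤ 0.3` gives
`STRAIN2_Xa`; the remainder are `BIALLELIC_EXCLUDED` — cells that appear to
carry two active X chromosomes, in practice barcode doublets. These are
retained in outputs (with their state) rather than silently dropped, so
doublet accounting is reproducible. Skew summaries report per-genotype state
percentages over the classifiable (non-low-coverage) cells.

Pseudobulk groups are plain column sums of the two layers over all
definite-state cells of one genotype × Xa state; empty groups are emitted as
zeros with a warning. Gene-level calls on pseudobulk reuse the allelic-ratio
machinery with a 30-read floor. Relative to the group's Xa strain, an X gene
is `xa_exclusive` (normal XCI), `escaping` (biallelic: expressed from Xi as
well as Xa), or `xi_exclusive` (the *Xist* pattern). No attempt is made to
model partial escape levels; the calls are threshold classifications.

Normalisation, integration and clustering of expression space are out of
scope: the allelic analysis operates on raw counts, as allele-specific
pipelines do.

## Downstream arithmetic

DE gene sets are thresholded at FDR ≤ 0.01 and |shrunk log₂FC| ≥ 1, both
inclusive; DE model fitting itself is an input, not reimplemented. Overlaps
intersect by gene id; concordant genes additionally match in direction.
The concordance percentage divides by the smaller set by default (so 73
shared concordant genes against sets of 103 and 417 give 70.87 %) — the
denominator is configurable because the convention is not universal. Size
fold-ratios are reported to one decimal (1190 / 104 → 11.4), percentages to
two. The per-k sharing histogram counts genes significant in exactly k
conditions.

TPM: `TPM_g = 10⁶ · (c_g / L_g) / Σ_j (c_j / L_j)`, per sample; columns sum
to 10⁶ exactly and the vector is invariant under rescaling all counts.
Display summaries use `log₁₀(mean TPM + 1)`.

Phenotype tallies count parameters with uncorrected p < 0.05 (strict) per
group (knockout-specific, female-specific, male-specific) and per assay
category, with group percentages of the overall significant total.

## Synthetic data: what it emulates, what it does not

**Peaks.** Peak starts follow a Poisson process at `baseline_rate` per 100 kb
(default 5), multiplied by `fold` inside configured enriched regions for
female samples only; widths are uniform in 500–2000 bp. One underlying peak
set is drawn per organ-sex and replicates differ by ±100 bp boundary jitter
(plus optional dropout, default 0). Fully independent replicate draws would
make intersection-consensus nearly empty — real replicates share most peaks —
so replicate correlation is modelled explicitly while preserving the Poisson
per-window count expectation (a fold-4 window at baseline 5 has mean female
count ≈ 20 up to a ~0.5 % midpoint-edge correction).

**Bulk allele counts.** Per-feature totals are negative-binomial
(`var = μ + αμ²`, defaults μ = 100, α = 0.3). Allelic classes with expected
maternal fraction: biallelic 0.5, X-silenced 1, imprinted-maternal 1,
escaper uniform in (0.35, 0.65), Xist-like 0. Allele misassignment is
symmetric binomial thinning at rate `noise_eps` (default 0.02, a free choice:
the off-allele level of real data is not characterised here), so a silenced
gene's expected observed fraction is `1 − ε`. Class fractions are targets
over the whole default universe of 2000 autosomal + 200 X genes
(0.90 / 0.015 / 0.07 / 0.012 / 0.003); X-restricted classes land on X genes,
imprinting on autosomes, and the small X remainder defaults to X-silenced.
The small fixed universe keeps every test fast.

**Single cells.** Default 2000 cells per genotype over 1500 autosomal + 200 X
+ 10 mitochondrial genes, per-cell depth NB(8000, 0.05), lognormal gene
weights with *Xist* up-weighted ×5. Each cell's Xa is strain 1 with
probability `skew` (defaults WT 0.68, TKO-het 0.85, matching the
definite-state proportions reported for F1 spleen). X genes express from Xa
only (up to ε misassignment), escape genes 50/50, *Xist* from Xi only.
Doublets (default rate 0.03) are additive mixtures of two independently
drawn same-genotype cells. A configurable fraction of cells is constructed
to violate exactly one QC bound each, cycling through violation types, so QC
survivor counts are known in advance. Not emulated: ambient RNA, UMI
saturation, cell-type structure, depth-dependent allelic detection (every
simulated read is allele-informative, unlike real data where only SNP-spanning
reads are), and empty droplets. Passing tests therefore demonstrate the
correctness of the classification and aggregation logic under the stated
model, not robustness to those artefacts.

**DE tables.** A controlled fraction of the smaller set is shared across
conditions, a controlled fraction of shared genes is direction-concordant,
and true/null genes are placed strictly inside/outside the significance
boundaries, so threshold recall is exact by construction.

All generators are deterministic given their config seed (a fresh
`numpy.random.Generator` per call); identical configs give byte-identical
outputs.

## Numerical and scale choices

* Binomial tails via `scipy.stats.binom.sf(k − 1, n, ½)` — exact, no normal
  approximation.
* Window/peak assignment is a vectorised `searchsorted` sweep over the
  regular window grid; gene-feature SNP lookup uses an interval tree;
  consensus intersection is a two-pointer sweep over merged interval lists.
* Ties in window ranking break on (chrom, start) so ranked output is total
  and reproducible.
* Zero-total features never divide: they are `filtered` with a NaN ratio.
* Test and example problem sizes (a ~12 Mb three-chromosome toy genome,
  hundreds-to-thousands of cells, 100-seed recovery loops) were chosen so
  the full suite runs in well under a minute while keeping Monte-Carlo
  standard errors small enough for 3-SE assertions.

## Known limitations

* The scan scores windows independently; no spatial smoothing or
  neighbour-merging of significant windows is attempted.
* Escape calls are per-group threshold decisions; confidence intervals on
  ratios are not computed (the upstream convention reports ratios, not
  imbalance p-values).
* The doublet heuristic only detects mixed-Xa doublets; same-Xa doublets are
  indistinguishable from singlets by design of the statistic.
* The mitochondrial-fraction model in the simulator is a clipped normal, a
  crude stand-in adequate only for exercising the QC filter.
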