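# Methods

## Setting and data model

The pipeline analyses one contiguous target region deep-sequenced after
bisulfite conversion, with per-CpG methylated/total read counts per
sample. The in-memory model (`MethCallTable`) keeps sites, samples (with
cohort and optional sub-group labels) and two integer matrices. A cell
with zero total reads — including everything masked by the 5× coverage
filter — is *missing*, never 0% methylated; this tri-state matters for
the signature procedure's "measurable in every group" step and for
window means. All coordinates are 0-based half-open internally; printed
browser-style spans convert losslessly via `Interval.from_one_based`.
The canonical full-size region, `chr11:1,850,000–3,200,000`, is read as a
browser span of exactly 1,350,000 bp, which tiles into 135 windows of
10 kbp.

## Per-CpG differential test

At each CpG the methylated count of sample *j* is modeled as
beta-binomial, m_j ~ BB(n_j, p, ρ), where ρ is the intra-class
correlation (biological plus technical overdispersion relative to the
binomial). The test is a likelihood-ratio test of H₀: one shared p
against H₁: cohort-specific p's, with ρ held fixed per site:

- ρ is estimated per site by method of moments from the within-cohort
  Pearson residuals, ρ̂ = (X² − df) / Σ(n_j − 1), floored at 10⁻⁶ and
  capped at 0.5, then shrunk 50/50 toward the across-site median. The
  shrinkage stabilizes sites whose 24-sample MoM estimate is noisy while
  letting genuinely heterogeneous sites (e.g. sites where only one tumor
  sub-group deviates) keep a large ρ and, correctly, little significance
  for a cohort-mean shift.
- The p maximizing the BB likelihood is found by a vectorized
  golden-section search on [10⁻⁴, 1−10⁻⁴] (80 iterations, bracket width
  < 10⁻¹³; verified against `scipy.optimize.minimize_scalar`). Binomial
  coefficients are omitted — they cancel in the ratio. Missing cells
  contribute exactly zero log-likelihood.
- 2·(ℓ₁ − ℓ₀) is referred to χ²(1); sites where either cohort has fewer
  than two covered samples are reported `tested = False` with NaN p,
  never p = 1. BH-FDR is computed across tested sites only; significance
  means FDR < 0.005, the threshold appropriate for a small-cohort design.

Under the generator's null (no planted effects, dispersion 0.015, 5 vs 19
samples at 22×) the empirical type-I error at α = 0.05 is ≈ 0.056 across
20 seeds — mildly liberal, as expected for an LRT with plugged-in
dispersion at these sample sizes — and BH at 0.005 yields essentially no
false positives. The acceptance script recomputes both numbers.

The reported effect size `delta` is the difference of unweighted
per-sample mean betas (tumor − reference), deliberately not read-weighted,
so it matches the quantity averaged elsewhere (windows, promoters, sites).

## DMRs

Significant CpGs of the *same direction* are chained whenever consecutive
sites lie within the 1,000 bp bandwidth; chains need ≥ 3 constituents and
a maximum constituent FDR < 0.005, and span first-to-last constituent
plus one base. Direction-aware chaining is a deliberate choice: a hypo
run and a hyper run separated by less than the bandwidth are biologically
two events, and a mixed chain would make the region direction label
ill-posed. The caller never emits a DMR containing a non-significant
site.

## Hypo/hypermethylated regions

Per window, significant CpGs are counted by direction. Seed windows
exceed the 95th percentile (linear-interpolation convention, computed
over *all* windows including zero-count ones, separately per direction)
and have ≥ 75% of their significant CpGs in one direction. Same-direction
seeds merge across at most one sub-threshold window; merged spans snap to
the outermost endpoints of same-direction DMRs overlapping them (falling
back to window edges), and overlapping same-direction regions are
coalesced. Snapping to DMRs is what gives regions base-pair rather than
window resolution.

## Sub-group signature

The five steps are implemented literally: (1) within each tumor
sub-group, drop CpGs whose per-sample differential methylation (sample β
minus the reference-cohort mean β) has an SD above the group's 95th
percentile; (2) keep CpGs measurable in all three groups (a CpG dropped
or unmeasurable in *any* group is out); (3) average the differential per
group; (4) take the SD of the three group means; (5) call CpGs above the
95th percentile of that SD the signature (~5% of eligible CpGs). Note
that steps 1–2 unconditionally discard ≈ 1 − 0.95³ ≈ 14% of CpGs per
group regardless of effect, which caps per-group sensitivity; recovery is
therefore measured pooled over all planted signature CpGs.

The direction-vs-signature association uses the Pearson χ² (no continuity
correction, df = 1) on the 2×2 table of {hypo, hyper} × {in signature,
not} over significant CpGs.

## Element attribution, M-values, regulator enrichment

Promoters are TSS −1,500/+500 bp per isoform, strand-aware and clipped at
region bounds; gene bodies are per-gene maximum footprints. Element
classes are non-exclusive (a CpG in a promoter that lies inside a gene
body counts in both); the non-mapping class is the region minus the union
of all four classes. Binding-site density uses site lengths clipped to
the class span union divided by the union length, making the ratio
invariant to how class intervals are cut.

M = log2(β/(1−β)) with β clamped to [0.01, 0.99] (the M-value diverges at
0 and 1; the clamp bound is exposed). Promoter β per cohort is the
unweighted mean of constituent CpG cohort-mean βs. Isoform selection
minimizes |M-LFC/expr-LFC − 1| on the signed ratio — sign-discordant
isoforms are thereby penalized — with ties broken by isoform order and a
largest-|M-LFC| fallback when the expression fold change is zero.

Regulator enrichment scores each binding site by the fraction of its
nucleotides covered by CpG footprints [pos, pos+2), unioned and clipped;
per-regulator scores are the sums over sites, ranked descending with
average-rank ties, zero-score regulators excluded (list size N recorded).
ΔR = r₀/N₀ − r₁/N₁ uses plain size-normalized ranks (a percentile-rank
variant would be monotone-equivalent). ΔM̄ is the mean over sites of each
site's mean significant-constituent delta — a mean of means, not a pooled
mean. Classification cutoffs are the 5th/95th percentiles of ΔR and ΔM̄
over classifiable records (≥ 20 required); a class needs both dimensions
beyond a cutoff, single-dimension extremes are flagged separately, and
regulators absent from the significant-set ranking are only flagged as
drop-outs, never classified over-enriched. Site direction labels
elsewhere use the majority of significant constituents with ties labeled
`mixed`.

4C loop scores are kept at native coordinates — never window-averaged or
re-normalized — and joined read-only onto per-window site counts.

## The synthetic study

`SimConfig` defaults describe the full-size conditions: 1.35 Mbp region,
~22.7 CpGs/kb (≈ 30.6k sites), 5 reference vs 19 tumor samples with
sub-groups of 8/6/5, negative-binomial depth (mean 22, size 5 — the mean
is the study condition, the dispersion a generator choice), beta-binomial
biological dispersion ρ = 0.015. `SimConfig.scaled()` shrinks all lengths
tenfold (135 kb, 1 kb windows) while keeping per-site depth, cohort sizes
and effect sizes unchanged, so per-CpG statistics are identical and the
full pipeline runs in seconds; tests and the acceptance script use this
scale.

The landscape: methylated background at β = 0.80, gene loci at 0.35,
hyper-block base at 0.45. These levels are chosen so that the tumor-side
binomial variance p(1−p) is nearly uniform across gene loci (0.30) and
background (0.77) — otherwise the signature procedure's per-group
95th-percentile drop concentrates on whichever stratum has higher
variance and silently discards planted CpGs. Planted effects: broad
hypomethylation −0.03 region-wide and −0.05 at gene loci (visible in
profiles, only sporadically significant per site — mirroring broad but
weak loss); three hypermethylated blocks of +0.30 (3 kb scaled / 30 kb
full, window-aligned) and two hypomethylated blocks of −0.70 (near-total
loss, 5 kb / 50 kb). Blocks are flanked by 1.2 kb CpG-free shores —
emulating the sparse background around CpG-dense islands — which also
guarantees block DMRs end at block edges rather than chaining into
borderline background calls.

Sub-group signatures are simulated as *escape* sites: at each group's 40
signature CpGs the other tumors lose 0.60 of methylation while the group
itself retains the normal level. This gives a large across-group SD
(≈ 0.35 vs a ≈ 0.10 noise threshold), keeps every group's within-group
variance typical (so step 1 does not preferentially drop planted sites),
and still shifts the whole-cohort mean, so signature CpGs remain
associated with overall differential methylation — the association the
χ² statistic measures. A shift confined to one sub-group would make the
cohort bimodal, correctly inflate the estimated dispersion, and erase
both properties.

Regulators: a PDX1-like factor with 10 long sites confined to hyper
blocks, an NFATC1-like factor likewise confined to hypo blocks, and 40
background regulators with 20–50 shorter sites scattered outside all
blocks. Few sites put the planted regulators at the bottom of the
baseline coverage ranking; full significant-set coverage puts them at the
top of the significant-set ranking, so their ΔR is structurally maximal,
while background regulators keep correlated ranks in both lists. ATAC
peaks (4 pseudo-samples) get scores proportional to 1.05 minus the local
reference methylation with ±10% noise, making the negative
ATAC–methylation window correlation hold by construction. Expression
log2 fold changes for region genes are drawn independently of promoter
methylation around a mean of −1 (broad tumor downregulation): combined
with region-wide promoter hypomethylation this populates the
"discordant" same-sign quadrants of the methylation-vs-expression plane
while remaining decoupled from methylation. The NFATC1-like regulator is
emitted at log2FC = 3 (significant), the PDX1-like one at −1.5.

What the generator does *not* emulate: spatial correlation of methylation
beyond the piecewise landscape, bisulfite conversion errors, read-level
artifacts, copy-number aberrations, sample contamination, or realistic
CpG clustering (positions are uniform within strata). Passing recovery
tests therefore demonstrates the pipeline's correctness under its own
model assumptions, not performance on real tumor data.

## Numerical conventions

Percentiles use numpy's linear-interpolation convention everywhere.
Ties: average ranks in regulator rankings; first-ordinal wins in isoform
selection; `mixed` label for tied site directions; deterministic Ward
agglomeration on 1 − Pearson distance (pairwise-complete) for the
exploratory sample clustering. Window means pool all covered
(sample, site) cells; CIs come from per-sample window means
(t-distribution). Degenerate inputs raise explicit errors: empty χ²
margins, zero-variance correlation inputs, zero-signal ATAC samples,
groups with fewer than two samples, fewer than 20 regulator records.

## Problem sizes

The default test and acceptance scale is the tenfold-reduced region
(~2,800 CpGs × 24 samples); the per-CpG test on it takes ~1.5 s, a full
pipeline run ~4 s, the 20-replicate regulator battery and the 20-seed
null calibration ~1 min together. The full-size configuration
(~30k CpGs) runs the test in ~14 s and is exercised via
`imprintmeth simulate --paper-scale`.

## Known limitations

- The LRT is mildly liberal (α̂ ≈ 0.056 at α = 0.05) at n = 5 + 19;
  FDR control at 0.005 absorbs this in practice.
- The dispersion is estimated, not profiled, in the LRT; a full
  profile-likelihood treatment would be slower and was not needed for
  calibration at these depths.
- The chromatin-signature coverage rank requires a user-supplied
  background distribution of window coverages; no genome-wide background
  is bundled.
- `Interval` supports single-chromosome analyses per run; multi-region
  studies run the pipeline once per region.
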