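# Methods

`invscan` tests whether chromosomal inversion polymorphisms shape
transcript abundance across a panel of inbred lines, and whether the
affected loci can be explained by linked sequence variation, direct
breakpoint disruption, regional clustering, or pre-existing co-expression
structure. This note records the models, the numerical choices, and what
the synthetic data do and do not emulate.

## The expression model and its calibration

Each probe's log-scale expression is modeled per individual as

    Y_ijkl = mu + Sex_i + InvA_j + InvB_k + Line_(jk)l + eps_ijkl

where InvA and InvB are the two inversion karyotypes (line-level, inbred
lines only) and Line is coded as lines nested within the joint karyotype
combination: for each combination with n_c lines, n_c − 1 dummies. Under
the reference 34-line / 136-individual design this yields term degrees of
freedom Sex 1, InvA 1, InvB 1, Line 30, Residual 102.

Because karyotype is a property of the line, the inversion contrasts are
linear combinations of line contrasts; the inversion sums of squares are
therefore defined only *sequentially* (Type-I order Sex, InvA, InvB,
Line). The engine computes them by orthonormalizing each term block
against all preceding blocks (SVD with a 1e-7 singular-value cutoff, so
empty or aliased contrasts get 0 df rather than numerical garbage); term
SS is the squared norm of the block projection, vectorized over all
probes at once.

F ratios use the residual mean square. With real line variance this
denominator is anticonservative for a between-line factor — which is why
significance never comes from the F distribution but from a permutation
null: each round permutes each inversion's line-level labels
independently without replacement (inverted-line counts preserved,
individuals never changing lines), rebuilds the nested design, and refits
every probe. The same permutations are shared across probes.

**Permutation P estimator.** The default P-value is the percentile form
cnt/B (cnt = permuted F values at or above the observed one), floored at
1/(2B) so P stays in (0, 1] for the q-value step. The exactly-valid
(1+cnt)/(B+1) form is available (`estimator="add_one"`); its discreteness
at moderate B is measurably conservative: in the planted-effect recovery
experiment below it costs about 12 points of sensitivity at B = 1000
while the percentile form keeps the empirical FDR under the nominal
level. The add-one form is also the probability-integral transform of
the permutation count, so calibration tests use it when they need an
exactly uniform null grid.

**Multiple testing.** Storey q-values on the per-inversion P-value
family: pi0 is estimated on the lambda grid {0, 0.05, …, 0.90} with a
cubic polynomial smoother extrapolated to lambda = 1 and clamped into
(0, 1] (a non-positive extrapolation falls back to 1.0, the conservative
Benjamini–Hochberg limit, as do families of fewer than 100 P-values).
IAL ("inversion-affected loci") are probes with q strictly below the
threshold (default 0.05).

**Effect sizes.** Per-term eta² = SS_term/SS_total. Cohen's d is the
mean difference (inverted minus standard) over the root-mean-square of
the two group SDs, computed over line means by default — lines, not
individuals, receive a karyotype — with an individual-level switch. The
overlap interpretation uses the overlapping coefficient of two unit-SD
normals, 2·Phi(−|d|/2) (d = 1 → 61.7%).

**Model selection.** AIC = n·ln(RSS/n) + 2(p+1) over the main-effects
model, each pairwise interaction among Sex and the inversions added
singly, and each main effect dropped singly; the global model is the
per-probe-winner majority, with exact AIC ties broken toward fewer
terms. Two caveats a user should know. First, dropping an inversion term
is genuinely AIC-competitive on probes where that inversion does
nothing, so the main-effects model wins the majority only when the main
effects are real for most probes. Second, when a line carries both
inversions, the inversion-by-inversion interaction contrast is
confounded with that line's random effect and AIC (which judges it
against the residual, within-line, mean square) tends to prefer it; with
no doubly-inverted line the interaction column is empty and ties back to
the simpler model.

## SNP–inversion LD scan

For a diallelic SNP and a karyotype, over the N lines non-missing at
both: D = freq(major ∧ major) − p_S·p_I and r² = D²/(p_S(1−p_S)p_I(1−p_I)),
which equals the squared Pearson correlation of the two indicator
vectors; significance uses chi² = N·r² (1 df, identical to the 2×2
contingency chi-squared without continuity correction) against a per-arm
Bonferroni critical value (upper tail of chi²(1) at alpha/n_tests;
n_tests defaults to all diallelic SNPs on the arm, with a filter-passing
option). Filters: N ≥ 60 and MAF ≥ 10% for both the SNP and the
karyotype, both computed on the same N lines. A gene is "in LD" with the
inversion when ≥ 1 significant SNP falls inside its annotated interval
(1-based inclusive; optional flank).

## Enrichment

Overlaps are scored by the exact hypergeometric distribution:
E = nK/N, inclusive tails P(X ≥ x) and P(X ≤ x), two-tailed significance
at 0.025 per tail. Output rows additionally carry the exclusive tail
P(X > x) — the quantity R's `phyper(..., lower.tail = FALSE)` reports
and that the original analysis style tabulates — and always print the
draw count n explicitly. Two applications: IAL among genes in LD with
the inversion (universe = genes present in both the expression and
genome annotations), and IAL among distinct targets of TFs that carry
significant SNPs (universe = distinct targets of the annotation-
restricted network).

## Genomic structure

Location classes per (gene, inversion): *within* when the gene interval
overlaps the breakpoint span; on another arm *unlinked*; otherwise
*same-arm outside*, with the sub-class *within-flank* when the distance
from the gene boundary to the nearer breakpoint is strictly under 1 Mb.
A gene is breakpoint-interrupted iff start < breakpoint < end.

Physical clustering uses the coefficient of variation of intergenic
gaps: genes sorted by start, gap = max(0, next_start − prev_end − 1) (so
abutting 1-based-inclusive neighbors and overlapping genes both count 0),
terminal flanks excluded, CV = sample SD (n−1) / mean. The null draws
equally many genes uniformly without replacement from the arm
(default 100,000 draws) and takes the empirical 2.5–97.5% band. A CV
above the band is labeled "more clustered" — heterogeneous gaps mean
tight runs separated by voids — and the label convention is written into
the output header because the opposite reading exists in the literature;
under this gap convention both a tight run of genes and a run plus one
distant member push the CV above the band, and uniformly spread subsets
fall below it.

## Co-expression controls

Pairwise correlations are adjusted r² = 1 − (1−r²)(n−1)/(n−2), computed
on line means by default (config switch for individuals), averaged over
IAL×IAL, IAL×other, and all pairs. All classes are exhaustive up to
3,000 probes; beyond that the genome-wide mean is estimated from up to
5×10⁶ uniformly subsampled pairs with a seeded bootstrap CI (the
IAL-involving classes stay exhaustive). Module occupancy counts distinct
modules containing an IAL; its null shuffles the module-label vector
(module-size multiset preserved exactly, equivalent to drawing |IAL|
labels without replacement) 100,000 times by default.

## The synthetic-data generator

Defaults emulate the reference study conditions: 34 expression lines ×
2 sexes × 2 replicates = 136 individuals, 2 lines inverted for the
2L inversion and 7 for the 3R inversion with one line carrying both; a
200-line genotype panel with 19 and 17 inverted lines respectively;
five arms with release-5-like lengths and the cosmopolitan breakpoints
In(2L)t 2,225,744–13,154,180 and In(3R)Mo 17,232,639–24,857,019.

* **Expression.** Baseline per gene N(6, 2) on the log2 scale;
  sex effect +0.5 for females; line effects with SD sigma_line = 0.3
  split between a shared per-module line-level factor (weight
  sqrt(rho), default rho = 0.5, 20 modules) and a gene-specific part;
  residual SD 0.3. A planted effect d shifts inverted lines by
  d·sigma_between with sigma_between = sqrt(sigma_line² + sigma_resid²/4),
  the SD of line means, so the line-mean Cohen's d estimator targets d.
  The sigma values are plausible for processed microarray log
  intensities, but planted-effect detectability is essentially invariant
  to them: the permutation test reduces to a line-level comparison on
  the line-mean scale, on which d is defined.
* **Genotypes.** A SNP at distance delta from the nearer breakpoint of
  its arm's inversion targets correlation r(delta) = r_max·exp(−delta/λ)
  (defaults r_max 0.9, λ 1 Mb — the decay shape is a modeling choice,
  not an estimate): the minor allele copies the karyotype indicator with
  probability c and is otherwise an independent Bernoulli draw. With the
  default (SNP MAF = inversion frequency) c = r exactly; a decoupled
  `ld_snp_maf` is supported up to the Fréchet bound on the correlation
  of two Bernoullis. Off-inversion arms draw MAFs uniformly on
  (0.05, 0.5). Missing calls are injected uniformly at random
  (default 2%) — enough to exercise the N-filter, with no call-quality
  structure. Note that the default panel (19/200 and 17/200 inverted)
  sits at or below the 10% karyotype-MAF filter, as the corresponding
  real panels essentially did; experiments that need filter-passing
  karyotypes raise the inverted counts.
* **TF scenario.** Optionally one gene nearest the proximal breakpoint
  of the 3R inversion becomes a TF with a guaranteed maximal-LD SNP in
  its interval and planted trans effects (default d = 1) on its targets.

What the generator does **not** emulate: recombination/coalescent
structure (LD is imposed marginally per SNP, not haplotypically), probe
intensity artifacts or normalization residue, heterozygous karyotypes,
multiple probes per gene (supported but off by default), and any
structured missingness. Passing tests therefore validate the inference
machinery under the stated variance-component model, not robustness to
real microarray pathologies.

## Validation experiments and their sizes

* **Null calibration:** 2,000 probes with no planted effects on the
  default design, B = 200, module correlation set to 0 — the KS
  uniformity check requires independent draws, and with correlated
  probes the marginal uniformity still holds but the KS sampling
  distribution does not. Checked: KS P > 0.01 on the exact null grid
  and the fraction below 0.05 inside the 99% binomial band.
* **Recovery:** 20 replicates of 500 probes with 20 planted |d| = 2
  effects, B = 1,000, q < 0.05. Effects are planted on the 7-line
  inversion: with only 2 inverted lines the label space holds just
  C(34,2) = 561 distinct assignments, so the permutation floor alone
  caps attainable significance regardless of effect size — an
  identifiability limit of the 2-line arm, not of the method. Measured
  here: sensitivity ≈ 0.87, empirical FDR ≈ 0.04.
* **LD decay:** 600 SNPs placed exactly at the breakpoints (target
  r² = 0.81) plus 4,000 random SNPs binned by distance; realized r²
  matches the target within Monte-Carlo error (a small +O(1/N) upward
  bias of realized r² is expected) and decays monotonically.
* **Oracle equivalences:** sequential SS vs nested least-squares RSS
  drops on random small designs; N·r² vs contingency chi-squared;
  hypergeometric tails vs exhaustive draw enumeration for N ≤ 25;
  occupancy null vs exhaustive label-permutation enumeration on a
  10-gene/3-module case.

Problem sizes in the routine test suite are scaled to these values; the
operations themselves default to the full-scale settings (B = 10,000
permutations, 100,000 null draws).

## Known limitations

* Only homozygous karyotypes are modeled; dominance is out of reach by
  design.
* The nested-line ANOVA treats line as fixed; no REML/mixed model is
  offered, since the permutation supplies the correct null.
* The inversion×inversion interaction is not separable from line
  identity when few (or one) lines carry both inversions; model
  selection output should be read accordingly.
* Bonferroni counting pre- vs post-filter is a config choice
  (`bonferroni_universe`); the default counts all diallelic SNPs on the
  arm.
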