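# Methods

This note records the statistical definitions the package implements, the
conventions chosen where tools in this field disagree, what the synthetic
corpus does and does not emulate, and the numerical edge-case rules.

## Codon counting substrate

All statistics are computed from per-gene 64-codon count vectors taken in
reading frame 0 of the supplied CDS (no ORF scanning). Stop codons are
recorded but excluded from the sense-codon total L and from every
synonymous statistic; codons containing N are skipped, never imputed.
Validation is two-mode: `strict` rejects frame errors, internal stops and
ambiguity codes (reporting the gene id and 1-based codon position);
`lenient` truncates 3' overhangs and skips N codons with a warning. Only
the standard nuclear genetic code ships (all target species are plants and
the genes nuclear); the table id is a field so organelle codes can be
added.

## Composition conventions

Different CUB tools define the "silent base" metrics differently, and
published tables mix them, so both conventions are exposed:

* `style="codonw"` (default): A3s/T3s/C3s/G3s divide the count of
  synonymous codons ending in a base by the total count of synonymous
  codons belonging to families *able* to end in that base. The four values
  do not sum to 100 — e.g. Cys codons enter the T and C denominators but
  not A or G.
* `style="proportion"`: plain shares of the synonymous third-position
  multiset; sums to 100 and satisfies the obvious closure property (this
  is the style the property test asserts closure on).

GC3s is in both styles the plain G+C share of synonymous third positions
(families of degeneracy ≥ 2; Met, Trp, stops excluded). AT3 follows the
CAIcal convention: A+T share of third positions of *all* sense codons.
Overall A/T/G/C% run over the whole CDS including a recorded stop; GC1 and
GC2 run over sense codons; GC12 = (GC1+GC2)/2. Dataset means are
unweighted per-gene averages (not length-weighted), matching how
per-gene tables are usually summarised.

## Bias indices

**ENC** is Wright's estimator. Per family with n ≥ 2 codons,
F̂ = (nΣp̂² − 1)/(n − 1); families with n < 2 or F̂ ≤ 0 drop out of their
degeneracy-class average; a missing three-fold average (Ile unusable) is
imputed as (F̄₂+F̄₄)/2; ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ capped at 61.
If any other class has no usable family the value is reported undefined
rather than guessed. Note that F̂'s finite-sample correction makes ENC a
*sampling-model* estimator: realizations with sub-multinomial dispersion
(e.g. balanced designs) read higher than the profile's asymptotic ENC,
and the doubling-invariance of ENC holds only for per-family counts in
the thousands.

**CAI** is the Sharp–Li geometric mean of relative adaptiveness w over
sense codons of degenerate families (Met/Trp never contribute). The
default reference is the published Sharp & Li (1987) *E. coli* table —
the reference the classic CodonW workflow uses when none is specified —
shipped as packaged data; any two-column codon→weight TSV can replace it.
Zero or missing weights are floored at 0.01 with a warning.

**CBI** is Bennetzen–Hall: (N_opt − N_ran)/(N_tot − N_ran) over degenerate
families, with N_ran the optimal-codon count expected under uniform
synonymous usage and the optimal set taken from the reference's w = 1
codons. The index lives in [−1, 1]; negative values mean optimal codons
are used *less* than chance, which is the normal regime for plant genes
scored against an *E. coli* reference.

**GRAVY** uses the Kyte–Doolittle scale at the published 1-decimal
precision; **AROMA** is the Phe+Tyr+Trp residue fraction.

## RSCU, classification, optimal codons

Dataset-level RSCU/RFSC are computed on pooled codon counts
(concatenation), never as means of per-gene tables. Families with zero
count yield missing values (NaN), not zeros, except in the CA input
matrix (below). Classification thresholds: preferred RSCU > 1,
over-represented > 1.6, under-represented < 0.6 (strict inequalities as
printed in the source literature). Two high-frequency rules are
implemented because the published criterion is ambiguous: `rfsc60`
(RFSC > 0.60, the operational wording used for the reported codon sets)
and `avg150` (usage > 1.5× the synonymous average, algebraically
RSCU > 1.5); `rfsc60` is the default.

Optimal codons: genes ranked by ENC ascending (ties broken by id for
determinism); the extreme deciles (size = round-half-up of quantile·N,
minimum 1; 24 genes → 2, 30 → 3) form the high- and low-expression pools;
counts are pooled within each; a codon is optimal iff
ΔRSCU = RSCU_high − RSCU_low ≥ 0.08 with RSCU_high > 1 and RSCU_low < 1
(boundary inclusive on ΔRSCU).

## Mutation-vs-selection diagnostics

The expected-ENC curve is ENC_exp(s) = 2 + s + 29/(s² + (1−s)²), whose
supremum on [0,1] is ≈ 61.04 near s = 0.5; a gene is "below the curve"
iff ENC_obs < ENC_exp strictly. PR2 biases are computed over third
positions of all sense codons by default (the published wording), with a
fourfold-family-only mode for comparability with the other convention in
the literature; points with an empty A+T or G+C denominator are reported
missing. The neutrality fit is OLS of GC12 on GC3s with Pearson r and its
two-sided p (plus Spearman, since the correlation tables elsewhere in the
workflow are rank-based); mutation% = 100·slope, selection% = 100 −
mutation%. The split can leave [0, 100] when the fitted slope is
negative; it is reported as computed, not clipped.

Correspondence analysis takes the genes × 59-codon RSCU matrix (ATG, TGG
and stops excluded; missing-family entries set to 0 with a warning — the
matrix must be non-negative), scales it to the correspondence matrix,
decomposes the standardized residuals (P − rcᵀ)/√(rcᵀ) by SVD, and
reports principal coordinates for rows and columns plus per-axis inertia
percentages. Total inertia equals χ²/n (tested to 1e-10); axes with
singular values below 1e-12 of the largest are treated as null, so an
identical-rows matrix yields zero axes rather than noise axes. Inertia
percentages are invariant to the row/column scaling convention, which is
why they — not coordinates — are the comparison surface.

## Expression proxies and host screening

SCUO: per degenerate family, the normalized entropy deficit
Oᵢ = (ln nᵢ − Hᵢ)/ln nᵢ; the gene score is the codon-count-weighted mean,
giving exactly 1 for one-codon-per-family usage and 0 for uniform usage.

MILC: Σₐ Mₐ/L − C with Mₐ = 2Σ_c O_c ln(f_c/g_c) (observed counts O,
within-family frequencies f, expected within-family distribution g) and
C = Σₐ(nₐ−1)/L − 0.5 over families present. The expected distribution g
defaults to uniform-within-family; a dataset-mean option is provided
because the upstream tooling for this quantity does not document its
choice, and both are written in pipeline output. Doubling all counts
changes MILC by exactly df/(2L) (only the length correction moves).

Host comparison scales the gene set's sense-codon usage to per-1000 and
takes per-codon ratios against a host table; ratio ≤ 0.5 or ≥ 2
(boundaries inclusive, as printed in the source convention) flags a
divergent codon. Hosts are ranked by the per-gene min–max and mean of
divergent-codon counts. The six packaged host tables are **synthetic
stand-ins** (see `src/cubkit/data/hosts/MANIFEST.md`): offline builds
cannot snapshot a codon-usage database, so each table emulates only the
host's approximate GC3 character. They exercise the machinery end to end;
conclusions about real hosts require real tables, which the cusp reader
ingests directly.

Spearman correlation panels use the t-approximation for n ≥ 10 and an
exact permutation p for smaller samples (gene sets here are small);
constant columns yield missing correlations rather than errors — note the
emulated corpus makes GC2 exactly constant across paralogs (synonymous
swaps never change second-position GC), so its GC2 correlations are
genuinely undefined.

## Synthetic corpus: what it emulates, and what it does not

`emulate_study` generates 24 paralog-like genes of 600 codons (~1.8 kb):
one ancestor realized from a fixed, mildly uneven within-family weight
profile, and 23 descendants obtained by synonymous-only resampling at 3%
of codon sites (pairwise nucleotide identity ≥ 95%, amino-acid profile
exactly conserved), plus 6 divergent out-group genes with perturbed
amino-acid composition, independent bias profiles and GC3s targets spread
over 0.44–0.58.

The defaults are calibrated once to the study conditions of the
motivating corpus: amino-acid weights fitted so the expected panel lands
at GC1 ≈ 52.7%, GC2 ≈ 40.2%, GRAVY ≈ −0.476, AROMA ≈ 0.092 (a
Leu/Pro/Asp/Lys-rich, Trp/Cys/Met-poor PPO-like protein); within-family
log-spread σ = 0.52 and a GC3 tilt to 0.525 so the paralog set's measured
means land near GC ≈ 49%, GC3s ≈ 52.5%, ENC ≈ 56. The ancestor is a
balanced (largest-remainder) realization of the weight profile, so these
dataset means are stable across seeds; mutation noise and the out-groups
remain fully stochastic. All tilting and skewing preserves 2-nt-prefix
group masses within Leu/Ser/Arg, so first/second-position content is a
function of amino-acid composition alone and the corpus has a near-zero
neutrality slope *by construction*.

What passing tests on this corpus therefore show: every statistic,
classification rule and diagnostic behaves correctly on data with the
study's composition, bias strength, paralog structure and sample sizes.
What they do not show: distributional features the emulation does not
model — a real corpus's single divergent low-ENC isolate (which
concentrates CA inertia on axis 1 and enlarges the ENC-extreme decile
contrast, hence the published 18 high-frequency and 8 optimal codons,
versus fewer on the homogeneous synthetic paralogs), CpG-related codon
avoidance, and any real correlation between amino-acid usage and GC3.
Parameter-recovery claims are instead tested on purpose-built planted
generators: `plant_neutrality` (a GC3s gradient whose amino-acid
composition co-varies, carrying a computable noiseless regression slope —
necessarily so, since first/second-position GC is almost entirely
amino-acid-determined and synonymous choice alone can move the slope by
at most ~0.06) and `plant_optimal_codons` (target codons up-weighted to
0.8 family share in a strongly biased gene subset and down-weighted to
half the uniform share elsewhere, so the planted truth is unambiguous at
the ΔRSCU ≥ 0.08 threshold).

## Problem sizes

Default analysis sizes are those of the emulated corpus (30 genes × 600
codons). The recovery experiments use 24 genes × 700 codons × 100
replicates (neutrality) and 30 genes × 400 codons × 50 replicates
(optimal codons), sizes at which the recovered quantities' sampling error
is small against the planted effects while the whole suite runs in
seconds on one CPU.

## Known limitations

* CAI/CBI reproduce CodonW-style numbers only under the packaged
  *E. coli* reference assumption; with another reference the indices are
  internally consistent but not comparable to published tables.
* ENC's small-sample behaviour (drops, imputation) follows the CodonW
  conventions; other implementations differ in how they treat unusable
  families, so cross-tool differences of a few tenths are expected.
* The packaged host tables are synthetic; host rankings computed from
  them are demonstrations, not recommendations.
* The neutrality mutation/selection split is the conventional slope
  reading; it is a descriptive decomposition, not an inference with
  uncertainty attached.
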