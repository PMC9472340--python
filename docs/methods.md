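# Methods

This note documents the statistical procedures homoeokit implements, the
assumptions of its synthetic-data generator, and the choices made where the
design was genuinely open.  Conventions: subgenome R is the maternal
(goldfish-derived) chromosome set, C the paternal (carp-derived) one; all
intervals are 0-based half-open; "ML" is a methylation level in [0, 1].

## Expression and homoeolog expression bias

Counts are normalized per sample to the **mean library total** across all
samples (factor = mean total / sample total).  Any constant reference works;
the mean is documented for reproducibility.  Within-sample homoeolog ratios
are invariant to this scaling; cross-parent ratios acquire one common
offset log₂(f_R/f_C) whenever planted effects do not balance across the
library — negligible for realistic mostly-conserved panels, visible in
deliberately all-biased toy panels (the test suite checks the identity both
ways).

A pair enters any analysis only where both homoeologs have raw count
≥ `min_reads` (default 5) in **every** replicate of the relevant group; in a
parental group the rule applies to the homoeolog that parent carries.  The
filter is applied per group, so a pair can be eligible in F1 and not in F22.

HEB categories from log₂(R/C): |x| > 1 → R/C-biased, 0 < |x| ≤ 1 →
potentially biased, x = 0 → balanced.  The threshold is a strict `>`;
|x| = 1 exactly stays "potential".  Silencing states per gene and group:
all replicates 0 → silenced; all ≥ 5 → expressed; otherwise indeterminate.

The headline log₂(R/C) is the ratio of replicate-mean normalized counts;
per-replicate ratios are retained for the ratio test.  The in-silico-hybrid
reference pairs replicate *i* of each parent in sample-sheet order; the
two-sample formulation of the ratio test makes results invariant to that
pairing.

## Cis/trans decomposition

Per pair and hybrid generation: *P* = log₂(parent_R/parent_C),
*H* = log₂(R/C in the hybrid), *T* = P − H.  Three tests on the log₂ scale
(counts get a 0.5 pseudocount):

* `sig_P`: parental R-ortholog replicates vs C-ortholog replicates;
* `sig_H`: hybrid R vs C homoeolog replicates;
* `sig_T`: parental per-replicate ratios vs hybrid per-replicate ratios.

Flags map to categories via the rule table (conserved, cis only, trans
only, cis + trans / cis × trans by sign agreement of H and T,
compensatory, ambiguous).  Sign ties (|x| ≤ 1e-9) fall to ambiguous.

**Variance moderation.**  With three replicates a raw per-pair t-test at
α = 0.01 has roughly 40–70% power against 2-log₂ effects at depth 100 —
too little to characterize a genome.  The batch classifier therefore
shrinks per-pair variances toward a common prior fitted across all pairs
(empirical-Bayes moderated t; the prior degrees of freedom and scale come
from moment-matching log s² against a scaled inverse-χ² model, and the
posterior t uses d₀ + df degrees of freedom).  This is the standard remedy
for small-replicate expression designs.  The scalar `count_diff_test` /
`ratio_diff_test` functions keep the plain Welch form (with a deterministic
1e-9 log-scale jitter for zero-variance replicate sets); `moderated: false`
in the config makes the batch path use Welch too.

**Fold-change gate.**  Significance in classification is `p < 0.01` alone.
A fold-change gate (|log₂FC| > log₂ 4) exists behind `fc_gate: true` but is
off by default: the classical cis/trans scheme gates on statistical
significance only, and a 4-fold gate sits exactly on top of a 2-log₂ effect
(the pseudocount even pulls the expectation just below it), which would make
the classifier blind to canonical effect sizes.  No multiple-testing
correction is applied across pairs by default (`bh_correction` exposes BH),
matching raw-p usage in this literature.

**13 patterns.**  Conserved stays single; the six other categories split
into `_toR`/`_toC`.  Cis-driven categories split by the sign of *H*;
trans_only and compensatory split by the sign of *T*, the component that
carries their direction.  A `strong` flag marks |P| or |H| beyond log₂ 4 or
a supplied methylation difference above 0.3.

**Downstream.**  Ka/Ks tables (consumed, never estimated) are summarized
per category with Welch tests of cis-only and trans-only against all genes.
The MRG–category association is the φ coefficient (Pearson correlation of
the 0/1 indicators) with a continuity-corrected 2×2 χ² p-value; "Pearson
correlation on ranks of binary flags" and φ coincide, which is how the
naming ambiguity (rank correlation vs phi on binary flags) is resolved.

## Methylation

5mC calling: one-sided upper-tail binomial p = P(X ≥ k | n, p₀) against the
error rate p₀ (default 0.01 — bisulfite non-conversion plus sequencing
error; configurable, and estimable as the
genome-wide non-CpG mean of the input).  Sites need depth > 4X (n ≥ 5);
BH correction runs across all tested sites with FDR < 0.05.  The one-sided
direction is the only one meaningful for 5mC detection.

Region profiles: promoter (2 kb 5′ of TSS), gene body, terminator (2 kb 3′
of TTS), each in 20 equal windows, strand-aware (windows run 5′→3′; for
"−" genes upstream lies at higher coordinates).  Window ML = Σk/Σn over the
window's CpGs; only CpG context enters profiles, CHG/CHH records are parsed
and counted in the log.  Empty windows are NaN and excluded from the
coverage-weighted region mean.

The DMR step is a declared **simplified surrogate**: a Fisher exact test on
pooled region counts [[k_A, n_A−k_A], [k_B, n_B−k_B]] with p < 1e-5 and
|ΔML| > 0.1.  The multi-stage external DMR callers it replaces provide
region discovery this pipeline does not need — downstream DMG logic only
consumes a region-level decision on fixed gene-anchored regions.

DMG classes on promoter |DM| (parental orthologs vs hybrid homoeologs,
sign = first-named minus second-named, R minus C):
hyper-DMG ⇔ |DM_parents| > 0.6 and |DM_hybrid| < 0.3;
hypo-DMG ⇔ 0 < |DM_parents| < 0.6 and |DM_hybrid| < 0.2.  The rules are
implemented verbatim, including the asymmetric hybrid thresholds; note the
hypo arm's `> 0` bound admits arbitrarily small parental differences, so on
noisy data most non-hyper pairs satisfy it — consumers should treat
hyper-DMG as the informative class.  MRG: |DM| > 0.4 and |log₂FC| > log₂ 4
with opposite signs (hypermethylation paired with lower expression).

## Homoeologous recombination scan

Copy ratio per pair: log₁₀((R_reads/R_len)/(C_reads/C_len)).  States:
balanced for |x| ≤ log₁₀ 2 (0.30103), R_gain / C_gain beyond (strict
inequality; boundary handling at the threshold itself is a declared
convention).  Zero counts are sentinels, not pseudocounts: R = 0 → −∞ /
R_absent, C = 0 → +∞ / C_absent, both 0 → untestable.  Complete block
replacement is a distinct biological state and pseudocounts would shrink it
toward callable-but-wrong magnitudes; `hr_pseudocount: true` enables a
0.5-read mode for noisy data.

Segments are maximal runs of ≥ `min_run` (default 3) **consecutive
order_index** genes whose states share a direction ({R_gain, C_absent} →
toward_R; {C_gain, R_absent} → toward_C).  Contiguity is positional in the
homoeolog map, not genomic distance; balanced/untestable genes and index
gaps break runs; runs never span chromosome-pair boundaries.  Cross-sample
comparison calls a segment shared when a same-direction segment of another
sample overlaps ≥ 50% of both gene counts (boundary inclusive).

Detection only uses the depth-ratio evidence; merging with split-read SV
calls is out of scope, so reported event counts are ratio-based segments.

## TE / SV association and divergence summaries

TE coverage uses interval-union semantics (duplicated or re-fragmented
annotations never double-count).  SVs are TE-proximal when the distance to
the nearest TE base is strictly below 1 kb (0 inside a TE).  Window tracks
(default 100 kb, configurable) carry
TE density and SV count; association is reported two ways because
either reading of a "t test" here is defensible: the correlation t (r·√(n−2)/√(1−r²),
two-sided, matched against a permutation p in the test suite) and a Welch
t-test of per-window TE-proximal vs no-TE SV counts.  Per-superfamily
analyses key on the BED name field (CACTA, hAT, ...).  OCP summaries report
per-chromosome-pair gene counts, orthologous fractions and TE-coverage
differences.

## Synthetic-data generator

The generator emulates the statistical structure of the real inputs at the
count/interval level (no sequences) and records every planted effect.

* **Genome**: pairs spread evenly over chromosome pairs, gene lengths
  log-uniform in [500, 5000] bp, non-overlapping, with gaps that keep 2-kb
  flanks disjoint; TE intervals target a per-100-kb-window density uniform
  in [0, 0.6].
* **Expression**: per pair a category is drawn (defaults: 40% conserved,
  15% cis-only, 15% trans-only, 10% each cis+trans, cis×trans,
  compensatory); cis/trans effects of ±2 log₂ units set P = cis + trans,
  H(F1) = cis, H(F22) = cis·(1 − trans_compensation), default compensation
  0.5 — the post-polyploidization decay of bias modelled as a tunable
  mechanism rather than a hard-coded outcome.  Parental means split
  symmetrically (b·2^{±P/2}) around a log-normal baseline (median = depth
  100, σ = 0.5) so total expression is category-independent.  Counts are
  negative-binomial with a single shared dispersion (0.05; per-gene
  dispersion adds nothing at this scale), Poisson in the dispersion→0
  limit.  Cis×trans is planted with |trans| = trans_effect/2: with equal
  magnitudes P would vanish and the category would coincide exactly with
  compensatory.
* **Methylation**: region MLs ~ Beta(2, 2) shared between homoeologs;
  a planted fraction (default 20%) of promoters carries a parental
  difference of 0.7 (the carp-side ML is rescaled into [0, 1−0.7] so the
  difference survives clamping), hybrids sit at the parental mean separated
  by 0.05.  Per cytosine: depth ~ Poisson(30), methylated reads ~
  Binomial(depth, clip(ML + p₀, 0, 1)); ~10% of records are emitted as CHH
  to exercise the context filter.
* **Copy number**: default state (2, 2); planted segments set (r, c)
  copies — (3, 1), (1, 3), or (0, 4) for complete replacement, which
  produces structural zeros and exercises the sentinel policy.  Reads ~
  Poisson(depth · copies/2 · length_kb).
* **SVs**: per-window counts ~ Poisson(exp(α + slope·TE_density)) with α
  solved so the genome-wide mean is 2 per window; slope default 3.

Every generator is a pure function of (params, seed); sub-streams are keyed
so each generator is independently reproducible.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: mappability and alignment artifacts, shared
trans factors inducing correlation between pairs, per-gene dispersion and
GC/length biases, spatially autocorrelated methylation, DMRs outside
gene-anchored regions, SV length spectra, and biological replicate
structure beyond exchangeable replicates.  Recovery rates measured here are
upper bounds that reflect the declared noise model only.

## Numerical and scale choices

Validation scale in the shipped tests and acceptance script: 1,000 pairs
for cis/trans recovery, a 10,000-gene single-chromosome track with ten
planted 3:1 segments (lengths 3–20) for the HR scan, 10⁵ null cytosines
(plus a 5,000-site methylated spike for a meaningful realized FDP) for FDR
control, ~700 2-kb windows for the TE–SV correlation.  These sizes give
stable estimates in seconds on one CPU.  On a pure-null cytosine set the
realized false-discovery proportion is degenerate (0 or 1); at depth 30 and
p₀ = 0.01 the discreteness of binomial p-values makes BH reject nothing,
which the suite asserts directly.

HR recovery metrics: a truth segment counts as recalled when any detected
same-direction segment overlaps it; boundary error is the offset between
truth boundaries and the union of overlapping detected segments, averaged
over recovered ends (single-gene interior dips then count against recall
conservatively but do not explode the boundary metric).

Degenerate inputs: zero-variance replicate vectors get deterministic 1e-9
log-scale jitter before scalar t-tests; genes shorter than the window count
fall back to a single profiling window with a warning; empty methylation
regions yield NaN means flagged downstream; `write_records` refuses empty
collections unless explicitly allowed.  Floats serialize at 6 significant
digits, and every writer round-trips bit-stably through its reader at that
precision.
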