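# Methods

## Scope and model

`tenoscreen` implements a rank-based in-silico screening pipeline for
compounds that promote tendon stem/progenitor cell (TSPC) stemness:
up/down gene-signature extraction from two-group expression data, KS
running-sum enrichment scoring of per-compound transcriptional-change
profiles (CTPs), dual-axis ranking with intersection selection, per-gene
evaluation of a profile predictor against empirical measurements, and the
in-vivo functional indices (AFI, grip/BW) used to assess tendon repair in
rodents.  The deep model that predicts CTPs from molecular structure is out
of scope; profiles are inputs, and the synthetic generators stand in for
both the predictor and the deposited expression data.

## Differential-expression signatures

Per gene, the two groups are compared by **Welch's unequal-variance t
test** on log2-scale values.  The test is a deliberate choice — the
screening protocol this mirrors states only "ranked by fold change and
filtered by P value with a threshold of 0.05" — because it is
assumption-light for small-n (here 6 vs 6) group comparison.  Fold change
is the difference of group means of log2 values, first group level minus
the second (the condition of interest minus the reference).  Genes passing
the **raw** P threshold (default 0.05; no multiple-testing correction, an
optional Benjamini–Hochberg flag exists but is off by default) are split by
fold-change sign; each side is ranked by |log2FC| descending (ties broken
by gene id) and truncated to `max_up`/`max_down` when given.  Zero-variance
rows: if both groups are constant with equal means the gene carries no
evidence (P := 1); a deterministic mean difference is called with P := 0.
Genes with exactly zero fold change are assigned to neither side.

Universe restriction drops signature genes absent from a profile universe
with one warning per dropped gene (mirroring how curated stemness factors
absent from a prediction universe are handled); a signature left empty on
both sides is an error.

## KS enrichment score

Profiles are ranked by predicted change, descending; **ties break by gene
id ascending** and ranks are 1-based — both conventions are ours, chosen
for cross-platform determinism, as the source formulas do not specify
them.  For a query set of size `t` with sorted ranks `V(j)`:

    a =  max_j [ j/t − V(j)/n ]
    b = −max_j [ (V(j)−1)/n − (j−1)/t ]

`a` is the maximal positive deviation of the query-set empirical CDF above
the uniform line (evaluated just after each query position); `−b` is the
maximal deviation below it (evaluated just before).  Hence `0 ≤ a < 1` and
`−1 < b ≤ 0` always.  The combined score for a two-sided signature is
`a − b` when `a·b < 0` and `0` otherwise.  Because the signs of `a` and `b`
are fixed, `a·b > 0` is unreachable (the implementation still encodes the
branch, and a property test confirms it never fires); the `otherwise`
branch is taken exactly when either statistic is zero, i.e. no coherent
deviation.  One-sided signatures bypass the sign condition and score `a`
(up-only) or `−b` (down-only) — otherwise an up-only stemness query set
would score identically zero.

### Reversal

`EnrichmentResult.reversal_score` is the negation `−(a − b)`.  Note,
however, that the combined score is non-negative by construction, so the
negation is bounded above by zero and **saturates at 0 for every strong
reverser**: a compound that pushes the up genes to the bottom and the down
genes to the top drives both `a` and `b` to 0.  A ranking axis built on the
negated score therefore cannot discriminate among good reversers (they tie
at 0, occasionally joined by null compounds whose `a` or `b` is exactly
zero by chance).

The screen's `reverse` orientation therefore *reverses the gene signature*
instead: it scores the signature with its up and down sets **swapped**.
This is exactly equivalent (up to rank-tie discretization) to scoring the
sign-negated profile — negating deltas maps rank `V` to `n + 1 − V`, which
interchanges the roles of the two statistics — and it spreads reversers
over the same `[0, 2)` scale the mimic orientation uses, so both screen
axes are comparable and finely resolved.  A test verifies the
swap/negated-profile identity on random instances.

No weighted (signal-to-noise) running sum, permutation significance, or
leading-edge extraction is provided: the scoring statistic here is the
unweighted KS form.

## Dual-axis screen

Default orientations: stemness axis = `mimic` (an up-only stemness set
should be induced), tendon axis = `reverse` of the adult-vs-neonatal
signature (the screen seeks compounds restoring the neonatal state).  Both
are explicit configuration.  Compounds are ranked 1..N per axis, highest
score first, ties broken by compound id ascending; `selected` flags
membership in both per-axis top-K sets.  K defaults to the top 5% of the
library per axis (the protocol this mirrors reports the outcome of its
intersection — 12 of 3,680 — but not its cutoff).  Selection is monotone
in K, and scores/ranks are invariant to library row order.

## Predictor evaluation

Pearson `r` per gene across molecules (≥ 3 molecules required).  Genes with
zero variance in either matrix have undefined `r` and are recorded as
missing, excluded from summaries with a logged count.  The distribution
"peak" is reported as the **histogram mode**: the midpoint of the tallest
bin of a histogram over [−1, 1], with the bin width chosen by the
Freedman–Diaconis rule on the observed values (capped at 1024 bins;
first-tallest bin wins ties; a numerically constant vector short-circuits
to its median, since a binned mode would be off by half a bin width).  The
maximum is reported alongside, as "peak" is ambiguous between mode and max
in informal usage.  Raw (not z-scored) values are correlated.

## Synthetic data

All generators are pure functions of a `SimulationConfig` and its seed;
one global seed fans out to fixed per-generator substreams, so reruns are
byte-identical and stages can be regenerated independently.  Defaults
mirror the screening study design; `test_scale()` shrinks sizes for speed.

* **Expression**: per-gene baselines ~ N(8, 2) on the log2 scale, drawn
  once; the first group is shifted ±`effect_size` (default 2) on planted
  up/down genes (default 100/150, mirroring the 99/143 signature the
  protocol reports); i.i.d. Gaussian noise, SD 0.5, everywhere.  Gaussian
  noise on the log2 scale is the simplest model under which the
  Welch/Pearson machinery is exact.
* **Compound library**: null compounds have i.i.d. N(0, `noise_sd`) deltas
  over the universe (default 12,328 genes × 3,680 compounds).  Hits shift
  signature genes by `reversal_strength · noise_sd` (default 3): stemness
  hits mimic the stemness signature, tendon hits reverse the tendon
  signature, dual hits do both.  The default library plants 20 compounds of
  each category — dual, stemness-only, tendon-only — reflecting that a real
  library contains single-axis actives; with all three categories present
  the per-axis top-40 sets are filled by strong compounds, making the
  dual-hit benchmark robust to the noise seed.
* **Benchmark signatures**: the planted-hit benchmark queries a
  100-up/150-down tendon signature and a 20-gene up-only stemness
  signature drawn disjointly from it.  The stemness query is kept up-only
  (like a stemness-factor set) but larger than the 3-gene Yamanaka set:
  with only 3 query genes the null distribution of `a` over ~2,000
  compounds overlaps the hit range, and no scoring method could guarantee
  clean top-40 separation of 3-SD shifts.
* **Paired profiles**: per gene `g` with target correlation ρ_g, predicted
  values are standard normal over molecules and empirical values are
  `ρ_g·x + √(1−ρ_g²)·ε` — bivariate normal with exactly the target
  population correlation.  The helper `draw_rho_beta` draws ρ from
  Beta(mean·c, (1−mean)·c) (default mean 0.74, c = 10), a right-skewed
  distribution peaking near 0.8 — a plausible shape for a well-trained
  predictor.  Targets must lie strictly inside (−1, 1).
* **Footprints/grip**: normal-side lengths from rat-plausible ranges
  (PL 28–35 mm, TS 18–24 mm, IT 9–13 mm); an injury factor `f ∈ (0, 1]`
  shrinks toe spreads by `f`, stretches print length by `1/f` (an injured
  paw drags) and scales grip readings by `f`, with fractional measurement
  noise.  `f = 1` without noise reproduces AFI = −5 exactly for every
  animal.

What the generators do **not** emulate: count-based sequencing noise,
normalization or batch structure, gene–gene correlation, any
chemistry-conditional structure in the compound profiles (hits are planted
by construction, not predicted), and heavy-tailed measurement error.
Passing tests therefore demonstrate that the statistics recover known
structure under their own assumptions — not that the pipeline is robust to
real-data pathologies such as correlated genes or batch effects.

## Functional indices

Implemented exactly as printed: `PLF = (NPL−EPL)/EPL` (note the
experimental denominator — gait literature varies here, and the printed
equations are followed literally), `TSF = (ETS−NTS)/NTS`,
`ITF = (EIT−NIT)/NIT`, `AFI = 74·PLF + 161·TSF + 48·ITF − 5`.  Lengths
carry mm in I/O but the factors are ratios, so units cancel.  The grip
index interprets "mean of 3 median values" of five sequential pulls as the
mean of the middle three order statistics (the only reading consistent
with five tests and three retained values), divided by body weight.

## Problem sizes in the test suite

The test and acceptance runs use the reduced preset — 2,000 genes, 2,000
compounds, 500 paired molecules, 10,000 genes for the null-calibration
check — chosen so the full suite completes in seconds while keeping every
statistical margin wide (the dual-screen score gap between hits and nulls
exceeds 0.3 at these sizes).  The paper-scale preset (12,328 × 3,680 ×
3,000) runs the identical code paths.

## Known limitations

* The combined KS score is unsigned; mimicry and reversal are separate
  orientations rather than two signs of one statistic.
* No significance estimates accompany scores; ranks are the interface.
* DEG calling assumes approximately Gaussian log2 expression; it is not a
  count-model method and applies no normalization.
* The histogram mode is bin-width dependent by nature; the reported
  maximum is provided for disambiguation.
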