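# tenoscreen

Connectivity-map-style transcriptional-signature screening for tendon
stemness compounds, plus the rodent functional indices used to evaluate
tendon repair in vivo.

## The problem

Tendon stem/progenitor cells (TSPCs) lose stemness with age, and aged
tendons repair poorly.  One route to a therapeutic is in-silico screening:
given a library of small molecules, each represented by its predicted
change of transcriptional profile (CTP) over a fixed gene universe, find
compounds that (i) induce stemness-factor expression and (ii) reverse the
adult-vs-neonatal tendon expression signature.  `tenoscreen` implements the
post-prediction half of that pipeline — the CTPs themselves are inputs
(e.g. from a trained deep predictor) — together with synthetic generators
that produce every input with known planted ground truth, so each stage can
be validated end to end.

## The statistics

**Signature extraction.** Differentially expressed genes between two
sample groups are called per gene by Welch's t test on log2 expression;
genes with `P < 0.05` are split by fold-change sign and ranked by |log2FC|
to form an up/down gene signature.

**Enrichment scoring.** Genes of a profile are ranked by predicted change,
descending (rank 1 = most upregulated).  For a query set of `t` genes with
sorted ranks `V(1) < … < V(t)` in a universe of `n` genes:

```
a =  max_{j=1..t} [ j/t − V(j)/n ]          # up-set statistic,   0 ≤ a < 1
b = −max_{j=1..t} [ (V(j)−1)/n − (j−1)/t ]  # down-set statistic, −1 < b ≤ 0

Score = a − b   when a·b < 0
Score = 0       otherwise
```

These are the closed-form maxima of the Kolmogorov–Smirnov running sum of
the query set against the uniform line.  An up-only signature (such as the
Yamanaka stemness factors) scores `a` directly.  *Reversal* of a signature
is implemented by swapping its up and down query sets — equivalent to
scoring the sign-negated profile — so reversers spread out on the same
`[0, 2)` scale that mimics use.

**Dual-axis screening.** Every compound gets a stemness score (mimic
orientation) and a tendon score (reverse orientation); compounds are ranked
on each axis and the screen selects the intersection of the per-axis top-K
sets.

**Predictor evaluation.** For matched predicted/empirical change matrices
(molecules × genes), Pearson `r` is computed per gene across molecules and
the distribution's mean, mode (peak) and maximum are reported.

**Functional indices.** The Achilles functional index from paired
normal/experimental footprints:

```
PLF = (NPL − EPL)/EPL    TSF = (ETS − NTS)/NTS    ITF = (EIT − NIT)/NIT
AFI = 74·PLF + 161·TSF + 48·ITF − 5
```

and the grip index: mean of the middle three of five dynamometer readings,
normalized by body weight (g/BW).

## Worked example

```python
import tenoscreen as ts
from tenoscreen.synthetic import gene_universe, random_signature

cfg = ts.SimulationConfig.test_scale(seed=1)      # 2,000 genes x 2,000 compounds
expr, deg_truth = ts.simulate_expression(cfg)     # 6 vs 6, planted 100 up / 150 down
tendon, records = ts.compute_deg_signature(expr, max_up=100, max_down=150)

stemness = random_signature(gene_universe(cfg.n_genes), 20, 0, "stemness",
                            seed=2, exclude=tendon.up | tendon.down)
library, hit_truth = ts.simulate_ctp_library(cfg, stemness, tendon)
table = ts.dual_score_screen(library, stemness, tendon,
                             top_k_stemness=40, top_k_tendon=40)
selected = set(table.loc[table.selected, "compound_id"])
print(len(tendon.up), len(tendon.down))           # 100 150
print(len(selected), selected == set(hit_truth.dual_hits))  # 20 True
```

The DEG caller recovers the planted signature (100 up / 150 down at
|log2FC| = 2, noise SD 0.5), and the dual screen's top-40 ∩ top-40
intersection is exactly the 20 planted dual hits — no false positives.
The same pipeline is exposed on the command line:

```bash
tenoscreen simulate-expression --out-dir expr --seed 1
tenoscreen make-signature --expression expr/expression.tsv --groups expr/groups.tsv \
    --out-gmt tendon.gmt --max-up 100 --max-down 150
tenoscreen simulate-library --out-dir lib --signatures sigs.gmt --seed 1
tenoscreen screen --config screen.yaml
tenoscreen afi --input footprints.csv --output afi.csv
```

For the AFI, an uninjured paw (experimental = normal) scores exactly −5:

```python
>>> from tenoscreen import FootprintMeasure, footprint_factors, afi
>>> n = FootprintMeasure(PL=31, TS=21, IT=11)
>>> afi(*footprint_factors(n, n))
-5.0
>>> afi(*footprint_factors(n, FootprintMeasure(PL=15.5, TS=21, IT=11)))
69.0
```

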