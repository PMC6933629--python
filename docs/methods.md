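# Methods

## Model and inference procedure

The package treats GRN inference as N independent regression problems, one
per target gene.  For target *i*, every candidate regulator *j* (the TF set,
minus the target itself — self-regulation is ignored throughout) is
represented by a block of polynomial basis columns: the regulator's z-scored
expression vector raised elementwise to powers 1…P₁.  The target's z-scored
expression is then explained by a greedy block-sparse least-squares fit: at
each of up to L steps, every unselected candidate is evaluated by refitting
the target on [intercept | already-selected blocks | candidate block] and
the candidate with the smallest residual 2-norm joins the design.  The fit
is the minimum-norm least-squares solution, so rank-deficient designs
(inevitable under bootstrap row duplication) are handled by singular-value
cutoff rather than erroring.

The greedy pass runs on *b* bootstrap resamples of the expression rows
(classic bootstrap: M rows drawn with replacement, the same row multiset for
target and candidates; resample size equals M).  Standardization is
recomputed on each resample so every bootstrap fit is a self-contained
regression.  Selections are aggregated by area-based scoring: with
ϕ[j, l] the fraction of runs selecting regulator *j* at step ≤ l, the edge
score is S = mean over l = 1…L of ϕ[j, l].  Equivalently S = Σ over runs of
(L − step + 1)/(L·b), so a step-1 selection is worth L times a step-L
selection.  The score matrix is indexed S[regulator, target]; a published
description of this scoring is ambiguous about edge direction, and this
package fixes the convention as regulator → target everywhere.

All (regulator, target) pairs with S > 0 form the global ranking, sorted by
descending score with ties broken by ascending (regulator index, target
index).

## Parameters

| Parameter | Default | Meaning and guidance |
| --- | --- | --- |
| b (`--bootstrap`) | 200 | Bootstrap runs per target. Rankings stabilise once b reaches a few hundred; the tests use 20–50 for speed. |
| L (`--steps`) | 3 | Greedy steps = max regulators per target per run. Best near the true mean in-degree; with a gold standard `--steps auto` uses round(2 × #edges / #genes), floored at 1. |
| P₁ (`--poly-degree`) | 5 | Polynomial basis functions per regulator block. |
| tol | 1e-6 | Relative-improvement stop (the triggering step is rejected) and relative-residual stop (the triggering step is kept). With L small the step budget, not tol, normally terminates the loop. |
| seed (`--seed`) | 0 | Master seed; a substream is derived per (target, run) pair, so results are identical for any `--jobs` value. |

## Numerical choices

- **Standardization before exponentiation.**  Raw expression raised to the
  fifth power destroys least-squares conditioning; z-scoring each gene per
  resample keeps the Gram matrices tame.  Selection is unaffected in
  substance because each block's span, not its scale, drives the fit — the
  test suite verifies rankings are invariant to affine rescaling of any
  single gene.  Zero-variance columns become all-zero blocks and can never
  be selected.
- **Intercept.**  The basis has no constant term; an intercept column is
  part of the regression design instead, added by the selector.
- **Residual evaluation.**  Candidate residuals are computed by orthogonal
  projection against an incrementally maintained orthonormal basis of the
  accepted design (one batched Gram eigendecomposition per step across all
  candidates), which equals the pseudo-inverse refit residual for any rank.
  Rank cutoffs sit at machine-epsilon × block magnitude.  When a candidate
  residual falls below 1e-4 of the initial residual — the regime where the
  Gram route loses half the mantissa to cancellation — it is recomputed by
  explicit projection so that near-zero residuals compare exactly.  The test
  suite checks step-by-step agreement with a literal pinv-refit enumeration.
- **Ties.**  Candidates within 1e-12 relative residual resolve to the lower
  regulator index; zero-score pairs omitted from output files are appended
  in (regulator, target) index order during evaluation so every metric is
  deterministic.

## Evaluation

AUPR follows the literal prefix construction: precision and recall are
computed for the top-q edges for q = 1, 2, … over the full candidate
universe (ranked pairs first, zero-score pairs appended), and the area is
the step-wise sum of precision × recall-increment at every rank where a true
edge appears — identical to average precision, no interpolation.  AUROC is
the Mann–Whitney statistic on the scores, counting tied scores (including
all appended zeros) one half.  For TF-restricted inputs the candidate
universe is |I| × (N − 1) pairs (regulator in the TF set, no self-pairs);
when every gene is a regulator this coincides with N(N − 1).  Note that the
expected AUPR of a *random* ranking exceeds the true-edge prevalence by an
O(1) factor on finite universes (≈1.4× at 300 pairs); prevalence is the
asymptotic anchor, not the finite-sample expectation.

## Synthetic benchmark

The generator emulates DREAM-style multifactorial data well enough to test
the pipeline end to end, with no claim of fidelity to real regulatory
kinetics:

- **Topology.**  The first K genes are TFs.  Every gene draws
  max(1, Poisson(mean in-degree)) distinct parents uniformly from the TFs
  with lower index (clipped, with a warning, when fewer exist — gene 1 is
  always a root), giving a DAG by construction.  Edge weights are uniform on
  ±[0.5, 1.5].
- **Expression.**  Each TF draws an i.i.d. standard-normal baseline plus its
  own N(0, perturbation_sd) per-sample perturbation (default 0.3) — every
  sample is one multifactorial jitter of all inputs.  A regulated gene adds
  the regulatory function (identity, tanh, or u + 0.25u²) of its parents'
  weighted sum, with the weight vector scaled to unit 2-norm; a regulated TF
  averages that term with its baseline at equal variance, and a non-TF gene
  receives it plus N(0, noise_sd) observation noise (default 0.1).

Two of these choices exist purely for identifiability and deserve
explanation.  Without the unit-norm weight scaling, TF→TF cascades compound
variance geometrically (variances in the hundreds a few levels down), so a
deep TF becomes numerically a deterministic function of its ancestors and
its own outgoing edges cannot be attributed to it.  Without a substantial
independent baseline on every TF, the same degeneracy appears statistically.
The equal-variance split is the neutral point between detecting a TF's
in-edges (regulation share) and distinguishing the TF from its ancestors and
children (baseline share).

What passing tests on this generator do **not** show: performance on real
expression data.  The generator's regulated genes are near-noiseless linear
mixtures of their parents, which makes forward edges far easier than in real
data but also plants the classic direction ambiguity — a child gene is an
excellent (wrong) predictor of its own TF parent.  On dense draws
(prevalence ≳ 0.15 of the candidate universe) this caps achievable AUPR
around 0.75–0.8: each regulated TF tends to contribute one high-scoring
reverse or indirect false positive, a limitation shared by all
regression-based GRN methods on observational data.

## Known limitations

- Only first-order (single-regulator) basis blocks; no pairwise or
  higher-order interaction terms.
- No time-series dynamics: the method regresses expression on expression,
  which is the steady-state reading of the underlying dynamic formulation.
- Ranking only — no edge-count threshold, no network stability analysis,
  no significance calibration of AUPR.
- The direction of regulation between strongly coupled genes is weakly
  identified from observational steady-state data (see above); knockout or
  time-course information, which the pipeline does not consume, would be
  needed to break those ties.
- On DREAM-scale inputs (thousands of genes, b = 200) runtime is dominated
  by b × N greedy selections; `--jobs` parallelises over targets with
  bit-identical results.  The bundled benchmark sizes (20–50 genes in tests,
  50 genes in `scripts/acceptance.py`) were chosen so the whole suite runs
  in minutes on one core.

## Reproducing DREAM results

With user-supplied DREAM4 files (not bundled), the challenge-scale experiment is

```sh
d3grn infer --expression net1_expression.tsv --out net1_pred.tsv \
      --bootstrap 200 --steps 2 --seed 0
d3grn eval --predictions net1_pred.tsv --gold net1_gold.tsv \
      --expression net1_expression.tsv
```

(no regulator file: every gene is a candidate regulator).  This is a
documented experiment, not part of the test suite, since it requires the
external download.
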