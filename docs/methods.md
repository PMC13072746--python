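# Methods

## Model and estimation

The baseline relates the natural-log folding rate to chain length:

    ln(k_f) = a0 + a1 · ln(L) + ε,     ε ~ (0, σ²)

with `L` the residue count and `k_f` in s⁻¹. The coefficients are the
ordinary-least-squares minimisers, computed in closed form from centred
moments: `a1 = Σ(x−x̄)(y−ȳ) / Σ(x−x̄)²` with `x = ln L`, and
`a0 = ȳ − a1·x̄`. A two-parameter problem does not need matrix machinery,
and the closed form makes the estimator auditable; the test suite
cross-checks it against an independent normal-equations solve
(`np.linalg.solve`) to 1e-9 and its standard errors against
`scipy.stats.linregress`. Standard errors use the unbiased residual variance
(df = n−2). Duplicated PDB codes count as independent observations, because
that is how the experimental compilations use repeated measurements; no
observation weighting is applied. Degenerate designs (all lengths equal,
n < 3) are rejected with specific exceptions rather than producing NaNs.

Assumptions worth keeping in mind: homoscedastic residuals on the log scale,
no error in `L` (sequence lengths are treated as exact even though
compilations disagree on them — that disagreement is *measured* by the
discrepancy module, not modelled), and a single global law with no
kinetic-class or structural-class stratification.

## Evaluation modes

* **fit** — metrics over the training records from the fitted model.
* **loo** — leave-one-out cross-validation by explicit refits: each record
  predicted from a model fitted to the other n−1. At n ≤ ~150 the n refits
  cost microseconds, so no shortcut is used in the implementation; the
  hat-matrix identity `e_(i) = e_i / (1 − h_i)` serves as an independent
  oracle in the tests (agreement to 1e-9). Because leverages lie in [0, 1),
  LOO RMSE ≥ fit RMSE always — asserted as an invariant.
* **external** — predictions on a set never used in fitting, either from a
  fitted baseline or from an ingested third-party prediction table; nothing
  is ever refit in this mode. An optional `min_length` filter reproduces the
  behaviour of prediction servers that refuse chains under 50 residues.

Pearson correlation is undefined for constant vectors or n < 2; it is
raised/flagged (`None` in reports) and never silently reported as 0, which
would quietly distort model comparisons. Reports display at 2 decimals (the
field's table convention) but serialise full precision.

## Subset provenance

For a dataset pair (A, B), four subsets drive the validation workflow:
`A∩B` (codes in both, **data from A**), `B∩A` (data from B), `A\B`, `B\A`.
Overlap keeps every record of the provenance set whose code occurs in the
other set — so duplicated codes in the provenance set are retained, while
duplicates in the membership set never multiply records. This asymmetric
convention is what real compilations require: with 50 shared codes and two
duplicated proteins in the first set, the two overlaps have sizes 52 and 50.
Overlap and difference partition the provenance set exactly (a property
test, duplicates included).

## Discrepancy analysis

Comparisons are made per *distinct* shared PDB code (first occurrence on
each side), since duplicate entries would otherwise double-count. Sequence
identity is exact string equality after upper-casing; pairs lacking a
sequence on either side are excluded from sequence counts and reported
separately. Two rates are non-identical when |Δ ln k_f| ≥ 0.01 — the
resolution at which compilations print rates — applied with a 1e-9 guard so
that decimal differences like 5.010 vs 5.000 compare correctly in binary
floating point. Length differences use sequence lengths when sequences are
present. Raising the threshold can only reduce the non-identical count
(property-tested), and the summary is symmetric in its arguments.

## Theory mapping

`to_rate_law` exponentiates a fitted model to `k_f = c0·L^a1` with
`c0 = exp(a0)` in s⁻¹; `folding_time` is its reciprocal. `tst_time`
evaluates `t = τ·exp(ΔG‡/RT)` with R fixed at 8.314 J·mol⁻¹·K⁻¹, default
T = 298.15 K and τ = 1 ns (the elementary per-residue structuring time at
L ≈ 100). `n_secondary_elements` implements the two standard estimates of
the number of secondary-structure elements positioned during folding,
`L^(2/3)/3` and `L/15`; `scaling_time` evaluates `t ~ τ_s·L^N`, identical by
construction to its `exp(N·ln L)` form. The consistency report tabulates
(−a1, c0) per model with the mean intercept and the one-decimal range of
−a1; note that `exp(30.4) ≈ 1.59e13`, so agreement with the ~1.5e13 s⁻¹
attempt-frequency scale is an order-of-magnitude/2-significant-figure
statement, and the report treats it as such rather than asserting printed
digits. The module also ships the six published overlap-subset coefficient
pairs (`PUBLISHED_LENGTH_MODELS`) as reference inputs for that report.

## Synthetic-data generator

The generator emulates the real compilations' statistical structure:

| parameter | default | rationale |
|---|---|---|
| n | 80 | typical compilation size (tens to ~150) |
| L range | 40–400 | spans the observed length range with margin around the ~50–150 bulk |
| a0 | 30.4 | centre of published intercepts |
| a1 | −6.0 | centre of the published −4.5…−7.1 slope range |
| σ | 2.6 | ln-units; the fit-RMSE scale (≈2.5–3) real compilations show |

Lengths are drawn log-uniformly (integers) so that `ln L`, the actual
regressor, has near-uniform leverage; sequences are i.i.d. uniform over the
20 standard residues, sufficient because the analysis only ever reads their
length. Residuals are Gaussian — the real residual distribution about the
length trend is uncharacterised, and this is an explicit assumption.
Synthetic ids are PDB-style digit+3-letters, unique within a dataset; an
`id_offset` keeps independently drawn train/test sets disjoint in codes,
as real external sets are.

Paired variants perturb a dataset in place: with probability `p_seq_change`
a sequence gains or loses up to `max_len_delta` residues; with probability
`p_rate_change` the rate shifts by a sign-symmetric exponential magnitude
(mean 0.5 by default). The exponential reproduces the heavy-tailed pattern
real compilation pairs show — wide discrepancy ranges (~0.01–3.4) around
small means (~0.2–0.7) — without claiming a fitted distribution. The
perturbation log returned alongside is the oracle the discrepancy tests
reconcile against exactly.

`generate_overfit_predictor` emulates a model memorising its training
compilation: predictions are observation + Normal(0, σ_train) on training
ids and observation + bias + Normal(0, σ_test) externally, so the
external/training RMSE ratio is controlled by construction
(≈ √(bias² + σ_test²)/σ_train in expectation).

All randomness flows through `numpy.random.default_rng(seed)`; a seed fully
determines a dataset across platforms. Replicated studies in the test suite
draw per-replicate seeds from a single master generator, numpy's
recommended scheme for independent streams.

What passing tests on synthetic data do **not** show: that real folding
kinetics are homoscedastic-Gaussian about a log-linear trend, that real
inter-compilation discrepancies are exponential, or anything about
structural-class effects. The generator validates the *machinery* — subset
algebra, estimation, cross-validation, external scoring, discrepancy
bookkeeping — under conditions that match the real data's sizes and noise
scales.

## Problem sizes and numerical choices

Replicated studies use 500 replicates at n = 50 for parameter
recovery/coverage and 100 replicates for the overfitting demonstration —
enough for 3σ binomial bands of a few percent while the whole suite runs in
seconds. Coefficient agreement is asserted at 1e-9 (closed form vs
oracle), algebraic identities at 1e-12 relative, and published coefficients
at their printed 3-decimal precision. Record parsing fixes one rule for
conflicting length fields: the sequence wins and the conflict is logged,
because the published tables themselves disagree internally and a single
authoritative rule is better than silent ambiguity. Nonstandard residues
(B, Z, X, U, O) are rejected by default and admitted as length-contributing
unknowns under a permissive flag.

## Known limitations

* Matching between datasets is strict by PDB code; no sequence-similarity
  or fuzzy matching, and chain suffixes are treated as part of the key.
* No multivariate descriptor models, class-specific submodels, or
  3D-structure descriptors (contact order and relatives) — only their
  prediction outputs can be ingested and scored.
* The applicability domain is minimal (training length range only);
  similarity-based domains are out of scope.
* No fetching from the PDB or any web service; users export their tables to
  TSV/CSV first.
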