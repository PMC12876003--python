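# Methods

This note documents the models implemented in `danpv`, the conventions
chosen where the methods literature admits variants, the synthetic
questionnaire generators, and the package's known limitations.

## Pipeline overview

The package evaluates one community against an absolute aspiration level
in four stages: fuzzy-Delphi screening fixes the criteria framework;
DEMATEL turns expert pairwise-influence judgments into a total-influence
network; DANP extracts criterion weights from that network; modified
VIKOR converts panel satisfaction ratings into weighted aspiration gaps.
All stages index the criteria space in dimension-major framework order,
so each dimension owns a contiguous block of matrix indices and block
arithmetic (T_D, supermatrix blocks, local weights) needs no index maps.

## Fuzzy Delphi screening

Per criterion, the conservative and optimistic rating pools are condensed
to triangular fuzzy numbers as (min, geometric mean, max). The geometric
mean is the canonical central estimate for the double-triangular
construction; it is clamped into [min, max] against float roundoff.
The gray-zone test Z = C_high − O_low against M = O_mid − C_mid selects
the consensus formula (midpoint of peaks; edge crossing; undefined). The
edge-crossing abscissa is the unique intersection of the descending
conservative edge and the ascending optimistic edge; a zero denominator
can only occur with both edges vertical, which forces Z ≤ 0, so the
midpoint fallback for that case is defensive rather than reachable.
Questionnaires are invalidated whole (any missing item or any item with
conservative ≥ optimistic), mirroring how panel surveys are audited in
practice; item-wise repair would blur the validity count. The retention
threshold (default 4 on the 1–10 scale) is inclusive.

Consequences worth knowing: the consensus G is only shift-equivariant on
the no-overlap branch with constant panels (the geometric mean is not
translation-equivariant), and raising every rating can only grow the
retained set on that branch — both are asserted as scoped property tests.

## DEMATEL conventions

- Questionnaire scale: integers 0–4 (0 = no influence, 4 = very high),
  the dominant DEMATEL convention.
- Panel aggregation: element-wise arithmetic mean.
- Normalisation divisor: max(max row sum, max column sum). For a
  nonnegative matrix with some strict inequality this bounds the spectral
  radius below 1, so the Neumann series converges and
  T = D(I − D)⁻¹ is well defined. The solve refuses condition numbers
  above 1e12; at n = 16 robustness matters more than speed.
- T_D is the arithmetic mean of each (row-dimension, column-dimension)
  block of T_C — linear in T_C, hence scale-commuting.
- Influence priority ranks by net relation r − c descending; ties break
  by prominence, then framework order, so degenerate synthetic inputs
  rank reproducibly.
- INRM edge rule: an edge p → q is drawn when T(p, q) is at or above the
  mean of the off-diagonal entries of its own level's matrix. The rule is
  configurable (any numeric threshold) because published network maps
  rarely state one; the mean-off-diagonal default reproduces the
  qualitative case patterns (e.g. the environmental-exposure dimension
  receiving edges from all five others).
- Test–retest consistency: sum and mean of |M1 − M2| over all n² ordered
  entry pairs (256 at n = 16, diagonal included — that is the pair count
  the published consistency figure implies).

## DANP conventions

Columns of the supermatrix are "influenced-by" distributions: W is the
transpose of the block-row-normalised T_C, and block (p, q) of W is scaled
by row-normalised T_D entry (q, p). Both steps preserve column sums, so
the weighted supermatrix is column-stochastic whenever no block row of
T_C and no row of T_D is entirely zero (all-zero block rows pass through
as zeros and are logged; a zero T_D row raises, since it means a
disconnected dimension).

The limit is computed by repeated squaring to tolerance 1e-9 (at most
200 squarings; a positive 16×16 matrix converges in a handful). If the
fixed point's columns disagree, a period-2 cycle collapsed onto distinct
even/odd limits and the Cesàro average of two consecutive powers is used;
if columns still disagree the structure is reducible and the computation
fails loudly with diagnostics rather than returning arbitrary weights.
Global weights are the (renormalised) limit column; dimension weights are
block sums; local weights the within-block renormalisation, so
global = dimension × local holds to machine precision. Weights are kept
at full precision; 3-decimal half-up rounding is applied only in the
reporting layer.

## Modified VIKOR conventions

- Aspiration 10, worst 0. These were derived from the published
  performance/gap pairs (e.g. 8.036 ↔ 0.196 and 2.579 ↔ 0.742 both fit
  (10 − p)/10 exactly, and reject worst = 1).
- Panel integration weights are the valid respondent counts (140, 10);
  the published integrated values (7.213, 2.867, 3.828, …) reproduce this
  choice exactly.
- Because the gap ratio is affine in performance, weighted aggregation
  and the gap transform commute exactly; dimension and total gaps can be
  computed on either side of the transform.
- Dimension aggregation is Σ local_weight × criterion_performance and the
  total Σ global_weight × criterion_performance. When an evaluation is
  built from a pre-aggregated performance table (as published tables are
  printed), the table's own dimension/total panel values take precedence
  and integration applies the panel-size formula to them. This matters
  because published weights are rounded to 3 decimals: re-aggregating
  from rounded weights shifts dimension values by up to ~0.07, while the
  printed-panel-value route reproduces the integrated results exactly.
  For the same reason the weight-sum precondition on the aggregation
  helpers tolerates a drift of 0.02, so published rounded weight vectors
  (which sum to ≈0.985) remain usable.
- Respondent validity: questionnaires with more than a configurable
  fraction of missing items (default: any) are dropped whole before
  means; remaining missing items are ignored item-wise.
- Sample adequacy uses the Cochran margin of error
  z·sqrt(p(1 − p)/n) with the two-sided normal quantile
  (z = 1.959964 at 95%).

## Synthetic questionnaire generators

The generators emulate the three questionnaire types so every stage runs
without external data; all take an explicit integer seed and are
bit-reproducible.

- **Satisfaction surveys**: latent normal draws at the per-criterion
  target mean (default dispersion 1.5 rating points — a realistic spread
  for 10-point community-satisfaction items), rounded and clipped to
  1–10, then greedily adjusted in ±1 steps on randomly chosen respondents
  until the criterion sum equals round(n × target). A panel therefore
  hits any 3-decimal target to |error| ≤ 0.5/n (≤ 0.0036 at n = 140),
  which is what lets the synthetic path reproduce the published
  per-criterion means essentially exactly.
- **DEMATEL panels**: a base matrix of dimension-block intensities
  (optionally constructed by `priority_structure` to realise a prescribed
  net-influence order), dithered before integer rounding so fractional
  block levels survive panel averaging, plus per-expert uniform integer
  noise in [−k, k], clipped to 0–4, zero diagonal. Default panel size 9
  experts. With noise 0 all experts are identical (retest difference 0);
  the retest difference grows monotonically with the noise level.
- **FDM panels**: conservative ratings drawn below optimistic ones per
  item; criteria flagged "low consensus" are rated near the scale bottom
  so screening excludes them; a configurable number of experts is
  corrupted (an inverted pair or a missing item) to exercise
  questionnaire-level invalidation. Default panel 27 questionnaires with
  4 invalid, matching the case survey's audit counts.

What the generators do **not** model: respondent demographics and
response-style biases (acquiescence, central tendency), item
non-response correlated with respondent traits, expert heterogeneity in
the DEMATEL ratings beyond iid noise, and any dependence between the
satisfaction panels and the influence network. Passing tests therefore
demonstrate the pipeline's arithmetic and its parameter recovery under
clean conditions, not robustness to real survey pathologies.

The published case enters through `case_fixture()`: the printed per-panel
criterion and dimension performances, panel totals, local/dimension
weights and panel sizes. Global weights in the fixture are reconstructed
as dimension × local so the weight identities hold exactly; the printed
global column differs from these products only by independent rounding.

## Problem sizes and runtime

All computations run at the case scale (16 criteria, 6 dimensions,
panels of 140/10 respondents and 9/27 experts); property suites use
16×16 random matrices for the Neumann-series and eigenvector oracles and
4–6×6 matrices for hand-checkable identities. The full test suite and
the acceptance script each complete in seconds on one core.

## Known limitations

- Single evaluation target: no classical VIKOR S/R/Q compromise ranking
  across multiple alternatives.
- One-round Delphi: no iterative convergence loop.
- Crisp DEMATEL only (no fuzzy-DEMATEL variant); no Saaty-style pairwise
  ANP input mode — weights come exclusively from the influence matrices.
- INRM export is edge lists and DOT text; rendering is left to graphviz
  or any plotting tool.
- The framework supports exactly two levels (dimension → criterion).
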