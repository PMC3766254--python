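# Methods

## Scope and data flow

The package models a social system as a fuzzy cognitive map: concepts are
nodes of a signed weighted digraph, and the strength of each directed
influence is elicited from three ordinal linguistic judgements rather than
estimated from data. The pipeline is

1. **knowledge base** — concepts plus evidence edges, each carrying a sign
   and exactly three levels on the scale VL < L < M < H < VH (a closed
   phrase → level lexicon supports the transcription);
2. **fuzzy inference** — each level triple becomes a crisp magnitude in
   (0, 1), the sign is applied afterwards;
3. **dynamics** — synchronous iteration of the state vector under a
   threshold function;
4. **scenarios and network analysis** — what-if runs, centrality, and
   one-at-a-time sensitivity sweeps.

The packaged homelessness map has 14 concepts and 31 edges (93 linguistic
terms). Homelessness is a pure sink: every edge into it is an influence *on*
homelessness, none emanate from it. A secondary six-concept
exercise/heart-disease map with ±1 weights ships as the engine's validation
fixture.

## Fuzzy inference

Partition of [0, 1]: VL = (0, 0, 0.25), L = (0, 0.25, 0.5),
M = (0.25, 0.5, 0.75), H = (0.5, 0.75, 1), VH = (0.75, 1, 1) — symmetric
interior hats of half-width 0.25 and boundary shoulders. Every rule
antecedent is the binary presence of the source concept, so all three rules
fire at full strength and min-implication passes the consequent sets through
unchanged; aggregation is the pointwise max on a uniform 1001-point grid and
defuzzification is the centroid by the trapezoid rule. 1001 points keeps all
partition breakpoints (multiples of 1/8) exactly on the grid; the remaining
trapezoid error comes from the piecewise-quadratic moment integrand and is
below 2e-5, and doubling the grid moves no value by more than 1e-3.

**Calibration.** This partition is the unique triangular one consistent with
the exactly stated reference cases {L,L,L} → 0.25 and {M,L,H} → 0.5 (and with
the low-degree centrality values below). Reference values for triples that
touch a boundary shoulder are reported slightly lower than this partition
produces — {M,H,VH} is quoted as 0.648 where the analytic centroid is
2/3 ≈ 0.6667, {M,M,VH} as 0.6344 vs 0.6389, {H,VL,M} as 0.4984 vs 0.5046.
The shoulder realisation behind those published numbers is not recoverable;
all discrepancies are ≤ 0.02 absolute and the package documents ±0.02 as the
trust band for boundary-involving magnitudes. Symmetric-interior cases are
exact.

**Properties.** The realisation is mirror-symmetric: reflecting a triple
about the scale midpoint (VL↔VH, L↔H) maps the magnitude w to 1 − w, for all
35 unordered triples. Monotonicity under raising a single level holds on the
interior hats {L, M, H} but **not universally**: max-union centroids are not
monotone once a boundary shoulder enters or a duplicate level un-merges.
Two counterexamples are instructive — {VL,VL,M} = 0.3611 > {VL,L,M} = 0.3333
(raising VL to L adds L's mass, which lies left of the current centroid) and
{M,H,VH} = 0.6667 > {M,VH,VH} = 0.6389 (VH's shoulder carries half the area
of H's hat, so the replacement removes right-side mass). This is a structural
property of Mamdani max-centroid systems with unequal-area sets, not an
implementation artefact; no triangular partition matching the exact worked
values avoids it. The suite asserts the restricted invariant and pins the
counterexamples.

## Dynamics

Update rule: `A_i(k+1) = f(Σ_{j≠i} A_j(k) W_ji + self_memory · A_i(k))`,
followed by overwriting any clamped concepts. Conventions:

- The self term is a setting, not a weight. The six-concept validation
  fixture stores its printed +1 diagonal, but its documented trace is only
  reproduced with the self term excluded (`self_memory=0`) and the activated
  input concept clamped at 1 — that configuration is the packaged default
  for sign-mode replication. Graded runs use `self_memory=1` and no
  clamping, so activated concepts evolve freely.
- Sign mode terminates on exact state repetition: an immediate repeat is a
  fixed point ("converged"), an older repeat a limit cycle reported with its
  period. The state space is finite ({−1,0,1}^N), so termination within
  3^N + 1 produced states is guaranteed and property-tested. ε is ignored.
- Tanh mode terminates when max_i |ΔA_i| ≤ ε (default 1e-5), cap
  `max_iter=100`. Trace length counts produced state vectors including the
  initial one.
- Concepts with no incoming edges decay to 0 only asymptotically under
  `self_memory=1` (A ← tanh(A)), so runs containing such concepts may end at
  `max_iter` with the outcome concept itself long settled; outcome levels
  quoted anywhere in the package are insensitive to ε across [1e-6, 1e-4].

## Scenarios

A scenario activates a subset of concepts at levels in [0, 1]; the outcome
concept is never pre-activated. Packaged cases (tanh, self-memory on):

| case | activations | outcome |
|---|---|---|
| 1 | Addiction .65, Family Breakdown .57, Govt Assistance .46, Mental Illness .61 | saturates high (0.9998) |
| 2 | Addiction .30, Social Support .61, Education 1.0, Family Breakdown .30, Income .72 | settles low (−0.9998) |
| 3 | Addiction .20, Social Support .11, Education .94, Family Breakdown .51, Income 1.0 | rises high, above case 2, below case 1 |

Classification thresholds: final outcome level ≥ 0.9 → likely, ≤ 0.1 →
unlikely, else uncertain. The 0.9/0.1 defaults mirror the saturated-versus-
near-zero regimes the extreme cases produce and are configurable; the
interesting observable is the ordering case 1 > case 3 > case 2, which is
stable across ε ∈ [1e-6, 1e-4]. In the protective configuration (case 2),
addiction activations below 0.30 never produce the "likely" outcome —
asserted on a grid.

## Network analysis

- **Degree centrality**: Σ |w_out| + |w_in| per concept, self-loops excluded
  by default (the packaged map has none; the validation fixture's diagonal
  must not contaminate degrees).
- **Closeness centrality**: per-edge distance d = 1/|w|; all-pairs shortest
  directed paths are computed on true infinities first (Dijkstra via
  networkx), and unreachable pairs are replaced by Big-M = 100 only in the
  closeness sum 1/Σd. Computing on true infinities first avoids Big-M-length
  multi-hop artefacts. 100 safely exceeds the longest possible finite path:
  the largest single-edge distance is 4 (the 0.25-weight edge) and a path
  visits at most 13 edges, bounding paths by 52. Raising Big-M to 1000
  reorders nothing (asserted on the packaged map). Because raw values are
  ~1e-4 when unreachable pairs exist, a ×10^4 scaled copy is reported
  alongside.
- **Sensitivity sweep**: all concepts start at a 0.01 baseline except the
  outcome (0) and the swept concept (grid 0.1..1.0, step 0.1); three tanh
  iterations; the outcome level is recorded per grid point and summarised by
  min/quartiles/max. The small baseline and short horizon keep the response
  away from ±1 saturation, where every curve would flatten and concepts
  would be indistinguishable. Box width (IQR) measures how variable a
  concept's impact is: a strong driver such as addiction shows a narrow box,
  a weak one such as housing cost a wide one.

## Synthetic data

Generators produce structurally faithful test inputs: random signed maps of
configurable size/density with no self-edges and an optional outcome-only
sink (the packaged map's 14-node/31-edge shape is density 31/169 with the
sink flagged), random three-level evidence triples, and random scenario
activations, all from a single seeded stream per call. They target
structural, not statistical, realism: weights are uniform on a sub-interval
of (0, 1], signs are Bernoulli, and no social-indicator correlation
structure is emulated — so passing tests demonstrate the machinery's
correctness on the assumed graph shapes, not empirical validity of any map.
On all-positive synthetic maps, sweeping any concept yields a monotone
non-decreasing sink response (a guaranteed-hypothesis version of the
monotonicity seen on the packaged map).

## Problem sizes and numerics in the suite

Property tests use maps of 3–10 concepts (50 random maps for the
centrality-versus-brute-force checks, with a min-plus relaxation oracle for
distances and a double-loop oracle for degrees), sign-mode termination is
exercised at N = 6 against its 3^6 bound, and fuzzy properties are
enumerated exhaustively over all 35 unordered level triples. Tie-breaks:
case ordering uses strict comparison on full-precision finals; ranking ties
in comparisons share a rank (stable mergesort).

## Known limitations

- The boundary-shoulder realisation behind the published 0.648-class values
  is unrecoverable; boundary-involving magnitudes carry a ±0.02 band.
- Universal single-level monotonicity of the FIS is impossible under the
  exactly-calibrated partition (see above).
- Several published high-degree centrality rows (e.g. education ≈ 5.42)
  exceed what the printed 31-edge list can produce (five incident edges
  bound that degree by 5) and cannot be reproduced from the shipped
  transcription; only the low-degree rows are treated as checkable, and the
  published closeness column is likewise inconsistent with the printed edge
  set except for the housing-cost computation and the Big-M ranking claim.
- The phrase lexicon contains two phrases printed under two levels
  ("most effective", "statistically significant"); the packaged lexicon
  resolves each to its lower level. Edge levels are transcribed directly and
  never pass through the lexicon, so weights are unaffected.
- Dynamics are synchronous and memoryless beyond the self term; no learning
  of weights from data is provided.
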