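# Methods

`cdmst` builds and validates multistage tests (MST) for cognitive
diagnosis (CD). This note documents the models, the selection heuristic,
the simulation design the package's defaults encode, and the numerical
and design choices a maintainer would want to know.

## The response model

Examinees are characterized by a knowledge state α ∈ {0,1}^K, a binary
vector of attribute masteries. Items declare the attributes they measure
through a Q-matrix row q_j ∈ {0,1}^K (never all-zero). The response model
is the saturated identity-link G-DINA model: each *reduced pattern* α*
(the restriction of α to the measured attributes) carries its own
correct-response probability

    P_j(α*) = δ_j0 + Σ_k δ_jk α*_k + Σ_{k<k'} δ_jkk' α*_k α*_k' + … ,

so the probability table over the 2^{K*_j} reduced patterns and the δ
coefficients are exact bijections (subset sums one way, Möbius inversion
the other; `delta_from_prob_table` / `prob_table_from_delta`). Tables are
required to be monotone: mastering a superset of measured attributes
never lowers the probability.

**Item simulation.** The guessing and slipping endpoints follow
P_j(0) ~ U(0, 0.25) and 1 − P_j(1) ~ U(0, 0.25). The model pins only the
endpoints; the interior reduced-pattern probabilities are drawn i.i.d.
U(P(0), P(1)) and assigned in sorted order by mastery count, which
preserves the endpoints and guarantees a valid monotone item. This is
one admissible interior scheme among several used in G-DINA simulation
practice; nothing downstream depends on more than monotonicity and the
endpoint law.

**Population.** Knowledge states are drawn uniformly from all 2^K states
(32 for K = 5), Q-matrix rows uniformly from the 2^K − 1 nonzero patterns
(31 for K = 5).

## The difficulty index

Item difficulty in CD is defined as the mean correct-response probability
over all knowledge states, Diff_j = 2^{−K} Σ_c P_j(α_c) ∈ [0,1]; since
every reduced pattern corresponds to equally many full states this is the
unweighted mean of the probability table. Lower Diff_j = harder. The
index is validated by calibrating the same simulated responses with a
Rasch model (marginal ML) and correlating Diff_j with b_j; the magnitude
reliably exceeds 0.85 (typically ≈ 0.98), with the expected negative sign.

Banks are partitioned into three **equal-width difficulty bins** over the
realized [min Diff, max Diff] range — hard, medium, easy from low to high
Diff. Intervals are half-open [lo, hi) except the topmost, so every item
gets exactly one label. A degenerate bank (all difficulties equal) is an
error. Because Diff_j is a mean of reduced-pattern probabilities whose
expectation is (P(0)+P(1))/2 ≈ 0.5, the distribution concentrates near
0.5 and the outer bins are materially smaller than the middle bin (on a
1,000-item bank typically ~60–250 items each); this drives the
exclusivity design choice below.

## Attribute reliability

The quantitative assembly target is per-attribute test-retest
reliability. From responses X to an item set, each examinee's posterior
over the 2^K states is w_ec ∝ prior(c) Π_j P_j(c)^{x_ej}(1−P_j(c))^{1−x_ej}
with a uniform prior (matching the generating population). Marginal
mastery probabilities p̂_ek = Σ_{c: α_ck=1} w_ec feed a 2×2 replication
table per attribute,

    p11 = mean(p̂²), p10 = p01 = mean(p̂(1−p̂)), p00 = mean((1−p̂)²),

whose tetrachoric correlation is the attribute reliability u_k. The
tetrachoric fit finds the ρ for which a bivariate standard normal with
thresholds τ_i = Φ⁻¹(1 − margin_i) reproduces the p11 quadrant. Quadrant
probabilities use the Owen's-T decomposition of the bivariate normal CDF
(`scipy.special.owens_t`), cross-checked in tests against
`scipy.stats.multivariate_normal`. The scalar API uses Brent root-finding
(bracket ±0.999999, xtol 1e−12); the assembly hot path uses a vectorized
60-step bisection, which brackets ρ far beyond the 1e−8 tolerance on the
quadrant probability. Degenerate margins (0 or 1) are an error at the
primitive level and are clamped to reliability 1 with a warning at the
vector level, since such an attribute is perfectly determined.

## NWADH selection

With J items selected, candidate i in the remaining pool R_J is scored by
the mean absolute deviation d_i = (1/K) Σ_k |T_k − u_k^{J+1,i}| of the
candidate-extended reliabilities from the targets T_k (0.90 by default),
normalized to the priority index e_i = 1 − d_i / Σ d, plus a content term:

    e*_i = e_i + c_i / Σ c,   c_i = Σ_g [v_ig W_g + (1 − v_ig) W̄],
    W̄ = max_g W_g − (1/G) Σ_g W_g,

with v_ig the indicator that item i bears constraint category g and
W_g = 2 while category g's minimum count is unmet, otherwise 1 (a
category at a finite maximum also has weight 1). The argmax of e*_i is
selected; ties are broken by smallest |Diff − bin midpoint|, then lowest
item id — deterministic and difficulty-coherent. An alternative reading
of the content weight with the complement indicator replaced by
(1 + v_ig) appears in some statements of the heuristic and is available
via `printed_content_weight=True`; the default is the form above, which
rewards category-bearing items exactly when their categories are needed.

Two efficiency contracts make the ~1,000-candidate scan desk-scale:
candidate posteriors are never refit — a single-item update multiplies
one likelihood factor into the cached posterior, and for scoring, the
updated marginal masteries of *all* candidates reduce to two matrix
products per attribute ((1−p) and (2p−1) decompositions of the Bernoulli
likelihood). The fast path is verified against from-scratch refits and a
brute-force next-item oracle in the test suite.

**Constraint table** (defaults, per pathway): content balance 4
categories × min 4; item types 2 × min 8; answer keys 4 × min 4; enemy
pairs max 0; attribute coverage K × min 3. Enemy exclusion is enforced as
a hard candidate filter within a pathway, not through the weights.
Features are assigned uniformly at simulation time (content and answer
keys over 1–4, types over {1,2}); 2% of items form enemy pairs — enough
to exercise the filter while keeping a 1,000-item bank comfortably
feasible.

## Panel architecture and assembly order

Each panel has three stages. Stage 1 is a shared medium-difficulty module
of exactly one single-attribute item per attribute (K items) — the
minimal design that secures early identifiability of all attributes.
Stages 2 and 3 hold easy/medium/hard modules; the three **primary
pathways** (medium→easy→easy, medium→medium→medium, medium→hard→hard)
are the assembly targets. Stage sizes follow the study design: (5, 8, 8)
for 21-item tests and (5, 10, 10) for 25-item tests. Pathways are
assembled sequentially hard → medium → easy (configurable), each seeded
with the stage-1 module's posterior and feature counts and restricted to
its difficulty bin.

**Item exclusivity.** Items are unique within a panel, and stage-1
modules are item-exclusive across panels — which also makes the
deterministic greedy runs of successive panels diverge. Stage-2/3 items
*may* recur across panels: full cross-panel exclusivity is arithmetically
infeasible under this generating scheme, because the easy bin of a
1,000-item bank (~60–100 items) cannot supply even 5 panels × 16
exclusive easy items, let alone 10 × 20. Parallelism across panels comes
from identical targets and constraints, not from disjoint item sets;
users with larger banks or wider difficulty spreads can tighten this by
pre-partitioning the bank per panel.

Reliability during assembly is evaluated on a fixed simulated calibration
sample (default 1,000 examinees, regenerated per replication from the
seed); evaluation afterwards uses a fresh sample of the same size, so
reported deviations include sampling error rather than in-sample fit.

## Evaluation

Per pathway and panel: reliability deviations D_ik = R_ik − T_ik;
per-category violation indicators (count below minimum, above a finite
maximum, or any co-occurring enemy pair) summing to the pathway total;
expected number-correct scores Σ_j P_j(α_e) from the true states; and
Cronbach's α on simulated responses. Expected scores and α are emitted at
two granularities: per panel, and concatenated across a condition's
panels with multiplicity — the cross-panel aggregate is the headline
statistic (a 5-panel × 25-item easy pathway has 125 item slots), and both
are reported because the aggregation level of such summaries is a
genuine modelling choice. The Rasch cross-calibration runs once per
condition on the union of distinct selected items (marginal ML, standard
normal ability, 41 Gauss–Hermite nodes, Newton M-steps, tolerance 1e−6,
mean-centered — centering changes no correlation or ordering used here)
and is summarized per pathway over item slots.

## The replication study

`run_study` executes a 2 × 2 grid — test length {21, 25} × panels
{5, 10} — with a fresh bank (1,000 items), calibration sample and
evaluation sample per replication, all sub-seeded from one master seed
via `numpy` SeedSequence spawning, so reruns are byte-identical and
replications are independent (they could run concurrently without
changing results; the implementation runs them serially). The full
design uses 100 replications; the package default is 10, and the
acceptance script uses 10 replications for the 21-item/5-panel condition
and 5 for the other three — sizes chosen so the whole study remains a
desk-scale computation while keeping Monte-Carlo noise well below the
decision bands (the quantities checked move by ≲0.01 across replications).

## What the simulation does and does not show

The generator emulates the study conditions exactly: uniform states,
uniform nonzero Q-rows, U(0, 0.25) guessing/slipping, uniform categorical
features. Real item banks differ in ways that matter: attributes are
correlated, Q-rows and content categories are curated rather than
uniform, difficulty distributions can be wider or skewed, and item
parameters come from fallible calibration instead of the generating
truth. Passing tests therefore demonstrate the *method* — that the
heuristic hits reliability targets, respects constraints and orders
difficulty correctly under its stated data-generating process — not that
any particular operational bank is feasible. Known limitations: no
estimation of G-DINA parameters from data (true parameters throughout),
no adaptive routing of examinees, no bottom-up (module-parallel)
assembly, and no classification-accuracy/consistency reliability
alternatives.
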