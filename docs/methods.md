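# Methods

This note documents the statistical model behind `mrnetwork`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish about real data.

## Two-sample MR model

All estimators consume GWAS summary statistics only. For instrument *j*,
exposure *X* and outcome *Y*, the per-variant inputs are (β̂_Xj, se_Xj,
β̂_Yj, se_Yj, EAFⱼ, N). Under the instrumental-variable assumptions the Wald
ratio θ̂ⱼ = β̂_Yj/β̂_Xj estimates the causal effect, with first-order
(delta-method) standard error se_Yj/|β̂_Xj|. Instruments with β̂_Xj = 0 are
excluded from ratio-based estimators with a warning.

### The seven estimators

* **FE_IVW / RE_IVW** — zero-intercept WLS of β̂_Y on β̂_X with weights
  1/se²_Y. Both share the point estimate. The fixed-effect standard error is
  (Σ wⱼ β̂²_Xj)^(−1/2); the multiplicative random-effects model inflates it
  by σ̂ = √(Q/(J−1)), truncated below at 1 by default
  (`re_truncate_sigma_at_1`), so the RE standard error can never undercut
  the FE one. RE_IVW is the default main model; FE_IVW is selectable via the
  `main_model` switch since either convention appears in practice.
* **RO_IVW** — the same regression solved by iteratively reweighted least
  squares with Tukey's biweight (tuning constant 4.685, the classical 95%-
  efficiency value). The residual scale is the median absolute deviation
  about **zero** (normal-consistent factor 1.4826): the regression runs
  through the origin, and centring at zero also makes the estimator exactly
  equivariant under joint sign flips of any instrument's (β̂_X, β̂_Y) — a
  pure allele-relabeling that must not change results. The variance is the
  HC0 sandwich of the final weighted estimating equation. (Implemented
  directly because statsmodels' RLM does not accept prior inverse-variance
  weights.)
* **EGGER** — instruments are oriented so every β̂_Xj > 0, then WLS with
  intercept. The slope estimates the causal effect; the intercept the
  average directional pleiotropy. Standard errors carry the multiplicative
  scale σ̂ = √(Q_egger/(J−2)) (truncated at 1); coefficient p-values use the
  normal reference, which differs negligibly from the t reference at J ≥ 10.
* **WME / SM** — the interpolated weighted median: sort θ̂ ascending, form
  cumulative midpoints p_k = Σ_{i≤k} w′ᵢ − w′_k/2 with normalized weights,
  and interpolate linearly at p = 1/2. SM uses equal weights. Standard
  errors come from B = 1000 parametric bootstrap resamples
  θ*ⱼ ~ N(θ̂ⱼ, se(θ̂ⱼ)) with fixed weights, seeded.
* **WMD** — weighted-mode: Gaussian kernel density of the ratios with
  inverse-variance weights normalized to one, bandwidth
  h = φ·0.9·min(sd, IQR/1.34)·J^(−1/5) (modified Silverman, φ = 1 by
  default), evaluated on a 512-point grid spanning [min θ̂ − 3h,
  max θ̂ + 3h]; the estimate is the grid argmax. If h = 0 (all ratios
  identical) the common ratio is returned. Bootstrap as for the medians.

Confidence intervals are β̂ ± 1.96·se throughout; p-values are two-sided
normal, floored at 10⁻³⁰⁰ so downstream step-up adjustment (which requires
p ∈ (0, 1]) is always well-defined.

### Sensitivity analyses

* **Cochran's Q** — Q = Σⱼ wⱼ(θ̂ⱼ − β̂_IVW)² with ratio weights
  wⱼ = β̂²_Xj/se²_Yj, referred to χ²(J−1). Its null presumes negligible
  exposure measurement error (NOME), which holds for the strong instruments
  the p < 5×10⁻⁶ screen admits.
* **Egger intercept test** — two-sided normal z-test of the intercept; a
  rejection indicates directional pleiotropy.
* **MR-PRESSO** — observed statistic RSS = Σⱼ wⱼ(β̂_Yj − β̂₍₋ⱼ₎β̂_Xj)² with
  wⱼ = 1/se²_Yj and leave-one-out IVW slopes β̂₍₋ⱼ₎. The null distribution
  comes from parametric simulations β*_X ~ N(β̂_X, se_X),
  β*_Y ~ N(β̂₍₋ⱼ₎β̂_X, se_Y) with the statistic recomputed per draw; the
  global p uses add-one smoothing, so p ≥ 1/(sims+1). Per-instrument
  residuals are compared with their own simulated distributions and
  Bonferroni-corrected across the J instruments; flagged instruments are
  removed before the seven models are fitted. Defaults: 1000 simulations,
  outlier α = 0.05. Note the arithmetic constraint J/(sims+1) < α: at J = 30
  fewer than ~600 simulations make outlier flagging impossible. The
  distortion test is intentionally out of scope — the pipeline uses
  MR-PRESSO only to exclude pleiotropic instruments.

## Instrument filtration

The six steps run in order, each counting its removals into a provenance
record (initial = final + Σ drops is enforced):

1. exposure association p < `p_instrument` (5×10⁻⁶, the study's screening
   threshold);
2. greedy clumping by ascending p within `clump_kb` (default 10,000 kb) at
   r² < `clump_r2` (default 0.001); without an LD table, within-window pairs
   count as r² = 1 (distance clumping);
3. removal of variants associated with ≥ 2 exposure traits of the same
   analysis group at `p_cross_trait` (defaults to `p_instrument`) — scope is
   the group's exposures, since the filters are defined per analysis;
4. removal of variants associated with any registered confounder trait at
   `p_confounder` (10⁻⁵); the confounder list is a pluggable registry class,
   empty by default, because no canonical list exists;
5. removal of variants associated with the outcome at `p_outcome`
   (genome-wide 5×10⁻⁸);
6. harmonization: allele swaps negate the outcome beta, strand complements
   (A↔T, C↔G) are resolved, palindromic variants are oriented by allele
   frequency and dropped when either frequency lies in 0.5 ± 0.08, and
   unresolvable allele pairs are dropped. Exposure effects are never
   altered.

Pairs with fewer than `min_ivs` = 3 surviving instruments are skipped with a
reason code; 3 is the smallest count supporting the median and mode
estimators.

## Study orchestration

Groups run in the order A_forward, A_reverse, B_forward, B_reverse, C.
Group C pairs are cell/protein couples whose members are each main-model
significant (raw p < 0.05, either direction) with the same sarcopenia trait;
each couple runs in both directions, and reciprocal significant edges are
both retained. The B-H family is, by default, all main-model p-values of one
analysis group for one outcome trait (`per_outcome`); `per_group` and
`global` families are selectable. The per-outcome family is the narrowest
defensible choice for a screening design in which each outcome's result set
is reported separately.

## Network construction

Edges point exposure → outcome and carry sign(β̂), β̂, p, FDR and the source
group. Per-outcome maps contain every immune ↔ focal-trait edge passing the
threshold plus the group-C cell↔protein edges touching the retained immune
traits. The comprehensive map is the union of the per-outcome FDR maps with
immune nodes linked to fewer than two distinct sarcopenia traits removed —
unless they lie on a directed path between a retained immune node and a
sarcopenia trait (the pathway-contribution exemption, on by default; a
strict variant is selectable). The final map iteratively removes immune
nodes with total degree < 2 *or* no direct sarcopenia edge until a fixed
point. Both removal conditions are antitone (removing a node only lowers
degrees and never creates sarcopenia links), so the fixed point is unique
and order-independent; the tests verify this by randomized-order pruning.
The single-trait omission is applied after group-C edges are merged.

## Centrality and rank-sum consensus

The twelve algorithms are computed on the undirected simple projection of
the causal map (reciprocal edge pairs collapse), because the clique-based
measures are undefined on digraphs. Constants follow the algorithms'
original definitions, none being dictated elsewhere: DMNC ε = 1.7; EPC
K = 1000 percolations at edge-retention threshold 0.5; BottleNeck subtree
fraction 1/4 with lowest-node-id BFS-parent tie-breaking. Closeness uses the
harmonic form so disconnected maps are well-defined; Radiality normalizes
within connected components; EcCentricity is ranked like every other score
(higher = more central) with an inversion option, since either convention is
found in hub-detection practice. Stress and Betweenness share a BFS
path-counting pass (Brandes-style σ counts) and are checked against
exhaustive path enumeration on small graphs.

Within each algorithm, nodes are ranked so the highest score receives rank
n (ties averaged); the rank sum across algorithms orders the candidates,
ties broken by node id. By default only immune traits are ranked — the
consensus is a hub score *for immunity traits*; sarcopenia nodes can be
included via the node-subset argument.

## Synthetic-data generator

The generator emulates a two-sample summary-statistics study with known
truth. Each trait owns `m_snps` instruments whose direct effects are drawn
N(0, h²/m) and oriented positive — the effect allele is defined as the
trait-increasing allele, a pure relabeling that fixes the sign convention.
(Without a sign convention, directional pleiotropy would cancel in IVW in
expectation and the directional-bias regime could not exist.) Marginal
effects propagate through the causal DAG by path algebra: with direct-effect
matrix A, total effects are (I − A)⁻¹, the sum over directed paths of edge
products. Observed effects add independent per-trait noise with
se = (2·EAF(1−EAF)·N)^(−1/2), EAF ~ U(0.05, 0.95), and two-sided normal
p-values.

Contamination controls: a `pleiotropy_frac` share of instruments gains a
direct effect on one randomly chosen other trait (a graph descendant when
one exists, otherwise any other trait), drawn with scale
`pleiotropy_scale`·√(h²/m) — 0.3 by default, i.e. pleiotropic effects ~30%
of the typical instrument effect, a moderate-contamination regime — with
mean zero (balanced) or one pleiotropy-scale positive (directional).
An `outlier_frac` share gains a direct effect of ±10·√(h²/m), gross
outliers at ten times the instrument scale. `n_shared_snps` variants
instrument two traits at once, exercising the cross-trait filter.

Randomness is keyed per (trait) for instrument definitions and per (trait,
source-trait block) for observation noise, so a given seed is byte-stable
and appending traits never perturbs existing draws. Because exposure and
outcome noise come from different streams, the two-sample (no overlap)
regime holds exactly.

**The default scenario** (`default_scenario`) is the desk-scale analogue of
the full design: 20 cell traits, 8 protein traits, 2 sarcopenia outcomes,
and 12 true edges — 3 cell→outcome, 3 protein→outcome, 4 cell→protein and
2 reverse outcome→cell edges — with effect magnitudes 0.15–0.4,
40 instruments per trait, h² = 0.25, N = 200,000, 5% balanced pleiotropy,
2% outliers and 5 shared instruments. Evaluation against the generator uses
the *total-effect* pairs ((I − A)⁻¹ off-diagonal), not just direct edges:
MR estimates total effects, so an exposure upstream of a mediator truly
causes the downstream trait.

What the generator does **not** emulate: linkage disequilibrium beyond the
shared-instrument device (real clumping decisions are approximated by the
distance rule), sample overlap between exposure and outcome GWAS, winner's
curse from discovery-stage selection, binary-trait liability scales,
population stratification, and allele-frequency differences between
cohorts. Passing tests therefore establish the correctness and calibration
of the estimators and rules under clean two-sample asymptotics, not
robustness to those real-data artifacts.

## Problem sizes used in the validation runs

The validation suite and `scripts/acceptance.py` use: 1000 replicates of a
30-instrument null universe (N = 100,000) for RE-IVW type-I error; 200
replicates of a 50-instrument single-edge universe (θ = 0.3) for parameter
recovery, and another 200 with 30% directional pleiotropy for the
median-vs-IVW robustness contrast (the single-edge recovery runs apply the
selection, clumping and harmonization steps; the outcome-association screen
is bypassed there because with a strong true effect it removes *valid*
instruments by construction); 100 replicates with two 10× outliers among 30
instruments (1000 simulations each) for MR-PRESSO power plus 300 null
replicates (200 simulations each) for its calibration; 100 random toy
networks for pruning confluence; and one full default-scenario run
(~300 analysed pairs, ~1000 model fits) for end-to-end recall/precision.
The whole acceptance run completes in roughly half a minute on one CPU.

## Known limitations

* Group C couples are formed from raw-p significance of the main model
  only, mirroring the screening design; couples significant only under
  other estimators are not explored.
* The robust IVW sandwich variance is first-order; at very small J it can
  be optimistic. The minimum-instrument rule (J ≥ 3, J ≥ 4 for MR-PRESSO)
  bounds but does not remove this.
* BottleNeck's deterministic lowest-id tie-break makes its score depend on
  node labels when shortest-path trees are ambiguous (e.g. even cycles);
  any deterministic tie-break shares this property.
* FDR families are computed per estimation method; cross-method selection
  (e.g. "significant under any model") is not corrected for.
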