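# Methods

This note documents the model, the numerical choices and the validation
design of `stoichcorr`, in the package's own terms.

## The statistic

For two disjoint metabolite subsets U_p, U_q of cardinality at most two,
the stoichiometric correlation is the maximum Pearson correlation between
f = Σ βᵢ log xᵢ (i ∈ U_p) and g = Σ ηⱼ log xⱼ (j ∈ U_q) over integer
weights in {1, …, I_max}, default I_max = 4. The rationale is that under
mass action kinetics the log of a reaction rate is exactly such a weighted
sum of log-concentrations of its substrate complex, with the weights being
stoichiometric coefficients; coupled reaction rates (constant rate ratio
across the sampled states) therefore appear as stoichiometric correlations
of 1 between the corresponding substrate sets. Both sides are
log-transformed, including singleton sides — the statistic is a
correlation between log-linear forms throughout, which also makes the
pair category coincide with plain Pearson correlation of log-profiles.

The maximization is of the *signed* correlation. Negative values are
retained in the records (they are informative diagnostics) but can never
pass the positive significance thresholds.

### Search space and tie-breaking

Pearson correlation is invariant to positive affine maps per side, so
within a side only the weight *ratio* matters. The engine therefore
enumerates coprime tuples only: `(1,)` for a singleton side and the 11
coprime (a, b) with 1 ≤ a, b ≤ 4 for a two-member side; this provably
yields the same maximum as the exhaustive 4² × 4² grid (verified against a
brute-force oracle in the tests). When several weight assignments tie
within a relative tolerance of 1e-12, the assignment with the smallest
Euclidean norm ‖(β, η)‖ of the concatenated weight vector is reported —
the minimal-magnitude representative of the optimum — with lexicographic
order on (β, η) as a final, deterministic tie-break. All enumeration
orders are fixed, so results are bit-stable across runs and worker counts.

### Hypothesis family and counting unit

Every canonical split is a separate hypothesis: C(n,2) pairs, 3·C(n,3)
triplet splits (each unordered triple partitions three ways into pair vs
singleton) and 3·C(n,4) quadruple splits (three pair-vs-pair partitions),
e.g. 14,706 hypotheses for n = 19. Canonical form: members ascending
within a side, min(side A) < min(side B). This counting unit is used both
for the reported category counts and for multiple-testing correction, and
is recorded in output provenance.

## Significance

The default p-value is the classical two-sided correlation test,
t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom. For maximized
statistics this ignores selection over the weight grid, so a permutation
alternative is provided: the sample order of side B alone is permuted and
the full maximization is repeated per permutation,
p = (1 + #{r_b ≥ r_obs}) / (B + 1). The permutation null is verified to be
uniform under independence (Kolmogorov–Smirnov over 200 seeded runs).
Benjamini–Hochberg step-up correction (via statsmodels) is applied jointly
across all splits of one run — a conservative family choice, recorded in
provenance. Threshold comparisons are inclusive (r ≥ τ, p_adj ≤ α).

Splits need at least 5 usable samples; with the `drop-sample` missing-value
policy each split uses its complete cases and thin splits are skipped and
logged. The default policy for nonpositive or missing abundances is a hard
error, so silent distortion of a log-scale analysis is impossible; an
`offset` policy (add a recorded positive constant) is available for tables
with true zeros.

## Kinetic simulation

Networks are reaction lists with non-negative integer stoichiometries;
dx/dt = N·v(x) is integrated with LSODA at rtol 1e-8 / atol 1e-10.
Supported laws: irreversible and reversible mass action, and reversible
convenience (Michaelis–Menten) kinetics, which for 1:1 reactions reduces
exactly to the textbook reversible uni-uni form
(Vf·s/KmS − Vr·p/KmP)/(1 + s/KmS + p/KmP) and generalizes it for the one
bi-substrate reaction of the TCA fixture. Steady states are accepted at
‖dx/dt‖∞ ≤ 1e-9·(1 + ‖x‖∞), with the integration horizon doubled up to 5
times before a draw is excluded (excluded draws are logged and the
ensemble continues). Negative solver excursions are clipped at zero and
logged when below −1e-9. Conserved moieties are computed as the exact
rational left null space of N and checked to drift by < 1e-8 relative
along trajectories.

Enzyme action is modeled by expanding a flagged reaction into the three
elementary mass-action steps binding / unbinding / catalysis with defaults
k_on = k_off = 100, k_cat = 1 — chosen so that with total enzyme well
below substrate the system sits in the quasi-steady-state regime, where
the expanded flux must match Vmax·s/(Km + s) with Vmax = k_cat·E_tot,
Km = (k_off + k_cat)/k_on; the tests assert agreement within 2%.

### Fixtures

* **Toy cycle** — S1 + S2 →(k1) S3 →(k2) S4 →(k3) S1 + S2 with
  k = (1, 2, 1.5). A four-species single loop whose product complex of the
  closing reaction mirrors the substrate complex of the first, making the
  network mass-conserving with a positive, globally stable steady state in
  every stoichiometric compatibility class (it is a deficiency-zero,
  weakly reversible network). A variant with product complex 2S1 + S2 was
  considered and rejected: its S1 and S2 balances conflict, so it admits
  no positive steady state. In the shipped fixture the proportionality of
  x1 and x2 holds only on the invariant set x1 = x2 (their difference is
  conserved); the {S1, S2} vs {S4} coupling k1·x1·x2 = k3·x4 holds at
  every steady state and is the worked example throughout.
* **Mini TCA loop** (`fixture_tca_mini`) — 11 metabolites (acetyl-CoA,
  oxaloacetate, citrate, cis-aconitate, isocitrate, oxalosuccinate,
  2-oxoglutarate, succinyl-CoA, succinate, fumarate, malate), 10 reactions
  forming a single loop with exactly one bi-substrate reaction
  (accoa + oaa → cit) closed by mal → oaa + accoa. Three kinetic variants
  over the identical metabolite set: irreversible mass action with rate
  constants 0.6–1.4 (varied so no two reactions are numerically
  interchangeable), the same loop with every reaction enzyme-expanded, and
  reversible Michaelis–Menten with Vf equal to the mass-action constants,
  Vr = 0.3·Vf and all Km = 1. The parameters are package defaults — the
  fixture emulates the *shape* of a published-model comparison, not any
  published parameterization — so the relative ordering of correlation
  counts between variants is reported, not asserted.

Default ensemble protocol: initial concentrations drawn uniformly from
(0.1, 10) per metabolite (enzymes (0.05, 0.5), complexes (0.01, 0.1)),
10 repetitions, time courses over 0–1280 minutes sampled at t = 0 plus 20
log-spaced points — log-spacing because the transient dynamics that
distinguish the kinetic variants are concentrated at early times and no
canonical list of sampling times exists. All draws are seeded.

## Synthetic benchmark

Background metabolites are i.i.d. log-normal with unit log-variance — the
multiplicative structure mass-action dynamics induces — and each planted
coupling constructs the designated dependent member of side B from
η·log x_B = β·log x_A + ε with Gaussian ε on the log scale (sd 0.01 by
default; 12 metabolites, 50 samples, 5 planted quadruples with distinct
dependents). At zero noise the planted splits are recovered exactly
(r = 1, planted coefficients); the suite asserts ≥ 95% recovery with
correct coefficients at τ = 0.95, α = 0.05 averaged over 20 seeds, recall
monotone along a 0.3 → 0.1 → 0.01 noise ladder, and false discoveries
below the 0.05 budget with no plants.

What the generator does *not* emulate: real metabolomics covariance
(pathway-driven correlation among "background" metabolites), measurement
heteroscedasticity, missingness patterns, or replicate structure. Passing
these tests therefore demonstrates correctness of the search, the
statistics and the pipeline — not field performance on any particular
biological dataset.

## Known limitations

* The analytic p-value understates selection over the weight grid; use
  `pvalue_method="permutation"` when calibrated per-split p-values matter
  (it is B times slower).
* Incidental near-couplings are expected by construction: a planted
  quadruple relation also elevates correlations of its sub-splits, so
  precision against a planted-truth list is not a meaningful error rate.
* The quadruple stage is O(n⁴) splits; n ≈ 50 metabolites
  (≈ 700k hypotheses) is the practical desk-scale limit, mitigated by
  `n_jobs` (deterministic regardless of worker count).
* The model-file format is a minimal structured text schema; SBML import
  and stochastic simulation are out of scope.
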