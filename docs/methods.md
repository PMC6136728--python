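# Methods

## Binding heat model

The deterministic model treats the calorimeter as a perfusion cell of
fixed active volume V0: each injection of volume v_n displaces an equal
volume of the current cell contents. The cumulative dilution factor is
d_n = Π_{i≤n} (1 − v_i/V0), so after n injections the total titrand
concentration is [R]0·d_n and the total titrant concentration
[L]s·(1 − d_n). The 1:1 complex concentration c_n is the physical root
of the mass-action quadratic,

c_n = ½ [ S − sqrt(S² − 4·R_n·L_n) ],  S = R_n + L_n + 1/K_a,

with K_a = exp(−ΔG/RT), R = 1.9872×10⁻³ kcal/(mol·K). The heat of
injection n is the enthalpy times the change in moles of complex inside
the cell (complex carried out with the displaced volume evolved its heat
before leaving), plus a constant per-injection offset:

q*_n = V0·ΔH·10³·( c_n − c_{n−1}·(1 − v_n/V0) ) + ΔH0,  c_0 = 0.

Internally heats are in cal, molar energies in kcal/mol, volumes in L,
concentrations in mol/L; conversions (µcal, mM, µL) happen only at the
I/O boundary. The displaced-volume convention is the default; the
continuous-overflow alternative d_n = exp(−ΣV/V0) is available via
`dilution_model="exponential"`. The two were checked against each other
(they agree to ~2% for v ≪ V0 injections) and the displaced-volume model
against linearity-in-ΔH and tight-binding limits: for K_a → 10¹⁵ with a
large titrant excess the total evolved heat equals ΔH times the receptor
equivalents to within v₁/V0.

## Probability model

Likelihood: q_n ~ N(q*_n(θ), σ²), iid across injections (one σ per
experiment, appropriate when all injections integrate the same number of
power readings). Priors:

* ΔG ~ Uniform(−40, 40) kcal/mol; ΔH ~ Uniform(−100, 100) kcal/mol.
* ΔH0 ~ Uniform(q_min − Δq, q_max + Δq) where q_min/q_max/Δq are the
  minimum, maximum and range of the *observed* heats, in cal.
* Concentrations: three selectable models. **general** — both [L]s and
  [R]0 lognormal with mean equal to the stated value and a 10%
  coefficient of variation; **flat-r0** — [R]0 uniform on
  (stated/10, 10·stated) (unknown titrand purity/activity), [L]s
  lognormal 10%; **comparison** — [R]0 uniform and [L]s lognormal with
  CV 0.1%, mimicking the fixed-titrant assumption of the standard
  least-squares analysis.
* σ: Jeffreys p(σ) ∝ 1/σ, made proper by restricting
  ln σ ∈ (ln(Δq·10⁻⁴), ln(Δq·10)). The sampler works on the coordinate
  ln σ, on which this prior is flat, so no Jacobian term is needed.

The lognormal parameterisation is deliberately the *mean/CV* convention:
the concentration itself is lognormal with mean = stated and SD =
CV·stated (log-scale parameters µ = ln m − s²/2, s² = ln(1 + CV²)). The
simulator draws true concentrations from exactly the same law, which is
what makes simulation-based calibration of credible intervals a
meaningful self-consistency check.

## Sampler

Sequential-Gibbs Metropolis-Hastings on
x = (ΔG, ΔH, ΔH0, [L]s, [R]0, ln σ): one coordinate is perturbed per
trial move with a normal proposal and accepted by the Metropolis
criterion; coordinates cycle in fixed order; a state is stored every
`thin` trial moves (default 2000) until `n_stored_samples` (default
5000) are kept. Default initialisation: concentrations at their stated
values, the three energies at zero, σ at the SD of the last four heats
(floored at 1 µcal equivalents when degenerate). Default proposal SDs:
1 kcal/mol for ΔG and ΔH, 1 µcal for ΔH0 (its natural instrument unit),
the stated concentration for each concentration, 0.5 for ln σ.

Two optional accelerations matter when chains are shortened below the
full 10⁷-move protocol:

* `start="map"` — a multi-start Nelder-Mead optimisation of the log
  posterior provides the initial state. The zero-energy start describes
  no binding, so a short chain spends a large fraction of its stored
  samples finding the binding mode; the warm start removes that
  transient.
* `adapt=True` — proposal scales are tuned during the discarded burn-in
  phase by the standard acceptance-rate rule (×0.9 below 20%
  acceptance, ×1.1 above 50%, etc., per 100 trials) and frozen before
  storage begins. This matters because ΔH, [L]s and [R]0 are correlated
  at ρ ≈ 0.99: fixed stated-value-sized proposals accept only ~4% of
  concentration moves and cannot traverse the ridge in a shortened
  chain, which collapses the ΔH marginal. (Widely used Metropolis
  implementations tune the same way by default.)

The inner loop is compiled with numba (~0.4 µs per trial move); a pure
Python reference path implements the identical update rule and is
checked against the compiled log-posterior to 10⁻¹² relative. Both
backends are deterministic under a seed but consume different RNG
streams. Every run records per-coordinate acceptance rates; a run in
which nothing is ever accepted raises a warning.

## Summaries and comparisons

* **Shortest credible intervals**: among all windows of ⌈level·n⌉
  consecutive order statistics, the narrowest (ties go to the lower
  window). The ceiling makes the interval conservative; the shortest
  window also makes it robust to a small fraction of far-outlying
  draws. Verified against an exhaustive window scan and against the
  analytic normal HDI.
* **TΔS = ΔH − ΔG** is computed per draw before summarising.
* **Correlation matrices** are Pearson correlations over the six stored
  coordinates with bootstrap SDs from resampling stored states with
  replacement (post-thinning states are treated as independent);
  zero-variance columns yield NaN, never silent zeros.
* **Convergence report**: running 95%-interval bounds per chain; a
  parameter is flagged when the across-chain SD of either final bound
  exceeds 5% of the mean interval length.
* **NLS comparator**: least squares over (ln K_a, ΔH, n, ΔH0) with
  [L]s fixed at its stated value and effective cell concentration
  n·[R]0stated — the standard treatment in which the free stoichiometry
  absorbs titrand concentration error. Standard errors come from the
  residual-variance-scaled inverse Gauss-Newton normal matrix; K_a's SE
  is delta-method back-transformed from ln K_a. ΔH0 is fitted as a
  fourth parameter rather than fixed. Confidence intervals are
  estimate ± z·SE.
* **Coverage curves**: fraction of experiments whose interval contains
  the reference value per stated level, bootstrapped over experiments.
  For simulations the reference is the true value; for replicate
  experiments the median of per-experiment estimates.
* **KL divergence** between (ΔG, ΔH) sample clouds: Gaussian KDEs
  (default bandwidth 0.03 kcal/mol) for both densities; the integral is
  the Monte-Carlo average of ln p̂1 − ln p̂2 over the first cloud
  (dimension-robust, no quadrature grid). ln p̂1 is evaluated
  leave-one-out — the self-kernel term is subtracted analytically —
  because scoring a KDE at its own training points biases the
  divergence upward. Identical inputs short-circuit to exactly zero.
  Underflowing p̂2 is clipped with a warning. The estimator was checked
  against the closed-form Gaussian KL at posterior-like cloud widths
  (0.1–0.15 kcal/mol), where it is accurate to a few percent; for
  clouds much wider or narrower than the bandwidth the intrinsic
  KDE bias grows, so the bandwidth should be scaled with the posterior
  width if the method is applied outside that regime.

## Synthetic data

`SimulationSpec` defaults define the validation study: ΔG = −10,
ΔH = −5 kcal/mol, ΔH0 = 0.5 µcal, stated 0.1 mM (cell) / 1 mM
(syringe), 10% lognormal concentration error, σ = 1 µcal Gaussian heat
noise, 24 injections, 50 replicate curves. The injection schedule is the
standard VP-ITC metal:chelator protocol (2 µL then 23 × 12 µL) with a
1.43 mL cell at 298.15 K — the cell volume is an instrument nominal, set
in `mgedta_design` and overridable. Each replicate draws fresh true
concentrations and noise from one seeded stream.

What the generator does *not* emulate: baseline drift and integration
error (heats are assumed correctly integrated upstream), the
first-injection anomaly (an `exclude_first` flag drops injection 1 from
the likelihood but the simulator never produces anomalous first
injections), injection-duration-dependent noise, and titrant impurity
beyond a concentration scale factor. Passing calibration tests on these
simulations therefore demonstrates internal consistency of model +
sampler + intervals under the stated error model, not robustness to the
artefacts above.

A note on these study conditions: at ΔG = −10 kcal/mol and
[R]0 = 0.1 mM the Wiseman parameter c = K_a·[R]0 is ≈ 2000, well into
the tight-binding regime, and for some concentration draws the
likelihood develops a wide, nearly flat plateau toward more negative ΔG
(a sharper step fits almost as well). That plateau is genuine posterior
mass: per-curve posterior *means* of ΔG are occasionally pulled well
below −10 while medians stay put. Cross-curve aggregates therefore use
the median over curves (of per-curve medians, and of per-curve means),
the aggregation that is robust to these heavy-tailed replicates; the
shortest-interval construction is likewise robust to the ≤5% of draws
in the plateau.

## Problem sizes in tests and the acceptance script

The full protocol (5000 stored × 2000 thinning per curve, no burn-in)
costs ~10⁷ moves per curve. The package's validation runs scale this
down while keeping estimates converged (checked against longer chains):

* 50-curve study (parameter recovery + interval calibration): 2000
  stored × 400 thinning per curve, 250-stored-equivalents burn-in, MAP
  start, adaptation on.
* Five-chain reproducibility: 5000 stored × 2000 thinning (the protocol
  thinning) in the test suite, 4000 in the acceptance script, five seeds.
* Mg:EDTA-like correlation structure: one curve at ΔG = −8.2,
  ΔH = −2.25 kcal/mol (c ≈ 100, the regime of the metal:chelator
  experiments), 2000 stored × 1000 thinning.

With these settings the 50-curve credible intervals are calibrated
within binomial 95% bands at every level from 10% to 95%, and the
five-chain 95%-interval bound SD stays below 5% of the interval length.

## Known limitations

* Single-site 1:1 binding only; no competitive, multi-site or
  cooperative models, no kinetics, no proton-linkage corrections.
* One experiment per posterior: no hierarchical sharing of
  concentration errors across titrations, and the concentration CVs are
  fixed hyper-parameters, not inferred.
* The Gibbs sampler is adequate but not efficient for the ρ ≈ 0.99
  concentration-enthalpy ridge; at full protocol cost it matches the
  shortened adaptive runs, but gradient-based samplers would traverse
  the ridge far more cheaply.
* Raw instrument power traces are out of scope: inputs are integrated
  injection heats (e.g. from NITPIC) in plain CSV.
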