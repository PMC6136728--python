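# itcfit

Bayesian and least-squares analysis of isothermal titration calorimetry
(ITC) binding data.

ITC measures the heat evolved as a titrant (usually a small-molecule
ligand) is injected stepwise into a titrand (usually a macromolecule),
and is the only technique that yields both the enthalpy ΔH and the free
energy ΔG — hence the entropy, TΔS = ΔH − ΔG — of non-covalent
association from a single experiment. The standard analysis (nonlinear
least squares on the 1:1 Wiseman isotherm) treats the syringe
concentration as exactly known and therefore reports uncertainties that
are far too small, especially for ΔH: titrant concentration errors of
~10% are common and propagate almost entirely into the enthalpy.

`itcfit` instead samples the full posterior

p(θ | q₁…q_N) ∝ p(q₁…q_N | θ) · p(θ),  θ = (ΔG, ΔH, ΔH₀, [L]ₛ, [R]₀, σ)

where q_n are the integrated injection heats, ΔH₀ is a per-injection
dilution/stirring offset, [L]ₛ and [R]₀ are the *true* syringe and cell
concentrations (nuisance parameters with lognormal priors centred on the
stated values, 10% relative uncertainty by default), and σ is the heat
noise scale (Jeffreys prior). The likelihood is Gaussian,
q_n ~ N(q*_n(θ), σ²), with q*_n the deterministic 1:1 binding heat in a
perfusion cell with displaced-volume dilution. Sampling is sequential-
Gibbs Metropolis-Hastings; interval estimates are *shortest* credible
intervals (highest-density style). A frequentist comparator (NLS fit of
K_a, ΔH, stoichiometry n, ΔH₀ with normal-theory confidence intervals),
coverage-calibration curves, and a KDE-based Kullback-Leibler divergence
between (ΔG, ΔH) posteriors round out the toolkit.

## Worked example

Simulate one standard metal:chelator-style experiment (24 injections,
true ΔG = −10, ΔH = −5 kcal/mol, ΔH₀ = 0.5 µcal, stated concentrations
0.1 mM cell / 1 mM syringe perturbed by 10% lognormal error, 1 µcal
Gaussian heat noise) and fit it both ways:

```python
import itcfit as it

design = it.mgedta_design()                      # VP-ITC: 2 µL + 23 × 12 µL, 1.43 mL cell
spec = it.SimulationSpec(seed=11)                # defaults are the standard conditions
heats, truth = it.simulate_experiment(spec, design)
# this draw has true [L]s = 1.140 mM, [R]0 = 0.0998 mM

model = it.BayesianITC(heats, design, prior_model="general")
res = model.fit(n_samples=2000, thin=1000, seed=42,
                start="map", burn_in=300, adapt=True)
print(res.summary(levels=(0.95,)))
```

```
             median      mean   lower_95  upper_95
parameter
dG           -10.04    -10.04      -10.3    -9.809
dH            -5.43    -5.444     -6.175     -4.66
dH0       2.437e-07 2.358e-07 -3.282e-07 8.189e-07
Ls         0.001046  0.001048  0.0009078  0.001197
R0        9.151e-05 9.166e-05  7.812e-05 0.0001034
ln_sigma     -13.87    -13.85     -14.15    -13.51
TdS           4.629       4.6      3.854     5.261
```

The 95% credible interval for ΔG, (−10.30, −9.81) kcal/mol, contains the
true −10; the ΔH interval (−6.18, −4.66) is ~1.5 kcal/mol wide because a
single titration cannot pin the enthalpy down better than the
concentrations are known. Compare the standard analysis:

```python
nls = it.ITCLeastSquares(heats, design).fit()
print(nls.conf_int("dH", 0.95))   # (-5.753, -5.609) kcal/mol
```

The least-squares 95% interval for ΔH is only 0.14 kcal/mol wide and
*excludes* the true value −5 — the overconfidence the Bayesian treatment
corrects. Concentrations are in mol/L, energies in kcal/mol, heats in
cal; `units="ucal"` converts on input.

A CLI wraps the same pipeline:

```bash
itc simulate --seed 3 --n-replicates 50 --out-dir sim/
itc fit-bayes sim/curve_000.csv --config sim/manifest.yaml --units ucal \
    --prior-model general --samples 5000 --thin 2000 --seed 1 --chains 5
itc summarize curve_000_trace_0.csv
itc compare curve_*_trace_0.csv --parameter dG
```

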