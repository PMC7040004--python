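# halodyn

Quantitative analysis of low-salt stress and recovery in extreme halophilic
archaea, for biophysicists and microbial physiologists who work with
elastic incoherent neutron scattering (EINS) and classical stress/viability
assays.

Extreme halophiles such as *Halobacterium salinarum* balance molar external
salt with molar intracellular KCl; their proteome *requires* high salt to
stay folded. When the environmental salt drops, proteins soften and unfold,
respiration collapses, membranes fail — yet a subpopulation survives and
regrows once physiological salt returns. `halodyn` implements the complete
measurement chain behind that story:

* **Proteome resilience from elastic neutron scans.** In the Gaussian
  approximation the normalized elastic intensity falls off as
  `I(Q,T) ∝ exp(−Q²⟨u²(T)⟩/6)`, so a weighted fit of `ln I` against `Q²`
  over a low-Q window yields the mean square displacement ⟨u²⟩ (Å²) at each
  temperature. For a quasi-harmonic proteome ⟨u²⟩ grows linearly with
  temperature and the mean effective force constant (the structural
  resilience) is `⟨k'⟩ = 2 k_B / (d⟨u²⟩/dT)` in N/m — softer, more
  unfolded ensembles have steeper MSD slopes and lower ⟨k'⟩. The package
  reduces raw scan triplets (sample, empty cell, vanadium) with monitor
  scaling, transmission-weighted empty-cell subtraction and vanadium
  normalization, propagating counting errors throughout.
* **Phenotype kinetics.** Survival under stress is fitted with the
  two-subpopulation death model
  `n(t) = n0·[f·e^(−k_fast·t) + (1−f)·e^(−k_slow·t)]` (AIC-selected against
  a single exponential), regrowth lag with a flat-then-exponential
  breakpoint model with bootstrap confidence intervals, membrane damage
  from SYTO9/PI cytometry event tables via deterministic control-quantile
  gating, and respiration as the oxygen-depletion slope normalized to
  10⁸ cells and expressed as percent of an unstressed basal reference.
* **Synthetic data.** Every input the pipeline consumes can be generated
  with the statistical structure the estimators assume (Poisson counting
  noise, log-normal density noise, bivariate log-normal cytometry
  mixtures), so the whole chain is testable without instrument access.

## Worked example

Run the packaged stress → recovery scenario (three simulated elastic-scan
conditions plus kill-curve, lag, cytometry and respiration assays):

```bash
halodyn run --seed 1 --out demo_run
```

prints

```
halodyn pipeline report
=======================
config hash : 74dd1e1e5989abdf
seed        : 1
   control <k'> : 0.3595 ± 0.0512 N/m
 recovered <k'> : 0.3807 ± 0.0575 N/m
  stressed <k'> : 0.1794 ± 0.0132 N/m
recovered vs control : consistent at 95%
kill curve : biphasic (f=0.990, k_fast=1.98/d, k_slow=0.045/d)
recovery lag : 3.01 d (95% CI [3.00, 3.04])
gating (stressed) : PI+ fraction 0.312, Syto- fraction 0.310
respiration (stressed) : 0.625 nmol/min/1e8 cells = 25.0% of basal
respiration (recovered) : 2.25 nmol/min/1e8 cells = 90.0% of basal
```

Reading the numbers: the control condition is a single stiff population
(k' = 0.35 N/m planted); the stressed condition mixes in an equal-weight
softened subpopulation, and the apparent ⟨k'⟩ drops to about half — the
proteome has softened. The recovered condition, regenerated with control
dynamics, is statistically indistinguishable from the control
(difference within 1.96·SE). The kill curve is correctly identified as
biphasic with a ~1% tolerant plateau, the planted 3-day regrowth lag is
recovered to within an hour, the planted 30% membrane-damaged (PI+)
fraction is gated to 0.312, and respiration percentages are exact ratios
of the planted depletion slopes. Machine-readable records for every number
are in `demo_run/report.json`; the same scenario is available as a config
file at `examples/demo.yaml` (`halodyn run --config examples/demo.yaml
--out demo_run`).

The library mirrors the CLI with statsmodels-style model objects:

```python
from halodyn import DynamicsModel, InstrumentConfig, ResilienceModel, simulate_elastic_bundle

model = DynamicsModel(populations=[(1.0, 0.2, 0.5)])   # (weight, k' N/m, u2_ref Å²)
bundle = simulate_elastic_bundle(model, InstrumentConfig(), seed=0, noise=True)
results = ResilienceModel.from_bundle(bundle).fit()
print(results.force.summary())   # slope 0.0138 Å²/K -> k' = 0.200 N/m
```

Subcommands `simulate`, `reduce`, `msd`, `resilience`, `kinetics`,
`cytometry`, `respiration`, `run` and `report` operate on the plain-text
CSV dialects written by `halodyn.io` (a `#`-prefixed `key=value` metadata
block above a CSV table).

## Layout

```
src/halodyn/
  synthetic.py   generators for scans, kill/recovery curves, events, O2 traces
  reduction.py   empty-cell subtraction, vanadium normalization, error propagation
  dynamics.py    MSD extraction, force-constant model, length scales
  kinetics.py    kill-curve/lag/ratio models, gating, respiration
  io.py          CSV dialects + JSON records
  config.py      typed YAML run configuration
  pipeline.py    end-to-end scenario runner
  cli.py         click command-line interface
docs/methods.md  model assumptions, defaults, numerical choices, limitations
```
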