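# cellphenofit

A cell-line **phenotype digitizer**: fits canonical mathematical models
of cell population dynamics to time-series cell counts and turns them
into quantitative, comparable phenotype parameters — net growth rate,
birth rate, death rate, dead-cell clearance rate, carrying capacity,
doubling time — each with an uncertainty estimate.

It is written for experimental biologists analysing proliferation
assays and high-content screens (HCS): one spreadsheet in, a ranked
report of fitted models out, no modelling expertise required. Because
it fits *mechanistic* live/dead models rather than a single net-rate
regression, it can decouple **cytostatic** drug effects (suppressed
birth) from **cytotoxic** ones (increased death) — a distinction a net
growth curve alone cannot make.

## Models and statistics

Six canonical models, selected automatically from the data supplied:

* exponential — d[Live]/dt = r·[Live] (also for total counts),
* logistic — d[Live]/dt = r·(1 − [Live]/L_cap)·[Live] for confluence or
  substrate limitation,
* birth–death–clearance —
  d[Live]/dt = (b − d)·[Live],
  d[Dead]/dt = d·[Live] − c·[Dead],
  optionally with logistic limitation of birth.

Replicates are averaged per time point and models are calibrated by
Levenberg–Marquardt least squares on the weighted objective

    WSSE = Σᵢ (1/σᵢ)·(Dataᵢ − Simᵢ)²/Dataᵢ

where σᵢ is the replicate standard deviation — noisy points carry the
least weight. Competing models are ranked by MAPE and by reduced
chi-square χ²ν = WSSE/(N_data − N_parameters); parameter uncertainty is
SEMᵢ = √(χ²ν·Cov(i,i)). A model with n parameters needs n data points
to fit, n+1 to report uncertainties; two points suffice for the
exponential model. See `docs/methods.md` for the full treatment.

The package also ships a seeded synthetic HCS generator (two drug
archetypes × 5 doses × 5 replicates of live/dead counts with 10 %
multiplicative noise, ground truth serialized alongside) used to
validate that drug-dependent birth and death rates are recovered.

## Worked example

Generate a synthetic drug screen, fit the birth–death–clearance model
to every condition, and score recovery against the generator's truth:

```python
import logging; logging.disable(logging.WARNING)
from cellphenofit import (ScreenDesign, default_screen_specs, generate_screen,
                          fit_model, recovery_report, doubling_time,
                          confidence_interval)
from cellphenofit.cli import condition_series

design = ScreenDesign(noise_cv=0.10, seed=1)
dataset, truth = generate_screen(default_screen_specs(), design)

fits = {c.label: fit_model("live_dead", condition_series(c))
        for c in dataset.conditions}
errors = recovery_report(truth, fits)
print(f"mean |error|: birth {errors['birth']:.1f}%, "
      f"death {errors['death']:.1f}%, net {errors['net']:.1f}%")

fit = fits["drug_A@0.1"]
b, d = fit.estimates["birth_rate"], fit.estimates["death_rate"]
sem = (fit.sem["birth_rate"]**2 + fit.sem["death_rate"]**2) ** 0.5
lo, hi = confidence_interval(b - d, sem, 95)
print(f"drug_A@0.1: birth {b:.4f}/h, death {d:.4f}/h, "
      f"net {b-d:.4f}/h (95% CI [{lo:.4f}, {hi:.4f}])")
print(f"doubling time {doubling_time(b - d):.1f} h")
```

prints

```
mean |error|: birth 8.4%, death 6.9%, net 4.3%
drug_A@0.1: birth 0.0367/h, death 0.0105/h, net 0.0262/h (95% CI [0.0238, 0.0286])
doubling time 26.5 h
```

The three error figures say the fitted birth, death and net growth
rates land within a few percent of the rates that generated the data,
at 10 % measurement noise. The per-condition line reads off the fitted
mechanistic rates at the lowest dose of the cytostatic drug: the
population doubles roughly daily, and the confidence interval quantifies
how sharply the 5-replicate design pins the net rate down.

The same pipeline runs from a shell:

```sh
cellphenofit generate --seed 1 --outdir screen/
cellphenofit fit --input screen/screen.xlsx --outdir report/
```

`report/index.html` ranks every fitted model per condition (by both
MAPE and χ²ν), links per-model pages with parameter tables and
layperson descriptions, and includes growth-curve figures,
dose–response panels (net/birth/death vs dose), CSV/XLSX tables and a
phenotype XML record per condition.

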