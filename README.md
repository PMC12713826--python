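# hypnodense

Hypnodensity analytics for sleep staging: per-epoch sleep-stage probability
distributions from multi-scorer hypnograms, inter-scorer agreement
statistics, probability-based sleep parameters, and sleep-disordered-
breathing metrics for polysomnography (PSG) and home sleep apnea testing
(HSAT).

## The problem

Human experts score sleep in 30-second epochs using one of five AASM
stages — W, N1, N2, N3, R — even when the signals are ambiguous.  When
several scorers stage the same night independently, they disagree often,
and the disagreement compounds: the percentage of epochs on which *all* k
scorers agree decays approximately as a power law, y = a·k^b with an
exponent near −0.5, so complete agreement typically falls to ~50% once
four scorers are compared.  A single hypnogram hides all of this.

The *hypnodensity* keeps it: for each epoch, the relative vote frequency
of every stage, an epochs × stages matrix of probabilities whose rows sum
to 1.  From it one can recover a consensus hypnogram, integrate the
per-stage probability curves into sleep parameters (the stage "areas"
equal the mean of the per-scorer stage times), and quantify scoring
uncertainty itself:

* **ambiguity** `100·(1 − p_max)` per epoch,
* **continuity** `100·(1 − |Δp_max|)` across adjacent same-stage epochs,
* ambiguous-epoch fractions (`p_max ≤ 0.95`), stable NREM/REM pair
  fractions (`p_N2+p_N3 > 0.95`, `p_R > 0.95`), and a weighted NREM depth
  `100·(p_N1 + 2·p_N2 + 4·p_N3)/4`.

For HSAT, the package computes the apnea-hypopnea index per hour of
total/NREM/REM sleep, the respiratory event index per monitoring hour,
the REM-related OSA rule (AHI_NREM < 5, AHI_REM ≥ 5, ≥ 30 min REM), and
the hypoxic burden: the respiratory event-associated area under the SpO2
desaturation curve below the pre-event baseline, integrated over a
subject-specific search window anchored at each event's termination, in
%·min per hour of sleep.

A seeded synthetic-data module generates every input — Markov-chain
hypnograms, scorer panels with controllable reliability, Dirichlet
hypnodensities, and oximetry with event-coupled desaturations whose
analytic areas are returned for validation — so the entire pipeline is
testable without recordings.

## Worked example

```python
import numpy as np
from hypnodense import *
from hypnodense.simulate import *
from hypnodense.agreement import agreement_curve, fit_power_law
from hypnodense.features import hypnodensity_parameters, hypnodensity_features

truth = simulate_true_hypnogram(transition_matrix_preset(), "W", 960, seed=7)
models = [ScorerModel.from_bias(b) for b in np.linspace(0, 1, 12)]
panel = simulate_scorer_panel(truth, models, seed=8)

dens = build_hypnodensity(panel)            # 960 x 5 probability matrix
curve = agreement_curve(panel)              # complete agreement vs k
fit = fit_power_law(curve)                  # y = a * k^b
pars = hypnodensity_parameters(dens)        # probability-area parameters
feats = hypnodensity_features(dens)         # ambiguity / stability / depth
```

With those seeds this prints:

```
agreement: [100.0, 65.5, 51.3, 41.6, 34.2, 28.3, 23.5, 19.5, 16.3, 13.7, 11.5, 9.7]
power law: a=104.0  b=-0.754  R2=0.9731
TST=374.4 min  SL=1.0  SEFF=78.0%
stage min: {'N1': 67.9, 'N2': 193.0, 'N3': 50.2, 'R': 63.3}
ambiguity=21.2%  continuity=88.7%  stableNREM=13.3%  depth=50.2%
```

The agreement across this simulated 12-scorer panel decays from 100% for
a single scorer to under 10% when all twelve are compared, and the decay
is well modelled by a power law (R² = 0.97) — the hallmark behaviour of
real scorer panels, with the exponent controlled here by the scorer
confusion templates.  TST comes from integrating the sleep-stage
probability curves; the ambiguity and stability figures summarize how
equivocal the simulated scorers were.

The same operations are exposed on the shell:

```bash
hypnodense simulate --seed 7 --out-prefix study
hypnodense agreement --in study_panel.csv --out agreement.json
hypnodense features --in study_hypnodensity.csv
hypnodense sdb --events study_events.csv --oximetry study_oximetry.csv \
               --hypnogram study_sdb_hypnogram.csv
hypnodense plot --in study_hypnodensity.csv --out study.png
```

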