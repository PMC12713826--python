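# Named presets for the synthetic-data generators.
#
# Transition matrices are first-order Markov chains over the five-stage
# vocabulary in the fixed order W, N1, N2, N3, R (rows = current stage,
# columns = next stage, each row sums to 1).  They reproduce plausible
# overnight stage proportions and bout lengths for 30-s epochs, not the
# ~90-min REM cyclicity (a documented limitation of the first-order model).
#
# Confusion templates are row-stochastic matrices P(label | true stage) in
# the same stage order.  "precision" under-calls N1 and N3 (conservative
# scorer); "sensitivity" over-calls them; "typical" sits between the two
# and yields pairwise agreements near 0.76, the level reported for
# experienced human scorers.  A scorer model interpolates precision ->
# sensitivity with its sensitivity_bias.

transition_matrices:
  adult_sleep:
    stages: [W, N1, N2, N3, R]
    matrix:
      - [0.88, 0.09, 0.02, 0.00, 0.01]   # W: long wake bouts, enter sleep via N1
      - [0.12, 0.55, 0.30, 0.00, 0.03]   # N1: transitional, promotes to N2
      - [0.03, 0.04, 0.85, 0.05, 0.03]   # N2: backbone of NREM
      - [0.02, 0.01, 0.10, 0.87, 0.00]   # N3: consolidated deep sleep
      - [0.03, 0.04, 0.04, 0.00, 0.89]   # R: consolidated REM bouts

confusion_templates:
  identity:
    stages: [W, N1, N2, N3, R]
    matrix:
      - [1.00, 0.00, 0.00, 0.00, 0.00]
      - [0.00, 1.00, 0.00, 0.00, 0.00]
      - [0.00, 0.00, 1.00, 0.00, 0.00]
      - [0.00, 0.00, 0.00, 1.00, 0.00]
      - [0.00, 0.00, 0.00, 0.00, 1.00]
  typical:
    stages: [W, N1, N2, N3, R]
    matrix:
      - [0.86, 0.10, 0.02, 0.00, 0.02]   # W scored reliably
      - [0.18, 0.55, 0.24, 0.00, 0.03]   # N1 is the least reliable stage
      - [0.02, 0.10, 0.80, 0.06, 0.02]
      - [0.00, 0.01, 0.24, 0.75, 0.00]   # N3 confused with N2 (slow-wave threshold)
      - [0.03, 0.05, 0.03, 0.00, 0.89]   # R scored reliably
  precision:
    stages: [W, N1, N2, N3, R]
    matrix:
      - [0.92, 0.05, 0.02, 0.00, 0.01]
      - [0.30, 0.40, 0.27, 0.00, 0.03]   # under-calls N1 in favour of W/N2
      - [0.02, 0.06, 0.86, 0.04, 0.02]
      - [0.00, 0.01, 0.40, 0.59, 0.00]   # strict slow-wave criterion
      - [0.03, 0.04, 0.04, 0.00, 0.89]
  sensitivity:
    stages: [W, N1, N2, N3, R]
    matrix:
      - [0.78, 0.17, 0.03, 0.00, 0.02]
      - [0.08, 0.70, 0.18, 0.00, 0.04]   # over-calls N1
      - [0.02, 0.14, 0.72, 0.10, 0.02]
      - [0.00, 0.01, 0.10, 0.89, 0.00]   # lenient slow-wave criterion
      - [0.02, 0.06, 0.03, 0.00, 0.89]
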