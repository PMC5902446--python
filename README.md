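# pausekin

Kinetic analysis of transcription-initiation pausing from single-molecule
FRET trajectories — with a generative simulator of the branching kinetic
model, so every stage of the analysis can be validated by parameter
recovery.

## The problem

Bacterial RNA polymerase pauses after synthesising a 6-nt RNA (the ITC6
checkpoint). From that pause the complex branches between productive
promoter escape and a futile cycle of DNA unscrunching/scrunching. A
surface-immobilised polymerase–promoter complex reports the scrunching
state through the FRET efficiency E = I_DA/(I_DA + I_DD) of a dye pair on
the promoter: unscrunched **US** (E ≈ 0.49), partly scrunched paused
**PS** (E ≈ 0.37), fully scrunched **FS** (E ≈ 0.80).

The quantities of interest, and how this package estimates them:

- **k_ITC6** — single-exponential pause exit rate, from an MLE fit to the
  PS dwell of molecules that go US → PS → FS in a single attempt.
- **K_NTP, P_max,esc** — the NTP dependence of the probability of escaping
  the pause on the first attempt, fitted with the binding isotherm
  p(NTP) = P_max · [NTP]/([NTP] + K_NTP).
- **k1, k2, P(k1)** — two-exponential kinetics of the unscrunching/
  scrunching cycle, from an m-exponential mixture MLE
  p_t(τ) = Σ p_n k_n e^(−k_n τ) with the component count chosen by
  BIC = −2L + (2m−1) ln N and uncertainties from 1000 bootstrap refits.

The analysis chain is: trace selection (single-pair photobleaching
criteria) → FRET computation → hidden-Markov level segmentation → a step
filter keyed to the Allan deviation of the noise → mapping to calibrated
US/PS/FS levels → dwell pooling (first/last dwells removed, detection
floor handled by a left-truncated likelihood) → mixture MLE, pathway
classification, isotherm fit, transition counting, and a dwell-memory
permutation test.

Because the raw experimental recordings are not publicly deposited, the
package includes a first-class simulator (`pausekin.schemes`,
`pausekin.simulate`): exact Gillespie paths from the branching scheme,
rendered into noisy three-channel ALEX traces with photobleaching. Its
defaults are the study conditions (0.2 s frames, E noise ≈ 0.05,
k_ITC6 = 0.11 s⁻¹, K_NTP = 28 µM, P_max = 0.79, k1 = 0.15 s⁻¹,
k2 = 0.02 s⁻¹, P(k1) = 0.6). See `docs/methods.md` for the model and all
estimator details.

## Worked example

`examples/escape_isotherm.py` classifies simulated trajectories at six
NTP concentrations and fits the escape isotherm:

```
 NTP (uM)   p(first attempt)   95% CI
       1      0.045          [0.024, 0.083]  (n=200)
       5      0.115          [0.078, 0.167]  (n=200)
      10      0.210          [0.159, 0.272]  (n=200)
      30      0.445          [0.378, 0.514]  (n=200)
      80      0.545          [0.476, 0.613]  (n=200)
     500      0.760          [0.696, 0.814]  (n=200)

fitted K_NTP  =  26.9 +/- 7.1 uM   (truth 28)
fitted P_max  =  0.79 +/- 0.06      (truth 0.79)
```

The first-attempt probability is the fraction of pause-resolving molecules
that reach the fully scrunched level without returning to US; its rise and
saturation with NTP is what K_NTP (half-saturation) and P_max (plateau)
quantify. `examples/ntp_withdrawal.py` shows the complementary analysis of
molecules that keep cycling after NTP removal:

```
per-subpopulation two-exponential US dwell kinetics:
  US/PS    : k1 = 0.17 1/s, k2 = 0.021 1/s, P(k1) = 0.57  (441 dwells)
  US/PS/FS : k1 = 0.93 1/s, k2 = 0.077 1/s, P(k1) = 0.80  (2984 dwells)
```

The other examples cover trace simulation (`simulate_traces.py`),
segmentation plus dwell fitting (`segment_and_fit_dwells.py`), and the
orchestrated multi-condition pipeline (`full_pipeline.py`).

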