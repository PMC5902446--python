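# Methods

`pausekin` analyses single-molecule FRET trajectories of bacterial RNA
polymerase during initial transcription, and simulates the branching
kinetic model those trajectories are interpreted with. This note documents
the model, the estimators, the numerical choices, and what the synthetic
benchmarks do and do not establish.

## The kinetic model

A surface-immobilised polymerase–promoter complex reports the extent of
downstream-DNA scrunching through the FRET efficiency of a donor/acceptor
pair flanking the transcription bubble. Three observable levels are
calibrated: the unscrunched open complex **US** (E ≈ 0.49), the partly
scrunched paused complex holding a 6-nt RNA **PS** (E ≈ 0.37), and the
fully scrunched pause-cleared complex at 11 nt **FS** (E ≈ 0.80).

After NTP addition the complex synthesises a 6-mer almost immediately and
pauses (PS). The pause is the branch point of the model
(`schemes.build_default_scheme`):

- Pause exit is single-exponential with rate `k_itc6` (default 0.11 s⁻¹,
  the wild-type promoter / ApA value; 0.26 s⁻¹ reproduces the fast pause
  variant).
- On exit the complex escapes productively to FS with probability

      p(NTP) = P_max · [NTP] / ([NTP] + K_NTP),

  defaults `K_NTP = 28 µM`, `P_max = 0.79`; otherwise it enters a futile
  unscrunching/scrunching cycle between US and PS.
- Each cycling observable is backed by two hidden substates with exit
  rates `k1 = 0.15 s⁻¹` (fast) and `k2 = 0.02 s⁻¹` (slow), entered with
  probability `P(k1) = 0.6` / `1 − P(k1)` independently at each visit.
  This is the minimal memory-less mechanism that produces the observed
  two-exponential dwell distributions; because the substate is re-drawn at
  every visit, successive dwell times are uncorrelated by construction.
- Every cycling PS exit makes a fresh escape attempt with the same
  p(NTP). The microscopic alternative — a distinct re-entered pause with
  its own single-exponential rate — would make cycling PS dwells
  single-exponential, contradicting the two-exponential dwells the model
  must reproduce, so it is not used.
- FS is absorbing (promoter escape ends the observation); departure of
  the complex from the field of view is not modelled.

`build_withdrawal_scheme` provides the NTP-withdrawal populations: a
US/PS-only cycler (k1 = 0.16, k2 = 0.02, P = 0.57) and a US/PS/FS cycler
roughly six-fold faster (k1 = 0.96, k2 = 0.07, P = 0.79) whose US↔FS
exchange is four-fold more frequent than US↔PS, with PS↔FS rare.

## Trace synthesis

`simulate.gillespie_simulate` draws exact continuous-time Markov paths
(exponential dwells, successors proportional to outgoing rates).
`render_trace` converts a path into three ALEX channels on a 0.2 s frame
grid (100 ms per excitation; 0.08 s frames are supported):

- Each frame shows the FRET level of the state occupying the majority of
  the frame. Events shorter than half a frame are therefore invisible —
  this detection floor is a deliberate property of the emulation, and the
  dwell-time likelihood accounts for it (below).
- Expected intensities are I_DA = total·E, I_DD = total·(1−E),
  I_AA = total, plus independent zero-mean Gaussian noise per channel.
  The default channel noise (SD 14 at total 200) gives a per-frame E SD
  of ≈ 0.05 at mid-range E, matching the working regime of the analysis;
  `noise_sd_for_e_sd` converts a target E SD into a channel SD by
  first-order error propagation.
- Donor and acceptor bleach once, at exponential times (default rate
  0.002 s⁻¹ each, i.e. ~500 s mean — records are bleach-limited on the
  10-minute acquisitions). After acceptor bleach the FRET channel drops
  to noise and all donor-excitation light appears in I_DD; after donor
  bleach both donor-excitation channels drop to noise. The full hidden
  path is retained alongside the trace for ground-truth scoring.
- `simulate_experiment` prepends a 20 s pre-injection US baseline
  (the open complex awaiting NTPs) and can hold a chosen fraction of
  molecules inactive.

What the generator does **not** emulate: blinking photophysics,
γ-factor/cross-talk distortions of E, intensity heterogeneity between
molecules, drift, or baseline wander. Passing the recovery benchmarks
therefore shows the estimators are correct for well-behaved traces of
realistic noise, length and censoring — not that they are robust to every
artefact of real recordings.

## Trace selection

Selection emulates manual curation reproducibly. A trace is kept when its
I_AA shows a single terminal drop at most (acceptor presence until one
bleach), its donor-excitation sum shows at most one discrete drop, its
recoverable I_AA dropouts (blinks) number ≤ 2, and its initial brightness
is within 1.5× the population median. The last rule is the trace-level
surrogate for image-plane spot filters against multi-dye spots: a summed
two-molecule trace in which neither dye happens to bleach shows no step
at all and is only detectable by brightness. Change points are found by
recursive two-segment mean-shift fits accepted at 4 local noise SDs.
The analysis window of a kept trace ends at its first bleach event.

## Segmentation and the step filter

Levels are inferred with a Gaussian-emission hidden Markov model fitted
by EM, the state count chosen by BIC (2–4 by default), and Viterbi
decoding per trace. Two choices matter:

- **One shared emission variance** (tied covariance). Camera noise does
  not depend on the FRET level, and without this constraint EM prefers to
  split the heavily occupied FS level into two states rather than resolve
  the close-lying PS/US pair.
- **Deterministic initialisation**: means spread evenly over the observed
  E range, variance from half the mean squared frame-to-frame difference
  (a pure noise estimate), sticky transitions (0.95 self-probability).
  Repeated runs with the same seed give identical segmentations.

Ensemble (shared) mode pools emission parameters across traces; EM may be
fitted on a subset of traces (`fit_subset`) with decoding on all — the
estimator is unchanged, the cost becomes linear in ensemble size.

This EM/BIC route deliberately replaces empirical-Bayes variational state
inference: what downstream analysis consumes is the state sequence plus
the step filter, and maximum-likelihood EM reproduces that without
re-implementing variational hyperpriors.

The step filter then (i) absorbs segments of ≤ 2 frames into the
neighbour nearest in level (shortest first, earliest on ties) and (ii)
fuses adjacent segments whose levels differ by no more than twice the
Allan deviation estimated at five-frame blocks, iterating to a fixed
point; total duration is conserved exactly. The Allan deviation

    σ_A = sqrt(½ ⟨(ȳ_{i+1} − ȳ_i)²⟩),   ȳ = non-overlapping 5-frame means

is computed on the pre-injection baseline when one exists (the paper-style
noise floor without kinetic transitions), else on the whole trace. The
threshold is read as a *level separation* criterion; the alternative
reading — a significance test on step height against local noise — is
noted as unresolved ambiguity.

## Level calibration and state mapping

Peak centers come from the **unweighted** histogram of per-segment mean E
values: one vote per visit, so a long-lived level (FS dominates occupancy
at high NTP) cannot swamp the others — the per-frame histogram is
marginally unidentifiable in exactly that regime, and only the temporal
structure exploited by the HMM separates PS from US there. The
`n_levels` most prominent histogram modes initialise a sum-of-Gaussians
least-squares fit (robust to small spurious clusters produced when BIC
admits an extra state for a noise tail). Each level's reported width is
the MAD-based SD of the per-frame E values nearest its center — the noise
scale that the assignment tolerance is measured in. Noiseless input with
exactly three distinct values returns those values verbatim.

Segments are labelled by nearest calibrated center; segments farther than
3 peak SDs from every center become `unassigned` and are excluded from
dwell pooling; exact ties break to the lower level and flag the path. E
is never clipped to [0, 1]: clipping would bias the Gaussian level fits.

## Dwell-time likelihood

Pooled dwell times are modelled by the m-exponential mixture

    p_t(τ) = Σ_n p_n k_n e^{−k_n τ},   L = Σ_i ln p_t(τ_i),

maximised in log-rate / logit-weight space (rates boxed to
[10⁻⁴, 10³] s⁻¹ — frame time and record length bound what is observable)
with 20 random restarts spread over the dwell quantiles; m is chosen by
BIC = −2L + (2m−1) ln N with ties to the smaller m; uncertainties are one
SD over 1000 nonparametric bootstrap refits, components matched by
descending rate to avoid label switching. m = 1 uses the closed form
k = 1/mean(τ).

Two censoring conventions:

- **Right**: the first and last dwell of every trace are removed (the
  first precedes NTP addition, the last is cut by bleaching or by the
  transition out of the window), so pooled dwells are complete and the
  likelihood needs no survival term. A survival-term option for
  right-censored dwells exists but is off by default.
- **Left**: steps at or below the 2-frame minimum are invisible, so
  pooled dwells are left-truncated at t_min = 3 frames (0.6 s). Fits use
  the truncated density p_t(τ)/S(t_min). This matters for the fast
  cycling rate: on ground-truth dwells the naive fit returns k1 ≈ 0.12
  for a truth of 0.15 while the truncated likelihood returns ≈ 0.14.
  For m = 1 the truncated MLE is the closed form k = 1/(mean − t_min).

Cycling-dwell pools from measured paths additionally drop the first PS
visit of each trace: that visit is the initial pause, whose exit law is
`k_itc6`, not the cycling mixture.

## Pathway statistics

Classification is rule-based on the post-injection label sequence (the
state occupied just before injection is retained as a zero-duration
marker so a transition at the injection boundary counts): FS with no
PS→US return ⇒ single-scrunch (with/without a detectable pause, i.e. a
PS dwell of ≥ 2 frames); returns then FS ⇒ cycling-then-FS; returns and
no FS ⇒ cycling-only (bleach-truncated cyclers included); a single level
⇒ inactive. A trace cut inside its first pause before either outcome
fits none of these and its class is withheld (it is excluded from
first-attempt denominators); this is rare under default conditions.

"Single attempt" includes trajectories without a detectable pause. The
first-attempt probability p = #single / (#single + #cycling) carries a
Wilson 95% interval. The isotherm p(NTP) is fitted by least squares,
weighted by inverse squared CI half-widths by default; the fit refuses
non-identifiable designs (fewer than four distinct concentrations, or all
points on the saturated plateau). Note the information content of a
realistic design is modest: for six concentrations spanning 1–500 µM with
100 molecules each, the Cramér–Rao bound on K_NTP is ≈ 19% relative — a
single experiment of that size determines K to no better than about a
fifth of its value.

The memory test pools consecutive visits to one state, computes the
Spearman correlation of (τ_j, τ_{j+1}), and assesses it against 10⁴
seeded permutations; constant dwell lists are reported NA. Withdrawal
runs are split by visited-level set (US/PS vs US/PS/FS; single-level
traces excluded) with per-subpopulation mixture fits.

## Pipeline and reproducibility

`RunConfig` serialises losslessly to JSON; every output carries a
config hash (computed over everything but the output directory) and the
seed. Per-condition seeds derive from one root `SeedSequence`, so
conditions can be rerun independently and identically. Default problem
sizes (150 traces per condition, 600 s records, EM on 60 traces,
bootstrap B = 200) keep a six-condition run in the low minutes on one
core while leaving ≥ 3σ headroom on every recovered parameter.

## Known limitations

- Events shorter than ~half a frame are invisible; dwells shorter than
  the 2-frame filter floor are excluded and handled by truncation, but a
  missed brief excursion still *merges* its two flanking dwells, which
  the likelihood cannot undo. The residual bias on the fast cycling rate
  after truncation correction is ≈ −10%.
- Interior dwells must complete within the record, so the slowest rates
  are measurable only when 1/k is well below the bleach-limited record
  length; k2 estimates carry a small (+10–20%) completion bias at the
  default record length.
- Level calibration assumes three resolvable levels; heavily overlapping
  peaks set a merged-level flag rather than failing silently.
- The classifier assumes FS is absorbing within an NTP run; it is not
  meant for withdrawal runs, which have their own subpopulation analysis.
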