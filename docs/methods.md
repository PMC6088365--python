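# Methods

## Scope and data model

`vsnadapt` analyses repeated-stimulation experiments on vomeronasal sensory
neurons (VSNs) in three paradigms, each described by an explicit
`StimulusProtocol` (a sorted, non-overlapping list of timed events):

1. **Decreasing-ISI** single-stimulus runs (default: four 10-s urine pulses
   at 180/60/30-s ISIs, a recovery probe after a further 180 s, and a
   terminal 50-mM-K⁺ viability pulse), analysed at a 1-Hz frame rate.
2. **Accelerating / decelerating block** designs: two ligands (DCA and CA,
   10 µM) applied in blocks of three 15-s trials each while the ISI steps
   through 180/150/120/90/60/30/15 s (or the reverse), at one volumetric
   stack every 3 s.  At a block transition the upcoming block's ISI is used.
3. **Paired-pulse** loose-patch runs: two identical 5-s urine pulses at ISIs
   of 5/10/20/60 s, pairs separated by ≥ 120 s, sampled at 5 kHz.

Throughout, the ISI convention is **offset-to-onset** (stimulus end to next
stimulus start).  The source experiments never state the convention
explicitly; offset-to-onset matches the "recovery period" phrasing used for
the block designs, and is fixed package-wide rather than configurable so
that protocol files are unambiguous.

## Synthetic-data generator

### Amplitude model

The generator is phenomenological, not biophysical.  Each cell's response
amplitude to its k-th effective stimulus is

    A_k = A₀ · (1 + f)^(k−1) · Rf_k · Rs_k · ε_k

* `Rf` (fast resource) and `Rs` (slow resource) start at 1, are depleted
  multiplicatively at each effective stimulus offset (`R ← R·(1 − d)`), and
  relax back toward 1 between stimuli with time constants `recovery_tau`
  and `slow_recovery_tau`.
* With `slow_recovery_tau = ∞` the slow resource reduces to the purely
  cumulative factor `(1 − d_slow)^(k−1)`; the decreasing-ISI preset uses
  this limit (the paradigm is too short to constrain slow recovery).
* A finite `slow_recovery_tau` is what lets the same cell show cumulative
  adaptation when ISIs keep shrinking (accelerating blocks) yet recover when
  ISIs lengthen again (decelerating blocks).  A purely cumulative per-count
  factor cannot express that ISI-order dependence, which is the central
  qualitative contrast between the two block paradigms.
* `f` (facilitation, default 0) models the minority of non-adapting cells
  whose responses grow mildly with repeated stimulation.
* `ε_k` is mean-1 lognormal trial-to-trial variability with coefficient of
  variation `response_cv`.  Without it, within-cell normalized responses are
  nearly degenerate (every cell's best trial is exactly 1) and
  discriminability values are unrealistically large.

Selectivity classes gate which stimuli are "effective": `ligandA_only` /
`ligandB_only` cells respond only to their ligand, `both` cells to any test
ligand, `unresponsive` cells to none.  Every class responds to the high-K⁺
depolarization control (amplitude `A₀`, independent of adapted state — the
control bypasses receptor-driven transduction) and none respond to
artificial urine.

### Indicator kernel

Fluorescence is the step response of a first-order indicator: during the
stimulus the signal relaxes toward `A_k` with `indicator_rise_tau` (1 s
default), after offset it decays with `indicator_decay_tau` (4 s for the
synthetic-dye confocal preset, 2.5 s for the GCaMP6s volumetric preset).
Raw traces are `F₀·(1 + ΔF/F)` plus white Gaussian noise (`noise_sd`, raw
units; default 1 % of the F₀ = 100 baseline).

### Populations, mixtures and determinism

Class and adapter counts are produced by **largest-remainder rounding** of
the configured fractions, never by sampling, so preset mixtures are exact at
any population size (259 cells → exactly 227 adapters).  All randomness
derives from one seed through named `SeedSequence` substreams, one per cell
(parameter draw and noise draw separated), so enlarging a population does
not perturb existing cells' traces.  Growing the population can still
relabel the boundary cell's class, because exact rounding must reassign it.

### Calibrated presets

`paper_calibrated_preset(name)` returns configurations whose population
statistics reproduce, in expectation, the published group results for each
paradigm:

| preset | n | mixture | key parameters |
|---|---|---|---|
| `decreasing_isi_urine` | 259 | 87.6 % adapters | adapters: d = 0.388 ± 0.06, τ_rec = 195.8 s, d_slow = 0.0324 (no slow recovery); non-adapters: facilitation 0.0621 ± 0.02 |
| `accelerating_bile` | 486 | 27.8/28.0/44.2 % A-only/B-only/both | d_fast = 0.65 ± 0.08, τ_fast = 45 s, d_slow = 0.14 ± 0.03, τ_slow = 800 s |
| `decelerating_bile` | 336 | 30.6/34.5/34.8 % | same as accelerating |
| `paired_pulse` | 14 | — | spont 1.5 Hz (dispersion 2), evoked 25 Hz, attenuation {5 s: 0.1, 10 s: 0.4, 20 s: 0.8, 60 s: 1.0}, template 40 pA, noise 5 pA |

The decreasing-ISI adapter parameters were obtained by inverting the
closed-form expected pipeline output — quadrature over the truncated-normal
depletion jitter times the `1 + cv²` ratio bias of the lognormal trial
variability — against the target normalized amplitudes (85.7/67.5/53.8 % at
stimulations 2–4, 71.8 % at the probe) given the 227/32 adapter split and
the non-adapters' 121 % fourth-stimulation mean.  Three free parameters fit
the four targets with residuals < 0.15 percentage points.  The recovery time
constant that falls out (≈ 196 s, i.e. recovery over minutes) is otherwise
unconstrained by any published number and should not be over-interpreted.
The block-paradigm parameters were chosen against qualitative features only
(strong within-block adaptation at 15-s ISIs; monotone interblock decline
only in the accelerating direction; d′ loss confined to the 15-s block when
decelerating); no quantitative block-level group means exist to calibrate
against.

Trial-to-trial variability is `response_cv = 0.10` in both imaging presets —
a typical Ca²⁺-response CV — and is the main driver of the across-cell
spread of normalized amplitudes.  A side effect worth knowing: a non-adapter
whose true fourth-stimulation expectation is 121 % can fluctuate below the
95 % classification boundary, so the *classified* adapting fraction runs
≈ 1 point above the configured 87.6 % mixture.

### Spike recordings

Spontaneous activity is a **gamma-renewal process** with shape
`1/burstiness` (dispersion 2 by default: bursty, CV² = 2).  During each
stimulus an independent evoked renewal process (shape 2, i.e. more regular,
as high-rate evoked firing is) at `evoked_rate × attenuation` is
superimposed; artificial urine evokes nothing; high-K⁺ evokes the full
rate.  The merged train is thinned to a 3-ms dead time — chosen as the
spike-template span so that no two ground-truth spikes ever overlap into a
single threshold crossing; it also caps firing at a physiological ~300 Hz.
The dead time deletes the bursty process's shortest intervals (≈ 6 % at
2 Hz, dispersion 2), which the rate-recovery tests account for via the
gamma interval CDF; its effect on paired-pulse *ratios* is < 1 SEM and is
neglected in `expected_pair_ratios()` (which therefore equals
`(s + a·e)/(s + e)` — spontaneous firing continues during pulses, so the
observable ratio is not the attenuation itself).

Each spike is rendered as a biphasic template (0.8-ms negative main lobe,
slower positive lobe, ~3 ms total, negative polarity as in loose-patch
capacitive currents) plus white Gaussian noise.

### What the generator does not emulate

No photobleaching, phototoxicity or slow tissue drift (the slow resource is
*stimulus-driven* by construction); no image misregistration or motion (the
movie fixture renders static, non-overlapping disks); no receptor-level
cross-adaptation asymmetries (a `both` cell depletes one shared resource for
either ligand); no electrode drift, burst-structure changes during evoked
firing, or multi-unit contamination.  Passing tests therefore validate the
*analysis arithmetic and classification logic*, not robustness to those
real-world artefacts — registration and movement correction are explicitly
out of scope and masks/ROI tables are taken as inputs.

## Analysis pipeline choices

* **Confocal amplitudes** are peak ΔF/F between stimulus onset and
  offset + 10 s (indicator-decay margin).  The baseline (mean and SD) is
  re-estimated from the 10 s immediately preceding *each* stimulus so slow
  drift does not inflate amplitudes; the residual cost is that at a 30-s ISI
  the baseline still contains ≈ exp(−20/4) of the previous transient's tail
  (≲ 0.5 % amplitude bias, visible in the oracle tests' tolerances).
* **Responsiveness** requires the high-K⁺ gate, a ≥ 3-s supra-threshold run
  (3 × baseline SD, measured as frame coverage n·Δt), and a threshold
  crossing beginning within the stimulus window.  On pure-noise traces the
  false-positive rate is ≪ 1 %.  A cell whose baseline crosses threshold
  for ≥ 3 s *outside* any stimulus window can be excluded by the optional
  `flag_high_baseline_cells` filter (off by default), mirroring the manual
  exclusion of high-spontaneous-activity cells.
* **Volumetric trial amplitudes** are (mean of the first 3 stacks at/after
  onset − mean of the 3 stacks before onset) / prestimulus mean; timestamps,
  not indices, are authoritative.  Trial responsiveness compares the
  amplitude against `3 × σ_rest·√(1/3 + 1/3)/F₀`, with σ_rest estimated from
  the pre-stimulus rest period.
* **Selectivity** is majority-rule: a cell counts as responsive to a ligand
  when more than half of its basis-block trials of that ligand pass
  (≥ 4 of 6 with two basis blocks).  Basis blocks are 1–2 for the
  accelerating paradigm and 3–4 for the decelerating one, where fast
  adaptation degrades the earliest blocks.
* **d′** uses sample SDs (n−1) and within-cell normalization by the cell's
  **global** maximum across all trials of all stimuli.  Normalizing per
  cell-stimulus pair (as interblock normalization does) would rescale the
  non-preferred ligand's pure-noise responses to ≈ 1 and destroy the
  group separation, so the global max is used for d′ only.
* **Spike detection** low-pass smooths the high-passed trace at 800 Hz
  (2nd-order zero-phase Butterworth) before thresholding at 4 × the robust
  (MAD-based) noise SD; each supra-threshold run yields one spike at its
  extremum and extrema within 2 ms merge.  The MAD is floored at 2 % of the
  absolute signal maximum so the threshold stays defined on noise-free
  input.  At a template-to-noise ratio of 4 this yields recall and
  precision above 0.95; "shape inspection" of candidate spikes is not
  reimplemented.
* **Statistics**: ANOVA + Tukey HSD, Dunnett, paired t and Shapiro–Wilk
  delegate to scipy; the Friedman statistic delegates to scipy with a
  special case (statistic 0, p 1) when every block is fully tied, where the
  tie correction degenerates; the Tukey–Nemenyi post hoc is computed
  directly from mean within-block ranks, q = |R_i − R_j| / √(k(k+1)/(12n)),
  referred to the studentized-range distribution with infinite df.  SEMs
  use n−1 SDs with cells as the unit of analysis.

## Problem sizes

The shipped studies use the full preset populations (259, 486 and 336
cells; 14 paired-pulse cells) and average 10 runs for imaging statistics
and 50 single-cell runs for paired-pulse recovery — sizes at which every
recovery test resolves its target well inside the published uncertainty
while a complete run of the suite plus the acceptance script stays in the
low minutes on one CPU.

## Known limitations

* The adapting/non-adapting split uses the fourth stimulation only (no
  trend test), and normalized values above 100 % are not capped.
* `both`-class cells experience depletion from every effective stimulus,
  so in block paradigms they adapt roughly twice as fast per unit time as
  selective cells; the real data show similar slow-adaptation rates across
  clusters, so cross-cluster rate comparisons on synthetic data are not
  meaningful.
* The amplitude model is multiplicative-resource phenomenology; it cannot
  express supra-linear sensitization, threshold nonlinearities, or
  within-stimulus (single-trial) rate adaptation.
* Expected paired-pulse ratios ignore dead-time compression (< 1 SEM at
  default rates) and detection is single-unit by assumption.
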