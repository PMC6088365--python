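"""Ground-truth simulator for VSN adaptation experiments.

Generates Ca2+ fluorescence traces, toy image-stack movies and loose-patch
current recordings whose adaptation behaviour is known exactly, so that every
analysis stage can be validated without access to real recordings.

Adaptation model
----------------
Each cell's response amplitude to its k-th effective stimulus is

    A_k = base_amplitude * (1 + facilitation)^(k-1) * Rf_k * Rs_k

where ``Rf`` (fast) and ``Rs`` (slow) are releasable resources in [0, 1].
At each effective stimulus offset the resources are depleted
multiplicatively (``R <- R * (1 - d)``) and between stimuli they relax back
toward 1 with their own recovery time constants.  An infinite slow-recovery
time constant reduces the slow resource to the purely cumulative factor
``(1 - d_slow)^(k-1)``.  The fast component expresses short-term adaptation
that is reversible within minutes; the slowly recovering component expresses
adaptation that accumulates over dozens of closely spaced stimuli but fades
when intervals lengthen again.  The facilitation term models the minority of
cells whose responses grow slightly with repeated stimulation.

The indicator is modelled as a first-order filter driven by a boxcar
stimulus: fluorescence relaxes toward the response amplitude with
``indicator_rise_tau`` while the stimulus is on and decays exponentially
with ``indicator_decay_tau`` after stimulus offset.

Spike recordings superimpose a gamma-renewal spontaneous process (shape < 1
for bursting) and per-stimulus evoked renewal processes, render each spike
as a biphasic template and add Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GeneratorError, ProtocolError
from .protocols import (
    ARTIFICIAL_URINE,
    HIGHK,
    StimulusEvent,
    StimulusProtocol,
    build_block_protocol,
    build_decreasing_isi_protocol,
    build_paired_pulse_protocol,
)

__all__ = [
    "CellGroundTruth",
    "ParamDist",
    "GeneratorConfig",
    "SpikeGroundTruth",
    "largest_remainder_counts",
    "simulate_cell_trace",
    "expected_event_amplitudes",
    "simulate_population",
    "simulate_stack_movie",
    "simulate_spike_recording",
    "paper_calibrated_preset",
    "preset_protocol",
    "PRESET_NAMES",
]

SELECTIVITY_CLASSES = ("ligandA_only", "ligandB_only", "both", "unresponsive")


# ---------------------------------------------------------------------------
# ground-truth parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellGroundTruth:
    """True generative parameters of one synthetic cell."""

    cell_id: str
    selectivity_class: str = "both"
    is_adapter: bool = True
    base_amplitude: float = 1.0          # peak dF/F of an unadapted response
    short_term_depletion: float = 0.0    # fast fraction lost per stimulus
    recovery_tau: float = 60.0           # fast recovery time constant (s)
    slow_adaptation_rate: float = 0.0    # slow fraction lost per stimulus
    slow_recovery_tau: float = math.inf  # slow recovery time constant (s)
    facilitation_rate: float = 0.0       # fractional growth per stimulus
    response_cv: float = 0.0             # trial-to-trial amplitude CV
    indicator_rise_tau: float = 1.0      # s
    indicator_decay_tau: float = 4.0     # s
    noise_sd: float = 0.0                # raw fluorescence units
    baseline_f0: float = 100.0           # raw baseline fluorescence

    def __post_init__(self) -> None:
        if self.selectivity_class not in SELECTIVITY_CLASSES:
            raise GeneratorError(
                f"unknown selectivity class {self.selectivity_class!r}"
            )
        if not 0.0 <= self.short_term_depletion <= 1.0:
            raise GeneratorError("short_term_depletion must be in [0, 1]")
        if not 0.0 <= self.slow_adaptation_rate <= 1.0:
            raise GeneratorError("slow_adaptation_rate must be in [0, 1]")
        if self.recovery_tau <= 0 or self.slow_recovery_tau <= 0:
            raise GeneratorError("recovery time constants must be > 0")
        if self.noise_sd < 0:
            raise GeneratorError("noise_sd must be >= 0")
        if self.response_cv < 0:
            raise GeneratorError("response_cv must be >= 0")
        if self.baseline_f0 <= 0:
            raise GeneratorError("baseline_f0 must be > 0")

    def responds_to(self, stimulus_id: str, ligands: tuple[str, str | None]) -> bool:
        """Does this cell respond to the given stimulus label?

        All classes respond to the high-K+ depolarizing control; none respond
        to artificial urine.  Ligand-selective cells respond only to their
        ligand; 'both' cells respond to any test stimulus.
        """
        if stimulus_id == HIGHK:
            return True
        if stimulus_id == ARTIFICIAL_URINE:
            return False
        cls = self.selectivity_class
        if cls == "unresponsive":
            return False
        if cls == "both":
            return True
        if cls == "ligandA_only":
            return stimulus_id == ligands[0]
        return stimulus_id == ligands[1]


@dataclass(frozen=True)
class ParamDist:
    """Truncated-normal distribution for a per-cell parameter."""

    mean: float
    sd: float = 0.0
    low: float = -math.inf
    high: float = math.inf

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return float(np.clip(self.mean, self.low, self.high))
        for _ in range(1000):
            v = rng.normal(self.mean, self.sd)
            if self.low <= v <= self.high:
                return float(v)
        raise GeneratorError("truncated-normal rejection sampling failed")


def _as_dist(v: "ParamDist | float") -> ParamDist:
    return v if isinstance(v, ParamDist) else ParamDist(float(v))


@dataclass(frozen=True)
class SpikeGroundTruth:
    """True generative parameters of one loose-patch recording."""

    spontaneous_rate: float = 1.5        # Hz
    burstiness: float = 2.0              # dispersion >= 1 (gamma shape = 1/burstiness)
    evoked_rate: float = 25.0            # Hz added during effective stimuli
    paired_pulse_attenuation: Mapping[float, float] = field(
        default_factory=lambda: {5.0: 0.1, 10.0: 0.4, 20.0: 0.8, 60.0: 1.0}
    )
    spike_template_amplitude: float = 40.0  # pA
    recording_noise_sd: float = 5.0         # pA
    refractory: float = 0.003               # s, dead time between spikes
    evoked_shape: float = 2.0               # gamma shape of evoked renewal

    def __post_init__(self) -> None:
        if self.spontaneous_rate < 0 or self.evoked_rate < 0:
            raise GeneratorError("rates must be >= 0")
        if self.burstiness < 1:
            raise GeneratorError("burstiness (dispersion) must be >= 1")
        for isi, a in self.paired_pulse_attenuation.items():
            if not 0.0 <= a <= 1.5:
                raise GeneratorError(
                    f"attenuation fraction at ISI {isi} s must be in [0, 1.5]"
                )

    def attenuation_at(self, isi: float, tol: float = 0.5) -> float:
        """Attenuation for the nearest tabulated ISI (within ``tol`` s)."""
        keys = np.array(sorted(self.paired_pulse_attenuation))
        i = int(np.argmin(np.abs(keys - isi)))
        if abs(keys[i] - isi) > tol:
            raise GeneratorError(f"no attenuation entry near ISI {isi} s")
        return float(self.paired_pulse_attenuation[float(keys[i])])

    def expected_pair_ratios(self) -> dict[float, float]:
        """Expected second/first pulse rate ratio per ISI.

        Spontaneous firing continues during pulses, so the observable ratio
        is (spont + a * evoked) / (spont + evoked), not ``a`` itself.  The
        3-ms dead time removes well under 2 % of spikes at the default rates
        (the evoked renewal is regular, with few short intervals), so its
        effect on the ratio is neglected here.
        """
        s, e = self.spontaneous_rate, self.evoked_rate
        return {
            float(isi): (s + a * e) / (s + e)
            for isi, a in sorted(self.paired_pulse_attenuation.items())
        }


@dataclass(frozen=True)
class GeneratorConfig:
    """Population-level recipe: class mixture plus per-group parameter laws."""

    n_cells: int
    class_mixture: Mapping[str, float]
    adapter_fraction: float = 1.0
    adapter_params: Mapping[str, "ParamDist | float"] = field(default_factory=dict)
    nonadapter_params: Mapping[str, "ParamDist | float"] = field(default_factory=dict)
    common_params: Mapping[str, "ParamDist | float"] = field(default_factory=dict)
    ligands: tuple[str, str | None] = ("urine", None)
    seed: int | None = None
    paper_preset: str | None = None
    spike: SpikeGroundTruth | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise GeneratorError("n_cells must be >= 1")
        total = float(sum(self.class_mixture.values()))
        if abs(total - 1.0) > 1e-9:
            raise GeneratorError(
                f"class mixture fractions must sum to 1 (got {total!r})"
            )
        for cls in self.class_mixture:
            if cls not in SELECTIVITY_CLASSES:
                raise GeneratorError(f"unknown selectivity class {cls!r}")
        if not 0.0 <= self.adapter_fraction <= 1.0:
            raise GeneratorError("adapter_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# deterministic mixture rounding
# ---------------------------------------------------------------------------


def largest_remainder_counts(fractions: Sequence[float], n: int) -> list[int]:
    """Integer counts summing to ``n`` whose proportions best match
    ``fractions`` (largest-remainder rounding; ties broken by position)."""
    fr = np.asarray(fractions, dtype=float)
    if np.any(fr < 0):
        raise GeneratorError("fractions must be >= 0")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise GeneratorError("fractions must sum to 1")
    exact = fr * n
    counts = np.floor(exact).astype(int)
    short = n - int(counts.sum())
    # stable sort on descending remainder => ties go to earlier entries
    order = np.argsort(-(exact - counts), kind="stable")
    for i in order[:short]:
        counts[i] += 1
    return counts.tolist()


# ---------------------------------------------------------------------------
# single-cell fluorescence traces
# ---------------------------------------------------------------------------


def _event_amplitudes(
    truth: CellGroundTruth,
    protocol: StimulusProtocol,
    ligands: tuple[str, str | None],
) -> list[float]:
    """Noise-free response amplitude for every protocol event (0 where the
    cell does not respond).  High-K+ responses probe viability directly and
    neither consume nor respect the adapted state."""
    amps: list[float] = []
    rf = rs = 1.0
    k = 0  # effective test-stimulus counter
    last_offset: float | None = None
    for ev in protocol.events:
        if not truth.responds_to(ev.stimulus_id, ligands):
            amps.append(0.0)
            continue
        if ev.stimulus_id == HIGHK:
            amps.append(truth.base_amplitude)
            continue
        if last_offset is not None:
            gap = ev.onset - last_offset
            rf = 1.0 - (1.0 - rf) * math.exp(-gap / truth.recovery_tau)
            if math.isfinite(truth.slow_recovery_tau):
                rs = 1.0 - (1.0 - rs) * math.exp(-gap / truth.slow_recovery_tau)
        k += 1
        amps.append(
            truth.base_amplitude
            * (1.0 + truth.facilitation_rate) ** (k - 1)
            * rf
            * rs
        )
        rf *= 1.0 - truth.short_term_depletion
        rs *= 1.0 - truth.slow_adaptation_rate
        last_offset = ev.offset
    return amps


def expected_event_amplitudes(
    truth: CellGroundTruth,
    protocol: StimulusProtocol,
    ligands: tuple[str, str | None] = ("urine", None),
) -> pd.DataFrame:
    """Ground-truth amplitude table (one row per protocol event)."""
    amps = _event_amplitudes(truth, protocol, ligands)
    return pd.DataFrame(
        {
            "cell_id": truth.cell_id,
            "stimulus": [ev.stimulus_id for ev in protocol.events],
            "block": [ev.block_index for ev in protocol.events],
            "trial": [ev.trial_index for ev in protocol.events],
            "onset_s": [ev.onset for ev in protocol.events],
            "amplitude": amps,
        }
    )


def _render_response(
    times: np.ndarray,
    out: np.ndarray,
    ev: StimulusEvent,
    amplitude: float,
    rise_tau: float,
    decay_tau: float,
) -> None:
    """Add one indicator transient (in dF/F units) to ``out`` in place."""
    if amplitude == 0.0:
        return
    hi = ev.offset + 8.0 * decay_tau  # beyond this the tail is < 3e-4
    sel = (times >= ev.onset) & (times <= hi)
    t = times[sel]
    rising = t <= ev.offset
    resp = np.empty(t.shape)
    resp[rising] = amplitude * (1.0 - np.exp(-(t[rising] - ev.onset) / rise_tau))
    peak = amplitude * (1.0 - math.exp(-ev.duration / rise_tau))
    resp[~rising] = peak * np.exp(-(t[~rising] - ev.offset) / decay_tau)
    out[sel] += resp


def simulate_cell_trace(
    truth: CellGroundTruth,
    protocol: StimulusProtocol,
    seed: int | np.random.SeedSequence,
    ligands: tuple[str, str | None] = ("urine", None),
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one cell's raw fluorescence trace on the protocol's grid.

    Returns ``(values, timestamps)``.  Deterministic given
    ``(truth, protocol, seed)``.
    """
    times = protocol.frame_times()
    dff = np.zeros_like(times)
    amps = np.asarray(_event_amplitudes(truth, protocol, ligands))
    rng = np.random.default_rng(seed)
    if truth.response_cv > 0:
        # mean-1 lognormal trial-to-trial amplitude variability
        sigma = math.sqrt(math.log1p(truth.response_cv**2))
        amps = amps * rng.lognormal(-0.5 * sigma**2, sigma, size=amps.size)
    for ev, a in zip(protocol.events, amps):
        _render_response(
            times, dff, ev, float(a), truth.indicator_rise_tau, truth.indicator_decay_tau
        )
    f = truth.baseline_f0 * (1.0 + dff)
    if truth.noise_sd > 0:
        f = f + rng.normal(0.0, truth.noise_sd, size=times.shape)
    return f, times


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

_ADAPTER_FIELDS = (
    "short_term_depletion",
    "recovery_tau",
    "slow_adaptation_rate",
    "slow_recovery_tau",
    "facilitation_rate",
)
_COMMON_FIELDS = (
    "base_amplitude",
    "response_cv",
    "indicator_rise_tau",
    "indicator_decay_tau",
    "noise_sd",
    "baseline_f0",
)


def _draw_cell(
    cell_id: str,
    cls: str,
    is_adapter: bool,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> CellGroundTruth:
    group = config.adapter_params if is_adapter else config.nonadapter_params
    kwargs: dict[str, float] = {}
    for name in _COMMON_FIELDS:
        if name in config.common_params:
            kwargs[name] = _as_dist(config.common_params[name]).draw(rng)
    for name in _ADAPTER_FIELDS:
        if name in group:
            kwargs[name] = _as_dist(group[name]).draw(rng)
    return CellGroundTruth(
        cell_id=cell_id, selectivity_class=cls, is_adapter=is_adapter, **kwargs
    )


def draw_population_truths(config: GeneratorConfig) -> list[CellGroundTruth]:
    """Draw per-cell ground truths.  Class and adapter counts are rounded
    deterministically (largest remainder), never sampled, so the configured
    fractions are exact at any population size.  Each cell consumes its own
    seed substream: adding cells does not perturb existing ones."""
    classes = list(config.class_mixture)
    counts = largest_remainder_counts(
        [config.class_mixture[c] for c in classes], config.n_cells
    )
    labels: list[tuple[str, bool]] = []
    for cls, cnt in zip(classes, counts):
        n_ad = largest_remainder_counts(
            [config.adapter_fraction, 1.0 - config.adapter_fraction], cnt
        )[0]
        labels += [(cls, True)] * n_ad + [(cls, False)] * (cnt - n_ad)
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_cells)
    width = len(str(config.n_cells))
    return [
        _draw_cell(f"cell_{i:0{width}d}", cls, ad, config, np.random.default_rng(ss.spawn(1)[0]))
        for i, ((cls, ad), ss) in enumerate(zip(labels, streams), start=1)
    ]


def truth_table(truths: Sequence[CellGroundTruth]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in truths])


def simulate_population(
    config: GeneratorConfig, protocol: StimulusProtocol
) -> tuple["TraceMatrix", pd.DataFrame]:
    """Simulate ``config.n_cells`` traces on the protocol's sampling grid.

    Returns the trace matrix plus the ground-truth table."""
    from .imaging import TraceMatrix  # local import to avoid a cycle

    truths = draw_population_truths(config)
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_cells)
    times = protocol.frame_times()
    values = np.empty((len(truths), times.size))
    for i, (truth, ss) in enumerate(zip(truths, streams)):
        noise_seed = ss.spawn(2)[1]
        values[i], _ = simulate_cell_trace(
            truth, protocol, noise_seed, ligands=config.ligands
        )
    tm = TraceMatrix([t.cell_id for t in truths], times, values)
    return tm, truth_table(truths)


# ---------------------------------------------------------------------------
# toy image-stack movies
# ---------------------------------------------------------------------------


def simulate_stack_movie(
    truths: Sequence[CellGroundTruth],
    protocol: StimulusProtocol,
    frame_shape: tuple[int, int] = (64, 64),
    seed: int | np.random.SeedSequence = 0,
    radius: float = 3.0,
    background: float = 20.0,
    ligands: tuple[str, str | None] = ("urine", None),
    max_attempts: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Render each cell as a disk whose intensity follows its simulated trace
    over a flat background; one frame per acquisition interval.

    Returns ``(stacks, masks)`` with ``stacks`` of shape (T, H, W) and
    ``masks`` a label image (0 = background, i = cell i, 1-based in the
    order of ``truths``)."""
    h, w = frame_shape
    if h > 128 or w > 128:
        raise GeneratorError("frame_shape is limited to 128 x 128 (toy scale)")
    root = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    rng = np.random.default_rng(root.spawn(1)[0])
    masks = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    centers: list[tuple[float, float]] = []
    for i in range(len(truths)):
        for attempt in range(max_attempts):
            cy = rng.uniform(radius + 1, h - radius - 1)
            cx = rng.uniform(radius + 1, w - radius - 1)
            if all((cy - y) ** 2 + (cx - x) ** 2 >= (2 * radius + 1) ** 2
                   for y, x in centers):
                break
        else:
            raise GeneratorError(
                f"could not place disk for cell index {i} without overlap"
            )
        centers.append((cy, cx))
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        masks[disk] = i + 1

    times = protocol.frame_times()
    stacks = np.full((times.size, h, w), float(background))
    cell_streams = root.spawn(len(truths))
    for i, truth in enumerate(truths):
        trace, _ = simulate_cell_trace(truth, protocol, cell_streams[i], ligands=ligands)
        sel = masks == i + 1
        stacks[:, sel] = trace[:, None]
    return stacks, masks


# ---------------------------------------------------------------------------
# loose-patch recordings
# ---------------------------------------------------------------------------


def _renewal_times(
    rng: np.random.Generator, rate: float, t0: float, t1: float, shape: float
) -> np.ndarray:
    """Gamma-renewal arrivals in [t0, t1) at mean rate ``rate``."""
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    span = t1 - t0
    n_guess = max(20, int(rate * span * 2 + 10 * math.sqrt(rate * span + 1)))
    # unit-mean gamma intervals scaled by 1/rate
    ivals = rng.gamma(shape, 1.0 / (shape * rate), size=n_guess)
    t = t0 + np.cumsum(ivals)
    while t.size and t[-1] < t1:
        more = rng.gamma(shape, 1.0 / (shape * rate), size=n_guess)
        t = np.concatenate([t, t[-1] + np.cumsum(more)])
    return t[t < t1]


def _spike_template(sample_rate: float, amplitude: float) -> np.ndarray:
    """Biphasic loose-patch spike: negative main lobe followed by a slower
    positive lobe, ~3 ms total, peak magnitude = ``amplitude`` (negative
    polarity)."""
    t = np.arange(0.0, 0.003, 1.0 / sample_rate)
    wave = -np.exp(-((t - 0.0008) ** 2) / (2 * 0.0004**2)) + 0.45 * np.exp(
        -((t - 0.0018) ** 2) / (2 * 0.0006**2)
    )
    return amplitude * wave / np.abs(wave).max()


def simulate_spike_recording(
    truth: SpikeGroundTruth,
    protocol: StimulusProtocol,
    sample_rate: float = 5000.0,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate a loose-patch current recording.

    Spontaneous activity is a gamma-renewal process (shape ``1/burstiness``)
    running for the whole recording.  During urine pulses an evoked renewal
    process at ``evoked_rate`` (scaled by the paired-pulse attenuation for
    second pulses) is superimposed; high-K+ pulses evoke the full rate;
    artificial-urine pulses evoke nothing.  Spikes closer than the
    refractory floor are merged.  Returns ``(times, current_pA,
    spike_times)``; deterministic given the seed.
    """
    if sample_rate < 1000:
        raise GeneratorError("sample_rate must be >= 1000 Hz")
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    ss_spont, ss_evoked, ss_noise = root.spawn(3)
    duration = protocol.total_duration
    spikes = [
        _renewal_times(
            np.random.default_rng(ss_spont),
            truth.spontaneous_rate,
            0.0,
            duration,
            1.0 / truth.burstiness,
        )
    ]
    rng_ev = np.random.default_rng(ss_evoked)
    pair_first_offset: dict[int, float] = {}
    for ev in protocol.events:
        if ev.stimulus_id == ARTIFICIAL_URINE:
            continue
        rate = truth.evoked_rate
        if ev.stimulus_id != HIGHK and ev.pair_index is not None:
            if ev.trial_index == 1:
                pair_first_offset[ev.pair_index] = ev.offset
            else:
                isi = ev.onset - pair_first_offset[ev.pair_index]
                rate *= truth.attenuation_at(isi)
        spikes.append(
            _renewal_times(rng_ev, rate, ev.onset, ev.offset, truth.evoked_shape)
        )
    t_spk = np.sort(np.concatenate(spikes))
    if t_spk.size:
        keep = np.concatenate([[True], np.diff(t_spk) >= truth.refractory])
        t_spk = t_spk[keep]

    n = int(duration * sample_rate) + 1
    times = np.arange(n) / sample_rate
    rng_noise = np.random.default_rng(ss_noise)
    current = (
        rng_noise.normal(0.0, truth.recording_noise_sd, size=n)
        if truth.recording_noise_sd > 0
        else np.zeros(n)
    )
    template = _spike_template(sample_rate, truth.spike_template_amplitude)
    for t in t_spk:
        i = int(round(t * sample_rate))
        j = min(i + template.size, n)
        if i < n:
            current[i:j] += template[: j - i]
    return times, current, t_spk


# ---------------------------------------------------------------------------
# paper-calibrated presets
# ---------------------------------------------------------------------------

PRESET_NAMES = (
    "decreasing_isi_urine",
    "accelerating_bile",
    "decelerating_bile",
    "paired_pulse",
)

# Decreasing-ISI urine preset: the adapter class's two-factor parameters were
# obtained by inverting the closed-form expected population mean (quadrature
# over the per-cell depletion jitter, times the 1 + cv^2 ratio bias of the
# mean-1 lognormal trial variability) against the target normalized
# amplitudes at stimulations 2-4 and the recovery probe; the non-adapter
# facilitation rate reproduces a 121% fourth-stimulation amplitude in
# expectation.
_IMAGING_TRIAL_CV = 0.10
_DEC_ADAPTER_D = ParamDist(0.388030, 0.06, 0.0, 0.95)
_DEC_ADAPTER_TAU = 195.751
_DEC_ADAPTER_SLOW = 0.032415
_NONADAPTER_FACIL = ParamDist(0.0620737, 0.02, 0.0, 0.2)

# Block-paradigm preset: fast resource handles within-block adaptation at
# short ISIs; the slowly recovering resource accumulates when ISIs shrink
# (accelerating) but fades again when they lengthen (decelerating).
_BLOCK_FAST_D = ParamDist(0.65, 0.08, 0.0, 0.95)
_BLOCK_FAST_TAU = 45.0
_BLOCK_SLOW_D = ParamDist(0.14, 0.03, 0.0, 0.5)
_BLOCK_SLOW_TAU = 800.0


def paper_calibrated_preset(name: str) -> GeneratorConfig:
    """Generator configuration reproducing, in expectation, the published
    population statistics of the named stimulation paradigm."""
    if name == "decreasing_isi_urine":
        return GeneratorConfig(
            n_cells=259,
            class_mixture={"both": 1.0},
            adapter_fraction=227 / 259,
            adapter_params={
                "short_term_depletion": _DEC_ADAPTER_D,
                "recovery_tau": _DEC_ADAPTER_TAU,
                "slow_adaptation_rate": _DEC_ADAPTER_SLOW,
                "slow_recovery_tau": math.inf,
            },
            nonadapter_params={
                "short_term_depletion": 0.0,
                "slow_adaptation_rate": 0.0,
                "facilitation_rate": _NONADAPTER_FACIL,
            },
            common_params={
                "base_amplitude": ParamDist(1.2, 0.35, 0.3, 3.0),
                "response_cv": _IMAGING_TRIAL_CV,
                "indicator_rise_tau": 1.0,
                "indicator_decay_tau": 4.0,
                "noise_sd": 1.0,
                "baseline_f0": 100.0,
            },
            ligands=("urine", None),
            paper_preset=name,
        )
    if name in ("accelerating_bile", "decelerating_bile"):
        if name == "accelerating_bile":
            n_cells, counts = 486, (135, 136, 215)
        else:
            n_cells, counts = 336, (103, 116, 117)
        a, b, both = (c / n_cells for c in counts)
        return GeneratorConfig(
            n_cells=n_cells,
            class_mixture={"ligandA_only": a, "ligandB_only": b, "both": both},
            adapter_fraction=1.0,
            adapter_params={
                "short_term_depletion": _BLOCK_FAST_D,
                "recovery_tau": _BLOCK_FAST_TAU,
                "slow_adaptation_rate": _BLOCK_SLOW_D,
                "slow_recovery_tau": _BLOCK_SLOW_TAU,
            },
            common_params={
                "base_amplitude": ParamDist(1.5, 0.4, 0.4, 4.0),
                "response_cv": _IMAGING_TRIAL_CV,
                "indicator_rise_tau": 1.0,
                "indicator_decay_tau": 2.5,
                "noise_sd": 1.0,
                "baseline_f0": 100.0,
            },
            ligands=("DCA", "CA"),
            paper_preset=name,
        )
    if name == "paired_pulse":
        return GeneratorConfig(
            n_cells=14,
            class_mixture={"both": 1.0},
            adapter_fraction=1.0,
            ligands=("urine", None),
            paper_preset=name,
            spike=SpikeGroundTruth(),
        )
    raise GeneratorError(
        f"unknown preset {name!r}; expected one of {PRESET_NAMES}"
    )


def save_stack_movie(path_stacks, path_masks, stacks: np.ndarray, masks: np.ndarray) -> None:
    """Write a simulated movie as multi-page TIFF plus a label-image TIFF."""
    import tifffile

    tifffile.imwrite(path_stacks, np.asarray(stacks, dtype=np.float32))
    tifffile.imwrite(path_masks, np.asarray(masks, dtype=np.int32))


def load_stack_movie(path_stacks, path_masks) -> tuple[np.ndarray, np.ndarray]:
    """Read back a movie written by :func:`save_stack_movie`."""
    import tifffile

    return (
        np.asarray(tifffile.imread(path_stacks), dtype=float),
        np.asarray(tifffile.imread(path_masks)),
    )


def preset_protocol(name: str) -> StimulusProtocol:
    """The stimulation protocol conventionally paired with each preset."""
    if name == "decreasing_isi_urine":
        return build_decreasing_isi_protocol(
            [180.0, 60.0, 30.0],
            stim_duration=10.0,
            recovery_probe_isi=180.0,
            include_highK=True,
        )
    if name == "accelerating_bile":
        return build_block_protocol(
            "accelerating", [180, 150, 120, 90, 60, 30, 15]
        )
    if name == "decelerating_bile":
        return build_block_protocol(
            "decelerating", [15, 30, 60, 90, 120, 150, 180]
        )
    if name == "paired_pulse":
        return build_paired_pulse_protocol(
            [5.0, 10.0, 20.0, 60.0], pulse_duration=5.0,
            inter_experiment_gap=120.0, initial_rest=60.0,
        )
    raise GeneratorError(
        f"unknown preset {name!r}; expected one of {PRESET_NAMES}"
    )
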