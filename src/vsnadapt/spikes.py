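"""Loose-patch spike-train analysis.

Pipeline: zero-phase 2-Hz high-pass filtering to remove baseline drift,
threshold spike detection (robust-SD threshold on a lightly smoothed trace,
refractory merging, extremum timestamps), rate binning, spontaneous-rate
statistics over 1-s windows, the 2-SD urine-responsiveness criterion with an
artificial-urine veto, and paired-pulse adaptation (second-pulse rate
normalized to the first).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import AnalysisError
from .protocols import ARTIFICIAL_URINE, HIGHK, StimulusEvent, StimulusProtocol

__all__ = [
    "SpikeTrain",
    "SpikeResponse",
    "highpass_filter",
    "detect_spikes",
    "bin_rates",
    "spontaneous_stats",
    "classify_urine_responsive",
    "event_rate",
    "paired_pulse_adaptation",
    "analyze_screening",
]


@dataclass
class SpikeTrain:
    """Sorted spike times of a single unit."""

    cell_id: str
    spike_times: np.ndarray
    recording_duration: float
    sample_rate: float

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size:
            if np.any(np.diff(self.spike_times) < 0):
                raise AnalysisError("spike times must be sorted")
            if self.spike_times[0] < 0 or self.spike_times[-1] > self.recording_duration:
                raise AnalysisError("spike times outside the recording")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def count(self, t0: float, t1: float) -> int:
        return int(np.count_nonzero((self.spike_times >= t0) & (self.spike_times < t1)))


@dataclass
class SpikeResponse:
    """Summary of one cell's screening analysis."""

    cell_id: str
    spontaneous_mean: float
    spontaneous_sd: float
    evoked_rates: pd.DataFrame
    urine_responsive: bool
    artificial_urine_responsive: bool
    normalized_pair_frequency: dict[float, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# filtering and detection
# ---------------------------------------------------------------------------


def highpass_filter(
    recording: np.ndarray,
    sample_rate: float,
    cutoff: float = 2.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase high-pass (forward-backward second-order sections) that
    removes DC and slow baseline drift while preserving spike waveforms."""
    nyq = sample_rate / 2.0
    if cutoff >= nyq:
        raise AnalysisError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, cutoff, btype="highpass", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(recording, dtype=float))


def _robust_sd(x: np.ndarray) -> float:
    """Noise SD from the median absolute deviation (spike-resistant)."""
    return float(np.median(np.abs(x - np.median(x))) / 0.6744897501960817)


def detect_spikes(
    filtered: np.ndarray,
    sample_rate: float,
    threshold_sd: float = 4.0,
    threshold_pa: float | None = None,
    refractory: float = 0.002,
    polarity: str = "negative",
    smooth_cutoff: float | None = 800.0,
) -> SpikeTrain:
    """Threshold spike detection on a filtered recording.

    The trace is optionally low-pass smoothed (default 800 Hz) before
    thresholding to suppress single-sample noise excursions.  The threshold
    is ``threshold_sd`` times the robust (MAD-based) noise SD unless an
    absolute ``threshold_pa`` is given; each contiguous supra-threshold run
    yields one spike timestamped at its extremum, and extrema closer than
    the refractory window are merged (larger one kept)."""
    if threshold_pa is not None and threshold_pa <= 0:
        raise AnalysisError("threshold_pa must be > 0")
    if threshold_sd <= 0:
        raise AnalysisError("threshold_sd must be > 0")
    x = np.asarray(filtered, dtype=float)
    if polarity == "negative":
        y = -x
    elif polarity == "positive":
        y = x
    else:
        raise AnalysisError(f"unknown polarity {polarity!r}")
    if smooth_cutoff is not None and smooth_cutoff < sample_rate / 2.0:
        sos = signal.butter(2, smooth_cutoff, btype="lowpass", fs=sample_rate, output="sos")
        y = signal.sosfiltfilt(sos, y)
    if threshold_pa is not None:
        thr = threshold_pa
    else:
        sd = _robust_sd(y)
        # floor guards the noise-free limit, where the MAD collapses to 0
        sd = max(sd, 0.02 * float(np.max(np.abs(y), initial=0.0)))
        thr = threshold_sd * sd
    above = y > thr
    if not above.any():
        return SpikeTrain("", np.empty(0), x.size / sample_rate, sample_rate)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.astype(int), [0]])))
    peaks, heights = [], []
    for a, b in zip(edges[::2], edges[1::2]):
        i = a + int(np.argmax(y[a:b]))
        peaks.append(i)
        heights.append(y[i])
    # refractory merge, keeping the larger extremum
    merged: list[tuple[int, float]] = []
    gap = refractory * sample_rate
    for i, h in zip(peaks, heights):
        if merged and i - merged[-1][0] < gap:
            if h > merged[-1][1]:
                merged[-1] = (i, h)
        else:
            merged.append((i, h))
    times = np.array([i / sample_rate for i, _ in merged])
    return SpikeTrain("", times, x.size / sample_rate, sample_rate)


# ---------------------------------------------------------------------------
# rates and criteria
# ---------------------------------------------------------------------------


def bin_rates(
    train: SpikeTrain, bin_width: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Firing rate (Hz) in consecutive bins; the final partial bin is
    normalized by its actual width.  Returns (bin_edges, rates)."""
    if bin_width <= 0:
        raise AnalysisError("bin_width must be > 0")
    T = train.recording_duration
    edges = np.arange(0.0, T, bin_width)
    edges = np.append(edges, T)
    counts, _ = np.histogram(train.spike_times, bins=edges)
    widths = np.diff(edges)
    return edges, counts / widths


def spontaneous_stats(
    train: SpikeTrain,
    baseline_windows: list[tuple[float, float]],
    unit_width: float = 1.0,
) -> tuple[float, float]:
    """Mean and sample SD of per-window firing rates over baseline intervals
    (carved into ``unit_width``-second windows, stimulus periods excluded
    by construction of the windows)."""
    rates = []
    for lo, hi in baseline_windows:
        n_units = int(np.floor((hi - lo) / unit_width))
        for k in range(n_units):
            a = lo + k * unit_width
            rates.append(train.count(a, a + unit_width) / unit_width)
    if len(rates) < 10:
        raise AnalysisError(
            f"insufficient baseline: {len(rates)} unit windows (< 10)"
        )
    r = np.asarray(rates)
    return float(r.mean()), float(r.std(ddof=1))


def classify_urine_responsive(
    evoked_rate: float,
    spont: tuple[float, float],
    artificial_urine_responsive: bool,
) -> bool:
    """The 2-SD criterion: responsive iff the evoked rate exceeds the
    spontaneous mean + 2 SD and the cell did not respond to artificial
    urine (ionic negative control)."""
    mean, sd = spont
    return bool(evoked_rate > mean + 2.0 * sd) and not artificial_urine_responsive


def event_rate(train: SpikeTrain, event: StimulusEvent, latency: float = 0.0) -> float:
    """Mean firing rate in [onset + latency, offset + latency)."""
    return train.count(event.onset + latency, event.offset + latency) / event.duration


def paired_pulse_adaptation(
    train: SpikeTrain, protocol: StimulusProtocol, latency: float = 0.0
) -> pd.DataFrame:
    """Second-pulse firing rate normalized to the first, per pulse pair.

    Returns a frame with columns pair, isi_s, rate1_hz, rate2_hz, ratio.
    Pairs with a silent first pulse have no defined ratio (NaN, with a
    warning)."""
    pairs: dict[int, dict[int, StimulusEvent]] = {}
    for ev in protocol.events:
        if ev.pair_index is not None:
            pairs.setdefault(ev.pair_index, {})[ev.trial_index] = ev
    if not pairs:
        raise AnalysisError("protocol contains no labelled pulse pairs")
    rows = []
    for pair in sorted(pairs):
        if set(pairs[pair]) != {1, 2}:
            raise AnalysisError(f"pulse pair {pair} is incomplete")
        p1, p2 = pairs[pair][1], pairs[pair][2]
        isi = p2.onset - p1.offset
        r1 = event_rate(train, p1, latency)
        r2 = event_rate(train, p2, latency)
        if r1 == 0:
            warnings.warn(
                f"pair {pair} (ISI {isi:g} s): no spikes in the first pulse; "
                "normalized frequency undefined",
                stacklevel=2,
            )
            ratio = np.nan
        else:
            ratio = r2 / r1
        rows.append((pair, float(isi), r1, r2, ratio))
    return pd.DataFrame(rows, columns=["pair", "isi_s", "rate1_hz", "rate2_hz", "ratio"])


def analyze_screening(
    train: SpikeTrain,
    protocol: StimulusProtocol,
    cell_id: str = "",
    unit_width: float = 1.0,
) -> SpikeResponse:
    """Responsiveness screening: spontaneous statistics from the silent
    period before the first stimulus, mean evoked rate per stimulus type,
    and the 2-SD urine criterion with the artificial-urine veto (artificial
    urine is itself evaluated by the same 2-SD rule)."""
    first_onset = protocol.events[0].onset
    spont = spontaneous_stats(train, [(0.0, first_onset)], unit_width)
    rows = [
        (ev.stimulus_id, ev.trial_index, event_rate(train, ev))
        for ev in protocol.events
    ]
    rates = pd.DataFrame(rows, columns=["stimulus", "trial", "rate_hz"])

    def mean_rate(stim: str) -> float:
        sel = rates.loc[rates["stimulus"] == stim, "rate_hz"]
        return float(sel.mean()) if len(sel) else np.nan

    au_rate = mean_rate(ARTIFICIAL_URINE)
    au_resp = (
        bool(au_rate > spont[0] + 2.0 * spont[1]) if np.isfinite(au_rate) else False
    )
    urine_rate = mean_rate("urine")
    urine_resp = (
        classify_urine_responsive(urine_rate, spont, au_resp)
        if np.isfinite(urine_rate)
        else False
    )
    return SpikeResponse(
        cell_id=cell_id,
        spontaneous_mean=spont[0],
        spontaneous_sd=spont[1],
        evoked_rates=rates,
        urine_responsive=urine_resp,
        artificial_urine_responsive=au_resp,
    )
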