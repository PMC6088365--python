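"""ROI trace extraction, dF/F computation and responsiveness classification.

Two dF/F conventions are implemented, matching the two imaging modalities:

* trace mode (confocal, ~1 Hz frame rate): a baseline window before each
  stimulus yields F0 and its standard deviation; dF/F is computed over the
  whole trace and per-stimulus amplitudes are taken as the peak dF/F inside
  a response window,
* stack-trial mode (volumetric light-sheet, one stack every ~3 s): the
  amplitude of each trial is (mean of the stacks during the stimulus minus
  mean of the stacks immediately before it) divided by the prestimulus mean.

Responsiveness uses three criteria: a robust high-K+ transient (viability),
an excursion above baseline mean + 3 SD sustained for at least 3 s, and a
threshold crossing beginning within the stimulus-application window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .protocols import HIGHK, StimulusEvent, StimulusProtocol

__all__ = [
    "TraceMatrix",
    "DffTrace",
    "RESPONSE_COLUMNS",
    "extract_roi_traces",
    "compute_dff_trace",
    "compute_trial_dff",
    "classify_responsive",
    "check_highK_response",
    "peak_amplitude",
    "confocal_response_table",
    "flag_high_baseline_cells",
]

#: canonical column order of a ResponseTable
RESPONSE_COLUMNS = [
    "cell_id", "block", "trial", "stimulus", "dff", "responsive", "peak_time_s",
]


@dataclass
class TraceMatrix:
    """roi x frame fluorescence with shared timestamps."""

    cell_ids: list[str]
    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(np.diff(self.timestamps) <= 0):
            raise AnalysisError("timestamps must be strictly increasing")
        if self.values.shape != (len(self.cell_ids), self.timestamps.size):
            raise AnalysisError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {self.timestamps.size} frames"
            )

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def row(self, cell_id: str) -> np.ndarray:
        return self.values[self.cell_ids.index(cell_id)]

    # -- I/O (long CSV: cell_id, time_s, fluorescence) ------------------

    def to_long_frame(self) -> pd.DataFrame:
        n = self.timestamps.size
        return pd.DataFrame(
            {
                "cell_id": np.repeat(self.cell_ids, n),
                "time_s": np.tile(self.timestamps, self.n_cells),
                "fluorescence": self.values.ravel(),
            }
        )

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "TraceMatrix":
        cells = list(dict.fromkeys(df["cell_id"]))
        first = df[df["cell_id"] == cells[0]]
        ts = first["time_s"].to_numpy(dtype=float)
        values = np.vstack(
            [df.loc[df["cell_id"] == c, "fluorescence"].to_numpy() for c in cells]
        )
        return cls(cells, ts, values)

    def to_csv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TraceMatrix":
        return cls.from_long_frame(pd.read_csv(path))


@dataclass
class DffTrace:
    """Relative fluorescence change of one cell, with its baseline stats
    (baseline mean and SD are in raw intensity units)."""

    cell_id: str
    timestamps: np.ndarray
    dff: np.ndarray
    baseline_mean: float
    baseline_sd: float

    def __post_init__(self) -> None:
        if self.baseline_sd < 0:
            raise AnalysisError("baseline_sd must be >= 0")

    @property
    def dff_threshold(self) -> float:
        """Baseline mean + k SD expressed in dF/F units is k * this value."""
        return self.baseline_sd / self.baseline_mean


# ---------------------------------------------------------------------------
# extraction and dF/F
# ---------------------------------------------------------------------------


def extract_roi_traces(
    stacks: np.ndarray,
    masks: np.ndarray,
    timestamps: np.ndarray | None = None,
    labels: Sequence[int] | None = None,
) -> TraceMatrix:
    """Mean intensity over each ROI mask for every stack.

    ``masks`` is a label image (0 = background).  ``labels`` defaults to the
    nonzero labels present; an explicitly requested label with no pixels
    raises an error naming it."""
    stacks = np.asarray(stacks, dtype=float)
    masks = np.asarray(masks)
    if stacks.shape[1:] != masks.shape:
        raise AnalysisError(
            f"stack spatial shape {stacks.shape[1:]} != mask shape {masks.shape}"
        )
    if labels is None:
        labels = [int(v) for v in np.unique(masks) if v != 0]
    traces = []
    for lab in labels:
        sel = masks == lab
        if not sel.any():
            raise AnalysisError(f"ROI label {lab} has no pixels in the mask")
        traces.append(stacks[:, sel].mean(axis=1))
    if timestamps is None:
        timestamps = np.arange(stacks.shape[0], dtype=float)
    return TraceMatrix([f"roi_{lab}" for lab in labels], timestamps, np.vstack(traces))


def compute_dff_trace(
    values: np.ndarray,
    timestamps: np.ndarray,
    baseline_window: tuple[float, float],
    cell_id: str = "",
    protocol: StimulusProtocol | None = None,
) -> DffTrace:
    """dF/F against the mean of ``baseline_window`` (>= 3 samples, stimulus
    free when a protocol is supplied)."""
    values = np.asarray(values, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    lo, hi = baseline_window
    sel = (timestamps >= lo) & (timestamps < hi)
    if sel.sum() < 3:
        raise AnalysisError(
            f"baseline window [{lo}, {hi}) contains {int(sel.sum())} samples (< 3)"
        )
    if protocol is not None:
        for ev in protocol.events:
            if ev.onset < hi and ev.offset > lo:
                raise AnalysisError(
                    f"baseline window [{lo}, {hi}) overlaps stimulus "
                    f"'{ev.stimulus_id}' at {ev.onset} s"
                )
    f0 = float(values[sel].mean())
    if f0 <= 0:
        raise AnalysisError(f"non-physical baseline: F0 = {f0}")
    sd = float(values[sel].std(ddof=1))
    return DffTrace(cell_id, timestamps, (values - f0) / f0, f0, sd)


def peak_amplitude(
    dff: DffTrace, window: tuple[float, float]
) -> tuple[float, float]:
    """Maximum dF/F in ``window`` and the time at which it occurs."""
    lo, hi = window
    sel = (dff.timestamps >= lo) & (dff.timestamps <= hi)
    if not sel.any():
        raise AnalysisError(f"window [{lo}, {hi}] contains no samples")
    vals = dff.dff[sel]
    ts = dff.timestamps[sel]
    i = int(np.argmax(vals))
    return float(vals[i]), float(ts[i])


# ---------------------------------------------------------------------------
# responsiveness criteria
# ---------------------------------------------------------------------------


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of contiguous True runs (stop exclusive)."""
    out = []
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(int), [0]])))
    for a, b in zip(idx[::2], idx[1::2]):
        out.append((int(a), int(b)))
    return out


def classify_responsive(
    dff: DffTrace,
    event: StimulusEvent,
    highK_ok: bool,
    min_duration: float = 3.0,
    sd_mult: float = 3.0,
    response_window: float | None = None,
) -> bool:
    """Three-criteria responsiveness call for one stimulus.

    True iff (1) the cell produced a robust high-K+ transient
    (``highK_ok``), (2) dF/F exceeded baseline mean + ``sd_mult`` SD
    continuously for at least ``min_duration`` seconds, and (3) the
    threshold crossing began within ``response_window`` seconds of stimulus
    onset (default: the stimulus duration)."""
    if response_window is None:
        response_window = event.duration
    if event.onset + response_window > dff.timestamps[-1]:
        raise AnalysisError("response window extends beyond the recording")
    if not highK_ok:
        return False
    thr = sd_mult * dff.dff_threshold
    dt = float(np.median(np.diff(dff.timestamps)))
    above = dff.dff > thr
    for a, b in _runs_above(above):
        run_duration = (b - a) * dt  # frame coverage
        starts_in_window = (
            event.onset <= dff.timestamps[a] <= event.onset + response_window
        )
        if starts_in_window and run_duration >= min_duration:
            return True
    return False


def check_highK_response(
    dff: DffTrace,
    highK_event: StimulusEvent | None,
    sd_mult: float = 3.0,
    decay_margin: float = 10.0,
) -> bool:
    """Criterion (1): a robust Ca2+ transient under high extracellular K+,
    quantified as a peak > baseline mean + ``sd_mult`` SD inside the high-K+
    window (plus an indicator decay margin)."""
    if highK_event is None or highK_event.stimulus_id != HIGHK:
        raise AnalysisError("protocol has no high-K+ event")
    peak, _ = peak_amplitude(
        dff, (highK_event.onset, highK_event.offset + decay_margin)
    )
    return peak > sd_mult * dff.dff_threshold


# ---------------------------------------------------------------------------
# trial tables
# ---------------------------------------------------------------------------


def _rest_noise_sd(
    values: np.ndarray, timestamps: np.ndarray, first_onset: float
) -> tuple[float, float]:
    """(mean, SD) of the raw trace over the silent pre-stimulus rest."""
    sel = timestamps < first_onset
    if sel.sum() < 3:
        raise AnalysisError("fewer than 3 pre-stimulus rest frames")
    return float(values[sel].mean()), float(values[sel].std(ddof=1))


def compute_trial_dff(
    traces: TraceMatrix,
    protocol: StimulusProtocol,
    n_pre: int = 3,
    n_during: int = 3,
    sd_mult: float = 3.0,
) -> pd.DataFrame:
    """Per-trial dF/F amplitudes for volumetric stack data (ResponseTable).

    For each stimulus event the amplitude is (mean of the first ``n_during``
    stacks at/after onset minus mean of the ``n_pre`` stacks immediately
    preceding onset) divided by the prestimulus mean.  A trial is flagged
    responsive when its amplitude exceeds ``sd_mult`` times the amplitude
    noise expected from the cell's rest-period variability."""
    ts = traces.timestamps
    rows = []
    first_onset = protocol.events[0].onset
    rest = [
        _rest_noise_sd(traces.values[i], ts, first_onset)
        for i in range(traces.n_cells)
    ]
    for ev in protocol.events:
        pre_idx = np.flatnonzero(ts < ev.onset)[-n_pre:]
        if pre_idx.size < n_pre:
            raise AnalysisError(
                f"event '{ev.stimulus_id}' at {ev.onset} s has fewer than "
                f"{n_pre} prestimulus stacks"
            )
        during_idx = np.flatnonzero((ts >= ev.onset) & (ts < ev.offset))[:n_during]
        if during_idx.size < n_during:
            raise AnalysisError(
                f"event '{ev.stimulus_id}' at {ev.onset} s has fewer than "
                f"{n_during} stacks during stimulation"
            )
        pre = traces.values[:, pre_idx].mean(axis=1)
        during = traces.values[:, during_idx].mean(axis=1)
        amp = (during - pre) / pre
        peak_t = ts[during_idx[0]]
        for i, cell in enumerate(traces.cell_ids):
            mean_rest, sd_rest = rest[i]
            amp_noise_sd = sd_rest * np.sqrt(1.0 / n_pre + 1.0 / n_during) / mean_rest
            rows.append(
                (
                    cell, ev.block_index, ev.trial_index, ev.stimulus_id,
                    float(amp[i]), bool(amp[i] > sd_mult * amp_noise_sd),
                    float(peak_t),
                )
            )
    df = pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
    df["block"] = df["block"].astype("Int64")
    df["trial"] = df["trial"].astype("Int64")
    return df


def confocal_response_table(
    traces: TraceMatrix,
    protocol: StimulusProtocol,
    baseline_s: float = 10.0,
    peak_margin: float = 10.0,
    sd_mult: float = 3.0,
    min_duration: float = 3.0,
) -> pd.DataFrame:
    """Per-stimulus peak dF/F amplitudes for trace (confocal) data.

    The baseline is re-estimated from the ``baseline_s`` seconds immediately
    preceding each stimulus so that slow drift does not inflate amplitudes;
    the peak is searched from onset to offset + ``peak_margin`` (indicator
    decay).  The responsive flag applies all three criteria, with the
    high-K+ gate taken from the protocol's high-K+ event if present."""
    ts = traces.timestamps
    highk_events = protocol.events_for(HIGHK)
    rows = []
    for i, cell in enumerate(traces.cell_ids):
        values = traces.values[i]
        highk_ok = True
        if highk_events:
            ev = highk_events[0]
            d = compute_dff_trace(
                values, ts, (ev.onset - baseline_s, ev.onset), cell_id=cell
            )
            highk_ok = check_highK_response(d, ev, sd_mult=sd_mult)
        for ev in protocol.events:
            dff = compute_dff_trace(
                values, ts, (ev.onset - baseline_s, ev.onset), cell_id=cell
            )
            peak, peak_t = peak_amplitude(
                dff, (ev.onset, ev.offset + peak_margin)
            )
            if ev.stimulus_id == HIGHK:
                responsive = highk_ok
            else:
                responsive = classify_responsive(
                    dff, ev, highk_ok, min_duration=min_duration, sd_mult=sd_mult
                )
            rows.append(
                (
                    cell, ev.block_index, ev.trial_index, ev.stimulus_id,
                    float(peak), bool(responsive), float(peak_t),
                )
            )
    df = pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
    df["block"] = df["block"].astype("Int64")
    df["trial"] = df["trial"].astype("Int64")
    return df


def flag_high_baseline_cells(
    traces: TraceMatrix,
    protocol: StimulusProtocol,
    baseline_window: tuple[float, float],
    sd_mult: float = 3.0,
    min_duration: float = 3.0,
    margin: float = 10.0,
) -> list[str]:
    """Optional spontaneous-activity filter (off by default in pipelines).

    Returns cells whose dF/F crosses the ``sd_mult``-SD threshold for at
    least ``min_duration`` seconds entirely outside every stimulus window
    (stimulus windows are extended by ``margin`` s for indicator decay).
    Such cells would have been excluded by eye in a manual workflow."""
    flagged = []
    dt = float(np.median(np.diff(traces.timestamps)))
    for i, cell in enumerate(traces.cell_ids):
        dff = compute_dff_trace(
            traces.values[i], traces.timestamps, baseline_window, cell_id=cell
        )
        above = dff.dff > sd_mult * dff.dff_threshold
        for a, b in _runs_above(above):
            if (b - a) * dt < min_duration:
                continue
            t0, t1 = dff.timestamps[a], dff.timestamps[b - 1]
            inside = any(
                t0 < ev.offset + margin and t1 > ev.onset for ev in protocol.events
            )
            if not inside:
                flagged.append(cell)
                break
    return flagged
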