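"""Stimulation timelines for vomeronasal sensory-neuron (VSN) adaptation assays.

A protocol is an explicit schedule of timed stimulus events shared by the
synthetic-data generator and every analysis stage.  Three paradigms are
supported:

* a decreasing-ISI sequence (repeated urine pulses at 180/60/30-s intervals,
  optionally followed by a recovery probe and a terminal high-K+ viability
  control),
* accelerating / decelerating block designs in which two ligands are applied
  in blocks of consecutive trials while the interstimulus interval shrinks
  or grows between blocks,
* paired-pulse designs for spike-frequency adaptation (two identical pulses
  per interpulse interval, with long recovery gaps between pairs).

Throughout the package the interstimulus interval (ISI) is defined
offset-to-onset: the time from the end of one stimulus to the start of the
next.  Times are continuous seconds; sampling grids are derived downstream
from ``acquisition_rate`` and never stored in the protocol itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ProtocolError

__all__ = [
    "StimulusEvent",
    "StimulusProtocol",
    "build_decreasing_isi_protocol",
    "build_block_protocol",
    "build_paired_pulse_protocol",
    "build_screening_protocol",
]

ISI_CONVENTION = "offset-to-onset"

#: stimulus labels with fixed meaning across the package
HIGHK = "highK"
ARTIFICIAL_URINE = "artificial_urine"


@dataclass(frozen=True)
class StimulusEvent:
    """A single timed stimulus application.

    ``block_index``/``trial_index`` are 1-based labels used by the block
    paradigms; ``pair_index`` labels paired-pulse experiments.
    """

    stimulus_id: str
    onset: float
    duration: float
    block_index: int | None = None
    trial_index: int | None = None
    pair_index: int | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ProtocolError(
                f"event '{self.stimulus_id}': duration must be > 0, got {self.duration}"
            )
        if self.onset < 0:
            raise ProtocolError(
                f"event '{self.stimulus_id}': onset must be >= 0, got {self.onset}"
            )

    @property
    def offset(self) -> float:
        """Stimulus end time (s)."""
        return self.onset + self.duration


@dataclass(frozen=True)
class StimulusProtocol:
    """An ordered, non-overlapping schedule of stimulus events."""

    events: tuple[StimulusEvent, ...]
    acquisition_rate: float
    total_duration: float
    isi_convention: str = ISI_CONVENTION

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        if self.acquisition_rate <= 0:
            raise ProtocolError("acquisition_rate must be > 0")
        if self.isi_convention != ISI_CONVENTION:
            raise ProtocolError(f"unsupported ISI convention: {self.isi_convention!r}")
        prev: StimulusEvent | None = None
        for ev in self.events:
            if prev is not None:
                if ev.onset <= prev.onset:
                    raise ProtocolError("event onsets must be strictly increasing")
                if ev.onset < prev.offset:
                    raise ProtocolError(
                        f"events overlap: '{prev.stimulus_id}' at {prev.onset} s and "
                        f"'{ev.stimulus_id}' at {ev.onset} s"
                    )
            prev = ev
        if self.events and self.total_duration < self.events[-1].offset:
            raise ProtocolError("total_duration must cover the last event")

    # -- convenience ---------------------------------------------------

    def frame_times(self) -> np.ndarray:
        """Acquisition timestamps derived from ``acquisition_rate``."""
        dt = 1.0 / self.acquisition_rate
        n = int(np.floor(self.total_duration / dt)) + 1
        return np.arange(n) * dt

    def events_for(self, stimulus_id: str) -> tuple[StimulusEvent, ...]:
        return tuple(ev for ev in self.events if ev.stimulus_id == stimulus_id)

    @property
    def test_events(self) -> tuple[StimulusEvent, ...]:
        """Events that are test stimuli (neither high-K+ nor artificial urine)."""
        return tuple(
            ev for ev in self.events if ev.stimulus_id not in (HIGHK, ARTIFICIAL_URINE)
        )

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "isi_convention": self.isi_convention,
            "acquisition_rate": self.acquisition_rate,
            "total_duration": self.total_duration,
            "events": [asdict(ev) for ev in self.events],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        events = tuple(StimulusEvent(**ev) for ev in d["events"])
        return cls(
            events=events,
            acquisition_rate=d["acquisition_rate"],
            total_duration=d["total_duration"],
            isi_convention=d.get("isi_convention", ISI_CONVENTION),
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "StimulusProtocol":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


def _check_positive(name: str, values: Iterable[float]) -> None:
    for v in values:
        if v <= 0:
            raise ProtocolError(f"{name} must be > 0, got {v}")


def build_decreasing_isi_protocol(
    isis: Sequence[float],
    stim_duration: float,
    recovery_probe_isi: float | None = None,
    include_highK: bool = False,
    stimulus_id: str = "urine",
    initial_rest: float = 60.0,
    highK_isi: float = 180.0,
    highK_duration: float | None = None,
    acquisition_rate: float = 1.0,
    tail: float = 30.0,
) -> StimulusProtocol:
    """Repeated single-stimulus exposures at decreasing ISIs.

    Produces ``1 + len(isis)`` test stimuli (consecutive onsets obey
    ``onset[k+1] = onset[k] + stim_duration + isis[k]``), optionally a
    recovery probe after ``recovery_probe_isi`` and a terminal high-K+
    viability control after ``highK_isi``.  ``initial_rest`` is the silent
    pre-stimulus period used downstream for baseline estimation.
    """
    _check_positive("stim_duration", [stim_duration])
    _check_positive("ISI", isis)
    if initial_rest < 0:
        raise ProtocolError("initial_rest must be >= 0")
    all_isis = list(isis)
    if recovery_probe_isi is not None:
        _check_positive("recovery_probe_isi", [recovery_probe_isi])
        all_isis.append(recovery_probe_isi)

    events: list[StimulusEvent] = []
    t = float(initial_rest)
    for k in range(len(all_isis) + 1):
        events.append(
            StimulusEvent(stimulus_id, onset=t, duration=stim_duration, trial_index=k + 1)
        )
        if k < len(all_isis):
            t += stim_duration + all_isis[k]
    if include_highK:
        _check_positive("highK_isi", [highK_isi])
        dur = stim_duration if highK_duration is None else highK_duration
        events.append(
            StimulusEvent(HIGHK, onset=events[-1].offset + highK_isi, duration=dur)
        )
    total = events[-1].offset + tail
    return StimulusProtocol(tuple(events), acquisition_rate, total)


def build_block_protocol(
    direction: str,
    block_isis: Sequence[float],
    ligands: tuple[str, str] = ("DCA", "CA"),
    trials_per_ligand: int = 3,
    stim_duration: float = 15.0,
    initial_rest: float = 60.0,
    acquisition_rate: float = 1.0 / 3.0,
    tail: float = 30.0,
) -> StimulusProtocol:
    """Block design: per block, ``trials_per_ligand`` consecutive trials of
    ligand A, then of ligand B, with within-block gaps equal to the block's
    ISI.  At block transitions the *upcoming* block's ISI is used.

    ``direction`` must be ``"accelerating"`` (strictly decreasing ISIs) or
    ``"decelerating"`` (strictly increasing ISIs).
    """
    if direction not in ("accelerating", "decelerating"):
        raise ProtocolError(f"unknown direction {direction!r}")
    if trials_per_ligand < 1:
        raise ProtocolError("trials_per_ligand must be >= 1")
    if len(ligands) != 2 or ligands[0] == ligands[1]:
        raise ProtocolError("ligands must be two distinct labels")
    _check_positive("block ISI", block_isis)
    _check_positive("stim_duration", [stim_duration])
    diffs = np.diff(np.asarray(block_isis, dtype=float))
    if direction == "accelerating" and not np.all(diffs < 0):
        raise ProtocolError("accelerating protocol requires strictly decreasing block ISIs")
    if direction == "decelerating" and not np.all(diffs > 0):
        raise ProtocolError("decelerating protocol requires strictly increasing block ISIs")

    events: list[StimulusEvent] = []
    t = float(initial_rest)
    for b, isi in enumerate(block_isis, start=1):
        if b > 1:
            # gap between block b-1 and b equals block b's ISI
            t = events[-1].offset + isi
        first_in_block = True
        for ligand in ligands:
            for trial in range(1, trials_per_ligand + 1):
                if not first_in_block:
                    t = events[-1].offset + isi
                events.append(
                    StimulusEvent(
                        ligand, onset=t, duration=stim_duration,
                        block_index=b, trial_index=trial,
                    )
                )
                first_in_block = False
    total = events[-1].offset + tail
    return StimulusProtocol(tuple(events), acquisition_rate, total)


def build_paired_pulse_protocol(
    isis: Sequence[float],
    pulse_duration: float = 5.0,
    inter_experiment_gap: float = 120.0,
    min_gap: float = 120.0,
    stimulus_id: str = "urine",
    initial_rest: float = 0.0,
    acquisition_rate: float = 5000.0,
    tail: float = 30.0,
) -> StimulusProtocol:
    """One pulse pair per ISI (offset-to-onset spacing), pairs separated by
    ``inter_experiment_gap`` (floor ``min_gap``, default 2 min so adaptation
    resets between pairs)."""
    if len(isis) == 0:
        raise ProtocolError("at least one interpulse interval is required")
    _check_positive("interpulse interval", isis)
    _check_positive("pulse_duration", [pulse_duration])
    if inter_experiment_gap < min_gap:
        raise ProtocolError(
            f"inter_experiment_gap {inter_experiment_gap} s below floor {min_gap} s"
        )
    events: list[StimulusEvent] = []
    t = float(initial_rest)
    for pair, isi in enumerate(isis, start=1):
        events.append(
            StimulusEvent(stimulus_id, onset=t, duration=pulse_duration,
                          pair_index=pair, trial_index=1)
        )
        events.append(
            StimulusEvent(stimulus_id, onset=events[-1].offset + isi,
                          duration=pulse_duration, pair_index=pair, trial_index=2)
        )
        t = events[-1].offset + inter_experiment_gap
    total = events[-1].offset + tail
    return StimulusProtocol(tuple(events), acquisition_rate, total)


def build_screening_protocol(
    n_repeats: int = 3,
    pulse_duration: float = 5.0,
    gap: float = 120.0,
    initial_rest: float = 60.0,
    acquisition_rate: float = 5000.0,
    tail: float = 30.0,
) -> StimulusProtocol:
    """Responsiveness screening for loose-patch recordings: repeated high-K+
    pulses (viability), then urine, then artificial urine (negative control),
    each ``n_repeats`` times with long recovery gaps."""
    if n_repeats < 1:
        raise ProtocolError("n_repeats must be >= 1")
    events: list[StimulusEvent] = []
    t = float(initial_rest)
    for stim in (HIGHK, "urine", ARTIFICIAL_URINE):
        for trial in range(1, n_repeats + 1):
            events.append(
                StimulusEvent(stim, onset=t, duration=pulse_duration, trial_index=trial)
            )
            t = events[-1].offset + gap
    total = events[-1].offset + tail
    return StimulusProtocol(tuple(events), acquisition_rate, total)
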