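"""Adaptation statistics: normalized amplitudes, adapting/non-adapting
classification, intrablock and interblock indices, selectivity clustering,
population discriminability (d') and recovery.

Conventions
-----------
* Normalized amplitudes are percentages of the initial response.
* A cell is "adapting" when its final normalized amplitude is < 95 %
  (the boundary value 95.0 counts as non-adapting).
* The intrablock index I(b) = (dFF_t3 - dFF_t1) / (dFF_t1 + 0.1) compares
  the third and first trials of a block; the 0.1 denominator offset guards
  the divide-by-zero pole.  Negative values indicate within-block adaptation.
* Interblock adaptation is the first-trial dF/F of each block normalized to
  the cell's maximal dF/F across all trials of that stimulus.
* d' = (mean_A - mean_B) / sqrt((sd_A^2 + sd_B^2) / 2), computed on
  within-cell normalized responses (each cell's dF/F divided by its maximum
  across all trials), sample SDs with n-1 denominator.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError

__all__ = [
    "normalize_to_initial",
    "classify_adapting",
    "intrablock_index",
    "interblock_normalize",
    "assign_selectivity",
    "discriminability",
    "discriminability_series",
    "recovery_percent",
    "adaptation_summary",
]


def normalize_to_initial(amplitudes: Sequence[float]) -> np.ndarray:
    """Signal strength as a percentage of the initial response amplitude."""
    amps = np.asarray(amplitudes, dtype=float)
    if amps.size == 0:
        raise AnalysisError("empty amplitude sequence")
    if amps[0] == 0:
        raise AnalysisError("initial amplitude is zero; cannot normalize")
    return 100.0 * amps / amps[0]


def classify_adapting(normalized_final: float, threshold: float = 95.0) -> bool:
    """True (adapting) iff the final normalized amplitude is strictly below
    ``threshold`` percent; values at or above it count as non-adapting."""
    if not np.isfinite(normalized_final):
        raise AnalysisError("normalized_final must be finite")
    return bool(normalized_final < threshold)


def intrablock_index(dff_t1: float, dff_t3: float, offset: float = 0.1) -> float:
    """(dFF_t3 - dFF_t1) / (dFF_t1 + offset); negative = within-block
    adaptation."""
    if not (np.isfinite(dff_t1) and np.isfinite(dff_t3)):
        raise AnalysisError("trial amplitudes must be finite")
    denom = dff_t1 + offset
    if denom == 0:
        raise AnalysisError(f"degenerate denominator: dff_t1 == {-offset}")
    return (dff_t3 - dff_t1) / denom


def interblock_normalize(
    responses: pd.DataFrame, stimulus: str | None = None
) -> pd.DataFrame:
    """First-trial dF/F per block normalized to the cell's maximal dF/F
    across all trials of that stimulus.

    ``responses`` is a ResponseTable.  Cells whose maximal response is <= 0
    cannot be normalized; they are excluded and marked in the ``excluded``
    output (one frame returned with columns cell_id, stimulus, block,
    norm_first_trial, excluded)."""
    df = responses.dropna(subset=["block"])
    if stimulus is not None:
        df = df[df["stimulus"] == stimulus]
    if df.empty:
        raise AnalysisError("no block-labelled trials to normalize")
    rows = []
    for (cell, stim), grp in df.groupby(["cell_id", "stimulus"], sort=False):
        peak = grp["dff"].max()
        bad = peak <= 0
        firsts = grp[grp["trial"] == 1]
        for _, r in firsts.iterrows():
            rows.append(
                (
                    cell, stim, int(r["block"]),
                    np.nan if bad else r["dff"] / peak, bad,
                )
            )
    return pd.DataFrame(
        rows, columns=["cell_id", "stimulus", "block", "norm_first_trial", "excluded"]
    )


def assign_selectivity(
    responses: pd.DataFrame,
    basis_blocks: Sequence[int] = (1, 2),
    ligands: tuple[str, str] = ("DCA", "CA"),
    min_responsive: int | None = None,
) -> pd.DataFrame:
    """Assign each cell to ligandA_only / ligandB_only / both / unresponsive
    from its pattern of responsiveness across the basis blocks.

    A cell counts as responsive to a ligand when at least ``min_responsive``
    of its basis-block trials of that ligand are flagged responsive
    (default: a majority)."""
    basis = responses[responses["block"].isin(list(basis_blocks))]
    rows = []
    for lig in ligands:
        if not (basis["stimulus"] == lig).any():
            raise AnalysisError(f"basis blocks contain no trials of {lig!r}")
    for cell, grp in basis.groupby("cell_id", sort=False):
        flags = {}
        for lig in ligands:
            trials = grp[grp["stimulus"] == lig]
            n = len(trials)
            m = min_responsive if min_responsive is not None else n // 2 + 1
            flags[lig] = int(trials["responsive"].sum()) >= m
        if flags[ligands[0]] and flags[ligands[1]]:
            cls = "both"
        elif flags[ligands[0]]:
            cls = "ligandA_only"
        elif flags[ligands[1]]:
            cls = "ligandB_only"
        else:
            cls = "unresponsive"
        rows.append((cell, cls, tuple(basis_blocks)))
    return pd.DataFrame(rows, columns=["cell_id", "sel_class", "basis_blocks"])


def discriminability(
    responses_a: Sequence[float], responses_b: Sequence[float]
) -> float:
    """d' between two groups of (normalized) responses.

    Sign convention: first argument minus second."""
    a = np.asarray(responses_a, dtype=float)
    b = np.asarray(responses_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise AnalysisError("both groups need n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = (va + vb) / 2.0
    if pooled <= 0:
        raise AnalysisError("pooled variance is zero; d' undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled))


def _within_cell_normalized(responses: pd.DataFrame) -> pd.DataFrame:
    """Each cell's dF/F divided by its maximum across all its trials."""
    out = responses.copy()
    out["norm_dff"] = out.groupby("cell_id")["dff"].transform(
        lambda s: s / s.max() if s.max() > 0 else np.nan
    )
    return out


def discriminability_series(
    responses: pd.DataFrame,
    assignments: pd.DataFrame,
    stimulus: str,
    class_a: str = "ligandA_only",
    class_b: str = "ligandB_only",
) -> pd.DataFrame:
    """d' between two selectivity clusters for every (block, trial) of a
    stimulus, computed on within-cell normalized dF/F.

    The per-cell normalization uses the cell's global maximum across all
    trials of all stimuli, so that cells selective for the other ligand
    contribute near-zero normalized responses rather than rescaled noise."""
    merged = _within_cell_normalized(responses).merge(assignments, on="cell_id")
    sub = merged[merged["stimulus"] == stimulus].dropna(subset=["block", "norm_dff"])
    rows = []
    for (block, trial), grp in sub.groupby(["block", "trial"], sort=True):
        a = grp.loc[grp["sel_class"] == class_a, "norm_dff"].to_numpy()
        b = grp.loc[grp["sel_class"] == class_b, "norm_dff"].to_numpy()
        if a.size < 2 or b.size < 2:
            continue
        try:
            dp = discriminability(a, b)
        except AnalysisError:
            continue
        rows.append((int(block), int(trial), dp, a.size, b.size))
    return pd.DataFrame(rows, columns=["block", "trial", "d_prime", "n_a", "n_b"])


def recovery_percent(probe_amplitude: float, initial_amplitude: float) -> float:
    """Probe response as a percentage of the initial response."""
    if initial_amplitude == 0:
        raise AnalysisError("initial amplitude is zero; recovery undefined")
    return 100.0 * probe_amplitude / initial_amplitude


def adaptation_summary(
    responses: pd.DataFrame,
    stimulus: str = "urine",
    final_trial: int = 4,
    probe_trial: int | None = 5,
    threshold: float = 95.0,
    require_responsive: bool = True,
) -> pd.DataFrame:
    """Per-cell adaptation summary for the decreasing-ISI paradigm.

    Returns one row per cell with its normalized amplitudes (percent of the
    initial response, columns ``norm_1..norm_k``), the adapting flag taken
    from the ``final_trial`` amplitude and the recovery percentage at the
    probe.  Cells are included when their initial amplitude is positive and,
    if ``require_responsive``, at least one trial passed the responsiveness
    criteria."""
    sub = responses[responses["stimulus"] == stimulus]
    rows = []
    for cell, grp in sub.groupby("cell_id", sort=False):
        grp = grp.sort_values("trial")
        amps = grp["dff"].to_numpy(dtype=float)
        if amps[0] <= 0:
            continue
        if require_responsive and not grp["responsive"].any():
            continue
        norm = normalize_to_initial(amps)
        trials = grp["trial"].to_numpy()
        by_trial = dict(zip(trials, norm))
        if final_trial not in by_trial:
            raise AnalysisError(f"cell {cell} has no trial {final_trial}")
        rec = (
            recovery_percent(by_trial[probe_trial], 100.0)
            if probe_trial is not None and probe_trial in by_trial
            else np.nan
        )
        rows.append(
            {
                "cell_id": cell,
                **{f"norm_{int(t)}": v for t, v in by_trial.items()},
                "adapting": classify_adapting(by_trial[final_trial], threshold),
                "recovery_percent": rec,
            }
        )
    if not rows:
        raise AnalysisError("no analyzable cells (zero initial amplitudes?)")
    return pd.DataFrame(rows)
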