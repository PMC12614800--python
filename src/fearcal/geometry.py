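"""Population vector distance (PVD) between CS and US representations.

The US reference is the per-cell mean baselined response over the 5 s after
shock onset, averaged across shocks. Each 30 s CS presentation yields one
population vector per analysis bin; the mean Euclidean distance of those
vectors to the US reference is the presentation's PVD. Changes are reported
as percentages of the first CS/US pairing (within conditioning) or of the
habituation-day distance (across days); negative change means CS and US
representations converge. Cluster-removal ablations quantify which response
archetypes carry the convergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import HABITUATION, AlignedTensor

US_WINDOW = 5.0
CS_WINDOW = 30.0
EARLY_PAIRINGS = (0, 1)   # pairings 1-2 (0-based)
LATE_PAIRINGS = (3, 4)    # pairings 4-5


def us_reference_vector(us_tensor: AlignedTensor, window: float | None = None) -> np.ndarray:
    """Per-cell mean baselined US response over [0, window) s, across trials.

    ``None`` uses the full post-onset extent of the tensor.
    """
    if us_tensor.n_trials < 1:
        raise ValueError("need at least one US trial")
    return us_tensor.post(window).mean(axis=(1, 2))


def pvd_per_presentation(
    cs_tensor: AlignedTensor,
    us_vector: np.ndarray,
    window: float | None = None,
    mode: str = "per_bin",
) -> np.ndarray:
    """Mean Euclidean distance of CS population vectors to the US reference.

    ``per_bin`` (default) computes one distance per analysis bin of the
    30 s response and averages them within each presentation;
    ``mean_vector`` first averages the response over the window and takes
    a single distance — the alternative reading of "30 s binned responses".
    """
    us_vector = np.asarray(us_vector, dtype=float)
    if cs_tensor.n_cells != len(us_vector):
        raise ValueError("cell sets of CS tensor and US vector differ")
    post = cs_tensor.post(window)                      # (cells, trials, bins)
    if mode == "per_bin":
        diff = post - us_vector[:, None, None]
        return np.sqrt((diff**2).sum(axis=0)).mean(axis=1)
    if mode == "mean_vector":
        diff = post.mean(axis=2) - us_vector[:, None]
        return np.sqrt((diff**2).sum(axis=0))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class PvdResult:
    """Per-presentation (or per-day) PVD with normalized change."""

    distances: np.ndarray        # per presentation
    change_pct: np.ndarray       # 100 * (d_t - d_ref) / d_ref
    early_mean: float            # mean change, pairings 1-2
    late_mean: float             # mean change, pairings 4-5
    reference: str = "first_pairing"
    ablation: str = "All cells"

    @property
    def late_minus_early(self) -> float:
        return self.late_mean - self.early_mean

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "presentation": np.arange(1, len(self.distances) + 1),
            "distance": self.distances,
            "change_pct": self.change_pct,
            "ablation": self.ablation,
        })


def pvd_conditioning(
    cs_tensor: AlignedTensor,
    us_tensor: AlignedTensor,
    window: float | None = None,
    us_window: float | None = None,
    mode: str = "per_bin",
    ablation: str = "All cells",
) -> PvdResult:
    """PVD change across the five CS/US pairings of the conditioning session.

    Change per presentation is normalized to the first pairing:
    ``100 * (d_t - d_1) / d_1``; the early (pairings 1-2) and late
    (pairings 4-5) means summarize convergence.
    """
    if cs_tensor.n_trials != 5:
        raise ValueError(f"conditioning PVD expects 5 CS presentations, got {cs_tensor.n_trials}")
    us_vec = us_reference_vector(us_tensor, us_window)
    d = pvd_per_presentation(cs_tensor, us_vec, window, mode)
    if d[0] == 0:
        raise ValueError("degenerate reference: first-pairing PVD is 0")
    change = 100.0 * (d - d[0]) / d[0]
    return PvdResult(
        distances=d, change_pct=change,
        early_mean=float(change[list(EARLY_PAIRINGS)].mean()),
        late_mean=float(change[list(LATE_PAIRINGS)].mean()),
        ablation=ablation,
    )


def pvd_ablation(
    cs_tensor: AlignedTensor,
    us_tensor: AlignedTensor,
    removal_sets: dict[str, np.ndarray],
    window: float | None = None,
    us_window: float | None = None,
    mode: str = "per_bin",
) -> pd.DataFrame:
    """Re-run the conditioning PVD with named cell groups removed.

    ``removal_sets`` maps a cluster name to the cell indices to drop; the
    untouched population is reported as "All cells". Removing a set that
    leaves fewer than 2 cells is rejected.
    """
    n = cs_tensor.n_cells
    rows = []
    sets = {"All cells": np.array([], dtype=int), **removal_sets}
    for name, removed in sets.items():
        removed = np.asarray(removed, dtype=int)
        if len(np.setdiff1d(removed, np.arange(n))):
            raise ValueError(f"removal set {name!r} names cells outside the population")
        keep = np.setdiff1d(np.arange(n), removed)
        if len(keep) < 2:
            raise ValueError(f"removing {name!r} leaves fewer than 2 cells")
        res = pvd_conditioning(
            _subset_cells(cs_tensor, keep), _subset_cells(us_tensor, keep),
            window, us_window, mode, ablation=name,
        )
        rows.append({"ablation": name, "early_mean": res.early_mean,
                     "late_mean": res.late_mean,
                     "late_minus_early": res.late_minus_early,
                     "n_cells": len(keep)})
    return pd.DataFrame(rows)


def _subset_cells(tensor: AlignedTensor, idx: np.ndarray) -> AlignedTensor:
    return AlignedTensor(
        label=tensor.label, data=tensor.data[idx], pre_window=tensor.pre_window,
        post_window=tensor.post_window, baseline_window=tensor.baseline_window,
        bin_width=tensor.bin_width, trial_indices=list(tensor.trial_indices),
    )


def pvd_across_days(
    cs_tensors: dict[str, AlignedTensor],
    us_vector: np.ndarray,
    window: float | None = None,
    mode: str = "per_bin",
    reference_day: str = HABITUATION,
) -> pd.DataFrame:
    """Per-day mean PVD (first 4 CS presentations) vs the conditioning US.

    The caller passes tensors already restricted to the across-day trial
    subsets; each day's PVD is the mean over its presentations and the
    change is normalized to the habituation-day distance.
    """
    if reference_day not in cs_tensors:
        raise ValueError(f"reference day {reference_day!r} missing")
    dist = {day: float(pvd_per_presentation(t, us_vector, window, mode).mean())
            for day, t in cs_tensors.items()}
    d_ref = dist[reference_day]
    if d_ref == 0:
        raise ValueError("degenerate reference: habituation PVD is 0")
    return pd.DataFrame([
        {"day": day, "distance": d, "change_pct": 100.0 * (d - d_ref) / d_ref}
        for day, d in dist.items()
    ])
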