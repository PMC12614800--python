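"""Pose-based immobility analysis and behaviour metrics.

Immobility (the imaging proxy for freezing) is any interval of at least 2 s
during which all five core body points — left/right ear base, upper spine,
middle spine, tail base — show frame-to-frame displacement below a
per-animal threshold calibrated within 0.7–3.5 px/frame. Neural activity is
aligned to bout onsets/offsets (excluding bouts overlapping a CS), and a
discrimination score DS = (Imm_CS+ - Imm_CS-)/(Imm_CS+ + Imm_CS-)
summarizes cue discrimination from CS-evoked immobility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .protocol import (
    CS_MINUS,
    CS_PLUS,
    AlignedTensor,
    AucTable,
    EventTable,
    TracePopulation,
)

logger = logging.getLogger("fearcal")

BODY_PARTS = (
    "nose",
    "miniscope_base",
    "left_ear_base",
    "right_ear_base",
    "neck",
    "upper_spine",
    "middle_spine",
    "tail_base",
)
#: points entering the immobility criterion
DISPLACEMENT_POINTS = (
    "left_ear_base",
    "right_ear_base",
    "upper_spine",
    "middle_spine",
    "tail_base",
)
DEFAULT_LIKELIHOOD_THRESHOLD = 0.9
DEFAULT_DISPLACEMENT_THRESHOLD = 2.0   # px/frame, within the 0.7-3.5 calibration range
DISPLACEMENT_CALIBRATION_RANGE = (0.7, 3.5)
MIN_BOUT_DURATION = 2.0                # s


@dataclass
class PoseTrack:
    """Per-frame body-part coordinates with tracking likelihoods.

    ``data`` has a two-level column index (body part, field) with fields
    ``x``, ``y`` (pixels) and ``likelihood`` in [0, 1], one row per frame.
    """

    data: pd.DataFrame
    frame_rate: float

    def __post_init__(self) -> None:
        like = self.data.xs("likelihood", axis=1, level=1)
        if ((like < 0) | (like > 1)).any().any():
            raise ValueError("likelihoods must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def body_parts(self) -> list[str]:
        return list(self.data.columns.get_level_values(0).unique())

    def xy(self, part: str) -> np.ndarray:
        return self.data[part][["x", "y"]].to_numpy(dtype=float)

    def likelihood(self, part: str) -> np.ndarray:
        return self.data[(part, "likelihood")].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        # wide layout, two header rows: body part / field
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_rate: float) -> "PoseTrack":
        df = pd.read_csv(path, header=[0, 1])
        return cls(df, frame_rate)


def make_pose_frame(parts: dict[str, np.ndarray], likelihood: dict[str, np.ndarray]) -> pd.DataFrame:
    """Assemble the two-level pose DataFrame from (frames, 2) coordinate arrays."""
    cols = {}
    for part, xy in parts.items():
        cols[(part, "x")] = xy[:, 0]
        cols[(part, "y")] = xy[:, 1]
        cols[(part, "likelihood")] = likelihood[part]
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return df


def filter_pose(pose: PoseTrack, likelihood_threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD) -> PoseTrack:
    """Replace low-likelihood positions with the most recent confident ones.

    Leading unconfident frames are back-filled from the first confident
    frame (the hold-last rule is undefined at t=0).
    """
    out = pose.data.copy()
    for part in pose.body_parts:
        like = pose.likelihood(part)
        ok = like >= likelihood_threshold
        if not ok.any():
            raise ValueError(f"body part {part!r} has no frame above the likelihood threshold")
        idx = np.where(ok, np.arange(len(ok)), -1)
        idx = np.maximum.accumulate(idx)
        first = np.argmax(ok)
        idx[idx < 0] = first
        for fieldname in ("x", "y"):
            vals = out[(part, fieldname)].to_numpy(dtype=float)
            out[(part, fieldname)] = vals[idx]
    return PoseTrack(out, pose.frame_rate)


def displacement(pose: PoseTrack, points=DISPLACEMENT_POINTS) -> pd.DataFrame:
    """Frame-to-frame Euclidean displacement (px/frame) per tracked point.

    The first frame has displacement 0. Invariant to global coordinate
    offsets by construction.
    """
    unknown = set(points) - set(pose.body_parts)
    if unknown:
        raise ValueError(f"unknown body part(s): {sorted(unknown)}")
    out = {}
    for part in points:
        xy = pose.xy(part)
        d = np.zeros(len(xy))
        d[1:] = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        out[part] = d
    return pd.DataFrame(out)


@dataclass
class ImmobilityBouts:
    """Sorted, non-overlapping immobility intervals of >= 2 s."""

    bouts: pd.DataFrame            # columns start_s, stop_s, overlaps_cs
    min_duration: float
    threshold: float
    frame_rate: float

    def __post_init__(self) -> None:
        b = self.bouts
        if len(b):
            if not (b["stop_s"] - b["start_s"] >= self.min_duration - 1e-9).all():
                raise ValueError("bout shorter than the minimum duration")
            if (b["start_s"].to_numpy()[1:] < b["stop_s"].to_numpy()[:-1]).any():
                raise ValueError("bouts overlap or are unsorted")

    def usable(self) -> pd.DataFrame:
        """Bouts outside any CS window (valid for neural alignment)."""
        return self.bouts[~self.bouts["overlaps_cs"]]

    def to_tsv(self, path) -> None:
        self.bouts.to_csv(path, sep="\t", index=False)


def detect_immobility(
    displacements: pd.DataFrame,
    frame_rate: float,
    threshold: float = DEFAULT_DISPLACEMENT_THRESHOLD,
    min_duration: float = MIN_BOUT_DURATION,
    events: EventTable | None = None,
) -> ImmobilityBouts:
    """Detect immobility bouts from per-point displacements.

    Frames where every point moves less than ``threshold`` px form
    candidate runs; runs of at least ``min_duration`` s become bouts.
    Bouts intersecting any CS window are flagged ``overlaps_cs`` (they are
    kept for behaviour metrics but excluded from neural alignment).
    """
    lo, hi = DISPLACEMENT_CALIBRATION_RANGE
    if not (lo <= threshold <= hi):
        logger.warning("displacement threshold %.2f outside calibration range [%s, %s]",
                       threshold, lo, hi)
    quiet = (displacements.to_numpy() < threshold).all(axis=1)
    min_frames = int(np.ceil(min_duration * frame_rate))

    padded = np.concatenate([[False], quiet, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = edges[::2], edges[1::2]
    keep = (stops - starts) >= min_frames
    starts, stops = starts[keep], stops[keep]

    start_s = starts / frame_rate
    stop_s = stops / frame_rate
    if events is not None:
        cs = events.intervals((CS_PLUS, CS_MINUS))
        overlaps = np.array([
            bool(((s < cs[:, 1]) & (e > cs[:, 0])).any()) for s, e in zip(start_s, stop_s)
        ]) if len(cs) else np.zeros(len(start_s), bool)
    else:
        overlaps = np.zeros(len(start_s), bool)

    bouts = pd.DataFrame({"start_s": start_s, "stop_s": stop_s, "overlaps_cs": overlaps})
    return ImmobilityBouts(bouts, min_duration, threshold, frame_rate)


# --- immobility-aligned neural activity --------------------------------------

def _align_to_times(
    traces: np.ndarray,
    times: np.ndarray,
    bin_width: float,
    pre_window: float,
    post_window: float,
    baseline_window: float,
) -> np.ndarray:
    """(cells, events, bins) snippets around arbitrary times, baselined."""
    pre_bins = int(round(pre_window / bin_width))
    post_bins = int(round(post_window / bin_width))
    base_bins = int(round(baseline_window / bin_width))
    n_bins = traces.shape[1]
    snippets = []
    for t in times:
        b = int(np.floor(t / bin_width))
        lo, hi = b - pre_bins, b + post_bins
        if lo < 0 or hi > n_bins:
            continue
        snippets.append(traces[:, lo:hi])
    if not snippets:
        return np.empty((traces.shape[0], 0, pre_bins + post_bins))
    data = np.stack(snippets, axis=1)
    base = data[:, :, pre_bins - base_bins: pre_bins].mean(axis=2, keepdims=True)
    return data - base


@dataclass
class ImmobilityActivity:
    """Pooled bout-onset and bout-offset aligned activity with per-cell AUC."""

    onset: AlignedTensor
    offset: AlignedTensor
    onset_auc: np.ndarray    # (cells,) AUC of the pooled mean trace, [0, 2) s
    offset_auc: np.ndarray
    per_session_onset_auc: dict[str, np.ndarray] = field(default_factory=dict)
    per_session_offset_auc: dict[str, np.ndarray] = field(default_factory=dict)
    n_bouts: int = 0


def immobility_aligned_activity(
    pop: TracePopulation,
    bouts: dict[str, ImmobilityBouts],
    sessions: tuple[str, ...] = ("test_ext1", "ext2"),
    pre_window: float = 2.0,
    post_window: float = 4.0,
    baseline_window: float = 2.0,
    auc_window: float = 2.0,
) -> ImmobilityActivity:
    """Align traces to immobility onsets/offsets, pool sessions, compute AUC.

    Only bouts outside CS windows are used. Snippets from all listed
    sessions are pooled and averaged into a single onset and offset trace
    per cell; the AUC covers ``[0, auc_window)`` after the event. Per-session
    AUCs are kept for the cross-session stability analysis.
    """
    onset_parts, offset_parts = [], []
    per_onset, per_offset = {}, {}
    total = 0
    for day in sessions:
        if day not in bouts or day not in pop.sessions:
            continue
        usable = bouts[day].usable()
        if usable.empty:
            continue
        traces = pop.sessions[day]
        on = _align_to_times(traces, usable["start_s"].to_numpy(), pop.bin_width,
                             pre_window, post_window, baseline_window)
        off = _align_to_times(traces, usable["stop_s"].to_numpy(), pop.bin_width,
                              pre_window, post_window, baseline_window)
        total += on.shape[1]
        onset_parts.append(on)
        offset_parts.append(off)
        nw = int(round(auc_window / pop.bin_width))
        pre_bins = int(round(pre_window / pop.bin_width))
        per_onset[day] = on.mean(axis=1)[:, pre_bins: pre_bins + nw].sum(axis=1) * pop.bin_width
        per_offset[day] = off.mean(axis=1)[:, pre_bins: pre_bins + nw].sum(axis=1) * pop.bin_width
    if not onset_parts or total == 0:
        raise ValueError("no usable immobility bout in the requested sessions")

    def pooled(parts: list[np.ndarray], label: str) -> AlignedTensor:
        data = np.concatenate(parts, axis=1)
        return AlignedTensor(label=label, data=data, pre_window=pre_window,
                             post_window=post_window, baseline_window=baseline_window,
                             bin_width=pop.bin_width)

    onset = pooled(onset_parts, "immobility_onset")
    offset = pooled(offset_parts, "immobility_offset")
    onset_auc = compute_mean_auc(onset, auc_window)
    offset_auc = compute_mean_auc(offset, auc_window)
    return ImmobilityActivity(onset, offset, onset_auc, offset_auc,
                              per_onset, per_offset, n_bouts=total)


def compute_mean_auc(tensor: AlignedTensor, window: float) -> np.ndarray:
    """AUC of the trial/bout-averaged trace per cell over [0, window) s."""
    mean_trace = tensor.post(window).mean(axis=1)
    return mean_trace.sum(axis=1) * tensor.bin_width


def stability_across_sessions(
    per_animal_auc: dict[str, dict[str, np.ndarray]],
    min_cells: int = 3,
) -> pd.DataFrame:
    """Spearman correlation of per-cell immobility AUCs between sessions.

    ``per_animal_auc`` maps animal -> session -> per-cell AUC vector. For
    each animal and session pair the Spearman rho is computed; across
    animals each pair is tested against 0 with a one-sample t-test.
    Animals with fewer than ``min_cells`` cells are excluded with a warning.
    """
    rows = []
    for animal, by_session in per_animal_auc.items():
        days = sorted(by_session)
        n = len(next(iter(by_session.values())))
        if n < min_cells:
            logger.warning("stability: animal %s excluded (%d < %d cells)", animal, n, min_cells)
            continue
        for i, a in enumerate(days):
            for b in days[i + 1:]:
                rho, _ = stats.spearmanr(by_session[a], by_session[b])
                rows.append({"animal": animal, "session_a": a, "session_b": b, "rho": rho})
    per_pair = pd.DataFrame(rows)
    if per_pair.empty:
        return per_pair
    tests = []
    for (a, b), grp in per_pair.groupby(["session_a", "session_b"]):
        rhos = grp["rho"].dropna().to_numpy()
        if len(rhos) >= 2 and np.ptp(rhos) > 0:
            t, p = stats.ttest_1samp(rhos, 0.0)
        else:
            t, p = np.nan, np.nan
        tests.append({"session_a": a, "session_b": b, "mean_rho": rhos.mean() if len(rhos) else np.nan,
                      "t": t, "p": p, "n_animals": len(rhos)})
    per_pair.attrs["group_tests"] = pd.DataFrame(tests)
    return per_pair


# --- behaviour metrics --------------------------------------------------------

def immobile_fraction_in_windows(bouts: ImmobilityBouts, windows: np.ndarray) -> float:
    """Fraction of the given [start, stop) windows spent immobile."""
    if len(windows) == 0:
        return np.nan
    total = float(np.sum(windows[:, 1] - windows[:, 0]))
    covered = 0.0
    for w0, w1 in windows:
        for _, b in bouts.bouts.iterrows():
            covered += max(0.0, min(w1, b["stop_s"]) - max(w0, b["start_s"]))
    return covered / total


def discrimination_score(imm_plus: float, imm_minus: float) -> float:
    """DS = (Imm_CS+ - Imm_CS-)/(Imm_CS+ + Imm_CS-), in [-1, 1].

    Undefined (NaN, with a warning) when both immobility fractions are 0.
    """
    if imm_plus < 0 or imm_minus < 0:
        raise ValueError("immobility fractions must be non-negative")
    denom = imm_plus + imm_minus
    if denom == 0:
        logger.warning("discrimination score undefined: no CS immobility at all")
        return np.nan
    return (imm_plus - imm_minus) / denom


def behaviour_metrics(
    bouts: ImmobilityBouts,
    events: EventTable,
    n_trials: int = 4,
    use_all_cs_plus: bool = False,
) -> dict[str, float]:
    """Imm_CS+, Imm_CS- and DS for the test/extinction-1 session.

    By default the first ``n_trials`` CS+ are balanced against the
    ``n_trials`` CS- presentations; ``use_all_cs_plus`` switches to all 12.
    """
    plus = events.intervals((CS_PLUS,))
    minus = events.intervals((CS_MINUS,))
    if not use_all_cs_plus:
        plus = plus[:n_trials]
    imm_plus = immobile_fraction_in_windows(bouts, plus)
    imm_minus = immobile_fraction_in_windows(bouts, minus)
    return {
        "imm_cs_plus": imm_plus,
        "imm_cs_minus": imm_minus,
        "ds": discrimination_score(imm_plus, imm_minus),
    }


def correlate_counts_with_behaviour(
    counts: pd.DataFrame, ds: pd.Series, min_animals: int = 4
) -> pd.DataFrame:
    """Spearman correlation of per-animal cluster counts with the DS.

    ``counts`` is animals x clusters; ``ds`` the per-animal discrimination
    score. Clusters with constant counts are flagged undefined.
    """
    common = counts.index.intersection(ds.index)
    if len(common) < min_animals:
        raise ValueError(f"need >= {min_animals} animals, got {len(common)}")
    rows = []
    for cluster in counts.columns:
        x = counts.loc[common, cluster].to_numpy(dtype=float)
        y = ds.loc[common].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"cluster": cluster, "rho": np.nan, "p": np.nan, "defined": False})
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append({"cluster": cluster, "rho": rho, "p": p, "defined": True})
    return pd.DataFrame(rows).set_index("cluster")
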