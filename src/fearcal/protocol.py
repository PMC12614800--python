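"""Core data model for the 4-day fear-conditioning imaging protocol.

Defines the session/event/trace containers shared by every analysis stage:
timed stimulus tables (:class:`EventTable`), cross-day registered population
traces (:class:`TracePopulation`), event-aligned tensors
(:class:`AlignedTensor`) and AUC tables, plus the preprocessing primitives
(z-scoring, binning, event alignment, baselining, trapezoid-free AUC).

Conventions
-----------
* All times are seconds; intervals are half-open ``[onset, offset)``.
* Time bin ``b`` covers ``[b * w, (b + 1) * w)`` for bin width ``w``.
* Traces are z-scored per cell over the concatenated multi-session
  recording, then mean-binned (default 0.25 s at a 20 Hz raw rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger("fearcal")

# --- protocol constants -----------------------------------------------------

SAMPLING_RATE = 20.0          # Hz, miniscope frame rate
DEFAULT_BIN_WIDTH = 0.25      # s, analysis bin
CS_DURATION = 30.0            # s, tone duration
US_DURATION = 2.0             # s, foot shock
PIP_RATE = 0.9                # Hz, tone pip repetition rate
PIP_DURATION = 0.2            # s, single pip
PIP_PERIOD = 1.0 / PIP_RATE
N_PIPS = 27                   # pips fitting a 30 s tone at 0.9 Hz
BASELINE_DURATION = 120.0     # s, silence before the first CS
SESSION_TAIL = 60.0           # s, recording after the last stimulus

CS_PLUS = "CS_PLUS"
CS_MINUS = "CS_MINUS"
US = "US"
EVENT_LABELS = (CS_PLUS, CS_MINUS, US)

HABITUATION = "habituation"
CONDITIONING = "conditioning"
TEST_EXT1 = "test_ext1"
EXT2 = "ext2"
DAY_ORDER = (HABITUATION, CONDITIONING, TEST_EXT1, EXT2)

#: expected number of trials per label for each day kind
TRIAL_COUNTS: dict[str, dict[str, int]] = {
    HABITUATION: {CS_PLUS: 5, CS_MINUS: 5, US: 0},
    CONDITIONING: {CS_PLUS: 5, CS_MINUS: 5, US: 5},
    TEST_EXT1: {CS_PLUS: 12, CS_MINUS: 4, US: 0},
    EXT2: {CS_PLUS: 12, CS_MINUS: 4, US: 0},
}

EVENT_COLUMNS = ["session_id", "day_kind", "label", "onset_s", "offset_s", "trial_index"]


# --- event tables -----------------------------------------------------------

@dataclass
class EventTable:
    """Timed, labelled stimulus records for one session.

    ``events`` holds one row per stimulus with columns ``label``,
    ``onset_s``, ``offset_s`` and 1-based ``trial_index`` (counted per
    label). ``duration_s`` is the total session length.
    """

    session_id: str
    day_kind: str
    events: pd.DataFrame
    duration_s: float

    def __post_init__(self) -> None:
        self.events = self.events.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        if self.day_kind not in TRIAL_COUNTS:
            raise ValueError(f"unknown day_kind {self.day_kind!r}; expected one of {DAY_ORDER}")
        ev = self.events
        missing = {"label", "onset_s", "offset_s", "trial_index"} - set(ev.columns)
        if missing:
            raise ValueError(f"event table missing columns {sorted(missing)}")
        if not (ev["onset_s"] < ev["offset_s"]).all():
            raise ValueError("every event must satisfy onset < offset")
        if not ev["onset_s"].is_monotonic_increasing:
            raise ValueError("events must be sorted by onset")
        dur = ev["offset_s"] - ev["onset_s"]
        cs = ev["label"].isin([CS_PLUS, CS_MINUS])
        if not np.allclose(dur[cs], CS_DURATION):
            raise ValueError(f"CS events must last {CS_DURATION} s")
        if not np.allclose(dur[ev["label"] == US], US_DURATION):
            raise ValueError(f"US events must last {US_DURATION} s")
        counts = ev["label"].value_counts()
        for label, expected in TRIAL_COUNTS[self.day_kind].items():
            if counts.get(label, 0) != expected:
                raise ValueError(
                    f"{self.day_kind} requires {expected} {label} trials, "
                    f"got {counts.get(label, 0)}"
                )
        if self.day_kind == CONDITIONING:
            plus_off = ev.loc[ev["label"] == CS_PLUS, "offset_s"].to_numpy()
            us_on = ev.loc[ev["label"] == US, "onset_s"].to_numpy()
            if not (us_on > plus_off).all():
                raise ValueError("each US onset must follow its paired CS+ offset")
        if ev["offset_s"].max() > self.duration_s:
            raise ValueError("events extend past the stated session duration")

    def onsets(self, label: str) -> np.ndarray:
        sel = self.events[self.events["label"] == label].sort_values("trial_index")
        return sel["onset_s"].to_numpy()

    def intervals(self, labels: Sequence[str] = (CS_PLUS, CS_MINUS)) -> np.ndarray:
        """(k, 2) array of [onset, offset) windows for the given labels."""
        sel = self.events[self.events["label"].isin(labels)]
        return sel[["onset_s", "offset_s"]].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        out = self.events.copy()
        out.insert(0, "day_kind", self.day_kind)
        out.insert(0, "session_id", self.session_id)
        return out[EVENT_COLUMNS]

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, duration_s: float | None = None) -> "EventTable":
        df = pd.read_csv(path, sep="\t")
        missing = set(EVENT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        session_id = str(df["session_id"].iloc[0])
        day_kind = str(df["day_kind"].iloc[0])
        if duration_s is None:
            duration_s = float(df["offset_s"].max()) + SESSION_TAIL
        return cls(session_id, day_kind,
                   df[["label", "onset_s", "offset_s", "trial_index"]], duration_s)


def build_protocol(
    day_kind: str,
    iti_range: tuple[float, float] = (60.0, 90.0),
    seed: int | None = None,
    session_id: str | None = None,
    us_lag: float = PIP_PERIOD,
) -> EventTable:
    """Construct the stimulus timeline of one session.

    Habituation: 5 CS+ and 5 CS- alternated. Conditioning: 5 alternated
    CS+/CS- pairs with a 2 s US following each CS+ offset by one pip
    period. Test/extinction days: 4 CS- followed by 12 CS+. Inter-trial
    intervals are drawn uniformly from ``iti_range`` with a 2 min baseline
    before the first tone. The 0.9 Hz pip substructure of each tone is a
    synthesis concern; here a CS is one 30 s event.
    """
    if day_kind not in TRIAL_COUNTS:
        raise ValueError(f"unknown day_kind {day_kind!r}; expected one of {DAY_ORDER}")
    lo, hi = iti_range
    if not (0 < lo <= hi):
        raise ValueError(f"iti_range must be positive and ordered, got {iti_range}")
    rng = np.random.default_rng(seed)
    if day_kind in (HABITUATION, CONDITIONING):
        order = [CS_PLUS, CS_MINUS] * 5
    else:
        order = [CS_MINUS] * 4 + [CS_PLUS] * 12

    rows = []
    trial_counter = {CS_PLUS: 0, CS_MINUS: 0, US: 0}
    t = BASELINE_DURATION
    for label in order:
        onset, offset = t, t + CS_DURATION
        trial_counter[label] += 1
        rows.append((label, onset, offset, trial_counter[label]))
        t = offset
        if day_kind == CONDITIONING and label == CS_PLUS:
            us_on = offset + us_lag
            trial_counter[US] += 1
            rows.append((US, us_on, us_on + US_DURATION, trial_counter[US]))
            t = us_on + US_DURATION
        t += rng.uniform(lo, hi)

    events = pd.DataFrame(rows, columns=["label", "onset_s", "offset_s", "trial_index"])
    duration = float(events["offset_s"].max()) + SESSION_TAIL
    if session_id is None:
        session_id = day_kind
    return EventTable(session_id, day_kind, events, duration)


def build_all_protocols(
    iti_range: tuple[float, float] = (60.0, 90.0), seed: int | None = None
) -> dict[str, EventTable]:
    """One :class:`EventTable` per day of the 4-day paradigm."""
    rng = np.random.default_rng(seed)
    return {
        day: build_protocol(day, iti_range, seed=int(rng.integers(2**31)))
        for day in DAY_ORDER
    }


# --- trace populations ------------------------------------------------------

@dataclass
class TracePopulation:
    """Cross-day registered cells x binned-time activity for one animal.

    The same cells, in the same order, appear in every session. Traces are
    z-scored per cell over the concatenated recording and mean-binned at
    ``bin_width`` seconds.
    """

    animal_id: str
    cell_ids: list[str]
    sessions: dict[str, np.ndarray]   # day_kind -> (cells, bins)
    bin_width: float = DEFAULT_BIN_WIDTH
    sampling_rate_raw: float = SAMPLING_RATE
    centroids: np.ndarray | None = None   # (cells, 2) pixel coordinates

    def __post_init__(self) -> None:
        n = len(self.cell_ids)
        for day, mat in self.sessions.items():
            if mat.shape[0] != n:
                raise ValueError(f"session {day}: {mat.shape[0]} rows for {n} cells")
            if np.isnan(mat).any():
                raise ValueError(f"session {day}: missing values after preprocessing")
        if self.centroids is not None and len(self.centroids) != n:
            raise ValueError("one centroid per cell required")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.sessions[d] for d in self.session_order()], axis=1)

    def session_order(self) -> list[str]:
        return [d for d in DAY_ORDER if d in self.sessions] + [
            d for d in self.sessions if d not in DAY_ORDER
        ]

    def subset(self, cell_idx: np.ndarray) -> "TracePopulation":
        return TracePopulation(
            animal_id=self.animal_id,
            cell_ids=[self.cell_ids[i] for i in np.atleast_1d(cell_idx)],
            sessions={d: m[cell_idx] for d, m in self.sessions.items()},
            bin_width=self.bin_width,
            sampling_rate_raw=self.sampling_rate_raw,
            centroids=None if self.centroids is None else self.centroids[cell_idx],
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["animal_id"] = self.animal_id
            f.attrs["bin_width"] = self.bin_width
            f.attrs["sampling_rate_raw"] = self.sampling_rate_raw
            f.create_dataset("cell_ids", data=np.array(self.cell_ids, dtype="S"))
            if self.centroids is not None:
                f.create_dataset("centroids", data=self.centroids)
            g = f.create_group("sessions")
            for day, mat in self.sessions.items():
                g.create_dataset(day, data=mat)

    @classmethod
    def from_hdf5(cls, path) -> "TracePopulation":
        with h5py.File(path, "r") as f:
            return cls(
                animal_id=str(f.attrs["animal_id"]),
                cell_ids=[c.decode() for c in f["cell_ids"][()]],
                sessions={day: f["sessions"][day][()] for day in f["sessions"]},
                bin_width=float(f.attrs["bin_width"]),
                sampling_rate_raw=float(f.attrs["sampling_rate_raw"]),
                centroids=f["centroids"][()] if "centroids" in f else None,
            )


def zscore_traces(raw: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Per-row z-score; constant rows become zeros with a warning."""
    mean = raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, keepdims=True)
    flat = sd[:, 0] < eps
    if flat.any():
        logger.warning("%d constant trace(s) z-scored to zeros", int(flat.sum()))
        sd = np.where(sd < eps, 1.0, sd)
    out = (raw - mean) / sd
    out[flat] = 0.0
    return out


def bin_traces(traces: np.ndarray, bin_width: float, sampling_rate: float) -> np.ndarray:
    """Mean-bin raw samples; trailing partial bin is dropped."""
    per_bin = bin_width * sampling_rate
    if abs(per_bin - round(per_bin)) > 1e-9 or per_bin < 1:
        raise ValueError(
            f"bin_width {bin_width} s is not a positive multiple of the "
            f"sample interval {1 / sampling_rate} s"
        )
    per_bin = int(round(per_bin))
    n_bins = traces.shape[1] // per_bin
    return traces[:, : n_bins * per_bin].reshape(traces.shape[0], n_bins, per_bin).mean(axis=2)


def preprocess_traces(
    raw: Mapping[str, np.ndarray] | np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    sampling_rate: float = SAMPLING_RATE,
    animal_id: str = "animal",
    cell_ids: Sequence[str] | None = None,
    centroids: np.ndarray | None = None,
    zscore_scope: str = "concatenated",
) -> TracePopulation:
    """Z-score per cell, then mean-bin, one or several raw sessions.

    ``raw`` maps day kind to a (cells, samples) array at ``sampling_rate``;
    a bare array is treated as a single generic session. By default cells
    are standardized over the full concatenated multi-session trace
    (``zscore_scope="concatenated"``); ``"per_session"`` standardizes each
    session independently.
    """
    if isinstance(raw, np.ndarray):
        raw = {"session": raw}
    days = list(raw)
    mats = [np.asarray(raw[d], dtype=float) for d in days]
    if any(m.ndim != 2 or m.shape[0] < 1 for m in mats):
        raise ValueError("each session must be a 2-D cells x samples array with >= 1 cell")
    n_cells = mats[0].shape[0]
    if any(m.shape[0] != n_cells for m in mats):
        raise ValueError("identical cell count required in every session")
    if any(np.isnan(m).any() for m in mats):
        raise ValueError("missing values in raw traces; interpolate upstream")

    if zscore_scope == "concatenated":
        cat = zscore_traces(np.concatenate(mats, axis=1))
        splits = np.cumsum([m.shape[1] for m in mats])[:-1]
        zs = np.split(cat, splits, axis=1)
    elif zscore_scope == "per_session":
        zs = [zscore_traces(m) for m in mats]
    else:
        raise ValueError(f"unknown zscore_scope {zscore_scope!r}")

    sessions = {d: bin_traces(z, bin_width, sampling_rate) for d, z in zip(days, zs)}
    if cell_ids is None:
        cell_ids = [f"{animal_id}_c{i:04d}" for i in range(n_cells)]
    return TracePopulation(
        animal_id=animal_id,
        cell_ids=list(cell_ids),
        sessions=sessions,
        bin_width=bin_width,
        sampling_rate_raw=sampling_rate,
        centroids=centroids,
    )


# --- event alignment --------------------------------------------------------

@dataclass
class AlignedTensor:
    """Per-trial snippets around one event type, baseline-corrected.

    ``data`` is (cells, trials, bins) covering ``[-pre_window, post_window)``
    relative to event onset; the mean over the last ``baseline_window``
    seconds before onset has been subtracted per cell and trial.
    """

    label: str
    data: np.ndarray
    pre_window: float
    post_window: float
    baseline_window: float
    bin_width: float
    trial_indices: list[int] = field(default_factory=list)
    n_dropped: int = 0

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def pre_bins(self) -> int:
        return int(round(self.pre_window / self.bin_width))

    @property
    def times(self) -> np.ndarray:
        """Left edge of each bin relative to event onset (s)."""
        return (np.arange(self.data.shape[2]) - self.pre_bins) * self.bin_width

    def baseline_slice(self) -> slice:
        nb = int(round(self.baseline_window / self.bin_width))
        return slice(self.pre_bins - nb, self.pre_bins)

    def post(self, window: float | None = None) -> np.ndarray:
        """Post-onset bins covering ``[0, window)`` s (default: all)."""
        if window is None:
            return self.data[:, :, self.pre_bins:]
        nw = int(round(window / self.bin_width))
        if nw > self.data.shape[2] - self.pre_bins:
            raise ValueError(f"window {window} s exceeds tensor extent")
        return self.data[:, :, self.pre_bins: self.pre_bins + nw]

    def pre(self, window: float | None = None) -> np.ndarray:
        """Pre-onset bins; default the baseline window."""
        if window is None:
            return self.data[:, :, self.baseline_slice()]
        nw = int(round(window / self.bin_width))
        return self.data[:, :, self.pre_bins - nw: self.pre_bins]

    def select_trials(self, indices: Sequence[int]) -> "AlignedTensor":
        idx = np.asarray(indices)
        return AlignedTensor(
            label=self.label,
            data=self.data[:, idx, :],
            pre_window=self.pre_window,
            post_window=self.post_window,
            baseline_window=self.baseline_window,
            bin_width=self.bin_width,
            trial_indices=[self.trial_indices[i] for i in idx] if self.trial_indices else [],
            n_dropped=self.n_dropped,
        )


def align_to_events(
    pop: TracePopulation,
    events: EventTable,
    label: str,
    pre_window: float,
    post_window: float,
    baseline_window: float | None = None,
) -> AlignedTensor:
    """Cut per-trial snippets around each event of ``label`` and baseline them.

    The baseline is the mean over the ``baseline_window`` seconds before
    onset (defaults to ``pre_window``), subtracted per cell and trial.
    Trials whose window leaves the session are dropped with a logged count.
    """
    if baseline_window is None:
        baseline_window = pre_window
    if baseline_window > pre_window:
        raise ValueError("baseline_window must not exceed pre_window")
    traces = pop.sessions[events.day_kind]
    w = pop.bin_width
    pre_bins = int(round(pre_window / w))
    post_bins = int(round(post_window / w))
    n_bins = traces.shape[1]

    snippets, kept, dropped = [], [], 0
    rows = events.events[events.events["label"] == label].sort_values("trial_index")
    if rows.empty:
        raise ValueError(f"no {label} events on {events.day_kind}")
    for _, row in rows.iterrows():
        onset_bin = int(np.floor(row["onset_s"] / w))
        lo, hi = onset_bin - pre_bins, onset_bin + post_bins
        if lo < 0 or hi > n_bins:
            dropped += 1
            continue
        snippets.append(traces[:, lo:hi])
        kept.append(int(row["trial_index"]))
    if dropped:
        logger.warning("align_to_events(%s, %s): dropped %d out-of-range trial(s)",
                       events.day_kind, label, dropped)
    if not snippets:
        raise ValueError(f"all {label} trials fall outside the recorded session")

    data = np.stack(snippets, axis=1)  # cells x trials x bins
    base_bins = int(round(baseline_window / w))
    base = data[:, :, pre_bins - base_bins: pre_bins].mean(axis=2, keepdims=True)
    return AlignedTensor(
        label=label,
        data=data - base,
        pre_window=pre_window,
        post_window=post_window,
        baseline_window=baseline_window,
        bin_width=w,
        trial_indices=kept,
        n_dropped=dropped,
    )


# --- AUC --------------------------------------------------------------------

@dataclass
class AucTable:
    """Per (cell, trial) integral of the baselined trace over [0, window) s."""

    label: str
    values: np.ndarray   # (cells, trials)
    window: float

    def per_cell(self) -> np.ndarray:
        return self.values.mean(axis=1)


def compute_auc(tensor: AlignedTensor, window: float) -> AucTable:
    """Integrate the baselined response over ``[0, window)`` after onset.

    Binned samples are means over their bin, so the exact integral of the
    underlying trace is the bin sum times the bin width; this keeps the AUC
    exactly linear, additive over disjoint windows, and equal to
    height x width for rectangular responses.
    """
    post = tensor.post(window)
    return AucTable(tensor.label, post.sum(axis=2) * tensor.bin_width, window)


# --- summaries --------------------------------------------------------------

@dataclass
class TraceSummary:
    mean: np.ndarray
    sem: np.ndarray
    over: str
    n: int
    sem_defined: bool = True


def summarize_traces(tensor: AlignedTensor, over: str = "trials") -> TraceSummary:
    """Mean trace with s.e.m. over cells, trials or both.

    The s.e.m. uses the n-1 denominator; with a single observation it is
    undefined and flagged (NaN).
    """
    axes = {"cells": (0,), "trials": (1,), "both": (0, 1)}
    if over not in axes:
        raise ValueError(f"over must be one of {sorted(axes)}")
    if tensor.data.size == 0:
        raise ValueError("empty tensor")
    ax = axes[over]
    n = int(np.prod([tensor.data.shape[a] for a in ax]))
    mean = tensor.data.mean(axis=ax)
    if n > 1:
        sem = tensor.data.std(axis=ax, ddof=1) / np.sqrt(n)
        defined = True
    else:
        sem = np.full_like(mean, np.nan)
        defined = False
        logger.warning("summarize_traces: s.e.m. undefined for n=1 along %s", over)
    return TraceSummary(mean=mean, sem=sem, over=over, n=n, sem_defined=defined)
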