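"""Per-cell responsiveness classification and spatial organisation.

A cell is "responsive" to a stimulus when the Wilcoxon rank-sum test between
its baseline-window and evoked-window activity reaches p < 0.01 on at least
3 presentations; the direction (activated / inhibited) is the majority sign
of the significant trials. Overlap of responsiveness across stimuli is
compared against an independence model, and spatial clustering of responder
groups is probed through within-group centroid distance distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist

from .protocol import CS_MINUS, CS_PLUS, EXT2, HABITUATION, TEST_EXT1, US, AlignedTensor

logger = logging.getLogger("fearcal")

DEFAULT_ALPHA = 0.01
DEFAULT_MIN_SIGNIFICANT = 3

ACTIVATED = "activated"
INHIBITED = "inhibited"
NONE = "none"


def trial_response_test(
    tensor: AlignedTensor,
    evoked_window: float | None = None,
    baseline_window: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rank-sum test of evoked vs baseline bins, per cell and trial.

    Returns two-sided p-values and response signs, both (cells, trials).
    The evoked window defaults to the full post-onset extent (30 s for a
    CS); for the US the caller passes 2 s evoked against the 5 s baseline.
    Uses the normal approximation with tie correction — the windows hold
    tens to hundreds of bins, where exact enumeration buys nothing.
    """
    evoked = tensor.post(evoked_window)
    base = tensor.pre(baseline_window)
    if evoked.shape[2] < 2 or base.shape[2] < 2:
        raise ValueError("need at least 2 bins in both the baseline and evoked windows")
    # Mann-Whitney U is the rank-sum test; asymptotic method applies the
    # tie correction the plain rank-sum implementation lacks.
    res = stats.mannwhitneyu(evoked, base, axis=2, alternative="two-sided",
                             method="asymptotic")
    signs = np.sign(evoked.mean(axis=2) - base.mean(axis=2)).astype(int)
    return res.pvalue, signs


@dataclass
class ResponseClassification:
    """Per-cell responsiveness verdicts for one stimulus."""

    stimulus: str
    pvalues: np.ndarray          # (cells, trials)
    signs: np.ndarray            # (cells, trials)
    responsive: np.ndarray       # (cells,) bool
    direction: np.ndarray        # (cells,) in {activated, inhibited, none}
    alpha: float
    min_significant: int
    trial_indices: list[int]

    @property
    def n_cells(self) -> int:
        return len(self.responsive)

    def to_frame(self, cell_ids=None) -> pd.DataFrame:
        n_trials = self.pvalues.shape[1]
        df = pd.DataFrame(self.pvalues, columns=[f"p{i + 1}" for i in range(n_trials)])
        df.insert(0, "cell_id", cell_ids if cell_ids is not None else np.arange(self.n_cells))
        df.insert(1, "stimulus", self.stimulus)
        df["responsive"] = self.responsive
        df["direction"] = self.direction
        return df


def classify_cells(
    pvals: np.ndarray,
    signs: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    min_significant: int = DEFAULT_MIN_SIGNIFICANT,
    stimulus: str = "stimulus",
    trial_indices: list[int] | None = None,
    tiebreak: np.ndarray | None = None,
) -> ResponseClassification:
    """Apply the ">= min_significant trials at p < alpha" rule.

    Direction is the majority sign among significant trials. An exact tie
    falls back to the sign of ``tiebreak`` (e.g. mean AUC per cell) when
    provided, else to the sign of the mean trial sign; ties are logged.
    """
    pvals = np.atleast_2d(pvals)
    signs = np.atleast_2d(signs)
    n_trials = pvals.shape[1]
    if min_significant > n_trials:
        raise ValueError(f"min_significant={min_significant} exceeds {n_trials} trials")

    sig = pvals < alpha
    responsive = sig.sum(axis=1) >= min_significant
    vote = (signs * sig).sum(axis=1)

    ties = responsive & (vote == 0)
    if ties.any():
        logger.info("classify_cells(%s): %d direction tie(s) broken by fallback",
                    stimulus, int(ties.sum()))
        fallback = tiebreak if tiebreak is not None else signs.sum(axis=1)
        vote = np.where(ties, np.sign(fallback), vote)

    direction = np.full(pvals.shape[0], NONE, dtype=object)
    direction[responsive & (vote > 0)] = ACTIVATED
    direction[responsive & (vote < 0)] = INHIBITED
    # a residual zero vote (tiebreak itself zero) counts as activated: log it
    residual = responsive & (vote == 0)
    if residual.any():
        logger.warning("classify_cells(%s): %d unresolved tie(s) labelled activated",
                       stimulus, int(residual.sum()))
        direction[residual] = ACTIVATED

    return ResponseClassification(
        stimulus=stimulus, pvalues=pvals, signs=signs, responsive=responsive,
        direction=direction, alpha=alpha, min_significant=min_significant,
        trial_indices=trial_indices or list(range(1, n_trials + 1)),
    )


def classify_tensor(
    tensor: AlignedTensor,
    evoked_window: float | None = None,
    alpha: float = DEFAULT_ALPHA,
    min_significant: int = DEFAULT_MIN_SIGNIFICANT,
    stimulus: str | None = None,
) -> ResponseClassification:
    """Convenience: test + classify in one step."""
    pvals, signs = trial_response_test(tensor, evoked_window)
    return classify_cells(pvals, signs, alpha, min_significant,
                          stimulus or tensor.label, tensor.trial_indices or None)


def across_day_trial_sets(day_kind: str, stimulus: str, n_trials: int | None = None) -> list[int]:
    """0-based trial indices entering across-day comparisons.

    Habituation contributes the first four presentations of each CS;
    test/extinction-1 the first four CS+ (all four CS-); extinction-2 the
    last four CS+ (all four CS-). This balances trial counts across days.
    """
    counts = {HABITUATION: {CS_PLUS: 5, CS_MINUS: 5},
              TEST_EXT1: {CS_PLUS: 12, CS_MINUS: 4},
              EXT2: {CS_PLUS: 12, CS_MINUS: 4}}
    if day_kind not in counts or stimulus not in counts[day_kind]:
        raise ValueError(f"no across-day trial rule for {stimulus} on {day_kind}")
    available = counts[day_kind][stimulus] if n_trials is None else n_trials
    if available < 4:
        raise ValueError(f"{stimulus} on {day_kind}: need >= 4 trials, have {available}")
    if day_kind == EXT2 and stimulus == CS_PLUS:
        return list(range(available - 4, available))
    return [0, 1, 2, 3]


def responsive_fractions(
    classifications: dict[str, ResponseClassification] | ResponseClassification,
    animal_ids: np.ndarray | None = None,
    group_by: str = "population",
) -> pd.DataFrame:
    """Fractions of activated / inhibited / unresponsive cells per stimulus.

    With ``group_by="animal"`` (requires ``animal_ids``), fractions are
    computed within each animal.
    """
    if isinstance(classifications, ResponseClassification):
        classifications = {classifications.stimulus: classifications}
    if group_by not in ("population", "animal"):
        raise ValueError("group_by must be 'population' or 'animal'")
    rows = []
    for stim, cls in classifications.items():
        if cls.n_cells == 0:
            raise ValueError(f"no classified cells for {stim}")
        if group_by == "population":
            groups = {"all": np.ones(cls.n_cells, bool)}
        else:
            if animal_ids is None:
                raise ValueError("animal_ids required for per-animal fractions")
            groups = {a: np.asarray(animal_ids) == a for a in pd.unique(np.asarray(animal_ids))}
        for name, mask in groups.items():
            if not mask.any():
                raise ValueError(f"empty group {name!r}")
            d = cls.direction[mask]
            n = mask.sum()
            rows.append({
                "stimulus": stim, "group": name, "n_cells": int(n),
                "responsive": float(cls.responsive[mask].mean()),
                "activated": float((d == ACTIVATED).mean()),
                "inhibited": float((d == INHIBITED).mean()),
                "none": float((d == NONE).mean()),
            })
    return pd.DataFrame(rows)


# --- overlap against chance -----------------------------------------------------

COMBINATIONS = (
    (True, False, False), (False, True, False), (False, False, True),
    (True, True, False), (True, False, True), (False, True, True),
    (True, True, True),
)


def _combo_name(combo: tuple[bool, bool, bool]) -> str:
    names = [n for n, on in zip(("CS+", "CS-", "US"), combo) if on]
    return "/".join(names)


@dataclass
class OverlapSummary:
    """Observed vs independence-chance responsiveness overlap."""

    per_animal: pd.DataFrame     # animal, combination, observed, chance
    pooled: pd.DataFrame         # combination, observed, chance (animal means)


def overlap_with_chance(
    classifications: dict[str, ResponseClassification],
    animal_ids: np.ndarray,
) -> OverlapSummary:
    """Observed fraction per responsiveness combination and its chance level.

    The chance level for a combination is the product of the member
    stimuli's marginal responsive fractions times the product of
    (1 - marginal) for excluded stimuli, computed per animal under
    independence, then averaged across animals.
    """
    stimuli = (CS_PLUS, CS_MINUS, US)
    missing = set(stimuli) - set(classifications)
    if missing:
        raise ValueError(f"overlap needs all three stimuli; missing {sorted(missing)}")
    flags = {s: classifications[s].responsive for s in stimuli}
    n = len(next(iter(flags.values())))
    if any(len(f) != n for f in flags.values()) or len(animal_ids) != n:
        raise ValueError("classifications and animal_ids must cover the same cells")

    rows = []
    for animal in pd.unique(np.asarray(animal_ids)):
        mask = np.asarray(animal_ids) == animal
        marg = {s: flags[s][mask].mean() for s in stimuli}
        for combo in COMBINATIONS:
            observed = np.ones(mask.sum(), bool)
            chance = 1.0
            for s, on in zip(stimuli, combo):
                observed &= flags[s][mask] == on
                chance *= marg[s] if on else 1.0 - marg[s]
            rows.append({"animal": animal, "combination": _combo_name(combo),
                         "observed": float(observed.mean()), "chance": float(chance)})
        none_obs = ~(flags[CS_PLUS][mask] | flags[CS_MINUS][mask] | flags[US][mask])
        rows.append({"animal": animal, "combination": "none",
                     "observed": float(none_obs.mean()),
                     "chance": float(np.prod([1 - marg[s] for s in stimuli]))})
    per_animal = pd.DataFrame(rows)
    pooled = per_animal.groupby("combination", sort=False)[["observed", "chance"]].mean().reset_index()
    return OverlapSummary(per_animal, pooled)


# --- spatial organisation --------------------------------------------------------

def spatial_distance_distribution(
    centroids: np.ndarray, labels: np.ndarray
) -> pd.DataFrame:
    """Mean within-group centroid distance per cell, by group.

    For each cell the mean Euclidean pixel distance to all other cells of
    the same group. Singleton groups are excluded with a warning. The
    returned frame (cell index, group, mean_distance) feeds empirical CDFs.
    """
    centroids = np.asarray(centroids, dtype=float)
    labels = np.asarray(labels)
    dist = squareform(pdist(centroids))
    rows = []
    for group in pd.unique(labels):
        idx = np.flatnonzero(labels == group)
        if len(idx) < 2:
            logger.warning("spatial distances: singleton group %r excluded", group)
            continue
        sub = dist[np.ix_(idx, idx)]
        mean_d = sub.sum(axis=1) / (len(idx) - 1)
        rows.extend({"cell": int(i), "group": group, "mean_distance": float(d)}
                    for i, d in zip(idx, mean_d))
    return pd.DataFrame(rows)


def distance_cdf(distances: pd.DataFrame, group: str) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF (x, F(x)) of within-group distances for one group."""
    vals = np.sort(distances.loc[distances["group"] == group, "mean_distance"].to_numpy())
    return vals, np.arange(1, len(vals) + 1) / len(vals)
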