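"""Linear-SVM population decoding of stimulus identity.

Datasets are class-balanced: each CS presentation contributes a 30-sample
block (the 30 s tone at 1 s bins) and each selected presentation donates the
30 s immediately before tone onset as a baseline block. To equalize
population size across animals, 37 cells are subsampled per iteration (the
smallest recorded population), and reported metrics average 100 iterations.
Intra-day decoding is a one-vs-one linear-SVM multiclass with 10-fold
cross-validation; cross-day transfer trains two-way decoders (baseline vs
one CS) on one session and evaluates them, without retraining, on another.
Controls: temporally shuffled labels and size-matched random cell subsets.
Per-cell absolute weights of the two-way decoders index each cell's
contribution, and their CS+/CS- correlation probes stimulus selectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .protocol import CS_MINUS, CS_PLUS, EventTable, TracePopulation
from .responsiveness import ResponseClassification

logger = logging.getLogger("fearcal")

BASELINE = "BASELINE"
DEFAULT_CLASSES = (BASELINE, CS_PLUS, CS_MINUS)
DEFAULT_N_CELLS = 37
DEFAULT_FOLDS = 10
DEFAULT_ITERATIONS = 100
DECODER_BIN = 1.0       # s
CS_WINDOW = 30.0        # s
SVM_C = 1.0


@dataclass
class DecoderDataset:
    """Class-balanced samples x cells matrix for one animal and day."""

    X: np.ndarray
    y: np.ndarray
    animal_id: str
    day_kind: str
    cell_indices: np.ndarray
    bin_width: float
    seed: int | None = None

    def __post_init__(self) -> None:
        counts = pd.Series(self.y).value_counts()
        if counts.nunique() > 1:
            raise ValueError(f"class counts must be exactly equal, got {counts.to_dict()}")

    @property
    def classes(self) -> list[str]:
        return sorted(pd.unique(self.y))

    def restrict(self, classes: tuple[str, ...]) -> "DecoderDataset":
        mask = np.isin(self.y, classes)
        return DecoderDataset(self.X[mask], self.y[mask], self.animal_id,
                              self.day_kind, self.cell_indices, self.bin_width, self.seed)


def _rebin(session: np.ndarray, from_width: float, to_width: float) -> np.ndarray:
    factor = to_width / from_width
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("decoder bin width must be a multiple of the analysis bin")
    factor = int(round(factor))
    n = session.shape[1] // factor
    return session[:, : n * factor].reshape(session.shape[0], n, factor).mean(axis=2)


def build_dataset(
    pop: TracePopulation,
    events: EventTable,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
    n_cells: int = DEFAULT_N_CELLS,
    seed: int | None = 0,
    cells: np.ndarray | None = None,
    decoder_bin: float = DECODER_BIN,
    window: float = CS_WINDOW,
) -> DecoderDataset:
    """Assemble a balanced decoding dataset from one session.

    Every selected CS presentation contributes ``window / decoder_bin``
    samples; baseline blocks are the ``window`` seconds immediately
    preceding the selected CS+ onsets (inter-trial intervals of >= 60 s
    guarantee those windows are stimulus-free). The block count per class
    is the smallest CS trial count, so classes stay exactly balanced.
    ``cells`` pins the subsample; otherwise ``n_cells`` cells are drawn
    with ``seed``.
    """
    rng = np.random.default_rng(seed)
    if cells is None:
        if pop.n_cells < n_cells:
            raise ValueError(
                f"animal {pop.animal_id}: {pop.n_cells} cells < requested {n_cells}")
        cells = np.sort(rng.choice(pop.n_cells, size=n_cells, replace=False))
    cells = np.asarray(cells)

    traces = _rebin(pop.sessions[events.day_kind], pop.bin_width, decoder_bin)[cells]
    bins_per_block = int(round(window / decoder_bin))

    cs_classes = [c for c in classes if c != BASELINE]
    onsets = {c: events.onsets(c) for c in cs_classes}
    n_blocks = min(len(o) for o in onsets.values())
    if n_blocks == 0:
        raise ValueError("a requested CS class has no presentations on this day")

    def block(t0: float) -> np.ndarray:
        b0 = int(np.floor(t0 / decoder_bin))
        return traces[:, b0: b0 + bins_per_block].T    # samples x cells

    X_parts, y_parts = [], []
    for c in cs_classes:
        for t0 in onsets[c][:n_blocks]:
            X_parts.append(block(t0))
            y_parts.append(np.full(bins_per_block, c))
    if BASELINE in classes:
        base_anchor = onsets[cs_classes[0]][:n_blocks]
        for t0 in base_anchor:
            if t0 - window < 0:
                raise ValueError("baseline window precedes the recording start")
            X_parts.append(block(t0 - window))
            y_parts.append(np.full(bins_per_block, BASELINE))

    return DecoderDataset(
        X=np.concatenate(X_parts), y=np.concatenate(y_parts),
        animal_id=pop.animal_id, day_kind=events.day_kind,
        cell_indices=cells, bin_width=decoder_bin, seed=seed,
    )


# --- metrics -------------------------------------------------------------------

@dataclass
class DecoderResult:
    """Confusion-matrix metrics of one decoder evaluation."""

    confusion: pd.DataFrame            # true x predicted
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    folds: int = 1
    n_iterations: int = 1

    @classmethod
    def from_confusion(cls, confusion: pd.DataFrame, folds: int = 1,
                       n_iterations: int = 1) -> "DecoderResult":
        cm = confusion.to_numpy(dtype=float)
        accuracy = float(np.trace(cm) / cm.sum())
        precision, recall, f1 = {}, {}, {}
        for i, c in enumerate(confusion.index):
            tp = cm[i, i]
            p = tp / cm[:, i].sum() if cm[:, i].sum() else 0.0
            r = tp / cm[i, :].sum() if cm[i, :].sum() else 0.0
            precision[c], recall[c] = float(p), float(r)
            f1[c] = float(2 * p * r / (p + r)) if (p + r) else 0.0
        return cls(confusion, accuracy, precision, recall, f1, folds, n_iterations)

    def summary(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes: list[str]) -> pd.DataFrame:
    cm = pd.crosstab(pd.Series(y_true, name="true"), pd.Series(y_pred, name="predicted"))
    return cm.reindex(index=classes, columns=classes, fill_value=0)


def _svm() -> SVC:
    # one-vs-one linear SVMs with majority vote is SVC's native multiclass
    return SVC(kernel="linear", C=SVM_C, decision_function_shape="ovo")


def crossval_multiclass(
    dataset: DecoderDataset, folds: int = DEFAULT_FOLDS, seed: int = 0
) -> DecoderResult:
    """K-fold cross-validated one-vs-one linear-SVM decoding.

    The confusion matrix aggregates every held-out prediction across folds.
    """
    classes = dataset.classes
    if len(classes) < 2:
        raise ValueError("decoding needs at least two classes")
    counts = pd.Series(dataset.y).value_counts()
    if counts.min() < folds:
        raise ValueError(f"need >= {folds} samples per class for {folds}-fold CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(dataset.y)
    for train, test in skf.split(dataset.X, dataset.y):
        clf = _svm().fit(dataset.X[train], dataset.y[train])
        y_pred[test] = clf.predict(dataset.X[test])
    return DecoderResult.from_confusion(_confusion(dataset.y, y_pred, classes), folds=folds)


def repeated_crossval(
    pop: TracePopulation,
    events: EventTable,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
    n_cells: int = DEFAULT_N_CELLS,
    n_iterations: int = DEFAULT_ITERATIONS,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    cell_pool: np.ndarray | None = None,
) -> pd.DataFrame:
    """CV metrics over fresh cell subsamples; one row per iteration.

    ``cell_pool`` restricts the subsampling universe (e.g. responsive-only
    decoders); when the pool is not larger than ``n_cells`` the whole pool
    is used every iteration.
    """
    rng = np.random.default_rng(seed)
    rows = []
    pool = np.arange(pop.n_cells) if cell_pool is None else np.asarray(cell_pool)
    for it in range(n_iterations):
        it_seed = int(rng.integers(2**31))
        it_rng = np.random.default_rng(it_seed)
        take = min(n_cells, len(pool))
        cells = np.sort(it_rng.choice(pool, size=take, replace=False))
        ds = build_dataset(pop, events, classes, seed=it_seed, cells=cells)
        res = crossval_multiclass(ds, folds=folds, seed=it_seed)
        rows.append({"iteration": it, "accuracy": res.accuracy,
                     **{f"f1_{c}": res.f1[c] for c in res.f1}})
    return pd.DataFrame(rows)


def shuffled_label_control(
    dataset: DecoderDataset,
    n_shuffles: int = DEFAULT_ITERATIONS,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> np.ndarray:
    """CV accuracy distribution after permuting labels in time."""
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    rng = np.random.default_rng(seed)
    accs = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = rng.permutation(len(dataset.y))
        shuffled = DecoderDataset(dataset.X, dataset.y[perm], dataset.animal_id,
                                  dataset.day_kind, dataset.cell_indices,
                                  dataset.bin_width, dataset.seed)
        accs[i] = crossval_multiclass(shuffled, folds, seed=int(rng.integers(2**31))).accuracy
    return accs


def select_cells(
    classifications: dict[str, ResponseClassification],
    mode: str,
    n_total: int,
    n_match: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Cell subsets for decoder controls.

    ``responsive_only``: cells responsive to CS+ or CS-;
    ``nonresponsive_only``: the complement; ``random_size_matched``:
    ``n_match`` cells drawn from everyone — the size control for the
    non-responsive decoder.
    """
    resp = np.zeros(n_total, dtype=bool)
    for stim in (CS_PLUS, CS_MINUS):
        if stim in classifications:
            resp |= classifications[stim].responsive
    if mode == "responsive_only":
        idx = np.flatnonzero(resp)
    elif mode == "nonresponsive_only":
        idx = np.flatnonzero(~resp)
    elif mode == "random_size_matched":
        if n_match is None:
            raise ValueError("random_size_matched requires n_match")
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n_total, size=n_match, replace=False))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(idx) < 2:
        raise ValueError(f"subset {mode!r} has fewer than 2 cells")
    return idx


# --- two-way decoders and cross-day transfer --------------------------------------

@dataclass
class TwoWayDecoder:
    """Linear SVM for baseline vs one CS, with per-cell absolute weights."""

    clf: SVC
    classes: list[str]
    weights: np.ndarray
    cell_indices: np.ndarray
    day_kind: str

    @property
    def abs_weights(self) -> np.ndarray:
        return np.abs(self.weights)


def train_twoway(dataset: DecoderDataset) -> TwoWayDecoder:
    """Fit a two-class linear SVM on the full day and expose its weights."""
    classes = dataset.classes
    if len(classes) != 2:
        raise ValueError(f"two-way decoder needs exactly 2 classes, got {classes}")
    clf = _svm().fit(dataset.X, dataset.y)
    return TwoWayDecoder(clf=clf, classes=classes, weights=clf.coef_[0].copy(),
                         cell_indices=dataset.cell_indices, day_kind=dataset.day_kind)


def cross_day_evaluate(model: TwoWayDecoder, dataset: DecoderDataset) -> DecoderResult:
    """Apply a trained decoder to another session without retraining."""
    if dataset.X.shape[1] != len(model.cell_indices) or not np.array_equal(
            np.asarray(dataset.cell_indices), np.asarray(model.cell_indices)):
        raise ValueError("cross-day evaluation requires the identical cell subsample")
    if sorted(dataset.classes) != sorted(model.classes):
        raise ValueError("class sets differ between training and evaluation day")
    y_pred = model.clf.predict(dataset.X)
    return DecoderResult.from_confusion(_confusion(dataset.y, y_pred, sorted(model.classes)))


def weight_selectivity(wplus: np.ndarray, wminus: np.ndarray, method: str = "pearson") -> float:
    """Correlation of absolute CS+ and CS- decoding weights.

    Negative correlation indicates stimulus-selective cells. Constant
    weight vectors make the correlation undefined (NaN, with a warning).
    """
    a, b = np.abs(np.asarray(wplus)), np.abs(np.asarray(wminus))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("weight correlation undefined: constant weight vector")
        return np.nan
    if method == "pearson":
        return float(stats.pearsonr(a, b)[0])
    if method == "spearman":
        return float(stats.spearmanr(a, b)[0])
    raise ValueError(f"unknown correlation method {method!r}")


def weight_selectivity_iterations(
    pop: TracePopulation,
    events: EventTable,
    n_cells: int = DEFAULT_N_CELLS,
    n_iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-iteration |w(CS+)| vs |w(CS-)| correlation for one animal/day."""
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(n_iterations):
        it_seed = int(rng.integers(2**31))
        it_rng = np.random.default_rng(it_seed)
        cells = np.sort(it_rng.choice(pop.n_cells, size=min(n_cells, pop.n_cells),
                                      replace=False))
        r_by_stim = {}
        for stim in (CS_PLUS, CS_MINUS):
            ds = build_dataset(pop, events, (BASELINE, stim), seed=it_seed, cells=cells)
            r_by_stim[stim] = train_twoway(ds).abs_weights
        rows.append({"iteration": it,
                     "r": weight_selectivity(r_by_stim[CS_PLUS], r_by_stim[CS_MINUS], method)})
    return pd.DataFrame(rows)


def weight_stability_control(
    dataset: DecoderDataset,
    n_pairs: int = DEFAULT_ITERATIONS,
    train_fraction: float = 0.9,
    seed: int = 0,
    method: str = "pearson",
) -> np.ndarray:
    """Stability of |w| across refits: correlate successive 90%-partition fits.

    Trains ``2 * n_pairs`` decoders on random ``train_fraction`` partitions
    and correlates the absolute weights of iterations (1, 2), (3, 4), ...
    """
    rng = np.random.default_rng(seed)
    n = len(dataset.y)
    n_train = int(round(train_fraction * n))
    weights = []
    for _ in range(2 * n_pairs):
        idx = rng.choice(n, size=n_train, replace=False)
        clf = _svm().fit(dataset.X[idx], dataset.y[idx])
        weights.append(np.abs(clf.coef_[0]))
    return np.array([
        weight_selectivity(weights[2 * i], weights[2 * i + 1], method)
        for i in range(n_pairs)
    ])
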