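"""Configuration, orchestration and group-comparison reporting.

:class:`PipelineConfig` serializes every analysis parameter (defaults match
the published protocol: alpha 0.01, >= 3 significant trials, 80% PCA
variance, k = 16/8/10/5 for US / conditioning-CS / across-day / extinction
clusterings, 37-cell decoder subsamples, 100 iterations, 10-fold CV,
0.25 s analysis and 1 s decoder bins, 30/5/2 s windows). ``run_pipeline``
executes the stages in dependency order on synthetic or file inputs and
writes a reproducible results bundle. ``group_comparison`` provides the
non-parametric test battery used for group contrasts (Friedman + Dunn,
Mann-Whitney / Wilcoxon with Bonferroni, chi-square with Yates correction
for small expected counts), with normality and variance screening reported
alongside.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import behaviour as bhv
from . import clustering as clu
from . import decoding as dec
from . import geometry as geo
from . import responsiveness as resp
from . import synth
from .protocol import (
    CONDITIONING,
    CS_MINUS,
    CS_PLUS,
    DAY_ORDER,
    EXT2,
    HABITUATION,
    TEST_EXT1,
    US,
    EventTable,
    TracePopulation,
    align_to_events,
    compute_auc,
)

logger = logging.getLogger("fearcal")

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Complete, serializable description of one analysis run."""

    seed: int = 0
    mode: str = "synthetic"                      # or "files"
    input_dir: str | None = None
    out_dir: str | None = None
    synthetic: synth.SynthConfig = field(default_factory=synth.SynthConfig)
    stages: dict[str, bool] = field(default_factory=lambda: {
        "classify": True, "cluster": True, "pvd": True,
        "decode": True, "behaviour": True,
    })
    # responsiveness
    alpha: float = 0.01
    min_significant: int = 3
    # clustering
    variance_threshold: float = 0.80
    k_us: int = 16
    k_cs: int = 8
    k_across_day: int = 10
    k_extinction: int = 5
    min_flow: int = 5
    # decoding
    n_cells_decoder: int = 37
    decoder_iterations: int = 100
    decoder_folds: int = 10
    n_shuffles: int = 100
    # time bases and windows (s)
    bin_width: float = 0.25
    decoder_bin_width: float = 1.0
    cs_window: float = 30.0
    us_window: float = 5.0
    us_evoked_window: float = 2.0
    us_post_window: float = 10.0
    immobility_window: float = 2.0
    # behaviour
    likelihood_threshold: float = 0.9
    displacement_threshold: float = 2.0
    min_bout_duration: float = 2.0
    iti_range: tuple[float, float] = (60.0, 90.0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["iti_range"] = list(d["iti_range"])
        sc = d["synthetic"]
        for key in ("iti_range", "immobile_dwell", "mobile_dwell"):
            sc[key] = list(sc[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sc = dict(d.pop("synthetic", {}))
        for key in ("iti_range", "immobile_dwell", "mobile_dwell"):
            if key in sc:
                sc[key] = tuple(sc[key])
        if "iti_range" in d:
            d["iti_range"] = tuple(d["iti_range"])
        return cls(synthetic=synth.SynthConfig(**sc), **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def small_config(seed: int = 0, n_animals: int = 2, cells: int = 48) -> PipelineConfig:
    """A scaled-down configuration for smoke runs and determinism checks.

    Analysis parameters keep their defaults; only cohort size, iteration
    counts and cluster counts shrink so a full run stays in the minutes
    range on one CPU.
    """
    cfg = PipelineConfig(seed=seed)
    cfg.synthetic = dataclasses.replace(
        synth.SynthConfig(), n_animals=n_animals, cells_per_animal=cells, seed=seed)
    cfg.decoder_iterations = 3
    cfg.n_shuffles = 3
    cfg.k_us = 6
    cfg.k_cs = 4
    cfg.k_across_day = 4
    return cfg


# --- input loading ----------------------------------------------------------------


def load_inputs(config: PipelineConfig):
    """Populations, event tables, pose tracks and (synthetic) ground truth.

    In ``synthetic`` mode everything comes from the generator, ground truth
    attached. In ``files`` mode, ``input_dir`` must hold
    ``events_<day>.tsv``, ``population_<animal>.h5`` and optionally
    ``pose_<animal>_<day>.csv`` in the formats this package writes.
    """
    if config.mode == "synthetic":
        ds = synth.generate_dataset(config.synthetic)
        return ds.protocols, ds.populations, ds.pose, ds.ground_truths
    if config.mode != "files":
        raise ValueError(f"unknown mode {config.mode!r}")
    root = Path(config.input_dir or ".")
    protocols = {}
    for day in DAY_ORDER:
        p = root / f"events_{day}.tsv"
        if p.exists():
            protocols[day] = EventTable.from_tsv(p)
    if not protocols:
        raise ValueError(f"no events_<day>.tsv found under {root}")
    populations = [TracePopulation.from_hdf5(p) for p in sorted(root.glob("population_*.h5"))]
    if not populations:
        raise ValueError(f"no population_*.h5 found under {root}")
    pose = {}
    for pop in populations:
        tracks = {}
        for day in protocols:
            p = root / f"pose_{pop.animal_id}_{day}.csv"
            if p.exists():
                tracks[day] = bhv.PoseTrack.from_csv(p, frame_rate=config.synthetic.frame_rate)
        pose[pop.animal_id] = tracks
    return protocols, populations, pose, None


# --- stage runners ------------------------------------------------------------------


def _classify_stage(config, protocols, populations):
    out = {"per_animal": [], "fractions": None, "overlap": None, "spatial": None}
    cond = protocols[CONDITIONING]
    all_cls = {CS_PLUS: [], CS_MINUS: [], US: []}
    animal_ids, centroids = [], []
    for pop in populations:
        cls_by_stim = {}
        for stim in (CS_PLUS, CS_MINUS):
            tensor = align_to_events(pop, cond, stim, config.cs_window,
                                     config.cs_window, config.cs_window)
            cls_by_stim[stim] = resp.classify_tensor(
                tensor, alpha=config.alpha, min_significant=config.min_significant)
        us_tensor = align_to_events(pop, cond, US, config.us_window,
                                    config.us_post_window, config.us_window)
        cls_by_stim[US] = resp.classify_tensor(
            us_tensor, config.us_evoked_window, config.alpha, config.min_significant)
        for stim, c in cls_by_stim.items():
            all_cls[stim].append(c)
        animal_ids.extend([pop.animal_id] * pop.n_cells)
        if pop.centroids is not None:
            centroids.append(pop.centroids)
        out["per_animal"].append({stim: c.to_frame(pop.cell_ids)
                                  for stim, c in cls_by_stim.items()})

    pooled = {stim: _pool_classifications(cls_list) for stim, cls_list in all_cls.items()}
    animal_ids = np.array(animal_ids)
    out["classifications"] = pooled
    out["animal_ids"] = animal_ids
    out["fractions"] = resp.responsive_fractions(pooled, animal_ids, group_by="animal")
    out["overlap"] = resp.overlap_with_chance(pooled, animal_ids)
    if centroids:
        cents = np.concatenate(centroids)
        rows = []
        for stim, c in pooled.items():
            labels = np.where(c.responsive, stim, "non")
            d = resp.spatial_distance_distribution(cents, labels)
            rows.append(d[d["group"] == stim])
        out["spatial"] = pd.concat(rows, ignore_index=True) if rows else None
    return out


def _pool_classifications(cls_list):
    return resp.ResponseClassification(
        stimulus=cls_list[0].stimulus,
        pvalues=np.concatenate([c.pvalues for c in cls_list]),
        signs=np.concatenate([c.signs for c in cls_list]),
        responsive=np.concatenate([c.responsive for c in cls_list]),
        direction=np.concatenate([c.direction for c in cls_list]),
        alpha=cls_list[0].alpha,
        min_significant=cls_list[0].min_significant,
        trial_indices=cls_list[0].trial_indices,
    )


def _cluster_stage(config, protocols, populations, classify_out):
    cond = protocols[CONDITIONING]
    us_tensors = [align_to_events(p, cond, US, config.us_window,
                                  config.us_post_window, config.us_window)
                  for p in populations]
    X = np.concatenate([clu.feature_matrix(t) for t in us_tensors])
    responsive = classify_out["classifications"][US].responsive
    X_resp = X[responsive]
    k = min(config.k_us, max(2, len(X_resp) - 1))
    if k != config.k_us:
        logger.warning("cluster stage: k_us reduced to %d for %d cells", k, len(X_resp))
    model = clu.fit_cluster_model(X_resp, k, config.variance_threshold, seed=config.seed)
    templates = synth.template_library("us", us_tensors[0].n_trials,
                                       config.us_post_window, config.synthetic)
    labeled = clu.merge_and_label(model, X_resp, templates)
    fractions = clu.cluster_fractions_per_animal(
        labeled.final_labels, classify_out["animal_ids"][responsive])
    return {"model": model, "labeled": labeled, "responsive_mask": responsive,
            "fractions": fractions, "report": labeled.report}


def _pvd_stage(config, protocols, populations, cluster_out):
    rows, across = [], []
    offset = 0
    for pop in populations:
        cond = protocols[CONDITIONING]
        cs = align_to_events(pop, cond, CS_PLUS, config.cs_window,
                             config.cs_window, config.cs_window)
        us = align_to_events(pop, cond, US, config.us_window,
                             config.us_post_window, config.us_window)
        res = geo.pvd_conditioning(cs, us, config.cs_window, config.us_window)
        df = res.to_frame()
        df["animal"] = pop.animal_id
        rows.append(df)

        # ablations by final US cluster label, within this animal
        mask = cluster_out["responsive_mask"][offset: offset + pop.n_cells]
        labels = np.full(pop.n_cells, "non_responsive", dtype=object)
        labels[mask] = cluster_out["labeled"].final_labels[
            cluster_out["responsive_mask"].cumsum()[offset: offset + pop.n_cells][mask] - 1]
        removal = {lab: np.flatnonzero(labels == lab)
                   for lab in pd.unique(labels) if lab != "non_responsive"}
        removal = {k: v for k, v in removal.items() if 0 < len(v) < pop.n_cells - 1}
        try:
            abl = geo.pvd_ablation(cs, us, removal, config.cs_window, config.us_window)
            abl["animal"] = pop.animal_id
            rows.append(abl)
        except ValueError as err:
            logger.warning("pvd ablation skipped for %s: %s", pop.animal_id, err)

        # across days, first-four CS+ per day vs the conditioning US vector
        us_vec = geo.us_reference_vector(us, config.us_window)
        tensors = {}
        for day in (HABITUATION, TEST_EXT1, EXT2):
            if day not in protocols:
                continue
            t = align_to_events(pop, protocols[day], CS_PLUS, config.cs_window,
                                config.cs_window, config.cs_window)
            keep = resp.across_day_trial_sets(day, CS_PLUS, t.n_trials)
            tensors[day] = t.select_trials(keep)
        if HABITUATION in tensors:
            days_df = geo.pvd_across_days(tensors, us_vec, config.cs_window)
            days_df["animal"] = pop.animal_id
            across.append(days_df)
        offset += pop.n_cells
    return {"conditioning": pd.concat([r for r in rows if "presentation" in r], ignore_index=True),
            "ablation": pd.concat([r for r in rows if "ablation" in r and "presentation" not in r],
                                  ignore_index=True) if any("late_minus_early" in r for r in rows) else None,
            "across_days": pd.concat(across, ignore_index=True) if across else None}


def _decode_stage(config, protocols, populations, rng):
    cond = protocols[CONDITIONING]
    intra_rows, cross_rows, weight_rows = [], [], []
    for pop in populations:
        seed = int(rng.integers(2**31))
        intra = dec.repeated_crossval(
            pop, cond, n_cells=config.n_cells_decoder,
            n_iterations=config.decoder_iterations, folds=config.decoder_folds, seed=seed)
        intra["animal"] = pop.animal_id
        intra_rows.append(intra)

        ds = dec.build_dataset(pop, cond, n_cells=config.n_cells_decoder, seed=seed)
        shuffled = dec.shuffled_label_control(ds, config.n_shuffles,
                                              config.decoder_folds, seed=seed)
        intra_rows[-1]["shuffled_mean"] = shuffled.mean()

        # cross-day two-way transfer between the two extinction sessions
        if TEST_EXT1 in protocols and EXT2 in protocols:
            cells = np.sort(np.random.default_rng(seed).choice(
                pop.n_cells, size=min(config.n_cells_decoder, pop.n_cells), replace=False))
            for stim in (CS_PLUS, CS_MINUS):
                ds_a = dec.build_dataset(pop, protocols[TEST_EXT1],
                                         (dec.BASELINE, stim), cells=cells, seed=seed)
                ds_b = dec.build_dataset(pop, protocols[EXT2],
                                         (dec.BASELINE, stim), cells=cells, seed=seed)
                model = dec.train_twoway(ds_a)
                intra_res = dec.crossval_multiclass(ds_a, config.decoder_folds, seed)
                cross_res = dec.cross_day_evaluate(model, ds_b)
                cross_rows.append({"animal": pop.animal_id, "stimulus": stim,
                                   "train_day": TEST_EXT1, "test_day": EXT2,
                                   "intra_accuracy": intra_res.accuracy,
                                   "cross_accuracy": cross_res.accuracy})
        wdf = dec.weight_selectivity_iterations(
            pop, cond, config.n_cells_decoder,
            n_iterations=min(config.decoder_iterations, 20), seed=seed)
        weight_rows.append({"animal": pop.animal_id, "mean_r": wdf["r"].mean()})
    return {"intra_day": pd.concat(intra_rows, ignore_index=True),
            "cross_day": pd.DataFrame(cross_rows) if cross_rows else None,
            "weight_selectivity": pd.DataFrame(weight_rows)}


def _behaviour_stage(config, protocols, populations, pose, cluster_out):
    per_animal_metrics, stability_input = [], {}
    for pop in populations:
        tracks = pose.get(pop.animal_id, {})
        bouts_by_day = {}
        for day, track in tracks.items():
            filtered = bhv.filter_pose(track, config.likelihood_threshold)
            disp = bhv.displacement(filtered)
            bouts_by_day[day] = bhv.detect_immobility(
                disp, track.frame_rate, config.displacement_threshold,
                config.min_bout_duration, protocols.get(day))
        if TEST_EXT1 in bouts_by_day:
            m = bhv.behaviour_metrics(bouts_by_day[TEST_EXT1], protocols[TEST_EXT1])
            m["animal"] = pop.animal_id
            per_animal_metrics.append(m)
        try:
            act = bhv.immobility_aligned_activity(
                pop, bouts_by_day, pre_window=config.immobility_window,
                baseline_window=config.immobility_window,
                auc_window=config.immobility_window)
            stability_input[pop.animal_id] = act.per_session_onset_auc
        except ValueError as err:
            logger.warning("behaviour stage: %s", err)

    metrics = pd.DataFrame(per_animal_metrics)
    stability = bhv.stability_across_sessions(stability_input) if stability_input else None
    correlation = None
    if cluster_out is not None and len(metrics):
        fractions = cluster_out["fractions"]
        ds = metrics.set_index("animal")["ds"]
        try:
            correlation = bhv.correlate_counts_with_behaviour(fractions, ds)
        except ValueError as err:
            logger.warning("behaviour-cluster correlation skipped: %s", err)
    return {"metrics": metrics, "stability": stability,
            "cluster_correlation": correlation}


# --- bundle -------------------------------------------------------------------------


@dataclass
class ResultsBundle:
    """All stage outputs plus provenance of the run that produced them."""

    results: dict
    config: PipelineConfig
    config_hash: str
    seed: int
    version: str = __version__
    timings: dict = field(default_factory=dict)
    partial: bool = False
    failed_stage: str | None = None

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary = {"config_hash": self.config_hash, "seed": self.seed,
                   "version": self.version, "partial": self.partial,
                   "stages": sorted(self.results)}
        (out / "provenance.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        self.config.to_yaml(out / "config.yaml")
        for stage, payload in self.results.items():
            _write_stage(out, stage, payload)
        return out


def _write_stage(out: Path, stage: str, payload) -> None:
    if isinstance(payload, pd.DataFrame):
        payload.to_csv(out / f"{stage}.tsv", sep="\t", index=True, float_format="%.10g")
    elif isinstance(payload, dict):
        scalars = {}
        for key, val in payload.items():
            if isinstance(val, pd.DataFrame):
                val.to_csv(out / f"{stage}_{key}.tsv", sep="\t", float_format="%.10g")
            elif np.isscalar(val) or val is None:
                scalars[key] = None if val is None else float(val) if isinstance(
                    val, (int, float, np.floating, np.integer)) else str(val)
        if scalars:
            (out / f"{stage}.json").write_text(json.dumps(scalars, indent=2, sort_keys=True))


def hash_outputs(out_dir) -> dict[str, str]:
    """SHA-256 of every text artefact a run wrote, for determinism checks."""
    out = {}
    for p in sorted(Path(out_dir).rglob("*")):
        if p.is_file():
            out[str(p.relative_to(out_dir))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Execute the stages in dependency order and collect their outputs.

    A failing stage marks the bundle partial, records the stage name and
    re-raises; stages toggled off are skipped together with anything that
    depends on them (with a warning).
    """
    rng = np.random.default_rng(config.seed)
    bundle = ResultsBundle(results={}, config=config, config_hash=config.hash(),
                           seed=config.seed)
    protocols, populations, pose, ground_truth = load_inputs(config)
    if ground_truth is not None:
        bundle.results["ground_truth"] = {
            "labels": pd.concat([gt.labels for gt in ground_truth], ignore_index=True)}

    stage_fns = {
        "classify": lambda: _classify_stage(config, protocols, populations),
        "cluster": lambda: _cluster_stage(config, protocols, populations,
                                          bundle.results.get("classify")),
        "pvd": lambda: _pvd_stage(config, protocols, populations,
                                  bundle.results.get("cluster")),
        "decode": lambda: _decode_stage(config, protocols, populations, rng),
        "behaviour": lambda: _behaviour_stage(config, protocols, populations, pose,
                                              bundle.results.get("cluster")),
    }
    dependencies = {"cluster": ("classify",), "pvd": ("classify", "cluster"),
                    "behaviour": ("classify",)}
    for stage, fn in stage_fns.items():
        if not config.stages.get(stage, True):
            logger.warning("stage %s toggled off", stage)
            continue
        missing = [d for d in dependencies.get(stage, ()) if d not in bundle.results]
        if missing:
            logger.warning("stage %s skipped: depends on disabled %s", stage, missing)
            continue
        t0 = time.perf_counter()
        try:
            bundle.results[stage] = fn()
        except Exception:
            bundle.partial = True
            bundle.failed_stage = stage
            logger.exception("stage %s failed", stage)
            raise
        bundle.timings[stage] = time.perf_counter() - t0
        logger.info("stage %s done in %.1f s", stage, bundle.timings[stage])
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle


# --- group comparisons ----------------------------------------------------------------


@dataclass
class GroupComparison:
    """Omnibus + pairwise non-parametric comparison report."""

    design: str
    omnibus_test: str
    statistic: float
    p: float
    pairwise: pd.DataFrame
    screening: pd.DataFrame


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's multiple comparisons on Friedman (within-block) ranks."""
    names = list(groups)
    data = np.column_stack([groups[n] for n in names])
    n_blocks, k = data.shape
    ranks = stats.rankdata(data, axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n_blocks))
    m = k * (k - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = min(1.0, 2 * stats.norm.sf(abs(z)) * m)
        rows.append({"group_a": names[i], "group_b": names[j], "z": z, "p_adjusted": p})
    return pd.DataFrame(rows)


def _screening(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    try:
        lev_p = stats.levene(*arrays).pvalue if len(arrays) > 1 else np.nan
    except ValueError:
        lev_p = np.nan
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) >= 3 and np.ptp(vals) > 0:
            sw_p = stats.shapiro(vals).pvalue
        else:
            sw_p = np.nan
        rows.append({"group": name, "n": len(vals), "shapiro_p": sw_p, "levene_p": lev_p})
    return pd.DataFrame(rows)


def group_comparison(groups: dict, design: str) -> GroupComparison:
    """Non-parametric group contrast with Bonferroni-adjusted pairwise tests.

    ``repeated``: Friedman omnibus, Dunn post hoc (equal-length groups,
    blocks = subjects). ``independent``: Kruskal-Wallis omnibus, pairwise
    Mann-Whitney. ``paired``: Friedman omnibus, pairwise Wilcoxon signed
    rank. ``proportions``: groups are (successes, total) pairs; chi-square
    omnibus, pairwise 2x2 chi-square with Yates continuity correction when
    any expected count is below 5. Normality (Shapiro-Wilk) and variance
    (Levene) screening is reported but the non-parametric path is always
    used.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")

    if design == "proportions":
        names = list(groups)
        table = np.array([[groups[n][0], groups[n][1] - groups[n][0]] for n in names])
        if (table < 0).any():
            raise ValueError("successes must not exceed totals")
        if np.ptp(table[:, 0] / table.sum(axis=1)) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        m = len(names) * (len(names) - 1) // 2
        rows = []
        for a, b in itertools.combinations(names, 2):
            sub = np.array([[groups[a][0], groups[a][1] - groups[a][0]],
                            [groups[b][0], groups[b][1] - groups[b][0]]])
            expected = stats.contingency.expected_freq(sub)
            yates = bool((expected < 5).any())
            if np.ptp(sub[:, 0] / sub.sum(axis=1)) == 0:
                pp = 1.0
            else:
                pp = stats.chi2_contingency(sub, correction=yates)[1]
            rows.append({"group_a": a, "group_b": b, "yates": yates,
                         "p_adjusted": min(1.0, pp * m)})
        screening = pd.DataFrame({"group": names,
                                  "n": [groups[n][1] for n in names],
                                  "shapiro_p": np.nan, "levene_p": np.nan})
        return GroupComparison(design, "chi-square", float(stat), float(p),
                               pd.DataFrame(rows), screening)

    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(len(v) < 2 for v in arrays.values()):
        raise ValueError("every group needs n >= 2")
    screening = _screening(arrays)
    names = list(arrays)
    m = len(names) * (len(names) - 1) // 2

    def identical(a, b):
        return len(a) == len(b) and np.array_equal(a, b)

    if design in ("repeated", "paired"):
        lengths = {len(v) for v in arrays.values()}
        if len(lengths) != 1:
            raise ValueError("repeated/paired designs need equal group lengths")
        data = np.column_stack(list(arrays.values()))
        if np.ptp(stats.rankdata(data, axis=1), axis=1).max() == 0 or np.allclose(
                data, data[:, [0]]):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.friedmanchisquare(*arrays.values())
        if design == "repeated":
            pairwise = _dunn_posthoc(arrays)
        else:
            rows = []
            for a, b in itertools.combinations(names, 2):
                if identical(arrays[a], arrays[b]):
                    pp = 1.0
                else:
                    pp = stats.wilcoxon(arrays[a], arrays[b]).pvalue
                rows.append({"group_a": a, "group_b": b, "p_adjusted": min(1.0, pp * m)})
            pairwise = pd.DataFrame(rows)
        return GroupComparison(design, "friedman", float(stat), float(p), pairwise, screening)

    if design == "independent":
        if all(identical(arrays[names[0]], arrays[n]) for n in names[1:]):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.kruskal(*arrays.values())
        rows = []
        for a, b in itertools.combinations(names, 2):
            if identical(arrays[a], arrays[b]):
                pp = 1.0
            else:
                pp = stats.mannwhitneyu(arrays[a], arrays[b], alternative="two-sided").pvalue
            rows.append({"group_a": a, "group_b": b, "p_adjusted": min(1.0, pp * m)})
        return GroupComparison(design, "kruskal-wallis", float(stat), float(p),
                               pd.DataFrame(rows), screening)

    raise ValueError(f"unknown design {design!r}")
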