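"""Synthetic multi-day calcium recordings with planted response archetypes.

Generates 20 Hz GCaMP-like fluorescence traces over the 4-day
habituation / conditioning / test-extinction protocol, with per-cell
response archetypes planted as ground truth so every downstream stage
(responsiveness, clustering, population geometry, decoding, behaviour) can
be validated against a known answer. The trace model is

    trace = AR(1) noise + (event-locked rate drive * calcium kernel),

where the drive follows the 0.9 Hz / 200 ms pip structure for tones, a 2 s
boxcar for shocks, and per-trial amplitude schedules defined by the planted
archetype. Inhibited archetypes are negative drives: z-scored traces of
tonically active interneurons express suppression as negative deflections
regardless of the raw baseline level, so the sign of the drive is the only
thing the analysis can see.

Archetype families
------------------
* US (shock, conditioning day): activated stable / down / up, inhibited
  stable / up, US off (post-shock response), null.
* CS conditioning (per tone, 5 trials): up, down inhibited, stable
  activated, first activated, first inhibited, down activated, null.
* Across days (gating of tone responses outside conditioning): tone
  activated/inhibited (all days, both tones), fear / fear inhibited
  (CS+ on test/extinction-1 only), extinction / extinction inhibited
  (CS+ on extinction-2 only), stable activated/inhibited (CS+ on all
  days), remapped (day-specific random code, a decoding control), null.

Default mixture proportions follow the cluster sizes reported for the
in-vivo population (out of 519 cells); sessions sizes default to 9 animals
with 58 cells each.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from . import protocol as proto
from .behaviour import BODY_PARTS, ImmobilityBouts, PoseTrack, make_pose_frame
from .protocol import (
    CONDITIONING,
    CS_MINUS,
    CS_PLUS,
    EXT2,
    HABITUATION,
    N_PIPS,
    PIP_DURATION,
    PIP_PERIOD,
    TEST_EXT1,
    US,
    US_DURATION,
    AlignedTensor,
    EventTable,
    TracePopulation,
    preprocess_traces,
)

US_ARCHETYPES = (
    "activated_stable", "activated_down", "activated_up",
    "inhibited_stable", "inhibited_up", "us_off", "null",
)
CS_ARCHETYPES = (
    "up", "down_inhibited", "stable_activated",
    "first_activated", "first_inhibited", "down_activated", "null",
)
XDAY_ARCHETYPES = (
    "tone_activated", "tone_inhibited", "fear", "fear_inhibited",
    "extinction", "extinction_inhibited", "stable_activated",
    "stable_inhibited", "remapped", "null",
)

# mixture defaults from the reported cluster sizes (fractions of 519 cells);
# "Else" and non-responsive cells are folded into null
_US_DEFAULT = {
    "activated_stable": 70, "activated_down": 112, "activated_up": 36,
    "inhibited_stable": 63, "inhibited_up": 73, "us_off": 28, "null": 137,
}
_CS_PLUS_DEFAULT = {
    "up": 63, "down_inhibited": 38, "stable_activated": 72,
    "first_activated": 49, "first_inhibited": 44, "down_activated": 0, "null": 253,
}
_CS_MINUS_DEFAULT = {
    "up": 88, "down_inhibited": 61, "stable_activated": 0,
    "first_activated": 39, "first_inhibited": 40, "down_activated": 27, "null": 264,
}
_XDAY_DEFAULT = {
    "tone_activated": 65, "tone_inhibited": 40, "fear": 66, "fear_inhibited": 48,
    "extinction": 63, "extinction_inhibited": 33, "stable_activated": 0,
    "stable_inhibited": 50, "remapped": 0, "null": 154,
}


def _normalize(counts: dict[str, float]) -> dict[str, float]:
    total = float(sum(counts.values()))
    return {k: v / total for k, v in counts.items()}


@dataclass
class SynthConfig:
    """Stated world of the generator; defaults mirror the recorded cohort."""

    n_animals: int = 9
    cells_per_animal: int = 58
    evoked_amplitude: float = 3.0        # z units, peak rate drive (3x noise sd)
    # geometric decay / ramp floor of the per-trial schedules; at 0.5 the
    # "down" archetypes decay below single-trial detectability by trial ~3,
    # so they are recovered by their early trials (see docs/methods.md)
    ramp: float = 0.5
    # AR(1) noise at the 20 Hz sample rate; the coefficient is chosen so the
    # noise decorrelates at the 0.25 s analysis bin (correlation time ~0.1 s),
    # keeping the rank-sum responsiveness test calibrated. Innovation sd gives
    # unit marginal variance.
    ar_coef: float = 0.6
    noise_sd: float = 1.0
    rise_tau: float = 0.1                # s, GCaMP6f-like
    decay_tau: float = 0.6               # s
    sampling_rate: float = proto.SAMPLING_RATE
    bin_width: float = proto.DEFAULT_BIN_WIDTH
    us_proportions: dict[str, float] = field(default_factory=lambda: _normalize(_US_DEFAULT))
    cs_plus_proportions: dict[str, float] = field(default_factory=lambda: _normalize(_CS_PLUS_DEFAULT))
    cs_minus_proportions: dict[str, float] = field(default_factory=lambda: _normalize(_CS_MINUS_DEFAULT))
    xday_proportions: dict[str, float] = field(default_factory=lambda: _normalize(_XDAY_DEFAULT))
    # behavioural-state modulation: fraction of cells suppressed / enhanced
    # during immobility and the drive amplitude of that modulation
    state_suppressed_fraction: float = 0.15
    state_enhanced_fraction: float = 0.15
    state_amplitude: float = 1.0
    # two-state semi-Markov behaviour model
    frame_rate: float = 20.0
    immobility_prob: float = 0.8         # chance of an immobile bout after a mobile dwell
    immobile_dwell: tuple[float, float] = (2.5, 8.0)    # s, uniform
    mobile_dwell: tuple[float, float] = (5.0, 20.0)     # s, uniform
    immobile_step: float = 0.2           # px/frame
    mobile_step: float = 4.0             # px/frame
    dropout_prob: float = 0.02
    dropout_likelihood: float = 0.2
    base_likelihood: float = 0.99
    iti_range: tuple[float, float] = (60.0, 90.0)
    fov_size: float = 300.0              # px, centroid scatter
    seed: int = 0

    def validate(self) -> None:
        if not (self.decay_tau > self.rise_tau > 0):
            raise ValueError("calcium kernel requires decay_tau > rise_tau > 0")
        if not np.isfinite(self.evoked_amplitude):
            raise ValueError("evoked amplitude must be finite")
        for name, props, allowed in (
            ("us", self.us_proportions, US_ARCHETYPES),
            ("cs_plus", self.cs_plus_proportions, CS_ARCHETYPES),
            ("cs_minus", self.cs_minus_proportions, CS_ARCHETYPES),
            ("xday", self.xday_proportions, XDAY_ARCHETYPES),
        ):
            unknown = set(props) - set(allowed)
            if unknown:
                raise ValueError(f"{name} proportions name unknown archetypes {sorted(unknown)}")
            if abs(sum(props.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} proportions must sum to 1")


@dataclass
class GroundTruth:
    """Planted per-cell archetype labels and per-session immobility bouts."""

    labels: pd.DataFrame            # cell_id, us, cs_plus, cs_minus, across_day, state_sign
    bouts: dict[str, np.ndarray] = field(default_factory=dict)   # day -> (k, 2) s

    def to_tsv(self, path) -> None:
        long = self.labels.melt(id_vars="cell_id", var_name="family", value_name="label")
        long.to_csv(path, sep="\t", index=False)


# --- primitives ---------------------------------------------------------------

def calcium_kernel(rise_tau: float, decay_tau: float, dt: float) -> np.ndarray:
    """Difference-of-exponentials transient, peak-normalized to 1.

    Truncated five decay constants after the (analytic) peak time, where the
    normalized tail has fallen below 1% of the peak.
    """
    if not (decay_tau > rise_tau > 0):
        raise ValueError("requires decay_tau > rise_tau > 0")
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    t = np.arange(0.0, t_peak + 5.0 * decay_tau, dt)
    k = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    return k / k.max()


def archetype_amplitude_schedule(
    archetype: str, n_trials: int, base_amp: float = 1.0, ramp: float = 0.5
) -> np.ndarray:
    """Per-trial drive amplitudes for a planted archetype.

    Covers both the US family and the CS-conditioning family; the sign
    encodes activation vs. suppression. ``us_off`` keeps a flat positive
    schedule — its post-offset placement is handled by the generator.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    t = np.arange(1, n_trials + 1, dtype=float)
    flat = np.full(n_trials, base_amp)
    if n_trials > 1:
        ramp_up = base_amp * (ramp + (1 - ramp) * (t - 1) / (n_trials - 1))
        grow = base_amp * (t - 1) / (n_trials - 1)          # 0 -> base_amp
    else:
        ramp_up = grow = flat
    first = np.zeros(n_trials)
    first[0] = base_amp
    down_act = np.where(t <= 2, base_amp, 0.0)

    schedules = {
        "activated_stable": flat,
        "activated_down": base_amp * ramp ** (t - 1),
        "activated_up": ramp_up,
        "inhibited_stable": -flat,
        "inhibited_up": -ramp_up,
        "us_off": flat,
        "up": grow,
        "down_inhibited": -grow,
        "stable_activated": flat,
        "first_activated": first,
        "first_inhibited": -first,
        "down_activated": down_act,
        "null": np.zeros(n_trials),
    }
    if archetype not in schedules:
        raise ValueError(f"unknown archetype {archetype!r}")
    return schedules[archetype]


def _xday_gate(archetype: str, day: str, label: str) -> float:
    """Multiplier applied to tone drives outside the conditioning day."""
    if archetype in ("tone_activated", "tone_inhibited"):
        sign = 1.0 if archetype == "tone_activated" else -1.0
        return sign
    if label != CS_PLUS:
        return 0.0
    gates = {
        "fear": (TEST_EXT1, 1.0),
        "fear_inhibited": (TEST_EXT1, -1.0),
        "extinction": (EXT2, 1.0),
        "extinction_inhibited": (EXT2, -1.0),
    }
    if archetype in gates:
        gday, sign = gates[archetype]
        return sign if day == gday else 0.0
    if archetype == "stable_activated":
        return 1.0
    if archetype == "stable_inhibited":
        return -1.0
    return 0.0   # null / remapped handled elsewhere


def _pip_drive(drive: np.ndarray, cells_amp: np.ndarray, onset: float, fs: float) -> None:
    """Add the 0.9 Hz / 200 ms pip-structured tone drive in place."""
    pip_samples = max(1, int(round(PIP_DURATION * fs)))
    for k in range(N_PIPS):
        s0 = int(np.floor((onset + k * PIP_PERIOD) * fs))
        drive[:, s0: s0 + pip_samples] += cells_amp[:, None]


def _boxcar_drive(drive: np.ndarray, cells_amp: np.ndarray, start: float, stop: float, fs: float) -> None:
    s0, s1 = int(np.floor(start * fs)), int(np.floor(stop * fs))
    drive[:, s0:s1] += cells_amp[:, None]


def ar1_noise(rng: np.random.Generator, shape: tuple[int, int], coef: float, sd: float) -> np.ndarray:
    """AR(1) noise with unit-variance-calibrated innovations, scaled to ``sd``."""
    innov = rng.standard_normal(shape) * np.sqrt(1.0 - coef**2) * sd
    return signal.lfilter([1.0], [1.0, -coef], innov, axis=-1)


# --- population generator ------------------------------------------------------

def generate_population(
    config: SynthConfig,
    protocols: dict[str, EventTable],
    animal_id: str = "A0",
    seed: int | None = None,
    bouts: dict[str, np.ndarray] | None = None,
) -> tuple[TracePopulation, GroundTruth]:
    """Simulate one animal's multi-session recording with planted archetypes.

    ``protocols`` may hold any subset of the four days. ``bouts`` (day ->
    (k, 2) second intervals) adds behavioural-state modulation for cells
    with a nonzero planted state sign. Deterministic under ``seed``
    (defaults to ``config.seed``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.cells_per_animal
    fs = config.sampling_rate

    def draw(props: dict[str, float], names) -> np.ndarray:
        keys = [k for k in names if k in props]
        p = np.array([props[k] for k in keys])
        return rng.choice(keys, size=n, p=p / p.sum())

    us_arch = draw(config.us_proportions, US_ARCHETYPES)
    csp_arch = draw(config.cs_plus_proportions, CS_ARCHETYPES)
    csm_arch = draw(config.cs_minus_proportions, CS_ARCHETYPES)
    xday_arch = draw(config.xday_proportions, XDAY_ARCHETYPES)
    fs_, fe = config.state_suppressed_fraction, config.state_enhanced_fraction
    state_sign = rng.choice([-1, 0, 1], size=n, p=[fs_, 1 - fs_ - fe, fe])

    kernel = calcium_kernel(config.rise_tau, config.decay_tau, 1.0 / fs)
    kernel = kernel / kernel.sum()   # unit mass: sustained drives keep their amplitude
    amp = config.evoked_amplitude

    raw: dict[str, np.ndarray] = {}
    for day in [d for d in proto.DAY_ORDER if d in protocols]:
        events = protocols[day]
        n_samples = int(round(events.duration_s * fs))
        noise = ar1_noise(rng, (n, n_samples), config.ar_coef, config.noise_sd)
        drive = np.zeros((n, n_samples))

        # day-specific remapped code: fresh random response sign per day/tone
        remap = xday_arch == "remapped"
        remap_mult = {
            lab: np.where(remap, rng.choice([-1.0, 0.0, 1.0], size=n, p=[0.35, 0.3, 0.35]), 0.0)
            for lab in (CS_PLUS, CS_MINUS)
        }

        for label in (CS_PLUS, CS_MINUS):
            rows = events.events[events.events["label"] == label]
            if rows.empty:
                continue
            n_trials = len(rows)
            if day == CONDITIONING:
                arch = csp_arch if label == CS_PLUS else csm_arch
                sched = {a: archetype_amplitude_schedule(a, n_trials, amp, config.ramp)
                         for a in np.unique(arch)}
                per_trial = np.stack([sched[a] for a in arch])        # (cells, trials)
            else:
                gate = np.array([_xday_gate(a, day, label) for a in xday_arch])
                gate = gate + remap_mult[label]
                per_trial = np.repeat((amp * gate)[:, None], n_trials, axis=1)
            for j, (_, row) in enumerate(rows.sort_values("trial_index").iterrows()):
                if np.any(per_trial[:, j]):
                    _pip_drive(drive, per_trial[:, j], row["onset_s"], fs)

        us_rows = events.events[events.events["label"] == US]
        if not us_rows.empty:
            n_trials = len(us_rows)
            sched = {a: archetype_amplitude_schedule(a, n_trials, amp, config.ramp)
                     for a in np.unique(us_arch)}
            per_trial = np.stack([sched[a] for a in us_arch])
            is_off = us_arch == "us_off"
            for j, (_, row) in enumerate(us_rows.sort_values("trial_index").iterrows()):
                a_on = np.where(is_off, 0.0, per_trial[:, j])
                a_off = np.where(is_off, per_trial[:, j], 0.0)
                if np.any(a_on):
                    _boxcar_drive(drive, a_on, row["onset_s"], row["offset_s"], fs)
                if np.any(a_off):
                    _boxcar_drive(drive, a_off, row["offset_s"], row["offset_s"] + US_DURATION, fs)

        if bouts and day in bouts and len(bouts[day]):
            mod = state_sign.astype(float) * config.state_amplitude
            for b0, b1 in bouts[day]:
                _boxcar_drive(drive, mod, float(b0), float(b1), fs)

        if drive.any():
            evoked = signal.fftconvolve(drive, kernel[None, :], mode="full", axes=1)[:, :n_samples]
            raw[day] = noise + evoked
        else:
            raw[day] = noise

    cell_ids = [f"{animal_id}_c{i:04d}" for i in range(n)]
    centroids = rng.uniform(0.0, config.fov_size, size=(n, 2))
    pop = preprocess_traces(raw, config.bin_width, fs, animal_id, cell_ids, centroids)
    labels = pd.DataFrame({
        "cell_id": cell_ids,
        "us": us_arch,
        "cs_plus": csp_arch,
        "cs_minus": csm_arch,
        "across_day": xday_arch,
        "state_sign": state_sign,
    })
    return pop, GroundTruth(labels)


def generate_behaviour(
    config: SynthConfig, events: EventTable, seed: int | None = None
) -> tuple[PoseTrack, np.ndarray]:
    """Simulate pose tracking with planted immobility bouts for one session.

    A two-state semi-Markov chain alternates mobile and immobile epochs
    (immobile dwell >= 2 s); body parts share a random-walk base position
    whose per-frame step is large when mobile and small when immobile.
    Occasional likelihood dropouts produce garbage coordinates that the
    pose filter must remove. Returns the pose track and the planted
    (k, 2) bout intervals in seconds.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fr = config.frame_rate
    n_frames = int(round(events.duration_s * fr))

    immobile = np.zeros(n_frames, dtype=bool)
    planted = []
    t = 0
    while t < n_frames:
        t += int(round(rng.uniform(*config.mobile_dwell) * fr))
        if t >= n_frames:
            break
        if rng.uniform() >= config.immobility_prob:
            continue
        dwell = int(round(rng.uniform(*config.immobile_dwell) * fr))
        stop = min(t + dwell, n_frames)
        if (stop - t) / fr >= 2.0:
            immobile[t:stop] = True
            planted.append((t / fr, stop / fr))
        t = stop

    step = np.where(immobile, config.immobile_step, config.mobile_step)
    heading = rng.uniform(0, 2 * np.pi, n_frames)
    base = np.cumsum(np.stack([step * np.cos(heading), step * np.sin(heading)], axis=1), axis=0)
    base += rng.uniform(100, 200, size=2)

    parts, likes = {}, {}
    for part in BODY_PARTS:
        offset = rng.uniform(-10, 10, size=2)
        jitter = rng.normal(0.0, 0.02, size=(n_frames, 2))
        xy = base + offset + jitter
        like = np.full(n_frames, config.base_likelihood)
        drop = rng.uniform(size=n_frames) < config.dropout_prob
        like[drop] = config.dropout_likelihood
        xy[drop] = rng.uniform(0, 500, size=(int(drop.sum()), 2))   # garbage when unconfident
        parts[part] = xy
        likes[part] = like

    pose = PoseTrack(make_pose_frame(parts, likes), fr)
    return pose, np.array(planted).reshape(-1, 2)


@dataclass
class SyntheticDataset:
    """Everything one simulated cohort produces."""

    protocols: dict[str, EventTable]
    populations: list[TracePopulation]
    ground_truths: list[GroundTruth]
    pose: dict[str, dict[str, PoseTrack]]        # animal -> day -> pose
    config: SynthConfig


def generate_dataset(config: SynthConfig, days: tuple[str, ...] = proto.DAY_ORDER) -> SyntheticDataset:
    """Full cohort: protocols, populations with state modulation, behaviour."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    proto_seed, *animal_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(config.n_animals + 1)]
    protocols = {day: tab for day, tab in proto.build_all_protocols(config.iti_range, proto_seed).items()
                 if day in days}

    populations, truths, pose = [], [], {}
    for a in range(config.n_animals):
        animal_id = f"A{a:02d}"
        arng = np.random.default_rng(animal_seeds[a])
        pose[animal_id] = {}
        bouts: dict[str, np.ndarray] = {}
        for day in (TEST_EXT1, EXT2, HABITUATION):
            if day not in protocols:
                continue
            track, planted = generate_behaviour(config, protocols[day],
                                                seed=int(arng.integers(2**31)))
            pose[animal_id][day] = track
            bouts[day] = planted
        pop, gt = generate_population(config, protocols, animal_id,
                                      seed=int(arng.integers(2**31)), bouts=bouts)
        gt.bouts = bouts
        populations.append(pop)
        truths.append(gt)
    return SyntheticDataset(protocols, populations, truths, pose, config)


# --- noiseless templates for cluster labeling ----------------------------------

def archetype_template(
    family: str,
    archetype: str,
    n_trials: int,
    post_window: float,
    config: SynthConfig | None = None,
) -> np.ndarray:
    """Expected per-trial-concatenated feature vector of a planted archetype.

    Built through the same drive -> kernel -> bin path as the generator but
    noiseless, at unit amplitude; used by the cluster labeling stage as the
    template library.
    """
    config = config or SynthConfig()
    fs = config.sampling_rate
    kernel = calcium_kernel(config.rise_tau, config.decay_tau, 1.0 / fs)
    kernel = kernel / kernel.sum()
    pre = 2.0   # template pre-roll so the kernel onset is not clipped
    n_samples = int(round((pre + post_window + 5 * config.decay_tau) * fs))
    sched = archetype_amplitude_schedule(archetype, n_trials, 1.0, config.ramp)

    pieces = []
    for a in sched:
        drive = np.zeros((1, n_samples))
        if family == "us":
            if archetype == "us_off":
                _boxcar_drive(drive, np.array([a]), pre + US_DURATION, pre + 2 * US_DURATION, fs)
            else:
                _boxcar_drive(drive, np.array([a]), pre, pre + US_DURATION, fs)
        else:
            _pip_drive(drive, np.array([a]), pre, fs)
        trace = signal.fftconvolve(drive, kernel[None, :], mode="full", axes=1)[:, :n_samples]
        binned = proto.bin_traces(trace, config.bin_width, fs)[0]
        b0 = int(round(pre / config.bin_width))
        nb = int(round(post_window / config.bin_width))
        pieces.append(binned[b0: b0 + nb])
    return np.concatenate(pieces)


def template_library(
    family: str,
    n_trials: int,
    post_window: float,
    config: SynthConfig | None = None,
    archetypes: tuple[str, ...] | None = None,
) -> dict[str, np.ndarray]:
    """Named noiseless templates for one archetype family (null excluded)."""
    if archetypes is None:
        archetypes = US_ARCHETYPES if family == "us" else CS_ARCHETYPES
    return {
        a: archetype_template(family, a, n_trials, post_window, config)
        for a in archetypes if a != "null"
    }


# --- purpose-built constructions for validation ---------------------------------

def separable_decoder_dataset(
    n_cells: int = 37,
    n_blocks: int = 4,
    bins_per_block: int = 30,
    noise_sd: float = 0.3,
    seed: int = 0,
    classes: tuple[str, ...] = ("BASELINE", CS_PLUS, CS_MINUS),
):
    """Linearly separable multi-class dataset with class-specific mean patterns.

    Baseline samples are pure noise; each CS class adds a fixed random
    population pattern. Returns a :class:`fearcal.decoding.DecoderDataset`.
    """
    from .decoding import BASELINE, DecoderDataset

    rng = np.random.default_rng(seed)
    patterns = {c: np.zeros(n_cells) if c == BASELINE else rng.normal(0.0, 1.0, n_cells)
                for c in classes}
    n_per = n_blocks * bins_per_block
    X = np.concatenate([patterns[c] + rng.normal(0.0, noise_sd, (n_per, n_cells))
                        for c in classes])
    y = np.repeat(list(classes), n_per)
    return DecoderDataset(X=X, y=y, animal_id="synthetic", day_kind="synthetic",
                          cell_indices=np.arange(n_cells), bin_width=1.0, seed=seed)


def cs_us_morph_tensors(
    convergence: float,
    n_cells: int = 50,
    amp: float = 2.0,
    noise_sd: float = 0.1,
    n_trials: int = 5,
    cs_bins: int = 120,
    us_bins: int = 20,
    bin_width: float = proto.DEFAULT_BIN_WIDTH,
    seed: int = 0,
    with_truth: bool = False,
):
    """CS responses that linearly morph toward the US pattern across pairings.

    With convergence rate ``r``, the CS population pattern on pairing t is
    ``c_t = c_1 + m_t (u - c_1)`` with ``m = [0, (1-r)/3, 2(1-r)/3, 1-r,
    1-r]``, so both late pairings sit at distance ``r * d_1`` from the US
    pattern and the normalized late change equals ``-100 (1 - r)`` percent
    up to the (quantifiable) noise inflation of measured distances.

    With ``with_truth`` a third element carries the noiseless patterns and
    exact pattern distances, so a test can derive the expected value of the
    noisy distance estimator in closed form.
    """
    r = convergence
    if not 0 <= r <= 1:
        raise ValueError("convergence rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, amp, n_cells)
    c1 = rng.normal(0.0, amp, n_cells)
    m = np.concatenate([np.linspace(0.0, 1.0 - r, max(n_trials - 1, 1)), [1.0 - r]])[:n_trials]

    cs = np.empty((n_cells, n_trials, cs_bins))
    patterns = np.empty((n_trials, n_cells))
    for t in range(n_trials):
        patterns[t] = c1 + m[t] * (u - c1)
        cs[:, t, :] = patterns[t][:, None] + rng.normal(0.0, noise_sd, (n_cells, cs_bins))
    us = u[:, None, None] + rng.normal(0.0, noise_sd, (n_cells, n_trials, us_bins))

    def tensor(data: np.ndarray, label: str, window: float) -> AlignedTensor:
        return AlignedTensor(label=label, data=data, pre_window=0.0, post_window=window,
                             baseline_window=0.0, bin_width=bin_width)

    out = (tensor(cs, CS_PLUS, cs_bins * bin_width), tensor(us, US, us_bins * bin_width))
    if not with_truth:
        return out
    truth = {
        "us_pattern": u,
        "cs_patterns": patterns,
        "pattern_distances": np.linalg.norm(patterns - u, axis=1),
        "noise_sd": noise_sd,
        "n_us_samples": n_trials * us_bins,
    }
    return out + (truth,)


def null_config(n_cells: int, seed: int = 0, **overrides) -> SynthConfig:
    """Config whose every archetype family is 100% null (pure-noise cells)."""
    return replace(
        SynthConfig(seed=seed, cells_per_animal=n_cells, n_animals=1),
        us_proportions={"null": 1.0},
        cs_plus_proportions={"null": 1.0},
        cs_minus_proportions={"null": 1.0},
        xday_proportions={"null": 1.0},
        state_suppressed_fraction=0.0,
        state_enhanced_fraction=0.0,
        **overrides,
    )
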