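"""Synthetic delayed grasp-to-hold sessions: conditions, kinematics, spiking.

The generator emulates the structure of a macaque grasping experiment in which
two handle grips plus 48 objects (six parametric shape families of six sizes,
a mixed set, and six abstract forms requiring one common grip) are grasped in
a delayed grasp-and-hold task while three cortical populations (AIP, F5, M1)
are recorded together with 27 joint angles of the acting hand.

Three structural dissociations are built in by construction:

* abstract objects differ visually but share one hand configuration,
* the handle conditions 00/01 share the visual stimulus but demand maximally
  different grips (precision vs power),
* object shape dominates object size in the visual feature code (4:1).

Firing of each unit follows ``rate(t) = max(0, baseline + envelope(epoch) *
(visual_gain * v(condition) * gate(t) + motor_gain * m(joint angles)))`` where
``gate`` switches on ``latency_s`` after cue onset and drops to ``dark_gain``
after cue offset.  The intensity is piecewise constant within a trial, so
spikes are drawn as an exact inhomogeneous Poisson process: Poisson counts per
constant-rate segment with uniform times inside each segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import EPOCHS, FAMILIES, GeneratorConfig, config_hash

N_JOINT_ANGLES = 27

#: parametric shape families (one turntable each, six sizes each)
PARAMETRIC_SHAPES = ("ring", "cube", "sphere", "cylinder_h", "bar", "cylinder_v")

_FAMILY_BLOCK = {
    "handle": 0,
    "mixed": 1,
    "ring": 2,
    "cube": 3,
    "sphere": 4,
    "cylinder_h": 5,
    "bar": 6,
    "cylinder_v": 7,
    "abstract": 9,
}

_SIZES_MM = (15, 20, 25, 30, 35, 40)

# mixed turntable: average-sized objects of the parametric shapes, plus one
# small sphere and one big ring whose grips match the small-object and the
# enclosing-grip groups respectively
_MIXED_OBJECTS = (
    ("11", "sphere", 15),
    ("12", "cube", 30),
    ("13", "bar", 30),
    ("14", "cylinder_h", 30),
    ("15", "sphere", 35),
    ("16", "ring", 35),
)

# prototype geometry channels
_CH_WRIST = 0          # wrist rotation (deg); 90 for enclosing grips
_CH_APERTURE = (1, 2)  # grip aperture channels, monotone in object size


def _grip_class(cid: str, shape: str, size_mm: float) -> str:
    if cid == "00":
        return "precision"
    if cid == "01":
        return "power"
    if shape == "abstract":
        return "abstract_common"
    if shape in ("ring", "cube", "sphere") and size_mm <= 20:
        return "precision_small"
    if shape == "cylinder_v" or (shape == "ring" and size_mm >= 25):
        return "enclose_rotated"
    if cid == "56":
        # biggest horizontal cylinder, grasped from below (supinated)
        return "enclose_supinated"
    return f"power_{shape}"


def make_condition_catalog(families: Iterable[str] | None = None) -> pd.DataFrame:
    """Build the condition catalog (default: the full 50-condition task).

    Each condition carries a two-digit id whose first digit encodes the
    turntable/family and whose second digit encodes the size rank for the six
    parametric families.  Returns a DataFrame with columns
    ``id, shape, size_mm, grip_class, block`` sorted by ascending id.
    """
    if families is None:
        families = FAMILIES
    families = tuple(families)
    unknown = set(families) - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown object families: {sorted(unknown)}")

    rows: list[tuple[str, str, float, str, int]] = []
    for fam in families:
        block = _FAMILY_BLOCK[fam]
        if fam == "handle":
            rows.append(("00", "handle", 30, "precision", block))
            rows.append(("01", "handle", 30, "power", block))
        elif fam == "mixed":
            for cid, shape, size in _MIXED_OBJECTS:
                rows.append((cid, shape, float(size), _grip_class(cid, shape, size), block))
        elif fam == "abstract":
            for i in range(1, 7):
                cid = f"9{i}"
                rows.append((cid, "abstract", 25.0, "abstract_common", block))
        else:  # parametric family
            for rank, size in enumerate(_SIZES_MM, start=1):
                cid = f"{block}{rank}"
                rows.append((cid, fam, float(size), _grip_class(cid, fam, size), block))

    catalog = pd.DataFrame(
        rows, columns=["id", "shape", "size_mm", "grip_class", "block"]
    ).sort_values("id", ignore_index=True)
    if catalog["id"].duplicated().any():
        raise AssertionError("condition ids must be unique")
    return catalog


def make_grip_prototypes(
    catalog: pd.DataFrame,
    rng: np.random.Generator,
    *,
    class_sigma_deg: float = 12.0,
    condition_sigma_deg: float = 2.5,
    handle_separation_deg: float = 75.0,
) -> dict[str, np.ndarray]:
    """Mean hold-epoch joint-angle vector (27 channels, degrees) per condition.

    Prototypes are built from one base posture per grip class plus a small
    per-condition offset, a wrist-rotation channel (90 deg for enclosing
    grips on vertical cylinders and big rings, -90 deg supinated) and two
    aperture channels that scale monotonically with object size.  The handle
    grips sit at +/- ``handle_separation_deg`` along one posture direction so
    that precision (00) and power (01) are the most distant condition pair.
    Abstract objects share one identical prototype.
    """
    posture_dim = N_JOINT_ANGLES - 3
    u = rng.standard_normal(posture_dim)
    u /= np.linalg.norm(u)

    bases: dict[str, np.ndarray] = {}
    for grip_class in sorted(catalog["grip_class"].unique()):
        bases[grip_class] = rng.normal(0.0, class_sigma_deg, posture_dim)
    if "precision" in bases:
        bases["precision"] = handle_separation_deg * u
    if "power" in bases:
        bases["power"] = -handle_separation_deg * u

    prototypes: dict[str, np.ndarray] = {}
    for row in catalog.sort_values("id").itertuples(index=False):
        vec = np.zeros(N_JOINT_ANGLES)
        if row.grip_class == "enclose_rotated":
            vec[_CH_WRIST] = 90.0
        elif row.grip_class == "enclose_supinated":
            vec[_CH_WRIST] = -90.0
        # handle apertures reflect the executed grip, not the object size
        aperture_size = {"00": 15.0, "01": 40.0}.get(row.id, float(row.size_mm))
        vec[_CH_APERTURE[0]] = 0.9 * aperture_size
        vec[_CH_APERTURE[1]] = 0.55 * aperture_size
        posture = bases[row.grip_class]
        if row.grip_class not in ("abstract_common", "precision", "power"):
            posture = posture + rng.normal(0.0, condition_sigma_deg, posture_dim)
        vec[3:] = posture
        prototypes[row.id] = vec
    return prototypes


def visual_feature_matrix(
    catalog: pd.DataFrame, w_shape: float = 4.0, w_size: float = 1.0
) -> tuple[np.ndarray, list[str]]:
    """Visual feature vectors: weighted one-hot shape identity + scalar size.

    Every abstract object gets its own identity slot (they look different);
    both handle conditions share one slot (same object).  Returns the
    conditions x features matrix (catalog id order) and the slot names, with
    the last column holding ``w_size * normalized size``.
    """
    slots: list[str] = []
    for shape in PARAMETRIC_SHAPES:
        if (catalog["shape"] == shape).any():
            slots.append(shape)
    if (catalog["shape"] == "handle").any():
        slots.append("handle")
    for cid in sorted(catalog.loc[catalog["shape"] == "abstract", "id"]):
        slots.append(f"abstract_{cid}")

    features = np.zeros((len(catalog), len(slots) + 1))
    slot_index = {name: i for i, name in enumerate(slots)}
    for i, row in enumerate(catalog.itertuples(index=False)):
        name = f"abstract_{row.id}" if row.shape == "abstract" else row.shape
        features[i, slot_index[name]] = w_shape
        features[i, -1] = w_size * (row.size_mm - 15.0) / 25.0
    return features, slots + ["size"]


@dataclass
class UnitSpec:
    """Generative parameters of one simulated unit."""

    unit_id: int
    area: str               # AIP | F5 | M1
    subarray: str           # ventral | dorsal | none
    baseline_hz: float
    visual_gain: float
    motor_gain: float
    latency_s: float
    dark_gain: float
    envelope: dict[str, float]
    w_visual: np.ndarray    # weights over visual feature slots (+ size)
    w_motor: np.ndarray     # weights over the 27 joint-angle channels

    def __post_init__(self) -> None:
        if self.baseline_hz < 0:
            raise ValueError("baseline_hz must be nonnegative")
        if self.visual_gain < 0 or self.motor_gain < 0 or self.dark_gain < 0:
            raise ValueError("gains must be nonnegative")
        missing = set(EPOCHS) - set(self.envelope)
        if missing:
            raise ValueError(f"envelope missing epochs: {sorted(missing)}")


def make_unit_specs(
    config: GeneratorConfig,
    n_visual_features: int,
    rng: np.random.Generator,
) -> list[UnitSpec]:
    """Draw the unit populations for one session from the area presets."""
    specs: list[UnitSpec] = []
    uid = 0
    for area in ("AIP", "F5", "M1"):
        n = config.unit_counts.get(area, 0)
        n_ventral = int(round(config.f5_visual_fraction * n)) if area == "F5" else 0
        for i in range(n):
            if area == "F5":
                subarray = "ventral" if i < n_ventral else "dorsal"
                params = config.area_params["F5_ventral" if i < n_ventral else "F5_dorsal"]
            else:
                subarray = "none"
                params = config.area_params[area]
            gain_factor = float(rng.lognormal(0.0, params.gain_spread))
            specs.append(
                UnitSpec(
                    unit_id=uid,
                    area=area,
                    subarray=subarray,
                    baseline_hz=float(rng.gamma(params.baseline_shape, params.baseline_scale)),
                    visual_gain=params.visual_gain * gain_factor,
                    motor_gain=params.motor_gain * gain_factor,
                    latency_s=params.latency_s,
                    dark_gain=params.dark_gain,
                    envelope=dict(params.envelope),
                    w_visual=rng.standard_normal(n_visual_features),
                    w_motor=rng.standard_normal(N_JOINT_ANGLES),
                )
            )
            uid += 1
    return specs


@dataclass
class _DriveContext:
    """Precomputed per-unit condition drives shared by all trials."""

    condition_ids: list[str]
    visual_drive: np.ndarray    # units x conditions (Hz)
    motor_scale: np.ndarray     # 27 per-channel std used to normalize postures
    motor_center: np.ndarray    # 27 per-channel mean
    w_motor_norm: np.ndarray    # units x 27, scaled for unit-variance readout


def build_drive_context(
    catalog: pd.DataFrame,
    prototypes: dict[str, np.ndarray],
    specs: Sequence[UnitSpec],
    config: GeneratorConfig,
) -> _DriveContext:
    features, _ = visual_feature_matrix(catalog, config.w_shape, config.w_size)
    norm = float(np.hypot(config.w_shape, config.w_size))
    if norm == 0:
        norm = 1.0
    w_vis = np.array([s.w_visual for s in specs])          # units x features
    v = (w_vis @ features.T) / norm                        # units x conditions
    gains = np.array([s.visual_gain for s in specs])
    visual_drive = gains[:, None] * v

    proto = np.array([prototypes[cid] for cid in catalog["id"]])
    center = proto.mean(axis=0)
    scale = proto.std(axis=0)
    scale[scale == 0] = 1.0
    w_mot = np.array([s.w_motor for s in specs]) / np.sqrt(N_JOINT_ANGLES)
    return _DriveContext(
        condition_ids=list(catalog["id"]),
        visual_drive=visual_drive,
        motor_scale=scale,
        motor_center=center,
        w_motor_norm=w_mot,
    )


def sample_timeline(config: GeneratorConfig, rng: np.random.Generator) -> dict[str, float]:
    """Draw one trial timeline; all times in seconds relative to fixation_on."""
    fixation_on = 0.0
    cue_on = fixation_on + rng.uniform(*config.fixation_range_s)
    cue_off = cue_on + config.cue_duration_s
    go = cue_off + rng.uniform(*config.plan_range_s)
    movement_onset = go + rng.uniform(*config.reaction_range_s)
    hold_on = movement_onset + config.movement_duration_s
    hold_off = hold_on + config.hold_duration_s
    return {
        "fixation_on": fixation_on,
        "cue_on": cue_on,
        "cue_off": cue_off,
        "go": go,
        "movement_onset": movement_onset,
        "hold_on": hold_on,
        "hold_off": hold_off,
    }


def _trial_trajectory(
    timeline: dict[str, float],
    posture: np.ndarray,
    config: GeneratorConfig,
) -> np.ndarray:
    """50 Hz joint-angle trajectory: rest -> smooth transport -> hold posture."""
    dt = 1.0 / config.kin_rate_hz
    n = int(np.floor(timeline["hold_off"] / dt)) + 1
    t = np.arange(n) * dt
    tau = (t - timeline["movement_onset"]) / (
        timeline["hold_on"] - timeline["movement_onset"]
    )
    tau = np.clip(tau, 0.0, 1.0)
    ramp = 0.5 - 0.5 * np.cos(np.pi * tau)   # smooth cosine transport
    return ramp[:, None] * posture[None, :]


def _rate_segments(
    timeline: dict[str, float],
    visual_drive: np.ndarray,    # per unit (Hz), condition already selected
    motor_drive: np.ndarray,     # per unit (Hz), trial posture already applied
    specs: Sequence[UnitSpec],
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant firing rates: (boundaries[s+1], rates[units, s])."""
    latencies = np.array([s.latency_s for s in specs])
    distinct = sorted(set(latencies))
    # segment boundaries common to all units, plus per-latency visual onsets
    events = [
        timeline["fixation_on"],
        timeline["cue_on"],
        *[timeline["cue_on"] + lat for lat in distinct if lat > 0],
        timeline["cue_off"],
        timeline["go"],
        timeline["movement_onset"],
        timeline["hold_on"],
        timeline["hold_off"],
    ]
    bounds = np.unique(np.array(events))
    mids = 0.5 * (bounds[:-1] + bounds[1:])

    epoch_of = np.empty(len(mids), dtype=object)
    epoch_of[mids < timeline["cue_on"]] = "fixation"
    epoch_of[(mids >= timeline["cue_on"]) & (mids < timeline["cue_off"])] = "cue"
    epoch_of[(mids >= timeline["cue_off"]) & (mids < timeline["movement_onset"])] = "plan"
    epoch_of[(mids >= timeline["movement_onset"]) & (mids < timeline["hold_on"])] = "move"
    epoch_of[mids >= timeline["hold_on"]] = "hold"

    n_units = len(specs)
    env = np.empty((n_units, len(mids)))
    gate = np.empty((n_units, len(mids)))
    baseline = np.array([s.baseline_hz for s in specs])
    dark = np.array([s.dark_gain for s in specs])
    for j, mid in enumerate(mids):
        ep = epoch_of[j]
        env[:, j] = [s.envelope[ep] for s in specs]
        if mid < timeline["cue_on"]:
            gate[:, j] = 0.0
        elif mid < timeline["cue_off"]:
            gate[:, j] = (mid >= timeline["cue_on"] + latencies).astype(float)
        else:
            gate[:, j] = dark
    rates = baseline[:, None] + env * (
        gate * visual_drive[:, None] + motor_drive[:, None]
    )
    np.maximum(rates, 0.0, out=rates)
    return bounds, rates


def _sample_segment_spikes(
    bounds: np.ndarray, rates: np.ndarray, rng: np.random.Generator
) -> list[np.ndarray]:
    """Exact Poisson sampling from a piecewise-constant intensity, per unit."""
    durs = np.diff(bounds)
    counts = rng.poisson(rates * durs[None, :])
    spikes: list[np.ndarray] = []
    for u in range(rates.shape[0]):
        total = int(counts[u].sum())
        if total == 0:
            spikes.append(np.empty(0))
            continue
        starts = np.repeat(bounds[:-1], counts[u])
        widths = np.repeat(durs, counts[u])
        times = starts + widths * rng.random(total)
        times.sort()
        spikes.append(times)
    return spikes


def sample_trial(
    condition_id: str,
    prototypes: dict[str, np.ndarray],
    specs: Sequence[UnitSpec],
    drive: _DriveContext,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, float], np.ndarray, list[np.ndarray]]:
    """Simulate one trial: (timeline, 50 Hz trajectory [T x 27], spikes/unit)."""
    timeline = sample_timeline(config, rng)
    posture = prototypes[condition_id] + rng.normal(
        0.0, config.kinematic_noise_deg, N_JOINT_ANGLES
    )
    trajectory = _trial_trajectory(timeline, posture, config)

    cond_idx = drive.condition_ids.index(condition_id)
    z = (posture - drive.motor_center) / drive.motor_scale
    motor_gains = np.array([s.motor_gain for s in specs])
    motor_drive = motor_gains * (drive.w_motor_norm @ z)
    bounds, rates = _rate_segments(
        timeline, drive.visual_drive[:, cond_idx], motor_drive, specs
    )
    spikes = _sample_segment_spikes(bounds, rates, rng)
    return timeline, trajectory, spikes


_TRIAL_COLUMNS = [
    "trial_id",
    "condition_id",
    "fixation_on",
    "cue_on",
    "cue_off",
    "go",
    "movement_onset",
    "hold_on",
    "hold_off",
]


@dataclass
class SessionData:
    """One synthetic recording session.

    ``spikes[t][u]`` holds sorted spike times (s, relative to fixation_on) of
    unit ``u`` in trial ``t``; ``kinematics[t]`` the 50 Hz trajectory (T x 27,
    degrees).  ``unit_specs`` and ``prototypes`` retain the generative ground
    truth for parameter-recovery tests; they are not part of the on-disk
    schema.
    """

    conditions: pd.DataFrame
    units: pd.DataFrame
    trials: pd.DataFrame
    spikes: list[list[np.ndarray]]
    kinematics: list[np.ndarray]
    seed: int
    config_hash: str
    kin_rate_hz: float = 50.0
    unit_specs: list[UnitSpec] | None = None
    prototypes: dict[str, np.ndarray] | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def unit_index(self, area: str | None = None) -> np.ndarray:
        if area is None:
            return np.arange(self.n_units)
        return np.flatnonzero((self.units["area"] == area).to_numpy())

    def validate(self) -> None:
        known = set(self.conditions["id"])
        if not set(self.trials["condition_id"]).issubset(known):
            raise AssertionError("every trial must reference a catalog condition")
        for t, row in enumerate(self.trials.itertuples(index=False)):
            times = [getattr(row, c) for c in _TRIAL_COLUMNS[2:]]
            if not np.all(np.diff(times) > 0):
                raise AssertionError("event times must be strictly increasing")
            for train in self.spikes[t]:
                if train.size and (
                    np.any(np.diff(train) < 0)
                    or train[0] < row.fixation_on
                    or train[-1] > row.hold_off
                ):
                    raise AssertionError("spikes must be sorted inside the trial window")


def generate_session(config: GeneratorConfig, seed: int) -> SessionData:
    """Generate a reproducible session from (config, seed).

    Uses one session-level seed with deterministic per-trial substreams, so
    identical inputs yield byte-identical sessions on disk.
    """
    config.validate()
    catalog = make_condition_catalog(config.families)

    root = np.random.SeedSequence(seed)
    ss_proto, ss_units, ss_order, ss_trials = root.spawn(4)
    prototypes = make_grip_prototypes(catalog, np.random.default_rng(ss_proto))
    features, _ = visual_feature_matrix(catalog, config.w_shape, config.w_size)
    specs = make_unit_specs(config, features.shape[1], np.random.default_rng(ss_units))
    drive = build_drive_context(catalog, prototypes, specs, config)

    condition_ids = np.repeat(
        catalog["id"].to_numpy(), config.trials_per_condition
    )
    order = np.random.default_rng(ss_order).permutation(len(condition_ids))
    condition_ids = condition_ids[order]

    trial_streams = ss_trials.spawn(len(condition_ids))
    rows = []
    spikes: list[list[np.ndarray]] = []
    kinematics: list[np.ndarray] = []
    for t, cid in enumerate(condition_ids):
        rng = np.random.default_rng(trial_streams[t])
        timeline, trajectory, trial_spikes = sample_trial(
            cid, prototypes, specs, drive, config, rng
        )
        rows.append([t, cid] + [timeline[c] for c in _TRIAL_COLUMNS[2:]])
        spikes.append(trial_spikes)
        kinematics.append(trajectory)

    trials = pd.DataFrame(rows, columns=_TRIAL_COLUMNS)
    units = pd.DataFrame(
        {
            "unit_id": [s.unit_id for s in specs],
            "area": [s.area for s in specs],
            "subarray": [s.subarray for s in specs],
        }
    )
    session = SessionData(
        conditions=catalog,
        units=units,
        trials=trials,
        spikes=spikes,
        kinematics=kinematics,
        seed=seed,
        config_hash=config_hash(config),
        kin_rate_hz=config.kin_rate_hz,
        unit_specs=specs,
        prototypes=prototypes,
    )
    session.validate()
    return session
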