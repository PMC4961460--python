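"""Configuration objects for the synthetic task generator and the analysis pipeline.

All tunable parameters of the package live here as plain dataclasses so that a
whole run is reproducible from (config, seed) alone.  Analysis defaults follow
the settings of the delayed grasp-to-hold study this package models: Gaussian
rate smoothing with sigma = 50 ms evaluated in 1 ms steps for the sliding
ANOVA, 10 ms bins with sigma = 300 ms smoothing for the feature-code
correlation, significance level p < 0.01, and a 27-dimensional joint space.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

#: Task epochs in temporal order.
EPOCHS = ("fixation", "cue", "plan", "move", "hold")

#: Object families selectable in the condition catalog.
FAMILIES = (
    "handle",
    "mixed",
    "ring",
    "cube",
    "sphere",
    "cylinder_h",
    "bar",
    "cylinder_v",
    "abstract",
)


@dataclass
class AreaParams:
    """Tuning parameters of one simulated unit population.

    ``visual_gain`` and ``motor_gain`` are the between-condition firing-rate
    standard deviations (Hz) contributed by the visual-feature and joint-angle
    readouts at full envelope; ``dark_gain`` multiplies the visual drive after
    cue offset (lights off); ``latency_s`` delays the visual drive after cue
    onset.  ``envelope`` holds per-epoch multiplicative gains.
    """

    baseline_shape: float = 4.0   # gamma shape of per-unit baseline rates
    baseline_scale: float = 2.5   # gamma scale (Hz); mean baseline = 10 Hz
    visual_gain: float = 0.0
    motor_gain: float = 0.0
    latency_s: float = 0.05
    dark_gain: float = 0.0
    gain_spread: float = 0.4      # sigma of the per-unit lognormal gain factor
    envelope: dict[str, float] = field(
        default_factory=lambda: {e: 0.0 for e in EPOCHS}
    )

    def validate(self) -> None:
        if self.visual_gain < 0 or self.motor_gain < 0:
            raise ValueError("gains must be nonnegative")
        if self.dark_gain < 0:
            raise ValueError("dark_gain must be nonnegative")
        missing = set(EPOCHS) - set(self.envelope)
        if missing:
            raise ValueError(f"envelope missing epochs: {sorted(missing)}")
        if any(g < 0 for g in self.envelope.values()):
            raise ValueError("envelope gains must be nonnegative")


def _aip_params() -> AreaParams:
    # Visually dominated, fast (50 ms) responses, coding maintained at
    # reduced gain in the dark.
    return AreaParams(
        visual_gain=6.0,
        motor_gain=0.5,
        latency_s=0.05,
        dark_gain=0.6,
        envelope={"fixation": 0.0, "cue": 1.0, "plan": 1.0, "move": 1.0, "hold": 1.0},
    )


def _f5_ventral_params() -> AreaParams:
    # F5a-like: mixed visual/motor units with planning activity; visual
    # sharing is transient (small dark gain), onset lag 80 ms.
    return AreaParams(
        visual_gain=3.0,
        motor_gain=3.0,
        latency_s=0.08,
        dark_gain=0.15,
        envelope={"fixation": 0.0, "cue": 1.0, "plan": 0.8, "move": 1.0, "hold": 1.0},
    )


def _f5_dorsal_params() -> AreaParams:
    # F5p-like: purely motor, ramping up towards execution.
    return AreaParams(
        visual_gain=0.0,
        motor_gain=5.0,
        latency_s=0.08,
        dark_gain=0.0,
        envelope={"fixation": 0.0, "cue": 0.1, "plan": 0.3, "move": 1.0, "hold": 1.0},
    )


def _m1_params() -> AreaParams:
    # Execution only: silent (at baseline) before movement onset.
    return AreaParams(
        visual_gain=0.0,
        motor_gain=6.0,
        latency_s=0.0,
        dark_gain=0.0,
        envelope={"fixation": 0.0, "cue": 0.0, "plan": 0.0, "move": 1.0, "hold": 1.0},
    )


@dataclass
class GeneratorConfig:
    """Study conditions of a synthetic recording session.

    Defaults emulate the recorded sessions: 50 task conditions, >= 10
    repetitions each, and 240 units split across AIP, F5 and M1 (the real
    sessions held 202 +/- 7 and 355 +/- 20 units).
    """

    unit_counts: dict[str, int] = field(
        default_factory=lambda: {"AIP": 70, "F5": 80, "M1": 90}
    )
    trials_per_condition: int = 10
    families: tuple[str, ...] | None = None  # None -> full 50-condition catalog
    f5_visual_fraction: float = 0.4          # share of F5 units on the ventral array

    # visual feature weighting: shape dominates size 4:1
    w_shape: float = 4.0
    w_size: float = 1.0

    kinematic_noise_deg: float = 2.0   # per-trial, per-channel hold-posture jitter
    kin_rate_hz: float = 50.0

    # task timing (seconds)
    fixation_range_s: tuple[float, float] = (0.5, 0.8)
    cue_duration_s: float = 0.7
    plan_range_s: tuple[float, float] = (0.6, 1.0)
    reaction_range_s: tuple[float, float] = (0.15, 0.25)
    movement_duration_s: float = 0.3
    hold_duration_s: float = 0.5

    area_params: dict[str, AreaParams] = field(
        default_factory=lambda: {
            "AIP": _aip_params(),
            "F5_ventral": _f5_ventral_params(),
            "F5_dorsal": _f5_dorsal_params(),
            "M1": _m1_params(),
        }
    )

    def validate(self) -> None:
        if self.trials_per_condition < 2:
            raise ValueError(
                "trials_per_condition must be >= 2; downstream statistics "
                "(ANOVA, within-condition covariance) are undefined otherwise"
            )
        if self.families is not None:
            unknown = set(self.families) - set(FAMILIES)
            if unknown:
                raise ValueError(f"unknown object families: {sorted(unknown)}")
        if not 0.0 <= self.f5_visual_fraction <= 1.0:
            raise ValueError("f5_visual_fraction must be in [0, 1]")
        if self.kinematic_noise_deg < 0:
            raise ValueError("kinematic_noise_deg must be nonnegative")
        for params in self.area_params.values():
            params.validate()

    @classmethod
    def null(cls, **kwargs: Any) -> "GeneratorConfig":
        """A null model: all visual and motor gains zero (pure baseline)."""
        cfg = cls(**kwargs)
        for params in cfg.area_params.values():
            params.visual_gain = 0.0
            params.motor_gain = 0.0
            params.dark_gain = 0.0
        return cfg


@dataclass
class AnalysisConfig:
    """Analysis-side parameters; defaults are the study's stated settings."""

    alpha: float = 0.01
    sliding_bin_s: float = 0.001
    sliding_sigma_s: float = 0.05
    featcorr_bin_s: float = 0.01
    featcorr_sigma_s: float = 0.3
    window_cue: tuple[float, float] = (-0.2, 1.0)
    window_go: tuple[float, float] = (-0.2, 0.9)
    baseline_epoch: str = "fixation"
    lowpass_cutoff_hz: float = 10.0    # Kaiser-window FIR passband (5-20 Hz valid)
    n_components: int = 27             # common dimensionality for Procrustes
    shrinkage: float | str = "auto"
    procrustes_scaling: bool = True
    procrustes_reflection: bool = True
    hca_k: int = 6                     # dendrogram cut level (number of shape families)
    md_epoch: str = "cue"
    procrustes_epoch: str = "hold"

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 5.0 <= self.lowpass_cutoff_hz <= 20.0:
            raise ValueError("lowpass_cutoff_hz must lie in the 5-20 Hz passband range")
        for name in (self.baseline_epoch, self.md_epoch, self.procrustes_epoch):
            if name not in EPOCHS:
                raise ValueError(f"unknown epoch: {name!r}")


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    n_sessions: int = 10   # sessions per simulated animal

    def validate(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        self.generator.validate()
        self.analysis.validate()


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def config_to_dict(config: Any) -> dict:
    return _to_plain(config)


def config_hash(config: Any) -> str:
    """Stable sha256 of a config, used in session/run manifests."""
    payload = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def _area_params_from_dict(d: dict) -> AreaParams:
    return AreaParams(**d)


def generator_config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if "area_params" in d:
        d["area_params"] = {
            k: _area_params_from_dict(v) for k, v in d["area_params"].items()
        }
    for key in ("families",):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    for key in ("fixation_range_s", "plan_range_s", "reaction_range_s"):
        if key in d:
            d[key] = tuple(d[key])
    return GeneratorConfig(**d)


def analysis_config_from_dict(d: dict) -> AnalysisConfig:
    d = dict(d)
    for key in ("window_cue", "window_go"):
        if key in d:
            d[key] = tuple(d[key])
    return AnalysisConfig(**d)


def pipeline_config_from_dict(d: dict) -> PipelineConfig:
    cfg = PipelineConfig(
        generator=generator_config_from_dict(d.get("generator", {})),
        analysis=analysis_config_from_dict(d.get("analysis", {})),
        n_sessions=d.get("n_sessions", 10),
    )
    return cfg


def load_pipeline_config(path: str | Path | None) -> PipelineConfig:
    """Read a pipeline config from YAML or JSON; ``None`` gives the defaults."""
    if path is None:
        cfg = PipelineConfig()
    else:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        cfg = pipeline_config_from_dict(data)
    cfg.validate()
    return cfg
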