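"""Configuration objects for the synthetic cohort and the end-to-end pipeline.

All quantities carry the units used throughout the package: areas in mm²,
perimeters in mm, time in days (wound records) or seconds (thermal sessions),
temperatures in °C, irradiance in mW/cm².
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ConfigurationError

#: default sampling schedule: every 4th day through day 28
DEFAULT_SAMPLING_DAYS: tuple[int, ...] = tuple(range(0, 29, 4))

#: default therapy arms: sham control plus the three LED wavelengths
DEFAULT_GROUPS: tuple[str, ...] = ("control", "red", "green", "blue")


@dataclass(frozen=True)
class GroupKinetics:
    """Generating truth for one arm's plateau-exponential closure trajectory.

    ``%W(t) = (w0_rel - wp_rel) * exp(-k * t) + wp_rel`` in percent of the
    day-0 wound area.
    """

    w0_rel: float = 100.0  # % at day 0 (pre-noise)
    wp_rel: float = 25.0   # plateau, %
    k: float = 0.065       # closure rate constant, per day

    def validate(self, label: str = "") -> None:
        tag = f" for group {label!r}" if label else ""
        if self.k <= 0:
            raise ConfigurationError(f"k must be > 0{tag}, got {self.k}")
        if not 0 <= self.wp_rel < self.w0_rel:
            raise ConfigurationError(
                f"need 0 <= wp_rel < w0_rel{tag}, got wp_rel={self.wp_rel}, w0_rel={self.w0_rel}"
            )


#: arm-specific closure kinetics: red heals fastest, blue barely differs from control
DEFAULT_GROUP_KINETICS: Mapping[str, GroupKinetics] = {
    "control": GroupKinetics(100.0, 25.0, 0.065),
    "red": GroupKinetics(100.0, 20.0, 0.080),
    "green": GroupKinetics(100.0, 22.0, 0.074),
    "blue": GroupKinetics(100.0, 25.0, 0.067),
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic wound-measurement cohort.

    The cohort emulates a 4-arm excision-wound study: ø ``initial_diameter``
    full-thickness wounds photographed every 4th day, whose relative area
    follows a plateau-exponential decay with an early gaping transient
    (a Gaussian-in-time bump centred near day 4), multiplicative lognormal
    measurement noise, and perimeters tied to a wound-size-dependent
    eccentricity trajectory.
    """

    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_per_group: int = 8
    sampling_days: tuple[int, ...] = DEFAULT_SAMPLING_DAYS
    initial_diameter: float = 1.4  # cm
    kinetics: Mapping[str, GroupKinetics] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_KINETICS)
    )
    gaping_amplitude: float = 25.0  # % of initial area, bump height
    gaping_center: float = 4.0      # day
    gaping_width: float = 1.5       # day (Gaussian sigma)
    noise_cv: float = 0.15          # coefficient of variation of area
    eccentricity_start: float = 0.735   # limiting eccentricity of near-closed wounds
    eccentricity_plateau: float = 0.95  # eccentricity plateau at large wound sizes
    eccentricity_k: float = 0.03        # per mm²: rate of approach to the plateau
    initial_depth: float = 2.0          # mm, scales with relative area
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ConfigurationError(f"n_per_group must be >= 1, got {self.n_per_group}")
        if len(self.sampling_days) < 2 or sorted(set(self.sampling_days)) != sorted(
            self.sampling_days
        ):
            raise ConfigurationError("sampling_days must be >= 2 strictly increasing days")
        if self.sampling_days[0] != 0:
            raise ConfigurationError("sampling_days must start at day 0")
        if self.initial_diameter <= 0:
            raise ConfigurationError(
                f"initial_diameter must be > 0, got {self.initial_diameter}"
            )
        if self.noise_cv < 0:
            raise ConfigurationError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.gaping_width <= 0:
            raise ConfigurationError(f"gaping_width must be > 0, got {self.gaping_width}")
        for name in ("eccentricity_start", "eccentricity_plateau"):
            val = getattr(self, name)
            if not 0 < val <= 1:
                raise ConfigurationError(f"{name} must lie in (0, 1], got {val}")
        if self.eccentricity_k < 0:
            raise ConfigurationError(
                f"eccentricity_k must be >= 0, got {self.eccentricity_k}"
            )
        for label in self.groups:
            if label not in self.kinetics:
                raise ConfigurationError(f"kinetics missing entry for group {label!r}")
            self.kinetics[label].validate(label)

    @property
    def initial_area_mm2(self) -> float:
        import math

        r_mm = self.initial_diameter * 10.0 / 2.0
        return math.pi * r_mm * r_mm


#: steady-state irradiative heating (°C) emulating the per-colour CI midpoints
DEFAULT_TS_TRUE: Mapping[str, float] = {
    "control": 0.0,
    "red": 0.80,
    "green": 1.54,
    "blue": 1.73,
}

#: post−pre core-temperature shift per arm, °C (red warms the core the most)
DEFAULT_CORE_SHIFT: Mapping[str, float] = {
    "control": 0.10,
    "red": 0.50,
    "green": 0.30,
    "blue": 0.15,
}


@dataclass(frozen=True)
class ThermalSessionConfig:
    """Parameters of a synthetic 6-minute therapy-session temperature recording.

    Every arm shares a delayed-onset internal drift (no surface change for the
    first ``control_onset`` seconds, then a linear rise); treated arms add a
    saturating irradiative component ``Ts_true·[1−exp(−k_true·t)]``.
    """

    duration: float = 360.0      # s
    interval: float = 20.0       # s
    ts_true: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TS_TRUE))
    k_true: float = 0.012        # per s
    control_onset: float = 140.0  # s before any internal drift surfaces
    control_slope: float = 0.004  # °C/s after onset
    baseline_temp: float = 33.5   # °C wound-surface baseline
    noise_sd: float = 0.10        # °C additive Gaussian
    core_pre_mean: float = 36.4   # °C
    core_shift: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CORE_SHIFT)
    )
    core_sd: float = 0.15         # °C
    seed: int = 0

    def validate(self) -> None:
        if self.interval <= 0 or self.duration <= 0:
            raise ConfigurationError("duration and interval must be > 0")
        n_steps = self.duration / self.interval
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ConfigurationError(
                f"duration {self.duration} not divisible by interval {self.interval}"
            )
        if not 0 <= self.control_onset <= self.duration:
            raise ConfigurationError(
                f"control_onset must lie in [0, duration], got {self.control_onset}"
            )
        for label, ts in self.ts_true.items():
            if ts < 0:
                raise ConfigurationError(f"ts_true must be >= 0 for {label!r}, got {ts}")
        if self.noise_sd < 0 or self.core_sd < 0:
            raise ConfigurationError("noise levels must be >= 0")

    @property
    def times(self) -> tuple[float, ...]:
        n = int(round(self.duration / self.interval))
        return tuple(i * self.interval for i in range(n + 1))


@dataclass(frozen=True)
class ReflectanceSceneConfig:
    """Geometry and photometry of a synthetic calibration-card wound photograph.

    The scene holds two rectangular card patches of known reflectance and a
    circular wound region, imaged under monochromatic therapy illumination.
    Rectangles are (x0, y0, x1, y1) pixel bounds, exclusive on the right/bottom.
    """

    width: int = 160
    height: int = 120
    card_reflectances: tuple[float, float] = (0.18, 0.90)  # (gray, white)
    gray_patch: tuple[int, int, int, int] = (10, 10, 44, 52)
    white_patch: tuple[int, int, int, int] = (10, 68, 44, 110)
    wound_center: tuple[float, float] = (110.0, 60.0)  # (x, y) px
    wound_radius: float = 25.0  # px
    true_wound_reflectance: Mapping[str, float] = field(
        default_factory=lambda: {"red": 0.55, "green": 0.40, "blue": 0.30}
    )
    background_reflectance: float = 0.06
    gain: float = 1.0           # sensor gain applied to all linear intensities
    stereo_gain_ratio: float = 0.97  # view-2 gain relative to view 1
    crosstalk: float = 0.04     # off-channel sensor response fraction
    noise_sd: float = 0.005     # additive Gaussian on linear intensities
    seed: int = 0

    def validate(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ConfigurationError("image must be at least 8x8 pixels")
        g, w = self.card_reflectances
        if not 0 < g < w <= 1:
            raise ConfigurationError(
                f"card reflectances must satisfy 0 < gray < white <= 1, got {g}, {w}"
            )
        for label, refl in self.true_wound_reflectance.items():
            if not 0 <= refl <= 1:
                raise ConfigurationError(
                    f"true_wound_reflectance[{label!r}] must lie in [0,1], got {refl}"
                )
        if not 0 <= self.background_reflectance <= 1:
            raise ConfigurationError("background_reflectance must lie in [0,1]")
        if self.gain <= 0:
            raise ConfigurationError(f"gain must be > 0, got {self.gain}")
        if not 0 < self.stereo_gain_ratio:
            raise ConfigurationError("stereo_gain_ratio must be > 0")
        if not 0 <= self.crosstalk < 1:
            raise ConfigurationError("crosstalk must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration (synthetic inputs or CSV paths)."""

    output_dir: str = "results"
    synthetic: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    thermal: ThermalSessionConfig = field(default_factory=ThermalSessionConfig)
    scene: ReflectanceSceneConfig = field(default_factory=ReflectanceSceneConfig)
    wounds_path: str | None = None
    temps_path: str | None = None
    control_group: str = "control"
    confidence: float = 0.95
    t_max: float = 28.0  # days, horizon for the delay curve
    irradiance_mw_cm2: float = 40.0
    session_duration_s: float = 360.0
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.synthetic and (self.wounds_path or self.temps_path):
            raise ConfigurationError(
                "exactly one of synthetic inputs or file paths may be active"
            )
        if not self.synthetic and self.wounds_path is None:
            raise ConfigurationError("wounds_path required when synthetic is off")
        if not 0 < self.confidence < 1:
            raise ConfigurationError(f"confidence must lie in (0,1), got {self.confidence}")
        if self.t_max <= 0:
            raise ConfigurationError(f"t_max must be > 0, got {self.t_max}")
        self.cohort.validate()
        self.thermal.validate()
        self.scene.validate()


def _as_dict(obj) -> dict:
    d = dataclasses.asdict(obj)

    def clean(v):
        if isinstance(v, Mapping):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        return v

    return {k: clean(v) for k, v in d.items()}


def config_to_dict(cfg: RunConfig) -> dict:
    """Serializable view of a run configuration (for manifests and YAML)."""
    return _as_dict(cfg)


def _build_cohort(d: Mapping) -> CohortConfig:
    d = dict(d)
    if "kinetics" in d:
        d["kinetics"] = {k: GroupKinetics(**v) for k, v in d["kinetics"].items()}
    for key in ("groups", "sampling_days"):
        if key in d:
            d[key] = tuple(d[key])
    return CohortConfig(**d)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a pipeline configuration from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"config file {path} does not contain a mapping")
    d = dict(data)
    if "cohort" in d:
        d["cohort"] = _build_cohort(d["cohort"])
    if "thermal" in d:
        d["thermal"] = ThermalSessionConfig(**d["thermal"])
    if "scene" in d:
        sc = dict(d["scene"])
        for key in ("card_reflectances", "gray_patch", "white_patch", "wound_center"):
            if key in sc:
                sc[key] = tuple(sc[key])
        d["scene"] = ReflectanceSceneConfig(**sc)
    cfg = RunConfig(**d)
    cfg.validate()
    return cfg
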