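"""Synthetic study-cohort generation.

Generates complete stand-in datasets with the statistical structure the
downstream analyses assume: wound-measurement trajectories for a 4-arm
(control / red / green / blue) excision-wound study, 6-minute therapy-session
temperature recordings, stereoscopic reference-card reflectance scenes, and
simple group-shifted perfusion / erythema tables for exercising the
statistics stage.

Reproducibility contract: identical configuration + seed give byte-identical
outputs. Each animal draws from its own substream derived by stable hashing
of (seed, group, animal index), so adding a group or animals never perturbs
previously generated ones.
"""

from __future__ import annotations

import math
import zlib

import numpy as np
import pandas as pd

from ._plateau import plateau_model
from .config import CohortConfig, ReflectanceSceneConfig, ThermalSessionConfig
from .errors import ConfigurationError, GeometryError
from .reflectance import CHANNEL_INDEX, encode_srgb

__all__ = [
    "generate_cohort",
    "generate_temperature_sessions",
    "generate_reflectance_scene",
    "generate_perfusion",
    "generate_paired_scores",
    "animal_rng",
]


def animal_rng(seed: int, group: str, index: int, stream: str = "") -> np.random.Generator:
    """Deterministic per-animal random substream.

    The spawn key hashes the group label (CRC-32) and animal index so streams
    are stable under reordering or extension of the group list.
    """
    key = [
        int(seed),
        zlib.crc32(group.encode("utf-8")),
        int(index),
        zlib.crc32(stream.encode("utf-8")),
    ]
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(key)))


def _eccentricity_of_size(config: CohortConfig, size_mm2):
    """Wound-size-dependent eccentricity: plateau-exponential in size.

    Large wounds sit near ``eccentricity_plateau``; as the wound closes the
    shape elongates toward ``eccentricity_start`` (the near-closure limit).
    """
    return plateau_model(
        size_mm2,
        config.eccentricity_start,
        config.eccentricity_plateau,
        config.eccentricity_k,
    )


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Wound-measurement table for the configured synthetic cohort.

    One row per animal x sampling day with columns
    ``animal_id, group, day, area_mm2, perimeter_mm, depth_mm``. The mean
    relative-area trajectory is the plateau-exponential closure curve plus a
    Gaussian-in-time gaping bump; measurement noise is multiplicative
    lognormal with the configured coefficient of variation (unit mean).
    Perimeters follow from the area and the size-dependent eccentricity via
    ``P = 2*sqrt(pi*A)/ecc``.
    """
    config.validate()
    a0 = config.initial_area_mm2
    days = np.asarray(config.sampling_days, dtype=float)
    sigma = math.sqrt(math.log1p(config.noise_cv**2))
    rows = []
    for group in config.groups:
        kin = config.kinetics[group]
        for idx in range(config.n_per_group):
            rng = animal_rng(config.seed, group, idx, "wounds")
            rel = plateau_model(days, kin.w0_rel, kin.wp_rel, kin.k)
            # gaping bump, anchored to zero at day 0 so rel(0) stays exactly W0
            bump = np.exp(
                -((days - config.gaping_center) ** 2) / (2.0 * config.gaping_width**2)
            )
            bump0 = math.exp(-(config.gaping_center**2) / (2.0 * config.gaping_width**2))
            rel = rel + config.gaping_amplitude * (bump - bump0)
            if sigma > 0:
                factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(days))
            else:
                factors = np.ones(len(days))
            area = a0 * rel / 100.0 * factors
            ecc = _eccentricity_of_size(config, area)
            perimeter = 2.0 * np.sqrt(np.pi * area) / ecc
            depth = config.initial_depth * rel / 100.0
            animal = f"{group}-{idx + 1:02d}"
            for d, a, p, z in zip(days, area, perimeter, depth):
                rows.append(
                    {
                        "animal_id": animal,
                        "group": group,
                        "day": int(d),
                        "area_mm2": float(a),
                        "perimeter_mm": float(p),
                        "depth_mm": float(max(z, 0.0)),
                    }
                )
    return pd.DataFrame(
        rows, columns=["animal_id", "group", "day", "area_mm2", "perimeter_mm", "depth_mm"]
    )


def generate_temperature_sessions(
    config: ThermalSessionConfig, group: str, n: int, session_day: int = 0
) -> pd.DataFrame:
    """Surface-temperature sessions for ``n`` animals of one arm.

    Readings at 0, interval, ..., duration. Every arm shares the delayed-onset
    internal drift (flat before ``control_onset``, linear after); treated arms
    add the saturating irradiative term ``Ts_true*(1-exp(-k_true*t))``; the
    control arm omits it. Paired pre/post core temperatures ride on the t=0
    row. Columns: ``animal_id, group, session_day, t_s, surface_C,
    core_pre_C, core_post_C``.
    """
    config.validate()
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    if group not in config.ts_true:
        raise ConfigurationError(f"ts_true has no entry for group {group!r}")
    t = np.asarray(config.times, dtype=float)
    drift = np.where(
        t <= config.control_onset, 0.0, (t - config.control_onset) * config.control_slope
    )
    ts_true = config.ts_true[group] if group != "control" else 0.0
    irradiative = ts_true * (1.0 - np.exp(-config.k_true * t))
    rows = []
    for idx in range(n):
        rng = animal_rng(config.seed, group, idx, "thermal")
        noise = rng.normal(0.0, config.noise_sd, size=len(t)) if config.noise_sd > 0 else 0.0
        surface = config.baseline_temp + drift + irradiative + noise
        core_pre = config.core_pre_mean + (
            rng.normal(0.0, config.core_sd) if config.core_sd > 0 else 0.0
        )
        core_post = core_pre + config.core_shift.get(group, 0.0) + (
            rng.normal(0.0, config.core_sd) if config.core_sd > 0 else 0.0
        )
        animal = f"{group}-{idx + 1:02d}"
        for j, (tj, sj) in enumerate(zip(t, np.atleast_1d(surface))):
            rows.append(
                {
                    "animal_id": animal,
                    "group": group,
                    "session_day": session_day,
                    "t_s": float(tj),
                    "surface_C": float(sj),
                    "core_pre_C": float(core_pre) if j == 0 else np.nan,
                    "core_post_C": float(core_post) if j == 0 else np.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "animal_id", "group", "session_day", "t_s", "surface_C",
            "core_pre_C", "core_post_C",
        ],
    )


def _region_masks(config: ReflectanceSceneConfig):
    h, w = config.height, config.width
    yy, xx = np.mgrid[0:h, 0:w]
    masks = {}
    for name, rect in (("card_gray", config.gray_patch), ("card_white", config.white_patch)):
        x0, y0, x1, y1 = rect
        if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
            raise GeometryError(f"{name} patch {rect} not inside the {w}x{h} image")
        m = np.zeros((h, w), dtype=bool)
        m[y0:y1, x0:x1] = True
        masks[name] = m
    cx, cy = config.wound_center
    wound = (xx - cx) ** 2 + (yy - cy) ** 2 <= config.wound_radius**2
    if not wound.any():
        raise GeometryError("wound region lies outside the image")
    if (
        (xx[wound].min() < 0) or (xx[wound].max() >= w)
        or cx - config.wound_radius < 0 or cx + config.wound_radius >= w
        or cy - config.wound_radius < 0 or cy + config.wound_radius >= h
    ):
        raise GeometryError("wound region extends beyond the image bounds")
    masks["wound"] = wound
    for a, b in (("card_gray", "card_white"), ("card_gray", "wound"), ("card_white", "wound")):
        if (masks[a] & masks[b]).any():
            raise GeometryError(f"regions {a} and {b} overlap")
    return masks


def generate_reflectance_scene(
    config: ReflectanceSceneConfig, wavelength_label: str = "red"
):
    """Stereoscopic 8-bit sRGB image pair of a wound plus reference card.

    The scene is rendered under monochromatic illumination of the given
    wavelength: the matching sensor channel carries ``reflectance * gain``
    (plus Gaussian noise on the linear intensity) and the off channels carry
    the configured crosstalk fraction of it; intensities are then sRGB
    gamma-encoded and quantized — the inverse of the measurement pipeline's
    linearization. View 2 differs by the stereo gain ratio. Returns
    ``(image1, image2, masks)`` with masks for ``wound``, ``card_gray`` and
    ``card_white``.
    """
    config.validate()
    if wavelength_label not in CHANNEL_INDEX:
        raise ConfigurationError(
            f"unknown wavelength label {wavelength_label!r}; expected one of "
            f"{sorted(CHANNEL_INDEX)}"
        )
    if wavelength_label not in config.true_wound_reflectance:
        raise ConfigurationError(
            f"true_wound_reflectance has no entry for {wavelength_label!r}"
        )
    masks = _region_masks(config)
    channel = CHANNEL_INDEX[wavelength_label]
    h, w = config.height, config.width
    reflectance = np.full((h, w), config.background_reflectance)
    gray_refl, white_refl = config.card_reflectances
    reflectance[masks["card_gray"]] = gray_refl
    reflectance[masks["card_white"]] = white_refl
    reflectance[masks["wound"]] = config.true_wound_reflectance[wavelength_label]

    rng = animal_rng(config.seed, wavelength_label, 0, "scene")
    images = []
    for view, gain in enumerate((config.gain, config.gain * config.stereo_gain_ratio)):
        intensity = reflectance * gain
        if config.noise_sd > 0:
            intensity = intensity + rng.normal(0.0, config.noise_sd, size=intensity.shape)
        linear = np.empty((h, w, 3))
        for c in range(3):
            linear[..., c] = intensity if c == channel else intensity * config.crosstalk
        images.append(encode_srgb(linear))
    return images[0], images[1], masks


def generate_perfusion(
    seed: int,
    groups=("control", "red", "green", "blue"),
    n_per_group: int = 8,
    means=None,
    sd: float = 100.0,
    day: int = 0,
) -> pd.DataFrame:
    """Group-shifted Gaussian perfusion (LDI) values in arbitrary units."""
    if means is None:
        means = {"control": 350.0, "red": 544.0, "green": 495.0, "blue": 420.0}
    rows = []
    for group in groups:
        for idx in range(n_per_group):
            rng = animal_rng(seed, group, idx, f"ldi-{day}")
            rows.append(
                {
                    "animal_id": f"{group}-{idx + 1:02d}",
                    "group": group,
                    "day": day,
                    "ldi_au": float(rng.normal(means.get(group, 350.0), sd)),
                }
            )
    return pd.DataFrame(rows)


#: post−pre erythema shift per arm: red/green redden most, blue barely changes
DEFAULT_SEV_SHIFT = {"control": 0.15, "red": 0.30, "green": 0.35, "blue": 0.05}


def generate_paired_scores(
    seed: int,
    group: str,
    n: int = 8,
    pre_mean: float = 1.0,
    shift: float | None = None,
    sd: float = 0.15,
) -> pd.DataFrame:
    """Paired pre/post erythema-style scores for one arm (signed-rank fodder)."""
    if shift is None:
        shift = DEFAULT_SEV_SHIFT.get(group, 0.2)
    rows = []
    for idx in range(n):
        rng = animal_rng(seed, group, idx, "sev")
        pre = rng.normal(pre_mean, sd)
        post = pre + shift + rng.normal(0.0, sd)
        rows.append(
            {
                "animal_id": f"{group}-{idx + 1:02d}",
                "group": group,
                "sev_pre": float(pre),
                "sev_post": float(post),
            }
        )
    return pd.DataFrame(rows)
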