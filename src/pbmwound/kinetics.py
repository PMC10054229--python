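"""Wound-closure kinetics.

The relative wound area (% of the day-0 area) is modelled as an exponential
approach to a plateau,

    %W(t) = (W0 - Wp) * exp(-k * t) + Wp,

with initial level ``W0``, plateau ``Wp`` (incomplete closure) and rate
constant ``k`` (per day). Milestones such as the time to 50% of the initial
size are read off the fitted curve in closed form; treatment effects are
summarized as the *delay curve*: for each wound-size level reached by both a
reference (control) and a treated curve within the observation horizon, the
difference in days needed to reach it. The perimeter-normalized healing rate
converts an area change between two visits into the mean daily advancement of
the wound margin (mm/day):

    rate = (A1 - A2) / (0.5 * (P1 + P2)) / (T2 - T1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from ._plateau import PlateauFit, fit_plateau_exponential, plateau_model
from .errors import (
    DataError,
    DomainError,
    InsufficientDataError,
    UnreachableLevelError,
)

__all__ = [
    "PlateauFit",
    "plateau_model",
    "relative_area",
    "fit_plateau",
    "fit_group_plateaus",
    "time_to_level",
    "delay_curve",
    "DelayResult",
    "healing_rate",
    "windowed_healing_rate",
    "healing_rate_table",
]


def relative_area(records: pd.DataFrame) -> pd.DataFrame:
    """Percentage wound area relative to each animal's day-0 measurement.

    Adds a ``relative_area_pct`` column: ``100 * area(day) / area(0)`` per
    animal. Raises :class:`DataError` naming any animal whose day-0 record is
    missing or has zero area.
    """
    out = records.copy()
    rel = np.empty(len(out), dtype=float)
    for animal, idx in out.groupby("animal_id", sort=False).groups.items():
        sub = out.loc[idx]
        day0 = sub.loc[sub["day"] == 0, "area_mm2"]
        if day0.empty:
            raise DataError(f"animal {animal!r} has no day-0 record")
        a0 = float(day0.iloc[0])
        if a0 <= 0:
            raise DataError(f"animal {animal!r} has non-positive day-0 area {a0}")
        rel[out.index.get_indexer(idx)] = 100.0 * sub["area_mm2"].to_numpy() / a0
    out["relative_area_pct"] = rel
    return out


def fit_plateau(days, values) -> PlateauFit:
    """Least-squares plateau-exponential fit of %area over days.

    Needs >= 4 points spanning >= 3 distinct days. The returned fit carries
    the (W0, Wp, k) estimates, their Jacobian-based covariance, and a
    ``degenerate`` flag when the rate constant pinned at its lower bound
    (flat trajectories).
    """
    return fit_plateau_exponential(days, values, min_points=4, min_distinct=3)


def fit_group_plateaus(
    records: pd.DataFrame, per_animal: bool = False
) -> dict[str, PlateauFit]:
    """One pooled plateau fit per group over all animals' points.

    The fit is to the individual measurements pooled within a group (not to
    per-day group means). With ``per_animal=True`` a fit is returned per
    ``(group, animal_id)`` pair instead.
    """
    if "relative_area_pct" not in records.columns:
        records = relative_area(records)
    fits: dict = {}
    keys = ["group", "animal_id"] if per_animal else ["group"]
    for key, sub in records.groupby(keys, sort=False):
        fits[key if per_animal else key[0]] = fit_plateau(
            sub["day"].to_numpy(float), sub["relative_area_pct"].to_numpy(float)
        )
    return fits


def time_to_level(fit: PlateauFit, level: float) -> float:
    """Days until the fitted curve reaches ``level`` % of the initial area.

    Closed-form inversion ``t = -ln((level - Wp) / (W0 - Wp)) / k``; levels at
    or below the plateau are unreachable, levels above W0 are out of range.
    """
    w0, wp, k = fit.w0, fit.wp, fit.k
    if level <= wp:
        raise UnreachableLevelError(
            f"level {level}% is at or below the plateau Wp={wp:.4g}%"
        )
    if level > w0:
        raise DomainError(f"level {level}% exceeds the initial level W0={w0:.4g}%")
    return -math.log((level - wp) / (w0 - wp)) / k


@dataclass(frozen=True)
class DelayResult:
    """Maximum healing delay between a reference and a treated closure curve.

    ``delay_star`` (days) is the maximum of ``t_ref(level) - t_trt(level)``
    over the admissible level grid; ``level_star`` is the %-of-initial wound
    size where it occurs; ``day_ref``/``day_trt`` are the days at which each
    curve attains that level (the two clocks differ by ``delay_star``).
    ``boundary`` marks maxima attained at an admissible-range endpoint, which
    arise whenever the delay is monotone over the observation horizon.
    """

    level_star: float
    delay_star: float
    day_ref: float
    day_trt: float
    boundary: bool
    curve: pd.DataFrame = field(repr=False)


def delay_curve(
    ref: PlateauFit, trt: PlateauFit, t_max: float = 28.0, n_grid: int = 2000
) -> DelayResult:
    """Healing-delay curve of a treated arm relative to a reference arm.

    Admissible levels are those reached by *both* fitted curves within
    ``[0, t_max]``; for each, ``delay = time_to_level(ref) - time_to_level(trt)``
    (positive when the treatment is ahead). The maximizer over a dense grid of
    ``n_grid`` levels is refined by bounded scalar optimization; a negative
    maximum (treatment slower everywhere) is reported as-is, never clipped.
    """
    if t_max <= 0:
        raise DomainError(f"t_max must be > 0, got {t_max}")
    hi = min(ref.w0, trt.w0)
    lo = max(
        float(ref.predict(t_max)),
        float(trt.predict(t_max)),
    )
    # keep strictly above both plateaus / below both initial levels
    eps = 1e-9 * max(1.0, abs(hi))
    lo, hi = lo + eps, hi - eps
    if not lo < hi:
        raise DomainError(
            "no admissible level range: the curves share no levels within the horizon"
        )

    levels = np.linspace(hi, lo, n_grid)

    def delay_of(level: float) -> float:
        return time_to_level(ref, level) - time_to_level(trt, level)

    delays = np.array([delay_of(lv) for lv in levels])
    i = int(np.argmax(delays))
    boundary = i in (0, n_grid - 1)
    if boundary:
        level_star, delay_star = float(levels[i]), float(delays[i])
    else:
        res = optimize.minimize_scalar(
            lambda lv: -delay_of(lv),
            bounds=(min(levels[i + 1], levels[i - 1]), max(levels[i + 1], levels[i - 1])),
            method="bounded",
            options={"xatol": 1e-10},
        )
        level_star, delay_star = float(res.x), float(-res.fun)
    curve = pd.DataFrame({"level_pct": levels, "delay_days": delays})
    return DelayResult(
        level_star=level_star,
        delay_star=delay_star,
        day_ref=time_to_level(ref, level_star),
        day_trt=time_to_level(trt, level_star),
        boundary=boundary,
        curve=curve,
    )


def healing_rate(
    a1: float, p1: float, a2: float, p2: float, dt: float
) -> float:
    """Perimeter-normalized healing rate (mm/day) between two visits.

    ``(A1 - A2) / (0.5 * (P1 + P2)) / dt`` — the mean daily advancement of the
    wound margin; negative when the wound gapes. Antisymmetric under swapping
    the endpoints.
    """
    if dt <= 0:
        raise DomainError(f"dt must be > 0, got {dt}")
    if p1 <= 0 or p2 <= 0:
        raise DomainError(f"perimeters must be > 0, got {p1}, {p2}")
    return (a1 - a2) / (0.5 * (p1 + p2)) / dt


def windowed_healing_rate(trajectory: pd.DataFrame, center: float) -> float:
    """Healing rate at an interior visit, averaged over its flanking visits.

    Endpoints are the nearest sampled days strictly before and after
    ``center`` (with 4-day sampling this spans ``center - 4`` to
    ``center + 4``). Boundary days raise :class:`DomainError`.
    ``trajectory`` holds one animal's records with columns
    ``day, area_mm2, perimeter_mm``.
    """
    days = trajectory["day"].to_numpy(dtype=float)
    before = days[days < center]
    after = days[days > center]
    if center not in days:
        raise DomainError(f"day {center} is not a sampled day")
    if before.size == 0 or after.size == 0:
        raise DomainError(f"day {center} is not interior to the sampling schedule")
    d1, d2 = float(before.max()), float(after.min())
    row1 = trajectory.loc[trajectory["day"] == d1].iloc[0]
    row2 = trajectory.loc[trajectory["day"] == d2].iloc[0]
    return healing_rate(
        float(row1["area_mm2"]), float(row1["perimeter_mm"]),
        float(row2["area_mm2"]), float(row2["perimeter_mm"]),
        d2 - d1,
    )


def healing_rate_table(records: pd.DataFrame) -> pd.DataFrame:
    """Windowed healing rate at every interior day for every animal."""
    rows = []
    for (animal, group), sub in records.groupby(["animal_id", "group"], sort=False):
        sub = sub.sort_values("day")
        days = sub["day"].to_numpy(dtype=float)
        for day in days[1:-1]:
            rows.append(
                {
                    "animal_id": animal,
                    "group": group,
                    "day": day,
                    "rate_mm_per_day": windowed_healing_rate(sub, day),
                }
            )
    return pd.DataFrame(rows, columns=["animal_id", "group", "day", "rate_mm_per_day"])
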