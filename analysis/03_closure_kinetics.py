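#!/usr/bin/env python
"""Closure kinetics: plateau-exponential fits, milestones and healing delay.

Fits %W(t) = (W0-Wp)*exp(-k*t) + Wp per arm (pooled over animals), reads off
the time to 50% of the initial wound size, and computes each treated arm's
healing-delay curve against the control: the extra days the control needs to
reach the same wound-size level, maximized over the levels both curves reach
within the 28-day observation period. Writes fits.csv, milestones.csv,
delay.csv and a trajectory figure.
"""

import argparse
import pathlib

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from pbmwound import io, kinetics
from pbmwound.errors import PbmWoundError

COLORS = {"control": "0.3", "red": "tab:red", "green": "tab:green", "blue": "tab:blue"}


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=pathlib.Path, default=pathlib.Path("results"))
    ap.add_argument("--t-max", type=float, default=28.0)
    args = ap.parse_args()
    wounds = io.read_wounds(args.outdir / "data" / "wounds.csv")
    rel = kinetics.relative_area(wounds)
    fits = kinetics.fit_group_plateaus(rel)

    rows, milestones = [], []
    for arm, fit in fits.items():
        se = fit.standard_errors
        rows.append(
            {"group": arm, "W0": fit.w0, "Wp": fit.wp, "k": fit.k,
             "se_W0": se[0], "se_Wp": se[1], "se_k": se[2],
             "rss": fit.residual_ss, "n": fit.n}
        )
        try:
            t50 = kinetics.time_to_level(fit, 50.0)
        except PbmWoundError:
            t50 = np.nan
        milestones.append({"group": arm, "t50_days": t50})
        print(
            f"{arm:8s} W0={fit.w0:6.1f}%  Wp={fit.wp:5.1f}%  k={fit.k:.3f}/d  "
            f"t50={t50:5.1f} d"
        )
    pd.DataFrame(rows).to_csv(args.outdir / "fits.csv", index=False)
    pd.DataFrame(milestones).to_csv(args.outdir / "milestones.csv", index=False)

    curves = []
    for arm, fit in fits.items():
        if arm == "control":
            continue
        res = kinetics.delay_curve(fits["control"], fit, t_max=args.t_max)
        print(
            f"{arm:8s} max healing delay {res.delay_star:4.1f} d at "
            f"{res.level_star:.1f}% of initial size "
            f"(control day {res.day_ref:.1f}, treated day {res.day_trt:.1f}"
            f"{', at horizon boundary' if res.boundary else ''})"
        )
        curve = res.curve.copy()
        curve.insert(0, "group", arm)
        curves.append(curve)
    pd.concat(curves).to_csv(args.outdir / "delay.csv", index=False)

    grid = np.linspace(0.0, args.t_max, 200)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for arm, fit in fits.items():
        sub = rel[rel["group"] == arm].groupby("day")["relative_area_pct"]
        ax.errorbar(
            sub.mean().index, sub.mean(), yerr=sub.sem(), fmt="o", ms=3,
            color=COLORS.get(arm, "k"), label=arm,
        )
        ax.plot(grid, fit.predict(grid), "-", color=COLORS.get(arm, "k"), lw=1)
    ax.axhline(50.0, ls=":", c="k", lw=0.8)
    ax.set_xlabel("day")
    ax.set_ylabel("wound area (% of day 0)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(args.outdir / "closure_fits.png", dpi=120)
    print(f"figure: {args.outdir / 'closure_fits.png'}")


if __name__ == "__main__":
    main()
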