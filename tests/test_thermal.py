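"""Control-corrected heating kinetics, onset detection and dosimetry."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from pbmwound import synthetic, thermal as th
from pbmwound.config import ThermalSessionConfig
from pbmwound.errors import DataError, DomainError, InsufficientDataError


def session_frame(series_by_animal, interval=20.0):
    rows = []
    for animal, values in series_by_animal.items():
        for i, v in enumerate(values):
            rows.append(
                {"animal_id": animal, "group": "g", "session_day": 0,
                 "t_s": i * interval, "surface_C": v}
            )
    return pd.DataFrame(rows)


# --- control correction ----------------------------------------------------

def test_self_correction_is_identically_zero(noiseless_thermal_config):
    ctl = synthetic.generate_temperature_sessions(noiseless_thermal_config, "control", 4)
    corrected = th.control_correct(ctl, ctl)
    assert np.allclose(corrected["delta_T_C"], 0.0, atol=1e-12)


def test_self_correction_nullity_with_noise():
    cfg = ThermalSessionConfig(noise_sd=0.3, seed=5)
    grp = synthetic.generate_temperature_sessions(cfg, "green", 6)
    corrected = th.control_correct(grp, grp)
    # per-time mean of the corrected series vanishes by construction
    assert np.allclose(corrected.groupby("t_s")["delta_T_C"].mean(), 0.0, atol=1e-12)


def test_offset_passes_through_flat_control():
    ctl = session_frame({"c1": [33.0] * 5, "c2": [33.5] * 5})
    trt = session_frame({"t1": [34.0, 34.5, 34.5, 34.5, 34.5]})
    corrected = th.control_correct(trt, ctl)
    expected = [0.0, 0.5, 0.5, 0.5, 0.5]
    assert corrected.sort_values("t_s")["delta_T_C"].tolist() == pytest.approx(expected)


def test_correction_requires_overlapping_grid_and_control():
    trt = session_frame({"t1": [34.0, 34.2]})
    ctl = session_frame({"c1": [33.0, 33.1]}, interval=7.0)
    with pytest.raises(DataError):
        th.control_correct(trt, ctl)
    with pytest.raises(DataError):
        th.control_correct(trt, ctl.iloc[0:0])


# --- heating fit -----------------------------------------------------------

def test_fit_recovers_noiseless_truth_with_vanishing_ci(noiseless_thermal_config):
    trt = synthetic.generate_temperature_sessions(noiseless_thermal_config, "green", 4)
    ctl = synthetic.generate_temperature_sessions(noiseless_thermal_config, "control", 4)
    fit = th.fit_heating(th.control_correct(trt, ctl))
    true_ts = noiseless_thermal_config.ts_true["green"]
    assert abs(fit.ts - true_ts) < 1e-6
    assert fit.k == pytest.approx(noiseless_thermal_config.k_true, rel=1e-5)
    assert fit.ci_high - fit.ci_low < 1e-6
    assert fit.ci_low <= fit.ts <= fit.ci_high


def test_fit_zero_series_gives_zero_with_ci_containing_zero():
    t = np.arange(0.0, 361.0, 20.0)
    corrected = pd.DataFrame({"t_s": t, "delta_T_C": np.zeros_like(t)})
    fit = th.fit_heating(corrected)
    assert fit.ts == pytest.approx(0.0, abs=1e-9)
    assert fit.ci_low <= 0.0 <= fit.ci_high


def test_fit_prediction_passes_through_origin():
    t = np.arange(0.0, 361.0, 20.0)
    corrected = pd.DataFrame({"t_s": t, "delta_T_C": th.heating_model(t, 1.5, 0.02)})
    fit = th.fit_heating(corrected)
    assert fit.predict(0.0) == 0.0
    assert fit.ts == pytest.approx(1.5, abs=1e-6)


def test_fit_needs_four_time_points():
    corrected = pd.DataFrame({"t_s": [0.0, 20.0, 40.0], "delta_T_C": [0.0, 0.1, 0.2]})
    with pytest.raises(InsufficientDataError):
        th.fit_heating(corrected)


def test_ci_coverage_over_replicates():
    """Wald CI on Ts covers the truth at close to nominal rate.

    50 replicates here (the 500-replicate calibration runs in the acceptance
    suite): coverage must land in the 90-99% window at 95% nominal.
    """
    covered = 0
    n_rep = 50
    for rep in range(n_rep):
        cfg = ThermalSessionConfig(noise_sd=0.1, seed=3000 + rep)
        trt = synthetic.generate_temperature_sessions(cfg, "green", 1)
        drift = np.where(
            trt["t_s"] <= cfg.control_onset, 0.0,
            (trt["t_s"] - cfg.control_onset) * cfg.control_slope,
        )
        corrected = pd.DataFrame(
            {"t_s": trt["t_s"],
             "delta_T_C": trt["surface_C"] - cfg.baseline_temp - drift}
        )
        fit = th.fit_heating(corrected)
        covered += fit.ci_low <= cfg.ts_true["green"] <= fit.ci_high
    assert 0.85 <= covered / n_rep <= 1.0


# --- onset detection -------------------------------------------------------

def test_onset_matches_generator_configuration(noiseless_thermal_config):
    ctl = synthetic.generate_temperature_sessions(noiseless_thermal_config, "control", 3)
    assert th.detect_onset(ctl, tolerance=0.05) == 140.0


def test_onset_flat_series_returns_sentinel():
    ctl = session_frame({"c1": [33.0] * 10, "c2": [33.0] * 10})
    assert math.isinf(th.detect_onset(ctl, tolerance=0.05))


def test_onset_zero_tolerance_on_noisy_data_degenerates():
    cfg = ThermalSessionConfig(noise_sd=0.2, seed=9)
    ctl = synthetic.generate_temperature_sessions(cfg, "control", 3)
    assert th.detect_onset(ctl, tolerance=0.0) == 0.0


def test_onset_needs_two_animals():
    ctl = session_frame({"c1": [33.0] * 5})
    with pytest.raises(InsufficientDataError):
        th.detect_onset(ctl)


# --- dosimetry -------------------------------------------------------------

def test_radiant_exposure_reference_dose():
    assert th.radiant_exposure(40.0, 360.0) == pytest.approx(14.4)
    assert th.radiant_exposure(40.0, 0.0) == 0.0
    assert th.radiant_exposure(40.0, 360.0, duty_factor=0.5) == pytest.approx(7.2)


def test_radiant_exposure_domain_errors():
    with pytest.raises(DomainError):
        th.radiant_exposure(-1.0, 10.0)
    with pytest.raises(DomainError):
        th.radiant_exposure(1.0, -10.0)
    with pytest.raises(DomainError):
        th.radiant_exposure(1.0, 10.0, duty_factor=0.0)


@given(
    irr=st_.floats(min_value=0.0, max_value=200.0),
    dur=st_.floats(min_value=0.0, max_value=3600.0),
    scale=st_.floats(min_value=0.1, max_value=10.0),
)
@settings(max_examples=200, deadline=None)
def test_radiant_exposure_linear_in_each_argument(irr, dur, scale):
    base = th.radiant_exposure(irr, dur)
    assert th.radiant_exposure(scale * irr, dur) == pytest.approx(scale * base, rel=1e-12)
    assert th.radiant_exposure(irr, scale * dur) == pytest.approx(scale * base, rel=1e-12)


# --- core temperature ------------------------------------------------------

def test_core_change_zero_and_constant_shift():
    df = pd.DataFrame(
        {
            "animal_id": ["a1", "a2", "b1", "b2"],
            "group": ["a", "a", "b", "b"],
            "core_pre_C": [36.0, 36.5, 36.2, 36.4],
            "core_post_C": [36.0, 36.5, 36.5, 36.7],
        }
    )
    out = th.core_temperature_change(df).set_index("group")
    assert out.loc["a", "mean_delta_C"] == pytest.approx(0.0)
    assert out.loc["b", "mean_delta_C"] == pytest.approx(0.3)
    assert out.loc["b", "sd_delta_C"] == pytest.approx(0.0, abs=1e-12)


def test_core_change_skips_missing_with_warning(caplog):
    df = pd.DataFrame(
        {
            "animal_id": ["a1", "a2", "a3"],
            "group": ["a"] * 3,
            "core_pre_C": [36.0, 36.5, 36.2],
            "core_post_C": [36.3, np.nan, 36.5],
        }
    )
    with caplog.at_level("WARNING"):
        out = th.core_temperature_change(df)
    assert out.loc[0, "n"] == 2
    assert "skipping" in caplog.text
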