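"""Color-space linearization, reference-card calibration and the calibrated
wound reflection fraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from pbmwound import reflectance as r, synthetic
from pbmwound.config import ReflectanceSceneConfig
from pbmwound.errors import (
    CalibrationError,
    ConfigurationError,
    DataError,
    DomainError,
    SaturationError,
)


def rgb_to_xyz_from_chromaticities(primaries, white):
    """Independent construction of an RGB->XYZ matrix from (x, y) primaries."""
    cols = []
    for x, y in primaries:
        cols.append(np.array([x / y, 1.0, (1.0 - x - y) / y]))
    P = np.column_stack(cols)
    xw, yw = white
    white_xyz = np.array([xw / yw, 1.0, (1.0 - xw - yw) / yw])
    scale = np.linalg.solve(P, white_xyz)
    return P * scale


SRGB_PRIMARIES = [(0.64, 0.33), (0.30, 0.60), (0.15, 0.06)]
ADOBE_PRIMARIES = [(0.64, 0.33), (0.21, 0.71), (0.15, 0.06)]
D65 = (0.3127, 0.3290)


# --- sRGB decode -----------------------------------------------------------

@pytest.mark.parametrize(
    "encoded,expected",
    [(0, 0.0), (255, 1.0), (128, 0.21586)],
)
def test_decode_srgb_values(encoded, expected):
    assert r.decode_srgb(encoded) == pytest.approx(expected, abs=1e-5)


def test_decode_srgb_monotone_and_bounded():
    values = r.decode_srgb(np.arange(256))
    assert np.all(np.diff(values) > 0)
    assert values[0] == 0.0 and values[-1] == 1.0


def test_decode_srgb_rejects_out_of_range():
    with pytest.raises(DataError):
        r.decode_srgb([-1])
    with pytest.raises(DataError):
        r.decode_srgb([256])


def test_encode_decode_round_trip_within_quantization():
    linear = np.linspace(0.0, 1.0, 1001)
    back = r.decode_srgb(r.encode_srgb(linear).astype(float))
    # half-step quantization error amplified by the EOTF slope (max 2.4/1.055)
    assert np.max(np.abs(back - linear)) <= 0.5 / 255.0 * 2.4 / 1.055 + 1e-12


# --- primaries conversion --------------------------------------------------

def test_adobe_conversion_matches_chromaticity_oracle():
    srgb2xyz = rgb_to_xyz_from_chromaticities(SRGB_PRIMARIES, D65)
    adobe2xyz = rgb_to_xyz_from_chromaticities(ADOBE_PRIMARIES, D65)
    oracle = np.linalg.inv(adobe2xyz) @ srgb2xyz
    for triplet in ([1.0, 0.0, 0.0], [0.2, 0.5, 0.7], [1.0, 1.0, 1.0]):
        expected = oracle @ np.asarray(triplet)
        got = r.convert_to_linear_adobe(triplet)
        assert got == pytest.approx(expected, abs=2e-4)


def test_adobe_conversion_preserves_white_and_black():
    assert r.convert_to_linear_adobe([1.0, 1.0, 1.0]) == pytest.approx(
        [1.0, 1.0, 1.0], abs=1e-4
    )
    assert r.convert_to_linear_adobe([0.0, 0.0, 0.0]) == pytest.approx(
        [0.0, 0.0, 0.0], abs=1e-12
    )


def test_pure_srgb_red_maps_to_adobe_red_axis():
    linear = r.convert_to_linear_adobe([1.0, 0.0, 0.0])
    assert linear[0] == pytest.approx(0.7152, abs=2e-4)
    assert abs(linear[1]) < 1e-3 and abs(linear[2]) < 1e-3
    # the gamma-encoded Adobe value of that channel
    assert r.adobe_gamma_encode(linear[0]) == pytest.approx(0.8588, abs=5e-4)


def test_adobe_conversion_rejects_non_finite():
    with pytest.raises(DomainError):
        r.convert_to_linear_adobe([np.nan, 0.0, 0.0])


# --- two-point calibration -------------------------------------------------

def test_calibration_proportional_sensor_is_identity_up_to_gain():
    card = r.ReferenceCard(0.18, 0.90)
    for gain in (0.2, 1.0, 3.7):
        cal = r.two_point_calibrate(0.18 * gain, 0.90 * gain, card)
        assert cal(0.18 * gain) == pytest.approx(0.18, abs=1e-12)
        assert cal(0.54 * gain) == pytest.approx(0.54, abs=1e-12)


def test_calibration_hand_solved_affine_map():
    card = r.ReferenceCard(0.18, 0.90)
    cal = r.two_point_calibrate(0.2, 0.8, card)
    assert cal(0.5) == pytest.approx(0.18 + (0.5 - 0.2) * (0.72 / 0.6), abs=1e-12)
    assert cal(0.2) == pytest.approx(0.18)
    assert cal(0.8) == pytest.approx(0.90)


def test_calibration_rejects_equal_or_inverted_patches():
    card = r.ReferenceCard(0.18, 0.90)
    with pytest.raises(CalibrationError):
        r.two_point_calibrate(0.5, 0.5, card)
    with pytest.raises(CalibrationError):
        r.two_point_calibrate(0.8, 0.2, card)


def test_reference_card_ordering_enforced():
    with pytest.raises(DomainError):
        r.ReferenceCard(0.9, 0.18)


# --- wound fraction on synthetic scenes ------------------------------------

def measure_scene(config, label):
    img1, img2, masks = synthetic.generate_reflectance_scene(config, label)
    card = r.ReferenceCard(*config.card_reflectances)
    return r.wound_reflection_fraction(
        (img1, img2), masks["wound"], masks["card_gray"], masks["card_white"],
        card, label,
    )


@pytest.mark.parametrize("label", ["red", "green", "blue"])
def test_round_trip_recovers_configured_reflectance(label, noiseless_scene_config):
    res = measure_scene(noiseless_scene_config, label)
    assert res.fraction_view1 == pytest.approx(0.54, abs=1.0 / 255.0)
    assert res.fraction_view2 == pytest.approx(0.54, abs=1.0 / 255.0)
    assert res.stereo_mean == pytest.approx(
        0.5 * (res.fraction_view1 + res.fraction_view2)
    )


def test_wound_equal_to_white_patch_reads_white(noiseless_scene_config):
    import dataclasses

    cfg = dataclasses.replace(
        noiseless_scene_config, true_wound_reflectance={"red": 0.90}
    )
    res = measure_scene(cfg, "red")
    assert res.stereo_mean == pytest.approx(0.90, abs=1.0 / 255.0)


def test_calibration_exactness_on_card_patches(noiseless_scene_config):
    """After calibration the card patches map to exactly 0.18 and 0.90."""
    img1, _, masks = synthetic.generate_reflectance_scene(noiseless_scene_config, "red")
    linear = r.convert_to_linear_adobe(r.decode_srgb(img1.astype(float)))[..., 0]
    gray = float(linear[masks["card_gray"]].mean())
    white = float(linear[masks["card_white"]].mean())
    cal = r.two_point_calibrate(gray, white, r.ReferenceCard(0.18, 0.90))
    assert cal(gray) == pytest.approx(0.18, abs=1e-12)
    assert cal(white) == pytest.approx(0.90, abs=1e-12)


def test_saturated_wound_raises():
    cfg = ReflectanceSceneConfig(
        noise_sd=0.0, true_wound_reflectance={"red": 1.0}, gain=3.0
    )
    with pytest.raises(SaturationError):
        measure_scene(cfg, "red")


def test_gain_invariance_of_calibrated_fraction():
    """Two-point calibration absorbs sensor gain across the usable range."""
    import dataclasses

    # base gain 0.55 keeps the white patch unclipped across the whole factor range
    base = ReflectanceSceneConfig(
        true_wound_reflectance={"red": 0.54}, gain=0.55, seed=11
    )
    reference = measure_scene(base, "red").stereo_mean
    for factor in (0.5, 0.75, 1.25, 1.5):
        res = measure_scene(
            dataclasses.replace(base, gain=base.gain * factor), "red"
        )
        assert abs(res.stereo_mean - reference) < 1.0 / 255.0


def test_wound_fraction_monotone_in_wound_intensity():
    import dataclasses

    base = ReflectanceSceneConfig(noise_sd=0.0)
    fractions = [
        measure_scene(
            dataclasses.replace(base, true_wound_reflectance={"red": refl}), "red"
        ).stereo_mean
        for refl in (0.2, 0.4, 0.6, 0.8)
    ]
    assert np.all(np.diff(fractions) > 0)


def test_unknown_wavelength_and_bad_pair_rejected(noiseless_scene_config):
    img1, img2, masks = synthetic.generate_reflectance_scene(noiseless_scene_config, "red")
    card = r.ReferenceCard(0.18, 0.90)
    with pytest.raises(DomainError):
        r.wound_reflection_fraction(
            (img1, img2), masks["wound"], masks["card_gray"], masks["card_white"],
            card, "ultraviolet",
        )
    with pytest.raises(DomainError):
        r.wound_reflection_fraction(
            (img1,), masks["wound"], masks["card_gray"], masks["card_white"],
            card, "red",
        )
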