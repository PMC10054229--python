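"""Calibrated fractional wound reflectance from reference-card photographs.

Wound photographs taken under monochromatic therapy illumination include a
gray/white reference card with patches of known reflectance (18% and 90%).
The pipeline per stereoscopic view is:

1. decode the 8-bit sRGB image to linear intensities (piecewise sRGB EOTF),
2. convert linear sRGB to linear Adobe RGB (1998) — a pure primaries
   conversion, since both spaces share the D65 white point and the Adobe
   gamma cancels once the image is re-linearized,
3. select the channel matching the therapy wavelength (off-channel signal is
   sensor crosstalk),
4. average over the wound and card-patch masks, and
5. map the wound mean through the two-point affine calibration defined by the
   card patches, which absorbs sensor gain and offset.

The reported wound reflection fraction is the mean of the two per-view
calibrated fractions (each view sees its own card).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, DataError, DomainError, GeometryError, SaturationError

__all__ = [
    "decode_srgb",
    "encode_srgb",
    "convert_to_linear_adobe",
    "adobe_gamma_encode",
    "ReferenceCard",
    "ReflectanceResult",
    "two_point_calibrate",
    "wound_reflection_fraction",
    "SRGB_TO_XYZ",
    "XYZ_TO_ADOBE",
    "ADOBE_GAMMA",
]

#: linear sRGB -> CIE XYZ (D65), IEC 61966-2-1 primaries
SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

#: CIE XYZ (D65) -> linear Adobe RGB (1998)
XYZ_TO_ADOBE = np.array(
    [
        [2.0413690, -0.5649464, -0.3446944],
        [-0.9692660, 1.8760108, 0.0415560],
        [0.0134474, -0.1183897, 1.0154096],
    ]
)

_SRGB_TO_ADOBE = XYZ_TO_ADOBE @ SRGB_TO_XYZ
_ADOBE_TO_SRGB = np.linalg.inv(_SRGB_TO_ADOBE)

#: Adobe RGB (1998) encoding gamma, 563/256
ADOBE_GAMMA = 2.19921875

CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


def decode_srgb(encoded) -> np.ndarray:
    """Linearize 8-bit sRGB channel values to [0, 1].

    Applies the piecewise sRGB EOTF: ``v/12.92`` below the toe, else
    ``((v + 0.055)/1.055)**2.4`` with ``v = value/255``. Monotone; 0 maps to
    0.0 and 255 to 1.0. Values outside [0, 255] raise :class:`DataError`.
    """
    arr = np.asarray(encoded, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 255):
        raise DataError(
            f"encoded values must lie in [0, 255], got range [{arr.min()}, {arr.max()}]"
        )
    v = arr / 255.0
    out = np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)
    return out if out.shape else float(out)


def encode_srgb(linear) -> np.ndarray:
    """Inverse of :func:`decode_srgb`: linear [0,1] to quantized 8-bit values."""
    v = np.clip(np.asarray(linear, dtype=float), 0.0, 1.0)
    enc = np.where(v <= 0.0031308, v * 12.92, 1.055 * v ** (1.0 / 2.4) - 0.055)
    out = np.rint(enc * 255.0).astype(np.uint8)
    return out


def convert_to_linear_adobe(linear_srgb) -> np.ndarray:
    """Linear sRGB triplet(s) -> linear Adobe RGB (1998) triplet(s).

    A single matrix product through CIE XYZ (both spaces are D65, so no
    chromatic adaptation is needed); white (1,1,1) maps to (1,1,1) to within
    1e-4. Accepts a 3-vector or an (..., 3) array. Since the measurement
    pipeline re-linearizes after the conversion, the Adobe encoding gamma
    never enters — only the primaries change.
    """
    arr = np.asarray(linear_srgb, dtype=float)
    if arr.shape[-1] != 3:
        raise DomainError(f"expected trailing dimension 3, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise DomainError("non-finite input")
    return arr @ _SRGB_TO_ADOBE.T


def adobe_gamma_encode(linear) -> np.ndarray:
    """Adobe RGB (1998) gamma encoding ``v**(1/2.19921875)`` of linear values."""
    v = np.clip(np.asarray(linear, dtype=float), 0.0, None)
    return v ** (1.0 / ADOBE_GAMMA)


def adobe_to_linear_srgb(linear_adobe) -> np.ndarray:
    """Inverse primaries conversion, linear Adobe RGB -> linear sRGB."""
    arr = np.asarray(linear_adobe, dtype=float)
    return arr @ _ADOBE_TO_SRGB.T


@dataclass(frozen=True)
class ReferenceCard:
    """Reference card with two patches of known calibrated reflectance."""

    reflectance_gray: float = 0.18
    reflectance_white: float = 0.90

    def __post_init__(self):
        if not 0 < self.reflectance_gray < self.reflectance_white <= 1:
            raise DomainError(
                "card needs 0 < gray < white <= 1, got "
                f"{self.reflectance_gray}, {self.reflectance_white}"
            )


@dataclass(frozen=True)
class TwoPointCalibration:
    """Affine intensity->reflectance map anchored at the two card patches."""

    slope: float
    intercept: float

    def __call__(self, intensity):
        return self.slope * np.asarray(intensity, dtype=float) + self.intercept


def two_point_calibrate(
    mean_gray: float, mean_white: float, card: ReferenceCard
) -> TwoPointCalibration:
    """Affine map sending the measured patch means to the card reflectances.

    ``mean_gray`` maps exactly to the gray-patch reflectance and
    ``mean_white`` to the white-patch reflectance; sensor gain and offset are
    absorbed. Equal or inverted patch intensities are a calibration error.
    """
    if not mean_white > mean_gray > 0:
        raise CalibrationError(
            f"need mean_white > mean_gray > 0, got gray={mean_gray}, white={mean_white}"
        )
    slope = (card.reflectance_white - card.reflectance_gray) / (mean_white - mean_gray)
    intercept = card.reflectance_gray - slope * mean_gray
    return TwoPointCalibration(slope=slope, intercept=intercept)


@dataclass(frozen=True)
class ReflectanceResult:
    """Calibrated wound reflection fraction of a stereoscopic image pair."""

    wavelength_label: str
    fraction_view1: float
    fraction_view2: float

    @property
    def stereo_mean(self) -> float:
        return 0.5 * (self.fraction_view1 + self.fraction_view2)


def _region_mean_linear_adobe(
    image: np.ndarray, mask: np.ndarray, channel: int, max_saturated_fraction: float
) -> float:
    if mask.shape != image.shape[:2]:
        raise GeometryError(
            f"mask shape {mask.shape} does not match image shape {image.shape[:2]}"
        )
    mask = mask.astype(bool)
    if not mask.any():
        raise GeometryError("empty region mask")
    pixels = image[mask]  # (n, 3) uint8
    saturated = np.mean(pixels[:, channel] >= 254)
    if saturated > max_saturated_fraction:
        raise SaturationError(
            f"{saturated:.1%} of region pixels saturated in channel {channel}"
        )
    linear = decode_srgb(pixels.astype(float))
    adobe = convert_to_linear_adobe(linear)
    return float(adobe[:, channel].mean())


def _measure_view(
    image, wound_mask, gray_mask, white_mask, card, channel, max_saturated_fraction
) -> float:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise GeometryError(f"expected an (H, W, 3) image, got shape {image.shape}")
    gray = _region_mean_linear_adobe(image, gray_mask, channel, max_saturated_fraction)
    white = _region_mean_linear_adobe(image, white_mask, channel, max_saturated_fraction)
    wound = _region_mean_linear_adobe(image, wound_mask, channel, max_saturated_fraction)
    cal = two_point_calibrate(gray, white, card)
    return float(cal(wound))


def wound_reflection_fraction(
    images: tuple,
    wound_mask,
    gray_mask,
    white_mask,
    card: ReferenceCard,
    wavelength_label: str,
    max_saturated_fraction: float = 0.01,
) -> ReflectanceResult:
    """Calibrated wound reflection fraction from a stereoscopic image pair.

    ``images`` is a pair of 8-bit (H, W, 3) sRGB arrays sharing the masks.
    The channel is chosen by the therapy wavelength label (red/green/blue);
    each view is calibrated against its own card patches and the stereo mean
    of the two fractions is the headline value. Regions with more than
    ``max_saturated_fraction`` of pixels at encoded values >= 254 raise
    :class:`SaturationError`.
    """
    if wavelength_label not in CHANNEL_INDEX:
        raise DomainError(
            f"unknown wavelength label {wavelength_label!r}; expected one of "
            f"{sorted(CHANNEL_INDEX)}"
        )
    if len(images) != 2:
        raise DomainError(f"expected a stereoscopic pair, got {len(images)} image(s)")
    channel = CHANNEL_INDEX[wavelength_label]
    fractions = [
        _measure_view(
            img, wound_mask, gray_mask, white_mask, card, channel, max_saturated_fraction
        )
        for img in images
    ]
    return ReflectanceResult(
        wavelength_label=wavelength_label,
        fraction_view1=fractions[0],
        fraction_view2=fractions[1],
    )
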