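"""Illumination correction by polynomial surface fitting.

Uneven illumination across a stitched fluorescence field is modelled as a
smooth bivariate quadratic surface

    s(x, y) = a + b x + c y + d x**2 + e y**2 + f x y

fitted to all pixel intensities by least squares over coordinates
normalized to [0, 1] (for conditioning).  Correction divides the image by
the mean-normalized surface — illumination is treated as multiplicative —
or optionally subtracts the mean-centred surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .containers import ChannelImage
from .exceptions import ParameterError, ShapeMismatchError

__all__ = ["IlluminationModel", "fit_illumination", "apply_illumination"]

#: Surface values are floored at this fraction of the surface maximum so
#: division cannot blow up in dark corners.
FLOOR_FRACTION = 1e-3


def _design_matrix(shape: Tuple[int, int]) -> np.ndarray:
    h, w = shape
    y = np.linspace(0.0, 1.0, h) if h > 1 else np.zeros(1)
    x = np.linspace(0.0, 1.0, w) if w > 1 else np.zeros(1)
    xg, yg = np.meshgrid(x, y)
    xf, yf = xg.ravel(), yg.ravel()
    return np.column_stack(
        [np.ones_like(xf), xf, yf, xf**2, yf**2, xf * yf]
    )


@dataclass
class IlluminationModel:
    """Fitted quadratic illumination surface.

    ``coefficients`` are (a, b, c, d, e, f) for
    ``a + b x + c y + d x^2 + e y^2 + f xy`` over coordinates normalized
    to [0, 1]; ``shape`` is the image the model was fitted on.  The
    evaluated surface is floored at ``floor_fraction`` times its maximum
    so it is strictly positive wherever the image is not identically zero.
    """

    coefficients: np.ndarray
    shape: Tuple[int, int]
    floor_fraction: float = FLOOR_FRACTION

    def surface(self) -> np.ndarray:
        """Evaluate the floored surface over the image domain."""
        s = (_design_matrix(self.shape) @ self.coefficients).reshape(self.shape)
        smax = float(s.max())
        if smax <= 0.0:
            # all-zero (or negative) fit: unit surface leaves the image alone
            return np.ones(self.shape)
        return np.maximum(s, self.floor_fraction * smax)


def fit_illumination(img: ChannelImage) -> IlluminationModel:
    """Least-squares fit of the quadratic surface to all pixel intensities.

    Exact (to machine precision) for any image already in the quadratic
    model class; an all-equal image yields the constant surface at that
    value.
    """
    h, w = img.shape
    if h < 3 or w < 3:
        raise ParameterError(f"image must be at least 3x3 to fit illumination, got {img.shape}")
    A = _design_matrix(img.shape)
    b = img.astype_float().ravel()
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    return IlluminationModel(coefficients=coef, shape=(h, w))


def apply_illumination(
    img: ChannelImage, model: IlluminationModel, mode: str = "divide"
) -> ChannelImage:
    """Correct a channel with a fitted illumination model.

    ``divide`` (default) divides by the surface scaled to unit mean, which
    preserves the global intensity scale; ``subtract`` removes the
    mean-centred surface instead.  Output is clipped to the bit range and
    returned as a float-valued channel.
    """
    if model.shape != img.shape:
        raise ShapeMismatchError(
            f"model fitted on {model.shape}, image is {img.shape}"
        )
    if mode not in ("divide", "subtract"):
        raise ParameterError(f"mode must be 'divide' or 'subtract', got {mode!r}")
    s = model.surface()
    px = img.astype_float()
    if mode == "divide":
        out = px / (s / s.mean())
    else:
        out = px - (s - s.mean())
    return img.with_pixels(np.clip(out, 0.0, img.max_value))
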