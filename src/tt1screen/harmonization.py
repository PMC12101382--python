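"""Cross-assay harmonization of succinylacetone (SA) measurements.

Two generations of the non-derivatized FIA-MS/MS kit used in Dutch newborn
screening (NeoBase, 2008-2017; NeoBase 2, since 2018) report systematically
different SA concentrations for the same dried-blood-spot specimen.  Pooling
referral data across assay eras therefore requires mapping old-assay SA values
onto the new-assay scale.  Clinical chemistry does this with an
errors-in-both-variables straight line fitted by Deming regression, since both
assays measure with error.

This module provides

* :class:`ConversionModel` — a fitted (or published) linear mapping,
* :func:`fit_deming` — the closed-form Deming estimator,
* :func:`convert_sa` — application of a mapping with the screening programme's
  two-decimal reporting convention, and
* :data:`NEOBASE_TO_NEOBASE2` — the published national mapping
  ``NeoBase2 = 0.019 + 0.572 x NeoBase`` (fitted on 1093 residual screening
  specimens and quality-control samples; the original fit itself is not
  reproducible here, only its coefficients are shipped).

Other biomarkers (tyrosine, phenylalanine) agreed between the kits and are
passed through unconverted elsewhere in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "ConversionModel",
    "MethodPair",
    "NEOBASE_TO_NEOBASE2",
    "BUILTIN_MODELS",
    "fit_deming",
    "convert_sa",
    "round_half_up",
]


def round_half_up(value, ndigits: int = 0):
    """Round to ``ndigits`` decimals with ties going up (away from zero).

    Vectorised: accepts scalars or array-likes of non-negative numbers and
    returns the same shape.  A guard of 1e-9 on the scaled value keeps
    midpoints that land a hair below .5 purely through binary representation
    (e.g. ``3.15/60 -> 0.052499999...``) rounding up, which is the behaviour
    of decimal half-up on values printed to assay resolution.
    """
    scale = 10.0 ** ndigits
    scaled = np.asarray(value, dtype=float) * scale
    out = np.floor(scaled + 0.5 + 1e-9) / scale
    if np.ndim(value) == 0:
        return float(out)
    return out


class MethodPair(NamedTuple):
    """One calibration specimen measured on both assays (µmol/L blood)."""

    x: float  # old assay (NeoBase)
    y: float  # new assay (NeoBase 2)


@dataclass(frozen=True)
class ConversionModel:
    """Linear mapping ``y = intercept + slope * x`` between two assay scales.

    Parameters
    ----------
    slope
        Dimensionless; must be positive (both assays measure the same analyte).
    intercept
        µmol/L blood on the target (y) scale.
    variance_ratio
        Assumed ratio of measurement-error variances ``var(err_y)/var(err_x)``
        used by the Deming fit.  1.0 means both assays are equally noisy; the
        limit ``variance_ratio -> inf`` corresponds to ordinary least squares
        of y on x.
    n_pairs
        Optional provenance: number of calibration pairs behind the fit.
    """

    slope: float
    intercept: float
    variance_ratio: float = 1.0
    n_pairs: int | None = None

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"slope must be positive, got {self.slope}")
        if not self.variance_ratio > 0:
            raise ValueError(
                f"variance_ratio must be positive, got {self.variance_ratio}"
            )

    def convert(self, sa):
        return convert_sa(sa, self)

    def to_dict(self) -> dict:
        d = {
            "slope": self.slope,
            "intercept": self.intercept,
            "variance_ratio": self.variance_ratio,
        }
        if self.n_pairs is not None:
            d["n_pairs"] = self.n_pairs
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ConversionModel":
        return cls(
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            variance_ratio=float(d.get("variance_ratio", 1.0)),
            n_pairs=int(d["n_pairs"]) if d.get("n_pairs") is not None else None,
        )


#: Published national mapping from NeoBase SA to the NeoBase 2 scale.
NEOBASE_TO_NEOBASE2 = ConversionModel(
    slope=0.572, intercept=0.019, variance_ratio=1.0, n_pairs=1093
)

BUILTIN_MODELS: dict[str, ConversionModel] = {
    "neobase_to_neobase2": NEOBASE_TO_NEOBASE2,
    "identity": ConversionModel(slope=1.0, intercept=0.0),
}


def fit_deming(
    x,
    y=None,
    *,
    variance_ratio: float = 1.0,
) -> ConversionModel:
    """Fit a Deming (errors-in-both-variables) regression line.

    Accepts either two equal-length sequences ``x`` (old assay) and ``y`` (new
    assay), or a single sequence of :class:`MethodPair` / ``(x, y)`` tuples.

    The closed-form estimator minimises the sum of squared perpendicular
    distances weighted by ``variance_ratio = var(err_y)/var(err_x)``:

        b = (s_yy - d*s_xx + sqrt((s_yy - d*s_xx)^2 + 4*d*s_xy^2)) / (2*s_xy)

    with moment sums s_xx, s_yy, s_xy and d = variance_ratio.  As d -> inf the
    slope tends to the ordinary least-squares slope s_xy/s_xx.

    Raises
    ------
    ValueError
        Fewer than 3 pairs, negative concentrations, degenerate x variance,
        or non-positive x-y covariance (no positive line fits such data).
    """
    if y is None:
        pairs = [MethodPair(*p) for p in x]
        xv = np.asarray([p.x for p in pairs], dtype=float)
        yv = np.asarray([p.y for p in pairs], dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    if xv.size < 3:
        raise ValueError(f"need at least 3 method-comparison pairs, got {xv.size}")
    if not (np.all(np.isfinite(xv)) and np.all(np.isfinite(yv))):
        raise ValueError("non-finite measurement in method-comparison pairs")
    if np.any(xv < 0) or np.any(yv < 0):
        raise ValueError("concentrations must be non-negative")
    if not variance_ratio > 0:
        raise ValueError("variance_ratio must be positive")

    mx, my = xv.mean(), yv.mean()
    dx, dy = xv - mx, yv - my
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    sxy = float(dx @ dy)
    if sxx <= 0 or math.isclose(sxx, 0.0, abs_tol=1e-300):
        raise ValueError("x values are all identical; slope is undefined")
    if sxy <= 0:
        raise ValueError(
            "non-positive covariance between methods; no positive-slope "
            "conversion line exists for these pairs"
        )

    d = float(variance_ratio)
    diff = syy - d * sxx
    root = math.sqrt(diff**2 + 4.0 * d * sxy**2)
    # two algebraically equal forms; pick the one that avoids cancellation
    if diff > 0:
        slope = (diff + root) / (2.0 * sxy)
    else:
        slope = (2.0 * d * sxy) / (root - diff)
    intercept = my - slope * mx
    return ConversionModel(
        slope=slope,
        intercept=intercept,
        variance_ratio=d,
        n_pairs=int(xv.size),
    )


def convert_sa(sa, model: ConversionModel = NEOBASE_TO_NEOBASE2):
    """Map an SA concentration onto the model's target scale.

    Returns ``round_half_up(intercept + slope * sa, 2)`` — converted SA is
    reported at the assay's two-decimal resolution before any downstream use,
    matching the national programme's reporting convention.  Monotone
    non-decreasing in the input for any positive slope.  Scalar in, scalar
    out; array in, array out.
    """
    arr = np.asarray(sa, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("SA concentration must be finite and non-negative")
    return round_half_up(model.intercept + model.slope * arr, 2)
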