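"""In-gel densitometric protein quantification.

A serial dilution of purified protein is run on the same gel as the unknown,
band densities (mean gray values over fixed ROIs) are measured, a line
``density = slope · ng + intercept`` is fitted by ordinary least squares on
the replicate means, and unknown band densities are inverted through the
line to nanograms.  Uncertainty on an estimate propagates the slope /
intercept covariance of the fit together with the replicate scatter of the
measured density.  A final unit conversion yields ng of protein per mg of
tissue fresh weight, with every extraction factor (buffer volume, loaded
volume, dilution) explicit.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Sequence

import numpy as np

from .errors import PlastidkitError


@dataclasses.dataclass(frozen=True)
class StandardCurve:
    """Fitted line mapping band density to protein amount (ng)."""

    slope: float  # density units per ng
    intercept: float  # density units
    r_squared: float
    n_points: int
    replicate_sd: tuple[float, ...]  # per-point SD of replicate densities
    cov: tuple[tuple[float, float], ...]  # (slope, intercept) covariance
    through_origin: bool = False

    def predict_density(self, amount_ng: float) -> float:
        return self.slope * amount_ng + self.intercept

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "replicate_sd": list(self.replicate_sd),
            "through_origin": self.through_origin,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


@dataclasses.dataclass(frozen=True)
class AmountEstimate:
    """Inverted estimate: ng with propagated SD; negatives flagged."""

    amount_ng: float
    sd_ng: float
    below_detection: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class ExtractionContext:
    """Extraction arithmetic: how a band maps back to tissue fresh weight."""

    fresh_weight_mg: float
    buffer_volume_ul: float
    loaded_volume_ul: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("fresh_weight_mg", "buffer_volume_ul", "loaded_volume_ul", "dilution_factor"):
            if getattr(self, name) <= 0:
                raise PlastidkitError(f"{name} must be positive")


def fit_standard_curve(
    amounts_ng: Sequence[float],
    densities: Sequence[Sequence[float]],
    weighted: bool = False,
    through_origin: bool = False,
) -> StandardCurve:
    """OLS fit of replicate-mean density against amount.

    ``densities[i]`` holds the replicate measurements for ``amounts_ng[i]``
    (a bare scalar is treated as a single replicate).  ``weighted`` uses
    inverse-variance weights from the replicate SDs (points with zero SD fall
    back to the median weight).  ``through_origin`` forces intercept = 0.
    """
    amounts = np.asarray(amounts_ng, dtype=float)
    if amounts.size < 2 or np.unique(amounts).size < 2:
        raise PlastidkitError("need at least 2 distinct amounts to fit a line")
    reps = [np.atleast_1d(np.asarray(d, dtype=float)) for d in densities]
    if len(reps) != amounts.size:
        raise PlastidkitError("amounts and densities differ in length")
    means = np.array([r.mean() for r in reps])
    sds = np.array([r.std(ddof=1) if r.size > 1 else 0.0 for r in reps])

    if weighted:
        var = sds**2
        positive = var[var > 0]
        fallback = np.median(positive) if positive.size else 1.0
        w = 1.0 / np.where(var > 0, var, fallback)
    else:
        w = np.ones_like(means)

    if through_origin:
        sw = w.sum()
        sxx = float((w * amounts * amounts).sum())
        slope = float((w * amounts * means).sum() / sxx)
        intercept = 0.0
        resid = means - slope * amounts
        dof = max(amounts.size - 1, 1)
        s2 = float((w * resid**2).sum() / dof)
        cov = ((s2 / sxx, 0.0), (0.0, 0.0))
        ss_tot = float((w * means**2).sum())  # uncentered for origin fits
    else:
        # weighted OLS with parameter covariance
        X = np.column_stack([amounts, np.ones_like(amounts)])
        W = np.diag(w)
        xtwx = X.T @ W @ X
        beta = np.linalg.solve(xtwx, X.T @ W @ means)
        slope, intercept = float(beta[0]), float(beta[1])
        resid = means - X @ beta
        dof = max(amounts.size - 2, 1)
        s2 = float((w * resid**2).sum() / dof)
        cov_m = s2 * np.linalg.inv(xtwx)
        cov = tuple(tuple(float(v) for v in row) for row in cov_m)
        wbar = float((w * means).sum() / w.sum())
        ss_tot = float((w * (means - wbar) ** 2).sum())
    ss_res = float((w * resid**2).sum())
    r_squared = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return StandardCurve(
        slope=slope,
        intercept=intercept,
        r_squared=min(r_squared, 1.0),
        n_points=int(amounts.size),
        replicate_sd=tuple(float(s) for s in sds),
        cov=cov,
        through_origin=through_origin,
    )


def estimate_amount(
    band_density: float,
    curve: StandardCurve,
    density_sd: float | None = None,
) -> AmountEstimate:
    """Invert a band density through the standard curve.

    ``ng = (density − intercept) / slope``.  The propagated SD combines the
    measurement SD of the density (``density_sd``; defaults to the mean
    replicate SD of the curve) with the slope/intercept covariance by the
    delta method.  A negative estimate is flagged ``below_detection`` with
    the raw negative value retained.
    """
    if curve.slope == 0:
        raise PlastidkitError("standard curve slope is zero; cannot invert")
    m, b = curve.slope, curve.intercept
    ng = (band_density - b) / m
    if density_sd is None:
        density_sd = float(np.mean(curve.replicate_sd)) if curve.replicate_sd else 0.0
    (vmm, vmb), (_, vbb) = curve.cov
    # delta method on g(m, b, d) = (d - b)/m
    dg_dm = -ng / m
    dg_db = -1.0 / m
    dg_dd = 1.0 / m
    var = (
        dg_dm**2 * vmm
        + dg_db**2 * vbb
        + 2 * dg_dm * dg_db * vmb
        + dg_dd**2 * density_sd**2
    )
    return AmountEstimate(
        amount_ng=float(ng),
        sd_ng=float(math.sqrt(max(var, 0.0))),
        below_detection=bool(ng < 0),
    )


def concentration_fw(amount_ng: float, ctx: ExtractionContext) -> float:
    """Convert an on-gel amount (ng) to ng per mg tissue fresh weight.

    ng/mg = amount · (buffer volume / loaded volume) · dilution / fresh weight.
    """
    return (
        amount_ng
        * (ctx.buffer_volume_ul / ctx.loaded_volume_ul)
        * ctx.dilution_factor
        / ctx.fresh_weight_mg
    )
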