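"""Empirical laws linking (mu/nu, t) to the gamma (alpha, beta), and their
recalibration from fresh simulations.

With ``r = mu/nu``, the invisible-length gamma parameters follow

    1/alpha - 1 = s(r) * (t - 1),      s(r) = a2 r^2 + a1 r + a0
    1/beta      = mu * exp(b(r) * (t - 1)),  b(r) = b2 r^2 + b1 r + b0

so invisible lengths are exponential (alpha = 1, beta = 1/mu) after the
first sweep, the reciprocal shape grows linearly in t, and the log
reciprocal rate grows linearly in t with slope depending only on r.  The
reference coefficients were obtained by fitting those two stages on a
simulation grid; :func:`calibrate` reruns that pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError
from .fitting import fit_gamma
from .simulator import SimConfig, SweepParams, collect_lengths, run_fractionation

__all__ = [
    "CoefficientSet",
    "REFERENCE_COEFFICIENTS",
    "shape_slope",
    "rate_slope",
    "shape_law",
    "rate_law",
    "calibrate",
]


@dataclass(frozen=True)
class CoefficientSet:
    """Quadratic (in r = mu/nu) slope coefficients of the two laws.

    shape_quad = (a2, a1, a0) for the 1/alpha stage;
    rate_quad  = (b2, b1, b0) for the log 1/beta stage.
    """

    shape_quad: tuple[float, float, float]
    rate_quad: tuple[float, float, float]
    provenance: str = "reference"
    #: (r_min, r_max) over which the quadratics are an interpolation; the
    #: shape-law inversion rejects roots outside it.  None means only the
    #: generic cap applies (the reference set's negative intercept already
    #: keeps inverted ratios away from 0).
    r_domain: tuple[float, float] | None = None
    diagnostics: dict = field(default_factory=dict, compare=False)


#: reference coefficients of the published calibration
REFERENCE_COEFFICIENTS = CoefficientSet(
    shape_quad=(-0.1725, 0.5333, -0.039),
    rate_quad=(-0.2458, 0.9257, -0.0212),
    provenance="reference",
)


def shape_slope(r: float, coeffs: CoefficientSet = REFERENCE_COEFFICIENTS) -> float:
    a2, a1, a0 = coeffs.shape_quad
    return a2 * r * r + a1 * r + a0


def rate_slope(r: float, coeffs: CoefficientSet = REFERENCE_COEFFICIENTS) -> float:
    b2, b1, b0 = coeffs.rate_quad
    return b2 * r * r + b1 * r + b0


def shape_law(
    r: float, t: int, coeffs: CoefficientSet = REFERENCE_COEFFICIENTS
) -> float:
    """Predicted gamma shape ``alpha = 1 / (1 + s(r) (t-1))``."""
    if t < 1:
        raise ValueError("t must be >= 1")
    if not (r > 0):
        raise ValueError("r = mu/nu must be positive")
    denom = 1.0 + shape_slope(r, coeffs) * (t - 1)
    if denom <= 0:
        raise DomainError(
            f"shape law undefined: 1 + s(r)(t-1) = {denom} <= 0 at r={r}, t={t}"
        )
    return 1.0 / denom


def rate_law(
    mu: float, r: float, t: int, coeffs: CoefficientSet = REFERENCE_COEFFICIENTS
) -> float:
    """Predicted gamma rate ``beta = 1 / (mu * exp(b(r) (t-1)))``."""
    if t < 1:
        raise ValueError("t must be >= 1")
    if not (mu > 0):
        raise ValueError("mu must be positive")
    return 1.0 / (mu * math.exp(rate_slope(r, coeffs) * (t - 1)))


def _slope_through_origin(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y on x with the intercept pinned at 0."""
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ConfigurationError("need at least one sweep with t > 1")
    return float(np.dot(x, y) / sxx)


def calibrate(
    ratios,
    sweeps,
    mu: float = 1.0,
    genome_length: float = 10_000.0,
    replicates: int = 5,
    seed: int = 0,
    pinned_intercept: bool = True,
) -> CoefficientSet:
    """Rerun the two-stage calibration pipeline on fresh simulations.

    For each ratio ``r`` the simulator runs at (mu, nu = mu/r) through the
    requested sweeps; pooled invisible lengths per sweep are fitted by
    gamma MLE.  Stage one fits, per r, the line ``1/alpha - 1`` vs
    ``t - 1`` and the line ``ln(1/(beta mu))`` vs ``t - 1`` (through the
    origin by default, which both laws force at t = 1).  Stage two fits a
    quadratic in r to each family of slopes.  Seed-reproducible.
    """
    ratios = [float(r) for r in ratios]
    sweeps = [int(t) for t in sweeps]
    if len(set(ratios)) < 3:
        raise ConfigurationError("need at least 3 distinct ratios")
    if len(set(sweeps)) < 3:
        raise ConfigurationError("need at least 3 distinct sweep counts")
    t_max = max(sweeps)

    shape_slopes, rate_slopes, kept_ratios = [], [], []
    diag_cells = []
    for k, r in enumerate(ratios):
        params = SweepParams(nu=mu / r, mu=mu)
        config = SimConfig(
            sweeps=t_max,
            genome_length=genome_length,
            replicates=replicates,
            seed=seed + 7919 * k,
        )
        result = run_fractionation(params, config)
        xs, ys_shape, ys_rate = [], [], []
        for t in sweeps:
            try:
                sample = collect_lengths(result.states[t])
                fit = fit_gamma(sample.invisible, method="mle")
            except Exception as exc:  # noqa: BLE001 - drop the cell, keep going
                import warnings

                warnings.warn(f"calibration cell r={r}, t={t} dropped: {exc}")
                continue
            xs.append(t - 1)
            ys_shape.append(1.0 / fit.alpha - 1.0)
            ys_rate.append(math.log(1.0 / (fit.beta * mu)))
            diag_cells.append(
                {"r": r, "t": t, "alpha": fit.alpha, "beta": fit.beta}
            )
        if len(xs) < 2:
            continue
        x = np.asarray(xs, dtype=float)
        if pinned_intercept:
            shape_slopes.append(_slope_through_origin(x, np.asarray(ys_shape)))
            rate_slopes.append(_slope_through_origin(x, np.asarray(ys_rate)))
        else:
            shape_slopes.append(float(np.polyfit(x, ys_shape, 1)[0]))
            rate_slopes.append(float(np.polyfit(x, ys_rate, 1)[0]))
        kept_ratios.append(r)

    if len(kept_ratios) < 3:
        raise ConfigurationError(
            f"only {len(kept_ratios)} ratios survived; cannot fit quadratics"
        )

    rr = np.asarray(kept_ratios)
    shape_quad = np.polyfit(rr, shape_slopes, 2)
    rate_quad = np.polyfit(rr, rate_slopes, 2)

    def r2(y, yhat):
        y = np.asarray(y)
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    diagnostics = {
        "ratios": kept_ratios,
        "shape_slopes": [float(s) for s in shape_slopes],
        "rate_slopes": [float(s) for s in rate_slopes],
        "shape_r2": r2(shape_slopes, np.polyval(shape_quad, rr)),
        "rate_r2": r2(rate_slopes, np.polyval(rate_quad, rr)),
        "cells": diag_cells,
        "seed": seed,
    }
    return CoefficientSet(
        shape_quad=tuple(float(c) for c in shape_quad),
        rate_quad=tuple(float(c) for c in rate_quad),
        provenance="recalibrated",
        # the quadratics are interpolations over the calibration grid;
        # allow modest extrapolation above it, none below (tiny-r roots
        # produce degenerate many-sweeps-of-nothing solutions)
        r_domain=(min(kept_ratios), 2.0 * max(kept_ratios)),
        diagnostics=diagnostics,
    )
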