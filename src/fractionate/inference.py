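"""Recover (mu, nu, t) from observed length-distribution summaries.

The observables are the exponential rate of visible lengths
(``lambda_inv = t/nu``) and the gamma shape/rate (``alpha``, ``beta``) of
invisible lengths.  Since ``t`` is an integer, each candidate ``t`` yields
``nu_t = t / lambda_inv``, a ratio ``r`` from inverting the shape law, and
hence ``mu_t = r nu_t`` and a predicted rate ``beta_t``.  The estimate is
the candidate minimizing the normalized rate discrepancy
``delta = |beta - beta_t| / beta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .calibration import REFERENCE_COEFFICIENTS, CoefficientSet, rate_law
from .errors import InferenceError

__all__ = [
    "Observables",
    "InferenceCandidate",
    "InferenceResult",
    "DEFAULT_R_CAP",
    "invert_shape_law",
    "candidate",
    "infer",
]

#: admissible upper bound on r = mu/nu when inverting the shape law; the
#: slope quadratic peaks near r = 1.55 with the reference coefficients, so
#: the map r -> s(r) is increasing (hence invertible) below the cap
DEFAULT_R_CAP = 1.5


@dataclass(frozen=True)
class Observables:
    """Observed (lambda^{-1}, alpha, beta) of one genome at unknown t."""

    lambda_inv: float
    alpha: float
    beta: float

    def __post_init__(self):
        for name in ("lambda_inv", "alpha", "beta"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class InferenceCandidate:
    t: int
    nu_t: float
    mu_t: float | None = None
    beta_t: float | None = None
    delta: float | None = None

    @property
    def status(self) -> str:
        return "ok" if self.mu_t is not None else "no_solution"


@dataclass(frozen=True)
class InferenceResult:
    candidates: tuple[InferenceCandidate, ...]
    t_hat: int
    mu_hat: float
    nu_hat: float

    def best(self) -> InferenceCandidate:
        return next(c for c in self.candidates if c.t == self.t_hat)

    def table(self) -> list[dict]:
        """Candidate table in the conventional layout (100*delta column)."""
        return [
            {
                "t": c.t,
                "mu_t": c.mu_t,
                "nu_t": c.nu_t,
                "beta_t": c.beta_t,
                "delta_x100": None if c.delta is None else 100.0 * c.delta,
                "status": c.status,
            }
            for c in self.candidates
        ]


def _r_bounds(coeffs: CoefficientSet, r_cap: float) -> tuple[float, float]:
    if coeffs.r_domain is not None:
        lo, hi = coeffs.r_domain
        return lo, min(hi, r_cap)
    return 0.0, r_cap


def invert_shape_law(
    alpha: float,
    t: int,
    coeffs: CoefficientSet = REFERENCE_COEFFICIENTS,
    r_cap: float = DEFAULT_R_CAP,
) -> float | None:
    """Solve the shape law for ``r = mu/nu`` at a fixed candidate ``t``.

    Solves ``a2 r^2 + a1 r + a0 = (1/alpha - 1)/(t - 1)``.  On the
    physically plausible range the slope quadratic is increasing, so the
    smaller real root is the admissible inverse; it is returned when it
    lies in the admissible range (``(0, r_cap]``, intersected with the
    coefficient set's calibrated r-domain when it has one), otherwise
    ``None`` (no solution — at small t the required slope can exceed the
    quadratic's maximum).
    """
    if not (alpha > 0):
        raise ValueError("alpha must be positive")
    if t < 2:
        return None  # r is unidentifiable at t = 1 (the law forces alpha = 1)
    a2, a1, a0 = coeffs.shape_quad
    target = (1.0 / alpha - 1.0) / (t - 1)
    # a2 r^2 + a1 r + (a0 - target) = 0
    c0 = a0 - target
    disc = a1 * a1 - 4.0 * a2 * c0
    if disc < 0:
        return None
    sq = math.sqrt(disc)
    roots = sorted(((-a1 + sq) / (2 * a2), (-a1 - sq) / (2 * a2)))
    lo, hi = _r_bounds(coeffs, r_cap)
    for r in roots:  # smaller admissible root first
        if lo <= r <= hi and r > 0:
            return r
    return None


def candidate(
    t: int,
    obs: Observables,
    coeffs: CoefficientSet = REFERENCE_COEFFICIENTS,
    r_cap: float = DEFAULT_R_CAP,
) -> InferenceCandidate:
    """Evaluate one candidate sweep count against the observables."""
    if t < 1:
        raise ValueError("t must be >= 1")
    nu_t = t / obs.lambda_inv
    r = invert_shape_law(obs.alpha, t, coeffs, r_cap)
    if r is None:
        return InferenceCandidate(t=t, nu_t=nu_t)
    mu_t = r * nu_t
    beta_t = rate_law(mu_t, r, t, coeffs)
    delta = abs(obs.beta - beta_t) / obs.beta
    return InferenceCandidate(t=t, nu_t=nu_t, mu_t=mu_t, beta_t=beta_t, delta=delta)


def infer(
    obs: Observables,
    t_range: Iterable[int] = range(1, 31),
    coeffs: CoefficientSet = REFERENCE_COEFFICIENTS,
    r_cap: float = DEFAULT_R_CAP,
) -> InferenceResult:
    """Scan candidate sweep counts and pick the arg-min of ``delta``.

    Ties (practically impossible with float delta) break toward the
    smaller, more parsimonious ``t``.  Raises :class:`InferenceError`
    carrying the candidate table when no candidate admits a solution.
    """
    ts = sorted(set(int(t) for t in t_range))
    if not ts:
        raise ValueError("t_range is empty")
    cands = tuple(candidate(t, obs, coeffs, r_cap) for t in ts)
    ok = [c for c in cands if c.status == "ok"]
    if not ok:
        raise InferenceError(
            f"no admissible (mu, nu) solution for any t in {ts[0]}..{ts[-1]}",
            candidates=cands,
        )
    best = min(ok, key=lambda c: (c.delta, c.t))
    return InferenceResult(
        candidates=cands, t_hat=best.t, mu_hat=best.mu_t, nu_hat=best.nu_t
    )
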