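"""Closed-form and recursive results of the fractionation model.

Under the sweep model, the mean spacing of surviving deletion points after
sweep ``t`` is ``lambda_t = nu / t``; visible segment lengths are
exponential with that mean.  The number ``q`` of pre-existing deletion
points swallowed by a new deletion event is geometric on ``q = 0, 1, ...``
with parameter ``mu / (mu + lambda)``.  From the geometric law one can
propagate the distribution ``pi_t(i)`` of event-counter values sweep by
sweep, treating swallowed counters as independent draws from the current
``pi`` (a stated approximation of the model, not corrected here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .errors import DomainError

__all__ = [
    "lambda_exact",
    "lambda_recursion",
    "lambda_two_sweep_approx",
    "overlap_pmf",
    "overlap_pmf_integral_oracle",
    "retained_proportion",
    "CountDistribution",
    "pi_initial",
    "pi_delta",
    "pi_update",
    "pi_trajectory",
]


# ---------------------------------------------------------------------------
# visible spacing
# ---------------------------------------------------------------------------


def lambda_exact(nu: float, t: int) -> float:
    """Mean visible spacing after sweep ``t``: ``nu / t``."""
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    if not (nu > 0):
        raise ValueError("nu must be positive")
    return nu / t


def lambda_recursion(nu: float, t: int) -> float:
    """Mean visible spacing via the one-step recursion.

    Starting from ``lambda_1 = nu``, each sweep superimposes a fresh
    point process with parameter ``nu`` on the surviving points:
    ``lambda_t = nu / (1 + nu / lambda_{t-1})``.  Telescopes to ``nu/t``.
    """
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    lam = float(nu)
    for _ in range(1, t):
        lam = nu / (1.0 + nu / lam)
    return lam


def lambda_two_sweep_approx(nu: float, mu: float) -> float:
    """Historical two-sweep approximation ``nu / (1 + nu/(nu+mu))``.

    Documented for completeness only; it disagrees with the recursion's
    ``lambda_2 = nu/2`` and is not used anywhere downstream.
    """
    return nu / (1.0 + nu / (nu + mu))


def retained_proportion(mu: float, nu: float, t: int) -> float:
    """Expected visible fraction after ``t`` sweeps: ``(1 - mu/(nu+mu))**t``."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return (1.0 - mu / (nu + mu)) ** t


# ---------------------------------------------------------------------------
# overlap-count distribution
# ---------------------------------------------------------------------------


def overlap_pmf(q: int, mu: float, lam: float) -> float:
    """P(new deletion event swallows exactly ``q`` existing deletion points).

    Geometric on ``q = 0, 1, ...`` with parameter ``mu/(mu+lam)``:
    ``p_q = lam/(mu+lam) * (mu/(mu+lam))**q``.
    """
    if q < 0:
        raise ValueError(f"q must be non-negative, got {q}")
    if not (mu > 0 and lam > 0):
        raise ValueError("mu and lam must be positive")
    ratio = mu / (mu + lam)
    return lam / (mu + lam) * ratio**q


def overlap_pmf_integral_oracle(
    q: int, mu: float, lam: float, epsabs: float = 1e-10
) -> float:
    """Quadrature of the defining integrals of ``p_0`` and ``p_1``.

    ``p_0`` integrates, over a length-biased visible spacing ``l`` and a
    uniform deletion-point position ``x`` inside it, the probability that
    the deletion length stays short of the next deletion point:

        p_0 = int_l  l*Lam(l)/lam  int_x (1/l)  int_0^{l-x} gamma(y) dy dx dl

    ``p_1`` adds one further spacing ``z`` and asks the deletion to end
    inside it.  Used only as an independent test oracle for
    :func:`overlap_pmf`; supports ``q`` in {0, 1}.
    """
    if q not in (0, 1):
        raise ValueError("the integral oracle is defined for q in {0, 1} only")

    def Lam(l):
        return np.exp(-l / lam) / lam

    def F_gamma(y):
        # int_0^y gamma(u) du for the exponential deletion-length density
        return -np.expm1(-y / mu) if y > 0 else 0.0

    if q == 0:

        def inner(l):
            val, _ = integrate.quad(
                lambda x: F_gamma(l - x) / l, 0.0, l, epsabs=epsabs, limit=200
            )
            return val

        p, err = integrate.quad(
            lambda l: l * Lam(l) / lam * inner(l),
            0.0,
            np.inf,
            epsabs=epsabs,
            limit=200,
        )
    else:

        def inner_x(l, z):
            val, _ = integrate.quad(
                lambda x: F_gamma(l - x + z) - F_gamma(l - x),
                0.0,
                l,
                epsabs=epsabs,
                limit=200,
            )
            return val

        p, err = integrate.dblquad(
            lambda z, l: Lam(l) * Lam(z) * inner_x(l, z) / lam,
            0.0,
            np.inf,
            0.0,
            np.inf,
            epsabs=epsabs,
        )
    if not np.isfinite(p) or err > 1e-5:
        raise ArithmeticError(
            f"quadrature did not converge (value={p}, error estimate={err})"
        )
    return p


# ---------------------------------------------------------------------------
# event-count distribution pi_t
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountDistribution:
    """Distribution of event-counter values ``i = 1 .. i_max``.

    ``probs[i-1]`` holds ``pi(i)``; mass beyond ``i_max`` is truncated.
    """

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if np.any(p < -1e-12):
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {p.sum()}")

    @property
    def i_max(self) -> int:
        return len(self.probs)

    def __getitem__(self, i: int) -> float:
        if i < 1:
            raise IndexError("counter values start at 1")
        if i > len(self.probs):
            return 0.0
        return float(self.probs[i - 1])

    def as_dict(self) -> dict[int, float]:
        return {i + 1: float(p) for i, p in enumerate(self.probs)}


def pi_initial(i_max: int = 50) -> CountDistribution:
    """After the first sweep every counter equals 1: a point mass at 1."""
    p = np.zeros(i_max)
    p[0] = 1.0
    return CountDistribution(p)


def pi_delta(pi: CountDistribution, mu: float, lam: float) -> np.ndarray:
    """Expected per-event change ``Delta(i)`` of the counter counts.

    A deletion event swallowing ``q`` existing counters (probability
    ``p_q``) creates one counter of value ``1 + sum`` of the ``q``
    swallowed values and destroys those ``q``.  Treating swallowed values
    as independent draws from ``pi``:

        gain(i) = p_0 * 1{i=1}
                + sum_{q=1}^{i-1} p_q * sum over ordered compositions
                  (c_1..c_q) of i-1 into q positive parts of prod pi(c_j)
        loss(i) = pi(i) * sum_q q p_q = pi(i) * mu/lam

    The composition sum is the ``q``-fold convolution of ``pi`` at
    ``i - 1``, which is how it is computed here.
    """
    p = pi.probs
    i_max = len(p)
    ratio = mu / (mu + lam)
    p0 = lam / (mu + lam)

    gain = np.zeros(i_max)
    gain[0] = p0
    # conv[j] = P(sum of q draws from pi equals j + q); draws start at 1,
    # so the q-fold convolution is index-shifted by q
    conv = p.copy()
    for q in range(1, i_max):
        pq = p0 * ratio**q
        # counter value i = 1 + (sum of q parts); sum ranges over q..i_max-1
        for i in range(q + 1, i_max + 1):
            m = i - 1 - q  # shifted index of the swallowed total i - 1
            if 0 <= m < len(conv):
                gain[i - 1] += pq * conv[m]
        if pq < 1e-16:
            break
        conv = np.convolve(conv, p)[:i_max]

    loss = p * (mu / lam)
    return gain - loss


def pi_update(
    pi: CountDistribution,
    mu: float,
    lam: float,
    mode: str = "event-rate",
    events_per_counter: float | None = None,
) -> CountDistribution:
    """Advance ``pi`` by one sweep of deletion events.

    mode="event-rate" (default): proper bookkeeping of counter counts.
    With ``N`` existing counters and ``E`` new events, the updated
    proportions are ``(N*pi(i) + E*Delta(i)) / (N + E*(1 - mu/lam))``
    (each event creates one counter and destroys ``mu/lam`` on average).
    ``events_per_counter`` supplies ``E/N``; under the sweep model it is
    ``lam / (nu + mu)`` with ``lam`` the pre-sweep spacing.

    mode="renormalize": the rate-free variant ``pi + Delta`` renormalized,
    i.e. one event per existing counter.  Exposed for comparison; it
    over-weights the new events relative to the simulated process.
    """
    delta = pi_delta(pi, mu, lam)
    if mode == "event-rate":
        if events_per_counter is None:
            raise ValueError("mode='event-rate' requires events_per_counter (E/N)")
        counts = pi.probs + events_per_counter * delta
    elif mode == "renormalize":
        counts = pi.probs + delta
    else:
        raise ValueError(f"unknown mode {mode!r}")
    counts = np.clip(counts, 0.0, None)
    total = counts.sum()
    if total <= 0:
        raise ArithmeticError("pi update produced no probability mass")
    return CountDistribution(counts / total)


def pi_trajectory(
    mu: float,
    nu: float,
    t: int,
    i_max: int = 50,
    mode: str = "event-rate",
) -> list[CountDistribution]:
    """Event-count distributions ``pi_1 .. pi_t``.

    ``pi_1`` is the exact point mass at 1.  Sweep ``s >= 2`` applies
    :func:`pi_update` with ``lam = nu/(s-1)``, the spacing among the
    points that exist when the sweep runs, and (in the default mode)
    ``E/N = lam/(nu+mu)`` events per existing counter.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    out = [pi_initial(i_max)]
    for s in range(2, t + 1):
        lam = nu / (s - 1)
        epc = lam / (nu + mu) if mode == "event-rate" else None
        out.append(pi_update(out[-1], mu, lam, mode=mode, events_per_counter=epc))
    return out
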