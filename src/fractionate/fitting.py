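"""Fit the observable summaries from segment-length samples.

Visible lengths are modelled as exponential; their maximum-likelihood
rate estimates ``lambda^{-1} = t/nu``.  Invisible lengths are modelled as
gamma with shape ``alpha`` and rate ``beta`` (rate, not scale: ``1/beta``
scales proportionally with ``mu``).  Cullen–Frey moment coordinates
(squared skewness vs kurtosis, Pearson convention with normal = 3) are
provided as the distribution-identification diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateSampleError
from .simulator import LengthSample

__all__ = [
    "FitSummary",
    "GammaFit",
    "CullenFreyPoint",
    "CullenFreyResult",
    "fit_exponential",
    "fit_gamma",
    "fit_lengths",
    "cullen_frey",
    "ks_exponential",
    "ks_gamma",
]

log = logging.getLogger(__name__)

#: lengths below this are float-truncation artefacts of replenishment
#: splices (the continuous model produces none) and are dropped
ZERO_LENGTH_TOL = 1e-12


def _clean(lengths, min_n: int, what: str) -> np.ndarray:
    x = np.asarray(lengths, dtype=float).ravel()
    if x.size and np.any(x < 0):
        raise ValueError(f"{what} lengths must be non-negative")
    kept = x[x > ZERO_LENGTH_TOL]
    dropped = x.size - kept.size
    if dropped:
        log.info("dropped %d near-zero %s lengths", dropped, what)
    if kept.size < min_n:
        raise ValueError(
            f"need at least {min_n} positive {what} lengths, got {kept.size}"
        )
    return kept


@dataclass(frozen=True)
class GammaFit:
    alpha: float
    beta: float  # rate
    method: str  # 'mle' | 'moments'

    @property
    def scale(self) -> float:
        return 1.0 / self.beta


@dataclass(frozen=True)
class CullenFreyPoint:
    skewness_sq: float
    kurtosis: float  # Pearson convention: normal = 3


@dataclass(frozen=True)
class CullenFreyResult:
    point: CullenFreyPoint
    bootstrap: tuple[CullenFreyPoint, ...] = ()

    @staticmethod
    def gamma_reference(shape: float) -> CullenFreyPoint:
        """Moment coordinates of a Gamma(shape) law: (4/k, 3 + 6/k)."""
        return CullenFreyPoint(4.0 / shape, 3.0 + 6.0 / shape)

    #: the exponential law sits at skewness^2 = 4, kurtosis = 9
    EXPONENTIAL = None  # set below


CullenFreyResult.EXPONENTIAL = CullenFreyPoint(4.0, 9.0)


@dataclass(frozen=True)
class FitSummary:
    """Observed (lambda^{-1}, alpha, beta) of one length sample."""

    lambda_inv: float
    alpha: float
    beta: float
    n_visible: int
    n_invisible: int
    method: str
    ks_visible: float | None = None  # KS statistic vs fitted exponential
    ks_invisible: float | None = None  # KS statistic vs fitted gamma


def fit_exponential(lengths) -> float:
    """Maximum-likelihood exponential rate: ``1 / sample mean``."""
    x = _clean(lengths, 2, "visible")
    return 1.0 / float(np.mean(x))


def fit_gamma(lengths, method: str = "mle") -> GammaFit:
    """Fit a gamma law, returning (shape ``alpha``, rate ``beta``).

    method='mle' maximizes the gamma likelihood (location fixed at 0);
    method='moments' uses shape = mean^2/var, rate = mean/var.  If the
    MLE optimizer fails, the moment estimate is returned with the method
    recorded accordingly.
    """
    x = _clean(lengths, 10, "invisible")
    mean = float(np.mean(x))
    var = float(np.var(x))
    if var < 1e-15 * mean**2:
        raise DegenerateSampleError(
            "sample variance is (near) zero; gamma fit is undefined"
        )
    mom = GammaFit(alpha=mean**2 / var, beta=mean / var, method="moments")
    if method == "moments":
        return mom
    if method != "mle":
        raise ValueError(f"unknown method {method!r}")
    try:
        shape, _, scale = stats.gamma.fit(x, floc=0, method="MLE")
        if not (np.isfinite(shape) and shape > 0 and np.isfinite(scale) and scale > 0):
            raise ArithmeticError("non-finite MLE")
        return GammaFit(alpha=float(shape), beta=1.0 / float(scale), method="mle")
    except Exception:  # noqa: BLE001 - fall back to moments with a warning
        log.warning("gamma MLE did not converge; falling back to moments")
        return GammaFit(alpha=mom.alpha, beta=mom.beta, method="moments")


def ks_exponential(lengths, rate: float) -> tuple[float, float]:
    """KS statistic and p-value of lengths against Exponential(rate)."""
    x = _clean(lengths, 2, "visible")
    res = stats.kstest(x, "expon", args=(0, 1.0 / rate))
    return float(res.statistic), float(res.pvalue)


def ks_gamma(lengths, alpha: float, beta: float) -> tuple[float, float]:
    """KS statistic and p-value of lengths against Gamma(alpha, rate beta)."""
    x = _clean(lengths, 2, "invisible")
    res = stats.kstest(x, "gamma", args=(alpha, 0, 1.0 / beta))
    return float(res.statistic), float(res.pvalue)


def fit_lengths(sample: LengthSample, method: str = "mle") -> FitSummary:
    """Fit both length families of one sample and report the observables."""
    rate = fit_exponential(sample.visible)
    gam = fit_gamma(sample.invisible, method=method)
    ks_vis, _ = ks_exponential(sample.visible, rate)
    ks_inv, _ = ks_gamma(sample.invisible, gam.alpha, gam.beta)
    return FitSummary(
        lambda_inv=rate,
        alpha=gam.alpha,
        beta=gam.beta,
        n_visible=int(np.sum(np.asarray(sample.visible) > ZERO_LENGTH_TOL)),
        n_invisible=int(np.sum(np.asarray(sample.invisible) > ZERO_LENGTH_TOL)),
        method=gam.method,
        ks_visible=ks_vis,
        ks_invisible=ks_inv,
    )


def _moment_point(x: np.ndarray) -> CullenFreyPoint:
    skew = stats.skew(x, bias=False)
    kurt = stats.kurtosis(x, fisher=False, bias=False)
    return CullenFreyPoint(float(skew) ** 2, float(kurt))


def cullen_frey(
    lengths, n_boot: int = 0, rng: np.random.Generator | None = None
) -> CullenFreyResult:
    """Sample moment coordinates plus an optional bootstrap cloud."""
    x = _clean(lengths, 10, "sample")
    point = _moment_point(x)
    cloud = []
    if n_boot:
        rng = rng if rng is not None else np.random.default_rng()
        for _ in range(n_boot):
            cloud.append(_moment_point(rng.choice(x, size=x.size, replace=True)))
    return CullenFreyResult(point=point, bootstrap=tuple(cloud))
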