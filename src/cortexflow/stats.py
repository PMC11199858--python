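"""Degree/strength distributions, distribution-family fits and decay fits.

The descriptive layer of the analysis: counts of in/out links per area
(degree k), sums of link weights (weighted degree, a.k.a. strength),
maximum-likelihood comparison of candidate weight/degree distributions, and
ordinary-least-squares fits of the link weight-distance relation in log
space (exponential decay ``w ~ exp(-d/lambda)`` vs power law
``w ~ d^-gamma``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .connectome import Connectome

__all__ = [
    "DegreeVector",
    "FitResult",
    "DecayFit",
    "degree",
    "fit_family",
    "compare_families",
    "weight_distance_fit",
]

FAMILIES = ("exponential", "normal", "lognormal")


@dataclass
class DegreeVector:
    """Per-node degree (link count) or strength (weight sum), one direction."""

    labels: list[str]
    values: np.ndarray
    direction: str  # "in" | "out"
    weighted: bool

    def max(self) -> float:
        return float(self.values.max()) if len(self.values) else 0.0


@dataclass
class FitResult:
    """Maximum-likelihood fit of one distribution family."""

    family: str
    params: dict[str, float]
    log_likelihood: float
    n: int
    n_excluded: int = 0


@dataclass
class DecayFit:
    """OLS fit of log weight against distance (exponential) or log distance
    (power law); ``r_squared`` is the coefficient of determination in the
    transformed (log) space."""

    model: str  # "exponential" | "powerlaw"
    decay_length_mm: float | None  # lambda, exponential only
    exponent: float | None  # gamma, power law only
    intercept: float
    r_squared: float
    n_links: int
    n_excluded: int = 0


def degree(c: Connectome, direction: str = "in", weighted: bool = False) -> DegreeVector:
    """Node degree k (non-zero link count) or strength (weight sum).

    ``direction="out"`` reads rows of W, ``"in"`` reads columns.
    """
    if direction not in ("in", "out"):
        raise ValueError(f"direction must be 'in' or 'out', got {direction!r}")
    axis = 0 if direction == "in" else 1
    if weighted:
        vals = c.W.sum(axis=axis)
    else:
        vals = np.count_nonzero(c.W, axis=axis).astype(float)
    return DegreeVector(list(c.labels), vals, direction, weighted)


def fit_family(samples: Sequence[float], family: str) -> FitResult:
    """Fit one family by maximum likelihood and return its log likelihood.

    MLEs: exponential rate = 1/mean; normal mean and (biased) MLE variance;
    lognormal mean and MLE variance of the logs.  For the positive-support
    families zero samples are excluded (count reported in ``n_excluded``)
    and negative samples are an error.  A zero-variance sample is degenerate
    for every family.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    n_excluded = 0
    if family in ("exponential", "lognormal"):
        if np.any(x < 0):
            raise ValueError(f"{family} fit requires non-negative samples")
        n_excluded = int(np.sum(x == 0))
        x = x[x > 0]
    if len(x) < 2:
        raise ValueError("need at least 2 (positive) samples")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: zero variance")

    n = len(x)
    if family == "exponential":
        rate = 1.0 / x.mean()
        ll = float(sps.expon(scale=1.0 / rate).logpdf(x).sum())
        params = {"rate": float(rate)}
    elif family == "normal":
        mu = float(x.mean())
        sigma = float(x.std(ddof=0))
        ll = float(sps.norm(loc=mu, scale=sigma).logpdf(x).sum())
        params = {"mean": mu, "sd": sigma}
    else:  # lognormal
        lx = np.log(x)
        mu = float(lx.mean())
        sigma = float(lx.std(ddof=0))
        if sigma == 0:
            raise ValueError("degenerate sample: zero variance of logs")
        ll = float(sps.lognorm(s=sigma, scale=np.exp(mu)).logpdf(x).sum())
        params = {"log_mean": mu, "log_sd": sigma}
    return FitResult(family=family, params=params, log_likelihood=ll, n=n, n_excluded=n_excluded)


def compare_families(
    samples: Sequence[float], families: Sequence[str] = FAMILIES
) -> list[FitResult]:
    """Fit several families and rank them by total log likelihood, descending.

    All families here have two parameters, so the bare log likelihoods are
    directly comparable (no AIC/BIC penalty).  Sorting is stable: ties keep
    the requested order.
    """
    if len(families) < 2:
        raise ValueError("need at least 2 families to compare")
    fits = [fit_family(samples, f) for f in families]
    return sorted(fits, key=lambda f: -f.log_likelihood)


def weight_distance_fit(c: Connectome, model: str = "exponential") -> DecayFit:
    """Fit the link weight-distance decay by OLS on log-transformed data.

    exponential: ``ln w = a - d/lambda`` (lambda = -1/slope);
    powerlaw:    ``ln w = a - gamma ln d`` (gamma = -slope).
    Only links with positive weight and positive, finite distance enter the
    fit; the number excluded is reported.  R^2 is computed in the
    transformed space, matching a linear fit on a log plot.
    """
    if model not in ("exponential", "powerlaw"):
        raise ValueError(f"model must be 'exponential' or 'powerlaw', got {model!r}")
    if c.D is None:
        raise ValueError("connectome has no distance matrix; run compute_distances first")
    ss, tt = np.nonzero(c.W)
    w = c.W[ss, tt]
    d = c.D[ss, tt]
    ok = (w > 0) & (d > 0) & np.isfinite(d)
    n_excluded = int(len(w) - ok.sum())
    w, d = w[ok], d[ok]
    if len(w) < 3:
        raise ValueError("fewer than 3 usable links for the decay fit")
    if np.ptp(d) == 0:
        raise ValueError("all link distances equal; decay fit undefined")
    y = np.log(w)
    x = d if model == "exponential" else np.log(d)
    res = sps.linregress(x, y)
    r2 = float(res.rvalue**2)
    if model == "exponential":
        if res.slope >= 0:
            lam = float("inf")  # no decay; growth with distance
        else:
            lam = -1.0 / float(res.slope)
        return DecayFit("exponential", lam, None, float(res.intercept), r2, len(w), n_excluded)
    return DecayFit("powerlaw", None, -float(res.slope), float(res.intercept), r2, len(w), n_excluded)
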