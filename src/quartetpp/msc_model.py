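"""Coalescent probability model for quartet frequencies around a branch.

Under the multi-species coalescent, a quartet around an internal branch of
total length ``d`` (coalescent units) shows the species-tree topology in a
gene tree with probability ``theta = 1 - (2/3) exp(-d)`` and each of the
two alternatives with probability ``(1 - theta) / 2``. Treating the
averaged per-branch quartet frequencies z = (z1, z2, z3) as the outcome of
``n`` multinomial trials, and putting a Yule-process prior with speciation
rate ``lambda`` on branch lengths — which induces the prior density
``f(t) = lam * (3(1-t)/2)**(2*lam - 1)`` on theta over [1/3, 1], flat for
lam = 1/2 — the posterior probability that the branch is in the species
tree has the closed form

    pp1 = h(z1) / (h(z1) + 2**(z2-z1) h(z2) + 2**(z3-z1) h(z3)),
    h(x) = B(x+1, n-x+2*lam) * (1 - I_{1/3}(x+1, n-x+2*lam)),

with B the beta function and I the regularized incomplete beta. All
arithmetic is done in log space; the incomplete-beta complement is
evaluated with swapped arguments at 2/3 to avoid cancellation. Conditional
on the branch being correct, the ML and MAP lengths are
``-ln(3/2 (1 - z1/n))`` and ``-ln(3/2 (1 - z1/(n + 2*lam)))``, zero at and
below the thresholds z1 = n/3 and z1 = (n + 2*lam)/3.

Fractional z values are supported throughout (missing data makes the
averages non-integer); gamma-function continuation replaces factorials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate
from scipy.special import betainc, betaln, logsumexp

__all__ = [
    "PriorConfig",
    "PosteriorTriple",
    "LengthEstimates",
    "theta_from_length",
    "length_from_theta",
    "yule_prior_density",
    "log_h",
    "local_pp",
    "local_pp_numeric",
    "branch_length_estimates",
]

THETA_MIN = 1.0 / 3.0

#: default cap substituted for an infinite length estimate (z1 == n)
DEFAULT_LENGTH_CAP = 10.0


@dataclass(frozen=True)
class PriorConfig:
    """Yule speciation rate (per coalescent time unit); 1/2 is a flat prior."""

    lam: float = 0.5

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("Yule rate lambda must be positive")


@dataclass(frozen=True)
class PosteriorTriple:
    """Local posterior probabilities aligned with (Q, Q2, Q3)."""

    pp1: float
    pp2: float
    pp3: float

    @property
    def values(self) -> tuple[float, float, float]:
        return (self.pp1, self.pp2, self.pp3)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.pp1)

    @staticmethod
    def undefined() -> "PosteriorTriple":
        nan = float("nan")
        return PosteriorTriple(nan, nan, nan)


@dataclass(frozen=True)
class LengthEstimates:
    """ML and MAP internal branch lengths in coalescent units.

    ``capped`` flags a z1 = n case where the raw estimate is infinite and a
    finite cap was substituted (newick consumers reject "inf").
    """

    ml: float
    map: float
    capped: bool = False


# ---------------------------------------------------------------------------
# theta <-> length


def theta_from_length(d: float) -> float:
    """P(dominant quartet topology) for internal branch length d >= 0."""
    if d < 0:
        raise ValueError("branch length must be non-negative")
    return 1.0 - (2.0 / 3.0) * math.exp(-d)


def length_from_theta(theta: float) -> float:
    """Inverse map; theta below 1/3 clamps to 0, theta = 1 gives +inf."""
    if theta > 1.0:
        raise ValueError("theta cannot exceed 1")
    if theta < THETA_MIN:
        return 0.0
    if theta == 1.0:
        return math.inf
    return -math.log(1.5 * (1.0 - theta))


# ---------------------------------------------------------------------------
# prior


def yule_prior_density(t: float, prior: PriorConfig = PriorConfig()) -> float:
    """Prior density of theta at t on [1/3, 1] induced by the Yule process.

    Integrates to 1/3 over [1/3, 1]: each of the three topologies is equally
    likely a priori, and this density covers the one where the branch is
    present. Constant 1/2 when lam = 1/2.
    """
    if not (THETA_MIN <= t <= 1.0):
        raise ValueError("theta must lie in [1/3, 1]")
    lam = prior.lam
    return lam * (3.0 * (1.0 - t) / 2.0) ** (2.0 * lam - 1.0)


# ---------------------------------------------------------------------------
# posterior, closed form


def log_h(x: float, n: float, prior: PriorConfig = PriorConfig()) -> float:
    """log of h(x) = B(x+1, n-x+2*lam) * (1 - I_{1/3}(x+1, n-x+2*lam)).

    The complement of the incomplete beta is evaluated as I_{2/3}(b, a),
    which is accurate when I_{1/3}(a, b) is close to 1. For extreme skew the
    tail can underflow in double precision; it is then bounded below through
    the log of the leading series term, keeping log_h finite.
    """
    if x < 0 or x > n:
        raise ValueError("require 0 <= x <= n")
    a = x + 1.0
    b = n - x + 2.0 * prior.lam
    tail = betainc(b, a, 2.0 / 3.0)
    if tail > 0.0:
        log_tail = math.log(tail)
    else:
        # I_{2/3}(b, a) >= (2/3)^b (1/3)^(a-1) / (b B(b, a)); log of that bound
        log_tail = (
            b * math.log(2.0 / 3.0)
            + (a - 1.0) * math.log(1.0 / 3.0)
            - math.log(b)
            - betaln(b, a)
        )
    return betaln(a, b) + log_tail


def local_pp(
    z: tuple[float, float, float],
    n: float,
    prior: PriorConfig = PriorConfig(),
    tol: float = 1e-9,
) -> PosteriorTriple:
    """Closed-form local posterior probabilities for the three topologies.

    pp_j is proportional to 2**z_j * h(z_j); the triple is normalized in log
    space. n <= 0 (no effective genes) yields the flagged undefined triple.
    """
    if n <= 0:
        return PosteriorTriple.undefined()
    if any(zj < 0 for zj in z):
        raise ValueError("quartet frequencies must be non-negative")
    if sum(z) > n * (1.0 + 1e-12) + tol:
        raise ValueError("z1 + z2 + z3 exceeds the trial count n")
    logs = np.array(
        [zj * math.log(2.0) + log_h(min(zj, n), n, prior) for zj in z]
    )
    pps = np.exp(logs - logsumexp(logs))
    pps /= pps.sum()
    return PosteriorTriple(*pps)


# ---------------------------------------------------------------------------
# posterior, numeric-integration oracle


def local_pp_numeric(
    z: tuple[float, float, float],
    n: float,
    prior: PriorConfig = PriorConfig(),
) -> PosteriorTriple:
    """Posterior by adaptive quadrature of the multinomial-likelihood integrals.

    For each topology j integrates t**z_j * ((1-t)/2)**(n-z_j) * f(t) over
    t in [1/3, 1] (the shared multinomial coefficient cancels) and normalizes
    across the three. Integrands are rescaled by their joint log maximum so
    large n does not underflow. Independent of the closed form; used as its
    oracle.
    """
    if n <= 0:
        return PosteriorTriple.undefined()

    def log_kernel(t: float, zj: float) -> float:
        if t >= 1.0:
            t = 1.0 - 1e-15
        return zj * math.log(t) + (n - zj) * math.log((1.0 - t) / 2.0)

    grid = np.linspace(THETA_MIN, 1.0 - 1e-9, 513)
    log_max = max(
        log_kernel(t, zj) + math.log(yule_prior_density(t, prior))
        for zj in z
        for t in grid
    )
    vals = []
    for zj in z:
        f = lambda t: math.exp(
            log_kernel(t, zj) + math.log(yule_prior_density(t, prior)) - log_max
        )
        val, _ = integrate.quad(f, THETA_MIN, 1.0, limit=200)
        vals.append(val)
    total = sum(vals)
    return PosteriorTriple(*(v / total for v in vals))


# ---------------------------------------------------------------------------
# branch lengths


def branch_length_estimates(
    z1: float,
    n: float,
    prior: PriorConfig = PriorConfig(),
    length_cap: Optional[float] = DEFAULT_LENGTH_CAP,
) -> LengthEstimates:
    """ML and MAP branch lengths (coalescent units) from the dominant count.

    ML   = -ln(3/2 (1 - z1/n))            if z1 >= n/3, else 0
    MAP  = -ln(3/2 (1 - z1/(n + 2 lam)))  if z1 >= (n + 2 lam)/3, else 0

    Both are continuous in z1 and vanish exactly at their thresholds. When
    z1 = n the ML estimate is infinite and is reported as ``length_cap``
    (pass None to keep the raw infinity), with ``capped=True``.
    """
    if not (0 <= z1 <= n):
        raise ValueError("require 0 <= z1 <= n")
    ml = length_from_theta(min(z1 / n, 1.0))
    map_ = length_from_theta(z1 / (n + 2.0 * prior.lam))
    capped = False
    if length_cap is not None:
        if math.isinf(ml):
            ml, capped = length_cap, True
        if math.isinf(map_):
            map_, capped = length_cap, True
        ml = min(ml, length_cap)
        map_ = min(map_, length_cap)
    return LengthEstimates(ml=ml, map=map_, capped=capped)
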