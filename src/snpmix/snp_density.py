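"""Semi-nonparametric (SNP) density family.

A semi-nonparametric density of order ``K`` is a squared, truncated Hermite
polynomial modulating a Gaussian kernel:

    f(z) = [ sum_{j=0}^{K} a_j w^j ]^2  phi(w) / v,      w = (z - u) / v,

where ``phi`` is the standard normal density, ``u`` is a location, ``v > 0``
a scale, and the polynomial coefficients satisfy the unit-integral
restriction E[P(Z)^2] = 1 for Z ~ N(0, 1).  With K = 0 the family is exactly
Gaussian; K = 1 adds skewness; K = 2 additionally admits heavy tails and
bimodality.  The restriction is enforced automatically through a
trigonometric (angle) parameterization of the coefficients, which keeps the
parameter space unconstrained and the likelihood smooth.

This module provides the angle-to-coefficient transform, log-density,
closed-form moments and CDF, and inverse-CDF sampling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "SNPParams",
    "coeffs_from_angles",
    "restriction_value",
    "snp_logpdf",
    "snp_pdf",
    "snp_moments",
    "snp_cdf",
    "snp_sample",
]

_SQRT2 = math.sqrt(2.0)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

#: Standard normal moments E[Z^k] for k = 0..6 (odd moments vanish).
_NORM_MOM = np.array([1.0, 0.0, 1.0, 0.0, 3.0, 0.0, 15.0])


def coeffs_from_angles(K: int, angles: Sequence[float]) -> np.ndarray:
    """Map the angle parameterization to polynomial coefficients (a_0..a_K).

    The transform guarantees the unit-integral restriction
    ``E[(sum_j a_j Z^j)^2] = 1`` for standard normal Z, for every angle
    vector:

    * K = 0:  a_0 = 1 (the density is exactly standard normal).
    * K = 1:  a_0 = sin(phi), a_1 = cos(phi).
    * K = 2:  a_0 = sin(phi1) - cos(phi1) cos(phi2) / sqrt(2),
              a_1 = cos(phi1) sin(phi2),
              a_2 = cos(phi1) cos(phi2) / sqrt(2).

    Angles are periodic and intentionally unconstrained.
    """
    angles = tuple(float(a) for a in angles)
    if len(angles) != K:
        raise ValueError(f"expected {K} angles, got {len(angles)}")
    if K == 0:
        return np.array([1.0])
    if K == 1:
        (phi,) = angles
        return np.array([math.sin(phi), math.cos(phi)])
    if K == 2:
        p1, p2 = angles
        c1 = math.cos(p1)
        return np.array(
            [
                math.sin(p1) - c1 * math.cos(p2) / _SQRT2,
                c1 * math.sin(p2),
                c1 * math.cos(p2) / _SQRT2,
            ]
        )
    raise ValueError(f"unsupported tuning order K={K}; must be 0, 1 or 2")


def restriction_value(coeffs: np.ndarray) -> float:
    """E[P(Z)^2] for Z ~ N(0,1); equals 1 for valid SNP coefficients."""
    a = np.asarray(coeffs, dtype=float)
    n = len(a)
    # sum_{j,k} a_j a_k E[Z^{j+k}]
    return float(sum(a[j] * a[k] * _NORM_MOM[j + k] for j in range(n) for k in range(n)))


@dataclass(frozen=True)
class SNPParams:
    """Parameters of one semi-nonparametric density.

    Attributes
    ----------
    K : int
        Hermite truncation order, one of {0, 1, 2}.
    angles : tuple of float
        Angle parameterization of the polynomial coefficients; length K.
    u : float
        Location.
    v : float
        Scale, strictly positive.
    """

    K: int
    angles: tuple[float, ...]
    u: float
    v: float
    _coeffs: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.K not in (0, 1, 2):
            raise ValueError(f"K must be 0, 1 or 2, got {self.K}")
        object.__setattr__(self, "angles", tuple(float(a) for a in self.angles))
        if len(self.angles) != self.K:
            raise ValueError(f"expected {self.K} angles, got {len(self.angles)}")
        if not (self.v > 0):
            raise ValueError(f"scale v must be positive, got {self.v}")
        object.__setattr__(self, "_coeffs", coeffs_from_angles(self.K, self.angles))

    @property
    def coeffs(self) -> np.ndarray:
        """Polynomial coefficients (a_0, ..., a_K) implied by the angles."""
        return self._coeffs

    def to_dict(self) -> dict:
        return {"K": self.K, "angles": list(self.angles), "u": self.u, "v": self.v}

    @classmethod
    def from_dict(cls, d: dict) -> "SNPParams":
        return cls(K=int(d["K"]), angles=tuple(d["angles"]), u=float(d["u"]), v=float(d["v"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "SNPParams":
        return cls.from_dict(json.loads(s))


def _poly_eval(coeffs: np.ndarray, w: np.ndarray) -> np.ndarray:
    # np.polyval wants highest-order first
    return np.polyval(coeffs[::-1], w)


def snp_logpdf(p: SNPParams, z) -> np.ndarray | float:
    """Log-density of the SNP density at ``z`` (scalar or array).

    Returns -inf at exact zeros of the Hermite polynomial (the density
    vanishes there); callers accumulating responsibilities should floor
    the value before exponentiating.
    """
    z_arr = np.asarray(z, dtype=float)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        w = (z_arr - p.u) / p.v
        if p.K == 0:  # plain Gaussian, skip polynomial machinery
            out = -0.5 * w * w - math.log(p.v) - _LOG_SQRT_2PI
        else:
            P = _poly_eval(p.coeffs, w)
            logP2 = np.where(P == 0.0, -np.inf, 2.0 * np.log(np.abs(np.where(P == 0.0, 1.0, P))))
            out = logP2 - 0.5 * w * w - math.log(p.v) - _LOG_SQRT_2PI
        out = np.where(np.isnan(out), -np.inf, out)
    return out if z_arr.ndim else float(out)


def snp_pdf(p: SNPParams, z) -> np.ndarray | float:
    """Density of the SNP density at ``z``."""
    lp = snp_logpdf(p, z)
    return np.exp(lp)


def _core_moments(coeffs: np.ndarray) -> tuple[float, float]:
    """(E[W], E[W^2]) of the standardized SNP core with coefficients a."""
    a = np.pad(np.asarray(coeffs, dtype=float), (0, 3 - len(coeffs)))
    a0, a1, a2 = a
    m1 = 2.0 * a0 * a1 + 6.0 * a1 * a2
    m2 = a0**2 + 3.0 * (a1**2 + 2.0 * a0 * a2) + 15.0 * a2**2
    return m1, m2


def snp_moments(p: SNPParams) -> tuple[float, float]:
    """Exact (mean, sd) of the SNP density via Gaussian moment algebra.

    With P(w) = sum a_j w^j and Z ~ N(0,1):
    E[Z P(Z)^2] = 2 a0 a1 + 6 a1 a2 and
    E[Z^2 P(Z)^2] = a0^2 + 3(a1^2 + 2 a0 a2) + 15 a2^2,
    so mean = u + v m1 and sd = v sqrt(m2 - m1^2).
    """
    m1, m2 = _core_moments(p.coeffs)
    return p.u + p.v * m1, p.v * math.sqrt(m2 - m1 * m1)


def snp_cdf(p: SNPParams, z) -> np.ndarray | float:
    """CDF of the SNP density, in closed form.

    P(w)^2 phi(w) integrates termwise: with P^2 = sum_k c_k w^k (k <= 4),
    each incomplete moment I_k(x) = int_{-inf}^x w^k phi(w) dw is a
    polynomial-in-x combination of phi(x) and Phi(x).
    """
    z_arr = np.asarray(z, dtype=float)
    x = (z_arr - p.u) / p.v
    c = np.polynomial.polynomial.polymul(p.coeffs, p.coeffs)  # c_0..c_{2K}
    c = np.pad(c, (0, 5 - len(c)))
    Phi = norm.cdf(x)
    phi = norm.pdf(x)
    I = [
        Phi,
        -phi,
        Phi - x * phi,
        -(x**2 + 2.0) * phi,
        3.0 * Phi - (x**3 + 3.0 * x) * phi,
    ]
    out = sum(ck * Ik for ck, Ik in zip(c, I))
    out = np.clip(out, 0.0, 1.0)
    return out if z_arr.ndim else float(out)


def snp_sample(p: SNPParams, n: int, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. samples via inverse-CDF on a dense grid.

    The closed-form CDF is tabulated on 8001 points over [u - 10v, u + 10v]
    and inverted by linear interpolation; the grid is deterministic, so the
    draw is fully reproducible given the seed.  ``seed`` may be an int or a
    ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = np.linspace(p.u - 10.0 * p.v, p.u + 10.0 * p.v, 8001)
    cdf = np.asarray(snp_cdf(p, grid))
    # strictly increasing table for interpolation (flats at density zeros)
    cdf_m = np.maximum.accumulate(cdf)
    uu = rng.uniform(size=n)
    return np.interp(uu, cdf_m, grid)
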