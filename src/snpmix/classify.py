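"""Posterior classification of proteins with FDR/FNR control.

Given the fitted mixture, each protein's posterior probability of being
inconsistent is

    P(R_i = 1 | z_i) = lambda1 f1(z_i) / (lambda0 f0(z_i) + lambda1 f1(z_i)),

and a protein is declared inconsistent when its posterior exceeds a cutoff
c*.  The estimated error rates of a declaration vector delta are

    FDR_hat = sum (1 - p_i) delta_i / sum delta_i
    FNR_hat = sum p_i (1 - delta_i) / sum (1 - delta_i),

and the cutoff is chosen by sweeping the number d of declared proteins
(equivalently, the posterior order statistics) and minimizing the cost

    gamma FDR_hat d/m + (1 - gamma) FNR_hat (m - d)/m.

A 2:1 penalty of false discoveries over false non-discoveries corresponds
to gamma = 2/3 (exposed as ``GAMMA_COST_2TO1``).  When the true labels are
known (simulations), realized FDR = V/R and FNR = T/(m - R) are computed
from the classification contingency counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixture import MixtureModel, e_step

__all__ = [
    "GAMMA_COST_2TO1",
    "TruthLabels",
    "ClassificationResult",
    "posteriors",
    "estimate_fdr_fnr",
    "min_cost_threshold",
    "true_error_rates",
]

#: gamma implementing a 2:1 cost ratio of false discovery to false non-discovery
GAMMA_COST_2TO1 = 2.0 / 3.0


@dataclass(frozen=True)
class TruthLabels:
    protein_id: np.ndarray
    inconsistent: np.ndarray  # 0/1


@dataclass
class ClassificationResult:
    protein_id: np.ndarray
    posterior_inconsistent: np.ndarray
    delta: np.ndarray  # 0/1 declarations
    d: int
    fdr_hat: float
    fnr_hat: float
    cutoff: float
    gamma: float
    cost_curve: pd.DataFrame  # columns d, fdr_hat, fnr_hat, cost
    fdr_defined: bool = True
    fnr_defined: bool = True


def posteriors(m: MixtureModel, z) -> np.ndarray:
    """Posterior probability of inconsistency per protein (log-sum-exp guarded)."""
    return e_step(m, z)


def estimate_fdr_fnr(post, delta) -> tuple[float, float]:
    """Posterior-based estimates of FDR and FNR for a declaration vector.

    A side whose denominator is zero (nothing declared, or everything
    declared) is returned as 0.0; ``min_cost_threshold`` tracks definedness
    flags where that distinction matters.
    """
    post = np.asarray(post, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if post.shape != delta.shape:
        raise ValueError("posterior and declaration vectors must align")
    nd = delta.sum()
    nc = (1.0 - delta).sum()
    fdr = float(((1.0 - post) * delta).sum() / nd) if nd > 0 else 0.0
    fnr = float((post * (1.0 - delta)).sum() / nc) if nc > 0 else 0.0
    return fdr, fnr


def min_cost_threshold(post, gamma: float = 0.5, protein_id=None) -> ClassificationResult:
    """Sweep every achievable declared count d and minimize the expected cost.

    Declaring the d largest posteriors inconsistent makes the cutoff and
    the count equivalent; the sweep over d = 0..m is exact and finite.
    Cost ties break toward smaller d.
    """
    if not (0.0 <= gamma <= 1.0):
        raise ValueError("gamma must lie in [0, 1]")
    post = np.asarray(post, dtype=float)
    m = post.size
    pid = np.arange(m) if protein_id is None else np.asarray(protein_id)
    order = np.argsort(-post, kind="stable")
    p_sorted = post[order]
    csum = np.concatenate([[0.0], np.cumsum(p_sorted)])
    total = csum[-1]
    d_all = np.arange(m + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fdr = np.where(d_all > 0, (d_all - csum) / np.maximum(d_all, 1), 0.0)
        rem = m - d_all
        fnr = np.where(rem > 0, (total - csum) / np.maximum(rem, 1), 0.0)
    cost = gamma * fdr * d_all / m + (1.0 - gamma) * fnr * (m - d_all) / m
    d_star = int(np.argmin(cost))  # argmin returns the first (smallest d) tie
    delta = np.zeros(m, dtype=int)
    delta[order[:d_star]] = 1
    if d_star == 0:
        cutoff = 1.0
    elif d_star == m:
        cutoff = float(p_sorted[-1])
    else:
        cutoff = float(0.5 * (p_sorted[d_star - 1] + p_sorted[d_star]))
    curve = pd.DataFrame({"d": d_all, "fdr_hat": fdr, "fnr_hat": fnr, "cost": cost})
    return ClassificationResult(
        protein_id=pid,
        posterior_inconsistent=post,
        delta=delta,
        d=d_star,
        fdr_hat=float(fdr[d_star]),
        fnr_hat=float(fnr[d_star]),
        cutoff=cutoff,
        gamma=gamma,
        cost_curve=curve,
        fdr_defined=d_star > 0,
        fnr_defined=d_star < m,
    )


def true_error_rates(stat, truth: TruthLabels | np.ndarray, d: int,
                     direction: str = "higher-is-inconsistent") -> tuple[float, float]:
    """Realized FDR and FNR when the d most-extreme proteins are declared.

    With R = d declared inconsistent, V truly-consistent among them and T
    truly-inconsistent among the rest, returns (V/R, T/(m-R)), each 0 when
    its denominator is 0.  Ties in the statistic break by stable input
    order.
    """
    stat = np.asarray(stat, dtype=float)
    labels = truth.inconsistent if isinstance(truth, TruthLabels) else truth
    labels = np.asarray(labels, dtype=int)
    m = stat.size
    if labels.size != m:
        raise ValueError("statistic and truth vectors must align")
    if not (0 <= d <= m):
        raise ValueError("d must lie in [0, m]")
    if direction == "higher-is-inconsistent":
        order = np.argsort(-stat, kind="stable")
    elif direction == "lower-is-inconsistent":
        order = np.argsort(stat, kind="stable")
    else:
        raise ValueError(f"unknown direction {direction!r}")
    declared = np.zeros(m, dtype=bool)
    declared[order[:d]] = True
    V = int((declared & (labels == 0)).sum())
    T = int((~declared & (labels == 1)).sum())
    fdr = V / d if d > 0 else 0.0
    fnr = T / (m - d) if d < m else 0.0
    return float(fdr), float(fnr)
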