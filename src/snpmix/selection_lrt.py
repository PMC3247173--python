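"""Model selection over SNP tuning orders and the bootstrap likelihood-ratio test.

Whether the consistency statistics actually separate into two components is
decided by a likelihood-ratio test of

    H0: one component   vs.   Ha: two components,

with both hypotheses fitted at their information-criterion-best tuning
orders (K in {0,1,2} for the null; the 9 (K0,K1) pairs for the
alternative).  Because the mixing proportion sits on the boundary under H0
the usual chi-square calibration fails, so the null distribution of
-2 log(lambda) is approximated by a parametric bootstrap from the fitted
null density (500 replicates by default).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .mixture import FitConfig, MixtureModel, SingleFit, fit_em, fit_single
from .snp_density import snp_sample

__all__ = [
    "SelectionResult",
    "LRTResult",
    "info_criterion",
    "count_params",
    "select_model",
    "lrt_stat",
    "bootstrap_null",
    "lrt_pvalue",
    "bootstrap_lrt",
]

log = logging.getLogger(__name__)

_CRITERIA = ("aic", "bic", "hq")


def info_criterion(loglik: float, p: int, N: int, which: str) -> float:
    """Penalized log-likelihood -2 logL + C(N) p.

    C(N) = 2 for AIC, log(N) for BIC, 2 log(log(N)) for HQ (natural logs).
    """
    which = which.lower()
    if N < 2 or p < 1:
        raise ValueError("need N >= 2 and p >= 1")
    if which == "aic":
        c = 2.0
    elif which == "bic":
        c = math.log(N)
    elif which == "hq":
        c = 2.0 * math.log(math.log(N))
    else:
        raise ValueError(f"unknown criterion {which!r}; expected one of {_CRITERIA}")
    return -2.0 * loglik + c * p


def count_params(K0: int, K1: int | None = None) -> int:
    """Free-parameter count: (u, v, K angles) per component, plus lambda for a mixture."""
    for K in (K0,) if K1 is None else (K0, K1):
        if K not in (0, 1, 2):
            raise ValueError(f"K must be 0, 1 or 2, got {K}")
    if K1 is None:
        return 2 + K0
    return 1 + (2 + K0) + (2 + K1)


@dataclass(frozen=True)
class SelectionResult:
    criterion: str
    best_null: SingleFit
    best_null_K: int
    best_alt: MixtureModel
    best_alt_K: tuple[int, int]
    score_table: dict  # {"null": {K: score}, "alt": {(K0,K1): score}}


@dataclass(frozen=True)
class LRTResult:
    stat: float
    boot_stats: np.ndarray
    p_value: float
    reject: bool
    alpha: float


def select_model(z, criterion: str = "bic", cfg: FitConfig | None = None,
                 null_Ks=(0, 1, 2), alt_Ks=None) -> SelectionResult:
    """Fit every candidate tuning order and keep the criterion minimizers.

    All three single-density nulls and all nine (K0, K1) mixture
    alternatives are fitted; ties in the criterion break toward smaller
    total K (parsimony).  A candidate whose fit raises is excluded with a
    logged warning; if every candidate on a side fails, an error is raised.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    cfg = cfg or FitConfig()
    if alt_Ks is None:
        alt_Ks = list(itertools.product((0, 1, 2), repeat=2))
    null_scores: dict[int, float] = {}
    null_fits: dict[int, SingleFit] = {}
    for K in null_Ks:
        try:
            f = fit_single(z, K, cfg)
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("null fit K=%d failed: %s", K, exc)
            continue
        null_fits[K] = f
        null_scores[K] = info_criterion(f.loglik, count_params(K), z.size, criterion)
    alt_scores: dict[tuple[int, int], float] = {}
    alt_fits: dict[tuple[int, int], MixtureModel] = {}
    for K0, K1 in alt_Ks:
        try:
            m = fit_em(z, K0, K1, cfg)
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("mixture fit K=(%d,%d) failed: %s", K0, K1, exc)
            continue
        alt_fits[(K0, K1)] = m
        alt_scores[(K0, K1)] = info_criterion(m.loglik, count_params(K0, K1), z.size, criterion)
    if not null_fits or not alt_fits:
        raise RuntimeError("all candidate fits failed")
    bn = min(sorted(null_scores), key=lambda K: (null_scores[K], K))
    ba = min(sorted(alt_scores), key=lambda p: (alt_scores[p], p[0] + p[1]))
    return SelectionResult(
        criterion=criterion.lower(),
        best_null=null_fits[bn],
        best_null_K=bn,
        best_alt=alt_fits[ba],
        best_alt_K=ba,
        score_table={"null": null_scores, "alt": alt_scores},
    )


def lrt_stat(null_fit: SingleFit, alt_fit: MixtureModel) -> float:
    """-2 log(lambda) = 2 (loglik_alt - loglik_null)."""
    return 2.0 * (alt_fit.loglik - null_fit.loglik)


def lrt_pvalue(stat: float, boot_stats) -> float:
    """Add-one bootstrap p-value (1 + #{boot >= stat}) / (B + 1)."""
    boot = np.atleast_1d(np.asarray(boot_stats, dtype=float))
    if boot.size == 0:
        raise ValueError("empty bootstrap vector")
    return float((1 + int((boot >= stat).sum())) / (boot.size + 1))


def bootstrap_null(null_fit: SingleFit, n: int, B: int = 500, criterion: str = "bic",
                   cfg: FitConfig | None = None, seed: int = 0,
                   alt_K: tuple[int, int] = (0, 0), full_selection: bool = False) -> np.ndarray:
    """Likelihood-ratio statistics under the fitted one-component null.

    Each replicate draws ``n`` points from the fitted null density and
    recomputes the test statistic.  By default both hypotheses are refitted
    at the tuning orders already selected on the observed data (``null_fit``'s
    K and ``alt_K``), the standard parametric-bootstrap practice for mixture
    LRTs; ``full_selection=True`` instead reruns the complete
    information-criterion search on every replicate.  Because the closure of
    the two-component family contains every single density (a boundary
    mixing proportion), each replicate's alternative log-likelihood is
    floored at its null log-likelihood, keeping the statistics nonnegative.
    A replicate whose fits fail is redrawn up to 3 times, then dropped with
    a warning.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    cfg = cfg or FitConfig()
    rng = np.random.default_rng(seed)
    stats = []
    for b in range(B):
        for attempt in range(4):
            zb = snp_sample(null_fit.params, n, rng)
            try:
                if full_selection:
                    sel = select_model(zb, criterion, cfg)
                    nf, af = sel.best_null, sel.best_alt
                else:
                    nf = fit_single(zb, null_fit.params.K, cfg)
                    af = fit_em(zb, alt_K[0], alt_K[1], cfg)
                stats.append(max(lrt_stat(nf, af), 0.0))
                break
            except Exception as exc:
                if attempt == 3:
                    log.warning("bootstrap replicate %d dropped after retries: %s", b, exc)
    return np.asarray(stats)


def bootstrap_lrt(z, criterion: str = "bic", B: int = 500, alpha: float = 0.05,
                  cfg: FitConfig | None = None, seed: int = 0,
                  full_selection: bool = False) -> tuple[LRTResult, SelectionResult]:
    """Full test: select models on the data, bootstrap the null, compare.

    Rejects when the observed statistic exceeds the empirical (1 - alpha)
    quantile of the bootstrap null statistics.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    sel = select_model(z, criterion, cfg)
    stat = lrt_stat(sel.best_null, sel.best_alt)
    boot = bootstrap_null(sel.best_null, z.size, B, criterion, cfg, seed,
                          alt_K=sel.best_alt_K, full_selection=full_selection)
    p = lrt_pvalue(stat, boot)
    thresh = float(np.quantile(boot, 1.0 - alpha)) if boot.size else np.inf
    return (
        LRTResult(stat=stat, boot_stats=boot, p_value=p, reject=bool(stat > thresh), alpha=alpha),
        sel,
    )
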