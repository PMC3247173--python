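"""Two-component SNP mixture likelihood and EM-gradient fitting.

The observed statistics z_1..z_m are modelled as draws from

    f(z) = lambda0 f0(z | theta0) + lambda1 f1(z | theta1),

where f0 (consistent component, smaller mean) and f1 (inconsistent
component) are semi-nonparametric densities and lambda0 + lambda1 = 1.

Fitting follows an EM scheme in which the M-step is a single Newton-like
step on each component's expected complete-data log-likelihood Q, with the
curvature corrected by Davidon's rank-one quasi-Newton update.  The mixing
proportion has a closed-form maximizer (the mean responsibility) and is
updated exactly.  Steps are safeguarded so the observed-data log-likelihood
never decreases: a step that would decrease it is halved (up to 20 times)
and, failing that, replaced by a bounded numerical maximization of Q.

Component scales are optimized on the log scale so every quasi-Newton
iterate stays in the valid parameter space; angles are unconstrained
(the coefficient transform is periodic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .snp_density import SNPParams, _core_moments, coeffs_from_angles, snp_logpdf, snp_moments

__all__ = [
    "FitConfig",
    "MixtureModel",
    "SingleFit",
    "mixture_loglik",
    "e_step",
    "m_step",
    "fit_em",
    "fit_single",
]

#: floor for log-densities (smallest exponent exp() can represent)
_LOG_FLOOR = -745.0


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the EM fitter.

    max_iter : EM iteration cap (default 500).
    tol : relative observed log-likelihood change declaring convergence.
    n_starts : number of multistart initializations.
    seed : seed for the start-jitter RNG.
    """

    max_iter: int = 500
    tol: float = 1e-8
    n_starts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (self.tol > 0):
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class MixtureModel:
    """A fitted (or candidate) two-component SNP mixture."""

    comp0: SNPParams
    comp1: SNPParams
    lambda0: float
    loglik: float = float("nan")
    n_iter: int = 0
    converged: bool = False
    boundary: bool = False

    def to_dict(self) -> dict:
        return {
            "comp0": self.comp0.to_dict(),
            "comp1": self.comp1.to_dict(),
            "lambda0": self.lambda0,
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        return cls(
            comp0=SNPParams.from_dict(d["comp0"]),
            comp1=SNPParams.from_dict(d["comp1"]),
            lambda0=float(d["lambda0"]),
            loglik=float(d.get("loglik", float("nan"))),
            n_iter=int(d.get("n_iter", 0)),
            converged=bool(d.get("converged", False)),
        )


@dataclass(frozen=True)
class SingleFit:
    """Maximum-likelihood fit of a single SNP density (the one-component null)."""

    params: SNPParams
    loglik: float
    converged: bool = True


# ---------------------------------------------------------------------------
# likelihood pieces
# ---------------------------------------------------------------------------


def _log_components(m: MixtureModel, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lf0 = np.maximum(np.asarray(snp_logpdf(m.comp0, z)), _LOG_FLOOR)
    lf1 = np.maximum(np.asarray(snp_logpdf(m.comp1, z)), _LOG_FLOOR)
    return lf0, lf1


def mixture_loglik(m: MixtureModel, z) -> float:
    """Observed-data log-likelihood sum_i log[l0 f0(z_i) + l1 f1(z_i)]."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if z.size == 0:
        raise ValueError("empty data vector")
    lf0, lf1 = _log_components(m, z)
    l0 = max(m.lambda0, 1e-300)
    l1 = max(1.0 - m.lambda0, 1e-300)
    return float(np.logaddexp(math.log(l0) + lf0, math.log(l1) + lf1).sum())


def e_step(m: MixtureModel, z) -> np.ndarray:
    """Responsibilities r_i = P(inconsistent | z_i), computed in log space."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    lf0, lf1 = _log_components(m, z)
    l0 = max(m.lambda0, 1e-300)
    l1 = max(1.0 - m.lambda0, 1e-300)
    a0 = math.log(l0) + lf0
    a1 = math.log(l1) + lf1
    r = np.exp(a1 - np.logaddexp(a0, a1))
    return np.clip(r, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Q function, gradient, Hessian in the unconstrained coordinates
# theta = (u, log v, angles...)
# ---------------------------------------------------------------------------


def _theta_of(p: SNPParams) -> np.ndarray:
    return np.array([p.u, math.log(p.v), *p.angles])


def _params_of(K: int, theta: np.ndarray) -> SNPParams:
    return SNPParams(K=K, angles=tuple(theta[2:]), u=float(theta[0]), v=float(math.exp(theta[1])))


def _q_value(K: int, theta: np.ndarray, z: np.ndarray, w: np.ndarray) -> float:
    lf = np.maximum(np.asarray(snp_logpdf(_params_of(K, theta), z)), _LOG_FLOOR)
    return float(np.dot(w, lf))


def _dcoeffs_dangles(K: int, angles: tuple[float, ...]) -> np.ndarray:
    """(K, K+1) array of partial derivatives d a_j / d phi_r."""
    if K == 0:
        return np.zeros((0, 1))
    if K == 1:
        (phi,) = angles
        return np.array([[math.cos(phi), -math.sin(phi)]])
    p1, p2 = angles
    s1, c1 = math.sin(p1), math.cos(p1)
    s2, c2 = math.sin(p2), math.cos(p2)
    r2 = math.sqrt(2.0)
    return np.array(
        [
            [c1 + s1 * c2 / r2, -s1 * s2, -s1 * c2 / r2],
            [c1 * s2 / r2, c1 * c2, -c1 * s2 / r2],
        ]
    )


def _grad_q(K: int, theta: np.ndarray, z: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Analytic gradient of Q(theta) = sum_i w_i log f(z_i | theta)."""
    u, logv = theta[0], theta[1]
    v = math.exp(min(logv, 700.0))
    t = (z - u) / v
    if K == 0:  # Gaussian core: core = -t
        return np.array([np.dot(w, t) / v, np.dot(w, t * t - 1.0)])
    angles = tuple(theta[2:])
    a = coeffs_from_angles(K, angles)
    P = np.polyval(a[::-1], t)
    Pp = np.polyval(np.polyder(a[::-1]), t) if K > 0 else np.zeros_like(t)
    Psafe = np.where(np.abs(P) < 1e-300, np.copysign(1e-300, np.where(P == 0, 1.0, P)), P)
    core = 2.0 * Pp / Psafe - t  # d log f / d t
    g = np.empty(2 + K)
    with np.errstate(over="ignore", invalid="ignore"):
        g[0] = np.dot(w, -core / v)
        g[1] = np.dot(w, -t * core - 1.0)
        da = _dcoeffs_dangles(K, angles)  # (K, K+1)
        # powers t^j for j = 0..K
        tp = np.vander(t, K + 1, increasing=True)  # (n, K+1)
        for r in range(K):
            g[2 + r] = np.dot(w, 2.0 * (tp @ da[r]) / Psafe)
    return g


def _hess_q(K: int, theta: np.ndarray, z: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Hessian of Q: closed form for the Gaussian (K=0) component, central
    differences of the analytic gradient otherwise."""
    if K == 0:
        u, logv = theta
        v = math.exp(logv)
        t = (z - u) / v
        sw = float(w.sum())
        swt = float(np.dot(w, t))
        swt2 = float(np.dot(w, t * t))
        return np.array([[-sw / (v * v), -2.0 * swt / v], [-2.0 * swt / v, -2.0 * swt2]])
    d = len(theta)
    H = np.empty((d, d))
    h = 1e-5
    for j in range(d):
        tp = theta.copy()
        tm = theta.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (_grad_q(K, tp, z, w) - _grad_q(K, tm, z, w)) / (2.0 * h)
    return 0.5 * (H + H.T)


def _maximize_q_numeric(K: int, theta0: np.ndarray, z: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Fallback M-step: bounded quasi-Newton maximization of Q.

    The location and log-scale are boxed to the data range so a component
    cannot collapse onto a single point (unbounded likelihood spike).
    """
    sd = float(z.std()) or 1.0
    lo, hi = float(z.min()), float(z.max())
    bounds = [(lo - 10 * sd, hi + 10 * sd), (math.log(1e-4 * sd), math.log(100 * sd))]
    bounds += [(None, None)] * K
    res = optimize.minimize(
        lambda th: -_q_value(K, th, z, w),
        theta0,
        jac=lambda th: -_grad_q(K, th, z, w),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 40},
    )
    return res.x if np.all(np.isfinite(res.x)) else theta0


# ---------------------------------------------------------------------------
# M-step with Davidon acceleration
# ---------------------------------------------------------------------------


@dataclass
class _DavidonComp:
    """Per-component curvature state carried across EM iterations."""

    B: np.ndarray
    prev_theta: np.ndarray | None = None
    prev_grad: np.ndarray | None = None  # d1Q at prev_theta under the responsibilities of its own iteration


@dataclass
class CurvatureState:
    comp: dict = field(default_factory=dict)

    @classmethod
    def fresh(cls, K0: int, K1: int) -> "CurvatureState":
        return cls(
            comp={
                0: _DavidonComp(B=np.zeros((2 + K0, 2 + K0))),
                1: _DavidonComp(B=np.zeros((2 + K1, 2 + K1))),
            }
        )


def _davidon_update(st: _DavidonComp, K: int, theta_now: np.ndarray, z: np.ndarray, w_now: np.ndarray) -> None:
    """Rank-one update B <- B + a c c' using the gradient of Q at the previous
    iterate evaluated under the new responsibilities minus under the old ones."""
    if st.prev_theta is None:
        return
    s = st.prev_theta - theta_now
    if not np.any(s):
        return
    g_new = _grad_q(K, st.prev_theta, z, w_now)
    gvec = g_new - st.prev_grad
    c = gvec - st.B @ s
    denom = float(c @ s)
    if abs(denom) > 1e-10 * (np.linalg.norm(c) * np.linalg.norm(s) + 1e-30):
        st.B = st.B + np.outer(c, c) / denom


def m_step(m: MixtureModel, z, r, state: CurvatureState | None = None) -> tuple[MixtureModel, CurvatureState]:
    """One safeguarded M-step.

    lambda1 is set to the mean responsibility (its exact maximizer); each
    component's parameters take one EM-gradient step
    theta <- theta - (d2Q - B)^{-1} d1Q with B maintained by Davidon's
    rank-one update.  If a step would decrease the observed-data
    log-likelihood it is halved (<= 20 times), then replaced by numerical
    maximization of Q, and never accepted below the current value.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    r = np.asarray(r, dtype=float)
    if state is None:
        state = CurvatureState.fresh(m.comp0.K, m.comp1.K)
    lam1 = float(np.clip(r.mean(), 1e-8, 1.0 - 1e-8))
    model = replace(m, lambda0=1.0 - lam1)

    # cached per-component log-densities; only the component being updated
    # needs re-evaluation inside the safeguard loop
    lf = list(_log_components(model, z))
    log_lam = (math.log(model.lambda0), math.log(1.0 - model.lambda0))

    def obs_ll(lf0: np.ndarray, lf1: np.ndarray) -> float:
        return float(np.logaddexp(log_lam[0] + lf0, log_lam[1] + lf1).sum())

    # box the iterates: a component collapsing onto a handful of points
    # (v -> 0) creates an unbounded likelihood spike, not a useful ML fit
    sd_z = float(z.std()) or 1.0
    u_box = (float(z.min()) - 10.0 * sd_z, float(z.max()) + 10.0 * sd_z)
    logv_box = (math.log(1e-4 * sd_z), math.log(100.0 * sd_z))

    def in_box(th: np.ndarray) -> bool:
        return u_box[0] <= th[0] <= u_box[1] and logv_box[0] <= th[1] <= logv_box[1]

    comps = [model.comp0, model.comp1]
    for ci, wts in ((0, 1.0 - r), (1, r)):
        K = comps[ci].K
        theta = _theta_of(comps[ci])
        st = state.comp[ci]
        _davidon_update(st, K, theta, z, wts)
        g = _grad_q(K, theta, z, wts)
        ll_cur = obs_ll(lf[0], lf[1])
        theta_accept, lf_accept = theta, lf[ci]
        gnorm = float(np.linalg.norm(g))
        if np.all(np.isfinite(g)) and gnorm > 1e-9 * (1.0 + abs(ll_cur)):
            H = _hess_q(K, theta, z, wts)
            step = None
            # the Davidon-corrected step must be an ascent direction for Q;
            # a rank-one update can spoil the curvature, in which case fall
            # back to the plain Newton step on Q
            for M in (H - st.B, H):
                try:
                    cand = np.linalg.solve(M, g)
                except np.linalg.LinAlgError:
                    continue
                if np.all(np.isfinite(cand)) and float(g @ cand) < 0.0:
                    step = cand
                    break
            if step is not None:
                cand_step = step
                for _ in range(21):
                    if np.all(np.abs(cand_step) <= 1e-14 * (1.0 + np.abs(theta))):
                        break
                    theta_try = theta - cand_step
                    if not in_box(theta_try):
                        cand_step = cand_step / 2.0
                        continue
                    try:
                        comp_try = _params_of(K, theta_try)
                    except (ValueError, OverflowError):
                        cand_step = cand_step / 2.0
                        continue
                    lf_try = np.maximum(np.asarray(snp_logpdf(comp_try, z)), _LOG_FLOOR)
                    pair = (lf_try, lf[1]) if ci == 0 else (lf[0], lf_try)
                    if obs_ll(*pair) >= ll_cur - 1e-10:
                        theta_accept, lf_accept = theta_try, lf_try
                        break
                    cand_step = cand_step / 2.0
            if theta_accept is theta:
                # gradient step failed to improve: numerical Q maximization
                theta_num = _maximize_q_numeric(K, theta, z, wts)
                try:
                    comp_num = _params_of(K, theta_num)
                    lf_num = np.maximum(np.asarray(snp_logpdf(comp_num, z)), _LOG_FLOOR)
                    pair = (lf_num, lf[1]) if ci == 0 else (lf[0], lf_num)
                    if obs_ll(*pair) >= ll_cur - 1e-10:
                        theta_accept, lf_accept = theta_num, lf_num
                except (ValueError, OverflowError):
                    pass
        st.prev_theta = theta
        st.prev_grad = g
        comps[ci] = _params_of(K, theta_accept)
        lf[ci] = lf_accept
    return replace(model, comp0=comps[0], comp1=comps[1]), state


# ---------------------------------------------------------------------------
# full fits
# ---------------------------------------------------------------------------


def _initial_models(z: np.ndarray, K0: int, K1: int, cfg: FitConfig) -> list[MixtureModel]:
    """Median-split initialization plus seeded jittered variants."""
    med = float(np.median(z))
    lo, hi = z[z <= med], z[z > med]
    sd_all = float(z.std()) or 1.0
    if hi.size == 0:  # degenerate (near-constant) data
        hi = lo + sd_all

    def mk(u0, v0, u1, v1, lam0):
        a0 = tuple([math.pi / 2] * K0)
        a1 = tuple([math.pi / 2] * K1)
        v0 = max(v0, 1e-3 * sd_all)
        v1 = max(v1, 1e-3 * sd_all)
        return MixtureModel(
            comp0=SNPParams(K0, a0, u0, v0),
            comp1=SNPParams(K1, a1, u1, v1),
            lambda0=float(np.clip(lam0, 0.05, 0.95)),
        )

    u0, v0 = float(lo.mean()), float(lo.std()) if lo.size > 1 else 0.5 * sd_all
    u1, v1 = float(hi.mean()), float(hi.std()) if hi.size > 1 else 0.5 * sd_all
    starts = [mk(u0, v0 or 0.5 * sd_all, u1, v1 or 0.5 * sd_all, lo.size / z.size)]
    rng = np.random.default_rng(cfg.seed)
    for _ in range(max(cfg.n_starts - 1, 0)):
        j0, j1 = rng.uniform(-0.5, 0.5, 2) * sd_all
        starts.append(mk(u0 + j0, v0 or 0.5 * sd_all, u1 + j1, v1 or 0.5 * sd_all, rng.uniform(0.3, 0.7)))
    return starts


def _order_components(m: MixtureModel) -> MixtureModel:
    if snp_moments(m.comp0)[0] > snp_moments(m.comp1)[0]:
        return replace(m, comp0=m.comp1, comp1=m.comp0, lambda0=1.0 - m.lambda0)
    return m


def fit_em(z, K0: int, K1: int, cfg: FitConfig | None = None) -> MixtureModel:
    """Fit the two-component SNP mixture by safeguarded EM-gradient iteration.

    Runs ``cfg.n_starts`` initializations and keeps the best final
    log-likelihood.  The returned model has mean(comp0) <= mean(comp1)
    (components relabelled if needed) and carries the fit metadata.
    """
    z = np.sort(np.atleast_1d(np.asarray(z, dtype=float)))
    if z.size < 10:
        raise ValueError("need at least 10 observations to fit a mixture")
    cfg = cfg or FitConfig()
    best: MixtureModel | None = None
    for start in _initial_models(z, K0, K1, cfg):
        model = start
        state = CurvatureState.fresh(K0, K1)
        ll_old = mixture_loglik(model, z)
        converged = False
        it = 0
        for it in range(1, cfg.max_iter + 1):
            r = e_step(model, z)
            model, state = m_step(model, z, r, state)
            ll_new = mixture_loglik(model, z)
            if abs(ll_new - ll_old) <= cfg.tol * (abs(ll_old) + 1.0):
                ll_old = ll_new
                converged = True
                break
            ll_old = ll_new
        lam = model.lambda0
        model = replace(
            model,
            loglik=ll_old,
            n_iter=it,
            converged=converged,
            boundary=bool(lam < 1e-3 or lam > 1.0 - 1e-3),
        )
        if best is None or model.loglik > best.loglik:
            best = model
    return _order_components(best)


def fit_single(z, K: int, cfg: FitConfig | None = None) -> SingleFit:
    """Maximum-likelihood single SNP density (the one-component null model).

    K = 0 has the closed-form Gaussian MLE; K >= 1 is fitted by multistart
    L-BFGS-B over (u, log v, angles) with the analytic gradient.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if z.size < 5:
        raise ValueError("need at least 5 observations")
    cfg = cfg or FitConfig()
    mean = float(z.mean())
    sd = float(z.std()) or 1e-6
    if K == 0:
        p = SNPParams(0, (), mean, sd)
        lf = np.asarray(snp_logpdf(p, z))
        return SingleFit(params=p, loglik=float(lf.sum()))
    w = np.ones_like(z)
    rng = np.random.default_rng(cfg.seed)
    # canonical shape starts (normal, skewed both ways, bimodal), each with
    # u and v moment-matched to the sample for that shape
    if K == 1:
        angle_starts = [(math.pi / 2,), (2.17,), (0.97,)]
    else:
        angle_starts = [(math.pi / 2, math.pi / 2), (2.0, 2.75), (4.1, 0.9), (0.97, math.pi / 2)]
    starts = []
    for ang in angle_starts:
        m1, m2 = _core_moments(coeffs_from_angles(K, ang))
        core_sd = math.sqrt(max(m2 - m1 * m1, 1e-6))
        v0 = sd / core_sd
        starts.append(np.array([mean - v0 * m1, math.log(v0), *ang]))
    for _ in range(max(cfg.n_starts - 1, 0)):
        starts.append(
            np.array(
                [
                    mean + rng.uniform(-0.3, 0.3) * sd,
                    math.log(sd) + rng.uniform(-0.3, 0.3),
                    *rng.uniform(0.3, math.pi - 0.3, K),
                ]
            )
        )
    bounds = [
        (float(z.min()) - 10 * sd, float(z.max()) + 10 * sd),
        (math.log(1e-4 * sd), math.log(100 * sd)),
    ] + [(None, None)] * K
    best_theta, best_val, ok = None, -np.inf, False
    for th0 in starts:
        res = optimize.minimize(
            lambda th: -_q_value(K, th, z, w),
            th0,
            jac=lambda th: -_grad_q(K, th, z, w),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200},
        )
        if np.all(np.isfinite(res.x)):
            val = -res.fun
            if val > best_val:
                best_theta, best_val, ok = res.x, val, bool(res.success)
    p = _params_of(K, best_theta)
    return SingleFit(params=p, loglik=float(best_val), converged=ok)
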