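"""Synthetic-data generators and simulation harnesses.

Two generators drive validation of the whole pipeline:

1. **Protein-microarray generator** — a reference-design experiment with I
   repeated experiments, J patient groups of K patients each, and L
   on-array replicates per protein.  Per protein, log2 patient abundances
   are mu_jk with log2(mu_jk) = mu + G_j + S_k(j) (group effects G_j ~
   U[g_range]; patient effects S_k(j) ~ N(0, (0.4 v_j)^2), v_j ~
   U[v_range]); the observed log-ratios are

       y_ijkl = C + G_j + S_k(j) + delta_ijk + eps_ijkl,
       C = -log2( sum_jk 2^{G_j + S_k(j)} / (J K) ),

   with between-array error delta ~ N(0, sigma_delta^2) and within-array
   error eps ~ N(0, sigma_eps^2).  A chosen fraction of proteins is made
   *inconsistent* by adding, to a uniformly-random number of arrays
   (between a configurable floor and all of them), a shared per-array
   shift with sd drawn from U[sb_range] plus per-replicate noise with sd
   from U[sw_range].

2. **Direct mixture draws** — samples from nine catalogued two-component
   SNP mixtures (``TABLE1_MODELS``) spanning normal, skewed and bimodal
   component shapes at component separations D = 1 or 2, used by the
   likelihood-ratio-test power study.

The harnesses (error curves, power study, replication sweeps) operate on
raw value arrays internally for speed and expose tidy DataFrames.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .anova_vc import AbundanceTable, vc_components
from .classify import TruthLabels, min_cost_threshold, posteriors
from .mixture import FitConfig
from .selection_lrt import bootstrap_null, fit_single, lrt_stat, select_model
from .snp_density import SNPParams, snp_sample

__all__ = [
    "ArrayDesign",
    "NoiseSpec",
    "SimOutput",
    "TABLE1_MODELS",
    "simulate_consistent",
    "inject_inconsistency",
    "simulate_dataset",
    "pearson_stat",
    "error_curves",
    "simulate_mixture_data",
    "power_study",
    "replication_sweep",
]

log = logging.getLogger(__name__)

_PI2 = math.pi / 2


@dataclass(frozen=True)
class ArrayDesign:
    """Replicated reference-design layout (defaults: the 40-patient study)."""

    I: int = 2  # repeated experiments
    J: int = 4  # patient groups
    K: int = 10  # patients per group
    L: int = 6  # on-array replicates per protein
    m: int = 300  # proteins
    inconsistent_fraction: float = 0.5

    def __post_init__(self) -> None:
        if min(self.I, self.J, self.K, self.L, self.m) < 1:
            raise ValueError("all design counts must be >= 1")
        if not (0.0 <= self.inconsistent_fraction <= 1.0):
            raise ValueError("inconsistent_fraction must lie in [0, 1]")

    @property
    def n_arrays(self) -> int:
        return self.I * self.J * self.K


@dataclass(frozen=True)
class NoiseSpec:
    """Variance settings of the generative model and the injected damage."""

    sigma_delta: float = 0.2
    sigma_eps: float = 0.15
    g_range: tuple[float, float] = (-1.0, 1.0)
    v_range: tuple[float, float] = (0.5, 2.0)
    sb_range: tuple[float, float] = (0.05, 0.5)
    sw_range: tuple[float, float] = (0.1, 0.4)
    #: lower bound, as a fraction of the total array count, on the number of
    #: arrays an inconsistent protein damages; the count is uniform between
    #: this floor and all arrays.  A floor of zero dilutes the damage so much
    #: that a fifth of "inconsistent" proteins become statistically
    #: indistinguishable from consistent ones.
    min_affected_frac: float = 0.25

    def __post_init__(self) -> None:
        if self.sigma_delta < 0 or self.sigma_eps < 0:
            raise ValueError("error sds must be nonnegative")
        if not (0.0 <= self.min_affected_frac <= 1.0):
            raise ValueError("min_affected_frac must lie in [0, 1]")
        for name in ("g_range", "v_range", "sb_range", "sw_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} bounds must be ordered")


@dataclass
class SimOutput:
    table: AbundanceTable
    truth: TruthLabels
    seed: int
    values: np.ndarray = field(repr=False)  # (m, I, J, K, L)
    design: ArrayDesign = field(default_factory=ArrayDesign)


# ---------------------------------------------------------------------------
# microarray generator (array core + long-table wrappers)
# ---------------------------------------------------------------------------


def _consistent_values(design: ArrayDesign, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    d, m = design, design.m
    G = rng.uniform(*noise.g_range, size=(m, d.J))  # per protein x group
    v = rng.uniform(*noise.v_range, size=(m, d.J))
    S = rng.normal(0.0, 1.0, size=(m, d.J, d.K)) * (0.4 * v)[:, :, None]
    theta = G[:, :, None] + S  # (m, J, K) = G_j + S_k(j)
    C = -np.log2(np.exp2(theta).mean(axis=(1, 2)))  # (m,)
    mean = C[:, None, None, None] + theta[:, None, :, :]  # (m, 1, J, K)
    delta = rng.normal(0.0, noise.sigma_delta, size=(m, d.I, d.J, d.K))
    eps = rng.normal(0.0, noise.sigma_eps, size=(m, d.I, d.J, d.K, d.L))
    return mean[..., None] + delta[..., None] + eps  # (m, I, J, K, L)


def _inject_values(values: np.ndarray, design: ArrayDesign, noise: NoiseSpec,
                   rng: np.random.Generator) -> np.ndarray:
    """Return (values, labels): damage a random protein subset in place."""
    m = design.m
    n_inc = round(m * design.inconsistent_fraction)
    labels = np.zeros(m, dtype=int)
    if n_inc == 0:
        return labels
    chosen = rng.choice(m, size=n_inc, replace=False)
    labels[chosen] = 1
    n_arr = design.n_arrays
    flat = values.reshape(m, n_arr, design.L)
    a_min = max(1, round(noise.min_affected_frac * n_arr))
    for p in chosen:
        s_b = rng.uniform(*noise.sb_range)
        s_w = rng.uniform(*noise.sw_range)
        A = int(rng.integers(a_min, n_arr + 1))
        arrays = rng.choice(n_arr, size=A, replace=False)
        shifts = rng.normal(0.0, s_b, size=A)
        flat[p, arrays, :] += shifts[:, None] + rng.normal(0.0, s_w, size=(A, design.L))
    return labels


def _to_table(values: np.ndarray, design: ArrayDesign) -> AbundanceTable:
    d = design
    idx = np.indices((d.m, d.I, d.J, d.K, d.L)).reshape(5, -1)
    df = pd.DataFrame(
        {
            "protein_id": idx[0] + 1,
            "experiment": idx[1] + 1,
            "group": idx[2] + 1,
            "sample": idx[3] + 1,
            "replicate": idx[4] + 1,
            "value": values.ravel(),
        }
    )
    return AbundanceTable(df)


def simulate_consistent(design: ArrayDesign, noise: NoiseSpec, seed) -> AbundanceTable:
    """Long-format table of a fully consistent simulated experiment."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _to_table(_consistent_values(design, noise, rng), design)


def inject_inconsistency(out: SimOutput, noise: NoiseSpec, seed) -> SimOutput:
    """Damage a random protein subset of an already-simulated dataset."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    design = out.design
    vals = out.values.copy()
    labels = _inject_values(vals, design, noise, rng)
    return SimOutput(
        table=_to_table(vals, design),
        truth=TruthLabels(protein_id=np.arange(design.m) + 1, inconsistent=labels),
        seed=out.seed,
        values=vals,
        design=design,
    )


def simulate_dataset(design: ArrayDesign | None = None, noise: NoiseSpec | None = None,
                     seed: int = 0) -> SimOutput:
    """Full generator: consistent experiment plus inconsistency injection."""
    design = design or ArrayDesign()
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    values = _consistent_values(design, noise, rng)
    labels = _inject_values(values, design, noise, rng)
    return SimOutput(
        table=_to_table(values, design),
        truth=TruthLabels(protein_id=np.arange(design.m) + 1, inconsistent=labels),
        seed=seed,
        values=values,
        design=design,
    )


# ---------------------------------------------------------------------------
# Pearson-correlation baseline
# ---------------------------------------------------------------------------


def _pearson_from_values(values: np.ndarray) -> np.ndarray:
    """Per-protein correlation between the two experiments' patient profiles."""
    if values.shape[1] != 2:
        raise ValueError("Pearson baseline requires exactly I = 2 experiments")
    prof = values.mean(axis=-1).reshape(values.shape[0], 2, -1)  # replicate-avg, (m, 2, JK)
    x = prof[:, 0] - prof[:, 0].mean(axis=1, keepdims=True)
    y = prof[:, 1] - prof[:, 1].mean(axis=1, keepdims=True)
    denom = np.sqrt((x * x).sum(axis=1) * (y * y).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x * y).sum(axis=1) / denom
    return np.where(denom > 0, r, 0.0)


def pearson_stat(tbl: AbundanceTable) -> pd.Series:
    """Pearson correlation of replicate-averaged patient profiles (I = 2).

    Lower correlation ranks as more inconsistent.
    """
    pid, vals = tbl.to_array()  # (m, I, C, L)
    r = _pearson_from_values(vals)
    return pd.Series(r, index=pd.Index(pid, name="protein_id"), name="pearson_r")


# ---------------------------------------------------------------------------
# averaged error-rate curves (VC vs. Pearson)
# ---------------------------------------------------------------------------


def _rate_curves(stat: np.ndarray, labels: np.ndarray, higher_is_inconsistent: bool) -> tuple[np.ndarray, np.ndarray]:
    """Realized (FDR, FNR) for every declared count d = 0..m, vectorized."""
    order = np.argsort(-stat if higher_is_inconsistent else stat, kind="stable")
    lab = labels[order]
    d = np.arange(len(stat) + 1)
    false_disc = np.concatenate([[0], np.cumsum(lab == 0)])
    missed = lab.sum() - np.concatenate([[0], np.cumsum(lab == 1)])
    with np.errstate(invalid="ignore", divide="ignore"):
        fdr = np.where(d > 0, false_disc / np.maximum(d, 1), 0.0)
        fnr = np.where(d < len(stat), missed / np.maximum(len(stat) - d, 1), 0.0)
    return fdr, fnr


def _est_curves(post: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-estimated (FDR_hat, FNR_hat) for every declared count d."""
    p = np.sort(post)[::-1]
    m = p.size
    csum = np.concatenate([[0.0], np.cumsum(p)])
    d = np.arange(m + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fdr = np.where(d > 0, (d - csum) / np.maximum(d, 1), 0.0)
        fnr = np.where(d < m, (csum[-1] - csum) / np.maximum(m - d, 1), 0.0)
    return fdr, fnr


def error_curves(stat_name: str, design: ArrayDesign | None = None,
                 noise: NoiseSpec | None = None, n_reps: int = 100, seed: int = 0,
                 fit: bool = False, criterion: str = "bic",
                 cfg: FitConfig | None = None) -> pd.DataFrame:
    """Average true (and optionally estimated) error rates over replicates.

    For each replicate a dataset is simulated, the chosen statistic
    (``"vc"`` or ``"pcc"``) computed and ranked, and realized FDR/FNR
    recorded for every declared count d.  With ``fit=True`` (VC only) the
    selected SNP mixture is additionally fitted to the statistics and the
    posterior-based estimates recorded; replicates whose fit fails are
    excluded from the estimated-rate averages only.
    """
    if stat_name not in ("vc", "pcc"):
        raise ValueError("stat_name must be 'vc' or 'pcc'")
    design = design or ArrayDesign()
    noise = noise or NoiseSpec()
    cfg = cfg or FitConfig(tol=1e-7, max_iter=300, n_starts=2)
    root = np.random.default_rng(seed)
    m = design.m
    acc_true = np.zeros((2, m + 1))
    acc_est = np.zeros((2, m + 1))
    n_est = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(root.integers(2**31))
        values = _consistent_values(design, noise, rng)
        labels = _inject_values(values, design, noise, rng)
        if stat_name == "vc":
            sd, se = vc_components(values.reshape(m, design.I, design.J * design.K, design.L))
            stat = np.maximum(sd, 0.0) + se
            higher = True
        else:
            stat = _pearson_from_values(values.reshape(m, design.I, design.J * design.K, design.L))
            higher = False
        fdr, fnr = _rate_curves(stat, labels, higher)
        acc_true[0] += fdr
        acc_true[1] += fnr
        if fit and stat_name == "vc":
            try:
                sel = select_model(stat, criterion, cfg)
                post = posteriors(sel.best_alt, stat)
                ef, en = _est_curves(post)
                acc_est[0] += ef
                acc_est[1] += en
                n_est += 1
            except Exception as exc:
                log.warning("replicate %d mixture fit failed: %s", rep, exc)
    out = pd.DataFrame(
        {
            "d": np.arange(m + 1),
            "fdr_true": acc_true[0] / n_reps,
            "fnr_true": acc_true[1] / n_reps,
        }
    )
    if fit and stat_name == "vc":
        out["fdr_hat"] = acc_est[0] / max(n_est, 1)
        out["fnr_hat"] = acc_est[1] / max(n_est, 1)
        out.attrs["n_fit"] = n_est
    return out


# ---------------------------------------------------------------------------
# direct mixture draws (power study)
# ---------------------------------------------------------------------------


def _c(a1: float, a2: float, u: float, v: float) -> SNPParams:
    return SNPParams(K=2, angles=(a1, a2), u=u, v=v)


#: The nine catalogued two-component mixtures, per separation D.
#: Angles of pi/2 zero the corresponding Hermite terms, so e.g. model 1 is
#: a plain two-normal mixture.
TABLE1_MODELS: dict[int, dict[int, tuple[SNPParams, SNPParams]]] = {
    1: {1: (_c(_PI2, _PI2, 12, 2), _c(_PI2, _PI2, 17, 3)),
        2: (_c(_PI2, _PI2, 12, 2), _c(_PI2, _PI2, 24, 4))},
    2: {1: (_c(_PI2, _PI2, 12, 2), _c(2.17, _PI2, 19.4, 3)),
        2: (_c(_PI2, _PI2, 12, 2), _c(2.17, _PI2, 26.7, 4))},
    3: {1: (_c(_PI2, _PI2, 12, 2), _c(2.0, 2.75, 18, 2)),
        2: (_c(_PI2, _PI2, 12, 2), _c(2.0, 2.75, 30.3, 4))},
    4: {1: (_c(0.97, _PI2, 9.8, 2.3), _c(_PI2, _PI2, 17, 3)),
        2: (_c(0.97, _PI2, 9.8, 2.3), _c(_PI2, _PI2, 24, 4))},
    5: {1: (_c(0.97, _PI2, 10, 2), _c(2.17, _PI2, 18.15, 2.5)),
        2: (_c(0.97, _PI2, 10, 2), _c(2.17, _PI2, 26.15, 4))},
    6: {1: (_c(0.97, _PI2, 9.8, 2.3), _c(2.0, 2.75, 19.8, 2.5)),
        2: (_c(0.97, _PI2, 9.8, 2.3), _c(2.0, 2.75, 31.3, 4))},
    7: {1: (_c(4.1, 0.9, 9.7, 1.8), _c(_PI2, _PI2, 17, 3)),
        2: (_c(4.1, 0.9, 9.7, 1.8), _c(_PI2, _PI2, 24, 4))},
    8: {1: (_c(4.1, 0.9, 9.7, 1.8), _c(2.17, _PI2, 20.5, 3.5)),
        2: (_c(4.1, 0.9, 9.7, 1.8), _c(2.17, _PI2, 28.5, 4.6))},
    9: {1: (_c(4.1, 0.9, 10, 2), _c(2.0, 2.75, 19.8, 2.5)),
        2: (_c(4.1, 0.9, 10, 2), _c(2.0, 2.75, 31.3, 4))},
}


def simulate_mixture_data(model: int, D: int, lambda0: float, n: int, seed) -> np.ndarray:
    """Draw n values from catalogued mixture ``model`` at separation ``D``."""
    if model not in TABLE1_MODELS:
        raise ValueError(f"unknown model id {model}; expected 1..9")
    if D not in (1, 2):
        raise ValueError("D must be 1 or 2")
    comp1, comp2 = TABLE1_MODELS[model][D]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from1 = rng.uniform(size=n) < lambda0
    out = np.empty(n)
    n1 = int(from1.sum())
    if n1:
        out[from1] = snp_sample(comp1, n1, rng)
    if n - n1:
        out[~from1] = snp_sample(comp2, n - n1, rng)
    return out


def power_study(models=(1,), n_grid=(50, 100, 300, 500), lambda0_grid=(0.2, 0.5, 0.8),
                D_grid=(1, 2), n_reps: int = 50, B: int = 100, alpha: float = 0.05,
                criterion: str = "bic", seed: int = 0, cfg: FitConfig | None = None,
                threshold_strategy: str = "shared") -> pd.DataFrame:
    """Rejection rate of the bootstrap LRT across the simulation grid.

    ``threshold_strategy="shared"`` (default) bootstraps one null threshold
    per grid cell — from the single-density fit to that cell's first
    replicate — and reuses it across replicates; ``"per-dataset"`` runs the
    full bootstrap on every replicate.
    """
    cfg = cfg or FitConfig(tol=1e-7, max_iter=300, n_starts=2)
    root = np.random.default_rng(seed)
    rows = []
    for model in models:
        for D in D_grid:
            for lam0 in lambda0_grid:
                for n in n_grid:
                    cell_rng = np.random.default_rng(root.integers(2**31))
                    datasets = [
                        simulate_mixture_data(model, D, lam0, n, cell_rng)
                        for _ in range(n_reps)
                    ]
                    sels = [select_model(zb, criterion, cfg) for zb in datasets]
                    stats = [lrt_stat(s.best_null, s.best_alt) for s in sels]
                    if threshold_strategy == "shared":
                        s0 = sels[0]
                        boot = bootstrap_null(
                            s0.best_null, n, B, criterion, cfg,
                            seed=int(cell_rng.integers(2**31)), alt_K=s0.best_alt_K,
                        )
                        thresh = float(np.quantile(boot, 1.0 - alpha))
                        rejects = [s > thresh for s in stats]
                    elif threshold_strategy == "per-dataset":
                        rejects = []
                        for zb, s, st in zip(datasets, sels, stats):
                            boot = bootstrap_null(
                                s.best_null, n, B, criterion, cfg,
                                seed=int(cell_rng.integers(2**31)), alt_K=s.best_alt_K,
                            )
                            rejects.append(st > float(np.quantile(boot, 1.0 - alpha)))
                    else:
                        raise ValueError(f"unknown threshold_strategy {threshold_strategy!r}")
                    rows.append(
                        {"model": model, "D": D, "lambda0": lam0, "n": n,
                         "power": float(np.mean(rejects))}
                    )
    return pd.DataFrame(rows)


def replication_sweep(vary: str, grid, design: ArrayDesign | None = None,
                      noise: NoiseSpec | None = None, gamma: float = 0.5,
                      n_reps: int = 5, criterion: str = "bic", seed: int = 0,
                      cfg: FitConfig | None = None) -> pd.DataFrame:
    """Minimum classification cost as replication grows.

    ``vary="biological"`` sweeps total patient count (split evenly over the
    J groups, so grid values must be divisible by J) at fixed L;
    ``vary="technical"`` sweeps on-array replicates L at fixed patients.
    Each grid point averages the minimized cost over ``n_reps``
    simulate-fit-classify runs.
    """
    if vary not in ("biological", "technical"):
        raise ValueError("vary must be 'biological' or 'technical'")
    design = design or ArrayDesign()
    noise = noise or NoiseSpec()
    cfg = cfg or FitConfig(tol=1e-7, max_iter=300, n_starts=2)
    root = np.random.default_rng(seed)
    rows = []
    for gval in grid:
        if vary == "biological":
            if gval % design.J:
                raise ValueError(f"patient total {gval} not divisible by J={design.J}")
            d = replace(design, K=gval // design.J)
        else:
            if gval < 2:
                raise ValueError("need at least 2 technical replicates")
            d = replace(design, L=int(gval))
        costs = []
        for _ in range(n_reps):
            rng = np.random.default_rng(root.integers(2**31))
            values = _consistent_values(d, noise, rng)
            _inject_values(values, d, noise, rng)
            sd, se = vc_components(values.reshape(d.m, d.I, d.J * d.K, d.L))
            stat = np.maximum(sd, 0.0) + se
            try:
                sel = select_model(stat, criterion, cfg)
                res = min_cost_threshold(posteriors(sel.best_alt, stat), gamma)
                costs.append(float(res.cost_curve["cost"].iloc[res.d]))
            except Exception as exc:
                log.warning("sweep replicate failed at %s=%s: %s", vary, gval, exc)
        rows.append({"vary": vary, "grid": gval, "min_cost": float(np.mean(costs)) if costs else np.nan,
                     "n_ok": len(costs)})
    return pd.DataFrame(rows)
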