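"""Per-protein variance-component ANOVA and the consistency statistic.

Each protein's normalized log2 sample/reference ratios follow the balanced
repeated-design ANOVA

    Y_ijkl = mu + T_j + S_k(j) + delta_ijk + eps_ijkl,

with experiments i = 1..I, patient groups j = 1..J, samples k = 1..K within
group, and on-array replicates l = 1..L.  delta (between-array /
between-experiment error, variance sigma_delta^2) and eps (within-array
error, variance sigma_eps^2) are the random-error strata; their sum

    z = sigma_delta^2 + sigma_eps^2

is the per-protein consistency statistic: probes that lost structure or
orientation report irreproducibly and inflate both strata.

Estimation is least-squares / expected-mean-squares on the balanced design:

    MS_within = sum (Y_ijkl - Ybar_ijk.)^2 / (I J K (L-1))      -> sigma_eps^2
    MS_exp    = L sum_i,j,k (Ybar_ijk. - Ybar_.jk.)^2 / (J K (I-1))
    sigma_delta^2 = (MS_exp - MS_within) / L

The per-(j,k) centering absorbs all fixed effects, so the statistic is
invariant to group and sample means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "AbundanceTable",
    "ConsistencyStats",
    "vc_components",
    "fit_anova_vc",
    "consistency_stats",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("protein_id", "experiment", "group", "sample", "replicate", "value")


@dataclass
class AbundanceTable:
    """Long-format replicated-design measurements.

    Wraps a DataFrame with columns protein_id, experiment, group, sample,
    replicate, value.  ``validate`` checks the design is balanced and
    complete (every cell present exactly once, I >= 2, L >= 2).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        self._cache: tuple | None = None

    def validate(self) -> None:
        """Raise with the offending cells if the design is unbalanced/incomplete."""
        df = self.df
        if not np.issubdtype(df["value"].dtype, np.number):
            raise ValueError("value column must be numeric")
        counts = df.groupby(["protein_id", "experiment", "group", "sample", "replicate"], sort=False).size()
        dup = counts[counts > 1]
        if len(dup):
            raise ValueError(f"duplicated design cells (first few): {list(dup.index[:5])}")
        n_exp = df["experiment"].nunique()
        n_rep = df["replicate"].nunique()
        if n_exp < 2 or n_rep < 2:
            raise ValueError(f"need I >= 2 experiments and L >= 2 replicates, got I={n_exp}, L={n_rep}")
        expected = (
            df["protein_id"].nunique() * n_exp * df.groupby("group")["sample"].nunique().sum() * n_rep
        )
        if len(df) != expected:
            per = df.groupby("protein_id").size()
            bad = per[per != per.mode().iat[0]]
            raise ValueError(
                f"incomplete design: {len(df)} rows, expected {expected}"
                + (f"; offending proteins (first few): {list(bad.index[:5])}" if len(bad) else "")
            )

    def to_array(self) -> tuple[np.ndarray, np.ndarray]:
        """(protein_ids, values) with values shaped (m, I, JK, L).

        Groups and samples are flattened into one patient axis: the
        variance-component estimator only needs the (j, k) cell identity.
        """
        if self._cache is not None:
            return self._cache
        df = self.df
        pid, p_codes = np.unique(df["protein_id"].to_numpy(), return_inverse=True)
        _, i_codes = np.unique(df["experiment"].to_numpy(), return_inverse=True)
        cell_key = pd.MultiIndex.from_arrays([df["group"], df["sample"]])
        _, c_codes = np.unique(np.asarray(cell_key.to_numpy()), return_inverse=True)
        _, l_codes = np.unique(df["replicate"].to_numpy(), return_inverse=True)
        m, I = len(pid), i_codes.max() + 1
        C, L = c_codes.max() + 1, l_codes.max() + 1
        vals = np.full((m, I, C, L), np.nan)
        vals[p_codes, i_codes, c_codes, l_codes] = df["value"].to_numpy(dtype=float)
        if np.isnan(vals).any():
            n_missing = int(np.isnan(vals).sum())
            raise ValueError(f"incomplete design: {n_missing} missing cells")
        self._cache = (pid, vals)
        return self._cache


@dataclass
class ConsistencyStats:
    """Per-protein variance components and their total z."""

    protein_id: np.ndarray
    sigma_delta_sq: np.ndarray  # after truncation policy
    sigma_eps_sq: np.ndarray
    z: np.ndarray
    raw_sigma_delta_sq: np.ndarray  # untruncated

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.protein_id,
                "sigma_delta_sq": self.sigma_delta_sq,
                "sigma_eps_sq": self.sigma_eps_sq,
                "z": self.z,
            }
        )


def vc_components(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """EMS variance components from an array shaped (..., I, C, L).

    Returns (sigma_delta_sq_raw, sigma_eps_sq) per leading index.  C is the
    number of (group, sample) cells; the per-cell mean over experiments
    absorbs every fixed effect.
    """
    I, C, L = values.shape[-3:]
    if I < 2 or L < 2:
        raise ValueError("need I >= 2 and L >= 2")
    cell_mean = values.mean(axis=-1)  # (..., I, C)
    ms_within = ((values - cell_mean[..., None]) ** 2).sum(axis=(-3, -2, -1)) / (I * C * (L - 1))
    grand_cell = cell_mean.mean(axis=-2)  # (..., C), mean over experiments
    ms_exp = L * ((cell_mean - grand_cell[..., None, :]) ** 2).sum(axis=(-2, -1)) / (C * (I - 1))
    sigma_delta = (ms_exp - ms_within) / L
    return sigma_delta, ms_within


def fit_anova_vc(tbl: AbundanceTable, protein) -> tuple[float, float]:
    """(sigma_delta_sq, sigma_eps_sq) for one protein, untruncated."""
    pid, vals = tbl.to_array()
    idx = np.flatnonzero(pid == protein)
    if idx.size == 0:
        raise KeyError(f"protein {protein!r} not in table")
    sd, se = vc_components(vals[idx[0]])
    return float(sd), float(se)


def consistency_stats(tbl: AbundanceTable, truncate: bool = True) -> ConsistencyStats:
    """Per-protein consistency statistic z = sigma_delta^2 + sigma_eps^2.

    Negative between-array components (possible under method-of-moments)
    are truncated to zero before summing when ``truncate`` (the default).
    Proteins with no signal at all (all values missing/NaN) are dropped
    with a logged count.
    """
    pid, vals = tbl.to_array()
    if len(pid) == 0:
        raise ValueError("empty table")
    flat = vals.reshape(len(pid), -1)
    dead = np.all(~np.isfinite(flat), axis=1)
    if dead.any():
        log.info("dropping %d protein(s) with no signal", int(dead.sum()))
        pid, vals = pid[~dead], vals[~dead]
    sd_raw, se = vc_components(vals)
    sd = np.maximum(sd_raw, 0.0) if truncate else sd_raw
    return ConsistencyStats(
        protein_id=pid,
        sigma_delta_sq=sd,
        sigma_eps_sq=se,
        z=sd + se,
        raw_sigma_delta_sq=sd_raw,
    )
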