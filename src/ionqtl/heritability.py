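"""Broad-sense heritability from unbalanced two-way and one-way ANOVA.

Across environments, total phenotypic variance is partitioned into genetic
and environmental components using a type-II decomposition obtained from
two sequential least-squares fits: ``trait ~ line + environment`` and
``trait ~ environment + line``.  Each factor's adjusted sum of squares is
taken from the fit in which it enters second, which accounts for the
unbalanced sets of lines shared across environments.  Variance components
are then recovered from the adjusted mean squares by method of moments
(``VG = (MS_line - MS_resid) / c_g`` with the usual unbalanced group-size
coefficient), and

``H2 = VG / (VG + VE + Vres)``.

Within a replicated environment, a one-way ANOVA on lines with two or more
replicates yields ``H2 = VG / (VG + Vres)``.  Negative component estimates
are clipped to zero (logged), so H2 always lies in [0, 1].  The raw
sum-of-squares and mean-square ratios are also reported on the result for
comparison, since "genetic variance" is ambiguous between these readings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

from .core import IonQTLError, logger

__all__ = ["HeritabilityResult", "h2_across_env", "h2_within_env", "BroadSenseHeritability"]


@dataclass(frozen=True)
class HeritabilityResult:
    """Variance partition and broad-sense heritability for one trait."""

    trait: str
    scope: str  # "all_env" or an environment id
    var_genetic: float
    var_env: float | None
    var_resid: float
    h2: float
    h2_ms: float = float("nan")  # mean-square ratio variant
    h2_ss: float = float("nan")  # sum-of-squares ratio variant
    n_obs: int = 0
    clipped: bool = False


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Treatment-coded indicator columns (reference level dropped)."""
    out = np.zeros((codes.size, n_levels - 1))
    for k in range(1, n_levels):
        out[codes == k, k - 1] = 1.0
    return out


def _ms_coefficient(counts: np.ndarray) -> float:
    """Unbalanced one-way coefficient: E[MS_between] = sigma^2 + c * V."""
    n = counts.sum()
    return float((n - (counts**2).sum() / n) / (counts.size - 1))


def h2_across_env(values: pd.DataFrame, trait: str = "") -> HeritabilityResult:
    """Across-environment broad-sense heritability from a lines x environments table.

    ``values`` holds one trait: rows are lines, columns environments, cells
    the line's trait value in that environment (NaN where not grown).
    Requires >= 2 environments and >= 2 lines observed in >= 2 environments,
    and a connected line-environment incidence (otherwise genetic and
    environmental variance are not separable).
    """
    long = values.stack().rename("y").reset_index()
    long.columns = ["line_id", "env_id", "y"]
    long = long.dropna(subset=["y"])
    line_codes, line_levels = pd.factorize(long["line_id"], sort=True)
    env_codes, env_levels = pd.factorize(long["env_id"], sort=True)
    L, E, N = len(line_levels), len(env_levels), len(long)
    if E < 2:
        raise IonQTLError("need >= 2 environments with data")
    if L < 2:
        raise IonQTLError("need >= 2 lines with data")
    env_per_line = np.bincount(line_codes, minlength=L)
    if (env_per_line >= 2).sum() < 2:
        raise IonQTLError("need >= 2 lines present in >= 2 environments")
    inc = coo_matrix((np.ones(N), (line_codes, env_codes)), shape=(L, E))
    graph = coo_matrix(
        (
            np.ones(2 * N),
            (
                np.concatenate([line_codes, env_codes + L]),
                np.concatenate([env_codes + L, line_codes]),
            ),
        ),
        shape=(L + E, L + E),
    )
    n_comp, _ = connected_components(graph, directed=False)
    if n_comp > 1:
        raise IonQTLError("disconnected line/environment design; variance not separable")

    y = long["y"].to_numpy(dtype=float)
    ones = np.ones((N, 1))
    DL = _dummies(line_codes, L)
    DE = _dummies(env_codes, E)
    rss_0 = float(((y - y.mean()) ** 2).sum())
    rss_l = _rss(np.hstack([ones, DL]), y)
    rss_e = _rss(np.hstack([ones, DE]), y)
    rss_le = _rss(np.hstack([ones, DL, DE]), y)

    ss_g = max(rss_e - rss_le, 0.0)  # line adjusted for environment
    ss_e = max(rss_l - rss_le, 0.0)  # environment adjusted for line
    ss_r = rss_le
    df_g, df_e = L - 1, E - 1
    df_r = N - L - E + 1
    if df_r <= 0:
        raise IonQTLError("no residual degrees of freedom")
    ms_g, ms_e, ms_r = ss_g / df_g, ss_e / df_e, ss_r / df_r

    c_g = _ms_coefficient(env_per_line)
    c_e = _ms_coefficient(np.bincount(env_codes, minlength=E))
    vg, ve, vr = (ms_g - ms_r) / c_g, (ms_e - ms_r) / c_e, ms_r
    clipped = vg < 0 or ve < 0
    if clipped:
        logger.warning("[clipped-variance] trait=%s negative component set to 0", trait)
    vg, ve = max(vg, 0.0), max(ve, 0.0)
    total = vg + ve + vr
    h2 = vg / total if total > 0 else float("nan")
    return HeritabilityResult(
        trait=trait,
        scope="all_env",
        var_genetic=vg,
        var_env=ve,
        var_resid=vr,
        h2=h2,
        h2_ms=ms_g / (ms_g + ms_e + ms_r) if (ms_g + ms_e + ms_r) > 0 else float("nan"),
        h2_ss=ss_g / (ss_g + ss_e + ss_r) if (ss_g + ss_e + ss_r) > 0 else float("nan"),
        n_obs=N,
        clipped=clipped,
    )


def h2_within_env(
    replicates: pd.DataFrame,
    trait: str = "",
    env_id: str = "",
    value_col: str = "y",
) -> HeritabilityResult:
    """Within-environment heritability from replicate-level values.

    ``replicates`` has columns ``line_id`` and ``value_col``.  Missing
    values and lines with fewer than two replicates are removed first; at
    least two lines must survive.  If the surviving values are all
    identical the heritability is undefined and reported missing.
    """
    df = replicates.dropna(subset=[value_col])
    counts = df.groupby("line_id")[value_col].transform("size")
    df = df[counts >= 2]
    line_codes, levels = pd.factorize(df["line_id"], sort=True)
    L, N = len(levels), len(df)
    if L < 2:
        raise IonQTLError("fewer than 2 lines with >= 2 replicates")
    y = df[value_col].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        logger.warning("[degenerate] trait=%s env=%s: zero total variance", trait, env_id)
        return HeritabilityResult(trait, env_id or "env", 0.0, None, 0.0, float("nan"), n_obs=N)
    group_sums = np.bincount(line_codes, weights=y, minlength=L)
    group_n = np.bincount(line_codes, minlength=L)
    ss_total = float(((y - y.mean()) ** 2).sum())
    ss_between = float((group_sums**2 / group_n).sum() - y.sum() ** 2 / N)
    ss_within = ss_total - ss_between
    df_b, df_w = L - 1, N - L
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w if df_w > 0 else 0.0
    c = _ms_coefficient(group_n)
    vg = (ms_b - ms_w) / c
    clipped = vg < 0
    if clipped:
        logger.warning("[clipped-variance] trait=%s env=%s", trait, env_id)
    vg = max(vg, 0.0)
    total = vg + ms_w
    h2 = vg / total if total > 0 else float("nan")
    return HeritabilityResult(
        trait=trait,
        scope=env_id or "env",
        var_genetic=vg,
        var_env=None,
        var_resid=ms_w,
        h2=h2,
        h2_ms=ms_b / (ms_b + ms_w) if (ms_b + ms_w) > 0 else float("nan"),
        h2_ss=ss_between / ss_total,
        n_obs=N,
        clipped=clipped,
    )


class BroadSenseHeritability(BaseEstimator):
    """Estimator wrapper around the two ANOVA heritability procedures.

    Parameters
    ----------
    scope : {"across", "within"}
        "across" expects a lines x environments wide table in :meth:`fit`;
        "within" expects a replicate-level frame with ``line_id`` and a
        value column.
    """

    def __init__(self, scope: str = "across", value_col: str = "y", trait: str = ""):
        self.scope = scope
        self.value_col = value_col
        self.trait = trait

    def fit(self, X: pd.DataFrame, y=None) -> "BroadSenseHeritability":
        if self.scope == "across":
            res = h2_across_env(X, trait=self.trait)
        elif self.scope == "within":
            res = h2_within_env(X, trait=self.trait, value_col=self.value_col)
        else:
            raise IonQTLError(f"scope must be 'across' or 'within', got {self.scope!r}")
        self.result_ = res
        self.h2_ = res.h2
        self.var_genetic_ = res.var_genetic
        self.var_env_ = res.var_env
        self.var_resid_ = res.var_resid
        return self
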