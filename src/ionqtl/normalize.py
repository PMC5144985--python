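"""Single-seed ionomics normalization.

Raw ICP-MS concentrations of single seeds are confounded by seed weight
(small seeds show inflated apparent concentrations, consistent with a
weight-independent contamination term) and by run-to-run analytical
variation.  This module provides the two-step normalization:

1. robust outlier flagging — within each (line, environment) group and
   element, a seed whose absolute deviation from the group median exceeds
   6.2 group-MADs is flagged and treated as missing downstream;
2. ECDM (estimated concentration difference from the mean) — the residual
   of a per-element least-squares fit of the raw concentration on an
   intercept, seed weight, and the analytical run as a categorical factor.
   If every seed had the same analyte concentration the fit would predict
   raw values perfectly from weight and the residuals would all be zero; a
   seed's residual therefore estimates its concentration difference from
   the population mean.

The MAD score is the raw ratio ``|x - median| / MAD`` by default (no
1.4826 normal-consistency constant); set ``consistency=True`` to scale the
MAD to a normal-SD estimate.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .core import ELEMENTS, IonQTLError, logger

__all__ = [
    "flag_outliers_mad",
    "compute_ecdm",
    "line_averages",
    "MADOutlierFlagger",
    "ECDMNormalizer",
]

MAD_CONSISTENCY = 1.4826


def _elements_in(seeds: pd.DataFrame, elements: Sequence[str] | None) -> list[str]:
    if elements is not None:
        return list(elements)
    found = [c[4:] for c in seeds.columns if c.startswith("raw_")]
    return found if found else [e for e in ELEMENTS if f"raw_{e}" in seeds.columns]


def flag_outliers_mad(
    seeds: pd.DataFrame,
    threshold: float = 6.2,
    elements: Sequence[str] | None = None,
    consistency: bool = False,
    group_keys: Sequence[str] = ("line_id", "env_id"),
) -> pd.DataFrame:
    """Flag per-element analytical outliers within (line, environment) groups.

    A value is flagged when ``|x - median(group)| / MAD(group)`` is strictly
    greater than ``threshold``.  Groups with MAD = 0 or fewer than 3
    non-missing seeds are left unflagged.  Flagging is a single pass on the
    input values; flags are stored in boolean ``flag_<element>`` columns.
    """
    if threshold <= 0:
        raise IonQTLError("threshold must be > 0")
    out = seeds.copy()
    if len(out) == 0:
        for el in _elements_in(out, elements):
            out[f"flag_{el}"] = pd.Series(dtype=bool)
        return out
    grp = out.groupby(list(group_keys), sort=False)
    for el in _elements_in(out, elements):
        col = f"raw_{el}"
        x = out[col].astype(float)
        med = grp[col].transform("median")
        mad = grp[col].transform(lambda v: float(np.nanmedian(np.abs(v - v.median()))))
        if consistency:
            mad = mad * MAD_CONSISTENCY
        n_obs = grp[col].transform("count")
        with np.errstate(divide="ignore", invalid="ignore"):
            score = (x - med).abs() / mad
        flag = (score > threshold) & (mad > 0) & (n_obs >= 3)
        out[f"flag_{el}"] = flag.fillna(False).astype(bool)
    return out


def _ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def compute_ecdm(
    seeds: pd.DataFrame,
    elements: Sequence[str] | None = None,
    per_env: bool = True,
) -> pd.DataFrame:
    """Fit raw ~ intercept + weight + run per element; store residuals.

    Flagged seeds (``flag_<el>`` True) and seeds with missing raw value or
    weight are excluded from the fit and receive a missing ECDM.  A fit
    block is one environment by default (``per_env=True``) or the pooled
    table.  Degenerate terms are dropped with a logged notice: a single run
    level drops the run factor; constant weight drops the weight term.
    """
    out = seeds.copy()
    els = _elements_in(out, elements)
    for el in els:
        out[f"ecdm_{el}"] = np.nan
    blocks = out.groupby("env_id", sort=False).indices.items() if per_env else [
        ("all", np.arange(len(out)))
    ]
    for env, idx in blocks:
        sub = out.iloc[idx]
        for el in els:
            col = f"raw_{el}"
            keep = sub[col].notna() & sub["weight_mg"].notna()
            fcol = f"flag_{el}"
            if fcol in sub.columns:
                keep &= ~sub[fcol].astype(bool)
            rows = idx[np.asarray(keep)]
            if rows.size < 2:
                logger.warning("[dropped-fit] %s/%s: <2 usable seeds", env, el)
                continue
            y = out[col].to_numpy(dtype=float)[rows]
            w = out["weight_mg"].to_numpy(dtype=float)[rows]
            cols = [np.ones_like(y)]
            if np.ptp(w) > 0:
                cols.append(w)
            else:
                logger.warning("[dropped-term] %s/%s: constant weight", env, el)
            runs = out["run_id"].to_numpy()[rows]
            levels = pd.unique(runs)
            if len(levels) >= 2:
                for lev in levels[1:]:
                    cols.append((runs == lev).astype(float))
            else:
                logger.warning("[dropped-term] %s/%s: single run level", env, el)
            resid = _ols_residuals(y, np.column_stack(cols))
            vals = out[f"ecdm_{el}"].to_numpy()
            vals[rows] = resid
            out[f"ecdm_{el}"] = vals
    return out


def line_averages(
    seeds: pd.DataFrame,
    elements: Sequence[str] | None = None,
    by_rep: bool = False,
    value_prefix: str = "ecdm",
) -> dict[str, pd.DataFrame]:
    """Average seed-level ECDM values into line x trait matrices per environment.

    Means are taken over non-missing values only; a line with zero retained
    seeds for a trait gets a missing entry, never zero.  Seed weight is
    averaged alongside the elements.  With ``by_rep=True`` the replicate
    structure is preserved (one row per line and replicate), as needed for
    within-environment heritability.
    """
    els = _elements_in(seeds, elements)
    keys = ["line_id", "rep_id"] if by_rep else ["line_id"]
    out: dict[str, pd.DataFrame] = {}
    for env, sub in seeds.groupby("env_id", sort=False):
        cols = {"weight": sub["weight_mg"].astype(float)}
        for el in els:
            vcol = f"{value_prefix}_{el}"
            if vcol not in sub.columns:
                raise IonQTLError(f"column {vcol!r} missing; run compute_ecdm first")
            cols[el] = sub[vcol].astype(float)
        tmp = pd.DataFrame(cols, index=sub.index)
        tmp[keys] = sub[keys]
        mat = tmp.groupby(keys, sort=True).mean()
        if not by_rep:
            mat.index.name = "line_id"
        out[str(env)] = mat
    return out


class MADOutlierFlagger(BaseEstimator, TransformerMixin):
    """Stateless transformer wrapping :func:`flag_outliers_mad`."""

    def __init__(
        self,
        threshold: float = 6.2,
        consistency: bool = False,
        elements: Sequence[str] | None = None,
    ):
        self.threshold = threshold
        self.consistency = consistency
        self.elements = elements

    def fit(self, X: pd.DataFrame, y=None) -> "MADOutlierFlagger":
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return flag_outliers_mad(
            X,
            threshold=self.threshold,
            elements=self.elements,
            consistency=self.consistency,
        )


class ECDMNormalizer(BaseEstimator, TransformerMixin):
    """Transformer computing per-element ECDM residuals on a seed table.

    The regression is refit on each table passed to :meth:`transform`
    (normalization is defined relative to the analysis set itself), so
    :meth:`fit` is a no-op.
    """

    def __init__(self, per_env: bool = True, elements: Sequence[str] | None = None):
        self.per_env = per_env
        self.elements = elements

    def fit(self, X: pd.DataFrame, y=None) -> "ECDMNormalizer":
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return compute_ecdm(X, elements=self.elements, per_env=self.per_env)
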