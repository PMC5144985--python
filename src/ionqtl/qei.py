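"""QTL-by-environment interaction (QEI) detection.

Two complementary procedures:

1. **Location-covariate model comparison.**  Growouts from multiple years
   at the same location are pooled under one location label, and two fixed
   effects models are fit at every marker:

   full:     y = mu + b_g * g + b_x * x + gamma * g * x + eps
   additive: y = mu + b_g * g + b_x * x + eps

   where g is the marker genotype and x the location.  Each model's LOD is
   computed against the shared genotype-free null ``y ~ location``, and the
   interaction signal is the difference ``delta LOD = LOD_full - LOD_add``
   (non-negative up to rounding, since the full model nests the additive
   one).  Significance comes from permutations of the full three-step
   procedure (fit both models, subtract), shuffling trait values within
   each location stratum so location main effects and per-location trait
   marginals are preserved under the null.

2. **Within-location between-year difference mapping.**  For two growouts
   of the same location, the per-line trait difference between years is
   mapped as a trait of its own with the standard stepwise/permutation
   machinery; loci with year-stable effects cancel and only year-dependent
   effects remain mappable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import Cross, GENO_A, GENO_B, GeneticMap, IonQTLError, logger
from .qtl import QTLModel, ScanProfile, permutation_threshold, stepwise_qtl

__all__ = [
    "StackedCross",
    "QEIResult",
    "stack_locations",
    "qei_delta_lod",
    "qei_permutation_threshold",
    "trait_differences",
    "map_difference_qtl",
    "QEIScanner",
]


@dataclass
class StackedCross:
    """One observation per (line, growout), with a location label per row."""

    genmap: GeneticMap
    geno: np.ndarray  # observations x markers (genotype row repeated per growout)
    traits: pd.DataFrame  # observations x traits
    location: np.ndarray  # location label per observation
    line_id: np.ndarray
    env_id: np.ndarray

    def __post_init__(self) -> None:
        locs, counts = np.unique(self.location, return_counts=True)
        if len(locs) < 2:
            raise IonQTLError("need >= 2 locations after pooling")
        if (counts < 2).any():
            raise IonQTLError("every location needs >= 2 observations")

    @property
    def locations(self) -> np.ndarray:
        return np.unique(self.location)


@dataclass(frozen=True)
class QEIResult:
    """Per-marker delta-LOD profile with its permutation threshold."""

    trait: str
    profile: pd.DataFrame  # marker_id, chromosome, position_cm, lod_full, lod_add, delta_lod
    threshold: float
    significant: pd.DataFrame  # rows of profile with delta_lod > threshold


def stack_locations(
    crosses: Sequence[Cross], pooling: Mapping[str, str]
) -> StackedCross:
    """Stack per-growout crosses, pooling years under location labels.

    ``pooling`` maps each cross's env_id to a location label (e.g. FL05 and
    FL06 both to "FL").  Lines grown in multiple years of a location
    contribute one observation per year, with identical genotype rows.
    """
    rows_geno, rows_traits, loc, lid, eid = [], [], [], [], []
    for cross in crosses:
        if cross.env_id not in pooling:
            raise IonQTLError(f"no location label for growout {cross.env_id!r}")
        G = cross.geno_for_traits()
        rows_geno.append(G)
        rows_traits.append(cross.traits.reset_index(drop=True))
        loc.append(np.full(len(cross.traits), pooling[cross.env_id], dtype=object))
        lid.append(np.asarray(cross.traits.index, dtype=object))
        eid.append(np.full(len(cross.traits), cross.env_id, dtype=object))
    first = crosses[0].genmap
    for c in crosses[1:]:
        if list(c.genmap.marker_id) != list(first.marker_id):
            raise IonQTLError("crosses do not share one genetic map")
    return StackedCross(
        genmap=first,
        geno=np.vstack(rows_geno),
        traits=pd.concat(rows_traits, ignore_index=True),
        location=np.concatenate(loc),
        line_id=np.concatenate(lid),
        env_id=np.concatenate(eid),
    )


def _informative_markers(G: np.ndarray, loc_codes: np.ndarray, n_loc: int) -> np.ndarray:
    """Markers where every location carries both genotype classes."""
    ok = np.ones(G.shape[1], dtype=bool)
    for l in range(n_loc):
        sub = G[loc_codes == l]
        ok &= (sub == GENO_A).sum(axis=0) > 0
        ok &= (sub == GENO_B).sum(axis=0) > 0
    ok &= np.isfinite(G).all(axis=0)
    return ok


def _qei_rss(
    G: np.ndarray, Y: np.ndarray, loc_codes: np.ndarray, n_loc: int
) -> tuple[np.ndarray, np.ndarray]:
    """RSS of the additive and the full (cell-mean) model.

    ``Y`` is observations x P trait columns (P >= 1); returns
    (rss_add, rss_full), each markers x P.  Markers must be complete and
    informative (filter first).
    """
    n, m = G.shape
    D = np.column_stack(
        [np.ones(n)] + [(loc_codes == l).astype(float) for l in range(1, n_loc)]
    )
    L1 = D.shape[1]
    DtD = D.T @ D
    DtG = D.T @ G  # L1 x m
    gtg = (G * G).sum(axis=0)
    A = np.empty((m, L1 + 1, L1 + 1))
    A[:, :L1, :L1] = DtD[None]
    A[:, :L1, L1] = DtG.T
    A[:, L1, :L1] = DtG.T
    A[:, L1, L1] = gtg
    Ainv = np.linalg.inv(A)
    b = np.empty((m, L1 + 1, Y.shape[1]))
    b[:, :L1, :] = (D.T @ Y)[None]
    b[:, L1, :] = G.T @ Y
    beta = Ainv @ b
    yty = (Y * Y).sum(axis=0)  # P
    rss_add = yty[None, :] - np.einsum("mkp,mkp->mp", beta, b)

    rss_full = np.tile(yty, (m, 1)).astype(float)
    for l in range(n_loc):
        rows = loc_codes == l
        Gl, Yl = G[rows], Y[rows]
        for allele in (GENO_A, GENO_B):
            M = (Gl == allele).astype(float)  # n_l x m
            cnt = M.sum(axis=0)  # m (>0 by informativeness)
            sums = M.T @ Yl  # m x P
            rss_full -= sums**2 / cnt[:, None]
    return rss_add, rss_full


def _stacked_arrays(stacked: StackedCross, trait: str):
    y = stacked.traits[trait].to_numpy(dtype=float)
    keep = np.isfinite(y)
    G = stacked.geno[keep]
    y = y[keep]
    loc_codes, loc_levels = pd.factorize(stacked.location[keep], sort=True)
    return G, y, loc_codes, len(loc_levels)


def qei_delta_lod(stacked: StackedCross, trait: str) -> pd.DataFrame:
    """Per-marker full-vs-additive delta-LOD profile.

    Returns a frame with lod_full, lod_add and delta_lod per marker; markers
    where some location lacks a genotype class (or with missing genotypes)
    are skipped with NaN entries and a logged notice.
    """
    G, y, loc_codes, n_loc = _stacked_arrays(stacked, trait)
    m = G.shape[1]
    ok = _informative_markers(G, loc_codes, n_loc)
    if (~ok).any():
        logger.warning("[skipped-marker] qei: %d uninformative markers", int((~ok).sum()))
    lod_full = np.full(m, np.nan)
    lod_add = np.full(m, np.nan)
    if ok.any():
        n = y.size
        rss_add, rss_full = _qei_rss(G[:, ok], y[:, None], loc_codes, n_loc)
        # genotype-free null: location group means
        rss_null = float((y * y).sum())
        for l in range(n_loc):
            yl = y[loc_codes == l]
            rss_null -= yl.sum() ** 2 / yl.size
        floor = 1e-12 * max(float(np.var(y)), 1e-300) * n
        ra = np.maximum(rss_add[:, 0], floor)
        rf = np.maximum(rss_full[:, 0], floor)
        lod_add[ok] = (n / 2.0) * np.log10(rss_null / ra)
        lod_full[ok] = (n / 2.0) * np.log10(rss_null / rf)
    df = stacked.genmap.to_frame()
    df["lod_full"] = lod_full
    df["lod_add"] = lod_add
    df["delta_lod"] = lod_full - lod_add
    return df


def _permute_within_strata(
    y: np.ndarray, loc_codes: np.ndarray, n_loc: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """n x n_perm matrix of within-location permutations of y."""
    Y = np.tile(y[:, None], (1, n_perm))
    for l in range(n_loc):
        rows = np.flatnonzero(loc_codes == l)
        Y[rows] = rng.permuted(Y[rows], axis=0)
    return Y


def qei_permutation_threshold(
    stacked: StackedCross,
    trait: str,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    stratified: bool = True,
    batch: int = 200,
) -> float:
    """Permutation threshold for the three-step delta-LOD procedure.

    Each permutation shuffles trait values within each location stratum
    (preserving location main effects and per-location marginals — for the
    statistics involved this is equivalent to shuffling the line-to-genotype
    assignment within strata), refits both models at every informative
    marker, subtracts the LODs, and records the genome-wide maximum; the
    (1 - alpha) empirical quantile is returned.  ``stratified=False``
    shuffles across all observations instead.
    """
    if not 0 < alpha < 1:
        raise IonQTLError("alpha must be in (0, 1)")
    if n_perm < 1:
        raise IonQTLError("n_perm must be >= 1")
    G, y, loc_codes, n_loc = _stacked_arrays(stacked, trait)
    ok = _informative_markers(G, loc_codes, n_loc)
    if not ok.any():
        raise IonQTLError("no informative markers for QEI permutations")
    Gok = G[:, ok]
    rng = np.random.default_rng(seed)
    n = y.size
    floor = 1e-12 * max(float(np.var(y)), 1e-300) * n
    maxima = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        if stratified:
            Y = _permute_within_strata(y, loc_codes, n_loc, b, rng)
        else:
            Y = rng.permuted(np.tile(y[:, None], (1, b)), axis=0)
        rss_add, rss_full = _qei_rss(Gok, Y, loc_codes, n_loc)
        delta = (n / 2.0) * np.log10(
            np.maximum(rss_add, floor) / np.maximum(rss_full, floor)
        )
        maxima[done : done + b] = delta.max(axis=0)
        done += b
    return float(np.quantile(maxima, 1.0 - alpha))


def qei_scan(
    stacked: StackedCross,
    trait: str,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    stratified: bool = True,
) -> QEIResult:
    """Full QEI analysis: delta-LOD profile, threshold, significant markers."""
    profile = qei_delta_lod(stacked, trait)
    threshold = qei_permutation_threshold(
        stacked, trait, n_perm=n_perm, alpha=alpha, seed=seed, stratified=stratified
    )
    sig = profile[profile["delta_lod"] > threshold].reset_index(drop=True)
    return QEIResult(trait=trait, profile=profile, threshold=threshold, significant=sig)


def trait_differences(cross_a: Cross, cross_b: Cross) -> Cross:
    """Between-growout trait differences on the common lines.

    The returned cross carries ``value_a - value_b`` per common line and
    trait, with genotypes and map from ``cross_a``.
    """
    if list(cross_a.genmap.marker_id) != list(cross_b.genmap.marker_id):
        raise IonQTLError("crosses do not share one genetic map")
    common = cross_a.traits.index.intersection(cross_b.traits.index)
    if len(common) < 3:
        raise IonQTLError(f"only {len(common)} common lines; need >= 3")
    cols = [c for c in cross_a.traits.columns if c in cross_b.traits.columns]
    diff = cross_a.traits.loc[common, cols] - cross_b.traits.loc[common, cols]
    return Cross(
        genmap=cross_a.genmap,
        geno=cross_a.geno.loc[common],
        traits=diff,
        env_id=f"{cross_a.env_id}-{cross_b.env_id}",
    )


def map_difference_qtl(
    diff_cross: Cross,
    trait: str,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    max_qtl: int = 10,
) -> QTLModel:
    """Stepwise QTL mapping on a between-year difference trait."""
    y = diff_cross.trait_values(trait)
    y = y[np.isfinite(y)]
    if y.size < 3 or np.ptp(y) == 0:
        logger.warning("[degenerate] difference trait %s has no variance", trait)
        return QTLModel(trait, (), 0.0, float("inf"))
    penalty = permutation_threshold(diff_cross, trait, n_perm, alpha, seed)
    return stepwise_qtl(diff_cross, trait, penalty, max_qtl)


class QEIScanner(BaseEstimator):
    """Estimator form of the location-covariate delta-LOD test.

    ``fit(X, y, locations=...)`` takes the stacked observations x markers
    genotype matrix, the trait vector, and a location label per
    observation; it computes ``delta_lod_`` per marker, ``threshold_`` and
    ``significant_``.
    """

    def __init__(
        self,
        genmap: GeneticMap | None = None,
        n_perm: int = 1000,
        alpha: float = 0.05,
        stratified: bool = True,
        random_state: int = 0,
        trait: str = "y",
    ):
        self.genmap = genmap
        self.n_perm = n_perm
        self.alpha = alpha
        self.stratified = stratified
        self.random_state = random_state
        self.trait = trait

    def fit(self, X, y, locations=None) -> "QEIScanner":
        if locations is None:
            raise IonQTLError("QEIScanner.fit requires locations=")
        if self.genmap is None:
            raise IonQTLError("QEIScanner requires a genmap")
        G = np.asarray(X, dtype=float)
        stacked = StackedCross(
            genmap=self.genmap,
            geno=G,
            traits=pd.DataFrame({self.trait: np.asarray(y, dtype=float)}),
            location=np.asarray(locations, dtype=object),
            line_id=np.array([f"L{i}" for i in range(G.shape[0])], dtype=object),
            env_id=np.asarray(locations, dtype=object),
        )
        res = qei_scan(
            stacked,
            self.trait,
            n_perm=self.n_perm,
            alpha=self.alpha,
            seed=self.random_state,
            stratified=self.stratified,
        )
        self.result_ = res
        self.delta_lod_ = res.profile["delta_lod"].to_numpy()
        self.threshold_ = res.threshold
        self.significant_ = res.significant
        self.n_features_in_ = G.shape[1]
        return self
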