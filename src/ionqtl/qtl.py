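"""Marker-regression QTL mapping.

The LOD score at a marker is the log10 likelihood ratio of the marker
regression against the null model on the same lines,
``LOD = (n/2) * log10(RSS_null / RSS_marker)``.  Scans are at markers only
(the map is dense enough that pseudomarker imputation buys little).  Lines
with a missing genotype at a marker are dropped at that marker, with the
null RSS recomputed on the same subset so the LOD remains a valid
likelihood ratio.

Genome-wide significance is the empirical (1 - alpha) quantile of the
maximum LOD over permutations that shuffle trait values across lines with
genotypes fixed.  Multi-QTL models are selected by penalized forward /
backward stepwise search over additive marker models, scored by
``model LOD - penalty * n_loci`` with the permutation threshold as the
per-QTL penalty, at most 10 loci, and no interaction terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .core import Cross, GeneticMap, IonQTLError, logger

__all__ = [
    "ScanProfile",
    "Locus",
    "QTLModel",
    "marker_lod_scan",
    "permutation_null",
    "permutation_threshold",
    "stepwise_qtl",
    "refine_positions",
    "merge_qtl",
    "MarkerScanner",
    "StepwiseQTLMapper",
]

_CAP_EPS = 1e-12  # RSS floor, as a fraction of trait variance
_MIN_N = 3  # minimum informative lines per marker


# ---------------------------------------------------------------------------
# vectorized scan kernels
# ---------------------------------------------------------------------------

def _rss_floor(y: np.ndarray) -> float:
    v = float(np.var(y))
    return _CAP_EPS * v if v > 0 else _CAP_EPS


def _scan_lod(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-marker LOD at every marker; y must be free of NaN.

    Returns (lod, n) with NaN lod where fewer than 3 informative lines.
    """
    valid = np.isfinite(G)
    n = valid.sum(axis=0).astype(float)
    Vf = valid.astype(float)
    Xv = np.where(valid, G, 0.0)
    sy = Vf.T @ y
    syy = Vf.T @ (y * y)
    sx = Xv.sum(axis=0)
    sxx = (Xv * Xv).sum(axis=0)
    sxy = Xv.T @ y
    with np.errstate(divide="ignore", invalid="ignore"):
        syy_c = syy - sy * sy / n
        sxx_c = sxx - sx * sx / n
        sxy_c = sxy - sx * sy / n
        gain = np.where(sxx_c > 0, sxy_c**2 / sxx_c, 0.0)
    rss1 = np.maximum(syy_c - gain, _rss_floor(y))
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = np.where(syy_c > 0, (n / 2.0) * np.log10(syy_c / rss1), 0.0)
    lod = np.maximum(lod, 0.0)
    lod[n < _MIN_N] = np.nan
    return lod, n


def _scan_lod_many(G: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """LOD profiles for many trait vectors at once (markers x columns)."""
    valid = np.isfinite(G)
    n = valid.sum(axis=0).astype(float)[:, None]
    Vf = valid.astype(float)
    Xv = np.where(valid, G, 0.0)
    SY = Vf.T @ Y
    SYY = Vf.T @ (Y * Y)
    sx = Xv.sum(axis=0)[:, None]
    sxx = (Xv * Xv).sum(axis=0)[:, None]
    SXY = Xv.T @ Y
    with np.errstate(divide="ignore", invalid="ignore"):
        Syy = SYY - SY * SY / n
        Sxx = sxx - sx * sx / n
        Sxy = SXY - sx * SY / n
        gain = np.where(Sxx > 0, Sxy**2 / Sxx, 0.0)
        rss1 = np.maximum(Syy - gain, _CAP_EPS * np.maximum(Y.var(axis=0), 1e-300))
        lod = np.where(Syy > 0, (n / 2.0) * np.log10(Syy / rss1), 0.0)
    lod = np.maximum(lod, 0.0)
    lod[(n < _MIN_N).ravel(), :] = np.nan
    return lod


def _model_lod(G_sel: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, int]:
    """LOD of the additive multi-locus model against the intercept-only null.

    Complete-case over the selected loci.  Returns (lod, coefficients
    including intercept first, n).
    """
    if G_sel.ndim == 1:
        G_sel = G_sel[:, None]
    rows = np.isfinite(G_sel).all(axis=1) & np.isfinite(y)
    Gs, ys = G_sel[rows], y[rows]
    n = int(rows.sum())
    if n < _MIN_N:
        return 0.0, np.zeros(G_sel.shape[1] + 1), n
    X = np.column_stack([np.ones(n), Gs])
    beta, *_ = np.linalg.lstsq(X, ys, rcond=None)
    r = ys - X @ beta
    rss = float(r @ r)
    rss0 = float(((ys - ys.mean()) ** 2).sum())
    if rss0 <= 0:
        return 0.0, beta, n
    floor = _rss_floor(ys) * n
    if rss < floor:
        logger.warning("[capped-lod] perfect fit capped at RSS floor")
        rss = floor
    return (n / 2.0) * np.log10(rss0 / rss), beta, n


def _fwl_scan(
    Gc: np.ndarray, ys: np.ndarray, D: np.ndarray, null: str = "intercept"
) -> np.ndarray:
    """Per-marker LOD with design ``D`` (intercept included) as covariates.

    With ``null="intercept"`` the LOD compares ``y ~ D + g`` against the
    intercept-only model (the multi-QTL model LOD used by stepwise search);
    with ``null="design"`` it compares against ``y ~ D`` (a covariate scan).
    Uses Frisch-Waugh residualization; exact for markers with no missing
    values beyond the rows already dropped, a close approximation otherwise.
    """
    n_rows = ys.size
    by, *_ = np.linalg.lstsq(D, ys, rcond=None)
    ry = ys - D @ by
    valid = np.isfinite(Gc)
    if not valid.all():
        col_mean = np.nanmean(np.where(valid, Gc, np.nan), axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        G_fill = np.where(valid, Gc, col_mean)
    else:
        G_fill = Gc
    BG, *_ = np.linalg.lstsq(D, G_fill, rcond=None)
    RG = np.where(valid, Gc - D @ BG, 0.0)
    Vf = valid.astype(float)
    n = valid.sum(axis=0).astype(float)
    sry2 = Vf.T @ (ry * ry)
    srr = (RG * RG).sum(axis=0)
    srxy = RG.T @ ry
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(srr > 1e-10 * n_rows, srxy**2 / srr, 0.0)
    rss1 = np.maximum(sry2 - gain, _rss_floor(ys) * np.maximum(n, 1))
    if null == "design":
        rss0 = np.maximum(sry2, _rss_floor(ys) * np.maximum(n, 1))
    else:
        rss0 = float(((ys - ys.mean()) ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = np.where(rss0 > 0, (n / 2.0) * np.log10(rss0 / rss1), 0.0)
    lod = np.maximum(lod, 0.0)
    lod[n < _MIN_N] = np.nan
    return lod


def _forward_scan(
    G: np.ndarray, y: np.ndarray, sel: Sequence[int], candidates: np.ndarray | None = None
) -> np.ndarray:
    """Model LOD of sel + [j] for every candidate marker j."""
    m = G.shape[1]
    cand = np.arange(m) if candidates is None else np.asarray(candidates)
    if not sel:
        lod, _ = _scan_lod(G[:, cand], y)
        return lod
    Gsel = G[:, list(sel)]
    rows = np.isfinite(Gsel).all(axis=1) & np.isfinite(y)
    n_rows = int(rows.sum())
    if n_rows < _MIN_N + len(sel):
        return np.full(cand.size, np.nan)
    D = np.column_stack([np.ones(n_rows), Gsel[rows]])
    return _fwl_scan(G[rows][:, cand], y[rows], D)


# ---------------------------------------------------------------------------
# public scan API
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Locus:
    """One selected QTL: map location, additive effect, LOD contribution."""

    marker_id: str
    chromosome: int
    position_cm: float
    effect: float  # A-vs-B trait mean difference
    lod_drop: float
    marker_index: int = -1


@dataclass(frozen=True)
class QTLModel:
    """A fitted additive multi-QTL model for one trait."""

    trait: str
    loci: tuple[Locus, ...]
    model_lod: float
    penalty: float
    intercept: float = 0.0

    @property
    def penalized_lod(self) -> float:
        return self.model_lod - self.penalty * len(self.loci)

    def positions(self) -> list[tuple[int, float]]:
        return [(l.chromosome, l.position_cm) for l in self.loci]


def ScanProfile(genmap: GeneticMap, lod: np.ndarray, n: np.ndarray | None = None) -> pd.DataFrame:
    """Assemble a scan profile table (one row per map marker)."""
    df = genmap.to_frame()
    df["lod"] = lod
    if n is not None:
        df["n"] = n.astype(int)
    return df


def _prepare(cross: Cross, trait: str) -> tuple[np.ndarray, np.ndarray]:
    y = cross.trait_values(trait)
    G = cross.geno_for_traits()
    keep = np.isfinite(y)
    return G[keep], y[keep]


def marker_lod_scan(
    cross: Cross, trait: str, covariates: np.ndarray | None = None
) -> pd.DataFrame:
    """Single-marker LOD scan across the genome.

    ``covariates`` is an optional design block aligned with the trait rows
    of the cross; with covariates the LOD compares
    ``trait ~ covariates + genotype`` against ``trait ~ covariates``.
    """
    y = cross.trait_values(trait)
    G = cross.geno_for_traits()
    keep = np.isfinite(y)
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        keep &= np.isfinite(C).all(axis=1)
        scanner = MarkerScanner().fit(G[keep], y[keep], covariates=C[keep])
    else:
        scanner = MarkerScanner().fit(G[keep], y[keep])
    if np.isnan(scanner.lod_).any():
        logger.warning(
            "[skipped-marker] %d markers with <%d informative lines",
            int(np.isnan(scanner.lod_).sum()), _MIN_N,
        )
    return ScanProfile(cross.genmap, scanner.lod_)


def permutation_null(
    cross: Cross, trait: str, n_perm: int, seed: int, batch: int = 250
) -> np.ndarray:
    """Genome-wide max-LOD null distribution from trait permutations."""
    if n_perm < 1:
        raise IonQTLError("n_perm must be >= 1")
    G, y = _prepare(cross, trait)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        Y = rng.permuted(np.tile(y, (b, 1)), axis=1).T
        lod = _scan_lod_many(G, Y)
        maxima[done : done + b] = np.nanmax(lod, axis=0)
        done += b
    return maxima


def permutation_threshold(
    cross: Cross,
    trait: str,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """(1 - alpha) quantile of the genome-wide max LOD under permutation."""
    if not 0 < alpha < 1:
        raise IonQTLError("alpha must be in (0, 1)")
    maxima = permutation_null(cross, trait, n_perm, seed)
    return float(np.quantile(maxima, 1.0 - alpha))


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

def _build_model(
    cross: Cross, trait: str, sel: Sequence[int], penalty: float
) -> QTLModel:
    G, y = _prepare(cross, trait)
    sel = sorted(
        sel,
        key=lambda j: (cross.genmap.chromosome[j], cross.genmap.position_cm[j]),
    )
    if not sel:
        return QTLModel(trait, (), 0.0, penalty)
    full_lod, beta, _ = _model_lod(G[:, sel], y)
    loci = []
    for k, j in enumerate(sel):
        rest = [s for s in sel if s != j]
        sub_lod = _model_lod(G[:, rest], y)[0] if rest else 0.0
        loci.append(
            Locus(
                marker_id=str(cross.genmap.marker_id[j]),
                chromosome=int(cross.genmap.chromosome[j]),
                position_cm=float(cross.genmap.position_cm[j]),
                effect=float(beta[k + 1]),
                lod_drop=float(full_lod - sub_lod),
                marker_index=int(j),
            )
        )
    return QTLModel(trait, tuple(loci), float(full_lod), penalty, float(beta[0]))


def _stepwise_search(
    G: np.ndarray, y: np.ndarray, penalty: float, max_qtl: int
) -> tuple[list[int], float]:
    """Forward/backward penalized search; returns (best selection, model lod)."""
    sel: list[int] = []
    best_sel: list[int] = []
    best_plod = 0.0
    cur_plod = 0.0
    tol = 1e-9
    while len(sel) < max_qtl:
        lods = _forward_scan(G, y, sel)
        for j in sel:
            lods[j] = np.nan
        if np.all(np.isnan(lods)):
            break
        j = int(np.nanargmax(lods))  # first maximum: lowest chrom, then position
        ml = float(lods[j])
        plod = ml - penalty * (len(sel) + 1)
        if plod <= cur_plod + tol:
            break
        sel.append(j)
        cur_plod = plod
        if plod > best_plod + tol:
            best_plod, best_sel = plod, list(sel)
    # backward elimination from the forward endpoint
    while len(sel) > 1:
        improved = False
        base = cur_plod
        drop_at, drop_plod = -1, base
        for i in range(len(sel)):
            rest = sel[:i] + sel[i + 1 :]
            ml = _model_lod(G[:, rest], y)[0]
            plod = ml - penalty * len(rest)
            if plod > drop_plod + tol:
                drop_plod, drop_at = plod, i
        if drop_at >= 0:
            sel.pop(drop_at)
            cur_plod = drop_plod
            improved = True
            if cur_plod > best_plod + tol:
                best_plod, best_sel = cur_plod, list(sel)
        if not improved:
            break
    return (best_sel, best_plod) if best_plod > tol else ([], 0.0)


def stepwise_qtl(
    cross: Cross, trait: str, penalty: float, max_qtl: int = 10
) -> QTLModel:
    """Penalized additive stepwise multi-QTL model selection.

    Forward steps add the marker maximizing the model LOD while the
    penalized LOD (model LOD minus ``penalty`` per locus) increases and the
    locus count stays at most ``max_qtl``; backward steps then drop loci
    whose removal raises the penalized LOD.  The penalized-LOD-maximal model
    visited is returned (empty if no model beats the null).
    """
    if not penalty > 0:
        raise IonQTLError("penalty must be > 0")
    G, y = _prepare(cross, trait)
    if len(y) < _MIN_N or np.ptp(y) == 0:
        logger.warning("[degenerate] trait %s has no usable variance", trait)
        return QTLModel(trait, (), 0.0, penalty)
    sel, _ = _stepwise_search(G, y, penalty, max_qtl)
    return _build_model(cross, trait, sel, penalty)


def refine_positions(cross: Cross, model: QTLModel, seed: int = 0, max_iter: int = 10) -> QTLModel:
    """Iteratively relocate each locus to its chromosome-wide optimum.

    Loci are visited in seeded-random order; each is re-scanned along its
    own chromosome holding the other loci fixed as additive covariates and
    moved to the maximum-LOD marker.  The model LOD never decreases.
    """
    if not model.loci:
        raise IonQTLError("cannot refine an empty model")
    G, y = _prepare(cross, model.trait)
    rng = np.random.default_rng(seed)
    sel = [l.marker_index for l in model.loci]
    cur_lod = _model_lod(G[:, sel], y)[0]
    for _ in range(max_iter):
        moved = False
        for i in rng.permutation(len(sel)):
            chrom = int(cross.genmap.chromosome[sel[i]])
            cand = cross.genmap.chrom_indices(chrom)
            others = [s for k, s in enumerate(sel) if k != i]
            lods = _forward_scan(G, y, others, candidates=cand)
            if np.all(np.isnan(lods)):
                continue
            j = int(cand[np.nanargmax(lods)])
            new_lod = float(np.nanmax(lods))
            if j != sel[i] and new_lod > cur_lod + 1e-9:
                sel[i] = j
                cur_lod = new_lod
                moved = True
        if not moved:
            break
    return _build_model(cross, model.trait, sel, model.penalty)


def merge_qtl(
    models: Iterable[tuple[str, QTLModel]], window_cm: float = 5.0
) -> pd.DataFrame:
    """Merge per-environment QTL models into cross-environment loci.

    Loci of the same trait on the same chromosome are single-linkage
    clustered with linkage distance ``window_cm``: peaks within 5 cM of any
    cluster member are the same QTL.  Returns one row per merged locus.
    """
    rows = []
    for env_id, model in models:
        for loc in model.loci:
            rows.append(
                {
                    "trait": model.trait,
                    "chromosome": loc.chromosome,
                    "position_cm": loc.position_cm,
                    "env_id": env_id,
                    "lod": loc.lod_drop,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=[
                "trait", "chromosome", "pos_min_cm", "pos_max_cm",
                "n_envs", "environments", "lod_by_env",
            ]
        )
    df = pd.DataFrame(rows).sort_values(["trait", "chromosome", "position_cm"])
    out = []
    for (trait, chrom), sub in df.groupby(["trait", "chromosome"], sort=True):
        pos = sub["position_cm"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > window_cm)
        cluster_id = np.zeros(len(sub), dtype=int)
        for b in breaks:
            cluster_id[b + 1 :] += 1
        sub = sub.assign(_c=cluster_id)
        for _, cl in sub.groupby("_c"):
            envs = sorted(cl["env_id"].unique())
            out.append(
                {
                    "trait": trait,
                    "chromosome": chrom,
                    "pos_min_cm": float(cl["position_cm"].min()),
                    "pos_max_cm": float(cl["position_cm"].max()),
                    "n_envs": len(envs),
                    "environments": ";".join(envs),
                    "lod_by_env": ";".join(
                        f"{r.env_id}:{r.lod:.2f}" for r in cl.itertuples()
                    ),
                }
            )
    return pd.DataFrame(out).sort_values(
        ["trait", "chromosome", "pos_min_cm"], ignore_index=True
    )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class MarkerScanner(BaseEstimator):
    """Single-marker LOD genome scanner.

    ``fit(X, y)`` takes a lines x markers genotype matrix (numeric codes
    +-0.5, NaN missing) and a trait vector, and computes ``lod_`` per
    marker.  Optional ``covariates`` (passed to ``fit``) enter both the
    null and the marker model.
    """

    def fit(self, X, y, covariates: np.ndarray | None = None) -> "MarkerScanner":
        G = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if G.shape[0] != y.shape[0]:
            raise IonQTLError("X and y have different numbers of lines")
        keep = np.isfinite(y)
        if covariates is not None:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            keep &= np.isfinite(C).all(axis=1)
        G, y = G[keep], y[keep]
        if y.size < _MIN_N:
            raise IonQTLError("need >= 3 lines with trait and genotype data")
        if np.ptp(y) == 0:
            logger.warning("[degenerate] zero-variance trait; all LOD = 0")
            self.lod_ = np.zeros(G.shape[1])
            self.n_ = np.isfinite(G).sum(axis=0)
            return self
        if covariates is None:
            lod, n = _scan_lod(G, y)
        else:
            D = np.column_stack([np.ones(y.size), C[keep]])
            lod = _fwl_scan(G, y, D, null="design")
            n = np.isfinite(G).sum(axis=0)
        self.lod_ = lod
        self.n_ = n
        self.n_features_in_ = G.shape[1]
        return self


class StepwiseQTLMapper(BaseEstimator, RegressorMixin):
    """Penalized stepwise additive multi-QTL model, sklearn style.

    Parameters
    ----------
    genmap : GeneticMap
        Marker coordinates for the columns of X.
    penalty : float or None
        Per-QTL penalty on the model LOD; if None it is derived as the
        (1 - alpha) quantile of ``n_perm`` genome-wide max-LOD permutations.
    n_perm, alpha, random_state
        Permutation settings used when ``penalty`` is None.
    max_qtl : int
        Locus cap for the model (default 10).
    refine : bool
        Re-optimize each locus position after selection.
    """

    def __init__(
        self,
        genmap: GeneticMap | None = None,
        penalty: float | None = None,
        n_perm: int = 1000,
        alpha: float = 0.05,
        max_qtl: int = 10,
        refine: bool = False,
        random_state: int = 0,
        trait: str = "y",
    ):
        self.genmap = genmap
        self.penalty = penalty
        self.n_perm = n_perm
        self.alpha = alpha
        self.max_qtl = max_qtl
        self.refine = refine
        self.random_state = random_state
        self.trait = trait

    def _as_cross(self, X, y) -> Cross:
        if self.genmap is None:
            raise IonQTLError("StepwiseQTLMapper requires a genmap")
        G = np.asarray(X, dtype=float)
        lines = [f"L{i}" for i in range(G.shape[0])]
        geno = pd.DataFrame(G, index=lines, columns=list(self.genmap.marker_id))
        traits = pd.DataFrame({self.trait: np.asarray(y, dtype=float)}, index=lines)
        return Cross(self.genmap, geno, traits)

    def fit(self, X, y) -> "StepwiseQTLMapper":
        cross = self._as_cross(X, y)
        if self.penalty is None:
            self.penalty_ = permutation_threshold(
                cross, self.trait, self.n_perm, self.alpha, self.random_state
            )
        else:
            self.penalty_ = float(self.penalty)
        model = stepwise_qtl(cross, self.trait, self.penalty_, self.max_qtl)
        if self.refine and model.loci:
            model = refine_positions(cross, model, seed=self.random_state)
        self.model_ = model
        self.loci_ = model.loci
        self.model_lod_ = model.model_lod
        self.intercept_ = model.intercept
        self.coef_ = np.zeros(np.asarray(X).shape[1])
        for loc in model.loci:
            self.coef_[loc.marker_index] = loc.effect
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        G = np.nan_to_num(np.asarray(X, dtype=float))
        return self.intercept_ + G @ self.coef_
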