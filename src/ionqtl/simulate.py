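"""Synthetic multi-environment RIL ionomics data.

Emulates the statistical structure of a multi-environment single-seed
ionomics study on an intermated RIL population: ~300 homozygous lines
genotyped at thousands of biallelic SNPs on 10 chromosomes, grown as
overlapping subsets in 10 environments (three with replicate rows), with
per-seed raw element concentrations confounded by seed weight, analytical
run batches, and heavy-tailed analytical outliers.

Map distances are treated as realized RIL recombination distances: the
intermated map already incorporates the map expansion from intermating, so
no extra selfing-expansion transform is applied.  Genotypes follow a Markov
chain along each chromosome with Haldane switch probabilities
``r = (1 - exp(-2 d / 100)) / 2`` for an inter-marker gap of ``d`` cM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ELEMENTS, GENO_A, GENO_B, GeneticMap, IonQTLError, logger

__all__ = [
    "EnvironmentSpec",
    "QTLEffect",
    "WeightModel",
    "SimScenario",
    "make_map",
    "simulate_ril_genotypes",
    "simulate_env_traits",
    "simulate_seed_measurements",
    "haldane_r",
]


def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def make_map(n_chr: int, markers_per_chr: int, chr_length_cm: float) -> GeneticMap:
    """Evenly spaced markers from 0 to ``chr_length_cm`` on each chromosome."""
    if n_chr < 1:
        raise IonQTLError(f"n_chr must be >= 1, got {n_chr}")
    if markers_per_chr < 2:
        raise IonQTLError(f"markers_per_chr must be >= 2, got {markers_per_chr}")
    if not chr_length_cm > 0:
        raise IonQTLError(f"chr_length_cm must be > 0, got {chr_length_cm}")
    pos = np.linspace(0.0, float(chr_length_cm), int(markers_per_chr))
    chrom = np.repeat(np.arange(1, n_chr + 1), markers_per_chr)
    position = np.tile(pos, n_chr)
    names = np.array(
        [f"c{c}m{i + 1}" for c in range(1, n_chr + 1) for i in range(markers_per_chr)],
        dtype=object,
    )
    return GeneticMap(names, chrom, position)


@dataclass(frozen=True)
class EnvironmentSpec:
    """One growout: its id, how many lines were planted, replicate rows."""

    env_id: str
    n_lines: int
    n_reps: int = 1


@dataclass(frozen=True)
class QTLEffect:
    """A simulated additive QTL.

    ``effects`` is either one additive effect (A minus B mean difference, in
    trait units) applied in every environment, or a mapping env_id -> effect.
    Environments absent from the mapping get effect 0.
    """

    trait: str
    chromosome: int
    position_cm: float
    effects: float | Mapping[str, float] = 1.0

    def effect_in(self, env_id: str) -> float:
        if isinstance(self.effects, Mapping):
            return float(self.effects.get(env_id, 0.0))
        return float(self.effects)


@dataclass(frozen=True)
class WeightModel:
    """Single-kernel weight distribution and weight-independent contamination.

    Maize kernels weigh ~250 mg with wide variation between lines and seeds.
    ``contamination`` is an additive, weight-independent term on the raw
    concentration scale — the artifact that makes naive weight division
    overestimate concentrations in small seeds.
    """

    mean_mg: float = 250.0
    sd_mg: float = 50.0
    contamination: float = 0.0


# Growout subsets of the study design: six locations over five years,
# 82-256 lines each, replicate rows in NY05 / NC06 / MO06 only.
_DEFAULT_ENVIRONMENTS = (
    EnvironmentSpec("FL05", 220, 1),
    EnvironmentSpec("FL06", 118, 1),
    EnvironmentSpec("IN09", 193, 1),
    EnvironmentSpec("IN10", 168, 1),
    EnvironmentSpec("NC06", 197, 3),
    EnvironmentSpec("NY05", 256, 3),
    EnvironmentSpec("NY06", 82, 1),
    EnvironmentSpec("NY12", 168, 1),
    EnvironmentSpec("MO06", 97, 2),
    EnvironmentSpec("SA10", 87, 1),
)


@dataclass(frozen=True)
class SimScenario:
    """Full description of one simulated study.

    Defaults reproduce the design of the source study: a 302-line intermated
    RIL pool genotyped at ~4217 SNPs on 10 chromosomes, grown as overlapping
    subsets in 10 environments, with 20 elemental traits.
    """

    n_lines: int = 302
    n_chr: int = 10
    markers_per_chr: int = 422
    chr_length_cm: float = 700.0
    environments: tuple[EnvironmentSpec, ...] = _DEFAULT_ENVIRONMENTS
    traits: tuple[str, ...] = ELEMENTS
    qtl_effects: tuple[QTLEffect, ...] = ()
    env_main_effects: Mapping[str, float] = field(default_factory=dict)
    mu: float = 0.0
    residual_sd: float = 1.0
    weight: WeightModel = field(default_factory=WeightModel)
    n_runs: int = 4
    run_offsets: tuple[float, ...] = ()
    measurement_sd: float = 0.05
    outlier_rate: float = 0.01
    missing_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.residual_sd > 0:
            raise IonQTLError("residual_sd must be > 0")
        if not 0 <= self.outlier_rate < 1:
            raise IonQTLError("outlier_rate must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise IonQTLError("missing_rate must be in [0, 1)")
        for env in self.environments:
            if env.n_lines > self.n_lines:
                raise IonQTLError(
                    f"{env.env_id}: subset size {env.n_lines} exceeds n_lines"
                )
            if env.n_reps < 1:
                raise IonQTLError(f"{env.env_id}: n_reps must be >= 1")
        if self.run_offsets and len(self.run_offsets) != self.n_runs:
            raise IonQTLError("run_offsets length must equal n_runs")

    def make_map(self) -> GeneticMap:
        return make_map(self.n_chr, self.markers_per_chr, self.chr_length_cm)

    def run_offset(self, k: int) -> float:
        return self.run_offsets[k] if self.run_offsets else 0.0


def _rng(seed: int, *offsets: int) -> np.random.Generator:
    """Deterministic sub-stream: one root seed plus fixed integer offsets."""
    return np.random.default_rng([int(seed)] + [int(o) for o in offsets])


def simulate_ril_genotypes(
    genmap: GeneticMap,
    n_lines: int,
    seed: int,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Simulate homozygous RIL genotypes as Markov chains along chromosomes.

    The first marker of each chromosome is A or B with probability 1/2;
    adjacent markers switch allele with the Haldane probability for their
    map gap.  Returns a lines x markers DataFrame of numeric codes.
    """
    if n_lines < 1:
        raise IonQTLError("n_lines must be >= 1")
    rng = _rng(seed, 0)
    cols = []
    for c in np.unique(genmap.chromosome):
        idx = genmap.chrom_indices(c)
        m = idx.size
        first = np.where(rng.random(n_lines) < 0.5, GENO_A, GENO_B)
        if m == 1:
            cols.append(first[:, None])
            continue
        gaps = np.diff(genmap.position_cm[idx])
        r = haldane_r(gaps)
        switch = rng.random((n_lines, m - 1)) < r[None, :]
        signs = np.hstack([np.ones((n_lines, 1)), 1.0 - 2.0 * switch])
        cols.append(first[:, None] * np.cumprod(signs, axis=1))
    geno = np.hstack(cols)
    if missing_rate > 0:
        miss = rng.random(geno.shape) < missing_rate
        geno = np.where(miss, np.nan, geno)
    lines = [f"RIL{i + 1:04d}" for i in range(n_lines)]
    return pd.DataFrame(geno, index=lines, columns=list(genmap.marker_id))


def _qtl_marker_index(genmap: GeneticMap, q: QTLEffect) -> int:
    idx = genmap.chrom_indices(q.chromosome)
    if idx.size == 0:
        raise IonQTLError(f"QTL chromosome {q.chromosome} is not on the map")
    lo = genmap.position_cm[idx].min()
    hi = genmap.position_cm[idx].max()
    if not lo <= q.position_cm <= hi:
        raise IonQTLError(
            f"QTL position {q.position_cm} cM is off chromosome {q.chromosome} "
            f"({lo}-{hi} cM)"
        )
    return genmap.nearest_marker(q.chromosome, q.position_cm)


def simulate_env_traits(
    geno: pd.DataFrame,
    scenario: SimScenario,
    genmap: GeneticMap | None = None,
) -> dict[str, pd.DataFrame]:
    """Simulate line-level trait values for every environment.

    For environment ``e`` and line ``i``:
    ``y = mu + sum_k a_{k,e} * g_{ik} + E_e + eps``, with genotype ``g``
    coded +-1/2 at the marker nearest each QTL, environment offset ``E_e``
    and ``eps ~ Normal(0, residual_sd^2)`` drawn independently per replicate
    row.  Only the environment's line subset receives values.

    Returns a dict env_id -> DataFrame with columns ``line_id``, ``rep_id``
    and one column per trait.
    """
    genmap = genmap if genmap is not None else scenario.make_map()
    qtl_idx = [(q, _qtl_marker_index(genmap, q)) for q in scenario.qtl_effects]
    all_lines = np.asarray(geno.index, dtype=object)
    G = geno.to_numpy(dtype=float)
    out: dict[str, pd.DataFrame] = {}
    for e_i, env in enumerate(scenario.environments):
        rng = _rng(scenario.rng_seed, 1, e_i)
        sub = np.sort(rng.choice(len(all_lines), size=env.n_lines, replace=False))
        n = sub.size
        e_off = float(scenario.env_main_effects.get(env.env_id, 0.0))
        rows = {
            "line_id": np.repeat(all_lines[sub], env.n_reps),
            "rep_id": np.tile(np.arange(1, env.n_reps + 1), n),
        }
        for trait in scenario.traits:
            base = np.full(n, scenario.mu + e_off)
            for q, m_idx in qtl_idx:
                if q.trait != trait:
                    continue
                g = G[sub, m_idx]
                base = base + q.effect_in(env.env_id) * np.nan_to_num(g)
            vals = np.repeat(base, env.n_reps) + rng.normal(
                0.0, scenario.residual_sd, n * env.n_reps
            )
            rows[trait] = vals
        df = pd.DataFrame(rows)
        # interleave reps per line -> sort not needed; keep (line, rep) order
        out[env.env_id] = df
    return out


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal draws truncated to be strictly positive (resampling)."""
    x = rng.normal(mean, sd, n)
    bad = x <= 0
    while bad.any():
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = x <= 0
    return x


def simulate_seed_measurements(
    env_traits: Mapping[str, pd.DataFrame],
    scenario: SimScenario,
    return_outliers: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Turn line-level trait values into a raw single-seed measurement table.

    Each replicate row becomes one seed.  Per seed and element:
    ``raw = weight * trait + contamination + run_offset + noise``; a
    fraction ``outlier_rate`` of seeds per element additionally receives an
    offset of 12 group-MADs (random sign), injected only into
    (line, environment) groups of >= 3 seeds so every injected outlier is
    recoverable by the MAD rule.  Runs are assigned round-robin in
    contiguous blocks over the full table.

    With ``return_outliers=True`` also returns a (row, element) truth table
    of the injected outliers.
    """
    frames = []
    env_ids = list(env_traits)
    for e_i, env_id in enumerate(env_ids):
        df = env_traits[env_id]
        rng = _rng(scenario.rng_seed, 2, e_i)
        n = len(df)
        weight = _truncated_normal(
            rng, scenario.weight.mean_mg, scenario.weight.sd_mg, n
        )
        block = {
            "line_id": df["line_id"].to_numpy(),
            "env_id": np.full(n, env_id, dtype=object),
            "rep_id": df["rep_id"].astype(str).to_numpy(),
            "weight_mg": weight,
        }
        for trait in scenario.traits:
            noise = rng.normal(0.0, scenario.measurement_sd, n)
            block[f"raw_{trait}"] = (
                weight * df[trait].to_numpy()
                + scenario.weight.contamination
                + noise
            )
        frames.append(pd.DataFrame(block))
    seeds = pd.concat(frames, ignore_index=True)

    # run batches: contiguous blocks in row order
    n_total = len(seeds)
    block_size = max(1, math.ceil(n_total / max(1, scenario.n_runs)))
    run_k = np.minimum(np.arange(n_total) // block_size, scenario.n_runs - 1)
    seeds.insert(3, "run_id", np.array([f"run{k + 1}" for k in run_k], dtype=object))
    for trait in scenario.traits:
        seeds[f"raw_{trait}"] = seeds[f"raw_{trait}"].to_numpy() + np.array(
            [scenario.run_offset(k) for k in run_k]
        )

    truth_rows: list[dict] = []
    if scenario.outlier_rate > 0:
        rng = _rng(scenario.rng_seed, 3)
        group_codes, _ = pd.factorize(
            seeds["line_id"].astype(str) + "\x00" + seeds["env_id"].astype(str)
        )
        sizes = np.bincount(group_codes)
        # one contaminated seed per group at most, so a single extreme value
        # can never corrupt its own group's median/MAD beyond recovery
        eligible_groups = np.flatnonzero(sizes >= 3)
        n_eligible_seeds = int(sizes[eligible_groups].sum())
        for trait in scenario.traits:
            col = f"raw_{trait}"
            n_out = min(
                int(round(scenario.outlier_rate * n_eligible_seeds)),
                eligible_groups.size,
            )
            if n_out == 0:
                continue
            x = seeds[col].to_numpy().copy()
            hit_groups = rng.choice(eligible_groups, size=n_out, replace=False)
            pick = np.array(
                [rng.choice(np.flatnonzero(group_codes == g)) for g in hit_groups]
            )
            sign = np.where(rng.random(n_out) < 0.5, -1.0, 1.0)
            factor = 12.0
            for _ in range(30):  # amplify until every injection scores > threshold
                for k, (i, g) in enumerate(zip(pick, hit_groups)):
                    rows = np.flatnonzero(group_codes == g)
                    others = x[rows[rows != i]]
                    med = float(np.median(others))
                    mad = float(np.median(np.abs(others - med)))
                    scale = mad if mad > 0 else max(scenario.measurement_sd, 1e-6)
                    x[i] = med + sign[k] * factor * scale
                med_g = pd.Series(x).groupby(group_codes).transform("median").to_numpy()
                mad_g = (
                    pd.Series(x)
                    .groupby(group_codes)
                    .transform(lambda v: float(np.median(np.abs(v - v.median()))))
                    .to_numpy()
                )
                scores = np.where(
                    mad_g[pick] > 0, np.abs(x[pick] - med_g[pick]) / mad_g[pick], np.inf
                )
                if (scores > 6.5).all():
                    break
                factor *= 2.0
            seeds[col] = x
            truth_rows.extend({"row": int(i), "element": trait} for i in pick)
    if return_outliers:
        truth = pd.DataFrame(truth_rows, columns=["row", "element"])
        return seeds, truth
    return seeds
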