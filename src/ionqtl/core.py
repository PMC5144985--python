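"""Shared domain types: genetic maps, crosses, and genotype coding.

Genotypes of recombinant inbred lines (RILs) are biallelic and homozygous,
and are coded numerically as +0.5 (allele A), -0.5 (allele B) or NaN
(missing).  With this coding the regression coefficient of a trait on a
marker equals the A-vs-B mean difference, i.e. the additive QTL effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ionqtl")

#: numeric genotype codes
GENO_A = 0.5
GENO_B = -0.5

#: the 20 elements profiled in maize kernels by ICP-MS, in periodic-table order
ELEMENTS = (
    "B", "Na", "Mg", "Al", "P", "S", "K", "Ca", "Mn", "Fe",
    "Co", "Ni", "Cu", "Zn", "As", "Se", "Rb", "Sr", "Mo", "Cd",
)


class IonQTLError(ValueError):
    """Base class for argument and state errors raised by this package."""


@dataclass(frozen=True)
class GeneticMap:
    """Marker positions on a genetic map.

    Parameters
    ----------
    marker_id : array of str
        Unique marker names.
    chromosome : array of int
        Chromosome of each marker (1..C).
    position_cm : array of float
        Genetic position in centimorgans; nondecreasing within chromosome.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_cm: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_id", np.asarray(self.marker_id, dtype=object))
        object.__setattr__(self, "chromosome", np.asarray(self.chromosome, dtype=int))
        object.__setattr__(self, "position_cm", np.asarray(self.position_cm, dtype=float))
        if not (len(self.marker_id) == len(self.chromosome) == len(self.position_cm)):
            raise IonQTLError("map fields must have equal length")
        if len(np.unique(self.marker_id)) != len(self.marker_id):
            raise IonQTLError("marker_id values must be unique")
        if np.any(self.position_cm < 0):
            raise IonQTLError("positions must be non-negative")
        for c in np.unique(self.chromosome):
            pos = self.position_cm[self.chromosome == c]
            if np.any(np.diff(pos) < 0):
                raise IonQTLError(f"positions not nondecreasing on chromosome {c}")

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chromosome)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "position_cm": self.position_cm,
            }
        )

    def chrom_indices(self, chrom: int) -> np.ndarray:
        """Indices of the markers on one chromosome, in map order."""
        return np.flatnonzero(self.chromosome == int(chrom))

    def nearest_marker(self, chrom: int, position_cm: float) -> int:
        """Index of the marker on ``chrom`` nearest ``position_cm``.

        Ties are broken toward the lower position.
        """
        idx = self.chrom_indices(chrom)
        if idx.size == 0:
            raise IonQTLError(f"no markers on chromosome {chrom}")
        d = np.abs(self.position_cm[idx] - float(position_cm))
        return int(idx[np.argmin(d)])  # argmin takes the first (lower-position) tie


@dataclass
class Cross:
    """Genotypes, genetic map and line-level traits for one environment.

    ``geno`` is a lines x markers DataFrame of numeric genotype codes and
    ``traits`` a lines x traits DataFrame; trait rows must be a subset of
    the genotyped lines.
    """

    genmap: GeneticMap
    geno: pd.DataFrame
    traits: pd.DataFrame
    env_id: str = ""

    def __post_init__(self) -> None:
        if list(self.geno.columns) != list(self.genmap.marker_id):
            raise IonQTLError("genotype columns do not match the map markers")
        missing = self.traits.index.difference(self.geno.index)
        if len(missing):
            raise IonQTLError(
                f"trait rows not among genotyped lines: {list(missing)[:5]}"
            )
        vals = self.geno.to_numpy(dtype=float)
        bad = np.isfinite(vals) & (vals != GENO_A) & (vals != GENO_B)
        if bad.any():
            raise IonQTLError("genotype codes must be +0.5 (A), -0.5 (B) or NaN")

    @property
    def n_lines(self) -> int:
        return len(self.traits.index)

    def geno_for_traits(self) -> np.ndarray:
        """Genotype matrix aligned to the trait rows (float, NaN = missing)."""
        return self.geno.reindex(self.traits.index).to_numpy(dtype=float)

    def trait_values(self, trait: str) -> np.ndarray:
        if trait not in self.traits.columns:
            raise IonQTLError(f"unknown trait {trait!r} in cross {self.env_id!r}")
        return self.traits[trait].to_numpy(dtype=float)


def validate_positive(name: str, value: float) -> None:
    if not value > 0:
        raise IonQTLError(f"{name} must be positive, got {value!r}")
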