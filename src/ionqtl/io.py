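"""Readers/writers for the cross and seed-table formats, reports, and config.

The cross file is a rotated CSV: row 1 holds trait names then marker names,
row 2 leaves trait cells empty and gives chromosome ids under markers,
row 3 likewise gives cM positions, and each following row is one RIL with
trait values then genotype codes A / B / - ("-" = missing).  An ``id``
trait column, when present, carries the line identifiers.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import Cross, GENO_A, GENO_B, GeneticMap, IonQTLError, logger
from .heritability import HeritabilityResult
from .qtl import QTLModel

__all__ = [
    "read_cross_csv",
    "write_cross_csv",
    "read_seed_csv",
    "write_seed_csv",
    "write_report",
    "RunConfig",
    "load_config",
]

_GENO_IN = {"A": GENO_A, "B": GENO_B, "-": np.nan, "−": np.nan, "": np.nan}
_GENO_OUT = {GENO_A: "A", GENO_B: "B"}


class CrossParseError(IonQTLError):
    """Malformed cross file; message names the offending row and column."""


def read_cross_csv(path: str | Path, env_id: str | None = None) -> Cross:
    """Read a rotated-dialect cross CSV into a :class:`Cross`."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise CrossParseError(f"{path.name}: need header rows plus >= 1 line row")
    header, chrom_row, pos_row = rows[0], rows[1], rows[2]
    width = len(header)
    for r_i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise CrossParseError(
                f"{path.name}: row {r_i} has {len(row)} cells, expected {width}"
            )
    is_marker = [c.strip() != "" for c in chrom_row]
    trait_cols = [j for j in range(width) if not is_marker[j]]
    marker_cols = [j for j in range(width) if is_marker[j]]
    if not marker_cols:
        raise CrossParseError(f"{path.name}: no marker columns (row 2 all empty)")
    try:
        chrom = np.array([int(chrom_row[j]) for j in marker_cols])
    except ValueError as err:
        raise CrossParseError(f"{path.name}: bad chromosome id in row 2: {err}") from None
    try:
        pos = np.array([float(pos_row[j]) for j in marker_cols])
    except ValueError as err:
        raise CrossParseError(f"{path.name}: bad cM position in row 3: {err}") from None
    marker_ids = np.array([header[j] for j in marker_cols], dtype=object)
    # markers must arrive sorted within chromosome; GeneticMap validates
    genmap = GeneticMap(marker_ids, chrom, pos)

    id_col = next(
        (j for j in trait_cols if header[j].strip().lower() == "id"), None
    )
    value_cols = [j for j in trait_cols if j != id_col]
    line_ids, geno_rows, trait_rows = [], [], []
    for r_i, row in enumerate(rows[3:], start=4):
        if id_col is not None:
            line_ids.append(row[id_col])
        else:
            line_ids.append(f"RIL{r_i - 3:04d}")
        tvals = []
        for j in value_cols:
            cell = row[j].strip()
            if cell in ("", "NA", "-"):
                tvals.append(np.nan)
            else:
                try:
                    tvals.append(float(cell))
                except ValueError:
                    raise CrossParseError(
                        f"{path.name}: row {r_i}, column {j + 1} "
                        f"({header[j]!r}): bad trait value {cell!r}"
                    ) from None
        trait_rows.append(tvals)
        gvals = []
        for j in marker_cols:
            code = row[j].strip()
            if code not in _GENO_IN:
                raise CrossParseError(
                    f"{path.name}: row {r_i}, column {j + 1} "
                    f"({header[j]!r}): unknown genotype code {code!r}"
                )
            gvals.append(_GENO_IN[code])
        geno_rows.append(gvals)
    geno = pd.DataFrame(geno_rows, index=line_ids, columns=list(marker_ids))
    traits = pd.DataFrame(
        trait_rows, index=line_ids, columns=[header[j] for j in value_cols]
    )
    return Cross(genmap, geno, traits, env_id=env_id or path.stem)


def write_cross_csv(cross: Cross, path: str | Path) -> None:
    """Write a :class:`Cross` in the rotated dialect (lossless roundtrip)."""
    path = Path(path)
    gm = cross.genmap
    traits = cross.traits
    geno = cross.geno.reindex(traits.index)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["id"] + list(traits.columns) + list(gm.marker_id))
        blank = [""] * (1 + len(traits.columns))
        w.writerow(blank + [str(int(c)) for c in gm.chromosome])
        w.writerow(blank + [repr(float(p)) for p in gm.position_cm])
        G = geno.to_numpy(dtype=float)
        T = traits.to_numpy(dtype=float)
        for i, line in enumerate(traits.index):
            tcells = ["" if not np.isfinite(v) else repr(float(v)) for v in T[i]]
            gcells = ["-" if not np.isfinite(g) else _GENO_OUT[g] for g in G[i]]
            w.writerow([str(line)] + tcells + gcells)


_SEED_REQUIRED = ("line_id", "env_id", "rep_id", "run_id", "weight_mg")


def read_seed_csv(path: str | Path) -> pd.DataFrame:
    seeds = pd.read_csv(path, dtype={"line_id": str, "env_id": str, "rep_id": str, "run_id": str})
    missing = [c for c in _SEED_REQUIRED if c not in seeds.columns]
    if missing:
        raise IonQTLError(f"seed table missing columns: {missing}")
    return seeds


def write_seed_csv(seeds: pd.DataFrame, path: str | Path) -> None:
    seeds.to_csv(path, index=False)


def _fmt(value: float, nd: int) -> str:
    return "" if value is None or not np.isfinite(value) else f"{value:.{nd}f}"


def write_report(results, kind: str, path: str | Path) -> None:
    """Write a deterministic TSV report.

    kind = "herit": list of HeritabilityResult -> trait rows, scope columns.
    kind = "qtl": iterable of (env_id, QTLModel) -> one row per locus.
    kind = "qei_cov": list of QEIResult -> significant markers per trait.
    kind = "qei_diff": iterable of (pair_id, QTLModel) -> one row per locus.

    LOD and H2 are printed at 2 decimals, cM positions at 1 decimal; rows
    sort by (trait, chromosome, position).
    """
    path = Path(path)
    lines: list[list[str]] = []
    if kind == "herit":
        scopes = sorted({r.scope for r in results})
        header = ["Trait"] + scopes
        by_trait: dict[str, dict[str, float]] = {}
        for r in results:
            by_trait.setdefault(r.trait, {})[r.scope] = r.h2
        for trait in sorted(by_trait):
            lines.append(
                [trait] + [_fmt(by_trait[trait].get(s, float("nan")), 2) for s in scopes]
            )
    elif kind == "qtl":
        header = ["Trait", "Env", "Chr", "Pos (cM)", "Marker", "Effect", "LOD"]
        rows = []
        for env_id, model in results:
            for loc in model.loci:
                rows.append((model.trait, env_id, loc))
        rows.sort(key=lambda r: (r[0], r[2].chromosome, r[2].position_cm, r[1]))
        for trait, env_id, loc in rows:
            lines.append(
                [trait, env_id, str(loc.chromosome), _fmt(loc.position_cm, 1),
                 loc.marker_id, _fmt(loc.effect, 3), _fmt(loc.lod_drop, 2)]
            )
    elif kind == "qei_cov":
        header = ["Trait", "Chr", "Pos (cM)", "LOD", "Significance Threshold"]
        rows = []
        for res in results:
            for r in res.significant.itertuples():
                rows.append((res.trait, r.chromosome, r.position_cm, r.delta_lod, res.threshold))
        rows.sort(key=lambda r: (r[0], r[1], r[2]))
        for trait, chrom, pos, dl, thr in rows:
            lines.append([trait, str(chrom), _fmt(pos, 1), _fmt(dl, 2), _fmt(thr, 2)])
    elif kind == "qei_diff":
        header = ["Trait", "Pair", "Chr", "Pos (cM)", "Effect", "LOD"]
        rows = []
        for pair_id, model in results:
            for loc in model.loci:
                rows.append((model.trait, pair_id, loc))
        rows.sort(key=lambda r: (r[0], r[2].chromosome, r[2].position_cm, r[1]))
        for trait, pair_id, loc in rows:
            lines.append(
                [trait, pair_id, str(loc.chromosome), _fmt(loc.position_cm, 1),
                 _fmt(loc.effect, 3), _fmt(loc.lod_drop, 2)]
            )
    else:
        raise IonQTLError(f"unknown report kind {kind!r}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(header) + "\n")
        for row in lines:
            fh.write("\t".join(row) + "\n")


@dataclass
class RunConfig:
    """Pipeline settings; defaults match the study's analysis choices."""

    elements: tuple[str, ...] = ()
    mad_threshold: float = 6.2
    n_perm: int = 1000
    alpha: float = 0.05
    merge_window_cm: float = 5.0
    max_qtl: int = 10
    seed: int = 0
    out_dir: str = "."

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise IonQTLError(f"unknown config keys: {sorted(unknown)}")
    if "elements" in data:
        data["elements"] = tuple(data["elements"])
    return RunConfig(**data)
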