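"""Plate normalization and treated/untreated viability ratios.

Two algebraic steps take raw WST-1 signals to the per-gene statistic the
hit criteria operate on:

1. *Percent-of-control normalization.*  Every well on an assay plate is
   divided by the arithmetic mean of the non-targeting (NT) negative-control
   wells of that same plate, replicate and condition.  This removes
   multiplicative plate-to-plate effects exactly; by construction the NT
   wells of each plate average to viability 1.

2. *Viability ratio.*  For each gene (or individual siRNA in a
   deconvolution screen) the normalized treated viability is divided by the
   normalized untreated viability, and that quotient is divided by the NT
   treated/untreated quotient:

       R_g = (T_g / U_g) / (T_NT / U_NT)

   After step 1 the NT terms are exactly 1, so R_g = T_g / U_g; the general
   quotient is kept so the operation is also correct on inputs that were
   not pre-normalized.  R < 1 means the knockdown sensitizes to the drug,
   R > 1 means it confers resistance.

Knockdowns that are lethal on their own make the ratio meaningless; a
toxicity floor on untreated viability flags them for separate reporting
(they are never silently dropped).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .plate_io import (
    Condition,
    MeasurementRecord,
    PlateMap,
    WellRole,
    well_sort_key,
)

__all__ = [
    "NormalizationError",
    "NormalizedWell",
    "GeneViabilityRatio",
    "NTWellRatio",
    "normalize_plate",
    "normalize_screen",
    "gene_ratios",
    "nt_well_ratios",
    "flag_toxic",
    "screen_ratios",
    "DEFAULT_TOXICITY_FLOOR",
]

#: Untreated-viability floor below which a knockdown is flagged toxic.
DEFAULT_TOXICITY_FLOOR = 0.05


class NormalizationError(ValueError):
    """Raised when a plate cannot be normalized or paired."""


@dataclass(frozen=True)
class NormalizedWell:
    """One well signal expressed as a fraction of its plate's NT mean."""

    plate_id: str
    well: str
    role: WellRole
    gene_symbol: str | None
    sirna_id: str | None
    replicate: int
    condition: Condition
    viability: float


@dataclass(frozen=True)
class GeneViabilityRatio:
    """Per-gene (or per-siRNA), per-replicate normalized viability ratio R."""

    gene_symbol: str
    replicate: int
    ratio: float  # NaN when toxic_flag is set
    untreated_viability: float
    toxic_flag: bool = False
    sirna_id: str | None = None
    is_control: bool = False


@dataclass(frozen=True)
class NTWellRatio:
    """Treated/untreated ratio of a single NT well (the t-test null group)."""

    plate_id: str
    well: str
    replicate: int
    ratio: float


def normalize_plate(
    records: Sequence[MeasurementRecord],
    plate_map: PlateMap,
    nt_statistic: str = "mean",
) -> list[NormalizedWell]:
    """Normalize one plate/replicate/condition's signals to its NT level.

    ``records`` must all belong to the same plate, replicate and condition.
    Wells present in the records but absent from the map (e.g. background
    reads of empty wells) are ignored; mapped wells missing from the
    records are an error.  ``nt_statistic`` is ``"mean"`` (the default,
    matching normalization to the average of the negative controls) or
    ``"median"`` for outlier-resistant control summarization.
    """
    if not records:
        raise NormalizationError("no measurements supplied")
    keys = {(r.plate_id, r.replicate, r.condition) for r in records}
    if len(keys) != 1:
        raise NormalizationError(
            f"records span multiple plate/replicate/condition groups: {sorted(map(str, keys))}"
        )
    (plate_id, replicate, condition), = keys
    if plate_id != plate_map.plate_id:
        raise NormalizationError(
            f"measurements are for plate {plate_id!r} but map describes {plate_map.plate_id!r}"
        )
    by_well = {r.well: r for r in records}
    missing = [w for w in plate_map.wells if w not in by_well]
    if missing:
        raise NormalizationError(
            f"plate {plate_id} rep {replicate} {condition.value}: "
            f"missing wells {sorted(missing, key=well_sort_key)}"
        )
    if nt_statistic not in ("mean", "median"):
        raise NormalizationError(f"nt_statistic must be 'mean' or 'median', got {nt_statistic!r}")
    nt_wells = plate_map.wells_with_role(WellRole.NT)
    nt_signals = [by_well[w].signal for w in nt_wells]
    nt_mean = (
        sum(nt_signals) / len(nt_signals)
        if nt_statistic == "mean"
        else float(np.median(nt_signals))
    )
    if nt_mean <= 0:
        raise NormalizationError(
            f"plate {plate_id} rep {replicate} {condition.value}: "
            "all NT signals are zero; plate unusable"
        )
    out = []
    for coord in sorted(plate_map.wells, key=well_sort_key):
        a = plate_map.wells[coord]
        out.append(
            NormalizedWell(
                plate_id=plate_id,
                well=coord,
                role=a.role,
                gene_symbol=a.gene_symbol,
                sirna_id=a.sirna_id,
                replicate=replicate,
                condition=condition,
                viability=by_well[coord].signal / nt_mean,
            )
        )
    return out


def normalize_screen(
    measurements: Sequence[MeasurementRecord], plate_maps: Sequence[PlateMap]
) -> dict[tuple[str, int, Condition], list[NormalizedWell]]:
    """Group measurements by (plate, replicate, condition) and normalize each."""
    maps = {m.plate_id: m for m in plate_maps}
    groups: dict[tuple[str, int, Condition], list[MeasurementRecord]] = defaultdict(list)
    for r in measurements:
        groups[(r.plate_id, r.replicate, r.condition)].append(r)
    out = {}
    for key in sorted(groups, key=lambda k: (k[0], k[1], k[2].value)):
        plate_id = key[0]
        if plate_id not in maps:
            raise NormalizationError(f"no plate map for plate {plate_id!r}")
        out[key] = normalize_plate(groups[key], maps[plate_id])
    return out


def _target_key(w: NormalizedWell) -> tuple[str, str | None, bool]:
    """(symbol, sirna_id, is_control) for effect-bearing wells; None for NT/EMPTY."""
    if w.role is WellRole.GENE:
        return (w.gene_symbol, w.sirna_id, False)
    if w.role in (WellRole.ATR, WellRole.CHK1):
        return (w.role.value, w.sirna_id, True)
    return None


def _mean_viability_by_target(wells: Iterable[NormalizedWell]):
    acc: dict[tuple, list[float]] = defaultdict(list)
    for w in wells:
        key = _target_key(w)
        if key is not None:
            acc[key].append(w.viability)
    return {k: sum(v) / len(v) for k, v in acc.items()}


def _nt_mean(wells: Sequence[NormalizedWell]) -> float:
    vals = [w.viability for w in wells if w.role is WellRole.NT]
    if not vals:
        raise NormalizationError("no NT wells in normalized input")
    return sum(vals) / len(vals)


def gene_ratios(
    treated: Sequence[NormalizedWell], untreated: Sequence[NormalizedWell]
) -> list[GeneViabilityRatio]:
    """Per-gene treated/untreated viability ratios for one sister-plate pair.

    Both inputs must come from the same plate lineage and replicate and
    cover the same genes.  ATR/CHK1 control wells yield ratios flagged
    ``is_control`` so downstream scoring can exclude them from the library
    z-score population.  A gene with untreated viability 0 is flagged toxic
    and its ratio carried as NaN.
    """
    reps = {w.replicate for w in treated} | {w.replicate for w in untreated}
    if len(reps) != 1:
        raise NormalizationError(f"inputs span multiple replicates: {sorted(reps)}")
    (replicate,) = reps
    if {w.condition for w in treated} != {Condition.TREATED} or {
        w.condition for w in untreated
    } != {Condition.UNTREATED}:
        raise NormalizationError("treated/untreated inputs have mismatched conditions")
    t_means = _mean_viability_by_target(treated)
    u_means = _mean_viability_by_target(untreated)
    if set(t_means) != set(u_means):
        only_t = sorted(k[0] for k in set(t_means) - set(u_means))
        only_u = sorted(k[0] for k in set(u_means) - set(t_means))
        raise NormalizationError(
            f"genes present in only one condition: treated-only={only_t}, untreated-only={only_u}"
        )
    nt_term = _nt_mean(treated) / _nt_mean(untreated)
    out = []
    for key in sorted(t_means, key=lambda k: (k[0], k[1] or "")):
        symbol, sirna_id, is_control = key
        t_g, u_g = t_means[key], u_means[key]
        if u_g == 0:
            out.append(
                GeneViabilityRatio(symbol, replicate, math.nan, 0.0, True, sirna_id, is_control)
            )
        else:
            out.append(
                GeneViabilityRatio(
                    symbol, replicate, (t_g / u_g) / nt_term, u_g, False, sirna_id, is_control
                )
            )
    return out


def nt_well_ratios(
    treated: Sequence[NormalizedWell], untreated: Sequence[NormalizedWell]
) -> list[NTWellRatio]:
    """Per-NT-well treated/untreated ratios (paired by coordinate).

    These form the null comparison group of the one-tailed t-test; each NT
    well's ratio is taken against its own plate's NT means, exactly as gene
    ratios are.
    """
    t_nt = {w.well: w for w in treated if w.role is WellRole.NT}
    u_nt = {w.well: w for w in untreated if w.role is WellRole.NT}
    if set(t_nt) != set(u_nt):
        raise NormalizationError("NT wells differ between treated and untreated plates")
    nt_term = _nt_mean(treated) / _nt_mean(untreated)
    out = []
    for coord in sorted(t_nt, key=well_sort_key):
        tw, uw = t_nt[coord], u_nt[coord]
        if uw.viability == 0:
            raise NormalizationError(f"NT well {coord}: untreated viability is zero")
        out.append(
            NTWellRatio(tw.plate_id, coord, tw.replicate, (tw.viability / uw.viability) / nt_term)
        )
    return out


def flag_toxic(
    ratios: Iterable[GeneViabilityRatio], floor: float = DEFAULT_TOXICITY_FLOOR
) -> list[GeneViabilityRatio]:
    """Flag entries whose untreated viability falls below ``floor``."""
    if not 0 <= floor < 1:
        raise ValueError(f"toxicity floor must be in [0,1), got {floor}")
    out = []
    for r in ratios:
        if not r.toxic_flag and r.untreated_viability < floor:
            out.append(replace(r, toxic_flag=True, ratio=math.nan))
        else:
            out.append(r)
    return out


def screen_ratios(
    measurements: Sequence[MeasurementRecord],
    plate_maps: Sequence[PlateMap],
    toxicity_floor: float = DEFAULT_TOXICITY_FLOOR,
) -> tuple[list[GeneViabilityRatio], list[NTWellRatio]]:
    """Full normalization pass over a screen.

    Normalizes every (plate, replicate, condition) group, pairs sister
    plates by (plate id, replicate), and returns per-gene ratios (toxicity
    flagged) together with the pooled per-NT-well ratios.
    """
    normalized = normalize_screen(measurements, plate_maps)
    pairs: dict[tuple[str, int], dict[Condition, list[NormalizedWell]]] = defaultdict(dict)
    for (plate_id, replicate, condition), wells in normalized.items():
        pairs[(plate_id, replicate)][condition] = wells
    gene_rs: list[GeneViabilityRatio] = []
    nt_rs: list[NTWellRatio] = []
    for key in sorted(pairs):
        arms = pairs[key]
        if set(arms) != {Condition.TREATED, Condition.UNTREATED}:
            missing = {Condition.TREATED, Condition.UNTREATED} - set(arms)
            raise NormalizationError(
                f"plate {key[0]} rep {key[1]}: missing {sorted(c.value for c in missing)} sister plate"
            )
        gene_rs.extend(gene_ratios(arms[Condition.TREATED], arms[Condition.UNTREATED]))
        nt_rs.extend(nt_well_ratios(arms[Condition.TREATED], arms[Condition.UNTREATED]))
    return flag_toxic(gene_rs, toxicity_floor), nt_rs
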