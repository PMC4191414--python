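"""Synthetic plate-data generator for the screen pipeline.

Emulates the design of a pooled-siRNA drug-sensitization viability screen:
~1006 library genes arrayed one gene per well on 96-well plates, each
plate carrying ATR and CHK1 positive-control wells and several
non-targeting (NT) negative-control wells; three replicates; paired
treated / untreated sister plates split from one transfection.

The generative model for the raw signal of well *w* on assay plate
(plate p, replicate r, condition c) is multiplicative:

    signal = baseline * plate_factor(p, r, c) * edge(w) * u_g * cond * eps

where ``u_g`` is the knockdown's drug-independent viability (toxicity),
``cond`` is 1 untreated and ``nt_treated_fraction * rho_g`` treated
(``rho_g`` the gene's true normalized sensitization/resistance ratio,
1 for NT wells), ``eps`` is lognormal well noise with a given CV, the
plate factor is lognormal with a given log-sd, and ``edge`` multiplies
border wells only.  Because every effect left of ``eps`` is
multiplicative and plate-wide or gene-specific, NT normalization removes
plate and baseline terms exactly; at zero noise the pipeline returns each
gene's configured ``rho_g`` to machine precision.

Randomness comes from numpy's PCG64 generator; the global seed is split
into independent per-plate streams with ``SeedSequence.spawn``, so
growing the screen adds plates without reshuffling existing ones.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .hit_calling import GeneScore
from .plate_io import (
    Call,
    Condition,
    LibraryEntry,
    MeasurementRecord,
    PlateMap,
    PLATE_ROWS,
    WellAssignment,
    WellRole,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "TrueClass",
    "SimulationError",
    "simulate_library",
    "simulate_primary",
    "simulate_secondary",
    "truth_confusion",
]


class SimulationError(ValueError):
    pass


class TrueClass(str, enum.Enum):
    SENSITIZER = "SENSITIZER"
    RESISTOR = "RESISTOR"
    NULL = "NULL"
    TOXIC = "TOXIC"


_ALL_WELLS = [f"{row}{col}" for row in PLATE_ROWS for col in range(1, 13)]
_EDGE_WELLS = {w for w in _ALL_WELLS if w[0] in "AH" or int(w[1:]) in (1, 12)}


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic screen.

    Defaults reproduce the primary-screen design: 1006 genes in pools of
    four siRNAs, 88 gene wells per plate alongside 1 ATR + 1 CHK1 + 4 NT
    control wells, three replicates, paired treated/untreated sister
    plates, 10% lognormal well noise and 10% (log-sd) plate effects.
    ``nt_treated_fraction`` is the fraction of NT signal surviving drug
    treatment; it cancels in every downstream ratio.
    """

    n_genes: int = 1006
    sirnas_per_gene: int = 4
    n_replicates: int = 3
    nt_wells_per_plate: int = 4
    atr_wells: int = 1
    chk1_wells: int = 1
    genes_per_plate: int = 88
    baseline_signal: float = 1000.0
    nt_treated_fraction: float = 0.5
    effect_map: Mapping[str, float] = field(default_factory=dict)
    knockdown_viability_map: Mapping[str, float] = field(default_factory=dict)
    noise_cv: float = 0.10
    plate_effect_sd: float = 0.10
    edge_effect: float = 1.0
    atr_true_ratio: float = 0.7
    chk1_true_ratio: float = 0.55
    toxic_class_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1 or self.genes_per_plate < 1:
            raise SimulationError("n_genes, n_replicates and genes_per_plate must be >=1")
        controls = self.nt_wells_per_plate + self.atr_wells + self.chk1_wells
        if self.nt_wells_per_plate < 1 or self.atr_wells < 1 or self.chk1_wells < 1:
            raise SimulationError("each plate needs >=1 NT, ATR and CHK1 well")
        if self.genes_per_plate + controls > 96:
            raise SimulationError(
                f"infeasible layout: {self.genes_per_plate} gene wells + "
                f"{controls} control wells exceed 96"
            )
        if self.noise_cv < 0 or self.plate_effect_sd < 0:
            raise SimulationError("noise_cv and plate_effect_sd must be >=0")
        if self.baseline_signal <= 0 or self.nt_treated_fraction <= 0 or self.edge_effect <= 0:
            raise SimulationError("baseline, nt_treated_fraction and edge_effect must be >0")
        for g, rho in self.effect_map.items():
            if rho <= 0:
                raise SimulationError(f"effect_map[{g!r}] must be >0, got {rho}")
        for g, u in self.knockdown_viability_map.items():
            if not 0 < u <= 1:
                raise SimulationError(f"knockdown_viability_map[{g!r}] must be in (0,1], got {u}")

    def gene_symbols(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def rho(self, gene: str) -> float:
        return float(self.effect_map.get(gene, 1.0))

    def knockdown_viability(self, gene: str) -> float:
        return float(self.knockdown_viability_map.get(gene, 1.0))


@dataclass(frozen=True)
class GroundTruth:
    """True gene effects behind a simulated screen, for recovery tests."""

    rho: Mapping[str, float]
    knockdown_viability: Mapping[str, float]
    classes: Mapping[str, TrueClass]
    on_target: Mapping[str, bool] = field(default_factory=dict)  # per siRNA (secondary)


def _true_class(rho: float, u: float, toxic_floor: float) -> TrueClass:
    if u < toxic_floor:
        return TrueClass.TOXIC
    if rho < 1.0:
        return TrueClass.SENSITIZER
    if rho > 1.0:
        return TrueClass.RESISTOR
    return TrueClass.NULL


def simulate_library(config: SimulationConfig) -> list[LibraryEntry]:
    """The library manifest matching a simulated screen (4 siRNAs per gene)."""
    return [
        LibraryEntry(g, tuple(f"{g}_si{k}" for k in range(1, config.sirnas_per_gene + 1)))
        for g in config.gene_symbols()
    ]


def _build_plate_maps(
    targets: Sequence[tuple[str, str | None]],
    per_plate: int,
    config: SimulationConfig,
    plate_prefix: str,
) -> list[PlateMap]:
    """Lay out (gene, sirna) targets onto plates with the control complement.

    Controls occupy the head of the row-major well order: ATR wells, then
    CHK1, then NT; targets fill the remainder.  Deterministic.
    """
    n_plates = math.ceil(len(targets) / per_plate)
    maps = []
    for p in range(n_plates):
        plate_id = f"{plate_prefix}{p + 1:02d}"
        chunk = targets[p * per_plate : (p + 1) * per_plate]
        wells: dict[str, WellAssignment] = {}
        it = iter(_ALL_WELLS)
        for _ in range(config.atr_wells):
            wells[next(it)] = WellAssignment(WellRole.ATR)
        for _ in range(config.chk1_wells):
            wells[next(it)] = WellAssignment(WellRole.CHK1)
        for _ in range(config.nt_wells_per_plate):
            wells[next(it)] = WellAssignment(WellRole.NT)
        for gene, sirna in chunk:
            wells[next(it)] = WellAssignment(WellRole.GENE, gene, sirna)
        maps.append(PlateMap(plate_id, wells))
    return maps


def _well_effects(assignment: WellAssignment, config: SimulationConfig,
                  rho_overrides: Mapping[str, float] | None = None) -> tuple[float, float]:
    """(u, rho) for a well; rho_overrides keys siRNA ids (secondary screens)."""
    role = assignment.role
    if role is WellRole.NT:
        return 1.0, 1.0
    if role is WellRole.ATR:
        return 1.0, config.atr_true_ratio
    if role is WellRole.CHK1:
        return 1.0, config.chk1_true_ratio
    gene = assignment.gene_symbol
    u = config.knockdown_viability(gene)
    if rho_overrides is not None and assignment.sirna_id is not None:
        rho = rho_overrides.get(assignment.sirna_id, 1.0)
    else:
        rho = config.rho(gene)
    return u, rho


def _simulate_measurements(
    maps: Sequence[PlateMap],
    config: SimulationConfig,
    seed_key: Sequence[int],
    rho_overrides: Mapping[str, float] | None = None,
) -> list[MeasurementRecord]:
    sigma = math.sqrt(math.log1p(config.noise_cv**2))  # lognormal, mean 1, CV = noise_cv
    children = np.random.SeedSequence(seed_key).spawn(len(maps))
    records: list[MeasurementRecord] = []
    for pmap, child in zip(maps, children):
        rng = np.random.default_rng(child)
        coords = sorted(pmap.wells, key=lambda w: _ALL_WELLS.index(w))
        for rep in range(1, config.n_replicates + 1):
            for condition in (Condition.UNTREATED, Condition.TREATED):
                plate_factor = math.exp(rng.normal(0.0, config.plate_effect_sd))
                for coord in coords:
                    a = pmap.wells[coord]
                    u, rho = _well_effects(a, config, rho_overrides)
                    cond = 1.0 if condition is Condition.UNTREATED else (
                        config.nt_treated_fraction * rho
                    )
                    edge = config.edge_effect if coord in _EDGE_WELLS else 1.0
                    eps = math.exp(rng.normal(-0.5 * sigma**2, sigma))
                    signal = config.baseline_signal * plate_factor * edge * u * cond * eps
                    records.append(
                        MeasurementRecord(pmap.plate_id, coord, rep, condition, signal)
                    )
    return records


def simulate_primary(
    config: SimulationConfig,
) -> tuple[list[PlateMap], list[MeasurementRecord], GroundTruth]:
    """Generate a complete pooled primary screen.

    Returns plate maps, raw measurements and the ground truth; byte-for-byte
    deterministic given ``config.seed``.
    """
    genes = config.gene_symbols()
    maps = _build_plate_maps(
        [(g, None) for g in genes], config.genes_per_plate, config, "P"
    )
    records = _simulate_measurements(maps, config, [config.seed, 0])
    truth = GroundTruth(
        rho={g: config.rho(g) for g in genes},
        knockdown_viability={g: config.knockdown_viability(g) for g in genes},
        classes={
            g: _true_class(config.rho(g), config.knockdown_viability(g), config.toxic_class_floor)
            for g in genes
        },
    )
    return maps, records, truth


def simulate_secondary(
    config: SimulationConfig,
    candidates: Sequence[str],
    on_target_counts: Mapping[str, int] | None = None,
    on_target_probability: float = 1.0,
) -> tuple[list[PlateMap], list[MeasurementRecord], GroundTruth]:
    """Generate a deconvolution screen for ``candidates``.

    Each candidate's four siRNAs occupy separate wells.  An on-target
    siRNA carries its gene's true ratio; an off-target one carries 1.
    Flags come from ``on_target_counts`` (first *k* siRNAs on-target, the
    zero-noise forcing used in tests) or else are Bernoulli draws with
    ``on_target_probability``, seed-deterministic.
    """
    known = set(config.gene_symbols())
    unknown = [g for g in candidates if g not in known]
    if unknown:
        raise SimulationError(f"candidates not in simulated library: {unknown}")
    if not 0 <= on_target_probability <= 1:
        raise SimulationError("on_target_probability must be in [0,1]")
    sirnas = [
        (g, f"{g}_si{k}") for g in candidates for k in range(1, config.sirnas_per_gene + 1)
    ]
    flag_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    on_target: dict[str, bool] = {}
    for g, sid in sirnas:
        if on_target_counts is not None:
            k = int(sid.rsplit("_si", 1)[1])
            on_target[sid] = k <= on_target_counts.get(g, config.sirnas_per_gene)
        else:
            on_target[sid] = bool(flag_rng.random() < on_target_probability)
    rho_overrides = {
        sid: config.rho(g) if on_target[sid] else 1.0 for g, sid in sirnas
    }
    maps = _build_plate_maps(sirnas, config.genes_per_plate, config, "S")
    records = _simulate_measurements(maps, config, [config.seed, 2], rho_overrides)
    truth = GroundTruth(
        rho={g: config.rho(g) for g in candidates},
        knockdown_viability={g: config.knockdown_viability(g) for g in candidates},
        classes={
            g: _true_class(config.rho(g), config.knockdown_viability(g), config.toxic_class_floor)
            for g in candidates
        },
        on_target=on_target,
    )
    return maps, records, truth


_CALL_TO_CLASS = {
    Call.SENSITIZATION: TrueClass.SENSITIZER,
    Call.RESISTANCE: TrueClass.RESISTOR,
    Call.NONE: TrueClass.NULL,
    Call.TOXIC_EXCLUDED: TrueClass.TOXIC,
}


def truth_confusion(
    scores: Sequence[GeneScore], truth: GroundTruth
) -> dict[TrueClass, dict[str, int]]:
    """One-vs-rest confusion counts (TP/FP/TN/FN) per true class.

    Control pseudo-genes are ignored; the score and truth gene universes
    must otherwise coincide.  For every class the four counts sum to the
    number of genes.
    """
    predicted = {s.gene_symbol: _CALL_TO_CLASS[s.call] for s in scores if not s.is_control}
    if set(predicted) != set(truth.classes):
        raise SimulationError(
            "gene universes differ between calls and ground truth "
            f"(calls only: {sorted(set(predicted) - set(truth.classes))[:5]}, "
            f"truth only: {sorted(set(truth.classes) - set(predicted))[:5]})"
        )
    out: dict[TrueClass, dict[str, int]] = {}
    for cls in TrueClass:
        tp = fp = tn = fn = 0
        for g, pred in predicted.items():
            actual = truth.classes[g]
            if pred is cls and actual is cls:
                tp += 1
            elif pred is cls:
                fp += 1
            elif actual is cls:
                fn += 1
            else:
                tn += 1
        out[cls] = {"TP": tp, "FP": fp, "TN": tn, "FN": fn}
    return out
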