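"""siRNA-pool deconvolution: the secondary validation screen.

The primary screen assays a pool of four siRNAs per gene, so an apparent
hit can be driven by an off-target effect of a single reagent.  The
secondary screen re-tests each candidate gene with its four siRNAs in
separate wells.  A single siRNA *significantly sensitizes* when its
normalized treated/untreated viability ratio is below 0.8 with a
one-tailed (lower tail) Student's t-test P < 0.05 against the NT wells;
a gene is *validated* when two or more of its individual siRNAs do so
independently.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

from .hit_calling import DEFAULT_THRESHOLDS, Thresholds, one_tailed_p
from .normalization import DEFAULT_TOXICITY_FLOOR, screen_ratios
from .plate_io import MeasurementRecord, PlateMap

__all__ = [
    "DeconvolutionResult",
    "ValidationCall",
    "SecondaryScreenError",
    "evaluate_sirna",
    "validate_gene",
    "run_secondary",
]


class SecondaryScreenError(ValueError):
    pass


@dataclass(frozen=True)
class DeconvolutionResult:
    """Outcome for one individual siRNA in the deconvolution screen."""

    gene_symbol: str
    sirna_id: str
    normalized_viability: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class ValidationCall:
    """Per-gene verdict of the >=2-of-4 deconvolution rule."""

    gene_symbol: str
    n_significant: int
    validated: bool


def evaluate_sirna(
    viability: float, p: float, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> bool:
    """True iff this siRNA independently sensitizes (both bounds strict)."""
    return viability < thresholds.secondary_viability_max and p < thresholds.secondary_p_max


def validate_gene(results: Sequence[DeconvolutionResult]) -> ValidationCall:
    """Count significant siRNAs for one gene and apply the >=2 rule.

    Genes tested with fewer than four siRNAs are allowed; the rule applies
    to the results present.  Duplicate siRNA ids are an error.
    """
    if not results:
        raise SecondaryScreenError("no deconvolution results supplied")
    genes = {r.gene_symbol for r in results}
    if len(genes) != 1:
        raise SecondaryScreenError(f"results span multiple genes: {sorted(genes)}")
    ids = [r.sirna_id for r in results]
    if len(set(ids)) != len(ids):
        raise SecondaryScreenError(f"duplicate siRNA id for gene {results[0].gene_symbol!r}")
    n_sig = sum(r.significant for r in results)
    return ValidationCall(results[0].gene_symbol, n_sig, n_sig >= DEFAULT_THRESHOLDS.secondary_min_sirnas)


def run_secondary(
    measurements: Sequence[MeasurementRecord],
    plate_maps: Sequence[PlateMap],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    toxicity_floor: float = DEFAULT_TOXICITY_FLOOR,
) -> tuple[list[DeconvolutionResult], list[ValidationCall]]:
    """Run the deconvolution screen end to end.

    Reuses the primary screen's normalization and t-test at single-siRNA
    granularity (wells must carry ``sirna_id`` in their plate maps), then
    applies the per-siRNA significance rule and the per-gene >=2-of-4 rule.
    The t-test uses the lower tail only, since only sensitization validates.
    """
    ratios, nt = screen_ratios(measurements, plate_maps, toxicity_floor)
    nt_values = [r.ratio for r in nt]
    by_sirna: dict[tuple[str, str], list] = defaultdict(list)
    for r in ratios:
        if r.is_control:
            continue
        if r.sirna_id is None:
            raise SecondaryScreenError(
                f"gene {r.gene_symbol!r}: secondary-screen wells must carry sirna_id"
            )
        by_sirna[(r.gene_symbol, r.sirna_id)].append(r)
    results: list[DeconvolutionResult] = []
    for (gene, sirna) in sorted(by_sirna):
        values = [r.ratio for r in by_sirna[(gene, sirna)] if not r.toxic_flag]
        if len(values) < 2:
            raise SecondaryScreenError(
                f"siRNA {sirna!r} ({gene}): fewer than 2 usable replicates"
            )
        mean_v = sum(values) / len(values)
        p = one_tailed_p(values, nt_values, alternative="less")
        results.append(
            DeconvolutionResult(gene, sirna, mean_v, p, evaluate_sirna(mean_v, p, thresholds))
        )
    by_gene: dict[str, list[DeconvolutionResult]] = defaultdict(list)
    for r in results:
        by_gene[r.gene_symbol].append(r)
    n_min = thresholds.secondary_min_sirnas
    calls = [
        ValidationCall(g, n := sum(r.significant for r in rs), n >= n_min)
        for g, rs in sorted(by_gene.items())
    ]
    return results, calls
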