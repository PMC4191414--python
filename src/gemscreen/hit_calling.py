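"""Replicate aggregation, screen statistics and three-criteria hit calling.

A gene is a *sensitization* hit when all three of the following hold
(strict inequalities throughout), and a *resistance* hit for the mirrored
bounds:

* mean normalized viability ratio R < 0.7         (resistance: R > 1.3)
* z-score of log2 R over the library  z < -1.5    (resistance: z > +1.5)
* -log10 P > 1, P from a one-tailed two-sample Student's t-test of the
  gene's per-replicate ratios against the pooled NT-well ratios.

The z-score standardizes each gene's log2(mean R) against the mean and
sample standard deviation (n-1 denominator) of all eligible library genes
— positive controls and toxicity-excluded genes are excluded from the
population but still receive a z against it.  The t-test uses pooled
variance with df = n1 + n2 - 2; the tail is resolved per gene in the
direction of its observed deviation from the NT mean (a fixed tail can be
requested, e.g. the lower tail for sensitization-only secondary screens).

No multiple-testing correction is applied to the calls: the joint
three-criteria AND rule is itself the false-positive control.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .normalization import (
    DEFAULT_TOXICITY_FLOOR,
    GeneViabilityRatio,
    NTWellRatio,
    screen_ratios,
)
from .plate_io import Call, MeasurementRecord, PlateMap

__all__ = [
    "Thresholds",
    "DEFAULT_THRESHOLDS",
    "THRESHOLD_SETS",
    "GeneScore",
    "HitCallingError",
    "InsufficientReplicatesError",
    "DegenerateScreenError",
    "aggregate_gene",
    "one_tailed_p",
    "compute_zscores",
    "classify_gene",
    "call_hits",
    "run_primary_screen",
    "P_FLOOR",
]

#: Underflow guard applied before -log10.
P_FLOOR = 1e-300


class HitCallingError(ValueError):
    pass


class InsufficientReplicatesError(HitCallingError):
    """Fewer than two usable replicates: gene cannot be scored."""


class DegenerateScreenError(HitCallingError):
    """Zero spread in log2 ratios: z-scores undefined."""


@dataclass(frozen=True)
class Thresholds:
    """Hit-criteria constants for the primary and secondary screens."""

    sens_ratio_max: float = 0.7
    res_ratio_min: float = 1.3
    z_low: float = -1.5
    z_high: float = 1.5
    neg_log_p_min: float = 1.0
    secondary_viability_max: float = 0.8
    secondary_p_max: float = 0.05
    secondary_min_sirnas: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.sens_ratio_max < 1 < self.res_ratio_min):
            raise HitCallingError("require sens_ratio_max < 1 < res_ratio_min, both positive")
        if not (self.z_low < 0 < self.z_high):
            raise HitCallingError("require z_low < 0 < z_high")
        if min(self.neg_log_p_min, self.secondary_viability_max, self.secondary_p_max) <= 0:
            raise HitCallingError("p/viability bounds must be positive")
        if self.secondary_min_sirnas < 1:
            raise HitCallingError("secondary_min_sirnas must be >= 1")


DEFAULT_THRESHOLDS = Thresholds()

#: Named threshold sets selectable from configs and the CLI.
THRESHOLD_SETS: Mapping[str, Thresholds] = {"primary-screen": DEFAULT_THRESHOLDS}


@dataclass(frozen=True)
class GeneScore:
    """Per-gene aggregate over the screen replicates."""

    gene_symbol: str
    n_replicates: int
    mean_ratio: float
    log2_ratio: float
    zscore: float
    p_one_tailed: float
    neg_log10_p: float
    call: Call
    is_control: bool = False
    sd_ratio: float = field(default=math.nan, compare=False)
    #: Benjamini-Hochberg adjusted p over the library, informational only:
    #: the hit criteria use the raw one-tailed p, never this.
    bh_q: float = field(default=math.nan, compare=False)


def aggregate_gene(ratios: Sequence[GeneViabilityRatio]) -> tuple[float, float, int]:
    """Mean and sample sd of R across a gene's unflagged replicates.

    Raises :class:`InsufficientReplicatesError` when fewer than two
    replicates survive the toxicity filter.
    """
    values = [r.ratio for r in ratios if not r.toxic_flag]
    n = len(values)
    if n < 2:
        raise InsufficientReplicatesError(
            f"{ratios[0].gene_symbol if ratios else '?'}: {n} usable replicate(s)"
        )
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    return mean, sd, n


def one_tailed_p(
    gene_values: Sequence[float],
    nt_values: Sequence[float],
    alternative: Literal["auto", "less", "greater"] = "auto",
) -> float:
    """One-tailed pooled-variance Student's t-test of a gene vs the NT group.

    ``alternative="auto"`` resolves the tail in the direction of the
    observed deviation of the gene mean from the NT mean, so the returned
    p lies in (0, 0.5] except for degenerate inputs.  Zero-variance
    conventions: equal means -> p = 1; unequal means -> p = 1e-300.
    """
    g = np.asarray(gene_values, dtype=float)
    nt = np.asarray(nt_values, dtype=float)
    n1, n2 = g.size, nt.size
    if n1 < 2 or n2 < 2:
        raise HitCallingError(f"need >=2 values per group, got {n1} and {n2}")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * g.var(ddof=1) + (n2 - 1) * nt.var(ddof=1)) / df
    diff = g.mean() - nt.mean()
    if sp2 == 0:
        return 1.0 if diff == 0 else P_FLOOR
    t = diff / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    if alternative == "auto":
        p = stats.t.sf(abs(t), df)
    elif alternative == "less":
        p = stats.t.cdf(t, df)
    elif alternative == "greater":
        p = stats.t.sf(t, df)
    else:
        raise HitCallingError(f"unknown alternative {alternative!r}")
    return float(min(max(p, P_FLOOR), 1.0))


def compute_zscores(
    scores: Sequence[GeneScore], exclude: Iterable[str] = (), robust: bool = False
) -> list[GeneScore]:
    """Standardize log2 ratios over the eligible library population.

    Eligible genes are scored, non-control genes not listed in
    ``exclude``; their log2 ratios define the location/scale used to
    assign a z to every scored gene (controls included, against the
    library population).  The default is the classical z (mean, n-1 sd);
    ``robust=True`` substitutes median and normal-consistent MAD
    (scale 1.4826), resistant to heavy hit tails.  Raises
    :class:`DegenerateScreenError` on zero spread.
    """
    exclude = set(exclude)

    def eligible(s: GeneScore) -> bool:
        return (
            not s.is_control
            and s.call is not Call.TOXIC_EXCLUDED
            and s.gene_symbol not in exclude
            and math.isfinite(s.log2_ratio)
        )

    population = np.array([s.log2_ratio for s in scores if eligible(s)])
    if population.size < 2:
        raise HitCallingError(f"need >=2 eligible genes for z-scores, got {population.size}")
    if robust:
        m = float(np.median(population))
        s_ = 1.4826 * float(np.median(np.abs(population - m)))
    else:
        m = population.mean()
        s_ = population.std(ddof=1)
    if s_ == 0:
        raise DegenerateScreenError("degenerate screen: zero spread in log2 ratios")
    out = []
    for score in scores:
        if score.call is Call.TOXIC_EXCLUDED or not math.isfinite(score.log2_ratio):
            out.append(score)
        else:
            out.append(replace(score, zscore=float((score.log2_ratio - m) / s_)))
    return out


def classify_gene(score: GeneScore, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> Call:
    """Apply the joint three-criteria rule (all inequalities strict)."""
    if score.call is Call.TOXIC_EXCLUDED:
        return Call.TOXIC_EXCLUDED
    if (
        score.mean_ratio < thresholds.sens_ratio_max
        and score.zscore < thresholds.z_low
        and score.neg_log10_p > thresholds.neg_log_p_min
    ):
        return Call.SENSITIZATION
    if (
        score.mean_ratio > thresholds.res_ratio_min
        and score.zscore > thresholds.z_high
        and score.neg_log10_p > thresholds.neg_log_p_min
    ):
        return Call.RESISTANCE
    return Call.NONE


def call_hits(
    ratios: Sequence[GeneViabilityRatio],
    nt_ratios: Sequence[NTWellRatio] | Sequence[float],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[GeneScore]:
    """Score and classify every gene from its per-replicate ratios.

    ``nt_ratios`` is the pooled NT-well null group (either
    :class:`~gemscreen.normalization.NTWellRatio` objects or bare floats).
    Returns one :class:`GeneScore` per gene, sorted by symbol; genes with
    fewer than two usable replicates come back as TOXIC/EXCLUDED.
    """
    nt_values = [r.ratio if isinstance(r, NTWellRatio) else float(r) for r in nt_ratios]
    by_gene: dict[tuple[str, bool], list[GeneViabilityRatio]] = defaultdict(list)
    for r in ratios:
        by_gene[(r.gene_symbol, r.is_control)].append(r)
    scores: list[GeneScore] = []
    for (gene, is_control) in sorted(by_gene):
        # fixed intra-gene order makes the result invariant to input order
        gene_rs = sorted(
            by_gene[(gene, is_control)], key=lambda r: (r.replicate, r.sirna_id or "")
        )
        try:
            mean, sd, n = aggregate_gene(gene_rs)
        except InsufficientReplicatesError:
            scores.append(
                GeneScore(
                    gene, sum(not r.toxic_flag for r in gene_rs), math.nan, math.nan,
                    math.nan, math.nan, math.nan, Call.TOXIC_EXCLUDED, is_control,
                )
            )
            continue
        values = [r.ratio for r in gene_rs if not r.toxic_flag]
        p = one_tailed_p(values, nt_values)
        scores.append(
            GeneScore(
                gene_symbol=gene,
                n_replicates=n,
                mean_ratio=mean,
                log2_ratio=math.log2(mean) if mean > 0 else math.nan,
                zscore=math.nan,
                p_one_tailed=p,
                neg_log10_p=-math.log10(max(p, P_FLOOR)),
                call=Call.NONE,
                is_control=is_control,
                sd_ratio=sd,
            )
        )
    scores = compute_zscores(scores)
    scores = [
        s if s.call is Call.TOXIC_EXCLUDED else replace(s, call=classify_gene(s, thresholds))
        for s in scores
    ]
    # informational BH column over the scored library genes; never enters calls
    library_idx = [
        i for i, s in enumerate(scores)
        if not s.is_control and s.call is not Call.TOXIC_EXCLUDED
    ]
    if library_idx:
        q = stats.false_discovery_control([scores[i].p_one_tailed for i in library_idx])
        for i, qi in zip(library_idx, q):
            scores[i] = replace(scores[i], bh_q=float(qi))
    return scores


def run_primary_screen(
    measurements: Sequence[MeasurementRecord],
    plate_maps: Sequence[PlateMap],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    toxicity_floor: float = DEFAULT_TOXICITY_FLOOR,
) -> list[GeneScore]:
    """Full primary-screen pipeline: normalize, ratio, aggregate, classify."""
    ratios, nt = screen_ratios(measurements, plate_maps, toxicity_floor)
    return call_hits(ratios, nt, thresholds)
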