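"""Summary artifacts: volcano table, z-score rank table, category breakdown.

All reports are plain TSV data tables derivable from the gene-score table
alone; optional matplotlib figures render the same tables.  The volcano
region flag uses the ratio and p criteria only (the plot's shaded region);
full hit calls additionally require the z criterion, so both are carried.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .hit_calling import DEFAULT_THRESHOLDS, GeneScore, Thresholds
from .plate_io import Call, _atomic_write_text

__all__ = [
    "VolcanoRow",
    "volcano_table",
    "zscore_rank_table",
    "category_summary",
    "write_volcano_table",
    "write_zscore_rank_table",
    "write_category_summary",
    "volcano_figure",
]


@dataclass(frozen=True)
class VolcanoRow:
    gene_symbol: str
    mean_ratio: float
    neg_log10_p: float
    call: Call
    in_shaded_region: bool


def volcano_table(
    scores: Sequence[GeneScore], thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> list[VolcanoRow]:
    """One row per scored gene; flag = (ratio outside [0.7, 1.3]) and -log10 p > 1."""
    rows = []
    for s in scores:
        if s.call is Call.TOXIC_EXCLUDED:
            continue
        flagged = (
            s.mean_ratio < thresholds.sens_ratio_max or s.mean_ratio > thresholds.res_ratio_min
        ) and s.neg_log10_p > thresholds.neg_log_p_min
        rows.append(VolcanoRow(s.gene_symbol, s.mean_ratio, s.neg_log10_p, s.call, flagged))
    return rows


def zscore_rank_table(
    scores: Sequence[GeneScore], thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> list[tuple[int, str, float, bool]]:
    """Genes sorted ascending by z (ties alphabetical); flag = |z| beyond bounds."""
    scored = [s for s in scores if s.call is not Call.TOXIC_EXCLUDED]
    ordered = sorted(scored, key=lambda s: (s.zscore, s.gene_symbol))
    return [
        (
            rank,
            s.gene_symbol,
            s.zscore,
            s.zscore < thresholds.z_low or s.zscore > thresholds.z_high,
        )
        for rank, s in enumerate(ordered, start=1)
    ]


def category_summary(
    hit_genes: Iterable[str], annotations: Mapping[str, str | None]
) -> dict[str, int]:
    """Hit counts per functional-category label; unannotated -> "unknown"."""
    counts = Counter(annotations.get(g) or "unknown" for g in hit_genes)
    return dict(sorted(counts.items()))


def write_volcano_table(rows: Sequence[VolcanoRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "gene": r.gene_symbol,
                "mean_ratio": f"{r.mean_ratio:.6g}",
                "neg_log10_p": f"{r.neg_log10_p:.6g}",
                "call": r.call.value,
                "in_shaded_region": str(r.in_shaded_region).lower(),
            }
            for r in rows
        ],
        columns=["gene", "mean_ratio", "neg_log10_p", "call", "in_shaded_region"],
    )
    _atomic_write_text(path, df.to_csv(index=False, sep="\t"))


def write_zscore_rank_table(
    rows: Sequence[tuple[int, str, float, bool]], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            {"rank": rank, "gene": gene, "zscore": f"{z:.6g}", "flagged": str(f).lower()}
            for rank, gene, z, f in rows
        ],
        columns=["rank", "gene", "zscore", "flagged"],
    )
    _atomic_write_text(path, df.to_csv(index=False, sep="\t"))


def write_category_summary(summary: Mapping[str, int], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"category": k, "hits": v} for k, v in summary.items()],
        columns=["category", "hits"],
    )
    _atomic_write_text(path, df.to_csv(index=False, sep="\t"))


def volcano_figure(rows: Sequence[VolcanoRow], thresholds: Thresholds = DEFAULT_THRESHOLDS):
    """Optional matplotlib rendering of the volcano table (returns a Figure)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    x = [r.mean_ratio for r in rows]
    y = [r.neg_log10_p for r in rows]
    colors = ["tab:red" if r.in_shaded_region else "0.6" for r in rows]
    ax.scatter(x, y, s=8, c=colors, linewidths=0)
    ax.axvline(thresholds.sens_ratio_max, ls="--", lw=0.8, color="k")
    ax.axvline(thresholds.res_ratio_min, ls="--", lw=0.8, color="k")
    ax.axhline(thresholds.neg_log_p_min, ls="--", lw=0.8, color="k")
    ax.set_xlabel("treated/untreated viability ratio")
    ax.set_ylabel(r"$-\log_{10} P$")
    fig.tight_layout()
    return fig
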