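"""Readers and writers for every tabular artifact the screen pipeline touches.

All interchange formats are plain text: CSV (library manifests, plate maps,
raw well measurements) and TSV (gene-score and hit tables), UTF-8, header
row mandatory, "." decimal separator.  Well coordinates follow 96-well
plate-reader convention: rows A-H, columns 1-12, written ``A1``..``H12``
(case-insensitive on read, canonical uppercase on write).  Replicate
indices are 1-based.

Extra columns found in input tables are tolerated and ignored; they are
never interpreted.
"""

from __future__ import annotations

import enum
import math
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PlateIOError",
    "WellRole",
    "Condition",
    "Call",
    "LibraryEntry",
    "WellAssignment",
    "PlateMap",
    "MeasurementRecord",
    "HitRecord",
    "well_coordinate",
    "read_library_manifest",
    "write_library_manifest",
    "read_plate_map",
    "read_plate_maps",
    "write_plate_maps",
    "read_measurements",
    "write_measurements",
    "write_gene_score_table",
    "read_gene_score_table",
    "read_hit_table",
]


class PlateIOError(ValueError):
    """Raised when a tabular artifact violates its schema or invariants."""


PLATE_ROWS = "ABCDEFGH"
PLATE_COLUMNS = range(1, 13)
_WELL_RE = re.compile(r"^([A-Ha-h])(\d{1,2})$")


def well_coordinate(token: str) -> str:
    """Canonicalize a 96-well coordinate (``'a01'`` -> ``'A1'``).

    Raises :class:`PlateIOError` for anything outside rows A-H / columns 1-12.
    """
    m = _WELL_RE.match(str(token).strip())
    if not m:
        raise PlateIOError(f"invalid well coordinate {token!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if col not in PLATE_COLUMNS:
        raise PlateIOError(f"invalid well coordinate {token!r}: column {col} outside 1-12")
    return f"{row}{col}"


def well_sort_key(well: str) -> tuple[int, int]:
    return (PLATE_ROWS.index(well[0]), int(well[1:]))


class WellRole(str, enum.Enum):
    """What a plate well contains."""

    GENE = "GENE"
    NT = "NT"       # non-targeting siRNA negative control
    ATR = "ATR"     # positive control knockdown
    CHK1 = "CHK1"   # positive control knockdown
    EMPTY = "EMPTY"


class Condition(str, enum.Enum):
    TREATED = "TREATED"
    UNTREATED = "UNTREATED"


class Call(str, enum.Enum):
    """Primary-screen classification of a gene."""

    SENSITIZATION = "SENSITIZATION"
    RESISTANCE = "RESISTANCE"
    NONE = "NONE"
    TOXIC_EXCLUDED = "TOXIC/EXCLUDED"


#: Tokens accepted by :func:`read_hit_table` for each classification, so
#: externally produced hit lists with informal labels still parse.
CALL_TOKENS: Mapping[str, Call] = {
    "sensitization": Call.SENSITIZATION,
    "sensitizer": Call.SENSITIZATION,
    "sens": Call.SENSITIZATION,
    "resistance": Call.RESISTANCE,
    "resistor": Call.RESISTANCE,
    "res": Call.RESISTANCE,
    "none": Call.NONE,
    "ns": Call.NONE,
    "toxic": Call.TOXIC_EXCLUDED,
    "excluded": Call.TOXIC_EXCLUDED,
    "toxic/excluded": Call.TOXIC_EXCLUDED,
}


def parse_call(token: str) -> Call:
    try:
        return CALL_TOKENS[str(token).strip().lower()]
    except KeyError:
        raise PlateIOError(f"unparseable classification token {token!r}") from None


@dataclass(frozen=True)
class LibraryEntry:
    """One library gene and its pool of exactly four siRNA reagents."""

    gene_symbol: str
    sirna_ids: tuple[str, str, str, str]
    category: str | None = None
    plate_assignment: tuple[str, str] | None = None  # (plate_id, well)

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise PlateIOError("empty gene symbol")
        if len(self.sirna_ids) != 4 or any(not s for s in self.sirna_ids):
            raise PlateIOError(
                f"gene {self.gene_symbol!r}: expected exactly 4 siRNA ids, "
                f"got {len(self.sirna_ids)}"
            )
        if len(set(self.sirna_ids)) != 4:
            raise PlateIOError(f"gene {self.gene_symbol!r}: duplicate siRNA id within pool")


@dataclass(frozen=True)
class WellAssignment:
    """Content of one (non-empty) plate well."""

    role: WellRole
    gene_symbol: str | None = None
    sirna_id: str | None = None

    def __post_init__(self) -> None:
        if self.role is WellRole.GENE and not self.gene_symbol:
            raise PlateIOError("GENE well without gene symbol")
        if self.role is not WellRole.GENE and self.gene_symbol:
            raise PlateIOError(f"{self.role.value} well must not carry a gene symbol")


@dataclass(frozen=True)
class PlateMap:
    """Assignment of roles/genes to the wells of one 96-well plate.

    ``wells`` holds only occupied wells; absent coordinates are EMPTY.
    Every plate must carry the control complement the normalization and
    hit-calling steps rely on: at least one NT (negative) well and at
    least one ATR and one CHK1 positive-control well.
    """

    plate_id: str
    wells: Mapping[str, WellAssignment] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon: dict[str, WellAssignment] = {}
        for coord, assignment in self.wells.items():
            canon[well_coordinate(coord)] = assignment
        if len(canon) != len(self.wells):
            raise PlateIOError(f"plate {self.plate_id}: duplicate well coordinate")
        object.__setattr__(self, "wells", canon)
        for role in (WellRole.NT, WellRole.ATR, WellRole.CHK1):
            if not self.wells_with_role(role):
                raise PlateIOError(
                    f"plate {self.plate_id}: no {role.value} well "
                    f"({'normalization' if role is WellRole.NT else 'control layout'} impossible)"
                )
        # A pooled gene (no sirna_id) occupies at most one well per plate; in a
        # deconvolution layout a gene may occupy several wells, one per siRNA.
        seen: set[tuple[str, str | None]] = set()
        for a in canon.values():
            if a.role is not WellRole.GENE:
                continue
            key = (a.gene_symbol, a.sirna_id)
            if key in seen:
                raise PlateIOError(
                    f"plate {self.plate_id}: gene {a.gene_symbol!r}"
                    + (f" siRNA {a.sirna_id!r}" if a.sirna_id else "")
                    + " occupies more than one well"
                )
            seen.add(key)

    def wells_with_role(self, role: WellRole) -> list[str]:
        return sorted(
            (w for w, a in self.wells.items() if a.role is role), key=well_sort_key
        )


@dataclass(frozen=True)
class MeasurementRecord:
    """One raw well signal (WST-1 absorbance, arbitrary units)."""

    plate_id: str
    well: str
    replicate: int
    condition: Condition
    signal: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "well", well_coordinate(self.well))
        if self.replicate < 1:
            raise PlateIOError(f"replicate index must be >=1, got {self.replicate}")
        if not math.isfinite(self.signal) or self.signal < 0:
            raise PlateIOError(
                f"negative or non-finite signal {self.signal!r} at "
                f"{self.plate_id}:{self.well} rep {self.replicate}"
            )


@dataclass(frozen=True)
class HitRecord:
    gene_symbol: str
    call: Call
    category: str | None = None


# ---------------------------------------------------------------------------
# helpers

def _atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise PlateIOError(f"{path}: missing required column(s) {missing}")


_SIRNA_COLS = ["sirna_1", "sirna_2", "sirna_3", "sirna_4"]


# ---------------------------------------------------------------------------
# library manifests

def read_library_manifest(path: str | Path) -> list[LibraryEntry]:
    """Read a library manifest CSV into validated :class:`LibraryEntry` rows.

    Required columns: ``gene`` plus ``sirna_1..sirna_4``.  Optional:
    ``category`` and a pooled-well assignment as ``plate``/``well``.
    Gene symbols must be unique; siRNA ids must be globally unique.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["gene"] + _SIRNA_COLS, path)
    entries: list[LibraryEntry] = []
    seen_genes: dict[str, int] = {}
    seen_sirnas: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # data rows start at line 2
        gene = getattr(row, "gene")
        if pd.isna(gene) or not str(gene).strip():
            raise PlateIOError(f"{path}: row {i}: missing gene symbol")
        gene = str(gene).strip()
        if gene in seen_genes:
            raise PlateIOError(
                f"{path}: row {i}: duplicate gene symbol {gene!r} "
                f"(first seen at row {seen_genes[gene]})"
            )
        seen_genes[gene] = i
        ids = []
        for col in _SIRNA_COLS:
            v = getattr(row, col)
            if pd.isna(v) or not str(v).strip():
                raise PlateIOError(f"{path}: row {i}: gene {gene!r} has fewer than 4 siRNA ids")
            ids.append(str(v).strip())
        for s in ids:
            if s in seen_sirnas:
                raise PlateIOError(
                    f"{path}: row {i}: siRNA id {s!r} already used by gene {seen_sirnas[s]!r}"
                )
            seen_sirnas[s] = gene
        category = getattr(row, "category", None)
        category = None if category is None or pd.isna(category) else str(category)
        plate = getattr(row, "plate", None)
        well = getattr(row, "well", None)
        assignment = None
        if plate is not None and not pd.isna(plate) and well is not None and not pd.isna(well):
            assignment = (str(plate), well_coordinate(well))
        entries.append(LibraryEntry(gene, tuple(ids), category, assignment))
    return entries


def write_library_manifest(entries: Iterable[LibraryEntry], path: str | Path) -> None:
    rows = []
    for e in entries:
        row = {"gene": e.gene_symbol}
        row.update(dict(zip(_SIRNA_COLS, e.sirna_ids)))
        row["category"] = e.category if e.category is not None else ""
        row["plate"] = e.plate_assignment[0] if e.plate_assignment else ""
        row["well"] = e.plate_assignment[1] if e.plate_assignment else ""
        rows.append(row)
    df = pd.DataFrame(rows, columns=["gene", *_SIRNA_COLS, "category", "plate", "well"])
    _atomic_write_text(path, df.to_csv(index=False))


# ---------------------------------------------------------------------------
# plate maps

def read_plate_maps(path: str | Path) -> list[PlateMap]:
    """Read one or more plate maps from a CSV with columns
    ``plate_id, well, role[, gene_symbol, sirna_id]``."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["plate_id", "well", "role"], path)
    by_plate: dict[str, dict[str, WellAssignment]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        plate = str(getattr(row, "plate_id"))
        role_token = str(getattr(row, "role")).strip().upper()
        try:
            role = WellRole(role_token)
        except ValueError:
            raise PlateIOError(f"{path}: row {i}: unknown well role {role_token!r}") from None
        if role is WellRole.EMPTY:
            continue
        gene = getattr(row, "gene_symbol", None)
        gene = None if gene is None or pd.isna(gene) or not str(gene).strip() else str(gene).strip()
        sirna = getattr(row, "sirna_id", None)
        sirna = None if sirna is None or pd.isna(sirna) or not str(sirna).strip() else str(sirna).strip()
        coord = well_coordinate(getattr(row, "well"))
        wells = by_plate.setdefault(plate, {})
        if coord in wells:
            raise PlateIOError(f"{path}: row {i}: duplicate well {plate}:{coord}")
        wells[coord] = WellAssignment(role, gene, sirna)
    return [PlateMap(pid, wells) for pid, wells in by_plate.items()]


def read_plate_map(path: str | Path) -> PlateMap:
    """Read a CSV expected to describe exactly one plate."""
    maps = read_plate_maps(path)
    if len(maps) != 1:
        raise PlateIOError(f"{path}: expected exactly one plate, found {len(maps)}")
    return maps[0]


def write_plate_maps(maps: Iterable[PlateMap], path: str | Path) -> None:
    rows = []
    for m in maps:
        for coord in sorted(m.wells, key=well_sort_key):
            a = m.wells[coord]
            rows.append(
                {
                    "plate_id": m.plate_id,
                    "well": coord,
                    "role": a.role.value,
                    "gene_symbol": a.gene_symbol or "",
                    "sirna_id": a.sirna_id or "",
                }
            )
    df = pd.DataFrame(rows, columns=["plate_id", "well", "role", "gene_symbol", "sirna_id"])
    _atomic_write_text(path, df.to_csv(index=False))


# ---------------------------------------------------------------------------
# raw measurements

def read_measurements(path: str | Path) -> list[MeasurementRecord]:
    """Read raw well signals; validates signs, condition tokens and uniqueness
    of (plate, well, replicate, condition)."""
    df = pd.read_csv(
        path,
        dtype={"plate_id": str, "well": str, "condition": str},
        float_precision="round_trip",
    )
    _require_columns(df, ["plate_id", "well", "replicate", "condition", "signal"], path)
    records: list[MeasurementRecord] = []
    seen: set[tuple[str, str, int, Condition]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        signal = getattr(row, "signal")
        if signal is None or (isinstance(signal, float) and math.isnan(signal)):
            raise PlateIOError(f"{path}: row {i}: missing signal value")
        try:
            signal = float(signal)
        except (TypeError, ValueError):
            raise PlateIOError(f"{path}: row {i}: non-numeric signal {signal!r}") from None
        cond_token = str(getattr(row, "condition")).strip().upper()
        try:
            condition = Condition(cond_token)
        except ValueError:
            raise PlateIOError(f"{path}: row {i}: unknown condition token {cond_token!r}") from None
        try:
            rec = MeasurementRecord(
                plate_id=str(getattr(row, "plate_id")),
                well=str(getattr(row, "well")),
                replicate=int(getattr(row, "replicate")),
                condition=condition,
                signal=signal,
            )
        except PlateIOError as exc:
            raise PlateIOError(f"{path}: row {i}: {exc}") from None
        key = (rec.plate_id, rec.well, rec.replicate, rec.condition)
        if key in seen:
            raise PlateIOError(
                f"{path}: row {i}: duplicate measurement for "
                f"{rec.plate_id}:{rec.well} rep {rec.replicate} {rec.condition.value}"
            )
        seen.add(key)
        records.append(rec)
    return records


def write_measurements(records: Iterable[MeasurementRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "plate_id": r.plate_id,
                "well": r.well,
                "replicate": r.replicate,
                "condition": r.condition.value,
                "signal": repr(r.signal),
            }
            for r in records
        ],
        columns=["plate_id", "well", "replicate", "condition", "signal"],
    )
    _atomic_write_text(path, df.to_csv(index=False))


# ---------------------------------------------------------------------------
# gene-score and hit tables

GENE_SCORE_COLUMNS = [
    "gene",
    "n_replicates",
    "mean_ratio",
    "log2_ratio",
    "zscore",
    "p_one_tailed",
    "neg_log10_p",
    "call",
    "is_control",
    "bh_q",
]


def _fmt6(x: float | None) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return f"{x:.6g}"


def write_gene_score_table(scores, path: str | Path) -> None:
    """Write per-gene scores as TSV; numeric fields at 6 significant digits."""
    scores = list(scores)
    if not scores:
        raise PlateIOError("refusing to write an empty gene-score table")
    rows = []
    for s in scores:
        rows.append(
            {
                "gene": s.gene_symbol,
                "n_replicates": s.n_replicates,
                "mean_ratio": _fmt6(s.mean_ratio),
                "log2_ratio": _fmt6(s.log2_ratio),
                "zscore": _fmt6(s.zscore),
                "p_one_tailed": _fmt6(s.p_one_tailed),
                "neg_log10_p": _fmt6(s.neg_log10_p),
                "call": s.call.value,
                "is_control": str(bool(s.is_control)).lower(),
                "bh_q": _fmt6(s.bh_q),
            }
        )
    df = pd.DataFrame(rows, columns=GENE_SCORE_COLUMNS)
    _atomic_write_text(path, df.to_csv(index=False, sep="\t"))


def read_gene_score_table(path: str | Path) -> list:
    """Read a gene-score TSV back into :class:`~gemscreen.hit_calling.GeneScore`."""
    from .hit_calling import GeneScore  # deferred: hit_calling builds on this module

    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "call": str, "is_control": str})
    _require_columns(df, GENE_SCORE_COLUMNS[:8], path)
    has_bh = "bh_q" in df.columns
    out = []
    for row in df.itertuples(index=False):
        def num(name: str) -> float:
            v = getattr(row, name)
            return float("nan") if v is None or pd.isna(v) else float(v)

        out.append(
            GeneScore(
                gene_symbol=str(getattr(row, "gene")),
                n_replicates=int(getattr(row, "n_replicates")),
                mean_ratio=num("mean_ratio"),
                log2_ratio=num("log2_ratio"),
                zscore=num("zscore"),
                p_one_tailed=num("p_one_tailed"),
                neg_log10_p=num("neg_log10_p"),
                call=parse_call(getattr(row, "call")),
                is_control=str(getattr(row, "is_control", "false")).strip().lower() == "true",
                bh_q=num("bh_q") if has_bh else float("nan"),
            )
        )
    return out


def read_hit_table(
    path: str | Path,
    *,
    gene_col: str = "gene",
    call_col: str = "call",
    category_col: str | None = "category",
    on_duplicate: str = "error",
) -> list[HitRecord]:
    """Read a generic gene/classification table (e.g. a published hit list).

    Column names are configurable because published supplementary tables
    carry arbitrary schemas; extra columns are ignored.  ``on_duplicate``
    is ``"error"`` (default) or ``"dedup"`` (keep first occurrence).
    Delimiter is sniffed, so both CSV and TSV parse.
    """
    if on_duplicate not in ("error", "dedup"):
        raise PlateIOError(f"on_duplicate must be 'error' or 'dedup', got {on_duplicate!r}")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    needed = [gene_col, call_col]
    _require_columns(df, needed, path)
    use_category = category_col is not None and category_col in df.columns
    categories = df[category_col] if use_category else [None] * len(df)
    out: list[HitRecord] = []
    seen: set[str] = set()
    for i, (gene, call_token, cat) in enumerate(
        zip(df[gene_col], df[call_col], categories), start=2
    ):
        gene = str(gene).strip()
        if gene in seen:
            if on_duplicate == "error":
                raise PlateIOError(f"{path}: row {i}: gene {gene!r} repeated")
            continue
        seen.add(gene)
        call = parse_call(call_token)
        category = None if cat is None or pd.isna(cat) or not str(cat).strip() else str(cat).strip()
        out.append(HitRecord(gene, call, category))
    return out
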