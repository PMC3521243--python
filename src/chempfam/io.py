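"""Domain types and TSV readers/writers.

All tabular inputs and outputs are tab-separated UTF-8 text with a header
row. Coordinates are 1-based and inclusive throughout (Pfam/Uniprot
convention). Readers are strict about required columns, lenient about
extra ones, and never silently drop rows: a malformed row raises
:class:`RowError` (or is counted, when a collecting reader is used).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DomainHit",
    "TargetRecord",
    "ActivityRecord",
    "BindingSite",
    "BindingSiteSource",
    "MappingRow",
    "MapType",
    "FormatError",
    "RowError",
    "read_domain_annotations",
    "read_activities",
    "read_binding_sites",
    "read_descriptors",
    "read_id_list",
    "write_mappings",
    "read_mappings",
    "write_seed_list",
    "targets_from_domain_hits",
]

DESCRIPTOR_COLUMNS = ("mw", "alogp", "psa", "rtb", "hbd", "hba")


class FormatError(ValueError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class RowError(ValueError):
    """A single row violates the schema; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class DomainHit:
    """One Pfam-A domain instance on a protein, boundaries 1-based inclusive."""

    target_accession: str
    family: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("family must be non-empty")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid boundaries [{self.start}, {self.end}] for "
                f"{self.target_accession}/{self.family}: need 1 <= start <= end"
            )

    def contains(self, residue: int) -> bool:
        return self.start <= residue <= self.end


@dataclass
class TargetRecord:
    """A protein target with its Pfam-A domain architecture."""

    accession: str
    domains: list[DomainHit] = field(default_factory=list)
    sequence_length: int | None = None
    species_tag: str = ""

    def __post_init__(self) -> None:
        if self.sequence_length is not None:
            bad = [d for d in self.domains if d.end > self.sequence_length]
            if bad:
                raise ValueError(
                    f"{self.accession}: domain end {bad[0].end} exceeds "
                    f"sequence length {self.sequence_length}"
                )

    @property
    def families(self) -> set[str]:
        """Distinct Pfam families present (copies collapse to one)."""
        return {d.family for d in self.domains}

    def hits_of(self, family: str) -> list[DomainHit]:
        return [d for d in self.domains if d.family == family]


@dataclass(frozen=True)
class ActivityRecord:
    """One measured bioactivity linking a compound to a protein target."""

    activity_id: int
    compound_id: int
    target_accession: str
    assay_type: str
    multi_flag: bool
    complex_flag: bool
    activity_type: str
    value: float
    unit: str = ""


class BindingSiteSource(str, Enum):
    UNIPROT = "uniprot"
    PDBE = "pdbe"


@dataclass(frozen=True)
class BindingSite:
    """A set of ligand-binding residue positions on one target.

    Residues are 1-based Uniprot coordinates.  Uniprot-style annotations
    list sparse key residues; PDBe-style annotations list every contact
    residue and usually carry the ligand's three-letter code.
    """

    target_accession: str
    residues: frozenset[int]
    source: BindingSiteSource = BindingSiteSource.UNIPROT
    ligand_code: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("binding site must contain at least one residue")
        if any(r < 1 for r in self.residues):
            raise ValueError("residue indices are 1-based; got a value < 1")


class MapType(str, Enum):
    SINGLE = "single"
    MULTI = "multi"


@dataclass(frozen=True)
class MappingRow:
    """One activity mapped to the Pfam-A family mediating its binding."""

    activity_id: int
    domain: str
    compound_id: int
    target_accession: str
    maptype: MapType


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                         encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file (expected a header row)")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def _to_int(raw: str, col: str, line: int) -> int:
    try:
        return int(raw)
    except ValueError:
        raise RowError(f"column '{col}': expected integer, got {raw!r}", line)


def _to_float(raw: str, col: str, line: int) -> float:
    try:
        v = float(raw)
    except ValueError:
        raise RowError(f"column '{col}': expected number, got {raw!r}", line)
    if not math.isfinite(v):
        raise RowError(f"column '{col}': non-finite value {raw!r}", line)
    return v


def read_domain_annotations(path: str | Path) -> list[DomainHit]:
    """Read a domain-annotation table (columns uniprot, pfam, start, end).

    One :class:`DomainHit` per row, in file order.  Duplicate rows are
    preserved: a family may legitimately hit a protein more than once.
    """
    df = _read_tsv(path, ("uniprot", "pfam", "start", "end"))
    hits: list[DomainHit] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        start = _to_int(row.start, "start", line)
        end = _to_int(row.end, "end", line)
        try:
            hits.append(DomainHit(row.uniprot, row.pfam, start, end))
        except ValueError as exc:
            raise RowError(str(exc), line)
    return hits


def targets_from_domain_hits(
    hits: Iterable[DomainHit],
    sequence_lengths: Mapping[str, int] | None = None,
) -> dict[str, TargetRecord]:
    """Group domain hits into TargetRecords keyed by accession."""
    targets: dict[str, TargetRecord] = {}
    for h in hits:
        rec = targets.get(h.target_accession)
        if rec is None:
            length = sequence_lengths.get(h.target_accession) if sequence_lengths else None
            rec = TargetRecord(h.target_accession, [], length)
            targets[h.target_accession] = rec
        rec.domains.append(h)
    if sequence_lengths:
        for acc, length in sequence_lengths.items():
            targets.setdefault(acc, TargetRecord(acc, [], length))
    return targets


_ACTIVITY_COLS = ("activity_id", "molregno", "uniprot", "assay_type",
                  "multi", "complex", "type", "value", "unit")


def _to_flag(raw: str, col: str, line: int) -> bool:
    if raw in ("0", "1"):
        return raw == "1"
    raise RowError(f"column '{col}': expected 0 or 1, got {raw!r}", line)


def read_activities(path: str | Path) -> list[ActivityRecord]:
    """Read a ChEMBL-export-style activity table.

    Duplicate activity_ids are kept (with a logged warning); the reader
    does not deduplicate.
    """
    df = _read_tsv(path, _ACTIVITY_COLS)
    records: list[ActivityRecord] = []
    seen: set[int] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        act_id = _to_int(row.activity_id, "activity_id", line)
        if act_id in seen:
            logger.warning("%s line %d: duplicated activity_id %d (kept)",
                           path, line, act_id)
        seen.add(act_id)
        records.append(ActivityRecord(
            activity_id=act_id,
            compound_id=_to_int(row.molregno, "molregno", line),
            target_accession=row.uniprot,
            assay_type=row.assay_type,
            multi_flag=_to_flag(row.multi, "multi", line),
            complex_flag=_to_flag(getattr(row, "complex"), "complex", line),
            activity_type=row.type,
            value=_to_float(row.value, "value", line),
            unit=row.unit,
        ))
    return records


def read_binding_sites(path: str | Path) -> list[BindingSite]:
    """Read a binding-site table (uniprot, source, ligand, residues).

    ``residues`` is a comma-separated list of 1-based integers; ``ligand``
    may be empty (Uniprot-style sites have no ligand code).
    """
    df = _read_tsv(path, ("uniprot", "source", "residues"))
    has_ligand = "ligand" in df.columns
    sites: list[BindingSite] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            source = BindingSiteSource(row.source)
        except ValueError:
            raise RowError(f"column 'source': expected uniprot|pdbe, got {row.source!r}", line)
        raw = [tok for tok in row.residues.split(",") if tok.strip()]
        if not raw:
            raise RowError("column 'residues': empty residue list", line)
        residues = frozenset(_to_int(tok.strip(), "residues", line) for tok in raw)
        ligand = (row.ligand or None) if has_ligand else None
        try:
            sites.append(BindingSite(row.uniprot, residues, source, ligand))
        except ValueError as exc:
            raise RowError(str(exc), line)
    return sites


def read_descriptors(path: str | Path) -> pd.DataFrame:
    """Read a molecular-descriptor table into a DataFrame indexed by molregno.

    Columns: mw (Da), alogp, psa (Å²), rtb, hbd, hba.
    """
    df = _read_tsv(path, ("molregno",) + DESCRIPTOR_COLUMNS)
    out = df[["molregno", *DESCRIPTOR_COLUMNS]].copy()
    for col in out.columns:
        out[col] = pd.to_numeric(out[col], errors="raise")
    out["molregno"] = out["molregno"].astype(int)
    return out.set_index("molregno")


def read_id_list(path: str | Path) -> set[str]:
    """Read a one-id-per-line list (manual seeds, excluded targets).

    Blank lines and ``#`` comments are ignored; an inline comment after the
    id (whitespace-separated) is allowed, mirroring curation files that
    carry a justification per entry.
    """
    ids: set[str] = set()
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            continue
        ids.add(stripped.split()[0])
    return ids


# ---------------------------------------------------------------------------
# writers


def write_mappings(rows: Iterable[MappingRow], path: str | Path) -> None:
    """Write mapping rows as TSV (activity, domain, molregno, uniprot, maptype).

    Rows are sorted by activity_id so output is deterministic regardless of
    input order.
    """
    ordered = sorted(rows, key=lambda r: r.activity_id)
    df = pd.DataFrame(
        [(r.activity_id, r.domain, r.compound_id, r.target_accession,
          r.maptype.value) for r in ordered],
        columns=["activity", "domain", "molregno", "uniprot", "maptype"],
    )
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_mappings(path: str | Path) -> list[MappingRow]:
    df = _read_tsv(path, ("activity", "domain", "molregno", "uniprot", "maptype"))
    rows: list[MappingRow] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            maptype = MapType(row.maptype)
        except ValueError:
            raise RowError(f"column 'maptype': expected single|multi, got {row.maptype!r}", line)
        rows.append(MappingRow(
            activity_id=_to_int(row.activity, "activity", line),
            domain=row.domain,
            compound_id=_to_int(row.molregno, "molregno", line),
            target_accession=row.uniprot,
            maptype=maptype,
        ))
    return rows


def write_seed_list(families: Mapping[str, str], path: str | Path) -> None:
    """Write a seed-family list as TSV (family, provenance), sorted by family."""
    df = pd.DataFrame(sorted(families.items()), columns=["family", "provenance"])
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
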