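"""Reading and writing the file formats the pipeline touches.

Inputs are AIRR-style rearrangement TSVs (one row per annotated read),
reference clonotype databases (TSV of V gene + CDR3 aa), protein FASTA and
plain-text HLA allele lists.  The single output format is the clonotype
table.  Parsing is strict: a row either becomes a :class:`Rearrangement`
or is collected as a rejected row with a reason; rows are never silently
dropped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import FormatError
from .models import Clonotype, Rearrangement, ReferenceClonotypeDB, STANDARD_AA

logger = logging.getLogger(__name__)

#: Default column names, following the AIRR Rearrangement schema.
DEFAULT_DIALECT: dict[str, str] = {
    "sample_id": "sample_id",
    "sequence_id": "sequence_id",
    "v_call": "v_call",
    "d_call": "d_call",
    "j_call": "j_call",
    "cdr3_aa": "cdr3_aa",
    "junction_aa": "junction_aa",
    "productive": "productive",
    "v_identity": "v_identity",
    "duplicate_count": "duplicate_count",
}

_TRUE = {"t", "true", "1", "yes", "y"}
_FALSE = {"f", "false", "0", "no", "n"}

_VALID_CDR3 = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY*]*$")


def normalize_v_gene(v_call: str) -> str:
    """Reduce an IMGT-style V call to a bare gene name.

    Takes the first gene of an ambiguous (comma-separated) call, strips the
    allele suffix (``*01``) and surrounding whitespace:
    ``"TRBV12-3*01, TRBV12-4*01"`` -> ``"TRBV12-3"``.
    """
    first = v_call.split(",")[0]
    return first.split("*")[0].strip()


@dataclass
class RejectedRow:
    row_number: int  # 1-based data-row index
    reason: str
    raw: dict = field(default_factory=dict)


@dataclass
class RearrangementSet:
    """Parsed rearrangements plus the rows that failed to parse."""

    records: list[Rearrangement]
    rejected: list[RejectedRow]

    @property
    def n_input_rows(self) -> int:
        return len(self.records) + len(self.rejected)


def _parse_bool(value: str) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"unparseable productivity value {value!r}")


def read_rearrangements(
    path: str | Path,
    dialect: Optional[Mapping[str, str]] = None,
    sample_id: Optional[str] = None,
) -> RearrangementSet:
    """Read an AIRR-style rearrangement TSV.

    ``dialect`` maps logical field names (keys of :data:`DEFAULT_DIALECT`)
    to the file's column headers.  The CDR3 may be given either directly
    (``cdr3_aa``) or as a junction (``junction_aa``), in which case the
    conserved anchor residues (first and last) are stripped.  ``sample_id``
    overrides / substitutes a sample_id column; when neither is available
    the file stem is used.

    Raises :class:`FormatError` if a mandatory column is missing; row-level
    problems are collected in ``rejected`` rather than raised.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return read_rearrangements_frame(
        df, dialect=dialect, sample_id=sample_id or path.stem, source=str(path)
    )


def read_rearrangements_frame(
    df: pd.DataFrame,
    dialect: Optional[Mapping[str, str]] = None,
    sample_id: Optional[str] = None,
    source: str = "<frame>",
) -> RearrangementSet:
    """Parse an in-memory rearrangement table (string-typed columns); same
    contract as :func:`read_rearrangements`."""
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)

    for logical in ("v_call", "productive", "v_identity"):
        if cols[logical] not in df.columns:
            raise FormatError(f"missing mandatory column: {cols[logical]}")
    has_cdr3 = cols["cdr3_aa"] in df.columns
    has_junction = cols["junction_aa"] in df.columns
    if not (has_cdr3 or has_junction):
        raise FormatError(
            f"missing mandatory column: {cols['cdr3_aa']} (or {cols['junction_aa']})"
        )

    default_sample = sample_id or "sample"
    records: list[Rearrangement] = []
    rejected: list[RejectedRow] = []
    scaled_identity = False

    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            productive = _parse_bool(row[cols["productive"]])
            v_identity = float(row[cols["v_identity"]])
            if 0.0 <= v_identity <= 1.0:
                # fractional identity: auto-scale to percent
                v_identity *= 100.0
                scaled_identity = True
            if not (0.0 <= v_identity <= 100.0):
                raise ValueError(f"v_identity {v_identity} outside [0, 100]")
            if has_cdr3 and row.get(cols["cdr3_aa"], ""):
                cdr3 = row[cols["cdr3_aa"]].strip().upper()
            elif has_junction and row.get(cols["junction_aa"], ""):
                junction = row[cols["junction_aa"]].strip().upper()
                # strip the conserved C / F-W anchors flanking the CDR3
                cdr3 = junction[1:-1] if len(junction) >= 2 else ""
            else:
                cdr3 = ""
            if not _VALID_CDR3.match(cdr3):
                raise ValueError(f"invalid CDR3 characters in {cdr3!r}")
            if "*" in cdr3 and productive:
                raise ValueError("stop codon '*' in a productive CDR3")
            dup_col = cols["duplicate_count"]
            dup_raw = row.get(dup_col, "")
            duplicate_count = int(dup_raw) if dup_raw else 1
            if duplicate_count < 1:
                raise ValueError(f"duplicate_count {duplicate_count} < 1")
            records.append(
                Rearrangement(
                    sample_id=row.get(cols["sample_id"], "") or default_sample,
                    sequence_id=row.get(cols["sequence_id"], "") or f"row{i}",
                    v_call=row[cols["v_call"]],
                    d_call=row.get(cols["d_call"], ""),
                    j_call=row.get(cols["j_call"], ""),
                    cdr3_aa=cdr3,
                    productive=productive,
                    v_identity=v_identity,
                    duplicate_count=duplicate_count,
                )
            )
        except (ValueError, KeyError) as exc:
            rejected.append(RejectedRow(row_number=i, reason=str(exc), raw=row))

    if scaled_identity:
        logger.warning(
            "%s: v_identity values in [0,1] were interpreted as fractions "
            "and scaled to percent",
            source,
        )
    if rejected:
        logger.info("%s: rejected %d of %d rows", source, len(rejected), len(df))
    return RearrangementSet(records=records, rejected=rejected)


def read_reference_db(path: str | Path, name: Optional[str] = None) -> ReferenceClonotypeDB:
    """Read a reference clonotype database TSV (columns v_gene, cdr3_aa).

    Allele suffixes are stripped and duplicate pairs collapsed.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("v_gene", "cdr3_aa"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column: {col}")
    entries = {
        (normalize_v_gene(v), c.strip().upper())
        for v, c in zip(df["v_gene"], df["cdr3_aa"])
        if v and c
    }
    db = ReferenceClonotypeDB(name=name or path.stem, entries=entries)
    if not entries:
        logger.warning("%s: reference database is empty", path)
    else:
        logger.info("%s: %d unique reference clonotypes", path, len(entries))
    return db


CLONOTYPE_COLUMNS = ["sample_id", "v_gene", "cdr3_aa", "read_count", "frequency", "rank"]


def write_clonotype_table(path: str | Path, clonotypes: Sequence[Clonotype]) -> None:
    """Write clonotypes as a TSV; frequencies keep full float precision so
    the write -> read round-trip is exact."""
    df = pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "v_gene": c.v_gene,
                "cdr3_aa": c.cdr3_aa,
                "read_count": c.read_count,
                "frequency": repr(c.frequency),
                "rank": c.rank,
            }
            for c in clonotypes
        ],
        columns=CLONOTYPE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_clonotype_table(path: str | Path) -> list[Clonotype]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CLONOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column: {missing[0]}")
    return [
        Clonotype(
            sample_id=r["sample_id"],
            v_gene=r["v_gene"],
            cdr3_aa=r["cdr3_aa"],
            read_count=int(r["read_count"]),
            frequency=float(r["frequency"]),
            rank=int(r["rank"]),
        )
        for r in df.to_dict("records")
    ]


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into name -> sequence; sequences are upper-cased
    and a trailing '*' terminator is stripped."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        for pos, aa in enumerate(seq, start=1):
            if aa not in STANDARD_AA:
                raise FormatError(
                    f"{path}: record {record.id!r} has non-amino-acid "
                    f"character {aa!r} at position {pos}"
                )
        if not seq:
            raise FormatError(f"{path}: record {record.id!r} is empty")
        sequences[record.id] = seq
    return sequences


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a nucleotide FASTA (no validation beyond upper-casing)."""
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def read_hla_list(path: str | Path) -> list[str]:
    """Read an HLA allele list, one allele per line, preserved verbatim."""
    alleles = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            alleles.append(line)
    return alleles
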