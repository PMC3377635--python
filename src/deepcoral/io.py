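"""Readers and writers for the standard formats the pipeline touches.

Sequences travel as FASTA with a sidecar delimited metadata table keyed by
``seq_id`` (taxonomy, basin and depth are too structured for defline
parsing). Occurrence records and every output table are plain CSV with a
header. Parsers are total: every input row either yields a typed object or
a logged rejection, and accepted + rejected = input.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .datamodel import AlignedSequence, Alignment, AlignmentError, SpecimenRecord

__all__ = [
    "read_alignment",
    "write_alignment",
    "read_specimen_table",
    "write_specimen_table",
    "write_table",
    "read_table",
]

logger = logging.getLogger(__name__)

_OPTIONAL_STR = ("species", "family", "basin", "source")


def _opt_str(value: Any) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    return text or None


def _opt_float(value: Any) -> float | None:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    return float(value)


def read_alignment(
    fasta_path: str | Path,
    metadata_path: str | Path | None = None,
    marker_name: str = "",
) -> Alignment:
    """Read a FASTA alignment plus (optionally) its sidecar metadata table.

    The metadata table must have a ``seq_id`` column resolving one-to-one
    against the FASTA ids; recognized columns are ``genus``, ``species``,
    ``family``, ``basin`` and ``depth_m``. Sequences are upper-cased and
    U is mapped to T. Unequal row lengths, unmatched ids and symbols
    outside the IUPAC alphabet are hard errors.
    """
    fasta_path = Path(fasta_path)
    seqs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")]
    if not seqs:
        raise AlignmentError(f"no sequences found in {fasta_path}")

    meta: dict[str, dict[str, Any]] = {}
    if metadata_path is not None:
        table = pd.read_csv(metadata_path, dtype={"seq_id": str})
        if "seq_id" not in table.columns:
            raise AlignmentError(f"metadata {metadata_path} lacks a seq_id column")
        meta = {str(row["seq_id"]): dict(row) for _, row in table.iterrows()}
        fasta_ids = {sid for sid, _ in seqs}
        missing = fasta_ids - set(meta)
        if missing:
            raise AlignmentError(
                "metadata rows missing for FASTA ids: " + ", ".join(sorted(missing))
            )

    rows = []
    for seq_id, symbols in seqs:
        m = meta.get(seq_id, {})
        rows.append(
            AlignedSequence(
                seq_id=seq_id,
                symbols=symbols,
                genus=_opt_str(m.get("genus")) or "",
                species=_opt_str(m.get("species")),
                family=_opt_str(m.get("family")),
                basin=_opt_str(m.get("basin")),
                depth_m=_opt_float(m.get("depth_m")),
            )
        )
    name = marker_name or fasta_path.stem
    return Alignment(rows=tuple(rows), marker_name=name)


def write_alignment(
    alignment: Alignment,
    fasta_path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write an alignment back to FASTA (+ metadata CSV), inverse of
    :func:`read_alignment`."""
    with open(fasta_path, "w") as fh:
        for row in alignment:
            fh.write(f">{row.seq_id}\n{row.symbols}\n")
    if metadata_path is not None:
        write_table(
            [
                {
                    "seq_id": r.seq_id,
                    "genus": r.genus,
                    "species": r.species,
                    "family": r.family,
                    "basin": r.basin,
                    "depth_m": r.depth_m,
                }
                for r in alignment
            ],
            metadata_path,
        )


def read_specimen_table(
    csv_path: str | Path,
) -> tuple[list[SpecimenRecord], list[tuple[str, str]]]:
    """Read occurrence records from CSV.

    Required columns: ``record_id``, ``genus`` and either a point ``depth_m``
    column or ``depth_min_m``/``depth_max_m`` (a point depth is copied into
    both bounds). Rows violating the record invariants (min > max,
    nonpositive depth) are rejected, not fatal: the function returns
    ``(records, rejections)`` with one ``(record_id, reason)`` pair per
    rejected row, and logs each rejection.
    """
    table = pd.read_csv(csv_path, dtype={"record_id": str})
    required = {"record_id", "genus"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{csv_path}: missing required columns {sorted(missing)}")
    has_point = "depth_m" in table.columns
    has_range = {"depth_min_m", "depth_max_m"} <= set(table.columns)
    if not (has_point or has_range):
        raise ValueError(
            f"{csv_path}: need either a depth_m column or depth_min_m/depth_max_m"
        )

    records: list[SpecimenRecord] = []
    rejections: list[tuple[str, str]] = []
    for _, row in table.iterrows():
        rid = str(row["record_id"])
        try:
            dmin = _opt_float(row.get("depth_min_m")) if has_range else None
            dmax = _opt_float(row.get("depth_max_m")) if has_range else None
            if dmin is None or dmax is None:
                point = _opt_float(row.get("depth_m")) if has_point else None
                if point is None:
                    raise ValueError(f"record {rid!r}: no depth given")
                dmin = dmax = point
            records.append(
                SpecimenRecord(
                    record_id=rid,
                    genus=_opt_str(row.get("genus")) or "",
                    species=_opt_str(row.get("species")),
                    basin=_opt_str(row.get("basin")),
                    lat=_opt_float(row.get("lat")),
                    lon=_opt_float(row.get("lon")),
                    depth_min_m=dmin,
                    depth_max_m=dmax,
                    n_colonies=int(row["n_colonies"])
                    if "n_colonies" in table.columns and pd.notna(row["n_colonies"])
                    else 1,
                    source=_opt_str(row.get("source")) or "collection",
                )
            )
        except (ValueError, TypeError) as exc:
            logger.warning("rejected record %s: %s", rid, exc)
            rejections.append((rid, str(exc)))
    assert len(records) + len(rejections) == len(table)
    return records, rejections


def write_specimen_table(
    records: Iterable[SpecimenRecord], csv_path: str | Path
) -> None:
    write_table([dataclasses.asdict(r) for r in records], csv_path)


def write_table(
    rows: Sequence[Mapping[str, Any]] | pd.DataFrame,
    csv_path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write rows sharing a header to CSV; lossless against
    :func:`read_table`. An empty row set with explicit ``columns`` yields a
    header-only file."""
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        frame = pd.DataFrame(list(rows), columns=columns)
    frame.to_csv(csv_path, index=False)


def read_table(csv_path: str | Path) -> pd.DataFrame:
    return pd.read_csv(csv_path)
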