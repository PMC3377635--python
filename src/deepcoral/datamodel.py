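"""Shared domain types for the octocoral barcode/biogeography pipeline.

The pipeline moves three kinds of objects between stages: aligned barcode
sequences with specimen metadata (taxonomy, ocean basin, collection depth),
occurrence records with a station depth interval, and the derived summary
tables. Everything here is a plain dataclass with eager validation so that
downstream stages can assume their invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

__all__ = [
    "BASINS",
    "IUPAC_SYMBOLS",
    "UNAMBIGUOUS",
    "AMBIGUITY_EXPANSION",
    "AlignedSequence",
    "Alignment",
    "SpecimenRecord",
    "AlignmentError",
]

#: Recognized ocean-basin labels (inputs, never inferred from coordinates).
BASINS: tuple[str, ...] = ("Atlantic", "Indian", "Pacific", "Antarctic")

#: Canonical alignment alphabet: the four bases, IUPAC ambiguity codes, gap.
IUPAC_SYMBOLS: frozenset[str] = frozenset("ACGTRYSWKMBDHVN-")

#: Symbols that denote a single, unambiguous nucleotide state.
UNAMBIGUOUS: frozenset[str] = frozenset("ACGT")

#: Which bases each ambiguity code is compatible with.
AMBIGUITY_EXPANSION: dict[str, frozenset[str]] = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


class AlignmentError(ValueError):
    """Raised when sequence data violates the alignment invariants."""


def _normalize_symbols(seq_id: str, raw: str) -> str:
    """Upper-case, map U->T, and reject anything outside the alphabet."""
    symbols = raw.upper().replace("U", "T")
    for pos, ch in enumerate(symbols):
        if ch not in IUPAC_SYMBOLS:
            raise AlignmentError(
                f"sequence {seq_id!r}: illegal symbol {ch!r} at position {pos}"
            )
    return symbols


@dataclass(frozen=True)
class AlignedSequence:
    """One aligned barcode sequence with its specimen metadata.

    ``symbols`` is stored upper-case over the IUPAC nucleotide alphabet plus
    gap; U is mapped to T at construction. ``basin`` must be one of
    :data:`BASINS` when present; ``depth_m`` is meters below surface (> 0).
    """

    seq_id: str
    symbols: str
    genus: str = ""
    species: str | None = None
    family: str | None = None
    basin: str | None = None
    depth_m: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "symbols", _normalize_symbols(self.seq_id, self.symbols)
        )
        if self.basin is not None and self.basin not in BASINS:
            raise ValueError(
                f"sequence {self.seq_id!r}: unknown basin {self.basin!r}; "
                f"expected one of {BASINS}"
            )
        if self.depth_m is not None and not self.depth_m > 0:
            raise ValueError(
                f"sequence {self.seq_id!r}: depth_m must be > 0, got {self.depth_m}"
            )

    def __len__(self) -> int:
        return len(self.symbols)

    def degapped_length(self) -> int:
        return len(self.symbols) - self.symbols.count("-")


@dataclass(frozen=True)
class Alignment:
    """An equal-length collection of :class:`AlignedSequence` rows."""

    rows: tuple[AlignedSequence, ...]
    marker_name: str = ""

    def __post_init__(self) -> None:
        rows = tuple(self.rows)
        object.__setattr__(self, "rows", rows)
        if not rows:
            raise AlignmentError("alignment must contain at least one sequence")
        length = len(rows[0])
        if length == 0:
            raise AlignmentError("alignment length must be > 0")
        offenders = [r.seq_id for r in rows if len(r) != length]
        if offenders:
            raise AlignmentError(
                "unequal sequence lengths; offending ids: " + ", ".join(offenders)
            )
        ids = [r.seq_id for r in rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError("duplicate seq_ids: " + ", ".join(dupes))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.seq_id for r in self.rows)

    def __iter__(self) -> Iterator[AlignedSequence]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def subset(self, seq_ids: Iterable[str]) -> "Alignment":
        wanted = set(seq_ids)
        return Alignment(
            rows=tuple(r for r in self.rows if r.seq_id in wanted),
            marker_name=self.marker_name,
        )

    def concatenate(self, other: "Alignment", marker_name: str = "") -> "Alignment":
        """Column-wise concatenation for alignments over the same row ids."""
        other_by_id = {r.seq_id: r for r in other.rows}
        if set(other_by_id) != set(self.ids):
            raise AlignmentError("concatenation requires identical row id sets")
        rows = tuple(
            replace(r, symbols=r.symbols + other_by_id[r.seq_id].symbols)
            for r in self.rows
        )
        return Alignment(rows=rows, marker_name=marker_name or
                         f"{self.marker_name}+{other.marker_name}")


@dataclass(frozen=True)
class SpecimenRecord:
    """One occurrence record: a specimen or sampling station with a depth
    interval.

    Point records (a single sounding) carry ``depth_min_m == depth_max_m``;
    trawl/dredge stations report the gear's depth interval. ``n_colonies``
    is the minimum number of colonies the record represents.
    """

    record_id: str
    genus: str
    depth_min_m: float
    depth_max_m: float
    species: str | None = None
    basin: str | None = None
    lat: float | None = None
    lon: float | None = None
    n_colonies: int = 1
    source: str = "collection"

    def __post_init__(self) -> None:
        if not self.depth_min_m > 0:
            raise ValueError(
                f"record {self.record_id!r}: nonpositive depth_min_m "
                f"{self.depth_min_m}"
            )
        if self.depth_min_m > self.depth_max_m:
            raise ValueError(
                f"record {self.record_id!r}: depth_min_m {self.depth_min_m} "
                f"> depth_max_m {self.depth_max_m}"
            )
        if self.n_colonies < 1:
            raise ValueError(
                f"record {self.record_id!r}: n_colonies must be >= 1"
            )
        if self.basin is not None and self.basin not in BASINS:
            raise ValueError(
                f"record {self.record_id!r}: unknown basin {self.basin!r}"
            )
        if self.source not in ("literature", "museum", "collection"):
            raise ValueError(
                f"record {self.record_id!r}: unknown source {self.source!r}"
            )

    @property
    def is_point(self) -> bool:
        return self.depth_min_m == self.depth_max_m

    @property
    def depth_range_m(self) -> float:
        return self.depth_max_m - self.depth_min_m

    @property
    def depth_mean_m(self) -> float:
        return (self.depth_min_m + self.depth_max_m) / 2.0
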