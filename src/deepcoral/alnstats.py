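"""Alignment information-content summaries.

For each marker alignment this module reports the standard description used
to compare barcode markers: number of taxa, alignment length, de-gapped
sequence length range, and counts (with integer percentages of alignment
length) of variable and parsimony-informative sites.

A column's *state set* is, by default, the distinct unambiguous bases
{A, C, G, T} present in it — gaps and IUPAC ambiguity codes contribute no
state. A column is *variable* when its state set has at least two elements,
and *parsimony-informative* when at least two of those states are each
carried by at least two rows. A switch treats the gap as a fifth state.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .datamodel import Alignment, UNAMBIGUOUS

__all__ = [
    "AlignmentSummary",
    "degapped_length_range",
    "count_variable_sites",
    "count_parsimony_informative_sites",
    "summarize_alignment",
]


@dataclass(frozen=True)
class AlignmentSummary:
    """One marker's row of the information-content table."""

    marker_name: str
    n_taxa: int
    n_columns: int
    degapped_min: int
    degapped_max: int
    n_variable: int
    pct_variable: int
    n_parsinf: int
    pct_parsinf: int

    def __post_init__(self) -> None:
        assert self.n_parsinf <= self.n_variable <= self.n_columns
        assert self.degapped_min <= self.degapped_max <= self.n_columns


def round_half_up_percent(count: int, total: int) -> int:
    """Nearest-integer percentage, ties away from zero (384/829 -> 46)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(np.floor(100.0 * count / total + 0.5))


def _columns(alignment: Alignment) -> np.ndarray:
    """Alignment as a (n_columns, n_rows) array of single characters."""
    mat = np.array([list(r.symbols) for r in alignment.rows], dtype="U1")
    return mat.T


def _state_counts(column: np.ndarray, gaps_as_state: bool) -> Counter:
    allowed = set(UNAMBIGUOUS) | ({"-"} if gaps_as_state else set())
    return Counter(ch for ch in column if ch in allowed)


def degapped_length_range(alignment: Alignment) -> tuple[int, int]:
    """(shortest, longest) de-gapped sequence length over the rows."""
    lengths = [r.degapped_length() for r in alignment.rows]
    return min(lengths), max(lengths)


def count_variable_sites(alignment: Alignment, gaps_as_state: bool = False) -> int:
    """Number of columns with >= 2 states."""
    return sum(
        1
        for col in _columns(alignment)
        if len(_state_counts(col, gaps_as_state)) >= 2
    )


def count_parsimony_informative_sites(
    alignment: Alignment, gaps_as_state: bool = False
) -> int:
    """Number of columns with >= 2 states each carried by >= 2 rows."""
    n = 0
    for col in _columns(alignment):
        counts = _state_counts(col, gaps_as_state)
        if sum(1 for c in counts.values() if c >= 2) >= 2:
            n += 1
    return n


def summarize_alignment(
    alignment: Alignment, gaps_as_state: bool = False
) -> AlignmentSummary:
    lo, hi = degapped_length_range(alignment)
    n_var = count_variable_sites(alignment, gaps_as_state)
    n_pars = count_parsimony_informative_sites(alignment, gaps_as_state)
    L = alignment.n_columns
    return AlignmentSummary(
        marker_name=alignment.marker_name,
        n_taxa=alignment.n_rows,
        n_columns=L,
        degapped_min=lo,
        degapped_max=hi,
        n_variable=n_var,
        pct_variable=round_half_up_percent(n_var, L),
        n_parsinf=n_pars,
        pct_parsinf=round_half_up_percent(n_pars, L),
    )
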