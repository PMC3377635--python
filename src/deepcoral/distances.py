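"""Uncorrected p-distances, transition/transversion tallies, and the
distance-threshold family-delimitation rule.

The uncorrected p-distance between two aligned sequences is the proportion
of differing sites among the sites compared, with *pairwise deletion*: per
pair, a column is compared only when both symbols are unambiguous bases
(A, C, G or T). No substitution-model correction is applied — for the
closely related taxa this package targets, multiple hits are rare and the
raw proportion is the quantity reported in the field's barcoding
literature.

The delimitation rule compares a candidate taxon's distances to the members
of an established family against two calibrated thresholds: a maximum
observed intra-familial distance (default 4.9%) and a minimum observed
inter-familial distance (default 3.8%). Distances all at or below the
inter-familial minimum place the candidate inside the family; distances all
at or above the intra-familial maximum support a distinct family; anything
else is ambiguous (the two calibration thresholds overlap, so an ambiguous
zone exists by construction). The defaults are data-derived constants from
an external calcaxonian reference dataset and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .datamodel import Alignment

__all__ = [
    "DistanceMatrix",
    "GroupDistanceSummary",
    "DelimitationThresholds",
    "TiTvTally",
    "NoComparableSitesError",
    "p_distance",
    "distance_matrix",
    "titv_tally",
    "group_distance_summary",
    "assess_rank_delimitation",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
#: transition partners among A,C,G,T (purine<->purine, pyrimidine<->pyrimidine)
_TRANSITIONS = {(65, 71), (71, 65), (67, 84), (84, 67)}  # A<->G, C<->T


class NoComparableSitesError(ValueError):
    """Raised when a sequence pair shares no unambiguous columns."""


def _encode(symbols: str) -> np.ndarray:
    return np.frombuffer(symbols.encode("ascii"), dtype=np.uint8)


def _valid_mask(arr: np.ndarray) -> np.ndarray:
    return np.isin(arr, _BASES)


def p_distance(row_a: str, row_b: str) -> tuple[float, int]:
    """Uncorrected p-distance under pairwise deletion.

    Returns ``(p, n_compared)`` where ``p`` is differing compared columns /
    compared columns. Raises :class:`NoComparableSitesError` when no column
    has an unambiguous base in both rows.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal (aligned) length")
    a, b = _encode(row_a), _encode(row_b)
    both = _valid_mask(a) & _valid_mask(b)
    n_compared = int(both.sum())
    if n_compared == 0:
        raise NoComparableSitesError("no comparable (unambiguous) sites in pair")
    mismatches = int((a[both] != b[both]).sum())
    return mismatches / n_compared, n_compared


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise p-distance matrix with compared-site counts.

    Pairs with no comparable sites are NaN in ``p`` (0 in ``compared``) and
    listed in ``failed_pairs`` rather than aborting the whole matrix.
    """

    ids: tuple[str, ...]
    p: np.ndarray
    compared: np.ndarray
    failed_pairs: tuple[tuple[str, str], ...] = ()

    def get(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.p[i, j])


def distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """All-pairs p-distance via pairwise deletion."""
    n = alignment.n_rows
    enc = np.stack([_encode(r.symbols) for r in alignment.rows])
    valid = _valid_mask(enc)
    p = np.zeros((n, n), dtype=float)
    compared = np.zeros((n, n), dtype=np.int64)
    failed: list[tuple[str, str]] = []
    # self-comparisons: zero distance over the row's own unambiguous sites
    for i in range(n):
        compared[i, i] = int(valid[i].sum())
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nc = int(both.sum())
            compared[i, j] = compared[j, i] = nc
            if nc == 0:
                p[i, j] = p[j, i] = np.nan
                failed.append((alignment.ids[i], alignment.ids[j]))
                continue
            mm = int((enc[i, both] != enc[j, both]).sum())
            p[i, j] = p[j, i] = mm / nc
    return DistanceMatrix(
        ids=alignment.ids, p=p, compared=compared, failed_pairs=tuple(failed)
    )


@dataclass(frozen=True)
class TiTvTally:
    """Pooled transition/transversion counts over all sequence pairs."""

    transitions: int
    transversions: int

    @property
    def ratio(self) -> float | None:
        """ti/tv count ratio; None when no transversions were observed."""
        if self.transversions == 0:
            return None
        return self.transitions / self.transversions


def titv_tally(alignment: Alignment) -> TiTvTally:
    """Tally transitions (A<->G, C<->T) and transversions over all pairs,
    pairwise deletion, pooled across the matrix's upper triangle."""
    enc = np.stack([_encode(r.symbols) for r in alignment.rows])
    valid = _valid_mask(enc)
    n = alignment.n_rows
    is_purine = (enc == ord("A")) | (enc == ord("G"))
    ti = tv = 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            diff = both & (enc[i] != enc[j])
            same_class = is_purine[i] == is_purine[j]
            ti += int((diff & same_class).sum())
            tv += int((diff & ~same_class).sum())
    return TiTvTally(transitions=ti, transversions=tv)


@dataclass(frozen=True)
class GroupDistanceSummary:
    """Within/between-group distance extrema with the attaining pairs.

    ``intra_max`` maps group -> (p, id_a, id_b) for the largest within-group
    distance (groups with a single member have no entry); ``inter_min`` maps
    (group_a, group_b) sorted pairs -> (p, id_a, id_b) for the smallest
    between-group distance.
    """

    intra_max: dict[str, tuple[float, str, str]]
    inter_min: dict[tuple[str, str], tuple[float, str, str]]


def group_distance_summary(
    matrix: DistanceMatrix, group_labels: Mapping[str, str]
) -> GroupDistanceSummary:
    """Per-group max intra-group p and per-group-pair min inter-group p."""
    unlabeled = [i for i in matrix.ids if i not in group_labels]
    if unlabeled:
        raise ValueError("unlabeled ids: " + ", ".join(unlabeled))
    intra: dict[str, tuple[float, str, str]] = {}
    inter: dict[tuple[str, str], tuple[float, str, str]] = {}
    n = len(matrix.ids)
    for i in range(n):
        for j in range(i + 1, n):
            pij = float(matrix.p[i, j])
            if np.isnan(pij):
                continue
            a, b = matrix.ids[i], matrix.ids[j]
            ga, gb = group_labels[a], group_labels[b]
            if ga == gb:
                if ga not in intra or pij > intra[ga][0]:
                    intra[ga] = (pij, a, b)
            else:
                key = tuple(sorted((ga, gb)))
                if key not in inter or pij < inter[key][0]:
                    inter[key] = (pij, a, b)
    return GroupDistanceSummary(intra_max=intra, inter_min=inter)


@dataclass(frozen=True)
class DelimitationThresholds:
    """Calibrated distance thresholds for the family-rank rule (proportions).

    ``intra_max`` is the largest distance observed within any reference
    family; ``inter_min`` the smallest observed between families.
    """

    intra_max: float = 0.049
    inter_min: float = 0.038

    def __post_init__(self) -> None:
        if not self.inter_min > 0:
            raise ValueError("inter_min must be > 0")


def assess_rank_delimitation(
    candidate_to_group_distances: Sequence[float],
    thresholds: DelimitationThresholds = DelimitationThresholds(),
) -> str:
    """Family-rank verdict from a candidate's distances to a family's members.

    Returns ``"within_family"`` when every distance is <= the inter-family
    minimum, ``"distinct_family"`` when every distance is >= the
    intra-family maximum, else ``"ambiguous"``.
    """
    distances = list(candidate_to_group_distances)
    if not distances:
        raise ValueError("empty distance list")
    if any(d < 0 for d in distances):
        raise ValueError("distances must be nonnegative")
    if all(d <= thresholds.inter_min for d in distances):
        return "within_family"
    if all(d >= thresholds.intra_max for d in distances):
        return "distinct_family"
    return "ambiguous"
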