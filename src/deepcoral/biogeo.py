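"""Occurrence-record curation and bathymetric diversity profiling.

Depth records come from point stations and from trawl/dredge stations that
report a depth interval. Each record is reduced to a single point depth —
the mean of its bounds — and a record is excluded when its interval is too
wide to be meaningful: range greater than half the mean depth (strict).
A manually maintained exclusion list handles records known to be erroneous
(e.g. implausibly shallow museum stations); manual exclusion takes
precedence in the bookkeeping when both rules fire.

Downstream summaries all use the curated point depths: Tukey five-number
summaries per genus with the conventional 1.5x IQR outlier rule, species
depth ranges (min/max of point depths), counts of species extending above a
depth threshold, and a range-through species-diversity profile in 100-m
bins — a species counts in every bin its depth interval overlaps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .datamodel import SpecimenRecord

__all__ = [
    "CuratedRecord",
    "CurationReport",
    "DepthSummary",
    "SpeciesDepthRange",
    "DiversityProfile",
    "curate_records",
    "tukey_five_numbers",
    "genus_depth_summary",
    "species_depth_ranges",
    "species_shallower_than",
    "diversity_profile",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CuratedRecord:
    """A specimen record with its point depth and exclusion flags."""

    record: SpecimenRecord
    depth_point_m: float
    excluded_range_rule: bool
    excluded_manual: bool

    @property
    def retained(self) -> bool:
        return not (self.excluded_range_rule or self.excluded_manual)


@dataclass(frozen=True)
class CurationReport:
    """Accounting of the curation pass: input = retained + excluded."""

    n_input: int
    n_excluded_range: int
    n_excluded_manual: int
    n_retained: int
    n_colonies_retained: int

    def __post_init__(self) -> None:
        assert (
            self.n_input
            == self.n_retained + self.n_excluded_range + self.n_excluded_manual
        )


def curate_records(
    records: Sequence[SpecimenRecord],
    manual_exclusion_ids: Iterable[str] = (),
) -> tuple[list[CuratedRecord], CurationReport]:
    """Apply the depth-range rule and the manual exclusion list.

    A record is excluded by the range rule when
    ``depth_max - depth_min > 0.5 * (depth_min + depth_max) / 2`` (strict);
    point records (zero range) always pass it. Manual exclusions take
    precedence in the report when both apply. Every exclusion is logged.
    """
    manual = set(manual_exclusion_ids)
    curated: list[CuratedRecord] = []
    n_range = n_manual = n_kept = colonies = 0
    for rec in records:
        point = rec.depth_mean_m
        range_hit = rec.depth_range_m > 0.5 * point
        manual_hit = rec.record_id in manual
        curated.append(
            CuratedRecord(
                record=rec,
                depth_point_m=point,
                excluded_range_rule=range_hit,
                excluded_manual=manual_hit,
            )
        )
        if manual_hit:
            n_manual += 1
            logger.info("excluded (manual list): %s", rec.record_id)
        elif range_hit:
            n_range += 1
            logger.info(
                "excluded (range rule): %s range %.1f m > half of mean %.1f m",
                rec.record_id,
                rec.depth_range_m,
                point,
            )
        else:
            n_kept += 1
            colonies += rec.n_colonies
    report = CurationReport(
        n_input=len(curated),
        n_excluded_range=n_range,
        n_excluded_manual=n_manual,
        n_retained=n_kept,
        n_colonies_retained=colonies,
    )
    return curated, report


def tukey_five_numbers(values: Sequence[float]) -> tuple[float, float, float, float, float]:
    """(min, lower hinge, median, upper hinge, max) with Tukey hinges.

    Hinges are medians of the lower/upper halves, each half including the
    overall median position when n is odd — the construction behind the
    classic box-and-whisker plot, not interpolated percentiles.
    """
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 0:
        raise ValueError("empty value list")

    def _median(seq: Sequence[float]) -> float:
        m = len(seq)
        mid = m // 2
        return seq[mid] if m % 2 else (seq[mid - 1] + seq[mid]) / 2.0

    half = (n + 1) // 2  # halves share the middle element when n is odd
    return (xs[0], _median(xs[:half]), _median(xs), _median(xs[n - half:]), xs[-1])


@dataclass(frozen=True)
class DepthSummary:
    """Tukey five-number depth summary for one genus, with outliers."""

    genus: str
    n_records: int
    minimum: float
    lower_hinge: float
    median: float
    upper_hinge: float
    maximum: float
    outliers: tuple[float, ...]

    def __post_init__(self) -> None:
        assert (
            self.minimum
            <= self.lower_hinge
            <= self.median
            <= self.upper_hinge
            <= self.maximum
        )


def genus_depth_summary(curated: Sequence[CuratedRecord]) -> list[DepthSummary]:
    """Per-genus five-number summary of retained point depths.

    Outliers are depths beyond hinge +/- 1.5x the inter-hinge spread.
    Genera with no retained records are omitted with a log notice.
    """
    by_genus: dict[str, list[float]] = {}
    seen: set[str] = set()
    for c in curated:
        seen.add(c.record.genus)
        if c.retained:
            by_genus.setdefault(c.record.genus, []).append(c.depth_point_m)
    for genus in sorted(seen - set(by_genus)):
        logger.info("genus %s has no retained records; omitted", genus)
    out = []
    for genus in sorted(by_genus):
        depths = by_genus[genus]
        lo, h1, med, h3, hi = tukey_five_numbers(depths)
        iqr = h3 - h1
        fence_lo, fence_hi = h1 - 1.5 * iqr, h3 + 1.5 * iqr
        outliers = tuple(sorted(d for d in depths if d < fence_lo or d > fence_hi))
        out.append(
            DepthSummary(
                genus=genus,
                n_records=len(depths),
                minimum=lo,
                lower_hinge=h1,
                median=med,
                upper_hinge=h3,
                maximum=hi,
                outliers=outliers,
            )
        )
    return out


@dataclass(frozen=True)
class SpeciesDepthRange:
    """A species' depth interval: min/max of curated point depths."""

    species: str
    depth_lo: float
    depth_hi: float
    n_records: int

    def __post_init__(self) -> None:
        assert self.depth_lo <= self.depth_hi


def species_depth_ranges(
    curated: Sequence[CuratedRecord], use_raw_extremes: bool = False
) -> list[SpeciesDepthRange]:
    """Per-species depth range over retained records with a species label.

    By default ranges span the curated point depths; ``use_raw_extremes``
    spans the raw station min/max instead (both readings of published
    range tables exist in practice).
    """
    spans: dict[str, list[float]] = {}
    for c in curated:
        if not c.retained or c.record.species is None:
            continue
        label = f"{c.record.genus} {c.record.species}"
        vals = spans.setdefault(label, [])
        if use_raw_extremes:
            vals.extend((c.record.depth_min_m, c.record.depth_max_m))
        else:
            vals.append(c.depth_point_m)
    return [
        SpeciesDepthRange(
            species=label,
            depth_lo=min(vals),
            depth_hi=max(vals),
            n_records=len(vals) if not use_raw_extremes else len(vals) // 2,
        )
        for label, vals in sorted(spans.items())
    ]


def species_shallower_than(
    ranges: Sequence[SpeciesDepthRange], threshold_m: float = 200.0
) -> tuple[int, list[str]]:
    """Species whose shallow end lies strictly above the threshold."""
    hits = sorted(r.species for r in ranges if r.depth_lo < threshold_m)
    return len(hits), hits


@dataclass(frozen=True)
class DiversityProfile:
    """Species counts per depth bin (half-open [lo, hi) bins)."""

    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]

    def bins(self) -> list[tuple[float, float]]:
        return list(zip(self.bin_edges[:-1], self.bin_edges[1:]))


def diversity_profile(
    ranges: Sequence[SpeciesDepthRange],
    bin_width: float = 100.0,
    max_depth: float = 4500.0,
    mode: str = "interval",
) -> DiversityProfile:
    """Range-through species-diversity profile across depth.

    ``interval`` mode (default) counts a species in every half-open bin
    ``[b, b + width)`` its closed depth interval overlaps; ``point`` mode
    counts it at each level ``0, width, 2*width, ...`` falling inside its
    interval. Ranges extending below ``max_depth`` are counted in the
    terminal bin and logged.
    """
    if mode not in ("interval", "point"):
        raise ValueError(f"unknown mode {mode!r}")
    edges = [i * bin_width for i in range(int(round(max_depth / bin_width)) + 1)]
    counts = [0] * (len(edges) - 1)
    for r in ranges:
        hi = r.depth_hi
        if hi > max_depth:
            logger.info(
                "species %s extends to %.0f m, beyond profile limit %.0f m",
                r.species,
                hi,
                max_depth,
            )
            hi = max_depth - 1e-9  # keep it inside the terminal bin
        lo_end = min(r.depth_lo, hi)
        if mode == "interval":
            for k, (lo, up) in enumerate(zip(edges[:-1], edges[1:])):
                if lo_end < up and hi >= lo:
                    counts[k] += 1
        else:
            for k, level in enumerate(edges[:-1]):
                if lo_end <= level <= hi:
                    counts[k] += 1
    return DiversityProfile(bin_edges=tuple(edges), counts=tuple(counts))
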