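"""End-to-end orchestration: one config in, a manifest of tables out.

``run_all`` wires every stage together for a single dataset: alignment
summary, haplotype assignment and richness, distance matrix with ti/tv
tallies and per-group-pair delimitation verdicts, record curation, depth
summaries and the diversity profile. Outputs are deterministic for a fixed
(config, inputs) pair and each artifact's SHA-256 goes into a manifest so
reruns can be compared byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alnstats, biogeo, distances, haplotypes
from .io import read_alignment, read_specimen_table, write_table

__all__ = ["RunConfig", "run_all", "DEFAULT_MANUAL_EXCLUSIONS"]

logger = logging.getLogger(__name__)

#: Record ids excluded by default: implausibly shallow historical stations
#: known to be data errors in the assembled museum database.
DEFAULT_MANUAL_EXCLUSIONS: tuple[str, ...] = (
    "USNM 56792",
    "Blake station 259",
)


@dataclass(frozen=True)
class RunConfig:
    """Everything a full run needs; loadable from a YAML file."""

    fasta: str
    metadata: str
    records: str | None = None
    out_dir: str = "deepcoral-out"
    marker_name: str = ""
    policy: str = "strict"
    group_field: str = "genus"
    delimit_group_field: str = "family"
    intra_max: float = 0.049
    inter_min: float = 0.038
    manual_exclusions: tuple[str, ...] = DEFAULT_MANUAL_EXCLUSIONS
    bin_width: float = 100.0
    max_depth: float = 4500.0
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "manual_exclusions" in raw:
            raw["manual_exclusions"] = tuple(raw["manual_exclusions"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        for label, p in (("fasta", self.fasta), ("metadata", self.metadata),
                         ("records", self.records)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} input not found: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def delimitation_table(
    matrix: distances.DistanceMatrix,
    group_labels: dict[str, str],
    thresholds: distances.DelimitationThresholds,
) -> pd.DataFrame:
    """Per-group-pair distance extrema and family-rank verdicts."""
    groups = sorted(set(group_labels.values()))
    ids_by_group = {
        g: [i for i in matrix.ids if group_labels[i] == g] for g in groups
    }
    rows = []
    for ga, gb in itertools.combinations(groups, 2):
        ds = []
        for a in ids_by_group[ga]:
            for b in ids_by_group[gb]:
                v = matrix.get(a, b)
                if not np.isnan(v):
                    ds.append(v)
        if not ds:
            continue
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "n_pairs": len(ds),
                "min_p": min(ds),
                "max_p": max(ds),
                "verdict": distances.assess_rank_delimitation(ds, thresholds),
            }
        )
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "n_pairs", "min_p", "max_p", "verdict"]
    )


def run_all(config: RunConfig) -> dict[str, str]:
    """Run every stage; return {artifact name: sha256} manifest.

    Any stage failure propagates as an exception after the stage is named
    in the log; artifacts written before the failure remain on disk.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def emit(name: str, frame: pd.DataFrame | list, columns=None) -> None:
        path = out / name
        write_table(frame, path, columns=columns)
        manifest[name] = _sha256(path)
        logger.info("wrote %s (%s)", path, manifest[name][:12])

    logger.info("stage: alignment ingest")
    aln = read_alignment(config.fasta, config.metadata, config.marker_name)

    logger.info("stage: alignment summary")
    summary = alnstats.summarize_alignment(aln)
    emit("alignment_summary.csv", [dataclasses.asdict(summary)])

    logger.info("stage: haplotype collapsing (%s)", config.policy)
    assignment = haplotypes.collapse_haplotypes(aln, policy=config.policy)
    emit(
        "haplotype_assignment.csv",
        [
            {"seq_id": sid, "haplotype": h}
            for sid, h in assignment.members.items()
        ],
    )
    emit(
        "richness.csv",
        haplotypes.richness_by_group(assignment, aln, config.group_field),
    )

    logger.info("stage: distances")
    matrix = distances.distance_matrix(aln)
    frame = pd.DataFrame(matrix.p, index=matrix.ids, columns=matrix.ids)
    frame.insert(0, "seq_id", matrix.ids)
    emit("distance_matrix.csv", frame)
    tally = distances.titv_tally(aln)
    emit(
        "titv.csv",
        [
            {
                "transitions": tally.transitions,
                "transversions": tally.transversions,
                "ratio": tally.ratio,
            }
        ],
    )

    labels = {
        r.seq_id: (getattr(r, config.delimit_group_field) or "(unassigned)")
        for r in aln
    }
    thresholds = distances.DelimitationThresholds(
        intra_max=config.intra_max, inter_min=config.inter_min
    )
    emit("delimitation.csv", delimitation_table(matrix, labels, thresholds))

    if config.records is not None:
        logger.info("stage: biogeography curation")
        records, rejections = read_specimen_table(config.records)
        if rejections:
            emit(
                "ingest_rejections.csv",
                [{"record_id": r, "reason": why} for r, why in rejections],
            )
        curated, report = biogeo.curate_records(records, config.manual_exclusions)
        emit("curation_report.csv", [dataclasses.asdict(report)])
        emit(
            "curated_records.csv",
            [
                {
                    "record_id": c.record.record_id,
                    "genus": c.record.genus,
                    "species": c.record.species,
                    "depth_point_m": c.depth_point_m,
                    "excluded_range_rule": c.excluded_range_rule,
                    "excluded_manual": c.excluded_manual,
                    "retained": c.retained,
                }
                for c in curated
            ],
        )
        logger.info("stage: depth summaries")
        emit(
            "depth_summary.csv",
            [
                {**dataclasses.asdict(s), "outliers": ";".join(
                    f"{d:g}" for d in s.outliers)}
                for s in biogeo.genus_depth_summary(curated)
            ],
        )
        ranges = biogeo.species_depth_ranges(curated)
        emit("species_ranges.csv", [dataclasses.asdict(r) for r in ranges])
        profile = biogeo.diversity_profile(
            ranges, bin_width=config.bin_width, max_depth=config.max_depth
        )
        emit(
            "diversity_profile.csv",
            [
                {"bin_lo_m": lo, "bin_hi_m": hi, "n_species": c}
                for (lo, hi), c in zip(profile.bins(), profile.counts)
            ],
        )

    emit(
        "manifest.csv",
        [{"artifact": k, "sha256": v} for k, v in sorted(manifest.items())],
    )
    return manifest
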