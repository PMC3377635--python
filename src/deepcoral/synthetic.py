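"""Synthetic sequence alignments and occurrence records with known truth.

Every pipeline stage is exercised against data whose ground truth is known
by construction: alignments evolved on a birth-death tree under a
two-parameter (transition-bias kappa) symmetric nucleotide process, with
ambiguity codes and gaps injected afterwards at stated rates; and
occurrence databases mixing point and trawl stations with a controllable
number of records violating the depth-range curation rule.

The substitution process is simulated event by event (jump chain with a
Poisson number of events per site per branch), so the *realized* counts of
transitions and transversions — including multiple hits — are recorded
exactly and can serve as the oracle for pairwise ti/tv tallies. Ambiguity
injection replaces a true base with a compatible IUPAC code, mimicking the
sequencing ambiguity that inflates strict haplotype counts in ribosomal
markers; truth therefore stores the pre-injection haplotype partition.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .datamodel import (
    AMBIGUITY_EXPANSION,
    AlignedSequence,
    Alignment,
    BASINS,
    SpecimenRecord,
)

__all__ = [
    "SeqSimConfig",
    "RecordSimConfig",
    "GenusDepthLaw",
    "SimTruth",
    "simulate_tree",
    "simulate_alignment",
    "construct_alignment_with_counts",
    "simulate_records",
]

_BASES = "ACGT"
_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS_OF = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
#: ambiguity codes compatible with each base (codes of size >= 2 containing it)
_CODES_FOR = {
    b: sorted(code for code, bases in AMBIGUITY_EXPANSION.items() if b in bases)
    for b in _BASES
}


@dataclass(frozen=True)
class SimTruth:
    """Ground truth emitted alongside simulated data."""

    haplotype_partition: dict[str, int] = field(default_factory=dict)
    n_haplotypes: int = 0
    transitions: int = 0
    transversions: int = 0
    record_excluded_range: dict[str, bool] = field(default_factory=dict)
    record_excluded_manual: dict[str, bool] = field(default_factory=dict)
    species_depth_intervals: dict[str, tuple[float, float]] = field(
        default_factory=dict
    )


def simulate_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> str:
    """A seeded pure-birth (Yule) tree with ``n_taxa`` leaves, as newick.

    Leaves are relabeled ``t1..tN``; branch lengths are strictly positive.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = random.Random(seed)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=rng,
    )
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i}"
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length <= 0:
            edge.length = 1e-6
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass(frozen=True)
class SeqSimConfig:
    """Parameters of the alignment simulator.

    ``rate`` is the expected number of substitutions per site along a
    branch of unit length; ``kappa`` the instantaneous transition/
    transversion rate bias (kappa = 1 is Jukes-Cantor-like);
    ``ambiguity_rate`` and ``gap_rate`` are per-symbol post-hoc injection
    probabilities. The seed fixes the full output.
    """

    n_taxa: int = 20
    n_columns: int = 800
    tree: str | None = None
    birth_rate: float = 1.0
    rate: float = 0.05
    kappa: float = 2.0
    ambiguity_rate: float = 0.0
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.ambiguity_rate <= 1 and 0 <= self.gap_rate <= 1):
            raise ValueError("injection rates must lie in [0, 1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")


def _evolve_branch(
    parent: np.ndarray,
    length: float,
    rate: float,
    kappa: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int, int]:
    """Evolve one branch site by site; return (child, n_ti, n_tv) realized."""
    child = parent.copy()
    n_events = rng.poisson(rate * length, size=parent.size)
    p_transition = kappa / (kappa + 2.0)  # 1 ti target at rate kappa, 2 tv at 1
    ti = tv = 0
    for site in np.nonzero(n_events)[0]:
        state = child[site]
        for _ in range(n_events[site]):
            if rng.random() < p_transition:
                state = _TRANSITION_OF[state]
                ti += 1
            else:
                state = _TRANSVERSIONS_OF[state][rng.integers(2)]
                tv += 1
        child[site] = state
    return child, ti, tv


def simulate_alignment(config: SeqSimConfig) -> tuple[Alignment, SimTruth]:
    """Evolve an alignment on a tree; inject ambiguity codes and gaps.

    Returns the alignment (leaves carry round-robin basin labels and a
    single synthetic genus so grouping operations are exercisable) and the
    truth: the pre-injection haplotype partition and the realized
    transition/transversion event counts.
    """
    rng = np.random.default_rng(config.seed)
    newick = config.tree or simulate_tree(
        config.n_taxa, config.birth_rate, seed=int(rng.integers(2**31))
    )
    tree = dendropy.Tree.get(data=newick, schema="newick")
    root_seq = rng.choice(list(_BASES), size=config.n_columns)

    seqs: dict[int, np.ndarray] = {}
    ti_total = tv_total = 0
    leaf_seqs: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seqs[id(node)] = root_seq
        else:
            length = node.edge.length or 0.0
            child, ti, tv = _evolve_branch(
                seqs[id(node.parent_node)], length, config.rate, config.kappa, rng
            )
            seqs[id(node)] = child
            ti_total += ti
            tv_total += tv
        if node.is_leaf():
            leaf_seqs[node.taxon.label] = seqs[id(node)]

    # truth partition on the clean (pre-injection) sequences
    partition: dict[str, int] = {}
    seen: dict[str, int] = {}
    labels = sorted(leaf_seqs, key=lambda s: (len(s), s))  # t1, t2, ... order
    for label in labels:
        key = "".join(leaf_seqs[label])
        partition[label] = seen.setdefault(key, len(seen))

    rows = []
    for k, label in enumerate(labels):
        symbols = leaf_seqs[label].copy()
        for site in range(symbols.size):
            u = rng.random()
            if u < config.gap_rate:
                symbols[site] = "-"
            elif u < config.gap_rate + config.ambiguity_rate:
                codes = _CODES_FOR[symbols[site]]
                symbols[site] = codes[rng.integers(len(codes))]
        rows.append(
            AlignedSequence(
                seq_id=label,
                symbols="".join(symbols),
                genus="Simulogorgia",
                basin=BASINS[k % len(BASINS)],
                depth_m=float(rng.uniform(200, 2000)),
            )
        )
    alignment = Alignment(rows=tuple(rows), marker_name="simulated")
    truth = SimTruth(
        haplotype_partition=partition,
        n_haplotypes=len(set(partition.values())),
        transitions=ti_total,
        transversions=tv_total,
    )
    return alignment, truth


def construct_alignment_with_counts(
    n_taxa: int, n_columns: int, n_variable: int, n_parsinf: int
) -> Alignment:
    """Build an ungapped alignment whose site counts are exactly as requested.

    Parsimony-informative columns give the first two rows one base and the
    rest another; variable-but-uninformative columns give only the first
    row a variant base; remaining columns are constant. Requires
    ``n_parsinf <= n_variable <= n_columns`` and at least 4 rows when
    informative columns are requested.
    """
    if not 0 <= n_parsinf <= n_variable <= n_columns:
        raise ValueError("need 0 <= n_parsinf <= n_variable <= n_columns")
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if n_parsinf > 0 and n_taxa < 4:
        raise ValueError("parsimony-informative columns require n_taxa >= 4")
    n_singleton = n_variable - n_parsinf
    cols = (
        ["informative"] * n_parsinf
        + ["singleton"] * n_singleton
        + ["constant"] * (n_columns - n_variable)
    )
    rows = []
    for i in range(n_taxa):
        chars = []
        for kind in cols:
            if kind == "informative":
                chars.append("C" if i < 2 else "A")
            elif kind == "singleton":
                chars.append("G" if i == 0 else "A")
            else:
                chars.append("A")
        rows.append(AlignedSequence(seq_id=f"s{i + 1}", symbols="".join(chars)))
    return Alignment(rows=tuple(rows), marker_name="constructed")


@dataclass(frozen=True)
class GenusDepthLaw:
    """Truncated log-normal depth law for one genus (meters).

    ``median`` is the law's median depth, ``sigma`` the log-scale spread,
    ``lo``/``hi`` the truncation bounds (resampling truncation).
    """

    median: float = 1000.0
    sigma: float = 0.5
    lo: float = 10.0
    hi: float = 4400.0
    n_species: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.lo <= self.median <= self.hi:
            raise ValueError("need 0 < lo <= median <= hi")


@dataclass(frozen=True)
class RecordSimConfig:
    """Parameters of the occurrence-record simulator.

    Defaults emulate the scale of a curated deep-sea octocoral database:
    985 records across a handful of genera, about a third of stations being
    trawls with a reported depth interval, 24 records violating the
    depth-range rule and 2 known-bad records on a manual exclusion list.
    """

    genus_laws: dict[str, GenusDepthLaw] = field(
        default_factory=lambda: {
            "Chrysogorgia": GenusDepthLaw(1000.0, 0.7, 31.0, 4400.0, 30),
            "Metallogorgia": GenusDepthLaw(1400.0, 0.3, 560.0, 2300.0, 4),
            "Iridogorgia": GenusDepthLaw(1300.0, 0.3, 560.0, 2350.0, 5),
            "Radicipes": GenusDepthLaw(1200.0, 0.6, 190.0, 3600.0, 7),
        }
    )
    n_records: int = 985
    trawl_fraction: float = 0.35
    compliant_halfwidth: tuple[float, float] = (0.02, 0.2)
    violating_halfwidth: tuple[float, float] = (0.3, 0.6)
    n_forced_range_violations: int = 24
    n_forced_manual_exclusions: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        forced = self.n_forced_range_violations + self.n_forced_manual_exclusions
        if forced > self.n_records:
            raise ValueError("forced exclusion counts exceed n_records")
        if not 0 <= self.trawl_fraction <= 1:
            raise ValueError("trawl_fraction must lie in [0, 1]")
        if not self.violating_halfwidth[0] > 0.25:
            # (max-min) = 2 f * mean; rule fires iff 2 f > 0.5, i.e. f > 0.25
            raise ValueError("violating halfwidth fraction must exceed 0.25")
        if not self.compliant_halfwidth[1] <= 0.25:
            raise ValueError("compliant halfwidth fraction must stay <= 0.25")


def _truncated_lognormal(
    law: GenusDepthLaw, size: int, rng: np.random.Generator
) -> np.ndarray:
    mu = np.log(law.median)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(mu, law.sigma, size=size - filled)
        ok = draw[(draw >= law.lo) & (draw <= law.hi)]
        out[filled : filled + ok.size] = ok
        filled += ok.size
    return out


def simulate_records(
    config: RecordSimConfig,
) -> tuple[list[SpecimenRecord], SimTruth]:
    """Generate an occurrence database with known curation outcome.

    Exactly ``n_forced_range_violations`` records violate the depth-range
    rule (wide trawl intervals) and ``n_forced_manual_exclusions`` distinct
    records carry ids placed on the manual list (``MANUAL-k``); every other
    record passes curation by construction. Truth stores the per-record
    exclusion flags and the per-species depth intervals realized by the
    retained records.
    """
    rng = np.random.default_rng(config.seed)
    genera = sorted(config.genus_laws)
    weights = np.array([config.genus_laws[g].n_species for g in genera], float)
    weights /= weights.sum()
    genus_choice = rng.choice(len(genera), size=config.n_records, p=weights)

    points = np.empty(config.n_records)
    species = []
    for gi, genus in enumerate(genera):
        idx = np.nonzero(genus_choice == gi)[0]
        law = config.genus_laws[genus]
        points[idx] = _truncated_lognormal(law, idx.size, rng)
        sp = rng.integers(1, law.n_species + 1, size=idx.size)
        for k, i in enumerate(idx):
            species.append((i, f"sp{sp[k]}"))
    species_of = {i: s for i, s in species}

    n = config.n_records
    forced = rng.choice(
        n,
        size=config.n_forced_range_violations + config.n_forced_manual_exclusions,
        replace=False,
    )
    violators = set(forced[: config.n_forced_range_violations].tolist())
    manual = set(forced[config.n_forced_range_violations :].tolist())

    records: list[SpecimenRecord] = []
    truth_range: dict[str, bool] = {}
    truth_manual: dict[str, bool] = {}
    intervals: dict[str, list[float]] = {}
    manual_counter = 0
    for i in range(n):
        genus = genera[genus_choice[i]]
        m = points[i]
        if i in violators:
            f = rng.uniform(*config.violating_halfwidth)
        elif rng.random() < config.trawl_fraction:
            f = rng.uniform(*config.compliant_halfwidth)
        else:
            f = 0.0
        dmin, dmax = m * (1 - f), m * (1 + f)
        if i in manual:
            manual_counter += 1
            rid = f"MANUAL-{manual_counter}"
        else:
            rid = f"R{i + 1:04d}"
        rec = SpecimenRecord(
            record_id=rid,
            genus=genus,
            species=species_of[i],
            basin=BASINS[int(rng.integers(len(BASINS)))],
            depth_min_m=dmin,
            depth_max_m=dmax,
            n_colonies=int(rng.integers(1, 6)),
            source=("literature", "museum", "collection")[int(rng.integers(3))],
        )
        records.append(rec)
        truth_range[rid] = i in violators
        truth_manual[rid] = i in manual
        if i not in violators and i not in manual:
            label = f"{genus} {species_of[i]}"
            intervals.setdefault(label, []).append(rec.depth_mean_m)

    truth = SimTruth(
        record_excluded_range=truth_range,
        record_excluded_manual=truth_manual,
        species_depth_intervals={
            lab: (min(v), max(v)) for lab, v in intervals.items()
        },
    )
    return records, truth
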