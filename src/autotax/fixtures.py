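"""Deterministic synthetic data with known rank structure.

The generator builds a lineage tree over a random root sequence by
allocating a *disjoint* block of substitution positions to every tree edge.
Because no position is touched twice, the Hamming distance between any two
leaves is exactly the sum of the edge sizes on the path between them, so
every pairwise percent identity is known by construction and can be placed
strictly inside a rank-threshold band (with a guard band so that realized
identities classify unambiguously). Realized identities are nevertheless
re-measured with the alignment-based identity before the world is returned
— assertions downstream always rest on measured, not intended, values.

The default edge sizes, at sequence length 1,400 nt (a trimmed full-length
16S gene), realize these pairwise identities:

    same genus, different species   96.43  (94.5 < . < 98.7)
    same family, different genus    91.00  (86.5 < . < 94.5)
    same order, different family    84.57  (82.0 < . < 86.5)
    same class, different order     80.00  (78.5 < . < 82.0)
    same phylum, different class    76.71  (75.0 < . < 78.5)
    different phylum                73.86  (< 75.0)

The emitted world contains a backbone database (with semicolon lineages, no
species rank), a type-strain subset with binomial names, a raw read pool
with controlled abundances and planted artifacts (an error variant inside
the denoiser's merge radius, a singleton, a two-parent chimera, an
off-target junk read, mixed strands), and a truth table giving every
designed FL-ASV's expected final seven-rank taxonomy, provenance, novelty
class per rank, and species call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import BackboneRecord
from .records import (
    CLUSTERED_RANKS,
    PROV_BACKBONE,
    PROV_DENOVO,
    PROV_TYPESTRAIN,
    RANK_CODES,
    RANKS,
    RankThresholds,
    SeqRecord,
    TaxProfile,
    reverse_complement,
)
from .seqcore import global_identity
from .taxonomy_engine import TypeStrain, binomial

_BASES = "ACGT"

#: default per-edge substitution counts (see module docstring)
DEFAULT_EDGE_SUBS: Mapping[str, int] = {
    "phylum": 20,
    "class": 23,
    "order": 32,
    "family": 45,
    "genus": 38,
    "species": 25,
}

# primer sites embedded in every synthetic sequence (27F / 534R, V1-V3)
_FWD_PRIMER = "AGAGTTTGATCCTGGCTCAG"
_REV_PRIMER = "ATTACCGCGGCTGCTGG"
_FWD_AT = 10
_REV_AT = 530  # start of the reverse priming site on the plus strand


@dataclass(frozen=True)
class LineageSpec:
    """Shape and divergence structure of a synthetic world.

    ``n_*`` are children per node at each rank. Target identities are
    implied by ``edge_subs`` (disjoint substitutions per tree edge) and must
    keep every realized identity at least ``guard_band`` percentage points
    away from every rank threshold.
    """

    n_phyla: int = 2
    n_classes: int = 1
    n_orders: int = 1
    n_families: int = 1
    n_genera: int = 2
    n_species: int = 2
    length: int = 1400
    edge_subs: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_EDGE_SUBS))
    backbone_subs: int = 5
    typestrain_subs: int = 4
    guard_band: float = 0.3
    top_size: int = 100
    size_step: int = 5
    embed_primers: bool = True
    novel_genus: bool = True  # genera beyond the first in a family lack backbone refs
    plant_variant: bool = True
    plant_singleton: bool = True
    plant_chimera: bool = True
    plant_junk: bool = True
    ambiguous_typestrain: bool = False
    thresholds: RankThresholds = field(default_factory=RankThresholds)


@dataclass
class SyntheticWorld:
    """Everything a pipeline run needs, plus the designed truth."""

    spec: LineageSpec
    seed: int
    backbone: list[BackboneRecord]
    typestrains: list[TypeStrain]
    pool: list[SeqRecord]
    expected_flasvs: list[SeqRecord]
    expected_profiles: dict[str, TaxProfile]
    truth: pd.DataFrame


def mutate_to_identity(
    seq: str,
    target_identity: float,
    rng: np.random.Generator,
    guard_band: float = 0.3,
) -> tuple[SeqRecord, float]:
    """Substitute random positions until identity to ``seq`` hits the target.

    Returns the mutant and its REALIZED identity, re-measured with the
    alignment-based identity; raises when the target cannot be realized
    within ``guard_band`` at this length.
    """
    if not 0 < target_identity <= 100:
        raise ValueError(f"target identity out of range: {target_identity}")
    n = len(seq)
    m = round(n * (1 - target_identity / 100.0))
    if m >= n:
        raise ValueError("target identity unreachable at this length")
    positions = rng.choice(n, size=m, replace=False) if m else np.array([], dtype=int)
    mutant = _substitute(seq, positions, rng)
    realized = 100.0 if m == 0 else global_identity(seq, mutant)
    if abs(realized - target_identity) > guard_band:
        raise ValueError(
            f"realized identity {realized:.2f} misses target "
            f"{target_identity:.2f} by more than the guard band"
        )
    return SeqRecord(id="mutant", seq=mutant), realized


def _substitute(seq: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    chars = list(seq)
    for p in positions:
        alternatives = [b for b in _BASES if b != chars[p]]
        chars[p] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


class _PositionPool:
    """Hands out disjoint substitution positions, skipping protected sites."""

    def __init__(self, length: int, protected: set[int], rng: np.random.Generator):
        order = rng.permutation(length)
        self._free = [int(p) for p in order if p not in protected]
        self._ptr = 0

    def take(self, n: int) -> list[int]:
        if self._ptr + n > len(self._free):
            raise ValueError(
                "substitution budget exhausted; shrink the lineage spec or "
                "its edge_subs"
            )
        block = self._free[self._ptr : self._ptr + n]
        self._ptr += n
        return block


@dataclass
class _Leaf:
    index: int  # 0-based canonical order
    path: tuple[int, ...]  # (phylum, class, order, family, genus, species)
    seq: str
    labels: dict[str, str]  # designed backbone-style names per rank


def _build_leaves(
    spec: LineageSpec, root: str, pool: _PositionPool, rng: np.random.Generator
) -> list[_Leaf]:
    leaves: list[_Leaf] = []
    fanout = {
        "phylum": spec.n_phyla,
        "class": spec.n_classes,
        "order": spec.n_orders,
        "family": spec.n_families,
        "genus": spec.n_genera,
        "species": spec.n_species,
    }

    def descend(rank_idx: int, seq: str, path: tuple[int, ...], labels: dict[str, str]):
        if rank_idx == len(CLUSTERED_RANKS):
            leaves.append(_Leaf(index=len(leaves), path=path, seq=seq, labels=dict(labels)))
            return
        rank = CLUSTERED_RANKS[rank_idx]
        for child in range(fanout[rank]):
            child_seq = _substitute(seq, pool.take(spec.edge_subs[rank]), rng)
            suffix = "_".join(str(i + 1) for i in path + (child,))
            labels[rank] = f"{rank.capitalize()}_{suffix}"
            descend(rank_idx + 1, child_seq, path + (child,), labels)
        labels.pop(rank, None)

    descend(0, root, (), {"kingdom": "Bacteria"})
    return leaves


def _tree_distance(a: _Leaf, b: _Leaf, spec: LineageSpec) -> int:
    """Exact Hamming distance between two leaves (disjoint edge blocks)."""
    if a.path == b.path:
        return 0
    depth = 0
    while a.path[depth] == b.path[depth]:
        depth += 1
    return 2 * sum(spec.edge_subs[r] for r in CLUSTERED_RANKS[depth:])


def _identity(distance: int, length: int) -> float:
    return 100.0 * (1 - distance / length)


def make_synthetic_world(spec: LineageSpec = LineageSpec(), seed: int = 0) -> SyntheticWorld:
    """Generate a backbone, type strains, a read pool, and the truth table."""
    rng = np.random.default_rng(seed)
    length = spec.length
    root = "".join(_BASES[i] for i in rng.integers(0, 4, length))
    protected: set[int] = set()
    if spec.embed_primers:
        fwd = _FWD_PRIMER
        rev_site = reverse_complement(_REV_PRIMER)
        root = (
            root[:_FWD_AT]
            + fwd
            + root[_FWD_AT + len(fwd) : _REV_AT]
            + rev_site
            + root[_REV_AT + len(rev_site) :]
        )
        protected |= set(range(_FWD_AT, _FWD_AT + len(fwd)))
        protected |= set(range(_REV_AT, _REV_AT + len(rev_site)))
    pos_pool = _PositionPool(length, protected, rng)
    leaves = _build_leaves(spec, root, pos_pool, rng)

    # ---- backbone + type strains ------------------------------------------
    backbone: list[BackboneRecord] = []
    typestrains: list[TypeStrain] = []
    backbone_src: list[_Leaf] = []  # parallel to backbone
    species_call: dict[int, str | None] = {leaf.index: None for leaf in leaves}
    for leaf in leaves:
        genus_idx, species_idx = leaf.path[4], leaf.path[5]
        genus_has_backbone = (genus_idx == 0) or not spec.novel_genus
        if genus_has_backbone and species_idx == 0:
            bb_seq = _substitute(leaf.seq, pos_pool.take(spec.backbone_subs), rng)
            names = [leaf.labels[r] for r in RANKS[:-1]]
            backbone.append(
                BackboneRecord(
                    accession=f"BB{len(backbone) + 1}",
                    seq=bb_seq,
                    tax=TaxProfile.from_names(names),
                )
            )
            backbone_src.append(leaf)
            ts_seq = _substitute(leaf.seq, pos_pool.take(spec.typestrain_subs), rng)
            organism = f"{leaf.labels['genus']} specimen{len(typestrains) + 1}"
            typestrains.append(
                TypeStrain(accession=f"TS{len(typestrains) + 1}", seq=ts_seq, organism=organism)
            )
            species_call[leaf.index] = organism
    if spec.ambiguous_typestrain and leaves:
        # a second, differently named species within range of leaf 0
        leaf0 = leaves[0]
        ts_seq = _substitute(leaf0.seq, pos_pool.take(spec.typestrain_subs + 2), rng)
        typestrains.append(
            TypeStrain(
                accession=f"TS{len(typestrains) + 1}",
                seq=ts_seq,
                organism=f"{leaf0.labels['genus']} ambiguum",
            )
        )
        species_call[leaf0.index] = None  # two species in range -> no call
    if not backbone:
        raise ValueError("spec produced no backbone references")

    # ---- best-hit identity per leaf (exact, from tree distances) ----------
    best_hit_identity: dict[int, float] = {}
    for leaf in leaves:
        dists = [
            _tree_distance(leaf, src, spec) + spec.backbone_subs
            for src in backbone_src
        ]
        best_hit_identity[leaf.index] = _identity(min(dists), length)

    # ---- verify realized identities against the guard bands ---------------
    thresholds = spec.thresholds
    tvals = [thresholds[r] for r in CLUSTERED_RANKS]

    def check_banded(value: float, what: str) -> None:
        for t in tvals:
            if abs(value - t) <= spec.guard_band:
                raise ValueError(
                    f"{what}: realized identity {value:.2f} falls inside the "
                    f"guard band of threshold {t}"
                )

    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            designed = _identity(_tree_distance(a, b, spec), length)
            realized = global_identity(a.seq, b.seq)
            if abs(realized - designed) > 1e-9:
                raise ValueError(
                    f"leaf pair ({a.index}, {b.index}): realized {realized:.4f} "
                    f"!= designed {designed:.4f}"
                )
            check_banded(realized, f"leaf pair ({a.index}, {b.index})")
    for leaf in leaves:
        check_banded(best_hit_identity[leaf.index], f"leaf {leaf.index} best hit")

    # ---- expected taxonomy -------------------------------------------------
    # de novo clusters at each rank are the designed path-prefix groups;
    # the centroid is the first leaf of the group in canonical order.
    centroid_of: dict[tuple[str, tuple[int, ...]], int] = {}
    for leaf in leaves:
        for depth, rank in enumerate(CLUSTERED_RANKS, start=1):
            key = (rank, leaf.path[:depth])
            centroid_of.setdefault(key, leaf.index)

    expected_profiles: dict[str, TaxProfile] = {}
    expected_flasvs: list[SeqRecord] = []
    truth_rows = []
    for leaf in leaves:
        fid = f"FLASV{leaf.index + 1}"
        size = spec.top_size - spec.size_step * leaf.index
        if size < 2:
            raise ValueError("size schedule fell below the denoiser minsize")
        expected_flasvs.append(SeqRecord(id=fid, seq=leaf.seq, size=size))
        ident = best_hit_identity[leaf.index]
        profile = TaxProfile()
        for depth, rank in enumerate(RANKS):
            if rank == "kingdom":
                profile = profile.replace(rank, leaf.labels["kingdom"], PROV_BACKBONE)
            elif rank == "species":
                call = species_call[leaf.index]
                if call is not None:
                    profile = profile.replace(rank, binomial(call), PROV_TYPESTRAIN)
                else:
                    centroid = centroid_of[(rank, leaf.path)]
                    profile = profile.replace(
                        rank, f"denovo_s_{centroid + 1}", PROV_DENOVO
                    )
            else:
                if ident >= thresholds[rank]:
                    profile = profile.replace(rank, leaf.labels[rank], PROV_BACKBONE)
                else:
                    centroid = centroid_of[(rank, leaf.path[:depth])]
                    profile = profile.replace(
                        rank, f"denovo_{RANK_CODES[rank]}_{centroid + 1}", PROV_DENOVO
                    )
        expected_profiles[fid] = profile
        row = {
            "flasv": fid,
            "size": size,
            "best_hit_identity": ident,
            "species_call": profile.name("species")
            if profile.prov("species") == PROV_TYPESTRAIN
            else None,
        }
        for rank in CLUSTERED_RANKS:
            row[f"novel_{rank}"] = ident < thresholds[rank]
        for rank in RANKS:
            row[f"expected_{rank}"] = profile.name(rank)
            row[f"prov_{rank}"] = profile.prov(rank)
            row[f"designed_{rank}"] = leaf.labels.get(rank, "")
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)

    # ---- raw read pool -----------------------------------------------------
    pool_reads: list[SeqRecord] = []
    counter = 0

    def emit(seq: str, tag: str, copies: int) -> None:
        nonlocal counter
        for _ in range(copies):
            s = reverse_complement(seq) if counter % 3 == 2 else seq
            pool_reads.append(SeqRecord(id=f"r{counter:05d}_{tag}", seq=s))
            counter += 1

    for leaf in leaves:
        emit(leaf.seq, f"leaf{leaf.index}", spec.top_size - spec.size_step * leaf.index)
    if spec.plant_variant:
        # 1-mismatch variant at skew 0.10 <= beta(1) = 0.125: merged by the denoiser
        var_seq = _substitute(leaves[0].seq, pos_pool.take(1), rng)
        emit(var_seq, "var0", max(1, spec.top_size // 10))
    if spec.plant_singleton and len(leaves) > 1:
        # 3 mismatches from leaf 1: beta(3) < 1/size(leaf1), and minsize kills it
        single_seq = _substitute(leaves[1].seq, pos_pool.take(3), rng)
        emit(single_seq, "single", 1)
    if spec.plant_chimera and len(leaves) > 1:
        half = length // 2
        chimera = leaves[0].seq[:half] + leaves[-1].seq[half:]
        emit(chimera, "chim", 1)
    if spec.plant_junk:
        ref_kmers = {
            s[i : i + 12]
            for b in backbone
            for s in (b.seq, reverse_complement(b.seq))
            for i in range(len(s) - 11)
        }
        for _ in range(20):
            junk = "".join(_BASES[i] for i in rng.integers(0, 4, 50))
            jk = {junk[i : i + 12] for i in range(len(junk) - 11)}
            rjk = {
                reverse_complement(junk)[i : i + 12] for i in range(len(junk) - 11)
            }
            if not (jk & ref_kmers) and not (rjk & ref_kmers):
                pool_reads.append(SeqRecord(id="r_junk", seq=junk))
                break

    return SyntheticWorld(
        spec=spec,
        seed=seed,
        backbone=backbone,
        typestrains=typestrains,
        pool=pool_reads,
        expected_flasvs=expected_flasvs,
        expected_profiles=expected_profiles,
        truth=truth,
    )
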