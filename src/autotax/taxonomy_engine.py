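"""Taxonomy assignment: backbone trimming, type-strain species calls,
placeholder naming, merging, and conflict resolution.

Each FL-ASV receives a complete seven-rank taxonomy assembled from three
sources in fixed precedence:

1. the backbone taxonomy of its closest reference, trimmed to the ranks the
   best-hit percent identity supports (retain rank r iff identity >=
   threshold(r); kingdom is always retained — any 16S hit shares a domain);
2. a binomial species name adopted from type strains, but only when exactly
   one distinct species lies strictly above the species threshold — two or
   more candidate species within range means no call (misclassification
   risk);
3. stable *de novo* placeholder names ``denovo_<rank-letter>_<centroid
   FL-ASV number>`` minted from the greedy rank clusterings, filling every
   rank the first two sources leave empty.

A final bottom-up pass repairs rank conflicts (the same lower-rank taxon
spanning two parents) by adopting the centroid FL-ASV's parent name, which
makes the name hierarchy a tree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import BackboneRecord
from .records import (
    CLUSTERED_RANKS,
    ClusterSet,
    Hit,
    PROV_BACKBONE,
    PROV_DENOVO,
    PROV_TYPESTRAIN,
    RANK_CODES,
    RANKS,
    RankThresholds,
    SeqRecord,
    TaxProfile,
    flasv_number,
)
from .seqcore import AlignScoring, DEFAULT_SCORING, global_identity, top_hit


@dataclass(frozen=True)
class TrimmedBackboneCall:
    """Backbone taxonomy of the best hit, trimmed to supported ranks."""

    flasv_id: str
    best_hit: Hit
    tax: TaxProfile


@dataclass(frozen=True)
class SpeciesCall:
    """Type-strain species assignment (present iff exactly one in range)."""

    flasv_id: str
    species_name: str | None
    n_species_in_range: int

    def __post_init__(self) -> None:
        if (self.species_name is not None) != (self.n_species_in_range == 1):
            raise ValueError("species_name present iff n_species_in_range == 1")


@dataclass(frozen=True)
class TypeStrain:
    """A cultured type-strain reference with its formal organism name."""

    accession: str
    seq: str
    organism: str


_STRAIN_TOKENS = {"strain", "str.", "str", "subsp.", "subsp", "bv.", "pv."}


def binomial(organism: str) -> str:
    """First two whitespace words of an organism name (strain tags dropped)."""
    words = [w for w in organism.split() if w.lower() not in _STRAIN_TOKENS]
    if len(words) < 2:
        raise ValueError(f"cannot extract a binomial from {organism!r}")
    return " ".join(words[:2])


def trim_taxonomy(
    backbone_tax: TaxProfile,
    identity: float,
    thresholds: RankThresholds = RankThresholds(),
) -> TaxProfile:
    """Discard backbone ranks not supported by the best-hit identity.

    Kingdom is always retained; each of phylum..genus is retained iff
    ``identity >= threshold(rank)``; species is always empty here (the
    backbone is not curated at the species level).
    """
    names: list[str] = []
    for rank in RANKS[:-1]:
        name = backbone_tax.name(rank)
        if rank != "kingdom" and identity < thresholds[rank]:
            break
        names.append(name)
    # a break above leaves deeper ranks empty; trailing unnamed ranks too
    while names and not names[-1]:
        names.pop()
    if not all(names):
        # incomplete backbone lineage: keep the contiguous top, drop the rest
        first_gap = names.index("")
        names = names[:first_gap]
    return TaxProfile.from_names(names, provenance=PROV_BACKBONE)


def assign_species(
    flasv: SeqRecord,
    typestrain_db: Sequence[TypeStrain],
    threshold: float = 98.7,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> SpeciesCall:
    """Species call from type strains strictly above the species threshold.

    All type strains with identity > threshold are collected; the call is
    made iff their names reduce to exactly one distinct binomial.
    """
    in_range: set[str] = set()
    for ts in typestrain_db:
        if global_identity(flasv.seq, ts.seq, scoring) > threshold:
            in_range.add(binomial(ts.organism))
    if len(in_range) == 1:
        (name,) = in_range
        return SpeciesCall(flasv.id, name, 1)
    return SpeciesCall(flasv.id, None, len(in_range))


def make_denovo_names(
    cluster_sets: Mapping[str, ClusterSet]
) -> dict[tuple[str, str], str]:
    """Placeholder names ``denovo_<code>_<centroid number>`` per (id, rank)."""
    names: dict[tuple[str, str], str] = {}
    for rank, cs in cluster_sets.items():
        code = RANK_CODES[rank]
        for member, centroid in cs.assignments.items():
            names[(member, rank)] = f"denovo_{code}_{flasv_number(centroid)}"
    return names


def merge_taxonomies(
    trimmed: TrimmedBackboneCall,
    species: SpeciesCall,
    denovo_names: Mapping[tuple[str, str], str],
) -> TaxProfile:
    """Fill gaps in the trimmed backbone taxonomy.

    Per-rank precedence: trimmed backbone > type-strain species (species rank
    only) > *de novo* placeholder. The result is complete (7 non-empty
    ranks) with provenance recorded.
    """
    if trimmed.flasv_id != species.flasv_id:
        raise ValueError("trimmed and species calls cover different FL-ASVs")
    fid = trimmed.flasv_id
    profile = TaxProfile()
    for rank in RANKS:
        backbone_name = trimmed.tax.name(rank)
        if backbone_name:
            profile = profile.replace(rank, backbone_name, PROV_BACKBONE)
        elif rank == "species" and species.species_name is not None:
            profile = profile.replace(rank, species.species_name, PROV_TYPESTRAIN)
        else:
            profile = profile.replace(rank, denovo_names[(fid, rank)], PROV_DENOVO)
    return profile


_DENOVO_RE = re.compile(r"^denovo_([kpcofgs])_(\d+)$")


def _representative(members: list[str], taxon_name: str) -> str:
    """The member whose lineage wins a conflict for this taxon.

    For placeholder taxa the centroid FL-ASV is encoded in the name; for
    backbone-named taxa (no centroid) the lowest-numbered member stands in.
    """
    m = _DENOVO_RE.match(taxon_name)
    if m:
        centroid = f"FLASV{m.group(2)}"
        if centroid in members:
            return centroid
    return min(members, key=flasv_number)


def resolve_conflicts(
    merged_profiles: Mapping[str, TaxProfile],
    cluster_sets: Mapping[str, ClusterSet] | None = None,
) -> dict[str, TaxProfile]:
    """Repair parent-rank conflicts bottom-up so names form a tree.

    For each rank pair (child r, parent r-1), members of a child taxon whose
    parent names disagree all adopt the parent name (and provenance) of the
    taxon's centroid FL-ASV. Applied species -> phylum; afterwards every
    taxon name has exactly one parent name. Idempotent.
    """
    profiles = dict(merged_profiles)
    for child_idx in range(len(RANKS) - 1, 0, -1):
        child_rank = RANKS[child_idx]
        parent_rank = RANKS[child_idx - 1]
        groups: dict[str, list[str]] = {}
        for fid, profile in profiles.items():
            groups.setdefault(profile.name(child_rank), []).append(fid)
        for taxon_name, members in groups.items():
            parents = {profiles[m].name(parent_rank) for m in members}
            if len(parents) <= 1:
                continue
            rep = _representative(members, taxon_name)
            rep_profile = profiles[rep]
            new_name = rep_profile.name(parent_rank)
            new_prov = rep_profile.prov(parent_rank)
            for m in members:
                if profiles[m].name(parent_rank) != new_name:
                    profiles[m] = profiles[m].replace(parent_rank, new_name, new_prov)
    return profiles


def check_tree(profiles: Mapping[str, TaxProfile]) -> list[str]:
    """Violations of the tree property (child taxon with >1 parent name)."""
    problems: list[str] = []
    for child_idx in range(1, len(RANKS)):
        child_rank, parent_rank = RANKS[child_idx], RANKS[child_idx - 1]
        parents: dict[str, set[str]] = {}
        for profile in profiles.values():
            child = profile.name(child_rank)
            if child:
                parents.setdefault(child, set()).add(profile.name(parent_rank))
        for child, pset in parents.items():
            if len(pset) > 1:
                problems.append(
                    f"{child_rank} {child!r} has parents {sorted(pset)}"
                )
    return problems


def round_percent(x: float) -> float:
    """Round a percentage the way the novelty table prints it:
    one decimal at >= 10%, two decimals below."""
    return round(x, 1) if x >= 10 else round(x, 2)


def novelty_report(
    flasvs: Sequence[SeqRecord],
    backbone_db: Sequence[BackboneRecord],
    thresholds: RankThresholds = RankThresholds(),
    hits: Mapping[str, Hit] | None = None,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> pd.DataFrame:
    """Per-rank counts and percentages of FL-ASVs in novel taxa.

    An FL-ASV is novel at rank r when its best-hit identity against the
    backbone is strictly below threshold(r) (e.g. "new species: < 98.7%").
    Precomputed ``hits`` may be supplied to avoid re-searching.
    """
    if hits is None:
        db = [SeqRecord(id=b.accession, seq=b.seq) for b in backbone_db]
        hits = {rec.id: top_hit(rec, db, scoring) for rec in flasvs}
    identities = [hits[rec.id].identity for rec in flasvs]
    n = len(flasvs)
    rows = []
    for rank in CLUSTERED_RANKS:
        t = thresholds[rank]
        count = sum(1 for ident in identities if ident < t)
        percent = round_percent(100.0 * count / n) if n else 0.0
        rows.append({"rank": rank, "threshold": t, "count": count, "percent": percent})
    return pd.DataFrame(rows)


def novelty_percentages(
    counts: Mapping[str, int], total: int
) -> dict[str, float]:
    """The novelty table's percentage arithmetic from per-rank counts."""
    if total <= 0:
        raise ValueError("total must be positive")
    return {rank: round_percent(100.0 * c / total) for rank, c in counts.items()}


def denovo_census(final_profiles: Mapping[str, TaxProfile]) -> pd.DataFrame:
    """Per-rank counts and percentages of taxa carrying placeholder names."""
    rows = []
    for rank in CLUSTERED_RANKS:
        by_name: dict[str, str] = {}
        for profile in final_profiles.values():
            name = profile.name(rank)
            if name:
                by_name[name] = profile.prov(rank)
        total = len(by_name)
        n_denovo = sum(1 for prov in by_name.values() if prov == PROV_DENOVO)
        percent = round_percent(100.0 * n_denovo / total) if total else 0.0
        rows.append(
            {"rank": rank, "n_denovo": n_denovo, "n_taxa": total, "percent": percent}
        )
    return pd.DataFrame(rows)


def assign_all(
    flasvs: Sequence[SeqRecord],
    backbone_db: Sequence[BackboneRecord],
    typestrain_db: Sequence[TypeStrain],
    thresholds: RankThresholds = RankThresholds(),
    scoring: AlignScoring = DEFAULT_SCORING,
) -> tuple[dict[str, TaxProfile], dict[str, Hit], Mapping[str, ClusterSet]]:
    """Run the full assignment path for a list of canonical FL-ASVs.

    Returns final (conflict-resolved) profiles, the best hits used, and the
    rank cluster sets.
    """
    from .denovo_cluster import cluster_all_ranks

    db = [SeqRecord(id=b.accession, seq=b.seq) for b in backbone_db]
    tax_by_acc = {b.accession: b.tax for b in backbone_db}
    cluster_sets = cluster_all_ranks(flasvs, thresholds, scoring=scoring)
    denovo_names = make_denovo_names(cluster_sets)
    hits: dict[str, Hit] = {}
    merged: dict[str, TaxProfile] = {}
    for rec in flasvs:
        if db:
            hit = top_hit(rec, db, scoring)
            trimmed_tax = trim_taxonomy(tax_by_acc[hit.target_id], hit.identity, thresholds)
        else:
            hit = Hit(rec.id, "", 0.0, 0)
            trimmed_tax = TaxProfile()
        hits[rec.id] = hit
        trimmed = TrimmedBackboneCall(rec.id, hit, trimmed_tax)
        species = assign_species(rec, typestrain_db, thresholds["species"], scoring)
        merged[rec.id] = merge_taxonomies(trimmed, species, denovo_names)
    resolved = resolve_conflicts(merged, cluster_sets)
    return resolved, hits, cluster_sets
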