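"""Taxonomy assembly: threshold trimming, type-strain species calls,
placeholder naming, merging precedence, conflict resolution, novelty and
census tables."""

import pytest

from autotax.records import (
    CLUSTERED_RANKS,
    ClusterSet,
    Hit,
    PROV_BACKBONE,
    PROV_DENOVO,
    PROV_TYPESTRAIN,
    RANKS,
    RankThresholds,
    SeqRecord,
    TaxProfile,
)
from autotax.taxonomy_engine import (
    SpeciesCall,
    TrimmedBackboneCall,
    TypeStrain,
    assign_species,
    binomial,
    check_tree,
    denovo_census,
    make_denovo_names,
    merge_taxonomies,
    novelty_percentages,
    novelty_report,
    resolve_conflicts,
    round_percent,
    trim_taxonomy,
)

from .conftest import random_seq, substituted

FULL_BACKBONE = TaxProfile.from_names(["K", "P", "C", "O", "F", "G"])


def retained_depth(profile):
    return sum(1 for n in profile.ranks if n)


class TestTrimTaxonomy:
    @pytest.mark.parametrize(
        "identity,expected_depth",
        [(99.0, 6), (96.0, 6), (90.0, 5), (83.0, 4), (80.0, 3), (74.0, 1)],
    )
    def test_retained_depth_follows_thresholds(self, identity, expected_depth):
        trimmed = trim_taxonomy(FULL_BACKBONE, identity)
        assert retained_depth(trimmed) == expected_depth
        assert trimmed.name("species") == ""
        assert trimmed.is_contiguous()

    def test_kingdom_always_retained(self):
        assert trim_taxonomy(FULL_BACKBONE, 10.0).ranks == ("K",) + ("",) * 6

    def test_monotone_in_identity(self):
        """Raising identity never removes a retained rank."""
        identities = [70, 74.9, 75, 78.5, 82, 86.4, 86.5, 94.5, 98.6, 98.7, 100]
        depths = [retained_depth(trim_taxonomy(FULL_BACKBONE, i)) for i in identities]
        assert depths == sorted(depths)

    def test_gappy_backbone_lineage_cut_at_first_gap(self):
        gappy = TaxProfile(
            ranks=("K", "P", "", "O", "", "", ""),
            provenance=("backbone", "backbone", "empty", "backbone", "empty", "empty", "empty"),
        )
        trimmed = trim_taxonomy(gappy, 99.0)
        assert trimmed.ranks == ("K", "P", "", "", "", "", "")


class TestAssignSpecies:
    def build_strains(self, rng, flasv_seq, spec):
        """spec: list of (organism, n_substitutions)."""
        return [
            TypeStrain(
                accession=f"TS{i}",
                seq=substituted(flasv_seq, rng.choice(len(flasv_seq), n, replace=False), rng),
                organism=org,
            )
            for i, (org, n) in enumerate(spec)
        ]

    def test_single_species_in_range_assigned(self, rng):
        seq = random_seq(rng, 1000)
        strains = self.build_strains(rng, seq, [("Escherichia coli", 8)])  # 99.2
        call = assign_species(SeqRecord("f", seq), strains)
        assert call.species_name == "Escherichia coli"

    def test_two_species_in_range_blocks_the_call(self, rng):
        seq = random_seq(rng, 1000)
        strains = self.build_strains(
            rng, seq, [("Escherichia coli", 8), ("Shigella flexneri", 11)]  # 99.2, 98.9
        )
        call = assign_species(SeqRecord("f", seq), strains)
        assert call.species_name is None and call.n_species_in_range == 2

    def test_two_strains_one_binomial_still_assigned(self, rng):
        seq = random_seq(rng, 1000)
        strains = self.build_strains(
            rng,
            seq,
            [("Escherichia coli strain K12", 10), ("Escherichia coli O157", 12)],
        )
        call = assign_species(SeqRecord("f", seq), strains)
        assert call.species_name == "Escherichia coli"

    def test_identity_exactly_at_threshold_excluded(self, rng):
        seq = random_seq(rng, 1000)
        strains = self.build_strains(rng, seq, [("Escherichia coli", 13)])  # 98.7
        call = assign_species(SeqRecord("f", seq), strains)
        assert call.species_name is None and call.n_species_in_range == 0

    def test_binomial_extraction(self):
        assert binomial("Escherichia coli strain K12") == "Escherichia coli"
        assert binomial("Bacillus subtilis subsp. subtilis") == "Bacillus subtilis"


class TestDenovoNames:
    def cluster_set(self, rank, assignments, order):
        return ClusterSet(rank=rank, threshold=None, assignments=assignments, centroid_order=order)

    def test_members_inherit_centroid_number(self):
        sets = {
            "genus": self.cluster_set(
                "genus", {"FLASV7": "FLASV7", "FLASV9": "FLASV7"}, ["FLASV7"]
            )
        }
        names = make_denovo_names(sets)
        assert names[("FLASV7", "genus")] == "denovo_g_7"
        assert names[("FLASV9", "genus")] == "denovo_g_7"

    def test_species_code(self):
        sets = {"species": self.cluster_set("species", {"FLASV12": "FLASV12"}, ["FLASV12"])}
        assert make_denovo_names(sets)[("FLASV12", "species")] == "denovo_s_12"

    def test_singleton_is_its_own_centroid_at_every_rank(self):
        sets = {
            rank: self.cluster_set(rank, {"FLASV3": "FLASV3"}, ["FLASV3"])
            for rank in RANKS
        }
        names = make_denovo_names(sets)
        assert names[("FLASV3", "phylum")] == "denovo_p_3"
        assert names[("FLASV3", "species")] == "denovo_s_3"


def denovo_name_map(fid, number=None):
    n = number if number is not None else int(fid.replace("FLASV", ""))
    return {(fid, rank): f"denovo_{code}_{n}" for rank, code in zip(RANKS, "kpcofgs")}


class TestMergeTaxonomies:
    def call(self, fid, identity, names=("K", "P", "C", "O", "F", "G")):
        tax = trim_taxonomy(TaxProfile.from_names(list(names)), identity)
        return TrimmedBackboneCall(fid, Hit(fid, "BB1", identity, 1000), tax)

    def test_backbone_through_family_then_placeholders(self):
        merged = merge_taxonomies(
            self.call("FLASV2", 90.0), SpeciesCall("FLASV2", None, 0), denovo_name_map("FLASV2")
        )
        assert merged.ranks[:5] == ("K", "P", "C", "O", "F")
        assert merged.ranks[5:] == ("denovo_g_2", "denovo_s_2")
        assert merged.provenance[5] == PROV_DENOVO

    def test_typestrain_species_wins_over_placeholder(self):
        merged = merge_taxonomies(
            self.call("FLASV1", 99.0),
            SpeciesCall("FLASV1", "Escherichia coli", 1),
            denovo_name_map("FLASV1"),
        )
        assert merged.name("species") == "Escherichia coli"
        assert merged.prov("species") == PROV_TYPESTRAIN
        assert merged.name("genus") == "G"

    def test_kingdom_only_backbone_gives_six_placeholders(self):
        merged = merge_taxonomies(
            self.call("FLASV4", 74.0), SpeciesCall("FLASV4", None, 0), denovo_name_map("FLASV4")
        )
        assert merged.name("kingdom") == "K"
        assert all(n.startswith("denovo_") for n in merged.ranks[1:])
        assert merged.is_complete()


def profile(names, provs=None):
    provs = provs or tuple(PROV_BACKBONE if n else "empty" for n in names)
    return TaxProfile(ranks=tuple(names), provenance=tuple(provs))


class TestResolveConflicts:
    def make_conflict(self):
        base = ("K", "P", "C", "O", "F")
        p10 = profile(base + ("GenusA", "denovo_s_10"),
                      ("backbone",) * 6 + ("denovo",))
        p22 = profile(base + ("GenusB", "denovo_s_10"),
                      ("backbone",) * 6 + ("denovo",))
        return {"FLASV10": p10, "FLASV22": p22}

    def test_member_adopts_centroid_genus(self):
        resolved = resolve_conflicts(self.make_conflict())
        assert resolved["FLASV22"].name("genus") == "GenusA"
        assert resolved["FLASV10"].name("genus") == "GenusA"
        assert check_tree(resolved) == []

    def test_no_conflicts_is_identity(self, world):
        resolved = resolve_conflicts(world.expected_profiles)
        assert resolved == dict(world.expected_profiles)

    def test_idempotent(self):
        once = resolve_conflicts(self.make_conflict())
        assert resolve_conflicts(once) == once

    def test_three_sequence_chain_resolves_to_centroid_lineage(self):
        """A conflict chain across two adjacent rank pairs collapses onto
        the centroid's lineage; verified against the exhaustive tree-repair
        oracle (every taxon's final parent equals its centroid's parent)."""
        profiles = {
            "FLASV1": profile(
                ("K", "P", "C", "O", "FamX", "denovo_g_1", "denovo_s_1"),
                ("backbone",) * 5 + ("denovo", "denovo"),
            ),
            "FLASV2": profile(
                ("K", "P", "C", "O", "FamY", "denovo_g_1", "denovo_s_2"),
                ("backbone",) * 5 + ("denovo", "denovo"),
            ),
            "FLASV3": profile(
                ("K", "P", "C", "O", "FamY", "denovo_g_3", "denovo_s_2"),
                ("backbone",) * 5 + ("denovo", "denovo"),
            ),
        }
        resolved = resolve_conflicts(profiles)
        assert check_tree(resolved) == []
        # species denovo_s_2 (centroid FLASV2) forces FLASV3's genus to the
        # centroid's genus; genus denovo_g_1 (centroid FLASV1) forces FamX
        assert resolved["FLASV3"].name("genus") == "denovo_g_1"
        for fid in profiles:
            assert resolved[fid].name("family") == "FamX"


class TestNoveltyReport:
    def test_counts_match_hand_enumeration(self, rng):
        flasvs = [SeqRecord(f"FLASV{i}", random_seq(rng, 50)) for i in range(1, 5)]
        hits = {
            "FLASV1": Hit("FLASV1", "B", 99.0, 50),
            "FLASV2": Hit("FLASV2", "B", 96.0, 50),
            "FLASV3": Hit("FLASV3", "B", 94.0, 50),
            "FLASV4": Hit("FLASV4", "B", 90.0, 50),
        }
        table = novelty_report(flasvs, [], hits=hits).set_index("rank")
        assert table.loc["genus", "count"] == 2  # 94.0 and 90.0 below 94.5
        assert table.loc["species", "count"] == 3  # all but 99.0 below 98.7
        assert table.loc["family", "count"] == 0
        assert table.loc["genus", "percent"] == 50.0

    def test_no_sequences_below_threshold(self, rng):
        flasvs = [SeqRecord("FLASV1", random_seq(rng, 50))]
        hits = {"FLASV1": Hit("FLASV1", "B", 99.9, 50)}
        table = novelty_report(flasvs, [], hits=hits)
        assert (table["count"] == 0).all() and (table["percent"] == 0.0).all()

    def test_percent_formatting_rule(self):
        assert round_percent(25.722) == 25.7
        assert round_percent(5.7557) == 5.76
        assert round_percent(0.16805) == 0.17

    def test_percentage_arithmetic(self):
        pct = novelty_percentages({"species": 2449, "genus": 548}, 9521)
        assert pct == {"species": 25.7, "genus": 5.76}


class TestDenovoCensus:
    def make(self, n_denovo, n_backbone):
        profiles = {}
        for i in range(n_denovo):
            profiles[f"FLASV{i+1}"] = profile(
                ("K", "P", "C", "O", "F", f"denovo_g_{i+1}", f"denovo_s_{i+1}"),
                ("backbone",) * 5 + ("denovo", "denovo"),
            )
        for i in range(n_backbone):
            profiles[f"FLASV{100+i}"] = profile(
                ("K", "P", "C", "O", "F", f"Genus{i}", f"denovo_s_{100+i}"),
                ("backbone",) * 6 + ("denovo",),
            )
        return profiles

    def test_all_placeholder(self):
        table = denovo_census(self.make(3, 0)).set_index("rank")
        assert table.loc["genus", "percent"] == 100.0
        assert table.loc["species", "percent"] == 100.0

    def test_no_placeholder(self):
        table = denovo_census(self.make(0, 2)).set_index("rank")
        assert table.loc["genus", "percent"] == 0.0
        assert table.loc["phylum", "percent"] == 0.0

    def test_mixed_counts(self):
        table = denovo_census(self.make(2, 3)).set_index("rank")
        assert table.loc["genus", "n_denovo"] == 2
        assert table.loc["genus", "n_taxa"] == 5
        assert table.loc["genus", "percent"] == 40.0
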