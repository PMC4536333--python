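import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from balaena.genetics import CdsRecord
from balaena.orthology import (
    GeneFamily,
    best_hits,
    cluster_families,
    extract_sgos,
    reciprocal_best_hits,
)
from balaena.seqio import HIT_COLUMNS


def hits_frame(rows):
    """rows: (query, subject, evalue, bitscore)"""
    return pd.DataFrame(
        [
            (q, s, 90.0, 100, 0, 0, 1, 100, 1, 100, e, b)
            for q, s, e, b in rows
        ],
        columns=HIT_COLUMNS,
    )


class TestBestHits:
    def test_highest_bit_score_wins(self):
        bh = best_hits(hits_frame([("q1", "s1", 1e-50, 200), ("q1", "s2", 1e-60, 150)]),
                       evalue_cutoff=1e-7)
        assert bh == {"q1": "s1"}

    def test_all_hits_above_cutoff_give_empty_map(self):
        assert best_hits(hits_frame([("q1", "s1", 1e-3, 50)]), 1e-7) == {}

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            best_hits(hits_frame([]), 1e-7)

    def test_tie_breaking_invariant_under_row_order(self):
        # bit-score tie -> lower e-value -> lexicographically smaller subject
        rows = [
            ("q1", "s_b", 1e-50, 200),
            ("q1", "s_a", 1e-50, 200),   # wins on subject id
            ("q1", "s_c", 1e-60, 200),   # wins outright on e-value
            ("q1", "s_d", 1e-40, 180),
        ]
        expected = {"q1": "s_c"}
        for perm in itertools.permutations(rows):
            assert best_hits(hits_frame(list(perm)), 1e-7) == expected


class TestReciprocalBestHits:
    def test_mutual_pair_kept(self):
        assert reciprocal_best_hits({"a1": "b1"}, {"b1": "a1"}) == [("a1", "b1")]

    def test_non_mutual_pair_dropped(self):
        assert reciprocal_best_hits({"a1": "b1"}, {"b1": "a2"}) == []

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_scan(self, data):
        n_a, n_b = 6, 6
        a_genes = [f"a{i}" for i in range(n_a)]
        b_genes = [f"b{i}" for i in range(n_b)]
        bh_ab = {
            g: data.draw(st.sampled_from(b_genes), label=f"bh[{g}]")
            for g in a_genes
            if data.draw(st.booleans(), label=f"has[{g}]")
        }
        bh_ba = {
            g: data.draw(st.sampled_from(a_genes), label=f"bh[{g}]")
            for g in b_genes
            if data.draw(st.booleans(), label=f"has[{g}]")
        }
        expected = sorted(
            (a, b)
            for a in a_genes
            for b in b_genes
            if bh_ab.get(a) == b and bh_ba.get(b) == a
        )
        assert reciprocal_best_hits(bh_ab, bh_ba) == expected


def species_of(gene: str) -> str:
    return gene.split("_")[0]


class TestClusterFamilies:
    def test_transitive_pairs_form_one_family(self):
        fams = cluster_families(
            [("sp1_a", "sp2_b"), ("sp2_b", "sp3_c")],
            ["sp1_a", "sp2_b", "sp3_c"],
            species_of,
        )
        assert len(fams) == 1
        assert {g for _, g in fams[0].members} == {"sp1_a", "sp2_b", "sp3_c"}

    def test_no_pairs_gives_singletons(self):
        fams = cluster_families([], ["sp1_a", "sp2_b"], species_of)
        assert len(fams) == 2
        assert all(len(f.members) == 1 for f in fams)

    def test_membership_is_a_partition(self, rng):
        genes = [f"sp{i % 5}_g{i}" for i in range(40)]
        pairs = [
            tuple(rng.choice(genes, size=2, replace=False)) for _ in range(30)
        ]
        fams = cluster_families(pairs, genes, species_of)
        seen = [g for f in fams for _, g in f.members]
        assert sorted(seen) == sorted(genes)

    def test_component_count_matches_brute_force(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 50))
            genes = [f"sp{i % 4}_g{i}" for i in range(n)]
            n_edges = int(rng.integers(0, n))
            pairs = [
                tuple(rng.choice(genes, size=2, replace=False))
                for _ in range(n_edges)
            ]
            fams = cluster_families(pairs, genes, species_of)
            # brute-force union-find, written independently
            parent = {g: g for g in genes}

            def find(x):
                while parent[x] != x:
                    x = parent[x]
                return x

            for a, b in pairs:
                parent[find(a)] = find(b)
            n_components = len({find(g) for g in genes})
            assert len(fams) == n_components


def family(fid, members):
    return GeneFamily(family_id=fid, members=set(members))


def cds_table(genes, sequence="ATGAAA"):
    return {
        g: CdsRecord(gene_id=g, species=s, sequence=sequence)
        for s, g in genes
    }


class TestExtractSgos:
    def test_eight_single_copy_species_kept(self):
        members = [(f"sp{i}", f"sp{i}_g") for i in range(8)]
        sgos, rejections = extract_sgos([family("f1", members)], cds_table(members))
        assert len(sgos) == 1 and not rejections
        assert sgos[0].species_count == 8

    def test_seven_species_rejected_on_boundary(self):
        members = [(f"sp{i}", f"sp{i}_g") for i in range(7)]
        sgos, rejections = extract_sgos([family("f1", members)], cds_table(members))
        assert not sgos
        assert rejections[0].reason == "too_few_species"

    def test_multi_copy_species_rejected(self):
        members = [(f"sp{i}", f"sp{i}_g") for i in range(8)] + [("sp0", "sp0_g2")]
        sgos, rejections = extract_sgos([family("f1", members)], cds_table(members))
        assert not sgos
        assert rejections[0].reason == "multi_copy"

    def test_internal_stop_member_rejected(self):
        members = [(f"sp{i}", f"sp{i}_g") for i in range(8)]
        table = cds_table(members)
        table["sp3_g"] = CdsRecord("sp3_g", "sp3", "ATGTAAAAA")
        sgos, rejections = extract_sgos([family("f1", members)], table)
        assert not sgos
        assert rejections[0].reason == "internal_stop"
        assert "sp3_g" in rejections[0].detail

    def test_missing_cds_rejected_with_reason(self):
        members = [(f"sp{i}", f"sp{i}_g") for i in range(8)]
        table = cds_table(members)
        del table["sp5_g"]
        _, rejections = extract_sgos([family("f1", members)], table)
        assert rejections[0].reason == "missing_cds"

    def test_idempotent_and_order_independent(self):
        fams = [
            family("f1", [(f"sp{i}", f"a{i}") for i in range(8)]),
            family("f2", [(f"sp{i}", f"b{i}") for i in range(9)]),
        ]
        table = {**cds_table(fams[0].members), **cds_table(fams[1].members)}
        once = extract_sgos(fams, table)
        twice = extract_sgos(list(reversed(fams)), table)
        assert [s.family_id for s in once[0]] == [s.family_id for s in twice[0]]
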