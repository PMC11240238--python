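"""Tryptic digestion, peptide indexing, LCA assignment, peptide tables."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from metaomix.core import ProteinRecord, TaxonNode, TaxonomyTree
from metaomix.dbbuild import ProteinDatabase, deduplicate
from metaomix.peptides import (
    UNMAPPED,
    DigestParams,
    aggregate_peptides,
    assign_lca,
    build_index,
    digest,
    taxon_table_from_peptides,
    unique_peptide_count,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_digest(seq: str, params: DigestParams) -> Counter:
    """Independent oracle: enumerate every substring and keep those that
    are valid tryptic products under the cleavage predicate."""

    def cleaves_after(k: int) -> bool:  # cut between k and k+1
        return seq[k] in "KR" and (k + 1 >= len(seq) or seq[k + 1] != "P")

    out = Counter()
    n = len(seq)
    for i in range(n):
        if not (i == 0 or cleaves_after(i - 1)):
            continue
        for j in range(i + 1, n + 1):
            if not (j == n or cleaves_after(j - 1)):
                continue
            internal = sum(1 for k in range(i, j - 1) if cleaves_after(k))
            if internal > params.missed_cleavages:
                continue
            if params.min_len <= j - i <= params.max_len:
                out[seq[i:j]] += 1
    return out


class TestDigest:
    def test_basic_cleavage_after_k_and_r(self):
        params = DigestParams(missed_cleavages=0, min_len=3, max_len=45)
        assert digest("AAAKBBBRCCC".replace("B", "G"), params) == ["AAAK", "GGGR", "CCC"]

    def test_no_cleavage_before_proline(self):
        params = DigestParams(missed_cleavages=0, min_len=3, max_len=45)
        assert digest("AAKPAA", params) == ["AAKPAA"]

    def test_missed_cleavage_products_in_position_order(self):
        params = DigestParams(missed_cleavages=1, min_len=1, max_len=45)
        assert digest("AKCKD", params) == ["AK", "AKCK", "CK", "CKD", "D"]

    def test_matches_brute_force_oracle_on_random_sequences(self):
        rng = np.random.default_rng(53)
        for i in range(100):
            seq = "".join(AA[j] for j in rng.integers(0, 20, int(rng.integers(10, 120))))
            params = DigestParams(
                missed_cleavages=int(rng.integers(0, 4)),
                min_len=int(rng.integers(1, 8)),
                max_len=int(rng.integers(10, 60)),
            )
            assert Counter(digest(seq, params)) == brute_force_digest(seq, params), seq

    def test_agrees_with_pyteomics_cleave(self):
        """Independent cross-check against an established proteomics library."""
        from pyteomics import parser as pt_parser

        rng = np.random.default_rng(59)
        params = DigestParams(missed_cleavages=2, min_len=1, max_len=10**6)
        # plain cleave-after-K/R-unless-P rule (the full expasy rule adds
        # WKP/MRP exception clauses that are out of scope here)
        rule = r"[KR](?!P)"
        for _ in range(30):
            seq = "".join(AA[j] for j in rng.integers(0, 20, 80))
            ours = set(digest(seq, params))
            theirs = pt_parser.cleave(seq, rule, 2)
            assert ours == set(theirs)

    def test_product_count_monotone_in_missed_cleavages(self):
        rng = np.random.default_rng(61)
        seq = "".join(AA[j] for j in rng.integers(0, 20, 200))
        counts = [
            len(digest(seq, DigestParams(missed_cleavages=mc, min_len=1, max_len=10**6)))
            for mc in range(5)
        ]
        assert counts == sorted(counts)


def _db(records):
    recs, tmap = deduplicate(records)
    return ProteinDatabase(records=recs, taxon_map=tmap)


class TestBuildIndex:
    def test_single_protein_maps_all_peptides_to_its_taxon(self):
        db = _db([ProteinRecord("p1", "tX", "MKVLAEKAGHLLYK")])
        index = build_index(db, DigestParams(missed_cleavages=1, min_len=4, max_len=45))
        assert len(index) > 0
        for entry in index.entries.values():
            assert entry["taxa"] == {"tX"}

    def test_shared_peptide_unions_taxa(self):
        shared = "AAAGHLLWQCK"
        db = _db(
            [
                ProteinRecord("p1", "t1", shared + "MMMMMMK"),
                ProteinRecord("p2", "t2", shared + "WWWWWWR"),
            ]
        )
        index = build_index(db, DigestParams(missed_cleavages=0, min_len=4, max_len=45))
        assert index.get(shared)["taxa"] == {"t1", "t2"}
        assert index.get(shared)["proteins"] == {"p1", "p2"}

    def test_agrees_with_per_protein_merge_oracle(self, community):
        from metaomix.dbbuild import collect_proteomes

        raw, _, _ = collect_proteomes(community.genera[:4], community.source)
        recs, tmap = deduplicate(raw)
        db = ProteinDatabase(records=recs, taxon_map=tmap)
        params = DigestParams()
        index = build_index(db, params)
        # oracle: digest each protein separately, merge dictionaries
        expected: dict = {}
        for rec in db.records:
            for pep in set(digest(rec.sequence, params)):
                key = params.collapse(pep)
                e = expected.setdefault(key, {"proteins": set(), "taxa": set()})
                e["proteins"].add(rec.id)
                e["taxa"] |= set(tmap[rec.id])
        assert set(index.entries) == set(expected)
        for key in expected:
            assert index.entries[key]["proteins"] == expected[key]["proteins"]
            assert index.entries[key]["taxa"] == expected[key]["taxa"]

    def test_il_collapse_never_increases_key_count(self, community):
        from metaomix.dbbuild import collect_proteomes

        raw, _, _ = collect_proteomes(community.genera[:3], community.source)
        recs, tmap = deduplicate(raw)
        db = ProteinDatabase(records=recs, taxon_map=tmap)
        with_il = build_index(db, DigestParams(equate_il=True))
        without = build_index(db, DigestParams(equate_il=False))
        assert len(with_il) <= len(without)

    def test_index_tsv_round_trip(self, tmp_path):
        db = _db(
            [
                ProteinRecord("p1", "t1", "MKVLAEKAGHLLYK", frozenset({"1.1.1.1"})),
                ProteinRecord("p2", "t2", "MKVLAEKWWHHLYR", ko=frozenset({"K00042"})),
            ]
        )
        index = build_index(db)
        index.to_tsv(tmp_path / "idx.tsv")
        from metaomix.peptides import PeptideIndex

        back = PeptideIndex.from_tsv(tmp_path / "idx.tsv", index.params)
        assert back.entries == index.entries


class TestAssignLCA:
    def test_singleton_is_itself(self, small_tree):
        assert small_tree.lca(["g1_s1"]) == "g1_s1"

    def test_sibling_genera_resolve_to_family(self, small_tree):
        assert small_tree.lca(["g1", "g2"]) == "Family_A"
        assert small_tree.lca(["g1", "g3"]) == "Bacteria"

    def test_unmapped_peptide_flagged_not_raised(self, small_tree):
        db = _db([ProteinRecord("p1", "g1", "MKVLAEKAGHLLYK")])
        index = build_index(db)
        assert assign_lca("NOTAPEPTIDEK", index, small_tree) == UNMAPPED

    def test_matches_path_intersection_oracle_on_random_trees(self):
        rng = np.random.default_rng(67)
        for trial in range(25):
            # random tree: each node's parent drawn among earlier nodes
            n = int(rng.integers(5, 40))
            nodes = {"n0": TaxonNode("n0", "unranked", "n0")}
            ids = ["n0"]
            for i in range(1, n):
                parent = ids[int(rng.integers(0, i))]
                nodes[f"n{i}"] = TaxonNode(f"n{i}", "unranked", parent)
                ids.append(f"n{i}")
            tree = TaxonomyTree(nodes)
            for _ in range(8):
                k = int(rng.integers(1, 6))
                subset = [ids[int(rng.integers(0, n))] for _ in range(k)]
                # oracle: intersect root paths, take the deepest common node
                common = set(tree.path_to_root(subset[0]))
                for t in subset[1:]:
                    common &= set(tree.path_to_root(t))
                expected = max(common, key=tree.depth)
                assert tree.lca(subset) == expected

    def test_lca_order_invariant_and_idempotent(self, small_tree):
        assert small_tree.lca(["g1", "g3"]) == small_tree.lca(["g3", "g1"])
        assert small_tree.lca(["g2"]) == "g2"


class TestAggregatePeptides:
    def test_two_peptides_one_sample(self):
        pt = aggregate_peptides([("s1", "PEPTIDEK", 3), ("s1", "AAAGHLLK", 2)])
        assert pt.matrix.shape == (2, 1)
        assert pt.matrix.values.loc["PEPTIDEK", "s1"] == 3

    def test_absent_combination_is_zero(self):
        pt = aggregate_peptides([("s1", "PEPTIDEK", 3), ("s2", "AAAGHLLK", 2)])
        assert pt.matrix.values.loc["PEPTIDEK", "s2"] == 0

    def test_duplicate_rows_summed_with_warning(self):
        with pytest.warns(UserWarning, match="summed"):
            pt = aggregate_peptides([("s1", "PEPTIDEK", 3), ("s1", "PEPTIDEK", 4)])
        assert pt.matrix.values.loc["PEPTIDEK", "s1"] == 7

    def test_tallies_conserved_on_fixture(self):
        rng = np.random.default_rng(71)
        rows = []
        for s in ["s1", "s2", "s3"]:
            for p in range(20):
                if rng.random() < 0.7:
                    rows.append((s, f"PEP{p:02d}K", int(rng.integers(1, 9))))
        pt = aggregate_peptides(rows)
        df = pd.DataFrame(rows, columns=["sample", "peptide", "count"])
        for s, sub in df.groupby("sample"):
            assert pt.matrix.values[s].sum() == sub["count"].sum()

    def test_nonpositive_counts_rejected(self):
        from metaomix.core import ValidationError

        with pytest.raises(ValidationError):
            aggregate_peptides([("s1", "PEPTIDEK", 0)])


class TestTaxonTableFromPeptides:
    def _table(self, small_tree):
        db = _db(
            [
                ProteinRecord("p1", "g1_s1", "MMMAAAGHLLWQCK"),  # unique to g1_s1
                ProteinRecord("p2", "g1_s2", "WWWTTTGHLLWQCK"),
                ProteinRecord("p3", "g1_s1", "CCCDDDGHLLWQK"),
                ProteinRecord("p4", "g3", "EEEFFFGHLLWQK"),
            ]
        )
        index = build_index(db, DigestParams(missed_cleavages=0, min_len=5))
        rows = [
            ("s1", "MMMAAAGHLLWQCK", 4),  # LCA g1_s1 -> genus g1
            ("s1", "EEEFFFGHLLWQK", 1),  # LCA g3
            ("s2", "WWWTTTGHLLWQCK", 2),  # LCA g1_s2 -> genus g1
            ("s2", "ZZZZZZZK".replace("Z", "W"), 5),  # unmapped
        ]
        return aggregate_peptides(rows, index=index, taxonomy=small_tree)

    def test_counts_credited_to_rank_ancestor(self, small_tree):
        pt = self._table(small_tree)
        out = taxon_table_from_peptides(pt, small_tree, "genus")
        assert out.values.loc["g1", "s1"] == 4
        assert out.values.loc["g3", "s1"] == 1
        assert out.values.loc["g1", "s2"] == 2

    def test_lca_above_rank_pools_unclassified(self, small_tree):
        db = _db(
            [
                ProteinRecord("p1", "g1", "AAAGHLLWQCKMMMMMMK"),
                ProteinRecord("p2", "g3", "AAAGHLLWQCKWWWWWWR"),
            ]
        )
        index = build_index(db, DigestParams(missed_cleavages=0, min_len=5))
        pt = aggregate_peptides([("s1", "AAAGHLLWQCK", 6)], index=index, taxonomy=small_tree)
        assert pt.annotations.iloc[0]["lca"] == "Bacteria"  # above genus
        out = taxon_table_from_peptides(pt, small_tree, "genus")
        assert out.values.loc["Unclassified", "s1"] == 6

    def test_totals_conserved(self, small_tree):
        pt = self._table(small_tree)
        out = taxon_table_from_peptides(pt, small_tree, "genus")
        np.testing.assert_array_equal(
            out.values.sum(axis=0).to_numpy(), pt.matrix.values.sum(axis=0).to_numpy()
        )


class TestEndToEndProvenance:
    def test_taxon_unique_peptides_get_their_taxon_or_ancestor(self, community):
        """Peptides generated from one taxon's proteins must never be
        assigned a disjoint taxon."""
        from metaomix.dbbuild import collect_proteomes
        from metaomix.profile import relative_abundance, aggregate_to_rank
        from metaomix.simulate import make_peptide_ids

        raw, _, _ = collect_proteomes(community.genera, community.source)
        recs, tmap = deduplicate(raw)
        db = ProteinDatabase(records=recs, taxon_map=tmap)
        index = build_index(db)
        ab = pd.DataFrame(
            np.ones((len(community.genera), 2)),
            index=community.genera, columns=["s1", "s2"],
        )
        _, truth = make_peptide_ids(community, ab, n_psms=400, seed=73)
        tree = community.tree
        checked = disjoint = 0
        for row in truth.itertuples(index=False):
            lca = assign_lca(row.peptide, index, tree)
            if lca == UNMAPPED:
                continue
            checked += 1
            path = set(tree.path_to_root(row.taxon))
            if lca not in path:
                disjoint += 1
        assert checked > 300
        assert disjoint == 0

    def test_merging_proteomes_shrinks_unique_peptides_of_original(self, community):
        from metaomix.dbbuild import collect_proteomes

        base_raw, _, _ = collect_proteomes(community.genera[:6], community.source)
        recs, tmap = deduplicate(base_raw)
        base_index = build_index(ProteinDatabase(records=recs, taxon_map=tmap))
        all_raw, _, _ = collect_proteomes(community.genera, community.source)
        recs2, tmap2 = deduplicate(all_raw)
        merged_index = build_index(ProteinDatabase(records=recs2, taxon_map=tmap2))
        base_unique = {
            p for p, e in base_index.entries.items() if len(e["taxa"]) == 1
        }
        still_unique = {
            p for p in base_unique if len(merged_index.entries[p]["taxa"]) == 1
        }
        # enlarging the database can only demote original unique peptides
        assert still_unique <= base_unique
        assert unique_peptide_count(merged_index) >= len(still_unique)
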