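"""Alignment, distances, neighbor joining, bootstrap, group transfer."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from erf_survey import oracles, phylogeny_grouping as pg, synthetic_data as sd

BLOSUM62 = substitution_matrices.load("BLOSUM62")


class TestPairwiseAlign:
    def test_self_alignment_score(self):
        a, b, score = pg.pairwise_global_align("AAEIRD", "AAEIRD")
        assert a == b == "AAEIRD"
        assert score == sum(BLOSUM62[c, c] for c in "AAEIRD")

    @pytest.mark.parametrize("x,y", [("ACD", "AD"), ("MKV", "MV"), ("WW", "WAW")])
    def test_matches_brute_force_optimum(self, x, y):
        _, _, score = pg.pairwise_global_align(x, y)
        brute = oracles.brute_force_alignment_score(x, y, BLOSUM62, -10.0, -0.5)
        assert score == pytest.approx(brute)

    def test_score_symmetry(self):
        _, _, s1 = pg.pairwise_global_align("MKVACD", "MACD")
        _, _, s2 = pg.pairwise_global_align("MACD", "MKVACD")
        assert s1 == pytest.approx(s2)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pg.pairwise_global_align("", "MKV")


class TestDistances:
    def test_identical_sequences_zero(self):
        dm = pg.distance_matrix([("a", "MKVL"), ("b", "MKVL")])
        assert dm.d[0, 1] == 0

    def test_one_in_four_mismatch(self):
        assert pg.p_distance("AAAA", "AAAT") == 0.25

    def test_gap_columns_excluded(self):
        assert pg.p_distance("AC-D", "ACED") == 0.0

    def test_no_comparable_columns_errors(self):
        with pytest.raises(ValueError):
            pg.p_distance("A--", "-AA")

    def test_symmetry_and_validation(self):
        dm = pg.distance_matrix([("a", "MKVLAC"), ("b", "MKVLAD"), ("c", "MKWLAD")])
        assert np.allclose(dm.d, dm.d.T)
        with pytest.raises(ValueError, match="symmetric"):
            pg.DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))


class TestNeighborJoining:
    def test_two_taxa_split_evenly(self):
        dm = pg.DistanceMatrix(["a", "b"], np.array([[0, 0.4], [0.4, 0]]))
        tree = pg.neighbor_joining(dm)
        lengths = sorted(ln for _, _, ln in tree.edges())
        assert lengths == pytest.approx([0.2, 0.2])

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = pg.neighbor_joining(pg.DistanceMatrix(["a", "b", "c"], d))
        # closed form: l_a = (d_ab + d_ac - d_bc)/2 etc.
        by_leaf = {}
        for u, v, ln in tree.edges():
            leaf = u if isinstance(u, str) else v
            by_leaf[leaf] = ln
        assert by_leaf["a"] == pytest.approx(0.1)
        assert by_leaf["b"] == pytest.approx(0.2)
        assert by_leaf["c"] == pytest.approx(0.4)

    def test_four_taxon_additive_recovery_with_branch_lengths(self):
        # tree: (a,b | c,d), internal 0.7; pendants 0.1 0.2 0.3 0.4
        d = np.array(
            [
                [0.0, 0.3, 1.1, 1.2],
                [0.3, 0.0, 1.2, 1.3],
                [1.1, 1.2, 0.0, 0.7],
                [1.2, 1.3, 0.7, 0.0],
            ]
        )
        tree = pg.neighbor_joining(pg.DistanceMatrix(list("abcd"), d))
        assert tree.bipartitions() == {frozenset({"c", "d"})}
        assert tree.total_length() == pytest.approx(0.1 + 0.2 + 0.3 + 0.4 + 0.7)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_additive_matrices_recover_generating_topology(self, n):
        for seed in range(12):
            dm, truth = sd.generate_additive_matrix(n, seed=seed)
            tree = pg.neighbor_joining(dm)
            assert tree.bipartitions() == truth

    @pytest.mark.parametrize("n", [5, 6])
    def test_generating_topology_is_least_squares_optimum(self, n):
        """Cross-check against the exhaustive-topology LS oracle."""
        for seed in (0, 1, 2):
            dm, truth = sd.generate_additive_matrix(n, seed=seed)
            bps, rss = oracles.exhaustive_ls_topology(dm.d)
            named = {frozenset(dm.labels[i] for i in bp) for bp in bps}
            assert named == truth
            assert rss < 1e-12

    def test_total_length_invariant_to_label_order(self):
        dm, _ = sd.generate_additive_matrix(6, seed=3)
        perm = np.random.default_rng(0).permutation(6)
        dm2 = pg.DistanceMatrix(
            [dm.labels[i] for i in perm], dm.d[np.ix_(perm, perm)]
        )
        t1, t2 = pg.neighbor_joining(dm), pg.neighbor_joining(dm2)
        assert t1.total_length() == pytest.approx(t2.total_length())
        assert set(t1.leaf_names) == set(t2.leaf_names)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            pg.DistanceMatrix(["a", "b"], np.array([[0, -0.1], [-0.1, 0]]))


class TestBootstrap:
    clean4 = [
        ("a", "A" * 30 + "C" * 30),
        ("b", "A" * 30 + "C" * 29 + "G"),
        ("c", "T" * 30 + "C" * 30),
        ("d", "T" * 30 + "C" * 29 + "G"),
    ]

    def test_clean_split_highly_supported(self):
        tree = pg.bootstrap_support(pg.center_star_msa(self.clean4), 200, seed=5)
        assert tree.support[frozenset({"c", "d"})] >= 0.95

    def test_same_seed_identical_supports(self):
        msa = pg.center_star_msa(self.clean4)
        t1 = pg.bootstrap_support(msa, 100, seed=42)
        t2 = pg.bootstrap_support(msa, 100, seed=42)
        assert t1.support == t2.support

    def test_identical_sequences_unresolved(self):
        msa = [("a", "MKVL"), ("b", "MKVL"), ("c", "MKVL"), ("d", "MKVL")]
        tree = pg.bootstrap_support(msa, 50, seed=0)
        assert tree.unresolved and tree.support == {}

    def test_fewer_than_two_columns_rejected(self):
        with pytest.raises(ValueError):
            pg.bootstrap_support([("a", "M"), ("b", "M")], 10, seed=0)

    def test_newick_contains_support_labels(self):
        tree = pg.bootstrap_support(pg.center_star_msa(self.clean4), 100, seed=5)
        nwk = tree.newick()
        assert nwk.endswith(";") and "(" in nwk
        assert any(f"){x}" in nwk for x in ("1.000", "0.9"))


class TestCenterStar:
    def test_rows_equal_length_and_ungap_to_inputs(self):
        seqs = [("a", "MKVLLG"), ("b", "MKVG"), ("c", "MKVLLGW")]
        msa = pg.center_star_msa(seqs)
        lengths = {len(s) for _, s in msa}
        assert len(lengths) == 1
        assert {n: s.replace("-", "") for n, s in msa} == dict(seqs)


class TestGroups:
    def test_clade_evidence(self):
        msa = pg.center_star_msa(self.make_family())
        tree = pg.bootstrap_support(msa, 100, seed=1)
        refs = [("B1_m1", "B1"), ("B1_m2", "B1"), ("B2_m1", "B2"), ("B2_m2", "B2")]
        out = {a.protein_id: a for a in pg.assign_groups(tree, refs)}
        assert out["B1_m3"].group == "B1"
        assert out["B2_m3"].group == "B2"

    @staticmethod
    def make_family():
        rng = np.random.default_rng(9)
        seqs, _ = sd.generate_grouped_proteins(2, 3, seed=9, length=50)
        return seqs

    def test_planted_six_group_recovery(self):
        seqs, truth = sd.generate_grouped_proteins(6, 8, seed=17)
        refs = [(f"B{g}_m{m}", f"B{g}") for g in range(1, 7) for m in (1, 2)]
        msa = pg.center_star_msa(seqs)
        tree = pg.bootstrap_support(
            msa, 100, seed=17, tree=pg.neighbor_joining(pg.msa_distance_matrix(msa))
        )
        asg = pg.assign_groups(tree, refs)
        acc = np.mean([truth[a.protein_id] == a.group for a in asg])
        assert acc >= 0.95

    def test_missing_reference_rejected(self):
        dm, _ = sd.generate_additive_matrix(4, seed=0)
        tree = pg.neighbor_joining(dm)
        with pytest.raises(ValueError, match="absent"):
            pg.assign_groups(tree, [("nope", "B1")])

    def test_nearest_reference_fallback_deterministic(self):
        # star-ish tree with no supported clades: force fallback
        d = np.array(
            [
                [0.0, 0.5, 0.5, 0.5],
                [0.5, 0.0, 0.5, 0.5],
                [0.5, 0.5, 0.0, 0.5],
                [0.5, 0.5, 0.5, 0.0],
            ]
        )
        tree = pg.neighbor_joining(pg.DistanceMatrix(list("abcq"), d))
        tree.support = {bp: 0.0 for bp in tree.bipartitions()}
        out = pg.assign_groups(tree, [("a", "B1"), ("b", "B2")])
        q = next(x for x in out if x.protein_id == "q")
        assert q.evidence == "nearest-reference"
        assert q.group == "B1"   # lexicographic tie-break on reference id
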