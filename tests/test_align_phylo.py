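import itertools
import math

import numpy as np
import pytest
from skbio import DistanceMatrix

from dcsminer.align_phylo import (Alignment, alignment_distance,
                                  bipartitions, bootstrap_support,
                                  closer_to_group, is_monophyletic,
                                  match_mismatch_matrix, neighbor_joining,
                                  pairwise_align, poisson_distance,
                                  progressive_msa)
from dcsminer.seqio import ProteinRecord
from dcsminer import seqio
from oracles import additive_matrix_from_random_tree, brute_force_score


# ---------------------------------------------------------------- pairwise

class TestPairwiseAlign:
    def test_identical_sequences_score_diagonal_sum_no_gaps(self):
        matrix = match_mismatch_matrix(2.0, -1.0)
        alignment, score = pairwise_align("MKTDD", "MKTDD", matrix, 1, 1)
        assert score == 10.0
        assert alignment.rows == ("MKTDD", "MKTDD")

    def test_dd_vs_dad_matches_enumeration(self):
        matrix = match_mismatch_matrix(1.0, -1.0)
        alignment, score = pairwise_align("DD", "DAD", matrix,
                                          gap_open=1, gap_extend=1)
        oracle = brute_force_score("DD", "DAD",
                                   lambda x, y: 1.0 if x == y else -1.0, 1, 1)
        assert score == oracle == 0.0
        assert alignment.ungapped(0) == "DD"
        assert alignment.ungapped(1) == "DAD"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_align("", "MK")

    def test_matches_brute_force_on_short_reduced_alphabet_pairs(self):
        rng = np.random.default_rng(7)
        alphabet = "AGPW"
        matrix = match_mismatch_matrix(2.0, -3.0)

        def mfn(x, y):
            return 2.0 if x == y else -3.0

        seqs = ["".join(alphabet[k] for k in rng.integers(0, 4, rng.integers(1, 7)))
                for _ in range(14)]
        for a, b in itertools.combinations(seqs, 2):
            _, score = pairwise_align(a, b, matrix, gap_open=2, gap_extend=1)
            assert score == pytest.approx(
                brute_force_score(a, b, mfn, 2, 1)), (a, b)


# ---------------------------------------------------------------- MSA

class TestProgressiveMsa:
    def test_two_identical_sequences_align_gap_free(self):
        aln = progressive_msa([ProteinRecord("a", "MKTDD"),
                               ProteinRecord("b", "MKTDD")])
        assert aln.rows == ("MKTDD", "MKTDD")

    def test_internal_insertion_is_gapped_in_other_rows(self):
        base = "MKTLLVDDEWQRSTY"
        withins = base[:7] + "PPP" + base[7:]
        aln = progressive_msa([ProteinRecord("a", base),
                               ProteinRecord("b", withins),
                               ProteinRecord("c", base)])
        assert aln.n_cols == len(base) + 3
        by_id = dict(zip(aln.ids, aln.rows))
        assert by_id["a"].count("-") == 3
        assert by_id["b"].count("-") == 0
        for rec_id, seq in (("a", base), ("b", withins), ("c", base)):
            assert by_id[rec_id].replace("-", "") == seq

    def test_column_count_at_least_max_input_length(self):
        rng = np.random.default_rng(3)
        recs = [ProteinRecord(f"s{i}", "".join(
            "ACDEFGHIKL"[k] for k in rng.integers(0, 10, rng.integers(5, 30))))
            for i in range(6)]
        aln = progressive_msa(recs)
        assert aln.n_cols >= max(len(r) for r in recs)
        for i, rec_id in enumerate(aln.ids):
            original = next(r for r in recs if r.id == rec_id)
            assert aln.ungapped(i) == original.residues

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            progressive_msa([ProteinRecord("a", "MK"), ProteinRecord("a", "MK")])


# ---------------------------------------------------------------- distances

class TestPoissonDistance:
    def test_identical_rows_distance_zero(self):
        aln = Alignment(("a", "b"), ("MKTDD", "MKTDD"))
        assert poisson_distance(aln)[0, 1] == 0.0

    def test_ten_percent_mismatch_closed_form(self):
        rows = ("A" * 10, "A" * 9 + "C")
        d = poisson_distance(Alignment(("a", "b"), rows))[0, 1]
        assert d == pytest.approx(-math.log(0.9), abs=1e-5)
        assert d == pytest.approx(0.10536, abs=1e-4)

    def test_saturated_pair_capped_at_five(self):
        rows = ("A" * 50, "C" * 50)
        assert poisson_distance(Alignment(("a", "b"), rows))[0, 1] == 5.0

    def test_gap_columns_pairwise_deleted(self):
        rows = ("AAAA--", "AA--CC")
        # comparable columns: 1,2 -> p = 0
        assert poisson_distance(Alignment(("a", "b"), rows))[0, 1] == 0.0

    def test_no_comparable_columns_raises_naming_pair(self):
        rows = ("AA--", "--CC")
        with pytest.raises(ValueError, match="'a'.*'b'"):
            poisson_distance(Alignment(("a", "b"), rows))


# ---------------------------------------------------------------- NJ

class TestNeighborJoining:
    def test_recovers_known_four_taxon_tree_exactly(self):
        # unrooted tree ((A:1,B:2):1,C:3,D:4) -> path-sum matrix
        labels = ["A", "B", "C", "D"]
        lengths = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        internal = 1.0
        mat = np.zeros((4, 4))
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i == j:
                    continue
                # A,B on one side of the internal edge; C,D on the other
                same_side = {x, y} in ({"A", "B"}, {"C", "D"})
                mat[i, j] = lengths[x] + lengths[y] + (0.0 if same_side else internal)
        tree = neighbor_joining(DistanceMatrix(mat, labels))
        assert is_monophyletic(tree, {"A", "B"})
        dists = tree.tip_tip_distances()
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                got = dists[dists.index(x), dists.index(y)]
                assert got == pytest.approx(mat[i, j], abs=1e-9)

    def test_three_taxon_closed_form(self):
        mat = np.array([[0.0, 2.0, 3.0], [2.0, 0.0, 3.0], [3.0, 3.0, 0.0]])
        tree = neighbor_joining(DistanceMatrix(mat, ["A", "B", "C"]))
        assert tree.find("A").length == pytest.approx(1.0)
        assert tree.find("B").length == pytest.approx(1.0)
        assert tree.find("C").length == pytest.approx(2.0)

    def test_inverts_path_sum_matrices_of_random_trees(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            dm = additive_matrix_from_random_tree(n, rng)
            tree = neighbor_joining(dm)
            dists = tree.tip_tip_distances()
            for i in range(n):
                for j in range(n):
                    got = dists[dists.index(f"L{i}"), dists.index(f"L{j}")]
                    assert got == pytest.approx(dm[i, j], abs=1e-9)

    def test_label_permutation_gives_identical_tree(self):
        rng = np.random.default_rng(4)
        dm = additive_matrix_from_random_tree(6, rng)
        perm = rng.permutation(6)
        permuted = DistanceMatrix(dm.data[np.ix_(perm, perm)],
                                  [dm.ids[p] for p in perm])
        assert bipartitions(neighbor_joining(dm)) == \
            bipartitions(neighbor_joining(permuted))

    def test_matches_independent_nj_implementation_topology(self):
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(9)
        dm = additive_matrix_from_random_tree(7, rng)
        ours = neighbor_joining(dm)
        theirs = skbio_nj(dm)
        assert bipartitions(ours) == bipartitions(theirs.unroot())

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ["A", "B"])
        with pytest.raises(ValueError):
            neighbor_joining(dm)


# ---------------------------------------------------------------- bootstrap

TWO_CLUSTER_RECORDS = [
    ProteinRecord("A1", "MKTLLVDDEWQRSTYF" * 4),
    ProteinRecord("A2", "MKTLLVDDEWQRSTYF" * 4),
    ProteinRecord("B1", "GGHHPPRRSSNNIIKK" * 4),
    ProteinRecord("B2", "GGHHPPRRSSNNIIKK" * 4),
]


class TestBootstrap:
    def test_identical_pair_clusters_get_full_support(self):
        aln = progressive_msa(TWO_CLUSTER_RECORDS)
        tree = bootstrap_support(aln, replicates=100, seed=5)
        internal = [n for n in tree.traverse(include_self=False)
                    if not n.is_tip() and n.name]
        assert internal and all(n.name == "100" for n in internal)

    def test_single_replicate_supports_are_zero_or_one(self):
        aln = progressive_msa(TWO_CLUSTER_RECORDS)
        tree = bootstrap_support(aln, replicates=1, seed=1)
        supports = {int(n.name) for n in tree.traverse(include_self=False)
                    if not n.is_tip() and n.name}
        assert supports <= {0, 1}

    def test_same_seed_reproduces_supports(self):
        aln = progressive_msa(TWO_CLUSTER_RECORDS)
        t1 = bootstrap_support(aln, 25, seed=3)
        t2 = bootstrap_support(aln, 25, seed=3)
        assert seqio.newick_string(t1) == seqio.newick_string(t2)


# ---------------------------------------------------------------- monophyly

class TestMonophyly:
    def tree(self):
        return seqio.read_newick("((A:1,B:1):1,(C:1,D:1):1);")

    def test_true_and_false_bipartitions(self):
        t = self.tree()
        assert is_monophyletic(t, {"A", "B"})
        assert not is_monophyletic(t, {"A", "C"})

    def test_singleton_always_true(self):
        assert is_monophyletic(self.tree(), {"C"})

    def test_complement_symmetry(self):
        t = self.tree()
        leaves = {tip.name for tip in t.tips()}
        for subset in ({"A", "B"}, {"A", "C"}, {"A"}):
            assert is_monophyletic(t, subset) == \
                is_monophyletic(t, leaves - subset)

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            is_monophyletic(self.tree(), {"A", "Z"})


# ---------------------------------------------------------------- filter

class TestCloserToGroup:
    def test_identical_to_reference_sides(self):
        dtc = [ProteinRecord("d1", "MKTLLVDDEWQRSTYF" * 3)]
        shc = [ProteinRecord("s1", "GGHHPPRRSSNNIIKK" * 3)]
        assert closer_to_group(dtc[0], dtc, shc) == "DTC_LIKE"
        assert closer_to_group(shc[0], dtc, shc) == "SHC_LIKE"

    def test_tie_resolves_to_shc(self):
        ref = ProteinRecord("r", "MKTLLVDDEW")
        assert closer_to_group(ref, [ref], [ref]) == "SHC_LIKE"

    def test_empty_reference_set_raises(self):
        ref = ProteinRecord("r", "MKTLLVDDEW")
        with pytest.raises(ValueError):
            closer_to_group(ref, [], [ref])

    def test_synthetic_gb_instances_beat_shc_decoys(self):
        from dcsminer.synthetic_proteomes import (GB_TEMPLATE, SHC_TEMPLATE,
                                                  SyntheticSpec,
                                                  generate_proteome)
        dtc_refs = [ProteinRecord("gbref", GB_TEMPLATE)]
        shc_refs = [ProteinRecord("shcref", SHC_TEMPLATE)]
        spec = SyntheticSpec(n_dcs_intact=0, n_dcs_aberrant=0, n_ts_only=0,
                             n_dtc_only=10, n_shc_decoy=0, n_background=0,
                             template_identity=0.9, seed=13)
        records, _ = generate_proteome(spec)
        for rec in records:
            assert closer_to_group(rec, dtc_refs, shc_refs) == "DTC_LIKE"
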