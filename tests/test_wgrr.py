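import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from phagenick.motif import IUPACMotif, scan_genome, strand_stats
from phagenick.synthetic_data import FamilySpec, SimulationSpec, make_family
from phagenick.wgrr import (BBHMap, ProteinSet, WGRRMatrix,
                            best_bidirectional_hits, cluster_genomes,
                            cluster_motif_summary, pairwise_identity, wgrr,
                            wgrr_matrix)

BLOSUM62 = substitution_matrices.load("BLOSUM62")
OPEN, EXTEND = -11.0, -1.0


def gotoh_align(a, b):
    """Independent textbook affine-gap global DP (Gotoh), returning
    (score, identities, columns) from its own traceback."""
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a residue vs gap)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = OPEN + (i - 1) * EXTEND
    for j in range(1, m + 1):
        Y[0, j] = OPEN + (j - 1) * EXTEND
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + OPEN, X[i - 1, j] + EXTEND,
                          Y[i - 1, j] + OPEN)
            Y[i, j] = max(M[i, j - 1] + OPEN, X[i, j - 1] + OPEN,
                          Y[i, j - 1] + EXTEND)
    score = max(M[n, m], X[n, m], Y[n, m])
    # traceback for identities / columns
    i, j = n, m
    state = max((M[n, m], "M"), (X[n, m], "X"), (Y[n, m], "Y"))[1]
    identities = columns = 0
    while i > 0 or j > 0:
        columns += 1
        if state == "M":
            s = BLOSUM62[a[i - 1], b[j - 1]]
            identities += a[i - 1] == b[j - 1]
            prev = max((M[i - 1, j - 1], "M"), (X[i - 1, j - 1], "X"),
                       (Y[i - 1, j - 1], "Y"))[1]
            i, j, state = i - 1, j - 1, prev
        elif state == "X":
            cands = [(M[i - 1, j] + OPEN, "M"), (X[i - 1, j] + EXTEND, "X"),
                     (Y[i - 1, j] + OPEN, "Y")]
            state = max(cands)[1]
            i -= 1
        else:
            cands = [(M[i, j - 1] + OPEN, "M"), (X[i, j - 1] + OPEN, "X"),
                     (Y[i, j - 1] + EXTEND, "Y")]
            state = max(cands)[1]
            j -= 1
    return score, identities, columns


def random_protein(rng, n=60):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


class TestPairwiseIdentity:
    def test_identical_sequences(self, rng):
        p = random_protein(rng, 50)
        score, ident = pairwise_identity(p, p)
        assert ident == 1.0

    def test_dissimilar_sequences(self):
        _, ident = pairwise_identity("K" * 30, "D" * 30)
        assert ident == 0.0

    def test_textbook_pair_matches_dp_oracle(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        score, ident = pairwise_identity(a, b)
        o_score, o_id, o_cols = gotoh_align(a, b)
        assert score == pytest.approx(o_score)
        assert ident == pytest.approx(o_id / o_cols)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_pairs_match_dp_score(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_protein(rng, 40), random_protein(rng, 35)
        score, _ = pairwise_identity(a, b)
        assert score == pytest.approx(gotoh_align(a, b)[0])

    def test_invalid_characters_error(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            pairwise_identity("ACDE", "AC1E")

    def test_shorter_denominator_option(self):
        _, ident = pairwise_identity("MKV" * 20, "MKV" * 10,
                                     denominator="shorter")
        assert ident == 1.0


def protein_set(gid, seqs):
    return ProteinSet(genome_id=gid, proteins=[(f"{gid}_p{i}", s)
                                               for i, s in enumerate(seqs)])


class TestBBHAndWGRR:
    def test_identical_sets_all_pairs(self, rng):
        seqs = [random_protein(rng) for _ in range(5)]
        A, B = protein_set("a", seqs), protein_set("b", seqs)
        bbh = best_bidirectional_hits(A, B)
        assert len(bbh.pairs) == 5
        assert all(p[2] == 1.0 for p in bbh.pairs)
        assert wgrr(A, B) == pytest.approx(1.0)

    def test_disjoint_sets_no_pairs(self, rng):
        A = protein_set("a", [random_protein(rng) for _ in range(4)])
        B = protein_set("b", [random_protein(rng) for _ in range(4)])
        assert best_bidirectional_hits(A, B).pairs == []
        assert wgrr(A, B) == 0.0

    def test_subset_denominator_is_min(self, rng):
        seqs = [random_protein(rng) for _ in range(10)]
        A = protein_set("a", seqs[:5])
        B = protein_set("b", seqs)
        assert wgrr(A, B) == pytest.approx(1.0)

    def test_protein_order_permutation_invariance(self, rng):
        seqs_a = [random_protein(rng) for _ in range(6)]
        seqs_b = [random_protein(rng) for _ in range(4)] + seqs_a[:2]
        A = protein_set("a", seqs_a)
        B = protein_set("b", seqs_b)
        v = wgrr(A, B)
        perm = protein_set("a", seqs_a[::-1])
        assert wgrr(perm, B) == pytest.approx(v)

    def test_matches_bruteforce_oracle(self, rng):
        """wGRR via the BBH module equals an all-pairs loop written from
        the definition."""
        anc = [random_protein(rng, 50) for _ in range(6)]

        def mutate(s, n_sub):
            s = list(s)
            for pos in rng.choice(len(s), size=n_sub, replace=False):
                s[pos] = "W"
            return "".join(s)

        A = protein_set("a", anc)
        B = protein_set("b", [mutate(s, 3) for s in anc[:4]] +
                        [random_protein(rng, 50) for _ in range(2)])
        ids = np.zeros((len(A), len(B)))
        scores = np.zeros((len(A), len(B)))
        for i, (_, sa) in enumerate(A.proteins):
            for j, (_, sb) in enumerate(B.proteins):
                scores[i, j], ids[i, j] = pairwise_identity(sa, sb)
        total = 0.0
        for i in range(len(A)):
            j = scores[i].argmax()
            if scores[:, j].argmax() == i and ids[i, j] >= 0.35:
                total += ids[i, j]  # coverage is 1 here (equal lengths)
        assert wgrr(A, B) == pytest.approx(total / min(len(A), len(B)))


class TestClustering:
    def block_matrix(self):
        ids = [f"g{i}" for i in range(6)]
        v = np.full((6, 6), 0.05)
        v[:3, :3] = 0.8
        v[3:, 3:] = 0.8
        np.fill_diagonal(v, 1.0)
        return WGRRMatrix(genome_ids=ids, values=v)

    def test_two_blocks_recovered(self):
        assign, leaf_order = cluster_genomes(self.block_matrix(), cut=0.3)
        labels = [assign[f"g{i}"] for i in range(6)]
        assert labels[:3] == [1] * 3 and labels[3:] == [2] * 3
        assert sorted(leaf_order) == sorted(assign)

    def test_identical_genomes_single_cluster(self):
        m = WGRRMatrix(genome_ids=["a", "b", "c"], values=np.ones((3, 3)))
        assign, _ = cluster_genomes(m, cut=0.5)
        assert set(assign.values()) == {1}

    def test_cut_above_max_isolates_everything(self):
        assign, _ = cluster_genomes(self.block_matrix(), cut=0.9)
        assert len(set(assign.values())) == 6

    def test_single_genome(self):
        m = WGRRMatrix(genome_ids=["only"], values=np.ones((1, 1)))
        assign, order = cluster_genomes(m, cut=0.5)
        assert assign == {"only": 1} and order == ["only"]

    def test_matrix_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            WGRRMatrix(genome_ids=["a", "b"],
                       values=np.array([[1.0, 0.2], [0.4, 1.0]]))
        with pytest.raises(ValueError, match="0, 1"):
            WGRRMatrix(genome_ids=["a", "b"],
                       values=np.array([[1.0, 1.4], [1.4, 1.0]]))


class TestClusterMotifSummary:
    class Net:
        def __init__(self, net):
            self.net = net

    def test_contrast(self):
        assign = {"a": 1, "b": 1, "c": 2, "d": 2}
        stats = {"a": self.Net(10), "b": self.Net(8), "c": self.Net(1),
                 "d": self.Net(0)}
        s = cluster_motif_summary(assign, stats, "a")
        assert s["mean_net_inside"] == 9.0
        assert s["mean_net_outside"] == 0.5
        assert (s["n_inside"], s["n_outside"]) == (2, 2)

    def test_single_cluster_outside_na(self):
        assign = {"a": 1, "b": 1}
        stats = {"a": self.Net(3), "b": self.Net(5)}
        assert cluster_motif_summary(assign, stats, "a")["mean_net_outside"] is None

    def test_all_zero_nets(self):
        assign = {"a": 1, "b": 2}
        stats = {"a": self.Net(0), "b": self.Net(0)}
        s = cluster_motif_summary(assign, stats, "a")
        assert s["mean_net_inside"] == 0 and s["mean_net_outside"] == 0

    def test_missing_focal_errors(self):
        with pytest.raises(ValueError, match="focal"):
            cluster_motif_summary({"a": 1}, {"a": self.Net(0)}, "zzz")


class TestFamilyRecovery:
    def test_planted_clades_and_motif_contrast(self):
        """End-to-end parameter recovery on one simulated family."""
        spec = SimulationSpec(seed=4, family=FamilySpec(
            n_in_clade=5, n_outgroup=5, proteins_per_genome=8,
            protein_length=90))
        fam = make_family(spec)
        ids = sorted(fam.proteomes)
        matrix = wgrr_matrix([fam.proteomes[g] for g in ids])
        assign, _ = cluster_genomes(matrix, cut=0.5)
        groups = {}
        for gid, lab in assign.items():
            groups.setdefault(lab, set()).add(gid)
        assert sorted(map(sorted, groups.values())) == sorted(map(sorted, [
            {g for g, c in fam.truth.clade_assignment.items() if c == 1},
            {g for g, c in fam.truth.clade_assignment.items() if c == 2}]))
        motif = IUPACMotif("WACTRTGAC")
        stats = {gid: strand_stats(scan_genome(g, motif), g, motif)
                 for gid, g in fam.genomes.items()}
        summ = cluster_motif_summary(assign, stats, "clade00")
        assert summ["mean_net_inside"] > 5 * max(summ["mean_net_outside"], 0.2)
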