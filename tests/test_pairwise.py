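import math
import random

import pytest
from Bio.Align import substitution_matrices

from p74kit.chimera import OrfRecord
from p74kit.pairwise import (
    AlignmentParams,
    compare,
    domain_matrix,
    global_align,
    identity_similarity,
)
from p74kit.simulate import FamilySpec, OrfSpec, simulate_family, simulate_orf

B62 = substitution_matrices.load("BLOSUM62")


def enumeration_oracle(a, b, open_=10.0, extend=0.5):
    """Exhaustive enumeration of all global alignments (affine gaps:
    a gap of length L costs open + (L-1)*extend)."""
    best = -math.inf

    def rec(i, j, last, score):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + B62[a[i], b[j]])
        if i < len(a):
            rec(i + 1, j, "A", score - (extend if last == "A" else open_))
        if j < len(b):
            rec(i, j + 1, "B", score - (extend if last == "B" else open_))

    rec(0, 0, "M", 0.0)
    return best


def gotoh_oracle(a, b, open_=10.0, extend=0.5):
    """Independent affine-gap DP (Gotoh three-state recurrence)."""
    n, m = len(a), len(b)
    NEG = -math.inf
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                s = B62[a[i - 1], b[j - 1]]
                M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                              Y[i - 1][j - 1]) + s
            if i > 0:
                X[i][j] = max(M[i - 1][j] - open_, X[i - 1][j] - extend,
                              Y[i - 1][j] - open_)
            if j > 0:
                Y[i][j] = max(M[i][j - 1] - open_, X[i][j - 1] - open_,
                              Y[i][j - 1] - extend)
    return max(M[n][m], X[n][m], Y[n][m])


ALPHABET = "ACDE"


class TestGlobalAlign:
    def test_identical_sequences_gapless_self_score(self):
        seq = "MKWVLCDEAG"
        pair = global_align(seq, seq)
        assert pair.a_gapped == pair.b_gapped == seq
        assert pair.score == sum(B62[c, c] for c in seq)

    def test_symmetry_of_score(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        assert global_align(a, b).score == global_align(b, a).score

    def test_known_pair_matches_oracles(self):
        a, b = "HEAGAWGH", "PAWHEA"
        score = global_align(a, b).score
        assert score == gotoh_oracle(a, b)
        assert score == enumeration_oracle(a, b)

    @pytest.mark.parametrize("seed", range(4))
    def test_score_equals_enumeration_oracle_small(self, seed):
        rng = random.Random(seed)
        for _ in range(6):
            a = "".join(rng.choice(ALPHABET)
                        for _ in range(rng.randint(1, 6)))
            b = "".join(rng.choice(ALPHABET)
                        for _ in range(rng.randint(1, 6)))
            score = global_align(a, b).score
            assert score == enumeration_oracle(a, b), (a, b)
            assert score == gotoh_oracle(a, b), (a, b)

    def test_gotoh_matches_package_to_length8(self):
        rng = random.Random(42)
        for _ in range(12):
            a = "".join(rng.choice(ALPHABET) for _ in range(rng.randint(7, 8)))
            b = "".join(rng.choice(ALPHABET) for _ in range(rng.randint(7, 8)))
            assert global_align(a, b).score == gotoh_oracle(a, b), (a, b)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            global_align("", "MAV")

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            AlignmentParams(gap_open=0.1, gap_extend=0.5)


class TestIdentitySimilarity:
    def test_self_comparison_is_100_100(self):
        res = compare("MKWVLCDEAGMKWVLCDEAG" * 2 + "MKWVLCDEAG", "MKWVLCDEAG" * 5)
        assert res.identity_pct == 100.0 and res.similarity_pct == 100.0

    def test_single_mismatch_blosum_zero_not_similar(self):
        # BLOSUM62(A, V) = 0, so V/A counts neither identical nor similar
        pair = global_align("AAAA", "AAAV")
        res = identity_similarity(pair)
        assert pair.a_gapped == "AAAA" and pair.b_gapped == "AAAV"
        assert res.identity_pct == 75.0
        assert res.similarity_pct == 75.0

    def test_positive_substitution_counts_as_similar(self):
        # BLOSUM62(I, L) = +2
        res = identity_similarity(global_align("AAIA", "AALA"))
        assert res.identity_pct == 75.0
        assert res.similarity_pct == 100.0

    def test_group_definition(self):
        params = AlignmentParams(similarity_def="group")
        res = identity_similarity(global_align("AAIA", "AALA"), params)
        assert res.similarity_pct == 100.0  # I,L share strong group MILV

    def test_gap_columns_in_denominator(self):
        pair = global_align("MKWVLCDEAG", "MKWVCDEAG")  # forces one gap
        res = identity_similarity(pair)
        assert res.alignment_length == 10
        assert res.aligned_pairs == 9
        assert res.identity_pct == 90.0

    def test_length_mismatch_rejected(self):
        from p74kit.pairwise import AlignedPair

        with pytest.raises(ValueError, match="differ"):
            identity_similarity(AlignedPair("a", "b", "MAV", "MA", 0.0))


class TestDomainMatrix:
    def _orfs(self):
        a, _ = simulate_orf(OrfSpec(length=60, wdp_positions=[20],
                                    d_codon_choice="GAC", seed=21, id="A"))
        b, _ = simulate_orf(OrfSpec(length=60, wdp_positions=[20],
                                    d_codon_choice="GAT", seed=22, id="B"))
        return a, b

    def test_identical_sequences_all_cells_100(self):
        a, _ = self._orfs()
        b = OrfRecord("B", a.cds)
        dm = domain_matrix([a, b])
        for region in ("complete", "nt", "ct"):
            for res in dm.results[region].values():
                assert res.identity_pct == 100.0
                assert res.similarity_pct == 100.0

    def test_diagonal_and_symmetry(self):
        a, b = self._orfs()
        dm = domain_matrix([a, b])
        for region in ("complete", "nt", "ct"):
            frame = dm.frame(region)
            assert frame.loc["A", "A"] == 100.0
            assert frame.loc["A", "B"] == frame.loc["B", "A"]

    def test_sequence_without_wdp_excluded_with_warning(self):
        a, _ = self._orfs()
        no_wdp = OrfRecord("nowdp", "ATGGCCGCAGCGTAA")
        with pytest.warns(UserWarning, match="nowdp"):
            dm = domain_matrix([a, no_wdp])
        assert dm.excluded == ["nowdp"]
        assert dm.ids == ["A"]

    def test_fragments_split_at_own_triad(self):
        a, b = self._orfs()
        dm = domain_matrix([a, b])
        res = dm.results["nt"][("A", "A")]
        assert res.alignment_length == 20  # Nt ends at the D, codon 20

    def test_generator_known_mutation_identity(self):
        # gap-free homologs: identity of template vs mutant equals
        # 100 * (1 - mutated_columns / length) when alignment is gapless
        spec = FamilySpec(n_sequences=2, length=120, seed=33,
                          strong_sub_rate=0.05, weak_sub_rate=0.0,
                          random_sub_rate=0.05)
        aln, truth = simulate_family(spec)
        s1, s2 = (r.residues for r in aln.records)
        pair = global_align(s1, s2)
        if "-" not in pair.a_gapped and "-" not in pair.b_gapped:
            diffs = sum(x != y for x, y in zip(s1, s2))
            res = identity_similarity(pair)
            assert res.identity_pct == pytest.approx(
                100.0 * (1 - diffs / 120)
            )
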