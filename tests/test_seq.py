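"""Alignment, cysteine windows, shuffled backgrounds, composition, motif-x."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from prxmap.seq import (
    CysteineWindow,
    aa_composition_enrichment,
    extract_all_windows,
    extract_cys_windows,
    motif_x,
    needleman_wunsch_align,
    pairwise_similarity_matrix,
    shuffle_background,
)
from prxmap.synthetic import AMINO_ACIDS

B62 = substitution_matrices.load("BLOSUM62")


def brute_force_alignment_score(a, b, gap_open=10.0, gap_extend=0.5):
    """Exhaustive enumeration of every global alignment.

    A gap run of length L costs gap_open + (L-1)*gap_extend unless it sits
    at either end of the alignment (free end gaps).  The end condition is
    local: a gap in b is terminal iff 0 or all of b has been consumed, and
    symmetrically for gaps in a.
    """
    la, lb = len(a), len(b)
    best = -np.inf

    def rec(i, j, score, state):
        nonlocal best
        if i == la and j == lb:
            best = max(best, score)
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, score + B62[a[i]][b[j]], "M")
        if i < la:  # gap in b
            if j == 0 or j == lb:
                cost = 0.0
            else:
                cost = gap_extend if state == "X" else gap_open
            rec(i + 1, j, score - cost, "X")
        if j < lb:  # gap in a
            if i == 0 or i == la:
                cost = 0.0
            else:
                cost = gap_extend if state == "Y" else gap_open
            rec(i, j + 1, score - cost, "Y")

    rec(0, 0, 0.0, None)
    return best


def _random_seq(rng, length):
    return "".join(rng.choice(list(AMINO_ACIDS), length))


class TestAlignment:
    def test_identical_sequences_full_identity_and_similarity(self):
        res = needleman_wunsch_align("ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKLMNPQRSTVWY")
        assert res.identity_pct == 100.0
        assert res.similarity_pct == 100.0

    def test_scores_match_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            a = _random_seq(rng, rng.integers(1, 7))
            b = _random_seq(rng, rng.integers(1, 7))
            got = needleman_wunsch_align(a, b).score
            want = brute_force_alignment_score(a, b)
            assert got == pytest.approx(want, abs=1e-9), (a, b)

    def test_scores_match_biopython_on_longer_pairs(self):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = B62
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
        rng = np.random.default_rng(1)
        for _ in range(30):
            a = _random_seq(rng, rng.integers(5, 60))
            b = _random_seq(rng, rng.integers(5, 60))
            got = needleman_wunsch_align(a, b).score
            assert got == pytest.approx(aligner.score(a, b), abs=1e-9)

    def test_similarity_at_least_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = _random_seq(rng, 25)
            b = _random_seq(rng, 25)
            res = needleman_wunsch_align(a, b)
            assert 0 <= res.identity_pct <= res.similarity_pct <= 100

    def test_score_consistent_with_alignment_reevaluation(self):
        rng = np.random.default_rng(3)
        a, b = _random_seq(rng, 30), _random_seq(rng, 24)
        res = needleman_wunsch_align(a, b)
        score = 0.0
        run_char, run_len, runs = None, 0, []
        for ca, cb in zip(res.aligned_a, res.aligned_b):
            if ca != "-" and cb != "-":
                score += B62[ca][cb]
            gap_side = "a" if ca == "-" else ("b" if cb == "-" else None)
            if gap_side == run_char and gap_side is not None:
                run_len += 1
            else:
                if run_char is not None:
                    runs.append((run_char, run_len))
                run_char, run_len = gap_side, 1 if gap_side else 0
        if run_char is not None:
            runs.append((run_char, run_len))
        cols = list(zip(res.aligned_a, res.aligned_b))
        # charge interior runs only (free end gaps)
        pos = 0
        interior_cost = 0.0
        i = 0
        while i < len(cols):
            ca, cb = cols[i]
            if ca == "-" or cb == "-":
                j = i
                side = "a" if ca == "-" else "b"
                while j < len(cols) and (cols[j][0] == "-" if side == "a" else cols[j][1] == "-"):
                    j += 1
                if i > 0 and j < len(cols):
                    interior_cost += 10.0 + 0.5 * (j - i - 1)
                i = j
            else:
                i += 1
        assert res.score == pytest.approx(score - interior_cost, abs=1e-9)

    def test_unknown_residue_position_named(self):
        with pytest.raises(ValueError, match="position 3"):
            needleman_wunsch_align("ACXD", "ACD")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            needleman_wunsch_align("", "ACD")

    def test_pairwise_matrix_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(4)
        seqs = {f"PRDX{i}": _random_seq(rng, 40) for i in range(1, 6)}
        m = pairwise_similarity_matrix(seqs)
        np.testing.assert_allclose(np.diag(m.to_numpy()), 100.0)
        np.testing.assert_allclose(m.to_numpy(), m.to_numpy().T, atol=1e-9)
        # recomposition: entries equal fresh per-pair calls
        got = m.loc["PRDX1", "PRDX2"]
        want = needleman_wunsch_align(seqs["PRDX1"], seqs["PRDX2"]).similarity_pct
        assert got == want


class TestWindows:
    def test_central_window_spans_whole_string(self):
        ws = extract_cys_windows("AAAACAAAA", protein_id="p")
        assert len(ws) == 1
        assert ws[0].window == "AAAACAAAA"
        assert ws[0].position == 5

    def test_left_terminal_padding(self):
        ws = extract_cys_windows("CAAAA")
        assert ws[0].window == "----CAAAA"

    def test_no_cysteine_no_windows(self):
        assert extract_cys_windows("AAAA") == []

    def test_centers_hold_cysteine_in_source(self):
        rng = np.random.default_rng(5)
        seq = _random_seq(rng, 200)
        for w in extract_cys_windows(seq, protein_id="p"):
            assert seq[w.position - 1] == "C"
            assert w.window[4] == "C"

    def test_window_must_be_centered(self):
        with pytest.raises(ValueError):
            CysteineWindow("p", 1, "AAAAAAAAA")


class TestShuffleBackground:
    def test_single_residue_type_identical_to_foreground(self):
        seqs = {"p": "CCCCCCCCC"}
        bg = shuffle_background(seqs, n_shuffles=3, seed=0)
        fg = extract_all_windows(seqs)
        assert {w.window for w in bg} == {w.window for w in fg}

    def test_composition_conserved_per_shuffle(self):
        rng = np.random.default_rng(6)
        seqs = {"p": _random_seq(rng, 80) + "C"}
        bg = shuffle_background(seqs, n_shuffles=1, seed=1)
        assert bg  # the cysteine persists somewhere
        # shuffling conserves the residue multiset, checked via one shuffle
        from prxmap.seq import PAD
        import numpy as np2

        chars = np2.frombuffer(seqs["p"].encode(), dtype="S1")
        shuffled_chars = np2.random.default_rng([1, 53]).permutation(chars)
        assert sorted(chars) == sorted(shuffled_chars)

    def test_background_flank_frequencies_approach_composition(self):
        """Flanking-residue frequencies in the shuffled background converge
        to the sequence's own composition (law of large numbers)."""
        rng = np.random.default_rng(7)
        seqs = {f"p{i}": _random_seq(rng, 500) for i in range(20)}
        seqs = {k: v if "C" in v else v[:-1] + "C" for k, v in seqs.items()}
        bg = shuffle_background(seqs, n_shuffles=100, seed=2)
        counts = {aa: 0 for aa in AMINO_ACIDS}
        total = 0
        for w in bg:
            for k, ch in enumerate(w.window):
                if k == 4 or ch == "-":
                    continue
                counts[ch] += 1
                total += 1
        overall = "".join(seqs.values())
        for aa in AMINO_ACIDS:
            if aa == "C":
                continue  # centers absorb cysteines
            expected = overall.count(aa) / len(overall)
            assert abs(counts[aa] / total - expected) <= 0.01


class TestCompositionEnrichment:
    def _windows(self, strings):
        return [CysteineWindow("p", 5, s) for s in strings]

    def test_identical_sets_give_unit_folds_and_no_hits(self):
        rng = np.random.default_rng(8)
        strings = [
            "".join(rng.choice(list(AMINO_ACIDS), 9)) for _ in range(1500)
        ]
        strings = [s[:4] + "C" + s[5:] for s in strings]
        fg = self._windows(strings)
        out = aa_composition_enrichment(fg, fg)
        assert (np.abs(out["fold"] - 1.0) < 0.01).all()
        assert (out["q"] >= 0.05).all()

    def test_planted_double_arginine_recovered(self):
        """2x arginine planted in the foreground shows fold in [1.8, 2.2]
        with q < 0.05 at 2000 windows."""
        rng = np.random.default_rng(9)

        def draw(p_r):
            probs = np.full(20, (1 - p_r) / 19)
            probs[AMINO_ACIDS.index("R")] = p_r
            s = "".join(rng.choice(list(AMINO_ACIDS), 9, p=probs))
            return s[:4] + "C" + s[5:]

        base_r = 1 / 20
        fg = self._windows([draw(2 * base_r) for _ in range(2000)])
        ctrl = self._windows([draw(base_r) for _ in range(2000)])
        out = aa_composition_enrichment(fg, ctrl).set_index("residue")
        assert 1.8 <= out.loc["R", "fold"] <= 2.2
        assert out.loc["R", "q"] < 0.05

    def test_residue_absent_everywhere_neutral(self):
        fg = self._windows(["AAAACAAAA"] * 50)
        out = aa_composition_enrichment(fg, fg).set_index("residue")
        assert out.loc["W", "fold"] == pytest.approx(1.0)
        assert out.loc["W", "p"] == pytest.approx(1.0)

    def test_empty_sets_rejected(self):
        fg = self._windows(["AAAACAAAA"])
        with pytest.raises(ValueError):
            aa_composition_enrichment(fg, [])


class TestMotifX:
    def _windows(self, strings):
        return [CysteineWindow("p", 5, s) for s in strings]

    def _uniform(self, rng, n):
        out = []
        for _ in range(n):
            s = "".join(rng.choice(list(AMINO_ACIDS), 9))
            out.append(s[:4] + "C" + s[5:])
        return out

    def test_identical_sets_give_no_motifs(self):
        rng = np.random.default_rng(10)
        fg = self._windows(self._uniform(rng, 400))
        assert motif_x(fg, fg) == []

    def test_planted_two_position_motif_recovered(self):
        """R at -3 and E at +2 planted jointly in 30% of foreground windows
        are both fixed by the greedy search."""
        rng = np.random.default_rng(11)
        fg_strings = self._uniform(rng, 1000)
        planted = []
        for k, s in enumerate(fg_strings):
            if k < 300:
                s = s[:1] + "R" + s[2:6] + "E" + s[7:]
            planted.append(s)
        fg = self._windows(planted)
        ctrl = self._windows(self._uniform(rng, 2000))
        motifs = motif_x(fg, ctrl, min_support=10, p_fix=1e-4)
        assert motifs, "planted motif not found"
        top = motifs[0]
        assert top.pattern.get(-3) == "R"
        assert top.pattern.get(2) == "E"
        assert top.support >= 250

    def test_min_support_larger_than_foreground_gives_nothing(self):
        rng = np.random.default_rng(12)
        fg = self._windows(self._uniform(rng, 5))
        ctrl = self._windows(self._uniform(rng, 100))
        assert motif_x(fg, ctrl, min_support=10) == []

    def test_mixed_window_lengths_rejected(self):
        from types import SimpleNamespace

        good = CysteineWindow("p", 5, "AAAACAAAA")
        short = SimpleNamespace(window="AAACAAA")  # malformed upstream input
        with pytest.raises(ValueError, match="length"):
            motif_x([good], [good, short], min_support=1)

    def test_reported_motifs_self_consistent(self):
        """Each returned motif re-tests significant and supported when its
        fixing steps are replayed from scratch."""
        from scipy.stats import binom as sp_binom

        rng = np.random.default_rng(13)
        fg_strings = self._uniform(rng, 600)
        fg_strings = [
            (s[:1] + "R" + s[2:]) if k < 200 else s for k, s in enumerate(fg_strings)
        ]
        fg = self._windows(fg_strings)
        ctrl = self._windows(self._uniform(rng, 1200))
        remaining = [w.window for w in fg]
        for motif in motif_x(fg, ctrl, min_support=10, p_fix=1e-4):
            assert motif.support >= 10
            fgw = list(remaining)
            ctw = [w.window for w in ctrl]
            for offset, residue, p_reported in motif.steps:
                pos = offset + 4
                k = sum(w[pos] == residue for w in fgw)
                n = sum(w[pos] != "-" for w in fgw)
                ct_k = sum(w[pos] == residue for w in ctw)
                ct_n = sum(w[pos] != "-" for w in ctw)
                p_bg = (ct_k + 0.5) / (ct_n + 1.0)
                p = float(sp_binom.sf(k - 1, n, p_bg))
                assert p == pytest.approx(p_reported, rel=1e-9)
                assert p < 1e-4
                fgw = [w for w in fgw if w[pos] == residue]
                ctw = [w for w in ctw if w[pos] == residue]
            remaining = [
                w
                for w in remaining
                if not all(w[off + 4] == res for off, res in motif.pattern.items())
            ]
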