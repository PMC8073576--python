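"""Cysteine-centered sequence analyses.

Covers four related tasks:

* global protein alignment (affine-gap Needleman-Wunsch with free end
  gaps, BLOSUM62) with needle-style identity/similarity percentages;
* extraction of 9-residue windows centered on every cysteine, the unit
  of all flanking-residue statistics;
* composition-preserving shuffled backgrounds;
* amino-acid composition enrichment and greedy iterative motif discovery
  (motif-x style) of foreground windows against a control window set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy.stats import binom, binomtest
from statsmodels.stats.multitest import multipletests

from .synthetic import AMINO_ACIDS

PAD = "-"
WINDOW = 9
CENTER = WINDOW // 2

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


# ---------------------------------------------------------------------------
# global alignment


@dataclass
class AlignmentResult:
    """Optimal global alignment of two protein sequences."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    similarity_pct: float

    @property
    def length(self) -> int:
        return len(self.aligned_a)


def _validate_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    for pos, ch in enumerate(seq):
        if ch not in AMINO_ACIDS:
            raise ValueError(f"{name}: unknown residue {ch!r} at position {pos + 1}")


def needleman_wunsch_align(
    seq_a: str,
    seq_b: str,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Affine-gap global alignment with unpenalized end gaps.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend`` except at
    either end of the alignment, where gaps are free (needle's default
    ``endweight false`` semantics).  Ties are broken deterministically:
    diagonal (match state), then up (gap in ``seq_b``), then left.

    Identity is the percentage of alignment columns with equal residues;
    similarity the percentage with a positive substitution score (gaps
    and end gaps count toward the length of the alignment).
    """
    if matrix is None:
        matrix = _BLOSUM62
    _validate_sequence(seq_a, "seq_a")
    _validate_sequence(seq_b, "seq_b")
    n, m = len(seq_a), len(seq_b)
    NEG = -np.inf

    sub = np.empty((n, m))
    for i, ca in enumerate(seq_a):
        for j, cb in enumerate(seq_b):
            sub[i, j] = matrix[ca][cb]

    # states: M diagonal, X gap in seq_b (consume a / "up"), Y gap in seq_a ("left")
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    X[1:, 0] = 0.0  # leading gap in b is free
    Y[0, 1:] = 0.0  # leading gap in a is free
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i, j] = sub[i - 1, j - 1] + max(
                M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]
            )
            X[i, j] = max(
                M[i - 1, j] - gap_open,
                X[i - 1, j] - gap_extend,
                Y[i - 1, j] - gap_open,
            )
            Y[i, j] = max(
                M[i, j - 1] - gap_open,
                X[i, j - 1] - gap_open,
                Y[i, j - 1] - gap_extend,
            )

    def best_state(i: int, j: int) -> tuple[float, str]:
        # tie-break order: diagonal, up, left
        for val, state in ((M[i, j], "M"), (X[i, j], "X"), (Y[i, j], "Y")):
            if val >= max(M[i, j], X[i, j], Y[i, j]):
                return val, state
        return M[i, j], "M"  # unreachable

    # free trailing gaps: end anywhere on the last row/column
    score, end_i, end_j = NEG, n, m
    for i in range(n, -1, -1):
        v, _ = best_state(i, m)
        if v > score:
            score, end_i, end_j = v, i, m
    for j in range(m, -1, -1):
        v, _ = best_state(n, j)
        if v > score:
            score, end_i, end_j = v, n, j

    al_a: list[str] = []
    al_b: list[str] = []
    # trailing unconsumed residues align to free end gaps
    for i in range(n, end_i, -1):
        al_a.append(seq_a[i - 1])
        al_b.append(PAD)
    for j in range(m, end_j, -1):
        al_a.append(PAD)
        al_b.append(seq_b[j - 1])

    i, j = end_i, end_j
    _, state = best_state(i, j)
    while i > 0 or j > 0:
        if i == 0:
            al_a.append(PAD)
            al_b.append(seq_b[j - 1])
            j -= 1
            continue
        if j == 0:
            al_a.append(seq_a[i - 1])
            al_b.append(PAD)
            i -= 1
            continue
        if state == "M":
            al_a.append(seq_a[i - 1])
            al_b.append(seq_b[j - 1])
            prev = sub[i - 1, j - 1]
            target = M[i, j] - prev
            i, j = i - 1, j - 1
            for val, st in ((M[i, j], "M"), (X[i, j], "X"), (Y[i, j], "Y")):
                if np.isclose(val, target):
                    state = st
                    break
        elif state == "X":
            al_a.append(seq_a[i - 1])
            al_b.append(PAD)
            target = X[i, j]
            i -= 1
            options = (
                (M[i, j] - gap_open, "M"),
                (X[i, j] - gap_extend, "X"),
                (Y[i, j] - gap_open, "Y"),
            )
            if i == 0 and np.isclose(0.0, target):
                state = "X0"  # reached the free leading-gap column
            else:
                for val, st in options:
                    if np.isclose(val, target):
                        state = st
                        break
        elif state == "Y":
            al_a.append(PAD)
            al_b.append(seq_b[j - 1])
            target = Y[i, j]
            j -= 1
            options = (
                (M[i, j] - gap_open, "M"),
                (X[i, j] - gap_open, "X"),
                (Y[i, j] - gap_extend, "Y"),
            )
            if j == 0 and np.isclose(0.0, target):
                state = "Y0"
            else:
                for val, st in options:
                    if np.isclose(val, target):
                        state = st
                        break
        elif state == "X0":  # free leading gap in b: consume the rest of a
            al_a.append(seq_a[i - 1])
            al_b.append(PAD)
            i -= 1
        else:  # Y0: free leading gap in a
            al_a.append(PAD)
            al_b.append(seq_b[j - 1])
            j -= 1

    aligned_a = "".join(reversed(al_a))
    aligned_b = "".join(reversed(al_b))
    length = len(aligned_a)
    matches = sum(a == b and a != PAD for a, b in zip(aligned_a, aligned_b))
    similar = sum(
        a != PAD and b != PAD and matrix[a][b] > 0
        for a, b in zip(aligned_a, aligned_b)
    )
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(score),
        identity_pct=100.0 * matches / length,
        similarity_pct=100.0 * similar / length,
    )


def pairwise_similarity_matrix(seqs: Mapping[str, str], **kwargs) -> pd.DataFrame:
    """Symmetric similarity-percentage table over all sequence pairs."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    names = list(seqs)
    out = pd.DataFrame(100.0, index=names, columns=names)
    for a_i in range(len(names)):
        for b_i in range(a_i + 1, len(names)):
            a, b = names[a_i], names[b_i]
            res = needleman_wunsch_align(seqs[a], seqs[b], **kwargs)
            out.loc[a, b] = out.loc[b, a] = res.similarity_pct
    return out


# ---------------------------------------------------------------------------
# cysteine windows


@dataclass(frozen=True)
class CysteineWindow:
    protein_id: str
    position: int  # 1-based cysteine position in the source sequence
    window: str  # length 9, '-' padded beyond termini

    def __post_init__(self):
        if len(self.window) != WINDOW or self.window[CENTER] != "C":
            raise ValueError("window must be 9 residues centered on C")


def extract_cys_windows(
    seq: str, protein_id: str = "", half_width: int = 4
) -> list[CysteineWindow]:
    """One +/-half_width window per cysteine, '-' padded at the termini."""
    padded = PAD * half_width + seq + PAD * half_width
    out = []
    for pos, ch in enumerate(seq):
        if ch == "C":
            start = pos  # == pos + half_width - half_width in padded coords
            out.append(
                CysteineWindow(
                    protein_id=protein_id,
                    position=pos + 1,
                    window=padded[start : start + 2 * half_width + 1],
                )
            )
    return out


def extract_all_windows(seqs: Mapping[str, str]) -> list[CysteineWindow]:
    out: list[CysteineWindow] = []
    for pid, seq in seqs.items():
        out.extend(extract_cys_windows(seq, protein_id=pid))
    return out


def shuffle_background(
    seqs: Mapping[str, str], n_shuffles: int = 100, seed: int = 0
) -> list[CysteineWindow]:
    """Composition-preserving shuffled-sequence background windows.

    Each sequence is independently permuted ``n_shuffles`` times and the
    cysteine windows of every shuffle are re-extracted, destroying any
    positional structure while keeping per-protein residue usage.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng([int(seed), 53])
    out: list[CysteineWindow] = []
    for pid, seq in seqs.items():
        chars = np.frombuffer(seq.encode(), dtype="S1")
        for k in range(n_shuffles):
            shuffled = rng.permutation(chars).tobytes().decode()
            out.extend(extract_cys_windows(shuffled, protein_id=f"{pid}|shuffle{k}"))
    return out


def _flank_counts(windows: Sequence[CysteineWindow]) -> tuple[dict[str, int], int]:
    """Residue counts over flanking positions (center and pads excluded)."""
    counts = {aa: 0 for aa in AMINO_ACIDS}
    total = 0
    for w in windows:
        for k, ch in enumerate(w.window):
            if k == CENTER or ch == PAD:
                continue
            counts[ch] += 1
            total += 1
    return counts, total


def aa_composition_enrichment(
    fg_windows: Sequence[CysteineWindow],
    ctrl_windows: Sequence[CysteineWindow],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Fold enrichment of each residue in foreground vs control flanks.

    Frequencies use additive smoothing (``pseudocount`` per residue); the
    two-sided p-value comes from a binomial test of the foreground count
    against the (smoothed) control frequency, BH-adjusted over the 20
    residues.
    """
    if not fg_windows or not ctrl_windows:
        raise ValueError("foreground and control window sets must be non-empty")
    fg_counts, fg_total = _flank_counts(fg_windows)
    ctrl_counts, ctrl_total = _flank_counts(ctrl_windows)
    denom = pseudocount * len(AMINO_ACIDS)
    rows = []
    for aa in AMINO_ACIDS:
        f_fg = (fg_counts[aa] + pseudocount) / (fg_total + denom)
        f_ctrl = (ctrl_counts[aa] + pseudocount) / (ctrl_total + denom)
        fold = f_fg / f_ctrl
        p = binomtest(fg_counts[aa], fg_total, p=f_ctrl, alternative="two-sided").pvalue
        rows.append({"residue": aa, "fold": fold, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# motif-x


@dataclass
class Motif:
    """A fixed-position motif over the 9-residue cysteine window.

    ``pattern`` maps offsets (-4..4, 0 = the central C) to residues; the
    center is always fixed to C.  ``score`` is the motif-x score, the sum
    of -log10(p) over the fixing steps.
    """

    pattern: dict[int, str]
    support: int
    fold_enrichment: float
    score: float
    steps: list[tuple[int, str, float]] = field(default_factory=list)

    def matches(self, window: str) -> bool:
        return all(window[off + CENTER] == res for off, res in self.pattern.items())

    def label(self) -> str:
        chars = ["."] * WINDOW
        chars[CENTER] = "C"
        for off, res in self.pattern.items():
            chars[off + CENTER] = res
        return "".join(chars)


def _position_counts(windows: Sequence[str], pos: int) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {aa: 0 for aa in AMINO_ACIDS}
    total = 0
    for w in windows:
        ch = w[pos]
        if ch != PAD:
            counts[ch] += 1
            total += 1
    return counts, total


def motif_x(
    fg_windows: Sequence[CysteineWindow],
    ctrl_windows: Sequence[CysteineWindow],
    min_support: int = 10,
    p_fix: float = 1e-4,
) -> list[Motif]:
    """Greedy iterative motif discovery against a control window set.

    Repeatedly finds the (position, residue) pair with the smallest
    one-sided binomial p-value of its foreground occurrence given the
    control frequency; if ``p < p_fix`` with at least ``min_support``
    matching windows, the pair is fixed, both window sets are filtered to
    matching windows, and the search recurses.  When no further pair can
    be fixed, the motif (if any position was fixed) is emitted, its
    matching windows are removed from the foreground, and the search
    restarts.  Ties break deterministically by (p, position, residue).
    """
    lengths = {len(w.window) for w in list(fg_windows) + list(ctrl_windows)}
    if lengths and lengths != {WINDOW}:
        raise ValueError(f"mixed window lengths: {sorted(lengths)}")
    fg = [w.window for w in fg_windows]
    ctrl_all = [w.window for w in ctrl_windows]
    motifs: list[Motif] = []

    while True:
        fgw = list(fg)
        ctw = list(ctrl_all)
        n_fg_start = len(fgw)
        pattern: dict[int, str] = {}
        steps: list[tuple[int, str, float]] = []
        while True:
            best = None  # (p, pos, residue, k)
            for pos in range(WINDOW):
                if pos == CENTER or pos in pattern:
                    continue
                fg_counts, fg_total = _position_counts(fgw, pos)
                ct_counts, ct_total = _position_counts(ctw, pos)
                for aa in AMINO_ACIDS:
                    k = fg_counts[aa]
                    if k < min_support:
                        continue
                    p_bg = (ct_counts[aa] + 0.5) / (ct_total + 1.0) if ct_total else 0.5
                    p = float(binom.sf(k - 1, fg_total, p_bg))
                    if p < p_fix:
                        cand = (p, pos, aa, k)
                        if best is None or cand[:3] < best[:3]:
                            best = cand
            if best is None:
                break
            p, pos, aa, _k = best
            pattern[pos] = aa
            steps.append((pos - CENTER, aa, p))
            fgw = [w for w in fgw if w[pos] == aa]
            ctw = [w for w in ctw if w[pos] == aa]
        if not pattern:
            break
        support = len(fgw)
        motif = Motif(
            pattern={pos - CENTER: aa for pos, aa in pattern.items()},
            support=support,
            fold_enrichment=_motif_fold(pattern, n_fg_start, support, ctrl_all),
            score=float(sum(-np.log10(max(p, 1e-300)) for _, _, p in steps)),
            steps=steps,
        )
        motifs.append(motif)
        fg = [w for w in fg if not all(w[pos] == aa for pos, aa in pattern.items())]
        if not fg:
            break
    return motifs


def _motif_fold(
    pattern: dict[int, str], n_fg: int, support: int, ctrl: Sequence[str]
) -> float:
    n_ctrl_match = sum(
        all(w[pos] == aa for pos, aa in pattern.items()) for w in ctrl
    )
    fg_frac = support / n_fg if n_fg else 0.0
    ctrl_frac = (n_ctrl_match + 0.5) / (len(ctrl) + 1.0) if ctrl else 0.5
    return fg_frac / ctrl_frac


def window_frame(windows: Iterable[CysteineWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [(w.protein_id, w.position, w.window) for w in windows],
        columns=["protein_id", "position", "window"],
    )
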