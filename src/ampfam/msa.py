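"""Progressive multiple sequence alignment of a peptide family.

Optional preprocessing before restrictive-property mining: families can be
aligned so that the envelope test sees gap-consistent sequences.  The
scheme is the classic one — affine-gap Needleman–Wunsch pairwise scores,
a UPGMA guide tree on score-derived distances, then profile–profile
merges up the tree with sum-of-pairs column scoring.

Scoring defaults to BLOSUM62 with gap open -10 and gap extend -1 (a gap
of length g costs ``gap_open + (g-1)*gap_extend``).  Traceback ties break
deterministically: diagonal, then up (gap in the second sequence), then
left.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

from .io_formats import Peptide

GAP = "-"

_NEG_INF = float("-inf")


def load_substitution_matrix(name: str = "BLOSUM62") -> dict[tuple[str, str], float]:
    mat = substitution_matrices.load(name)
    out: dict[tuple[str, str], float] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            out[(a, b)] = float(mat[a, b])
    return out


@dataclass
class Alignment:
    """Gapped rows keyed by peptide id plus the guide tree that built them."""

    rows: dict[str, str]
    guide_tree: object  # nested tuples of ids

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def degapped(self, pid: str) -> str:
        return self.rows[pid].replace(GAP, "")


def pairwise_global_align(
    a: str,
    b: str,
    matrix: dict[tuple[str, str], float] | None = None,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> tuple[float, tuple[str, str]]:
    """Optimal affine-gap global alignment of two sequences (Gotoh).

    Returns the score and one optimal aligned pair; traceback ties prefer
    diagonal over a gap in ``b`` over a gap in ``a``, making the output
    deterministic.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if matrix is None:
        matrix = load_substitution_matrix()
    n, m = len(a), len(b)
    # M: a[i] aligned to b[j]; X: gap in b (consume a); Y: gap in a (consume b)
    M = np.full((n + 1, m + 1), _NEG_INF)
    X = np.full((n + 1, m + 1), _NEG_INF)
    Y = np.full((n + 1, m + 1), _NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[(a[i - 1], b[j - 1])]
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(
                M[i - 1, j] + gap_open,
                X[i - 1, j] + gap_extend,
                Y[i - 1, j] + gap_open,
            )
            Y[i, j] = max(
                M[i, j - 1] + gap_open,
                Y[i, j - 1] + gap_extend,
                X[i, j - 1] + gap_open,
            )
    score = max(M[n, m], X[n, m], Y[n, m])

    # traceback; tie order: M (diagonal), X (up), Y (left)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    state = max(
        (("M", M[n, m]), ("X", X[n, m]), ("Y", Y[n, m])),
        key=lambda kv: (kv[1], {"M": 2, "X": 1, "Y": 0}[kv[0]]),
    )[0]
    while i > 0 or j > 0:
        if state == "M":
            s = matrix[(a[i - 1], b[j - 1])]
            prev = M[i, j] - s
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            for cand, val in (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])):
                if np.isclose(val, prev):
                    state = cand
                    break
        elif state == "X":
            cur = X[i, j]
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
            if i == 0 and j == 0:
                break
            for cand, val in (
                ("M", M[i, j] + gap_open),
                ("X", X[i, j] + gap_extend),
                ("Y", Y[i, j] + gap_open),
            ):
                if np.isclose(val, cur):
                    state = cand
                    break
        else:  # Y
            cur = Y[i, j]
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
            if i == 0 and j == 0:
                break
            for cand, val in (
                ("M", M[i, j] + gap_open),
                ("Y", Y[i, j] + gap_extend),
                ("X", X[i, j] + gap_open),
            ):
                if np.isclose(val, cur):
                    state = cand
                    break
    return float(score), ("".join(reversed(out_a)), "".join(reversed(out_b)))


def build_guide_tree(
    peptides: list[Peptide],
    matrix: dict[tuple[str, str], float] | None = None,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
):
    """UPGMA guide tree from pairwise alignment scores.

    Scores are turned into distances by ``d = s_max - s`` where ``s_max``
    is the largest pairwise score; merge ties break on the smaller id
    pair, so the tree is deterministic for a given input order of ids.
    Returns nested tuples of peptide ids.
    """
    if len(peptides) < 2:
        raise ValueError("need at least 2 peptides for a guide tree")
    if matrix is None:
        matrix = load_substitution_matrix()
    ids = [p.id for p in peptides]
    seqs = {p.id: p.sequence for p in peptides}
    score: dict[frozenset, float] = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            s, _ = pairwise_global_align(
                seqs[ids[i]], seqs[ids[j]], matrix, gap_open, gap_extend
            )
            score[frozenset((ids[i], ids[j]))] = s
    s_max = max(score.values())
    dist = {k: s_max - v for k, v in score.items()}

    # UPGMA on clusters; leaves keep their insertion order for tie-breaks
    clusters: list[tuple[object, list[str]]] = [(pid, [pid]) for pid in ids]
    d: dict[tuple[int, int], float] = {}
    index = {pid: k for k, pid in enumerate(ids)}

    def cdist(la: list[str], lb: list[str]) -> float:
        return float(
            np.mean([dist[frozenset((x, y))] for x in la for y in lb])
        )

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dd = cdist(clusters[i][1], clusters[j][1])
                if best is None or dd < best[0] - 1e-12:
                    best = (dd, i, j)
        _, i, j = best
        node = (clusters[i][0], clusters[j][0])
        members = clusters[i][1] + clusters[j][1]
        clusters = (
            [c for k, c in enumerate(clusters) if k not in (i, j)]
            + [(node, members)]
        )
    return clusters[0][0]


def _profile_align(
    rows_a: dict[str, str],
    rows_b: dict[str, str],
    matrix: dict[tuple[str, str], float],
    gap_open: float,
    gap_extend: float,
) -> dict[str, str]:
    """Align two gapped blocks column-wise (sum-of-pairs, affine gaps)."""
    a_ids, b_ids = list(rows_a), list(rows_b)
    A = [rows_a[i] for i in a_ids]
    B = [rows_b[i] for i in b_ids]
    n, m = len(A[0]), len(B[0])

    def col_score(i: int, j: int) -> float:
        tot = 0.0
        cnt = 0
        for ra in A:
            for rb in B:
                x, y = ra[i], rb[j]
                if x == GAP or y == GAP:
                    tot += gap_extend if not (x == GAP and y == GAP) else 0.0
                else:
                    tot += matrix[(x, y)]
                cnt += 1
        return tot / cnt

    M = np.full((n + 1, m + 1), _NEG_INF)
    X = np.full((n + 1, m + 1), _NEG_INF)
    Y = np.full((n + 1, m + 1), _NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = col_score(i - 1, j - 1)
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(
                M[i - 1, j] + gap_open,
                X[i - 1, j] + gap_extend,
                Y[i - 1, j] + gap_open,
            )
            Y[i, j] = max(
                M[i, j - 1] + gap_open,
                Y[i, j - 1] + gap_extend,
                X[i, j - 1] + gap_open,
            )
    # traceback (same tie order as pairwise)
    ops: list[str] = []
    i, j = n, m
    state = max(
        (("M", M[n, m]), ("X", X[n, m]), ("Y", Y[n, m])),
        key=lambda kv: (kv[1], {"M": 2, "X": 1, "Y": 0}[kv[0]]),
    )[0]
    while i > 0 or j > 0:
        if state == "M" and i > 0 and j > 0:
            s = col_score(i - 1, j - 1)
            prev = M[i, j] - s
            ops.append("M")
            i, j = i - 1, j - 1
            for cand, val in (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])):
                if np.isclose(val, prev):
                    state = cand
                    break
        elif state == "X" or j == 0:
            cur = X[i, j]
            ops.append("X")
            i -= 1
            if i == 0 and j == 0:
                break
            for cand, val in (
                ("M", M[i, j] + gap_open),
                ("X", X[i, j] + gap_extend),
                ("Y", Y[i, j] + gap_open),
            ):
                if np.isclose(val, cur):
                    state = cand
                    break
        else:
            cur = Y[i, j]
            ops.append("Y")
            j -= 1
            if i == 0 and j == 0:
                break
            for cand, val in (
                ("M", M[i, j] + gap_open),
                ("Y", Y[i, j] + gap_extend),
                ("X", X[i, j] + gap_open),
            ):
                if np.isclose(val, cur):
                    state = cand
                    break
    ops.reverse()

    out: dict[str, str] = {pid: [] for pid in a_ids + b_ids}
    i = j = 0
    for op in ops:
        if op == "M":
            for pid, row in zip(a_ids, A):
                out[pid].append(row[i])
            for pid, row in zip(b_ids, B):
                out[pid].append(row[j])
            i += 1
            j += 1
        elif op == "X":
            for pid, row in zip(a_ids, A):
                out[pid].append(row[i])
            for pid in b_ids:
                out[pid].append(GAP)
            i += 1
        else:
            for pid in a_ids:
                out[pid].append(GAP)
            for pid, row in zip(b_ids, B):
                out[pid].append(row[j])
            j += 1
    return {pid: "".join(chars) for pid, chars in out.items()}


def progressive_align(
    peptides: list[Peptide],
    matrix: dict[tuple[str, str], float] | None = None,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> Alignment:
    """Align a family progressively along its UPGMA guide tree."""
    if len(peptides) < 2:
        raise ValueError("need at least 2 peptides to align")
    if matrix is None:
        matrix = load_substitution_matrix()
    seqs = {p.id: p.sequence for p in peptides}
    tree = build_guide_tree(peptides, matrix, gap_open, gap_extend)

    def merge(node) -> dict[str, str]:
        if isinstance(node, str):
            return {node: seqs[node]}
        left, right = node
        return _profile_align(
            merge(left), merge(right), matrix, gap_open, gap_extend
        )

    rows = merge(tree)
    rows = {p.id: rows[p.id] for p in peptides}  # restore input order
    return Alignment(rows=rows, guide_tree=tree)


def read_alignment(path: str | Path) -> Alignment:
    """Escape hatch: load a pre-computed alignment from aligned FASTA."""
    rows = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }
    if not rows:
        raise ValueError(f"{path}: no alignment records")
    return Alignment(rows=rows, guide_tree=tuple(rows))


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, row in alignment.rows.items():
            fh.write(f">{pid}\n{row}\n")
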