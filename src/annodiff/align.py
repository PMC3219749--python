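"""Global pairwise protein alignment with affine gap penalties.

A Gotoh-style three-state dynamic program under the scoring model

    score = sum of substitution-matrix terms
            - sum over gaps of (gap_open + (len - 1) * gap_extend)

i.e. the first residue of a gap costs ``gap_open`` and each further residue
``gap_extend``.  Defaults are BLOSUM62 with gap_open 12 / gap_extend 2, the
conventional settings of EMBOSS-style global aligners.  Traceback is
deterministic: on score ties the diagonal move is preferred, then the
vertical (gap in the second sequence), then the horizontal.

Identity is the fraction of alignment columns with identical residues and
similarity the fraction with a positive substitution score; gap columns
count toward the alignment length but toward neither numerator.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import substitution_matrices

__all__ = ["AlignmentStats", "global_align", "load_matrix"]

NEG_INF = float("-inf")

_MATRIX_CACHE: dict[str, dict[tuple[str, str], float]] = {}


def load_matrix(name: str = "BLOSUM62") -> dict[tuple[str, str], float]:
    """A substitution matrix as a plain {(a, b): score} mapping."""
    if name not in _MATRIX_CACHE:
        m = substitution_matrices.load(name)
        d = {}
        for x in m.alphabet:
            for y in m.alphabet:
                d[(x, y)] = float(m[x, y])
        _MATRIX_CACHE[name] = d
    return _MATRIX_CACHE[name]


@dataclass
class AlignmentStats:
    """Metrics of one global alignment (identity/similarity in percent)."""

    score: float
    identity: float
    similarity: float
    gaps: int  # number of gap positions (columns containing a gap)
    length: int  # alignment length in columns
    aligned1: str
    aligned2: str

    def __post_init__(self) -> None:
        assert 0.0 <= self.identity <= self.similarity <= 100.0 + 1e-9
        assert self.gaps <= self.length


def _check_alphabet(seq: str, matrix: dict, which: str) -> None:
    alpha = {a for a, _ in matrix}
    for ch in seq:
        if ch not in alpha:
            raise ValueError(
                f"symbol {ch!r} in sequence {which} is outside the "
                "substitution-matrix alphabet"
            )


def global_align(
    p1: str,
    p2: str,
    matrix: str | dict = "BLOSUM62",
    gap_open: float = 12.0,
    gap_extend: float = 2.0,
) -> AlignmentStats:
    """Optimal global alignment of two non-empty protein sequences."""
    if not p1 or not p2:
        raise ValueError("global_align requires two non-empty sequences")
    sub = load_matrix(matrix) if isinstance(matrix, str) else matrix
    _check_alphabet(p1, sub, "1")
    _check_alphabet(p2, sub, "2")

    n, m = len(p1), len(p2)
    # state matrices: M ends in a match column, X in a gap consuming p1
    # (vertical / "up"), Y in a gap consuming p2 (horizontal / "left")
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + (j - 1) * gap_extend)

    for i in range(1, n + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        a = p1[i - 1]
        for j in range(1, m + 1):
            s = sub[(a, p2[j - 1])]
            Mi[j] = max(Mp[j - 1], Xp[j - 1], Yp[j - 1]) + s
            Xi[j] = max(Mp[j] - gap_open, Xp[j] - gap_extend, Yp[j] - gap_open)
            Yi[j] = max(Mi[j - 1] - gap_open, Xi[j - 1] - gap_open,
                        Yi[j - 1] - gap_extend)

    # deterministic traceback: prefer M (diagonal), then X (up), then Y (left)
    def best_state(i: int, j: int) -> str:
        if i == 0 and j == 0:
            return "M"
        cands = (("M", M[i][j]), ("X", X[i][j]), ("Y", Y[i][j]))
        top = max(v for _, v in cands)
        for name, v in cands:
            if v == top:
                return name
        raise AssertionError

    score = max(M[n][m], X[n][m], Y[n][m])
    i, j = n, m
    state = best_state(n, m)
    out1: list[str] = []
    out2: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            prev_vals = (
                ("M", M[i - 1][j - 1]),
                ("X", X[i - 1][j - 1]),
                ("Y", Y[i - 1][j - 1]),
            )
            target = max(v for _, v in prev_vals)
            state = next(name for name, v in prev_vals if v == target)
            out1.append(p1[i - 1])
            out2.append(p2[j - 1])
            i, j = i - 1, j - 1
        elif state == "X":
            target = X[i][j]
            if M[i - 1][j] - gap_open == target:
                state = "M"
            elif X[i - 1][j] - gap_extend == target:
                state = "X"
            else:
                state = "Y"
            out1.append(p1[i - 1])
            out2.append("-")
            i -= 1
        else:  # Y
            target = Y[i][j]
            if M[i][j - 1] - gap_open == target:
                state = "M"
            elif X[i][j - 1] - gap_open == target:
                state = "X"
            else:
                state = "Y"
            out1.append("-")
            out2.append(p2[j - 1])
            j -= 1
        if i == 0 and j == 0:
            break

    a1 = "".join(reversed(out1))
    a2 = "".join(reversed(out2))
    length = len(a1)
    ident = sum(1 for x, y in zip(a1, a2) if x == y and x != "-")
    simil = sum(
        1
        for x, y in zip(a1, a2)
        if x != "-" and y != "-" and sub[(x, y)] > 0
    )
    gaps = sum(1 for x, y in zip(a1, a2) if x == "-" or y == "-")
    return AlignmentStats(
        score=score,
        identity=100.0 * ident / length,
        similarity=100.0 * simil / length,
        gaps=gaps,
        length=length,
        aligned1=a1,
        aligned2=a2,
    )
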