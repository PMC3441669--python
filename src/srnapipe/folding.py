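"""RNA secondary-structure folding with a simple base-pair energy model.

The folder computes the maximum-pairing-energy nested (pseudoknot-free)
structure by dynamic programming, with per-pair energies

    G:C = -3.0 kcal/mol,  A:U = -2.0 kcal/mol,  G:U = -1.0 kcal/mol

and a minimum hairpin loop of 3 unpaired bases.  This is a deliberately
transparent stand-in for a full nearest-neighbour thermodynamic engine: it
is deterministic, exhaustively verifiable on short sequences, and fast
enough to fold every candidate precursor window.  Any callable with the
same contract (sequence -> (dot-bracket, mfe)) can be plugged in instead,
e.g. a wrapper around a thermodynamic folder.

The reported MFE is always the energy of the returned structure, and is 0
exactly when the structure has no pairs.

Tie-break: among equal-energy structures the traceback pairs the earliest
unresolved 5' position whenever pairing it achieves the optimum, choosing
its outermost admissible partner.  This makes the dot-bracket output a
pure function of the sequence and keeps long stems intact when
equal-energy local hairpins exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


from ._seq import to_rna

MIN_LOOP = 3

# Pair scores (positive; MFE = -score).  Indexed by base codes A=0 C=1 G=2 U=3.
_PAIR_SCORE = np.zeros((4, 4), dtype=np.int64)
_PAIR_SCORE[2, 1] = _PAIR_SCORE[1, 2] = 3  # G:C
_PAIR_SCORE[0, 3] = _PAIR_SCORE[3, 0] = 2  # A:U
_PAIR_SCORE[2, 3] = _PAIR_SCORE[3, 2] = 1  # G:U

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass(frozen=True)
class FoldResult:
    """A folded sequence: dot-bracket structure and its energy (kcal/mol)."""

    sequence: str
    structure: str
    mfe: float

    def pairs(self) -> list[tuple[int, int]]:
        """0-based (i, j) base pairs recovered from the dot-bracket string."""
        stack: list[int] = []
        out: list[tuple[int, int]] = []
        for idx, ch in enumerate(self.structure):
            if ch == "(":
                stack.append(idx)
            elif ch == ")":
                out.append((stack.pop(), idx))
        out.sort()
        return out


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string to integer base codes, raising on bad symbols."""
    rna = to_rna(seq)
    try:
        return np.array([_CODE[c] for c in rna], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r} in sequence") from None


@njit(cache=True)
def _fill(codes, pair_score, min_loop):  # pragma: no cover - jit-compiled
    n = codes.shape[0]
    w = np.zeros((n + 1, n + 1), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = w[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                s = pair_score[codes[i], codes[k]]
                if s > 0:
                    cand = s + w[i + 1, k - 1] + w[k + 1, j]
                    if cand > best:
                        best = cand
            w[i, j] = best
    return w


def _fill_python(codes: np.ndarray) -> np.ndarray:
    n = len(codes)
    w = np.zeros((n + 1, n + 1), dtype=np.int64)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = w[i + 1, j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                s = _PAIR_SCORE[codes[i], codes[k]]
                if s > 0:
                    cand = s + w[i + 1, k - 1] + w[k + 1, j]
                    if cand > best:
                        best = cand
            w[i, j] = best
    return w


def _traceback(codes: np.ndarray, w: np.ndarray) -> list[tuple[int, int]]:
    n = len(codes)
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        target = w[i, j]
        paired = False
        # Prefer pairing the earliest 5' position, with its outermost
        # admissible partner: equal-energy alternatives that close small
        # loops are avoided, which keeps long stems intact.
        for k in range(j, i + MIN_LOOP, -1):
            s = _PAIR_SCORE[codes[i], codes[k]]
            if s > 0 and s + w[i + 1, k - 1] + w[k + 1, j] == target:
                pairs.append((i, k))
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    return pairs


def fold(sequence: str, engine=None) -> FoldResult:
    """Fold an RNA sequence to its minimum-energy nested structure.

    Parameters
    ----------
    sequence : str
        RNA or DNA string (T and U are equivalent); any length >= 1.
    engine : callable, optional
        Replacement folding engine with signature
        ``engine(rna_string) -> (dot_bracket, mfe)``; when given, the
        default pairing-energy model is bypassed.
    """
    rna = to_rna(sequence)
    if engine is not None:
        structure, mfe = engine(rna)
        return FoldResult(rna, structure, float(mfe))
    codes = encode(rna)
    n = len(codes)
    if n <= MIN_LOOP + 1:
        return FoldResult(rna, "." * n, 0.0)
    if _HAVE_NUMBA:
        w = _fill(codes, _PAIR_SCORE, MIN_LOOP)
    else:
        w = _fill_python(codes)
    pairs = _traceback(codes, w)
    structure = ["."] * n
    for i, j in pairs:
        structure[i] = "("
        structure[j] = ")"
    mfe = -float(w[0, n - 1])
    return FoldResult(rna, "".join(structure), mfe if mfe != 0 else 0.0)


def structure_energy(sequence: str, structure: str) -> float:
    """Independent energy of a dot-bracket structure under the pair model.

    Raises ValueError on unbalanced brackets, non-canonical pairs, or loops
    shorter than the minimum.
    """
    codes = encode(sequence)
    if len(structure) != len(codes):
        raise ValueError("structure length does not match sequence")
    stack: list[int] = []
    score = 0
    for j, ch in enumerate(structure):
        if ch == "(":
            stack.append(j)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            i = stack.pop()
            if j - i - 1 < MIN_LOOP:
                raise ValueError(f"hairpin loop shorter than {MIN_LOOP} at ({i},{j})")
            s = _PAIR_SCORE[codes[i], codes[j]]
            if s == 0:
                raise ValueError(f"non-canonical pair at ({i},{j})")
            score += s
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced structure")
    return -float(score)
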