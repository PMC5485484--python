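"""RNA secondary-structure prediction for miRNA precursor hairpins.

Minimum-free-energy folding by a Zuker-style dynamic program over a
reduced nearest-neighbor energy model:

* Watson-Crick (AU, UA, CG, GC) and wobble (GU, UG) pairs, with a 6x6
  stacking-energy table;
* hairpin, bulge and interior-loop penalties that depend on loop size
  (Jacobson-Stockmayer logarithmic extrapolation beyond tabulated sizes),
  interior loops additionally pay an asymmetry penalty;
* multibranch loops scored with a linear model (closing penalty plus a
  per-branch term, unpaired bases free);
* no pseudoknots; terminal loops hold at least 3 nt; interior/bulge loops
  are capped at ``MAXLOOP`` unpaired nucleotides in total.

All energies are handled internally as integer tenths of kcal/mol so the
dynamic program, the loop-decomposition scorer (:func:`structure_energy`)
and the exhaustive small-sequence solver (:func:`brute_force_mfe`) agree
exactly, with no floating-point ties.  Absolute MFE values are
model-dependent; they are comparable within this package, not with other
folding engines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "HairpinStructure",
    "fold",
    "structure_energy",
    "enumerate_structures",
    "brute_force_mfe",
    "MAXLOOP",
    "MIN_HAIRPIN_LOOP",
]

INF = 1 << 40
MAXLOOP = 30          # max unpaired nt in a bulge/interior loop
MIN_HAIRPIN_LOOP = 3  # min unpaired nt in a terminal loop

_BASES = {"A": 0, "C": 1, "G": 2, "U": 3}

# pair codes: CG=0 GC=1 AU=2 UA=3 GU=4 UG=5; -1 = not pairable
_PAIR_IDX = -np.ones((4, 4), dtype=np.int64)
for _k, (_a, _b) in enumerate([(1, 2), (2, 1), (0, 3), (3, 0), (2, 3), (3, 2)]):
    _PAIR_IDX[_a, _b] = _k

# stacking energies, tenths of kcal/mol; rows: outer (closing) pair,
# cols: inner pair stacked 3' of it
_STACK = np.array(
    [
        # CG    GC    AU    UA    GU    UG
        [-33, -24, -21, -21, -14, -21],  # outer CG
        [-34, -33, -22, -24, -15, -25],  # outer GC
        [-24, -21, -11, -9, -6, -14],    # outer AU
        [-22, -21, -13, -11, -10, -13],  # outer UA
        [-25, -21, -14, -13, -5, -5],    # outer GU
        [-14, -15, -6, -10, -3, -5],     # outer UG
    ],
    dtype=np.int64,
)

_MULTI_CLOSE = 34   # multiloop closing penalty
_MULTI_BRANCH = 4   # per branch (incl. the closing pair)
_MULTI_UNPAIRED = 0

_HAIRPIN_TAB = {3: 54, 4: 56, 5: 57, 6: 58, 7: 59, 8: 60, 9: 61}
_BULGE_TAB = {1: 38, 2: 28, 3: 32, 4: 36, 5: 40, 6: 44}
_INTERNAL_TAB = {2: 15, 3: 20, 4: 25, 5: 28, 6: 30}


def _extrapolate(base: int, size: int, ref: int) -> int:
    return base + int(round(17.5 * math.log(size / ref)))


@lru_cache(maxsize=4096)
def hairpin_penalty(size: int) -> int:
    if size < MIN_HAIRPIN_LOOP:
        return INF
    if size in _HAIRPIN_TAB:
        return _HAIRPIN_TAB[size]
    return _extrapolate(61, size, 9)


@lru_cache(maxsize=4096)
def bulge_penalty(size: int) -> int:
    if size < 1 or size > MAXLOOP:
        return INF
    if size in _BULGE_TAB:
        return _BULGE_TAB[size]
    return _extrapolate(44, size, 6)


@lru_cache(maxsize=4096)
def internal_penalty(l1: int, l2: int) -> int:
    total = l1 + l2
    if l1 < 1 or l2 < 1 or total > MAXLOOP:
        return INF
    base = _INTERNAL_TAB[total] if total in _INTERNAL_TAB else _extrapolate(30, total, 6)
    return base + min(30, 5 * abs(l1 - l2))


def _two_loop_penalty(l1: int, l2: int) -> int:
    """Penalty for the loop between two pairs with l1/l2 unpaired nt per side."""
    if l1 == 0 and l2 == 0:
        return INF  # a stack, scored from the stacking table instead
    if l1 == 0 or l2 == 0:
        return bulge_penalty(l1 + l2)
    return internal_penalty(l1, l2)


# precomputed (MAXLOOP+1)^2 bulge/interior penalty matrix for the DP
_ILP = np.full((MAXLOOP + 1, MAXLOOP + 1), INF, dtype=np.int64)
for _l1 in range(MAXLOOP + 1):
    for _l2 in range(MAXLOOP + 1):
        if 1 <= _l1 + _l2 <= MAXLOOP:
            _ILP[_l1, _l2] = _two_loop_penalty(_l1, _l2)


def encode(sequence: str) -> np.ndarray:
    """Map an RNA/DNA string to integer codes (T is read as U)."""
    seq = sequence.upper().replace("T", "U")
    try:
        return np.array([_BASES[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGU symbol in sequence: {exc.args[0]!r}") from None


@dataclass
class HairpinStructure:
    """A folded sequence: dot-bracket string, MFE and the pairing map."""

    sequence: str
    structure: str
    mfe: float                       # kcal/mol
    pairs: dict[int, int] = field(repr=False)  # symmetric partner map
    loop_span: tuple[int, int] | None = None   # unique terminal loop, if any

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise ValueError("structure/sequence length mismatch")
        if self.loop_span is None:
            loops = self.hairpin_loops()
            if len(loops) == 1:
                self.loop_span = loops[0]

    def partner(self, i: int) -> int | None:
        return self.pairs.get(i)

    def hairpin_loops(self) -> list[tuple[int, int]]:
        """Half-open spans of unpaired stretches closed by a single pair."""
        loops = []
        for i, j in sorted(self.pairs.items()):
            if i < j and all(k not in self.pairs for k in range(i + 1, j)):
                loops.append((i + 1, j))
        return loops

    @property
    def n_pairs(self) -> int:
        return len(self.pairs) // 2


def _pairs_to_dotbracket(n: int, pairs: list[tuple[int, int]]) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return "".join(db)


def _fill(enc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fill the Zuker V / WM / external-W arrays."""
    n = len(enc)
    pidx = _PAIR_IDX[enc[:, None], enc[None, :]]
    V = np.full((n, n), INF, dtype=np.int64)
    WM = np.full((n, n), INF, dtype=np.int64)
    for d in range(4, n):
        for i in range(n - d):
            j = i + d
            pi = pidx[i, j]
            best = INF
            if pi >= 0:
                best = hairpin_penalty(d - 1)
                inner = pidx[i + 1, j - 1]
                if d >= 6 and inner >= 0 and V[i + 1, j - 1] < INF:
                    best = min(best, int(_STACK[pi, inner]) + int(V[i + 1, j - 1]))
                l1m = min(MAXLOOP, n - 2 - i)
                l2m = min(MAXLOOP, j - 1)
                if l1m >= 0 and l2m >= 0:
                    sub = V[i + 1 : i + 2 + l1m, j - 1 - l2m : j][:, ::-1]
                    cand = int((sub + _ILP[: l1m + 1, : l2m + 1]).min())
                    best = min(best, cand)
                if d >= 6:
                    a = WM[i + 1, i + 1 : j - 2]
                    b = WM[i + 2 : j - 1, j - 1]
                    if a.size:
                        ml = int((a + b).min())
                        if ml < INF:
                            best = min(best, _MULTI_CLOSE + _MULTI_BRANCH + ml)
                V[i, j] = best
            wm = INF
            if best < INF:
                wm = best + _MULTI_BRANCH
            wm = min(wm, int(WM[i + 1, j]) + _MULTI_UNPAIRED if WM[i + 1, j] < INF else INF)
            if WM[i, j - 1] < INF:
                wm = min(wm, int(WM[i, j - 1]) + _MULTI_UNPAIRED)
            a = WM[i, i : j]
            b = WM[i + 1 : j + 1, j]
            if a.size:
                sp = int((a + b).min())
                if sp < INF:
                    wm = min(wm, sp)
            WM[i, j] = wm
    W = np.zeros(n + 1, dtype=np.int64)
    for j in range(n):
        w = W[j]
        if j >= 4:
            vals = W[: j - 3] + V[: j - 3, j]
            w = min(w, int(vals.min()))
        W[j + 1] = w
    return V, WM, W, pidx


def _traceback(enc: np.ndarray, V, WM, W, pidx) -> list[tuple[int, int]]:
    n = len(enc)
    pairs: list[tuple[int, int]] = []
    stack: list[tuple[str, int, int]] = [("W", 0, n - 1)]
    while stack:
        kind, i, j = stack.pop()
        if kind == "W":
            # external segment enc[i..j]; W is cumulative so re-derive greedily
            jj = j
            while jj >= i:
                if W[jj + 1] == W[jj]:
                    jj -= 1
                    continue
                found = False
                for k in range(i, jj - 3):
                    if W[k] + V[k, jj] == W[jj + 1]:
                        pairs.append((k, jj))
                        stack.append(("V", k, jj))
                        jj = k - 1
                        found = True
                        break
                if not found:  # pragma: no cover - defensive
                    raise AssertionError("external traceback failed")
        elif kind == "V":
            e = V[i, j]
            pi = pidx[i, j]
            if e == hairpin_penalty(j - i - 1):
                continue
            inner = pidx[i + 1, j - 1]
            if (
                j - i >= 6
                and inner >= 0
                and V[i + 1, j - 1] < INF
                and e == _STACK[pi, inner] + V[i + 1, j - 1]
            ):
                pairs.append((i + 1, j - 1))
                stack.append(("V", i + 1, j - 1))
                continue
            hit = False
            for l1 in range(min(MAXLOOP, n - 2 - i) + 1):
                for l2 in range(min(MAXLOOP, j - 1) + 1):
                    ip, jp = i + 1 + l1, j - 1 - l2
                    if jp - ip < 4 or V[ip, jp] >= INF:
                        continue
                    pen = _ILP[l1, l2]
                    if pen < INF and e == pen + V[ip, jp]:
                        pairs.append((ip, jp))
                        stack.append(("V", ip, jp))
                        hit = True
                        break
                if hit:
                    break
            if hit:
                continue
            for k in range(i + 2, j - 1):
                if (
                    WM[i + 1, k - 1] < INF
                    and WM[k, j - 1] < INF
                    and e == _MULTI_CLOSE + _MULTI_BRANCH + WM[i + 1, k - 1] + WM[k, j - 1]
                ):
                    stack.append(("M", i + 1, k - 1))
                    stack.append(("M", k, j - 1))
                    hit = True
                    break
            if not hit:  # pragma: no cover - defensive
                raise AssertionError("V traceback failed")
        else:  # WM
            e = WM[i, j]
            if V[i, j] < INF and e == V[i, j] + _MULTI_BRANCH:
                pairs.append((i, j))
                stack.append(("V", i, j))
                continue
            if WM[i + 1, j] < INF and e == WM[i + 1, j] + _MULTI_UNPAIRED:
                stack.append(("M", i + 1, j))
                continue
            if WM[i, j - 1] < INF and e == WM[i, j - 1] + _MULTI_UNPAIRED:
                stack.append(("M", i, j - 1))
                continue
            hit = False
            for k in range(i + 1, j + 1):
                if WM[i, k - 1] < INF and WM[k, j] < INF and e == WM[i, k - 1] + WM[k, j]:
                    stack.append(("M", i, k - 1))
                    stack.append(("M", k, j))
                    hit = True
                    break
            if not hit:  # pragma: no cover - defensive
                raise AssertionError("WM traceback failed")
    return pairs


def fold(sequence: str) -> HairpinStructure:
    """Fold ``sequence`` and return its minimum-free-energy structure.

    Parameters
    ----------
    sequence : str
        RNA (or DNA; T read as U) string over ACGU, uppercase or lowercase.

    Returns
    -------
    HairpinStructure
        MFE in kcal/mol (0.0 for a sequence with no favorable pairing) and
        the dot-bracket string of one MFE structure.  Ties are broken
        deterministically by the traceback case order.
    """
    enc = encode(sequence)
    n = len(enc)
    if n < 5:
        return HairpinStructure(sequence, "." * n, 0.0, {})
    V, WM, W, pidx = _fill(enc)
    mfe10 = int(W[n])
    if mfe10 >= 0:
        return HairpinStructure(sequence, "." * n, 0.0, {})
    pairs = _traceback(enc, V, WM, W, pidx)
    pmap: dict[int, int] = {}
    for i, j in pairs:
        pmap[i] = j
        pmap[j] = i
    return HairpinStructure(sequence, _pairs_to_dotbracket(n, pairs), mfe10 / 10.0, pmap)


def structure_energy(sequence: str, pairs: list[tuple[int, int]]) -> float:
    """Energy (kcal/mol) of a given nested structure by loop decomposition.

    Independent of the dynamic program: the structure is decomposed into
    hairpin loops, stacks, bulge/interior loops and multiloops, and the
    same additive model is applied.  Returns ``math.inf`` for structures
    containing a bulge/interior loop larger than ``MAXLOOP`` (outside the
    model) and raises for non-nested or unpairable input.
    """
    e10 = _structure_energy10(encode(sequence), tuple(sorted(pairs)))
    return math.inf if e10 >= INF else e10 / 10.0


def _structure_energy10(enc: np.ndarray, pairs: tuple[tuple[int, int], ...]) -> int:
    n = len(enc)
    for i, j in pairs:
        if not (0 <= i < j < n):
            raise ValueError(f"pair out of range: {(i, j)}")
        if _PAIR_IDX[enc[i], enc[j]] < 0:
            raise ValueError(f"unpairable bases at {(i, j)}")
        if j - i - 1 < MIN_HAIRPIN_LOOP:
            raise ValueError(f"loop below {MIN_HAIRPIN_LOOP} nt at {(i, j)}")
    for a, b in pairs:
        for c, d in pairs:
            if a < c < b < d:
                raise ValueError("pseudoknotted pair set")
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    total = 0
    for p in sorted(pairs):
        parent = None
        for q in sorted(pairs):
            if q[0] < p[0] and p[1] < q[1]:
                if parent is None or q[0] > parent[0]:
                    parent = q
        children.setdefault(p, [])
        children.setdefault(parent, []).append(p)
    for p in list(pairs) + [None]:
        kids = children.get(p, [])
        if p is None:
            continue  # external loop is free
        i, j = p
        if not kids:
            total += hairpin_penalty(j - i - 1)
        elif len(kids) == 1:
            (a, b) = kids[0]
            l1, l2 = a - i - 1, j - b - 1
            if l1 == 0 and l2 == 0:
                total += int(_STACK[_PAIR_IDX[enc[i], enc[j]], _PAIR_IDX[enc[a], enc[b]]])
            else:
                pen = _two_loop_penalty(l1, l2)
                if pen >= INF:
                    return INF
                total += pen
        else:
            total += _MULTI_CLOSE + _MULTI_BRANCH * (len(kids) + 1)
            unpaired = (j - i - 1) - sum(b - a + 1 for a, b in kids)
            total += _MULTI_UNPAIRED * unpaired
    return total


def enumerate_structures(sequence: str) -> list[tuple[tuple[int, int], ...]]:
    """All nested pair sets over allowed pairs with terminal loops >= 3 nt.

    Exhaustive; intended for short sequences (<= ~20 nt) where it serves
    as an exact reference for :func:`fold`.
    """
    enc = encode(sequence)
    n = len(enc)

    @lru_cache(maxsize=None)
    def gen(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        if j - i < 4:
            return ((),)
        out = list(gen(i + 1, j))
        for k in range(i + 4, j + 1):
            if _PAIR_IDX[enc[i], enc[k]] >= 0:
                for inner in gen(i + 1, k - 1):
                    for rest in gen(k + 1, j):
                        out.append(((i, k),) + inner + rest)
        return tuple(out)

    result = gen(0, n - 1) if n >= 5 else ((),)
    gen.cache_clear()
    return list(result)


def brute_force_mfe(sequence: str) -> tuple[float, tuple[tuple[int, int], ...]]:
    """Exact MFE by exhaustive enumeration (small sequences only).

    Returns ``(mfe_kcal_mol, pairs)``; the open chain (energy 0) is always
    a candidate, so the MFE is never positive.
    """
    enc = encode(sequence)
    best_e, best_s = 0, ()
    for s in enumerate_structures(sequence):
        e = _structure_energy10(enc, tuple(sorted(s)))
        if e < best_e:
            best_e, best_s = e, s
    return best_e / 10.0, best_s
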