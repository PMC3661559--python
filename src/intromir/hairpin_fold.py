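"""Secondary-structure prediction and hairpin assessment for precursor
candidates.

The default folding engine is Nussinov base-pair maximization over the
canonical pairs {AU, UA, GC, CG, GU, UG} with a minimum hairpin loop of 3
unpaired nucleotides and a deterministic traceback.  A plug-in minimum-free-
energy folder (anything mapping sequence -> dot-bracket, e.g. ViennaRNA)
can be substituted as long as its output satisfies the same structural
invariants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from ._seq import to_rna

try:  # the DP fill is O(n^3); compile it when numba is available
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
# allowed pairs: AU, UA, GC, CG, GU, UG
_PAIRABLE = np.zeros((5, 5), dtype=np.bool_)
for a, b in [(0, 3), (3, 0), (2, 1), (1, 2), (2, 3), (3, 2)]:
    _PAIRABLE[a, b] = True


@dataclass(frozen=True)
class HairpinStructure:
    sequence: str
    dot_bracket: str
    pair_table: np.ndarray  # partner index per position, -1 for unpaired

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if len(self.dot_bracket) != n or len(self.pair_table) != n:
            raise ValueError("structure fields must all have sequence length")
        for i, j in enumerate(self.pair_table):
            if j >= 0 and self.pair_table[j] != i:
                raise ValueError("pair table is not involutive")

    @property
    def n_paired(self) -> int:
        return int((self.pair_table >= 0).sum())

    @property
    def paired_fraction(self) -> float:
        return self.n_paired / len(self.sequence)

    @property
    def n_pairs(self) -> int:
        return self.n_paired // 2

    def hairpin_loops(self) -> list[tuple[int, int]]:
        """Closing pairs (i,j) of hairpin loops: no paired position strictly
        between i and j."""
        return _hairpin_loops(self.pair_table)

    def dominant_stem_count(self, dominance: float = 0.25) -> int:
        """Number of distinct stem-loops after pruning insignificant side
        branches.

        Base-pair maximization happily pairs a handful of incidental bases
        into tiny parasite hairpins inside or beside the real stem; counting
        those as extra stems would reject genuine precursors.  Loops whose
        exclusive helix support falls below ``dominance`` of all pairs are
        therefore pruned (weakest first, support recomputed) and only the
        remaining stem-loops are counted."""
        return _dominant_stem_count(self.pair_table, dominance)

    @property
    def stem_count(self) -> int:
        return self.dominant_stem_count()

    def __len__(self) -> int:
        return len(self.sequence)


@njit(cache=True)
def _nussinov_fill(codes, pairable, min_loop):  # pragma: no cover - numba
    n = codes.shape[0]
    M = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1, j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if pairable[codes[i], codes[k]]:
                    inner = M[i + 1, k - 1] if k - 1 > i + 1 else 0
                    right = M[k + 1, j] if k + 1 <= j else 0
                    cand = 1 + inner + right
                    if cand > best:
                        best = cand
            M[i, j] = best
    return M


def _traceback(M: np.ndarray, codes: np.ndarray, min_loop: int) -> np.ndarray:
    """Deterministic traceback: prefer pairing i over leaving it unpaired,
    and the smallest pairing partner k on equal scores."""
    n = len(codes)
    pt = np.full(n, -1, dtype=np.int64)
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 1:
            continue
        target = M[i, j]
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            if not _PAIRABLE[codes[i], codes[k]]:
                continue
            inner = M[i + 1, k - 1] if k - 1 > i + 1 else 0
            right = M[k + 1, j] if k + 1 <= j else 0
            if 1 + inner + right == target:
                pt[i] = k
                pt[k] = i
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    return pt


def _hairpin_loops(pt: np.ndarray) -> list[tuple[int, int]]:
    return [
        (i, int(j))
        for i, j in enumerate(pt)
        if j > i and not (pt[i + 1 : j] >= 0).any()
    ]


def _exclusive_supports(pt: np.ndarray, loops: list[tuple[int, int]]) -> list[int]:
    """Pairs supporting each hairpin loop exclusively: a pair (a,b) belongs
    to a loop's own helix when that loop is the only one it encloses."""
    supports = [0] * len(loops)
    for a, b in enumerate(pt):
        if b <= a:
            continue
        inside = [k for k, (i, j) in enumerate(loops) if a <= i and j <= b]
        if len(inside) == 1:
            supports[inside[0]] += 1
    return supports


def _dominant_stem_count(pair_table: np.ndarray, dominance: float) -> int:
    pt = pair_table.copy()
    while True:
        loops = _hairpin_loops(pt)
        if not loops:
            return 0
        supports = _exclusive_supports(pt, loops)
        total_pairs = int((pt >= 0).sum()) // 2
        cutoff = max(1.0, dominance * total_pairs)
        weak = [k for k, s in enumerate(supports) if s < cutoff]
        if not weak:
            return len(loops)
        # prune the weakest loop's exclusive helix and re-evaluate
        k = min(weak, key=lambda k: supports[k])
        to_unpair = [
            (a, int(b))
            for a, b in enumerate(pt)
            if b > a
            and [m for m, (i, j) in enumerate(loops) if a <= i and j <= b] == [k]
        ]
        for a, b in to_unpair:
            pt[a] = -1
            pt[b] = -1


def pair_table_to_dot_bracket(pt: np.ndarray) -> str:
    out = []
    for i, j in enumerate(pt):
        out.append("." if j < 0 else ("(" if j > i else ")"))
    return "".join(out)


def dot_bracket_to_pair_table(db: str) -> np.ndarray:
    pt = np.full(len(db), -1, dtype=np.int64)
    stack: list[int] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pt[i], pt[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pt


def fold(sequence: str, min_loop: int = 3) -> HairpinStructure:
    """Maximize base pairs (Nussinov) with deterministic traceback.

    T is mapped to U; sequences shorter than 10 nt are rejected.
    """
    rna = to_rna(sequence)
    # 9 nt is the shortest hairpin: a 3-pair stem closing a 3-nt loop
    if len(rna) < 9:
        raise ValueError(f"sequence too short to fold ({len(rna)} < 9 nt)")
    codes = np.array([_BASE_CODE.get(c, 4) for c in rna], dtype=np.int8)
    M = _nussinov_fill(codes, _PAIRABLE, min_loop)
    pt = _traceback(M, codes, min_loop)
    return HairpinStructure(rna, pair_table_to_dot_bracket(pt), pt)


def structure_from_dot_bracket(sequence: str, db: str) -> HairpinStructure:
    """Build a HairpinStructure from an external folder's dot-bracket output."""
    return HairpinStructure(to_rna(sequence), db, dot_bracket_to_pair_table(db))


def viennarna_fold(sequence: str) -> HairpinStructure:
    """Optional MFE plug-in backed by the ViennaRNA python bindings."""
    import RNA

    db, _mfe = RNA.fold(to_rna(sequence))
    return structure_from_dot_bracket(sequence, db)


FoldEngine = Callable[[str], HairpinStructure]


@dataclass(frozen=True)
class HairpinAssessment:
    accepted: bool
    reasons: tuple[str, ...]


def assess_hairpin(
    structure: HairpinStructure,
    min_paired_fraction: float = 0.5,
    max_stems: int = 1,
) -> HairpinAssessment:
    """A 'good hairpin' folds into at most ``max_stems`` dominant stem-loops
    with at least ``min_paired_fraction`` of its positions paired."""
    reasons = []
    stems = structure.stem_count
    if stems == 0:
        reasons.append("no stem-loop formed")
    elif stems > max_stems:
        reasons.append(f"{stems} stem-loops exceed the maximum of {max_stems}")
    if structure.paired_fraction < min_paired_fraction:
        reasons.append(
            f"paired fraction {structure.paired_fraction:.2f} below "
            f"{min_paired_fraction:.2f}"
        )
    return HairpinAssessment(not reasons, tuple(reasons))
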