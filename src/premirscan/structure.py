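"""RNA secondary-structure prediction and dot-bracket manipulation.

Two folding backends are exposed through a single interface:

``fallback``
    A self-contained Nussinov-style maximum base-pairing dynamic program
    (minimum terminal loop 3 nt, Watson-Crick plus G·U wobble pairs).  Its
    "energy" is the surrogate score ``-(number of base pairs)`` and is
    flagged as such in every :class:`FoldResult`.
``rnafold``
    Thermodynamic minimum-free-energy folding via the ViennaRNA ``RNAfold``
    executable, when present on ``PATH``.  Energies are in kcal/mol.

The fallback keeps the whole pipeline runnable with no external binaries
while producing structures realistic enough for hairpin extraction and
structural features.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

MIN_LOOP = 3  # minimum unpaired nucleotides in a terminal loop

#: canonical pairs recognised by the fallback folder (Watson-Crick + wobble)
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

_RNA_RE = re.compile(r"^[ACGU]+$")


class StructureParseError(ValueError):
    """Raised for malformed dot-bracket strings; carries the offending index."""

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


class AmbiguousSequenceError(ValueError):
    """Raised when a sequence contains ambiguity codes and policy is 'reject'."""


def normalize_rna(seq: str, ambiguous: str = "reject") -> str:
    """Canonicalise a nucleotide string to uppercase RNA (T→U).

    Parameters
    ----------
    seq : str
        DNA or RNA string, any case.
    ambiguous : {'reject', 'map_to_a'}
        Policy for IUPAC ambiguity codes (N, R, Y, ...).  ``reject`` raises
        :class:`AmbiguousSequenceError`; ``map_to_a`` substitutes ``A``
        (a lossy coercion that the caller opts into explicitly).
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper().replace("T", "U")
    if _RNA_RE.match(s):
        return s
    bad = sorted({c for c in s if c not in "ACGU"})
    if ambiguous == "map_to_a" and all(c.isalpha() for c in bad):
        return "".join(c if c in "ACGU" else "A" for c in s)
    raise AmbiguousSequenceError(
        f"sequence contains non-ACGU characters {bad}; "
        "pass ambiguous='map_to_a' to coerce ambiguity codes"
    )


def parse_dotbracket(structure: str) -> set[tuple[int, int]]:
    """Return the set of 0-based base-pair index pairs ``(i, j)``, i < j.

    Raises :class:`StructureParseError` on characters outside ``(.)`` or on
    unbalanced brackets, reporting the offending index.
    """
    pairs: set[tuple[int, int]] = set()
    stack: list[int] = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise StructureParseError(f"unmatched ')' at index {idx}", idx)
            pairs.add((stack.pop(), idx))
        elif ch != ".":
            raise StructureParseError(f"invalid character {ch!r} at index {idx}", idx)
    if stack:
        raise StructureParseError(f"unmatched '(' at index {stack[-1]}", stack[-1])
    return pairs


def pairs_to_dotbracket(pairs: set[tuple[int, int]], length: int) -> str:
    db = ["."] * length
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return "".join(db)


def pair_table(structure: str) -> np.ndarray:
    """Partner index per position, -1 for unpaired."""
    pt = np.full(len(structure), -1, dtype=np.int64)
    for i, j in parse_dotbracket(structure):
        pt[i], pt[j] = j, i
    return pt


@dataclass(frozen=True)
class FoldResult:
    """A predicted secondary structure for one sequence."""

    sequence: str
    structure: str
    energy: float
    backend_id: str
    is_mfe: bool = True

    @property
    def energy_is_surrogate(self) -> bool:
        return self.backend_id == "fallback"

    @property
    def n_pairs(self) -> int:
        return self.structure.count("(")

    def __post_init__(self):
        if len(self.sequence) != len(self.structure):
            raise ValueError("structure length must equal sequence length")


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in CANONICAL_PAIRS


# ---------------------------------------------------------------------------
# Nussinov maximum-pairing DP (fallback backend)
# ---------------------------------------------------------------------------

_PAIR_MATRIX = np.zeros((4, 4), dtype=np.bool_)
_NT_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
for _a, _b in CANONICAL_PAIRS:
    _PAIR_MATRIX[_NT_INDEX[_a], _NT_INDEX[_b]] = True


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_NT_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))


def _nussinov_fill_python(enc, pairable, min_loop):
    n = enc.shape[0]
    dp = np.zeros((n, n), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if pairable[enc[i], enc[k]]:
                    inner = dp[i + 1, k - 1] if k - 1 > i else 0
                    right = dp[k + 1, j] if k + 1 <= j else 0
                    cand = inner + right + 1
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return dp

try:  # numba gives the O(n^3) fill usable speed on 500-nt genome fragments
    from numba import njit

    _nussinov_fill = njit(cache=False)(_nussinov_fill_python)
except ImportError:  # pragma: no cover - numba is a soft dependency
    _nussinov_fill = _nussinov_fill_python


def _traceback(dp, enc, pairable, min_loop, forbidden):
    """Deterministic traceback: pairing i with the smallest admissible k is
    preferred over leaving i unpaired, and smaller k over larger."""
    n = enc.shape[0]
    pairs = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        target = dp[i, j]
        if target == 0:
            continue
        placed = False
        for k in range(i + min_loop + 1, j + 1):
            if not pairable[enc[i], enc[k]] or (i, k) in forbidden:
                continue
            inner = dp[i + 1, k - 1] if k - 1 > i else 0
            right = dp[k + 1, j] if k + 1 <= j else 0
            if inner + right + 1 == target:
                pairs.append((i, k))
                if k - 1 > i:
                    stack.append((i + 1, k - 1))
                if k + 1 <= j:
                    stack.append((k + 1, j))
                placed = True
                break
        if not placed:
            stack.append((i + 1, j))
    return pairs


def _fold_fallback(seq: str, forbidden: frozenset = frozenset()) -> tuple[str, int]:
    enc = _encode(seq)
    n = len(seq)
    if forbidden:
        # mask forbidden pairs by running the pure-python fill with a check;
        # cheap because constraint folding is only used on short subopt calls
        dp = np.zeros((n, n), dtype=np.int64)
        for span in range(MIN_LOOP + 1, n):
            for i in range(n - span):
                j = i + span
                best = dp[i + 1, j]
                for k in range(i + MIN_LOOP + 1, j + 1):
                    if _PAIR_MATRIX[enc[i], enc[k]] and (i, k) not in forbidden:
                        inner = dp[i + 1, k - 1] if k - 1 > i else 0
                        right = dp[k + 1, j] if k + 1 <= j else 0
                        cand = inner + right + 1
                        if cand > best:
                            best = cand
                dp[i, j] = best
    else:
        dp = _nussinov_fill(enc, _PAIR_MATRIX, MIN_LOOP)
    pairs = _traceback(dp, enc, _PAIR_MATRIX, MIN_LOOP, forbidden)
    db = pairs_to_dotbracket(set(pairs), n)
    return db, len(pairs)


def _fold_rnafold(seq: str) -> tuple[str, float]:
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError(
            "RNAfold executable not found on PATH; use backend='fallback' "
            "(self-contained maximum-pairing folder)"
        )
    out = subprocess.run(
        [exe, "--noPS"], input=seq + "\n", capture_output=True, text=True, check=True
    ).stdout.splitlines()
    # second line: "((...)) (-12.30)"
    m = re.match(r"^([.()]+)\s+\(\s*(-?\d+\.\d+)\)", out[1])
    if not m:  # pragma: no cover
        raise RuntimeError(f"unparseable RNAfold output: {out[1]!r}")
    return m.group(1), float(m.group(2))


def fold(seq: str, backend: str = "fallback") -> FoldResult:
    """Predict the optimal (maximum-pairing or MFE) structure of ``seq``."""
    seq = normalize_rna(seq)
    if backend == "fallback":
        db, npairs = _fold_fallback(seq)
        return FoldResult(seq, db, float(-npairs), "fallback", is_mfe=True)
    if backend == "rnafold":
        db, energy = _fold_rnafold(seq)
        return FoldResult(seq, db, energy, "rnafold", is_mfe=True)
    raise ValueError(f"unknown backend {backend!r}")


# ---------------------------------------------------------------------------
# Exhaustive enumeration (brute-force oracle) and suboptimal structures
# ---------------------------------------------------------------------------

ENUMERATION_GUARD = 14


def enumerate_structures(seq: str) -> list[str]:
    """All valid secondary structures of ``seq`` (loop >= 3, canonical pairs).

    Exhaustive and duplicate-free; guarded to sequences of length <= 14
    because the structure count grows exponentially.  This is the test
    oracle for the fallback folder.
    """
    seq = normalize_rna(seq)
    n = len(seq)
    if n > ENUMERATION_GUARD:
        raise ValueError(f"enumeration limited to length <= {ENUMERATION_GUARD}")

    @lru_cache(maxsize=None)
    def structs(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        # all pair-sets on seq[i..j]
        if j - i <= MIN_LOOP:
            return ((),)
        out = set(structs(i + 1, j))  # i unpaired
        for k in range(i + MIN_LOOP + 1, j + 1):
            if _can_pair(seq[i], seq[k]):
                for inner in structs(i + 1, k - 1):
                    for right in structs(k + 1, j):
                        out.add(tuple(sorted(((i, k),) + inner + right)))
        return tuple(out)

    result = sorted(
        pairs_to_dotbracket(set(ps), n) for ps in structs(0, n - 1)
    )
    structs.cache_clear()
    return result


def subopt_fold(seq: str, k: int = 1, backend: str = "fallback") -> list[FoldResult]:
    """Up to ``k`` suboptimal structures, best first, none equal to the MFE.

    Under the fallback backend, suboptimals are produced by re-folding with
    each MFE base pair individually forbidden and collecting the distinct
    alternative structures; for short sequences this recovers the next-best
    pair counts that full enumeration would.  Sequences admitting no
    alternative structure return an empty list.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return []
    seq = normalize_rna(seq)
    mfe = fold(seq, backend=backend)
    if backend == "rnafold":
        return _subopt_rnafold(seq, mfe, k)
    mfe_pairs = parse_dotbracket(mfe.structure)
    seen: dict[str, int] = {}
    for pair in sorted(mfe_pairs):
        db, npairs = _fold_fallback(seq, forbidden=frozenset({pair}))
        if db != mfe.structure and db not in seen:
            seen[db] = npairs
    if not seen and mfe.n_pairs > 0:
        # forbid all MFE pairs at once: a structurally distinct fold if any
        db, npairs = _fold_fallback(seq, forbidden=frozenset(mfe_pairs))
        if db != mfe.structure:
            seen[db] = npairs
    ranked = sorted(seen.items(), key=lambda it: (-it[1], it[0]))[:k]
    return [
        FoldResult(seq, db, float(-np_), "fallback", is_mfe=False)
        for db, np_ in ranked
    ]


def _subopt_rnafold(seq: str, mfe: FoldResult, k: int) -> list[FoldResult]:
    exe = shutil.which("RNAsubopt")
    if exe is None:
        raise RuntimeError("RNAsubopt executable not found on PATH")
    out = subprocess.run(
        [exe, "-e", "5", "-s"], input=seq + "\n",
        capture_output=True, text=True, check=True,
    ).stdout.splitlines()
    results = []
    for line in out[1:]:
        m = re.match(r"^([.()]+)\s+(-?\d+\.\d+)", line)
        if m and m.group(1) != mfe.structure:
            results.append(
                FoldResult(seq, m.group(1), float(m.group(2)), "rnafold", is_mfe=False)
            )
        if len(results) >= k:
            break
    return results
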