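"""RNA secondary-structure prediction and dot-bracket utilities.

Pre-miRNA classification features are defined over a predicted secondary
structure in dot-bracket notation.  This module provides:

* :class:`RnaSequence`, :class:`DotBracket`, :class:`FoldResult` containers;
* :func:`fold` with two backends — a built-in Nussinov-style base-pair
  maximizer (no external software needed) and ``external-mfe``, which shells
  out to ViennaRNA's ``RNAfold`` when it is installed;
* the bracket normalization used by triplet features (``')'`` -> ``'('``),
  per-nucleotide paired/unpaired flags, and a hairpin-loop counter.

The built-in backend maximizes the number of base pairs (Watson-Crick plus
G·U wobble) over all pseudoknot-free structures with hairpin loops of at
least three unpaired nucleotides, and reports a surrogate free energy of
-1.0 kcal/mol per pair.  Traceback is deterministic: when several optimal
structures exist, the 5'-most nucleotide of the open interval is paired
with its 5'-most admissible partner.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass, field

import numpy as np

try:  # optional JIT for the O(L^3) DP fill; pure-Python fallback below
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba present in supported envs
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f

        return deco


RNA_ALPHABET = frozenset("ACGU")

#: minimum number of unpaired nucleotides inside a hairpin loop
MIN_LOOP = 3

#: energy surrogate of the built-in backend, kcal/mol per base pair
ENERGY_PER_PAIR = -1.0

BUILTIN_BACKEND = "builtin-nussinov"
EXTERNAL_BACKEND = "external-mfe"

_CANONICAL_PAIRS = {
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "U"), ("U", "G"),
}


class InvalidInputError(ValueError):
    """Raised for sequences or structures violating a precondition."""


class InvalidStructureError(InvalidInputError):
    """Raised for malformed dot-bracket strings."""


class BackendUnavailableError(RuntimeError):
    """Raised when the requested external folding engine cannot be run."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over the strict {A, C, G, U} alphabet.

    Ambiguity codes are rejected here; the mining pipeline flags and skips
    ambiguous windows before constructing :class:`RnaSequence` objects.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise InvalidInputError("empty sequence")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise InvalidInputError(
                f"non-RNA letters in sequence {self.id!r}: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DotBracket:
    """A pseudoknot-free secondary structure in dot-bracket notation."""

    symbols: str

    def __post_init__(self) -> None:
        depth = 0
        for ch in self.symbols:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise InvalidStructureError(
                        f"unbalanced ')' in structure {self.symbols!r}"
                    )
            elif ch != ".":
                raise InvalidStructureError(
                    f"illegal symbol {ch!r} in structure {self.symbols!r}"
                )
        if depth != 0:
            raise InvalidStructureError(
                f"{depth} unclosed '(' in structure {self.symbols!r}"
            )

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def length(self) -> int:
        return len(self.symbols)

    @property
    def pair_count(self) -> int:
        return self.symbols.count("(")


@dataclass(frozen=True)
class FoldResult:
    """A sequence together with its predicted structure and free energy."""

    sequence: RnaSequence
    structure: DotBracket
    mfe: float  # kcal/mol
    backend: str = BUILTIN_BACKEND

    def __post_init__(self) -> None:
        if self.structure.length != self.sequence.length:
            raise InvalidInputError("structure/sequence length mismatch")


# ---------------------------------------------------------------------------
# built-in Nussinov-style folding
# ---------------------------------------------------------------------------

def _pairing_matrix(residues: str) -> np.ndarray:
    """Boolean (L, L) matrix: can_pair[i, j] iff (i, j) may form a pair."""
    L = len(residues)
    codes = np.frombuffer(residues.encode(), dtype=np.uint8)
    can = np.zeros((L, L), dtype=np.bool_)
    for a, b in _CANONICAL_PAIRS:
        can |= (codes[:, None] == ord(a)) & (codes[None, :] == ord(b))
    # hairpin-loop constraint: at least MIN_LOOP unpaired nt between i and j
    i_idx = np.arange(L)
    can &= (i_idx[None, :] - i_idx[:, None]) > MIN_LOOP
    return can


@_njit(cache=False)
def _fill_dp(can_pair, L):  # pragma: no cover - exercised via fold()
    dp = np.zeros((L, L), dtype=np.int32)
    for d in range(MIN_LOOP + 1, L):
        for i in range(L - d):
            j = i + d
            best = dp[i + 1, j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                if can_pair[i, k]:
                    v = 1 + dp[i + 1, k - 1]
                    if k + 1 <= j:
                        v += dp[k + 1, j]
                    if v > best:
                        best = v
            dp[i, j] = best
    return dp


def _fill_dp_py(can_pair: np.ndarray, L: int) -> np.ndarray:
    dp = np.zeros((L, L), dtype=np.int32)
    for d in range(MIN_LOOP + 1, L):
        for i in range(L - d):
            j = i + d
            best = dp[i + 1, j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                if can_pair[i, k]:
                    v = 1 + dp[i + 1, k - 1]
                    if k + 1 <= j:
                        v += dp[k + 1, j]
                    if v > best:
                        best = v
            dp[i, j] = best
    return dp


def _nussinov_table(residues: str) -> np.ndarray:
    L = len(residues)
    can = _pairing_matrix(residues)
    if _HAVE_NUMBA:
        return _fill_dp(can, L)
    return _fill_dp_py(can, L)


def max_pair_count(seq: RnaSequence) -> int:
    """Maximum base pairs of any admissible structure (no traceback).

    Fast path used by the Monte-Carlo P-value, which only needs the
    surrogate energy (-1 kcal/mol x pairs) of each shuffled sequence.
    """
    L = seq.length
    if L <= MIN_LOOP + 1:
        return 0
    return int(_nussinov_table(seq.residues)[0, L - 1])


def _traceback(dp: np.ndarray, can: np.ndarray, L: int) -> str:
    symbols = ["."] * L
    stack = [(0, L - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        target = dp[i, j]
        if target == 0:
            continue
        paired = False
        # pair i with its 5'-most admissible optimal partner
        for k in range(i + MIN_LOOP + 1, j + 1):
            if not can[i, k]:
                continue
            v = 1 + dp[i + 1, k - 1]
            if k + 1 <= j:
                v += dp[k + 1, j]
            if v == target:
                symbols[i] = "("
                symbols[k] = ")"
                stack.append((i + 1, k - 1))
                if k + 1 <= j:
                    stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    return "".join(symbols)


def _fold_builtin(seq: RnaSequence) -> FoldResult:
    L = seq.length
    if L <= MIN_LOOP + 1:
        return FoldResult(seq, DotBracket("." * L), 0.0, BUILTIN_BACKEND)
    can = _pairing_matrix(seq.residues)
    dp = _fill_dp(can, L) if _HAVE_NUMBA else _fill_dp_py(can, L)
    symbols = _traceback(dp, can, L)
    pairs = symbols.count("(")
    return FoldResult(
        seq, DotBracket(symbols), ENERGY_PER_PAIR * pairs, BUILTIN_BACKEND
    )


# ---------------------------------------------------------------------------
# external RNAfold backend
# ---------------------------------------------------------------------------

_RNAFOLD_LINE = re.compile(r"^([().]+)\s+\(\s*(-?\d+(?:\.\d+)?)\s*\)")


def _fold_external(seq: RnaSequence) -> FoldResult:
    exe = shutil.which("RNAfold")
    if exe is None:
        raise BackendUnavailableError("RNAfold executable not found on PATH")
    try:
        proc = subprocess.run(
            [exe, "--noPS"],
            input=f">{seq.id}\n{seq.residues}\n",
            capture_output=True,
            text=True,
            check=True,
        )
    except (OSError, subprocess.CalledProcessError) as exc:
        raise BackendUnavailableError(f"RNAfold failed: {exc}") from exc
    for line in proc.stdout.splitlines():
        m = _RNAFOLD_LINE.match(line.strip())
        if m:
            structure = DotBracket(m.group(1))
            if structure.length != seq.length:
                raise BackendUnavailableError(
                    "RNAfold returned a structure of mismatched length"
                )
            return FoldResult(seq, structure, float(m.group(2)), EXTERNAL_BACKEND)
    raise BackendUnavailableError(
        f"could not parse RNAfold output: {proc.stdout!r}"
    )


def fold(seq: RnaSequence, backend: str = BUILTIN_BACKEND) -> FoldResult:
    """Predict a pseudoknot-free secondary structure for *seq*.

    Parameters
    ----------
    seq
        Validated RNA sequence.
    backend
        ``"builtin-nussinov"`` (default) or ``"external-mfe"`` (RNAfold).

    Raises
    ------
    InvalidInputError
        If the sequence is invalid (raised at construction time).
    BackendUnavailableError
        If the external engine is requested but cannot be run; callers may
        fall back to the built-in backend.
    """
    if backend == BUILTIN_BACKEND:
        return _fold_builtin(seq)
    if backend == EXTERNAL_BACKEND:
        return _fold_external(seq)
    raise InvalidInputError(f"unknown folding backend {backend!r}")


# ---------------------------------------------------------------------------
# dot-bracket utilities
# ---------------------------------------------------------------------------

def normalize_brackets(structure: DotBracket) -> str:
    """Collapse pairing direction: every ``')'`` becomes ``'('``.

    Triplet structure patterns distinguish only paired from unpaired
    nucleotides, so both bracket orientations map to the same symbol.
    Idempotent; dots are unchanged.
    """
    return structure.symbols.replace(")", "(")


def paired_flags(structure: DotBracket) -> np.ndarray:
    """Per-nucleotide binary flags: 1 if the base is paired, 0 if unpaired."""
    return np.frombuffer(
        structure.symbols.encode(), dtype=np.uint8
    ).__ne__(ord(".")).astype(np.int8)


_TERMINAL_LOOP = re.compile(r"\(\.*\)")


def count_terminal_loops(structure: DotBracket) -> int:
    """Number of hairpin (terminal) loops in the structure.

    A terminal loop is a maximal dot run directly enclosed by a pair —
    equivalently, an innermost pair.  Single stem-loops return 1;
    multi-branched structures return >= 2; fully unpaired returns 0.
    """
    return len(_TERMINAL_LOOP.findall(structure.symbols))


# ---------------------------------------------------------------------------
# dot-bracket sidecar files: one record per line, "id<TAB>structure<TAB>mfe"
# ---------------------------------------------------------------------------

def write_structure_sidecar(path, folds) -> None:
    with open(path, "w") as fh:
        for fr in folds:
            fh.write(f"{fr.sequence.id}\t{fr.structure.symbols}\t{fr.mfe}\n")


def read_structure_sidecar(path) -> dict:
    """Read a sidecar file into ``{id: (DotBracket, mfe)}``."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise InvalidInputError(
                    f"{path}:{lineno}: expected 3 tab-separated fields"
                )
            ident, symbols, mfe = parts
            out[ident] = (DotBracket(symbols), float(mfe))
    return out
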