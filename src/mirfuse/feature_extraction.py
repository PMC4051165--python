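"""Feature spaces of the four base classifiers.

Three feature vectors are extracted per folded hairpin candidate:

* ``triplet32`` — for every window of 3 adjacent nucleotides, the paired /
  unpaired pattern of the window (``')'`` normalized to ``'('``, so 8
  patterns) combined with the identity of the *middle* nucleotide:
  4 x 8 = 32 bins, normalized by the window count L - 2.
* ``hybrid34`` — the triplet vector extended by two thermodynamic features:
  the minimum free energy (MFE) of the predicted structure and the
  Monte-Carlo P-value, i.e. the fraction of dinucleotide-shuffled versions
  of the sequence whose MFE is strictly lower than the original's.
* ``seqstruct512`` — trinucleotide identity (64) crossed with the 3-bit
  bound/unbound state of the window's positions (8): 512 bins, labelled
  like ``"AUG001"`` (trinucleotide AUG, flags 0,0,1).

Bin orderings are fixed lexicographically (see the label constants) and
define the on-disk feature-matrix column order.  Dinucleotide shuffling
uses Euler-path sampling (Altschul–Erickson), which preserves the exact
multiset of overlapping dinucleotides and hence mono-nucleotide counts and
both terminal residues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_fold import (
    BUILTIN_BACKEND,
    DotBracket,
    FoldResult,
    InvalidInputError,
    RnaSequence,
    fold,
    max_pair_count,
    normalize_brackets,
    paired_flags,
)

NUCLEOTIDES = "ACGU"

#: the 8 triplet structure patterns in binary order with '(' < '.'
TRIPLET_PATTERNS = (
    "(((", "((.", "(.(", "(..", ".((", ".(.", "..(", "...",
)

#: 32 triplet bin labels: middle-nucleotide letter + structure pattern
TRIPLET_LABELS = tuple(
    n + p for n in NUCLEOTIDES for p in TRIPLET_PATTERNS
)

#: 512 sequence-structure bin labels: trinucleotide + 3-bit flag code
SEQSTRUCT_LABELS = tuple(
    a + b + c + f"{bits:03b}"
    for a in NUCLEOTIDES
    for b in NUCLEOTIDES
    for c in NUCLEOTIDES
    for bits in range(8)
)

_TRIPLET_INDEX = {lab: i for i, lab in enumerate(TRIPLET_LABELS)}
_SEQSTRUCT_INDEX = {lab: i for i, lab in enumerate(SEQSTRUCT_LABELS)}

DEFAULT_N_SHUFFLES = 1000


class TooShortError(InvalidInputError):
    """Sequence too short for the requested feature window."""


@dataclass(frozen=True)
class ThermoFeatures:
    """MFE (kcal/mol) and Monte-Carlo P-value of a folded sequence."""

    mfe: float
    p_value: float
    n_shuffles: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise InvalidInputError("p_value outside [0, 1]")
        if self.n_shuffles < 1:
            raise InvalidInputError("n_shuffles must be >= 1")


@dataclass(frozen=True)
class FeatureBundle:
    """The three feature vectors of one sequence, plus its thermo features."""

    triplet32: np.ndarray
    hybrid34: np.ndarray
    seqstruct512: np.ndarray
    thermo: ThermoFeatures


# ---------------------------------------------------------------------------
# windowed count features
# ---------------------------------------------------------------------------

def triplet32(
    seq: RnaSequence, structure: DotBracket, normalize: bool = True
) -> np.ndarray:
    """32-dimensional triplet structure-sequence vector.

    Each of the L - 2 windows of 3 adjacent nucleotides increments the bin
    indexed by (middle nucleotide, bracket-normalized 3-symbol pattern).
    With ``normalize`` the counts are divided by L - 2.
    """
    if seq.length < 3:
        raise TooShortError("triplet features need length >= 3")
    if structure.length != seq.length:
        raise InvalidInputError("structure/sequence length mismatch")
    pattern = normalize_brackets(structure)
    counts = np.zeros(32, dtype=float)
    res = seq.residues
    for i in range(seq.length - 2):
        counts[_TRIPLET_INDEX[res[i + 1] + pattern[i : i + 3]]] += 1
    if normalize:
        counts /= seq.length - 2
    return counts


def seqstruct512(
    seq: RnaSequence, flags, normalize: bool = True
) -> np.ndarray:
    """512-dimensional sequence-structure vector.

    Each 3-nt window increments the bin indexed by (trinucleotide, 3-bit
    paired-flag code), e.g. window AUG with flags (0,0,1) -> bin "AUG001".
    """
    if seq.length < 3:
        raise TooShortError("sequence-structure features need length >= 3")
    flags = np.asarray(flags, dtype=int)
    if flags.shape != (seq.length,):
        raise InvalidInputError("flags/sequence length mismatch")
    if not np.isin(flags, (0, 1)).all():
        raise InvalidInputError("flags must be binary")
    counts = np.zeros(512, dtype=float)
    res = seq.residues
    for i in range(seq.length - 2):
        label = res[i : i + 3] + "".join(map(str, flags[i : i + 3]))
        counts[_SEQSTRUCT_INDEX[label]] += 1
    if normalize:
        counts /= seq.length - 2
    return counts


# ---------------------------------------------------------------------------
# dinucleotide shuffling (Altschul–Erickson Euler-path sampling)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(
    seq: RnaSequence, rng: np.random.Generator
) -> RnaSequence:
    """Shuffle *seq* preserving its overlapping-dinucleotide multiset.

    The sequence is viewed as an Eulerian path in the directed multigraph
    whose vertices are nucleotides and whose edges are the observed
    dinucleotides.  A random spanning arborescence toward the final residue
    fixes each vertex's last outgoing edge; the remaining edges are permuted
    uniformly and the path is re-walked.  All valid shuffles are reachable,
    and the first and last residues are invariant.
    """
    if seq.length < 2:
        raise TooShortError("dinucleotide shuffle needs length >= 2")
    res = seq.residues
    first, last = res[0], res[-1]
    edges: dict[str, list[str]] = {}
    for a, b in zip(res, res[1:]):
        edges.setdefault(a, []).append(b)
    vertices = list(edges)  # vertices with outgoing edges

    if len(vertices) == 1 and len(set(edges[vertices[0]])) == 1:
        return RnaSequence(seq.id + "_shuf", res)  # homopolymer: unique path

    while True:
        # pick a candidate last-edge for every vertex except the terminal one
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        # accept iff the chosen edges form an arborescence toward `last`
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        perm = rng.permutation(len(rest))
        shuffled[v] = [rest[i] for i in perm]
        if v in last_edge:
            shuffled[v].append(last_edge[v])

    out = [first]
    ptr = {v: 0 for v in vertices}
    cur = first
    for _ in range(len(res) - 1):
        nxt = shuffled[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return RnaSequence(seq.id + "_shuf", "".join(out))


def _count_lower_shuffles(
    fold_result: FoldResult, n_shuffles: int, rng: np.random.Generator
) -> int:
    seq = fold_result.sequence
    lower = 0
    if fold_result.backend == BUILTIN_BACKEND:
        # surrogate energy is -1 per pair: compare pair counts, skip traceback
        orig_pairs = fold_result.structure.pair_count
        for _ in range(n_shuffles):
            if max_pair_count(dinucleotide_shuffle(seq, rng)) > orig_pairs:
                lower += 1
    else:
        for _ in range(n_shuffles):
            shuf = dinucleotide_shuffle(seq, rng)
            if fold(shuf, fold_result.backend).mfe < fold_result.mfe:
                lower += 1
    return lower


def mfe_pvalue(
    seq: RnaSequence,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    backend: str = BUILTIN_BACKEND,
    rng: np.random.Generator | None = None,
) -> ThermoFeatures:
    """MFE of *seq* and the fraction of shuffles folding strictly lower.

    P-value = (# dinucleotide shuffles with MFE strictly below the
    original's) / n_shuffles; ties count as not lower.  Deterministic for a
    seeded *rng*.
    """
    if n_shuffles < 1:
        raise InvalidInputError("n_shuffles must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    original = fold(seq, backend=backend)
    lower = _count_lower_shuffles(original, n_shuffles, rng)
    return ThermoFeatures(
        mfe=original.mfe, p_value=lower / n_shuffles, n_shuffles=n_shuffles
    )


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

def build_feature_bundle(
    fold_result: FoldResult,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    rng: np.random.Generator | None = None,
) -> FeatureBundle:
    """All three feature vectors, computed from one fold consistently."""
    seq = fold_result.sequence
    structure = fold_result.structure
    t32 = triplet32(seq, structure, normalize=True)
    flags = paired_flags(structure)
    s512 = seqstruct512(seq, flags, normalize=True)
    thermo_rng = rng if rng is not None else np.random.default_rng()
    lower = _count_lower_shuffles(fold_result, n_shuffles, thermo_rng)
    thermo = ThermoFeatures(fold_result.mfe, lower / n_shuffles, n_shuffles)
    hybrid = np.concatenate([t32, [thermo.mfe, thermo.p_value]])
    return FeatureBundle(t32, hybrid, s512, thermo)


# ---------------------------------------------------------------------------
# feature-matrix TSV I/O
# ---------------------------------------------------------------------------

def write_feature_matrix(path, matrix, labels, ids) -> None:
    """Write a feature matrix as TSV with bin labels as the header row."""
    df = pd.DataFrame(np.asarray(matrix), columns=list(labels), index=list(ids))
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def read_feature_matrix(path, labels) -> tuple[np.ndarray, list[str]]:
    """Read a feature-matrix TSV, reordering columns to match *labels*."""
    df = pd.read_csv(path, sep="\t", index_col="id")
    missing = set(labels) - set(df.columns)
    if missing:
        raise InvalidInputError(
            f"feature matrix misses {len(missing)} expected columns"
        )
    df = df[list(labels)]
    return df.to_numpy(dtype=float), list(df.index.astype(str))
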