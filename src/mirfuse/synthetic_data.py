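"""Synthetic corpora: designed hairpins, pseudo hairpins, planted contigs,
and simulated committee decision tables.

Everything the training and mining stages consume can be generated here,
seed-deterministically, without downloads:

* *positives* — designed stem-loops: a random 5' arm, a loop, and the
  reverse-complement 3' arm with mismatches injected at a set rate.  With
  the defaults (stem 22 bp, loop 8 nt) the precursors are 52 nt, in the
  published 60-70 nt precursor ballpark, and fold into long imperfect stems
  with low surrogate MFE.
* *negatives* — pseudo hairpins of matched length and composition: either a
  dinucleotide shuffle of a fresh hairpin (identical dinucleotide content,
  weaker fold) or a codon-structured random sequence without in-frame stop
  codons, emulating coding-region provenance.
* *planted contigs* — random DNA contigs with hairpins (U -> T) inserted at
  recorded loci, plus a BED-like truth sidecar, for end-to-end recovery
  tests of the mining pipeline.
* *committee tables* — simulated 4-classifier decision matrices with stated
  per-classifier sensitivity/specificity, prevalence, and an agreement
  parameter implemented as a single shared latent error source (spanning
  the independent-to-identical regimes), for fusion-network training tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .feature_extraction import (
    SEQSTRUCT_LABELS,
    TRIPLET_LABELS,
    build_feature_bundle,
    dinucleotide_shuffle,
)
from .structure_fold import InvalidInputError, RnaSequence, fold

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_STOP_CODONS = {"UAA", "UAG", "UGA"}


class SpecError(InvalidInputError):
    pass


@dataclass(frozen=True)
class HairpinSpec:
    """Geometry and composition of a designed stem-loop."""

    stem_length: int = 22  # paired positions per arm
    loop_length: int = 8  # unpaired loop nucleotides
    mismatch_rate: float = 0.1  # fraction of stem positions mutated
    gc_bias: float = 0.5  # target GC fraction

    def __post_init__(self) -> None:
        if self.stem_length < 1:
            raise SpecError("stem_length must be >= 1")
        if self.loop_length < 3:
            raise SpecError(
                "loop_length must be >= 3 (minimum hairpin loop of the fold)"
            )
        if not 0.0 <= self.mismatch_rate <= 1.0:
            raise SpecError("mismatch_rate must be in [0, 1]")
        if not 0.0 < self.gc_bias < 1.0:
            raise SpecError("gc_bias must be in (0, 1)")

    @property
    def total_length(self) -> int:
        return 2 * self.stem_length + self.loop_length


@dataclass(frozen=True)
class CommitteeSimSpec:
    """Error model of a simulated 4-classifier committee."""

    sens_spec: tuple  # four (sensitivity, specificity) pairs
    prevalence: float = 1.0 / 3.0
    n_samples: int = 1000
    correlation: float = 0.0  # shared-latent-error probability

    def __post_init__(self) -> None:
        if len(self.sens_spec) != 4:
            raise SpecError("sens_spec needs exactly 4 (sens, spec) pairs")
        for sens, spec in self.sens_spec:
            if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
                raise SpecError("rates must be in [0, 1]")
        if not 0.0 <= self.prevalence <= 1.0:
            raise SpecError("prevalence must be in [0, 1]")
        if not 0.0 <= self.correlation <= 1.0:
            raise SpecError("correlation must be in [0, 1]")
        if self.n_samples < 1:
            raise SpecError("n_samples must be >= 1")


def _random_base(rng: np.random.Generator, gc_bias: float) -> str:
    if rng.random() < gc_bias:
        return "G" if rng.random() < 0.5 else "C"
    return "A" if rng.random() < 0.5 else "U"


def _random_rna(rng: np.random.Generator, n: int, gc_bias: float) -> str:
    return "".join(_random_base(rng, gc_bias) for _ in range(n))


def gen_hairpin(
    spec: HairpinSpec, rng: np.random.Generator, ident: str = "hairpin"
) -> RnaSequence:
    """A designed stem-loop: 5' arm + loop + mismatched reverse complement."""
    arm5 = _random_rna(rng, spec.stem_length, spec.gc_bias)
    loop = _random_rna(rng, spec.loop_length, spec.gc_bias)
    arm3 = []
    for base in reversed(arm5):
        comp = _COMPLEMENT[base]
        if rng.random() < spec.mismatch_rate:
            choices = [b for b in "ACGU" if b != comp]
            comp = choices[rng.integers(3)]
        arm3.append(comp)
    return RnaSequence(ident, arm5 + loop + "".join(arm3))


def gen_pseudo_hairpin(
    spec: HairpinSpec,
    rng: np.random.Generator,
    mode: str = "shuffle",
    ident: str = "pseudo",
) -> RnaSequence:
    """A matched-length negative; *mode* is recorded in the sequence id.

    ``"shuffle"`` dinucleotide-shuffles a fresh designed hairpin;
    ``"codon"`` draws random stop-free codons, emulating coding sequence.
    """
    if mode == "shuffle":
        hp = gen_hairpin(spec, rng, ident="tmp")
        shuffled = dinucleotide_shuffle(hp, rng)
        return RnaSequence(f"{ident}|mode=shuffle", shuffled.residues)
    if mode == "codon":
        n = spec.total_length
        codons = []
        while 3 * len(codons) < n:
            codon = _random_rna(rng, 3, spec.gc_bias)
            if codon not in _STOP_CODONS:
                codons.append(codon)
        return RnaSequence(f"{ident}|mode=codon", "".join(codons)[:n])
    raise SpecError(f"unknown pseudo-hairpin mode {mode!r}")


# ---------------------------------------------------------------------------
# labeled datasets
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Sequences, labels and per-space feature matrices of one draw."""

    sequences: list
    labels: np.ndarray  # +-1 per sequence
    triplet32: np.ndarray
    hybrid34: np.ndarray
    seqstruct512: np.ndarray
    manifest: dict

    def labeled(self, space: str):
        from .base_committee import LabeledDataset

        return LabeledDataset(getattr(self, space), self.labels, space)


def gen_dataset(
    n_pos: int = 500,
    n_neg: int = 1000,
    spec: HairpinSpec = HairpinSpec(),
    rng: np.random.Generator | int | None = None,
    n_shuffles: int = 1000,
    neg_mode: str = "shuffle",
    out_dir=None,
) -> SyntheticDataset:
    """Draw a labeled corpus and featurize every sequence.

    Defaults mirror the published 500 positive / 1000 negative composition.
    When *out_dir* is given, positive and negative FASTA files, the three
    feature-matrix TSVs and a JSON manifest are written there.
    """
    if n_pos < 1 or n_neg < 1:
        raise SpecError("need at least one sequence per class")
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = None if rng is None else int(rng)
        rng = np.random.default_rng(seed)

    sequences = []
    labels = []
    for i in range(n_pos):
        sequences.append(gen_hairpin(spec, rng, ident=f"pos_{i}"))
        labels.append(1)
    for i in range(n_neg):
        sequences.append(
            gen_pseudo_hairpin(spec, rng, mode=neg_mode, ident=f"neg_{i}")
        )
        labels.append(-1)

    t32_rows, h34_rows, s512_rows = [], [], []
    for seq in sequences:
        bundle = build_feature_bundle(fold(seq), n_shuffles=n_shuffles, rng=rng)
        t32_rows.append(bundle.triplet32)
        h34_rows.append(bundle.hybrid34)
        s512_rows.append(bundle.seqstruct512)

    manifest = {
        "n_pos": n_pos,
        "n_neg": n_neg,
        "spec": asdict(spec),
        "n_shuffles": n_shuffles,
        "neg_mode": neg_mode,
        "seed": seed,
    }
    ds = SyntheticDataset(
        sequences=sequences,
        labels=np.asarray(labels),
        triplet32=np.vstack(t32_rows),
        hybrid34=np.vstack(h34_rows),
        seqstruct512=np.vstack(s512_rows),
        manifest=manifest,
    )
    if out_dir is not None:
        _write_dataset(ds, out_dir)
    return ds


def _write_dataset(ds: SyntheticDataset, out_dir) -> None:
    from pathlib import Path

    from .feature_extraction import write_feature_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, keep in (("positives.fasta", 1), ("negatives.fasta", -1)):
        with open(out / name, "w") as fh:
            for seq, label in zip(ds.sequences, ds.labels):
                if label == keep:
                    fh.write(f">{seq.id}\n{seq.residues}\n")
    ids = [s.id for s in ds.sequences]
    write_feature_matrix(out / "triplet32.tsv", ds.triplet32, TRIPLET_LABELS, ids)
    hybrid_labels = list(TRIPLET_LABELS) + ["MFE", "P_VALUE"]
    write_feature_matrix(out / "hybrid34.tsv", ds.hybrid34, hybrid_labels, ids)
    write_feature_matrix(
        out / "seqstruct512.tsv", ds.seqstruct512, SEQSTRUCT_LABELS, ids
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(ds.manifest, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# simulated committee decisions
# ---------------------------------------------------------------------------

def gen_committee_table(
    spec: CommitteeSimSpec, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (n, 4) +-1 decisions and the +-1 truth vector.

    Each classifier errs with probability 1 - sensitivity on positives and
    1 - specificity on negatives.  With probability ``correlation`` a sample
    uses one shared uniform draw for all four error decisions (correlated
    mistakes); otherwise the four draws are independent.  Marginal error
    rates are unchanged either way.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = spec.n_samples
    truth = np.where(rng.random(n) < spec.prevalence, 1, -1)
    decisions = np.empty((n, 4), dtype=int)
    err_pos = np.array([1.0 - s for s, _ in spec.sens_spec])
    err_neg = np.array([1.0 - sp for _, sp in spec.sens_spec])
    for i in range(n):
        rates = err_pos if truth[i] == 1 else err_neg
        if rng.random() < spec.correlation:
            u = np.full(4, rng.random())
        else:
            u = rng.random(4)
        flips = u < rates
        decisions[i] = np.where(flips, -truth[i], truth[i])
    return decisions, truth


# ---------------------------------------------------------------------------
# planted contigs
# ---------------------------------------------------------------------------

def gen_planted_contigs(
    n_contigs: int = 20,
    contig_length: int = 500,
    hairpin_spec: HairpinSpec = HairpinSpec(),
    n_planted: int = 3,
    rng: np.random.Generator | int | None = None,
    out_fasta=None,
    out_bed=None,
):
    """Random DNA contigs with hairpins planted at recorded loci.

    Returns ``(contigs, truth)`` where contigs is a list of
    ``(id, dna_string)`` pairs and truth a list of
    ``(contig_id, start, end, name)`` records (0-based, half-open).
    Hairpins are planted in distinct contigs, away from the edges.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    hp_len = hairpin_spec.total_length
    if contig_length <= hp_len:
        raise SpecError("contig_length must exceed the hairpin length")
    if n_planted > n_contigs:
        raise SpecError("cannot plant more hairpins than contigs")

    dna = [
        "".join("ACGT"[rng.integers(4)] for _ in range(contig_length))
        for _ in range(n_contigs)
    ]
    chosen = rng.choice(n_contigs, size=n_planted, replace=False)
    truth = []
    for j, ci in enumerate(sorted(int(c) for c in chosen)):
        hp = gen_hairpin(hairpin_spec, rng, ident=f"planted_{j}")
        start = int(rng.integers(0, contig_length - hp_len + 1))
        hp_dna = hp.residues.replace("U", "T")
        dna[ci] = dna[ci][:start] + hp_dna + dna[ci][start + hp_len :]
        truth.append((f"contig_{ci}", start, start + hp_len, f"planted_{j}"))

    contigs = [(f"contig_{i}", dna[i]) for i in range(n_contigs)]
    if out_fasta is not None:
        with open(out_fasta, "w") as fh:
            for ident, seq in contigs:
                fh.write(f">{ident}\n{seq}\n")
    if out_bed is not None:
        with open(out_bed, "w") as fh:
            for cid, start, end, name in truth:
                fh.write(f"{cid}\t{start}\t{end}\t{name}\n")
    return contigs, truth
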