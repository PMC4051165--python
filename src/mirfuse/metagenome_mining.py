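"""Sliding-window pre-miRNA mining over metagenomic contigs.

Contigs are fragmented into fixed-size windows (default 70 nt, the typical
precursor length) advanced by 1 nt, so every possible precursor placement
is scanned.  Each unambiguous window is transcribed, folded, featurized,
classified by the four base surrogates, and its decision vector fused by
the network; windows whose fused label is positive are reported as
candidate pre-miRNA loci.  Windows containing IUPAC ambiguity codes are
emitted but flagged and excluded from classification.

Coordinates are 0-based half-open internally; the human-readable TSV report
uses 1-based inclusive coordinates (stated in its header).  Only the given
strand is scanned by default; ``both_strands`` adds the reverse complement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .base_committee import COMMITTEE_ORDER, committee_decision_matrix
from .feature_extraction import build_feature_bundle
from .fusion_network import FusionNetwork, forward_batch
from .structure_fold import (
    BUILTIN_BACKEND,
    RnaSequence,
    count_terminal_loops,
    fold,
)

DEFAULT_WINDOW = 70
DEFAULT_STEP = 1

_RC = str.maketrans("ACGT", "TGCA")


class MiningError(RuntimeError):
    pass


@dataclass(frozen=True)
class Contig:
    """An assembled DNA sequence (IUPAC codes tolerated)."""

    id: str
    dna: str

    @property
    def length(self) -> int:
        return len(self.dna)


@dataclass(frozen=True)
class Fragment:
    """One window of a contig, already transcribed to RNA."""

    contig_id: str
    start: int  # 0-based offset on the contig
    rna: str  # transcribed window; may contain ambiguity codes
    strand: str = "+"

    @property
    def end(self) -> int:
        return self.start + len(self.rna)

    @property
    def ambiguous(self) -> bool:
        return bool(set(self.rna) - set("ACGU"))

    def to_rna_sequence(self) -> RnaSequence:
        return RnaSequence(f"{self.contig_id}:{self.start}{self.strand}", self.rna)


@dataclass(frozen=True)
class CandidateReport:
    """Classification outcome of one fragment."""

    fragment: Fragment
    decisions: tuple  # 4-tuple over {-1, +1}, COMMITTEE_ORDER
    fusion_score: float
    label: int  # fused decision in {-1, +1}
    single_loop: bool  # structure had exactly one terminal loop


@dataclass
class MiningConfig:
    window: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP
    threshold: float = 0.0
    polarity: int = +1
    n_shuffles: int = 1000
    seed: int = 0
    backend: str = BUILTIN_BACKEND
    single_loop_only: bool = False
    both_strands: bool = False

    def __post_init__(self) -> None:
        if self.window < 1 or self.step < 1:
            raise MiningError("window and step must be >= 1")
        if self.polarity not in (+1, -1):
            raise MiningError("polarity must be +1 or -1")


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------

def transcribe(dna_window: str) -> str:
    """Upper-case and T -> U; ambiguity codes pass through (flagged later)."""
    return dna_window.upper().replace("T", "U")


def fragment_contig(
    contig: Contig, window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP
) -> list[Fragment]:
    """All windows of *contig* at the given size and shift.

    Offsets are 0, step, 2*step, ... while offset + window <= length, i.e.
    max(0, floor((L - window)/step) + 1) fragments.  Contigs shorter than
    the window yield an empty list.
    """
    if window < 1 or step < 1:
        raise MiningError("window and step must be >= 1")
    out = []
    dna = contig.dna
    for start in range(0, contig.length - window + 1, step):
        out.append(
            Fragment(contig.id, start, transcribe(dna[start : start + window]))
        )
    return out


def read_contigs_fasta(path) -> list[Contig]:
    return [
        Contig(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def mine(
    contigs,
    models,
    net: FusionNetwork,
    config: MiningConfig | None = None,
) -> tuple[list[CandidateReport], dict]:
    """Scan contigs and classify every unambiguous window.

    Returns one :class:`CandidateReport` per classified fragment and a
    summary dict (fragment totals, skipped windows, positives).  Fully
    deterministic for a fixed config seed and input order.
    """
    if config is None:
        config = MiningConfig()
    rng = np.random.default_rng(config.seed)

    fragments: list[Fragment] = []
    for contig in contigs:
        fragments.extend(fragment_contig(contig, config.window, config.step))
        if config.both_strands:
            rc = Contig(contig.id, contig.dna.translate(_RC)[::-1])
            for frag in fragment_contig(rc, config.window, config.step):
                # report coordinates on the forward strand
                fragments.append(
                    Fragment(
                        contig.id,
                        contig.length - frag.start - config.window,
                        frag.rna,
                        strand="-",
                    )
                )

    clean, skipped_ambiguous = [], 0
    for frag in fragments:
        if frag.ambiguous:
            skipped_ambiguous += 1
        else:
            clean.append(frag)

    bundles = []
    kept = []
    skipped_multiloop = 0
    for frag in clean:
        fr = fold(frag.to_rna_sequence(), backend=config.backend)
        single = count_terminal_loops(fr.structure) == 1
        if config.single_loop_only and not single:
            skipped_multiloop += 1
            continue
        bundles.append(
            (frag, single, build_feature_bundle(fr, config.n_shuffles, rng))
        )
        kept.append(frag)

    reports: list[CandidateReport] = []
    if bundles:
        decision_matrix = committee_decision_matrix(
            [b for _, _, b in bundles], models
        )
        scores = forward_batch(net, decision_matrix.astype(float))
        for (frag, single, _), row, score in zip(
            bundles, decision_matrix, scores
        ):
            on = score >= config.threshold
            label = config.polarity if on else -config.polarity
            reports.append(
                CandidateReport(
                    fragment=frag,
                    decisions=tuple(int(d) for d in row),
                    fusion_score=float(score),
                    label=int(label),
                    single_loop=single,
                )
            )

    summary = {
        "contigs": len(list(contigs)),
        "fragments_total": len(fragments),
        "skipped_ambiguous": skipped_ambiguous,
        "skipped_multiloop": skipped_multiloop,
        "classified": len(reports),
        "positives": int(sum(r.label == 1 for r in reports)),
        "window": config.window,
        "step": config.step,
        "threshold": config.threshold,
        "polarity": config.polarity,
        "seed": config.seed,
    }
    return reports, summary


def merge_candidate_windows(
    reports, min_overlap: int = 1
) -> list[tuple]:
    """Merge runs of overlapping positive windows into candidate regions.

    Consecutive positive windows on one contig/strand overlapping by at
    least *min_overlap* nt collapse to ``(contig, start, end, best_score)``.
    """
    positives = sorted(
        (r for r in reports if r.label == 1),
        key=lambda r: (r.fragment.contig_id, r.fragment.strand, r.fragment.start),
    )
    regions = []
    current = None
    for rep in positives:
        f = rep.fragment
        if (
            current is not None
            and f.contig_id == current[0]
            and f.strand == current[4]
            and f.start <= current[2] - min_overlap
        ):
            current[2] = max(current[2], f.end)
            current[3] = max(current[3], rep.fusion_score)
        else:
            if current is not None:
                regions.append(tuple(current[:4]))
            current = [f.contig_id, f.start, f.end, rep.fusion_score, f.strand]
    if current is not None:
        regions.append(tuple(current[:4]))
    return regions


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------

def write_candidates_tsv(path, reports) -> None:
    """Candidate table; coordinates are 1-based inclusive (see header)."""
    cols = "\t".join(COMMITTEE_ORDER)
    with open(path, "w") as fh:
        fh.write(
            "# coordinates: 1-based, inclusive\n"
            f"contig\tstart\tend\tstrand\t{cols}\tfusion_score\tlabel\n"
        )
        for r in reports:
            f = r.fragment
            decs = "\t".join(str(d) for d in r.decisions)
            fh.write(
                f"{f.contig_id}\t{f.start + 1}\t{f.end}\t{f.strand}\t"
                f"{decs}\t{r.fusion_score:.6f}\t{r.label}\n"
            )


def write_summary_json(path, summary: dict) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")


def write_positive_fasta(path, reports) -> None:
    with open(path, "w") as fh:
        for r in reports:
            if r.label == 1:
                f = r.fragment
                fh.write(f">{f.contig_id}:{f.start + 1}-{f.end}({f.strand})\n")
                fh.write(f"{f.rna}\n")
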