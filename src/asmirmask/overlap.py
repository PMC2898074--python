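"""Sense-antisense overlap mapping.

For each transcript pair, the pairing (duplex-forming) region is taken as
the best local alignment between the sense transcript and the reverse
complement of the antisense transcript, with BLASTN-like scoring.  The
aligned span on each transcript becomes its pairing segment; the remainder
is non-pairing.  Pairs whose overlap is shorter than a minimum (25 nt by
default) are excluded from site scanning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import SequenceRecord, revcomp

logger = logging.getLogger("asmirmask")

MIN_OVERLAP_DEFAULT = 25


@dataclass(frozen=True)
class OverlapParams:
    """BLASTN-like local alignment parameters for overlap detection."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    min_score: float = 30.0

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")


@dataclass(frozen=True)
class TranscriptPair:
    pair_id: str
    sense: SequenceRecord
    antisense: SequenceRecord


@dataclass(frozen=True)
class Segment:
    transcript_id: str
    start: int
    end: int  # 0-based half-open
    seq: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RegionPartition:
    """Pairing and non-pairing segments of one sense-antisense pair.

    Segment coordinates within a transcript are disjoint and tile its full
    length; overlap_len is measured on the sense transcript's aligned span.
    """

    pair_id: str
    sense_id: str
    antisense_id: str
    pairing_segments: list[Segment]
    nonpairing_segments: list[Segment]
    overlap_len: int
    passes_filter: bool
    alignment_score: float = 0.0


def _make_aligner(params: OverlapParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    # explicit matrix so that N never pairs (it scores as mismatch even
    # against another N)
    alphabet = "ACGTN"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            mat[a, b] = params.match if (a == b and a != "N") else params.mismatch
    aligner.substitution_matrix = mat
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _segments(rec: SequenceRecord, span: tuple[int, int] | None) -> tuple[list[Segment], list[Segment]]:
    """(pairing, nonpairing) segments for one transcript given its aligned span."""
    if span is None:
        return [], [Segment(rec.id, 0, len(rec.seq), rec.seq)]
    s, e = span
    pairing = [Segment(rec.id, s, e, rec.seq[s:e])]
    nonpairing = []
    if s > 0:
        nonpairing.append(Segment(rec.id, 0, s, rec.seq[:s]))
    if e < len(rec.seq):
        nonpairing.append(Segment(rec.id, e, len(rec.seq), rec.seq[e:]))
    return pairing, nonpairing


def find_overlap(
    pair: TranscriptPair,
    params: OverlapParams | None = None,
    min_overlap: int = MIN_OVERLAP_DEFAULT,
) -> RegionPartition:
    """Partition a pair into pairing and non-pairing regions.

    The single best local alignment of sense vs revcomp(antisense) defines
    the overlap (no chaining of multiple high-scoring segments); if its
    score is below ``params.min_score`` the overlap is empty.  Among
    equal-scoring optima the aligner's first traceback is taken, which is
    deterministic.
    """
    params = params or OverlapParams()
    aligner = _make_aligner(params)
    rc = revcomp(pair.antisense.seq)
    alignments = aligner.align(pair.sense.seq, rc)
    span_s = span_a = None
    score = 0.0
    try:
        aln = alignments[0]
        score = float(aln.score)
    except (IndexError, ValueError):
        aln = None
    if aln is not None and score >= params.min_score:
        blocks_s, blocks_rc = aln.aligned
        s0, s1 = int(blocks_s[0][0]), int(blocks_s[-1][1])
        r0, r1 = int(blocks_rc[0][0]), int(blocks_rc[-1][1])
        n = len(pair.antisense.seq)
        span_s = (s0, s1)
        span_a = (n - r1, n - r0)
    pair_s, non_s = _segments(pair.sense, span_s)
    pair_a, non_a = _segments(pair.antisense, span_a)
    overlap_len = (span_s[1] - span_s[0]) if span_s else 0
    return RegionPartition(
        pair_id=pair.pair_id,
        sense_id=pair.sense.id,
        antisense_id=pair.antisense.id,
        pairing_segments=pair_s + pair_a,
        nonpairing_segments=non_s + non_a,
        overlap_len=overlap_len,
        passes_filter=overlap_len >= min_overlap,
        alignment_score=score if span_s else 0.0,
    )


def filter_pairs(
    partitions: list[RegionPartition], min_overlap: int = MIN_OVERLAP_DEFAULT
) -> tuple[list[RegionPartition], list[RegionPartition]]:
    """Retain pairs whose overlap length meets the minimum (inclusive)."""
    retained = [p for p in partitions if p.overlap_len >= min_overlap]
    dropped = [p for p in partitions if p.overlap_len < min_overlap]
    pct = 100.0 * len(retained) / len(partitions) if partitions else 0.0
    logger.info(
        "overlap filter (>=%d nt): %d retained (%.1f%%), %d dropped of %d",
        min_overlap, len(retained), pct, len(dropped), len(partitions),
    )
    return retained, dropped
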