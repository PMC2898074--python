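"""miRanda-style miRNA binding-site prediction.

Phase one aligns the reversed miRNA against the target with a local
(Smith-Waterman/Gotoh) dynamic program scoring *complementarity*: A:T and
G:C pair as matches, G:U as wobble, anything else (including N) as
mismatch, with affine gaps.  Per-position scores pairing miRNA seed
positions 2-8 (from the miRNA 5' end) are multiplied by a seed weight,
reflecting the dominant role of seed complementarity in target
recognition.  Phase two filters candidates by nearest-neighbor duplex free
energy (see :mod:`asmirmask.energy`).

The forward pass is vectorized over the target axis (the horizontal-gap
state is resolved with a running-maximum scan, which requires the gap-open
penalty to be at least the gap-extend penalty); tracebacks re-run a small
classic dynamic program on a window around each reported optimum.
Candidates of one miRNA are selected greedily best-first and never overlap
on the target; sites of different miRNAs may overlap freely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .energy import duplex_energy, LOOP_OPEN_PENALTY
from .io import SequenceRecord

logger = logging.getLogger("asmirmask")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_NEG = -1e9


@dataclass(frozen=True)
class ScanParams:
    """Scoring scheme and thresholds of the site scanner.

    Numeric defaults approximate the published miRanda scheme (match +5,
    wobble +1, mismatch -3, affine gaps -8/-2, seed positions 2-8 scaled
    x4); the score and energy thresholds control specificity.
    """

    match: float = 5.0
    wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    seed_scale: float = 4.0
    seed_start: int = 2  # 1-based miRNA position, inclusive
    seed_end: int = 8
    score_threshold: float = 90.0
    energy_threshold: float = -17.0  # kcal/mol, sites must be <= this
    loop_open_penalty: float = LOOP_OPEN_PENALTY

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.seed_scale < 1:
            raise ValueError("seed_scale must be >= 1")
        if self.gap_open > self.gap_extend or self.gap_extend >= 0:
            raise ValueError("require gap_open <= gap_extend < 0")

    def pair_score(self, target_base: str, mirna_base: str) -> float:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        if target_base == "N" or mirna_base == "N":
            return self.mismatch
        if comp.get(mirna_base) == target_base:
            return self.match
        if (target_base, mirna_base) in (("G", "T"), ("T", "G")):
            return self.wobble
        return self.mismatch


@dataclass(frozen=True)
class Candidate:
    """One alignment of a miRNA against a target stretch."""

    score: float
    target_start: int
    target_end: int  # 0-based half-open
    trace: tuple[tuple[int, int], ...]  # (target_index, mirna_index) pairs


@dataclass(frozen=True)
class TargetSite:
    """A predicted miRNA binding site on a transcript."""

    transcript_id: str
    region_class: str  # pairing | nonpairing
    start: int
    end: int  # 0-based half-open, transcript coordinates
    mirna_id: str
    score: float
    energy: float
    strand_scanned: str = "sense"
    pair_id: str = ""
    alignment: tuple[tuple[int, int], ...] = ()


def _score_rows(mirna: str, params: ScanParams) -> np.ndarray:
    """(L x 5) per-row score table: row k = reversed-miRNA position k."""
    L = len(mirna)
    rmir = mirna[::-1]
    rows = np.empty((L, 5))
    for k, mbase in enumerate(rmir):
        pos = L - k  # 1-based position from the miRNA 5' end
        scale = params.seed_scale if params.seed_start <= pos <= params.seed_end else 1.0
        for base, bi in _BASE_INDEX.items():
            rows[k, bi] = params.pair_score(base, mbase) * scale
    return rows


_ENCODE_TABLE = np.full(256, 4, dtype=np.intp)
for _b, _i in _BASE_INDEX.items():
    _ENCODE_TABLE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE_TABLE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _best_cell(rowscores: np.ndarray, tcodes: np.ndarray, open_pen: float,
               ext_pen: float) -> tuple[float, int, int]:
    """Vectorized local Gotoh forward pass; returns (best score, row, col)."""
    L = rowscores.shape[0]
    N = tcodes.shape[0]
    M_prev = np.full(N, _NEG)
    Iy_prev = np.full(N, _NEG)
    B_prev = np.zeros(N)  # max(0, M, Ix, Iy) of the previous row
    best = 0.0
    best_rc = (-1, -1)
    ar = np.arange(N, dtype=float) * ext_pen
    for i in range(L):
        s = rowscores[i, tcodes]
        M_row = np.empty(N)
        M_row[0] = s[0]
        M_row[1:] = s[1:] + B_prev[:-1]
        Iy_row = np.maximum(M_prev - open_pen, Iy_prev - ext_pen)
        # horizontal gap state via running maximum:
        # Ix[j] = max_{k<j} M_row[k] - open - ext*(j-1-k)
        Ix_row = np.full(N, _NEG)
        if N > 1:
            run = np.maximum.accumulate(M_row[:-1] + ar[:-1])
            Ix_row[1:] = run - open_pen + ext_pen - ar[1:]
        row_best = int(np.argmax(M_row))
        if M_row[row_best] > best:
            best = float(M_row[row_best])
            best_rc = (i, row_best)
        B_prev = np.maximum(0.0, np.maximum(M_row, np.maximum(Ix_row, Iy_row)))
        M_prev = M_row
        Iy_prev = Iy_row
    return best, best_rc[0], best_rc[1]


def _forward_full(rows: np.ndarray, tcodes: np.ndarray, open_pen: float,
                  ext_pen: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized local Gotoh storing all three state matrices (L x N)."""
    L, N = rows.shape[0], tcodes.shape[0]
    M = np.empty((L, N))
    Ix = np.empty((L, N))
    Iy = np.empty((L, N))
    B_prev = np.zeros(N)
    ar = np.arange(N, dtype=float) * ext_pen
    for i in range(L):
        s = rows[i, tcodes]
        M[i, 0] = s[0]
        M[i, 1:] = s[1:] + B_prev[:-1]
        if i == 0:
            Iy[i] = _NEG
        else:
            Iy[i] = np.maximum(M[i - 1] - open_pen, Iy[i - 1] - ext_pen)
        Ix[i, 0] = _NEG
        if N > 1:
            run = np.maximum.accumulate(M[i, :-1] + ar[:-1])
            Ix[i, 1:] = run - open_pen + ext_pen - ar[1:]
        B_prev = np.maximum(0.0, np.maximum(M[i], np.maximum(Ix[i], Iy[i])))
    return M, Ix, Iy


def _traceback(mirna: str, target: str, lo: int, hi: int, params: ScanParams
               ) -> tuple[float, tuple[tuple[int, int], ...]]:
    """Best local alignment on target[lo:hi]: vectorized forward pass, then
    a predecessor walk over the stored state matrices.  The trace holds
    global target coordinates and original (5'->3') miRNA indices."""
    L = len(mirna)
    rows = _score_rows(mirna, params)
    tcodes = _encode(target[lo:hi])
    open_pen = -params.gap_open
    ext_pen = -params.gap_extend
    M, Ix, Iy = _forward_full(rows, tcodes, open_pen, ext_pen)
    bi, bj = np.unravel_index(int(np.argmax(M)), M.shape)
    score = float(M[bi, bj])
    tol = 1e-9
    trace: list[tuple[int, int]] = []
    state, i, j = 1, int(bi), int(bj)  # states: 1=M, 2=Ix, 3=Iy
    while True:
        if state == 1:
            trace.append((lo + j, L - 1 - i))
            if i == 0 or j == 0:
                break
            prev = (0.0, M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            want = M[i, j] - rows[i, tcodes[j]]
            state = next(k for k, v in enumerate(prev) if abs(v - want) <= tol)
            i, j = i - 1, j - 1
            if state == 0:
                break
        elif state == 2:
            if abs(M[i, j - 1] - open_pen - Ix[i, j]) <= tol:
                state = 1
            j -= 1
        else:
            if abs(M[i - 1, j] - open_pen - Iy[i, j]) <= tol:
                state = 1
            i -= 1
    trace.reverse()
    return score, tuple(trace)


def align_mirna(mirna: SequenceRecord | str, target: str, params: ScanParams | None = None
                ) -> list[Candidate]:
    """All non-overlapping local complementarity optima above the score
    threshold, greedily selected best-first.

    The reversed miRNA is aligned against the target 5'->3' (the duplex is
    antiparallel); trace entries give (target_index, mirna_index) with
    miRNA indices counted from the miRNA 5' end.
    """
    params = params or ScanParams()
    mseq = mirna.seq if isinstance(mirna, SequenceRecord) else mirna
    if len(mseq) < 7:
        raise ValueError("miRNA shorter than 7 nt: no seed to align")
    if len(mseq) < 16:
        logger.warning("miRNA of %d nt is unusually short", len(mseq))
    if not target:
        raise ValueError("empty target")
    rows = _score_rows(mseq, params)
    tcodes = _encode(target)
    open_pen = -params.gap_open
    ext_pen = -params.gap_extend
    window = len(mseq) + 16

    out: list[Candidate] = []
    intervals = [(0, len(target))]
    while intervals:
        lo, hi = intervals.pop()
        if hi - lo < 1:
            continue
        best, _, bj = _best_cell(rows, tcodes[lo:hi], open_pen, ext_pen)
        if best < params.score_threshold:
            continue
        j_end = lo + bj + 1  # half-open end of the best alignment
        score, trace = _traceback(mseq, target, max(lo, j_end - window), min(hi, j_end), params)
        if abs(score - best) > 1e-6:
            # optimum not contained in the window (long gapped alignment):
            # fall back to a full traceback over the interval
            score, trace = _traceback(mseq, target, lo, hi, params)
        t_start, t_end = trace[0][0], trace[-1][0] + 1
        out.append(Candidate(score=score, target_start=t_start, target_end=t_end, trace=trace))
        intervals.append((lo, t_start))
        intervals.append((t_end, hi))
    out.sort(key=lambda c: (-c.score, c.target_start))
    return out


def scan_regions(
    mirnas: Iterable[SequenceRecord],
    partition,
    params: ScanParams | None = None,
    strands: str = "both",
) -> list[TargetSite]:
    """Scan every region segment of a pair against every miRNA.

    ``strands="both"`` (default) scans the segments of both transcripts;
    ``"sense"`` restricts to the sense transcript.  Candidates failing the
    energy threshold are dropped; surviving sites carry their region class.
    """
    params = params or ScanParams()
    if strands not in ("both", "sense"):
        raise ValueError(f"unknown strands mode {strands!r}")
    sites: list[TargetSite] = []
    for cls, segments in (("pairing", partition.pairing_segments),
                          ("nonpairing", partition.nonpairing_segments)):
        for seg in segments:
            if strands == "sense" and seg.transcript_id != partition.sense_id:
                continue
            if seg.end - seg.start < 7:
                logger.info("segment %s[%d,%d) shorter than 7 nt; skipped",
                            seg.transcript_id, seg.start, seg.end)
                continue
            strand = "sense" if seg.transcript_id == partition.sense_id else "antisense"
            for mir in mirnas:
                for cand in align_mirna(mir, seg.seq, params):
                    energy = duplex_energy(cand.trace, seg.seq, mir.seq,
                                           params.loop_open_penalty)
                    if energy > params.energy_threshold:
                        continue
                    shifted = tuple((t + seg.start, m) for t, m in cand.trace)
                    sites.append(TargetSite(
                        transcript_id=seg.transcript_id,
                        region_class=cls,
                        start=seg.start + cand.target_start,
                        end=seg.start + cand.target_end,
                        mirna_id=mir.id,
                        score=cand.score,
                        energy=energy,
                        strand_scanned=strand,
                        pair_id=partition.pair_id,
                        alignment=shifted,
                    ))
    return sites
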