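"""Synthetic sense-antisense pair sets with known, planted ground truth.

Each pair is built around a duplex ``core``: the sense transcript carries
the core flanked by non-pairing sequence, the antisense transcript carries
the exact reverse complement of the core (with its own flanks by default),
so the overlap mapper must recover the core coordinates.  miRNA-
complementary sites are planted as a Poisson process at separately
configurable per-nucleotide rates in the pairing and non-pairing regions.
Default rates and pair count mirror the aggregate densities the enrichment
analysis is designed to detect (0.0521 sites/nt in overlaps vs 0.0708 in
flanks, 391 pairs).

Two details matter for interpreting ground truth:

* Region lengths follow the both-strands scanning convention: the pairing
  length of a pair is twice the core length (both transcripts contribute),
  and planted pairing sites are split between the two strands.

* Site counts are drawn first (they are the Poisson ground truth consumed
  by the enrichment statistics); physical insertion then places each
  22-mer without overlapping previous insertions where possible.  At
  study-scale rates non-overlapping placement saturates (0.0708/nt exceeds
  the 1/22 per nt packing bound), in which case a site is written over
  earlier ones and any clobbered insertion is flagged ``intact=False``.
  At the low rates used for sequence-level recovery tests every planted
  site stays intact.

An 8-nt "insulator" block (sense side from {A,C}, antisense side chosen so
its reverse complement reads {G,T}) borders the core on every transcript,
so a local alignment can never extend across the planted duplex boundary
and the core coordinates are recovered exactly.  Insulators count toward
non-pairing length but never host planted sites.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .enrichment import DensityRecord
from .io import PairTable, SequenceRecord, revcomp

logger = logging.getLogger("asmirmask")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _str_to_codes(seq: str) -> np.ndarray:
    lut = np.zeros(256, dtype=np.int64)
    for i, c in enumerate(b"ACGT"):
        lut[c] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class SyntheticConfig:
    """Geometry, planting rates and background model of a synthetic set."""

    n_pairs: int = 391
    overlap_len_range: tuple[int, int] = (400, 1400)
    flank_len_range: tuple[int, int] = (500, 1500)  # per non-pairing flank
    rate_pairing: float = 0.0521  # planted sites per nt of pairing region
    rate_nonpairing: float = 0.0708
    mirna_panel_size: int = 20
    mirna_len: int = 22
    gc_content: float = 0.5
    mismatch_rate: float = 0.0  # per-base mutation rate inside planted sites
    antisense_flanks: bool = True
    insulator_len: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        for lo, hi in (self.overlap_len_range, self.flank_len_range):
            if lo <= 0 or hi < lo:
                raise ValueError("length ranges must be positive and ordered")
        if self.rate_pairing < 0 or self.rate_nonpairing < 0:
            raise ValueError("rates must be >= 0")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")
        if self.mirna_len < 7:
            raise ValueError("mirna_len must be >= 7")
        if self.overlap_len_range[0] < 25:
            logger.warning(
                "overlap_len_range minimum %d below the default 25-nt filter",
                self.overlap_len_range[0],
            )
        if self.rate_pairing > 0 and self.overlap_len_range[0] < self.mirna_len:
            raise ValueError("overlap too short to host a planted site")
        if self.rate_nonpairing > 0 and self.flank_len_range[0] < self.mirna_len:
            raise ValueError("flanks too short to host a planted site")


@dataclass(frozen=True)
class PlantedSite:
    pair_id: str
    transcript_id: str
    region_class: str  # pairing | nonpairing
    start: int
    end: int  # 0-based half-open transcript coordinates
    mirna_id: str
    intact: bool = True  # False if a later insertion overwrote part of it


@dataclass
class GroundTruth:
    """Everything the generator knows: planted sites and region lengths."""

    sites: list[PlantedSite]
    region_lengths: dict[str, dict[str, int]]  # pair_id -> class -> nt
    core_spans: dict[str, tuple[str, int, int]]  # pair_id -> (sense_id, start, end)

    def to_density_records(self) -> list[DensityRecord]:
        counts: dict[tuple[str, str], int] = defaultdict(int)
        for s in self.sites:
            counts[(s.pair_id, s.region_class)] += 1
        out = []
        for pair_id in sorted(self.region_lengths):
            for cls in ("pairing", "nonpairing"):
                L = self.region_lengths[pair_id][cls]
                if L > 0:
                    out.append(DensityRecord(
                        pair_id=pair_id, region_class=cls,
                        site_count=counts.get((pair_id, cls), 0), length_nt=L,
                    ))
        return out

    def intact_sites(self) -> list[PlantedSite]:
        return [s for s in self.sites if s.intact]


class GeneratedPairSet(NamedTuple):
    transcripts: list[SequenceRecord]
    pair_table: PairTable
    ground_truth: GroundTruth
    mirnas: list[SequenceRecord]


def generate_mirna_panel(size: int, length: int = 22, gc: float = 0.5,
                         rng_seed=0) -> list[SequenceRecord]:
    """Random mature-miRNA-like panel; deterministic under seed."""
    if size < 1:
        raise ValueError("panel size must be >= 1")
    rng = _as_rng(rng_seed)
    return [
        SequenceRecord(id=f"mir{i:04d}",
                       seq=_codes_to_str(_random_codes(rng, length, gc)),
                       source_alphabet="RNA")
        for i in range(size)
    ]


class _Region:
    """A mutable stretch of sequence accepting non-overlapping insertions."""

    def __init__(self, codes: np.ndarray):
        self.codes = codes
        self.occupied = np.zeros(len(codes), dtype=bool)
        self.placed: list[tuple[int, int, int]] = []  # (start, end, site_index)

    def place(self, insert: np.ndarray, rng: np.random.Generator,
              attempts: int = 100) -> tuple[int, list[int]]:
        """Insert ``insert`` at a random non-overlapping position; if none is
        found in ``attempts`` draws, overwrite at the first draw and return
        the indices of clobbered earlier insertions."""
        w = len(insert)
        hi = len(self.codes) - w
        if hi < 0:
            raise ValueError("region shorter than the site to plant")
        pos_try = rng.integers(0, hi + 1, size=attempts)
        clobbered: list[int] = []
        chosen = -1
        for p in pos_try:
            if not self.occupied[p:p + w].any():
                chosen = int(p)
                break
        if chosen < 0:
            chosen = int(pos_try[0])
            clobbered = [idx for (s, e, idx) in self.placed
                         if s < chosen + w and chosen < e]
        self.codes[chosen:chosen + w] = insert
        self.occupied[chosen:chosen + w] = True
        return chosen, clobbered


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    if rate <= 0:
        return codes, True
    hits = rng.random(len(codes)) < rate
    if not hits.any():
        return codes, True
    out = codes.copy()
    out[hits] = (out[hits] + rng.integers(1, 4, size=int(hits.sum()))) % 4
    return out, False


def generate_pair_set(cfg: SyntheticConfig, rng=None,
                      mirnas: list[SequenceRecord] | None = None) -> GeneratedPairSet:
    """Build a full synthetic pair set with ground truth.

    Deterministic under (cfg, seed).  Returns transcripts, the pair table,
    the ground truth (planted sites, region lengths, core coordinates) and
    the miRNA panel used for planting.
    """
    rng = _as_rng(cfg.seed if rng is None else rng)
    if mirnas is None:
        mirnas = generate_mirna_panel(cfg.mirna_panel_size, cfg.mirna_len,
                                      cfg.gc_content, rng)
    mir_codes = [_str_to_codes(m.seq) for m in mirnas]
    rc_mir_codes = [_str_to_codes(revcomp(m.seq)) for m in mirnas]

    ins_len = cfg.insulator_len
    # insulator alphabets: sense side {A,C}; antisense side chosen so that
    # revcomp(antisense insulator) reads over {G,T} -> never equal to the
    # sense side in the overlap alignment
    def _insulator(n: int) -> np.ndarray:
        return rng.choice([0, 1], size=n)  # codes for A, C

    transcripts: list[SequenceRecord] = []
    rows: list[tuple[str, str]] = []
    sites: list[PlantedSite] = []
    region_lengths: dict[str, dict[str, int]] = {}
    core_spans: dict[str, tuple[str, int, int]] = {}
    n_saturated = 0

    for i in range(cfg.n_pairs):
        pair_id = f"pair{i:04d}"
        sense_id, anti_id = f"{pair_id}_s", f"{pair_id}_as"
        core_len = int(rng.integers(cfg.overlap_len_range[0], cfg.overlap_len_range[1] + 1))
        flank_lens = {
            "s_l": int(rng.integers(cfg.flank_len_range[0], cfg.flank_len_range[1] + 1)),
            "s_r": int(rng.integers(cfg.flank_len_range[0], cfg.flank_len_range[1] + 1)),
        }
        if cfg.antisense_flanks:
            flank_lens["a_l"] = int(rng.integers(cfg.flank_len_range[0], cfg.flank_len_range[1] + 1))
            flank_lens["a_r"] = int(rng.integers(cfg.flank_len_range[0], cfg.flank_len_range[1] + 1))

        core = _Region(_random_codes(rng, core_len, cfg.gc_content))
        flanks = {k: _Region(_random_codes(rng, n, cfg.gc_content))
                  for k, n in flank_lens.items()}

        n_ins_blocks = 4 if cfg.antisense_flanks else 2
        pairing_len = 2 * core_len
        nonpairing_len = sum(flank_lens.values()) + n_ins_blocks * ins_len

        pending: list[dict] = []  # site records before final coordinates

        # --- pairing region: events split between the two strands ---
        n_pair_sites = int(rng.poisson(cfg.rate_pairing * pairing_len))
        for _ in range(n_pair_sites):
            mi = int(rng.integers(len(mirnas)))
            on_sense = bool(rng.integers(2))
            insert = rc_mir_codes[mi] if on_sense else mir_codes[mi]
            insert, intact = _mutate(insert, cfg.mismatch_rate, rng)
            pos, clobbered = core.place(insert, rng)
            if clobbered:
                n_saturated += 1
                for idx in clobbered:
                    pending[idx]["intact"] = False
            core.placed.append((pos, pos + len(insert), len(pending)))
            pending.append(dict(
                region="core", on_sense=on_sense, pos=pos, w=len(insert),
                mirna_id=mirnas[mi].id, intact=intact, cls="pairing",
            ))

        # --- non-pairing region: events over the flanks ---
        n_np_sites = int(rng.poisson(cfg.rate_nonpairing * nonpairing_len))
        flank_keys = list(flank_lens)
        weights = np.array([flank_lens[k] for k in flank_keys], dtype=float)
        weights /= weights.sum()
        for _ in range(n_np_sites):
            mi = int(rng.integers(len(mirnas)))
            fk = flank_keys[int(rng.choice(len(flank_keys), p=weights))]
            insert, intact = _mutate(rc_mir_codes[mi], cfg.mismatch_rate, rng)
            pos, clobbered = flanks[fk].place(insert, rng)
            if clobbered:
                n_saturated += 1
                for idx in clobbered:
                    pending[idx]["intact"] = False
            flanks[fk].placed.append((pos, pos + len(insert), len(pending)))
            pending.append(dict(
                region=fk, pos=pos, w=len(insert),
                mirna_id=mirnas[mi].id, intact=intact, cls="nonpairing",
            ))

        # --- assembly ---
        ins = {k: _insulator(ins_len) for k in ("sL", "sR", "aL", "aR")}
        sense_codes = np.concatenate([
            flanks["s_l"].codes, ins["sL"], core.codes, ins["sR"], flanks["s_r"].codes,
        ])
        rc_core = 3 - core.codes[::-1]
        if cfg.antisense_flanks:
            anti_codes = np.concatenate([
                flanks["a_l"].codes, ins["aL"], rc_core, ins["aR"], flanks["a_r"].codes,
            ])
            anti_core_off = flank_lens["a_l"] + ins_len
        else:
            anti_codes = rc_core
            anti_core_off = 0
            nonpairing_len = sum(flank_lens.values()) + 2 * ins_len

        sense_core_off = flank_lens["s_l"] + ins_len
        offsets = {
            "s_l": (sense_id, 0),
            "s_r": (sense_id, sense_core_off + core_len + ins_len),
        }
        if cfg.antisense_flanks:
            offsets["a_l"] = (anti_id, 0)
            offsets["a_r"] = (anti_id, anti_core_off + core_len + ins_len)

        for rec in pending:
            if rec["cls"] == "pairing":
                if rec["on_sense"]:
                    tid = sense_id
                    start = sense_core_off + rec["pos"]
                else:
                    tid = anti_id
                    start = anti_core_off + (core_len - rec["pos"] - rec["w"])
            else:
                tid, off = offsets[rec["region"]]
                start = off + rec["pos"]
            sites.append(PlantedSite(
                pair_id=pair_id, transcript_id=tid, region_class=rec["cls"],
                start=start, end=start + rec["w"], mirna_id=rec["mirna_id"],
                intact=rec["intact"],
            ))

        transcripts.append(SequenceRecord(sense_id, _codes_to_str(sense_codes)))
        transcripts.append(SequenceRecord(anti_id, _codes_to_str(anti_codes)))
        rows.append((sense_id, anti_id))
        region_lengths[pair_id] = {"pairing": pairing_len, "nonpairing": nonpairing_len}
        core_spans[pair_id] = (sense_id, sense_core_off, sense_core_off + core_len)

    if n_saturated:
        logger.warning(
            "generate_pair_set: %d insertions could not be placed without "
            "overlap after 100 attempts and overwrote earlier sites "
            "(planting rates near or above the 1/site-length packing bound)",
            n_saturated,
        )
    table = PairTable(rows=rows, provenance=f"synthetic seed={cfg.seed}")
    truth = GroundTruth(sites=sites, region_lengths=region_lengths, core_spans=core_spans)
    return GeneratedPairSet(transcripts, table, truth, mirnas)


def sample_density_records(
    n_pairs: int,
    rate_pairing: float,
    rate_nonpairing: float,
    overlap_len_range: tuple[int, int] = (400, 1400),
    nonpairing_len_range: tuple[int, int] = (2000, 6000),
    rng=None,
) -> list[DensityRecord]:
    """Count-level emulation of a synthetic pair set.

    Samples only the (site count, region length) records the enrichment
    statistics consume — pairing length is twice a drawn overlap length and
    counts are Poisson at the planted rates — without assembling sequence.
    Used for statistical calibration at repetition counts where building
    sequence sets adds nothing.
    """
    rng = _as_rng(rng)
    out: list[DensityRecord] = []
    for i in range(n_pairs):
        pid = f"pair{i:04d}"
        lp = 2 * int(rng.integers(overlap_len_range[0], overlap_len_range[1] + 1))
        ln = int(rng.integers(nonpairing_len_range[0], nonpairing_len_range[1] + 1))
        out.append(DensityRecord(pid, "pairing", int(rng.poisson(rate_pairing * lp)), lp))
        out.append(DensityRecord(pid, "nonpairing", int(rng.poisson(rate_nonpairing * ln)), ln))
    return out


def shuffle_sequence(seq: str, mode: str = "mono", rng_seed=0) -> str:
    """Shuffle a sequence preserving composition.

    ``mono`` preserves the exact base composition; ``dinucleotide``
    preserves the dinucleotide count vector (Euler-path shuffle after
    Altschul & Erickson).  Deterministic under seed.
    """
    if not seq:
        raise ValueError("empty sequence")
    rng = _as_rng(rng_seed)
    if mode == "mono":
        return "".join(rng.permutation(list(seq)))
    if mode != "dinucleotide":
        raise ValueError(f"unknown shuffle mode {mode!r}")
    if len(set(seq)) == 1 or len(seq) < 3:
        return seq
    first, last = seq[0], seq[-1]
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    vertices = [v for v in sorted(set(seq))]
    # draw random "last edges" until they form an arborescence into `last`
    for _ in range(10000):
        last_edge = {}
        ok = True
        for v in vertices:
            if v == last:
                continue
            outs = edges[v]
            if not outs:
                ok = False
                break
            last_edge[v] = outs[int(rng.integers(len(outs)))]
        if not ok:
            continue
        reaches = {last}
        good = True
        for v in vertices:
            path = []
            u = v
            while u not in reaches:
                if u in path or u == last or u not in last_edge:
                    good = False
                    break
                path.append(u)
                u = last_edge[u]
            if not good:
                break
            reaches.update(path)
        if good:
            break
    else:  # pragma: no cover - the walk terminates with probability 1
        raise RuntimeError("dinucleotide shuffle failed to find an Euler order")
    order: dict[str, list[str]] = {}
    for v in vertices:
        outs = list(edges[v])
        if v != last:
            outs.remove(last_edge[v])
        perm = [outs[j] for j in rng.permutation(len(outs))] if outs else []
        if v != last:
            perm.append(last_edge[v])
        order[v] = perm
    ptr = defaultdict(int)
    walk = [first]
    cur = first
    while ptr[cur] < len(order.get(cur, [])):
        nxt = order[cur][ptr[cur]]
        ptr[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)
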