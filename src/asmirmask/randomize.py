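"""Monte Carlo randomization null for the enrichment comparison.

The observed Wilcoxon comparison is re-computed on simulated pairing /
non-pairing datasets built from the pooled region records, keeping the
class sizes of the real data.  Two null constructions are provided:

* ``label_permutation`` (default): the cached per-region (site count,
  length) records are reassigned to the two simulated classes uniformly at
  random — no sequence is touched and no re-scanning happens, so the
  multiset of records is exactly conserved across randomizations.
* ``nucleotide_shuffle``: every region sequence is shuffled (mono- or
  dinucleotide-preserving), the shuffled sequences are randomly split into
  the two classes and re-scanned, and densities are recomputed.  This
  destroys planted/true sites and is far more expensive.

The randomization p-value is x / n_reps, where x counts randomizations
whose comparison metric (Wilcoxon p, or W) is strictly smaller than the
real data's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .enrichment import DensityRecord, EnrichmentResults, wilcoxon_rank_sum
from .scanner import ScanParams, align_mirna
from .simulate import _as_rng, shuffle_sequence
from .io import SequenceRecord

logger = logging.getLogger("asmirmask")


@dataclass
class RegionPool:
    """Pooled region records (and, for shuffle mode, their sequences).

    ``sequences`` maps (pair_id, region_class) to the list of segment
    sequences of that record; required only for ``nucleotide_shuffle``.
    """

    records: list[DensityRecord]
    sequences: dict[tuple[str, str], list[str]] | None = None
    mirnas: list[SequenceRecord] | None = None
    scan_params: ScanParams | None = None

    def class_sizes(self) -> tuple[int, int]:
        n_p = sum(1 for r in self.records if r.region_class == "pairing")
        return n_p, len(self.records) - n_p


@dataclass(frozen=True)
class RandomizationResult:
    n_reps: int
    x: int  # randomizations with metric strictly smaller than observed
    p_randomization: float  # x / n_reps exactly
    mode: str
    metric: str
    seed: object
    observed_w: float
    observed_p: float

    def __post_init__(self) -> None:
        if not (0 <= self.x <= self.n_reps):
            raise ValueError("x out of range")


def _scan_count(seq: str, mirnas, params: ScanParams) -> int:
    from .energy import duplex_energy

    n = 0
    if len(seq) < 7:
        return 0
    for mir in mirnas:
        for cand in align_mirna(mir, seq, params):
            e = duplex_energy(cand.trace, seq, mir.seq, params.loop_open_penalty)
            if e <= params.energy_threshold:
                n += 1
    return n


def randomize_once(pool: RegionPool, rng, mode: str = "label_permutation",
                   shuffle_mode: str = "mono") -> tuple[float, float]:
    """One simulated (W, p) under the null.

    ``label_permutation`` permutes class labels over the cached records;
    ``nucleotide_shuffle`` shuffles each region sequence, randomly splits the
    regions into classes of the real sizes and re-runs the scanner.
    """
    rng = _as_rng(rng)
    n_p, n_np = pool.class_sizes()
    if n_p == 0 or n_np == 0:
        raise ValueError("both classes must be represented in the pool")
    if mode == "label_permutation":
        dens = np.array([r.density for r in pool.records])
        perm = rng.permutation(len(dens))
        a = dens[perm[:n_p]]
        b = dens[perm[n_p:]]
        res = wilcoxon_rank_sum(a, b)
        return res.statistic, res.pvalue
    if mode != "nucleotide_shuffle":
        raise ValueError(f"unknown randomization mode {mode!r}")
    if pool.sequences is None or pool.mirnas is None:
        raise ValueError("nucleotide_shuffle mode needs pool.sequences and pool.mirnas")
    params = pool.scan_params or ScanParams()
    sim_dens = []
    for rec in pool.records:
        segs = pool.sequences[(rec.pair_id, rec.region_class)]
        count = 0
        for seq in segs:
            shuffled = shuffle_sequence(seq, mode=shuffle_mode, rng_seed=rng)
            count += _scan_count(shuffled, pool.mirnas, params)
        sim_dens.append(count / rec.length_nt)
    sim_dens = np.array(sim_dens)
    perm = rng.permutation(len(sim_dens))
    res = wilcoxon_rank_sum(sim_dens[perm[:n_p]], sim_dens[perm[n_p:]])
    return res.statistic, res.pvalue


def randomization_test(
    observed: EnrichmentResults | tuple[float, float],
    pool: RegionPool,
    n_reps: int = 1000,
    mode: str = "label_permutation",
    metric: str = "p",
    rng_seed=0,
    shuffle_mode: str = "mono",
) -> RandomizationResult:
    """Monte Carlo randomization test; p = x / n_reps.

    x counts randomizations whose metric (Wilcoxon ``p``, or ``W``) is
    strictly smaller than the observed one — ties count toward
    not-smaller.  Fully deterministic under seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if metric not in ("p", "W"):
        raise ValueError(f"unknown metric {metric!r}")
    if isinstance(observed, EnrichmentResults):
        obs_w, obs_p = observed.wilcoxon.statistic, observed.wilcoxon.pvalue
    else:
        obs_w, obs_p = observed
    obs_val = obs_p if metric == "p" else obs_w
    rng = _as_rng(rng_seed)
    x = 0
    for _ in range(n_reps):
        w, p = randomize_once(pool, rng, mode=mode, shuffle_mode=shuffle_mode)
        sim_val = p if metric == "p" else w
        if sim_val < obs_val:
            x += 1
    result = RandomizationResult(
        n_reps=n_reps, x=x, p_randomization=x / n_reps, mode=mode,
        metric=metric, seed=rng_seed, observed_w=obs_w, observed_p=obs_p,
    )
    logger.info("randomization test: x=%d of %d (%s, metric=%s) -> p=%.4g",
                x, n_reps, mode, metric, result.p_randomization)
    return result
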