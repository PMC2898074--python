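"""End-to-end pipeline: pair resolution -> overlap partition -> site scan
-> density enrichment -> randomization null.

Every stage logs its input counts and filter losses so the pair accounting
(listed -> usable -> retained for scanning) is auditable, and the final
summary JSON carries the statistics, the seeds and the parameters used.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .enrichment import EnrichmentResults, MirnaSiteEnrichment
from .io import (PairTable, SequenceRecord, index_records, write_density_table,
                 write_partition_table, write_site_table, write_summary_json)
from .overlap import (MIN_OVERLAP_DEFAULT, OverlapParams, RegionPartition,
                      TranscriptPair, filter_pairs, find_overlap)
from .randomize import RandomizationResult, RegionPool, randomization_test
from .scanner import ScanParams, TargetSite, scan_regions

logger = logging.getLogger("asmirmask")


@dataclass(frozen=True)
class FilterAccounting:
    """Pair bookkeeping across the pipeline's filters."""

    n_listed: int  # rows in the input pair table
    n_unresolved: int  # rows whose ids do not resolve against the FASTA
    n_usable: int  # n_listed - n_unresolved
    n_retained: int  # usable pairs with overlap >= min_overlap
    n_dropped: int  # usable pairs below the overlap filter
    pct_retained: float  # 100 * n_retained / n_usable

    @classmethod
    def build(cls, n_listed: int, n_unresolved: int, n_retained: int) -> "FilterAccounting":
        n_usable = n_listed - n_unresolved
        pct = 100.0 * n_retained / n_usable if n_usable else 0.0
        return cls(n_listed=n_listed, n_unresolved=n_unresolved, n_usable=n_usable,
                   n_retained=n_retained, n_dropped=n_usable - n_retained,
                   pct_retained=pct)


@dataclass
class PipelineResult:
    accounting: FilterAccounting
    partitions: list[RegionPartition]
    retained: list[RegionPartition]
    sites: list[TargetSite]
    enrichment: EnrichmentResults
    randomization: RandomizationResult | None

    def summary_dict(self, seed=None, params: Mapping | None = None) -> dict:
        out = {
            "accounting": asdict(self.accounting),
            "enrichment": self.enrichment.to_dict(),
            "seed": seed,
            "parameters": dict(params or {}),
        }
        if self.randomization is not None:
            out["randomization"] = {
                "n_reps": self.randomization.n_reps,
                "x": self.randomization.x,
                "p_randomization": self.randomization.p_randomization,
                "mode": self.randomization.mode,
                "metric": self.randomization.metric,
            }
        return out


def partition_pairs(
    transcripts: Sequence[SequenceRecord],
    pair_table: PairTable,
    overlap_params: OverlapParams | None = None,
    min_overlap: int = MIN_OVERLAP_DEFAULT,
) -> tuple[list[RegionPartition], FilterAccounting]:
    """Resolve pairs against the FASTA and map each pair's overlap."""
    by_id = index_records(transcripts)
    usable, dropped = pair_table.resolve(by_id)
    partitions = []
    for k, (sid, aid) in enumerate(usable.rows):
        pair = TranscriptPair(pair_id=f"pair{k:04d}", sense=by_id[sid],
                              antisense=by_id[aid])
        partitions.append(find_overlap(pair, overlap_params, min_overlap))
    retained, _ = filter_pairs(partitions, min_overlap)
    acc = FilterAccounting.build(len(pair_table), len(dropped), len(retained))
    logger.info(
        "accounting: %d listed -> %d usable -> %d retained (%.1f%%)",
        acc.n_listed, acc.n_usable, acc.n_retained, acc.pct_retained,
    )
    return partitions, acc


def run_pipeline(
    transcripts: Sequence[SequenceRecord],
    mirnas: Sequence[SequenceRecord],
    pair_table: PairTable,
    overlap_params: OverlapParams | None = None,
    scan_params: ScanParams | None = None,
    min_overlap: int = MIN_OVERLAP_DEFAULT,
    strands: str = "both",
    n_reps: int = 1000,
    mode: str = "label_permutation",
    metric: str = "p",
    seed=0,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis; optionally write all tables to ``out_dir``."""
    scan_params = scan_params or ScanParams()
    partitions, accounting = partition_pairs(transcripts, pair_table,
                                             overlap_params, min_overlap)
    retained = [p for p in partitions if p.passes_filter]
    if not retained:
        raise ValueError("no pair passes the overlap filter; nothing to scan")
    sites: list[TargetSite] = []
    for part in retained:
        sites.extend(scan_regions(mirnas, part, scan_params, strands))
    logger.info("scanned %d pairs: %d predicted sites", len(retained), len(sites))
    model = MirnaSiteEnrichment.from_sites(sites, retained, strands)
    enrichment = model.fit()
    randomization = None
    if n_reps > 0:
        pool = RegionPool(records=model.records)
        randomization = randomization_test(enrichment, pool, n_reps=n_reps,
                                           mode=mode, metric=metric, rng_seed=seed)
    result = PipelineResult(accounting=accounting, partitions=partitions,
                            retained=retained, sites=sites,
                            enrichment=enrichment, randomization=randomization)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_partition_table(partitions, out_dir / "partitions.tsv")
        write_site_table(sites, out_dir / "sites.tsv")
        write_density_table(model.records, out_dir / "densities.tsv")
        write_summary_json(result.summary_dict(seed=seed), out_dir / "summary.json")
    return result
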