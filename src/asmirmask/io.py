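"""Readers and writers for the external formats of the pipeline.

Transcripts and mature miRNAs arrive as FASTA (DNA or RNA alphabet);
sense-antisense pair lists as TSV.  Everything is normalized onto a single
internal DNA alphabet {A,C,G,T,N} (RNA U mapped to T) so that the overlap
aligner, the site scanner and the shufflers all compare sequences the same
way.  Internally all coordinates are 0-based half-open; every written table
uses 1-based inclusive coordinates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("asmirmask")

# IUPAC nucleotide codes; ambiguity codes other than N are collapsed to N
# (they occur in real transcript sets but never pair in any downstream step).
_IUPAC = set("ACGTUNRYSWKMBDHV")
_AMBIGUOUS = set("RYSWKMBDHV")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement on the internal DNA alphabet (N -> N)."""
    return seq.translate(COMPLEMENT)[::-1]


def normalize_sequence(raw: str, record_id: str, line: int | None = None) -> tuple[str, str]:
    """Uppercase, map U->T, collapse ambiguity codes to N.

    Returns (normalized_seq, source_alphabet) where source_alphabet is
    "RNA" if a U was seen (and no T), else "DNA".
    """
    up = raw.upper()
    bad = set(up) - _IUPAC
    if bad:
        where = f" near line {line}" if line is not None else ""
        raise ValueError(
            f"record '{record_id}'{where} contains non-IUPAC characters: "
            + ",".join(sorted(bad))
        )
    alphabet = "RNA" if ("U" in up and "T" not in up) else "DNA"
    seq = up.replace("U", "T")
    if set(seq) & _AMBIGUOUS:
        seq = "".join("N" if c in _AMBIGUOUS else c for c in seq)
    return seq, alphabet


@dataclass(frozen=True)
class SequenceRecord:
    """A transcript or mature miRNA on the internal DNA alphabet."""

    id: str
    seq: str
    source_alphabet: str = "DNA"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty sequence id")
        if not self.seq:
            raise ValueError(f"record '{self.id}' has an empty sequence")
        extra = set(self.seq) - set("ACGTN")
        if extra:
            raise ValueError(
                f"record '{self.id}' holds non-normalized characters: {sorted(extra)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path, alphabet_policy: str = "auto") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, in file order.

    alphabet_policy: "DNA", "RNA" or "auto".  With "RNA", U is expected and
    mapped to T; with "auto" the alphabet is inferred per record.  The header
    token before the first whitespace becomes the id; duplicate ids are an
    error.
    """
    path = Path(path)
    if alphabet_policy not in ("DNA", "RNA", "auto"):
        raise ValueError(f"unknown alphabet policy: {alphabet_policy!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise ValueError(f"duplicate FASTA id '{rid}' in {path}")
        seen.add(rid)
        if len(rec.seq) == 0:
            raise ValueError(f"empty FASTA record '{rid}' in {path}")
        seq, inferred = normalize_sequence(str(rec.seq), rid)
        alphabet = inferred if alphabet_policy == "auto" else alphabet_policy
        records.append(SequenceRecord(id=rid, seq=seq, source_alphabet=alphabet))
    logger.info("read_fasta: %d records from %s", len(records), path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def index_records(records: Iterable[SequenceRecord]) -> dict[str, SequenceRecord]:
    out: dict[str, SequenceRecord] = {}
    for rec in records:
        if rec.id in out:
            raise ValueError(f"duplicate id '{rec.id}' in record set")
        out[rec.id] = rec
    return out


@dataclass
class PairTable:
    """Ordered list of (sense_id, antisense_id) rows."""

    rows: list[tuple[str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.rows)) != len(self.rows):
            raise ValueError("duplicate sense/antisense pairs in pair table")

    def __len__(self) -> int:
        return len(self.rows)

    def resolve(
        self, records: Mapping[str, SequenceRecord]
    ) -> tuple["PairTable", list[tuple[str, str]]]:
        """Split rows into those whose ids both resolve and those that do not."""
        usable = [r for r in self.rows if r[0] in records and r[1] in records]
        dropped = [r for r in self.rows if r not in set(usable)]
        logger.info(
            "pair table: %d rows listed, %d unresolvable, %d usable",
            len(self.rows), len(dropped), len(usable),
        )
        return PairTable(rows=usable, provenance=self.provenance), dropped


def read_pair_table(path: str | Path, provenance: str = "") -> PairTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sense_id", "antisense_id"):
        if col not in df.columns:
            raise ValueError(f"pair table {path} misses required column '{col}'")
    rows = list(zip(df["sense_id"], df["antisense_id"]))
    if not rows:
        logger.warning("pair table %s is empty (header only)", path)
    logger.info("read_pair_table: %d rows from %s", len(rows), path)
    return PairTable(rows=rows, provenance=provenance or str(path))


def write_pair_table(table: PairTable, path: str | Path) -> None:
    df = pd.DataFrame(table.rows, columns=["sense_id", "antisense_id"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# site / density / partition tables

SITE_COLUMNS = [
    "transcript_id", "start", "end", "strand_scanned", "mirna_id",
    "region_class", "score", "energy_kcal_mol",
]


def write_site_table(sites: Sequence, path: str | Path) -> None:
    """Write predicted sites as TSV, 1-based inclusive coordinates.

    Deterministically sorted by (transcript_id, start, mirna_id) so equal
    site sets produce byte-identical files.
    """
    rows = [
        {
            "transcript_id": s.transcript_id,
            "start": s.start + 1,
            "end": s.end,
            "strand_scanned": s.strand_scanned,
            "mirna_id": s.mirna_id,
            "region_class": s.region_class,
            "score": f"{s.score:.2f}",
            "energy_kcal_mol": f"{s.energy:.2f}",
        }
        for s in sites
    ]
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    if len(df):
        df = df.sort_values(["transcript_id", "start", "mirna_id"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Read a site table back; coordinates converted to internal 0-based half-open."""
    df = pd.read_csv(path, sep="\t")
    if len(df):
        df["start"] = df["start"] - 1
    return df


DENSITY_COLUMNS = [
    "pair_id", "sense_id", "antisense_id", "region_class",
    "site_count", "length_nt", "density_per_nt", "density_per_100nt",
]


def write_density_table(records: Sequence, path: str | Path) -> None:
    """Per pair and region class: site count, scanned length, densities.

    Mirrors the shape of the study's supplementary pair listing; densities
    printed to 5 decimals.
    """
    rows = []
    for r in records:
        if r.length_nt <= 0:
            raise ValueError(f"density record for pair '{r.pair_id}' has length_nt <= 0")
        rows.append(
            {
                "pair_id": r.pair_id,
                "sense_id": getattr(r, "sense_id", ""),
                "antisense_id": getattr(r, "antisense_id", ""),
                "region_class": r.region_class,
                "site_count": r.site_count,
                "length_nt": r.length_nt,
                "density_per_nt": f"{r.site_count / r.length_nt:.5f}",
                "density_per_100nt": f"{100.0 * r.site_count / r.length_nt:.5f}",
            }
        )
    pd.DataFrame(rows, columns=DENSITY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_density_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


PARTITION_COLUMNS = [
    "pair_id", "transcript_id", "region_class", "start", "end", "overlap_len",
    "passes_filter",
]


def write_partition_table(partitions: Sequence, path: str | Path) -> None:
    """Region segments of each pair, 1-based inclusive coordinates."""
    rows = []
    for part in partitions:
        for cls, segs in (("pairing", part.pairing_segments),
                          ("nonpairing", part.nonpairing_segments)):
            for seg in segs:
                rows.append(
                    {
                        "pair_id": part.pair_id,
                        "transcript_id": seg.transcript_id,
                        "region_class": cls,
                        "start": seg.start + 1,
                        "end": seg.end,
                        "overlap_len": part.overlap_len,
                        "passes_filter": part.passes_filter,
                    }
                )
    pd.DataFrame(rows, columns=PARTITION_COLUMNS).to_csv(path, sep="\t", index=False)


def write_summary_json(summary: Mapping, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_config(path: str | Path | None) -> dict:
    """Flat key-value YAML config; CLI flags override config values."""
    if path is None:
        return {}
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    return cfg
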