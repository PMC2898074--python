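"""Shared fixtures: small synthetic pair sets with known ground truth."""

import pytest

from asmirmask import (SyntheticConfig, TranscriptPair, find_overlap,
                       generate_pair_set)


@pytest.fixture(scope="session")
def small_set():
    """20 pairs with low planted rates: every insertion stays intact."""
    cfg = SyntheticConfig(
        n_pairs=20, overlap_len_range=(100, 300), flank_len_range=(150, 400),
        rate_pairing=0.005, rate_nonpairing=0.01, mirna_panel_size=8, seed=42,
    )
    return generate_pair_set(cfg)


@pytest.fixture(scope="session")
def small_partitions(small_set):
    by_id = {r.id: r for r in small_set.transcripts}
    parts = []
    for sid, aid in small_set.pair_table.rows:
        pair = TranscriptPair(pair_id=sid[:-2], sense=by_id[sid], antisense=by_id[aid])
        parts.append(find_overlap(pair))
    return parts
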