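"""Nearest-neighbor RNA:RNA duplex free energy.

Stability of a predicted miRNA:target duplex is estimated by summing
published nearest-neighbor stacking free energies over consecutive paired
positions, plus a duplex initiation penalty and a terminal AU/GU penalty —
the thermodynamic filter of the two-phase (complementarity, then energy)
site-prediction scheme.

Parameters: Turner 2004 RNA:RNA DeltaG(37 C) stack table (Watson-Crick and
G:U wobble stacks), duplex initiation +4.10 kcal/mol, terminal AU/GU
penalty +0.50 kcal/mol per helix end.  The published table is asymmetric
by <= 0.1 kcal/mol from rounding; we symmetrize each stack with its 180
degree rotation.  Interior loops/bulges contribute a fixed opening penalty
(the scanner needs only a coarse destabilization term, not a full loop
model).  Sequences are held in the internal DNA alphabet (U as T).
"""

from __future__ import annotations

import logging
from typing import Sequence

logger = logging.getLogger("asmirmask")

DUPLEX_INITIATION = 4.10  # kcal/mol
TERMINAL_AU_PENALTY = 0.50  # per helix end closed by an A:U or G:U pair
LOOP_OPEN_PENALTY = 3.5  # per interior loop / bulge opening

# Pair order of the published stack table (RNA letters CG GC GU UG AU UA),
# here in the internal DNA alphabet.
_PAIR_ORDER = ("CG", "GC", "GT", "TG", "AT", "TA")

# M[row][col] = DeltaG37 (kcal/mol) for the stack with outer pair
# (top1, bot1) = row and inner pair written as col = (bot2, top2):
#   5'-top1 top2-3'
#   3'-bot1 bot2-5'
_STACK_MATRIX = (
    (-2.40, -3.30, -2.10, -1.40, -2.10, -2.10),  # CG
    (-3.30, -3.40, -2.50, -1.50, -2.20, -2.40),  # GC
    (-2.10, -2.50, +1.30, -0.50, -1.40, -1.30),  # GU
    (-1.40, -1.50, -0.50, +0.30, -0.60, -1.00),  # UG
    (-2.10, -2.20, -1.40, -0.60, -1.10, -0.90),  # AU
    (-2.10, -2.40, -1.30, -1.00, -0.90, -1.30),  # UA
)

WATSON_CRICK = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "T"), ("T", "G")}


def is_paired(b1: str, b2: str) -> bool:
    """True if b1:b2 is a Watson-Crick or G:U wobble pair (N never pairs)."""
    return (b1, b2) in WATSON_CRICK or (b1, b2) in WOBBLE


def _build_stacks() -> dict[tuple[str, str, str, str], float]:
    idx = {p: i for i, p in enumerate(_PAIR_ORDER)}
    raw: dict[tuple[str, str, str, str], float] = {}
    for t1, b1 in [tuple(p) for p in _PAIR_ORDER]:
        for t2, b2 in [tuple(p) for p in _PAIR_ORDER]:
            raw[(t1, b1, t2, b2)] = _STACK_MATRIX[idx[t1 + b1]][idx[b2 + t2]]
    # symmetrize with the 180-degree rotated reading of the same stack
    out: dict[tuple[str, str, str, str], float] = {}
    for (t1, b1, t2, b2), g in raw.items():
        out[(t1, b1, t2, b2)] = 0.5 * (g + raw[(b2, t2, b1, t1)])
    return out


STACKS = _build_stacks()


def stack_energy(top1: str, bot1: str, top2: str, bot2: str) -> float:
    """DeltaG37 of the stack 5'-top1 top2-3' / 3'-bot1 bot2-5' (kcal/mol)."""
    key = (top1, bot1, top2, bot2)
    if key not in STACKS:
        raise KeyError(f"not a stack of two canonical/wobble pairs: {key}")
    return STACKS[key]


def duplex_energy(
    trace: Sequence[tuple[int, int]],
    target: str,
    mirna: str,
    loop_open_penalty: float = LOOP_OPEN_PENALTY,
) -> float:
    """Free energy (kcal/mol, more negative = more stable) of an alignment.

    ``trace`` lists aligned positions (target_index, mirna_index); the duplex
    is antiparallel, so miRNA indices decrease as target indices increase.
    Only positions whose bases actually pair (Watson-Crick or wobble)
    contribute helix; aligned mismatches and gaps count as interior loop
    content, charged one fixed opening penalty per loop.
    """
    paired = sorted(
        (t, m) for t, m in trace if is_paired(target[t], mirna[m])
    )
    if not paired:
        logger.warning("duplex_energy: no paired positions in trace; energy 0")
        return 0.0
    energy = DUPLEX_INITIATION
    for (t1, m1), (t2, m2) in zip(paired, paired[1:]):
        if t2 == t1 + 1 and m2 == m1 - 1:
            energy += stack_energy(target[t1], mirna[m1], target[t2], mirna[m2])
        else:
            energy += loop_open_penalty
    for t, m in (paired[0], paired[-1]):
        if (target[t], mirna[m]) not in (("G", "C"), ("C", "G")):
            energy += TERMINAL_AU_PENALTY
    return energy
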