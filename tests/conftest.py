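"""Shared fixtures: constructed repeat pairs and simulated contigs.

Constructed records place the two repeat copies between homopolymer flanks
arranged so that every flank-vs-flank alignment column is a C-against-G
mismatch: the first copy is padded with C runs, the second with G runs, and
the copies sit further apart than twice the aligner's padding so the pads
never overlap. Flank columns can then neither align as matches nor look
like adenine-specific substitutions, which pins alignment boundaries
exactly and keeps tests of the substitution arithmetic free of boundary
refinement effects.
"""

from __future__ import annotations

import numpy as np
import pytest

from dgrfinder.seqio import SequenceRecord
from dgrfinder.simulate import SimParams, generate_dgr_contig

# 60 bp template: 10 AAY codons interleaved with GTC codons -> 20 adenines,
# 10 AAY triplets, and any mutation pattern leaves a long exact k-mer run
# when confined to the first 42 bp.
TEMPLATE_60 = ("AAC" + "GTC") * 10

# adenine / non-adenine positions away from the copy edges, so constructed
# substitutions are unambiguous parts of the repeat rather than boundary
# refinement cases
INTERIOR_A = [i for i, c in enumerate(TEMPLATE_60) if c == "A" and 5 < i < 54]
INTERIOR_G = [i for i, c in enumerate(TEMPLATE_60) if c == "G" and 8 < i < 50]

PAD = 120  # longer than the aligner's seed_pad so flanks dominate


GAP = 240  # > 2 * ScanParams.seed_pad


def make_pair_record(tr: str, vr: str, rec_id: str = "constructed") -> tuple[SequenceRecord, tuple[int, int], tuple[int, int]]:
    """Embed tr and vr between mutually non-matching homopolymer flanks.

    Returns the record plus 1-based inclusive (start, end) spans of the two
    copies.
    """
    seq = "C" * PAD + tr + "C" * (GAP // 2) + "G" * (GAP // 2) + vr + "G" * PAD
    a = (PAD + 1, PAD + len(tr))
    b_start = PAD + len(tr) + GAP + 1
    b = (b_start, b_start + len(vr) - 1)
    return SequenceRecord(id=rec_id, seq=seq), a, b


def mutate_at(template: str, positions: list[int], base_map=None) -> str:
    """Substitute at 0-based positions; A -> G by default, else cycle."""
    cycle = {"A": "G", "C": "G", "G": "C", "T": "C"}
    out = list(template)
    for p in positions:
        out[p] = (base_map or cycle)[out[p]]
    return "".join(out)


def random_bases(n: int, seed: int, gc: float = 0.45) -> str:
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(np.array(list("ACGT")), size=n, p=p))


@pytest.fixture(scope="session")
def sim_contig():
    """One default simulated contig with full truth (seed 1)."""
    return generate_dgr_contig(SimParams(seed=1))


@pytest.fixture(scope="session")
def sim_contig_no_rt():
    return generate_dgr_contig(SimParams(seed=2, include_rt=False))
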