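"""Synthetic DGR contig generator with machine-readable ground truth.

Every other module is testable without downloads: this module implants a
minimal DGR system — a reverse-transcriptase coding sequence, a template
region (TR), and a target ORF whose C-terminal codons contain the variable
region (VR) — into an i.i.d. random background contig, and returns the
exact coordinates and substituted positions as truth.

The VR is derived from the TR by adenine-specific substitution: exactly
``n_a_subs`` adenines of the TR (preferring adenines inside AAY triplets,
where real DGR hypervariation concentrates) are replaced by a random base
drawn uniformly from {C, G, T}, plus ``n_non_a_subs`` optional off-target
substitutions at non-adenine positions. The defaults (110 bp TR, 9 adenine
substitutions, no off-target substitutions, 50 kb contig) emulate the
repeat divergence of reported DGR systems, whose template regions run
roughly 60–160 bp.

The bundled RT coding sequence is synthetic: designed in silico around
canonical RT motifs and reverse-translated with a fixed seed (see
``data/synthetic_rt_cds.fasta``); it is not a natural sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from .seqio import GeneModel, Interval, SequenceRecord, write_fasta
from .pairfinder import count_aay

__all__ = [
    "SimParams",
    "SyntheticTruth",
    "make_tr",
    "mutate_tr_to_vr",
    "generate_dgr_contig",
    "bundled_rt_cds",
    "bundled_rt_protein",
    "write_truth_gff",
    "write_genes_gff",
]

_BASES = np.array(list("ACGT"))


def bundled_rt_cds() -> str:
    """The synthetic reverse-transcriptase coding sequence shipped as data."""
    text = resources.files("dgrfinder.data").joinpath("synthetic_rt_cds.fasta").read_text()
    return "".join(line.strip() for line in text.splitlines() if not line.startswith(">"))


def bundled_rt_protein() -> str:
    """Translation of the bundled RT coding sequence (stop removed)."""
    return str(Seq(bundled_rt_cds()).translate()).rstrip("*")


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated contig."""

    contig_len: int = 50_000
    gc: float = 0.45
    tr_len: int = 110
    n_a_subs: int = 9
    n_non_a_subs: int = 0
    include_rt: bool = True
    include_target: bool = True
    rt_cds: str = ""  # empty -> bundled synthetic RT CDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr_len < 60:
            raise ValueError("tr_len must be >= 60")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        if self.n_a_subs < 0 or self.n_non_a_subs < 0:
            raise ValueError("substitution counts must be non-negative")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth coordinates of the implanted components (1-based)."""

    tr: Interval
    vr: Interval
    rt: Optional[Interval]
    target_gene: Optional[Interval]
    substituted_positions: tuple  # (tr_pos within TR, tr_base, vr_base)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def make_tr(tr_len: int, gc: float = 0.45, seed: int = 0) -> str:
    """Build a random template region guaranteed to pass the AAY prefilter.

    ``max(3, tr_len // 20)`` AAY (AAC/AAT) codons are placed at
    codon-spaced offsets on top of an i.i.d. background, so an implant is
    never lost to the AAY speedup filter.
    """
    if tr_len < 60:
        raise ValueError("tr_len must be >= 60")
    rng = np.random.default_rng(seed)
    seq = list(_random_bases(rng, tr_len, gc))
    n_codons = tr_len // 3
    needed = max(3, tr_len // 20)
    codon_idx = rng.permutation(n_codons)[:needed]
    for c in sorted(codon_idx):
        off = 3 * int(c)
        seq[off] = "A"
        seq[off + 1] = "A"
        seq[off + 2] = "C" if rng.integers(2) == 0 else "T"
    tr = "".join(seq)
    assert count_aay(tr) >= needed
    return tr


def _aay_adenine_positions(tr: str) -> set[int]:
    pos = set()
    for i in range(len(tr) - 2):
        if tr[i] == "A" and tr[i + 1] == "A" and tr[i + 2] in "CT":
            pos.update((i, i + 1))
    return pos


def mutate_tr_to_vr(
    tr: str, n_a_subs: int, n_non_a_subs: int = 0, seed: int = 0
) -> tuple[str, list[tuple[int, str, str]]]:
    """Derive a variable region by adenine-specific substitution of ``tr``.

    Exactly ``n_a_subs`` adenine positions (preferring adenines inside AAY
    triplets) receive a uniform random base from {C, G, T}; exactly
    ``n_non_a_subs`` non-adenine positions receive a different non-adenine
    base, so every substitution column is unambiguous about which copy
    carries the adenine. Returns the VR and 1-based
    ``(tr_pos, tr_base, vr_base)`` tuples sorted by position.
    """
    rng = np.random.default_rng(seed)
    a_positions = [i for i, b in enumerate(tr) if b == "A"]
    if len(a_positions) < n_a_subs:
        raise ValueError(
            f"template has {len(a_positions)} adenines; cannot place {n_a_subs} substitutions"
        )
    preferred = sorted(set(a_positions) & _aay_adenine_positions(tr))
    others = sorted(set(a_positions) - set(preferred))
    chosen: list[int] = list(rng.permutation(preferred)[:n_a_subs])
    if len(chosen) < n_a_subs:
        chosen += list(rng.permutation(others)[: n_a_subs - len(chosen)])
    chosen = sorted(int(i) for i in chosen)

    non_a_positions = [i for i, b in enumerate(tr) if b != "A"]
    if len(non_a_positions) < n_non_a_subs:
        raise ValueError("not enough non-adenine positions")
    chosen_non_a = sorted(int(i) for i in rng.permutation(non_a_positions)[:n_non_a_subs])

    vr = list(tr)
    subs: list[tuple[int, str, str]] = []
    for i in chosen:
        vr[i] = str(rng.choice([b for b in "CGT"]))
        subs.append((i + 1, tr[i], vr[i]))
    for i in chosen_non_a:
        options = [b for b in "CGT" if b != tr[i]]
        vr[i] = str(rng.choice(options))
        subs.append((i + 1, tr[i], vr[i]))
    subs.sort()
    return "".join(vr), subs


def generate_dgr_contig(
    params: SimParams,
) -> tuple[SequenceRecord, SyntheticTruth, list[GeneModel]]:
    """Generate one contig with an implanted DGR system plus ground truth.

    Component order along the contig: RT coding sequence (optional), TR,
    spacer, target ORF whose final codons contain the VR with its 3' end
    16 bp upstream of the stop (inside the 60 bp C-terminal buffer). All
    placements are deterministic under ``params.seed``; identical params
    give byte-identical output.
    """
    rng = np.random.default_rng(params.seed)
    rt_cds = params.rt_cds or bundled_rt_cds()
    tr_seed = int(rng.integers(0, 2**31 - 1))
    vr_seed = int(rng.integers(0, 2**31 - 1))
    tr = make_tr(params.tr_len, params.gc, seed=tr_seed)
    vr, subs = mutate_tr_to_vr(tr, params.n_a_subs, params.n_non_a_subs, seed=vr_seed)

    margin = 1000
    spacer1 = int(rng.integers(1000, 3000))
    spacer2 = int(rng.integers(300, 800))
    filler_len = 300
    tail_len = 13 if (3 + filler_len + params.tr_len + 3) % 3 != 0 else 12
    # gene length must be a codon multiple
    while (3 + filler_len + params.tr_len + tail_len + 3) % 3 != 0:
        tail_len += 1

    pos = margin  # 0-based running offset
    rt_iv = None
    if params.include_rt:
        rt_start = pos
        pos += len(rt_cds)
        rt_iv = (rt_start, pos)  # 0-based half-open
        pos += spacer1
    tr_start = pos
    pos += params.tr_len
    pos += spacer2
    gene_iv = None
    if params.include_target:
        gene_start = pos
        vr_start = gene_start + 3 + filler_len
        gene_end = vr_start + params.tr_len + tail_len + 3
        gene_iv = (gene_start, gene_end)
        pos = gene_end
    else:
        vr_start = pos
        pos += params.tr_len
    required = pos + margin
    if params.contig_len < required:
        raise ValueError(
            f"contig_len {params.contig_len} too short; need at least {required} bp"
        )

    background = list(_random_bases(rng, params.contig_len, params.gc))

    def implant(start: int, s: str) -> None:
        background[start : start + len(s)] = list(s)

    if rt_iv is not None:
        implant(rt_iv[0], rt_cds)
    implant(tr_start, tr)
    if gene_iv is not None:
        filler = _random_bases(rng, filler_len, params.gc)
        filler = _strip_stops(filler)
        tail = _random_bases(rng, tail_len, params.gc)
        gene_seq = "ATG" + filler + vr + tail + "TAA"
        implant(gene_iv[0], gene_seq)
    else:
        implant(vr_start, vr)
    seq = "".join(background)

    rec_id = f"sim_contig_{params.seed}"
    record = SequenceRecord(id=rec_id, seq=seq, description="synthetic DGR implant")
    truth = SyntheticTruth(
        tr=Interval(rec_id, tr_start + 1, tr_start + params.tr_len, "+"),
        vr=Interval(rec_id, vr_start + 1, vr_start + params.tr_len, "+"),
        rt=Interval(rec_id, rt_iv[0] + 1, rt_iv[1], "+") if rt_iv else None,
        target_gene=Interval(rec_id, gene_iv[0] + 1, gene_iv[1], "+") if gene_iv else None,
        substituted_positions=tuple(subs),
    )
    genes: list[GeneModel] = []
    if rt_iv is not None:
        genes.append(
            GeneModel(
                id=f"{rec_id}_rt",
                location=truth.rt,
                product="reverse transcriptase (synthetic implant)",
            )
        )
    if gene_iv is not None:
        genes.append(
            GeneModel(
                id=f"{rec_id}_target",
                location=truth.target_gene,
                product="hypothetical protein (synthetic DGR target)",
            )
        )
    return record, truth, genes


_STOPS = ("TAA", "TAG", "TGA")


def _strip_stops(seq: str) -> str:
    """Replace in-frame stop codons so the target ORF stays open."""
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    return "".join("AAC" if c in _STOPS else c for c in codons)


def write_truth_gff(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        rows = [("template_region", truth.tr), ("variable_region", truth.vr)]
        if truth.rt is not None:
            rows.append(("RT_gene", truth.rt))
        if truth.target_gene is not None:
            rows.append(("target_gene", truth.target_gene))
        for i, (kind, iv) in enumerate(rows, 1):
            fh.write(
                f"{iv.seq_id}\tdgrfinder_sim\t{'CDS' if kind.endswith('gene') else 'repeat_region'}"
                f"\t{iv.start}\t{iv.end}\t.\t{iv.strand}\t.\tID=truth{i};kind={kind}\n"
            )


def write_genes_gff(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            loc = g.location
            fh.write(
                f"{loc.seq_id}\tdgrfinder_sim\tCDS\t{loc.start}\t{loc.end}\t.\t{loc.strand}\t.\t"
                f"ID={g.id};product={g.product}\n"
            )
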