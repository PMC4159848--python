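"""Assembly of repeat pairs, RT hits and gene models into DGR systems.

A minimal complete DGR system is a reverse-transcriptase gene, a template
region, and a variable region lying inside the C-terminal coding region of
a target gene. On fragmented assemblies only some components may be
recoverable, so systems carry an explicit completeness label:

- ``complete``  — RT, at least one TR–VR pair, at least one target gene;
- ``no_rt``     — pair(s) present, no RT evidence on the contig;
- ``no_vr``     — RT and pair present but the VR is not inside any
  C-terminal gene window (no target call);
- ``tr_only``   — a reference-TR match with no partnered VR (similarity
  mode only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import reverse_complement

from .homology import ReferenceTRHit, RTHit, rt_neighborhoods
from .pairfinder import (
    ScanParams,
    TRVRPair,
    _diagonal_segments,
    _encode,
    _kmer_positions,
    align_segments,
    call_tr_vr,
    profile_substitutions,
)
from .seqio import GeneModel, Interval, SequenceRecord

__all__ = [
    "TargetGeneCall",
    "DGRSystem",
    "attach_vr_to_reference_tr",
    "call_target_genes",
    "assemble_systems",
    "cluster_by_identity",
    "find_orfs",
]


@dataclass(frozen=True)
class TargetGeneCall:
    """A gene whose C-terminal coding region contains a variable region.

    ``cterm_offset`` is the distance, measured in the gene's reading
    direction, from the VR's 3'-most position to the gene's stop end:
    positive when the VR ends upstream of the stop, negative when it runs
    past it. Calls require |cterm_offset| within the configured buffer.
    """

    gene: GeneModel
    vr: Interval
    cterm_offset: int


@dataclass
class DGRSystem:
    system_id: str
    rt: Optional[RTHit] = None
    pairs: list = field(default_factory=list)
    reference_tr: Optional[ReferenceTRHit] = None
    targets: list = field(default_factory=list)
    completeness: str = "no_rt"


def attach_vr_to_reference_tr(
    record: SequenceRecord,
    tr_hit: ReferenceTRHit,
    params: ScanParams | None = None,
) -> Optional[TRVRPair]:
    """Search ``record`` for a variable-region partner of a reference-TR hit.

    The hit region is held fixed as one repeat copy and the whole record is
    searched for a second, non-overlapping copy; candidate partners go
    through the standard alignment, profiling and pair-calling rules. The
    best qualifying pair (most adenine substitutions) is returned, or None,
    in which case the system stays ``tr_only``.
    """
    params = params or ScanParams()
    hit_iv = tr_hit.location
    hit_fwd = hit_iv.slice_of(record.seq)
    hit_seq = reverse_complement(hit_fwd) if hit_iv.strand == "-" else hit_fwd

    contig = _encode(record.seq)
    n = len(record.seq)
    k = params.seed_kmer
    contig_index = _kmer_positions(record.seq, k, params.max_kmer_occ)
    best: Optional[TRVRPair] = None
    for strand, query in (("+", hit_seq), ("-", reverse_complement(hit_seq))):
        q = _encode(query)
        m = len(query)
        diags: set[int] = set()
        for i in range(m - k + 1):
            for p in contig_index.get(query[i : i + k], ()):
                diags.add(p - i)
        for d in sorted(diags):
            lo, hi = max(0, -d), min(m, n - d)
            if hi - lo < params.min_pair_len:
                continue
            for s, e in _diagonal_segments(
                q[lo:hi], contig[lo + d : hi + d], params.min_pair_len, params.seed_min_identity
            ):
                cand = Interval(record.id, lo + d + s + 1, lo + d + e, strand if hit_iv.strand == "+" else ("-" if strand == "+" else "+"))
                if cand.overlaps(hit_iv):
                    continue
                a_iv, b_iv = (hit_iv, cand) if hit_iv.start <= cand.start else (cand, hit_iv)
                # align_segments reads copy_b via its strand; normalise so
                # copy_a is treated as forward
                if a_iv.strand == "-" and b_iv.strand == "-":
                    a_iv = Interval(a_iv.seq_id, a_iv.start, a_iv.end, "+")
                    b_iv = Interval(b_iv.seq_id, b_iv.start, b_iv.end, "+")
                elif a_iv.strand == "-":
                    a_iv = Interval(a_iv.seq_id, a_iv.start, a_iv.end, "+")
                    b_iv = Interval(b_iv.seq_id, b_iv.start, b_iv.end, "-")
                try:
                    aln = align_segments(record, a_iv, b_iv, params)
                except ValueError:
                    continue
                if aln.copy_a.overlaps(aln.copy_b):
                    continue
                profile = profile_substitutions(aln)
                pair = call_tr_vr(record, aln, profile, params)
                if pair is not None and (best is None or pair.a_subs > best.a_subs):
                    best = pair
    return best


def call_target_genes(
    pair: TRVRPair,
    genes: Sequence[GeneModel],
    params: ScanParams | None = None,
) -> list[TargetGeneCall]:
    """Call target genes for one TR–VR pair.

    A gene is called when the VR overlaps its coding span and the VR's
    3'-most gene-oriented coordinate lies within ``vr_cterm_buffer`` bp of
    the gene's stop end — the C-terminal placement that DGR variable
    proteins share. Calls are sorted by |cterm_offset|.
    """
    params = params or ScanParams()
    vr = pair.vr
    calls: list[TargetGeneCall] = []
    for gene in genes:
        loc = gene.location
        if not vr.overlaps(loc):
            continue
        if loc.strand == "+":
            offset = loc.end - vr.end
        else:
            offset = vr.start - loc.start
        if abs(offset) <= params.vr_cterm_buffer:
            calls.append(TargetGeneCall(gene=gene, vr=vr, cterm_offset=offset))
    calls.sort(key=lambda c: (abs(c.cterm_offset), c.gene.location.start))
    return calls


def assemble_systems(
    record: SequenceRecord,
    pairs: Sequence[TRVRPair],
    rt_hits: Sequence[RTHit] = (),
    ref_tr_hits: Sequence[ReferenceTRHit] = (),
    genes: Sequence[GeneModel] = (),
    params: ScanParams | None = None,
) -> list[DGRSystem]:
    """Group components into DGR systems and label their completeness.

    Each pair attaches to the nearest RT hit whose neighborhood (``rt_flank``
    bp at both ends) contains either repeat copy; pairs sharing an RT form
    one multi-target system. Reference-TR hits that gained no partner are
    emitted as ``tr_only`` partial systems.
    """
    params = params or ScanParams()
    n = len(record.seq)

    def attached_rt(pair: TRVRPair) -> Optional[RTHit]:
        best = None
        best_dist = None
        for hit in rt_hits:
            hood = rt_neighborhoods([hit], n, params.rt_flank)[0]
            for copy in (pair.tr, pair.vr):
                if copy.overlaps(hood):
                    dist = min(
                        abs(copy.start - hit.location.end),
                        abs(hit.location.start - copy.end),
                    )
                    if best_dist is None or dist < best_dist:
                        best, best_dist = hit, dist
        return best

    groups: dict[tuple, list[TRVRPair]] = {}
    group_rt: dict[tuple, Optional[RTHit]] = {}
    for pair in sorted(pairs, key=lambda p: p.tr.start):
        rt = attached_rt(pair)
        key = (
            ("rt", rt.location.start, rt.location.end)
            if rt is not None
            else ("pair", pair.tr.start, pair.tr.end)
        )
        groups.setdefault(key, []).append(pair)
        group_rt[key] = rt

    used_refs = set()
    systems: list[DGRSystem] = []
    for key in sorted(groups, key=lambda k: min(p.tr.start for p in groups[k])):
        members = groups[key]
        rt = group_rt[key]
        targets: list[TargetGeneCall] = []
        for pair in members:
            targets.extend(call_target_genes(pair, genes, params))
        if rt is not None:
            completeness = "complete" if targets else "no_vr"
        else:
            completeness = "no_rt"
        systems.append(
            DGRSystem(
                system_id="",
                rt=rt,
                pairs=list(members),
                targets=targets,
                completeness=completeness,
            )
        )

    paired_spans = [p.tr for s in systems for p in s.pairs] + [
        p.vr for s in systems for p in s.pairs
    ]
    for hit in sorted(ref_tr_hits, key=lambda h: h.location.start):
        if any(hit.location.overlaps(iv) for iv in paired_spans):
            continue
        systems.append(
            DGRSystem(system_id="", reference_tr=hit, completeness="tr_only")
        )

    systems.sort(key=_system_anchor)
    for i, sys_ in enumerate(systems, 1):
        sys_.system_id = f"{record.id}:DGR{i}"
    return systems


def _system_anchor(sys_: DGRSystem) -> int:
    if sys_.pairs:
        return min(p.tr.start for p in sys_.pairs)
    if sys_.reference_tr is not None:
        return sys_.reference_tr.location.start
    return 1


_NT = frozenset("ACGTN")


def _identity_aligner(protein: bool) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    if protein:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
    else:
        aligner.match_score = 2.0
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = -5.0
        aligner.extend_gap_score = -1.0
    return aligner


def _global_identity(a: str, b: str, aligner: PairwiseAligner) -> float:
    """Identity = matching columns / total alignment columns (incl. gaps)."""
    aln = aligner.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    matches = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        matches += sum(1 for i, j in zip(range(a0, a1), range(b0, b1)) if a[i] == b[j])
    columns = aln.length
    return matches / columns if columns else 0.0


def cluster_by_identity(
    seqs: Sequence[SequenceRecord], threshold: float = 0.90
) -> list[list[str]]:
    """Greedy length-sorted clustering at a global-identity threshold.

    Mirrors CD-HIT's incremental strategy: sequences are sorted longest
    first, and each joins the first cluster whose representative it matches
    at ``threshold`` global identity (matches over all alignment columns,
    gaps included), otherwise founds a new cluster. Returns id lists, the
    representative first. Used to de-duplicate DGR systems by their RT
    proteins at 90% identity.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1.0]")
    if not seqs:
        return []
    protein = any(set(s.seq) - _NT for s in seqs)
    aligner = _identity_aligner(protein)
    order = sorted(seqs, key=lambda s: (-len(s.seq), s.id))
    reps: list[SequenceRecord] = []
    clusters: list[list[str]] = []
    for seq in order:
        placed = False
        for rep, cluster in zip(reps, clusters):
            if _global_identity(rep.seq, seq.seq, aligner) >= threshold:
                cluster.append(seq.id)
                placed = True
                break
        if not placed:
            reps.append(seq)
            clusters.append([seq.id])
    return clusters


_STOPS = {"TAA", "TAG", "TGA"}


def find_orfs(record: SequenceRecord, min_len: int = 150) -> list[GeneModel]:
    """Minimal ORF caller (ATG..stop, both strands, >= ``min_len`` bp).

    A fallback source of candidate gene models for target calling when no
    annotation is supplied; reported models carry product "orf_prediction".
    """
    genes: list[GeneModel] = []
    n = len(record.seq)
    counter = 0
    for strand, seq in (("+", record.seq), ("-", reverse_complement(record.seq))):
        for frame in range(3):
            start = None
            for i in range(frame, n - 2, 3):
                codon = seq[i : i + 3]
                if start is None:
                    if codon == "ATG":
                        start = i
                elif codon in _STOPS:
                    length = i + 3 - start
                    if length >= min_len:
                        counter += 1
                        if strand == "+":
                            iv = Interval(record.id, start + 1, i + 3, "+")
                        else:
                            iv = Interval(record.id, n - (i + 3) + 1, n - start, "-")
                        genes.append(
                            GeneModel(id=f"{record.id}_orf{counter}", location=iv, product="orf_prediction")
                        )
                    start = None
    genes.sort(key=lambda g: g.location.start)
    return genes
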