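"""Homology searches that constrain or seed the repeat-pair scan.

Two searches are provided: a translated search of reference
reverse-transcriptase (RT) proteins against all six frames of a contig
(used to restrict the de novo scan to RT neighborhoods), and a nucleotide
search of reference template regions against a contig (the
similarity-guided mode for fragmented assemblies).

Both searches run through BLAST+ (``tblastn``/``blastn``) when the
executables are on PATH, and otherwise through an internal
PairwiseAligner-based fallback that recovers the same loci on the test
fixtures. The backend is selected with ``params.aligner`` (auto, external,
internal).
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq, reverse_complement

from .pairfinder import ScanParams, _diagonal_segments, _encode, _kmer_positions
from .seqio import Interval, SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "RTHit",
    "ReferenceTRHit",
    "find_rt_hits",
    "rt_neighborhoods",
    "find_reference_tr_hits",
]


@dataclass(frozen=True)
class RTHit:
    """A reverse-transcriptase homology hit on a nucleotide sequence."""

    location: Interval
    ref_id: str
    identity: float  # amino-acid level
    aligned_len: int  # amino acids
    score: float
    frame: int  # 1..3 forward, -1..-3 reverse


@dataclass(frozen=True)
class ReferenceTRHit:
    """A nucleotide match of a known template region on an input sequence."""

    location: Interval
    ref_tr_id: str
    identity: float
    aligned_len: int


def _external_available(tool: str) -> bool:
    return shutil.which(tool) is not None


def _run_tblastn(
    record: SequenceRecord, rt_refs: Sequence[SequenceRecord], params: ScanParams
) -> list[RTHit]:
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        query = tmp / "refs.faa"
        subject = tmp / "contig.fna"
        with open(query, "w") as fh:
            for ref in rt_refs:
                fh.write(f">{ref.id}\n{ref.seq}\n")
        with open(subject, "w") as fh:
            fh.write(f">{record.id}\n{record.seq}\n")
        cmd = [
            "tblastn",
            "-query", str(query),
            "-subject", str(subject),
            "-evalue", str(params.rt_max_evalue),
            "-outfmt", "6 qseqid pident length sstart send evalue bitscore sframe",
        ]
        out = subprocess.run(cmd, capture_output=True, text=True, check=True)
    hits: list[RTHit] = []
    for line in out.stdout.splitlines():
        qseqid, pident, length, sstart, send, evalue, bitscore, sframe = line.split("\t")
        identity = float(pident) / 100.0
        aligned_len = int(length)
        if aligned_len < params.rt_min_aln_aa or identity < params.rt_min_identity:
            continue
        s, e = int(sstart), int(send)
        frame = int(sframe)
        start, end = (s, e) if s <= e else (e, s)
        strand = "+" if frame > 0 else "-"
        hits.append(
            RTHit(
                location=Interval(record.id, start, end, strand),
                ref_id=qseqid,
                identity=identity,
                aligned_len=aligned_len,
                score=float(bitscore),
                frame=frame,
            )
        )
    return hits


_PROTEIN_ALIGNER: Optional[PairwiseAligner] = None


def _protein_aligner() -> PairwiseAligner:
    global _PROTEIN_ALIGNER
    if _PROTEIN_ALIGNER is None:
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        _PROTEIN_ALIGNER = aligner
    return _PROTEIN_ALIGNER


def _six_frames(seq: str) -> list[tuple[int, str]]:
    frames = []
    rc = reverse_complement(seq)
    for f in (1, 2, 3):
        for frame, s in ((f, seq), (-f, rc)):
            sub = s[f - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            if sub:
                frames.append((frame, str(Seq(sub).translate())))
    return frames


def _internal_rt_search(
    record: SequenceRecord, rt_refs: Sequence[SequenceRecord], params: ScanParams
) -> list[RTHit]:
    aligner = _protein_aligner()
    n = len(record.seq)
    hits: list[RTHit] = []
    for frame, prot in _six_frames(record.seq):
        safe = prot.replace("*", "X").replace("B", "X").replace("Z", "X").replace("J", "X").replace("U", "X").replace("O", "X")
        for ref in rt_refs:
            ref_seq = ref.seq.replace("*", "X")
            try:
                aln = aligner.align(safe, ref_seq)[0]
            except (IndexError, ValueError):
                continue
            blocks_t, blocks_q = aln.aligned
            if len(blocks_t) == 0:
                continue
            matches = cols = 0
            for (t0, t1), (q0, q1) in zip(blocks_t, blocks_q):
                cols += t1 - t0
                matches += sum(
                    1 for i, j in zip(range(t0, t1), range(q0, q1)) if safe[i] == ref_seq[j]
                )
            if cols == 0:
                continue
            identity = matches / cols
            if cols < params.rt_min_aln_aa or identity < params.rt_min_identity:
                continue
            aa0 = int(blocks_t[0][0])
            aa1 = int(blocks_t[-1][1])
            off = abs(frame) - 1
            nt0 = off + 3 * aa0  # 0-based on the frame's strand
            nt1 = off + 3 * aa1 - 1
            if frame > 0:
                start, end, strand = nt0 + 1, nt1 + 1, "+"
            else:
                start, end, strand = n - nt1, n - nt0, "-"
            hits.append(
                RTHit(
                    location=Interval(record.id, start, end, strand),
                    ref_id=ref.id,
                    identity=identity,
                    aligned_len=cols,
                    score=float(aln.score),
                    frame=frame,
                )
            )
    return hits


def _merge_best(hits: list[RTHit]) -> list[RTHit]:
    """Reduce overlapping hits (possibly to different references) to the best."""
    hits = sorted(hits, key=lambda h: (-h.score, h.location.start, h.ref_id))
    kept: list[RTHit] = []
    for hit in hits:
        if any(hit.location.overlaps(k.location) for k in kept):
            continue
        kept.append(hit)
    kept.sort(key=lambda h: h.location.start)
    return kept


def find_rt_hits(
    record: SequenceRecord,
    rt_refs: Sequence[SequenceRecord],
    params: ScanParams | None = None,
) -> list[RTHit]:
    """Locate putative reverse-transcriptase genes by translated homology.

    All six frames of ``record`` are compared against every reference
    protein; hits shorter than ``rt_min_aln_aa`` amino acids or below
    ``rt_min_identity`` are discarded, and overlapping hits keep only the
    best-scoring reference.
    """
    params = params or ScanParams()
    if not rt_refs:
        raise ValueError("rt_refs must be non-empty")
    backend = params.aligner
    if backend == "auto":
        backend = "external" if _external_available("tblastn") else "internal"
    if backend == "external":
        try:
            hits = _run_tblastn(record, rt_refs, params)
        except (subprocess.CalledProcessError, OSError) as exc:
            logger.warning("external tblastn failed (%s); using internal fallback", exc)
            hits = _internal_rt_search(record, rt_refs, params)
    else:
        hits = _internal_rt_search(record, rt_refs, params)
    return _merge_best(hits)


def rt_neighborhoods(
    hits: Sequence[RTHit], record_len: int, flank: int = 10_000
) -> list[Interval]:
    """Clamped, merged ``flank``-bp neighborhoods around RT hits.

    The de novo repeat scan is restricted to these intervals: a functional
    DGR keeps its template close to the reverse transcriptase, so searching
    within ``flank`` bp at both ends of each RT gene finds the pair at a
    fraction of the whole-sequence cost.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    raw = sorted(
        (max(1, h.location.start - flank), min(record_len, h.location.end + flank), h.location.seq_id)
        for h in hits
    )
    merged: list[Interval] = []
    for start, end, seq_id in raw:
        if merged and start <= merged[-1].end and seq_id == merged[-1].seq_id:
            last = merged.pop()
            merged.append(Interval(seq_id, last.start, max(last.end, end), "+"))
        else:
            merged.append(Interval(seq_id, start, end, "+"))
    return merged


def _blastn_tr_search(
    record: SequenceRecord, ref_trs: Sequence[SequenceRecord], params: ScanParams
) -> list[ReferenceTRHit]:
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        query = tmp / "refs.fna"
        subject = tmp / "contig.fna"
        with open(query, "w") as fh:
            for ref in ref_trs:
                fh.write(f">{ref.id}\n{ref.seq}\n")
        with open(subject, "w") as fh:
            fh.write(f">{record.id}\n{record.seq}\n")
        cmd = [
            "blastn",
            "-task", "blastn",
            "-query", str(query),
            "-subject", str(subject),
            "-evalue", "1e-3",
            "-outfmt", "6 qseqid pident length sstart send bitscore",
        ]
        out = subprocess.run(cmd, capture_output=True, text=True, check=True)
    hits: list[ReferenceTRHit] = []
    for line in out.stdout.splitlines():
        qseqid, pident, length, sstart, send, _bit = line.split("\t")
        identity = float(pident) / 100.0
        aligned_len = int(length)
        if aligned_len < params.ref_tr_min_len or identity < params.ref_tr_min_identity:
            continue
        s, e = int(sstart), int(send)
        start, end, strand = (s, e, "+") if s <= e else (e, s, "-")
        hits.append(
            ReferenceTRHit(
                location=Interval(record.id, start, end, strand),
                ref_tr_id=qseqid,
                identity=identity,
                aligned_len=aligned_len,
            )
        )
    return hits


def _internal_tr_search(
    record: SequenceRecord, ref_trs: Sequence[SequenceRecord], params: ScanParams
) -> list[ReferenceTRHit]:
    """Ungapped diagonal search of each reference TR against both strands.

    A shorter word (8) than the de novo seed is used so that a reference
    copy diverged up to the 30% identity floor still shares an exact word.
    """
    hits: list[ReferenceTRHit] = []
    contig = _encode(record.seq)
    n = len(record.seq)
    k = min(params.seed_kmer, 8)
    contig_index = _kmer_positions(record.seq, k, params.max_kmer_occ)
    for ref in ref_trs:
        for strand, ref_seq in (("+", ref.seq), ("-", reverse_complement(ref.seq))):
            ref_arr = _encode(ref_seq)
            m = len(ref_seq)
            diags: set[int] = set()
            for i in range(m - k + 1):
                for p in contig_index.get(ref_seq[i : i + k], ()):
                    diags.add(p - i)
            for d in sorted(diags):
                lo = max(0, -d)
                hi = min(m, n - d)
                if hi - lo < params.ref_tr_min_len:
                    continue
                a = ref_arr[lo:hi]
                b = contig[lo + d : hi + d]
                for s, e in _diagonal_segments(
                    a, b, params.ref_tr_min_len, params.ref_tr_min_identity
                ):
                    c0 = lo + d + s  # 0-based contig start
                    c1 = lo + d + e
                    ident = float(np.mean(a[s:e] == b[s:e]))
                    hits.append(
                        ReferenceTRHit(
                            location=Interval(record.id, c0 + 1, c1, strand),
                            ref_tr_id=ref.id,
                            identity=ident,
                            aligned_len=e - s,
                        )
                    )
    return hits


def find_reference_tr_hits(
    record: SequenceRecord,
    ref_trs: Sequence[SequenceRecord],
    params: ScanParams | None = None,
) -> list[ReferenceTRHit]:
    """Locate copies of known template regions on ``record``, both strands.

    References shorter than ``ref_tr_min_len`` are skipped with a warning.
    Per reference, overlapping hits are reduced to the best one (by aligned
    length times identity).
    """
    params = params or ScanParams()
    usable = []
    for ref in ref_trs:
        if len(ref.seq) < params.ref_tr_min_len:
            logger.warning(
                "reference TR %s is %d bp (< %d); skipped",
                ref.id, len(ref.seq), params.ref_tr_min_len,
            )
            continue
        usable.append(ref)
    if not usable:
        return []
    backend = params.aligner
    if backend == "auto":
        backend = "external" if _external_available("blastn") else "internal"
    if backend == "external":
        try:
            hits = _blastn_tr_search(record, usable, params)
        except (subprocess.CalledProcessError, OSError) as exc:
            logger.warning("external blastn failed (%s); using internal fallback", exc)
            hits = _internal_tr_search(record, usable, params)
    else:
        hits = _internal_tr_search(record, usable, params)

    reduced: list[ReferenceTRHit] = []
    for ref_id in sorted({h.ref_tr_id for h in hits}):
        own = sorted(
            (h for h in hits if h.ref_tr_id == ref_id),
            key=lambda h: (-h.aligned_len * h.identity, h.location.start),
        )
        kept: list[ReferenceTRHit] = []
        for hit in own:
            if any(hit.location.overlaps(k.location) for k in kept):
                continue
            kept.append(hit)
        reduced.extend(kept)
    reduced.sort(key=lambda h: (h.location.start, h.ref_tr_id))
    return reduced
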