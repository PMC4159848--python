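"""De novo detection of template/variable repeat pairs (TR–VR pairs).

A diversity-generating retroelement (DGR) diversifies a target gene by
copying a template region (TR) into a variable region (VR) through
error-prone reverse transcription that randomizes adenines. The genomic
signature is therefore a pair of similar repeats whose differences sit
almost exclusively at adenine positions of one copy (the TR). This module
finds such pairs:

1. seed stage — ungapped diagonal segments of at least ``seed_min_len`` bp
   at ``seed_min_identity`` or better, located either on diagonals that
   share an exact k-mer (fast path) or on every diagonal (exhaustive mode);
2. refinement — a Smith–Waterman alignment of the seed segments padded by
   ``seed_pad`` bp, so the reported repeat boundaries are the maximal
   well-aligned span and both alignment ends are match/substitution columns;
3. calling — the substitution profile is counted per column and a pair is
   reported when one copy explains at least ``min_a_subs`` substitutions at
   its adenines with fewer than ``max_non_a_frac`` of substitutions at
   non-adenines of that same copy. That copy is the TR; the other is the VR.

Both orientations are searched by default: the VR of a phage or bacterial
DGR may lie on either strand relative to its TR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

from .seqio import Interval, SequenceRecord

__all__ = [
    "ScanParams",
    "SeedMatch",
    "PairAlignment",
    "SubstitutionProfile",
    "TRVRPair",
    "count_aay",
    "passes_aay_filter",
    "find_seed_matches",
    "align_segments",
    "profile_substitutions",
    "call_tr_vr",
    "scan_sequence",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class ScanParams:
    """Every tunable threshold of the scan, in one overridable place.

    The defaults encode the published detection rule: repeat pairs of at
    least 60 bp with 7 or more adenine-specific substitutions, fewer than
    30% of substitutions at non-adenines of the template copy, seeded by
    ungapped matches of at least 60 bp, an AAY-motif prefilter of at least
    3 AAY triplets per 60 bp window, a 10 kbp search neighborhood around
    reverse-transcriptase genes, and a 60 bp C-terminal buffer for target
    gene calls.
    """

    min_pair_len: int = 60
    min_a_subs: int = 7
    max_non_a_frac: float = 0.30  # strict upper bound: exactly 0.30 fails
    seed_min_len: int = 60
    seed_min_identity: float = 0.70
    aay_window: int = 60
    aay_min_count: int = 3
    rt_flank: int = 10_000
    vr_cterm_buffer: int = 60
    max_n_frac: float = 0.10
    both_strands: bool = True
    # implementation knobs (documented in docs/methods.md)
    seed_kmer: int = 11
    seed_pad: int = 100
    use_seed_index: bool = True  # False => exhaustive all-diagonals scan
    aay_filter: bool = True
    max_kmer_occ: int = 100
    # alignment scoring (match/mismatch, affine gaps)
    match_score: float = 2.0
    mismatch_score: float = -2.0
    gap_open_score: float = -6.0
    gap_extend_score: float = -2.0
    # homology-search floors (reverse-transcriptase / reference-TR hits)
    rt_min_aln_aa: int = 100
    rt_min_identity: float = 0.25
    rt_max_evalue: float = 1e-5
    ref_tr_min_len: int = 60
    ref_tr_min_identity: float = 0.70
    aligner: str = "auto"  # auto | external | internal

    def __post_init__(self) -> None:
        for name in ("min_pair_len", "seed_min_len", "aay_window", "seed_kmer"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("max_non_a_frac", "seed_min_identity", "max_n_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_a_subs < 0 or self.rt_flank < 0 or self.vr_cterm_buffer < 0:
            raise ValueError("counts and flanks must be non-negative")

    def without_speedups(self) -> "ScanParams":
        """The exhaustive configuration: no k-mer seeding, no AAY filter."""
        return replace(self, use_seed_index=False, aay_filter=False)


@dataclass(frozen=True)
class SeedMatch:
    """An ungapped candidate repeat: two equal-length segments on one record.

    ``copy_b.strand == "-"`` marks an inverted repeat; both intervals are
    forward-strand coordinates, and copy_a always starts left of copy_b.
    """

    copy_a: Interval
    copy_b: Interval
    length: int
    identity: float


@dataclass(frozen=True)
class PairAlignment:
    """A gapped alignment between two repeat copies.

    ``columns`` holds one tuple per alignment column:
    ``(pos_a, pos_b, base_a, base_b, kind)`` with 1-based forward-strand
    positions (``None`` at a gap) and kind in {match, substitution,
    insertion_a, insertion_b}. ``aligned_b`` is the strand-oriented reading
    of copy_b, i.e. its reverse complement when copy_b is on the minus
    strand.
    """

    copy_a: Interval
    copy_b: Interval
    aligned_a: str
    aligned_b: str
    columns: tuple
    #: half-open column ranges per template assignment
    #: {(bonus_base, copy_index): (lo, hi)}; None means the whole alignment
    variant_spans: Optional[dict] = None

    def span_a(self) -> int:
        return self.copy_a.length()

    def span_b(self) -> int:
        return self.copy_b.length()

    def span_for(self, bonus: str, copy_idx: int) -> tuple[int, int]:
        if self.variant_spans is None:
            return (0, len(self.columns))
        return self.variant_spans[(bonus, copy_idx)]


@dataclass(frozen=True)
class SubstitutionProfile:
    """Substitution counts of a pair alignment, by copy and reading.

    ``subs_at_A_in_a`` counts substitution columns where copy_a carries an
    adenine in its strand-oriented reading; ``subs_at_T_in_a`` counts
    columns where copy_a carries a T, i.e. an adenine when the pair is read
    on the opposite strand. Columns containing N are counted in
    ``total_subs`` only.
    """

    total_subs: int
    subs_at_A_in_a: int
    subs_at_A_in_b: int
    indel_columns: int
    subs_at_T_in_a: int = 0
    subs_at_T_in_b: int = 0


@dataclass(frozen=True)
class TRVRPair:
    """A called template/variable pair; the TR is the adenine-bearing copy."""

    tr: Interval
    vr: Interval
    alignment: PairAlignment
    profile: SubstitutionProfile
    a_subs: int
    non_a_frac: float

    def validate(self, params: ScanParams) -> None:
        assert self.tr.length() >= params.min_pair_len
        assert self.a_subs >= params.min_a_subs
        assert self.non_a_frac < params.max_non_a_frac
        assert not self.tr.overlaps(self.vr)


def count_aay(window: str) -> int:
    """Count AAY triplets (AAC or AAT) at every offset of ``window``.

    Hypervariation in DGRs targets adenines of 5'-AAY-3' asparagine codons,
    which maximizes amino-acid diversity without creating stop codons. The
    count is frame-free because the reading frame is unknown at scan time;
    overlapping occurrences all count.
    """
    n = 0
    for i in range(len(window) - 2):
        if window[i] == "A" and window[i + 1] == "A" and window[i + 2] in "CT":
            n += 1
    return n


def passes_aay_filter(window: str, params: ScanParams) -> bool:
    """True when ``window`` carries at least ``aay_min_count`` AAY triplets."""
    return count_aay(window) >= params.aay_min_count


def _has_aay_window(seq: str, params: ScanParams) -> bool:
    """Any ``aay_window``-sized window of seq (either reading) AAY-rich?

    Both readings are checked so the filter is strand-symmetric; a shorter
    sequence is evaluated as-is.
    """
    w = params.aay_window
    for s in (seq, reverse_complement(seq)):
        if len(s) <= w:
            if passes_aay_filter(s, params):
                return True
            continue
        # sliding count over all windows
        c = count_aay(s[:w])
        if c >= params.aay_min_count:
            return True
        for i in range(1, len(s) - w + 1):
            if s[i - 1] == "A" and s[i] == "A" and s[i + 1] in "CT":
                c -= 1
            j = i + w - 3
            if s[j] == "A" and s[j + 1] == "A" and s[j + 2] in "CT":
                c += 1
            if c >= params.aay_min_count:
                return True
    return False


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _diagonal_segments(
    a: np.ndarray, b: np.ndarray, min_len: int, min_identity: float
) -> list[tuple[int, int]]:
    """Maximal well-matching ungapped segments between two aligned arrays.

    ``a`` and ``b`` are equal-length uint8 views (one diagonal). Returns
    (start, end) index pairs, end exclusive, where every returned segment is
    at least ``min_len`` long, starts and ends on a match, and contains a
    window of ``min_len`` with identity >= ``min_identity``.
    """
    m = a == b
    n = m.size
    if n < min_len:
        return []
    need = int(np.ceil(min_len * min_identity))
    counts = np.convolve(m.astype(np.int32), np.ones(min_len, dtype=np.int32), "valid")
    ok = counts >= need
    if not ok.any():
        return []
    # merge overlapping qualifying windows into runs
    idx = np.flatnonzero(ok)
    segments: list[tuple[int, int]] = []
    run_start = idx[0]
    prev = idx[0]
    match_pos = np.flatnonzero(m)
    for i in idx[1:]:
        if i <= prev + min_len:  # windows overlap or touch -> same segment
            prev = i
            continue
        segments.append((run_start, prev + min_len))
        run_start = i
        prev = i
    segments.append((run_start, prev + min_len))
    # trim each segment to its first/last matching position
    trimmed = []
    for s, e in segments:
        inside = match_pos[(match_pos >= s) & (match_pos < e)]
        if inside.size == 0:
            continue
        s2, e2 = int(inside[0]), int(inside[-1]) + 1
        if e2 - s2 >= min_len:
            trimmed.append((s2, e2))
    return trimmed


def _kmer_positions(seq: str, k: int, max_occ: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return {kmer: pos for kmer, pos in index.items() if len(pos) <= max_occ}


def _forward_diagonals(seq: str, params: ScanParams, exhaustive: bool) -> Iterable[int]:
    n = len(seq)
    if exhaustive:
        yield from range(1, n - params.seed_min_len + 1)
        return
    index = _kmer_positions(seq, params.seed_kmer, params.max_kmer_occ)
    diags: set[int] = set()
    for positions in index.values():
        if len(positions) < 2:
            continue
        for i, p in enumerate(positions):
            for q in positions[i + 1 :]:
                diags.add(q - p)
    yield from sorted(d for d in diags if d > 0)


def _reverse_diagonals(seq: str, rc: str, params: ScanParams, exhaustive: bool) -> Iterable[int]:
    n = len(seq)
    if exhaustive:
        yield from range(-(n - params.seed_min_len), n - params.seed_min_len + 1)
        return
    fwd = _kmer_positions(seq, params.seed_kmer, params.max_kmer_occ)
    rev = _kmer_positions(rc, params.seed_kmer, params.max_kmer_occ)
    diags: set[int] = set()
    for kmer, positions in fwd.items():
        rpos = rev.get(kmer)
        if not rpos:
            continue
        for p in positions:
            for q in rpos:
                diags.add(q - p)
    yield from sorted(diags)


def find_seed_matches(
    record: SequenceRecord,
    params: ScanParams,
    restrict_to: Optional[Sequence[Interval]] = None,
) -> list[SeedMatch]:
    """Find ungapped candidate repeat pairs on ``record``.

    Fast path: only diagonals carrying a shared exact ``seed_kmer``-mer are
    scanned. Exhaustive mode (``params.use_seed_index = False``) scans every
    diagonal with the identical segment-extraction rule, which is the
    brute-force oracle the fast path is tested against. Inverted repeats are
    found by comparing the sequence against its own reverse complement when
    ``both_strands`` is set. Exact self-matches are impossible by
    construction (only off-diagonal, non-overlapping segments qualify).
    """
    seq = record.seq
    n = len(seq)
    arr = _encode(seq)
    exhaustive = not params.use_seed_index
    seeds: list[SeedMatch] = []

    for d in _forward_diagonals(seq, params, exhaustive):
        a, b = arr[: n - d], arr[d:]
        for s, e in _diagonal_segments(a, b, params.seed_min_len, params.seed_min_identity):
            copy_a = Interval(record.id, s + 1, e, "+")
            copy_b = Interval(record.id, s + d + 1, e + d, "+")
            if copy_a.overlaps(copy_b):
                continue
            ident = float(np.mean(arr[s:e] == arr[s + d : e + d]))
            seeds.append(SeedMatch(copy_a, copy_b, e - s, ident))

    if params.both_strands:
        rc = reverse_complement(seq)
        rc_arr = _encode(rc)
        for d in _reverse_diagonals(seq, rc, params, exhaustive):
            if d >= 0:
                a, b = arr[: n - d], rc_arr[d:]
                off_a, off_b = 0, d
            else:
                a, b = arr[-d:], rc_arr[: n + d]
                off_a, off_b = -d, 0
            for s, e in _diagonal_segments(a, b, params.seed_min_len, params.seed_min_identity):
                fa_s, fa_e = off_a + s, off_a + e  # on forward, 0-based half-open
                rb_s, rb_e = off_b + s, off_b + e  # on rc
                fb_s, fb_e = n - rb_e, n - rb_s  # mapped back to forward
                iv_a = Interval(record.id, fa_s + 1, fa_e, "+")
                iv_b = Interval(record.id, fb_s + 1, fb_e, "-")
                if iv_a.overlaps(iv_b):
                    continue
                if iv_a.start > iv_b.start:
                    # the same physical pair reappears mirrored on another
                    # diagonal; keep the left-copy-first representative only
                    continue
                ident = float(np.mean(a[s:e] == b[s:e]))
                seeds.append(SeedMatch(iv_a, iv_b, e - s, ident))

    if restrict_to:
        seeds = [
            sm
            for sm in seeds
            if any(
                _contained(sm.copy_a, iv) or _contained(sm.copy_b, iv)
                for iv in restrict_to
            )
        ]
    seeds.sort(key=lambda sm: (sm.copy_a.start, sm.copy_b.start, -sm.length))
    return seeds


def _contained(inner: Interval, outer: Interval) -> bool:
    return (
        inner.seq_id == outer.seq_id
        and inner.start >= outer.start
        and inner.end <= outer.end
    )


def _make_aligner(params: ScanParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.gap_open_score
    aligner.extend_gap_score = params.gap_extend_score
    return aligner


# Boundary refinement around the Smith-Waterman core.
#
# The core is first trimmed to its maximal-scoring column run under an
# identity score (match +1, substitution -7/3, gap column -3): a run scores
# positive only while local identity stays above the 70% seed floor, which
# removes chance flank pockets that the gapped local alignment can pick up
# in random sequence. The trimmed ends are then re-extended by:
#
# - an identity extension (match +1, anything else -2, X-drop 2) that adds
#   well-matching tail columns and essentially never a substitution;
# - a cluster rescue that re-attaches a dense run of template-consistent
#   substitutions: at least _RESCUE_MIN_SUBS substitutions of one template
#   variant (adenine of copy a or copy b, in forward or reverse-complement
#   reading, the latter seen as T) within _RESCUE_SPAN columns, with no
#   intervening other substitution. Random flanking sequence produces such
#   a run at per-end probability well under a percent, whereas a genuine
#   edge cluster of adenine-specific substitutions (which the identity trim
#   would otherwise discard) matches it exactly. Trying the T variants
#   keeps the scan strand-symmetric.
_EXT_MATCH = 1.0
_EXT_OTHER = -2.0
_EXT_XDROP = 2.0
_TRIM_SUB = -7.0 / 3.0
_TRIM_INDEL = -3.0
_RESCUE_MIN_SUBS = 3
_RESCUE_SPAN = 15


def _column_bases(col: tuple) -> tuple[str, str]:
    return col[2], col[3]


def _trim_core(columns: list[tuple]) -> tuple[int, int]:
    """Maximal identity-scoring column run (Kadane); half-open indices."""
    best_score = 0.0
    best = (0, 0)
    acc = 0.0
    start = 0
    for i, col in enumerate(columns):
        if acc < 0:
            acc, start = 0.0, i
        x, y = _column_bases(col)
        if col[4] == "match" and x != "N":
            acc += 1.0
        elif col[4] == "substitution":
            acc += _TRIM_SUB
        else:
            acc += _TRIM_INDEL
        if acc > best_score:
            best_score = acc
            best = (start, i + 1)
    return best


def _identity_extension(cols: list[tuple]) -> int:
    best = 0.0
    best_k = 0
    acc = 0.0
    for k, col in enumerate(cols, 1):
        x, y = _column_bases(col)
        acc += _EXT_MATCH if (col[4] == "match" and x != "N") else _EXT_OTHER
        if acc > best:
            best, best_k = acc, k
        elif acc < best - _EXT_XDROP:
            break
    return best_k


def _cluster_rescue(cols: list[tuple], bonus: str, copy_idx: int) -> int:
    n_subs = 0
    last_sub = 0
    for k, col in enumerate(cols[:_RESCUE_SPAN], 1):
        x, y = _column_bases(col)
        if "N" in (x, y) or "-" in (x, y):
            break
        if x == y:
            continue
        if (x, y)[copy_idx] != bonus:
            break
        n_subs += 1
        last_sub = k
    return last_sub if n_subs >= _RESCUE_MIN_SUBS else 0


def _terminal_sub(cols: list[tuple], bonus: str, copy_idx: int) -> int:
    """Re-attach 1-2 template-variant substitutions backed by 2 matches."""
    n_subs = 0
    for col in cols[:2]:
        x, y = _column_bases(col)
        if x == y or "N" in (x, y) or "-" in (x, y):
            break
        if (x, y)[copy_idx] != bonus:
            break
        n_subs += 1
    if n_subs == 0 or len(cols) < n_subs + 2:
        return 0
    for col in cols[n_subs : n_subs + 2]:
        cx, cy = _column_bases(col)
        if cx != cy or cx == "N":
            return 0
    return n_subs + 2


_VARIANTS = tuple((bonus, copy_idx) for bonus in ("A", "T") for copy_idx in (0, 1))


def _variant_extension(cols: list[tuple], bonus: str, copy_idx: int) -> int:
    """Extension chain with the substitution-bearing copy and reading fixed.

    Iterates identity extension, cluster rescue and terminal reattachment;
    the chain never accumulates substitutions of mixed template assignment.
    """
    total = 0
    while total < len(cols):
        remaining = cols[total:]
        step = max(
            _identity_extension(remaining),
            _cluster_rescue(remaining, bonus, copy_idx),
            _terminal_sub(remaining, bonus, copy_idx),
        )
        if step == 0:
            break
        total += step
    return total


def _all_extensions(cols: list[tuple]) -> dict:
    return {v: _variant_extension(cols, *v) for v in _VARIANTS}


def align_segments(
    record: SequenceRecord, a: Interval, b: Interval, params: ScanParams
) -> PairAlignment:
    """Align two candidate repeat copies and return the trimmed alignment.

    The copies are padded by ``seed_pad`` bp on each side and aligned
    end-gap-free under the configured scoring; the reported alignment is the
    maximal-scoring contiguous column run under a boundary score that
    rewards matches and adenine-involving substitutions and penalizes other
    substitutions and gaps, so dangling gaps and poorly-matching flanks are
    trimmed while substitution clusters at true repeat edges are kept. Both
    alignment ends are match/substitution columns. Minus-strand copies are
    aligned via their reverse complement; positions are reported on the
    forward strand.
    """
    if a.length() < 1 or b.length() < 1:
        raise ValueError("degenerate interval")
    if a.overlaps(b):
        raise ValueError("repeat copies overlap")
    n = len(record.seq)
    pad = params.seed_pad
    a_lo, a_hi = max(1, a.start - pad), min(n, a.end + pad)  # 1-based inclusive
    b_lo, b_hi = max(1, b.start - pad), min(n, b.end + pad)
    seg_a = record.seq[a_lo - 1 : a_hi]
    seg_b_fwd = record.seq[b_lo - 1 : b_hi]
    minus = b.strand == "-"
    seg_b = reverse_complement(seg_b_fwd) if minus else seg_b_fwd

    aligner = _make_aligner(params)
    aln = aligner.align(seg_a, seg_b)[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        raise ValueError("empty alignment between candidate repeat copies")

    def pos_a(i: int) -> int:  # 0-based seg index -> 1-based genome
        return a_lo + i

    def pos_b(j: int) -> int:
        if minus:
            return b_hi - j
        return b_lo + j

    def pair_column(i: int, j: int) -> tuple:
        ba, bb = seg_a[i], seg_b[j]
        kind = "match" if ba == bb else "substitution"
        return (pos_a(i), pos_b(j), ba, bb, kind)

    columns: list[tuple] = []
    for k in range(len(blocks_a)):
        a0, a1 = map(int, blocks_a[k])
        b0, b1 = map(int, blocks_b[k])
        for i, j in zip(range(a0, a1), range(b0, b1)):
            columns.append(pair_column(i, j))
        if k + 1 < len(blocks_a):
            na0 = int(blocks_a[k + 1][0])
            nb0 = int(blocks_b[k + 1][0])
            for i in range(a1, na0):
                columns.append((pos_a(i), None, seg_a[i], "-", "insertion_a"))
            for j in range(b1, nb0):
                columns.append((None, pos_b(j), "-", seg_b[j], "insertion_b"))

    # trim the core to its best identity run, then re-extend both ends over
    # the trimmed-off columns plus the ungapped continuation of the segments
    lo, hi = _trim_core(columns)
    if hi <= lo:
        raise ValueError("empty alignment between candidate repeat copies")
    core_a0, core_b0 = int(blocks_a[0][0]), int(blocks_b[0][0])
    core_a1, core_b1 = int(blocks_a[-1][1]), int(blocks_b[-1][1])

    beyond_right = [
        pair_column(i, j)
        for i, j in zip(range(core_a1, len(seg_a)), range(core_b1, len(seg_b)))
    ]
    right_cols = columns[hi:] + beyond_right
    right_ext = _all_extensions(right_cols)
    k_right = max(right_ext.values())

    beyond_left = [
        pair_column(i, j)
        for i, j in zip(range(core_a0 - 1, -1, -1), range(core_b0 - 1, -1, -1))
    ]
    left_cols = columns[lo - 1 :: -1] if lo > 0 else []
    left_cols = left_cols + beyond_left
    left_ext = _all_extensions(left_cols)
    k_left = max(left_ext.values())

    core_len = hi - lo
    columns = (
        list(reversed(left_cols[:k_left])) + columns[lo:hi] + right_cols[:k_right]
    )
    variant_spans = {
        v: (k_left - left_ext[v], k_left + core_len + right_ext[v])
        for v in _VARIANTS
    }

    a_positions = [c[0] for c in columns if c[0] is not None]
    b_positions = [c[1] for c in columns if c[1] is not None]
    if not a_positions or not b_positions:
        raise ValueError("empty alignment between candidate repeat copies")
    copy_a = Interval(record.id, min(a_positions), max(a_positions), a.strand)
    copy_b = Interval(record.id, min(b_positions), max(b_positions), b.strand)
    return PairAlignment(
        copy_a=copy_a,
        copy_b=copy_b,
        aligned_a="".join(c[2] for c in columns),
        aligned_b="".join(c[3] for c in columns),
        columns=tuple(columns),
        variant_spans=variant_spans,
    )


def _slice_alignment(aln: PairAlignment, lo: int, hi: int) -> Optional[PairAlignment]:
    """Restrict an alignment to a half-open column range."""
    columns = aln.columns[lo:hi]
    a_positions = [c[0] for c in columns if c[0] is not None]
    b_positions = [c[1] for c in columns if c[1] is not None]
    if not a_positions or not b_positions:
        return None
    return PairAlignment(
        copy_a=Interval(
            aln.copy_a.seq_id, min(a_positions), max(a_positions), aln.copy_a.strand
        ),
        copy_b=Interval(
            aln.copy_b.seq_id, min(b_positions), max(b_positions), aln.copy_b.strand
        ),
        aligned_a="".join(c[2] for c in columns),
        aligned_b="".join(c[3] for c in columns),
        columns=columns,
    )


def profile_substitutions(aln: PairAlignment) -> SubstitutionProfile:
    """Count substitution columns and how many sit at adenines of each copy.

    Adenines are counted in both readings: at the copy's forward-oriented A
    positions, and at its T positions (adenines of the reverse-complement
    reading), so a pair whose template lies on the opposite strand is still
    recognized.
    """
    total = at_a = at_b = t_a = t_b = indels = 0
    for _, _, base_a, base_b, kind in aln.columns:
        if kind == "substitution":
            total += 1
            if "N" in (base_a, base_b):
                continue
            if base_a == "A":
                at_a += 1
            if base_b == "A":
                at_b += 1
            if base_a == "T":
                t_a += 1
            if base_b == "T":
                t_b += 1
        elif kind in ("insertion_a", "insertion_b"):
            indels += 1
    return SubstitutionProfile(total, at_a, at_b, indels, t_a, t_b)


def call_tr_vr(
    record: SequenceRecord,
    aln: PairAlignment,
    profile: SubstitutionProfile,
    params: ScanParams,
) -> Optional[TRVRPair]:
    """Decide whether the aligned pair is a TR–VR pair and assign the roles.

    Each copy is evaluated as the template in both reading directions: its
    forward-oriented adenines, and its T positions, which are adenines of
    the reverse-complement reading (so a pair whose template lies on the
    opposite strand is still recognized, and scanning a reverse-complemented
    sequence mirrors the result). Every assignment is judged over its own
    boundary-refined column span — edge extensions consistent with a
    competing template assignment are excluded — and qualifies when it
    explains at least ``min_a_subs`` substitutions at template adenines
    with strictly fewer than ``max_non_a_frac`` of the span's substitutions
    falling elsewhere in that copy, over a span of at least
    ``min_pair_len``. The qualifying assignment with the most adenine
    substitutions wins; ties prefer the forward reading, then copy order.
    When the winning reading is the reverse complement, both reported
    intervals carry flipped strands.
    """
    # quick reject: per-span counts can never exceed the whole-alignment ones
    upper = max(
        profile.subs_at_A_in_a,
        profile.subs_at_A_in_b,
        profile.subs_at_T_in_a,
        profile.subs_at_T_in_b,
    )
    if upper < params.min_a_subs:
        return None

    candidates = []  # (a_subs, preference, assignment fields...)
    for pref, (bonus, copy_idx) in enumerate(_VARIANTS):
        lo, hi = aln.span_for(bonus, copy_idx)
        sub_aln = _slice_alignment(aln, lo, hi)
        if sub_aln is None:
            continue
        if min(sub_aln.span_a(), sub_aln.span_b()) < params.min_pair_len:
            continue
        sub_profile = profile_substitutions(sub_aln)
        counts = {
            ("A", 0): sub_profile.subs_at_A_in_a,
            ("A", 1): sub_profile.subs_at_A_in_b,
            ("T", 0): sub_profile.subs_at_T_in_a,
            ("T", 1): sub_profile.subs_at_T_in_b,
        }
        a_subs = counts[(bonus, copy_idx)]
        total = sub_profile.total_subs
        non_a_frac = 0.0 if total == 0 else (total - a_subs) / total
        if a_subs < params.min_a_subs or non_a_frac >= params.max_non_a_frac:
            continue
        candidates.append(
            (a_subs, pref, copy_idx, bonus == "T", sub_aln, sub_profile, non_a_frac)
        )
    if not candidates:
        return None
    candidates.sort(key=lambda t: (-t[0], t[1]))
    a_subs, _, copy_idx, flip, sub_aln, sub_profile, non_a_frac = candidates[0]
    tr, vr = (
        (sub_aln.copy_a, sub_aln.copy_b)
        if copy_idx == 0
        else (sub_aln.copy_b, sub_aln.copy_a)
    )
    if flip:
        tr = Interval(tr.seq_id, tr.start, tr.end, "-" if tr.strand == "+" else "+")
        vr = Interval(vr.seq_id, vr.start, vr.end, "-" if vr.strand == "+" else "+")
    pair = TRVRPair(
        tr=tr,
        vr=vr,
        alignment=sub_aln,
        profile=sub_profile,
        a_subs=a_subs,
        non_a_frac=non_a_frac,
    )
    pair.validate(params)
    return pair


def _n_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return seq.count("N") / len(seq)


def scan_sequence(
    record: SequenceRecord,
    params: ScanParams | None = None,
    restrict_to: Optional[Sequence[Interval]] = None,
) -> list[TRVRPair]:
    """Scan one sequence for TR–VR pairs.

    Pipeline: seed detection -> AAY-motif prefilter (a candidate survives if
    either copy carries a 60 bp window with at least 3 AAY triplets) ->
    N-content filter -> pairwise alignment -> substitution profiling ->
    pair calling -> overlap reduction so that no two reported template
    regions overlap (more adenine substitutions wins, then longer span, then
    leftmost). Output is sorted by TR start and deterministic.
    """
    params = params or ScanParams()
    seeds = find_seed_matches(record, params, restrict_to)

    candidates: list[TRVRPair] = []
    seen_spans: set[tuple] = set()
    for seed in seeds:
        if params.aay_filter:
            sa = seed.copy_a.slice_of(record.seq)
            sb = seed.copy_b.slice_of(record.seq)
            if not (_has_aay_window(sa, params) or _has_aay_window(sb, params)):
                continue
        if (
            _n_fraction(seed.copy_a.slice_of(record.seq)) > params.max_n_frac
            or _n_fraction(seed.copy_b.slice_of(record.seq)) > params.max_n_frac
        ):
            continue
        try:
            aln = align_segments(record, seed.copy_a, seed.copy_b, params)
        except ValueError:
            continue
        key = (aln.copy_a.start, aln.copy_a.end, aln.copy_b.start, aln.copy_b.end, aln.copy_b.strand)
        if key in seen_spans:
            continue
        seen_spans.add(key)
        if aln.copy_a.overlaps(aln.copy_b):
            continue
        profile = profile_substitutions(aln)
        pair = call_tr_vr(record, aln, profile, params)
        if pair is not None:
            candidates.append(pair)

    # overlap reduction: no two reported TRs overlap
    candidates.sort(key=lambda p: (-p.a_subs, -p.tr.length(), p.tr.start, p.vr.start))
    kept: list[TRVRPair] = []
    for pair in candidates:
        if any(pair.tr.overlaps(k.tr) for k in kept):
            continue
        kept.append(pair)
    kept.sort(key=lambda p: (p.tr.start, p.tr.end, p.vr.start))
    for pair in kept:
        pair.validate(params)
    return kept
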