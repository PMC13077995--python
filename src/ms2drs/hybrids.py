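"""Chimeric (template-switch) read detection and junction typing.

The MS2 replicase is error-prone and can dissociate from its template and
resume synthesis elsewhere, producing hybrid reads whose segments map to
two or more distinct genome loci.  This module finds those segments with a
local aligner, chains query-adjacent segments, and types each junction:

* ``pos_pos`` / ``neg_neg`` — same-strand joins, further classified as a
  deletion (template skipped ``delta`` nt forward) or a duplication
  (template re-copied ``delta`` nt), with the 20-60 nt range the replicase
  characteristically produces flagged;
* ``neg_pos`` / ``pos_neg`` — strand-switch joins;
* ``foldback`` — a (+/-) copyback/snapback read: the second segment is the
  reverse complement of (part of) the first, so the two segments overlap
  on the reference on opposite strands.

Segment finding uses exact k-mer seeding on the genome and its reverse
complement, maximal ungapped extension along each seed diagonal
(Smith-Waterman scoring +1 match / -2 mismatch), and gapped refinement of
near-diagonal candidates with Biopython's local PairwiseAligner
(gap open -4 / extend -2).  An exhaustive dynamic-programming oracle in
the test suite guards equivalence with full local alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .core_io import AlignedRead, GenomeModel, revcomp

logger = logging.getLogger("ms2drs")

MIN_READ_LEN = 60
DEFAULT_SCORING = (1, -2, -4, -2)  # match, mismatch, gap open, gap extend
RECOMBINATION_RANGE = (20, 60)     # |delta| range flagged as replicase recombination


@dataclass(frozen=True)
class AlignSegment:
    """One locally-aligned block of a read (query and ref 0-based half-open)."""

    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    strand: str
    score: float

    @property
    def bio_end3(self) -> int:
        """1-based genome position of the segment's biological 3' end."""
        return self.ref_end if self.strand == "+" else self.ref_start + 1

    @property
    def bio_start5(self) -> int:
        """1-based genome position of the segment's biological 5' start."""
        return self.ref_start + 1 if self.strand == "+" else self.ref_end


@dataclass
class HybridCall:
    """A chimeric read: ordered segments plus junction/event typing."""

    read_id: str
    segments: list[AlignSegment]
    junction_type: str
    event: str
    delta: int
    in_recombination_range: bool
    junction_ref_positions: tuple[int, int]
    query_length: int = 0
    timepoint: str = ""
    strand: str = "+"


# ---------------------------------------------------------------------------
# Segment finding
# ---------------------------------------------------------------------------


def _kmer_index(genome: GenomeModel, k: int) -> dict[str, list[int]]:
    cache = getattr(genome, "_kmer_cache", None)
    if cache is not None and cache[0] == k:
        return cache[1]
    index: dict[str, list[int]] = {}
    seq = genome.sequence
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)
    object.__setattr__(genome, "_kmer_cache", (k, index))
    return index


def _diagonal_candidates(query: str, index: dict[str, list[int]], k: int
                         ) -> dict[int, list[int]]:
    """Map diagonal (ref_pos - query_pos) -> sorted seed query positions."""
    diags: dict[int, list[int]] = {}
    for q in range(len(query) - k + 1):
        for r in index.get(query[q:q + k], ()):
            diags.setdefault(r - q, []).append(q)
    return diags


def _kadane_on_diagonal(query: str, ref: str, diag: int, match: int, mismatch: int
                        ) -> tuple[int, int, float]:
    """Best-scoring ungapped run on one diagonal: (q_start, q_end, score)."""
    q_lo = max(0, -diag)
    q_hi = min(len(query), len(ref) - diag)
    best = (0, 0, 0.0)
    cur_start, cur = q_lo, 0.0
    for q in range(q_lo, q_hi):
        cur += match if query[q] == ref[q + diag] else mismatch
        if cur <= 0:
            cur, cur_start = 0.0, q + 1
        elif cur > best[2]:
            best = (cur_start, q + 1, cur)
    return best


def _gapped_refine(query: str, ref: str, cands: list[tuple[int, int, int, float]],
                   scoring: tuple[int, int, int, int], diag_tol: int = 15,
                   join_tol: int = 10) -> list[tuple[int, int, int, float]]:
    """Merge candidates on nearby diagonals (small indels) via local SW."""
    if len(cands) < 2:
        return cands
    match, mismatch, gap_open, gap_extend = scoring
    aligner = Align.PairwiseAligner(mode="local", match_score=match,
                                    mismatch_score=mismatch,
                                    open_gap_score=gap_open,
                                    extend_gap_score=gap_extend)
    cands = sorted(cands, key=lambda c: c[0])
    merged = [cands[0]]
    for c in cands[1:]:
        p = merged[-1]
        if (abs(c[2] - p[2]) <= diag_tol and c[2] != p[2]
                and c[0] - p[1] <= join_tol):
            q_lo, q_hi = p[0], c[1]
            r_lo = max(0, min(p[0] + p[2], c[0] + c[2]) - 5)
            r_hi = min(len(ref), max(p[1] + p[2], c[1] + c[2]) + 5)
            aln = aligner.align(query[q_lo:q_hi], ref[r_lo:r_hi])
            if aln.score > max(p[3], c[3]):
                a = aln[0]
                qs, qe = int(a.aligned[0][0][0]), int(a.aligned[0][-1][1])
                rs = int(a.aligned[1][0][0])
                # pseudo-diagonal candidate (diag anchored at the refined start)
                merged[-1] = (q_lo + qs, q_lo + qe, (r_lo + rs) - (q_lo + qs),
                              float(aln.score))
                continue
        merged.append(c)
    return merged


def find_segments(read_seq: str, genome: GenomeModel, min_score: float = 60,
                  scoring: tuple[int, int, int, int] = DEFAULT_SCORING,
                  k: int = 13) -> list[AlignSegment]:
    """Find maximal non-redundant local alignments of a read to the genome
    (both strands).

    Reads shorter than 60 nt return an empty list with a logged note.
    For each strand, seeds on a common diagonal are extended to the
    maximal-scoring ungapped run; candidates on nearby diagonals are
    merged with a gapped local alignment.  Segments scoring below
    ``min_score`` are discarded; a segment whose query interval is >= 90%
    contained in a higher-scoring segment's interval is dropped as
    redundant.
    """
    if len(read_seq) < MIN_READ_LEN:
        logger.debug("read of %d nt below minimum %d; no segments",
                     len(read_seq), MIN_READ_LEN)
        return []
    read_seq = read_seq.upper().replace("U", "T")
    match, mismatch = scoring[0], scoring[1]
    index = _kmer_index(genome, k)
    ref = genome.sequence
    segments: list[AlignSegment] = []
    for strand in "+-":
        query = read_seq if strand == "+" else revcomp(read_seq)
        diags = _diagonal_candidates(query, index, k)
        cands = []
        for diag in diags:
            qs, qe, score = _kadane_on_diagonal(query, ref, diag, match, mismatch)
            if qe > qs and score > 0:
                cands.append((qs, qe, diag, score))
        cands = _gapped_refine(query, ref, cands, scoring)
        for qs, qe, diag, score in cands:
            if score < min_score:
                continue
            rs, re_ = qs + diag, qe + diag
            if strand == "-":
                # convert query coords from the revcomp frame back to the read
                qs, qe = len(read_seq) - qe, len(read_seq) - qs
            segments.append(AlignSegment(query_start=qs, query_end=qe,
                                         ref_start=rs, ref_end=re_,
                                         strand=strand, score=score))
    # drop segments redundant with a higher-scoring one on the query
    segments.sort(key=lambda s: -s.score)
    kept: list[AlignSegment] = []
    for seg in segments:
        redundant = False
        for other in kept:
            ov = min(seg.query_end, other.query_end) - max(seg.query_start, other.query_start)
            if ov >= 0.9 * (seg.query_end - seg.query_start):
                redundant = True
                break
        if not redundant:
            kept.append(seg)
    kept.sort(key=lambda s: s.query_start)
    return kept


# ---------------------------------------------------------------------------
# Chaining and junction typing
# ---------------------------------------------------------------------------


def _same_locus(a: AlignSegment, b: AlignSegment) -> bool:
    """Same locus = same strand and >= 50% reciprocal reference overlap."""
    if a.strand != b.strand:
        return False
    ov = min(a.ref_end, b.ref_end) - max(a.ref_start, b.ref_start)
    if ov <= 0:
        return False
    return (ov >= 0.5 * (a.ref_end - a.ref_start)
            and ov >= 0.5 * (b.ref_end - b.ref_start))


def _ref_overlap_min(a: AlignSegment, b: AlignSegment) -> float:
    ov = min(a.ref_end, b.ref_end) - max(a.ref_start, b.ref_start)
    if ov <= 0:
        return 0.0
    return ov / min(a.ref_end - a.ref_start, b.ref_end - b.ref_start)


def classify_event(first: AlignSegment, second: AlignSegment) -> tuple[str, int]:
    """Deletion/duplication typing of a same-strand junction.

    ``delta`` is the junction offset in transcript orientation ('-' strand
    junctions are evaluated on the reverse-complement frame): positive
    delta means the template skipped forward (deletion of delta nt),
    negative means it stepped back (duplication of |delta| nt); zero means
    the segments are contiguous (no event).

    The reference gap is corrected by the query gap/overlap between the
    segments: bases at the junction that happen to match both templates
    extend both segments' alignments symmetrically, and subtracting the
    query gap cancels that wobble exactly.
    """
    if first.strand != second.strand:
        raise ValueError("opposite-strand junction: use foldback/strand-switch typing")
    query_gap = second.query_start - first.query_end
    if first.strand == "+":
        delta = second.ref_start - first.ref_end - query_gap
    else:
        delta = first.ref_start - second.ref_end - query_gap
    if delta > 0:
        return "deletion", delta
    if delta < 0:
        return "duplication", delta
    return "none", 0


def chain_and_call(read_id: str, segments: list[AlignSegment],
                   query_gap_tol: int = 20, query_overlap_tol: int = 20,
                   min_loci: int = 2, timepoint: str = "",
                   query_length: int = 0) -> HybridCall | None:
    """Chain segments of one read and call it hybrid or not.

    Segments are greedily selected by score (discarding ones whose query
    interval overlaps an already-selected segment by more than
    ``query_overlap_tol`` nt), then ordered by query start.  The chain is
    the highest-scoring run of query-adjacent segments (gap between
    consecutive segments <= ``query_gap_tol``).  A read is hybrid iff the
    chain contains >= ``min_loci`` distinct loci (reference intervals with
    < 50% reciprocal overlap, or differing strand).
    """
    if len(segments) < 2:
        return None
    chosen: list[AlignSegment] = []
    for seg in sorted(segments, key=lambda s: -s.score):
        ok = True
        for other in chosen:
            ov = min(seg.query_end, other.query_end) - max(seg.query_start, other.query_start)
            if ov > query_overlap_tol:
                ok = False
                break
        if ok:
            chosen.append(seg)
    chosen.sort(key=lambda s: s.query_start)

    # split into maximal query-adjacent runs; keep the best-scoring run
    runs: list[list[AlignSegment]] = [[chosen[0]]]
    for seg in chosen[1:]:
        if seg.query_start - runs[-1][-1].query_end <= query_gap_tol:
            runs[-1].append(seg)
        else:
            runs.append([seg])
    chain = max(runs, key=lambda r: sum(s.score for s in r))
    if len(chain) < 2:
        return None
    distinct = any(not _same_locus(a, b)
                   for i, a in enumerate(chain) for b in chain[i + 1:])
    if not distinct or len(chain) < min_loci:
        return None

    first, second = chain[0], chain[1]
    junction = (first.bio_end3, second.bio_start5)
    if first.strand != second.strand:
        if _ref_overlap_min(first, second) >= 0.5:
            jtype = "foldback"
        else:
            names = {"+": "pos", "-": "neg"}
            jtype = f"{names[first.strand]}_{names[second.strand]}"
        event, delta = "none", 0
    else:
        jtype = "pos_pos" if first.strand == "+" else "neg_neg"
        event, delta = classify_event(first, second)
    in_range = (event in ("deletion", "duplication")
                and RECOMBINATION_RANGE[0] <= abs(delta) <= RECOMBINATION_RANGE[1])
    return HybridCall(read_id=read_id, segments=chain, junction_type=jtype,
                      event=event, delta=delta, in_recombination_range=in_range,
                      junction_ref_positions=junction,
                      query_length=query_length or max(s.query_end for s in chain),
                      timepoint=timepoint, strand=first.strand)


def detect_hybrids(sequences: dict[str, str], genome: GenomeModel,
                   min_score: float = 60,
                   scoring: tuple[int, int, int, int] = DEFAULT_SCORING,
                   timepoints: dict[str, str] | None = None,
                   **chain_kwargs) -> list[HybridCall]:
    """Run find_segments + chain_and_call over a read set."""
    calls = []
    for rid, seq in sequences.items():
        segs = find_segments(seq, genome, min_score=min_score, scoring=scoring)
        call = chain_and_call(rid, segs, query_length=len(seq),
                              timepoint=(timepoints or {}).get(rid, ""),
                              **chain_kwargs)
        if call is not None:
            calls.append(call)
    return calls


def calls_to_frame(calls: list[HybridCall]) -> pd.DataFrame:
    """Tabulate HybridCalls (junction positions 1-based)."""
    rows = [{"read_id": c.read_id, "junction_type": c.junction_type,
             "event": c.event, "delta": c.delta,
             "in_recombination_range": c.in_recombination_range,
             "junction_1": c.junction_ref_positions[0],
             "junction_2": c.junction_ref_positions[1],
             "n_segments": len(c.segments),
             "query_length": c.query_length,
             "strand": c.strand, "timepoint": c.timepoint}
            for c in calls]
    return pd.DataFrame(rows, columns=["read_id", "junction_type", "event", "delta",
                                       "in_recombination_range", "junction_1", "junction_2",
                                       "n_segments", "query_length", "strand",
                                       "timepoint"])


def hybrid_summary(calls: list[HybridCall], all_reads: list[AlignedRead],
                   group_by: tuple[str, ...] = ("timepoint", "strand")
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hybrid-to-total ratios per group plus a junction-type/event breakdown.

    The hybrid read's group strand is the strand of its first segment.
    Returns ``(summary, breakdown)``.
    """
    calls_df = calls_to_frame(calls)
    totals: dict[tuple, int] = {}
    for r in all_reads:
        key = tuple(getattr(r, g) for g in group_by)
        totals[key] = totals.get(key, 0) + 1
    rows = []
    for key in sorted(totals):
        n_total = totals[key]
        if len(calls_df):
            mask = np.ones(len(calls_df), dtype=bool)
            for g, v in zip(group_by, key):
                mask &= (calls_df[g] == v).to_numpy()
            n_hyb = int(mask.sum())
        else:
            n_hyb = 0
        row = dict(zip(group_by, key))
        row.update({"n_hybrid": n_hyb, "n_total": n_total,
                    "ratio": n_hyb / n_total if n_total else 0.0})
        rows.append(row)
    summary = pd.DataFrame(rows)
    if len(calls_df):
        breakdown = (calls_df.groupby(list(group_by) + ["junction_type", "event"])
                     .size().rename("count").reset_index())
    else:
        breakdown = pd.DataFrame(columns=list(group_by) + ["junction_type", "event", "count"])
    return summary, breakdown


def hybrid_length_histogram(calls: list[HybridCall], bin_width: int = 100) -> pd.DataFrame:
    """Read-length histogram of hybrid reads (per junction type)."""
    rows = [{"junction_type": c.junction_type,
             "length_bin": (c.query_length // bin_width) * bin_width} for c in calls]
    if not rows:
        return pd.DataFrame(columns=["junction_type", "length_bin", "count"])
    return (pd.DataFrame(rows).groupby(["junction_type", "length_bin"])
            .size().rename("count").reset_index())


# ---------------------------------------------------------------------------
# SA-style segment extraction from SAM split alignments
# ---------------------------------------------------------------------------

_CLIP_OPS = {4, 5}  # S, H


def segments_from_sam_records(records) -> dict[str, list[AlignSegment]]:
    """Build AlignSegments per read from pysam primary+supplementary records.

    Query intervals are recovered from the CIGAR clips, flipped to the
    original read orientation for reverse-strand records.
    """
    by_read: dict[str, list[AlignSegment]] = {}
    for rec in records:
        if rec.is_unmapped or rec.is_secondary or rec.cigartuples is None:
            continue
        cig = rec.cigartuples
        left = cig[0][1] if cig[0][0] in _CLIP_OPS else 0
        right = cig[-1][1] if cig[-1][0] in _CLIP_OPS else 0
        qlen = sum(n for op, n in cig if op in (0, 1, 4, 5, 7, 8))
        qs, qe = left, qlen - right
        if rec.is_reverse:
            qs, qe = qlen - qe, qlen - qs
        by_read.setdefault(rec.query_name, []).append(AlignSegment(
            query_start=qs, query_end=qe,
            ref_start=rec.reference_start, ref_end=rec.reference_end,
            strand="-" if rec.is_reverse else "+",
            score=float(qe - qs)))
    return by_read
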