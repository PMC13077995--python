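"""Read-length fractionation and subgenomic read classification.

Short viral reads in an MS2 DRS run fall into three explanatory blocks:
3'-anchored reads (Nanopore DRS sequences RNA 3'->5', so incomplete reads
keep the genomic 3' end), 5'-anchored reads (degradation products trimmed
from the 3'), and internal subgenomic reads containing the coat (or
coat+lys) ORF.  Reads spanning >= 90% of the genome are full-length.
"""

from __future__ import annotations

import pandas as pd

from .core_io import AlignedRead, GenomeModel, OrfAnnotation

FULL_LENGTH_FRAC = 0.90
LENGTH_BOUNDS = (800, 3000)

CLASS_LABELS = ("full_length", "three_prime_anchored", "five_prime_anchored",
                "coat_lys_subgenomic", "coat_subgenomic", "other_internal")


def fraction_by_length(reads: list[AlignedRead],
                       bounds: tuple[int, int] = LENGTH_BOUNDS) -> list[str]:
    """Label each read lt800 / mid / gt3000 by reference span.

    ``lt800`` iff span < bounds[0]; ``gt3000`` iff span > bounds[1]; else
    ``mid``.  Span is reference extent (ref_end - ref_start).
    """
    lo, hi = bounds
    if lo >= hi:
        raise ValueError("bounds must be strictly increasing")
    labels = []
    for r in reads:
        if r.span < lo:
            labels.append(f"lt{lo}")
        elif r.span > hi:
            labels.append(f"gt{hi}")
        else:
            labels.append("mid")
    return labels


def _coverage(read: AlignedRead, orf: OrfAnnotation) -> int:
    return max(0, min(read.ref_end, orf.end) - max(read.ref_start, orf.start))


def classify_read(read: AlignedRead, genome: GenomeModel, delta: int = 25) -> str:
    """Assign one class label per read (precedence order below).

    1. ``full_length`` — span >= 90% of the genome;
    2. ``three_prime_anchored`` — read reaches the biological 3'-end region
       (within ``delta`` nt) but not the 5' end: DRS 3'-bias truncations;
    3. ``five_prime_anchored`` — reaches the 5' end only: degraded RNA;
    4. ``coat_lys_subgenomic`` — covers >= 90% of both the coat and lys ORFs;
    5. ``coat_subgenomic`` — covers >= 90% of the coat ORF;
    6. ``other_internal``.

    For '-' strand reads the anchoring tests swap ends: the biological 3'
    of a negative-strand read is genome position 0.
    """
    L = genome.length
    if read.span >= FULL_LENGTH_FRAC * L:
        return "full_length"
    if read.strand == "+":
        at_3p = read.ref_end >= L - delta
        at_5p = read.ref_start <= delta
    else:
        at_3p = read.ref_start <= delta
        at_5p = read.ref_end >= L - delta
    if at_3p and not at_5p:
        return "three_prime_anchored"
    if at_5p and not at_3p:
        return "five_prime_anchored"
    try:
        coat = genome.orf("coat")
    except KeyError:
        return "other_internal"
    coat_ok = _coverage(read, coat) >= 0.9 * coat.length
    try:
        lys = genome.orf("lys")
        lys_ok = _coverage(read, lys) >= 0.9 * lys.length
    except KeyError:
        lys_ok = False
    if coat_ok and lys_ok:
        return "coat_lys_subgenomic"
    if coat_ok:
        return "coat_subgenomic"
    return "other_internal"


def classify_reads(reads: list[AlignedRead], genome: GenomeModel,
                   delta: int = 25) -> pd.DataFrame:
    """Classify every read; returns one row per read with length fraction,
    class, strand and timepoint."""
    fractions = fraction_by_length(reads)
    rows = [{"read_id": r.read_id,
             "length_fraction": frac,
             "read_class": classify_read(r, genome, delta=delta),
             "strand": r.strand,
             "timepoint": r.timepoint,
             "span": r.span,
             "ref_start": r.ref_start + 1,
             "ref_end": r.ref_end}
            for r, frac in zip(reads, fractions)]
    return pd.DataFrame(rows, columns=["read_id", "length_fraction", "read_class",
                                       "strand", "timepoint", "span",
                                       "ref_start", "ref_end"])


def class_proportions(classified: pd.DataFrame,
                      group_by: tuple[str, ...] = ("timepoint", "strand")) -> pd.DataFrame:
    """Per-group class counts and proportions (proportions sum to 1 per group)."""
    group_by = list(group_by)
    counts = (classified.groupby(group_by + ["read_class"], sort=True)
              .size().rename("count").reset_index())
    totals = counts.groupby(group_by)["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    return counts


def count_orf_containment(reads: list[AlignedRead], orfs: list[OrfAnnotation],
                          cover_frac: float = 0.9,
                          group_by: str = "timepoint") -> pd.DataFrame:
    """Count reads containing each ORF (>= ``cover_frac`` of the ORF covered).

    A read may count toward multiple ORFs; proportions are relative to the
    total mapped viral reads in the group.
    """
    if not (0 < cover_frac <= 1):
        raise ValueError("cover_frac must be in (0, 1]")
    rows = []
    groups: dict[str, list[AlignedRead]] = {}
    for r in reads:
        groups.setdefault(getattr(r, group_by), []).append(r)
    for gval in sorted(groups):
        greads = groups[gval]
        for orf in orfs:
            n = sum(1 for r in greads if _coverage(r, orf) >= cover_frac * orf.length)
            rows.append({group_by: gval, "orf": orf.name, "count": n,
                         "total_reads": len(greads),
                         "proportion": n / len(greads) if greads else 0.0})
    return pd.DataFrame(rows)
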