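"""Synthetic MS2-like data generator.

Emulates the read populations a direct RNA sequencing (DRS) run of
MS2-infected *E. coli* produces, with ground-truth labels, so every
downstream stage is testable without external data:

* full-length genomic reads (span >= 93% of the genome),
* 3'-anchored truncated reads (DRS sequences 3'->5', so incomplete reads
  keep the genomic 3' end),
* 5'-anchored reads (degraded RNA trimmed at the 3' end),
* internal subgenomic reads containing the coat ORF (or coat+lys),
* other internal fragments with an exponential-tail length distribution,
* negative-strand (replication intermediate) full-length reads,
* hybrid reads from template switching: same-strand deletions/duplications
  with a configurable junction offset, strand-switch joins, and (+/-)
  foldback (copyback) reads,
* per-read per-site modification calls with configurable stoichiometry,
  plus a modification-free in vitro transcribed (IVT) control.

Errors are substitution-only by default so chimera junctions stay exact in
the truth table.  All randomness flows from a single integer seed through
``numpy.random.default_rng``; the same seed yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    MOD_BASE,
    MS2_GENOME_LENGTH,
    AlignedRead,
    GenomeModel,
    ModCallRecord,
    OrfAnnotation,
    revcomp,
    write_alignments,
    write_genome,
)

# Read classes the generator can emit (the classifier's vocabulary).
READ_CLASSES = (
    "full_length",
    "three_prime_anchored",
    "five_prime_anchored",
    "coat_subgenomic",
    "coat_lys_subgenomic",
    "other_internal",
    "negative_full_length",
)

HYBRID_TYPES = (
    "pos_pos_deletion",
    "pos_pos_duplication",
    "neg_neg_deletion",
    "neg_neg_duplication",
    "neg_pos",
    "foldback",
)

#: classic MS2 ORF coordinates (0-based half-open), scaled when length != 3569
DEFAULT_ORF_LAYOUT = {
    "mat": (129, 1311),
    "coat": (1334, 1727),
    "lys": (1677, 1905),
    "rep": (1760, 3398),
}

#: Shine-Dalgarno-like purine-rich hexamer planted upstream of each ORF start
AG_HEXAMER = "AGGAGG"

_STOPS = ("TAA", "TAG", "TGA")

DEFAULT_TIMEPOINTS = ("0h", "20min", "40min", "3h", "6h")


@dataclass
class SimConfig:
    """Configuration of one simulated sequencing run (one timepoint).

    The default class mixture reflects a mid-infection positive-strand
    population dominated by full-length reads, DRS 3'-bias truncations and
    degradation products, with a growing coat-subgenomic compartment.
    """

    seed: int = 0
    n_reads: int = 2000
    class_mixture: dict[str, float] = field(default_factory=lambda: {
        "full_length": 0.30,
        "three_prime_anchored": 0.30,
        "five_prime_anchored": 0.20,
        "coat_subgenomic": 0.15,
        "other_internal": 0.05,
    })
    error_rate: float = 0.03
    mean_phred: float = 14.0
    #: exponential-tail mean (nt) for other_internal fragment lengths
    truncation_scale: float = 300.0
    timepoint: str = "0h"
    sample: str = "test"

    def validate(self) -> None:
        if abs(sum(self.class_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("class mixture proportions must sum to 1")
        for cls, p in self.class_mixture.items():
            if cls not in READ_CLASSES:
                raise ValueError(f"unknown read class {cls!r}")
            if p < 0:
                raise ValueError("mixture proportions must be >= 0")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate outside [0, 1)")


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def make_genome(length: int = MS2_GENOME_LENGTH, orf_layout: dict | None = None,
                seed: int = 0, name: str = "MS2_synth") -> GenomeModel:
    """Generate a random MS2-like genome with four ORFs in genomic order.

    Each ORF gets an ATG at its start, a stop codon at its end, and a
    purine-rich (Shine-Dalgarno-like) hexamer planted 8-12 nt upstream of
    its start.  The default layout uses the classic MS2 coordinates
    (mat/coat/lys/rep with the lys ORF overlapping the coat-rep boundary
    region), rescaled proportionally for non-default lengths.
    """
    if length < 600:
        raise ValueError("genome length must be >= 600")
    rng = np.random.default_rng(seed)
    if orf_layout is None:
        scale = length / MS2_GENOME_LENGTH
        orf_layout = {n: (int(s * scale), int(e * scale))
                      for n, (s, e) in DEFAULT_ORF_LAYOUT.items()}
    for orf_name, (s, e) in orf_layout.items():
        if not (0 <= s < e <= length):
            raise ValueError(f"ORF {orf_name} [{s}, {e}) does not fit in length {length}")
        if e - s < 6 or s < 15:
            raise ValueError(f"ORF {orf_name} layout cannot fit start/stop codons")

    seq = rng.choice(list("ACGT"), size=length).tolist()
    for orf_name, (s, e) in sorted(orf_layout.items(), key=lambda kv: kv[1][0]):
        seq[s:s + 3] = "ATG"
        stop = _STOPS[int(rng.integers(0, 3))]
        seq[e - 3:e] = stop
        offset = int(rng.integers(8, 13))  # hexamer 8-12 nt upstream
        up = s - offset - len(AG_HEXAMER)
        if up >= 0:
            seq[up:up + len(AG_HEXAMER)] = AG_HEXAMER
    orfs = [OrfAnnotation(name=n, start=s, end=e) for n, (s, e) in orf_layout.items()]
    return GenomeModel(name=name, sequence="".join(seq), orfs=orfs)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < error_rate
    idx = np.nonzero(hit)[0]
    bases = np.array([b"A", b"C", b"G", b"T"])
    for i in idx:
        choices = bases[bases != arr[i]]
        arr[i] = choices[int(rng.integers(0, len(choices)))]
    return arr.tobytes().decode()


def _phred_track(n: int, mean_phred: float, rng: np.random.Generator) -> list[int]:
    q = rng.normal(mean_phred, 3.0, size=n)
    return np.clip(np.rint(q), 2, 40).astype(int).tolist()


def _draw_span(cls: str, genome: GenomeModel, cfg: SimConfig,
               rng: np.random.Generator) -> tuple[int, int, str]:
    """Draw (ref_start, ref_end, strand) for one read of class ``cls``.

    Spans are sampled with a small margin away from the classifier decision
    boundaries (anchoring tolerance 25 nt, full-length threshold 0.90 L) so
    truth labels are well defined.
    """
    L = genome.length
    # interior spans stay below 0.893 L: safely under the 0.90 L full-length rule
    interior_cap = int(0.893 * L)
    min_span = 80

    if cls in ("full_length", "negative_full_length"):
        span = int(rng.uniform(0.93, 1.0) * L)
        start = int(rng.integers(0, L - span + 1))
        return start, start + span, "-" if cls == "negative_full_length" else "+"

    if cls == "three_prime_anchored":
        end = L - int(rng.integers(0, 10))
        lo = max(31, end - interior_cap)
        start = int(rng.integers(lo, end - min_span + 1))
        return start, end, "+"

    if cls == "five_prime_anchored":
        start = int(rng.integers(0, 10))
        hi = min(start + interior_cap, L - 31)
        end = int(rng.integers(start + min_span, hi + 1))
        return start, end, "+"

    coat = genome.orf("coat")
    try:
        lys = genome.orf("lys")
    except KeyError:
        lys = None

    if cls == "coat_subgenomic":
        # fully contains coat, total span <= 780 nt, and stays clear of
        # covering >= 90% of lys (which would flip the truth label)
        span = int(rng.integers(coat.length + 20, min(770, interior_cap) + 1))
        right_cap = L - 31
        if lys is not None:
            right_cap = min(right_cap, lys.start + int(0.85 * lys.length) - 1)
        for _ in range(1000):
            left = int(rng.integers(0, span - coat.length + 1))
            s = coat.start - left
            e = s + span
            if s >= 31 and e <= right_cap:
                return s, e, "+"
        raise RuntimeError("could not place coat_subgenomic read")

    if cls == "coat_lys_subgenomic":
        if lys is None:
            raise ValueError("genome lacks a lys ORF")
        base_s, base_e = coat.start, max(coat.end, lys.end)
        budget = min(770, interior_cap) - (base_e - base_s)
        if budget < 10:
            raise ValueError("coat+lys region too long for a <=770 nt read")
        left = int(rng.integers(5, budget - 4))
        return base_s - min(left, base_s - 31), base_e + int(rng.integers(5, budget - left + 1)), "+"

    if cls == "other_internal":
        for _ in range(1000):
            span = min_span + int(rng.exponential(cfg.truncation_scale))
            span = min(span, interior_cap)
            s = int(rng.integers(31, L - 31 - span))
            e = s + span
            cov_coat = max(0, min(e, coat.end) - max(s, coat.start))
            if cov_coat >= 0.85 * coat.length:
                continue
            if lys is not None:
                cov_lys = max(0, min(e, lys.end) - max(s, lys.start))
                if cov_lys >= 0.85 * lys.length:
                    continue
            return s, e, "+"
        raise RuntimeError("could not place other_internal read")

    raise ValueError(f"unknown read class {cls!r}")


def simulate_reads(genome: GenomeModel, config: SimConfig,
                   out_prefix: str | None = None):
    """Simulate one run of non-hybrid reads.

    Returns ``(reads, sequences, qualities, truth)`` where ``reads`` is a
    list of AlignedRead with true placements, ``sequences``/``qualities``
    map read_id to the read as sequenced (biological orientation) and
    ``truth`` is a DataFrame with one row per read.  With ``out_prefix``,
    also writes ``<prefix>.fastq``, ``<prefix>.sam`` (true placements, so
    stages run without an external aligner) and ``<prefix>.truth.tsv``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    classes = sorted(config.class_mixture)
    probs = np.array([config.class_mixture[c] for c in classes])
    draws = rng.choice(len(classes), size=config.n_reads, p=probs / probs.sum())

    reads, seqs, quals, rows = [], {}, {}, []
    for i, ci in enumerate(draws):
        cls = classes[int(ci)]
        s, e, strand = _draw_span(cls, genome, config, rng)
        rid = f"{config.sample}_{config.timepoint}_r{i:06d}"
        frag = genome.sequence[s:e]
        read_seq = revcomp(frag) if strand == "-" else frag
        read_seq = _apply_errors(read_seq, config.error_rate, rng)
        q = _phred_track(len(read_seq), config.mean_phred, rng)
        reads.append(AlignedRead(read_id=rid, strand=strand, ref_start=s, ref_end=e,
                                 query_length=len(read_seq),
                                 mean_phred=float(np.mean(q)),
                                 timepoint=config.timepoint, sample=config.sample))
        seqs[rid] = read_seq
        quals[rid] = q
        rows.append({"read_id": rid, "true_class": cls, "true_strand": strand,
                     "ref_start": s + 1, "ref_end": e,  # 1-based inclusive
                     "timepoint": config.timepoint, "sample": config.sample})
    truth = pd.DataFrame(rows)

    if out_prefix is not None:
        _write_fastq(f"{out_prefix}.fastq", [(r.read_id, seqs[r.read_id], quals[r.read_id])
                                             for r in reads])
        write_alignments(reads, genome, f"{out_prefix}.sam", sequences=seqs, qualities=quals)
        truth.to_csv(f"{out_prefix}.truth.tsv", sep="\t", index=False)
    return reads, seqs, quals, truth


def _write_fastq(path: str, items) -> None:
    with open(path, "w") as fh:
        for rid, seq, q in items:
            fh.write(f"@{rid}\n{seq}\n+\n{''.join(chr(x + 33) for x in q)}\n")


# ---------------------------------------------------------------------------
# Hybrid reads
# ---------------------------------------------------------------------------


def simulate_hybrids(genome: GenomeModel, hybrid_spec: list[tuple], seed: int = 0,
                     error_rate: float = 0.0, timepoint: str = "0h",
                     sample: str = "test", mean_phred: float = 14.0,
                     out_prefix: str | None = None):
    """Simulate chimeric (template-switch) reads.

    ``hybrid_spec`` is a list of ``(type, count, (delta_min, delta_max))``
    with type in HYBRID_TYPES; delta is the junction offset in nt (ignored
    for foldback and neg_pos).  Same-strand deletion reads skip delta nt of
    template at the junction; duplication reads re-copy delta nt.  Foldback
    reads are a segment followed by the reverse complement of a suffix of
    that segment (a (+/-) copyback).

    Returns ``(sequences, qualities, truth)``; ``truth`` records the type,
    1-based junction positions and delta per read.
    """
    rng = np.random.default_rng(seed)
    L = genome.length
    seg_min = 100
    seqs, quals, rows = {}, {}, []
    n = 0
    for htype, count, delta_range in hybrid_spec:
        if htype not in HYBRID_TYPES:
            raise ValueError(f"unknown hybrid type {htype!r}")
        dlo, dhi = (delta_range or (0, 0))
        if htype not in ("foldback", "neg_pos") and (dlo < 1 or dhi > 200 or dlo > dhi):
            raise ValueError("delta range must lie within [1, 200]")
        for _ in range(count):
            rid = f"{sample}_{timepoint}_h{n:05d}"
            n += 1
            if htype == "foldback":
                seg_len = int(rng.integers(250, 600))
                a = int(rng.integers(0, L - seg_len))
                arm = int(rng.integers(80, seg_len - 50))
                seg = genome.sequence[a:a + seg_len]
                read = seg + revcomp(seg[-arm:])
                rows.append(dict(read_id=rid, true_type="foldback",
                                 junction_1=a + seg_len, junction_2=a + seg_len,
                                 delta=0, timepoint=timepoint, sample=sample))
            elif htype == "neg_pos":
                l1 = int(rng.integers(150, 500))
                l2 = int(rng.integers(150, 500))
                a = int(rng.integers(0, L // 2 - l1))
                c = int(rng.integers(L // 2, L - l2))
                read = revcomp(genome.sequence[a:a + l1]) + genome.sequence[c:c + l2]
                rows.append(dict(read_id=rid, true_type="neg_pos",
                                 junction_1=a + 1, junction_2=c + 1,
                                 delta=0, timepoint=timepoint, sample=sample))
            else:
                delta = int(rng.integers(dlo, dhi + 1))
                if delta == 0:
                    raise ValueError("delta=0 is not a hybrid")
                event = "deletion" if htype.endswith("deletion") else "duplication"
                # work in the transcript frame: '+' for pos_pos, rc genome for neg_neg
                frame = genome.sequence if htype.startswith("pos") else revcomp(genome.sequence)
                lo = seg_min + 10
                hi = L - seg_min - 10 - (delta if event == "deletion" else 0)
                if hi <= lo:
                    raise ValueError("junction too close to genome ends for segment minimum")
                j1 = int(rng.integers(lo, hi))
                a = int(rng.integers(max(0, j1 - 900), j1 - seg_min + 1))
                resume = j1 + delta if event == "deletion" else j1 - delta
                b = int(rng.integers(resume + seg_min, min(L, resume + 900) + 1))
                read = frame[a:j1] + frame[resume:b]
                if htype.startswith("pos"):
                    g1, g2 = j1, resume + 1  # 1-based: end of seg1 (inclusive), start of seg2
                else:
                    g1, g2 = L - j1 + 1, L - resume  # map rc-frame coords back
                rows.append(dict(read_id=rid, true_type=htype,
                                 junction_1=g1, junction_2=g2,
                                 delta=delta if event == "deletion" else -delta,
                                 timepoint=timepoint, sample=sample))
            read = _apply_errors(read, error_rate, rng)
            seqs[rid] = read
            quals[rid] = _phred_track(len(read), mean_phred, rng)
    truth = pd.DataFrame(rows)
    if out_prefix is not None:
        _write_fastq(f"{out_prefix}.fastq", [(r, seqs[r], quals[r]) for r in seqs])
        truth.to_csv(f"{out_prefix}.truth.tsv", sep="\t", index=False)
    return seqs, quals, truth


# ---------------------------------------------------------------------------
# Modification calls
# ---------------------------------------------------------------------------


def simulate_modifications(genome: GenomeModel, mod_sites: list[tuple],
                           reads: list[AlignedRead], ivt: bool = False,
                           seed: int = 0, artifact_sites: list[tuple] | None = None,
                           ) -> list[ModCallRecord]:
    """Emit per-read modification calls at configured sites.

    ``mod_sites`` is a list of ``(ref_pos, mod_type, stoichiometry)`` where
    stoichiometry is either a float or a ``{timepoint: float}`` map.  Every
    positive-strand read covering a site yields one record: with
    probability equal to the true stoichiometry the read is modified and
    its call probability is drawn Uniform(0.85, 1.0), otherwise
    Uniform(0.0, 0.30).  With ``ivt=True`` the true stoichiometry is forced
    to 0 (the modification-free in vitro transcript) except at
    ``artifact_sites`` — systematic false-positive sites planted equally in
    test and IVT to exercise the background subtraction.
    """
    rng = np.random.default_rng(seed)
    effective: list[tuple] = []
    for pos, mtype, stoich in mod_sites:
        if mtype not in MOD_BASE:
            raise ValueError(f"unknown mod_type {mtype!r}")
        if not (0 <= pos < genome.length):
            raise ValueError(f"site {pos} outside genome")
        if genome.sequence[pos] != MOD_BASE[mtype]:
            raise ValueError(
                f"{mtype} site at {pos}: base {genome.sequence[pos]} is not {MOD_BASE[mtype]}")
        effective.append((pos, mtype, 0.0 if ivt else stoich))
    for pos, mtype, stoich in (artifact_sites or []):
        if genome.sequence[pos] != MOD_BASE[mtype]:
            raise ValueError(f"artifact {mtype} site at {pos}: incompatible base")
        effective.append((pos, mtype, stoich))

    records: list[ModCallRecord] = []
    for read in reads:
        if read.strand != "+":
            continue
        for pos, mtype, stoich in effective:
            if not (read.ref_start <= pos < read.ref_end):
                continue
            s = stoich.get(read.timepoint, 0.0) if isinstance(stoich, dict) else stoich
            if rng.random() < s:
                p = rng.uniform(0.85, 1.0)
            else:
                p = rng.uniform(0.0, 0.30)
            records.append(ModCallRecord(read_id=read.read_id, ref_pos=pos,
                                         mod_type=mtype, probability=float(p),
                                         sample=read.sample, timepoint=read.timepoint))
    return records
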