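"""Domain types and file IO shared by every pipeline stage.

Coordinate conventions
----------------------
All coordinates are 0-based half-open internally.  TSV/report output converts
positional columns to 1-based inclusive, matching the convention of genome
browsers and of positions quoted in the MS2 literature (e.g. the conserved
pseudouridine site "924 nt").

Negative-strand reads are stored in the genome frame (positive-strand
coordinates) with ``strand == '-'``.  The biological 5'→3' direction of a
'-' read therefore runs from high to low genome coordinates: its biological
5' end is ``ref_end - 1`` and its biological 3' end is ``ref_start``.  Every
stage that reasons about read ends (anchoring classification, start/end
hotspots) must honour this convention.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("ms2drs")

#: MS2 genome length in nt; the default for the synthetic genome generator.
MS2_GENOME_LENGTH = 3569

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA-alphabet sequence (T, not U)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_rna(seq: str) -> str:
    """Uppercase and convert U to T for internal storage."""
    return seq.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrfAnnotation:
    """One ORF interval on the positive-strand genome frame.

    ``start``/``end`` are 0-based half-open.  MS2 ORFs all lie on the
    positive strand (the genome is its own mRNA), so ``strand`` is '+'.
    """

    name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"ORF {self.name}: invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeModel:
    """Reference sequence plus ORF annotations — the coordinate frame for
    everything downstream."""

    name: str
    sequence: str
    orfs: list[OrfAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence)
        if len(self.sequence) < 100:
            raise ValueError(f"genome too short ({len(self.sequence)} nt; need >= 100)")
        names = [o.name for o in self.orfs]
        if len(set(names)) != len(names):
            raise ValueError("ORF names must be unique")
        for orf in self.orfs:
            if orf.end > len(self.sequence):
                raise ValueError(f"ORF {orf.name} extends past genome end")
        self.orfs = sorted(self.orfs, key=lambda o: o.start)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def orf(self, name: str) -> OrfAnnotation:
        for o in self.orfs:
            if o.name == name:
                return o
        raise KeyError(name)


@dataclass
class AlignedRead:
    """One oriented primary alignment of a read in the genome frame."""

    read_id: str
    strand: str
    ref_start: int
    ref_end: int
    query_length: int
    mean_phred: float = 0.0
    timepoint: str = ""
    sample: str = ""
    is_primary: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.ref_start < self.ref_end):
            raise ValueError(f"{self.read_id}: invalid span [{self.ref_start}, {self.ref_end})")
        if self.strand not in "+-":
            raise ValueError(f"{self.read_id}: bad strand {self.strand!r}")

    @property
    def span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def bio_start(self) -> int:
        """Genome coordinate of the biological 5' end."""
        return self.ref_start if self.strand == "+" else self.ref_end - 1

    @property
    def bio_end(self) -> int:
        """Genome coordinate of the biological 3' end."""
        return self.ref_end - 1 if self.strand == "+" else self.ref_start


@dataclass(frozen=True)
class ModCallRecord:
    """Per-read, per-site modified-base call (the pileup substrate)."""

    read_id: str
    ref_pos: int
    mod_type: str
    probability: float
    sample: str
    timepoint: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("probability outside [0, 1]")


MOD_TYPES = ("m5C", "psi", "m6A", "inosine")

#: canonical base each modification type sits on (genome/DNA alphabet)
MOD_BASE = {"m5C": "C", "psi": "T", "m6A": "A", "inosine": "A"}


# ---------------------------------------------------------------------------
# Genome loading
# ---------------------------------------------------------------------------


def _read_bed_orfs(path: str) -> list[OrfAnnotation]:
    orfs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            name = fields[3] if len(fields) > 3 else f"orf{len(orfs) + 1}"
            orfs.append(OrfAnnotation(name=name, start=int(fields[1]), end=int(fields[2])))
    return orfs


def _read_gff_orfs(path: str) -> list[OrfAnnotation]:
    import gffutils

    db = gffutils.create_db(path, ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    orfs = []
    for feat in db.all_features():
        if feat.featuretype not in ("CDS", "gene", "ORF"):
            continue
        name = (feat.attributes.get("Name") or feat.attributes.get("ID")
                or [f"orf{len(orfs) + 1}"])[0]
        # GFF is 1-based inclusive
        orfs.append(OrfAnnotation(name=name, start=feat.start - 1, end=feat.end))
    return orfs


def load_genome(fasta_path: str, annotation_path: str) -> GenomeModel:
    """Load the reference genome and its ORF annotations.

    The FASTA must contain exactly one record.  The annotation file may be
    GFF3 (``.gff``/``.gff3``; CDS/gene/ORF features) or BED (0-based
    half-open).  U is normalised to T internally; ORFs are sorted by start.
    """
    records = list(SeqIO.parse(fasta_path, "fasta"))
    if len(records) != 1:
        raise ValueError(f"ambiguous reference: FASTA has {len(records)} records, expected 1")
    rec = records[0]
    if annotation_path.endswith((".gff", ".gff3")):
        orfs = _read_gff_orfs(annotation_path)
    else:
        orfs = _read_bed_orfs(annotation_path)
    if not orfs:
        raise ValueError("annotation file contains no ORF intervals")
    return GenomeModel(name=rec.id, sequence=str(rec.seq), orfs=orfs)


def write_genome(genome: GenomeModel, fasta_path: str, gff_path: str | None = None) -> None:
    """Write the genome FASTA and (optionally) a GFF3 of its ORFs."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.name}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")
    if gff_path is not None:
        with open(gff_path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {genome.name} 1 {genome.length}\n")
            for orf in genome.orfs:
                attrs = f"ID={orf.name};Name={orf.name}"
                fh.write(f"{genome.name}\tms2drs\tCDS\t{orf.start + 1}\t{orf.end}\t.\t+\t0\t{attrs}\n")


# ---------------------------------------------------------------------------
# SAM/BAM
# ---------------------------------------------------------------------------

# Tags used to round-trip sample metadata through SAM.
_TAG_TIMEPOINT = "ZT"
_TAG_SAMPLE = "ZS"


def read_alignments(sam_path: str, min_phred: float = 10.0
                    ) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """Read primary and supplementary alignments from SAM/BAM.

    Reproduces the study's read filter: unmapped and secondary records are
    dropped, and primary records whose mean base quality (arithmetic mean
    PHRED) is below ``min_phred`` are dropped.  Supplementary records are
    returned in a separate list for the chimera stage and are exempt from
    the quality filter (their quality is judged on the primary).  Records
    without base qualities ('*') are retained, as the filter cannot be
    evaluated.  Reverse-flag records get ``strand='-'`` with coordinates
    kept in the genome frame.

    Returns ``(primary_reads, supplementary_records)``.
    """
    primaries: list[AlignedRead] = []
    supplementary: list[AlignedRead] = []
    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        if not fh.header.references:
            raise ValueError(f"{sam_path}: SAM header missing @SQ lines")
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            if rec.cigartuples is None:
                logger.warning("skipping CIGAR-less record %s", rec.query_name)
                continue
            quals = rec.query_qualities
            mean_q = float(np.mean(quals)) if quals is not None else float("nan")
            read = AlignedRead(
                read_id=rec.query_name,
                strand="-" if rec.is_reverse else "+",
                ref_start=rec.reference_start,
                ref_end=rec.reference_end,
                query_length=rec.infer_query_length() or 0,
                mean_phred=mean_q,
                timepoint=str(rec.get_tag(_TAG_TIMEPOINT)) if rec.has_tag(_TAG_TIMEPOINT) else "",
                sample=str(rec.get_tag(_TAG_SAMPLE)) if rec.has_tag(_TAG_SAMPLE) else "",
                is_primary=not rec.is_supplementary,
            )
            if rec.is_supplementary:
                supplementary.append(read)
            elif not (mean_q == mean_q and mean_q < min_phred):  # NaN-safe keep
                primaries.append(read)
    return primaries, supplementary


def write_alignments(reads: list[AlignedRead], genome: GenomeModel, sam_path: str,
                     sequences: dict[str, str] | None = None,
                     qualities: dict[str, list[int]] | None = None) -> None:
    """Write AlignedReads as SAM records against ``genome``.

    ``sequences``/``qualities`` map read_id to the read as sequenced
    (biological orientation); '-' reads are stored reverse-complemented
    with flag 16, per the SAM convention.  Without sequences a fully
    matching CIGAR over the reference span is emitted.
    """
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": genome.name, "LN": genome.length}]}
    with pysam.AlignmentFile(sam_path, "w", header=header) as out:
        for read in reads:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read.read_id
            rec.reference_id = 0
            rec.reference_start = read.ref_start
            rec.mapping_quality = 60
            flag = 0
            if read.strand == "-":
                flag |= 16
            if not read.is_primary:
                flag |= 2048
            rec.flag = flag
            seq = None
            if sequences and read.read_id in sequences:
                seq = sequences[read.read_id]
                if read.strand == "-":
                    seq = revcomp(seq)
            if seq is not None:
                rec.query_sequence = seq
                rec.cigarstring = f"{len(seq)}M"
                if qualities and read.read_id in qualities:
                    q = qualities[read.read_id]
                    rec.query_qualities = pysam.qualitystring_to_array(
                        "".join(chr(x + 33) for x in (q[::-1] if read.strand == "-" else q)))
            else:
                rec.cigarstring = f"{read.span}M"
            rec.set_tag(_TAG_TIMEPOINT, read.timepoint)
            rec.set_tag(_TAG_SAMPLE, read.sample)
            out.write(rec)


def split_strands(reads: list[AlignedRead]) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """Partition reads into (positive-strand, negative-strand) lists."""
    pos = [r for r in reads if r.strand == "+"]
    neg = [r for r in reads if r.strand == "-"]
    return pos, neg


# ---------------------------------------------------------------------------
# Mod-call tables
# ---------------------------------------------------------------------------

MODCALL_COLUMNS = ["read_id", "ref_pos", "mod_type", "probability", "sample",
                   "timepoint", "length_fraction"]


def write_modcall_table(records, path: str) -> None:
    """Write ModCallRecords as TSV (ref_pos emitted 1-based)."""
    import pandas as pd

    rows = [{"read_id": r.read_id, "ref_pos": r.ref_pos + 1, "mod_type": r.mod_type,
             "probability": r.probability, "sample": r.sample, "timepoint": r.timepoint}
            for r in records]
    pd.DataFrame(rows, columns=MODCALL_COLUMNS[:-1]).to_csv(path, sep="\t", index=False)


def read_modcall_table(path: str):
    """Read a mod-call TSV into a DataFrame with 0-based ``ref_pos``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    df["ref_pos"] = df["ref_pos"].astype(int) - 1
    return df
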