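"""On-disk formats: FASTA, BED6, SAM, TSV tables.

Coordinates are 0-based half-open everywhere in memory and in BED; SAM
conversion adds 1 to the start.  Collapsed reads use the ``readN_xCOUNT``
header convention, where COUNT is the number of identical sequenced
copies folded into the record.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from srnasurv.alignments import AlignedRead, Locus, SmallRead
from srnasurv.sequtils import revcomp

_COPIES_RE = re.compile(r"_x(\d+)$")


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA as a name -> uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_reads(path: str | Path, fmt: str | None = None) -> list[SmallRead]:
    """Read collapsed small-RNA reads from FASTA or FASTQ.

    A trailing ``_xCOUNT`` in the record id is parsed as the collapsed
    copy count; records without it count as one copy.
    """
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        m = _COPIES_RE.search(rec.id)
        copies = int(m.group(1)) if m else 1
        reads.append(SmallRead(id=rec.id, sequence=str(rec.seq).upper(), copies=copies))
    return reads


def write_reads_fasta(reads: Iterable[SmallRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.sequence}\n")


def write_reads_fastq(reads: Iterable[SmallRead], path: str | Path) -> None:
    # Constant quality: quality is unused downstream.
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def read_bed(path: str | Path) -> list[Locus]:
    """Read BED6 loci; the name field is ``class`` or ``class:id``."""
    loci = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"locus_{i}"
            strand = parts[5] if len(parts) > 5 else "."
            cls, _, lid = name.partition(":")
            loci.append(
                Locus(
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    feature_class=cls,
                    id=lid or name,
                )
            )
    return loci


def write_bed(loci: Iterable[Locus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for loc in loci:
            name = f"{loc.feature_class}:{loc.id}"
            fh.write(f"{loc.chrom}\t{loc.start}\t{loc.end}\t{name}\t0\t{loc.strand}\n")


def write_alignments_bed(alignments: Iterable[AlignedRead], path: str | Path) -> None:
    """Alignments as BED6 with the collapsed copy count in the score column."""
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.read_id}\t{a.copies}\t{a.strand}\n")


def write_alignments_sam(
    alignments: Iterable[AlignedRead], genome: dict[str, str], path: str | Path
) -> None:
    """Write alignments as SAM with NH (hit count) tags.

    The read's collapsed copy count travels in the ``readN_xCOUNT`` name.
    """
    header = pysam.AlignmentHeader.from_references(
        list(genome), [len(s) for s in genome.values()]
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = a.read_id
            # SAM stores SEQ in reference orientation
            seg.query_sequence = revcomp(a.sequence) if a.strand == "-" else a.sequence
            seg.flag = 16 if a.strand == "-" else 0
            seg.reference_id = list(genome).index(a.chrom)
            seg.reference_start = a.start
            seg.mapping_quality = 255
            seg.cigarstring = f"{a.end - a.start}M"
            seg.set_tag("NH", a.n_hits)
            out.write(seg)


def read_alignments_sam(path: str | Path) -> list[AlignedRead]:
    alignments = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            m = _COPIES_RE.search(seg.query_name)
            copies = int(m.group(1)) if m else 1
            seq = seg.query_sequence or ""
            if seg.is_reverse:
                seq = revcomp(seq)
            alignments.append(
                AlignedRead(
                    read_id=seg.query_name,
                    sequence=seq,
                    chrom=seg.reference_name,
                    start=seg.reference_start,
                    end=seg.reference_end,
                    strand="-" if seg.is_reverse else "+",
                    n_hits=seg.get_tag("NH") if seg.has_tag("NH") else 1,
                    copies=copies,
                )
            )
    return alignments
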