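"""Exact read mapping, multimap capping, feature assignment and locus discovery.

Small-RNA libraries are dominated by repeat-derived reads, so every exact
occurrence of every read is captured and reads hitting the genome too many
times are discarded wholesale: a read is kept only if it maps *fewer than*
``max_hits`` times (default 100).  Feature assignment labels each mapping
event with the class of the annotated locus it touches, with abundant
structural ncRNA classes taking precedence, and read sets are "cleaned" for
per-class analyses by dropping reads that touch any non-target class.
Expressed small-RNA loci are called from read footprints outside the
annotation: merged islands must exceed 1000 reads and 200 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from srnasurv.sequtils import find_all, revcomp

logger = logging.getLogger(__name__)

#: Classes an alignment can be assigned to, highest precedence first.
FEATURE_PRECEDENCE = ["rRNA", "tRNA", "snRNA", "miRNA", "mRNA", "TE", "master", "unknown"]

_PREC_RANK = {cls: i for i, cls in enumerate(FEATURE_PRECEDENCE)}


@dataclass
class SmallRead:
    """A collapsed small-RNA read: one unique sequence with its copy count."""

    id: str
    sequence: str
    copies: int = 1


@dataclass
class AlignedRead:
    """One mapping event of a collapsed read.

    ``sequence`` is the read as sequenced (5'->3'); on the minus strand it
    is the reverse complement of the genome slice [start, end).  ``n_hits``
    counts the read's mapping events genome-wide, on both strands.
    """

    read_id: str
    sequence: str
    chrom: str
    start: int
    end: int
    strand: str
    n_hits: int = 1
    copies: int = 1
    feature_class: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end (``end - 1`` on the minus strand)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class Locus:
    """An annotated or discovered genomic interval with a feature class."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    feature_class: str = "unknown"
    id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"locus {self.id}: start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


def map_reads_exact(
    reads: Iterable[SmallRead], genome: dict[str, str]
) -> tuple[list[AlignedRead], list[str]]:
    """Map reads to all exact genomic occurrences on both strands.

    Parameters
    ----------
    reads
        Collapsed reads; sequences must be over ACGT (others are skipped
        with a warning).
    genome
        Chromosome name -> uppercase sequence.

    Returns
    -------
    (alignments, unmapped_ids)
        One :class:`AlignedRead` per occurrence, with ``n_hits`` set to the
        read's total occurrence count, plus the ids of reads with no
        occurrence.
    """
    alignments: list[AlignedRead] = []
    unmapped: list[str] = []
    for read in reads:
        seq = read.sequence.upper()
        if set(seq) - set("ACGT"):
            logger.warning("read %s skipped: non-ACGT characters", read.id)
            continue
        hits: list[tuple[str, int, str]] = []
        rc = revcomp(seq)
        for chrom, chromseq in genome.items():
            for pos in find_all(chromseq, seq):
                hits.append((chrom, pos, "+"))
            for pos in find_all(chromseq, rc):
                hits.append((chrom, pos, "-"))
        if not hits:
            unmapped.append(read.id)
            continue
        for chrom, pos, strand in hits:
            alignments.append(
                AlignedRead(
                    read_id=read.id,
                    sequence=seq,
                    chrom=chrom,
                    start=pos,
                    end=pos + len(seq),
                    strand=strand,
                    n_hits=len(hits),
                    copies=read.copies,
                )
            )
    return alignments, unmapped


def cap_multimappers(
    alignments: Sequence[AlignedRead], max_hits: int = 100
) -> tuple[list[AlignedRead], float]:
    """Drop all alignments of reads mapping ``max_hits`` times or more.

    A read survives only if it maps *fewer than* ``max_hits`` times.
    Returns the kept alignments and the copies-weighted fraction of mapped
    reads that were discarded.
    """
    kept = [a for a in alignments if a.n_hits < max_hits]
    read_copies: dict[str, tuple[int, bool]] = {}
    for a in alignments:
        read_copies[a.read_id] = (a.copies, a.n_hits < max_hits)
    total = sum(c for c, _ in read_copies.values())
    removed = sum(c for c, keep in read_copies.values() if not keep)
    discarded_fraction = removed / total if total else 0.0
    return kept, discarded_fraction


def _annotation_tree(annotation: Iterable[Locus]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for loc in annotation:
        trees.setdefault(loc.chrom, IntervalTree()).addi(loc.start, loc.end, loc)
    return trees


def assign_to_features(
    alignments: Iterable[AlignedRead], annotation: Sequence[Locus]
) -> list[AlignedRead]:
    """Label each alignment with the feature class of the locus it overlaps.

    Overlap of >= 1 bp suffices; alignments touching no locus are labelled
    ``intergenic``.  When loci of different classes overlap an alignment the
    class earlier in :data:`FEATURE_PRECEDENCE` wins; equal-precedence ties
    break deterministically toward the locus with the smaller start and are
    logged.  Labels are written in place; the input list is returned.
    """
    trees = _annotation_tree(annotation)
    alignments = list(alignments)
    for a in alignments:
        tree = trees.get(a.chrom)
        hits = sorted(tree.overlap(a.start, a.end)) if tree is not None else []
        if not hits:
            a.feature_class = "intergenic"
            continue
        ranked = sorted(
            (iv.data for iv in hits),
            key=lambda loc: (_PREC_RANK.get(loc.feature_class, len(_PREC_RANK)), loc.start),
        )
        best = ranked[0]
        if len(ranked) > 1 and _PREC_RANK.get(ranked[1].feature_class) == _PREC_RANK.get(
            best.feature_class
        ):
            logger.debug(
                "alignment %s overlaps equal-precedence loci; assigned %s",
                a.read_id,
                best.id,
            )
        a.feature_class = best.feature_class
    return alignments


def clean_by_feature(
    reads: Iterable[SmallRead],
    genome: dict[str, str],
    annotation: Sequence[Locus],
    target_class: str,
) -> list[SmallRead]:
    """Keep reads whose every mapping event is in the target class or intergenic.

    This is the per-class dataset cleaning step: before a class-restricted
    analysis, any read with even one mapping event in a different annotated
    class is removed, so multi-mapping events cannot leak signal between
    classes.  Unmapped reads are removed too.
    """
    if target_class not in FEATURE_PRECEDENCE:
        raise ValueError(f"unknown target class {target_class!r}")
    reads = list(reads)
    alignments, unmapped = map_reads_exact(reads, genome)
    assign_to_features(alignments, annotation)
    bad_ids = {
        a.read_id
        for a in alignments
        if a.feature_class not in (target_class, "intergenic")
    }
    bad_ids.update(unmapped)
    mapped_ids = {a.read_id for a in alignments}
    return [r for r in reads if r.id in mapped_ids and r.id not in bad_ids]


def discover_expressed_loci(
    alignments: Sequence[AlignedRead],
    annotation: Sequence[Locus],
    min_reads: int = 1000,
    min_len: int = 200,
    merge_gap: int = 50,
) -> list[Locus]:
    """Call expressed small-RNA loci from read islands outside the annotation.

    Alignments overlapping any annotated locus are ignored; the remaining
    footprints are merged when separated by at most ``merge_gap`` bp, and an
    island becomes a locus when its copies-weighted read count is strictly
    greater than ``min_reads`` and its span strictly greater than
    ``min_len``.  Returned loci have class ``unknown`` and no strand.
    """
    trees = _annotation_tree(annotation)
    outside = [
        a
        for a in alignments
        if a.chrom not in trees or not trees[a.chrom].overlap(a.start, a.end)
    ]
    outside.sort(key=lambda a: (a.chrom, a.start))
    loci: list[Locus] = []
    island: list[AlignedRead] = []

    def flush() -> None:
        if not island:
            return
        start = island[0].start
        end = max(a.end for a in island)
        weight = sum(a.copies for a in island)
        if weight > min_reads and end - start > min_len:
            loci.append(
                Locus(
                    chrom=island[0].chrom,
                    start=start,
                    end=end,
                    strand=".",
                    feature_class="unknown",
                    id=f"expressed_{len(loci)}",
                )
            )

    cur_chrom, cur_end = None, -1
    for a in outside:
        if a.chrom != cur_chrom or a.start > cur_end + merge_gap:
            flush()
            island = []
            cur_chrom = a.chrom
            cur_end = a.end
        island.append(a)
        cur_end = max(cur_end, a.end)
    flush()
    return loci
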