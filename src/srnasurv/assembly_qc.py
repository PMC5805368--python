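"""Contig decontamination by matched fraction, and assembly statistics.

Contigs are screened against a foreign-sequence database upstream; this
module consumes the resulting hit intervals.  The matched fraction of a
contig is the length of the union of its hit intervals divided by the
contig length, and a contig is discarded when that fraction is strictly
greater than the threshold (default 10%).  N50 is the largest length L
such that contigs of length >= L sum to at least half the assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd


@dataclass
class ContigHitSet:
    """A contig's length plus its foreign-hit intervals (0-based half-open)."""

    contig_id: str
    contig_length: int
    hits: list[tuple[int, int]] = field(default_factory=list)


def matched_fraction(hitset: ContigHitSet) -> float:
    """Union length of hit intervals over contig length.

    Overlapping hits are merged, so the fraction never exceeds 1.
    """
    for s, e in hitset.hits:
        if s < 0 or e > hitset.contig_length or s >= e:
            raise ValueError(
                f"contig {hitset.contig_id}: hit [{s}, {e}) outside "
                f"[0, {hitset.contig_length})"
            )
    covered = 0
    cur_s = cur_e = None
    for s, e in sorted(hitset.hits):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered / hitset.contig_length


def summed_fraction(hitset: ContigHitSet) -> float:
    """Summed hit lengths over contig length (no union; can exceed 1)."""
    return sum(e - s for s, e in hitset.hits) / hitset.contig_length


def filter_contaminated(
    hitsets: Iterable[ContigHitSet],
    threshold: float = 0.10,
    mode: str = "union",
) -> tuple[list[str], list[str]]:
    """Split contigs into (kept, discarded) by matched fraction.

    A contig is discarded iff its fraction is *strictly greater* than
    ``threshold``; exactly at the threshold it is kept.
    """
    frac = matched_fraction if mode == "union" else summed_fraction
    kept, discarded = [], []
    for hs in hitsets:
        (discarded if frac(hs) > threshold else kept).append(hs.contig_id)
    return kept, discarded


def assembly_stats(lengths: Sequence[int]) -> tuple[int, int, int]:
    """(n_contigs, total_bp, N50) of an assembly.

    N50 is computed by descending cumulative sum: the length at which the
    running total first reaches half of the assembly.
    """
    lengths = list(lengths)
    if not lengths:
        raise ValueError("empty assembly")
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be positive")
    total = sum(lengths)
    running = 0
    for L in sorted(lengths, reverse=True):
        running += L
        if 2 * running >= total:
            return len(lengths), total, L
    raise AssertionError("unreachable")


def read_blast_hits(path: str, contig_lengths: dict[str, int]) -> list[ContigHitSet]:
    """Build hit sets from a BLAST outfmt-6-like TSV.

    Only the first three columns are used: qseqid, qstart, qend (1-based
    inclusive query coordinates, converted to 0-based half-open; reversed
    coordinates are normalised).  Contigs absent from the table get empty
    hit sets.
    """
    hits: dict[str, list[tuple[int, int]]] = {cid: [] for cid in contig_lengths}
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    for qseqid, qstart, qend in zip(df[0], df[1], df[2]):
        if qseqid not in hits:
            raise ValueError(f"hit for unknown contig {qseqid!r}")
        s, e = int(qstart), int(qend)
        if s > e:
            s, e = e, s
        hits[qseqid].append((s - 1, e))
    return [
        ContigHitSet(contig_id=cid, contig_length=contig_lengths[cid], hits=h)
        for cid, h in hits.items()
    ]


def read_bed_hits(path: str, contig_lengths: dict[str, int]) -> list[ContigHitSet]:
    """Build hit sets from a BED file of hit intervals on contigs."""
    hits: dict[str, list[tuple[int, int]]] = {cid: [] for cid in contig_lengths}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split("\t")[:3]
            if chrom not in hits:
                raise ValueError(f"hit for unknown contig {chrom!r}")
            hits[chrom].append((int(start), int(end)))
    return [
        ContigHitSet(contig_id=cid, contig_length=contig_lengths[cid], hits=h)
        for cid, h in hits.items()
    ]


def contig_lengths_from_fai(path: str) -> dict[str, int]:
    """Contig lengths from a samtools .fai index."""
    lengths = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split("\t")
            lengths[parts[0]] = int(parts[1])
    return lengths
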