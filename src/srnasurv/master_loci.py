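"""siRNA master-locus discovery and TE-read accountability.

A master locus is an expressed, dual-strand small-RNA locus assembled from
transposable-element fragments — a genomic catalogue of restricted
sequences.  Candidates come from expressed-locus discovery; a candidate is
called when (a) its strand bias stays at or below a cutoff (dual-strand,
dsRNA-derived) and (b) it shares at least one exact >= 25-bp segment with
a TE family in either orientation.  Accountability measures the
copies-weighted fraction of TE-mapped reads whose full sequence occurs
exactly within any master locus — how much of the TE-directed small-RNA
population the catalogue can explain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from srnasurv.alignments import AlignedRead, Locus, SmallRead
from srnasurv.locus_metrics import strand_bias
from srnasurv.sequtils import revcomp


@dataclass
class TESegment:
    """An exact match between a locus and a TE family sequence."""

    family: str
    start: int  # locus-relative, 0-based half-open
    end: int
    orientation: str  # + = family sense, - = reverse complement

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MasterLocus:
    """A called master locus with its evidence tracks."""

    locus: Locus
    strand_bias: float
    te_fragment_hits: list[TESegment]
    dual_strand: bool
    density_all: dict[str, np.ndarray] = field(default_factory=dict)  # strand -> per-base
    density_unique: dict[str, np.ndarray] = field(default_factory=dict)


def _diagonal_matches(locus_seq: str, te_seq: str, min_match: int) -> list[tuple[int, int]]:
    """Maximal exact-match runs >= min_match between two strings, as locus intervals."""
    n, m = len(locus_seq), len(te_seq)
    a = np.frombuffer(locus_seq.encode(), dtype=np.uint8)
    b = np.frombuffer(te_seq.encode(), dtype=np.uint8)
    out: list[tuple[int, int]] = []
    # diagonal d: locus index i pairs with te index i - d
    for d in range(-(m - min_match), n - min_match + 1):
        i0 = max(0, d)
        j0 = i0 - d
        length = min(n - i0, m - j0)
        if length < min_match:
            continue
        eq = a[i0 : i0 + length] == b[j0 : j0 + length]
        # run-length encode the boolean diagonal
        idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
        for s, e in zip(idx[::2], idx[1::2]):
            if e - s >= min_match:
                out.append((i0 + int(s), i0 + int(e)))
    return out


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def te_homology_segments(
    locus_seq: str,
    te_catalog: dict[str, str],
    min_match: int = 25,
) -> list[TESegment]:
    """Exact matches >= ``min_match`` bp between a locus and TE families.

    Both orientations are searched; overlapping matches of one family and
    orientation are merged into maximal locus intervals.
    """
    segments: list[TESegment] = []
    for family, te_seq in te_catalog.items():
        for orientation, query in (("+", te_seq), ("-", revcomp(te_seq))):
            raw = _diagonal_matches(locus_seq.upper(), query.upper(), min_match)
            for s, e in _merge_intervals(raw):
                segments.append(TESegment(family=family, start=s, end=e, orientation=orientation))
    segments.sort(key=lambda seg: (seg.start, seg.end, seg.family))
    return segments


def _density_tracks(
    locus: Locus, alignments: Sequence[AlignedRead]
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    all_tracks = {s: np.zeros(locus.length) for s in "+-"}
    uniq_tracks = {s: np.zeros(locus.length) for s in "+-"}
    for a in alignments:
        if a.chrom != locus.chrom or a.start >= locus.end or a.end <= locus.start:
            continue
        s = max(a.start, locus.start) - locus.start
        e = min(a.end, locus.end) - locus.start
        all_tracks[a.strand][s:e] += a.copies
        if a.n_hits == 1:
            uniq_tracks[a.strand][s:e] += a.copies
    return all_tracks, uniq_tracks


def call_master_loci(
    expressed_loci: Sequence[Locus],
    alignments: Sequence[AlignedRead],
    te_catalog: dict[str, str],
    genome: dict[str, str],
    bias_cutoff: float = 0.3,
    min_match: int = 25,
) -> list[MasterLocus]:
    """Call master loci: dual-strand expressed loci with TE-homologous segments.

    A candidate passes when its copies-weighted strand bias is at most
    ``bias_cutoff`` and it shares >= 1 exact ``min_match``-bp segment with
    a TE family.  Called loci carry per-strand all-mapping and
    unique-mapping per-base density tracks.
    """
    called: list[MasterLocus] = []
    for locus in expressed_loci:
        bias = strand_bias(locus, alignments)
        if bias is None or bias > bias_cutoff:
            continue
        locus_seq = genome[locus.chrom][locus.start : locus.end]
        segments = te_homology_segments(locus_seq, te_catalog, min_match)
        if not segments:
            continue
        all_tracks, uniq_tracks = _density_tracks(locus, alignments)
        called.append(
            MasterLocus(
                locus=locus,
                strand_bias=bias,
                te_fragment_hits=segments,
                dual_strand=True,
                density_all=all_tracks,
                density_unique=uniq_tracks,
            )
        )
    return called


def te_read_accountability(
    te_mapped_reads: Sequence[SmallRead],
    master_locus_seqs: Sequence[str],
) -> float:
    """Fraction of TE-mapped reads exactly contained in a master locus.

    Copies-weighted; a read counts if its sequence or reverse complement is
    a substring of any master-locus sequence.  Raises on an empty read set.
    """
    reads = list(te_mapped_reads)
    if not reads:
        raise ValueError("empty TE-mapped read set")
    seqs = [s.upper() for s in master_locus_seqs]
    total = 0
    accounted = 0
    for read in reads:
        total += read.copies
        seq = read.sequence.upper()
        rc = revcomp(seq)
        if any(seq in ml or rc in ml for ml in seqs):
            accounted += read.copies
    return accounted / total
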