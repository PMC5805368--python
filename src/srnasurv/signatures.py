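"""5'-overlap pair-count signatures and their z-scores.

The biogenesis statistic: for every plus-strand read 5' end and every
minus-strand read 5' end, the 5' overlap ``o`` is the number of bases
between and including the two 5' ends.  Counting copies-weighted pairs at
each overlap ``o`` in a window (default 1..30) and z-scoring the counts
over the window gives a profile whose peak identifies the biogenesis
mechanism: ping-pong slicing peaks at ``o = 10``; Dicer duplex products of
length L peak at ``o = L - 2`` (a 2-nt 3' overhang).  For size-matched
pairs the overlap axis converts to an overhang axis by ``h = L - o``.

Pairs are counted by 5' distance alone — two reads need not physically
overlap — and the "all" size column pools counts over every length
combination.  Windows with zero variance are undefined (rendered blank).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from srnasurv.alignments import AlignedRead, Locus

logger = logging.getLogger(__name__)

SIZE_RANGE = (18, 30)
O_MAX = 30


class FivePrimeProfile:
    """Copies-weighted 5'-end counts per (chrom, strand, read length).

    Minus-strand 5' ends are recorded at genomic coordinate ``end - 1``.
    """

    def __init__(self) -> None:
        self._counts: dict[tuple[str, str, int], Counter] = defaultdict(Counter)
        self.chroms: set[str] = set()
        self.sizes: set[int] = set()

    @classmethod
    def from_alignments(
        cls,
        alignments: Iterable[AlignedRead],
        size_range: tuple[int, int] = SIZE_RANGE,
        unique_only: bool = False,
    ) -> "FivePrimeProfile":
        prof = cls()
        lo, hi = size_range
        for a in alignments:
            if not lo <= a.length <= hi:
                continue
            if unique_only and a.n_hits != 1:
                continue
            prof._counts[(a.chrom, a.strand, a.length)][a.five_prime] += a.copies
            prof.chroms.add(a.chrom)
            prof.sizes.add(a.length)
        return prof

    def stratum(self, chrom: str, strand: str, size: int | str) -> Counter:
        """5'-end counts for one chromosome/strand at one size, or summed over all."""
        if size == "all":
            total: Counter = Counter()
            for L in self.sizes:
                total.update(self._counts.get((chrom, strand, L), {}))
            return total
        return self._counts.get((chrom, strand, size), Counter())

    def total(self) -> float:
        return float(sum(sum(c.values()) for c in self._counts.values()))


@dataclass
class OverlapSignature:
    """Pair counts (and z-scores) over a 5'-overlap window for one size pair."""

    size_pair: tuple[int | str, int | str]
    overlaps: np.ndarray  # window o = 1..O_max
    counts: np.ndarray
    z: np.ndarray | None = None
    defined: bool = False


@dataclass
class OverhangSignature:
    """An overlap signature re-indexed to 3'-overhang length ``h = L - o``."""

    size: int
    overhangs: np.ndarray
    counts: np.ndarray
    z: np.ndarray | None = None
    defined: bool = False


def build_profiles(
    alignments: Iterable[AlignedRead],
    size_range: tuple[int, int] = SIZE_RANGE,
    unique_only: bool = False,
) -> FivePrimeProfile:
    """Build per-stratum 5'-end count maps from alignments."""
    return FivePrimeProfile.from_alignments(alignments, size_range, unique_only)


def overlap_pair_counts(
    profile: FivePrimeProfile,
    L1: int | str,
    L2: int | str,
    o_max: int = O_MAX,
) -> OverlapSignature:
    """Count plus/minus 5'-end pairs at each overlap ``o`` in ``[1, o_max]``.

    ``Z(o) = sum over chrom, p of c_plus[L1](p) * c_minus[L2](p + o - 1)``,
    with copies-weighted counts; ``L1``/``L2`` may be ``"all"``.
    """
    overlaps = np.arange(1, o_max + 1)
    counts = np.zeros(o_max, dtype=float)
    for chrom in profile.chroms:
        plus = profile.stratum(chrom, "+", L1)
        minus = profile.stratum(chrom, "-", L2)
        if not plus or not minus:
            continue
        for p, cp in plus.items():
            for i, o in enumerate(overlaps):
                cm = minus.get(p + o - 1)
                if cm:
                    counts[i] += cp * cm
    return OverlapSignature(size_pair=(L1, L2), overlaps=overlaps, counts=counts)


def zscore(signature: OverlapSignature) -> OverlapSignature:
    """Standardise pair counts over the window (population SD).

    A window with zero variance has no signal to standardise; it is marked
    undefined and its z-scores are NaN (rendered blank downstream).
    """
    counts = signature.counts
    mu = counts.mean()
    sigma = counts.std()  # population SD: descriptive statistic on a fixed window
    if sigma == 0:
        signature.z = np.full_like(counts, np.nan)
        signature.defined = False
    else:
        signature.z = (counts - mu) / sigma
        signature.defined = True
    return signature


def overhang_signature(
    signature: OverlapSignature, positive_only: bool = False
) -> OverhangSignature:
    """Transpose a size-matched overlap signature to the overhang axis.

    Requires ``L1 == L2 == L``; the value at overhang ``h`` is the source
    value at overlap ``o = L - h``.  With ``positive_only`` negative
    z-scores are clamped to zero.
    """
    L1, L2 = signature.size_pair
    if L1 != L2 or not isinstance(L1, (int, np.integer)):
        raise ValueError("overhang conversion requires a size-matched integer pair")
    L = int(L1)
    overhangs = L - signature.overlaps
    order = np.argsort(overhangs)
    z = None
    if signature.z is not None:
        z = signature.z[order]
        if positive_only:
            z = np.where(np.isnan(z), z, np.clip(z, 0, None))
    return OverhangSignature(
        size=L,
        overhangs=overhangs[order],
        counts=signature.counts[order],
        z=z,
        defined=signature.defined,
    )


def argmax_overlap(signature: OverlapSignature) -> int | None:
    """Overlap with the highest z-score; ties break toward the smallest overlap."""
    if not signature.defined or signature.z is None:
        return None
    z = signature.z
    best = int(np.nanargmax(z))
    ties = np.flatnonzero(z == z[best])
    if len(ties) > 1:
        logger.debug("argmax tie over overlaps %s; taking smallest", signature.overlaps[ties])
    return int(signature.overlaps[ties[0]])


def signature_matrix(
    alignments: Iterable[AlignedRead],
    sizes: Sequence[int] | None = None,
    o_max: int = O_MAX,
    unique_only: bool = False,
) -> pd.DataFrame:
    """Z-score matrix: rows are overlaps 1..o_max, columns sizes plus "all".

    Per-size columns use size-matched (L, L) pairs; the "all" column pools
    pair counts over every size combination.  Undefined columns are NaN.
    """
    if sizes is None:
        sizes = range(SIZE_RANGE[0], SIZE_RANGE[1] + 1)
    profile = build_profiles(alignments, (min(sizes), max(sizes)), unique_only)
    data = {}
    for L in sizes:
        sig = zscore(overlap_pair_counts(profile, L, L, o_max))
        data[str(L)] = sig.z
    sig_all = zscore(overlap_pair_counts(profile, "all", "all", o_max))
    data["all"] = sig_all.z
    return pd.DataFrame(data, index=pd.Index(np.arange(1, o_max + 1), name="overlap"))


def per_locus_signatures(
    alignments: Sequence[AlignedRead],
    loci: Sequence[Locus],
    sizes: Sequence[int] | None = None,
    o_max: int = O_MAX,
) -> dict[str, dict]:
    """Per-locus signature matrices plus log2 read accumulation per size.

    Each locus gets the signature matrix of the alignments overlapping it
    by >= 1 bp and a per-size log2 copies-weighted read count (NaN for
    empty sizes); a locus with no reads yields an all-NaN matrix.
    """
    if sizes is None:
        sizes = range(SIZE_RANGE[0], SIZE_RANGE[1] + 1)
    results: dict[str, dict] = {}
    for locus in loci:
        in_locus = [
            a
            for a in alignments
            if a.chrom == locus.chrom and a.start < locus.end and a.end > locus.start
        ]
        matrix = signature_matrix(in_locus, sizes, o_max)
        size_counts = pd.Series(0.0, index=pd.Index(list(sizes), name="size"))
        for a in in_locus:
            if a.length in size_counts.index:
                size_counts[a.length] += a.copies
        log2_counts = size_counts.map(lambda c: np.log2(c) if c > 0 else np.nan)
        results[locus.id or f"{locus.chrom}:{locus.start}-{locus.end}"] = {
            "matrix": matrix,
            "log2_size_counts": log2_counts,
        }
    return results


def averaged_overhang(
    alignments: Sequence[AlignedRead],
    loci: Sequence[Locus] | None = None,
    sizes: Sequence[int] | None = None,
    o_max: int = O_MAX,
    h_range: tuple[int, int] = (1, 12),
) -> tuple[np.ndarray, np.ndarray, int]:
    """Average size-matched overhang z-score curves over uniquely mapping reads.

    For each size pair (18/18 ... 28/28) the overlap z-score signature is
    converted to the overhang axis (``h = L - o``) and the curves are
    averaged over the sizes where the signature is defined.  Returns
    ``(overhangs, mean_curve, argmax_overhang)``.
    """
    if sizes is None:
        sizes = range(18, 29)
    unique = [a for a in alignments if a.n_hits == 1]
    if loci is not None:
        unique = [
            a
            for a in unique
            if any(
                a.chrom == l.chrom and a.start < l.end and a.end > l.start for l in loci
            )
        ]
    if not unique:
        raise ValueError("empty input: no uniquely mapping alignments")
    profile = build_profiles(unique, (min(sizes), max(sizes)))
    hs = np.arange(h_range[0], h_range[1] + 1)
    curves = []
    for L in sizes:
        sig = zscore(overlap_pair_counts(profile, L, L, o_max))
        if not sig.defined:
            continue
        oh = overhang_signature(sig)
        by_h = dict(zip(oh.overhangs.tolist(), oh.z))
        curves.append([by_h.get(h, np.nan) for h in hs])
    if not curves:
        raise ValueError("empty input: no size pair has a defined signature")
    mean_curve = np.nanmean(np.array(curves, dtype=float), axis=0)
    best = np.nanargmax(mean_curve)
    ties = np.flatnonzero(mean_curve == mean_curve[best])
    return hs, mean_curve, int(hs[ties[0]])


def plot_signature_matrix(matrix: pd.DataFrame, path: str, title: str = "") -> None:
    """Basic heatmap rendering of a signature matrix (NaN cells blank)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.45 * len(matrix.columns) + 2, 6))
    im = ax.imshow(matrix.values, aspect="auto", cmap="viridis", origin="upper")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns)
    ax.set_yticks(range(0, len(matrix.index), 2), matrix.index[::2])
    ax.set_xlabel("read size")
    ax.set_ylabel("5' overlap (nt)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
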