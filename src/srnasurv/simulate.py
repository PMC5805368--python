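"""Synthetic genomes, small-RNA read populations and methylation call tables.

The generator emulates the structure the downstream analysis assumes:

* a genome carrying dispersed copies of transposable-element (TE) families,
  a dual-strand "master locus" concatenated from TE fragments in mixed
  orientations, and assorted mRNA/structural-RNA loci;
* read populations from three mechanisms — Dicer processing of long dsRNA
  (duplex products with 2-nt 3' overhangs, sizes peaked at 24 nt),
  ping-pong slicing (sense/antisense pairs with exactly 10-nt 5' overlaps
  and a parameterised 1U/10A bias) and single-stranded degradation
  fragments (no opposite-strand structure);
* per-cytosine methylation calls with binomial counts at per-context
  (CG/CHG/CHH) rates under Poisson coverage.

Each emitted read carries a mechanism label, and every read sequence is
the genome subsequence (reverse-complemented on the minus strand) at its
recorded coordinates — bias editing happens on the genome before reads
are extracted, so map-then-verify tests are exact.  All randomness flows
from one :class:`numpy.random.Generator` seeded by ``SimConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from srnasurv.alignments import Locus, SmallRead
from srnasurv.sequtils import revcomp

BASES = "ACGT"

#: Default read-length distribution: unimodal, peaked at 24 nt.
DEFAULT_SIZE_DIST = {22: 0.05, 23: 0.20, 24: 0.50, 25: 0.20, 26: 0.05}

#: Default mechanism mixture: Dicer-dominant with a degradation background
#: and no ping-pong, the configuration of a piRNA-less siRNA-based system.
DEFAULT_MIXTURE = {"dicer": 0.7, "pingpong": 0.0, "degradation": 0.3}

#: Default per-context methylation rates; ~0.5% overall.
DEFAULT_METHYL_RATES = {"CG": 0.005, "CHG": 0.005, "CHH": 0.005}


class CapacityError(ValueError):
    """Planted features do not fit in the requested genome length."""


@dataclass
class SimRead:
    """One simulated read with its mechanism-truth label."""

    sequence: str
    chrom: str
    start: int
    end: int
    strand: str
    mechanism: str  # dicer | pingpong | degradation
    role: str = ""  # guide / responder for ping-pong pairs


@dataclass
class SimConfig:
    """Parameters of a synthetic dataset.

    ``mixture`` fractions must be non-negative and sum to 1, as must
    ``size_dist``; all rates live in [0, 1].
    """

    seed: int = 0
    genome_length: int = 120_000
    te_families: int = 3
    te_copies: int = 4
    te_length: int = 1200
    master_locus_length: int = 4000
    n_mrna: int = 6
    mrna_length: int = 1500
    mixture: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    n_reads: int = 20_000
    size_dist: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_SIZE_DIST))
    guide_5p_bias: float = 0.75
    responder_10A_bias: float = 0.75
    methyl_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_METHYL_RATES))
    coverage_mean: float = 6.0

    def __post_init__(self) -> None:
        mix = self.mixture
        if any(v < 0 for v in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("mixture fractions must be non-negative and sum to 1")
        if any(v < 0 for v in self.size_dist.values()) or abs(
            sum(self.size_dist.values()) - 1.0
        ) > 1e-9:
            raise ValueError("size_dist must be a probability vector")
        if not all(18 <= L <= 30 for L in self.size_dist):
            raise ValueError("read lengths must lie in 18..30")
        for name, rate in [
            ("guide_5p_bias", self.guide_5p_bias),
            ("responder_10A_bias", self.responder_10A_bias),
            *self.methyl_rates.items(),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {name} = {rate} outside [0, 1]")


@dataclass
class SimulatedDataset:
    """A synthetic dataset plus its ground truth."""

    config: SimConfig
    genome: dict[str, str]
    annotation: list[Locus]
    te_catalog: dict[str, str]
    reads: list[SimRead]
    methyl_calls: pd.DataFrame

    @property
    def master_locus(self) -> Locus:
        return next(l for l in self.annotation if l.feature_class == "master")

    def truth_table(self) -> pd.DataFrame:
        """Per-read truth labels as a tidy table."""
        return pd.DataFrame(
            {
                "read": [f"sim{i}" for i in range(len(self.reads))],
                "chrom": [r.chrom for r in self.reads],
                "start": [r.start for r in self.reads],
                "end": [r.end for r in self.reads],
                "strand": [r.strand for r in self.reads],
                "mechanism": [r.mechanism for r in self.reads],
                "role": [r.role for r in self.reads],
            }
        )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _draw_length(rng: np.random.Generator, size_dist: dict[int, float]) -> int:
    lengths = sorted(size_dist)
    probs = np.array([size_dist[L] for L in lengths], dtype=float)
    return int(rng.choice(lengths, p=probs / probs.sum()))


def simulate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[Locus], dict[str, str]]:
    """Build a genome with planted TE copies, a master locus and other features.

    The master locus is a concatenation of >= 25-bp fragments drawn from
    every TE family in mixed orientations, so it shares an exact fragment
    with each family by construction; with zero TE families it is random
    sequence.  Features never overlap, separated by intergenic gaps.

    Returns ``(genome, annotation, te_catalog)`` where ``te_catalog`` maps
    family name -> consensus sequence.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chrom = "chr1"

    te_catalog = {
        f"TEfam{i}": _random_seq(rng, config.te_length) for i in range(config.te_families)
    }
    master_seq, master_frag_spans = _build_master_sequence(
        rng, te_catalog, config.master_locus_length
    )

    # (class, id, sequence-or-None, strand); None means background sequence.
    features: list[tuple[str, str, str | None, str]] = []
    for fam, seq in te_catalog.items():
        for c in range(config.te_copies):
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(("TE", f"{fam}_copy{c}", seq if strand == "+" else revcomp(seq), strand))
    features.append(("master", "master_0", master_seq, "."))
    for i in range(config.n_mrna):
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(("mRNA", f"mrna_{i}", None, strand))
    for cls, length, count in [("rRNA", 400, 2), ("tRNA", 80, 2), ("snRNA", 150, 2), ("unknown", 400, 2)]:
        for i in range(count):
            features.append((cls, f"{cls.lower()}_{i}", _random_seq(rng, length), "+"))

    def feat_len(f: tuple[str, str, str | None, str]) -> int:
        cls, _, seq, _ = f
        return len(seq) if seq is not None else config.mrna_length

    min_gap = 60  # leaves intergenic margin so duplex mates never cross a boundary
    total_feat = sum(feat_len(f) for f in features)
    n_gaps = len(features) + 1
    free = config.genome_length - total_feat - n_gaps * min_gap
    if free < 0:
        raise CapacityError(
            f"features need {total_feat + n_gaps * min_gap} bp "
            f"but genome_length is {config.genome_length}"
        )
    order = rng.permutation(len(features))
    extra = rng.multinomial(free, np.full(n_gaps, 1.0 / n_gaps))

    genome_parts: list[str] = []
    annotation: list[Locus] = []
    pos = 0
    for k, idx in enumerate(order):
        gap = min_gap + int(extra[k])
        genome_parts.append(_random_seq(rng, gap))
        pos += gap
        cls, fid, seq, strand = features[idx]
        if seq is None:
            seq = _random_seq(rng, config.mrna_length)
        genome_parts.append(seq)
        annotation.append(
            Locus(chrom=chrom, start=pos, end=pos + len(seq), strand=strand,
                  feature_class=cls, id=fid)
        )
        pos += len(seq)
    tail = min_gap + int(extra[-1])
    genome_parts.append(_random_seq(rng, tail))
    genome = {chrom: "".join(genome_parts)}
    annotation.sort(key=lambda l: l.start)
    return genome, annotation, te_catalog


def _build_master_sequence(
    rng: np.random.Generator, te_catalog: dict[str, str], length: int
) -> tuple[str, list[tuple[str, int, int]]]:
    """Concatenate TE fragments (mixed orientations) into a master-locus sequence."""
    if not te_catalog:
        return _random_seq(rng, length), []
    parts: list[str] = []
    spans: list[tuple[str, int, int]] = []
    fams = list(te_catalog)
    pos = 0
    i = 0
    while pos < length:
        # cycle families first so each contributes at least one intact fragment
        fam = fams[i % len(fams)] if i < len(fams) else fams[int(rng.integers(len(fams)))]
        src = te_catalog[fam]
        frag_len = int(rng.integers(80, min(251, len(src) + 1)))
        start = int(rng.integers(0, len(src) - frag_len + 1))
        frag = src[start : start + frag_len]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        remaining = length - pos
        if i >= len(fams) and len(frag) > remaining:
            frag = frag[:remaining]  # only filler fragments may be trimmed
        parts.append(frag)
        spans.append((fam, pos, pos + len(frag)))
        pos += len(frag)
        i += 1
    seq = "".join(parts)[:length] if pos <= length else "".join(parts)
    return seq, spans


def simulate_dicer_reads(
    genome: dict[str, str],
    region: Locus,
    n_duplexes: int,
    size_dist: dict[int, float] | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[SimRead]:
    """Emit Dicer duplex products: size-matched read pairs in the 2-nt register.

    Each duplex of length ``L`` at plus-strand 5' position ``p`` yields a
    plus read spanning ``[p, p+L)`` and a minus read spanning
    ``[p-2, p+L-2)``, i.e. a 2-nt 3' overhang on both duplex ends, so the
    pair's 5' overlap is exactly ``L - 2``.
    """
    size_dist = size_dist or DEFAULT_SIZE_DIST
    rng = _resolve_rng(rng, seed)
    max_len = max(size_dist)
    if region.length < max_len + 2:
        raise ValueError("region shorter than max read length + 2")
    seq = genome[region.chrom]
    reads: list[SimRead] = []
    for _ in range(n_duplexes):
        L = _draw_length(rng, size_dist)
        lo, hi = region.start + 2, region.end - L  # p-2 >= start and p+L <= end
        if lo > hi:
            raise ValueError(f"no valid duplex placement for length {L} in {region.id}")
        p = int(rng.integers(lo, hi + 1))
        reads.append(SimRead(seq[p : p + L], region.chrom, p, p + L, "+", "dicer"))
        reads.append(
            SimRead(revcomp(seq[p - 2 : p + L - 2]), region.chrom, p - 2, p + L - 2, "-", "dicer")
        )
    return reads


def simulate_pingpong_reads(
    genome: dict[str, str],
    region: Locus,
    n_pairs: int,
    size_dist: dict[int, float] | None = None,
    guide_5p_bias: float = 0.75,
    responder_10A_bias: float = 0.75,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[SimRead]:
    """Emit ping-pong pairs: guide/responder reads with exactly 10-nt 5' overlaps.

    The guide's 5' base and the responder's position-10 base are the two
    faces of one genomic base pair, so the 1U and 10A biases are planted by
    a single edit: the genome base under the guide 5' end is set, on the
    guide's strand, to T with probability ``(guide_5p_bias +
    responder_10A_bias) / 2`` and uniformly to A/C/G otherwise.  A genomic
    site claimed by one pair keeps its planted base and guide orientation
    for every later pair landing on it, so the planted fractions hold
    exactly even under dense placement.  Edits are applied before any
    sequence is extracted, so reads always match the (returned, possibly
    edited) genome.  ``genome`` is modified in place.
    """
    size_dist = size_dist or DEFAULT_SIZE_DIST
    rng = _resolve_rng(rng, seed)
    max_len = max(size_dist)
    if region.length < max_len + 10:
        raise ValueError("region shorter than max read length + 10")
    p_bias = (guide_5p_bias + responder_10A_bias) / 2.0
    chromseq = list(genome[region.chrom])
    claimed: dict[int, str] = {}  # guide-5' site -> guide strand
    placements: list[tuple[int, int, int, str]] = []  # (guide 5' site, Lg, Lr, strand)

    def site_range(strand: str, Lg: int, Lr: int) -> tuple[int, int]:
        if strand == "+":
            # guide [p, p+Lg) on +; responder [p+10-Lr, p+10) on -, 5' at p+9
            return max(region.start, region.start + Lr - 10), region.end - max(Lg, 10)
        # guide 5' at q on -; guide [q-Lg+1, q+1); responder [q-9, q-9+Lr) on +
        return region.start + max(Lg, 10) - 1, min(region.end - 1, region.end + 9 - Lr)

    for _ in range(n_pairs):
        Lg = _draw_length(rng, size_dist)
        Lr = _draw_length(rng, size_dist)
        for attempt in range(1000):
            strand = "+" if rng.random() < 0.5 else "-"
            lo, hi = site_range(strand, Lg, Lr)
            if lo > hi:
                continue
            site = int(rng.integers(lo, hi + 1))
            if site in claimed and claimed[site] != strand:
                strand = claimed[site]
                lo, hi = site_range(strand, Lg, Lr)
                if not lo <= site <= hi:
                    continue
            break
        else:
            raise ValueError(f"no valid ping-pong placement in {region.id}")
        if site not in claimed:
            base = "T" if rng.random() < p_bias else "ACG"[int(rng.integers(3))]
            chromseq[site] = base if strand == "+" else revcomp(base)
            claimed[site] = strand
        placements.append((site, Lg, Lr, strand))
    genome[region.chrom] = edited = "".join(chromseq)
    reads: list[SimRead] = []
    for p5, Lg, Lr, strand in placements:
        if strand == "+":
            reads.append(SimRead(edited[p5 : p5 + Lg], region.chrom, p5, p5 + Lg, "+",
                                 "pingpong", "guide"))
            r_start = p5 + 10 - Lr
            reads.append(SimRead(revcomp(edited[r_start : p5 + 10]), region.chrom,
                                 r_start, p5 + 10, "-", "pingpong", "responder"))
        else:
            g_start = p5 - Lg + 1
            reads.append(SimRead(revcomp(edited[g_start : p5 + 1]), region.chrom,
                                 g_start, p5 + 1, "-", "pingpong", "guide"))
            r_start = p5 - 9
            reads.append(SimRead(edited[r_start : r_start + Lr], region.chrom,
                                 r_start, r_start + Lr, "+", "pingpong", "responder"))
    return reads


def simulate_degradation_reads(
    genome: dict[str, str],
    transcript_locus: Locus,
    n: int,
    size_dist: dict[int, float] | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[SimRead]:
    """Emit degradation fragments: uniform starts on the transcript's own strand.

    Fragments are truncated at the transcript 3' end, so a minority can fall
    below the nominal size range; there is no opposite-strand structure.
    """
    size_dist = size_dist or DEFAULT_SIZE_DIST
    rng = _resolve_rng(rng, seed)
    if transcript_locus.strand not in "+-":
        raise ValueError("degradation simulation requires a stranded transcript locus")
    seq = genome[transcript_locus.chrom]
    loc = transcript_locus
    reads: list[SimRead] = []
    for _ in range(n):
        L = _draw_length(rng, size_dist)
        if loc.strand == "+":
            start = int(rng.integers(loc.start, loc.end))
            end = min(start + L, loc.end)
            reads.append(SimRead(seq[start:end], loc.chrom, start, end, "+", "degradation"))
        else:
            end = int(rng.integers(loc.start + 1, loc.end + 1))
            start = max(end - L, loc.start)
            reads.append(SimRead(revcomp(seq[start:end]), loc.chrom, start, end, "-", "degradation"))
    return reads


_CONTEXTS = ("CG", "CHG", "CHH")


def simulate_methyl_calls(
    genome: dict[str, str],
    methyl_rates: dict[str, float] | None = None,
    coverage_mean: float = 6.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-cytosine methylation calls with binomial counts at context rates.

    Every genomic C on either strand gets a CG/CHG/CHH context from the
    standard trinucleotide rules (H = A, C or T; boundary cytosines with a
    truncated trinucleotide count as CHH), a Poisson(``coverage_mean``)
    depth and ``n_meth ~ Binomial(depth, rate[context])``.

    Returns a table with columns chrom, pos (0-based), strand, context,
    n_meth, n_unmeth, true_rate.
    """
    methyl_rates = methyl_rates or DEFAULT_METHYL_RATES
    rng = _resolve_rng(rng, seed)
    rows: list[tuple] = []
    for chrom, seq in genome.items():
        for pos, strand in _iter_cytosines(seq):
            ctx = cytosine_context(seq, pos, strand)
            rate = methyl_rates.get(ctx, 0.0)
            depth = int(rng.poisson(coverage_mean))
            n_meth = int(rng.binomial(depth, rate)) if depth else 0
            rows.append((chrom, pos, strand, ctx, n_meth, depth - n_meth, rate))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_unmeth", "true_rate"]
    )


def _iter_cytosines(seq: str):
    for pos, base in enumerate(seq):
        if base == "C":
            yield pos, "+"
        elif base == "G":
            yield pos, "-"


def cytosine_context(seq: str, pos: int, strand: str) -> str:
    """CG/CHG/CHH context of the cytosine at ``pos`` on ``strand``."""
    if strand == "+":
        nxt = seq[pos + 1] if pos + 1 < len(seq) else ""
        nxt2 = seq[pos + 2] if pos + 2 < len(seq) else ""
    else:
        nxt = revcomp(seq[pos - 1]) if pos - 1 >= 0 else ""
        nxt2 = revcomp(seq[pos - 2]) if pos - 2 >= 0 else ""
    if nxt == "G":
        return "CG"
    if nxt and nxt != "G" and nxt2 == "G":
        return "CHG"
    return "CHH"


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a full dataset: genome, annotation, reads, methylation calls.

    Dicer-mode reads are placed on the master locus (its dual-strand
    source), ping-pong reads on TE copies, and degradation fragments on
    mRNA loci, in the proportions of ``config.mixture``.  Deterministic
    under a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genome, annotation, te_catalog = simulate_genome(config, rng)

    n_dicer_pairs = int(round(config.mixture.get("dicer", 0.0) * config.n_reads / 2))
    n_pp_pairs = int(round(config.mixture.get("pingpong", 0.0) * config.n_reads / 2))
    if config.mixture.get("degradation", 0.0) > 0:
        n_deg = max(0, config.n_reads - 2 * n_dicer_pairs - 2 * n_pp_pairs)
    else:
        n_deg = 0

    reads: list[SimRead] = []
    master = next(l for l in annotation if l.feature_class == "master")
    if n_dicer_pairs:
        reads += simulate_dicer_reads(genome, master, n_dicer_pairs, config.size_dist, rng)
    te_loci = [l for l in annotation if l.feature_class == "TE"]
    if n_pp_pairs:
        if not te_loci:
            raise CapacityError("ping-pong fraction > 0 requires TE loci")
        per = _split(n_pp_pairs, len(te_loci), rng)
        for loc, k in zip(te_loci, per):
            if k:
                reads += simulate_pingpong_reads(
                    genome, loc, k, config.size_dist,
                    config.guide_5p_bias, config.responder_10A_bias, rng,
                )
    mrna_loci = [l for l in annotation if l.feature_class == "mRNA"]
    if n_deg:
        if not mrna_loci:
            raise CapacityError("degradation fraction > 0 requires mRNA loci")
        per = _split(n_deg, len(mrna_loci), rng)
        for loc, k in zip(mrna_loci, per):
            if k:
                reads += simulate_degradation_reads(genome, loc, k, config.size_dist, rng)

    methyl = simulate_methyl_calls(genome, config.methyl_rates, config.coverage_mean, rng)
    return SimulatedDataset(config, genome, annotation, te_catalog, reads, methyl)


def _split(total: int, k: int, rng: np.random.Generator) -> np.ndarray:
    return rng.multinomial(total, np.full(k, 1.0 / k))


def collapse_reads(
    reads: Sequence[SimRead], size_range: tuple[int, int] = (18, 30)
) -> list[SmallRead]:
    """Collapse identical sequences into ``readN_xCOUNT`` records.

    Mimics small-RNA library construction: fragments outside ``size_range``
    (e.g. degradation fragments truncated below 18 nt) are size-selected
    away before collapsing.
    """
    lo, hi = size_range
    counts: dict[str, int] = {}
    for r in reads:
        if not lo <= len(r.sequence) <= hi:
            continue
        counts[r.sequence] = counts.get(r.sequence, 0) + 1
    return [
        SmallRead(id=f"read{i}_x{c}", sequence=seq, copies=c)
        for i, (seq, c) in enumerate(sorted(counts.items()))
    ]


def _resolve_rng(rng: np.random.Generator | None, seed: int | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(0 if seed is None else seed)
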