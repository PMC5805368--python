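# Methods

## The overlap-signature statistic

The central quantity is a pair count over 5′-end distances.  Reads are
first collapsed to unique sequences with copy counts; every exact genomic
occurrence of every read is an alignment, and each alignment contributes
its read's full copy count (a 1/n_hits fractional weighting is available
but off by default, since the analysis is designed around capturing all
mapping events of repeat-derived reads).  Per (chromosome, strand, read
length) we tabulate copies-weighted 5′-end counts, recording minus-strand
5′ ends at the right edge (`end - 1` in 0-based half-open coordinates).
For lengths L₁, L₂ (or pooled over all lengths) the pair count at overlap
o ∈ [1, 30] is

    Z(o) = Σ_chrom Σ_p  c⁺_{L1}(p) · c⁻_{L2}(p + o − 1)

Two reads pair by 5′ distance alone; they need not physically overlap.
An option to require physical overlap exists but is off by default — at
the overlaps of interest (10 and L−2, both shorter than any read) the two
definitions coincide.

Z is standardised over the window: z(o) = (Z(o) − μ)/σ with μ, σ the mean
and **population** SD of the 30 window values.  Population rather than
sample SD because this is a descriptive standardisation of a fixed,
complete window, not an inference from a sample.  A window whose counts
are constant (typically all zero) carries no signal; it is flagged
undefined and rendered blank rather than zero.  Argmax ties break toward
the smallest overlap and are logged.

Interpretation: ping-pong slicing places sense/antisense 5′ ends exactly
10 apart, so z peaks at o = 10 regardless of read length.  Dicer duplexes
of length L with 2-nt 3′ overhangs place them L − 2 apart, so size-matched
pairs peak at o = L − 2.  For size-matched pairs the signature converts to
the overhang axis by h = L − o; the summary curve averages the z-curves of
the 18/18 … 28/28 pairs (sizes with undefined signatures are skipped) over
h ∈ [1, 12] and reports the argmax, restricted to uniquely mapping reads
so that one multi-mapped duplex cannot dominate.

The "all" column of a signature matrix pools pair **counts** over every
(L₁, L₂) combination and z-scores the pooled window once.  The plausible
alternative — averaging per-size z-scores — weights rare sizes equally
with abundant ones; pooling was chosen so that the combined column
reflects the library's actual pair mass.

## Mapping, capping, segmentation, locus discovery

The mapper reports every exact occurrence of a read on either strand
(reverse complement on minus); `n_hits` is the total occurrence count.
Mismatches, indels and quality values are deliberately out of scope: at
the scale this package targets, exactness keeps every downstream count
reproducible and testable against brute-force enumeration.  A read whose
sequence is its own reverse complement would be reported once per strand;
with odd-biased small-RNA lengths this is essentially unobservable.

The multimap cap keeps a read only if it maps **fewer than** `max_hits`
(default 100) times: a read with exactly 100 mapping events is discarded.
The discarded fraction is reported copies-weighted over mapped reads.

Feature assignment labels an alignment by any ≥ 1-bp overlap with the
annotation, with precedence rRNA > tRNA > snRNA > miRNA > mRNA > TE >
master > unknown when annotations overlap: abundant structural-RNA
classes dominate contamination, so they win.  Equal-precedence ties break
toward the smaller locus start and are logged.  Per-class cleaning drops
any read with even one mapping event in a different annotated class
(intergenic events are tolerated), so multi-mapping cannot leak reads
between class-restricted analyses.

Expressed-locus discovery merges read footprints lying entirely outside
the annotation when gaps are ≤ `merge_gap` (50 bp; the merge radius also
bounds the coordinate error of a recovered locus) and keeps islands with
copies-weighted read count **strictly greater than** 1000 and span
strictly greater than 200 bp.  "Read density" is interpreted as a count,
not a per-kb rate; a rate interpretation is exposed through the
`min_reads`/`min_len` parameters if wanted.

## Master loci and accountability

A master locus is called from the expressed-locus candidates by two
criteria: copies-weighted strand bias ≤ 0.3 (the dual-strand criterion —
the cutoff is a package default chosen to sit far above the binomial
noise of a true dsRNA source at the read depths involved, and far below
the ≈ 1 bias of single-stranded sources), and at least one exact maximal
match ≥ 25 bp with a TE family in either orientation.  Homology is
operationalised as **exact** matching — full-length read membership for
accountability, ≥ 25-bp maximal exact segments for locus annotation —
rather than alignment-tool similarity: exactness makes every reported
number deterministic and oracle-checkable, at the price of undercounting
divergent homology.  Accountability is therefore a conservative measure
on real, mutation-bearing data; on the simulator, where master-locus
reads are genome-exact, it is exactly 1 by construction.  Called loci
carry four per-base density tracks (all-mapping and unique-mapping, per
strand).

## Methylation accounting

Call tables carry one row per genomic cytosine on either strand with
methylated/unmethylated counts and a CG/CHG/CHH context (H ∈ {A, C, T};
a cytosine whose trinucleotide is truncated by a sequence end counts as
CHH).  Sites must be covered by **strictly more than** `min_reads`
(default 4) reads.  Rates are pooled, Bismark-style:
100 · Σ n_meth / Σ coverage per context × feature class, not a mean of
per-site rates — pooling weights each sequenced base equally and is
robust to low-coverage sites.  Denominators (covered-site counts) are
emitted alongside the rates.

## Assembly decontamination

The contamination filter consumes a tabular foreign-hit report (BLAST
outfmt-6-like query coordinates or BED) rather than running a homology
search, keeping the result independent of search-database versions.  The
matched fraction is the length of the **union** of hit intervals over the
contig length (summed-HSP mode available as an option; union avoids
fractions above 1), and a contig is discarded only when the fraction is
strictly above the threshold (default 10 %) — exactly 10 % is kept.  N50
is the largest contig length at which the descending cumulative sum
reaches half the assembly.

## What the simulator emulates — and what it does not

The generator plants, on one chromosome: dispersed exact copies of random
TE-family consensus sequences (random orientation), a master locus
concatenated from 80–250-bp TE fragments in mixed orientations (every
family contributes at least one intact fragment, so the locus shares an
exact ≥ 25-bp segment with each family by construction), stranded mRNA
loci, and small rRNA/tRNA/snRNA/unknown features, all separated by
intergenic gaps of at least 60 bp.  Reads come from three mechanisms:

* **Dicer**: a duplex of length L at plus-strand 5′ position p yields a
  plus read [p, p+L) and a minus read [p−2, p+L−2) — 2-nt 3′ overhangs on
  both ends, both mates sharing one L.  Placed on the master locus.
* **Ping-pong**: guide and responder on opposite strands with 5′ ends
  exactly 10 apart, lengths drawn independently.  Placed on TE copies.
  The guide-position-1 and responder-position-10 bases are the two faces
  of a single genomic base pair, so the 1U and 10A biases cannot be
  planted independently: one draw per pair sets that base, on the guide
  strand, to T with probability (guide_5p_bias + responder_10A_bias)/2
  and uniformly to A/C/G otherwise.  Keep the two parameters equal (the
  default) for them to mean what their names say.  A site claimed by one
  pair keeps its base and guide orientation for later pairs landing on
  it, so planted fractions hold exactly even under dense placement; all
  edits happen before any read sequence is extracted, so every read
  remains an exact genome substring.
* **Degradation**: uniform starts along a stranded transcript, on the
  transcript strand only, truncated at the 3′ end.  Placed on mRNA loci.

Library construction (`collapse_reads`) applies the standard 18–30-nt
size selection before collapsing; this is where sub-18-nt truncated
degradation fragments — which would otherwise map promiscuously — are
removed, as in a real protocol.

Methylation calls give every genomic cytosine a Poisson(coverage_mean)
depth and Binomial(depth, context rate) methylated counts.

Defaults are the conditions of a piRNA-less, siRNA-based system: mixture
70 % Dicer / 0 % ping-pong / 30 % degradation; sizes {22: 0.05, 23: 0.20,
24: 0.50, 25: 0.20, 26: 0.05} (unimodal, peaked at 24 nt); per-context
methylation rates 0.005 (≈ 0.5 % overall) at 6× mean coverage.  The
ping-pong bias defaults to 0.75, a typical arthropod guide-1U prevalence,
and matters only when the ping-pong fraction is raised above zero for
comparative runs.  All randomness flows from a single seeded generator in
documented order, and identical configurations produce byte-identical
FASTA/BED/TSV outputs.

Deliberately **not** simulated: sequencing error, adapter contamination,
quality variation (FASTQ qualities are constant), Zucchini-phased piRNA
biogenesis, miRNA hairpins, TE-copy sequence divergence, and
base-resolution bisulfite artefacts.  Passing recovery tests on this
simulator therefore demonstrates that the statistics detect the
geometries they claim to detect under clean conditions; it does not
demonstrate robustness to alignment ambiguity from diverged repeats or to
sequencing noise, which real libraries have.

## Numerical and scale choices

Coordinates are 0-based half-open everywhere in memory and in BED; SAM
output adds 1.  Coverage metagenes use 100 bins (mean per bin; shorter
loci are interpolated, logged) oriented 5′→3′ by locus strand, and the
3′-enrichment score mean(last decile)/mean(first decile) is capped at
1e6 when the first decile is empty.  Sequence-logo information content is
2 + Σ f·log₂f bits without small-sample correction (descriptive, large
n).  Strand bias is computed on read counts by default, with a
coverage-weighted variant behind a flag.  Test and acceptance runs use
genomes of 40–120 kb and 1000–8000 reads, sizes at which the exact mapper
and brute-force oracles agree in seconds while every recovery statistic
is far beyond its detection threshold.

## Known limitations

Exact-match homology undercounts diverged TE relicts; the multimap cap
interacts with TE copy number in small simulated genomes (few copies →
few hits per read); expressed-locus discovery has no local background
model, so a uniform high-coverage background would merge islands; and the
per-class methylation table assigns a cytosine to one class by the same
precedence rule as reads, which can differ from per-feature averaging
when annotations overlap.
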