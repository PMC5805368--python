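"""Per-context cytosine methylation rates over feature classes.

Call tables carry one row per cytosine (both strands) with methylated and
unmethylated read counts and a CG/CHG/CHH context.  Sites are first
filtered to a minimum coverage — strictly more than ``min_reads`` reads —
and rates are then pooled per context and per annotated feature class:
``rate = 100 * sum(n_meth) / sum(coverage)`` (a Bismark-style pooled rate,
not a mean of per-site rates).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from srnasurv.alignments import Locus
from srnasurv.sequtils import revcomp
from srnasurv.simulate import cytosine_context

CONTEXTS = ("CG", "CHG", "CHH")

REQUIRED_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]


def load_calls(path: str, fmt: str = "tsv") -> pd.DataFrame:
    """Load a per-cytosine call table.

    ``fmt="tsv"`` expects the native column order (chrom, pos 0-based,
    strand, context, n_meth, n_unmeth); ``fmt="cytosine_report"`` accepts
    the Bismark cytosine-report order (chrom, pos 1-based, strand, n_meth,
    n_unmeth, context, trinucleotide) and converts positions to 0-based.
    """
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"call table missing columns: {missing}")
        return df[REQUIRED_COLUMNS + [c for c in df.columns if c not in REQUIRED_COLUMNS]]
    if fmt == "cytosine_report":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "tri"],
        )
        df["pos"] = df["pos"] - 1
        return df[REQUIRED_COLUMNS]
    raise ValueError(f"unknown call-table format {fmt!r}")


def coverage(calls: pd.DataFrame) -> pd.Series:
    return calls["n_meth"] + calls["n_unmeth"]


def filter_coverage(calls: pd.DataFrame, min_reads: int = 4) -> pd.DataFrame:
    """Keep sites covered by strictly more than ``min_reads`` reads."""
    return calls[coverage(calls) > min_reads].reset_index(drop=True)


def _class_labels(calls: pd.DataFrame, annotation: Sequence[Locus]) -> pd.Series:
    trees: dict[str, IntervalTree] = {}
    for loc in annotation:
        trees.setdefault(loc.chrom, IntervalTree()).addi(loc.start, loc.end, loc.feature_class)
    labels = []
    for chrom, pos in zip(calls["chrom"], calls["pos"]):
        tree = trees.get(chrom)
        hits = tree[pos] if tree is not None else None
        labels.append(sorted(iv.data for iv in hits)[0] if hits else "intergenic")
    return pd.Series(labels, index=calls.index)


def context_rates(
    calls: pd.DataFrame, annotation: Sequence[Locus] | None = None
) -> pd.DataFrame:
    """Pooled methylation percentage per context and feature class.

    Rows are feature classes (always including ``genome`` = all sites, and
    ``all_contexts`` columns pooled over contexts); values are
    ``100 * sum(n_meth) / sum(coverage)``, NaN where a class/context has no
    covered site.  Extra columns ``n_sites_<ctx>`` report the covered
    cytosine counts behind each rate.
    """
    calls = calls.copy()
    calls["coverage"] = coverage(calls)

    def _rates(group: pd.DataFrame) -> dict:
        row: dict[str, float] = {}
        for ctx in CONTEXTS:
            sub = group[group["context"] == ctx]
            cov = sub["coverage"].sum()
            row[ctx] = 100.0 * sub["n_meth"].sum() / cov if cov else np.nan
            row[f"n_sites_{ctx}"] = len(sub)
        cov_all = group["coverage"].sum()
        row["all_contexts"] = 100.0 * group["n_meth"].sum() / cov_all if cov_all else np.nan
        return row

    rows = {"genome": _rates(calls)}
    if annotation is not None:
        labels = _class_labels(calls, annotation)
        for cls, group in calls.groupby(labels):
            rows[str(cls)] = _rates(group)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "feature_class"
    return out


def context_annotate(
    genome: dict[str, str], positions: Sequence[tuple[str, int, str]]
) -> list[str]:
    """Contexts for (chrom, pos, strand) triples; every position must be a C.

    Raises a ``ValueError`` listing all offending records when a position
    does not carry a cytosine on the requested strand.
    """
    contexts = []
    offenders = []
    for chrom, pos, strand in positions:
        seq = genome[chrom]
        base = seq[pos] if strand == "+" else revcomp(seq[pos])
        if base != "C":
            offenders.append((chrom, pos, strand, base))
            continue
        contexts.append(cytosine_context(seq, pos, strand))
    if offenders:
        raise ValueError(f"positions are not cytosines on the given strand: {offenders}")
    return contexts
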