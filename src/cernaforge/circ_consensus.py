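"""Consensus circRNA identification from two back-spliced junction callers.

A circRNA enters the consensus set when both callers report a junction at
matching coordinates (within a configurable tolerance, default exact). The
per-sample consensus read count is the maximum of the two callers' counts —
a monotone, caller-symmetric combination rule.
Support filtering keeps junctions with at least ``min_reads`` back-spliced
reads in strictly more than half of the samples. Annotation classifies each
consensus circRNA against gene models with the precedence
protein_coding > sense_intronic > lncRNA > intergenic.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import BSJCall, GeneModel

ANNOTATION_CLASSES = ("protein_coding", "sense_intronic", "lncRNA", "intergenic")


@dataclass
class ConsensusConfig:
    min_reads: int = 2
    junction_match_tolerance: int = 0

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.junction_match_tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass
class CircRecord:
    """A consensus circRNA with its per-sample junction-read vector."""

    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sample_ids: list[str]
    counts: np.ndarray
    annotation_class: str | None = None
    host_gene_id: str | None = None
    exon_count: int | None = None
    spliced_length: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("read counts must be >= 0")
        if len(self.counts) != len(self.sample_ids):
            raise ValueError("counts length must match sample_ids")


def _strands_compatible(a: str, b: str) -> bool:
    return a == b or a == "." or b == "."


def _index_calls(calls: Iterable[BSJCall]):
    """(chrom -> junction list) and (junction -> sample -> reads) maps."""
    per_junction: dict[tuple, dict[str, int]] = defaultdict(dict)
    strands: dict[tuple, str] = {}
    samples: set[str] = set()
    for c in calls:
        key = (c.chrom, c.start, c.end)
        prev = per_junction[key].get(c.sample_id, 0)
        per_junction[key][c.sample_id] = max(prev, c.junction_reads)
        # a stranded observation wins over an unstranded one
        if key not in strands or strands[key] == ".":
            strands[key] = c.strand
        samples.add(c.sample_id)
    return per_junction, strands, samples


def intersect_callers(
    calls_a: Iterable[BSJCall],
    calls_b: Iterable[BSJCall],
    tolerance: int = 0,
    mode: str = "per_sample",
) -> list[CircRecord]:
    """Consensus junctions reported by both callers.

    ``mode="per_sample"`` (default) requires at least one sample in which
    both callers observe the junction; ``mode="pooled"`` only requires both
    callers to report it in some (possibly different) sample. Matched
    junctions take caller A's coordinates; per-sample counts are the
    element-wise maximum of the two callers.
    """
    if mode not in ("per_sample", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    junc_a, strand_a, samples_a = _index_calls(calls_a)
    junc_b, strand_b, samples_b = _index_calls(calls_b)
    sample_ids = sorted(samples_a | samples_b)

    by_chrom_b: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for chrom, start, end in junc_b:
        by_chrom_b[chrom].append((start, end))
    for lst in by_chrom_b.values():
        lst.sort()

    records: list[CircRecord] = []
    for key_a in sorted(junc_a):
        chrom, start, end = key_a
        candidates = by_chrom_b.get(chrom, [])
        if tolerance == 0:
            matches = [(start, end)] if (start, end) in set(candidates) else []
        else:
            lo = bisect_left(candidates, (start - tolerance, -1))
            matches = []
            for s, e in candidates[lo:]:
                if s > start + tolerance:
                    break
                if abs(e - end) <= tolerance:
                    matches.append((s, e))
        matched = None
        for s, e in matches:
            key_b = (chrom, s, e)
            if not _strands_compatible(strand_a[key_a], strand_b[key_b]):
                continue
            counts_a = junc_a[key_a]
            counts_b = junc_b[key_b]
            if mode == "per_sample":
                shared = {
                    smp for smp in set(counts_a) & set(counts_b)
                    if counts_a[smp] > 0 and counts_b[smp] > 0
                }
                if not shared:
                    continue
            matched = key_b
            break
        if matched is None:
            continue
        counts_a = junc_a[key_a]
        counts_b = junc_b[matched]
        counts = np.array(
            [max(counts_a.get(s, 0), counts_b.get(s, 0)) for s in sample_ids], dtype=int
        )
        strand = strand_a[key_a] if strand_a[key_a] != "." else strand_b[matched]
        records.append(
            CircRecord(
                circ_id=f"{chrom}_{start}_{end}",
                chrom=chrom, start=start, end=end, strand=strand,
                sample_ids=sample_ids, counts=counts,
            )
        )
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def filter_by_support(
    circs: Iterable[CircRecord], config: ConsensusConfig, n_samples: int
) -> list[CircRecord]:
    """Keep circRNAs with >= min_reads in strictly more than half of samples."""
    kept = []
    for c in circs:
        if len(c.counts) != n_samples:
            raise ValueError(f"{c.circ_id}: count vector length != n_samples")
        if int((c.counts >= config.min_reads).sum()) > n_samples / 2:
            kept.append(c)
    return kept


def _covering_exons(circ: CircRecord, model: GeneModel) -> list[tuple[int, int]]:
    return [(s, e) for s, e in model.exons if s < circ.end and e > circ.start]


def annotate_circ(circ: CircRecord, genes: Sequence[GeneModel]) -> CircRecord:
    """Assign an annotation class by intersection with gene models.

    Precedence: protein_coding (both junction endpoints fall on exons of one
    coding transcript) > sense_intronic (contained in an intron of a
    same-strand transcript) > lncRNA (overlaps an lncRNA transcript) >
    intergenic. exon_count / spliced_length come from the host transcript's
    exons between the junction endpoints (clipped to the junction).
    """
    same_chrom = [g for g in genes if g.chrom == circ.chrom]

    for g in same_chrom:
        if g.gene_type != "protein_coding":
            continue
        if not _strands_compatible(circ.strand, g.strand):
            continue
        start_on_exon = any(s <= circ.start < e for s, e in g.exons)
        end_on_exon = any(s < circ.end <= e for s, e in g.exons)
        if start_on_exon and end_on_exon:
            inside = _covering_exons(circ, g)
            circ.annotation_class = "protein_coding"
            circ.host_gene_id = g.gene_id
            circ.exon_count = len(inside)
            circ.spliced_length = sum(min(e, circ.end) - max(s, circ.start) for s, e in inside)
            return circ

    for g in same_chrom:
        if not _strands_compatible(circ.strand, g.strand):
            continue
        for istart, iend in g.introns:
            if istart <= circ.start and circ.end <= iend:
                circ.annotation_class = "sense_intronic"
                circ.host_gene_id = g.gene_id
                return circ

    for g in same_chrom:
        if g.gene_type == "lncRNA" and g.exons:
            gstart, gend = g.exons[0][0], g.exons[-1][1]
            if gstart < circ.end and gend > circ.start:
                circ.annotation_class = "lncRNA"
                circ.host_gene_id = g.gene_id
                return circ

    circ.annotation_class = "intergenic"
    return circ


def annotate_all(circs: Iterable[CircRecord], genes: Sequence[GeneModel]) -> list[CircRecord]:
    return [annotate_circ(c, genes) for c in circs]


# histogram bin edges (bp) for spliced-length summaries
LENGTH_BIN_EDGES = list(range(0, 2001, 200)) + [float("inf")]


def characterize(circs: Sequence[CircRecord]) -> dict[str, pd.Series]:
    """Isoforms-per-gene, spliced-length and exon-count histograms.

    Length bins are 200-bp wide up to 2000 bp with a final open bin;
    exon-count and isoforms-per-gene use unit bins 1..10 plus ">10".
    """
    def unit_bins(values: list[int]) -> pd.Series:
        labels = [str(i) for i in range(1, 11)] + [">10"]
        counts = {lab: 0 for lab in labels}
        for v in values:
            counts[str(v) if v <= 10 else ">10"] += 1
        return pd.Series(counts)

    per_gene: dict[str, int] = defaultdict(int)
    lengths, exon_counts = [], []
    for c in circs:
        if c.host_gene_id is not None:
            per_gene[c.host_gene_id] += 1
        if c.spliced_length is not None:
            lengths.append(c.spliced_length)
        if c.exon_count is not None:
            exon_counts.append(c.exon_count)

    length_labels = [
        f"{int(LENGTH_BIN_EDGES[i])}-{int(LENGTH_BIN_EDGES[i + 1])}"
        for i in range(len(LENGTH_BIN_EDGES) - 2)
    ] + ["2000+"]
    length_counts = {lab: 0 for lab in length_labels}
    for length in lengths:
        idx = min(length // 200, len(length_labels) - 1)
        length_counts[length_labels[idx]] += 1

    if not circs:
        return {
            "isoforms_per_gene": pd.Series(dtype=int),
            "spliced_length": pd.Series(dtype=int),
            "exon_count": pd.Series(dtype=int),
        }
    return {
        "isoforms_per_gene": unit_bins(list(per_gene.values())),
        "spliced_length": pd.Series(length_counts),
        "exon_count": unit_bins(exon_counts),
    }


def counts_frame(circs: Sequence[CircRecord]) -> pd.DataFrame:
    """Stack consensus records into a features x samples count matrix."""
    if not circs:
        return pd.DataFrame()
    return pd.DataFrame(
        np.vstack([c.counts for c in circs]),
        index=[c.circ_id for c in circs],
        columns=circs[0].sample_ids,
    )


def per_sample_report(
    calls_a: Iterable[BSJCall], calls_b: Iterable[BSJCall]
) -> pd.DataFrame:
    """Per-sample caller comparison: junctions per caller and their overlap."""
    junc_a, _, samples_a = _index_calls(calls_a)
    junc_b, _, samples_b = _index_calls(calls_b)
    rows = []
    for smp in sorted(samples_a | samples_b):
        set_a = {k for k, v in junc_a.items() if v.get(smp, 0) > 0}
        set_b = {k for k, v in junc_b.items() if v.get(smp, 0) > 0}
        rows.append((smp, len(set_a), len(set_b), len(set_a & set_b)))
    return pd.DataFrame(rows, columns=["sample_id", "find_circ", "circexplorer2", "overlap"])
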