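"""Readers and writers for every external representation the pipeline touches.

Tabular formats are tab-separated with a header row (except the caller BED
tables, which are headerless by convention of the tools that emit them).
Internal genomic coordinates are 0-based half-open (BED convention); the
``chr_start_end`` display identifier reproduces the raw coordinates of the
input files verbatim, since those identifiers are opaque labels.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_STRANDS = {"+", "-", "."}
VALID_STATUSES = {"Up", "Down"}

# Documented column-layout assumptions for the two supported callers:
#   find_circ       BED6-like; junction reads in the score column (5th).
#   circexplorer2   BED12+; junction reads in the 13th column (readNumber).
_DIALECTS = {"find_circ": 4, "circexplorer2": 12}


@dataclass(frozen=True)
class BSJCall:
    """One back-spliced junction observation from one caller in one sample."""

    chrom: str
    start: int
    end: int
    strand: str
    junction_reads: int
    caller: str
    sample_id: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"start must be < end ({self.chrom}:{self.start}-{self.end})")
        if self.junction_reads < 0:
            raise ValueError("junction_reads must be >= 0")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def circ_id(self) -> str:
        return f"{self.chrom}_{self.start}_{self.end}"


@dataclass(frozen=True)
class PairTableRow:
    """One printed miRNA-circRNA pair: statuses, duplex energy and position."""

    mirna_id: str
    mirna_status: str
    circ_id: str
    circ_status: str
    total_energy: float
    position: int

    def __post_init__(self) -> None:
        for status in (self.mirna_status, self.circ_status):
            if status not in VALID_STATUSES:
                raise ValueError(f"unknown status label {status!r}")
        if not pd.notna(self.total_energy) or self.total_energy in (float("inf"), float("-inf")):
            raise ValueError("total_energy must be finite")


@dataclass
class GeneModel:
    """One transcript of a gene: sorted, non-overlapping exon intervals."""

    gene_id: str
    gene_type: str  # protein_coding | lncRNA | other
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if not 0 <= s < e:
                raise ValueError(f"invalid exon interval ({s}, {e}) in {self.transcript_id}")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
            prev_end = e

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]


# ---------------------------------------------------------------------------
# caller tables
# ---------------------------------------------------------------------------

def read_bsj_calls(path: str | Path, dialect: str, sample_id: str | None = None) -> list[BSJCall]:
    """Parse one caller output table into normalized :class:`BSJCall` records.

    ``sample_id`` defaults to the file stem. Coordinates are taken as
    0-based half-open in both dialects (both callers emit BED intervals).
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    reads_col = _DIALECTS[dialect]
    calls: list[BSJCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) <= reads_col:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {reads_col + 1} columns for "
                    f"dialect {dialect!r}, got {len(fields)}"
                )
            try:
                call = BSJCall(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=fields[5] if len(fields) > 5 else ".",
                    junction_reads=int(round(float(fields[reads_col]))),
                    caller=dialect,
                    sample_id=sample_id,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
            calls.append(call)
    return calls


def write_bsj_calls(calls: Iterable[BSJCall], path: str | Path, dialect: str) -> None:
    """Write calls in the column layout of ``dialect`` (inverse of reading)."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for c in calls:
            if dialect == "find_circ":
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.circ_id}\t{c.junction_reads}\t{c.strand}\n")
            else:  # circexplorer2: BED12+ with readNumber in column 13
                fh.write(
                    f"{c.chrom}\t{c.start}\t{c.end}\tcircular_RNA/{c.circ_id}\t0\t{c.strand}"
                    f"\t{c.start}\t{c.end}\t0,0,0\t1\t{c.end - c.start}\t0"
                    f"\t{c.junction_reads}\tcircRNA\tNA\n"
                )


# ---------------------------------------------------------------------------
# pair table (worked-example fixture format)
# ---------------------------------------------------------------------------

def _parse_energy(raw: str) -> float:
    # accept both hyphen-minus and the typeset Unicode minus
    return float(str(raw).strip().replace("−", "-").replace("–", "-"))


def _normalize_status(raw: str) -> str:
    status = str(raw).strip().capitalize()
    if status not in VALID_STATUSES:
        raise ValueError(f"unknown status label {raw!r}")
    return status


def read_pair_table(path: str | Path) -> list[PairTableRow]:
    """Read a six-column miRNA-circRNA pair table (TSV with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["mirna_id", "mirna_status", "circ_id", "circ_status", "total_energy", "position"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(
            PairTableRow(
                mirna_id=rec.mirna_id.strip(),
                mirna_status=_normalize_status(rec.mirna_status),
                circ_id=rec.circ_id.strip(),
                circ_status=_normalize_status(rec.circ_status),
                total_energy=_parse_energy(rec.total_energy),
                position=int(rec.position),
            )
        )
    return rows


def write_pair_table(rows: Iterable[PairTableRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.mirna_id, r.mirna_status, r.circ_id, r.circ_status, r.total_energy, r.position)
            for r in rows
        ],
        columns=["mirna_id", "mirna_status", "circ_id", "circ_status", "total_energy", "position"],
    )
    df.to_csv(path, sep="\t", index=False)


def load_table3() -> list[PairTableRow]:
    """Load the packaged transcription of the worked-example pair table."""
    ref = importlib.resources.files("cernaforge.data") / "table3.tsv"
    with importlib.resources.as_file(ref) as p:
        return read_pair_table(p)


# ---------------------------------------------------------------------------
# matrices, groups, totals
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Features x samples TSV; first column is the feature identifier."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate feature identifiers")
    return df


def write_count_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_groups(path: str | Path) -> pd.Series:
    """Two-column TSV (sample_id, group) -> sample -> group Series."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")


def write_groups(groups: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", index=False
    )


def read_mapped_totals(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    totals = pd.Series(df.iloc[:, 1].astype(float).values, index=df.iloc[:, 0].values,
                       name="mapped_total")
    if (totals <= 0).any():
        raise ValueError(f"{path}: mapped totals must be positive")
    return totals


def write_mapped_totals(totals: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": totals.index, "mapped_total": totals.values}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# gene models (GTF-lite) and gene sets
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """GTF-lite TSV: gene_id, gene_type, transcript_id, chrom, strand, exon_start, exon_end."""
    df = pd.read_csv(path, sep="\t")
    models: dict[str, GeneModel] = {}
    for rec in df.itertuples(index=False):
        tid = rec.transcript_id
        if tid not in models:
            models[tid] = GeneModel(
                gene_id=rec.gene_id,
                gene_type=rec.gene_type,
                transcript_id=tid,
                chrom=rec.chrom,
                strand=rec.strand,
                exons=[],
            )
        models[tid].exons.append((int(rec.exon_start), int(rec.exon_end)))
    out = []
    for m in models.values():
        out.append(
            GeneModel(m.gene_id, m.gene_type, m.transcript_id, m.chrom, m.strand, m.exons)
        )
    return out


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    rows = []
    for m in models:
        for s, e in m.exons:
            rows.append((m.gene_id, m.gene_type, m.transcript_id, m.chrom, m.strand, s, e))
    pd.DataFrame(
        rows,
        columns=["gene_id", "gene_type", "transcript_id", "chrom", "strand",
                 "exon_start", "exon_end"],
    ).to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Term annotation TSV (term_id, term_name, gene_id) -> term -> gene set."""
    df = pd.read_csv(path, sep="\t")
    sets: dict[str, set[str]] = {}
    for rec in df.itertuples(index=False):
        sets.setdefault(rec.term_id, set()).add(rec.gene_id)
    return sets


def write_gene_sets(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [(term, term, g) for term, genes in sets.items() for g in sorted(genes)]
    pd.DataFrame(rows, columns=["term_id", "term_name", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate sequence ID {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# network export / import
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = [
    "source", "source_class", "source_status",
    "target", "target_class", "target_status",
    "layer", "total_energy", "position",
]


def _network_edge_frame(network) -> pd.DataFrame:
    rows = []
    for df, layer, src_class in (
        (network.circ_mi, "circ_mirna", "circRNA"),
        (network.mi_mrna, "mirna_mrna", "miRNA"),
    ):
        for rec in df.itertuples(index=False):
            if layer == "circ_mirna":
                rows.append((rec.partner_id, "circRNA", rec.partner_status,
                             rec.mirna_id, "miRNA", rec.mirna_status,
                             layer, rec.total_energy, rec.position))
            else:
                rows.append((rec.mirna_id, "miRNA", rec.mirna_status,
                             rec.partner_id, rec.partner_class, rec.partner_status,
                             layer, rec.total_energy, rec.position))
    return pd.DataFrame(rows, columns=_EDGE_COLUMNS)


def write_network(network, path: str | Path, format: str = "edge_list_tsv") -> None:
    """Export a ceRNA network as an edge list or GraphML; round-trips exactly."""
    edges = _network_edge_frame(network)
    if format == "edge_list_tsv":
        edges.to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        import networkx as nx

        g = nx.MultiDiGraph()
        for rec in edges.itertuples(index=False):
            g.add_node(rec.source, rna_class=rec.source_class, status=rec.source_status)
            g.add_node(rec.target, rna_class=rec.target_class, status=rec.target_status)
            g.add_edge(rec.source, rec.target, layer=rec.layer,
                       total_energy=float(rec.total_energy), position=int(rec.position))
        nx.write_graphml(g, str(path))
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "edge_list_tsv"):
    """Inverse of :func:`write_network`; returns a :class:`cerna.CeRNANetwork`."""
    from .cerna import network_from_edge_frame

    if format == "edge_list_tsv":
        edges = pd.read_csv(path, sep="\t")
        if edges.empty:
            edges = pd.DataFrame(columns=_EDGE_COLUMNS)
    elif format == "graphml":
        import networkx as nx

        g = nx.read_graphml(str(path))
        rows = []
        for u, v, data in g.edges(data=True):
            rows.append((u, g.nodes[u]["rna_class"], g.nodes[u]["status"],
                         v, g.nodes[v]["rna_class"], g.nodes[v]["status"],
                         data["layer"], float(data["total_energy"]), int(data["position"])))
        edges = pd.DataFrame(rows, columns=_EDGE_COLUMNS)
    else:
        raise ValueError(f"unknown network format {format!r}")
    return network_from_edge_frame(edges)
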