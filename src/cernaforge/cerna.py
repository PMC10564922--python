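"""Assembly of the circRNA-miRNA-mRNA competing-endogenous-RNA network.

circRNAs sponge shared miRNAs, so a retained circRNA-miRNA (and miRNA-mRNA)
edge must join one up-regulated and one down-regulated feature (the
inverse-expression constraint); applying the constraint to both bipartite
layers forces circRNA and mRNA in a triple to share direction. Triples are
all (circRNA, miRNA, mRNA) combinations through a shared miRNA.

Edges are DataFrames with columns mirna_id, mirna_status, partner_id,
partner_status, partner_class, total_energy, position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import PairTableRow
from .target_predict import DuplexHit

EDGE_COLUMNS = [
    "mirna_id", "mirna_status", "partner_id", "partner_status",
    "partner_class", "total_energy", "position",
]


def _empty_edges() -> pd.DataFrame:
    return pd.DataFrame(columns=EDGE_COLUMNS)


@dataclass
class CeRNANetwork:
    """Bipartite edge sets plus the assembled sponge triples."""

    circ_mi: pd.DataFrame = field(default_factory=_empty_edges)
    mi_mrna: pd.DataFrame = field(default_factory=_empty_edges)
    triples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["circ_id", "mirna_id", "mrna_id"])
    )

    def nodes(self) -> pd.DataFrame:
        rows = []
        for rec in self.circ_mi.itertuples(index=False):
            rows.append((rec.partner_id, "circRNA", rec.partner_status))
            rows.append((rec.mirna_id, "miRNA", rec.mirna_status))
        for rec in self.mi_mrna.itertuples(index=False):
            rows.append((rec.mirna_id, "miRNA", rec.mirna_status))
            rows.append((rec.partner_id, rec.partner_class, rec.partner_status))
        return pd.DataFrame(rows, columns=["node_id", "rna_class", "status"]).drop_duplicates()


def attach_status(
    hits: Iterable[DuplexHit],
    mirna_status: Mapping[str, str],
    partner_status: Mapping[str, str],
    partner_class: str = "circRNA",
) -> pd.DataFrame:
    """Join duplex hits to both endpoints' DE statuses; drop NS endpoints.

    Raises if any hit endpoint is absent from the status tables.
    """
    hits = list(hits)
    missing = sorted(
        {h.mirna_id for h in hits if h.mirna_id not in mirna_status}
        | {h.target_id for h in hits if h.target_id not in partner_status}
    )
    if missing:
        raise KeyError(f"features missing from DE tables: {missing}")
    rows = [
        (h.mirna_id, mirna_status[h.mirna_id], h.target_id, partner_status[h.target_id],
         partner_class, h.total_energy, h.position)
        for h in hits
        if mirna_status[h.mirna_id] != "NS" and partner_status[h.target_id] != "NS"
    ]
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def edges_from_pair_table(rows: Iterable[PairTableRow]) -> pd.DataFrame:
    """Status-annotated circRNA-miRNA edges from a printed pair table."""
    return pd.DataFrame(
        [(r.mirna_id, r.mirna_status, r.circ_id, r.circ_status, "circRNA",
          r.total_energy, r.position) for r in rows],
        columns=EDGE_COLUMNS,
    )


def inverse_filter(edges: pd.DataFrame) -> pd.DataFrame:
    """Retain edges joining one Up and one Down feature (idempotent)."""
    if edges.empty:
        return edges.copy()
    keep = edges["mirna_status"] != edges["partner_status"]
    return edges.loc[keep].reset_index(drop=True)


def assemble_triples(circ_mi: pd.DataFrame, mi_mrna: pd.DataFrame) -> CeRNANetwork:
    """All (circRNA, miRNA, mRNA) combinations through shared miRNAs.

    Edges whose miRNA has no partner in the other layer contribute nothing;
    such edges (and their nodes) are excluded from the assembled network.
    """
    shared = set(circ_mi["mirna_id"]) & set(mi_mrna["mirna_id"]) if not (
        circ_mi.empty or mi_mrna.empty
    ) else set()
    circ_part = circ_mi[circ_mi["mirna_id"].isin(shared)].reset_index(drop=True)
    mrna_part = mi_mrna[mi_mrna["mirna_id"].isin(shared)].reset_index(drop=True)
    if shared:
        triples = (
            circ_part[["partner_id", "mirna_id"]]
            .rename(columns={"partner_id": "circ_id"})
            .merge(
                mrna_part[["mirna_id", "partner_id"]].rename(columns={"partner_id": "mrna_id"}),
                on="mirna_id",
            )[["circ_id", "mirna_id", "mrna_id"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )
    else:
        triples = pd.DataFrame(columns=["circ_id", "mirna_id", "mrna_id"])
    return CeRNANetwork(circ_mi=circ_part, mi_mrna=mrna_part, triples=triples)


def network_from_edge_frame(edges: pd.DataFrame) -> CeRNANetwork:
    """Rebuild a network from the exported edge-list representation."""
    circ_rows, mrna_rows = [], []
    for rec in edges.itertuples(index=False):
        if rec.layer == "circ_mirna":
            circ_rows.append((rec.target, rec.target_status, rec.source, rec.source_status,
                              "circRNA", rec.total_energy, rec.position))
        else:
            mrna_rows.append((rec.source, rec.source_status, rec.target, rec.target_status,
                              rec.target_class, rec.total_energy, rec.position))
    circ_mi = pd.DataFrame(circ_rows, columns=EDGE_COLUMNS) if circ_rows else _empty_edges()
    mi_mrna = pd.DataFrame(mrna_rows, columns=EDGE_COLUMNS) if mrna_rows else _empty_edges()
    return assemble_triples(circ_mi, mi_mrna) if circ_rows and mrna_rows else CeRNANetwork(
        circ_mi=circ_mi, mi_mrna=mi_mrna
    )


def _round_half_up(x: float, ndigits: int = 1) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0." + "0" * ndigits), rounding=ROUND_HALF_UP))


def network_summary(edges: pd.DataFrame) -> dict:
    """Edge-set summary: pair/node counts, % opposite-status pairs, degrees.

    ``pct_opposite`` is 100 x (status-discordant pairs)/(pairs), rounded half
    away from zero to one decimal.
    """
    if edges.empty:
        return {
            "n_pairs": 0, "n_distinct_mirna": 0, "n_distinct_circ": 0,
            "n_distinct_mrna": 0, "pct_opposite": float("nan"),
            "n_mirna_up": 0, "n_mirna_down": 0,
            "n_partner_up": 0, "n_partner_down": 0,
            "mirna_degree": {},
        }
    circ_mask = edges["partner_class"] == "circRNA"
    mrna_mask = edges["partner_class"] == "mRNA"
    opposite = (edges["mirna_status"] != edges["partner_status"]).sum()
    mirna_status = edges.drop_duplicates("mirna_id").set_index("mirna_id")["mirna_status"]
    partner_status = edges.drop_duplicates("partner_id").set_index("partner_id")["partner_status"]
    return {
        "n_pairs": int(len(edges)),
        "n_distinct_mirna": int(edges["mirna_id"].nunique()),
        "n_distinct_circ": int(edges.loc[circ_mask, "partner_id"].nunique()),
        "n_distinct_mrna": int(edges.loc[mrna_mask, "partner_id"].nunique()),
        "pct_opposite": _round_half_up(100.0 * opposite / len(edges)),
        "n_mirna_up": int((mirna_status == "Up").sum()),
        "n_mirna_down": int((mirna_status == "Down").sum()),
        "n_partner_up": int((partner_status == "Up").sum()),
        "n_partner_down": int((partner_status == "Down").sum()),
        "mirna_degree": edges.groupby("mirna_id").size().to_dict(),
    }
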