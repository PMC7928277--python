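"""Pairwise co-occurrence mining and the co-prescription network.

*Support* of a pair is the raw count of prescriptions containing both
materials. *Confidence* of the directed rule A -> B is support(A,B)/fc(A);
a confidence of exactly 1 means no prescription contains A without B, and
is decided by integer equality, never floating comparison. The network
connects frequently used materials whose pair support passes an edge
threshold; core materials are ranked by citation count with weighted
degree as tie-break.

Count thresholds are strict (> t) by default, mirroring the "more than
41 / more than 18 times" reading; the RFC node cutoff is inclusive. Both
are exposed as flags. Only pairs are mined; higher-order itemsets are out
of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

from .records import IntegrityError, SurveyCorpus
from .indices import _decimal_fraction, select_frequent

PAIR_COLUMNS = [
    "material_a",
    "material_b",
    "support",
    "fc_a",
    "fc_b",
    "conf_a_to_b",
    "conf_b_to_a",
]
RULE_COLUMNS = ["antecedent", "consequent", "support", "fc_antecedent", "confidence"]


def count_pairs(corpus: SurveyCorpus) -> pd.DataFrame:
    """Exact support and both directional confidences for every unordered
    pair co-occurring at least once.

    Pairs are stored once with ``material_a < material_b``; rows sort by
    descending support, then (material_a, material_b).
    """
    fc: dict[str, int] = {}
    support: dict[tuple[str, str], int] = {}
    for p in corpus.prescriptions:
        members = sorted(p.materials)
        for mid in members:
            fc[mid] = fc.get(mid, 0) + 1
        for a, b in combinations(members, 2):
            support[(a, b)] = support.get((a, b), 0) + 1
    rows = [
        {
            "material_a": a,
            "material_b": b,
            "support": s,
            "fc_a": fc[a],
            "fc_b": fc[b],
            "conf_a_to_b": s / fc[a],
            "conf_b_to_a": s / fc[b],
        }
        for (a, b), s in support.items()
    ]
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["support", "material_a", "material_b"],
            ascending=[False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return df


def high_frequency_pairs(
    stats: pd.DataFrame, threshold: int = 41, strict: bool = True
) -> pd.DataFrame:
    """Pairs whose support exceeds (strict) or reaches (inclusive) the
    threshold, sorted by descending support."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    keep = stats["support"] > threshold if strict else stats["support"] >= threshold
    return stats.loc[keep].reset_index(drop=True)


def association_rules(
    stats: pd.DataFrame, min_support: int = 1, min_confidence: float = 1.0
) -> pd.DataFrame:
    """Directed pair rules passing support and confidence floors.

    Both directions of each qualifying pair are emitted independently.
    Confidence-1 rules are decided by the integer identity
    support == fc(antecedent).
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError(f"min_confidence {min_confidence} outside [0, 1]")
    floor = _decimal_fraction(min_confidence)
    rows = []
    for r in stats.itertuples(index=False):
        if r.support < min_support:
            continue
        for ante, cons, fca in (
            (r.material_a, r.material_b, r.fc_a),
            (r.material_b, r.material_a, r.fc_b),
        ):
            conf = Fraction(int(r.support), int(fca))
            if conf >= floor:
                rows.append(
                    {
                        "antecedent": ante,
                        "consequent": cons,
                        "support": int(r.support),
                        "fc_antecedent": int(fca),
                        "confidence": float(conf),
                    }
                )
    df = pd.DataFrame(rows, columns=RULE_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["confidence", "support", "antecedent", "consequent"],
            ascending=[False, False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return df


@dataclass
class CoPrescriptionNetwork:
    """Thresholded weighted undirected co-prescription graph.

    Nodes carry ``fc`` and ``rfc`` attributes; edge weights are pair
    supports. ``edge_threshold``/``strict`` record how edges were kept.
    """

    graph: nx.Graph
    edge_threshold: int
    strict: bool
    node_cutoff: float | None

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {"material_a": min(a, b), "material_b": max(a, b), "weight": d["weight"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["material_a", "material_b", "weight"])
        if len(df):
            df = df.sort_values(
                ["weight", "material_a", "material_b"],
                ascending=[False, True, True],
                kind="mergesort",
            ).reset_index(drop=True)
        return df


def build_network(
    stats: pd.DataFrame,
    rfc: pd.DataFrame,
    edge_threshold: int = 18,
    node_cutoff: float | None = 0.2,
    strict: bool = True,
) -> CoPrescriptionNetwork:
    """Build the co-prescription network.

    Nodes are materials with RFC >= ``node_cutoff`` (pass ``None`` for the
    unrestricted graph); edges are pairs among nodes whose support passes
    the edge threshold.
    """
    rfc_ids = set(rfc["material_id"])
    pair_ids = set(stats["material_a"]) | set(stats["material_b"])
    orphans = sorted(pair_ids - rfc_ids)
    if orphans:
        raise IntegrityError(
            f"pair statistics reference materials absent from the RFC table: {orphans}"
        )
    node_rows = rfc if node_cutoff is None else select_frequent(rfc, node_cutoff)
    g = nx.Graph()
    for r in node_rows.itertuples(index=False):
        g.add_node(r.material_id, fc=int(r.fc), rfc=float(r.rfc))
    kept = high_frequency_pairs(stats, edge_threshold, strict)
    for r in kept.itertuples(index=False):
        if r.material_a in g and r.material_b in g:
            g.add_edge(r.material_a, r.material_b, weight=int(r.support))
    return CoPrescriptionNetwork(
        graph=g, edge_threshold=edge_threshold, strict=strict, node_cutoff=node_cutoff
    )


def core_ranking(network: CoPrescriptionNetwork, k: int | None = None) -> list[str]:
    """Total core-material ordering: descending fc, then descending
    weighted degree, then material_id.

    The top rank is the primary core material; ranks 2-3 the secondary
    core. ``k`` beyond the node count returns all nodes with a warning.
    """
    g = network.graph
    if k is not None and k < 1:
        raise ValueError("k must be >= 1")
    wdeg = dict(g.degree(weight="weight"))
    order = sorted(
        g.nodes, key=lambda m: (-g.nodes[m]["fc"], -wdeg.get(m, 0), m)
    )
    if k is None:
        return order
    if k > len(order):
        warnings.warn(
            f"k={k} exceeds node count {len(order)}; returning all nodes"
        )
        return order
    return order[:k]


def write_graphml(network: CoPrescriptionNetwork, path: str | Path) -> None:
    g = network.graph.copy()
    ranking = {m: i + 1 for i, m in enumerate(core_ranking(network))}
    nx.set_node_attributes(g, ranking, "core_rank")
    nx.write_graphml(g, path)


def write_edgelist(network: CoPrescriptionNetwork, path: str | Path) -> None:
    network.edges.to_csv(path, sep="\t", index=False, lineterminator="\n")
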