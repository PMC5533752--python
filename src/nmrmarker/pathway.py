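"""Topology-aware pathway enrichment for selected markers.

Over-representation is scored with the hypergeometric upper tail over a
compound universe; topological importance is scored as pathway impact —
the sum of relative betweenness centralities of the pathway compounds hit
by the marker list.  A pathway is called significant when impact >= 0.4
and -log10(p) >= 2.

The bundled demo set contains ten small hand-built pathway graphs
(synthetic fixtures, not curated database topology) whose compounds all
come from the default metabolite library.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

IMPACT_MIN = 0.4
NEG_LOG10_P_MIN = 2.0


@dataclass
class PathwayGraph:
    id: str
    name: str
    graph: nx.Graph

    def __post_init__(self):
        if any(u == v for u, v in self.graph.edges):
            raise ValueError(f"{self.id}: self-loop")

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)


@dataclass
class PathwaySet:
    pathways: list

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self):
        return len(self.pathways)

    @property
    def universe(self) -> set:
        out: set = set()
        for p in self.pathways:
            out |= p.nodes
        return out

    def to_json(self, path) -> None:
        data = [
            {
                "id": p.id,
                "name": p.name,
                "nodes": sorted(p.graph.nodes),
                "edges": sorted([sorted(e) for e in p.graph.edges]),
            }
            for p in self.pathways
        ]
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PathwaySet":
        with open(path) as fh:
            data = json.load(fh)
        pathways = []
        for entry in data:
            g = nx.Graph()
            g.add_nodes_from(entry["nodes"])
            g.add_edges_from(entry["edges"])
            pathways.append(PathwayGraph(entry["id"], entry["name"], g))
        return cls(pathways)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def hypergeometric_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), inclusive."""
    if not (0 <= k <= min(K, n) <= N and K <= N and n <= N):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    from scipy import stats

    return float(stats.hypergeom.sf(k - 1, N, K, n))


def relative_betweenness(pathway: PathwayGraph) -> dict:
    """Betweenness centrality normalized to sum 1 over the pathway; if no
    node lies on any shortest path (no intermediate nodes) the centrality
    is uniform 1/|nodes|."""
    g = pathway.graph
    if len(g) == 0:
        raise ValueError("empty pathway graph")
    bc = nx.betweenness_centrality(g, normalized=False)
    total = sum(bc.values())
    if total <= 0:
        return {v: 1.0 / len(g) for v in g}
    return {v: c / total for v, c in bc.items()}


def pathway_impact(pathway: PathwayGraph, hit_nodes) -> float:
    """Sum of relative betweenness centralities over the hit compounds."""
    hits = set(hit_nodes)
    unknown = hits - pathway.nodes
    if unknown:
        raise ValueError(f"nodes not in pathway {pathway.id!r}: {sorted(unknown)}")
    cent = relative_betweenness(pathway)
    return float(sum(cent[v] for v in hits))


def enrich_pathways(markers, pathway_set: PathwaySet, universe=None) -> pd.DataFrame:
    """Enrichment table: hypergeometric p, impact and the significance
    flag (impact >= 0.4 and -log10 p >= 2) per pathway, plus the
    bubble-plot coordinates (x = impact, y = -log10 p)."""
    universe = set(universe) if universe is not None else pathway_set.universe
    for p in pathway_set:
        missing = p.nodes - universe
        if missing:
            raise ValueError(f"universe missing compounds of {p.id!r}: {sorted(missing)}")
    marker_set = set(markers) & universe
    N, n = len(universe), len(marker_set)
    rows = []
    for p in pathway_set:
        K = len(p.nodes)
        hits = marker_set & p.nodes
        k = len(hits)
        p_hyper = hypergeometric_upper_tail(N, K, n, k)
        neg_log10_p = float(-math.log10(p_hyper)) if p_hyper > 0 else float("inf")
        impact = pathway_impact(p, hits)
        rows.append(
            {
                "pathway_id": p.id,
                "pathway": p.name,
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "p_hyper": p_hyper,
                "neg_log10_p": neg_log10_p,
                "impact": impact,
                "significant": impact >= IMPACT_MIN and neg_log10_p >= NEG_LOG10_P_MIN,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Demo pathway set
# ---------------------------------------------------------------------------

def build_demo_pathways() -> PathwaySet:
    """Ten small synthetic pathway graphs built from library metabolites.

    Names follow the standard small-molecule pathway nomenclature
    (alanine/aspartate/glutamate metabolism, TCA cycle, ...); edges are a
    hand-drawn sketch of metabolic adjacency, adequate for exercising the
    impact statistic, not curated biochemistry.
    """
    defs = [
        ("p01", "alanine, aspartate and glutamate metabolism",
         [("glutamine", "glutamate"), ("glutamate", "GABA"),
          ("GABA", "succinate"), ("glutamate", "alpha-ketoglutarate"),
          ("alpha-ketoglutarate", "succinate"), ("aspartate", "glutamate"),
          ("aspartate", "N-acetylaspartate"), ("aspartate", "fumarate"),
          ("pyruvate", "alanine"), ("pyruvate", "alpha-ketoglutarate")]),
        ("p02", "arginine and proline metabolism",
         [("glutamate", "glycine"), ("glycine", "creatine"),
          ("creatine", "creatinine")]),
        ("p03", "butanoate metabolism",
         [("acetoacetate", "3-hydroxybutyrate"), ("acetoacetate", "succinate"),
          ("succinate", "GABA")]),
        ("p04", "D-glutamine and D-glutamate metabolism",
         [("glutamine", "glutamate"), ("glutamate", "alpha-ketoglutarate"),
          ("glutamate", "GABA")]),
        ("p05", "glycolysis or gluconeogenesis",
         [("alpha-glucose", "beta-glucose"), ("beta-glucose", "pyruvate"),
          ("pyruvate", "lactate"), ("pyruvate", "acetate")]),
        ("p06", "glyoxylate and dicarboxylate metabolism",
         [("citrate", "glycine"), ("glycine", "formate"),
          ("citrate", "succinate")]),
        ("p07", "histidine metabolism",
         [("histidine", "urocanate"), ("urocanate", "glutamate"),
          ("histidine", "1-methylhistidine"), ("glutamate", "aspartate")]),
        ("p08", "phenylalanine metabolism",
         [("phenylalanine", "tyrosine"), ("phenylalanine", "phenylacetylglycine"),
          ("phenylalanine", "ortho-hydroxyphenylacetate"),
          ("phenylalanine", "benzoate"), ("benzoate", "hippurate")]),
        ("p09", "phenylalanine, tyrosine and tryptophan biosynthesis",
         [("pyruvate", "tyrosine"), ("tyrosine", "phenylalanine"),
          ("phenylalanine", "glutamate")]),
        ("p10", "TCA cycle",
         [("citrate", "alpha-ketoglutarate"), ("alpha-ketoglutarate", "succinate"),
          ("succinate", "fumarate"), ("fumarate", "citrate"),
          ("pyruvate", "citrate")]),
    ]
    pathways = []
    for pid, name, edges in defs:
        g = nx.Graph()
        g.add_edges_from(edges)
        pathways.append(PathwayGraph(pid, name, g))
    return PathwaySet(pathways)
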