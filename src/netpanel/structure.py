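"""Composite sociometric network assembly and per-node structural metrics.

The composite graph joins three undirected edge layers over one node
set: RDS recruitment edges between egos, and confidant and sexual
nomination edges between an ego and their alters. Parallel nominations
merge into a single edge carrying a set of edge kinds and the waves at
which each tie was observed.

On observed (non-simulated) data the same real person named by two
different egos cannot be recognized as one node — the instrument only
confirms matches within a respondent's own lists — so each ego's alters
are distinct nodes, which inflates path lengths relative to the true
sociometric network. Simulated data carry ground-truth identities and
can optionally merge alters across egos.

Metrics: degree; betweenness centrality normalized by (n-1)(n-2)/2;
closeness centrality over each node's reachable set with the
component-size correction (reachable-1)/(n-1) (harmonic closeness
available by flag); and the node's mean geodesic distance to reachable
nodes. Isolated nodes get betweenness and closeness 0 and an undefined
(NaN) mean path length.
"""

from __future__ import annotations

from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from netpanel.roster import Dataset
from netpanel.simulate import GROUPS

EDGE_KINDS = ("rds", "confidant", "sexual")
METRICS = ("degree", "betweenness", "closeness", "avg_path_length")


class MissingLayerError(KeyError):
    """A requested edge layer is absent from the dataset."""


def _add_edge(g: nx.Graph, u, v, kind: str, wave) -> None:
    if u == v:
        return
    if g.has_edge(u, v):
        g[u][v]["kinds"].add(kind)
        if wave is not None:
            g[u][v]["waves"].add(int(wave))
    else:
        g.add_edge(u, v, kinds={kind}, waves=({int(wave)} if wave is not None else set()))


def assemble_graph(dataset: Dataset, edge_kinds: Iterable[str] = EDGE_KINDS,
                   waves: Optional[Iterable[int]] = None,
                   merge_alters: bool = False) -> nx.Graph:
    """Build the composite undirected graph from a validated dataset.

    ``edge_kinds`` selects layers (nonempty subset of rds / confidant /
    sexual); ``waves`` restricts nomination edges to those waves.  With
    ``merge_alters`` (simulated data only) alters are identified by
    ground truth across egos, and an alter that is itself an enrolled
    ego collapses onto that ego's node.
    """
    kinds = tuple(edge_kinds)
    if not kinds or any(k not in EDGE_KINDS for k in kinds):
        raise ValueError(f"edge_kinds must be a nonempty subset of {EDGE_KINDS}, got {kinds!r}")
    wave_filter = set(int(w) for w in waves) if waves is not None else None

    g = nx.Graph()
    for r in dataset.respondents.itertuples(index=False):
        g.add_node(r.ego_id, group=r.group, enrolled=True)

    if "rds" in kinds:
        if "recruiter_id" not in dataset.respondents.columns:
            raise MissingLayerError(
                "dataset has no recruitment information (recruiter_id column absent)"
            )
        for r in dataset.respondents.itertuples(index=False):
            rec = r.recruiter_id
            if rec is not None and not (isinstance(rec, float) and np.isnan(rec)) and rec != "":
                _add_edge(g, r.ego_id, rec, "rds", None)

    node_of_nomination: dict = {}
    if merge_alters:
        if dataset.ground_truth is None:
            raise MissingLayerError("merge_alters requires simulator ground truth")
        truth = dataset.ground_truth.nomination_members
        member_of = dict(zip(truth["nomination_id"], truth["member"]))
        # an alter who is an enrolled ego collapses onto the ego node
        em = dataset.ground_truth.ego_members
        ego_of_member = dict(zip(em["member"], em["ego_id"]))
        for nom, member in member_of.items():
            node_of_nomination[nom] = ego_of_member.get(member, member)
        for node in set(node_of_nomination.values()):
            if node not in g:
                g.add_node(node, group="", enrolled=False)
    else:
        amap = dataset.alter_map
        ego_nodes = set(dataset.respondents["ego_id"])
        for nom, alter in amap.alter_of.items():
            node_of_nomination[nom] = alter
        for alter in set(node_of_nomination.values()):
            if alter not in ego_nodes:
                g.add_node(alter, group="", enrolled=False)

    nomination_kinds = set(kinds) & {"confidant", "sexual"}
    if nomination_kinds:
        for r in dataset.rosters.itertuples(index=False):
            if r.kind not in nomination_kinds:
                continue
            if wave_filter is not None and int(r.wave) not in wave_filter:
                continue
            _add_edge(g, r.ego_id, node_of_nomination[r.nomination_id], r.kind, r.wave)
    return g


def node_metrics(graph: nx.Graph, closeness: str = "corrected") -> pd.DataFrame:
    """Per-node degree, betweenness, closeness, and mean geodesic distance.

    ``closeness`` is "corrected" (component-size–scaled, the default) or
    "harmonic" (mean of inverse distances over all other nodes).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    n = graph.number_of_nodes()
    deg = dict(graph.degree())
    btw = nx.betweenness_centrality(graph, normalized=True)
    if closeness not in ("corrected", "harmonic"):
        raise ValueError("closeness must be 'corrected' or 'harmonic'")

    rows = []
    for node in graph.nodes:
        lengths = nx.single_source_shortest_path_length(graph, node)
        dists = [d for v, d in lengths.items() if v != node]
        total = float(sum(dists))
        r = len(dists)  # reachable others
        if closeness == "corrected":
            # inverse mean distance within the reachable set, scaled by
            # (reachable-1)/(n-1) so small fragments cannot dominate
            clo = (r / total) * (r / (n - 1)) if total > 0 and n > 1 else 0.0
        else:
            clo = float(sum(1.0 / d for d in dists)) / (n - 1) if n > 1 else 0.0
        rows.append({
            "node": node,
            "degree": deg[node],
            "betweenness": btw[node],
            "closeness": clo,
            "avg_path_length": total / r if r else np.nan,
        })
    df = pd.DataFrame(rows).set_index("node")
    return df


def group_structure_comparison(metrics: pd.DataFrame, respondents: pd.DataFrame,
                               ttest: str = "welch") -> pd.DataFrame:
    """Group means of each structural metric over enrolled egos, with t-tests.

    Alter nodes are excluded: metrics are computed on the full composite
    graph but compared only across respondents with known group labels.
    """
    merged = metrics.join(
        respondents.set_index("ego_id")[["group"]], how="inner"
    )
    rows = []
    for metric in METRICS:
        vals = {g: merged.loc[(merged["group"] == g) & merged[metric].notna(), metric].to_numpy(dtype=float)
                for g in GROUPS}
        a, b = vals["TGW"], vals["MSM"]
        if len(a) < 2 or len(b) < 2:
            t, p, flag = np.nan, np.nan, "not-computable"
        elif np.var(a) == 0 and np.var(b) == 0:
            t, p, flag = (0.0, np.nan, "degenerate") if (len(a) and len(b) and np.mean(a) == np.mean(b)) else (np.inf, 0.0, "degenerate")
        else:
            t, p = sps.ttest_ind(a, b, equal_var=(ttest == "pooled"))
            t, p, flag = float(t), float(p), None
        rows.append({
            "metric": metric,
            "mean_tgw": float(np.mean(a)) if len(a) else np.nan,
            "mean_msm": float(np.mean(b)) if len(b) else np.nan,
            "n_tgw": len(a), "n_msm": len(b),
            "t_statistic": t, "p_value": p, "flag": flag,
        })
    return pd.DataFrame(rows)
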