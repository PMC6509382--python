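"""Proximity-based social networks (PBSNs) from rounds of simultaneous fixes.

Within each round, animals are partitioned into groups by the chain rule:
two animals are adjacent if they are within the association distance
(default 50 m) and groups are the connected components of that adjacency,
so A and C belong to one group whenever a chain of pairwise-close animals
links them even if A and C themselves are far apart. A dyad's association
weight is the simple ratio index

    SRI = x / (x + y_AB + y_A + y_B)

with x the number of rounds the two were grouped together, y_AB the rounds
both were observed but not grouped, and y_A (y_B) the rounds only one of
them was observed. Graph strength -- the sum of SRI weights incident to a
node -- is the per-individual sociality index.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

#: Default chain-rule association distance in metres.
ASSOCIATION_DISTANCE = 50.0

NETWORK_KEYS = ["herd", "season", "year"]


@dataclass(frozen=True)
class DyadCounts:
    """Round counts for one dyad (see module docstring for the SRI roles)."""

    x: int
    y_ab: int
    y_a: int
    y_b: int

    @property
    def denominator(self) -> int:
        return self.x + self.y_ab + self.y_a + self.y_b


def chain_group(xy: np.ndarray, threshold: float = ASSOCIATION_DISTANCE) -> np.ndarray:
    """Chain-rule group labels for one round of planar positions.

    Returns an integer label per row of ``xy``; equal labels mean same group
    (connected component of the <=threshold proximity graph).
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if n == 0:
        return np.empty(0, dtype=int)
    pairs = cKDTree(xy).query_pairs(threshold, output_type="ndarray")
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    return labels


def group_rounds(
    rounds: pd.DataFrame, threshold: float = ASSOCIATION_DISTANCE
) -> pd.DataFrame:
    """Attach a ``group`` label (unique across rounds) to every fix."""
    out = rounds.copy()
    labels = np.empty(len(out), dtype=np.int64)
    offset = 0
    for _, idx in out.groupby("round_time", sort=True).indices.items():
        sub = chain_group(out.iloc[idx][["x", "y"]].to_numpy(), threshold)
        labels[idx] = sub + offset
        offset += sub.max() + 1 if len(sub) else 0
    out["group"] = labels
    return out


def dyad_counts(grouped: pd.DataFrame, a: str, b: str) -> DyadCounts:
    """Count the SRI round categories for a dyad from group-labelled rounds."""
    rows_a = grouped[grouped["animal_id"] == a]
    rows_b = grouped[grouped["animal_id"] == b]
    ra = dict(zip(rows_a["round_time"], rows_a["group"]))
    rb = dict(zip(rows_b["round_time"], rows_b["group"]))
    joint = set(ra) & set(rb)
    x = sum(1 for t in joint if ra[t] == rb[t])
    return DyadCounts(
        x=x,
        y_ab=len(joint) - x,
        y_a=len(set(ra) - set(rb)),
        y_b=len(set(rb) - set(ra)),
    )


def sri(counts: DyadCounts) -> float | None:
    """Simple ratio index; ``None`` when the dyad was never observed."""
    if counts.denominator == 0:
        return None
    return counts.x / counts.denominator


def _sri_matrix(
    pos: np.ndarray, present: np.ndarray, threshold: float
) -> np.ndarray:
    """SRI matrix from dense round-by-animal arrays.

    ``pos`` is (R, N, 2) positions and ``present`` (R, N) a presence mask.
    All rounds are processed in one sparse connected-components pass by
    treating each round as an isolated block of an (R*N)-node graph.
    Entries with a zero denominator are NaN.
    """
    r, n, _ = pos.shape
    if r == 0 or n == 0:
        return np.full((n, n), np.nan)
    diff = pos[:, :, None, :] - pos[:, None, :, :]
    close = (diff[..., 0] ** 2 + diff[..., 1] ** 2) <= threshold**2
    close &= present[:, :, None] & present[:, None, :]
    ri, ai, aj = np.nonzero(np.triu(close, k=1))
    adj = sparse.coo_matrix(
        (np.ones(len(ri)), (ri * n + ai, ri * n + aj)), shape=(r * n, r * n)
    )
    _, labels = connected_components(adj, directed=False)
    labels = labels.reshape(r, n)

    same = (labels[:, :, None] == labels[:, None, :]) & present[:, :, None] & present[:, None, :]
    x = same.sum(axis=0).astype(float)
    joint = (present[:, :, None] & present[:, None, :]).sum(axis=0)
    n_obs = present.sum(axis=0)
    denom = (n_obs[:, None] + n_obs[None, :] - joint).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > 0, x / denom, np.nan)
    np.fill_diagonal(w, np.nan)
    return w


def _round_arrays(rounds: pd.DataFrame, ids: list) -> tuple[np.ndarray, np.ndarray]:
    """Dense (R, N, 2) position and (R, N) presence arrays from round rows."""
    round_times = np.sort(rounds["round_time"].unique())
    r_index = {t: i for i, t in enumerate(round_times)}
    a_index = {a: j for j, a in enumerate(ids)}
    r = len(round_times)
    n = len(ids)
    pos = np.zeros((r, n, 2))
    present = np.zeros((r, n), dtype=bool)
    ri = rounds["round_time"].map(r_index).to_numpy()
    ai = rounds["animal_id"].map(a_index).to_numpy()
    pos[ri, ai, 0] = rounds["x"].to_numpy(float)
    pos[ri, ai, 1] = rounds["y"].to_numpy(float)
    present[ri, ai] = True
    return pos, present


def build_pbsn(
    rounds: pd.DataFrame,
    ids: list | None = None,
    threshold: float = ASSOCIATION_DISTANCE,
) -> nx.Graph:
    """Build the weighted PBSN for one herd-season-year's rounds.

    Nodes are animal ids (all of ``ids`` if given, else the observed ones);
    edges carry the SRI weight for every dyad with a positive denominator.
    Never-observed dyads contribute no edge. Each node gets a ``strength``
    attribute (sum of incident SRI weights).
    """
    if ids is None:
        ids = sorted(rounds["animal_id"].unique())
    ids = list(ids)
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    if len(ids) >= 2 and len(rounds):
        pos, present = _round_arrays(rounds, ids)
        w = _sri_matrix(pos, present, threshold)
        ii, jj = np.nonzero(np.triu(~np.isnan(w), k=1))
        graph.add_weighted_edges_from(
            (ids[i], ids[j], float(w[i, j])) for i, j in zip(ii, jj)
        )
    for node in graph.nodes:
        graph.nodes[node]["strength"] = float(
            sum(d["weight"] for _, _, d in graph.edges(node, data=True))
        )
    return graph


def strengths(graph: nx.Graph) -> dict:
    """Per-node graph strength (sum of incident edge weights)."""
    return {v: graph.nodes[v]["strength"] for v in graph.nodes}


def build_pbsns(
    rounds: pd.DataFrame, threshold: float = ASSOCIATION_DISTANCE
) -> dict[tuple, nx.Graph]:
    """One PBSN per (herd, season, year) present in season-tagged rounds."""
    return {
        key: build_pbsn(sub, threshold=threshold)
        for key, sub in rounds.groupby(NETWORK_KEYS, sort=True)
    }


def strength_table(networks: dict[tuple, nx.Graph]) -> pd.DataFrame:
    """Long table (herd, season, year, animal_id, strength) over networks."""
    rows = [
        {"herd": h, "season": s, "year": y, "animal_id": a, "strength": st}
        for (h, s, y), g in networks.items()
        for a, st in strengths(g).items()
    ]
    return pd.DataFrame(rows, columns=["herd", "season", "year", "animal_id", "strength"])


def export_edges(networks: dict[tuple, nx.Graph]) -> pd.DataFrame:
    """Weighted edge list over all networks, one row per dyad."""
    rows = [
        {"herd": h, "season": s, "year": y, "node_a": a, "node_b": b, "sri": d["weight"]}
        for (h, s, y), g in networks.items()
        for a, b, d in g.edges(data=True)
    ]
    return pd.DataFrame(
        rows, columns=["herd", "season", "year", "node_a", "node_b", "sri"]
    )
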