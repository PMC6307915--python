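"""Interaction-network filtering and topology summaries.

Edge lists carry a confidence score in [0, 1] and an experimental-
evidence flag, mirroring a STRING-style export.  Filtering keeps edges
with score >= 0.4 (default) and, when required, experimental evidence,
then drops nodes left without any edge.  The summary statistics follow
the NetworkAnalyzer conventions: mean local clustering over nodes of
degree >= 2, heterogeneity as the population coefficient of variation of
degree, degree centralisation, and a power-law fit of the degree
histogram by least squares in log-log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np


def read_edge_list(path: str | Path, sep: str = "\t") -> list[tuple]:
    """Read a 3-4 column edge list: node_a, node_b, confidence
    [, experimental(0/1)].  A header row is detected and skipped."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(sep)
            if lineno == 1 and _looks_like_header(parts):
                continue
            records.append(_parse_edge(parts, lineno))
    return records


def _looks_like_header(parts: list[str]) -> bool:
    try:
        float(parts[2])
        return False
    except (IndexError, ValueError):
        return True


def _parse_edge(parts, lineno: int) -> tuple:
    if len(parts) not in (3, 4):
        raise ValueError(f"malformed edge record at line {lineno}: expected 3-4 fields")
    a, b = parts[0], parts[1]
    try:
        score = float(parts[2])
    except ValueError:
        raise ValueError(f"malformed edge record at line {lineno}: bad confidence {parts[2]!r}")
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"malformed edge record at line {lineno}: confidence outside [0, 1]")
    exp = True
    if len(parts) == 4:
        if parts[3] not in ("0", "1"):
            raise ValueError(f"malformed edge record at line {lineno}: evidence flag must be 0/1")
        exp = parts[3] == "1"
    return (a, b, score, exp)


def write_edge_list(graph: nx.Graph, path: str | Path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(sep.join(["node_a", "node_b", "confidence", "experimental"]) + "\n")
        for a, b, d in graph.edges(data=True):
            fh.write(
                sep.join(
                    [str(a), str(b), f"{d.get('confidence', 1.0):g}", "1" if d.get("experimental", True) else "0"]
                )
                + "\n"
            )


def filter_interactions(
    edges: Iterable[tuple] | nx.Graph,
    min_confidence: float = 0.4,
    require_experimental: bool = True,
) -> nx.Graph:
    """Build the filtered undirected interaction graph.

    Keeps edges with confidence >= ``min_confidence`` and, when
    ``require_experimental``, only those with experimental evidence;
    self-loops and duplicate edges are collapsed, and nodes left isolated
    by the filter are removed.
    """
    if isinstance(edges, nx.Graph):
        edges = [
            (a, b, d.get("confidence", 1.0), d.get("experimental", True))
            for a, b, d in edges.edges(data=True)
        ]
    g = nx.Graph()
    for rec in edges:
        a, b, score, exp = rec
        if a == b:
            continue
        if score < min_confidence:
            continue
        if require_experimental and not exp:
            continue
        g.add_edge(a, b, confidence=float(score), experimental=bool(exp))
    return g


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    avg_neighbours: float
    clustering: float
    density: float
    heterogeneity: float
    centralisation: float
    powerlaw_exponent: float | None
    powerlaw_r2: float | None


def powerlaw_fit(degrees: np.ndarray) -> tuple[float | None, float | None]:
    """Least-squares line through the log-log degree histogram (non-zero
    counts, positive degrees).  Returns (slope, R^2); a scale-free graph
    yields a negative slope with high R^2.  None when fewer than 3 points."""
    degrees = degrees[degrees > 0]
    vals, counts = np.unique(degrees, return_counts=True)
    if vals.size < 3:
        return None, None
    x, y = np.log10(vals), np.log10(counts)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(r2)


def network_summary(graph: nx.Graph) -> NetworkSummary:
    """Topology summary of a filtered interaction graph (>= 1 edge)."""
    if graph.number_of_edges() == 0:
        raise ValueError("graph has no edges")
    n = graph.number_of_nodes()
    e = graph.number_of_edges()
    deg = np.array([d for _, d in graph.degree()], dtype=float)
    local = nx.clustering(graph)
    eligible = [v for v, d in graph.degree() if d >= 2]
    clustering = float(np.mean([local[v] for v in eligible])) if eligible else 0.0
    mean_deg = deg.mean()
    heterogeneity = float(deg.std() / mean_deg) if mean_deg > 0 else 0.0  # population sd
    if n > 2:
        centralisation = float(n / (n - 2) * (deg.max() / (n - 1) - nx.density(graph)))
    else:
        centralisation = 0.0
    exponent, r2 = powerlaw_fit(deg)
    return NetworkSummary(
        n_nodes=n,
        n_edges=e,
        avg_neighbours=float(2.0 * e / n),
        clustering=clustering,
        density=float(nx.density(graph)),
        heterogeneity=heterogeneity,
        centralisation=centralisation,
        powerlaw_exponent=exponent,
        powerlaw_r2=r2,
    )
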