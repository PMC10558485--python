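"""Readers and writers for hyperedge lists, bipartite data and contact streams."""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import networkx as nx

from .hypergraph import ContactStream, Hypergraph

logger = logging.getLogger(__name__)

_SPLIT = re.compile(r"[,\s]+")


class HypergraphParseError(ValueError):
    pass


def read_hypergraph(path, dialect: str = "edgelist-text") -> Hypergraph:
    """Read a hypergraph from a file.

    ``edgelist-text``: one hyperedge per line, labels separated by whitespace
    or commas, ``#`` lines ignored.  ``json``: an object with ``"nodes"`` and
    ``"hyperedges"`` keys.  Duplicate hyperedges are merged and singletons
    dropped; both events are logged.
    """
    path = Path(path)
    if dialect == "edgelist-text":
        edges = []
        with open(path) as fh:
            lines = fh.read().splitlines()
        for lineno, line in enumerate(lines, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            labels = [tok for tok in _SPLIT.split(stripped) if tok]
            if not labels:
                raise HypergraphParseError(
                    f"{path}: malformed line {lineno}: {line!r}")
            edges.append(labels)
        if not edges:
            raise HypergraphParseError(f"{path}: empty hypergraph (no hyperedges)")
        H = Hypergraph(edges)
    elif dialect == "json":
        with open(path) as fh:
            try:
                obj = json.load(fh)
            except json.JSONDecodeError as exc:
                raise HypergraphParseError(
                    f"{path}: malformed JSON at line {exc.lineno}") from exc
        if not isinstance(obj, dict) or "hyperedges" not in obj:
            raise HypergraphParseError(f"{path}: missing 'hyperedges' key")
        if not obj["hyperedges"]:
            raise HypergraphParseError(f"{path}: empty hypergraph (no hyperedges)")
        H = Hypergraph(obj["hyperedges"], nodes=obj.get("nodes"))
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    if H.n_dropped_singletons:
        logger.info("%s: dropped %d singleton hyperedge(s)",
                    path, H.n_dropped_singletons)
    if H.n_duplicate_edges:
        logger.info("%s: merged %d duplicate hyperedge(s)",
                    path, H.n_duplicate_edges)
    if H.n_edges == 0:
        raise HypergraphParseError(
            f"{path}: empty hypergraph (no hyperedges of size >= 2)")
    return H


def write_hypergraph(H: Hypergraph, path, dialect: str = "edgelist-text") -> None:
    """Write a hypergraph; round-trips exactly under either dialect."""
    path = Path(path)
    if dialect == "edgelist-text":
        with open(path, "w") as fh:
            for e in H.edge_list:
                fh.write(" ".join(str(v) for v in sorted(e, key=str)) + "\n")
    elif dialect == "json":
        obj = {
            "nodes": [str(v) for v in H.nodes],
            "hyperedges": [sorted((str(v) for v in e))
                           for e in H.edge_list],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


def bipartite_to_hypergraph(path, side: str = "left") -> Hypergraph:
    """Project a two-column bipartite edge list onto one side.

    Each node of the *non*-chosen side yields a candidate hyperedge made of
    its neighbours on the chosen side (e.g. insect species pollinating the
    same plant).  Candidates of size < 2 are dropped and duplicates merged.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    path = Path(path)
    groups: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            toks = [t for t in _SPLIT.split(stripped) if t]
            if len(toks) != 2:
                raise HypergraphParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(toks)}")
            left, right = toks
            if side == "left":
                groups.setdefault(right, set()).add(left)
            else:
                groups.setdefault(left, set()).add(right)
    if not groups:
        raise HypergraphParseError(f"{path}: empty bipartite edge list")
    return Hypergraph(groups.values())


def read_contact_stream(path, window: int = 900) -> ContactStream:
    """Read a 3-column (t, i, j) whitespace-separated contact list."""
    events = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            toks = stripped.split()
            if len(toks) != 3:
                raise HypergraphParseError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(toks)}")
            try:
                t = int(toks[0])
            except ValueError as exc:
                raise HypergraphParseError(
                    f"{path}: line {lineno}: bad timestamp {toks[0]!r}") from exc
            events.append((t, toks[1], toks[2]))
    if not events:
        raise HypergraphParseError(f"{path}: empty contact stream")
    return ContactStream(events=tuple(events), window=window)


def contacts_to_hypergraph(stream: ContactStream) -> Hypergraph:
    """Aggregate a contact stream into a hypergraph of maximal cliques.

    Events are binned into fixed, non-overlapping half-open windows
    ``[t0 + w*q, t0 + w*(q+1))`` anchored at the first timestamp.  Within a
    window, all pairs with at least one event form a graph; every maximal
    clique of size >= 2 becomes a hyperedge.  The result is the deduplicated
    union over windows.
    """
    if not stream.events:
        raise ValueError("empty contact stream")
    t0 = stream.t0
    w = stream.window
    windows: dict[int, set[tuple]] = {}
    for t, i, j in stream.events:
        q = (t - t0) // w
        windows.setdefault(q, set()).add((i, j))
    edges: set[frozenset] = set()
    for pairs in windows.values():
        G = nx.Graph()
        G.add_edges_from(pairs)
        for clique in nx.find_cliques(G):
            if len(clique) >= 2:
                edges.add(frozenset(clique))
    return Hypergraph(edges)
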