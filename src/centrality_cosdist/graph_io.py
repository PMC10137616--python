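"""Network, seed-list and table I/O.

Networks are undirected simple :class:`networkx.Graph` objects. Loading
enforces the package-wide invariants: no self-loops, parallel edges
collapsed (weights summed), every weight strictly positive. Node
identifiers are opaque strings; no gene-ID normalisation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

logger = logging.getLogger("centrality_cosdist")

__all__ = [
    "SeedSet",
    "load_edgelist",
    "load_graphml",
    "load_seeds",
    "load_ranking",
    "write_table",
    "read_table",
]


class EdgeListParseError(ValueError):
    """A line of an edge-list file could not be parsed."""


class ValidationError(ValueError):
    """Input violated a structural requirement (empty file, bad weight...)."""


@dataclass(frozen=True)
class SeedSet:
    """A named, ordered collection of query node identifiers.

    Order is preserved from the input file and used only for deterministic
    reporting; membership is what the algorithms consume.
    """

    name: str
    members: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"seed set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, node: str) -> bool:
        return node in set(self.members)


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def load_edgelist(path: str | Path, weighted: bool = False) -> nx.Graph:
    """Read a 2- or 3-column whitespace/tab edge list into an undirected graph.

    Comment lines start with ``#``. In weighted mode a header line is
    auto-detected (non-numeric third column on the first data line) and
    skipped. Self-loops are dropped and duplicate edges collapsed; in
    weighted mode duplicate weights are summed. Both events are logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    G = nx.Graph()
    self_loops = 0
    duplicates = 0
    n_data_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            want = 3 if weighted else 2
            if len(fields) != want:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected {want} fields, got {len(fields)}: {line!r}"
                )
            if weighted and n_data_lines == 0 and not _is_number(fields[2]):
                # header line in weighted mode
                continue
            n_data_lines += 1
            u, v = fields[0], fields[1]
            if u == v:
                self_loops += 1
                continue
            if weighted:
                try:
                    w = float(fields[2])
                except ValueError:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: weight {fields[2]!r} is not a number"
                    ) from None
                if w <= 0:
                    raise ValidationError(
                        f"{path}:{lineno}: non-positive weight {w}"
                    )
                if G.has_edge(u, v):
                    duplicates += 1
                    G[u][v]["weight"] += w
                else:
                    G.add_edge(u, v, weight=w)
            else:
                if G.has_edge(u, v):
                    duplicates += 1
                else:
                    G.add_edge(u, v)
    if n_data_lines == 0:
        raise ValidationError(f"{path}: no edges found")
    if self_loops:
        logger.info("%s: removed %d self-loop(s)", path, self_loops)
    if duplicates:
        logger.info("%s: collapsed %d duplicate edge(s)", path, duplicates)
    return G


def load_graphml(path: str | Path) -> nx.Graph:
    """Read a GraphML file, coercing to a simple undirected string-labelled graph."""
    raw = nx.read_graphml(Path(path))
    G = nx.Graph()
    for u, v, data in raw.edges(data=True):
        u, v = str(u), str(v)
        if u == v:
            continue
        w = data.get("weight")
        if w is not None:
            if float(w) <= 0:
                raise ValidationError(f"{path}: non-positive weight on edge {u}-{v}")
            if G.has_edge(u, v):
                G[u][v]["weight"] += float(w)
            else:
                G.add_edge(u, v, weight=float(w))
        else:
            G.add_edge(u, v)
    G.add_nodes_from(str(n) for n in raw.nodes)
    if G.number_of_edges() == 0:
        raise ValidationError(f"{path}: no edges found")
    return G


def load_network(path: str | Path, weighted: bool = False) -> nx.Graph:
    """Dispatch on extension: ``.graphml`` via GraphML, anything else as edge list."""
    p = Path(path)
    if p.suffix.lower() == ".graphml":
        return load_graphml(p)
    return load_edgelist(p, weighted=weighted)


def load_seeds(
    path: str | Path, network: nx.Graph, name: str | None = None
) -> tuple[SeedSet, list[str]]:
    """Read one identifier per line; split into in-network seeds and missing ids.

    Missing identifiers are returned (and logged), never silently dropped.
    Zero seeds present in the network is fatal: every ranker is undefined
    without an anchor set.
    """
    path = Path(path)
    ids: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            token = raw.strip()
            if not token or token.startswith("#"):
                continue
            if token not in seen:
                seen.add(token)
                ids.append(token)
    if not ids:
        raise ValidationError(f"{path}: no seed identifiers found")
    present = [i for i in ids if network.has_node(i)]
    missing = [i for i in ids if not network.has_node(i)]
    if missing:
        logger.warning(
            "%s: %d seed(s) not in network: %s", path, len(missing), ", ".join(missing)
        )
    if not present:
        raise ValidationError(
            f"{path}: none of the {len(ids)} seeds are present in the network"
        )
    return SeedSet(name=name or path.stem, members=tuple(present)), missing


def make_seed_set(members: Iterable[str], name: str = "seeds") -> SeedSet:
    """Build a SeedSet from an in-memory iterable (order preserved, dupes rejected)."""
    return SeedSet(name=name, members=tuple(members))


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write any tabular result as TSV: header line, floats at 6 significant digits."""
    if rows is None or len(rows) == 0:
        raise ValidationError("refusing to write an empty table")
    rows.to_csv(Path(path), sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(Path(path), sep="\t", dtype={"node_id": str})


def load_ranking(path: str | Path) -> pd.DataFrame:
    """Read an externally produced ranking in the standard RankingTable format.

    Requires at least ``node_id`` and ``rank`` columns; used to feed
    rankings from methods not implemented here (e.g. embedding-based
    rankers) into the overlap analysis.
    """
    df = read_table(path)
    required = {"node_id", "rank"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: ranking file must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    return df.sort_values("rank", kind="stable").reset_index(drop=True)
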