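"""STRING-style protein-protein interaction edge lists.

The on-disk dialect is a 3-column TSV ``node<TAB>node<TAB>score`` with an
integer confidence score in 0..1000 (the STRING convention, where 700 marks
"high confidence").  Graphs are undirected, self-loop-free, and keyed by gene
symbol; protein-identifier mapping is assumed done upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import ConfigurationError, DataFormatError

DEFAULT_MIN_SCORE = 700


@dataclass
class PPIGraph:
    """Undirected confidence-scored interaction network.

    ``graph`` is a networkx Graph whose edges carry an integer ``score``
    attribute.  ``dropped_self_loops`` counts input rows discarded because
    both endpoints were the same symbol.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    dropped_self_loops: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, g: str) -> int:
        return self.graph.degree(g) if g in self.graph else 0

    def add_edge(self, a: str, b: str, score: int = 1000) -> None:
        """Insert an undirected edge, ignoring self-loops and keeping the
        maximum score on duplicates."""
        if a == b:
            self.dropped_self_loops += 1
            return
        if self.graph.has_edge(a, b):
            score = max(score, self.graph.edges[a, b]["score"])
        self.graph.add_edge(a, b, score=int(score))


def neighbors(ppi: PPIGraph, g: str) -> set[str]:
    """Set of nodes sharing an edge with ``g``; empty if absent or isolated."""
    if g not in ppi.graph:
        return set()
    return set(ppi.graph.neighbors(g))


def read_edge_list(path, min_score: int = DEFAULT_MIN_SCORE) -> PPIGraph:
    """Parse a STRING-style TSV into a :class:`PPIGraph`.

    Duplicated pairs (in either orientation) are collapsed keeping the
    maximum score, then edges below ``min_score`` are discarded.  Self-loops
    are dropped with a counted warning.  A header line is auto-detected by a
    non-numeric third field.
    """
    if not 0 <= min_score <= 1000:
        raise ConfigurationError(f"min_score must lie in [0, 1000], got {min_score}")
    raw = PPIGraph()
    n_rows = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise DataFormatError(
                    f"expected 3 tab-separated fields, found {len(fields)}", line=lineno
                )
            a, b, score_text = fields
            try:
                score = int(float(score_text))
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise DataFormatError(
                    f"non-numeric confidence score {score_text!r}", line=lineno
                ) from None
            if not 0 <= score <= 1000:
                raise DataFormatError(f"score {score} outside [0, 1000]", line=lineno)
            raw.add_edge(a, b, score)
            n_rows += 1
    if n_rows == 0:
        raw.warnings.append("empty interaction file: graph has no edges")
    if raw.dropped_self_loops:
        raw.warnings.append(f"dropped {raw.dropped_self_loops} self-loop(s)")
    # threshold after collapsing duplicates so the max-score rule applies first
    keep = [(a, b, d) for a, b, d in raw.graph.edges(data=True) if d["score"] >= min_score]
    out = PPIGraph(dropped_self_loops=raw.dropped_self_loops, warnings=list(raw.warnings))
    for a, b, d in keep:
        out.graph.add_edge(a, b, score=d["score"])
    return out


def write_edge_list(ppi: PPIGraph, path) -> None:
    """Write edges as a 3-column TSV, endpoints in sorted order per row."""
    with open(path, "wt", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in ppi.graph.edges):
            fh.write(f"{a}\t{b}\t{ppi.graph.edges[a, b]['score']}\n")
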