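"""Exception hierarchy.

Every error raised by the library derives from :class:`SpnetError`, so the
CLI (and embedding code) can map failure classes onto exit codes without
string matching.
"""

from __future__ import annotations


class SpnetError(Exception):
    """Base class for all spnet errors."""


class SifParseError(SpnetError):
    """A SIF line could not be parsed (e.g. exactly two tokens)."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class WeightParseError(SpnetError):
    """An edge-weight file could not be parsed."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class WeightAttributeMismatchError(SpnetError):
    """The attribute named in a Cytoscape edge-attribute header differs from the requested one."""

    def __init__(self, expected: str, found: str):
        self.expected = expected
        self.found = found
        super().__init__(
            f"weight file stores attribute {found!r}, not the requested {expected!r}"
        )


class MissingWeightError(SpnetError):
    """Some graph edges have no entry in the weight map."""

    def __init__(self, missing_edges):
        self.missing_edges = tuple(missing_edges)
        listing = ", ".join(f"({u},{v})" for u, v in self.missing_edges)
        super().__init__(f"no weight provided for edges: {listing}")


class UnknownNodeError(SpnetError):
    """A node identifier is not part of the graph."""

    def __init__(self, node: str):
        self.node = node
        super().__init__(f"unknown node: {node!r}")


class SelectionError(SpnetError):
    """The node selection does not satisfy a task's requirements."""


class DisconnectedError(SpnetError):
    """No member of the target set is reachable from the source node."""


class NegativeCycleError(SpnetError):
    """A negative-total-weight cycle is reachable from the source."""

    def __init__(self, cycle):
        self.cycle = tuple(cycle)
        super().__init__(
            "negative-weight cycle reachable from source: "
            + " -> ".join(self.cycle + (self.cycle[0],))
        )


class DegenerateCycleError(SpnetError):
    """A zero-total-weight cycle lies inside the shortest-path subgraph.

    In that situation "all shortest paths" is not a finite set of simple
    paths, so the computation refuses rather than enumerate walks.
    """


class IntegrityError(SpnetError):
    """A path references a node or edge absent from its graph."""
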