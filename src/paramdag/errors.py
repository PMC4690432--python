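"""Exception hierarchy shared by all paramdag modules."""

from __future__ import annotations


class ParamDagError(Exception):
    """Base class for every error raised deliberately by paramdag."""


# --- SBML layer -----------------------------------------------------------

class SBMLParseError(ParamDagError):
    pass


class UnsupportedFeature(ParamDagError):
    def __init__(self, feature: str, message: str | None = None):
        self.feature = feature
        super().__init__(message or f"unsupported SBML feature: {feature}")


# --- expression layer -----------------------------------------------------

class ExprSyntaxError(ParamDagError):
    """Malformed expression text; ``pos`` is the 0-based character offset."""

    def __init__(self, message: str, pos: int):
        self.pos = pos
        super().__init__(f"{message} (at position {pos})")


class MissingReference(ParamDagError):
    pass


# --- configuration graph --------------------------------------------------

class UnknownKey(ParamDagError):
    pass


class DuplicateName(ParamDagError):
    pass


class UnknownParent(ParamDagError):
    pass


class UnknownNode(ParamDagError):
    pass


class CycleError(ParamDagError):
    pass


class NonAncestorReference(ParamDagError):
    pass


class NoLocalAssignment(ParamDagError):
    pass


class ConflictError(ParamDagError):
    """Raised when resolving a key for which the node's parents disagree.

    Carries the :class:`~paramdag.graph.Conflict` record as ``conflict``.
    """

    def __init__(self, conflict):
        self.conflict = conflict
        cands = ", ".join(
            f"{p}={v!r}" for p, v in sorted(conflict.candidates.items())
        )
        super().__init__(
            f"conflict at node {conflict.node!r} key {conflict.key!r}: "
            f"candidates {{{cands}}}"
        )


class DanglingReference(ParamDagError):
    def __init__(self, node: str, message: str | None = None):
        self.node = node
        super().__init__(message or f"reference to deleted node {node!r}")


class ReferenceCycleError(ParamDagError):
    pass


class NoSuchConflict(ParamDagError):
    pass


# --- project / IO ---------------------------------------------------------

class FormatVersionError(ParamDagError):
    pass


class SchemaError(ParamDagError):
    def __init__(self, message: str, pointer: str = ""):
        self.pointer = pointer
        super().__init__(f"{message} (at {pointer or '/'})")


# --- simulation -----------------------------------------------------------

class IntegrationFailure(ParamDagError):
    pass


class BlockedByConflict(ParamDagError):
    def __init__(self, node: str):
        self.node = node
        super().__init__(f"node {node!r} has unresolved conflicts")


class BlockedByInconsistency(ParamDagError):
    def __init__(self, node: str):
        self.node = node
        super().__init__(f"node {node!r} is inconsistent (dangling reference)")
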