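"""Core model objects: dynamic arrays, DBN specifications, unrolling, sequence data.

A dynamic Bayesian network (DBN) is specified by one *slice* — an ordered list
of nodes, each with a distribution family — together with directed edges inside
a slice (*intra* edges) and edges from one slice to the next (*inter* edges).
The slice is conceptually duplicated along a sequence, with parameters tied
across slices.  Observation data is a set of sequences; each sequence carries
one value per (slice, node) plus a boolean mask marking hidden entries.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, SpecError

TWO_PI = 2.0 * math.pi

#: Supported distribution families.
FAMILIES = (
    "discrete",
    "multinomial",
    "poisson",
    "gaussian_uni",
    "gaussian_multi",
    "vonmises_uni",
    "vonmises_bi",
    "kent",
)

#: Families whose node value is a vector (stored with a trailing axis).
VECTOR_FAMILIES = {"multinomial", "gaussian_multi", "vonmises_bi", "kent"}

#: Families with integer-valued observations.
INT_FAMILIES = {"discrete", "poisson", "multinomial"}


# ---------------------------------------------------------------------------
# MDArray operations: run-time-dimensioned dense arrays (numpy-backed)
# ---------------------------------------------------------------------------

def mdarray_create(shape) -> np.ndarray:
    """Create a zero-initialized dense array with run-time shape.

    Parameters
    ----------
    shape : sequence of int
        Positive extents, one per axis.

    Returns
    -------
    numpy.ndarray
        A C-contiguous (row-major) float array of the given shape.
    """
    shape = [int(s) for s in shape]
    if len(shape) == 0:
        raise SpecError("mdarray shape must have at least one extent")
    if any(s < 1 for s in shape):
        raise SpecError(f"mdarray extents must be positive, got {shape}")
    return np.zeros(shape, dtype=float)


def mdarray_slice(a: np.ndarray, prefix) -> np.ndarray:
    """Slice an array along a prefix of its axes.

    ``prefix`` fixes the first ``len(prefix)`` indices; the result has the
    remaining shape.  An empty prefix returns the array itself.
    """
    prefix = tuple(int(i) for i in prefix)
    if len(prefix) >= a.ndim:
        raise IndexError(
            f"prefix of length {len(prefix)} too long for rank-{a.ndim} array"
        )
    for axis, idx in enumerate(prefix):
        if not 0 <= idx < a.shape[axis]:
            raise IndexError(
                f"index {idx} out of bounds for axis {axis} with extent {a.shape[axis]}"
            )
    return a[prefix]


def cpt_shape(parent_sizes, node_size) -> list[int]:
    """Shape of a conditional probability table.

    One axis per discrete parent (in parent order) followed by the node's own
    state axis: a node of size 2 with parents of sizes 3 and 4 has a 3 x 4 x 2
    table.
    """
    node_size = int(node_size)
    if node_size < 1:
        raise SpecError("node size must be >= 1")
    parent_sizes = [int(s) for s in parent_sizes]
    if any(s < 1 for s in parent_sizes):
        raise SpecError("parent sizes must be >= 1")
    return parent_sizes + [node_size]


# ---------------------------------------------------------------------------
# Specification types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeSpec:
    """One random variable of a slice.

    ``size`` is the state count for discrete nodes, the vector length for
    multinomial / multivariate-Gaussian nodes, 2 for bivariate von Mises
    (an angle pair on the torus) and 3 for Kent (a 3D unit vector).
    """

    name: str
    family: str
    size: int
    hidden_allowed: bool = False

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise SpecError(f"unknown family {self.family!r}")
        if self.size < 1:
            raise SpecError(f"node {self.name!r}: size must be >= 1")
        fixed = {"kent": 3, "vonmises_bi": 2, "vonmises_uni": 1,
                 "gaussian_uni": 1, "poisson": 1}
        want = fixed.get(self.family)
        if want is not None and self.size != want:
            raise SpecError(
                f"node {self.name!r}: family {self.family} requires size {want}"
            )
        if self.hidden_allowed and self.family != "discrete":
            raise SpecError(
                f"node {self.name!r}: hidden entries are only supported on "
                "discrete nodes"
            )


@dataclass(frozen=True)
class DBNSpec:
    """A DBN template: one slice of nodes plus intra- and inter-slice edges.

    Node order must be a topological order of the intra edges (parents before
    children); the constructor rejects other orderings rather than reordering.
    All parents must be discrete nodes — parent values index parameter
    components of the child.  Inter edges connect adjacent slices only.
    """

    nodes: tuple[NodeSpec, ...]
    intra_edges: tuple[tuple[int, int], ...] = ()
    inter_edges: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(
            self, "intra_edges", tuple((int(p), int(c)) for p, c in self.intra_edges)
        )
        object.__setattr__(
            self, "inter_edges", tuple((int(p), int(c)) for p, c in self.inter_edges)
        )
        n = len(self.nodes)
        if n == 0:
            raise SpecError("a DBN needs at least one node per slice")
        names = [nd.name for nd in self.nodes]
        if len(set(names)) != n:
            raise SpecError("node names must be unique")
        for kind, edges in (("intra", self.intra_edges), ("inter", self.inter_edges)):
            if len(set(edges)) != len(edges):
                raise SpecError(f"duplicate {kind} edge")
            for p, c in edges:
                if not (0 <= p < n and 0 <= c < n):
                    raise SpecError(f"{kind} edge ({p},{c}) out of range")
                if self.nodes[p].family != "discrete":
                    raise SpecError(
                        f"{kind} edge ({p},{c}): parent {names[p]!r} must be discrete"
                    )
        for p, c in self.intra_edges:
            if p >= c:
                raise SpecError(
                    f"intra edge ({p},{c}): node order must topologically order "
                    "intra edges (parent index < child index)"
                )

    # -- structural queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_index(self, name: str) -> int:
        for i, nd in enumerate(self.nodes):
            if nd.name == name:
                return i
        raise KeyError(name)

    def intra_parents(self, i: int) -> list[int]:
        return [p for p, c in self.intra_edges if c == i]

    def inter_parents(self, i: int) -> list[int]:
        return [p for p, c in self.inter_edges if c == i]

    def intra_children(self, i: int) -> list[int]:
        return [c for p, c in self.intra_edges if p == i]

    def inter_children(self, i: int) -> list[int]:
        return [c for p, c in self.inter_edges if p == i]

    def parents(self, i: int, initial: bool = False) -> list[tuple[int, int]]:
        """Parents of node ``i`` as (slice offset, node index) pairs.

        Offset -1 marks inter parents (previous slice), 0 intra parents.
        Inter parents come first; this fixes the axis order of conditional
        parameter tables.  At the initial slice (``initial=True``) inter
        parents do not exist and only intra parents are returned.
        """
        intra = [(0, p) for p in self.intra_parents(i)]
        if initial:
            return intra
        return [(-1, p) for p in self.inter_parents(i)] + intra

    def parent_sizes(self, i: int, initial: bool = False) -> list[int]:
        return [self.nodes[p].size for _, p in self.parents(i, initial)]

    def has_initial_params(self, i: int) -> bool:
        """True if node ``i`` needs a separate slice-0 parameter set."""
        return len(self.inter_parents(i)) > 0


def unroll(spec: DBNSpec, n_slices: int):
    """Instantiate the template over ``n_slices`` slices.

    Returns ``(parent_map, initial_nodes)`` where ``parent_map[(t, i)]`` is
    the list of (slice, node) parents of node ``i`` at slice ``t`` and
    ``initial_nodes`` is the set of (0, i) pairs whose inter parents were
    truncated away (these use the node's slice-0 parameter set).  Parameters
    are tied across slices per node; unrolling is purely structural.
    """
    n_slices = int(n_slices)
    if n_slices < 1:
        raise SpecError("n_slices must be >= 1")
    parent_map: dict[tuple[int, int], list[tuple[int, int]]] = {}
    initial: set[tuple[int, int]] = set()
    for t in range(n_slices):
        for i in range(spec.n_nodes):
            ps = []
            if t > 0:
                ps.extend((t - 1, p) for p in spec.inter_parents(i))
            elif spec.has_initial_params(i):
                initial.add((0, i))
            ps.extend((t, p) for p in spec.intra_parents(i))
            parent_map[(t, i)] = ps
    return parent_map, initial


# ---------------------------------------------------------------------------
# Sequence data
# ---------------------------------------------------------------------------

def _value_shape(node: NodeSpec, length: int) -> tuple[int, ...]:
    if node.family in VECTOR_FAMILIES:
        return (length, node.size)
    return (length,)


def _coerce_values(node: NodeSpec, arr, length: int) -> np.ndarray:
    dtype = np.int64 if node.family in INT_FAMILIES else float
    arr = np.asarray(arr, dtype=dtype)
    want = _value_shape(node, length)
    if arr.shape != want:
        raise DataError(
            f"node {node.name!r}: values have shape {arr.shape}, expected {want}"
        )
    return arr


@dataclass
class Sequence:
    """Per-node value arrays over the slices of one sequence.

    ``values[i]`` has shape (L,) for scalar families and (L, size) for vector
    families; ``mask[i]`` is a boolean (L,) array, True marking hidden entries.
    """

    values: list[np.ndarray]
    mask: list[np.ndarray]

    @property
    def length(self) -> int:
        return len(self.mask[0])


@dataclass
class SequenceBatch:
    """A set of observation sequences tied to a :class:`DBNSpec`.

    Construction validates values against the spec: observed angles must lie
    in [0, 2pi), observed Kent values are renormalized to unit length when
    within 1e-6 of it and rejected otherwise, and hidden entries are only
    permitted on discrete nodes flagged ``hidden_allowed``.
    """

    spec: DBNSpec
    sequences: list[Sequence] = field(default_factory=list)

    @classmethod
    def from_arrays(cls, spec: DBNSpec, per_sequence) -> "SequenceBatch":
        """Build and validate a batch.

        ``per_sequence`` is an iterable of (values, mask) pairs, each a list
        with one entry per node.
        """
        seqs = []
        for s, (values, mask) in enumerate(per_sequence):
            if len(values) != spec.n_nodes or len(mask) != spec.n_nodes:
                raise DataError(f"sequence {s}: need one value/mask array per node")
            masks = [np.asarray(m, dtype=bool) for m in mask]
            length = len(masks[0])
            vals = []
            for i, nd in enumerate(spec.nodes):
                if masks[i].shape != (length,):
                    raise DataError(
                        f"sequence {s}, node {nd.name!r}: mask shape "
                        f"{masks[i].shape} incongruent with length {length}"
                    )
                v = _coerce_values(nd, values[i], length)
                obs = ~masks[i]
                if masks[i].any() and not (nd.hidden_allowed and nd.family == "discrete"):
                    raise DataError(
                        f"sequence {s}, node {nd.name!r}: hidden entries only "
                        "allowed on discrete nodes with hidden_allowed"
                    )
                if nd.family == "discrete":
                    ok = (v[obs] >= 0) & (v[obs] < nd.size)
                    if not np.all(ok):
                        raise DataError(
                            f"sequence {s}, node {nd.name!r}: state out of range"
                        )
                elif nd.family in ("vonmises_uni", "vonmises_bi"):
                    if obs.any() and not np.all((v[obs] >= 0.0) & (v[obs] < TWO_PI)):
                        raise DataError(
                            f"sequence {s}, node {nd.name!r}: angles must lie "
                            "in [0, 2pi)"
                        )
                elif nd.family == "kent":
                    if obs.any():
                        norms = np.linalg.norm(v[obs], axis=-1)
                        if not np.all(np.abs(norms - 1.0) < 1e-6):
                            raise DataError(
                                f"sequence {s}, node {nd.name!r}: unit vectors "
                                "deviate from unit norm by more than 1e-6"
                            )
                        v = v.copy()
                        v[obs] = v[obs] / norms[:, None]
                elif nd.family in ("poisson", "multinomial"):
                    if obs.any() and np.any(v[obs] < 0):
                        raise DataError(
                            f"sequence {s}, node {nd.name!r}: counts must be >= 0"
                        )
                vals.append(v)
            seqs.append(Sequence(values=vals, mask=masks))
        return cls(spec=spec, sequences=seqs)

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def lengths(self) -> list[int]:
        return [s.length for s in self.sequences]

    @property
    def total_slices(self) -> int:
        return sum(self.lengths)

    def copy(self) -> "SequenceBatch":
        seqs = [
            Sequence(values=[v.copy() for v in s.values],
                     mask=[m.copy() for m in s.mask])
            for s in self.sequences
        ]
        return SequenceBatch(spec=self.spec, sequences=seqs)
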