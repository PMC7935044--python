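"""Particular partitions: grouping states into Markov-blanket particles.

A particle is a set of internal states plus the blanket (sensory and active
states) that insulates them: every parent, child and co-parent of an
internal state lies inside the particle.  Given a Jacobian J, the directed
adjacency A (A_ij = 1 iff state j influences state i, i.e. dF_i/dx_j != 0)
yields the blanket-forming matrix

    B = A + A' + A'A

whose n-th row marks the children, parents and parents-of-children of state
n -- exactly the moral-graph neighborhood that renders n conditionally
independent of everything else.  Internal states are seeded from the graph
Laplacian of the symmetrized coupling weights (densely coupled states
first), their blanket is read off B, and the procedure repeats until every
state is assigned.  Remaining states whose neighborhoods touch existing
particles become blanket-only particles.

Orientation convention: A_ij means j -> i, matching the Jacobian entry
J_ij = d(dx_i/dt)/dx_j.  Parents of n are the nonzeros of row n; children
of n are the nonzeros of column n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Adjacency",
    "BlanketMatrix",
    "GraphLaplacianView",
    "Particle",
    "Partition",
    "adjacency",
    "blanket_matrix",
    "graph_laplacian",
    "particular_partition",
    "classify_blanket",
    "verify_partition",
]


@dataclass
class Adjacency:
    """Binary influence matrix; A_ij = 1 iff j influences i (j -> i)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.ndim != 2 or \
                self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("adjacency must be square")

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    def parents(self, n: int) -> set:
        return set(np.flatnonzero(self.matrix[n]))

    def children(self, n: int) -> set:
        return set(np.flatnonzero(self.matrix[:, n]))

    def coparents(self, n: int) -> set:
        out: set = set()
        for c in self.children(n):
            out |= self.parents(c)
        out.discard(n)
        return out


@dataclass
class BlanketMatrix:
    """Boolean B = A + A' + A'A; row n = blanket candidates of state n."""

    matrix: np.ndarray

    def row(self, n: int) -> set:
        members = {int(k) for k in np.flatnonzero(self.matrix[n])}
        members.discard(n)     # the diagonal (from A'A) is bookkeeping only
        return members


@dataclass
class GraphLaplacianView:
    """L = D - W on symmetrized weights W = |J| + |J|', zero diagonal."""

    laplacian: np.ndarray
    weights: np.ndarray
    degree: np.ndarray


@dataclass(frozen=True)
class Particle:
    """Internal states plus their sensory/active blanket."""

    internal: frozenset
    sensory: frozenset
    active: frozenset

    @property
    def blanket(self) -> frozenset:
        return self.sensory | self.active

    @property
    def states(self) -> frozenset:
        return self.internal | self.blanket

    def __post_init__(self) -> None:
        if self.internal & self.sensory or self.internal & self.active \
                or self.sensory & self.active:
            raise ValueError("internal/sensory/active must be disjoint")


@dataclass
class Partition:
    """An ordered list of particles covering all states exactly once."""

    particles: list
    n_states: int
    state_to_particle: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mapping: dict = {}
        for idx, particle in enumerate(self.particles):
            for s in particle.states:
                if s in mapping:
                    raise ValueError(f"state {s} assigned twice")
                mapping[s] = idx
        if set(mapping) != set(range(self.n_states)):
            missing = set(range(self.n_states)) - set(mapping)
            raise ValueError(f"states not covered: {sorted(missing)}")
        self.state_to_particle = mapping

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    def membership(self) -> np.ndarray:
        out = np.empty(self.n_states, dtype=int)
        for s, p in self.state_to_particle.items():
            out[s] = p
        return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def adjacency(jacobian: np.ndarray, tol: float = 1e-6) -> Adjacency:
    """Threshold |J_ij| > tol off the diagonal (self-decay is not an edge)."""
    jac = np.asarray(jacobian)
    if jac.ndim != 2 or jac.shape[0] != jac.shape[1]:
        raise ValueError("Jacobian must be square")
    mat = np.abs(jac) > tol
    np.fill_diagonal(mat, False)
    return Adjacency(matrix=mat)


def blanket_matrix(adj: Adjacency) -> BlanketMatrix:
    a = adj.matrix.astype(int)
    b = a + a.T + a.T @ a
    return BlanketMatrix(matrix=b > 0)


def graph_laplacian(jacobian: np.ndarray) -> GraphLaplacianView:
    jac = np.asarray(jacobian)
    weights = np.abs(jac) + np.abs(jac).T
    np.fill_diagonal(weights, 0.0)
    degree = weights.sum(axis=1)
    laplacian = np.diag(degree) - weights
    return GraphLaplacianView(laplacian=laplacian, weights=weights,
                              degree=degree)


def particular_partition(jacobian: np.ndarray, n_internal: int = 1,
                         tol: float = 1e-6) -> Partition:
    """Group states into particles of internal + blanket states.

    Repeatedly: (1) among *eligible* states pick the one with the largest
    Laplacian degree as the internal seed -- a state is eligible when its
    whole blanket-candidate row is still unassigned, so the particle built
    around it satisfies the Markov-blanket condition by construction;
    (2) grow the internal set up to ``n_internal`` with eligible states
    whose symmetrized coupling to the seed exceeds the median of the seed's
    nonzero couplings; (3) take the blanket as the union of B-rows of the
    internal set, restricted to unassigned states.  When no eligible
    internal candidate remains, leftover states form blanket-only particles
    (one per connected component of the remainder).  Ties break towards the
    lowest state index.
    """
    jac = np.asarray(jacobian)
    n = jac.shape[0]
    if n < 2:
        raise ValueError("need at least 2 states to partition")
    adj = adjacency(jac, tol=tol)
    bmat = blanket_matrix(adj)
    lap = graph_laplacian(jac)

    unassigned = set(range(n))
    particles: list = []
    b_rows = [bmat.row(i) for i in range(n)]

    def eligible(state: int) -> bool:
        return b_rows[state] <= unassigned

    while unassigned:
        candidates = [s for s in sorted(unassigned) if eligible(s)]
        if not candidates:
            break
        # seed: largest Laplacian degree, lowest index on ties
        seed = max(candidates, key=lambda s: (lap.degree[s], -s))
        internal = {seed}
        if n_internal > 1:
            w_row = lap.weights[seed]
            nz = w_row[w_row > tol]
            thresh = np.median(nz) if nz.size else np.inf
            growth = [s for s in candidates
                      if s != seed and w_row[s] >= thresh]
            growth.sort(key=lambda s: (-w_row[s], s))
            for s in growth:
                if len(internal) >= n_internal:
                    break
                if b_rows[s] <= unassigned:
                    internal.add(s)
        blanket: set = set()
        for s in internal:
            blanket |= b_rows[s]
        blanket = (blanket & unassigned) - internal
        particles.append(Particle(internal=frozenset(internal),
                                  sensory=frozenset(blanket),
                                  active=frozenset()))
        unassigned -= internal | blanket

    # leftover states: blanket-only particles, one per connected component
    if unassigned:
        remaining = sorted(unassigned)
        weights = lap.weights
        seen: set = set()
        for start in remaining:
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                u = stack.pop()
                for v in np.flatnonzero(weights[u] > tol):
                    v = int(v)
                    if v in unassigned and v not in comp:
                        comp.add(v)
                        stack.append(v)
            seen |= comp
            particles.append(Particle(internal=frozenset(),
                                      sensory=frozenset(comp),
                                      active=frozenset()))

    partition = Partition(particles=particles, n_states=n)
    return classify_blanket(partition, adj)


def classify_blanket(partition: Partition, adj: Adjacency) -> Partition:
    """Label blanket states sensory or active.

    A blanket state is sensory iff it receives an edge from any state
    outside its particle (it is influenced by external states); otherwise it
    is active.  Idempotent: labels depend only on membership.
    """
    a = adj.matrix
    new_particles = []
    membership = partition.membership()
    for idx, particle in enumerate(partition.particles):
        sensory, active = set(), set()
        for s in sorted(particle.blanket):
            external_parents = [p for p in np.flatnonzero(a[s])
                                if membership[p] != idx]
            if external_parents:
                sensory.add(s)
            else:
                active.add(s)
        new_particles.append(Particle(internal=particle.internal,
                                      sensory=frozenset(sensory),
                                      active=frozenset(active)))
    return Partition(particles=new_particles, n_states=partition.n_states)


def verify_partition(partition: Partition, adj: Adjacency) -> list:
    """Machine-readable violation list (empty = pass).

    Checks coverage/disjointness (enforced by the Partition constructor),
    and that internal states have no edges, in either direction, to states
    outside their particle.
    """
    violations = []
    a = adj.matrix
    membership = partition.membership()
    for idx, particle in enumerate(partition.particles):
        for m in sorted(particle.internal):
            neighbors = set(np.flatnonzero(a[m])) | \
                set(np.flatnonzero(a[:, m]))
            for v in sorted(neighbors):
                if membership[v] != idx:
                    violations.append({
                        "particle": idx, "internal_state": int(m),
                        "external_state": int(v),
                        "reason": "internal state coupled outside particle",
                    })
    return violations
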