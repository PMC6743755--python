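"""Synthetic nets with known invariant ground truth.

Test articles for the analysis stages: nets planted from elementary
circuits (whose minimal t-invariants are known by construction), random
bipartite nets for property-based testing, and labelled integer vector
sets for the clustering stage.  Nothing here emulates BER biology; these
are structural instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exhaustive import exhaustive_t_invariants
from .invariants import InvariantSet, TInvariant
from .net import Arc, PetriNet

__all__ = [
    "PlantedNetSpec",
    "generate_planted_net",
    "generate_random_net",
    "generate_invariant_vectors",
]


class PlantingError(ValueError):
    """The requested overlap plan creates minimal invariants beyond the plan."""


@dataclass(frozen=True)
class PlantedNetSpec:
    """Plan for a net whose minimal t-invariants are planted circuits.

    ``circuit_lengths[i]`` is the number of transitions in circuit ``i``;
    ``shared_transitions`` maps ``(i, j) -> n`` asking circuits i and j to
    share their first ``n`` transitions (a common directed path).
    """

    circuit_lengths: tuple[int, ...]
    shared_transitions: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if any(l < 1 for l in self.circuit_lengths):
            raise ValueError("circuit lengths must be >= 1")
        for (i, j), n in dict(self.shared_transitions).items():
            if not (0 <= i < j < len(self.circuit_lengths)):
                raise ValueError(f"bad circuit pair {(i, j)}")
            if n >= min(self.circuit_lengths[i], self.circuit_lengths[j]):
                raise ValueError("shared path must be shorter than both circuits")


def generate_planted_net(spec: PlantedNetSpec, verify: bool = True):
    """Build a net of overlapping elementary circuits.

    Returns ``(net, invariants, mct_sets)`` where the invariant set and the
    MCT partition are the planted ground truth.  With ``verify`` (default)
    the construction is checked against bounded exhaustive enumeration and
    a :class:`PlantingError` is raised if extra minimal invariants exist —
    possible when shared paths close unplanned circuits.
    """
    shared = dict(spec.shared_transitions)
    circuits: list[list[str]] = []
    counter = 0
    for i, length in enumerate(spec.circuit_lengths):
        trans: list[str] = []
        for pos in range(length):
            reused = None
            for (a, b), n in shared.items():
                if b == i and pos < n:
                    reused = circuits[a][pos]
                    break
            if reused is None:
                trans.append(f"t{counter}")
                counter += 1
            else:
                trans.append(reused)
        circuits.append(trans)

    # Place naming keeps each circuit individually balanced around shared
    # path prefixes: a shared transition owns a single fork place on its
    # output side, and a shared transition entered from unshared branches
    # owns a single join place on its input side.
    from collections import Counter

    usage = Counter(t for c in circuits for t in set(c))
    is_shared = {t: usage[t] > 1 for c in circuits for t in c}

    def place_key(a: str, b: str) -> str:
        if is_shared[a]:
            return f"p_out_{a}"
        if is_shared[b]:
            return f"p_in_{b}"
        return f"p_{a}_{b}"

    places, arcs, pseen = [], [], set()
    for trans in circuits:
        m = len(trans)
        for pos in range(m):
            a, b = trans[pos], trans[(pos + 1) % m]
            pid = place_key(a, b)
            if pid not in pseen:
                pseen.add(pid)
                places.append(pid)
            arcs.append(Arc(a, pid))
            arcs.append(Arc(pid, b))
    all_trans = sorted({t for c in circuits for t in c}, key=lambda s: int(s[1:]))
    # duplicate arcs arise where circuits share a path; deduplicate
    arcs = sorted({(a.source, a.target): a for a in arcs}.values(),
                  key=lambda a: (a.source, a.target))
    net = PetriNet(places, all_trans, arcs, name=f"planted-{spec.circuit_lengths}")

    tids = tuple(net.transition_ids())
    idx = {t: k for k, t in enumerate(tids)}
    expected = []
    seen_vecs = set()
    for c in circuits:
        vec = [0] * len(tids)
        for t in c:
            vec[idx[t]] = 1
        if tuple(vec) not in seen_vecs:
            seen_vecs.add(tuple(vec))
            expected.append(TInvariant(tuple(vec), tids))
    expected.sort(key=lambda inv: (inv.support_indices, inv.vector))
    inv_set = InvariantSet(expected, tids)

    if verify:
        oracle = exhaustive_t_invariants(net, max_coeff=2)
        if {i.vector for i in oracle} != {i.vector for i in inv_set}:
            raise PlantingError(
                "overlap plan yields minimal invariants beyond the planted circuits"
            )

    from .mct import mct_sets

    return net, inv_set, mct_sets(inv_set, net)


def generate_random_net(n_places: int, n_transitions: int, arc_density: float,
                        seed: int = 0, max_weight: int = 1) -> PetriNet:
    """Random bipartite net; no structural ground truth claimed.

    Each of the ``2 * n_places * n_transitions`` possible directed arcs is
    included independently with probability ``arc_density``.
    """
    if n_places < 1 or n_transitions < 1:
        raise ValueError("sizes must be >= 1")
    if not 0.0 < arc_density <= 1.0:
        raise ValueError("arc_density must be in (0, 1]")
    rng = np.random.Generator(np.random.PCG64(seed))
    places = [f"p{i}" for i in range(n_places)]
    trans = [f"t{j}" for j in range(n_transitions)]
    arcs = []
    for p in places:
        for t in trans:
            if rng.random() < arc_density:
                arcs.append(Arc(p, t, int(rng.integers(1, max_weight + 1))))
            if rng.random() < arc_density:
                arcs.append(Arc(t, p, int(rng.integers(1, max_weight + 1))))
    marking = {p: int(rng.integers(0, 3)) for p in places}
    return PetriNet(places, trans, arcs, initial_marking=marking,
                    name=f"random-{n_places}x{n_transitions}-{seed}")


def generate_invariant_vectors(k_clusters: int, per_cluster: int, dim: int,
                               noise: float = 0.0, seed: int = 0):
    """Integer vectors around ``k_clusters`` disjoint support templates.

    Returns ``(vectors, labels)``.  Each cluster owns a contiguous block of
    ``dim // k_clusters`` coordinates; members set those coordinates to 1
    and, with probability ``noise`` per coordinate, flip a coordinate
    outside the template on (overlap) or a template coordinate off.
    """
    if k_clusters < 2:
        raise ValueError("need k >= 2")
    if dim < 2 * k_clusters:
        raise ValueError("dim too small for disjoint templates")
    rng = np.random.Generator(np.random.PCG64(seed))
    block = dim // k_clusters
    X = np.zeros((k_clusters * per_cluster, dim), dtype=np.int64)
    labels = np.repeat(np.arange(k_clusters), per_cluster)
    for r, c in enumerate(labels):
        X[r, c * block:(c + 1) * block] = 1
        if noise > 0:
            flips = rng.random(dim) < noise
            X[r, flips] = 1 - X[r, flips]
            if not X[r].any():  # keep vectors non-empty
                X[r, c * block] = 1
    return X, labels
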