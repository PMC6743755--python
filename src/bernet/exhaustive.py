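"""Bounded exhaustive t-invariant enumeration (independent oracle).

Brute-force enumeration of all non-negative integer solutions of
``A @ x == 0`` with entries bounded by ``max_coeff``, reduced to the
support-minimal, gcd-canonical set.  Exponential in the number of
transitions; intended for tiny nets (m <= 7 or so) where it provides ground
truth for the elimination-based enumerator and for the synthetic-net
generator's planted-structure checks.  Deliberately shares no algorithmic
machinery with :mod:`bernet.invariants`.
"""

from __future__ import annotations

import math

import numpy as np

from .invariants import InvariantSet, TInvariant

__all__ = ["exhaustive_t_invariants"]


def exhaustive_t_invariants(A, transition_ids=None, max_coeff: int = 4) -> InvariantSet:
    """All minimal t-invariants with entries in ``0..max_coeff``.

    Complete only for nets whose minimal invariants respect the entry bound;
    on ordinary nets built from elementary circuits the bound 4 is ample.
    """
    if hasattr(A, "incidence_matrix"):
        if transition_ids is None:
            transition_ids = A.transition_ids()
        A = A.incidence_matrix()
    A = np.asarray(A, dtype=np.int64)
    n, m = A.shape
    if transition_ids is None:
        transition_ids = tuple(f"t{j}" for j in range(m))
    transition_ids = tuple(transition_ids)

    # full grid of candidate vectors, one column per candidate
    axes = np.indices((max_coeff + 1,) * m).reshape(m, -1)
    ok = ~(axes == 0).all(axis=0)
    if n:
        ok &= (A @ axes == 0).all(axis=0)
    solutions = []
    for col in np.flatnonzero(ok):
        x = tuple(int(v) for v in axes[:, col])
        g = 0
        for v in x:
            g = math.gcd(g, v)
        solutions.append(tuple(v // g for v in x))

    uniq = sorted(set(solutions))
    supports = [frozenset(j for j, v in enumerate(x) if v) for x in uniq]
    minimal = []
    for i, x in enumerate(uniq):
        if any(supports[k] < supports[i] for k in range(len(uniq)) if k != i):
            continue
        minimal.append(x)
    invs = [TInvariant(x, transition_ids) for x in minimal]
    invs.sort(key=lambda inv: (inv.support_indices, inv.vector))
    return InvariantSet(invs, transition_ids)
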