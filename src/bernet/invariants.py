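"""Minimal semi-positive t-invariant enumeration.

A t-invariant is a non-negative integer vector ``x`` over transitions with
``A @ x == 0`` where ``A`` is the incidence matrix: a recipe of firing counts
that returns the net to the marking it started from.  The *support* of an
invariant is the set of transitions with a positive entry.  We enumerate the
unique set of support-minimal, canonically scaled (gcd 1) invariants with the
classic Fourier-Motzkin / Farkas elimination on the tableau ``[A^T | I]``:
place columns are eliminated one at a time by combining rows with opposite
signs, and rows whose support strictly contains another row's support are
discarded as they arise.  All arithmetic is exact (Python integers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["TInvariant", "InvariantSet", "minimal_t_invariants", "check_coverage"]


class EliminationOverflow(RuntimeError):
    """Raised when the intermediate tableau exceeds the configured row cap."""


@dataclass(frozen=True)
class TInvariant:
    """One minimal t-invariant: integer multiplicities plus its support."""

    vector: tuple[int, ...]
    transition_ids: tuple[str, ...]

    @property
    def support(self) -> frozenset[str]:
        return frozenset(
            tid for tid, v in zip(self.transition_ids, self.vector) if v > 0
        )

    @property
    def support_indices(self) -> tuple[int, ...]:
        return tuple(j for j, v in enumerate(self.vector) if v > 0)

    def __len__(self) -> int:
        return len(self.support_indices)


@dataclass
class InvariantSet:
    invariants: list[TInvariant]
    transition_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.invariants)

    def __iter__(self):
        return iter(self.invariants)

    def __getitem__(self, i):
        return self.invariants[i]

    def vectors(self) -> np.ndarray:
        """Invariant-by-transition multiplicity matrix (N x m)."""
        return np.array([inv.vector for inv in self.invariants], dtype=np.int64)

    def supports(self) -> list[frozenset[str]]:
        return [inv.support for inv in self.invariants]

    def covered_transitions(self) -> set[str]:
        out: set[str] = set()
        for inv in self.invariants:
            out |= inv.support
        return out

    def to_frame(self):
        import pandas as pd

        rows = []
        for k, inv in enumerate(self.invariants):
            sup = sorted(inv.support_indices)
            rows.append(
                {
                    "invariant": k,
                    "support_size": len(sup),
                    "transitions": ";".join(self.transition_ids[j] for j in sup),
                    "multiplicities": ";".join(str(inv.vector[j]) for j in sup),
                }
            )
        return pd.DataFrame(rows)


def _gcd_reduce(vec: list[int]) -> list[int]:
    g = 0
    for v in vec:
        g = math.gcd(g, v)
    if g > 1:
        return [v // g for v in vec]
    return vec


def minimal_t_invariants(A, transition_ids=None, max_rows: int = 2_000_000) -> InvariantSet:
    """Enumerate all minimal semi-positive solutions of ``A @ x == 0``.

    Parameters
    ----------
    A:
        Incidence matrix (n places x m transitions), integer entries, or a
        ``PetriNet`` (its incidence matrix and transition ids are used).
    transition_ids:
        Column labels; defaults to ``t0..t{m-1}`` when ``A`` is a bare matrix.
    max_rows:
        Guard on the intermediate tableau size.  Fourier-Motzkin can blow up
        exponentially on adversarial inputs; biochemical nets stay small, but
        a clear failure beats an opaque memory exhaustion.

    Returns
    -------
    InvariantSet
        Deterministically ordered (lexicographic by support indices).
    """
    if hasattr(A, "incidence_matrix"):
        if transition_ids is None:
            transition_ids = A.transition_ids()
        A = A.incidence_matrix()
    A = np.asarray(A)
    if A.ndim != 2:
        raise ValueError("incidence matrix must be 2-dimensional")
    n, m = A.shape
    if transition_ids is None:
        transition_ids = tuple(f"t{j}" for j in range(m))
    transition_ids = tuple(transition_ids)
    if len(transition_ids) != m:
        raise ValueError("transition_ids length does not match matrix width")

    # Tableau rows: (place_part as list[int] over remaining places,
    #               inv_part as list[int] over transitions, support bitmask).
    rows: list[tuple[list[int], list[int], int]] = []
    for j in range(m):
        place_part = [int(A[i, j]) for i in range(n)]
        inv_part = [0] * m
        inv_part[j] = 1
        rows.append((place_part, inv_part, 1 << j))

    remaining = list(range(n))
    col_of = {p: k for k, p in enumerate(remaining)}

    while remaining:
        # Pick the place whose elimination creates the fewest new rows.
        best_p, best_cost = None, None
        for p in remaining:
            c = col_of[p]
            pos = sum(1 for r in rows if r[0][c] > 0)
            neg = sum(1 for r in rows if r[0][c] < 0)
            cost = pos * neg - pos - neg
            if best_cost is None or cost < best_cost:
                best_p, best_cost = p, cost
        c = col_of[best_p]

        zero_rows = [r for r in rows if r[0][c] == 0]
        pos_rows = [r for r in rows if r[0][c] > 0]
        neg_rows = [r for r in rows if r[0][c] < 0]

        new_rows = list(zero_rows)
        masks = [r[2] for r in new_rows]
        for pr in pos_rows:
            a = pr[0][c]
            for nr in neg_rows:
                b = -nr[0][c]
                g = math.gcd(a, b)
                ka, kb = b // g, a // g  # ka*pr + kb*nr cancels column c
                mask = pr[2] | nr[2]
                # Minimality pruning: drop if an existing support is a subset.
                dominated = False
                for mk in masks:
                    if mk & mask == mk and mk != mask:
                        dominated = True
                        break
                if dominated:
                    continue
                place_part = [ka * x + kb * y for x, y in zip(pr[0], nr[0])]
                inv_part = _gcd_reduce([ka * x + kb * y for x, y in zip(pr[1], nr[1])])
                new_rows.append((place_part, inv_part, mask))
                masks.append(mask)
                if len(new_rows) > max_rows:
                    raise EliminationOverflow(
                        f"tableau exceeded {max_rows} rows while eliminating place {best_p};"
                        " raise max_rows or simplify the net"
                    )
        # Full pairwise support-minimality sweep (subsets may arrive late).
        keep: list[tuple[list[int], list[int], int]] = []
        new_rows.sort(key=lambda r: bin(r[2]).count("1"))
        kept_masks: list[int] = []
        seen_inv: set[tuple[int, ...]] = set()
        for r in new_rows:
            mask = r[2]
            if any(mk & mask == mk and mk != mask for mk in kept_masks):
                continue
            key = tuple(r[1]) + tuple(r[0])
            if key in seen_inv:
                continue
            seen_inv.add(key)
            keep.append(r)
            kept_masks.append(mask)
        rows = keep
        remaining.remove(best_p)
        col_of = {p: k for k, p in enumerate(remaining)}
        for idx, r in enumerate(rows):
            pp = r[0]
            rows[idx] = ([pp[i] for i in range(len(pp)) if i != c], r[1], r[2])

    # All place columns eliminated: every surviving row is an invariant.
    result: dict[tuple[int, ...], TInvariant] = {}
    for _, inv_part, mask in rows:
        if mask == 0:
            continue
        vec = tuple(_gcd_reduce(inv_part))
        result[vec] = TInvariant(vec, transition_ids)
    invs = sorted(result.values(), key=lambda inv: (inv.support_indices, inv.vector))
    return InvariantSet(invs, transition_ids)


def check_coverage(inv_set: InvariantSet, net) -> tuple[bool, set[str]]:
    """Is every transition of ``net`` in the support of some invariant?

    Returns ``(covered, uncovered_transition_ids)``.
    """
    all_ids = set(net.transition_ids() if hasattr(net, "transition_ids") else net)
    uncovered = all_ids - inv_set.covered_transitions()
    return (not uncovered, uncovered)
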