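"""Maximal common transition (MCT) set decomposition.

Two transitions belong to the same MCT set when they occur in exactly the
same t-invariant supports — they always act together, so an MCT set is the
elementary functional building block of the invariant structure.  MCT sets
partition the transition set; singletons are called *trivial*.  Membership
is judged on supports (binary), not multiplicities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .invariants import InvariantSet

__all__ = ["MCTSet", "mct_sets"]


@dataclass(frozen=True)
class MCTSet:
    id: str
    transitions: frozenset[str]
    signature: frozenset[int]  # indices of the invariants containing the set

    @property
    def trivial(self) -> bool:
        return len(self.transitions) == 1

    def __len__(self) -> int:
        return len(self.transitions)


def mct_sets(inv_set: InvariantSet, net=None) -> list[MCTSet]:
    """Partition transitions into MCT sets from invariant supports.

    Transitions outside every support (uncovered — a warning is emitted since
    the decomposition is only meaningful on covered nets) share the empty
    signature and end up together in one class.  Ids ``m_1, m_2, ...`` are
    assigned by descending set size, ties broken by the lexicographically
    smallest member, so the numbering is deterministic for a given net.
    """
    tids = list(net.transition_ids()) if net is not None else list(inv_set.transition_ids)
    signature: dict[str, set[int]] = {tid: set() for tid in tids}
    for k, inv in enumerate(inv_set):
        for tid in inv.support:
            signature.setdefault(tid, set()).add(k)

    uncovered = [tid for tid, sig in signature.items() if not sig]
    if uncovered:
        warnings.warn(
            f"{len(uncovered)} transitions are not covered by any invariant; "
            "they form MCT classes with an empty signature",
            stacklevel=2,
        )

    groups: dict[frozenset[int], set[str]] = {}
    for tid, sig in signature.items():
        groups.setdefault(frozenset(sig), set()).add(tid)

    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))
    return [
        MCTSet(f"m_{k}", frozenset(members), sig)
        for k, (sig, members) in enumerate(ordered, start=1)
    ]


def mct_frame(sets: list[MCTSet]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "mct_id": s.id,
                "size": len(s),
                "trivial": s.trivial,
                "transitions": ";".join(sorted(s.transitions)),
                "signature_size": len(s.signature),
            }
            for s in sets
        ]
    )
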