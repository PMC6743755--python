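"""Petri net data model, firing semantics and structural property checks.

A Petri net is a weighted directed bipartite graph: *places* hold tokens
(passive components — chemical species, complexes), *transitions* move them
(active components — reactions).  The state of the system is the *marking*,
the vector of token counts over places.  A transition is enabled when every
pre-place holds at least the weight of its connecting arc; firing consumes
those tokens and produces tokens on the post-places.  Transitions without
pre-places are continuously enabled (sources); transitions without
post-places consume without producing (sinks).

Everything here is exact integer arithmetic; no floats enter the incidence
matrix or the marking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "Place",
    "Transition",
    "Arc",
    "PetriNet",
    "StructuralReport",
    "NetStructureError",
    "FiringError",
]

SCHEMA_VERSION = "bernet-net/1"


class NetStructureError(ValueError):
    """Raised when a net violates a structural well-formedness contract."""


class FiringError(RuntimeError):
    """Raised when a disabled transition is asked to fire."""


@dataclass(frozen=True)
class Place:
    id: str
    label: str = ""
    index: int = -1


@dataclass(frozen=True)
class Transition:
    id: str
    label: str = ""
    index: int = -1


@dataclass(frozen=True)
class Arc:
    """Directed arc between a place and a transition (either orientation)."""

    source: str
    target: str
    weight: int = 1


@dataclass
class StructuralReport:
    """Boolean structure flags plus conflict and boundary-transition lists.

    ``pure``: no place/transition pair connected in both directions (no read
    arcs).  ``ordinary``: all arc weights 1.  ``homogeneous``: all outgoing
    arcs of any given place carry the same weight.  ``conservative``: every
    transition produces exactly as many tokens as it consumes.  Connectivity
    is judged on the directed bipartite graph; ``connected`` means weakly
    connected.
    """

    pure: bool
    ordinary: bool
    homogeneous: bool
    connected: bool
    strongly_connected: bool
    conservative: bool
    static_conflicts: list[tuple[str, str]]
    input_transitions: list[str]
    output_transitions: list[str]

    def as_dict(self) -> dict:
        return {
            "pure": self.pure,
            "ordinary": self.ordinary,
            "homogeneous": self.homogeneous,
            "connected": self.connected,
            "strongly_connected": self.strongly_connected,
            "conservative": self.conservative,
            "n_static_conflicts": len(self.static_conflicts),
            "input_transitions": list(self.input_transitions),
            "output_transitions": list(self.output_transitions),
        }


class PetriNet:
    """Immutable-ish container for places, transitions, arcs and a marking.

    Parameters
    ----------
    places, transitions:
        Iterables of ids or of :class:`Place` / :class:`Transition`.
        Order defines the row/column indexing of the incidence matrix.
    arcs:
        Iterable of :class:`Arc` or ``(source, target[, weight])`` tuples.
    initial_marking:
        Mapping place id -> token count.  Missing places default to 0.
    """

    def __init__(self, places, transitions, arcs, initial_marking=None, name=""):
        self.name = name
        self.places: list[Place] = []
        self.transitions: list[Transition] = []
        seen: set[str] = set()
        for i, p in enumerate(places):
            if isinstance(p, str):
                p = Place(p, p)
            p = Place(p.id, p.label or p.id, i)
            if p.id in seen:
                raise NetStructureError(f"duplicate place id {p.id!r}")
            seen.add(p.id)
            self.places.append(p)
        tseen: set[str] = set()
        for j, t in enumerate(transitions):
            if isinstance(t, str):
                t = Transition(t, t)
            t = Transition(t.id, t.label or t.id, j)
            if t.id in tseen:
                raise NetStructureError(f"duplicate transition id {t.id!r}")
            if t.id in seen:
                raise NetStructureError(f"id {t.id!r} used for both a place and a transition")
            tseen.add(t.id)
            self.transitions.append(t)
        self._pidx = {p.id: p.index for p in self.places}
        self._tidx = {t.id: t.index for t in self.transitions}

        self.arcs: list[Arc] = []
        arc_keys: set[tuple[str, str]] = set()
        for a in arcs:
            if not isinstance(a, Arc):
                a = Arc(*a)
            if a.weight < 1 or int(a.weight) != a.weight:
                raise NetStructureError(f"arc {a.source}->{a.target}: weight must be a positive integer")
            s_p, t_p = a.source in self._pidx, a.target in self._pidx
            s_t, t_t = a.source in self._tidx, a.target in self._tidx
            if not ((s_p and t_t) or (s_t and t_p)):
                raise NetStructureError(
                    f"arc {a.source}->{a.target}: endpoints must be one place and one transition, both present in the net"
                )
            key = (a.source, a.target)
            if key in arc_keys:
                raise NetStructureError(f"duplicate arc {a.source}->{a.target}")
            arc_keys.add(key)
            self.arcs.append(Arc(a.source, a.target, int(a.weight)))

        n, m = len(self.places), len(self.transitions)
        self._pre = np.zeros((n, m), dtype=np.int64)
        self._post = np.zeros((n, m), dtype=np.int64)
        for a in self.arcs:
            if a.source in self._pidx:  # place -> transition: consumption
                self._pre[self._pidx[a.source], self._tidx[a.target]] = a.weight
            else:  # transition -> place: production
                self._post[self._pidx[a.target], self._tidx[a.source]] = a.weight

        self.initial_marking = np.zeros(n, dtype=np.int64)
        if initial_marking:
            for pid, k in dict(initial_marking).items():
                if pid not in self._pidx:
                    raise NetStructureError(f"initial marking references unknown place {pid!r}")
                if k < 0:
                    raise NetStructureError(f"negative initial marking on {pid!r}")
                self.initial_marking[self._pidx[pid]] = int(k)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_places(self) -> int:
        return len(self.places)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def place_index(self, pid: str) -> int:
        return self._pidx[pid]

    def transition_index(self, tid: str) -> int:
        return self._tidx[tid]

    def transition_ids(self) -> list[str]:
        return [t.id for t in self.transitions]

    def place_ids(self) -> list[str]:
        return [p.id for p in self.places]

    def pre_matrix(self) -> np.ndarray:
        """n x m matrix of arc weights place -> transition (consumption)."""
        return self._pre.copy()

    def post_matrix(self) -> np.ndarray:
        """n x m matrix of arc weights transition -> place (production)."""
        return self._post.copy()

    def incidence_matrix(self) -> np.ndarray:
        """Incidence matrix A = post - pre (token change of one firing)."""
        return self._post - self._pre

    # -- token game --------------------------------------------------------

    def _check_marking(self, marking: np.ndarray) -> np.ndarray:
        marking = np.asarray(marking, dtype=np.int64)
        if marking.shape != (self.n_places,):
            raise ValueError(
                f"marking has length {marking.shape}, net has {self.n_places} places"
            )
        return marking

    def enabled(self, marking) -> set[str]:
        """Ids of transitions enabled under ``marking``.

        Transitions with an empty pre-set are continuously enabled.
        """
        marking = self._check_marking(marking)
        ok = (marking[:, None] >= self._pre).all(axis=0)
        return {t.id for t in self.transitions if ok[t.index]}

    def is_enabled(self, marking, tid: str) -> bool:
        marking = self._check_marking(marking)
        j = self._tidx[tid]
        return bool((marking >= self._pre[:, j]).all())

    def fire(self, marking, tid: str) -> np.ndarray:
        """Fire ``tid`` and return the successor marking (input unchanged)."""
        marking = self._check_marking(marking)
        j = self._tidx[tid]
        if not (marking >= self._pre[:, j]).all():
            raise FiringError(f"transition {tid!r} is not enabled under the given marking")
        return marking - self._pre[:, j] + self._post[:, j]

    # -- structure ---------------------------------------------------------

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from((p.id for p in self.places), kind="place")
        g.add_nodes_from((t.id for t in self.transitions), kind="transition")
        g.add_edges_from((a.source, a.target, {"weight": a.weight}) for a in self.arcs)
        return g

    def structural_report(self) -> StructuralReport:
        pre, post = self._pre, self._post
        pure = not np.any((pre > 0) & (post > 0))
        weights = np.array([a.weight for a in self.arcs], dtype=np.int64)
        ordinary = bool(weights.size == 0 or (weights == 1).all())
        homogeneous = True
        for i in range(self.n_places):
            out = pre[i][pre[i] > 0]
            if out.size and not (out == out[0]).all():
                homogeneous = False
                break
        g = self.to_digraph()
        connected = bool(g.number_of_nodes() and nx.is_weakly_connected(g))
        strongly_connected = bool(g.number_of_nodes() and nx.is_strongly_connected(g))
        conservative = bool((pre.sum(axis=0) == post.sum(axis=0)).all())
        conflicts: list[tuple[str, str]] = []
        for i in range(self.n_places):
            sharers = np.flatnonzero(pre[i] > 0)
            for a_ in range(len(sharers)):
                for b_ in range(a_ + 1, len(sharers)):
                    conflicts.append(
                        (self.transitions[sharers[a_]].id, self.transitions[sharers[b_]].id)
                    )
        conflicts = sorted(set(conflicts))
        inputs = [t.id for t in self.transitions if not pre[:, t.index].any()]
        outputs = [t.id for t in self.transitions if not post[:, t.index].any()]
        return StructuralReport(
            pure=bool(pure),
            ordinary=ordinary,
            homogeneous=homogeneous,
            connected=connected,
            strongly_connected=strongly_connected,
            conservative=conservative,
            static_conflicts=conflicts,
            input_transitions=inputs,
            output_transitions=outputs,
        )

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA_VERSION,
            "name": self.name,
            "places": [{"id": p.id, "label": p.label} for p in self.places],
            "transitions": [{"id": t.id, "label": t.label} for t in self.transitions],
            "arcs": [
                {"source": a.source, "target": a.target, "weight": a.weight} for a in self.arcs
            ],
            "initial_marking": {
                p.id: int(k) for p, k in zip(self.places, self.initial_marking) if k
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PetriNet":
        return cls(
            places=[Place(p["id"], p.get("label", "")) for p in d["places"]],
            transitions=[Transition(t["id"], t.get("label", "")) for t in d["transitions"]],
            arcs=[Arc(a["source"], a["target"], a.get("weight", 1)) for a in d["arcs"]],
            initial_marking=d.get("initial_marking", {}),
            name=d.get("name", ""),
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "PetriNet":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                d = json.loads(text)
            else:
                with open(text) as fh:
                    d = json.load(fh)
        return cls.from_dict(d)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PetriNet):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def __repr__(self) -> str:
        return (
            f"<PetriNet {self.name!r}: {self.n_places} places, "
            f"{self.n_transitions} transitions, {len(self.arcs)} arcs>"
        )
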