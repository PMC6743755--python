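"""End-to-end analysis pipeline: structure -> invariants -> MCT ->
clustering -> simulation -> knockout battery."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

from .invariants import check_coverage, minimal_t_invariants
from .mct import mct_sets
from .clustering import model_selection
from .simulate import SimulationConfig, knockout, path_report, simulate
from . import ber

logger = logging.getLogger("bernet")

__all__ = ["AnalysisBundle", "run_full_pipeline", "load_net", "KNOCKOUT_BATTERY"]

#: The systematic knockout battery: critical transitions per synthesis
#: sub-path (single and combined knockouts).
KNOCKOUT_BATTERY = (
    ("Path 1 (PNKP 3'P removal)", ("t_90",)),
    ("Path 2 partial (Polb recruitment)", ("t_62",)),
    ("Path 2 complete (Polb recruitment + 5'dRP removal)", ("t_62", "t_96")),
    ("Paths 3+4 (PCNA joins Polb complex)", ("t_102",)),
    ("Path 3 (Polb LP synthesis)", ("t_103",)),
    ("Path 4 (FEN1 5'dRP cleavage)", ("t_100",)),
    ("Paths 5+6 (Pold and Pole displacement)", ("t_60", "t_61")),
    ("Path 5 (Pold displacement)", ("t_60",)),
    ("Path 6 (Pole displacement)", ("t_61",)),
)


@dataclass
class AnalysisBundle:
    net: object
    structural: object
    invariants: object
    covered: bool
    uncovered: set
    mct: list
    clustering: object = None
    score_table: object = None
    simulation: object = None
    paths: object = None
    knockouts: list = field(default_factory=list)

    def summary(self) -> dict:
        out = {
            "places": self.net.n_places,
            "transitions": self.net.n_transitions,
            "structure": self.structural.as_dict(),
            "n_invariants": len(self.invariants),
            "covered": self.covered,
            "n_mct": len(self.mct),
            "n_mct_nontrivial": sum(1 for s in self.mct if not s.trivial),
            "n_mct_trivial": sum(1 for s in self.mct if s.trivial),
        }
        if self.clustering is not None:
            out["clustering"] = {
                "distance": self.clustering.distance,
                "linkage": self.clustering.linkage,
                "k": self.clustering.k,
                "n_singletons": self.clustering.n_singletons,
                "sizes": sorted(self.clustering.sizes),
                "ch": self.clustering.ch,
                "mss": self.clustering.mss,
            }
        if self.simulation is not None:
            out["simulation"] = {
                row["path"]: row["mean_frequency"]
                for row in self.paths.to_dict("records")
            } if self.paths is not None else {}
        if self.knockouts:
            out["knockouts"] = {
                ko.label: ko.result.frequency(ber.SUCCESS_MARKER) for ko in self.knockouts
            }
        return out

    def save_summary(self, path):
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=1, default=str)


def cluster_composition(invariants, mct, clustering) -> dict:
    """Per-cluster report: member invariants, their transitions, and the
    MCT sets each cluster touches (the module-level view of a t-cluster)."""
    by_transition = {}
    for s in mct:
        for tid in s.transitions:
            by_transition[tid] = s.id
    report = {}
    for c in range(clustering.k):
        members = [i for i, lab in enumerate(clustering.labels) if lab == c]
        transitions = sorted(set().union(*(invariants[i].support for i in members)))
        report[f"cluster_{c + 1}"] = {
            "size": len(members),
            "invariants": members,
            "transitions": transitions,
            "mct_sets": sorted(
                {by_transition[t] for t in transitions if t in by_transition},
                key=lambda m: int(m.split("_")[1]),
            ),
        }
    return report


def load_net(path, fmt: str | None = None):
    """Load a net from native JSON or SBML (``fmt`` inferred from suffix)."""
    from .net import PetriNet

    path = str(path)
    if fmt is None:
        fmt = "sbml" if path.endswith((".xml", ".sbml")) else "json"
    if fmt == "json":
        return PetriNet.from_json(path)
    if fmt == "sbml":
        from .io_sbml import read_sbml

        return read_sbml(path)
    raise ValueError(f"unknown net format {fmt!r} (expected 'json' or 'sbml')")


def run_full_pipeline(
    net=None,
    seed: int = 0,
    cluster: bool = True,
    simulate_steps: int = 20_000,
    replicates: int = 20,
    knockouts: bool = True,
    binary_vectors: bool = True,
) -> AnalysisBundle:
    """Run every analysis stage on ``net`` (default: the BER fixture).

    Stages log their timing; a failing stage raises with the stage name in
    the message, and everything computed so far is on the returned bundle
    (exceptions carry the partial bundle as ``exc.bundle``).
    """
    if net is None:
        net, _ = ber.build_ber_net()
    bundle = None
    stage = "structural analysis"
    try:
        t0 = time.time()
        report = net.structural_report()
        logger.info("structure done in %.1fs", time.time() - t0)

        stage = "invariant enumeration"
        inv = minimal_t_invariants(net)
        covered, uncovered = check_coverage(inv, net)
        logger.info("%d invariants, covered=%s", len(inv), covered)

        stage = "MCT decomposition"
        sets = mct_sets(inv, net)
        bundle = AnalysisBundle(net, report, inv, covered, uncovered, sets)

        if cluster and len(inv) >= 3:
            stage = "invariant clustering"
            best, table = model_selection(inv.vectors(), binary=binary_vectors)
            bundle.clustering, bundle.score_table = best, table
            logger.info("best clustering %s+%s k=%d", best.distance, best.linkage, best.k)

        if simulate_steps:
            stage = "baseline simulation"
            config = SimulationConfig(steps=simulate_steps, replicates=replicates, seed=seed)
            bundle.simulation = simulate(net, config)
            marker_ids = set(ber.PATH_MARKERS.values())
            if marker_ids <= set(net.transition_ids()):
                bundle.paths = path_report(bundle.simulation, ber.PATH_MARKERS)
            if knockouts:
                stage = "knockout battery"
                known = set(net.transition_ids())
                for label, disabled in KNOCKOUT_BATTERY:
                    if not set(disabled) <= known:
                        continue
                    bundle.knockouts.append(
                        knockout(net, disabled, config, baseline=bundle.simulation,
                                 label=label)
                    )
        return bundle
    except Exception as exc:
        exc.bundle = bundle
        raise type(exc)(f"pipeline stage '{stage}' failed: {exc}").with_traceback(
            exc.__traceback__
        ) from None
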