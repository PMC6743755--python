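"""Stochastic token-game simulation and in-silico knockouts.

The firing scheme is the randomised maximal-step game used for qualitative
nets: in every step each enabled transition independently joins the firing
list with probability ``fire_probability`` (default 50%); the list is then
visited in a random order, and each listed transition fires only if it is
still enabled when its turn comes (competing transitions can steal tokens
from each other within a step).  A transition therefore fires at most once
per step, and its *firing frequency* — firings divided by steps — lies in
[0, 1].

Randomness is drawn from numpy's PCG64 generator; replicate ``r`` of a run
with seed ``s`` uses ``PCG64(s + r)``, so results are reproducible
bit-for-bit.  Per step, one uniform pair is drawn for every transition in
index order: the first decides list membership, the second is the sort key
for the visiting order (ascending, ties by transition index).  The hot loop
is compiled with numba when available and falls back to the identical pure
Python code path otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "KnockoutExperiment",
    "simulate",
    "knockout",
    "path_report",
]


def _step_core(pre_ptr, pre_place, pre_w, post_ptr, post_place, post_w,
               marking, disabled, U, p, counts):
    """Run ``U.shape[0]`` steps in place.  One uniform pair per transition."""
    n_steps = U.shape[0]
    m = U.shape[1]
    cand = np.empty(m, dtype=np.int64)
    keys = np.empty(m, dtype=np.float64)
    for s in range(n_steps):
        nc = 0
        for j in range(m):
            if disabled[j]:
                continue
            ok = True
            for a in range(pre_ptr[j], pre_ptr[j + 1]):
                if marking[pre_place[a]] < pre_w[a]:
                    ok = False
                    break
            if ok and U[s, j, 0] < p:
                cand[nc] = j
                keys[nc] = U[s, j, 1]
                nc += 1
        if nc == 0:
            continue
        order = np.argsort(keys[:nc], kind="mergesort")
        for oi in range(nc):
            j = cand[order[oi]]
            ok = True
            for a in range(pre_ptr[j], pre_ptr[j + 1]):
                if marking[pre_place[a]] < pre_w[a]:
                    ok = False
                    break
            if not ok:
                continue
            for a in range(pre_ptr[j], pre_ptr[j + 1]):
                marking[pre_place[a]] -= pre_w[a]
            for a in range(post_ptr[j], post_ptr[j + 1]):
                marking[post_place[a]] += post_w[a]
            counts[j] += 1


try:  # pragma: no cover - exercised implicitly
    import numba

    _step_core_fast = numba.njit(cache=True)(_step_core)
except Exception:  # pragma: no cover
    _step_core_fast = _step_core


@dataclass
class SimulationConfig:
    steps: int = 20_000
    replicates: int = 20
    fire_probability: float = 0.5
    seed: int = 0
    disabled_transitions: frozenset[str] = field(default_factory=frozenset)
    tracked_transitions: frozenset[str] | None = None  # None = all

    def __post_init__(self):
        if self.steps < 1 or self.replicates < 1:
            raise ValueError("steps and replicates must be >= 1")
        if not 0.0 < self.fire_probability <= 1.0:
            raise ValueError("fire_probability must be in (0, 1]")


@dataclass
class SimulationResult:
    transition_ids: tuple[str, ...]
    firing_counts: np.ndarray      # (replicates, m)
    steps: int
    final_markings: np.ndarray     # (replicates, n)
    config: SimulationConfig

    @property
    def frequencies(self) -> np.ndarray:
        """Per-replicate firing frequencies, shape (replicates, m)."""
        return self.firing_counts / self.steps

    def frequency(self, tid: str) -> float:
        return float(self.frequencies[:, self.transition_ids.index(tid)].mean())

    def frequency_sd(self, tid: str) -> float:
        if self.firing_counts.shape[0] < 2:
            return 0.0
        return float(self.frequencies[:, self.transition_ids.index(tid)].std(ddof=1))

    def replicate_frequencies(self, tid: str) -> np.ndarray:
        return self.frequencies[:, self.transition_ids.index(tid)]

    def to_frame(self):
        import pandas as pd

        f = self.frequencies
        return pd.DataFrame(
            {
                "transition": self.transition_ids,
                "mean_frequency": f.mean(axis=0),
                "sd_frequency": f.std(axis=0, ddof=1) if f.shape[0] > 1 else 0.0,
                "total_firings": self.firing_counts.sum(axis=0),
            }
        )


def _csr(mat: np.ndarray):
    n, m = mat.shape
    ptr = np.zeros(m + 1, dtype=np.int64)
    places, weights = [], []
    for j in range(m):
        rows = np.flatnonzero(mat[:, j])
        ptr[j + 1] = ptr[j] + len(rows)
        places.extend(rows)
        weights.extend(mat[rows, j])
    return ptr, np.array(places, dtype=np.int64), np.array(weights, dtype=np.int64)


def simulate(net, config: SimulationConfig, chunk: int = 2000) -> SimulationResult:
    """Run the random token game on ``net`` under ``config``."""
    m = net.n_transitions
    tids = tuple(net.transition_ids())
    unknown = set(config.disabled_transitions) - set(tids)
    if unknown:
        raise ValueError(
            f"unknown disabled transitions {sorted(unknown)}; valid ids are the net's transitions"
        )
    disabled = np.zeros(m, dtype=np.bool_)
    for tid in config.disabled_transitions:
        disabled[net.transition_index(tid)] = True

    pre_ptr, pre_place, pre_w = _csr(net.pre_matrix())
    post_ptr, post_place, post_w = _csr(net.post_matrix())

    counts = np.zeros((config.replicates, m), dtype=np.int64)
    finals = np.zeros((config.replicates, net.n_places), dtype=np.int64)
    for r in range(config.replicates):
        rng = np.random.Generator(np.random.PCG64(config.seed + r))
        marking = net.initial_marking.copy()
        done = 0
        while done < config.steps:
            width = min(chunk, config.steps - done)
            U = rng.random((width, m, 2))
            _step_core_fast(
                pre_ptr, pre_place, pre_w, post_ptr, post_place, post_w,
                marking, disabled, U, config.fire_probability, counts[r],
            )
            done += width
        finals[r] = marking
    return SimulationResult(tids, counts, config.steps, finals, config)


@dataclass
class KnockoutExperiment:
    label: str
    disabled: frozenset[str]
    result: SimulationResult
    baseline: SimulationResult
    deltas: dict[str, float]
    welch_p: dict[str, float]

    def summary(self, tracked=None) -> dict:
        tracked = tracked or sorted(self.deltas)
        return {
            tid: {
                "baseline": self.baseline.frequency(tid),
                "knockout": self.result.frequency(tid),
                "delta": self.deltas[tid],
                "welch_p": self.welch_p[tid],
            }
            for tid in tracked
        }


def knockout(net, disabled, config: SimulationConfig,
             baseline: SimulationResult | None = None,
             label: str = "") -> KnockoutExperiment:
    """Simulate with ``disabled`` transitions silenced, against a baseline.

    Baseline and knockout runs use matched replicate seeds so per-replicate
    differences are paired.  For every tracked transition the mean frequency
    change and a two-sided Welch test p-value across replicates are reported
    (reported, not enforced — "no impact" judgements are the caller's).
    """
    from dataclasses import replace

    from scipy import stats

    disabled = frozenset(disabled)
    unknown = disabled - set(net.transition_ids())
    if unknown:
        raise ValueError(
            f"unknown transitions {sorted(unknown)}; valid ids include e.g. "
            f"{net.transition_ids()[:5]}..."
        )
    if baseline is None:
        baseline = simulate(net, replace(config, disabled_transitions=frozenset()))
    ko = simulate(net, replace(config, disabled_transitions=disabled))
    tracked = config.tracked_transitions or frozenset(net.transition_ids())
    deltas, pvals = {}, {}
    for tid in sorted(tracked):
        fb = baseline.replicate_frequencies(tid)
        fk = ko.replicate_frequencies(tid)
        deltas[tid] = float(fk.mean() - fb.mean())
        if np.allclose(fb, fb[0]) and np.allclose(fk, fk[0]):
            pvals[tid] = 1.0 if fb[0] == fk[0] else 0.0
        else:
            pvals[tid] = float(stats.ttest_ind(fk, fb, equal_var=False).pvalue)
    return KnockoutExperiment(
        label=label or "+".join(sorted(disabled)),
        disabled=disabled,
        result=ko,
        baseline=baseline,
        deltas=deltas,
        welch_p=pvals,
    )


def path_report(result: SimulationResult, markers: dict[str, str]):
    """Mean/sd firing frequency for each named path-marker transition.

    ``markers`` maps a path label to the id of the transition whose firing
    completes that repair route.
    """
    import pandas as pd

    missing = [tid for tid in markers.values() if tid not in result.transition_ids]
    if missing:
        raise ValueError(f"marker transitions {missing} absent from the simulated net")
    rows = [
        {
            "path": label,
            "transition": tid,
            "mean_frequency": result.frequency(tid),
            "sd_frequency": result.frequency_sd(tid),
        }
        for label, tid in markers.items()
    ]
    return pd.DataFrame(rows)
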