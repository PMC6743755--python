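"""Straightforward reference implementation of the random token game.

Kept deliberately naive and independent of :mod:`bernet.simulate`: markings
are dicts, enabledness is an arc-by-arc scan, and the per-step semantics
follow the documented draw order (one uniform pair per transition in index
order; candidates visited by ascending sort key).  Used to cross-check the
production engine transition-for-transition.
"""

import numpy as np


def simulate_reference(net, steps, seed, p=0.5, disabled=()):
    rng = np.random.Generator(np.random.PCG64(seed))
    marking = {pl.id: int(tok) for pl, tok in zip(net.places, net.initial_marking)}
    pre = {t.id: [] for t in net.transitions}
    post = {t.id: [] for t in net.transitions}
    for a in net.arcs:
        if a.source in marking:
            pre[a.target].append((a.source, a.weight))
        else:
            post[a.source].append((a.target, a.weight))
    tids = [t.id for t in net.transitions]
    counts = {t: 0 for t in tids}

    def enabled(tid):
        return all(marking[p_] >= w for p_, w in pre[tid])

    for _ in range(steps):
        draws = rng.random((len(tids), 2))
        candidates = []
        for j, tid in enumerate(tids):
            if tid in disabled:
                continue
            if enabled(tid) and draws[j, 0] < p:
                candidates.append((draws[j, 1], j, tid))
        candidates.sort()
        for _, _, tid in candidates:
            if not enabled(tid):
                continue
            for p_, w in pre[tid]:
                marking[p_] -= w
            for p_, w in post[tid]:
                marking[p_] += w
            counts[tid] += 1
    return counts, marking
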