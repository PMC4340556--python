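import numpy as np
import pytest

from afsim import ModelConfig, generate_substrate


@pytest.fixture
def paper_config():
    """The headline parameter set: L=200, tau=50, delta=eps=0.05, T=220."""
    return ModelConfig()


@pytest.fixture
def small_substrate():
    cfg = ModelConfig(L=20, nu=0.3, delta=0.1, epsilon=0.0, tau=6, T=40, seed=11)
    return generate_substrate(cfg)


def naive_run(substrate, n_steps, initial_counters=None, t0=0, pace=True,
              forced_failures=None):
    """Plain-loop reference implementation of the synchronous update rule.

    Written independently of the vectorised dynamics: explicit neighbour
    loops over the raw edge map.  ``forced_failures`` maps (t, y, x) ->
    True for dysfunctional-cell trials that must fail; all other trials
    succeed (i.e. this oracle covers epsilon = 0 and epsilon = 1 exactly,
    plus scripted block events).  Returns the list of counter grids after
    each step.
    """
    cfg = substrate.config
    tau, T = cfg.tau, cfg.T
    exc = tau + 1
    R, C = substrate.shape
    edges = substrate.vertical_edges
    dysf = substrate.dysfunctional
    abl = substrate.ablated
    cnt = (np.zeros((R, C), dtype=int) if initial_counters is None
           else np.array(initial_counters, dtype=int))
    eps_all_fail = cfg.epsilon >= 1.0
    forced_failures = forced_failures or {}
    t = t0
    history = []
    for _ in range(n_steps):
        old = cnt.copy()
        new = cnt.copy()
        for y in range(R):
            for x in range(C):
                if new[y, x] > 0:
                    new[y, x] -= 1
        for y in range(R):
            for x in range(C):
                if old[y, x] != 0 or abl[y, x]:
                    continue
                stimulated = False
                if x > 0 and old[y, x - 1] == exc:
                    stimulated = True
                if x < C - 1 and old[y, x + 1] == exc:
                    stimulated = True
                if edges[y, x] and old[(y + 1) % R, x] == exc:
                    stimulated = True
                if edges[(y - 1) % R, x] and old[(y - 1) % R, x] == exc:
                    stimulated = True
                if not stimulated:
                    continue
                if dysf[y, x]:
                    if eps_all_fail or forced_failures.get((t, y, x), False):
                        continue
                new[y, x] = exc
        if pace and t % T == 0:
            for y in range(R):
                if old[y, 0] == 0 and not abl[y, 0]:
                    new[y, 0] = exc
        cnt = new
        t += 1
        history.append(cnt.copy())
    return history
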