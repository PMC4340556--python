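"""Deterministic hand-built substrates for tests and worked examples.

Three kinds are available through :func:`make_fixture`:

``planar``
    Fully coupled sheet (nu = 1) without dysfunction: regular planar
    wavefronts for any pacing.

``toy_circuit``
    The minimal two-cable reentry motif on a 4-row strip: a dysfunctional
    cell on the lower cable, a transverse connection ``ell`` cells to its
    right, and a second connection immediately to its left closing the
    circuit.  :func:`toy_block_state` prepares the state just after the
    dysfunctional cell has blocked an antegrade front, from which the
    dynamics are fully deterministic (epsilon = 0): the retrograde wave
    re-excites the tissue and the circuit sustains iff ell >= tau/2.

``critical_one``
    An L x L sheet that is fully coupled except for one engineered
    critical region: a single dysfunctional cell at (x_d, y0) whose row
    has no incident transverse edges for the next ``ell`` columns.  The
    scanner finds exactly this one region, and with epsilon > 0 paced
    runs spontaneously develop a rotor there after an epsilon-failure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import TissueState, excited_value
from .substrate import ModelConfig, Substrate

__all__ = ["ToyGeometry", "make_fixture", "toy_geometry", "toy_block_state"]

_TOY_XD = 3        # column of the dysfunctional cell
_TOY_TOP = 1       # upper cable row
_TOY_BOT = 2       # lower cable row (holds the dysfunctional cell)


@dataclass(frozen=True)
class ToyGeometry:
    """Cell coordinates of the toy two-cable circuit."""

    x_d: int      # dysfunctional cell column (lower cable)
    x_conn: int   # column of the right transverse connection
    x_left: int   # column of the left transverse connection
    y_top: int
    y_bot: int
    n_rows: int
    n_cols: int


def toy_geometry(ell: int) -> ToyGeometry:
    if ell < 1:
        raise ValueError(f"ell must be >= 1, got {ell}")
    return ToyGeometry(
        x_d=_TOY_XD,
        x_conn=_TOY_XD + ell,
        x_left=_TOY_XD - 1,
        y_top=_TOY_TOP,
        y_bot=_TOY_BOT,
        n_rows=4,
        n_cols=_TOY_XD + ell + 4,
    )


def _toy_circuit(ell: int, tau: int, seed: int = 0) -> Substrate:
    geo = toy_geometry(ell)
    edges = np.zeros((geo.n_rows, geo.n_cols), dtype=bool)
    edges[geo.y_top, geo.x_conn] = True   # couples rows y_top and y_bot
    edges[geo.y_top, geo.x_left] = True
    dysf = np.zeros_like(edges)
    dysf[geo.y_bot, geo.x_d] = True
    config = ModelConfig(
        L=geo.n_cols,
        nu=0.0,
        delta=1.0 / edges.size,
        epsilon=0.0,
        tau=tau,
        T=2**30,  # effectively unpaced beyond t = 0
        seed=seed,
    )
    return Substrate(config=config, vertical_edges=edges, dysfunctional=dysf)


def toy_block_state(substrate: Substrate, ell: int) -> TissueState:
    """State of the toy circuit just after a conduction block.

    The antegrade front has reached the dysfunctional cell's column: the
    upper-cable cell at x_d is excited, the wake behind it (both cables)
    is graded refractory, and the lower cable from x_d rightwards is
    resting because the dysfunctional cell failed to fire.  Clock starts
    at t = 1 so no pacemaker beat interferes.
    """
    geo = toy_geometry(ell)
    tau = substrate.config.tau
    exc = excited_value(tau)
    counters = np.zeros(substrate.shape, dtype=np.int16)
    counters[geo.y_top, geo.x_d] = exc
    for x in range(geo.x_d):
        counters[geo.y_top, x] = max(exc - (geo.x_d - x), 0)
        counters[geo.y_bot, x] = max(exc - (geo.x_d - x), 0)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=substrate.seed, spawn_key=(1,))
    )
    return TissueState(counters=counters, t=1, rng=rng)


def _planar(L: int = 60, tau: int = 50, T: int = 220, seed: int = 0) -> Substrate:
    config = ModelConfig(L=L, nu=1.0, delta=0.0, epsilon=0.05, tau=tau, T=T, seed=seed)
    ones = np.ones((L, L), dtype=bool)
    return Substrate(config=config, vertical_edges=ones, dysfunctional=np.zeros_like(ones))


def _critical_one(
    L: int = 60,
    tau: int = 20,
    ell: int | None = None,
    x_d: int | None = None,
    T: int = 220,
    epsilon: float = 0.05,
    seed: int = 0,
) -> Substrate:
    if ell is None:
        ell = tau // 2 + 5
    if x_d is None:
        x_d = min(L // 2, L - ell - 5)
    if not (1 <= x_d and x_d + ell < L):
        raise ValueError(
            f"critical region (x_d={x_d}, ell={ell}) does not fit in L={L}"
        )
    y0 = L // 2
    edges = np.ones((L, L), dtype=bool)
    # isolate row y0 over [x_d, x_d + ell): no incident transverse edges
    edges[y0, x_d : x_d + ell] = False          # y0 <-> y0+1
    edges[y0 - 1, x_d : x_d + ell] = False      # y0-1 <-> y0
    dysf = np.zeros_like(edges)
    dysf[y0, x_d] = True
    config = ModelConfig(
        L=L, nu=1.0, delta=1.0 / (L * L), epsilon=epsilon, tau=tau, T=T, seed=seed
    )
    return Substrate(config=config, vertical_edges=edges, dysfunctional=dysf)


_KINDS = {
    "planar": _planar,
    "toy_circuit": _toy_circuit,
    "critical_one": _critical_one,
}


def make_fixture(kind: str, **params) -> Substrate:
    """Build a deterministic named substrate (see module docstring)."""
    try:
        builder = _KINDS[kind]
    except KeyError:
        raise ValueError(
            f"unknown fixture kind {kind!r}; expected one of {sorted(_KINDS)}"
        ) from None
    return builder(**params)
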