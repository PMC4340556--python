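"""Anisotropic cable substrate: parameters, generation, physical-unit conversion.

The tissue is a 2D sheet of longitudinal cables of single-cell thickness.
Cells are always coupled to their longitudinal (horizontal) neighbours;
each of the L x L candidate transverse (vertical) edges between a cell
(x, y) and the cell (x, (y+1) mod L) is present independently with
probability ``nu``.  A fraction ``delta`` of cells is dysfunctional and
fails to respond to a stimulus with probability ``epsilon``.  Boundary
conditions are periodic vertically (cylinder) and open horizontally; the
column x = 0 holds the pacemaker cells.

Once generated a substrate is fixed; the only permitted modification is
lesioning, which returns a copy (see :func:`afsim.dynamics.apply_lesion`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelConfig",
    "PhysicalParams",
    "Substrate",
    "coarse_grain_nu",
    "model_config_from_physical",
    "generate_substrate",
]


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ModelConfig:
    """Dimensionless model parameters.

    Parameters
    ----------
    L : int
        Lattice side length in cells (L x L sheet), >= 2.
    nu : float
        Probability that any given transverse edge is present.
    delta : float
        Fraction of dysfunctional cells.
    epsilon : float
        Probability that a stimulated dysfunctional cell fails to excite
        (one independent trial per cell per step).
    tau : int
        Refractory period in time steps: after its single excited step a
        cell is unexcitable for exactly ``tau`` further steps.
    T : int
        Pacing period in time steps; pacemaker cells self-excite whenever
        t = 0 (mod T) and they are resting.
    seed : int
        Seed for all randomness derived from this configuration.
    """

    L: int = 200
    nu: float = 0.18
    delta: float = 0.05
    epsilon: float = 0.05
    tau: int = 50
    T: int = 220
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.L) != self.L or self.L < 2:
            raise ValueError(f"L must be an integer >= 2, got {self.L!r}")
        _check_prob("nu", self.nu)
        _check_prob("delta", self.delta)
        _check_prob("epsilon", self.epsilon)
        if int(self.tau) != self.tau or self.tau < 1:
            raise ValueError(f"tau must be an integer >= 1, got {self.tau!r}")
        if int(self.T) != self.T or self.T < 1:
            raise ValueError(f"T must be an integer >= 1, got {self.T!r}")
        if int(self.seed) != self.seed:
            raise ValueError(f"seed must be an integer, got {self.seed!r}")


@dataclass(frozen=True)
class PhysicalParams:
    """Tissue-scale quantities in physical units.

    Lengths in micrometres and centimetres, times in milliseconds.  The
    defaults are the atrial values: myocytes of length dx = 100 um and
    diameter dy = 20 um, depolarisation time dt = 0.6 ms, a sheet of area
    L_phys^2 = 20 cm^2, refractory period 150 ms and sinus pacing period
    660 ms.  ``b`` is the coarse-graining factor (cells per lattice unit).

    The longitudinal conduction velocity is fixed by geometry,
    theta_x = dx/dt (um/ms), ~0.17 m/s for the defaults.
    """

    dx: float = 100.0        # cell length, um
    dy: float = 20.0         # cell diameter, um
    dt: float = 0.6          # depolarisation time, ms
    L_phys: float = math.sqrt(20.0)   # sheet side, cm
    tau_phys: float = 150.0  # refractory period, ms
    T_phys: float = 660.0    # pacing period, ms
    b: int = 5               # coarse-graining factor

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dt", "L_phys", "tau_phys", "T_phys"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)!r}")
        if int(self.b) != self.b or self.b < 1:
            raise ValueError(f"b must be a positive integer, got {self.b!r}")

    @property
    def theta_x(self) -> float:
        """Longitudinal conduction velocity, um/ms (= dx/dt identically)."""
        return self.dx / self.dt


def coarse_grain_nu(nu_fine: float, b: int) -> float:
    """Transverse-coupling probability after merging ``b`` cells per unit.

    A block of b cells has at least one vertical connection with
    probability 1 - (1 - nu_fine)**b.
    """
    _check_prob("nu_fine", nu_fine)
    if int(b) != b or b < 1:
        raise ValueError(f"b must be a positive integer, got {b!r}")
    return -math.expm1(b * math.log1p(-nu_fine)) if nu_fine < 1.0 else 1.0


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def model_config_from_physical(
    phys: PhysicalParams,
    nu: float,
    delta: float,
    epsilon: float,
    seed: int = 0,
) -> ModelConfig:
    """Translate tissue-scale parameters into a dimensionless ModelConfig.

    The L x L grid tiles the sheet with cells of pitch b*dx longitudinally
    and b*dy transversally, so the side length in lattice units is set by
    the geometric-mean pitch::

        L = round(L_phys / (b * sqrt(dx * dy)))

    which preserves the cell count L^2 = L_phys^2 / (b^2 dx dy) (2000
    dysfunctional cells at delta = 0.05 for the defaults).  Times rescale
    by b*dt: tau = round(tau_phys/(b dt)), T = round(T_phys/(b dt)).

    ``nu`` must already be the coarse-grained coupling probability; apply
    :func:`coarse_grain_nu` first when starting from the fine-scale value.
    """
    pitch_um = phys.b * math.sqrt(phys.dx * phys.dy)
    L = _round_half_away(phys.L_phys * 1e4 / pitch_um)
    tau = _round_half_away(phys.tau_phys / (phys.b * phys.dt))
    T = _round_half_away(phys.T_phys / (phys.b * phys.dt))
    if L < 2:
        raise ValueError(f"converted L must be >= 2, got {L}")
    if tau < 1:
        raise ValueError(f"converted tau must be >= 1, got {tau}")
    if T < 1:
        raise ValueError(f"converted T must be >= 1, got {T}")
    return ModelConfig(L=L, nu=nu, delta=delta, epsilon=epsilon, tau=tau, T=T, seed=seed)


def _locked(arr: np.ndarray) -> np.ndarray:
    out = np.ascontiguousarray(arr, dtype=bool)
    out.setflags(write=False)
    return out


@dataclass(frozen=True)
class Substrate:
    """Fixed coupling topology of one tissue realisation.

    ``vertical_edges[y, x]`` marks a transverse coupling between cell
    (x, y) and cell (x, (y+1) mod n_rows).  Horizontal couplings are
    implicit: always present between (x, y) and (x+1, y), absent across
    the open left/right boundaries.  Arrays are row-major (y, x) and are
    locked read-only after construction; lesioning returns a copy.

    Generated substrates are square (config.L x config.L); hand-built
    fixtures may be rectangular, in which case ``config.L`` is nominal.
    """

    config: ModelConfig
    vertical_edges: np.ndarray
    dysfunctional: np.ndarray
    ablated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ve = _locked(self.vertical_edges)
        dys = _locked(self.dysfunctional)
        abl = self.ablated
        if abl is None:
            abl = np.zeros_like(ve)
        abl = _locked(abl)
        if not (ve.shape == dys.shape == abl.shape) or ve.ndim != 2:
            raise ValueError(
                f"mask shapes must match and be 2D, got {ve.shape}, {dys.shape}, {abl.shape}"
            )
        object.__setattr__(self, "vertical_edges", ve)
        object.__setattr__(self, "dysfunctional", dys)
        object.__setattr__(self, "ablated", abl)

    @property
    def shape(self) -> tuple[int, int]:
        return self.vertical_edges.shape

    @property
    def n_rows(self) -> int:
        return self.shape[0]

    @property
    def n_cols(self) -> int:
        return self.shape[1]

    @property
    def L(self) -> int:
        return self.n_cols

    @property
    def seed(self) -> int:
        return self.config.seed

    @property
    def pacemaker_mask(self) -> np.ndarray:
        """Boolean mask of pacemaker cells: the full column x = 0."""
        mask = np.zeros(self.shape, dtype=bool)
        mask[:, 0] = True
        return mask

    def with_ablated(self, ablated: np.ndarray) -> "Substrate":
        return replace(self, ablated=ablated)


def generate_substrate(config: ModelConfig) -> Substrate:
    """Draw one random substrate realisation from ``config``.

    Each of the L^2 candidate vertical edges is present independently with
    probability nu; each cell is dysfunctional independently with
    probability delta (Bernoulli, so the number of dysfunctional cells has
    mean delta*L^2, matching the independence assumed by the analytic
    risk).  Draw order is fixed (edges first, then dysfunction) so the
    same seed always yields a bit-identical substrate.
    """
    rng = np.random.default_rng(config.seed)
    L = config.L
    vertical_edges = rng.random((L, L)) < config.nu
    dysfunctional = rng.random((L, L)) < config.delta
    return Substrate(
        config=config,
        vertical_edges=vertical_edges,
        dysfunctional=dysfunctional,
        ablated=np.zeros((L, L), dtype=bool),
    )
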