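"""Stochastic lattice model of the in vitro scratch-wound assay.

The cell monolayer is a 2-D lattice of square sites of edge ``delta`` (the
mean cell diameter, µm); each site is empty or holds one cell.  At t = 0 the
lattice is split into two lateral reservoirs (L, R) seeded at the experimental
cell density and a central cell-free band (W, the wound) of width ``b0``.
Each sweep, every occupied site acts once in random order: with probability
Pm = (1/Tm) / (1/Tm + 1/Td) it migrates into an empty Moore neighbour,
otherwise it proliferates, placing a daughter in an empty neighbour; a cell
with no empty neighbour is quiescent (contact inhibition).  A directional
bias toward the wound removes the two backward-diagonal target sites
("from 9 to 7" available sites).  The first and last columns act as an
infinite reservoir: any vacancy generated there during the simulation is
repopulated after the sweep, so the bulk tissue never depletes.

One sweep advances time by dt = (1/Tm + 1/Td)^-1 hours, so per-sweep action
probabilities equal rate x dt for both processes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import TARGET_BLOCK, TARGET_EMPTY, sweep_inplace, wound_component_sites, wound_runs

__all__ = [
    "DomainError",
    "ConfigurationError",
    "CAParams",
    "LatticeState",
    "Trajectory",
    "migration_probability",
    "tm_from_motility",
    "lattice_geometry",
    "init_lattice",
    "candidate_sites",
    "step",
    "simulate",
    "PHYSIOLOGICAL_RANGES",
]


class DomainError(ValueError):
    """A physical parameter is outside its mathematical domain."""


class ConfigurationError(ValueError):
    """A derived lattice configuration is unusable (e.g. zero wound columns)."""


#: Physiological ranges used for soft validation (warn, never error).
#: Units: Tm, Td in h; rho in cells/µm²; delta, b0 in µm.
PHYSIOLOGICAL_RANGES = {
    "tm": (0.005, 0.5),
    "td": (12.0, 40.0),
    "rho": (1e-6, 1e-3),
    "delta": (15.0, 25.0),
    "b0": (370.0, 900.0),
}

#: Default bias exclusion: the two backward diagonals, expressed for a cell
#: left of the wound center (backward = toward negative columns).  The pair
#: is mirrored in the column axis for cells right of center.
DEFAULT_BIAS_EXCLUDED = ((-1, -1), (1, -1))


def migration_probability(tm: float, td: float) -> tuple[float, float]:
    """Per-sweep migration and proliferation probabilities (Pm, Pd).

    Pm = (1/Tm) / (1/Tm + 1/Td) and Pd = (1/Td) / (1/Td + 1/Tm); the two
    characteristic times act as parallel resistances, so Pm + Pd = 1 and the
    faster process (shorter time) dominates.

    Parameters
    ----------
    tm : float
        Characteristic migration time (h): time to travel one cell size.
        ``math.inf`` is accepted (no migration).
    td : float
        Doubling time (h). ``math.inf`` is accepted (no proliferation).
    """
    if not tm > 0:
        raise DomainError(f"Tm must be positive, got {tm!r}")
    if not td > 0:
        raise DomainError(f"Td must be positive, got {td!r}")
    rm = 1.0 / tm
    rd = 1.0 / td
    total = rm + rd
    if total == 0.0:
        raise DomainError("Tm and Td cannot both be infinite")
    return rm / total, rd / total


def tm_from_motility(delta: float, D: float) -> float:
    """Migration time Tm = delta^2 / D from the random motility coefficient.

    Parameters
    ----------
    delta : float
        Cell size (µm).
    D : float
        Random motility (diffusion-like) coefficient (µm²/h).
    """
    if not delta > 0:
        raise DomainError(f"delta must be positive, got {delta!r}")
    if not D > 0:
        raise DomainError(f"D must be positive, got {D!r}")
    return delta * delta / D


def lattice_geometry(b0: float, delta: float) -> tuple[int, int]:
    """Column counts (n_wound, n_lateral) for wound width b0 and cell size delta.

    The wound band spans ``round(b0/delta)`` columns; each lateral reservoir
    spans half the wound width, rounded up.
    """
    n_w = int(round(b0 / delta))
    if n_w < 1:
        raise ConfigurationError(
            f"wound width b0={b0} below one cell size delta={delta}"
        )
    n_lat = math.ceil(n_w / 2)
    return n_w, n_lat


@dataclass(frozen=True)
class CAParams:
    """Full parameterization of one simulation.

    Attributes
    ----------
    tm : float
        Characteristic migration time (h).
    td : float
        Doubling time (h).
    rho : float
        Seeding density (cells/µm²); per-site occupation probability is
        f = min(1, rho * delta^2), clamped at confluence.
    delta : float
        Cell size = lattice spacing (µm).
    b0 : float
        Initial wound width (µm).
    n_rows : int or None
        Lattice rows; None gives a square lattice (rows = total columns).
    max_time : float
        Simulation horizon (h).
    bias_enabled : bool
        Directional bias toward the wound.
    bias_excluded : tuple of two (drow, dcol) offsets
        The two Moore offsets removed by the bias, in the frame of a cell
        left of the wound center (mirrored for the right side).
    boundary_refill : bool
        Reservoir refill of first/last columns.
    refill_mode : {"generated", "density"}
        "generated" (default): every boundary-column vacancy generated during
        the simulation is repopulated each sweep (sites never yet occupied
        stay empty), so the reservoir ratchets from the seeding density
        toward confluence as it is colonized.  "density": every empty
        boundary site refills with probability f each sweep, holding the
        reservoir at the seeding density instead.
    proliferation_enabled : bool
        When False, the proliferation branch is suppressed (Pm unchanged);
        used to isolate the migration contribution.
    target_selection : {"block", "empty"}
        How a cell picks its target site.  "block" (default) draws uniformly
        from the bias-reduced 3x3 block (self included) and acts only when
        the drawn site is vacant, giving excluded-random-walk transport at
        the physical front velocities; "empty" draws uniformly from the
        vacant candidates only, which makes fronts ballistic.
    seed : int
        RNG seed; identical params + seed give bit-identical trajectories.
    """

    tm: float
    td: float
    rho: float
    delta: float = 20.0
    b0: float = 575.0
    n_rows: int | None = None
    max_time: float = 48.0
    bias_enabled: bool = True
    bias_excluded: tuple[tuple[int, int], tuple[int, int]] = DEFAULT_BIAS_EXCLUDED
    boundary_refill: bool = True
    refill_mode: str = "generated"
    proliferation_enabled: bool = True
    target_selection: str = "block"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tm > 0:
            raise DomainError(f"Tm must be positive, got {self.tm!r}")
        if not self.td > 0:
            raise DomainError(f"Td must be positive, got {self.td!r}")
        if not self.rho >= 0:
            raise DomainError(f"rho must be non-negative, got {self.rho!r}")
        if not self.delta > 0:
            raise DomainError(f"delta must be positive, got {self.delta!r}")
        if not self.b0 > 0:
            raise DomainError(f"b0 must be positive, got {self.b0!r}")
        if not self.max_time > 0:
            raise DomainError(f"max_time must be positive, got {self.max_time!r}")
        n_w, n_lat = lattice_geometry(self.b0, self.delta)
        if self.n_rows is None:
            object.__setattr__(self, "n_rows", n_w + 2 * n_lat)
        if self.n_rows < 1:
            raise ConfigurationError(f"n_rows must be >= 1, got {self.n_rows!r}")
        if self.refill_mode not in ("generated", "density"):
            raise ConfigurationError(
                f"refill_mode must be 'generated' or 'density', got {self.refill_mode!r}"
            )
        if self.target_selection not in ("block", "empty"):
            raise ConfigurationError(
                f"target_selection must be 'block' or 'empty', got {self.target_selection!r}"
            )
        if self.rho * self.delta**2 > 1.0:
            warnings.warn(
                f"rho={self.rho} exceeds confluence for delta={self.delta} "
                "(rho*delta^2 > 1); occupancy clamped at 1",
                stacklevel=2,
            )
        for name, (lo, hi) in PHYSIOLOGICAL_RANGES.items():
            value = getattr(self, name)
            if not lo <= value <= hi and math.isfinite(value):
                warnings.warn(
                    f"{name}={value} outside the physiological range [{lo}, {hi}]",
                    stacklevel=2,
                )

    @property
    def occupancy_fraction(self) -> float:
        """Per-site seeding probability f = min(1, rho * delta^2)."""
        return min(1.0, self.rho * self.delta**2)

    @property
    def pm(self) -> float:
        return migration_probability(self.tm, self.td)[0]

    @property
    def pd(self) -> float:
        return migration_probability(self.tm, self.td)[1]

    @property
    def dt(self) -> float:
        """Physical duration of one sweep: (1/Tm + 1/Td)^-1 hours."""
        return 1.0 / (1.0 / self.tm + 1.0 / self.td)

    @property
    def phi(self) -> float:
        """Dimensionless migration/proliferation time ratio Tm/Td."""
        return self.tm / self.td

    def geometry(self) -> tuple[int, int]:
        return lattice_geometry(self.b0, self.delta)


@dataclass
class LatticeState:
    """Occupancy grid plus elapsed time: the evolving CA configuration.

    ``refillable`` marks the boundary-column sites (rows x {first, last})
    that have ever been occupied; under the default refill rule these are
    the sites the reservoir repopulates when they fall vacant.
    """

    grid: np.ndarray  # uint8, rows x cols; 1 = occupied
    time: float
    step_index: int
    wound_center_col: int
    wound_band: tuple[int, int]  # half-open [start, end) column interval
    delta: float
    refillable: np.ndarray | None = None  # bool, rows x 2

    @property
    def n_cells(self) -> int:
        return int(self.grid.sum())


@dataclass
class Trajectory:
    """Wound-area time series A(t) and A/A0 from one simulation."""

    times: np.ndarray  # h
    areas: np.ndarray  # µm²
    normalized: np.ndarray  # A/A0
    closed: bool
    params: CAParams

    def __len__(self) -> int:
        return len(self.times)


def init_lattice(params: CAParams, rng: np.random.Generator | None = None) -> LatticeState:
    """Build the t = 0 configuration: empty wound band, seeded reservoirs.

    The wound band spans round(b0/delta) central columns; the L and R
    sub-domains (each half the wound width) are seeded by independent
    per-site occupation at probability f = min(1, rho*delta^2).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_w, n_lat = params.geometry()
    n_cols = n_w + 2 * n_lat
    n_rows = params.n_rows
    f = params.occupancy_fraction
    grid = np.zeros((n_rows, n_cols), dtype=np.uint8)
    if f > 0:
        lateral = rng.random((n_rows, 2 * n_lat)) < f
        grid[:, :n_lat] = lateral[:, :n_lat]
        grid[:, n_lat + n_w :] = lateral[:, n_lat:]
    band = (n_lat, n_lat + n_w)
    center = n_lat + n_w // 2
    return LatticeState(
        grid=grid,
        time=0.0,
        step_index=0,
        wound_center_col=center,
        wound_band=band,
        delta=params.delta,
        refillable=grid[:, [0, n_cols - 1]].astype(bool),
    )


def candidate_sites(
    state: LatticeState,
    row: int,
    col: int,
    bias_enabled: bool = True,
    bias_excluded: tuple[tuple[int, int], tuple[int, int]] = DEFAULT_BIAS_EXCLUDED,
) -> list[tuple[int, int]]:
    """Empty target sites in the Moore neighbourhood of an occupied cell.

    Rows wrap periodically; columns stop at the lattice edge.  With the bias
    on, a cell strictly left (right) of the wound center loses the two
    excluded backward offsets (mirrored in the column axis for the right
    side); a cell exactly at the center is unbiased.  Returned in row-major
    offset order, which is the order the sweep kernel uses for target choice.
    """
    grid = state.grid
    n_rows, n_cols = grid.shape
    if not (0 <= row < n_rows and 0 <= col < n_cols):
        raise IndexError(f"site ({row}, {col}) outside a {n_rows}x{n_cols} lattice")
    if grid[row, col] == 0:
        raise ValueError(f"site ({row}, {col}) is not occupied")
    side = 0
    if bias_enabled:
        if col < state.wound_center_col:
            side = 1
        elif col > state.wound_center_col:
            side = -1
    out: list[tuple[int, int]] = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            if side != 0:
                edc = dc if side == 1 else -dc
                if (dr, edc) in bias_excluded:
                    continue
            cc = col + dc
            if not 0 <= cc < n_cols:
                continue
            rr = (row + dr) % n_rows
            if grid[rr, cc] == 0:
                out.append((rr, cc))
    return out


def _draw_sweep_randoms(grid: np.ndarray, rng: np.random.Generator):
    """Pre-draw the sweep randomness from ``rng``, in a fixed order:
    visit permutation, action draws, target draws."""
    occ = np.argwhere(grid != 0)
    perm = rng.permutation(occ.shape[0])
    order = occ[perm]
    n = occ.shape[0]
    lambdas = rng.random(n)
    choice_u = rng.random(n)
    return (
        np.ascontiguousarray(order[:, 0]) if n else np.empty(0, dtype=np.int64),
        np.ascontiguousarray(order[:, 1]) if n else np.empty(0, dtype=np.int64),
        lambdas,
        choice_u,
    )


def _refill_boundary(
    grid: np.ndarray, refillable: np.ndarray, params: CAParams, rng
) -> None:
    """Repopulate reservoir (first/last column) vacancies after a sweep."""
    if not params.boundary_refill:
        return
    for j, c in enumerate((0, grid.shape[1] - 1)):
        col = grid[:, c]
        if params.refill_mode == "generated":
            col[(col == 0) & refillable[:, j]] = 1
            refillable[:, j] |= col.astype(bool)
        else:  # "density": hold the reservoir at the seeding density
            f = params.occupancy_fraction
            if f > 0.0:
                draw = rng.random(col.shape[0])
                col[(col == 0) & (draw < f)] = 1


def _sweep(
    grid: np.ndarray,
    refillable: np.ndarray,
    params: CAParams,
    center_col: int,
    rng,
) -> None:
    """One in-place sweep of ``grid`` (plus refill) using draws from ``rng``."""
    order_r, order_c, lambdas, choice_u = _draw_sweep_randoms(grid, rng)
    (e0, e1) = params.bias_excluded
    mode = TARGET_BLOCK if params.target_selection == "block" else TARGET_EMPTY
    sweep_inplace(
        grid,
        order_r.astype(np.int64),
        order_c.astype(np.int64),
        lambdas,
        choice_u,
        params.pm,
        params.bias_enabled,
        center_col,
        e0[0],
        e0[1],
        e1[0],
        e1[1],
        mode,
        params.proliferation_enabled,
    )
    _refill_boundary(grid, refillable, params, rng)


def step(state: LatticeState, params: CAParams, rng: np.random.Generator) -> LatticeState:
    """Advance the lattice by one sweep and return the new state.

    Every site occupied at the start of the sweep acts once, in a fresh
    random permutation, against the live (in-place updated) grid; daughters
    placed during the sweep do not act until the next sweep.  Afterwards the
    reservoir columns refill and time advances by ``params.dt``.
    """
    grid = state.grid.copy()
    refillable = (
        state.refillable.copy()
        if state.refillable is not None
        else grid[:, [0, -1]].astype(bool)
    )
    _sweep(grid, refillable, params, state.wound_center_col, rng)
    return replace(
        state,
        grid=grid,
        refillable=refillable,
        time=state.time + params.dt,
        step_index=state.step_index + 1,
    )


def _wound_sites(grid: np.ndarray, band: tuple[int, int], center: int, method: str) -> int:
    """Empty-site count of the wound under the chosen area measure."""
    if method == "component":
        return wound_component_sites(grid, band[0], band[1])
    if method == "runs":
        return int(wound_runs(grid, center))
    raise ConfigurationError(f"unknown area method {method!r}")


def simulate(params: CAParams, area_method: str = "component") -> Trajectory:
    """Run the automaton from t = 0 until wound closure or ``max_time``.

    Records A(t) each sweep (including t = 0); ``closed`` is True when the
    measured wound area reached zero within the horizon.  ``area_method``
    selects the wound-area measure ("component": connected cell-free regions
    touching the initial band, the default; "runs": per-row empty runs
    through the wound center).  Identical params and seed give bit-identical
    trajectories.
    """
    rng = np.random.default_rng(params.seed)
    state = init_lattice(params, rng)
    grid = state.grid
    refillable = state.refillable
    dt = params.dt
    center = state.wound_center_col
    band = state.wound_band
    delta2 = params.delta**2
    times = [0.0]
    areas = [_wound_sites(grid, band, center, area_method) * delta2]
    t = 0.0
    while areas[-1] > 0 and t < params.max_time:
        _sweep(grid, refillable, params, center, rng)
        t += dt
        times.append(t)
        areas.append(_wound_sites(grid, band, center, area_method) * delta2)
    times_arr = np.asarray(times)
    areas_arr = np.asarray(areas, dtype=float)
    a0 = areas_arr[0]
    if a0 <= 0:
        raise ConfigurationError("initial wound area is zero; nothing to simulate")
    return Trajectory(
        times=times_arr,
        areas=areas_arr,
        normalized=areas_arr / a0,
        closed=bool(areas_arr[-1] == 0),
        params=params,
    )
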