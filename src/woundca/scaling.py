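"""Power-law scaling of the closure rate with the migration/proliferation ratio.

The dimensionless ratio Phi = Tm/Td compares the migration and proliferation
time scales (a Thiele-modulus analogue: small Phi = migration-dominated).
Across a random sweep of the physiological parameter box the closure rate
collapses onto the phenomenological power law

    alpha = a * Phi**(-b)

fitted by OLS in log-log space.  A paired simulation analysis (proliferation
on vs off at matched seeds) locates the critical Phi below which proliferation
contributes negligibly to closure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .lattice import CAParams, DomainError, simulate
from .metrics import InsufficientDataError, fit_closure_rate
from .sensitivity import ParamRanges, child_seeds

__all__ = [
    "PowerLawFit",
    "phi",
    "sweep",
    "fit_power_law",
    "predict_alpha",
    "critical_phi_analysis",
    "high_phi_bias",
]


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted alpha = a * Phi**(-b) with log-space standard errors."""

    a: float  # prefactor, 1/h
    b: float  # exponent, dimensionless
    a_stderr: float
    b_stderr: float
    n_points: int
    phi_range: tuple[float, float]
    r_squared: float


def phi(tm: float, td: float) -> float:
    """Migration/proliferation time ratio Phi = Tm/Td (dimensionless)."""
    if not tm > 0:
        raise DomainError(f"Tm must be positive, got {tm!r}")
    if not td > 0:
        raise DomainError(f"Td must be positive, got {td!r}")
    return tm / td


def sweep(
    ranges: ParamRanges | None = None,
    n_sims: int = 2000,
    master_seed: int = 0,
    max_time: float = 48.0,
    phi_span: tuple[float, float] | None = (1e-4, 0.5),
) -> pd.DataFrame:
    """Random parameter sweep returning one (Phi, alpha) pair per simulation.

    With the default ``phi_span``, Phi is drawn log-uniformly over the
    physiological span [1e-4, 0.5], Td and rho uniformly inside ``ranges``,
    and Tm = Phi * Td; this covers the span evenly on a log scale and reaches
    the poorly-motile regime (Tm of several hours, cf. osteoblasts) that a
    direct Tm draw from the migration-time range cannot.  With
    ``phi_span=None``, Tm is instead drawn log-uniformly inside
    ``ranges.tm``.  delta and b0 stay fixed.  Returns a tidy table
    (phi, alpha, tm, td, rho, closed, seed), reproducible under
    ``master_seed``; runs not closing within ``max_time`` are flagged, not
    dropped (their alpha is still measured from the partial decline).
    """
    if n_sims < 1:
        raise ValueError(f"n_sims must be >= 1, got {n_sims}")
    if ranges is None:
        ranges = ParamRanges()
    rng = np.random.default_rng(master_seed)
    td_vals = rng.uniform(*ranges.td, n_sims)
    if phi_span is not None:
        lo, hi = phi_span
        if not 0 < lo < hi:
            raise ValueError(f"phi_span must be increasing and positive, got {phi_span}")
        phi_vals = np.exp(rng.uniform(np.log(lo), np.log(hi), n_sims))
        tm_vals = phi_vals * td_vals
    else:
        tm_vals = np.exp(rng.uniform(np.log(ranges.tm[0]), np.log(ranges.tm[1]), n_sims))
    rho_vals = rng.uniform(*ranges.rho, n_sims)
    seeds = child_seeds(master_seed, n_sims)
    rows = []
    import warnings as _warnings

    for tm, td, rho, seed in zip(tm_vals, td_vals, rho_vals, seeds):
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # high-Phi Tm sits above the soft range
            params = CAParams(
                tm=float(tm),
                td=float(td),
                rho=float(rho),
                delta=ranges.delta,
                b0=ranges.b0,
                max_time=max_time,
                seed=int(seed),
            )
        traj = simulate(params)
        m = fit_closure_rate(traj)
        rows.append(
            {
                "phi": params.phi,
                "alpha": m.alpha,
                "tm": params.tm,
                "td": params.td,
                "rho": params.rho,
                "closed": traj.closed,
                "seed": int(seed),
            }
        )
    return pd.DataFrame(rows)


def fit_power_law(pairs: pd.DataFrame | np.ndarray) -> PowerLawFit:
    """Fit alpha = a * Phi**(-b) by OLS of ln(alpha) on ln(Phi).

    ``pairs`` is a DataFrame with ``phi``/``alpha`` columns or an (n, 2)
    array.  Only strictly positive pairs enter the fit; fewer than 3 usable
    points raise :class:`~woundca.metrics.InsufficientDataError`.
    """
    if isinstance(pairs, pd.DataFrame):
        phi_vals = pairs["phi"].to_numpy(float)
        alpha_vals = pairs["alpha"].to_numpy(float)
    else:
        arr = np.asarray(pairs, dtype=float)
        phi_vals, alpha_vals = arr[:, 0], arr[:, 1]
    ok = (phi_vals > 0) & (alpha_vals > 0)
    phi_vals, alpha_vals = phi_vals[ok], alpha_vals[ok]
    if phi_vals.size < 3:
        raise InsufficientDataError(
            f"need >= 3 positive (phi, alpha) pairs, got {phi_vals.size}"
        )
    res = stats.linregress(np.log(phi_vals), np.log(alpha_vals))
    a = float(np.exp(res.intercept))
    return PowerLawFit(
        a=a,
        b=-float(res.slope),
        a_stderr=a * float(res.intercept_stderr),  # delta method on exp(intercept)
        b_stderr=float(res.stderr),
        n_points=int(phi_vals.size),
        phi_range=(float(phi_vals.min()), float(phi_vals.max())),
        r_squared=float(res.rvalue**2),
    )


def predict_alpha(fit: PowerLawFit, phi_value: float | np.ndarray) -> float | np.ndarray:
    """Closure rate a * Phi**(-b) predicted by a fitted power law."""
    phi_arr = np.asarray(phi_value, dtype=float)
    if np.any(phi_arr <= 0):
        raise DomainError("Phi must be positive")
    out = fit.a * phi_arr ** (-fit.b)
    return float(out) if np.isscalar(phi_value) else out


def critical_phi_analysis(
    phi_grid: np.ndarray | None = None,
    n_seeds: int = 20,
    td: float = 24.0,
    rho: float = 2.5e-3,
    delta: float = 20.0,
    b0: float = 575.0,
    threshold: float = 0.1,
    master_seed: int = 0,
    max_time: float = 96.0,
) -> tuple[pd.DataFrame, float | None]:
    """Relative proliferation contribution to alpha along a Phi grid.

    For each Phi, Tm = Phi * Td and matched pairs of simulations are run at
    ``n_seeds`` shared seeds with proliferation enabled vs disabled (the
    proliferation branch suppressed, Pm unchanged).  The per-seed relative
    difference eps = |alpha_full - alpha_no_prolif| / alpha_full is averaged;
    the returned critical Phi is the smallest grid value whose mean eps
    exceeds ``threshold`` (None if none does).  Defaults probe a fully
    covered lattice (rho at confluence for delta = 20) so that eps isolates
    the kinetic role of proliferation rather than cell supply.
    """
    if phi_grid is None:
        phi_grid = np.geomspace(1e-4, 0.5, 8)
    phi_grid = np.asarray(phi_grid, dtype=float)
    if np.any(phi_grid <= 0):
        raise DomainError("phi_grid must be positive")
    seeds = child_seeds(master_seed, n_seeds)
    rows = []
    import warnings as _warnings

    for phi_value in phi_grid:
        tm = float(phi_value * td)
        eps_vals = []
        for seed in seeds:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # off-range Tm/rho are intentional here
                base = CAParams(
                    tm=tm, td=td, rho=rho, delta=delta, b0=b0,
                    max_time=max_time, seed=int(seed),
                )
                knockout = replace(base, proliferation_enabled=False)
            a_full = fit_closure_rate(simulate(base)).alpha
            a_mig = fit_closure_rate(simulate(knockout)).alpha
            if a_full > 0:
                eps_vals.append(abs(a_full - a_mig) / a_full)
        eps_arr = np.asarray(eps_vals)
        rows.append(
            {
                "phi": float(phi_value),
                "epsilon": float(eps_arr.mean()) if eps_arr.size else np.nan,
                "epsilon_sem": float(eps_arr.std(ddof=1) / np.sqrt(eps_arr.size))
                if eps_arr.size > 1
                else np.nan,
                "n_pairs": int(eps_arr.size),
            }
        )
    table = pd.DataFrame(rows)
    above = table.loc[table["epsilon"] > threshold, "phi"]
    critical = float(above.min()) if len(above) else None
    return table, critical


def high_phi_bias(pairs: pd.DataFrame, fit: PowerLawFit, phi_cutoff: float = 0.1) -> float:
    """Mean log-residual ln(alpha_sim / alpha_fit) over points with
    Phi > ``phi_cutoff``; positive when the fitted curve under-predicts the
    simulated closure rates in the high-Phi regime."""
    sel = pairs[(pairs["phi"] > phi_cutoff) & (pairs["alpha"] > 0)]
    if len(sel) == 0:
        raise InsufficientDataError(f"no positive pairs with phi > {phi_cutoff}")
    pred = predict_alpha(fit, sel["phi"].to_numpy(float))
    return float(np.mean(np.log(sel["alpha"].to_numpy(float) / pred)))
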