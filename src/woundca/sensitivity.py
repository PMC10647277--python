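"""Regression-based global sensitivity analysis of wound-closure kinetics.

Workflow: Latin hypercube sampling of (rho, Tm, Td) inside their physiological
box (delta and b0 fixed at their mid-range values, 20 µm and 575 µm, being
purely geometric), batch simulation, multiple linear regression
output = beta0 + beta_rho*rho + beta_Tm*Tm + beta_Td*Td on z-scored variables,
replicated over independent LHS sets, then one-way ANOVA + Tukey HSD on the
replicate |beta| distributions to rank parameters 1 (most significant) to 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats import qmc

from .lattice import CAParams, simulate
from .metrics import fit_closure_rate

__all__ = [
    "DegenerateDesignError",
    "InsufficientReplicatesError",
    "ParamRanges",
    "MLRAResult",
    "GSAResult",
    "lhs_sample",
    "child_seeds",
    "run_batch",
    "mlra",
    "rank_parameters",
    "run_gsa",
    "SAMPLED_PARAMETERS",
    "GSA_OUTPUTS",
]

SAMPLED_PARAMETERS = ("rho", "tm", "td")
GSA_OUTPUTS = ("alpha", "t_half", "t_closure")


class DegenerateDesignError(ValueError):
    """Constant or collinear regression design."""


class InsufficientReplicatesError(ValueError):
    """Fewer than two replicates per parameter."""


@dataclass(frozen=True)
class ParamRanges:
    """Sampling box for (Tm, Td, rho) with the geometric parameters fixed."""

    tm: tuple[float, float] = (0.005, 0.5)  # h
    td: tuple[float, float] = (12.0, 40.0)  # h
    rho: tuple[float, float] = (1e-6, 1e-3)  # cells/µm²
    delta: float = 20.0  # µm, fixed
    b0: float = 575.0  # µm, fixed

    def __post_init__(self) -> None:
        for name in SAMPLED_PARAMETERS:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"range for {name} must have low < high, got ({lo}, {hi})")
        if not (self.delta > 0 and self.b0 > 0):
            raise ValueError("fixed geometry (delta, b0) must be positive")


@dataclass(frozen=True)
class MLRAResult:
    """Standardized regression coefficients for one output."""

    output: str
    betas: dict[str, float]  # parameter -> standardized beta
    p_values: dict[str, float]
    intercept: float
    r_squared: float
    n_used: int
    n_excluded: int


@dataclass(frozen=True)
class GSAResult:
    """Replicate beta distributions plus the ANOVA/Tukey parameter ranking."""

    replicate_betas: pd.DataFrame  # columns: output, parameter, replicate, beta, p_value
    ranks: dict[str, dict[str, int]]  # output -> parameter -> rank (1 best)
    anova_p: dict[str, float]  # output -> one-way ANOVA p on |beta| groups
    tukey_p: dict[str, dict[tuple[str, str], float]]
    excluded: dict[str, int] = field(default_factory=dict)

    def weighted_ranking(self, weights: dict[str, float] | None = None) -> dict[str, float]:
        """Average of per-output ranks; equal weights unless given."""
        if weights is None:
            weights = {o: 1.0 for o in self.ranks}
        total = sum(weights.values())
        out: dict[str, float] = {}
        for p in SAMPLED_PARAMETERS:
            out[p] = sum(w * self.ranks[o][p] for o, w in weights.items()) / total
        return out


def lhs_sample(ranges: ParamRanges, n: int, seed: int) -> list[dict[str, float]]:
    """Latin hypercube sample of n (rho, Tm, Td) triples.

    Each marginal places exactly one point in each of the n equal-probability
    strata of its uniform range; deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    sampler = qmc.LatinHypercube(d=len(SAMPLED_PARAMETERS), seed=seed)
    unit = sampler.random(n)
    lows = np.array([getattr(ranges, p)[0] for p in SAMPLED_PARAMETERS])
    highs = np.array([getattr(ranges, p)[1] for p in SAMPLED_PARAMETERS])
    scaled = qmc.scale(unit, lows, highs)
    return [dict(zip(SAMPLED_PARAMETERS, row)) for row in scaled]


def child_seeds(master_seed: int, n: int) -> np.ndarray:
    """n deterministic child seeds (< 2^31) derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return (ss.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF).astype(np.int64)


def run_batch(
    param_sets: list[dict[str, float]],
    ranges: ParamRanges | None = None,
    master_seed: int = 0,
    max_time: float = 48.0,
) -> pd.DataFrame:
    """Simulate one trajectory per parameter set and extract its kinetics.

    Returns a tidy table with columns rho, tm, td, alpha, t_half, t_closure,
    closed, seed; non-closing runs keep NaN t_closure (and NaN t_half when
    50% closure was never reached) and are flagged by ``closed``.
    """
    if not param_sets:
        raise ValueError("param_sets is empty")
    if ranges is None:
        ranges = ParamRanges()
    seeds = child_seeds(master_seed, len(param_sets))
    rows = []
    for ps, seed in zip(param_sets, seeds):
        params = CAParams(
            tm=float(ps["tm"]),
            td=float(ps["td"]),
            rho=float(ps["rho"]),
            delta=ranges.delta,
            b0=ranges.b0,
            max_time=max_time,
            seed=int(seed),
        )
        traj = simulate(params)
        m = fit_closure_rate(traj)
        rows.append(
            {
                "rho": params.rho,
                "tm": params.tm,
                "td": params.td,
                "alpha": m.alpha,
                "t_half": np.nan if m.t_half is None else m.t_half,
                "t_closure": np.nan if m.t_closure is None else m.t_closure,
                "closed": traj.closed,
                "seed": int(seed),
            }
        )
    return pd.DataFrame(rows)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    # relative floor catches columns constant up to float summation error
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
        raise DegenerateDesignError("constant column in the regression design")
    return (x - x.mean()) / sd


def mlra(table: pd.DataFrame, output: str) -> MLRAResult:
    """Standardized multiple linear regression of one output on (rho, Tm, Td).

    Inputs and output are z-scored before the OLS fit so that the |beta| are
    comparable effect sizes across parameters with different units.  Rows
    with undefined output (e.g. T_closure of non-closing runs) are excluded.
    """
    if output not in table.columns:
        raise KeyError(f"output column {output!r} not in table")
    ok = table[output].notna()
    used = table.loc[ok]
    n_excluded = int((~ok).sum())
    if len(used) < 5:
        raise DegenerateDesignError(
            f"need >= 5 complete rows for {output!r}, got {len(used)}"
        )
    X = np.column_stack([_zscore(used[p].to_numpy(float)) for p in SAMPLED_PARAMETERS])
    y = _zscore(used[output].to_numpy(float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError("collinear regression design")
    model = sm.OLS(y, sm.add_constant(X)).fit()
    betas = dict(zip(SAMPLED_PARAMETERS, model.params[1:]))
    p_values = dict(zip(SAMPLED_PARAMETERS, model.pvalues[1:]))
    return MLRAResult(
        output=output,
        betas={k: float(v) for k, v in betas.items()},
        p_values={k: float(v) for k, v in p_values.items()},
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        n_used=int(len(used)),
        n_excluded=n_excluded,
    )


def rank_parameters(
    replicate_betas: pd.DataFrame, alpha_level: float = 0.05
) -> tuple[dict[str, dict[str, int]], dict[str, float], dict[str, dict[tuple[str, str], float]]]:
    """Rank parameters per output from replicate |beta| distributions.

    One-way ANOVA across the three parameters' |beta| distributions, then
    Tukey HSD at the 95% level; parameters are ordered by mean |beta|
    (descending) and assigned ranks 1-3, with Tukey-indistinguishable
    neighbours sharing the better rank.
    """
    ranks: dict[str, dict[str, int]] = {}
    anova_p: dict[str, float] = {}
    tukey_p: dict[str, dict[tuple[str, str], float]] = {}
    for output, sub in replicate_betas.groupby("output"):
        groups = {
            p: np.abs(sub.loc[sub["parameter"] == p, "beta"].to_numpy(float))
            for p in SAMPLED_PARAMETERS
        }
        if any(len(g) < 2 for g in groups.values()):
            raise InsufficientReplicatesError(
                f"output {output!r}: need >= 2 replicates per parameter"
            )
        samples = [groups[p] for p in SAMPLED_PARAMETERS]
        anova_p[output] = float(stats.f_oneway(*samples).pvalue)
        hsd = stats.tukey_hsd(*samples)
        pmat = {
            (SAMPLED_PARAMETERS[i], SAMPLED_PARAMETERS[j]): float(hsd.pvalue[i, j])
            for i in range(3)
            for j in range(3)
            if i < j
        }
        tukey_p[output] = pmat
        order = sorted(SAMPLED_PARAMETERS, key=lambda p: -groups[p].mean())
        out_ranks = {order[0]: 1}
        for i in range(1, len(order)):
            a, b = order[i - 1], order[i]
            key = (a, b) if (a, b) in pmat else (b, a)
            if pmat[key] >= alpha_level:  # indistinguishable: share the better rank
                out_ranks[b] = out_ranks[a]
            else:
                out_ranks[b] = i + 1
        ranks[output] = out_ranks
    return ranks, anova_p, tukey_p


def run_gsa(
    ranges: ParamRanges | None = None,
    n_samples: int = 500,
    n_replicates: int = 10,
    master_seed: int = 0,
    max_time: float = 48.0,
) -> GSAResult:
    """Full GSA pipeline: replicated LHS batches, MLRA per output, ranking."""
    if ranges is None:
        ranges = ParamRanges()
    rep_seeds = child_seeds(master_seed, 2 * n_replicates).reshape(n_replicates, 2)
    records = []
    excluded: dict[str, int] = {o: 0 for o in GSA_OUTPUTS}
    for rep in range(n_replicates):
        sets = lhs_sample(ranges, n_samples, seed=int(rep_seeds[rep, 0]))
        table = run_batch(sets, ranges, master_seed=int(rep_seeds[rep, 1]), max_time=max_time)
        for output in GSA_OUTPUTS:
            res = mlra(table, output)
            excluded[output] += res.n_excluded
            for p in SAMPLED_PARAMETERS:
                records.append(
                    {
                        "output": output,
                        "parameter": p,
                        "replicate": rep,
                        "beta": res.betas[p],
                        "p_value": res.p_values[p],
                        "significant": res.p_values[p] < 0.05,
                    }
                )
    betas = pd.DataFrame(records)
    ranks, anova_p, tukey_p = rank_parameters(betas)
    return GSAResult(
        replicate_betas=betas,
        ranks=ranks,
        anova_p=anova_p,
        tukey_p=tukey_p,
        excluded=excluded,
    )
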