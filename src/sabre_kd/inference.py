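"""Fitting binding and relaxation parameters to observed R2 data.

Three estimation problems, in the order the screening workflow runs them:

1. Catalyst titration: observed rates at several catalyst concentrations
   determine the free and catalyst-bound ligand rates (R2,f, R2,CL) and the
   catalyst association constant Keq.
2. Reporter-KD calibration: two observations (protein only; protein plus a
   competitor of known affinity) determine the reporter-protein dissociation
   constant KD jointly with the protein-bound rate R2,PL.
3. Competitor KD,2: one competition observation, with the calibrated
   reporter parameters held fixed, determines the competitor's dissociation
   constant.

All fits are bounded residual-sum-of-squares minimizations; concentrations
are bounded by their totals by construction of the equilibrium solver.
Uncertainty comes from a Monte Carlo analysis: observations are perturbed
with Gaussian noise and refitted, and each parameter is summarized by its
mean and the narrowest interval containing 90% of the draws.  Skewed draw
distributions can put the mean outside that interval; summaries never clip
it back in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .equilibria import (
    BindingConstants,
    SampleComposition,
    solve_binary_equilibrium,
    solve_coupled_equilibria,
)
from .relaxation_model import _pool_rates, predict_r2_catalyst, predict_r2_full

__all__ = [
    "TitrationPoint",
    "TitrationDataset",
    "FitResult",
    "MonteCarloConfig",
    "fit_catalyst_titration",
    "fit_reporter_kd",
    "fit_competitor_kd",
    "monte_carlo",
    "narrowest_interval",
    "MonteCarloError",
]


class MonteCarloError(RuntimeError):
    """Raised when too many Monte Carlo draws fail to refit."""


@dataclass(frozen=True)
class TitrationPoint:
    composition: SampleComposition
    r2_obs: float            # s^-1
    r2_sd: float | None = None
    cl_over_l: float | None = None  # optional high-field bound-fraction ratio [CL]/[L]

    def __post_init__(self) -> None:
        if not self.r2_obs > 0:
            raise ValueError(f"r2_obs must be > 0, got {self.r2_obs}")


@dataclass(frozen=True)
class TitrationDataset:
    points: tuple[TitrationPoint, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        if len(self.points) < 1:
            raise ValueError("dataset needs at least one point")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class FitResult:
    """Point estimates plus (optionally) Monte Carlo summaries.

    ``mc_mean`` may legitimately fall outside [ci_low, ci_high]: with skewed
    draw distributions a few divergent draws pull the mean past the narrowest
    90% region, and that effect is reported, not hidden.
    """

    estimates: dict[str, float]
    rss: float
    mc_mean: dict[str, float] | None = None
    ci_low: dict[str, float] | None = None
    ci_high: dict[str, float] | None = None
    n_boundary_draws: int = 0
    n_failed_draws: int = 0
    at_bounds: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.rss < -1e-300:
            raise ValueError("rss must be >= 0")
        if self.ci_low is not None and self.ci_high is not None:
            for k in self.ci_low:
                if self.ci_low[k] > self.ci_high[k]:
                    raise ValueError(f"ci_low > ci_high for {k}")


@dataclass(frozen=True)
class MonteCarloConfig:
    """Monte Carlo settings: number of refits and the noise source.

    ``noise_model``: 'replicate' uses per-point sds attached to the data,
    'fit_se' uses the standard error of the underlying R2 fits, 'fixed' uses
    ``fixed_sd`` for every observation.
    """

    n_draws: int = 10000
    seed: int = 0
    noise_model: str = "replicate"
    fixed_sd: float | None = None

    def __post_init__(self) -> None:
        if self.n_draws < 100:
            raise ValueError(f"n_draws must be >= 100, got {self.n_draws}")
        if self.noise_model not in ("replicate", "fit_se", "fixed"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.noise_model == "fixed" and not (self.fixed_sd is not None and self.fixed_sd >= 0):
            raise ValueError("fixed noise model requires fixed_sd >= 0")


# ---------------------------------------------------------------------------
# catalyst titration

_TITRATION_BOUNDS = ((1e-6, 1e-6, 1e-6), (100.0, 100.0, 100.0))


def _titration_residuals(
    theta: np.ndarray, data: TitrationDataset, ratio_weight: float | None
) -> np.ndarray:
    r2_f, r2_cl, k_eq = theta
    rates = _pool_rates(r2_f, r2_cl=r2_cl)
    out = []
    for pt in data.points:
        eq = solve_binary_equilibrium(pt.composition.c_tot, pt.composition.l_tot, k_eq)
        w = 1.0 / pt.r2_sd if pt.r2_sd else 1.0
        out.append(w * (predict_r2_catalyst(eq, rates) - pt.r2_obs))
        if pt.cl_over_l is not None and ratio_weight is not None:
            ratio_pred = eq.cl / eq.l_free if eq.l_free > 0 else math.inf
            out.append(ratio_weight * (ratio_pred - pt.cl_over_l))
    return np.asarray(out)


def fit_catalyst_titration(
    data: TitrationDataset,
    init: Sequence[float] | None = None,
    bounds: tuple[Sequence[float], Sequence[float]] = _TITRATION_BOUNDS,
    ratio_weight: float | None = None,
) -> FitResult:
    """Fit (R2,f, R2,CL, Keq) to a catalyst titration by bounded least squares.

    For fixed Keq the model is linear in the two rates, so the fit profiles
    the RSS over Keq (log-spaced scan plus Brent refinement) with the rates
    projected out by linear least squares at each step; a bounded
    Levenberg-Marquardt polish in all three parameters finishes from the
    profile optimum (and from ``init`` when supplied, e.g. for warm-started
    Monte Carlo refits).  When high-field [CL]/[L] ratios are attached to
    points and ``ratio_weight`` is given, weighted ratio residuals are added
    to the objective (auxiliary data, not hard constraints).
    """
    n_resid = len(data) + sum(
        1 for p in data.points if p.cl_over_l is not None and ratio_weight is not None
    )
    if n_resid < 3:
        raise ValueError("underdetermined: need >= 3 informative observations for 3 parameters")
    obs = np.array([p.r2_obs for p in data.points])
    if ratio_weight is None and any(p.cl_over_l is not None for p in data.points):
        # default weight makes a typical ratio residual comparable to a rate residual
        ratios = [p.cl_over_l for p in data.points if p.cl_over_l is not None]
        ratio_weight = float(np.mean(obs) / max(np.mean(ratios), 1e-12))
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)

    wts = np.array([1.0 / p.r2_sd if p.r2_sd else 1.0 for p in data.points])

    def profile_rates(k_eq: float) -> tuple[float, float]:
        # bound fraction per point, then weighted linear LS for (r2_f, r2_cl)
        frac = np.array(
            [
                solve_binary_equilibrium(
                    p.composition.c_tot, p.composition.l_tot, k_eq
                ).cl
                / p.composition.l_tot
                for p in data.points
            ]
        )
        design = np.column_stack([(1.0 - frac) * wts, frac * wts])
        sol, *_ = np.linalg.lstsq(design, obs * wts, rcond=None)
        return float(np.clip(sol[0], lo[0], hi[0])), float(np.clip(sol[1], lo[1], hi[1]))

    def profile_rss(log_keq: float) -> float:
        k_eq = 10.0 ** log_keq
        r2_f, r2_cl = profile_rates(k_eq)
        r = _titration_residuals(np.array([r2_f, r2_cl, k_eq]), data, ratio_weight)
        return float(r @ r)

    starts = []
    if init is not None:
        starts.append(np.asarray(init, dtype=float))
    else:
        # scan the Keq profile and refine every local minimum: with few
        # titration points the rate-only objective can have two exact roots
        # (a weak-binding and a strong-binding branch reproduce the same
        # observations), and both must be examined
        from scipy.optimize import minimize_scalar

        grid = np.linspace(math.log10(lo[2]), math.log10(hi[2]), 80)
        vals = np.array([profile_rss(x) for x in grid])
        minima_idx = [
            i
            for i in range(len(grid))
            if (i == 0 or vals[i] < vals[i - 1])
            and (i == len(grid) - 1 or vals[i] <= vals[i + 1])
        ]
        candidates = []
        for i in minima_idx:
            a = grid[max(i - 1, 0)]
            b = grid[min(i + 1, len(grid) - 1)]
            if a < b:
                r = minimize_scalar(
                    profile_rss, bounds=(a, b), method="bounded",
                    options={"xatol": 1e-12},
                )
                x = float(r.x) if r.fun <= vals[i] else float(grid[i])
            else:
                x = float(grid[i])
            candidates.append((profile_rss(x), 10.0 ** x))
        rss_min = min(c[0] for c in candidates)
        tie_tol = 1e-9 * float(obs @ obs)
        # within numerical ties the data cannot distinguish the branches;
        # prefer the weaker-binding (smaller Keq) root — supplying measured
        # [CL]/[L] ratios removes the ambiguity altogether
        k_eq0 = min(c[1] for c in candidates if c[0] <= rss_min + tie_tol)
        starts.append(np.array([*profile_rates(k_eq0), k_eq0]))
    best = None
    for x0 in starts:
        try:
            res = least_squares(
                _titration_residuals, np.clip(x0, lo, hi), bounds=(lo, hi),
                args=(data, ratio_weight), xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("titration fit failed from all starts")
    est = {"r2_f": float(best.x[0]), "r2_cl": float(best.x[1]), "k_eq": float(best.x[2])}
    at = tuple(
        name
        for name, v, l, h in zip(("r2_f", "r2_cl", "k_eq"), best.x, lo, hi)
        if v <= l * (1 + 1e-9) or v >= h * (1 - 1e-9)
    )
    return FitResult(estimates=est, rss=float(2 * best.cost), at_bounds=at)


# ---------------------------------------------------------------------------
# reporter KD calibration (two observations, two unknowns)

_KD_BOUNDS_UM = (1e-3, 1e7)
_R2PL_BOUNDS = (0.0, 1e4)


def _predict_protein_obs(
    comp: SampleComposition,
    k_d_um: float,
    k_d2_um: float | None,
    r2_pl: float,
    catalyst_fit: FitResult,
) -> float:
    k = BindingConstants(
        k_eq=catalyst_fit.estimates["k_eq"],
        k_d=k_d_um,
        k_d2=k_d2_um if comp.s_tot > 0 else None,
    )
    eq = solve_coupled_equilibria(comp, k)
    rates = _pool_rates(
        catalyst_fit.estimates["r2_f"], r2_cl=catalyst_fit.estimates["r2_cl"], r2_pl=r2_pl
    )
    return predict_r2_full(eq, rates)


def fit_reporter_kd(
    r2_protein_only: float,
    r2_with_competitor: float,
    comp_a: SampleComposition,
    comp_b: SampleComposition,
    known_kd2: float,
    catalyst_fit: FitResult,
    init: tuple[float, float] | None = None,
) -> FitResult:
    """Calibrate the reporter's KD (uM) and R2,PL from two observations.

    ``comp_a`` is the protein-only condition, ``comp_b`` the condition with a
    competitor whose dissociation constant ``known_kd2`` (uM) is known.  The
    two-observation / two-unknown system is solved by bounded least squares
    in (log10 KD, R2,PL); an exact fit (rss ~ 0) is attainable for consistent
    inputs.  If the optimum sits on a parameter bound, the observations were
    not jointly explainable and the result is flagged via ``at_bounds``.
    """
    if not known_kd2 > 0:
        raise ValueError("known_kd2 must be > 0")

    def residuals(theta: np.ndarray) -> np.ndarray:
        log_kd, r2_pl = theta
        kd = 10.0 ** log_kd
        pa = _predict_protein_obs(comp_a, kd, known_kd2, r2_pl, catalyst_fit)
        pb = _predict_protein_obs(comp_b, kd, known_kd2, r2_pl, catalyst_fit)
        return np.array([pa - r2_protein_only, pb - r2_with_competitor])

    lo = np.array([math.log10(_KD_BOUNDS_UM[0]), _R2PL_BOUNDS[0]])
    hi = np.array([math.log10(_KD_BOUNDS_UM[1]), _R2PL_BOUNDS[1]])
    if init is not None:
        starts = [(math.log10(init[0]), init[1])]  # warm start for Monte Carlo refits
    else:
        starts = [
            (math.log10(kd0), r2pl0)
            for kd0 in (1.0, 30.0, 300.0, 3000.0, 1e5)
            for r2pl0 in (10.0, 100.0)
        ]
    best = None
    for s in starts:
        x0 = np.clip(np.asarray(s, dtype=float), lo, hi)
        try:
            res = least_squares(
                residuals, x0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("reporter KD fit failed from all starts")
    kd_hat = float(10.0 ** best.x[0])
    est = {"k_d": kd_hat, "r2_pl": float(best.x[1])}
    at = []
    if best.x[0] <= lo[0] + 1e-6 or best.x[0] >= hi[0] - 1e-6:
        at.append("k_d")
    if best.x[1] >= hi[1] * (1 - 1e-9):
        at.append("r2_pl")
    return FitResult(estimates=est, rss=float(2 * best.cost), at_bounds=tuple(at))


def fit_competitor_kd(
    r2_with_competitor: float,
    comp: SampleComposition,
    known_kd: float,
    known_r2_pl: float,
    catalyst_fit: FitResult,
) -> FitResult:
    """Determine a competitor's KD,2 (uM) from a single competition observation.

    The predicted rate is strictly increasing in KD,2 (a weaker competitor
    displaces less reporter from the protein), so the 1-D problem is solved
    by bracketed root finding in log10 KD,2.  Observations outside the
    attainable range return the nearest bound, flagged in ``at_bounds``.
    """
    lo, hi = math.log10(_KD_BOUNDS_UM[0]), math.log10(_KD_BOUNDS_UM[1])

    def gap(log_kd2: float) -> float:
        return (
            _predict_protein_obs(comp, known_kd, 10.0 ** log_kd2, known_r2_pl, catalyst_fit)
            - r2_with_competitor
        )

    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo > 0:   # even the strongest competitor predicts too much binding
        log_hat, at = lo, ("k_d2",)
    elif g_hi < 0:  # even an inert competitor cannot reach the observation
        log_hat, at = hi, ("k_d2",)
    else:
        log_hat = brentq(gap, lo, hi, xtol=1e-13, rtol=8.9e-16)
        at = ()
    resid = gap(log_hat)
    return FitResult(
        estimates={"k_d2": float(10.0 ** log_hat)}, rss=float(resid * resid), at_bounds=at
    )


# ---------------------------------------------------------------------------
# Monte Carlo uncertainty

def narrowest_interval(
    samples: Sequence[float] | np.ndarray, mass: float = 0.90
) -> tuple[float, float]:
    """Narrowest contiguous window of sorted samples containing ``mass`` of them.

    Over the sorted sample the window holds ceil(mass*n) values; among all
    windows of that size the minimal-width one is returned, ties broken
    toward the lower window.  This is the highest-density-style summary used
    instead of central quantiles because parameter draw distributions are
    generally skewed.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    w = math.ceil(mass * n)
    if n < 2 or w > n:
        raise ValueError(f"sample of {n} too small for a {mass:.0%} window")
    widths = x[w - 1 :] - x[: n - w + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: lower window on ties
    return float(x[i]), float(x[i + w - 1])


def monte_carlo(
    refit: Callable[[np.ndarray], dict[str, float]],
    observations: np.ndarray,
    noise_sd: np.ndarray | float,
    cfg: MonteCarloConfig,
    base: FitResult | None = None,
    mass: float = 0.90,
) -> FitResult:
    """Perturb-and-refit uncertainty analysis.

    Each draw adds independent Gaussian noise (per-observation sd
    ``noise_sd``) to ``observations`` and calls ``refit``, which returns a
    dict of parameter estimates (and may signal a boundary solution via an
    ``"_at_bound"`` flag value).  Per-parameter mean and narrowest-``mass``
    interval are summarized into a :class:`FitResult`.  Reproducible given
    ``cfg.seed``.  Draws on parameter bounds are retained (they are what
    produces the mean-outside-interval signature) but counted; more than 10%
    outright failures is an error.
    """
    rng = np.random.default_rng(cfg.seed)
    obs = np.asarray(observations, dtype=float)
    sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), obs.shape)
    draws: dict[str, list[float]] = {}
    n_fail = 0
    n_boundary = 0
    failures: list[str] = []
    for _ in range(cfg.n_draws):
        y = obs + rng.normal(0.0, 1.0, size=obs.shape) * sd
        try:
            est = refit(y)
        except Exception as exc:  # noqa: BLE001 — any refit failure is a failed draw
            n_fail += 1
            if len(failures) < 5:
                failures.append(repr(exc))
            continue
        if est.pop("_at_bound", 0.0):
            n_boundary += 1
        for k, v in est.items():
            draws.setdefault(k, []).append(float(v))
    if n_fail > 0.10 * cfg.n_draws:
        raise MonteCarloError(
            f"{n_fail}/{cfg.n_draws} Monte Carlo draws failed; examples: {failures}"
        )
    mc_mean = {k: float(np.mean(v)) for k, v in draws.items()}
    ci = {k: narrowest_interval(v, mass) for k, v in draws.items()}
    result = base if base is not None else FitResult(
        estimates=dict(mc_mean), rss=math.nan
    )
    result = replace(
        result,
        mc_mean=mc_mean,
        ci_low={k: c[0] for k, c in ci.items()},
        ci_high={k: c[1] for k, c in ci.items()},
        n_boundary_draws=n_boundary,
        n_failed_draws=n_fail,
    )
    return result
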