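"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the solver strategies used by the package: the
equilibrium oracle is a nested grid-refinement search over free-species
concentrations, and the interval oracle enumerates every contiguous window.
"""

from __future__ import annotations

import math

import numpy as np


def grid_equilibrium_oracle(
    c_tot: float,
    l_tot: float,
    p_tot: float,
    s_tot: float,
    k_eq: float,
    k_d_um: float | None,
    k_d2_um: float | None,
    target: float = 1e-9,
) -> dict[str, float]:
    """Solve the coupled equilibria by grid refinement over (l_free, p_free).

    For candidate free concentrations, the remaining species follow from the
    mass-action laws and the catalyst/competitor conservation identities; the
    ligand and protein conservation residuals are minimized over a 2-D grid
    that is repeatedly zoomed around its argmin until the grid step is below
    ``target`` (mM).
    """
    kd = (k_d_um / 1000.0) if k_d_um is not None else math.inf
    kd2 = (k_d2_um / 1000.0) if k_d2_um is not None else math.inf
    n = 41

    def protein_residual_sq(l: np.ndarray, p: np.ndarray) -> np.ndarray:
        pl = p * l / kd if math.isfinite(kd) else np.zeros_like(p)
        ps = (
            s_tot * p / (kd2 + p)
            if (s_tot > 0 and math.isfinite(kd2))
            else np.zeros_like(p)
        )
        f2 = p + pl + ps - p_tot
        return f2 * f2

    def p_of_l(l: np.ndarray) -> np.ndarray:
        """Free protein per candidate free ligand, by 1-D grid refinement."""
        lo = np.zeros_like(l)
        hi = np.full_like(l, max(p_tot, 1e-30))
        frac = np.linspace(0.0, 1.0, n)
        while float(np.max(hi - lo)) >= target * 1e-3:
            grid = lo[:, None] + (hi - lo)[:, None] * frac[None, :]
            r = protein_residual_sq(l[:, None], grid)
            j = np.argmin(r, axis=1)
            step = (hi - lo) / (n - 1)
            best = grid[np.arange(len(l)), j]
            lo = np.maximum(best - 2 * step, 0.0)
            hi = np.minimum(best + 2 * step, p_tot if p_tot > 0 else 1e-30)
        return 0.5 * (lo + hi)

    def ligand_residual_sq(l: np.ndarray) -> np.ndarray:
        p = p_of_l(l)
        cl = c_tot * k_eq * l / (1.0 + k_eq * l) if k_eq > 0 else np.zeros_like(l)
        pl = p * l / kd if math.isfinite(kd) else np.zeros_like(l)
        f1 = l + cl + pl - l_tot
        return f1 * f1

    lo_l, hi_l = 0.0, max(l_tot, 1e-30)
    while True:
        ls = np.linspace(lo_l, hi_l, n)
        r = ligand_residual_sq(ls)
        i = int(np.argmin(r))
        step_l = ls[1] - ls[0]
        if step_l < target:
            l = float(ls[i])
            break
        lo_l = max(ls[i] - 2 * step_l, 0.0)
        hi_l = min(ls[i] + 2 * step_l, l_tot if l_tot > 0 else 1e-30)
    p = float(p_of_l(np.array([l]))[0])

    cl = c_tot * k_eq * l / (1.0 + k_eq * l) if k_eq > 0 else 0.0
    pl = p * l / kd if math.isfinite(kd) else 0.0
    ps = s_tot * p / (kd2 + p) if (s_tot > 0 and math.isfinite(kd2)) else 0.0
    return {
        "c_free": c_tot - cl,
        "l_free": l,
        "cl": cl,
        "p_free": p,
        "pl": pl,
        "s_free": s_tot - ps,
        "ps": ps,
    }


def exhaustive_narrowest_interval(samples, mass: float = 0.90) -> tuple[float, float]:
    """Enumerate every contiguous sorted window of size ceil(mass*n)."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    w = math.ceil(mass * n)
    best = None
    for i in range(n - w + 1):
        width = x[i + w - 1] - x[i]
        if best is None or width < best[0]:
            best = (width, x[i], x[i + w - 1])
    return float(best[1]), float(best[2])
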