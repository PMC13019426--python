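"""Forward models from equilibrium populations to observed R2, and the
orthohydrogen signal model.

Under fast ligand exchange at milli-Tesla fields the observed transverse
relaxation rate is the population-weighted average of the pool rates

    R2,obs = ([PL] R2,PL + [CL] R2,CL + [L] R2,f) / [L_tot]

with no exchange (Rex) contribution, because chemical-shift differences
vanish at low field.  The SABRE process also converts parahydrogen to
NMR-visible orthohydrogen, which adds a monoexponential component of
opposite sign and roughly one quarter of the ligand amplitude to the echo
integrals; this module simulates and removes that component.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .echo_processing import IntegralSeries, bracketed_minimum
from .equilibria import EquilibriumState

__all__ = [
    "RelaxationRates",
    "OrthohydrogenModel",
    "predict_r2_catalyst",
    "predict_r2_full",
    "orthohydrogen_integral",
    "correct_for_orthohydrogen",
]


@dataclass(frozen=True)
class RelaxationRates:
    """Pool-specific transverse relaxation rates, s^-1.

    Bound-pool rates normally exceed the free rate (slower tumbling of the
    complex); a violation is physically suspicious but not an error, so it
    only warns.
    """

    r2_f: float
    r2_cl: float = 0.0
    r2_pl: float = 0.0
    r2_ortho: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r2_f", "r2_cl", "r2_pl", "r2_ortho"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if (0 < self.r2_cl < self.r2_f) or (0 < self.r2_pl < self.r2_f):
            warnings.warn(
                "bound-pool R2 below free-ligand R2; check rate assignment",
                stacklevel=2,
            )


@dataclass(frozen=True)
class OrthohydrogenModel:
    """Orthohydrogen signal relative to the ligand signal.

    ``amplitude_ratio`` is ligand-to-orthohydrogen initial amplitude (the
    ligand signal is ~4x larger); ``sign`` is the orthohydrogen polarity
    relative to the ligand (opposite, i.e. -1, for this catalyst system).
    Both the rate and the relative amplitude are assumed transferable from
    the high-field calibration where they were measured — that assumption is
    exactly what this explicit config encodes.
    """

    amplitude_ratio: float = 4.0
    r2_ortho: float = 0.961
    sign: int = -1

    def __post_init__(self) -> None:
        if not self.amplitude_ratio > 0:
            raise ValueError(f"amplitude_ratio must be > 0, got {self.amplitude_ratio}")
        if self.sign not in (-1, 1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")
        if not self.r2_ortho >= 0:
            raise ValueError(f"r2_ortho must be >= 0, got {self.r2_ortho}")


def _pool_rates(
    r2_f: float, r2_cl: float = 0.0, r2_pl: float = 0.0, r2_ortho: float = 0.0
) -> RelaxationRates:
    """Build RelaxationRates without the bound-below-free warning.

    Optimizers legitimately pass through inverted-rate interiors; warning on
    every objective evaluation would be noise.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return RelaxationRates(r2_f=r2_f, r2_cl=r2_cl, r2_pl=r2_pl, r2_ortho=r2_ortho)


def predict_r2_catalyst(eq: EquilibriumState, rates: RelaxationRates) -> float:
    """Two-pool observed rate, ([CL] R2,CL + [L] R2,f)/[L_tot]; requires no PL."""
    if eq.pl != 0.0:
        raise ValueError("catalyst-only model requires pl = 0; use predict_r2_full")
    return predict_r2_full(eq, rates)


def predict_r2_full(eq: EquilibriumState, rates: RelaxationRates) -> float:
    """Three-pool population-weighted observed rate.

    The weights [PL]/[L_tot], [CL]/[L_tot], [L]/[L_tot] sum to one, so the
    result always lies in the convex hull of the pool rates.
    """
    l_tot = eq.l_free + eq.cl + eq.pl
    if l_tot <= 0:
        raise ValueError("total ligand must be > 0 to observe a rate")
    return (eq.pl * rates.r2_pl + eq.cl * rates.r2_cl + eq.l_free * rates.r2_f) / l_tot


def orthohydrogen_integral(
    times: np.ndarray, ligand_amplitude: float, model: OrthohydrogenModel
) -> np.ndarray:
    """Simulated orthohydrogen echo integrals, sign*(A_L/ratio)*exp(-R2,o t)."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if not math.isfinite(ligand_amplitude):
        raise ValueError("ligand_amplitude must be finite")
    return model.sign * (ligand_amplitude / model.amplitude_ratio) * np.exp(
        -model.r2_ortho * times
    )


def estimate_ligand_amplitude(
    series: IntegralSeries, model: OrthohydrogenModel
) -> tuple[float, float]:
    """Fit a contaminated series to A_L [exp(-R t) + sign/ratio exp(-R2,o t)].

    The orthohydrogen rate and relative amplitude are held at the model's
    calibrated values; only the ligand amplitude A_L and ligand rate R float.
    For fixed R the model is linear in A_L, so A_L is projected out in closed
    form and R is found by 1-D bounded minimization.  A_L is constrained to
    the sign of the ligand signal (nonnegative under the default convention):
    without that constraint a negative-amplitude solution at a large ligand
    rate can mimic the data through the orthohydrogen component alone
    whenever the two decay rates are similar.

    Returns ``(A_L, R)``.
    """
    t = series.echo_times
    y = series.integrals
    rel = model.sign / model.amplitude_ratio

    def basis(rate: float) -> np.ndarray:
        return np.exp(-rate * t) + rel * np.exp(-model.r2_ortho * t)

    def projected_amp(g: np.ndarray) -> float:
        gg = float(g @ g)
        amp = float(g @ y) / gg if gg > 0 else 0.0
        return max(amp, 0.0)

    def rss(rate: float) -> float:
        g = basis(rate)
        r = y - projected_amp(g) * g
        return float(r @ r)

    rate = bracketed_minimum(rss, 0.0, 50.0)
    return projected_amp(basis(rate)), rate


def correct_for_orthohydrogen(
    series: IntegralSeries, model: OrthohydrogenModel
) -> IntegralSeries:
    """Remove the simulated orthohydrogen component from measured integrals.

    The absolute orthohydrogen amplitude is anchored through the ligand
    amplitude estimate from :func:`estimate_ligand_amplitude`:
    corrected(t) = measured(t) - sign*(A_L/ratio)*exp(-R2,o t).
    Correcting a series that contains no orthohydrogen (infinite ratio, or a
    clean monoexponential) changes nothing.
    """
    if len(series.integrals) == 0:
        raise ValueError("series must be nonempty")
    if math.isinf(model.amplitude_ratio):
        return series
    amp, _ = estimate_ligand_amplitude(series, model)
    corrected = series.integrals - orthohydrogen_integral(series.echo_times, amp, model)
    return IntegralSeries(
        echo_times=series.echo_times, integrals=corrected, noise_sd=series.noise_sd
    )
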