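"""Mass-action binding equilibria for the SABRE reporter-ligand system.

Three coupled equilibria govern the speciation of the reporter ligand L:

* catalyst binding,  C + L <-> CL, association constant ``k_eq`` (mM^-1),
* protein binding,   P + L <-> PL, dissociation constant ``k_d`` (uM),
* competitor binding, P + S <-> PS, dissociation constant ``k_d2`` (uM),

subject to conservation of total catalyst, ligand, protein and competitor.
All internal concentrations are millimolar; protein dissociation constants
are accepted and reported in micromolar with an explicit /1000 conversion at
the model boundary.  Exactly one reporter ligand binds per catalyst complex;
the coligand (deuterated DMSO) occupies the remaining coordination sites and
is carried for bookkeeping only.  Competitor-catalyst binding is not modeled
(competitors are added only after hyperpolarization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "SampleComposition",
    "BindingConstants",
    "EquilibriumState",
    "solve_binary_equilibrium",
    "solve_coupled_equilibria",
    "mix_and_dilute",
    "EquilibriumError",
]

#: absolute tolerance on mass-action residuals (mM units)
RESIDUAL_TOL = 1e-12
#: iteration cap for the Newton stage of the coupled solver
MAX_ITER = 200


class EquilibriumError(RuntimeError):
    """Raised when the coupled solver fails to converge; carries the last residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class SampleComposition:
    """Total (analytical) concentrations of one sample, all in mM.

    ``volume`` (mL) is only required when the sample participates in mixing.
    """

    c_tot: float = 0.0   # polarization-transfer catalyst
    l_tot: float = 0.0   # reporter ligand
    col_tot: float = 0.0  # coligand (inert bookkeeping)
    p_tot: float = 0.0   # protein
    s_tot: float = 0.0   # competitor ligand
    volume: float | None = None  # mL

    def __post_init__(self) -> None:
        for name in ("c_tot", "l_tot", "col_tot", "p_tot", "s_tot"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.volume is not None and not self.volume > 0:
            raise ValueError(f"volume must be > 0 when set, got {self.volume}")


@dataclass(frozen=True)
class BindingConstants:
    """Equilibrium constants; units fixed by convention, never converted implicitly.

    ``k_eq``: catalyst-ligand *association* constant, mM^-1.
    ``k_d`` / ``k_d2``: reporter/competitor-protein *dissociation* constants, uM.
    ``None`` means "not applicable" (the corresponding species is absent).
    """

    k_eq: float | None = None
    k_d: float | None = None
    k_d2: float | None = None

    def __post_init__(self) -> None:
        for name in ("k_eq", "k_d", "k_d2"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be > 0 when set, got {v}")


@dataclass(frozen=True)
class EquilibriumState:
    """Free and bound species concentrations (mM) at equilibrium."""

    c_free: float = 0.0
    l_free: float = 0.0
    cl: float = 0.0
    p_free: float = 0.0
    pl: float = 0.0
    s_free: float = 0.0
    ps: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c_free", "l_free", "cl", "p_free", "pl", "s_free", "ps"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < -RESIDUAL_TOL:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    @property
    def c_tot(self) -> float:
        return self.c_free + self.cl

    @property
    def l_tot(self) -> float:
        return self.l_free + self.cl + self.pl

    @property
    def p_tot(self) -> float:
        return self.p_free + self.pl + self.ps

    @property
    def s_tot(self) -> float:
        return self.s_free + self.ps


def solve_binary_equilibrium(c_tot: float, l_tot: float, k_eq: float) -> EquilibriumState:
    """Solve C + L <-> CL alone (no protein, no competitor).

    The complex concentration is the physical root of

        cl^2 - (c_tot + l_tot + 1/k_eq) cl + c_tot l_tot = 0,

    computed in the numerically stable product form so that weak binding
    (small ``k_eq``) does not lose precision to cancellation.  ``k_eq = 0``
    is the exact no-binding case.
    """
    if c_tot < 0 or l_tot < 0:
        raise ValueError("total concentrations must be >= 0")
    if k_eq < 0:
        raise ValueError("k_eq must be >= 0")
    if k_eq == 0.0 or c_tot == 0.0 or l_tot == 0.0:
        return EquilibriumState(c_free=c_tot, l_free=l_tot)
    b = c_tot + l_tot + 1.0 / k_eq
    disc = b * b - 4.0 * c_tot * l_tot
    # disc >= (c_tot - l_tot)^2 + ... > 0 always
    cl = 2.0 * c_tot * l_tot / (b + math.sqrt(disc))
    cl = min(cl, c_tot, l_tot)
    return EquilibriumState(c_free=c_tot - cl, l_free=l_tot - cl, cl=cl)


def _species_from_unknowns(
    l: float, p: float, comp: SampleComposition, k_eq: float, kd_mm: float, kd2_mm: float
) -> tuple[float, float, float, float, float]:
    """Given free ligand and free protein, return (c_free, cl, pl, s_free, ps)."""
    if k_eq > 0:
        c_free = comp.c_tot / (1.0 + k_eq * l)
        cl = comp.c_tot - c_free
    else:
        c_free, cl = comp.c_tot, 0.0
    pl = p * l / kd_mm if math.isfinite(kd_mm) else 0.0
    if comp.s_tot > 0 and math.isfinite(kd2_mm):
        ps = comp.s_tot * p / (kd2_mm + p)
        s_free = comp.s_tot - ps
    else:
        s_free, ps = comp.s_tot, 0.0
    return c_free, cl, pl, s_free, ps


def solve_coupled_equilibria(comp: SampleComposition, k: BindingConstants) -> EquilibriumState:
    """Solve the three equilibria simultaneously under all conservation laws.

    Reduced to two unknowns, free ligand ``l`` and free protein ``p``:
    everything else follows in closed form.  A damped Newton iteration with
    the analytic Jacobian is tried first; if it stalls, the solver falls back
    to nested bisection on the two monotone conservation residuals, which is
    globally convergent.  Reduces exactly to :func:`solve_binary_equilibrium`
    when protein and competitor are absent.
    """
    k_eq = k.k_eq if k.k_eq is not None else 0.0
    if comp.p_tot > 0 and k.k_d is None:
        raise ValueError("k_d required when protein is present")
    if comp.s_tot > 0 and comp.p_tot > 0 and k.k_d2 is None:
        raise ValueError("k_d2 required when competitor and protein are present")
    kd_mm = (k.k_d / 1000.0) if k.k_d is not None else math.inf
    kd2_mm = (k.k_d2 / 1000.0) if k.k_d2 is not None else math.inf

    if comp.p_tot == 0.0:
        st = solve_binary_equilibrium(comp.c_tot, comp.l_tot, k_eq)
        return replace(st, s_free=comp.s_tot)

    def p_given_l(l: float) -> float:
        # protein conservation p*(1 + l/kd) + s_tot*p/(kd2+p) = p_tot, monotone in p
        if comp.p_tot == 0.0:
            return 0.0
        a = 1.0 + (l / kd_mm if math.isfinite(kd_mm) else 0.0)
        if not (comp.s_tot > 0 and math.isfinite(kd2_mm)):
            return comp.p_tot / a
        # quadratic: a p^2 + (a kd2 + s_tot - p_tot) p - p_tot kd2 = 0
        bq = a * kd2_mm + comp.s_tot - comp.p_tot
        cq = -comp.p_tot * kd2_mm
        return (2.0 * -cq) / (bq + math.sqrt(bq * bq - 4.0 * a * cq))

    def ligand_residual(l: float) -> tuple[float, float]:
        """Ligand conservation residual and its analytic derivative in l."""
        p = p_given_l(l)
        _, cl, pl, _, _ = _species_from_unknowns(l, p, comp, k_eq, kd_mm, kd2_mm)
        dcl = comp.c_tot * k_eq / (1.0 + k_eq * l) ** 2 if k_eq > 0 else 0.0
        if math.isfinite(kd_mm):
            a = 1.0 + l / kd_mm
            s_term = (
                comp.s_tot * kd2_mm / (kd2_mm + p) ** 2
                if (comp.s_tot > 0 and math.isfinite(kd2_mm))
                else 0.0
            )
            dp = -(p / kd_mm) / (a + s_term)
            dpl = (p + l * dp) / kd_mm
        else:
            dpl = 0.0
        return l + cl + pl - comp.l_tot, 1.0 + dcl + dpl

    if comp.l_tot == 0.0:
        l = 0.0
    else:
        # damped Newton on the 1-D monotone ligand residual (free protein
        # eliminated in closed form via the protein-conservation quadratic)
        l = comp.l_tot / 2.0
        converged = False
        for _ in range(MAX_ITER):
            f, df = ligand_residual(l)
            if abs(f) < RESIDUAL_TOL * max(1.0, comp.l_tot):
                converged = True
                break
            l_new = min(max(l - f / df, 0.0), comp.l_tot)
            if abs(l_new - l) < 1e-17 * max(1.0, comp.l_tot):
                l = l_new
                converged = abs(ligand_residual(l)[0]) < 1e-9 * max(1.0, comp.l_tot)
                break
            l = l_new
        if not converged:
            # bisection fallback: residual is strictly increasing in l
            lo, hi = 0.0, comp.l_tot
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if ligand_residual(mid)[0] > 0:
                    hi = mid
                else:
                    lo = mid
            l = 0.5 * (lo + hi)
            resid = abs(ligand_residual(l)[0])
            if resid > 1e-8 * max(1.0, comp.l_tot):
                raise EquilibriumError(
                    f"coupled equilibrium solver did not converge (residual {resid:.3e})",
                    residual=resid,
                )

    p = p_given_l(l)
    c_free, cl, pl, s_free, ps = _species_from_unknowns(l, p, comp, k_eq, kd_mm, kd2_mm)
    clamp = lambda x: max(x, 0.0)
    return EquilibriumState(
        c_free=clamp(c_free),
        l_free=clamp(l),
        cl=clamp(cl),
        p_free=clamp(p),
        pl=clamp(pl),
        s_free=clamp(s_free),
        ps=clamp(ps),
    )


def mix_and_dilute(a: SampleComposition, b: SampleComposition) -> SampleComposition:
    """Mix two samples; every total becomes the volume-weighted average.

    Conserves moles of each species exactly (closed-form arithmetic).  This is
    the bookkeeping behind the protein-injection protocol, where 1.25 mL of
    protein solution dilutes 0.25 mL of hyperpolarized sample six-fold.
    """
    if a.volume is None or b.volume is None:
        raise ValueError("both samples need a volume to be mixed")
    v = a.volume + b.volume
    if not v > 0:
        raise ValueError("total volume must be > 0")
    wa, wb = a.volume / v, b.volume / v
    return SampleComposition(
        c_tot=wa * a.c_tot + wb * b.c_tot,
        l_tot=wa * a.l_tot + wb * b.l_tot,
        col_tot=wa * a.col_tot + wb * b.col_tot,
        p_tot=wa * a.p_tot + wb * b.p_tot,
        s_tot=wa * a.s_tot + wb * b.s_tot,
        volume=v,
    )
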