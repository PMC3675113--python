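"""Mass-action equilibrium model for a two-site metal-binding protein.

The model describes an EF-hand pair (the high-affinity EF site and the
weaker CD site of a parvalbumin domain) that binds lanthanides (Tb3+,
Gd3+) and Ca2+ in competition with each other and with a chelator such
as NTA.  Sites are treated as independent 1:1 binders, so the whole
equilibrium is fixed by per-(site, metal) and per-(chelator, metal)
dissociation constants and by the total concentrations of each
component.

Two closed-form conversions between apparent and true dissociation
constants are provided.  In a competition titration the fitted midpoint
K_app is inflated over the true KD of the titrated species by the
presence of the competitor:

    K_app = KD_titrant * (1 + [competitor] / KD_competitor)

``cheng_prusoff_true_kd`` divides the inflation out; its transposition
``competitor_kd_from_kapp`` recovers the competitor's KD instead, which
is the direction used when the protein is the competitor of a chelator
of known affinity.

All concentrations are mol/L internally; helpers accepting µM convert
explicitly via :func:`lanthakit.units.umolar`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MetalSpecies",
    "BindingSite",
    "ChelatorSpecies",
    "BindingSystem",
    "MixtureSpec",
    "SpeciationState",
    "LuminescenceModel",
    "SpeciationError",
    "solve_speciation",
    "competition_curve",
    "cheng_prusoff_true_kd",
    "competitor_kd_from_kapp",
    "luminescence_intensity",
    "anisotropy_fraction_bound",
    "fraction_bound_quadratic",
]

#: Default CD/EF affinity ratio when only the EF-site constant is known.
#: The CD site binds roughly 5-6x more weakly than the EF site.
CD_OVER_EF_RATIO = 5.5


class SpeciationError(RuntimeError):
    """Equilibrium solve failed to converge; carries the final residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (residual={residual:.3e})")
        self.residual = residual


@dataclass(frozen=True)
class MetalSpecies:
    """A metal ion, e.g. Tb3+, Gd3+ or Ca2+."""

    id: str


@dataclass(frozen=True)
class BindingSite:
    """One 1:1 metal-binding site with per-metal dissociation constants (M)."""

    name: str
    kd: Mapping[str, float]

    def __post_init__(self):
        for metal, k in self.kd.items():
            if not (k > 0 and math.isfinite(k)):
                raise ValueError(f"kd for {metal!r} at site {self.name!r} must be > 0")


@dataclass(frozen=True)
class ChelatorSpecies:
    """A small-molecule chelator (e.g. NTA) with per-metal KDs (M)."""

    name: str
    kd: Mapping[str, float]

    def __post_init__(self):
        for metal, k in self.kd.items():
            if not (k > 0 and math.isfinite(k)):
                raise ValueError(f"kd for {metal!r} on {self.name!r} must be > 0")


@dataclass(frozen=True)
class BindingSystem:
    """Sites, metals and chelators plus every pairwise dissociation constant."""

    sites: Sequence[BindingSite]
    metals: Sequence[MetalSpecies]
    chelators: Sequence[ChelatorSpecies] = ()

    def __post_init__(self):
        ids = [m.id for m in self.metals]
        if len(ids) != len(set(ids)):
            raise ValueError("metal ids must be unique")
        names = [s.name for s in self.sites]
        if len(names) != len(set(names)):
            raise ValueError("site names must be unique")
        declared = set(ids)
        for holder in (*self.sites, *self.chelators):
            undeclared = set(holder.kd) - declared
            if undeclared:
                raise ValueError(
                    f"{holder.name!r} has kd entries for undeclared metals {sorted(undeclared)}"
                )

    def metal_ids(self) -> list[str]:
        return [m.id for m in self.metals]

    @staticmethod
    def two_site(
        metal_kds_ef: Mapping[str, float],
        metal_kds_cd: Mapping[str, float] | None = None,
        chelators: Sequence[ChelatorSpecies] = (),
    ) -> "BindingSystem":
        """EF/CD system; CD defaults to EF x 5.5 (the weaker site)."""
        if metal_kds_cd is None:
            metal_kds_cd = {m: k * CD_OVER_EF_RATIO for m, k in metal_kds_ef.items()}
        metals = sorted(set(metal_kds_ef) | set(metal_kds_cd) | {m for c in chelators for m in c.kd})
        return BindingSystem(
            sites=(BindingSite("EF", dict(metal_kds_ef)), BindingSite("CD", dict(metal_kds_cd))),
            metals=tuple(MetalSpecies(m) for m in metals),
            chelators=tuple(chelators),
        )


@dataclass(frozen=True)
class MixtureSpec:
    """Total (analytical) concentrations of every component, mol/L."""

    protein_total: float
    metal_total: Mapping[str, float] = field(default_factory=dict)
    chelator_total: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for label, value in (
            ("protein_total", self.protein_total),
            *self.metal_total.items(),
            *self.chelator_total.items(),
        ):
            if not (math.isfinite(value) and value >= 0):
                raise ValueError(f"total for {label!r} must be finite and >= 0, got {value}")

    def with_metal(self, metal: str, total: float) -> "MixtureSpec":
        new = dict(self.metal_total)
        new[metal] = total
        return MixtureSpec(self.protein_total, new, dict(self.chelator_total))


@dataclass(frozen=True)
class SpeciationState:
    """Equilibrium concentrations: free per component, bound per pair (mol/L)."""

    free: Mapping[str, float]
    site_bound: Mapping[tuple[str, str], float]
    chelator_bound: Mapping[tuple[str, str], float]

    def bound_to_site(self, site: str, metal: str) -> float:
        return self.site_bound.get((site, metal), 0.0)

    def total_bound(self, metal: str) -> float:
        return sum(v for (s, m), v in self.site_bound.items() if m == metal) + sum(
            v for (c, m), v in self.chelator_bound.items() if m == metal
        )


@dataclass(frozen=True)
class LuminescenceModel:
    """Linear signal model: weighted sum of site-bound luminescent metal.

    The EF site dominates the terbium luminescence (about 5x the CD-site
    contribution), hence the default weights.
    """

    luminescent_metal: str = "Tb3+"
    weight: Mapping[str, float] = field(default_factory=lambda: {"EF": 5.0, "CD": 1.0})

    def __post_init__(self):
        if any(w < 0 for w in self.weight.values()):
            raise ValueError("luminescence weights must be >= 0")


def _binding_factors(system: BindingSystem, free_metal: Mapping[str, float]):
    """Free site/chelator concentrations implied by free-metal levels.

    With independent 1:1 sites the occupancy of site s is analytic given
    the free metal concentrations:  [s]_free = S_tot / (1 + sum_m [m]/kd).
    """
    denom_sites = {
        s.name: 1.0 + sum(free_metal[m] / s.kd[m] for m in s.kd) for s in system.sites
    }
    denom_chel = {
        c.name: 1.0 + sum(free_metal[m] / c.kd[m] for m in c.kd) for c in system.chelators
    }
    return denom_sites, denom_chel


def solve_speciation(
    system: BindingSystem,
    mixture: MixtureSpec,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> SpeciationState:
    """Solve the coupled mass-action equilibrium of the full mixture.

    Damped fixed-point iteration on the free metal concentrations in log
    space; site and chelator occupancies follow analytically at each
    step.  The returned state closes every mass balance to a relative
    residual below ``tol``.

    Parameters
    ----------
    tol : relative mass-balance tolerance, in (0, 1e-3].
    max_iter : iteration cap; exceeding it raises :class:`SpeciationError`.
    """
    if not (0 < tol <= 1e-3):
        raise ValueError("tol must be in (0, 1e-3]")
    metals = system.metal_ids()
    undeclared = set(mixture.metal_total) - set(metals)
    if undeclared:
        raise ValueError(f"mixture references undeclared metals {sorted(undeclared)}")
    known_chel = {c.name for c in system.chelators}
    undeclared_c = set(mixture.chelator_total) - known_chel
    if undeclared_c:
        raise ValueError(f"mixture references undeclared chelators {sorted(undeclared_c)}")

    p_tot = mixture.protein_total
    m_tot = {m: mixture.metal_total.get(m, 0.0) for m in metals}
    c_tot = {c.name: mixture.chelator_total.get(c.name, 0.0) for c in system.chelators}

    active = [m for m in metals if m_tot[m] > 0]
    free_m = {m: m_tot[m] for m in metals}  # start from the no-binding limit

    def residual(fm: Mapping[str, float]) -> float:
        denom_sites, denom_chel = _binding_factors(system, fm)
        worst = 0.0
        for m in active:
            acc = fm[m]
            for s in system.sites:
                if m in s.kd:
                    acc += (p_tot / denom_sites[s.name]) * fm[m] / s.kd[m]
            for c in system.chelators:
                if m in c.kd:
                    acc += (c_tot[c.name] / denom_chel[c.name]) * fm[m] / c.kd[m]
            worst = max(worst, abs(acc - m_tot[m]) / m_tot[m])
        return worst

    damping = 1.0
    res = residual(free_m)
    for _ in range(max_iter):
        if res <= tol:
            break
        denom_sites, denom_chel = _binding_factors(system, free_m)
        proposal = {}
        for m in active:
            binder = 0.0
            for s in system.sites:
                if m in s.kd:
                    binder += (p_tot / denom_sites[s.name]) / s.kd[m]
            for c in system.chelators:
                if m in c.kd:
                    binder += (c_tot[c.name] / denom_chel[c.name]) / c.kd[m]
            proposal[m] = m_tot[m] / (1.0 + binder)
        # geometric (log-space) damping keeps iterates positive
        new_free = dict(free_m)
        for m in active:
            new_free[m] = free_m[m] ** (1 - damping) * proposal[m] ** damping
        new_res = residual(new_free)
        if new_res > res and damping > 1e-3:
            damping *= 0.5  # oscillation: damp harder, retry from current point
            continue
        free_m, res = new_free, new_res
    else:
        raise SpeciationError("speciation did not converge", res)

    denom_sites, denom_chel = _binding_factors(system, free_m)
    site_bound = {}
    free = dict(free_m)
    for s in system.sites:
        s_free = p_tot / denom_sites[s.name]
        free[s.name] = s_free
        for m in s.kd:
            site_bound[(s.name, m)] = s_free * free_m[m] / s.kd[m]
    chel_bound = {}
    for c in system.chelators:
        c_free = c_tot[c.name] / denom_chel[c.name]
        free[c.name] = c_free
        for m in c.kd:
            chel_bound[(c.name, m)] = c_free * free_m[m] / c.kd[m]
    return SpeciationState(free=free, site_bound=site_bound, chelator_bound=chel_bound)


def luminescence_intensity(state: SpeciationState, model: LuminescenceModel) -> float:
    """Weighted sum of site-bound luminescent metal, arbitrary units."""
    return sum(
        w * state.bound_to_site(site, model.luminescent_metal)
        for site, w in model.weight.items()
    )


def competition_curve(
    system: BindingSystem,
    mixture: MixtureSpec,
    titrant: str,
    grid: Sequence[float],
    signal: LuminescenceModel | None = None,
    tol: float = 1e-12,
):
    """Noiseless competition titration: one speciation solve per grid point.

    Returns a :class:`lanthakit.fitting.TitrationCurve` whose signal is
    the luminescence intensity of the (partially displaced) luminescent
    metal at each titrant concentration.
    """
    from .fitting import TitrationCurve  # avoid import cycle

    if signal is None:
        signal = LuminescenceModel()
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(grid < 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be non-negative and strictly increasing")
    declared = set(system.metal_ids()) | {c.name for c in system.chelators}
    if titrant not in declared:
        raise ValueError(f"titrant {titrant!r} not declared in system")

    values = []
    for total in grid:
        if titrant in system.metal_ids():
            mix = mixture.with_metal(titrant, float(total))
        else:
            chel = dict(mixture.chelator_total)
            chel[titrant] = float(total)
            mix = MixtureSpec(mixture.protein_total, dict(mixture.metal_total), chel)
        state = solve_speciation(system, mix, tol=tol)
        values.append(luminescence_intensity(state, signal))
    return TitrationCurve(
        titrant=grid,
        signal=np.asarray(values),
        meta={"signal_kind": "luminescence", "titrant": titrant,
              "protein_total_M": mixture.protein_total,
              "fixed_metals_M": dict(mixture.metal_total)},
    )


def cheng_prusoff_true_kd(kapp: float, competitor_conc: float, competitor_kd: float) -> float:
    """True KD of the titrated species from its competition-assay midpoint.

    KD = K_app / (1 + [competitor]/KD_competitor).
    """
    if min(kapp, competitor_conc, competitor_kd) <= 0:
        raise ValueError("all arguments must be > 0")
    return kapp / (1.0 + competitor_conc / competitor_kd)


def competitor_kd_from_kapp(kapp: float, competitor_conc: float, titrator_kd: float) -> float:
    """Transposed conversion: the competitor's true KD instead.

    KD_competitor = [competitor] * KD_titrator / (K_app - KD_titrator);
    requires K_app > KD_titrator (otherwise there was no competition).
    """
    if competitor_conc <= 0 or titrator_kd <= 0:
        raise ValueError("concentrations and KDs must be > 0")
    if kapp <= titrator_kd:
        raise ValueError("kapp must exceed the titrator KD (no competition signal)")
    return competitor_conc * titrator_kd / (kapp - titrator_kd)


def fraction_bound_quadratic(probe_total: float, ligand_total: float, kd: float) -> float:
    """Exact 1:1 bound fraction of the probe, with ligand depletion.

    Closed-form root of the binding quadratic:
    f = ((P+L+K) - sqrt((P+L+K)^2 - 4PL)) / (2P).
    """
    if probe_total <= 0:
        raise ValueError("probe_total must be > 0")
    if ligand_total < 0 or kd < 0:
        raise ValueError("ligand_total and kd must be >= 0")
    b = probe_total + ligand_total + kd
    disc = b * b - 4.0 * probe_total * ligand_total
    return (b - math.sqrt(max(disc, 0.0))) / (2.0 * probe_total)


# the anisotropy titration reads out exactly this bound fraction
anisotropy_fraction_bound = fraction_bound_quadratic
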