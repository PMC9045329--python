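"""Metabolic control analysis: scaled flux control and response coefficients.

The control a component exerts on growth is quantified by the scaled
coefficient eps = (phi/mu) dmu/dphi, computed by a forward finite
difference: the component level (enzyme proteome fraction, diffusion
coefficient, or moiety pool total) is increased by 1%, the steady state is
re-solved, and the fractional growth-rate change is divided by the
fractional perturbation.  Over enzymes and diffusion processes the scaled
coefficients obey the summation theorem (sum = 1 to finite-difference
tolerance); moiety response coefficients are not so constrained.

The systemic flux is the gross specific growth rate by default; any
reaction flux can be selected instead (used for toy networks that have no
growth coupling).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import MetabolicState, SteadyStateResult, solve_steady_state
from .network import NetworkModel

__all__ = ["ControlProfile", "flux_control_coefficient",
           "response_coefficient", "control_profile", "methanol_grid"]


class PerturbationError(RuntimeError):
    """Perturbed steady-state solve failed for a named component."""

    def __init__(self, component: str, message: str = ""):
        self.component = component
        super().__init__(f"perturbed solve failed for {component!r} {message}")


@dataclass
class ControlProfile:
    methanol: np.ndarray  # mol/L grid
    coefficients: dict[tuple[str, float], float]  # (component, methanol)
    component_kind: dict[str, str]  # enzyme | diffusion | moiety
    summation_residual: dict[float, float] = field(default_factory=dict)
    failures: list[tuple[str, float]] = field(default_factory=list)

    def series(self, component: str) -> np.ndarray:
        return np.array([self.coefficients.get((component, c), np.nan)
                         for c in self.methanol])


def methanol_grid(c_min: float = 1e-6, c_max: float = 1.0,
                  per_decade: int = 40) -> np.ndarray:
    """Logarithmic methanol grid (mol/L), inclusive of both endpoints."""
    n = int(round(np.log10(c_max / c_min) * per_decade)) + 1
    return np.logspace(np.log10(c_min), np.log10(c_max), n)


def _objective(ss: SteadyStateResult, objective: str) -> float:
    if objective == "mu":
        return ss.mu
    if objective == "mu_net":
        return ss.mu_net
    if objective.startswith("flux:"):
        return ss.velocities[objective.split(":", 1)[1]]
    raise ValueError(f"unknown objective {objective!r}")


def _solve(model: NetworkModel, x0: MetabolicState | None,
           **kw) -> SteadyStateResult:
    return solve_steady_state(model, x0=x0, polish=True, **kw)


def _perturbed(model: NetworkModel, enzyme_id: str, factor: float
               ) -> NetworkModel:
    diff_species = {d.species for d in model.diffusions}
    if enzyme_id in diff_species:
        diffs = [replace(d, d_coeff=d.d_coeff * factor)
                 if d.species == enzyme_id else d for d in model.diffusions]
        return replace(model, diffusions=diffs)
    rxn = model.reaction(enzyme_id)
    return model.with_phi(enzyme_id, rxn.phi * factor)


def flux_control_coefficient(model: NetworkModel, enzyme_id: str,
                             delta: float = 0.01, objective: str = "mu",
                             baseline: SteadyStateResult | None = None,
                             central: bool = False) -> float:
    """Scaled flux control coefficient of an enzyme or diffusion process.

    ``enzyme_id`` may name an enzyme reaction (its proteome fraction is
    perturbed) or a diffusion species (its diffusion coefficient is
    perturbed).  Forward difference at ``+delta`` relative by default;
    ``central=True`` uses a symmetric difference (second-order accurate,
    for robustness studies).
    """
    if baseline is None:
        baseline = _solve(model, None)
    mu0 = _objective(baseline, objective)
    if mu0 == 0:
        raise PerturbationError(enzyme_id, "(zero baseline flux)")

    ss = _solve(_perturbed(model, enzyme_id, 1 + delta), baseline.state)
    if not ss.converged:
        raise PerturbationError(enzyme_id, f"(residual {ss.residual:.2g})")
    mu_plus = _objective(ss, objective)
    if not central:
        return (mu_plus / mu0 - 1.0) / delta
    ss_m = _solve(_perturbed(model, enzyme_id, 1 - delta), baseline.state)
    if not ss_m.converged:
        raise PerturbationError(enzyme_id, f"(residual {ss_m.residual:.2g})")
    return (mu_plus - _objective(ss_m, objective)) / (2 * delta * mu0)


def response_coefficient(model: NetworkModel, moiety_id: str,
                         delta: float = 0.01, objective: str = "mu",
                         baseline: SteadyStateResult | None = None) -> float:
    """Scaled flux response coefficient of a conserved moiety pool total.

    The pool total is increased by ``delta`` relative and all member
    concentrations are rescaled proportionally (intra-pool ratios are
    preserved) before re-solving.
    """
    if baseline is None:
        baseline = _solve(model, None)
    mu0 = _objective(baseline, objective)
    if mu0 == 0:
        raise PerturbationError(moiety_id, "(zero baseline flux)")
    pool = model.moieties[moiety_id]
    if pool.total <= 0:
        raise PerturbationError(moiety_id, "(empty pool)")

    pert = model.copy()
    pert.moieties[moiety_id] = replace(pool, total=pool.total * (1 + delta))
    x0 = MetabolicState(dict(baseline.state.conc), baseline.state.psi)
    for member in pool.members:
        # members in several pools are scaled once; the algebraic
        # elimination restores exact conservation on the first rhs call
        x0.conc[member] = baseline.state.conc[member] * (1 + delta)
        pert.metabolites[member].concentration_init = x0.conc[member]
    ss = _solve(pert, x0)
    if not ss.converged:
        raise PerturbationError(moiety_id, f"(residual {ss.residual:.2g})")
    return (_objective(ss, objective) / mu0 - 1.0) / delta


def maintenance_coefficient(model: NetworkModel, delta: float = 0.01,
                            objective: str = "mu",
                            baseline: SteadyStateResult | None = None
                            ) -> float:
    """Scaled sensitivity of growth to the maintenance ATP demand."""
    if baseline is None:
        baseline = _solve(model, None)
    mu0 = _objective(baseline, objective)
    if mu0 == 0:
        raise PerturbationError("maintenance", "(zero baseline flux)")
    pert = model.copy()
    pert.cell = replace(pert.cell,
                        maintenance_atp=pert.cell.maintenance_atp
                        * (1 + delta))
    ss = _solve(pert, baseline.state)
    if not ss.converged:
        raise PerturbationError("maintenance",
                                f"(residual {ss.residual:.2g})")
    return (_objective(ss, objective) / mu0 - 1.0) / delta


def control_profile(model: NetworkModel, grid=None, delta: float = 0.01,
                    objective: str = "mu", components: list | None = None
                    ) -> ControlProfile:
    """Control/response coefficients of every component across methanol.

    Components default to all enzyme reactions, all diffusion processes and
    all moiety pools.  Failures at individual grid points are recorded on
    the profile, not raised.
    """
    grid = methanol_grid() if grid is None else np.asarray(grid, float)
    kinds: dict[str, str] = {}
    for r in model.enzyme_reactions:
        kinds[r.id] = "enzyme"
    for d in model.diffusions:
        kinds[d.species] = "diffusion"
    if model.cell.maintenance_atp > 0 and objective in ("mu", "mu_net"):
        # the constant maintenance drain is itself a flux-carrying process;
        # the summation theorem closes only over the full process set
        kinds["maintenance"] = "maintenance"
    for p in model.moieties.values():
        kinds[p.id] = "moiety"
    if components is not None:
        kinds = {k: v for k, v in kinds.items() if k in components}

    profile = ControlProfile(grid, {}, kinds)
    state = None
    for conc in grid:
        m = model.set_methanol(float(conc))
        base = _solve(m, state)
        state = base.state
        total = 0.0
        for comp, kind in kinds.items():
            try:
                if kind == "moiety":
                    eps = response_coefficient(m, comp, delta, objective,
                                               baseline=base)
                elif kind == "maintenance":
                    eps = maintenance_coefficient(m, delta, objective,
                                                  baseline=base)
                else:
                    eps = flux_control_coefficient(m, comp, delta, objective,
                                                   baseline=base)
            except PerturbationError:
                profile.failures.append((comp, float(conc)))
                continue
            profile.coefficients[(comp, float(conc))] = eps
            if kind != "moiety":
                total += eps
        profile.summation_residual[float(conc)] = total - 1.0
    return profile
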