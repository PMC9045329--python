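"""Per-reaction thermodynamics, velocities, and diffusive exchange fluxes.

Reaction free energy:  dG = RT ln(Q/K) + c_C F dpsi, with Q the mass-action
quotient over all participating species (clamped species included; unit-
activity species such as water and buffered H+/Na+ excluded, their
contribution being folded into the apparent K).

Reaction velocity uses the generalized reversible multiplicative
Michaelis-Menten form: a saturation factor (product of substrate
occupancies over an additive denominator) times the thermodynamic factor
[1 - exp(dG/(chi R T))], which forces v -> 0 at equilibrium and reverses
the reaction beyond it.  The proportionality constant is the enzyme's
maximum velocity W_prot * k_cat * phi (mol/s per cell).

Diffusive exchange with the environment follows the steady diffusion-to-a-
sphere flux J = 4 pi D r (C_env - C_cyto); this formula takes
concentrations in mol/m^3, so the internal mol/L values are scaled by 1e3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .network import (ACTIVITY_ONE_SPECIES, CellParameters, DiffusionProcess,
                      EnzymeReaction)

__all__ = ["ReactionThermo", "ReactionVelocity", "reaction_gibbs",
           "reaction_velocity", "diffusive_flux", "saturation_factor"]


@dataclass(frozen=True)
class ReactionThermo:
    delta_g: float  # J/mol
    quotient: float
    keq: float
    charge_term: float  # c_C * F * dpsi, J/mol


@dataclass(frozen=True)
class ReactionVelocity:
    v: float  # mol/s per cell
    saturation_factor: float
    thermo_factor: float


def reaction_gibbs(rxn: EnzymeReaction, state, cell: CellParameters
                   ) -> ReactionThermo:
    """Gibbs free energy change of ``rxn`` at the given metabolic state.

    ``state`` is any object with a ``conc`` mapping (mol/L) and ``psi`` (V).

    Raises
    ------
    ValueError
        if a species entering the quotient has a non-positive concentration.
    """
    ln_q = 0.0
    for sp, coef in rxn.stoich.items():
        if sp in ACTIVITY_ONE_SPECIES:
            continue
        c = state.conc[sp]
        if c <= 0:
            raise ValueError(
                f"reaction {rxn.id}: non-positive concentration for {sp}")
        ln_q += coef * math.log(c)
    charge = rxn.charge_out * cell.faraday * state.psi
    dg = cell.rt * (ln_q - math.log(rxn.keq)) + charge
    return ReactionThermo(dg, math.exp(ln_q), rxn.keq, charge)


def saturation_factor(rxn: EnzymeReaction, conc) -> float:
    """Kinetic occupancy term of the reversible MM rate law.

    Default ("additive") form:
        prod over substrates of (C_S/K_m,S)^|c|
        over 1 + sum over substrates and products of (C/K_m)^|c|.

    "convenience" form (independent site per substrate, e.g. for enzymes
    whose apparent catalytic constant factorizes per substrate):
        prod over substrates of r/(1+r), r = (C_S/K_m,S)^|c|,
        times 1/(1 + sum over products of (C_P/K_m,P)^|c|).

    Species without a Michaelis constant (unit-activity species) do not
    enter.  Negative concentrations are clipped to zero.
    """
    terms = [((max(conc[sp], 0.0) / rxn.km[sp]) ** abs(coef), coef < 0)
             for sp, coef in rxn.stoich.items() if sp in rxn.km]
    if rxn.rate_law == "convenience":
        sat = 1.0
        p_sum = 0.0
        for r, is_sub in terms:
            if is_sub:
                sat *= r / (1.0 + r)
            else:
                p_sum += r
        return sat / (1.0 + p_sum)
    num = 1.0
    den = 1.0
    for r, is_sub in terms:
        den += r
        if is_sub:
            num *= r
    return num / den


def reaction_velocity(rxn: EnzymeReaction, state, cell: CellParameters
                      ) -> ReactionVelocity:
    """Net velocity of an enzyme reaction (mol/s per cell).

    v = W_prot k phi * saturation * [1 - exp(dG/(chi R T))]; the sign of v
    always matches the sign of the thermodynamic driving force (-dG).
    """
    thermo = reaction_gibbs(rxn, state, cell)
    tf = 1.0 - math.exp(min(thermo.delta_g / (rxn.chi * cell.rt), 500.0))
    sat = saturation_factor(rxn, state.conc)
    vmax = cell.w_prot * rxn.kcat * rxn.phi
    return ReactionVelocity(vmax * sat * tf, sat, tf)


def diffusive_flux(proc: DiffusionProcess, state, cell: CellParameters
                   ) -> float:
    """Diffusive flux into the cell, mol/s (positive = net influx)."""
    delta_molar = proc.c_env - state.conc[proc.species]
    return 4.0 * math.pi * proc.d_coeff * cell.radius * (delta_molar * 1e3)
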