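"""Coupling of pathway fluxes to biomass synthesis and maintenance.

Herbert-Pirt logic: the ATP flux produced by ATP synthase is split between a
constant maintenance demand and biomass synthesis; the biomass pseudo-
reaction flux (g biomass per s per cell) is the ATP surplus divided by the
ATP cost per gram, and drags the reduced-cofactor and acetyl-CoA drains
along with fixed per-gram coefficients.  The gross specific growth rate is
the total ATP flux expressed in biomass equivalents; the net rate subtracts
the maintenance equivalent and is what a culture would realize.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dynamics import SteadyStateResult
from .network import BiomassStoichiometry, CellParameters, NetworkModel

__all__ = ["GrowthFluxes", "maintenance_reaction", "growth_rate_from_fluxes",
           "yield_report"]


@dataclass(frozen=True)
class GrowthFluxes:
    atp_synthase_flux: float  # mol ATP/s per cell
    maintenance_flux: float  # mol ATP/s per cell
    biomass_flux: float  # g biomass/s per cell (clamped at 0)
    mu: float  # net specific growth rate from the clamped biomass flux, 1/s
    mu_gross: float  # total ATP flux in biomass equivalents, 1/s
    drains: dict[str, float]  # mol/s consumed by biomass synthesis


def maintenance_reaction(cell: CellParameters) -> float:
    """Constant maintenance ATP-hydrolysis flux per cell (mol/s)."""
    return cell.maintenance_atp * cell.dry_mass


def growth_rate_from_fluxes(v_atp_synthase: float, maint: float,
                            bio: BiomassStoichiometry, cell: CellParameters
                            ) -> GrowthFluxes:
    """Partition the ATP synthase flux into maintenance and growth."""
    if bio.atp_per_g <= 0:
        raise ValueError("atp_per_g must be positive")
    biomass_flux = max(0.0, v_atp_synthase - maint) / bio.atp_per_g
    drains = {
        "atp": bio.atp_per_g * biomass_flux,
        "f420h2": bio.f420h2_per_g * biomass_flux,
        "fd_red": bio.fdred_per_g * biomass_flux,
        "accoa": bio.accoa_per_g * biomass_flux,
    }
    return GrowthFluxes(
        atp_synthase_flux=v_atp_synthase,
        maintenance_flux=maint,
        biomass_flux=biomass_flux,
        mu=biomass_flux / cell.dry_mass,
        mu_gross=v_atp_synthase / bio.atp_per_g / cell.dry_mass,
        drains=drains,
    )


def yield_report(ss: SteadyStateResult, model: NetworkModel | None = None
                 ) -> dict[str, float]:
    """CO2 and CH4 produced per methanol consumed at steady state.

    Effluxes are the negatives of the diffusive influxes.  Both ratios fall
    below the catabolic stoichiometry (1/4 CO2, 3/4 CH4 per methanol)
    whenever biosynthesis drains carbon and reducing power from the pathway.

    Raises
    ------
    ValueError
        if the methanol influx is zero (ratios undefined).
    """
    j_meoh = ss.fluxes.get("ch3oh_c", 0.0)
    if j_meoh == 0:
        raise ValueError("methanol influx is zero; yields undefined")
    return {
        "co2_per_methanol": -ss.fluxes.get("co2_c", 0.0) / j_meoh,
        "ch4_per_methanol": -ss.fluxes.get("ch4_c", 0.0) / j_meoh,
        "methanol_influx": j_meoh,
    }
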