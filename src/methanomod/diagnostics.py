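"""Steady-state validation summaries.

Three diagnostics mirror the classic physiological checks for
methylotrophic methanogenesis: how the electrons liberated by methyl-group
oxidation reach the heterodisulfide reductase (H2 cycling through the
membrane hydrogenases versus direct F420H2 oxidation), how free energy is
distributed over the enzyme reactions, and how metabolite concentrations
compare with the Michaelis constants of the enzymes that bind them.
"""

from __future__ import annotations

import pandas as pd

from .dynamics import SteadyStateResult
from .network import NetworkModel

__all__ = ["electron_flux_partition", "delta_g_census", "km_census"]


def electron_flux_partition(ss: SteadyStateResult, model: NetworkModel
                            ) -> dict[str, float]:
    """Partition of electron flux into methanophenazine reduction.

    Electrons from the oxidation branch reach the membrane pool either as
    H2 (produced by the F420-reducing and Ech hydrogenases and re-oxidized
    by the methanophenazine-dependent hydrogenase) or directly via the
    F420H2 dehydrogenase.  Shares are normalized to the total
    methanophenazine reduction flux and sum to one.
    """
    v_h2 = ss.velocities.get("VHT", 0.0)
    v_direct = ss.velocities.get("FPO", 0.0)
    total = v_h2 + v_direct
    if total == 0:
        raise ValueError("no electron flux into the membrane pool")
    return {"h2_cycling": v_h2 / total, "f420_direct": v_direct / total,
            "mcr_flux": ss.velocities.get("MCR", 0.0)}


def delta_g_census(ss: SteadyStateResult) -> pd.DataFrame:
    """Per-reaction Gibbs free energy table (kJ/mol), sorted ascending."""
    df = pd.DataFrame(
        {"reaction": list(ss.delta_g),
         "delta_g_kj_mol": [v / 1e3 for v in ss.delta_g.values()],
         "velocity": [ss.velocities[r] for r in ss.delta_g]})
    return df.sort_values("delta_g_kj_mol").reset_index(drop=True)


def km_census(ss: SteadyStateResult, model: NetworkModel
              ) -> tuple[float, pd.DataFrame]:
    """Fraction of (metabolite, enzyme) pairs with C above the Km.

    Every Michaelis constant of every enzyme reaction contributes one pair
    (a metabolite bound by several enzymes is counted once per enzyme),
    matching a concentration-vs-Km scatter.
    """
    rows = []
    for rxn in model.enzyme_reactions:
        for sp, km in rxn.km.items():
            c = ss.state.conc[sp]
            rows.append((rxn.id, sp, c, km, c / km, c > km))
    df = pd.DataFrame(rows, columns=["reaction", "metabolite",
                                     "concentration", "km", "ratio",
                                     "above"])
    return float(df["above"].mean()), df
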