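"""Network data model: the parameterized *M. barkeri* methanogenesis network.

The model couples a spherical two-compartment cell (cytoplasm wrapped by the
membrane) to its environment through free diffusion of methanol, CO2 and CH4.
Sixteen enzyme reactions (9 cytoplasmic, 7 membrane-associated), a constant
ATP-hydrolysis maintenance reaction and a pseudo-biomass reaction consume and
produce 35 metabolites; conserved cofactor moieties (coenzyme M, coenzyme B,
F420, ferredoxin, methanophenazine, H4SPT, methanofuran, coenzyme A) tie
metabolite concentrations together.

A model is usually built from a flat parameter table (one row per
(entity, parameter), tab-separated) via :func:`build_default_model`; the
packaged default table is produced by :mod:`methanomod.synthetic`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .constants import to_si

__all__ = [
    "Compartment",
    "Metabolite",
    "MoietyPool",
    "EnzymeReaction",
    "DiffusionProcess",
    "CellParameters",
    "BiomassStoichiometry",
    "NetworkModel",
    "ModelValidationError",
    "build_default_model",
    "validate_model",
    "model_to_table",
]

#: species treated at unit activity: excluded from reaction quotients and
#: saturation terms; their thermodynamic contribution is folded into the
#: apparent equilibrium constants (pH 7, buffered Na+, solvent water).
ACTIVITY_ONE_SPECIES = frozenset(
    {"h2o", "h_c", "h_out", "na_c", "na_out", "biomass"}
)


class ModelValidationError(ValueError):
    """Raised when a parameter table or assembled model is inconsistent."""

    def __init__(self, message: str, reaction: str | None = None,
                 fieldname: str | None = None):
        self.reaction = reaction
        self.fieldname = fieldname
        super().__init__(message)


@dataclass(frozen=True)
class Compartment:
    id: str
    volume: float  # L

    def __post_init__(self):
        if self.volume <= 0:
            raise ModelValidationError(
                f"compartment {self.id!r}: volume must be > 0")


@dataclass
class Metabolite:
    id: str
    compartment: str
    concentration_init: float  # mol/L
    fixed: bool = False
    moieties: list[str] = field(default_factory=list)


@dataclass
class MoietyPool:
    """A conserved chemical moiety: sum of member concentrations is constant."""

    id: str
    members: list[str]  # last-listed member is eliminated algebraically
    total: float  # mol/L


@dataclass
class EnzymeReaction:
    """One reaction with its thermodynamic/kinetic parameterization.

    ``kind`` is "enzyme" for the 16 catalyzed reactions, "maintenance" for
    the constant ATP drain, "biomass" for the pseudo-biomass reaction (whose
    flux is assigned from the ATP surplus, not from a rate law).
    """

    id: str
    stoich: dict[str, float]  # metabolite -> coefficient (negative = consumed)
    km: dict[str, float] = field(default_factory=dict)  # mol/L
    kcat: float = 0.0  # mol per g proteome per s
    phi: float = 0.0  # proteome mass fraction
    keq: float = 1.0  # apparent equilibrium constant (pH 7)
    chi: int = 1  # electrons transferred / charges translocated per turnover
    charge_out: float = 0.0  # c_C: charges moved out of the cytoplasm
    compartment: str = "cytoplasm"
    kind: str = "enzyme"
    #: saturation-term variant: "additive" (single shared denominator) or
    #: "convenience" (independent hyperbolic site per substrate, shared
    #: product-inhibition factor); the latter matches enzymes whose apparent
    #: catalytic constant factorizes per substrate
    rate_law: str = "additive"

    @property
    def substrates(self) -> list[str]:
        return [m for m, c in self.stoich.items() if c < 0]

    @property
    def products(self) -> list[str]:
        return [m for m, c in self.stoich.items() if c > 0]


@dataclass
class DiffusionProcess:
    """Free diffusion of a small solute across the membrane (Fiksen-type)."""

    species: str  # cytoplasmic metabolite id
    d_coeff: float  # m^2/s
    c_env: float  # environmental concentration, mol/L

    def __post_init__(self):
        if self.d_coeff <= 0:
            raise ModelValidationError(
                f"diffusion {self.species!r}: d_coeff must be > 0")


@dataclass
class CellParameters:
    radius: float  # m
    capacitance: float  # F (whole cell)
    w_prot: float  # g protein per cell
    dry_mass: float  # g dry weight per cell
    temperature: float  # K
    maintenance_atp: float  # mol ATP per gdw per s
    phi_membrane_total: float = 0.10
    faraday: float = 96485.0
    gas_const: float = 8.3145

    @property
    def rt(self) -> float:
        return self.gas_const * self.temperature


@dataclass
class BiomassStoichiometry:
    """Per-gram biomass demands (from genome-scale FBA, used as constants)."""

    atp_per_g: float  # mol ATP / g biomass
    fdred_per_g: float
    f420h2_per_g: float
    accoa_per_g: float
    y_p_ch3oh: float  # g biomass per mol methanol (gross, low-substrate limit)
    y_p_ch4: float  # g biomass per mol methane (gross, high-substrate limit)


@dataclass
class NetworkModel:
    compartments: dict[str, Compartment]
    metabolites: dict[str, Metabolite]
    moieties: dict[str, MoietyPool]
    reactions: list[EnzymeReaction]
    diffusions: list[DiffusionProcess]
    cell: CellParameters
    biomass: BiomassStoichiometry

    @property
    def n_reactions(self) -> int:
        """Total reaction count, diffusion processes included."""
        return len(self.reactions) + len(self.diffusions)

    @property
    def enzyme_reactions(self) -> list[EnzymeReaction]:
        return [r for r in self.reactions if r.kind == "enzyme"]

    @property
    def membrane_enzymes(self) -> list[EnzymeReaction]:
        return [r for r in self.enzyme_reactions if r.compartment == "membrane"]

    def reaction(self, rid: str) -> EnzymeReaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def set_methanol(self, conc: float) -> "NetworkModel":
        """Return a copy with the environmental methanol concentration set."""
        diffs = [replace(d, c_env=conc) if d.species == "ch3oh_c" else d
                 for d in self.diffusions]
        mets = dict(self.metabolites)
        if "ch3oh_env" in mets:
            mets["ch3oh_env"] = replace(mets["ch3oh_env"],
                                        concentration_init=conc)
        return replace(self, diffusions=diffs, metabolites=mets)

    def with_phi(self, rid: str, phi: float) -> "NetworkModel":
        """Return a copy with one enzyme's proteome fraction replaced."""
        rxns = [replace(r, phi=phi) if r.id == rid else r
                for r in self.reactions]
        return replace(self, reactions=rxns)

    def copy(self) -> "NetworkModel":
        return replace(
            self,
            compartments=dict(self.compartments),
            metabolites={k: replace(v, moieties=list(v.moieties))
                         for k, v in self.metabolites.items()},
            moieties={k: replace(v, members=list(v.members))
                      for k, v in self.moieties.items()},
            reactions=[replace(r, stoich=dict(r.stoich), km=dict(r.km))
                       for r in self.reactions],
            diffusions=[replace(d) for d in self.diffusions],
            cell=replace(self.cell),
            biomass=replace(self.biomass),
        )


# ---------------------------------------------------------------------------
# parameter-table parsing

_TABLE_COLUMNS = ["reaction_id", "param_kind", "species_id", "value", "units"]

_RXN_NUM_FIELDS = {"kcat": "mol/g/s", "phi": "dimensionless",
                   "keq": "dimensionless", "chi": "dimensionless",
                   "charge_out": "dimensionless"}

_CELL_FIELDS = {"radius": "m", "capacitance": "F", "w_prot": "g",
                "dry_mass": "g", "temperature": "K",
                "maintenance_atp": "mol/gdw/s",
                "phi_membrane_total": "dimensionless"}

_BIO_FIELDS = {"atp_per_g": "dimensionless", "fdred_per_g": "dimensionless",
               "f420h2_per_g": "dimensionless", "accoa_per_g": "dimensionless",
               "y_p_ch3oh": "g/mol", "y_p_ch4": "g/mol"}


def build_default_model(table: pd.DataFrame) -> NetworkModel:
    """Assemble and validate a :class:`NetworkModel` from a parameter table.

    The table uses the flat layout written by
    :func:`methanomod.synthetic.fixture_barkeri` (columns ``reaction_id``,
    ``param_kind``, ``species_id``, ``value``, ``units``; extra columns such
    as a provenance flag are ignored).

    Raises
    ------
    ModelValidationError
        naming the offending reaction and field if a required parameter is
        missing or inconsistent.
    """
    for col in _TABLE_COLUMNS:
        if col not in table.columns:
            raise ModelValidationError(f"parameter table lacks column {col!r}")

    rows = table.fillna({"species_id": "", "units": ""})

    def groups(prefix: str):
        mask = rows["param_kind"].str.startswith(prefix)
        return rows[mask]

    # compartments
    compartments: dict[str, Compartment] = {}
    for _, r in groups("comp_volume").iterrows():
        compartments[r.reaction_id] = Compartment(
            r.reaction_id, to_si(float(r.value), r.units))

    # metabolites
    metabolites: dict[str, Metabolite] = {}
    for _, r in groups("met_").iterrows():
        met = metabolites.setdefault(
            r.reaction_id, Metabolite(r.reaction_id, "cytoplasm", 0.0))
        if r.param_kind == "met_compartment":
            met.compartment = str(r.value)
        elif r.param_kind == "met_conc_init":
            met.concentration_init = to_si(float(r.value), r.units)
        elif r.param_kind == "met_fixed":
            met.fixed = bool(int(float(r.value)))

    # moiety pools
    moieties: dict[str, MoietyPool] = {}
    for _, r in groups("moiety_").iterrows():
        pool = moieties.setdefault(r.reaction_id,
                                   MoietyPool(r.reaction_id, [], 0.0))
        if r.param_kind == "moiety_member":
            pool.members.append(r.species_id)
            if r.species_id in metabolites:
                metabolites[r.species_id].moieties.append(r.reaction_id)
        elif r.param_kind == "moiety_total":
            pool.total = to_si(float(r.value), r.units)

    # reactions
    rxn_rows = rows[rows["param_kind"].isin(
        ["stoich", "km", "rxn_compartment", "rxn_kind", "rxn_rate_law",
         *_RXN_NUM_FIELDS])]
    reactions: list[EnzymeReaction] = []
    for rid in rxn_rows["reaction_id"].drop_duplicates():
        sub = rxn_rows[rxn_rows["reaction_id"] == rid]
        rxn = EnzymeReaction(rid, {})
        for _, r in sub.iterrows():
            if r.param_kind == "stoich":
                rxn.stoich[r.species_id] = float(r.value)
            elif r.param_kind == "km":
                rxn.km[r.species_id] = to_si(float(r.value), r.units)
            elif r.param_kind == "rxn_compartment":
                rxn.compartment = str(r.value)
            elif r.param_kind == "rxn_kind":
                rxn.kind = str(r.value)
            elif r.param_kind == "rxn_rate_law":
                rxn.rate_law = str(r.value)
            elif r.param_kind == "chi":
                rxn.chi = int(float(r.value))
            else:
                setattr(rxn, r.param_kind, to_si(float(r.value), r.units))
        reactions.append(rxn)

    # diffusion processes
    diffusions: list[DiffusionProcess] = []
    diff_rows = rows[rows["param_kind"].isin(["d_coeff", "c_env"])]
    for rid in diff_rows["reaction_id"].drop_duplicates():
        sub = diff_rows[diff_rows["reaction_id"] == rid]
        kw = {r.param_kind: to_si(float(r.value), r.units)
              for _, r in sub.iterrows()}
        species = sub["species_id"].iloc[0]
        diffusions.append(DiffusionProcess(species, **kw))

    cell_kw = {}
    for _, r in groups("cell_").iterrows():
        cell_kw[r.param_kind[len("cell_"):]] = to_si(float(r.value), r.units)
    missing = set(_CELL_FIELDS) - set(cell_kw)
    if missing:
        raise ModelValidationError(
            f"cell parameters missing: {sorted(missing)}", reaction="cell")
    cell = CellParameters(**cell_kw)

    bio_kw = {}
    for _, r in groups("bio_").iterrows():
        bio_kw[r.param_kind[len("bio_"):]] = to_si(float(r.value), r.units)
    missing = set(_BIO_FIELDS) - set(bio_kw)
    if missing:
        raise ModelValidationError(
            f"biomass stoichiometry missing: {sorted(missing)}",
            reaction="biomass")
    biomass = BiomassStoichiometry(**bio_kw)

    model = NetworkModel(compartments, metabolites, moieties, reactions,
                         diffusions, cell, biomass)
    _check_required(model)
    violations = validate_model(model)
    if violations:
        raise ModelValidationError("; ".join(violations))
    return model


def _check_required(model: NetworkModel) -> None:
    """Hard requirements: every rate-law participant has a Km, etc."""
    for rxn in model.enzyme_reactions:
        if rxn.kcat <= 0:
            raise ModelValidationError(
                f"reaction {rxn.id}: missing kcat", rxn.id, "kcat")
        for sp in rxn.stoich:
            if sp in ACTIVITY_ONE_SPECIES:
                continue
            if sp not in rxn.km:
                raise ModelValidationError(
                    f"reaction {rxn.id}: missing Km for {sp}", rxn.id, "km")


def validate_model(model: NetworkModel) -> list[str]:
    """Consistency diagnostics; returns a list of violations (empty = valid).

    Reports rather than throws so a partially built model can be inspected.
    """
    out: list[str] = []
    for met in model.metabolites.values():
        if met.concentration_init < 0:
            out.append(f"metabolite {met.id}: negative initial concentration")
        if met.compartment not in model.compartments:
            out.append(f"metabolite {met.id}: unknown compartment "
                       f"{met.compartment!r}")
    for pool in model.moieties.values():
        if not pool.members:
            out.append(f"moiety {pool.id}: no members")
            continue
        missing = [m for m in pool.members if m not in model.metabolites]
        if missing:
            out.append(f"moiety {pool.id}: unknown members {missing}")
            continue
        s = sum(model.metabolites[m].concentration_init
                for m in pool.members)
        if abs(s - pool.total) > 1e-9 * max(pool.total, 1e-30):
            out.append(f"moiety {pool.id}: member concentrations sum to "
                       f"{s:.6g}, pool total is {pool.total:.6g}")
    for rxn in model.reactions:
        if not 0 <= rxn.phi <= 1:
            out.append(f"reaction {rxn.id}: phi outside [0, 1]")
        if rxn.kind == "enzyme" and rxn.chi < 1:
            out.append(f"reaction {rxn.id}: chi must be >= 1")
        if rxn.compartment not in model.compartments:
            out.append(f"reaction {rxn.id}: unknown compartment")
        for sp in rxn.stoich:
            if sp not in model.metabolites:
                out.append(f"reaction {rxn.id}: unknown species {sp}")
    phi_m = sum(r.phi for r in model.membrane_enzymes)
    if abs(phi_m - model.cell.phi_membrane_total) > 1e-6:
        out.append(f"membrane enzyme fractions sum to {phi_m:.4g}, "
                   f"budget is {model.cell.phi_membrane_total:.4g}")
    for d in model.diffusions:
        if d.species not in model.metabolites:
            out.append(f"diffusion: unknown species {d.species}")
    return out


def model_to_table(model: NetworkModel, provenance: dict | None = None
                   ) -> pd.DataFrame:
    """Serialize a model back to the flat parameter-table layout.

    Inverse of :func:`build_default_model` up to row order and unit choice
    (everything is written in internal units).
    """
    prov = provenance or {}
    recs: list[tuple] = []

    def add(rid, kind, sp, value, units):
        recs.append((rid, kind, sp, value, units,
                     prov.get((rid, kind, sp), "fixture_default")))

    for comp in model.compartments.values():
        add(comp.id, "comp_volume", "", comp.volume, "L")
    for met in model.metabolites.values():
        add(met.id, "met_compartment", "", met.compartment, "")
        add(met.id, "met_conc_init", "", met.concentration_init, "M")
        add(met.id, "met_fixed", "", int(met.fixed), "dimensionless")
    for pool in model.moieties.values():
        add(pool.id, "moiety_total", "", pool.total, "M")
        for m in pool.members:
            add(pool.id, "moiety_member", m, 1, "dimensionless")
    for rxn in model.reactions:
        add(rxn.id, "rxn_kind", "", rxn.kind, "")
        add(rxn.id, "rxn_compartment", "", rxn.compartment, "")
        if rxn.rate_law != "additive":
            add(rxn.id, "rxn_rate_law", "", rxn.rate_law, "")
        for sp, c in rxn.stoich.items():
            add(rxn.id, "stoich", sp, c, "dimensionless")
        for sp, k in rxn.km.items():
            add(rxn.id, "km", sp, k, "M")
        if rxn.kind == "enzyme":
            for f, units in _RXN_NUM_FIELDS.items():
                add(rxn.id, f, "", getattr(rxn, f), units)
    for d in model.diffusions:
        add(f"diff_{d.species}", "d_coeff", d.species, d.d_coeff, "m2/s")
        add(f"diff_{d.species}", "c_env", d.species, d.c_env, "M")
    for f, units in _CELL_FIELDS.items():
        add("cell", f"cell_{f}", "", getattr(model.cell, f), units)
    for f, units in _BIO_FIELDS.items():
        add("biomass_stoich", f"bio_{f}", "", getattr(model.biomass, f), units)

    return pd.DataFrame.from_records(
        recs, columns=[*_TABLE_COLUMNS, "provenance"])
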