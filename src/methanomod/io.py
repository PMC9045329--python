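"""File formats: parameter TSV, SBML Level 3, result tables, YAML config.

The flat parameter TSV is the native format (one row per (entity,
parameter); see :mod:`methanomod.network`).  SBML L3 import/export covers
the constructs this model uses — compartments, species (clamped species as
boundary conditions), reactions with local parameters for the kinetic
constants, and a small custom annotation namespace for what core SBML does
not carry (moiety pools, charge translocation, rate-law variant, diffusion
processes, cell/biomass parameters).  Files written by this module read
back to an identical model.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml
from lxml import etree

from .network import (BiomassStoichiometry, CellParameters, Compartment,
                      DiffusionProcess, EnzymeReaction, Metabolite,
                      MoietyPool, NetworkModel, build_default_model,
                      model_to_table, _CELL_FIELDS, _BIO_FIELDS)

__all__ = ["read_parameter_tsv", "write_parameter_tsv", "model_to_sbml",
           "sbml_to_model", "write_sbml", "read_sbml", "write_table",
           "load_config", "write_fit_json"]

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_ANN_NS = "urn:methanomod:annotations"


def read_parameter_tsv(path) -> pd.DataFrame:
    """Read a flat parameter table (tab-separated, with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return df


def write_parameter_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_model_tsv(path) -> NetworkModel:
    return build_default_model(read_parameter_tsv(path))


def write_table(df: pd.DataFrame, path) -> None:
    """Write a tidy result table as TSV with headers."""
    df.to_csv(path, sep="\t", index=False)


def write_fit_json(fit, path) -> None:
    """Monod-fit report as JSON (rates in 1/day, K_M in mol/L)."""
    out = {k: getattr(fit, k) for k in
           ("mu_max", "k_m", "alpha", "mu_o", "beta_low", "beta_high")}
    Path(path).write_text(json.dumps(out, indent=2) + "\n")


def load_config(path) -> dict:
    """YAML run configuration (parameter table path, output dir, grids)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


# ---------------------------------------------------------------------------
# SBML

def _q(tag, ns=_SBML_NS):
    return f"{{{ns}}}{tag}"


def model_to_sbml(model: NetworkModel, model_id: str = "methanomod") -> str:
    """Serialize a model to SBML L3 (annotated), returned as a string."""
    E = lambda tag, **kw: etree.SubElement(parent_stack[-1], _q(tag),
                                           **{k: str(v) for k, v in
                                              kw.items()})
    root = etree.Element(_q("sbml"), nsmap={None: _SBML_NS, "mm": _ANN_NS},
                         level="3", version="2")
    parent_stack = [root]
    mdl = E("model", id=model_id)
    parent_stack.append(mdl)

    # annotation: moieties, diffusion, cell, biomass
    ann = etree.SubElement(mdl, _q("annotation"))
    mm = etree.SubElement(ann, _q("model", _ANN_NS))
    for pool in model.moieties.values():
        etree.SubElement(mm, _q("moiety", _ANN_NS), id=pool.id,
                         total=repr(pool.total),
                         members=",".join(pool.members))
    for d in model.diffusions:
        etree.SubElement(mm, _q("diffusion", _ANN_NS), species=d.species,
                         d_coeff=repr(d.d_coeff), c_env=repr(d.c_env))
    cell_el = etree.SubElement(mm, _q("cell", _ANN_NS))
    for f in _CELL_FIELDS:
        cell_el.set(f, repr(getattr(model.cell, f)))
    bio_el = etree.SubElement(mm, _q("biomass", _ANN_NS))
    for f in _BIO_FIELDS:
        bio_el.set(f, repr(getattr(model.biomass, f)))

    parent_stack.append(E("listOfCompartments"))
    for comp in model.compartments.values():
        E("compartment", id=comp.id, size=repr(comp.volume),
          constant="true", spatialDimensions="3")
    parent_stack.pop()

    parent_stack.append(E("listOfSpecies"))
    for met in model.metabolites.values():
        sp = E("species", id=met.id, compartment=met.compartment,
               initialConcentration=repr(met.concentration_init),
               boundaryCondition="true" if met.fixed else "false",
               constant="false", hasOnlySubstanceUnits="false")
        del sp  # attributes only
    parent_stack.pop()

    parent_stack.append(E("listOfReactions"))
    for rxn in model.reactions:
        r = E("reaction", id=rxn.id, reversible="true",
              compartment=rxn.compartment)
        r.set(_q("kind", _ANN_NS), rxn.kind)
        r.set(_q("rateLaw", _ANN_NS), rxn.rate_law)
        r.set(_q("chi", _ANN_NS), str(rxn.chi))
        r.set(_q("chargeOut", _ANN_NS), repr(rxn.charge_out))
        parent_stack.append(r)
        parent_stack.append(E("listOfReactants"))
        for sp, c in rxn.stoich.items():
            if c < 0:
                E("speciesReference", species=sp, stoichiometry=repr(-c),
                  constant="true")
        parent_stack.pop()
        parent_stack.append(E("listOfProducts"))
        for sp, c in rxn.stoich.items():
            if c > 0:
                E("speciesReference", species=sp, stoichiometry=repr(c),
                  constant="true")
        parent_stack.pop()
        if rxn.kind == "enzyme":
            kl = E("kineticLaw")
            parent_stack.append(kl)
            parent_stack.append(E("listOfLocalParameters"))
            E("localParameter", id="kcat", value=repr(rxn.kcat))
            E("localParameter", id="phi", value=repr(rxn.phi))
            E("localParameter", id="keq", value=repr(rxn.keq))
            for sp, km in rxn.km.items():
                E("localParameter", id=f"km_{sp}", value=repr(km))
            parent_stack.pop()
            parent_stack.pop()
        parent_stack.pop()
    parent_stack.pop()

    return etree.tostring(root, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8").decode()


def write_sbml(model: NetworkModel, path) -> None:
    Path(path).write_text(model_to_sbml(model))


class SBMLParseError(ValueError):
    pass


def sbml_to_model(source) -> NetworkModel:
    """Parse SBML written by :func:`model_to_sbml` back into a model.

    Unknown constructs are ignored; a missing chi annotation defaults to 1
    (with a warning).
    """
    import logging
    log = logging.getLogger(__name__)
    text = Path(source).read_text() if isinstance(source, (str, Path)) \
        and "\n" not in str(source) and Path(str(source)).exists() \
        else str(source)
    try:
        root = etree.fromstring(text.encode())
    except etree.XMLSyntaxError as exc:
        raise SBMLParseError(f"malformed SBML: {exc}") from None
    mdl = root.find(_q("model"))
    if mdl is None:
        raise SBMLParseError("no <model> element")

    comps = {}
    for el in mdl.findall(f"{_q('listOfCompartments')}/{_q('compartment')}"):
        comps[el.get("id")] = Compartment(el.get("id"),
                                          float(el.get("size")))
    mets = {}
    for el in mdl.findall(f"{_q('listOfSpecies')}/{_q('species')}"):
        mets[el.get("id")] = Metabolite(
            el.get("id"), el.get("compartment"),
            float(el.get("initialConcentration", "0")),
            fixed=el.get("boundaryCondition") == "true")

    pools, diffs = {}, []
    cell = biomass = None
    ann = mdl.find(f"{_q('annotation')}/{_q('model', _ANN_NS)}")
    if ann is not None:
        for el in ann.findall(_q("moiety", _ANN_NS)):
            members = el.get("members").split(",")
            pools[el.get("id")] = MoietyPool(el.get("id"), members,
                                             float(el.get("total")))
            for m in members:
                if m in mets:
                    mets[m].moieties.append(el.get("id"))
        for el in ann.findall(_q("diffusion", _ANN_NS)):
            diffs.append(DiffusionProcess(el.get("species"),
                                          float(el.get("d_coeff")),
                                          float(el.get("c_env"))))
        el = ann.find(_q("cell", _ANN_NS))
        if el is not None:
            cell = CellParameters(**{f: float(el.get(f))
                                     for f in _CELL_FIELDS})
        el = ann.find(_q("biomass", _ANN_NS))
        if el is not None:
            biomass = BiomassStoichiometry(**{f: float(el.get(f))
                                              for f in _BIO_FIELDS})
    if cell is None or biomass is None:
        raise SBMLParseError("missing cell/biomass annotation")

    rxns = []
    for el in mdl.findall(f"{_q('listOfReactions')}/{_q('reaction')}"):
        stoich: dict[str, float] = {}
        for ref in el.findall(f"{_q('listOfReactants')}"
                              f"/{_q('speciesReference')}"):
            stoich[ref.get("species")] = stoich.get(ref.get("species"), 0) \
                - float(ref.get("stoichiometry", "1"))
        for ref in el.findall(f"{_q('listOfProducts')}"
                              f"/{_q('speciesReference')}"):
            stoich[ref.get("species")] = stoich.get(ref.get("species"), 0) \
                + float(ref.get("stoichiometry", "1"))
        chi_attr = el.get(_q("chi", _ANN_NS))
        if chi_attr is None:
            log.warning("reaction %s: no chi annotation, defaulting to 1",
                        el.get("id"))
            chi_attr = "1"
        rxn = EnzymeReaction(
            el.get("id"), stoich, chi=int(chi_attr),
            charge_out=float(el.get(_q("chargeOut", _ANN_NS), "0")),
            compartment=el.get("compartment", "cytoplasm"),
            kind=el.get(_q("kind", _ANN_NS), "enzyme"),
            rate_law=el.get(_q("rateLaw", _ANN_NS), "additive"))
        for lp in el.findall(f"{_q('kineticLaw')}"
                             f"/{_q('listOfLocalParameters')}"
                             f"/{_q('localParameter')}"):
            pid, val = lp.get("id"), float(lp.get("value"))
            if pid.startswith("km_"):
                rxn.km[pid[3:]] = val
            else:
                setattr(rxn, pid, val)
        rxns.append(rxn)

    return NetworkModel(comps, mets, pools, rxns, diffs, cell, biomass)


def read_sbml(path) -> NetworkModel:
    return sbml_to_model(Path(path).read_text())
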