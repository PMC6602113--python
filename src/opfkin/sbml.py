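"""Minimal SBML Level 3 export/import for the reaction network.

The exporter writes the model's species (with initial concentrations in μM),
global parameters (second-order constants in μM⁻¹s⁻¹) and mass-action
reactions.  The importer reads parameter values and species initial
concentrations through an explicit identifier mapping, so a deposited model
whose internal identifiers differ from this package's names can be adapted by
editing the mapping table alone; a scale entry converts a deposited value into
this package's μM/seconds convention when the source units differ.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

from .model import CONSTANT_NAMES, SPECIES, RateConstants, StateVector

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

#: reaction name -> (reactants, products, rate-constant, modifiers)
REACTIONS = {
    "A1": (("ERO_rr", "PDI_red"), ("ERO_r1", "PDI_ox"), "ka1"),
    "A2": (("ERO_r1", "PDI_red"), ("ERO_act_ox", "PDI_ox"), "ka2"),
    "R2": (("ERO_act_ox", "PDI_red"), ("ERO_act_red", "PDI_ox"), "kox"),
    "R1": (("ERO_act_red", "O2"), ("ERO_act_ox", "H2O2"), "k1"),
    "G1": (("PDI_ox", "GSH"), ("PDI_mix",), "kg"),
    "G2": (("PDI_mix", "GSH"), ("PDI_red", "GSSG"), "kg"),
    "D1": (("ERO_rr", "DTT_red"), ("ERO_r1", "DTT_ox"), "kdtt"),
    "D2": (("ERO_r1", "DTT_red"), ("ERO_act_ox", "DTT_ox"), "kdtt"),
    "D3": (("ERO_act_ox", "DTT_red"), ("ERO_act_red", "DTT_ox"), "kdtt"),
}

#: identity mapping: local name -> SBML id (edit for deposited models)
DEFAULT_MAPPING: dict = {
    "parameters": {name: name for name in CONSTANT_NAMES},
    "species": {name: name for name in SPECIES},
    "units": {},
    "scale": {},
}


class SBMLImportError(ValueError):
    pass


def export_sbml(k: RateConstants, initial: StateVector, path: str | Path,
                model_id: str = "opf_redox_network") -> None:
    ET.register_namespace("", SBML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "1"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {"id": model_id})

    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{SBML_NS}}}compartment",
                  {"id": "cell", "size": "1", "constant": "true"})

    species_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for name in SPECIES:
        ET.SubElement(
            species_el,
            f"{{{SBML_NS}}}species",
            {
                "id": name,
                "compartment": "cell",
                "initialConcentration": repr(float(getattr(initial, name))),
                "hasOnlySubstanceUnits": "false",
                "boundaryCondition": "false",
                "constant": "false",
                "units": "micromolar",
            },
        )

    params_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    for name in CONSTANT_NAMES:
        units = "micromolar" if name == "o2_sat" else (
            "per_second" if name == "kdiff" else "per_micromolar_per_second"
        )
        ET.SubElement(
            params_el,
            f"{{{SBML_NS}}}parameter",
            {"id": name, "value": repr(float(getattr(k, name))),
             "constant": "true", "units": units},
        )

    reactions_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for rid, (reactants, products, kname) in REACTIONS.items():
        rx = ET.SubElement(reactions_el, f"{{{SBML_NS}}}reaction",
                           {"id": rid, "reversible": "false"})
        lor = ET.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
        for s in reactants:
            ET.SubElement(lor, f"{{{SBML_NS}}}speciesReference",
                          {"species": s, "stoichiometry": "1", "constant": "true"})
        lop = ET.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
        for s in products:
            ET.SubElement(lop, f"{{{SBML_NS}}}speciesReference",
                          {"species": s, "stoichiometry": "1", "constant": "true"})
        kl = ET.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        math = ET.SubElement(kl, f"{{{MATHML_NS}}}math")
        apply_el = ET.SubElement(math, f"{{{MATHML_NS}}}apply")
        ET.SubElement(apply_el, f"{{{MATHML_NS}}}times")
        for ci in (kname, *reactants):
            el = ET.SubElement(apply_el, f"{{{MATHML_NS}}}ci")
            el.text = f" {ci} "

    tree = ET.ElementTree(sbml)
    ET.indent(tree)
    tree.write(str(path), xml_declaration=True, encoding="utf-8")


def import_model_parameters(
    sbml_path: str | Path, mapping: dict | None = None
) -> tuple[RateConstants, StateVector, dict]:
    """Read rate constants and initial concentrations from an SBML file.

    ``mapping`` maps this package's names to the file's identifiers (see
    ``DEFAULT_MAPPING``); every mapped identifier must exist in the file.
    Returns the constants, the initial state, and a report listing file-side
    parameters/species no mapping entry refers to.
    """
    mapping = mapping or DEFAULT_MAPPING
    param_map = mapping.get("parameters", {})
    species_map = mapping.get("species", {})
    expected_units = mapping.get("units", {})
    scale = mapping.get("scale", {})

    missing_in_mapping = [n for n in CONSTANT_NAMES if n not in param_map]
    if missing_in_mapping:
        raise SBMLImportError(
            f"mapping does not cover constants: {', '.join(missing_in_mapping)}"
        )

    tree = ET.parse(sbml_path)
    root = tree.getroot()
    file_params = {}
    for p in root.iter(f"{{{SBML_NS}}}parameter"):
        file_params[p.get("id")] = (float(p.get("value")), p.get("units"))
    file_species = {}
    for s in root.iter(f"{{{SBML_NS}}}species"):
        conc = s.get("initialConcentration")
        file_species[s.get("id")] = (
            float(conc) if conc is not None else 0.0,
            s.get("units"),
        )

    constants = {}
    for local, sbml_id in param_map.items():
        if sbml_id not in file_params:
            raise SBMLImportError(f"mapped parameter '{sbml_id}' (for {local}) not in file")
        value, units = file_params[sbml_id]
        want = expected_units.get(local)
        if want is not None and units is not None and units != want:
            raise SBMLImportError(
                f"unit mismatch for {local}: file declares '{units}', expected '{want}'"
            )
        constants[local] = value * float(scale.get(local, 1.0))

    state_values = {}
    for local, sbml_id in species_map.items():
        if sbml_id not in file_species:
            raise SBMLImportError(f"mapped species '{sbml_id}' (for {local}) not in file")
        value, _units = file_species[sbml_id]
        state_values[local] = value * float(scale.get(local, 1.0))

    unmapped = {
        "parameters": sorted(set(file_params) - set(param_map.values())),
        "species": sorted(set(file_species) - set(species_map.values())),
    }
    return RateConstants(**constants), StateVector(**state_values), unmapped
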