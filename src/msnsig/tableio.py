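"""Reading and writing the reaction/parameter tables.

The frozen table dialect is two tab-separated files:

* a **reaction table** with columns
  ``reaction_id  class  reactants  products  kf  kr  kcat  notes`` where the
  reaction string uses ``A + 2 B`` syntax; for the enzymatic class the
  enzyme is listed first on both sides and the explicit Michaelis complex is
  the auto-named species ``cx_<reaction_id>``;
* a **species table** with columns
  ``species_id  moiety  compartment  tags  contents``;
* a **totals table** with columns ``moiety  total_uM  seed_species`` giving
  the conserved pool totals and the species each pool is seeded into before
  equilibration.

A loader validates both against the network invariants and supports
per-parameter overrides (the table is a transcription; overrides patch
individual constants without editing the file).
"""

from __future__ import annotations

import csv
import importlib.resources

from .network import Species, Reaction, ReactionNetwork, ParameterSet, INPUT_SPECIES

REACTION_COLUMNS = ("reaction_id", "class", "reactants", "products",
                    "kf", "kr", "kcat", "edge", "notes")
SPECIES_COLUMNS = ("species_id", "moiety", "compartment", "tags", "contents")
TOTALS_COLUMNS = ("moiety", "total_uM", "seed_species")


def _fmt_side(side):
    parts = []
    for sid, n in side:
        parts.append(f"{n} {sid}" if n != 1 else sid)
    return " + ".join(parts)


def _parse_side(text):
    out = []
    for term in text.split("+"):
        term = term.strip()
        if not term:
            continue
        bits = term.split()
        if len(bits) == 2:
            out.append((bits[1], int(bits[0])))
        else:
            out.append((bits[0], 1))
    return tuple(out)


def write_tables(net: ReactionNetwork, params: ParameterSet,
                 reactions_path, species_path, totals_path):
    with open(reactions_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(REACTION_COLUMNS)
        for r in net.reactions:
            if r.klass == "enzymatic":
                reac = _fmt_side(r.reactants)
                prod = _fmt_side(r.products)
            else:
                reac = _fmt_side(r.reactants)
                prod = _fmt_side(r.products)
            row = [r.id, r.klass, reac, prod,
                   repr(params[(r.id, "kf")]),
                   repr(params[(r.id, "kr")]) if r.klass != "irreversible" else "",
                   repr(params[(r.id, "kcat")]) if r.klass == "enzymatic" else "",
                   r.edge if r.edge is not None else "", r.notes]
            w.writerow(row)
    with open(species_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(SPECIES_COLUMNS)
        for s in net.species:
            contents = ";".join(f"{m}:{n}" for m, n in s.contents)
            w.writerow([s.id, s.moiety, s.compartment,
                        ";".join(sorted(s.tags)), contents])
    with open(totals_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(TOTALS_COLUMNS)
        for m, t in params.totals.items():
            w.writerow([m, repr(t), params.seeds[m]])


def load_tables(reactions_path, species_path, totals_path, overrides=None,
                totals_override=None):
    """Build (ReactionNetwork, ParameterSet) from the TSV pair.

    ``overrides`` maps (reaction_id, constant) -> value; ``totals_override``
    maps pool -> µM.  Unknown references raise.
    """
    species = []
    with open(species_path, newline="") as fh:
        rd = csv.DictReader(fh, delimiter="\t")
        for row in rd:
            contents = {}
            if row["contents"]:
                for part in row["contents"].split(";"):
                    m, n = part.split(":")
                    contents[m] = int(n)
            tags = frozenset(t for t in row["tags"].split(";") if t)
            species.append(Species(row["species_id"], row["moiety"],
                                   row["compartment"], tags,
                                   tuple(sorted(contents.items()))))
    totals = {}
    seeds = {}
    with open(totals_path, newline="") as fh:
        rd = csv.DictReader(fh, delimiter="\t")
        for row in rd:
            totals[row["moiety"]] = float(row["total_uM"])
            seeds[row["moiety"]] = row["seed_species"]
    reactions = []
    constants = {}
    declared = {s.id for s in species}
    with open(reactions_path, newline="") as fh:
        rd = csv.DictReader(fh, delimiter="\t")
        for row in rd:
            rid = row["reaction_id"]
            klass = row["class"]
            reac = _parse_side(row["reactants"])
            prod = _parse_side(row["products"])
            for sid, _n in (*reac, *prod):
                if sid not in declared and sid not in INPUT_SPECIES:
                    raise KeyError(f"reaction {rid}: unknown species {sid}")
            kf = float(row["kf"])
            if kf < 0:
                raise ValueError(f"reaction {rid}: negative rate constant")
            cx = f"cx_{rid}" if klass == "enzymatic" else None
            edge = int(row["edge"]) if row.get("edge") else None
            reactions.append(Reaction(rid, klass, reac, prod, complex_id=cx,
                                      edge=edge, notes=row.get("notes", "")))
            constants[(rid, "kf")] = kf
            if klass in ("reversible", "enzymatic"):
                constants[(rid, "kr")] = float(row["kr"])
            if klass == "enzymatic":
                constants[(rid, "kcat")] = float(row["kcat"])
    params = ParameterSet(constants, totals, seeds)
    if overrides:
        for key, val in overrides.items():
            if key not in params.constants:
                raise KeyError(f"override targets unknown constant {key}")
            params.constants[key] = float(val)
    if totals_override:
        for m, val in totals_override.items():
            if m not in params.totals:
                raise KeyError(f"override targets unknown pool {m}")
            params.totals[m] = float(val)
    net = ReactionNetwork(species, reactions)
    net.conserved_moieties(params)
    params.validate()
    return net, params


def load_default_tables(overrides=None, totals_override=None):
    """The packaged standard-model tables."""
    data = importlib.resources.files("msnsig").joinpath("data")
    return load_tables(data / "reactions.tsv", data / "species.tsv",
                       data / "totals.tsv",
                       overrides=overrides, totals_override=totals_override)


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"


def to_sbml(net: ReactionNetwork, params: ParameterSet) -> bytes:
    """Minimal SBML Level 3 serialisation of the expanded mass-action system
    (for cross-checking in standard simulators)."""
    from lxml import etree

    root = etree.Element("{%s}sbml" % SBML_NS, nsmap={None: SBML_NS},
                         level="3", version="2")
    model = etree.SubElement(root, "model", id="msn_d1r_signaling")
    comps = etree.SubElement(model, "listOfCompartments")
    etree.SubElement(comps, "compartment", id="spine", constant="true",
                     size="1")
    sp_list = etree.SubElement(model, "listOfSpecies")
    c0 = net.initial_state(params)
    for s, v in zip(net.species, c0):
        etree.SubElement(sp_list, "species", id=s.id.replace("@", "_p"),
                         compartment="spine", initialConcentration=repr(float(v)),
                         hasOnlySubstanceUnits="false", boundaryCondition="false",
                         constant="false")
    for ext in INPUT_SPECIES:
        etree.SubElement(sp_list, "species", id=ext, compartment="spine",
                         initialConcentration="0", hasOnlySubstanceUnits="false",
                         boundaryCondition="true", constant="false")
    rx_list = etree.SubElement(model, "listOfReactions")
    for key, k, lhs, rhs in net.elementary_steps(params):
        rid = f"{key[0]}__{key[1]}"
        rx = etree.SubElement(rx_list, "reaction", id=rid, reversible="false")
        lo = etree.SubElement(rx, "listOfReactants")
        for sid, n in lhs:
            etree.SubElement(lo, "speciesReference",
                             species=sid.replace("@", "_p"),
                             stoichiometry=str(n), constant="true")
        lp = etree.SubElement(rx, "listOfProducts")
        for sid, n in rhs:
            etree.SubElement(lp, "speciesReference",
                             species=sid.replace("@", "_p"),
                             stoichiometry=str(n), constant="true")
        kl = etree.SubElement(rx, "kineticLaw")
        math = etree.SubElement(
            kl, "{http://www.w3.org/1998/Math/MathML}math",
            nsmap={None: "http://www.w3.org/1998/Math/MathML"})
        apply_ = etree.SubElement(math, "apply")
        etree.SubElement(apply_, "times")
        cn = etree.SubElement(apply_, "cn")
        cn.text = repr(float(k))
        for sid, n in lhs:
            for _ in range(n):
                ci = etree.SubElement(apply_, "ci")
                ci.text = sid.replace("@", "_p")
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")
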