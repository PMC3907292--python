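"""Network assembly, conservation, crosstalk schemes and genotypes."""

import numpy as np
import pytest

from msnsig import (build_network, scheme_to_edges, CrosstalkScheme,
                    apply_genotype, SCHEME_CODES)
from msnsig.network import Species, Reaction, ReactionNetwork, ParameterSet


# ---------------------------------------------------------------------------
# assembly and mass-action structure
# ---------------------------------------------------------------------------

def test_toy_network_rhs_matches_hand_written_mass_action():
    """A + B <-> C; C -> D; E + S <-> ES -> E + P."""
    from msnsig.simulate import CompiledModel
    species = [Species(x, x) for x in "ABDESP"] + [
        Species("C", "A", contents=(("A", 1), ("B", 1))),
        Species("ES", "E", contents=(("E", 1), ("S", 1)))]
    rxns = [
        Reaction("bind", "reversible", (("A", 1), ("B", 1)), (("C", 1),)),
        Reaction("conv", "irreversible", (("C", 1),), (("D", 1),)),
        Reaction("cat", "enzymatic", (("E", 1), ("S", 1)), (("E", 1), ("P", 1)),
                 complex_id="ES"),
    ]
    consts = {("bind", "kf"): 2.0, ("bind", "kr"): 0.5, ("conv", "kf"): 0.3,
              ("cat", "kf"): 1.5, ("cat", "kr"): 0.7, ("cat", "kcat"): 0.2}
    net = ReactionNetwork(species, rxns)
    params = ParameterSet(consts, {}, {})
    cm = CompiledModel(net, params)
    y = np.array([0.4, 0.9, 0.2, 0.6, 0.25, 0.15, 0.3, 0.05])  # A B D E S P C ES
    idx = {s.id: i for i, s in enumerate(net.species)}
    got = cm.rhs(0.0, y, lambda t: 0.0, lambda t: 0.0)
    a, b, d, e, s, p, c, es = (y[idx[k]] for k in ("A", "B", "D", "E", "S", "P", "C", "ES"))
    vb = 2.0 * a * b - 0.5 * c
    vc = 0.3 * c
    v1 = 1.5 * e * s
    v2 = 0.7 * es
    v3 = 0.2 * es
    want = {
        "A": -vb, "B": -vb, "C": vb - vc, "D": vc,
        "E": -v1 + v2 + v3, "S": -v1 + v2, "ES": v1 - v2 - v3, "P": v3,
    }
    for sid, val in want.items():
        assert got[idx[sid]] == pytest.approx(val, rel=1e-12)


def test_default_network_reports_counts_and_documented_subsystems(model):
    net, params = model
    summary = net.summary()
    assert summary["reactions"] == net.n_reactions
    assert summary["species"] == net.n_species
    # documented subsystems are present
    ids = {s.id for s in net.species}
    for probe in ("AC5", "PDE1", "PDE4", "PDE10", "cAMP", "D32@34", "D32@75",
                  "B56", "B72", "GRF", "RASGTP", "RASRAF", "MEK@SS", "ERK@TY",
                  "STEP", "Fyn@420@527", "NRm@Y", "DUSP", "D1R_A", "D1R_N",
                  "Golf_A", "Golf_N", "D1Rres", "GluR1@845"):
        assert probe in ids, probe
    # perturbable parameters = distinct kinetic targets + the 40 totals
    assert len(params.totals) == 40
    nk = params.n_perturbable() - len(params.totals)
    assert nk == 2 * summary["enzymatic"] + 2 * summary["reversible"] \
        + summary["irreversible"]


def test_single_compartment_variant_equalises_anchors():
    net, params = build_network(scheme="010", two_compartments=False)
    assert params.totals["AncD_A"] == params.totals["AncD_N"]
    assert params.kd("bind_D1R_A") == params.kd("bind_D1R_N")


def test_malformed_inputs_are_rejected():
    with pytest.raises(ValueError):
        Reaction("r", "magic", (("A", 1),), (("B", 1),))
    with pytest.raises(KeyError):
        ReactionNetwork([Species("A", "A")],
                        [Reaction("r", "irreversible", (("A", 1),), (("Z", 1),))])
    p = ParameterSet({("r", "kf"): -1.0}, {}, {})
    with pytest.raises(ValueError):
        p.validate()
    with pytest.raises(ValueError):
        ParameterSet({}, {"X": -2.0}, {}).validate()


def test_rate_constants_inside_plausible_window_warn_only(model):
    net, params = model
    warnings = params.validate()     # no exception
    assert all(isinstance(w, str) for w in warnings)


# ---------------------------------------------------------------------------
# conserved moieties
# ---------------------------------------------------------------------------

def test_toy_enzyme_moieties_are_textbook(toy_enzyme):
    net, params = toy_enzyme
    assert set(net.conserved_moieties(params)) == {"E", "S"}
    wE = net.moiety_vector("E")
    wS = net.moiety_vector("S")
    assert list(wE) == [1, 0, 1, 0]      # E + ES
    assert list(wS) == [0, 1, 1, 1]      # S + ES + P


def test_declared_moieties_lie_in_left_null_space(model):
    """Oracle: every declared pool vector annihilates the stoichiometric
    matrix of the expanded elementary system."""
    net, params = model
    S = net.stoichiometric_matrix(params).toarray()
    for m in params.totals:
        w = net.moiety_vector(m)
        assert np.max(np.abs(w @ S)) < 1e-9, m


def test_full_network_has_forty_conserved_pools(model):
    net, params = model
    assert len(net.conserved_moieties(params)) == 40


def test_non_conserved_declaration_is_caught():
    species = [
        Species("E", "E"), Species("S", "S"),
        Species("ES", "E", contents=(("E", 1), ("S", 1))),
        Species("P", "P"),       # wrongly declared as its own pool
    ]
    rxn = Reaction("cat", "enzymatic", (("E", 1), ("S", 1)),
                   (("E", 1), ("P", 1)), complex_id="ES")
    net = ReactionNetwork(species, [rxn])
    params = ParameterSet({("cat", "kf"): 1.0, ("cat", "kr"): 2.0,
                           ("cat", "kcat"): 0.5},
                          {"E": 1.0, "P": 1.0}, {"E": "E", "P": "P"})
    with pytest.raises(ValueError, match="cat"):
        net.conserved_moieties(params)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def test_genotype_scaling_touches_only_targeted_totals(model):
    net, params = model
    het = apply_genotype(params, "Drd1a_het")
    assert het.totals["D1R"] == pytest.approx(0.2 * params.totals["D1R"])
    golf = apply_genotype(params, "Gnal_het")
    assert golf.totals["Gaolf"] == pytest.approx(0.4 * params.totals["Gaolf"])
    assert golf.totals["Gbg"] == pytest.approx(0.4 * params.totals["Gbg"])
    ko = apply_genotype(params, "D32KO")
    assert ko.totals["D32"] == 0.0
    wt = apply_genotype(params, "WT")
    assert wt.totals == params.totals and wt.constants == params.constants
    for g in (het, golf, ko):
        assert g.constants == params.constants       # rates untouched
        untouched = {m for m in params.totals} - {"D1R", "Gaolf", "Gbg", "D32"}
        for m in untouched:
            assert g.totals[m] == params.totals[m]
    with pytest.raises(KeyError):
        apply_genotype(params, "Grin1_KO")


# ---------------------------------------------------------------------------
# crosstalk schemes
# ---------------------------------------------------------------------------

def test_scheme_codes_map_to_documented_edge_sets():
    assert scheme_to_edges("010") == frozenset({1, 5, 6, 7, 8})
    for code in ("100", "101", "110", "111"):
        edges = scheme_to_edges(code)
        assert {5, 7} <= edges and not ({6, 8} & edges)
    for bad in ("210", "01", "0101", "abc"):
        with pytest.raises(ValueError):
            scheme_to_edges(bad)


def test_full_switch_matrix():
    """The eight schemes resolve to the expected (STEP form, substrate)
    switch matrix: single-pool schemes use edges 1/2 for ERK, two-pool
    schemes route ERK through the second pool (3/4); a crosstalk bit of 1
    leaves only the non-phosphorylated form active."""
    expected = {
        "000": {1, 2, 5, 6, 7, 8}, "001": {3, 4, 5, 6, 7, 8},
        "010": {1, 5, 6, 7, 8},    "011": {3, 5, 6, 7, 8},
        "100": {1, 2, 5, 7},       "101": {3, 4, 5, 7},
        "110": {1, 5, 7},          "111": {3, 5, 7},
    }
    got = {code: set(scheme_to_edges(code)) for code in SCHEME_CODES}
    assert got == expected


def test_scheme_to_edges_is_a_bijection():
    images = {scheme_to_edges(c) for c in SCHEME_CODES}
    assert len(images) == 8


def test_apply_scheme_switches_forward_rates_and_step_pools(model):
    net, params = model           # 010 already applied
    assert params[("stp_erk", "kf")] == 0.0       # edge 2 off
    assert params[("st_erk", "kf")] > 0.0         # edge 1 on
    assert params[("stp_nr_m", "kf")] > 0.0       # edge 8 on (no crosstalk there)
    assert params.totals["STEP2"] == 0.0
    two = net.apply_scheme(params, "011")
    assert two.totals["STEP"] == pytest.approx(two.totals["STEP2"])
    assert two[("st2_erk", "kf")] > 0.0 and two[("st2p_erk", "kf")] == 0.0
    assert two[("st_erk", "kf")] == 0.0           # ERK served by pool 2
    cs = CrosstalkScheme("011")
    assert cs.two_pools and cs.edges == scheme_to_edges("011")


# ---------------------------------------------------------------------------
# table IO and exports
# ---------------------------------------------------------------------------

def test_table_round_trip_and_overrides(tmp_path, model):
    from msnsig.tableio import write_tables, load_tables
    from msnsig.model_def import build_default
    net, params = build_default()
    paths = [tmp_path / f for f in ("r.tsv", "s.tsv", "t.tsv")]
    write_tables(net, params, *paths)
    net2, params2 = load_tables(*paths)
    assert params2.constants == params.constants
    assert params2.totals == params.totals
    net3, params3 = load_tables(*paths, overrides={("gef_A", "kcat"): 9.9},
                                totals_override={"D32": 25.0})
    assert params3[("gef_A", "kcat")] == 9.9
    assert params3.totals["D32"] == 25.0
    with pytest.raises(KeyError):
        load_tables(*paths, overrides={("nope", "kf"): 1.0})


def test_json_graph_and_sbml_exports_parse(model):
    import json
    from lxml import etree
    from msnsig.tableio import to_sbml
    net, params = model
    graph = json.loads(net.to_json_graph())
    assert len(graph["species"]) == net.n_species
    assert len(graph["reactions"]) == net.n_reactions
    doc = etree.fromstring(to_sbml(net, params))
    ns = "{http://www.sbml.org/sbml/level3/version2/core}"
    species = doc.findall(f".//{ns}species")
    assert len(species) == net.n_species + 2      # + clamped DA, Ca
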