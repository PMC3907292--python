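"""Core representation of the reaction network.

The model is a closed mass-action system: species are concentrations (µM),
reactions fall into three non-overlapping classes

* ``enzymatic``    -- E + S <-> ES -> E + P, constants (k_f, k_r, k_cat); the
  enzyme--substrate complex is an explicit species, no steady-state shortcut.
* ``reversible``   -- A + B <-> C, constants (k_f, k_r).
* ``irreversible`` -- A (+ B) -> products, constant k (stored as k_f); this
  class includes transport (exo/endocytosis, compartment exchange) steps.

Time is in seconds throughout; second-order constants are µM⁻¹ s⁻¹.

External inputs (dopamine and calcium) are *clamped* species: they appear in
rate laws but their concentration is prescribed by the stimulus protocol, so
they carry no ODE and belong to no conserved pool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

CLASSES = ("enzymatic", "reversible", "irreversible")

COMPARTMENTS = (
    "cytosol",            # spine cytosol / default well-stirred volume
    "PSD",                # post-synaptic density / synaptic membrane
    "NMDAR_reservoir",    # intracellular NMDAR pool
    "D1R_Golf_AC5",       # D1R/Golf compartment coupled to AC5
    "D1R_Golf_NMDAR",     # D1R/Golf compartment coupled to NMDAR enhancement
    "reservoir",          # non-signaling D1R/Golf reservoir
)

#: clamped input species (concentration prescribed by the protocol)
INPUT_SPECIES = ("DA", "Ca")


@dataclass(frozen=True)
class Species:
    """A chemical species.

    ``moiety`` is the primary conserved pool the species is accounted under
    (the pool whose total amount is a model parameter).  ``contents`` gives
    the full moiety composition -- a Michaelis complex E·S contains one unit
    of the enzyme pool and one of the substrate pool, and enters both
    conservation sums.
    """

    id: str
    moiety: str
    compartment: str = "cytosol"
    tags: frozenset = frozenset()
    contents: tuple = ()   # ((moiety, count), ...); defaults to ((moiety, 1),)

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"species {self.id}: unknown compartment {self.compartment!r}")
        if not self.contents:
            object.__setattr__(self, "contents", ((self.moiety, 1),))

    @property
    def content_map(self):
        return dict(self.contents)


@dataclass(frozen=True)
class Reaction:
    """One table row.  ``reactants``/``products`` are ((species_id, stoich), ...).

    For the enzymatic class the enzyme is listed first on both sides and
    ``complex_id`` names the explicit E·S species.
    """

    id: str
    klass: str
    reactants: tuple
    products: tuple
    complex_id: str | None = None
    edge: int | None = None      # crosstalk edge number (1..8), if any
    notes: str = ""

    def __post_init__(self):
        if self.klass not in CLASSES:
            raise ValueError(f"reaction {self.id}: malformed class {self.klass!r}")
        if self.klass == "enzymatic" and self.complex_id is None:
            raise ValueError(f"enzymatic reaction {self.id} needs a complex species")

    @property
    def enzyme(self):
        if self.klass != "enzymatic":
            return None
        return self.reactants[0][0]

    def constant_names(self):
        if self.klass == "enzymatic":
            return ("kf", "kr", "kcat")
        if self.klass == "reversible":
            return ("kf", "kr")
        return ("kf",)


# rate constants are expected to sit inside this window (warn outside, do not
# fail: deliberately lumped steps such as the ERK->DUSP transcription loop
# fall below it)
RATE_RANGE = (1e-3, 1e3)


class ParameterSet:
    """Rate constants keyed by (reaction id, constant name) plus the conserved
    pool totals (µM).  Supports genotype scaling and single-parameter
    perturbation by copy-and-modify."""

    def __init__(self, constants: dict, totals: dict, seeds: dict,
                 edge_defaults: dict | None = None):
        self.constants = dict(constants)
        self.totals = dict(totals)
        self.seeds = dict(seeds)      # moiety -> species id that holds the total initially
        #: pristine forward rates of the crosstalk-edge reactions (recorded
        #: the first time a scheme is applied, so schemes can be re-applied)
        self.edge_defaults = dict(edge_defaults or {})

    def copy(self) -> "ParameterSet":
        return ParameterSet(self.constants, self.totals, self.seeds,
                            self.edge_defaults)

    def __getitem__(self, key):
        return self.constants[key]

    def __setitem__(self, key, value):
        if key not in self.constants:
            raise KeyError(f"unknown rate constant {key}")
        self.constants[key] = value

    def kd(self, rid):
        """Dissociation constant k_r / k_f of a reversible (or enzymatic) step."""
        return self.constants[(rid, "kr")] / self.constants[(rid, "kf")]

    def km(self, rid):
        """Michaelis constant (k_cat + k_r) / k_f of an enzymatic reaction."""
        return (self.constants[(rid, "kcat")] + self.constants[(rid, "kr")]) \
            / self.constants[(rid, "kf")]

    def validate(self):
        problems = []
        for (rid, name), v in self.constants.items():
            if v < 0:
                raise ValueError(f"negative rate constant {name} in {rid}")
        for m, v in self.totals.items():
            if v < 0:
                raise ValueError(f"negative total for {m}")
        lo, hi = RATE_RANGE
        for (rid, name), v in self.constants.items():
            if v > 0 and not (lo <= v <= hi):
                problems.append(f"{rid}.{name}={v:g} outside [{lo:g},{hi:g}]")
        return problems  # warnings, not errors

    def n_perturbable(self):
        """Perturbable parameter count: per enzymatic reaction K_M and k_cat,
        per reversible k_f and k_r, per irreversible its k, plus one per
        conserved total."""
        rids = {}
        for (rid, name) in self.constants:
            rids.setdefault(rid, set()).add(name)
        nk = sum(2 if names == {"kf", "kr", "kcat"} else len(names)
                 for names in rids.values())
        return nk + len(self.totals)


GENOTYPES = {
    "WT": {},
    # single-copy mutants: striatal D1R at 20 % of WT, Gα-olf (and hence the
    # Golf heterotrimer, so the βγ pool is scaled alongside) at 40 %
    "Drd1a_het": {"D1R": 0.2},
    "Gnal_het": {"Gaolf": 0.4, "Gbg": 0.4},
    "D32KO": {"D32": 0.0},
}


def apply_genotype(params: ParameterSet, genotype: str) -> ParameterSet:
    """Scale the targeted conserved totals; rate constants are untouched."""
    try:
        scaling = GENOTYPES[genotype]
    except KeyError:
        raise KeyError(f"unknown genotype {genotype!r}") from None
    out = params.copy()
    for moiety, frac in scaling.items():
        if moiety not in out.totals:
            raise KeyError(f"genotype {genotype} targets unknown pool {moiety}")
        out.totals[moiety] = out.totals[moiety] * frac
    return out


# ---------------------------------------------------------------------------
# crosstalk schemes
# ---------------------------------------------------------------------------

#: numbered (STEP form, substrate) edges.  Substrate "Fynp" covers every
#: active phosphorylated Fyn form; "NMDARp" every Y1472-phosphorylated NMDAR.
EDGE_LABELS = {
    1: ("STEP", "ERKpp"),
    2: ("STEPp", "ERKpp"),
    3: ("STEP2", "ERKpp"),
    4: ("STEP2p", "ERKpp"),
    5: ("STEP", "Fynp"),
    6: ("STEPp", "Fynp"),
    7: ("STEP", "NMDARp"),
    8: ("STEPp", "NMDARp"),
}

SCHEME_CODES = ("000", "001", "010", "011", "100", "101", "110", "111")


def scheme_to_edges(code: str) -> frozenset:
    """Map a 3-bit crosstalk code to its active edge set.

    Bits: [PKA-sensitive crosstalk at Fyn&NR2B, PKA-sensitive crosstalk at
    ERK, two STEP pools].  A crosstalk bit of 1 means only the
    non-phosphorylated STEP form attacks that substrate (PKA phosphorylation
    silences it); 0 means both forms are equally active (no PKA sensitivity).
    With a single pool (third bit 0) the ERK edges use the first pool
    (edges 1/2); with two pools ERK is served by the second pool (edges 3/4)
    while Fyn and NMDAR stay on the first.
    """
    if not (isinstance(code, str) and len(code) == 3 and set(code) <= {"0", "1"}):
        raise ValueError(f"invalid crosstalk code {code!r}")
    fyn_bit, erk_bit, pools_bit = (c == "1" for c in code)
    edges = {5, 7} if fyn_bit else {5, 6, 7, 8}
    if pools_bit:
        edges |= {3} if erk_bit else {3, 4}
    else:
        edges |= {1} if erk_bit else {1, 2}
    return frozenset(edges)


@dataclass(frozen=True)
class CrosstalkScheme:
    code: str
    edges: frozenset = field(default=None)

    def __post_init__(self):
        edges = scheme_to_edges(self.code)
        if self.edges is None:
            object.__setattr__(self, "edges", edges)
        elif frozenset(self.edges) != edges:
            raise ValueError(f"edge set inconsistent with code {self.code}")

    @property
    def two_pools(self) -> bool:
        return self.code[2] == "1"


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class ReactionNetwork:
    def __init__(self, species, reactions):
        self.species = list(species)
        self.reactions = list(reactions)
        self.index = {s.id: i for i, s in enumerate(self.species)}
        if len(self.index) != len(self.species):
            raise ValueError("duplicate species ids")
        seen = set()
        for r in self.reactions:
            if r.id in seen:
                raise ValueError(f"duplicate reaction id {r.id}")
            seen.add(r.id)
            for sid, n in (*r.reactants, *r.products):
                if sid not in self.index and sid not in INPUT_SPECIES:
                    raise KeyError(f"reaction {r.id} references unknown species {sid}")
                if n != int(n) or n <= 0:
                    raise ValueError(f"reaction {r.id}: bad stoichiometry {n} for {sid}")
            if r.complex_id is not None and r.complex_id not in self.index:
                raise KeyError(f"reaction {r.id}: complex {r.complex_id} not declared")

    @property
    def n_species(self):
        return len(self.species)

    @property
    def n_reactions(self):
        return len(self.reactions)

    # -- elementary steps -------------------------------------------------
    def elementary_steps(self, params: ParameterSet):
        """Expand table rows into unidirectional mass-action steps:
        (key, rate-constant, reactant side, product side)."""
        steps = []
        for r in self.reactions:
            if r.klass == "enzymatic":
                e = r.reactants[0]
                subs = r.reactants[1:]
                prods = r.products[1:]
                cx = ((r.complex_id, 1),)
                steps.append(((r.id, "kf"), params[(r.id, "kf")], (e, *subs), cx))
                steps.append(((r.id, "kr"), params[(r.id, "kr")], cx, (e, *subs)))
                steps.append(((r.id, "kcat"), params[(r.id, "kcat")], cx, (e, *prods)))
            elif r.klass == "reversible":
                steps.append(((r.id, "kf"), params[(r.id, "kf")], r.reactants, r.products))
                steps.append(((r.id, "kr"), params[(r.id, "kr")], r.products, r.reactants))
            else:
                steps.append(((r.id, "kf"), params[(r.id, "kf")], r.reactants, r.products))
        return steps

    # -- conservation -----------------------------------------------------
    def moiety_vector(self, moiety: str) -> np.ndarray:
        w = np.zeros(self.n_species)
        for i, s in enumerate(self.species):
            w[i] = s.content_map.get(moiety, 0)
        return w

    def conserved_moieties(self, params: ParameterSet):
        """Return the declared conserved pools after verifying each is
        structurally invariant under every reaction (clamped inputs are
        exempt from the balance)."""
        moieties = list(params.totals)
        steps = self.elementary_steps(params)
        for m in moieties:
            w = self.moiety_vector(m)
            for key, _k, lhs, rhs in steps:
                bal = 0.0
                for sid, n in rhs:
                    if sid in INPUT_SPECIES:
                        continue
                    bal += n * w[self.index[sid]]
                for sid, n in lhs:
                    if sid in INPUT_SPECIES:
                        continue
                    bal -= n * w[self.index[sid]]
                if abs(bal) > 1e-12:
                    raise ValueError(
                        f"pool {m!r} is not conserved by reaction {key[0]} "
                        f"(step {key[1]}, imbalance {bal:+g})")
        return moieties

    def stoichiometric_matrix(self, params: ParameterSet):
        """Species × elementary-step stoichiometric matrix (inputs excluded)."""
        steps = self.elementary_steps(params)
        S = sparse.lil_matrix((self.n_species, len(steps)))
        for j, (_key, _k, lhs, rhs) in enumerate(steps):
            for sid, n in lhs:
                if sid not in INPUT_SPECIES:
                    S[self.index[sid], j] -= n
            for sid, n in rhs:
                if sid not in INPUT_SPECIES:
                    S[self.index[sid], j] += n
        return S.tocsr()

    def initial_state(self, params: ParameterSet) -> np.ndarray:
        """All-in-seed initial condition.  A species seeding several pools
        (e.g. a heterotrimer) is set once; every pool total must then be
        consistent with the resulting state."""
        c0 = np.zeros(self.n_species)
        seeded = set()
        for moiety, total in params.totals.items():
            sid = params.seeds[moiety]
            sp = self.species[self.index[sid]]
            mult = sp.content_map.get(moiety, 0)
            if mult == 0:
                raise ValueError(f"seed species {sid} carries no {moiety}")
            if sid not in seeded:
                already = float(self.moiety_vector(moiety) @ c0)
                c0[self.index[sid]] = (total - already) / mult
                seeded.add(sid)
        for moiety, total in params.totals.items():
            got = float(self.moiety_vector(moiety) @ c0)
            if abs(got - total) > 1e-9 * max(1.0, abs(total)):
                raise ValueError(
                    f"pool {moiety}: seeded state holds {got:g}, totals say "
                    f"{total:g}; shared-seed pools must scale together")
        return c0

    def moiety_totals(self, state: np.ndarray, params: ParameterSet) -> dict:
        return {m: float(self.moiety_vector(m) @ state) for m in params.totals}

    # -- scheme application ----------------------------------------------
    def apply_scheme(self, params: ParameterSet, scheme) -> ParameterSet:
        """Switch crosstalk edges by zeroing the forward rate constant of
        deselected STEP(-p)·substrate association reactions, and split the
        STEP total between the two pools when the scheme uses two."""
        if isinstance(scheme, str):
            scheme = CrosstalkScheme(scheme)
        out = params.copy()
        if not out.edge_defaults:
            out.edge_defaults = {r.id: out.constants[(r.id, "kf")]
                                 for r in self.reactions if r.edge is not None}
        for r in self.reactions:
            if r.edge is None:
                continue
            out.constants[(r.id, "kf")] = (out.edge_defaults[r.id]
                                           if r.edge in scheme.edges else 0.0)
        if scheme.two_pools:
            total = out.totals["STEP"] + out.totals["STEP2"]
            out.totals["STEP"] = 0.5 * total   # split not reported; configurable
            out.totals["STEP2"] = 0.5 * total
        else:
            out.totals["STEP"] = out.totals["STEP"] + out.totals["STEP2"]
            out.totals["STEP2"] = 0.0
        return out

    # -- exports ----------------------------------------------------------
    def to_json_graph(self) -> str:
        nodes = [{"id": s.id, "moiety": s.moiety, "compartment": s.compartment,
                  "tags": sorted(s.tags)} for s in self.species]
        edges = []
        for r in self.reactions:
            edges.append({"id": r.id, "class": r.klass,
                          "reactants": list(map(list, r.reactants)),
                          "products": list(map(list, r.products)),
                          "complex": r.complex_id, "edge": r.edge})
        return json.dumps({"species": nodes, "reactions": edges}, indent=1)

    def summary(self) -> dict:
        by_class = {}
        for r in self.reactions:
            by_class[r.klass] = by_class.get(r.klass, 0) + 1
        return {"species": self.n_species, "reactions": self.n_reactions,
                **by_class}
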