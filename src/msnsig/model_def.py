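"""Definition of the D1R⁺ medium-spiny-neuron signaling network.

The network couples two signaling axes that converge on a dendritic spine:

* the **AC5 axis** -- D1R/Golf-stimulated adenylyl cyclase 5, cAMP, PKA,
  DARPP-32 (Thr34/Thr75) control of PP1, phosphodiesterases PDE1/PDE4/PDE10a,
  two PP2A pools (Ca²⁺-activated B72, PKA-activated B56), readout GluR1
  phosphorylated at the PKA site (Ser845);
* the **NMDAR axis** -- NMDAR-mediated Ca²⁺ entry, CaM, RAS-GRF1, the
  RAS/RAF/MEK/ERK cascade with a DUSP negative feedback, the Fyn activation
  cycle (Y420/Y527), NMDAR membrane traffic, and the tyrosine phosphatase
  STEP acting on Fyn, NMDAR-Y1472 and ERK.

D1R and Golf are distributed over two signaling compartments (one driving
AC5, one driving NMDAR enhancement) through anchors of different capacity
and affinity, exchanging slowly through a non-signaling reservoir.

Everything is elementary mass action; enzymatic steps carry an explicit
Michaelis complex.  Units: µM and seconds.  Dopamine and calcium are clamped
inputs set by the stimulus protocol.

Phospho-states are written with the ``@site`` grammar (``D32@34``,
``Fyn@420@527``, ``NRm@Y`` for membrane NMDAR phosphorylated at NR2B-Y1472).
"""

from __future__ import annotations

from .network import Species, Reaction, ReactionNetwork, ParameterSet


class _Builder:
    def __init__(self):
        self.species = []
        self._sindex = {}
        self.reactions = []
        self.constants = {}
        self.totals = {}
        self.seeds = {}

    # -- species ----------------------------------------------------------
    def sp(self, sid, moiety, compartment="cytosol", tags=(), contents=None):
        s = Species(sid, moiety, compartment, frozenset(tags),
                    tuple(sorted(contents.items())) if contents else ())
        if sid in self._sindex:
            raise ValueError(f"species {sid} declared twice")
        self._sindex[sid] = s
        self.species.append(s)
        return sid

    def pool(self, moiety, total, seed):
        self.totals[moiety] = total
        self.seeds[moiety] = seed

    def _merge_contents(self, *sids):
        out = {}
        for sid in sids:
            if sid in ("DA", "Ca"):
                continue
            for m, n in self._sindex[sid].content_map.items():
                out[m] = out.get(m, 0) + n
        return out

    def _merge_tags(self, *sids):
        out = set()
        for sid in sids:
            if sid in ("DA", "Ca"):
                continue
            out |= self._sindex[sid].tags
        return out

    # -- reactions --------------------------------------------------------
    def rev(self, rid, lhs, rhs, kf, kr, notes="", complex_tags=None):
        """Reversible binding A (+ B) <-> C.  If the product species is not
        yet declared it is created as a complex of the reactants."""
        for sid, _ in rhs:
            if sid not in self._sindex and sid not in ("DA", "Ca"):
                assert len(rhs) == 1
                reac_ids = [s for s, n in lhs for _ in range(n)]
                base = self._sindex[[s for s in reac_ids if s not in ("DA", "Ca")][0]]
                tags = self._merge_tags(*reac_ids)
                if complex_tags:
                    tags |= set(complex_tags)
                self.sp(sid, base.moiety, base.compartment, tags,
                        self._merge_contents(*reac_ids))
        self.reactions.append(Reaction(rid, "reversible", tuple(lhs), tuple(rhs),
                                       notes=notes))
        self.constants[(rid, "kf")] = kf
        self.constants[(rid, "kr")] = kr

    def irr(self, rid, lhs, rhs, k, notes=""):
        self.reactions.append(Reaction(rid, "irreversible", tuple(lhs), tuple(rhs),
                                       notes=notes))
        self.constants[(rid, "kf")] = k

    def enz(self, rid, enzyme, substrate, products, kf, kr, kcat,
            notes="", edge=None, strip_tags=()):
        """Enzymatic E + S <-> E·S -> E + products, with an explicit complex
        species named cx_<rid>.  ``strip_tags`` removes marker tags from the
        complex (an epitope buried in the catalytic site is not counted)."""
        cx = f"cx_{rid}"
        e = self._sindex[enzyme]
        self.sp(cx, e.moiety, e.compartment,
                self._merge_tags(enzyme, substrate) - set(strip_tags),
                self._merge_contents(enzyme, substrate))
        if isinstance(products, str):
            products = (products,)
        self.reactions.append(Reaction(
            rid, "enzymatic",
            ((enzyme, 1), (substrate, 1)),
            ((enzyme, 1), *((p, 1) for p in products)),
            complex_id=cx, edge=edge, notes=notes))
        self.constants[(rid, "kf")] = kf
        self.constants[(rid, "kr")] = kr
        self.constants[(rid, "kcat")] = kcat

    def build(self):
        net = ReactionNetwork(self.species, self.reactions)
        params = ParameterSet(self.constants, self.totals, self.seeds)
        net.conserved_moieties(params)
        return net, params


def _enzkin(km, kcat, kf=None):
    """(kf, kr, kcat) from a Michaelis constant using the k_r = 4·k_cat
    convention; kf then follows from K_M = (k_cat + k_r)/k_f."""
    kr = 4.0 * kcat
    if kf is None:
        kf = (kcat + kr) / km
    return kf, kr, kcat


def build_default(two_compartments: bool = True):
    """Assemble the standard network.

    With ``two_compartments=False`` the D1R/Golf pool is shared (single
    compartment): both axes are driven by one anchored pool, the variant used
    to demonstrate that segregation requires the compartment split.
    """
    b = _Builder()

    # =====================================================================
    # D1R / Golf compartments
    # =====================================================================
    b.sp("D1Rres", "D1R", "reservoir")
    b.sp("Golfres", "Golf", "reservoir", contents={"Gaolf": 1, "Gbg": 1})
    b.sp("AncD_A", "AncD_A", "D1R_Golf_AC5")
    b.sp("AncD_N", "AncD_N", "D1R_Golf_NMDAR")
    b.sp("AncG_A", "AncG_A", "D1R_Golf_AC5")
    b.sp("AncG_N", "AncG_N", "D1R_Golf_NMDAR")
    b.pool("D1R", 1.0, "D1Rres")
    b.pool("Gaolf", 2.0, "Golfres")
    b.pool("Gbg", 2.0, "Golfres")
    # anchor capacities honour the haploinsufficiency bounds: AC5-compartment
    # D1R anchor = 20 % of WT D1R, NMDAR-compartment Golf anchor = 40 % of
    # WT Golf; affinities make the AC5 compartment win the competition for
    # D1R and the NMDAR compartment the one for Golf.
    b.pool("AncD_A", 0.2, "AncD_A")
    b.pool("AncD_N", 2.0, "AncD_N")
    b.pool("AncG_A", 2.0, "AncG_A")
    b.pool("AncG_N", 0.3, "AncG_N")

    for comp, tag in (("A", "D1R_Golf_AC5"), ("N", "D1R_Golf_NMDAR")):
        b.sp(f"D1R_{comp}", "D1R", tag, contents={"D1R": 1, f"AncD_{comp}": 1})
        b.sp(f"Golf_{comp}", "Golf", tag,
             contents={"Gaolf": 1, "Gbg": 1, f"AncG_{comp}": 1})
        b.sp(f"GaGTP_{comp}", "Gaolf", tag, tags=("Ga_active",))
        b.sp(f"GaGDP_{comp}", "Gaolf", tag)
        b.sp(f"Gbg_{comp}", "Gbg", tag, contents={"Gbg": 1, f"AncG_{comp}": 1})

    # slow anchor exchange through the reservoir (well below signaling rates)
    b.rev("bind_D1R_A", [("D1Rres", 1), ("AncD_A", 1)], [("D1R_A", 1)],
          kf=1e-2, kr=1e-5)                        # K_d 1 nM, protective
    b.rev("bind_D1R_N", [("D1Rres", 1), ("AncD_N", 1)], [("D1R_N", 1)],
          kf=1e-2, kr=1.5e-2)                      # K_d 1.5 µM, loose
    b.rev("bind_Golf_A", [("Golfres", 1), ("AncG_A", 1)], [("Golf_A", 1)],
          kf=1e-2, kr=3e-2)                        # K_d 3 µM, loose
    b.rev("bind_Golf_N", [("Golfres", 1), ("AncG_N", 1)], [("Golf_N", 1)],
          kf=1e-2, kr=1e-5)                        # K_d 1 nM, protective

    for comp in ("A", "N"):
        b.sp(f"D1RDA_{comp}", "D1R", b._sindex[f"D1R_{comp}"].compartment,
             tags=("D1R_active",),
             contents={"D1R": 1, f"AncD_{comp}": 1})
        # low-affinity dopamine site (K_d ≈ 1 µM)
        b.rev(f"bindDA_{comp}", [(f"D1R_{comp}", 1), ("DA", 1)],
              [(f"D1RDA_{comp}", 1)], kf=5.0, kr=5.0)
        # receptor-catalysed nucleotide exchange on anchored Golf: the active
        # receptor is the GEF, βγ stays membrane-anchored
        b.enz(f"gef_{comp}", f"D1RDA_{comp}", f"Golf_{comp}",
              (f"GaGTP_{comp}", f"Gbg_{comp}"), kf=10.0, kr=10.0,
              kcat=0.6 if comp == "A" else 1.0)
        b.irr(f"gtpase_{comp}", [(f"GaGTP_{comp}", 1)], [(f"GaGDP_{comp}", 1)],
              k=0.002 if comp == "A" else 0.1)
        b.irr(f"reassoc_{comp}", [(f"GaGDP_{comp}", 1), (f"Gbg_{comp}", 1)],
              [(f"Golf_{comp}", 1)], k=0.2)

    # =====================================================================
    # CaM, neurogranin, Ca buffer
    # =====================================================================
    b.sp("CaM", "CaM")
    b.sp("Ng", "Ng")
    b.pool("CaM", 10.0, "CaM")
    b.pool("Ng", 20.0, "Ng")

    prev = "CaM"
    # four equivalent sites (K_d 2.5 µM each): keeps the CaM·4Ca response on
    # its slope-four limb through the µM range probed by Ca²⁺ spikes
    for i, (kf, kr) in enumerate([(25.0, 81.0)] * 4, start=1):
        nxt = f"CaMc{i}"
        b.rev(f"cam_ca{i}", [(prev, 1), ("Ca", 1)], [(nxt, 1)], kf=kf, kr=kr)
        prev = nxt
    b.rev("ng_cam", [("Ng", 1), ("CaM", 1)], [("NgCaM", 1)], kf=5.0, kr=5.0)

    # =====================================================================
    # AC5 / cAMP
    # =====================================================================
    b.sp("AC5", "AC5")
    b.sp("AC5Ca", "AC5", tags=("AC5_Ca",))
    b.sp("ATP", "AdN")
    b.sp("cAMP", "AdN", tags=("cAMP",))
    b.sp("AMP", "AdN")
    b.pool("AC5", 0.15, "AC5")
    b.pool("AdN", 2000.0, "ATP")

    # Gαolf·GTP binds AC5 in the low-nanomolar range; Ca²⁺ binding halves the
    # catalytic output and is independent of Golf (detailed balance holds).
    b.rev("ac5_golf", [("AC5", 1), ("GaGTP_A", 1)], [("AC5Golf", 1)],
          kf=2.0, kr=0.05, complex_tags=("Ga_active",))
    b.rev("ac5_ca", [("AC5", 1), ("Ca", 1)], [("AC5Ca", 1)], kf=2.0, kr=4.0)
    b.rev("ac5golf_ca", [("AC5Golf", 1), ("Ca", 1)], [("AC5GolfCa", 1)],
          kf=2.0, kr=4.0)
    b.rev("ac5ca_golf", [("AC5Ca", 1), ("GaGTP_A", 1)], [("AC5GolfCa", 1)],
          kf=2.0, kr=0.05)
    # GTP hydrolysis on the cyclase returns Gα to the compartment cycle
    b.irr("ac5_gtpase", [("AC5Golf", 1)], [("AC5", 1), ("GaGDP_A", 1)], k=0.05)
    b.irr("ac5ca_gtpase", [("AC5GolfCa", 1)], [("AC5Ca", 1), ("GaGDP_A", 1)],
          k=0.05)
    # cyclase activity (ATP ~saturating, K_M ≈ 250 µM)
    b.enz("cyc_golf", "AC5Golf", "ATP", "cAMP", *_enzkin(250.0, 15.0))
    b.enz("cyc_golf_ca", "AC5GolfCa", "ATP", "cAMP", *_enzkin(250.0, 7.5))
    b.enz("cyc_basal", "AC5", "ATP", "cAMP", *_enzkin(250.0, 1.6))
    b.enz("cyc_basal_ca", "AC5Ca", "ATP", "cAMP", *_enzkin(250.0, 0.8))
    b.irr("amp_atp", [("AMP", 1)], [("ATP", 1)], k=1.0,
          notes="lumped nucleotide regeneration")

    # --- phosphodiesterases ---------------------------------------------
    b.sp("PDE1", "PDE1")
    b.sp("PDE4", "PDE4")
    b.sp("PDE4p", "PDE4", tags=("pde4_p",))
    b.sp("PDE10", "PDE10")
    b.pool("PDE1", 4.0, "PDE1")
    b.pool("PDE4", 2.0, "PDE4")
    b.pool("PDE10", 1.0, "PDE10")

    b.enz("pde1_camp", "PDE1", "cAMP", "AMP", *_enzkin(5.0, 0.5))
    b.rev("pde1_cam", [("PDE1", 1), ("CaMc4", 1)], [("PDE1act", 1)],
          kf=10.0, kr=1.0)
    b.enz("pde1act_camp", "PDE1act", "cAMP", "AMP", *_enzkin(5.0, 5.0))
    b.enz("pde4_camp", "PDE4", "cAMP", "AMP", *_enzkin(2.0, 2.0))
    b.enz("pde4p_camp", "PDE4p", "cAMP", "AMP", *_enzkin(2.0, 4.0))
    b.enz("pde10_camp", "PDE10", "cAMP", "AMP", *_enzkin(1.0, 1.0))
    b.rev("pde10_gaf", [("PDE10", 1), ("cAMP", 1)], [("PDE10c", 1)],
          kf=1.0, kr=0.2)
    b.enz("pde10c_camp", "PDE10c", "cAMP", "AMP", *_enzkin(1.0, 3.0))

    # =====================================================================
    # PKA
    # =====================================================================
    # R₂C₂ holoenzyme; four stepwise cAMP sites, then sequential release of
    # the two catalytic subunits.
    b.sp("PKA", "PKA_R", contents={"PKA_R": 1, "PKA_C": 2})
    b.sp("C", "PKA_C")
    b.pool("PKA_R", 1.2, "PKA")
    b.pool("PKA_C", 2.4, "PKA")

    prev = "PKA"
    for i in (1, 2, 3, 4):
        nxt = f"PKAc{i}"
        b.sp(nxt, "PKA_R", contents={**b._sindex[prev].content_map,
                                     "AdN": b._sindex[prev].content_map.get("AdN", 0) + 1})
        kf, kr = (2.0, 10.0) if i <= 2 else (2.0, 1.0)   # cooperative lobes
        b.rev(f"pka_camp{i}", [(prev, 1), ("cAMP", 1)], [(nxt, 1)], kf=kf, kr=kr)
        prev = nxt
    b.sp("PKAr1", "PKA_R", contents={"PKA_R": 1, "PKA_C": 1, "AdN": 4})
    b.sp("PKAr0", "PKA_R", contents={"PKA_R": 1, "AdN": 4})
    b.rev("pka_rel1", [("PKAc4", 1)], [("PKAr1", 1), ("C", 1)], kf=10.0, kr=20.0)
    b.rev("pka_rel2", [("PKAr1", 1)], [("PKAr0", 1), ("C", 1)], kf=10.0, kr=20.0)

    # RGS-accelerated GTP hydrolysis on Gαolf: a small, saturable pool that
    # caps basal deactivation flux -- receptor drive beyond its capacity
    # lets GaGTP accumulate toward the compartment pool (threshold behaviour)
    b.sp("RGS", "RGS", "D1R_Golf_AC5")
    b.pool("RGS", 0.05, "RGS")
    b.enz("rgs_A", "RGS", "GaGTP_A", "GaGDP_A", kf=160.0, kr=0.064, kcat=0.016)

    # =====================================================================
    # DARPP-32 (Thr34 / Thr75), PP1, CDK5, PP2A pools, PP2B
    # =====================================================================
    b.sp("D32", "D32")
    b.sp("D32@34", "D32", tags=("p34",))
    b.sp("D32@75", "D32", tags=("p75",))
    b.sp("D32@34@75", "D32", tags=("p34", "p75"))
    b.sp("CDK5", "CDK5")
    b.sp("PP1", "PP1")
    b.sp("B56", "B56")
    b.sp("B56p", "B56", tags=("b56_p",))
    b.sp("B72", "B72")
    b.sp("B72Ca", "B72", tags=("b72_ca",))
    b.sp("PP2B", "PP2B")
    b.pool("D32", 50.0, "D32")
    b.pool("CDK5", 1.8, "CDK5")
    b.pool("PP1", 2.0, "PP1")
    b.pool("B56", 2.0, "B56")
    b.pool("B72", 2.0, "B72")
    b.pool("PP2B", 4.0, "PP2B")

    # PKA phosphorylates Thr34 (fast, high-affinity site)
    b.enz("c_d32", "C", "D32", "D32@34", *_enzkin(150.0, 0.65))
    b.enz("c_d32_75", "C", "D32@75", "D32@34@75", *_enzkin(150.0, 0.22))
    # CDK5 phosphorylates Thr75
    b.enz("cdk5_d32", "CDK5", "D32", "D32@75", *_enzkin(12.0, 0.23))
    b.enz("cdk5_d32_34", "CDK5", "D32@34", "D32@34@75", *_enzkin(12.0, 0.02))
    # PP2B (calcineurin), active when CaM·4Ca-bound, removes Thr34
    b.rev("pp2b_cam", [("PP2B", 1), ("CaMc4", 1)], [("PP2Bact", 1)],
          kf=2.0, kr=1.05e-6)  # calcineurin-CaM: picomolar affinity, slow on-rate
    b.enz("pp2b_34", "PP2Bact", "D32@34", "D32", kf=0.15, kr=0.06, kcat=0.015)
    b.enz("pp2b_3475", "PP2Bact", "D32@34@75", "D32@75", kf=0.15, kr=0.06, kcat=0.015)
    # B72-PP2A: single-site Ca²⁺ activation, substrate-specific -- Ca raises
    # activity toward Thr75 but not toward Thr34
    b.rev("b72_ca", [("B72", 1), ("Ca", 1)], [("B72Ca", 1)], kf=1.0, kr=2.0)
    b.enz("b72_75", "B72", "D32@75", "D32", *_enzkin(200.0, 1.2))
    b.enz("b72ca_75", "B72Ca", "D32@75", "D32", *_enzkin(200.0, 4.2))
    b.enz("b72_3475", "B72", "D32@34@75", "D32@34", *_enzkin(200.0, 1.2))
    b.enz("b72ca_3475", "B72Ca", "D32@34@75", "D32@34", *_enzkin(200.0, 4.2))
    b.enz("b72_34", "B72", "D32@34", "D32", kf=0.004, kr=0.032, kcat=0.008)
    b.enz("b72ca_34", "B72Ca", "D32@34", "D32", kf=0.004, kr=0.032, kcat=0.008)
    # B56-PP2A, PKA-phosphorylated form is more active toward Thr75
    b.enz("c_b56", "C", "B56", "B56p", *_enzkin(4.0, 1.2))
    b.irr("b56_dephos", [("B56p", 1)], [("B56", 1)], k=0.005,
          notes="lumped B56 dephosphorylation")
    b.enz("b56_75", "B56", "D32@75", "D32", *_enzkin(200.0, 0.3))
    b.enz("b56p_75", "B56p", "D32@75", "D32", *_enzkin(200.0, 6.0))
    # Thr34-DARPP-32 is a tight PP1 inhibitor; the complex protects Thr34
    b.rev("pp1_d32", [("PP1", 1), ("D32@34", 1)], [("PP1D32", 1)],
          kf=1.0, kr=0.8)
    b.rev("pp1_d32_75", [("PP1", 1), ("D32@34@75", 1)], [("PP1D32_75", 1)],
          kf=1.0, kr=0.8)
    # Thr75-DARPP-32 inhibits PKA catalytic subunits
    b.rev("c_d32_75_inh", [("C", 1), ("D32@75", 1)], [("CD32_75", 1)],
          kf=2.0, kr=48.0)

    # =====================================================================
    # RAS-GRF1 / RAS / RAF
    # =====================================================================
    b.sp("GRF", "GRF")
    b.sp("RASGDP", "RAS", contents={"RAS": 1, "GuN": 1})
    b.sp("RASGTP", "RAS", tags=("RAS_GTP",), contents={"RAS": 1, "GuN": 1})
    b.sp("GTP", "GuN")
    b.sp("GDP", "GuN")
    b.sp("GAP", "GAP")
    b.sp("RAF", "RAF")
    b.pool("GRF", 0.5, "GRF")
    b.pool("RAS", 1.0, "RASGDP")
    b.pool("GuN", 100.0, "GTP")
    b.pool("GAP", 0.3, "GAP")
    b.pool("RAF", 0.5, "RAF")

    b.rev("grf_cam", [("GRF", 1), ("CaMc4", 1)], [("GRFact", 1)],
          kf=20.0, kr=0.5)
    # GEF cycle: ~10⁴-fold accelerated nucleotide release, the nucleotide-free
    # GTPase is stabilised on the GEF, and GTP (10× GDP) wins the re-binding
    b.rev("grf_rasgdp", [("GRFact", 1), ("RASGDP", 1)], [("GRFRASGDP", 1)],
          kf=20.0, kr=2.0)
    b.sp("GRFRAS0", "GRF", contents={"GRF": 1, "CaM": 1, "RAS": 1})
    b.irr("grf_release", [("GRFRASGDP", 1)], [("GRFRAS0", 1), ("GDP", 1)],
          k=10.0)
    b.irr("grf_load", [("GRFRAS0", 1), ("GTP", 1)],
          [("GRFact", 1), ("RASGTP", 1)], k=1.0)
    b.irr("gdp_gtp", [("GDP", 1)], [("GTP", 1)], k=1.0,
          notes="lumped nucleotide regeneration")
    b.enz("gap_ras", "GAP", "RASGTP", "RASGDP", *_enzkin(0.5, 1.0))
    b.irr("ras_hydrolysis", [("RASGTP", 1)], [("RASGDP", 1)], k=0.005)
    b.irr("ras_exchange", [("RASGDP", 1)], [("RASGTP", 1)], k=4e-3,
          notes="constitutive GEF-independent nucleotide exchange")
    b.rev("ras_raf", [("RASGTP", 1), ("RAF", 1)], [("RASRAF", 1)],
          kf=10.0, kr=1.0, complex_tags=("RASRAF",))

    # =====================================================================
    # MEK / ERK, STEP crosstalk edges, DUSP feedback
    # =====================================================================
    b.sp("MEK", "MEK")
    b.sp("MEK@S", "MEK", tags=("mek_p",))
    b.sp("MEK@SS", "MEK", tags=("mek_pp",))
    b.sp("ERK", "ERK")
    b.sp("ERK@T", "ERK", tags=("erk_pT",))
    b.sp("ERK@TY", "ERK", tags=("ERKpp",))
    b.pool("MEK", 1.0, "MEK")
    b.pool("ERK", 2.5, "ERK")

    b.enz("raf_mek1", "RASRAF", "MEK", "MEK@S", *_enzkin(0.5, 1.0))
    b.enz("raf_mek2", "RASRAF", "MEK@S", "MEK@SS", *_enzkin(0.5, 1.0))
    b.enz("b56_mek1", "B56", "MEK@S", "MEK", *_enzkin(3.0, 0.8))
    b.enz("b56_mek2", "B56", "MEK@SS", "MEK@S", *_enzkin(3.0, 0.8))
    b.enz("mek_erk1", "MEK@SS", "ERK", "ERK@T", *_enzkin(0.5, 1.2))
    b.enz("mek_erk2", "MEK@SS", "ERK@T", "ERK@TY", *_enzkin(0.5, 1.2))
    # tonic inactivation in concert: STEP removes pY (the crosstalk edges),
    # B56-PP2A removes the remaining pT
    b.enz("b56_erk", "B56", "ERK@T", "ERK", *_enzkin(3.0, 0.05))
    # PKA phosphorylation of B56 tunes its Thr75 activity only; MEK/ERK
    # dephosphorylation is shared by both forms
    b.enz("b56p_mek1", "B56p", "MEK@S", "MEK", *_enzkin(3.0, 0.8))
    b.enz("b56p_mek2", "B56p", "MEK@SS", "MEK@S", *_enzkin(3.0, 0.8))
    b.enz("b56p_erk", "B56p", "ERK@T", "ERK", *_enzkin(3.0, 0.05))

    b.sp("STEP", "STEP", tags=("STEPu",))
    b.sp("STEP@KIM", "STEP", tags=("STEPph",))
    b.sp("STEP2", "STEP2", tags=("STEPu",))
    b.sp("STEP2@KIM", "STEP2", tags=("STEPph",))
    b.pool("STEP", 0.6, "STEP")
    b.pool("STEP2", 0.0, "STEP2")

    for form, sid, edge in (("st", "STEP", 1), ("stp", "STEP@KIM", 2),
                            ("st2", "STEP2", 3), ("st2p", "STEP2@KIM", 4)):
        b.enz(f"{form}_erk", sid, "ERK@TY", "ERK@T",
              *_enzkin(0.15, 1.2), edge=edge, strip_tags=("ERKpp",))

    # PKA/PP1 cycle on the STEP KIM site (both pools)
    b.enz("c_step", "C", "STEP", "STEP@KIM", *_enzkin(3.0, 60.0))
    b.enz("c_step2", "C", "STEP2", "STEP2@KIM", *_enzkin(3.0, 60.0))
    b.enz("pp1_step", "PP1", "STEP@KIM", "STEP", *_enzkin(4.0, 1.1))
    b.enz("pp1_step2", "PP1", "STEP2@KIM", "STEP2", *_enzkin(4.0, 1.1))

    # DUSP negative feedback: ERK-dependent induction (transcription and
    # translation lumped into activation of a precursor pool)
    b.sp("GeneOff", "DUSPgene")
    b.sp("GeneOn", "DUSPgene", tags=("gene_on",))
    b.sp("DUSPpre", "DUSP")
    b.sp("DUSP", "DUSP", tags=("dusp",))
    b.pool("DUSPgene", 0.01, "GeneOff")
    b.pool("DUSP", 0.4, "DUSPpre")
    b.enz("erk_gene", "ERK@TY", "GeneOff", "GeneOn", *_enzkin(0.05, 1e-3))
    b.irr("gene_off", [("GeneOn", 1)], [("GeneOff", 1)], k=2e-3)
    b.enz("gene_dusp", "GeneOn", "DUSPpre", "DUSP", *_enzkin(0.5, 2.0))
    b.irr("dusp_decay", [("DUSP", 1)], [("DUSPpre", 1)], k=1.2e-3)
    b.enz("dusp_erk", "DUSP", "ERK@TY", "ERK", *_enzkin(0.3, 0.3),
          strip_tags=("ERKpp",))

    # =====================================================================
    # Fyn cycle (Y420 autophosphorylation / Y527 Csk-PTPa cycle)
    # =====================================================================
    b.sp("Fyn", "Fyn", tags=("Fyn_active",))
    b.sp("Fyn@420", "Fyn", tags=("Fyn_active", "fyn_p420"))
    b.sp("Fyn@527", "Fyn", tags=("fyn_p527",))
    b.sp("Fyn@420@527", "Fyn", tags=("Fyn_active", "fyn_p420", "fyn_p527"))
    b.sp("Csk", "Csk")
    b.sp("PTPa", "PTPa")
    b.pool("Fyn", 2.0, "Fyn@527")
    b.pool("Csk", 0.5, "Csk")
    b.pool("PTPa", 0.5, "PTPa")

    b.enz("csk_fyn", "Csk", "Fyn", "Fyn@527", *_enzkin(3.0, 1.0))
    b.enz("csk_fyn420", "Csk", "Fyn@420", "Fyn@420@527", *_enzkin(3.0, 1.0))
    b.enz("ptpa_527", "PTPa", "Fyn@527", "Fyn", *_enzkin(3.0, 0.005))
    b.enz("ptpa_420527", "PTPa", "Fyn@420@527", "Fyn@420", *_enzkin(3.0, 0.005))
    # trans-autophosphorylation of Y420 (blocked while Y527 is phosphorylated
    # unless Gβγ is bound)
    for kin in ("Fyn", "Fyn@420", "Fyn@420@527"):
        tag = kin.replace("@", "")
        b.enz(f"auto_{tag}", kin, "Fyn", "Fyn@420", *_enzkin(2.0, 0.05))
    # Gβγ of the NMDAR compartment recruits inhibited Fyn and licenses its
    # autophosphorylation
    b.rev("gbg_fyn", [("Gbg_N", 1), ("Fyn@527", 1)], [("GbgFyn", 1)],
          kf=20.0, kr=10.0)
    # trans-autophosphorylation within Gβγ-recruited pairs: second order in
    # the Gβγ·Fyn complex, releasing active doubly phosphorylated Fyn
    b.enz("gauto", "GbgFyn", "GbgFyn", ("Fyn@420@527", "Gbg_N"),
          kf=5.0, kr=20.0, kcat=5.0)
    # STEP dephosphorylates Y420 (crosstalk edges 5/6)
    b.enz("st_fyn420", "STEP", "Fyn@420", "Fyn", *_enzkin(1.0, 0.5), edge=5)
    b.enz("st_fyn420527", "STEP", "Fyn@420@527", "Fyn@527",
          *_enzkin(1.0, 0.5), edge=5)
    b.enz("stp_fyn420", "STEP@KIM", "Fyn@420", "Fyn", *_enzkin(1.0, 0.5), edge=6)
    b.enz("stp_fyn420527", "STEP@KIM", "Fyn@420@527", "Fyn@527",
          *_enzkin(1.0, 0.5), edge=6)

    # =====================================================================
    # NMDAR states and traffic
    # =====================================================================
    # location m (synaptic membrane, PSD-slot bound) / i (reservoir),
    # Y = NR2B-Y1472 phosphorylation, S = PKA serine site
    b.sp("Slot", "Slot", "PSD")
    b.pool("Slot", 0.45, "Slot")
    for loc, comp in (("m", "PSD"), ("i", "NMDAR_reservoir")):
        for y in ("", "Y"):
            for s in ("", "S"):
                sid = f"NR{loc}" + (f"@{y}{s}" if (y or s) else "")
                tags = ["NR"]
                if loc == "m":
                    tags.append("NR_mem")
                if y:
                    tags.append("NR_Yp")
                if s:
                    tags.append("NR_Sp")
                contents = {"NMDAR": 1}
                if loc == "m":
                    contents["Slot"] = 1
                b.sp(sid, "NMDAR", comp, tags=tuple(tags), contents=contents)
    b.pool("NMDAR", 0.6, "NRi")

    # traffic: Y1472 phosphorylation accelerates exocytosis and blocks
    # AP2-mediated endocytosis
    for y, s, kexo in (("", "", 4e-4), ("Y", "", 6e-3),
                       ("", "S", 4e-4), ("Y", "S", 6e-3)):
        suf = f"@{y}{s}" if (y or s) else ""
        b.irr(f"exo{y}{s}", [(f"NRi{suf}", 1), ("Slot", 1)],
              [(f"NRm{suf}", 1)], k=kexo)
    for s in ("", "S"):
        suf = f"@{s}" if s else ""
        b.irr(f"endo{s}", [(f"NRm{suf}", 1)], [(f"NRi{suf}", 1), ("Slot", 1)],
              k=1.5e-3)

    # Fyn phosphorylates Y1472 at both locations (all three active forms)
    for kin, pre in (("Fyn", "fyn"), ("Fyn@420", "fyn420"),
                     ("Fyn@420@527", "fyn420527")):
        for loc in ("m", "i"):
            for s in ("", "S"):
                suf = f"@{s}" if s else ""
                tgt = f"NR{loc}{suf}"
                out = f"NR{loc}@Y{s}"
                b.enz(f"{pre}_nr_{loc}{s}", kin, tgt, out, *_enzkin(1.5, 2.5))
    # STEP reverses Y1472 (crosstalk edges 7/8)
    for form, sid, edge in (("st", "STEP", 7), ("stp", "STEP@KIM", 8)):
        for loc in ("m", "i"):
            for s in ("", "S"):
                b.enz(f"{form}_nr_{loc}{s}", sid, f"NR{loc}@Y{s}",
                      f"NR{loc}{'@' + s if s else ''}",
                      *_enzkin(1.0, 2.0), edge=edge)
    # PKA / PP1 serine cycle at both locations
    for loc in ("m", "i"):
        for y in ("", "Y"):
            suf = f"@{y}" if y else ""
            b.enz(f"c_nr_{loc}{y}", "C", f"NR{loc}{suf}", f"NR{loc}@{y}S",
                  *_enzkin(3.0, 1.0))
            b.enz(f"pp1_nr_{loc}{y}", "PP1", f"NR{loc}@{y}S", f"NR{loc}{suf}",
                  *_enzkin(3.0, 0.5))

    # =====================================================================
    # GluR1 (PKA site Ser845)
    # =====================================================================
    b.sp("GluR1", "GluR1")
    b.sp("GluR1@845", "GluR1", tags=("GluR1p",))
    b.pool("GluR1", 2.0, "GluR1")
    b.enz("c_glur1", "C", "GluR1", "GluR1@845", *_enzkin(3.0, 1.2))
    b.enz("pp1_glur1", "PP1", "GluR1@845", "GluR1", *_enzkin(3.0, 0.3))

    # PKA phosphorylation of PDE4 (negative feedback on cAMP)
    b.enz("c_pde4", "C", "PDE4", "PDE4p", *_enzkin(4.0, 0.5))
    b.irr("pde4_dephos", [("PDE4p", 1)], [("PDE4", 1)], k=0.005)

    net, params = b.build()
    if not two_compartments:
        params = _merge_compartments(params)
    return net, params


def _merge_compartments(params: ParameterSet) -> ParameterSet:
    """Single-pool variant: one effective anchor environment.  Both axes see
    the same D1R/Golf pool -- implemented by making the two compartments'
    anchors kinetically identical (equal capacity and affinity), which
    abolishes the asymmetric distribution that produces segregation."""
    out = params.copy()
    cap_d = (out.totals["AncD_A"] + out.totals["AncD_N"]) / 2
    cap_g = (out.totals["AncG_A"] + out.totals["AncG_N"]) / 2
    out.totals["AncD_A"] = out.totals["AncD_N"] = cap_d
    out.totals["AncG_A"] = out.totals["AncG_N"] = cap_g
    for rid in ("bind_D1R_A", "bind_D1R_N", "bind_Golf_A", "bind_Golf_N"):
        out.constants[(rid, "kf")] = 1e-3
        out.constants[(rid, "kr")] = 1e-3
    return out


def build_network(tables=None, scheme=None, two_compartments=True,
                  overrides=None, totals_override=None):
    """Assemble a configured model.

    ``tables`` is a (reactions, species, totals) path triple; the packaged
    standard tables are used when omitted.  ``scheme`` applies a crosstalk
    code (edge switches and, for two-pool schemes, the STEP split);
    ``two_compartments=False`` collapses the D1R/Golf compartments into one
    shared pool.  Returns (ReactionNetwork, ParameterSet).
    """
    from .tableio import load_tables, load_default_tables
    if tables is None:
        net, params = load_default_tables(overrides=overrides,
                                          totals_override=totals_override)
    else:
        net, params = load_tables(*tables, overrides=overrides,
                                  totals_override=totals_override)
    if not two_compartments:
        params = _merge_compartments(params)
    if scheme is not None:
        params = net.apply_scheme(params, scheme)
    return net, params


#: calibrated fold constants: the value of F per mechanism for which the
#: peak NMDAR-enhancement factor over the acute-psychostimulant paradigm
#: equals 2.5 on the standard WT model (recomputable with
#: ``simulate.calibrate_mechanism``)
DEFAULT_F = {"yTrf": 1.7344, "sSCh": 0.0601, "ySCh": 0.4453}
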