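# Methods

## The model

`msnsig` simulates intracellular signaling in a dopamine-D1-receptor
expressing striatal medium spiny neuron as a single well-stirred mass-action
ODE system (µM, seconds).  Two inputs drive it: dopamine (DA) acting on D1R
coupled to the striatal G-protein Golf, and glutamatergic activity entering
as a prescribed dendritic Ca²⁺ signal.  Both inputs are clamped forcing
functions, not state variables.

Two signaling axes are modelled in full mechanistic detail:

* **AC5 axis** — D1R·DA catalyses nucleotide exchange on anchored Golf;
  Gα-olf·GTP binds adenylyl cyclase 5 and drives cAMP synthesis against
  PDE1 (CaM-activated), PDE4 (PKA-potentiated) and PDE10a (cAMP-stimulated)
  degradation; cAMP releases PKA catalytic subunits, which phosphorylate
  DARPP-32 at Thr34 (a PP1 inhibitor), GluR1 at Ser845, the STEP KIM site,
  B56-PP2A and PDE4.  CDK5 maintains the large Thr75 pool of DARPP-32,
  which inhibits PKA; calcineurin (PP2B, via CaM·4Ca) removes Thr34;
  the B72- and B56-PP2A pools remove Thr75, the former Ca²⁺-stimulated,
  the latter PKA-stimulated.
* **NMDAR axis** — Ca²⁺ loads calmodulin (four equivalent sites, K_d
  2.5 µM each, so the CaM·4Ca response runs on its slope-four limb in the
  µM range); CaM·4Ca activates RAS-GRF1, which loads RAS with GTP against
  GAP-accelerated hydrolysis; RAS·GTP recruits RAF, and the RAF→MEK→ERK
  cascade double-phosphorylates ERK.  ERK-pY is removed by STEP, ERK-pT by
  PP2A; an ERK-induced DUSP loop (transcription and translation lumped into
  activation of a precursor pool) terminates the response.  The Fyn cycle
  (Y420 trans-autophosphorylation, Y527 Csk/PTPα cycle, Gβγ-licensed
  activation of the Y527-inhibited form) phosphorylates NR2B-Y1472 on
  membrane and reservoir NMDAR; Y1472 phosphorylation accelerates
  exocytosis into a finite pool of synaptic slots and blocks endocytosis.
  STEP reverses Fyn-Y420 and NR2B-Y1472.

Every enzymatic step carries an explicit Michaelis complex (no quasi-steady
-state shortcut); reactions are classed enzymatic (k_f, k_r, k_cat, with
k_r = 4·k_cat used as the default convention when only K_M was known),
reversible (k_f, k_r) or irreversible (k).  The network ships as three
TSV tables (reactions, species, conserved totals) with 147 reactions, 198
species and 40 conserved pools; a loader validates conservation of every
pool against the stoichiometry and supports per-parameter overrides.

### The two D1R/Golf compartments

D1R and Golf distribute between an AC5-coupled and an NMDAR-coupled
signaling compartment through explicit anchor species, exchanging slowly
(minutes–hours) through a non-signaling reservoir.  The AC5 compartment
binds D1R with high affinity but a capacity of only 20 % of the wild-type
D1R total; the NMDAR compartment holds D1R loosely at high capacity.  For
Golf the asymmetry is mirrored (NMDAR-compartment anchor tight, capacity
below 40 % of total Golf).  Consequently a reduction of total D1R to 20 %
(the *Drd1a*⁺/⁻ condition) leaves the AC5 compartment essentially full and
empties the NMDAR compartment, while reducing Golf to 40 % (*Gnal*⁺/⁻)
spares the NMDAR compartment and strips the AC5 compartment.  Setting
`two_compartments=False` collapses the anchors into one kinetically uniform
environment, the single-pool variant in which this protective asymmetry
disappears.

### Crosstalk schemes

PKA-sensitive crosstalk through STEP is configured by a three-bit code:
crosstalk at Fyn&NR2B, crosstalk at ERK, and one vs two STEP pools.  Each
of eight numbered (STEP form, substrate) edges corresponds to the forward
rate constants of the association reactions between a STEP form and its
phospho-substrate; a scheme switches deselected edges to zero.  A crosstalk
bit of 1 means only non-phosphorylated STEP attacks that substrate.
Two-pool schemes instantiate a second STEP pool (totals split 50/50; the
split is configurable since no measured value exists) that serves the ERK
edge while the first pool serves Fyn and NMDAR.  The default scheme is
`010`: a single pool, PKA-sensitive only at ERK.

### NMDAR-enhancement mechanisms

Dopamine enhances NMDAR Ca²⁺ currents through one of three mechanisms,
expressed as a factor that multiplies the amplitude term of each Ca²⁺ spike
at its onset (baseline Ca²⁺ is never scaled): `sSCh` (fraction of membrane
NMDAR carrying the PKA serine site), `ySCh` (fraction carrying
NR2B-Y1472), and `yTrf` (membrane over total NMDAR, the traffic-based
mechanism and the default).  Factors are normalised to exactly 1 at the
equilibrated wild-type basal state and take the form 1 + F·(r/r₀ − 1); F is
calibrated per mechanism by bisection so the peak factor over the
psychostimulant paradigm is 2.5, and the calibrated values ship as
constants.  Mutant simulations reuse the wild-type calibration, so a mutant
with a genuinely lower membrane NMDAR fraction sees weaker enhancement —
the anchor point of the scaling is a property of the wild-type model, not
re-normalised per genotype.

## Stimulus protocols

Ca²⁺ spikes and the DA overflow are difference-of-exponential transients
(spike: 60 nM baseline, 500 nM peak, k₁ = 17.2 s⁻¹, k₂ = 15.7 s⁻¹; DA:
10 nM baseline, 300 nM peak, k₁ = 0.15 min⁻¹, k₂ = 0.055 min⁻¹, peak near
10.6 min).  Spiking runs at 0.1 s⁻¹, regular by default; Poisson trains
with seeded generators reproduce the stochastic case.  Named protocols:
`basal`, `DAslice` (tonic 10 µM DA, read at 5′), `NMDAslice` (bath NMDA
represented as tonic 10 µM Ca²⁺ — the level is a configuration constant,
not a measured mapping — read at 10′), `APA` (DA transient plus spiking,
read at 15′), `saline` (spiking only), `DA_only`/`Ca_only`,
`culture_sensitization` (tonic 3 µM DA, one slow Ca²⁺ elevation at 60 s
with ~20 s rise and ~4 min decay, standing in for bath NMDA in culture;
ERK read 8 min later) and `PP2B_inhibition` (tonic 10 µM Ca²⁺ with the
calcineurin catalytic step zeroed in the inhibited arm).  "Sampled at 5′"
is minutes after stimulus onset.

## Numerics

The compiled right-hand side evaluates all unidirectional mass-action steps
with index arrays; integration uses BDF with the analytic Jacobian sparsity
pattern (rtol 10⁻⁶, atol 10⁻¹² for protocol runs).  The integrator restarts
at every spike onset and caps the step inside each spike's support so the
sub-second transients are never stepped over; spike contributions are
dropped once below 10⁻⁷ µM.  Equilibration integrates the unstimulated
system over increasing windows (10³ → 3·10⁷ s) until
max |dC/dt| / max(C, 1 nM) < 10⁻⁸ s⁻¹ (3·10⁻⁸ for mutants, which have
slower relaxation modes), and fails loudly listing the worst species.
Fold changes compare stimulated to saline arms at matched readout times.

## What was fitted, and how

No supplementary parameter listing accompanies the source material, so the
rate constants and totals here are this package's own manual fit,
literature-guided where possible (K_M/k_cat conventions, CaM and
calcineurin affinities, PKA activation range) and otherwise adjusted
until the non-psychostimulant phenotype panel was reproduced.  The panel
values the shipped tables achieve (also recomputed by
`scripts/acceptance.py`): basal cAMP 62 nM, DARPP-32-p34 0.32 µM, p75
12.1 µM, STEP 72 % active; DA-slice p34 ×10.2 and p75 ×0.55 at 5′;
NMDA-slice p34 ×0.42 and p75 ×0.52 at 10′; RAS·RAF Hill h 4.3 with
K 0.87 µM; traffic rate ≈0.16 min⁻¹.

Three deliberate design elements carry the mutant phenotypes:

* a small AC5 pool (0.15 µM) downstream of a saturable RGS-limited Gα-olf
  deactivation: receptor drive beyond the RGS capacity lets Gα-olf·GTP
  accumulate toward the compartment pool, so the stimulated cAMP output
  saturates and a *Gnal*⁺/⁻ AC5-compartment deficit is strongly
  compressed, while basal cAMP is dominated by a Golf-independent AC5
  leak so the mutant's resting state barely moves;
* a small STEP pool (0.6 µM) with tight ERK-pp binding (K_M 0.15 µM):
  phospho-ERK sequesters STEP away from Fyn and NR2B, the
  retroactivity that lets a single STEP pool keep the axes segregated;
* the PP1-controlled STEP-KIM cycle (fast PKA phosphorylation against
  strong PP1 dephosphorylation), which converts the DARPP-32/PP1 state
  into the STEP tone on ERK.

## Known limitations

* The D32-knockout ERK ratio under the default scheme comes out near 1.0
  rather than the experimental 0.4: with saline-matched fold changes, the
  knockout's constitutively higher STEP tone depresses both the baseline
  and the stimulated ERK response, and the ratio largely cancels.  The
  D1R-haploinsufficient ERK ratio (≈0.24) overshoots the reduction below
  the experimental 0.5 for the converse structural reason — the
  NMDAR-compartment receptor loss is nearly complete, and the
  Fyn→NR2B→traffic chain cannot regenerate half the wild-type enhancement
  from a few per cent of the receptor.  Both signs are correct, the
  Gα-olf arm (ERK ≈ 0.94, GluR1 ≈ 0.73) and the D1R GluR1 arm (≈ 1.09)
  are near-quantitative, but the mutant-panel r² is well below the
  target.  These are left as honest misfits of this reconstruction rather
  than forced.
* Scheme logic holds comparatively rather than absolutely: removing all
  crosstalk (scheme 000) moves the knockout ERK ratio toward 1 but a
  residual coupling of DARPP-32 to basal ERK through PP2A availability and
  the DUSP preload leaves it near 1.4; Fyn-side crosstalk (1**) raises the
  D1R-haploinsufficient ERK ratio above its 010 value as expected.
* The Poisson-vs-regular convergence of the mean ERK time course reaches
  R² ≈ 0.93 at 20 replicates over the full 45-minute paradigm (≈ 0.98 over
  the first 25 minutes), short of the 0.995 reference; the steep RAS
  ultrasensitivity amplifies inter-spike-interval noise, most visibly in
  the DUSP-driven decay phase.
* The slow-mechanism sensitization ratios sit near 1.2–1.4 rather than
  exactly 1 because tonic dopamine also left-shifts the ERK dose response
  through the STEP crosstalk; the fast tyrosine mechanism remains clearly
  separated (ratio ≈ 2.6).
* Ca²⁺ entry is a prescribed waveform: no channel gating, no
  electrophysiology, no spatial gradients, no stochastic chemistry.
* The factor scaling a spike is evaluated at spike onset and held for that
  spike; for the slow culture Ca²⁺ elevation this is an approximation.
* The immunoblot heterogeneity correction FC = 1 + (W − 1)/(f_c·f_t)
  derives from an explicit mixture model (all cells contribute equal basal
  marker; the responsive cell type is the fraction f_c of cells, of which
  f_t respond FC-fold).  The underlying derivation in the source material
  is not printed, so this is a reconstruction that reproduces its
  documented limiting behaviours.

## Synthetic data

The stimulus generator *is* the study's input model: spike trains, DA
transients and slice protocols are the experimental conditions, not
adjustable fixtures.  The `synthetic_fit_fixtures` helper generates
Hill/monoexponential datasets with known parameters and seeded Gaussian
noise purely to exercise the fitting layer.  What passing tests show is
that the *model* reproduces the target phenotypes under idealised inputs;
they say nothing about unmodelled biology (receptor desensitisation,
electrogenic feedback, cell-to-cell variability).

## Problem sizes used by the test and acceptance runs

Psychostimulant runs integrate 960 s of model time (readout at 900 s);
the Poisson-convergence check uses 20 replicates of the full 2700 s
paradigm; the crosstalk-scheme screen runs the complete mutant panel for
all eight schemes; the full-model sensitivity matrix is exposed as
a resumable batch computation (`sensitivity_matrix` with a cache dict) and
is validated on analytic toy outputs and small parameter subsets.
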