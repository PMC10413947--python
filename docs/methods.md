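# Methods

## The model

`mitoresp` implements three parallel, thermodynamically constrained kinetic
models of isolated-mitochondria respiration and bioenergetics — one each for
rat heart, kidney cortex and kidney outer medulla (OM). Each model couples

* nine TCA-cycle reactions (PDH, CITS, ICDH, AKGDH, SCAS, NDK, FH, MDH, GOT),
* five electron-transport/OxPhos steps (CI, CII/SDH, CIII, CIV, CV),
* ten carriers of the inner membrane (pyruvate-H+ and glutamate-H+
  cotransporters, the succinate/Pi and malate/Pi dicarboxylate carriers DCCS
  and DCCM, the tricarboxylate and 2-oxoglutarate/malate exchangers, the
  electrogenic glutamate/aspartate exchanger, the adenine nucleotide
  translocase, the phosphate carrier, and the proton leak),

in three regions: the external buffer, the intermembrane space (holding only
cytochrome c; everything else equilibrates freely across the outer
membrane), and the matrix. The dynamic state comprises 34 concentrations
plus the membrane potential. Citrate and isocitrate are lumped into one pool
(the catalog carries no aconitase step), and the matrix GTP/GDP pair is
carried explicitly for substrate-level phosphorylation; with separate
citrate/isocitrate states the count would match the 37 states of the
original formulation.

### Rate laws

Reactions follow a generalized random-ordered rapid-equilibrium law: the net
rate is proportional to the displacement of the mass-action ratio from the
apparent equilibrium constant and saturates in every substrate and product.
K'eq is computed from the transformed Gibbs energy at pH 7, adjusted to the
working pH by a factor of 10 per proton produced or consumed, and rescaled
for the mM standard state by the molecularity difference. Carriers use
uniporter / symporter / antiporter laws with single- or double-occupancy
denominators.

Membrane-potential-coupled steps carry an explicit charge ledger (charges
exported from the matrix per forward turnover): CI +4, CIII +2, CIV +8
(per-O2 turnover), CV −3, ANT −1, glutamate/aspartate exchange −1, proton
leak −1. Their apparent equilibrium constants include the electrochemical
proton cost `u = F·dPsi + RT ln10 (pH_m − pH_e)` per charge, so every flux
is exactly zero at zero net driving force including the potential term. For
the electrogenic exchangers the potential factor divides the reverse term
(the whole electrical dependence is assigned to the reverse translocation
step), which preserves Michaelis saturation of the forward mode — the
physiological mode of both carriers — while keeping the equilibrium point
thermodynamically exact.

Three decarboxylating dehydrogenase complexes (PDH, NAD-linked ICDH, AKGDH)
are one-way: their reverse reactions (reductive carboxylation, succinyl-CoA
ligation back to 2-oxoglutarate) are catalysed in vivo by different enzymes
that are out of scope, and allowing them here drains the NADH pool through
routes the real complexes do not support.

Complex IV turnover is defined per O2 (four electrons), which makes the CIV
flux numerically identical to the measured oxygen consumption rate; the
stoichiometric factor between them is the named constant
`ocr_per_civ_turnover = 1`. The law is first-order in reduced and oxidized
cytochrome c with Michaelis saturation in O2 (K_O2 = 0.12 uM) and a
quarter-power O2 driving term placing the zero-flux point at the
four-electron equilibrium.

The proton leak is supralinear in the proton-motive force,
`J = T_max (exp(alpha (x - x_ref)) - exp(-alpha x_ref))` with `x = u/RT`,
`alpha = 3.7` and `x_ref = 6.455`; measured leak currents rise with roughly
this steepness near 180 mV, and the form is zero exactly at zero pmf.

### Succinate-pathway regulation

Matrix malate competitively raises the apparent succinate constant of DCCS;
matrix succinate competitively raises the apparent malate constant of DCCM;
and SDH carries an apparent succinate constant
`K'' = K_SUC (1 + OXA/K_OXA) / (1 + MAL/K_MAL)` inside a two-bracket
shared-site denominator (succinate and fumarate compete for the
dicarboxylate site, the two quinone species for the quinone site). The
regulatory binding constants are tissue-specific: succinate binds DCCM most
tightly in heart and matrix malate binds DCCS most weakly in heart, which is
what makes the heart's succinate response qualitatively different from the
kidney's. NADH product inhibition of ICDH/AKGDH is carried by their product
binding constants.

### Mass balances

Matrix species: `V_m dC/dt = sum(beta J_rxn) + sum(J_transport)` with V_m =
1 uL/mg protein; IMS cytochrome c uses V_ims = 0.1 V_m; buffer species:
`dC/dt = -J rho 1e-3` with rho the protein density in mg/mL (the chamber
volume cancels). The membrane potential integrates the charge-weighted flux
sum over a capacitance of 6.75e-3 mM/mV. The five conserved pools (NAD+NADH
= 3 mM, UQ+UQH2 = 1.5 mM, reduced+oxidized cytochrome c = 1 mM, matrix
ATP+ADP = 10 mM, CoA+acetyl-CoA+succinyl-CoA = 1 mM) are conserved exactly
by construction; the matrix GTP+GDP pool (1 mM, a stated default) likewise.
Dissolved CO2 is fixed at 21.4 mM and folded into the decarboxylation
equilibrium constants; matrix pH 7.6, buffer pH 7.15 and all cations are
fixed.

## Parameters

Extrinsic maximal rates (14 V_max, 10 T_max per tissue, nmol/min/mg at
37 degC) ship in `data/tissue_params.csv`, printed in units of 1e5 except
the proton-leak row. Intrinsic constants (binding constants, transformed
Gibbs energies, charge ledger, regulatory constants) ship in
`data/kinetics.json` and `data/model_config.json`. The thermodynamic
constants come from standard transformed-Gibbs-energy values; binding
constants start from isolated-enzyme kinetics and were then calibrated, with
the extrinsic rates held fixed at their published values, so that the models
reproduce the published emergent predictions (respiratory control indices,
state-3 membrane potentials, redox poise) as closely as the model structure
allows. Calibration targeted those emergent levels only, never individual
test cases.

Initial conditions: conserved pools at their totals with the pyridine pool
95% reduced (freshly isolated mitochondria keep NAD largely reduced, and
with rotenone present the NADH ratio simply persists at its initial value,
as observed); small endogenous matrix 2-oxoglutarate and aspartate (the
transaminase source of early oxaloacetate); buffer with 5 mM phosphate
(typical respiration medium), no substrates or adenine nucleotides, and
0.4 mM O2 — the oxygenation level used for isolated-mitochondria titrations,
chosen because plain air saturation (~0.19 mM) would be exhausted before the
last ADP dose of the sequential protocol at the stated protein densities.

## Protocols and observables

Protocol A (fitting): mitochondria at 0.05 mg/mL (heart) or 0.2 mg/mL
(kidney), substrate at t = 2 min (PM/GM/AM 5:2.5 mM, SUC 10 mM, rotenone
0.5 uM modelled as complete CI block and active from the start of the
recording), then six ADP doses (25, 50, 75, 100, 150, 250 uM). The first
dose comes 8 min after the substrate so every tissue reaches its leak-state
plateau (the slowest corner is OM with 2-oxoglutarate); later doses are
spaced 3 min, enough for each state-3 to state-4 transition to complete.
Protocol B (validation): one dose, 200 uM (heart, 0.1 mg/mL) or 100 uM
(kidney). Additions are instantaneous concentration jumps implemented as
integration restarts (LSODA; reporting tolerances rtol 1e-8 / atol 1e-10 by
default, 1e-7/1e-9 in the test suite, 1e-6/1e-8 inside fitting loops —
halving tolerances moves reported peaks by well under 1%).

State-2 OCR is the mean over the final minute before the first ADP dose;
each state-3 peak is the maximum OCR in its inter-dose window; the
respiratory control index (RCI) is the largest peak over the state-2 mean.
Redox ratios are reduced fractions of the pyridine, quinone and cytochrome c
pools. The leak scan multiplies the maximal leak rate by 1 to 9 under
protocol B.

## Estimation and diagnostics

The objective is the normalized sum of squared errors over state-3 peaks
(plus the state-2 mean as one extra point per substrate, configurable), each
dataset normalized by its own maximum observation and weighted by 1/N. A
simulation failure at a trial parameter vector contributes a large finite
penalty (1e6, logged) so evolutionary search stays totally ordered. Fitting
is two-stage: differential evolution over log10-transformed bounds
(log-uniform sampling), then Nelder-Mead refinement; both stages are
seedable. Normalized sensitivities use the 1% central difference normalized
by P0/E0; the sweep scans each parameter over 0.5-1.5 of its optimum. The
parameter correlation matrix is `CC = HM/sqrt(diag outer)` with `HM =
inv(JM' JM)` where JM holds 1% central differences of every fitted data
point with respect to every parameter — the Gauss-Newton information form, a
parameter-space matrix (a data-space inverse would not be indexable by
parameters); a singular information matrix falls back to the pseudo-inverse
with a warning, and pairs with |CC| > 0.8 are reported as weakly
identifiable.

## Synthetic data

The generator runs the protocol at the true parameters once, then applies
noise to the feature observables only (never to states or parameters):
default multiplicative Gaussian with 5% coefficient of variation, the
typical replicate spread of high-resolution respirometry. A fixed seed gives
byte-identical datasets; replicates advance the substream deterministically.
The full study layout is five substrate combinations x (one state-2 mean +
six peaks). The recovery study fits the adenine nucleotide translocase and
complex IV rates — the two most identifiability-relevant parameters — on a
reduced two-substrate design (pyruvate+malate and succinate, spanning the
NADH- and FADH2-linked pathways) with a small evolutionary stage (8-member
population, one generation) plus local refinement; this desk-scale problem
size recovers the sensitive parameters to well under 1% at zero noise.
Larger designs are a matter of configuration, not code.

## What the synthetic data do and do not show

The generator emulates the feature structure and replicate noise of a
sequential-ADP oxygraph experiment on the model's own dynamics. It does not
emulate instrument drift, chamber reoxygenation artifacts, O2 back-diffusion,
inter-preparation variability of mitochondrial quality, or fluorescence
calibration of the membrane potential. Passing recovery tests therefore
demonstrate the identifiability of parameters given the model and the
feature set — not that the same parameters would be recovered from a real
instrument record.

## Numerical choices and degenerate inputs

Concentrations are clipped at zero inside rate evaluations (stiff-solver
transients can undershoot by about the absolute tolerance). Non-finite
fluxes raise an error naming the offending step. RCI is undefined (an
explicit error) when the state-2 mean is nonpositive. The zero-noise
recovery objective is exactly zero at truth (generator and fitting runner
share one pipeline), so sensitivity ranking at that point falls back to a
curvature proxy.

## Known limitations

* The intrinsic kinetic constants are a reconstruction, calibrated against
  published emergent predictions; the source models' full intrinsic constant
  tables are not publicly available and are not reproduced here.
  Several published levels are structurally out of reach of this
  reconstruction and the corresponding checks fail honestly: the
  glutamate+malate respiratory control index runs high in all tissues (the
  glutamate-uptake limitation is weaker here than in the source models, and
  state-2 leak-driven respiration with glutamate cannot exceed the
  pyruvate+malate value under any single monotone leak curve), the cortex
  control indices run low (its state-2 leak is high relative to its
  oxidase-capped state 3), and the succinate runs keep cytochrome c more
  reduced at state 3 than published (a first-order oxidase law cannot carry
  the published rate at the published reduction with the published maximal
  rate). The kidney models also hold the 2-oxoglutarate+malate redox poise
  more oxidized at state 3 than published (their 2-oxoglutarate dehydrogenase
  rates are three orders of magnitude below the heart's, so the published
  ~10% reduced pyridine pool is only approached, not held).
* With succinate alone, the heart model's oxaloacetate inhibition of SDH
  becomes self-reinforcing at the highest ADP dose and respiration collapses
  rather than oscillating around a depressed level: once NADH is fully
  oxidized there is no matrix sink left for oxaloacetate. The qualitative
  chain (succinate accumulation -> DCCM inhibition -> malate accumulation ->
  oxaloacetate production -> SDH inhibition, absent with rotenone and in the
  kidney cortex) is reproduced.
* Kidney cortex succinate-with- and without-rotenone trajectories agree to
  about 0.2% of peak respiration, not to machine precision: complex I in the
  cortex sits close to, but not exactly at, equilibrium during succinate
  oxidation.
* Cations, matrix pH dynamics, reactive oxygen species, volume dynamics and
  chamber O2 exchange are fixed or absent by design.
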