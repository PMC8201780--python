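# Methods

`atrialab` models three gain-of-function potassium-channel mutations linked
to familial atrial fibrillation — KCNH2 T895M, KCNH2 T436M and KCNE3-V17M —
from the ion channel to 2D tissue. This note records the models, the
numerical choices, and what the defaults do and do not represent.

## Channel parameterisation

The baseline myocyte is the Courtemanche-Ramirez-Nattel human atrial model
(21 states, 37 C, standard constants; currents in pA with Cm = 100 pF).
Mutations act through 16 modifiers of the I_Kr and I_to Hodgkin-Huxley
formulations:

- `alpha_xr = p0r * 0.0003 (V + 14.1 + p1r) / (1 - exp(-(V + 14.1 + p1r)/(5 p2r)))`
- `beta_xr  = p3r * 7.3898e-5 (V - 3.3328 + p4r) / (exp((V - 3.3328 + p4r)/(5.1237 p5r)) - 1)`
- `I_Kr = Cm p6r g_Kr xr (V - E_K) / (1 + exp((V + 15 + p7r)/(22.4 p8r)))`
- `alpha_oi = p0t / (18.53 + exp((V + 113.7 + p1t)/(10.95 p2t)))`
- `beta_oi  = p3t / (35.56 + exp(-(V + 1.26 + p4t)/(7.44 p5t)))`
- `I_to = Cm p6t g_to oa^3 oi (V - E_K)`

Scales and slopes are 1 and shifts 0 for wild type, so the identity set
reproduces the baseline model exactly (tested against an independently
coded oracle to 1e-10 relative). The named presets carry the fitted values
for the three mutations; KCNE3-V17M applies its I_Kr and I_to columns
simultaneously since the accessory subunit impairs both channel complexes.

Removable singularities of the rate expressions (e.g. `alpha_xr` at
`V = -14.1 - p1r`) are evaluated by their analytic limits.

**Two views of the parameterised gates.** At the channel level (the `clamp`
module, used for fitting expressed-channel data) the steady state is
derived from the rates, `x_inf = alpha/(alpha+beta)`, so rate modifiers
move both kinetics and availability — this is where the ~14 mV depolarising
shift of Kv4.3/V17M steady-state inactivation lives. In the cell model the
modified rates enter through the time constants only
(`tau = 1/(alpha+beta)`, Q10 = 3 retained for oi) while the steady-state
curves keep the baseline sigmoids, as in the original model formulation —
i.e. the mutant rates are substituted into the existing gate update. The
package adopts this split deliberately: with fully rate-derived steady
states the V17M action potential loses its dome entirely (APD90 falls ~72%
instead of the ~46-50% the mixed formulation produces) and every mutant
biomarker moves far from its expected magnitude, whereas the mixed
formulation reproduces the mutation-level biomarker pattern coherently.
The inconsistency between the two views is confined to the two
mutation-bearing gates and is documented here rather than hidden.

## Acetylcholine-activated potassium current

`I_KACh = Cm * 10/(1 + 9.13652/[ACh]^0.477811) * (0.0517 +
0.4516/(1 + exp((V+59.53)/17.18))) * (V - E_K)`, with the dose constants
calibrated for [ACh] in mM (canine cholinergic-AF lineage). The default
dose is 0.005 uM — a physiological background level at which the current
is small and the 1-Hz APD90 of the stabilised wild-type right-atrial cell
stays at the baseline model's own value (~294 ms). Reading the same
constants as uM-calibrated would make 0.005 uM a strongly APD-shortening
dose (APD90 ~120 ms) and is not the default; the `ach` field of
`ModelSpec`/`CellConstants` exposes the dose for sensitivity studies.

## Regional heterogeneity

Conductance multipliers per region (RA reference): LA scales I_CaL 0.9 and
I_Kr 2.0; PV scales I_CaL 0.8, I_Kr 2.5, I_to 0.9, I_K1 0.9 and I_Ks 1.9.
Combined with the four genotypes this yields the twelve study models.

## Single-cell numerics and protocols

Fixed-step integration: Rush-Larsen exponential updates for the 15 gates,
forward Euler for V and the five concentrations, dt = 0.01 ms (halving dt
changes APD90 by < 0.5 ms; 0.02 ms does not meet that bound). An adaptive
LSODA path (rtol 1e-6 / atol 1e-8) is available for cross-checks. Pacing
follows the study protocol: 61 beats at each BCL from the published rested
state, 20 pA/pF stimuli of 2 ms; beat 61 is analysed. APD90 runs from the
maximum-upstroke time to the 90% repolarisation crossing (linear
interpolation, Vrest = pre-stimulus V).

Restitution paces each BCL as an independent 61-beat run from the rested
state (the alternative continuation-from-1-Hz variant is available through
`pace_cell(initial=...)`). Alternans is flagged from the trailing 11 beats:
mean |ΔAPD| > 2 ms (configurable) with sign alternation in at least 8 of
the 9 adjacent difference pairs. The restitution maximum slope is the
largest centred finite difference dAPD90/dBCL over captured,
non-alternating points.

## Genetic algorithm

Real-coded GA: uniform initialisation inside the sampling bounds
(scales/slopes (0.05, 20], shifts [-80, 80] mV), fitness = sum over
(channel, quantity) groups of record-weighted RMSEs, each group weighted by
1/RMS(uncertainty) so currents (pA/pF), time constants (ms) and normalised
curves contribute on comparable scales. Selection draws parents uniformly
from the top 15% ("simple select" truncation; fraction configurable).
Recombination is per-coordinate SBX with a self-adaptive distribution
index (eta starts at 2, multiplied by 1.5 after an improving generation,
divided by 1.5 otherwise, clamped to [0.5, 100]). Mutation perturbs each
coordinate with probability 0.9 by a gaussian whose sd is proportional to
the coordinate magnitude, annealed geometrically from 40% to 0.1% across
the generations — wide exploration early, refinement late. Elitism is 0;
the best-ever individual is tracked separately, making its trace
non-increasing by construction.

Identifiability shaped the default synthetic protocols: equilibrated 1-s
prepulse inactivation curves carry no kinetic information about the oi
forward rate (p0t), and peak I-V data alone cannot separate conductance
(p6t) from inactivation speed (p3t). The default I_to dataset therefore
includes the oi time constant versus voltage (recovery side -120..-60 mV
and transient decay at 0/20/40 mV), and the I_Kr deactivation-tau grid uses
5-mV steps over -120..-30 mV (a short-step 250-ms I_Kr protocol variant is
also provided). With these, fitting noise-free synthetic data at population
300 x 20 generations recovers the three-parameter I_Kr column and the
five-parameter I_to column reliably (5/5 seeds within 5% of scales/slopes
or 2 mV of shifts). The four-parameter KCNH2 columns are harder: their
fitted parameters trade off along a curved valley (a beta-rate rescale, a
voltage shift and a slope change can nearly compensate), and at this
evaluation budget a single GA run lands inside the 5%/2-mV box roughly
half to two-thirds of the time; more generations or a larger population
raise the rate, and multiple seeds with best-score selection are the
practical recipe.

## Tissue model

Monodomain reaction-diffusion on a homogeneous 2D patch, fibres along +x:
operator splitting (reaction step, then explicit 9-point anisotropic
diffusion on V) with mirrored no-flux boundaries and a hard CFL guard.
The study-scale geometry is 5 cm x 5 cm at 300 um (167 x 167 nodes),
dt = 0.01 ms. The printed capacitance-normalised conductivity
(0.0022 S/(cm pF)) cannot be converted to a diffusivity without a
surface-to-volume constant, so the longitudinal diffusivity is an explicit
constant D_L = 0.0022 cm^2/ms, calibrated so the wild-type RA longitudinal
conduction velocity is ~70 cm/s (physiological 60-75 band); transverse
diffusivity is 0.35 D_L (conductivity-ratio reading of "anisotropy 0.35",
giving a velocity ratio ~ sqrt(0.35)). At 300 um the explicit scheme
under-resolves the wavefront slightly: halving dx from 300 to 150 um
changes planar CV by ~7%, from 150 to 75 um by < 3%; the CV-sensitive
property tests therefore run at 150 um.

The cross-field protocol applies 10 planar S1 pulses (BCL 1000 ms) at the
bottom edge and a 1.8 cm x 2.6 cm S2 in the bottom-left corner at a chosen
S1-S2 interval (measured from the onset of the last S1; node-inclusive
rectangle edges), then simulates 5 s. Outcomes: "block" (no re-excitation
in a probe band just beyond the S2 edge, where the S1 wave has already
passed), "propagation" (re-excitation without chiral rotation), "reentry"
(a phase singularity completing >= 2 cycles, counted by activation
recurrence at probe nodes around the tip). The vulnerable-window scan
brackets the reentry interval range coarse-to-fine to 1-ms resolution and
classifies lifespans (< 1 s, 1-5 s, sustained) inside the window.

A full 5 cm / 15 s / 167x167 atrial-tissue run costs hours per interval on
one CPU, and a VW scan needs dozens of them; the protocol and analytics
logic is therefore exercised on the Barkley two-variable excitable medium
(a = 0.75, b = 0.02, eps = 0.02, recovery time 20 ms, D = 1e-3 cm^2/ms)
plugged into the same stepper, which produces planar waves, block and
stable spirals on a 3-cm patch in seconds. Full-model tissue physics is
verified separately by the diffusion fixed-point and heat-kernel oracles,
the CV anisotropy ratio, and space/time refinement checks on small strips.

## Phase analysis

Node phase is the angle of the analytic signal (Hilbert transform along
time) of the mean-subtracted voltage; constant traces are masked, no
filtering by default. Phase singularities are 2x2 plaquettes whose wrapped
phase differences wind by +-2 pi; the position is refined to sub-grid
accuracy as the zero of the bilinearly interpolated analytic signal, and
chirality is the winding sign. Tips link frame-to-frame by greedy nearest
neighbour (same chirality, max jump 5 dx per ms); tracks shorter than 10 ms
are dropped and the longest track is the principal rotor. The meander
ellipse is the minimum-area (Loewner-John) enclosing ellipse of the tip
points via Khachiyan's algorithm (relative tolerance 1e-3); "surrounded by
an ellipse" is read as containment, so the minimum-area ellipse rather than
a least-squares fit. Tip localisation degrades when the tip translates fast
relative to the rotation period (a radial bias appears in the Hilbert
estimate); scripted-movie tests keep tip speeds modest for this reason, and
snapshot cadence for phase analysis should stay at ~1-2 ms.

## Synthetic data

Clamp datasets are the package's own protocol simulations plus additive
homoscedastic gaussian noise (uncertainty column = noise sd, or a 5%
floor when noise-free); they stand in for experimental error bars and do
not emulate patch-clamp artefacts (leak, rundown, series resistance).
Stylised AP pulses (square / triangular / spike-and-dome) have closed-form
APD90 for testing the biomarker code; spiral movies prescribe an
Archimedean-spiral phase around scripted tips so tracking and meander
quantification can be validated against ground truth. Passing these tests
shows the analytics are correct on ideal fields; real tissue adds wavefront
curvature, meander and boundary effects that only the monodomain runs
exercise.

## Problem sizes used by the shipped checks

The test suite and the acceptance script use desk-scale problem sizes
chosen as the package's own defaults: the twelve 61-beat pacing runs at
1 Hz; restitution on a 50-ms BCL grid (300-1700 ms) for the slope
comparisons; the alternans scan at 10-ms resolution over 600-900 ms; GA
recovery at population 300 x 20 generations; tissue property checks on
2-3 cm patches. The full-size 5-cm vulnerable-window study is available
through `scan_vw`/`run_cross_field` with the default `TissueGrid` and
`CrossFieldProtocol`.

## Known limitations

- Homozygous mutation expression only; no heterozygous channel mixtures.
- Homogeneous tissue patches: no fibrosis, no 3D anatomy, no bidomain.
- The channel-level/cell-level split of the gate steady states (above) is a
  reconstruction choice; both views are exact for the wild type.
- The restitution maximum slope is a pointwise finite difference; smoothed
  or fitted-curve slope estimates can differ systematically on compressed
  mutant curves.
- Explicit diffusion at 300 um carries a few-percent CV discretisation
  error (quantified above).
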