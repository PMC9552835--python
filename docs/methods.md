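# Methods

## Model

`graftflow` simulates pulsatile blood flow through a network of 1D
elastic vessel segments coupled to 0D lumped elements, aimed at the
haemodynamics of coronary circulations with stenoses and bypass grafts.
Each segment carries the cross-sectionally averaged Navier–Stokes
equations in the (A, Q) variables,

    A_t + Q_x = 0
    Q_t + (α Q²/A)_x + (A/ρ) P_x = −2πν α/(α−1) · Q/A,

closed by the elastic tube law

    P − Pext = f (1 − √(A0/A)) + P0,   f = (4/3)(k1 e^{k2 R0} + k3),

with two wall-constant sets: a stiff coronary-like law (k1 = 20.0×10⁶
g s⁻² cm⁻¹, k2 = −22.5 cm⁻¹, k3 = 86.5×10⁴ g s⁻² cm⁻¹; also used for
internal mammary and radial conduits) and a compliant large-systemic law
(3.0×10⁶, −9.0, 33.7×10⁴). The Coriolis coefficient is α = 1.05 for the
aorta and its major branches and α = 1.1 for coronary-like vessels
(blunter-than-Poiseuille profiles). Blood is Newtonian with
ρ = 1.06 g/cm³ and μ = 0.046 dyn·s/cm².

The tube law is implemented in the square-root form written above: it is
the only form consistent with the unstressed wave speed c0² = f/(2ρ)
(Moens–Korteweg) and with a physically increasing P(A); its closed-form
inverse A(P) = A0 (1 − (P−Pext−P0)/f)⁻² is used at the pressure inlet.

### Topology

Networks are rooted, directed collections of constant-radius segments.
Taper is step-wise: radius changes only across junctions, which makes
the pressure-gradient term exactly expressible as a conservative flux
within each segment, F₂ = αQ²/A + (f/ρ)√(A0·A), with no geometric source
terms. Six junction kinds are supported (arity parents→children):
bifurcation 1→2, trifurcation 1→3, stenosis 1→1 (with a lumped pressure
drop), reverse bifurcation 2→1 (end-to-side graft), cross-junction 2→2
(sequential side-to-side graft), connector 1→1 (end-to-end graft
extension).

Scenario editing splits host segments: a stenosis renames the host to
`<host>_psten`/`<host>_dsten` around the throat; a graft anastomosis
renames its target to `<target>_pgraf`/`<target>_dgraf`. Edits conserve
the host's centreline length, and an in-situ conduit re-routed into the
coronary bed loses its previous terminal Windkessel.

### Stenosis model

A stenosis of percent-diameter grade s over length Ls in a host of
unstressed radius R0 contributes

    ΔP = a_v Q + a_t Q|Q| + a_u dQ/dt

with A0/As = 100/(100−s), La = 0.83 Ls + 3.28 Rs, Kt = 1.52, Ku = 1.2,

    a_v = μ Kv / (2π R0³),  Kv = (4α/(α−1)) (La/R0) (A0/As − 1)²
    a_t = ρ Kt / (2 A0²) (A0/As − 1)²
    a_u = Ku Lu,  Lu = ρ Ls / (π Rs²)   (constant-radius throat).

Ā0 is the mean of the proximal/distal unstressed areas (they coincide
for a constant-radius host). dQ/dt is discretised as a first-order
backward difference of the throat flow between time steps. The throat
flow in ΔP is the parent-end flow (mass conservation makes the two port
flows equal at the converged solution).

### Numerics

Interiors advance with the Richtmyer two-step Lax–Wendroff scheme
(second order in space and time). The half step evaluates fluxes and the
viscous source at staggered midpoints from averaged states; the
corrector uses the average of the two midpoint source evaluations.
Endpoints are closed each step by:

* **Inlet (root x0):** Dirichlet pressure from the prescribed aortic
  waveform; area from the inverse tube law, flow from the left-sided
  Keller-box relation.
* **Junctions:** each port contributes an affine relation Q = ±(Δx/Δt)·A
  + b obtained from Keller's box scheme on the mass equation over the
  boundary cell (− for parent ends, + for child starts). The n-port
  system — one mass equation, n−1 Bernoulli total-pressure equations
  (the first parent is the common reference for cross-junctions, which
  behave like trifurcations; the stenosis equation includes ΔP) — is
  solved for the port areas by Newton–Raphson with an analytic Jacobian:
  previous-step areas as the initial guess, tolerance 1e-10 (CGS) on the
  max residual, 50 iterations max, step halving on negative-area
  iterates, and acceptance at the floating-point floor (~1e-11 of the
  total-pressure scale) when the residual stalls below 1e-7.
* **Outlets:** each terminal couples to a three-element Windkessel
  (R1–Ct–R2) referenced to an external pressure. The RCR ODE is
  discretised with backward differences and rearranged for Q^{n+1}; the
  terminal pressure is found by successive substitution through the
  Windkessel update, the right-sided box relation and the tube law, with
  relaxation 0.5, tolerance 1e-10 mmHg, 100 iterations max.

Flow direction is topological: parent/child roles are fixed and reverse
flow is negative Q — exactly what the backward-flow metric measures.

The time step satisfies the CFL bound Δt ≤ Δx/(|V|+c) with a safety
factor 0.9 applied to the rest-state bound plus a 15% velocity allowance
on c0 (systolic velocities erode the rest-state margin). The bound is
re-audited every cycle from the evolved state: occupancy above 1.02
aborts; above 0.98 the step is reduced for the remaining cycles. Each
period is an exact multiple of the stored 100 sample intervals. Grid
spacing must satisfy Δx < Lmin/2 so every segment keeps ≥3 gridpoints;
a segment of length L uses M = max(2, round(L/Δx)) cells.

Runs start from rest (Q = 0, A = A0, P = P0 with P0 the inlet diastolic
pressure, 76.41 mmHg by default) and integrate 4 cardiac cycles; the 4th
cycle is stored at 100 equally spaced times per segment and gridpoint.
Convergence to the dynamic steady state is *measured*, not assumed: the
relative L2 drift between cycles 3 and 4 is reported per segment (flow
drift normalised by the cycle's flow norm, area drift by the area norm)
and can be asserted against a 1% tolerance. Disease-free networks
converge well under 1% in four cycles; a severely stenosed low-flow
branch can retain a few-percent transient, because its Windkessel
relaxes with a time constant R2·Ct/(1 + R1/R2) of order 1 s — comparable
to the whole four-cycle run. Add cycles when sub-percent periodicity is
needed behind tight lesions.

### External pressures

Coronary terminal vessels and their beds are squeezed by the myocardium:
the left-ventricular external-pressure waveform applies at factor 1.0
(LV beds), 0.2 (RV) or 0.6 (septal), entering both the terminal
segment's tube law and the Windkessel reference. Systemic beds see a
constant 1 mmHg venous pressure in the Windkessel only — a systemic
artery is not embedded in contracting muscle, so its 1D tube law carries
no external pressure. An outlet can also be given an explicit reference
waveform, which is how the rest-equilibrium property is exercised.

### Outlet calibration

Calibration runs on the *disease-free* network and the parameters are
carried unchanged to the stenosed/grafted variants — this staging is
what makes perfusion fall when stenoses are inserted and recover when
grafts are added.

* R1 is the characteristic impedance ρc0/A0 of the terminal vessel
  (minimises wave reflection at the 1D–0D interface).
* Mean outlet flows are prescribed: systemic outlets as fixed
  percentages of cardiac output (defaults fold the textbook branch
  shares: innominate 19.3% = RCC 11.3 + RVA 1.0 + RIMA 2.4 + RSCA 4.6,
  left common carotid 5.2%, left subclavian 6.4%, descending aorta
  64.6%), the coronary circulation 4.5% of CO, split across the LAD /
  CIRC / RCA territories (fixture defaults 42/27/31%, scaled from
  resting territory flows) and within a territory across outlets in
  proportion to A0^2.6 (Murray-type rule).
* The mean pressure at a terminal's start descends from the time-mean
  inlet pressure through the accumulated R1D·Q̄ drops along the
  root-to-terminal path, with R1D = (2α/(α−1)) μL/(πR⁴) the
  α-corrected Poiseuille resistance (α = 4/3 recovers 8μL/(πR⁴)). This
  path-resistance rule is this package's own estimator; it requires a
  pure tree, hence calibration precedes grafting.
* R2 closes the mean-flow balance R2 = (P̄start − P̄ext)/Q̄ − R1D − R1
  and must come out positive, else the prescription is infeasible and
  calibration fails naming the outlet.
* Ct = τ/(R1+R2) with τ the diastolic time constant, default 1.25 s,
  refittable from any inlet waveform by regressing the exponential
  diastolic decay (the decay window starts where the waveform falls
  through a reference pressure after its peak).

### Clinical outputs

All metrics evaluate the stored cycle. Mean flow is the plain mean of
the 100 samples (ml/min); PI = (Qmax−Qmin)/Q̄; BF is the negative flow
area as a percent of total unsigned area; DF is the diastolic share of
the (signed) flow integral. Graft metrics default to the last gridpoint
before the distal anastomosis — the site where intraoperative probes
are recommended — with the site as an override parameter. Systole runs
from the waveform foot (cycle minimum) to the dicrotic notch; fixture
waveforms carry an explicit notch time (default 0.40 T), measured
waveforms require the user to supply one, since no robust universal
notch detector exists. iFR is the ratio of wave-free-window mean
pressures distal/proximal to a stenosis, the window being the last 75%
of diastole by duration; the stenosis junction's own ports are
authoritative for which segments to read (a later graft edit may have
re-split `_dsten`). Regional perfusion sums outlet-end mean flows per
territory. Threshold flags: MGF > 15 ml/min, PI < 5, BF < 3%.

## Synthetic data

The fixtures module generates every input the pipeline consumes.

**Waveforms.** The inlet aortic pressure is piecewise: half-sine
systolic upstroke from the diastolic foot (76.41 mmHg) to the systolic
peak (120 mmHg), quarter-cosine fall to the dicrotic notch
(86.92 mmHg — the reference pressure at the start of the diastolic
decay), then an exponential decay with τ = 1.25 s whose asymptote is
chosen to land exactly back on the diastolic foot after one period
(T = 0.917 s, ≈65 bpm resting rate). The LV external pressure is a sin²
systolic squeeze peaking mid-systole (100 mmHg default — an effective
transmural squeeze of the order of LV systolic pressure) on a venous
plateau of 1 mmHg. These are parametric stand-ins shaped like textbook
resting waveforms; they are not digitised patient data.

**Toy network.** A 20-segment reduced circulation: aortic root →
{left main, right coronary, ascending aorta} trifurcation; arch branches
with internal mammary take-offs; three coronary territories with 2
outlets each (LAD: LAD2 + diagonal, CIRC: obtuse marginal + CIRC2, RCA:
PDA + right-ventricular branch). The stenosis scenario inserts 90% LAD,
95% marginal and 90% RCA lesions. The "separate" grafting scenario
uses in-situ LIMA→LAD, in-situ RIMA→OM and a free aortic radial
graft→PDA (3 inflows); the "composite" scenario uses a single LIMA
inflow with a radial Y limb, an end-to-end I-extension, a sequential
pass through the OM target and an onward limb to the PDA. Across the
variants every junction kind occurs at least once. Radii are jittered
±3% by the seed (lengths are fixed so edits always fit their hosts);
everything else is deterministic. The toy solver settings use Δx =
0.3 cm, sized to the shortest post-edit piece (0.6 cm stenotic
remainders still keep ≥3 gridpoints).

**What the generator does not emulate:** patient-specific geometry
(measured centrelines and radii, vessel counts in the hundreds),
digitised pressure waveforms, RCA ostium head loss, hyperaemia, and
autoregulation. Passing tests therefore demonstrate the numerics,
conservation properties, calibration closure and metric definitions on
realistic-scale synthetic networks — not agreement with any particular
patient's measurements.

## Problem sizes and tolerances

Test and acceptance runs use the toy network (20–30 segments) at
Δx = 0.3 cm, giving time steps around 1.5–2×10⁻⁴ s and ≈5–6×10³ steps
per cycle; single-vessel oracle runs use coarser grids. These sizes were
chosen so the whole property suite exercises every code path at
desk scale. Key tolerances: junction Newton 1e-10 (CGS), outlet fixed
point 1e-10 mmHg, cycle drift 1% (relative L2), calibration closure 5%
on cardiac output and 10% per territory, pulse speed 2% of c0,
Windkessel discretisation 1% against an ODE oracle.

## Design choices where the design was open

* Richtmyer source placement (averaged states at the half step,
  averaged midpoint sources in the corrector) — the scheme name alone
  does not fix this.
* CFL safety 0.9 with a 15% initial velocity allowance, re-audited per
  cycle — a fixed conservative step keeps the 100-sample alignment
  while protecting against systolic margin erosion.
* Cross-junction Bernoulli reference: the first parent is compared
  against the second parent and both children (trifurcation-like).
* Reverse bifurcation: the graft is a parent evaluated at its distal
  end; equations are unchanged under flow reversal (negative Q).
* Stenosis Ā0: arithmetic mean of the proximal/distal unstressed areas;
  Lu assumes a constant-radius throat.
* Axial positions are measured from the segment's proximal end.
* Windkessel fixed point with relaxation 0.5: the raw substitution map
  has contraction factor ≈ c·Δt/Δx near the CFL bound (≈0.9), which
  relaxation maps to ≈0.05.
* Step response of the RCR to an external-pressure step (both pressure
  nodes clamped) relaxes with τ = R1R2Ct/(R1+R2) — the capacitor sees
  R1 ∥ R2; the test suite asserts the ODE-oracle value.

## Known limitations

* Junction energy losses are Bernoulli-only: no angle-dependent loss
  coefficients and no RCA-ostium head-loss model, which overestimates
  systolic RCA inflow peaks.
* The upstream mean-pressure estimator ignores stenosis drops, so
  calibration should run on the disease-free network (enforced for
  grafted networks, advisory for stenosed ones).
* Single constant-radius throat per stenosis; no serial lesion merging.
* No hyperaemic simulation, hence iFR (a resting index) rather than FFR.
* The 3-element Windkessel underrepresents early-diastolic inertia in
  coronary beds; multi-compartment outlets are out of scope.
* Pure-Python/numpy solver: fixture-scale networks run in ~1–2 minutes
  per scenario; patient-scale networks (≈150 segments at Δx = 0.1 cm)
  would be proportionally slower.
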