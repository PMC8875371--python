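# Methods

This note documents the model equations, the parameter choices behind the
shipped defaults, the synthetic-patient generator, and the numerical and
design decisions a maintainer should know. Units are ms, mmHg, mL
throughout (flows mL/s; the integrator converts steps to seconds).

## Conduction system

Each of the 26 automata cycles SDD → UDP → ARP → RRP. Activation onset is
UDP entry; stimuli leave a node when its UDP ends and arrive after the
per-link delay, so the effective edge weight from node *u* to *v* is
`t_udp(u) + delay(u, v)`. A node in SDD activates on a stimulus; in ARP it
ignores stimuli; in RRP it activates with the UDP scaled by
`2 − elapsed/t_rrp` (slower upstroke for premature stimulation; both the
excitability of the RRP and the scaling are configurable off). Ties in the
event queue are broken by (time, event kind, source-node order, sequence
number), making every simulation exactly reproducible. The pacemaker's SDD
is derived from the requested RR interval minus its other phases, so heart
rate is a single input and the steady firing interval equals RR exactly.

No timing table is printed in the sources this model descends from; the
shipped phase durations and link delays were calibrated once so that the
synthesized PR interval (~165 ms), baseline QRS (~73 ms) and ventricular
refractory period (~250 ms) sit in physiological ranges. Two topology
choices were genuinely open:

- **Intact-LBB insertion.** The left bundle inserts into *all* 16 LV
  segments (uniform 10 ms fascicular delays), not only the septum. The
  healthy LV then activates synchronously, which the baseline strain
  premise requires: a staggered insertion (even 7 ms of apex-to-base
  spread) is amplified several-fold by isovolumic pre-stretch
  redistribution and breaks the homogeneity of baseline strain curves.
  Under LBBB every LBB link is removed (an `lbb_extra_delay` option models
  incomplete block instead), so LBBB activation proceeds RV → trans-septal
  links (25 ms default) → cell-to-cell myocardial links between adjacent
  AHA segments (15 ms/link default, the main dial for QRS width).
- **Myocardial adjacency.** Circumferential neighbours within each ring,
  longitudinal neighbours between rings, and each mid segment mapped onto
  the apical segment of its quadrant.

The ECG is a sum of parametric Gaussian waves: atrial waves at RA/LA
onsets, a ventricular wave per segment onset, and a low-amplitude
repolarization wave at each segment's ARP end. QRS width is measured as
the supra-threshold (5% of peak |v|) extent of runs containing at least
half-peak samples — P and T waves are synthesized well below half peak, so
only ventricular complexes qualify.

## Ventricular mechanics

Per segment: active tension `T_a = k_act · T_max · u(t) · λ(l/l0)` with a
normalized product-of-exponentials twitch
`u ∝ (1 − e^{−x/τ_c}) e^{−x/τ_r}`, `x = t − t_act − t_delay` (defaults
τ_c = 80 ms, τ_r = 180 ms, t_delay = 30 ms), and clipped-linear
length-tension factor `λ = clip(1 + 4(l/l0 − 1), 0, 1.5)`. Passive tension
is `k_p1(e^{k_p2 ε} − 1)` in stretch and linear with the matching slope in
compression (continuous first derivative). The twitch form and the
length-tension shape are design choices; the sources state only that a
driving function triggered by the automaton exists.

Tension couples to pressure through a piston of effective area `A`
(basal/mid 6.3, apical 4.2, RV 30 cm²-equivalent; `p_seg = T/A`), and
segment motion follows `dq/dt = (p_seg − p_load − r_h q)/l_h` with
`dl/dt = −q/A`. The hydraulic constants are specified at the reference
basal/mid area and scaled by 1/A, so equal fibre stresses give equal
strain dynamics regardless of segment size. Free-wall LV segments are
loaded by `p_LV`, RV layers by `p_RV`, septal segments by `p_LV − p_RV`.

**Cavity coupling.** Cavity blood volume V integrates valve flows only;
cavity pressure is a stiff penalty on the mismatch between V and the
wall-enclosed volume `V_w = V_c0 + Σ A_s (l_s − l0_s)`:
`p = k (V − V_w)`. During closed-valve phases the summed segment flows
equal `(dp/dt)/k` exactly, so isovolumic wall-volume creep is bounded by
`Δp/k ≈ 3 mL`, and total blood volume is conserved to solver round-off by
construction. `k_lv = 40, k_rv = 25 mmHg/mL` are the largest values for
which the RK4 solution is step-size independent at dt = 0.5 ms; stiffer
coupling under-resolves the fast penalty mode and biased the limit cycle
by several mmHg.

**Septal behaviour.** With the faithful trans-septal load, septal segments
carry less diastolic pre-stretch than the free wall (RV pressure distends
them less), so by the length-tension effect they shorten ~35% less at
identical parameters. Baseline septal curves therefore sit shallower than
free-wall curves (−12% vs −19%) while remaining synchronous in timing;
tests assert pairwise identity (<1%) among the 11 uniformly loaded
free-wall segments and a bounded (<8%) septal offset. The same coupling is
what produces pre-ejection septal motion under LBBB, so it is kept as is.

**Strain reference.** `l0` is the material reference; *reported* strain is
re-referenced each cycle to the segment lengths at the first ventricular
electrical activation of that cycle (the model's R-wave gating, matching
how echo strain is zeroed). Synthetic fixtures and all wall-curve
comparisons use the R-wave-to-R-wave cycle.

## Circulation and calibration

Chambers (aorta, systemic arteries and veins, vena cava, pulmonary artery
and veins) follow `P = e (V − V0)`; inter-chamber flows are resistive;
valves are perfect diodes clamped inside the right-hand side (no event
root-finding; at dt ≤ 0.5 ms switching chatter is negligible). The
pulmonary capillary bed is a resistance between the two pulmonary
chambers, not a chamber of its own.

No vascular parameter table is printed in the sources; the shipped set was
calibrated once against the reported baseline operating point — systolic
LV pressure 130 mmHg, aortic pressure 60–130 mmHg, LV volume 40–90 mL — at
RR = 1000 ms, yielding peak LV pressure 130.96, aortic range
[58.9, 130.0] and LV volume range [40.5, 89.1]. Initial chamber volumes
ship rebased to the cycle-start steady state, so the limit cycle is
reached within ~4 cycles (the default discards 5 as transient);
consecutive post-transient cycle peaks differ by <0.1%.

## Integration

Fixed-step classical RK4 over the 48 continuous states, dt = 0.5 ms by
default (≤1 ms enforced), with the discrete layer strictly upstream: the
automata schedule is computed for the whole horizon first and every
segment's drive u(t) and both atrial elastances are tabulated on the RK4
half-step grid. This is equivalent to applying events at step boundaries
and keeps runs bitwise reproducible; there is no randomness in the forward
path. Halving dt changes the final-cycle peak LV pressure by <0.01 mmHg.
Divergence (non-finite state or fibre collapse) raises an error naming the
time. With numba the 15-cycle baseline integrates in ~2 s; pure numpy is
~10x slower but identical.

## Personalization

`fit_one_at_a_time` encodes the manual workflow as deterministic cyclic
coordinate descent. Free parameters are tied per wall group (septal 5 /
lateral 5 / remaining 6) by default — two target curves cannot identify 16
independent values — with per-segment freeing available when 16 traces
exist. Scan order is the declared delays → contractility → driving time
constants → passive stiffness; each scan is a bounded grid (default 5
points) refined by zooming one grid step around the best value. Wall
curves are compared by RMSE after linear resampling onto a common
200-point cycle-normalized grid (model and patient RR differ; the full
cycle is compared, systole-only support is a configuration choice). Total
RMSE is non-increasing by construction; a simulation failure at a grid
point scores +inf and is logged. Forward runs inside the fit use 8 cycles
at the default 0.5 ms step (the same step as every other simulation in
the package); a full 6-parameter fit takes ~20 s.

The patient's two ECG scalars personalize conduction before fitting:
RR sets the pacemaker period and the QRS width sets the myocardial
cell-to-cell delay by bisection against the synthesized ECG.

Parameter recovery on model-generated targets: freed lateral contractility
0.3 is recovered within ±0.01 noiseless and within ±0.15 under 1% strain
noise at the default grid resolution.

## Synthetic patients

Four profiles define the study conditions: `healthy` (RR 1000 ms, uniform
contractility), and three LBBB patients at RR 900 ms (no cycle length is
reported for the clinical patients; 900 ms is a typical resting value for
this population) with QRS targets 136/157/152 ms achieved through the
profile's myocardial delay. All LBBB profiles share three preset groups:

- a septal-to-lateral electromechanical gradient (septal t_delay 0 ms with
  a brisk, early-relaxing septal twitch τ_c 30/τ_r 70 ms; free wall 85 ms;
  lateral 115 ms) — the early septal force decay is what lets the delayed
  lateral contraction re-stretch the septum during ejection;
- an early, brisk right ventricle (t_delay 5 ms, τ_c 40 ms): under LBBB
  the RV leads the LV, and its pressure rise during the LV pre-ejection
  period pushes the septum leftward through the trans-septal load;
- a heart-failure loading state (moderately reduced circulating volume and
  systemic resistance raised to 2.0 mmHg·s/mL, the compensatory
  vasoconstriction of a low-output heart). The higher aortic diastolic
  pressure lengthens the pre-ejection period — the phase in which the
  septal flash develops — and brings the profiles' ejection fractions into
  the reduced-EF class of this population (~23–28%).

Contractility presets: non-ischemic 0.60 septal / 0.85 lateral / 0.55
elsewhere; lateral scar 0.22 lateral, 0.90 septal; anteroseptal scar 0.32
in the anteroseptal + apical-cap territory. These presets are the
repository's stand-in for the three clinical patients and reproduce the
qualitative pattern matrix: septal flash with rebound in the non-ischemic
and anteroseptal-scar profiles, flash absent with collapsed lateral strain
and exaggerated septal strain in the lateral-scar profile.

When a fixture is fitted back, `fitting_base_config` supplies the base
model: the patient context that is known before fitting (conduction state,
loading conditions, twitch shape) with the to-be-estimated fields reset to
neutral defaults, so the fit starts agnostic of the generating values.

Fixture noise is additive i.i.d. Gaussian on strain samples (default
1% strain), seeded; the same seed regenerates a fixture byte-for-byte.
This is the simplest defensible stand-in for speckle-tracking noise — it
has no temporal correlation, no drift and no dropout, so passing recovery
tests bound only the estimator's behaviour under uncorrelated noise, not
under real tracking artefacts.

LGE phantoms are annular short-axis stacks (3 slices, 96×96) with AHA
sector labels; scarred sectors get a subendocardial bright band covering
the requested fraction of wall thickness at contrast ratio 3 (remote
myocardium 100, scar 300) plus seeded Gaussian noise. They carry explicit
per-voxel segment labels, sidestepping slice-to-segment assignment for
real data — which this package does not attempt.

## Scar analysis

Two-class fuzzy c-means (fuzzifier m = 2, tolerance 1e-5) on masked
intensities with deterministic 25th/75th-percentile centre initialization;
the LGE class is always the higher centre, so the output is invariant to
initial ordering, and the Bezdek objective is checked non-increasing at
every step. Memberships harden at 0.5 (how fuzzy memberships became
binary classes is not stated in the sources; 0.5 is the declared choice).
Transmurality per segment averages, over angular chord bins around the
slice centroid, the LGE fraction of each chord weighted by 1/r per voxel —
the weight converts annular voxel counts into radial length fractions. A
60% phantom band is recovered within ±0.6 points (tolerance ±5 in tests).

## Known limitations

- Segmental pistons have no spatial continuity, fibre orientation or
  torsion; strain is longitudinal-only by construction.
- The septal under-shortening at baseline (above) is a geometric artefact
  of loading pistons with the raw trans-septal gradient.
- Valve clamping without event localization slightly smears switch times
  (sub-dt); regurgitant or stenotic valves are out of scope.
- No baroreflex or respiratory coupling; the circulation is a fixed
  parameter set.
- The fitter is a local, deterministic search; it inherits the
  identifiability limits of two target curves and makes no claim of
  patient-specific uniqueness.
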