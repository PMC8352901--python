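# Methods

## The model

`perclock` simulates an effective circadian clock built on the
five-variable PER negative-feedback oscillator.  The state is
(M, P0, P1, P2, PN): cytosolic *per* mRNA, un-/mono-/biphosphorylated
PER protein, and nuclear biphosphorylated PER, all in µM.  mRNA is
transcribed under Hill-type inhibition by nuclear PER, translated at
rate ks·M, reversibly phosphorylated twice (Michaelis–Menten kinetics
with maxima V1–V4 and constants K1–K4), degraded from the P2 form
(vd, Kd) and exchanged with the nucleus at first-order rates k1/k2:

    dM/dt  = vs·KI^n/(KI^n + PN^n) − vm·M/(Km + M)
    dP0/dt = ks·M − V1·P0/(K1+P0) + V2·P1/(K2+P1)
    dP1/dt = V1·P0/(K1+P0) − V2·P1/(K2+P1) − V3·P1/(K3+P1) + V4·P2/(K4+P2)
    dP2/dt = V3·P1/(K3+P1) − V4·P2/(K4+P2) − k1·P2 + k2·PN − vd·P2/(Kd+P2)
    dPN/dt = k1·P2 − k2·PN

With the default parameters (vs=0.76, vm=0.65, Km=0.5, ks=0.38,
vd=0.95, k1=1.9, k2=1.3, KI=1, Kd=0.2, n=4, K1..K4=2, V1=3.2, V2=1.58,
V3=5, V4=2.5; initial state (0.5, 0.5, 0.5, 0.6, 1.5)) the system has a
limit cycle with free-running period 23.7 h.

The Hill term's constants are configurable through
`CoreParameters.hill_form`.  Besides the default `"KI"` form above, two
variants circulating in the literature are exposed for auditability:
`"K1"` (`vs·K1^n/(K1^n+PN^n)`, period 33.2 h with the default
constants) and `"mixed"` (`vs·K1^n/(KI^n+PN^n)`, which with these
constants has no oscillation at all).  Only the KI form reproduces the
23.7 h calibration anchor and the constant-light period tables, so it
is the default everywhere.

## External stimuli and ports

A stimulus is a dimensionless intensity u(t) ≥ 0.  It acts through
exactly one *port* — a bilinear term added to a single equation —
selected by the `VariantSpec`:

| kind          | term                    | effective picture                          | default constants |
|---------------|-------------------------|--------------------------------------------|-------------------|
| `mrna_decay`  | −α·u·M in dM/dt         | stimulus degrades *per* mRNA               | α = 0.05 (entrainment runs) |
| `fly`         | −α·u·P0 in dP0/dt       | light-driven PER/TIM degradation (insects) | α = 1 |
| `mammal`      | +γ·u·e^(−ϱM) in dM/dt   | light-induced *per* transcription (mammals)| γ = 2, ϱ = 1 |
| `mammal_machinery` | +γ·T* in dM/dt     | explicit transcription-machinery pool      | ϱ_m = 1, ξ = 0.5, T0 = 1 |

The machinery pool obeys dT/dt = −ϱ_m·u·T + ξ·T*, dT*/dt = −dT/dt, so
T + T* is conserved at T0; it unfolds the saturating exponential into a
mass-action mechanism.  A two-species linear subsystem
(`cooperativity_rhs`, dMi/dt = (u − γ_h)·Mi) likewise expresses a
quadratic stimulus effect u² as the product M1·M2, keeping every
interaction bilinear.  Coupling constants absorb units, so every added
term is in µM/h.

Stimulus waveforms: the raised cosine cos(2πt/period + φ)+1 (range
[0,2]); its quarter-amplitude version (range [0,0.5], used as the
feeding cue and for the coupled-clock experiments); constants; half-open
rectangular pulses; a phase-switching feeding schedule; and ln(1+u)
compression for wide illuminance ranges.  A phase φ corresponds to a
Zeitgeber advance of φ·period/2π hours.  Piecewise stimuli report their
breakpoints and the integrator restarts there.

## Coupling oscillators

Networks couple oscillators by letting a state variable of one act as
the stimulus of another.  All standard couplings inject into the
target's P0 equation (the injection point is configurable):

* product decay −α̃·P̃0·P0 — locks the pair near antiphase;
* gated decay −α̃·P̃0·e^(−β·P0) — a high central signal *suppresses*
  peripheral PER digestion; locks in phase;
* P2-driven product decay −α^P·P̃0·P2 — intermediate phase offsets,
  because P2 peaks at a different phase than P0;
* dual input — the gated term plus a feeding term −δ·ũ·P̃0, a
  peripheral clock integrating two Zeitgebers at once.

The standard two-oscillator configuration drives the central clock
through the fly port (α=1) with the quarter-amplitude light cycle.
The full-amplitude cycle yields locked lags of 11.7 h (product decay)
and 15.0 h (P2-driven); the quarter-amplitude cycle yields 12.5 h and
16.0 h, the values this package quotes, and is the configuration the
food-entrainment experiment explicitly builds on.  The stimulus
amplitude of these runs is therefore treated as part of the
configuration, exposed in `scn_periphery_network` / `food_network`.

Ensembles (`build_ensemble`) create n identical units whose stimulus
coupling constants are spread linearly over [α(1−s), α(1+s)]
(deterministic by default; an RNG can be supplied).  The macroscopic
readout is the summed mRNA.  Inhomogeneous coupling lets a single 1 h
pulse desynchronize the units and collapse the macroscopic amplitude —
the singularity mechanism by which one pulse can stop and a second
restart an apparent rhythm.

## Numerics

Integration uses LSODA (stiff-capable, adaptive) with rel_tol 1e-8,
abs_tol 1e-10, sampled at 0.05 h.  Periods quoted to 0.1 h are
tolerance-insensitive: refining both tolerances tenfold changes the
sampled trajectory by < 1e-5 µM (self-convergence test).  Stimulus
discontinuities (pulses, feeding switches) become integration restarts;
declaring them is an accuracy aid, not a semantic change (verified to
5e-5 µM).  State positivity is asserted (≥ −1e-9), never enforced by
clamping.

## Measurement procedures

**Period.**  Local maxima of a chosen variable (M in all standard
experiments) are refined by a quadratic fit through the three samples
around each grid maximum (ties resolve toward the earlier time); the
period is the mean spacing of successive peaks over an observation
window, 80–120 h by default.  A peak-to-peak cycle contributes when at
least half of it lies inside the window: this admits the bounding peaks
of a cycle straddling a window edge (a damped 25.4 h rhythm puts only
one peak strictly inside a 40 h window) but rejects cycles belonging to
a different regime, such as one spanning the moment a stimulus switches
off.  Trajectories therefore extend ~30 h past the window.

**Phase shift.**  The shift of rhythm B against rhythm A is the
circular mean of nearest-peak offsets at the common period T, reported
either centered in (−T/2, T/2] or as a forward lag in [0, T); positive
means B peaks later.  Both rhythms must be rhythmic with periods equal
within 0.5 h — loose enough to compare a 24 h-entrained rhythm with the
23.66 h free-running one over a finite window, tight enough to reject
genuinely unlocked pairs.

The shift induced by a Zeitgeber phase offset φ is measured against the
φ=0 entrained run rather than the free-running control: the free-running
and entrained periods differ by 0.34 h, so a control-relative offset
drifts by that much per cycle and is window-dependent, while the φ=0
run is in phase with the unperturbed clock and the φ-relative shift is
then exact by time-translation symmetry (12 h for φ=π, 6 h for φ=π/2).

**Arrhythmicity.**  A window of signal is arrhythmic when its
modulation depth — peak-to-trough amplitude divided by the window
mean — falls below 1%.  Normalising by the signal's own mean rather
than by the free-running amplitude makes the classification comparable
across ports that shift the mean mRNA level very differently (the fly
port raises mean M to ~4 µM under strong constant light, the mammalian
port holds it near 2 µM); a floor relative to the free-running
amplitude cannot separate the fading fly rhythm at c=1 (amplitude
0.037 µM) from the still-detectable mammalian rhythm at c=0.9
(0.028 µM), while the 1% modulation-depth floor separates all boundary
cases with ≥1.2× margin.

**Constant-light scans.**  For each intensity c on a grid the variant
model is integrated 150 h and the period measured in [80,120] h; the
grid argmin of the period is the turning point between shortening and
lengthening — the model's account of Aschoff's rule (the fly port turns
at c=0.2, the mammalian at c=0.4; both fade to arrhythmicity at c=1).

**Phase-response curves.**  Circadian time 0 is anchored at a
free-running M peak (the first after 48 h); CT x maps to x/24 of the
free-running period.  One rectangular pulse (default 1 h, magnitude 1 —
exposed as parameters, not asserted as canonical) is applied per run;
post-transient peaks are compared against the unpulsed control,
centered in (−T/2, T/2].  A zero pulse gives an identically zero curve.

**Entrainment range.**  For each Zeitgeber period T the driven model
runs 480 h; it counts as locked when the observed period matches T
within 0.1 h and the peak-phase drift over the last five cycles stays
under 0.5 h.  The horizon is long because the approach to lock is a
slowly damped phase oscillation (spacings still alternate ±0.5 h at
240 h near the edge of the range); the classification window starts at
half the horizon.  The locked interval reported is the contiguous grid
stretch containing 24 h.

**Resynchronization.**  After a feeding-schedule switch, the peripheral
clock's peaks are walked forward until the circular offset from the
nearest central peak first drops below 1 h (a declared choice); the
elapsed time is the resynchronization time (~20 h ≈ 1 day in the
standard configuration).

## Standard experiment sizes

Single-oscillator runs integrate 150–240 simulated hours; scans run
one integration per grid point (10–17 points); coupled-network runs use
240 h with a 144 h transient cut; entrainment-range runs use 480 h.
Every preset completes in seconds on one CPU.

## What the synthetic fixtures do and do not show

Unit tests exercise the measurement operations on analytic waveforms
(sinusoids, damped sinusoids, constants) with known periods, phases and
amplitudes — they validate the estimators, not the biology.  The ODE
experiments are deterministic idealizations: no molecular noise, no
parameter temperature-dependence, instantaneous signal transmission
between coupled clocks, and a single effective stimulus per port.
Passing tests show the framework reproduces the published behavior of
the effective model, not that the model captures any particular
organism quantitatively.

## Known limitations

* Alternative oscillator cores (PER/TIM, detailed mammalian, DDE
  models) are not implemented; the RHS-plug-in interface
  (`assemble_network` over any per-oscillator variant) is where they
  would attach.
* Arrhythmicity under strong constant stimulus is a damped spiral to a
  fixed point; "rhythmic" table entries at intermediate intensities are
  periods of decaying oscillations measured in the standard window, not
  sustained limit cycles.
* The entrainment-range classifier is conservative near the range
  edges, where locking transients exceed the 480 h horizon.
* No spatially extended or delay-coupled networks; no stochastic
  integration.
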