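# perclock

An effective circadian-clock simulator: the five-variable PER
limit-cycle oscillator extended with a bilinear external-stimulus
framework, an input–output interface for coupling oscillators, and the
measurement procedures chronobiologists apply to such models — period
estimation, phase shifts, arrhythmicity detection, constant-light
(Aschoff) scans, phase-response curves and entrainment ranges.

It is aimed at systems biologists and modellers who want a small,
auditable model of entrainment phenomena: how light and feeding cues
synchronize an endogenous ~24 h rhythm, why constant light shortens or
lengthens the free-running period depending on intensity and species,
and how a central (SCN-like) clock imposes phase on peripheral tissue
clocks.

## The model

The core is the PER negative-feedback oscillator over
(M, P0, P1, P2, PN) — *per* mRNA, three phosphorylation states of PER
and nuclear PER:

    dM/dt  = vs·KI^n/(KI^n + PN^n) − vm·M/(Km + M)
    dP0/dt = ks·M − V1·P0/(K1+P0) + V2·P1/(K2+P1)
    ...
    dPN/dt = k1·P2 − k2·PN

which free-runs with a 23.7 h period at the default parameters.
External stimuli u(t) ≥ 0 act through *ports* — single bilinear terms:
−α·u·M (mRNA decay), −α·u·P0 (fly-like PER degradation), or
+γ·u·e^(−ϱM) (mammal-like induced transcription, optionally unfolded
into an explicit transcription-machinery pool).  Oscillators couple by
using one clock's state variable as another's stimulus, e.g.
−α̃·P̃0·P0 (antiphase lock) or −α̃·P̃0·e^(−βP0) (in-phase lock).
See `docs/methods.md` for the full model, conventions and numerics.

## Worked example

```python
from perclock import VariantSpec, StimulusSpec, SolverSettings
from perclock.analysis import run_single, estimate_period, scan_constant_light

# free-running clock
traj = run_single(settings=SolverSettings(t_end=150.0))
est = estimate_period(traj, "osc.M")
print(f"free-running period: {est.period:.1f} h")

# constant light through the fly port: Aschoff scan
scan = scan_constant_light("fly", c_grid=[0.0, 0.2, 0.5, 0.9], alpha=1.0)
print(scan.table.to_string(index=False))
print(f"turning point: c = {scan.turning_point}")
```

prints

    free-running period: 23.7 h
      c    period  amplitude   status
    0.0 23.663263   2.376206 rhythmic
    0.2 23.428452   1.385604 rhythmic
    0.5 25.392066   0.288677 rhythmic
    0.9 29.628005   0.055328 rhythmic
    turning point: c = 0.2

Reading: in darkness (c=0) the clock free-runs at 23.7 h.  Weak
constant light through the fly port shortens the period (23.4 h at
c=0.2, the turning point), stronger light lengthens it while damping
the oscillation (25.4 h at c=0.5, 29.6 h at c=0.9 with 4% of the dark
amplitude); at c=1 the rhythm fades below detection — the intensity
dependence behind Aschoff's rule.

The same experiments are scriptable from the shell:

    perclock preset freerun --out out/
    perclock scan-light --variant mammal --c-from 0 --c-to 0.9 --c-step 0.1
    perclock preset couple-p2 --out out/

The last command assembles the two-oscillator network in which the
peripheral clock's PER is degraded in proportion to the central clock's
P2 and prints `{"locked_period_h": 24.0, "shift_h": 15.95}`: the
peripheral mRNA locks 15.9 h behind the central one, an intermediate
phase between plain in-phase and antiphase coupling.  Presets cover the
free run, phase entrainment, both constant-light scans, the three
coupled-clock configurations, food entrainment, PRC, entrainment range
and the inhomogeneous-ensemble singularity demonstration
(`perclock preset --help` lists them).

Experiments can also be declared in JSON configs (`perclock simulate
--config cfg.json`); an empty config `{}` is the default free run, and
unknown keys or dangling references are rejected by name.

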