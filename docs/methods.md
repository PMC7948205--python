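# Methods

## Model structure

`retisim` simulates a linked three-part compartmental model of
whole-body vitamin A metabolism in an adult human.

**Tracer side (fraction of dose).** An oral dose enters the gut lumen
(component 1), where digestion splits it between an absorptive path and
unabsorbed fecal loss; absorption efficiency *a* is the rate split
`a = L(2,1)/(L(2,1)+L(0,1))`, and the total exit rate from the gut is
held fixed when *a* is varied, so post-gut tracer curves scale exactly
with the absorbed fraction. Absorbed retinyl esters pass a discrete
digestion/packaging delay (DT(3) ≈ 0.2 d), appear in a plasma
chylomicron pool, and reach hepatocytes through a short remnant-uptake
delay (DT(25) ≈ 0.08 d). Hepatocytes secrete retinol into plasma, which
exchanges with a large storage pool (hepatic stellate cells) and a
small fast extravascular pool; irreversible disposal leaves from the
storage pool into a sink.

**Tracee side (μmol).** A mirrored compartment set carries unlabeled
retinol with the *same* fractional transfer coefficients and a constant
dietary input; the steady-state solution anchored at the assigned
plasma pool supplies every pool size, flow, and the sustaining intake.

**RBP side.** Apo-RBP is synthesized into a hepatocyte pool (43) at
rate U(43). At steady state U(43) equals the RBP-mediated retinol flow
into plasma, P(43) = R(15,14) + R(15,16), and is routed between direct
hepatocyte secretion and transfer to a stellate-cell pool (44) in
proportion to those two flows (10% / 90% for the replica). Holo-RBP
formation consumes apo-RBP 1:1 with retinol secretion, enters a plasma
holo-RBP pool sized so M(45) equals the plasma retinol pool, and is
cleared first order. The coupling is bilinear: retinol secretion
coefficients are multiplied by the apo-RBP pool relative to its steady
state (`L(15,14)·M43/M43_ss`, `L(15,16)·M44/M44_ss`), and the same
multipliers act on the tracer coefficients L(5,4) and L(5,6), so both
isotope forms respond identically to RBP availability. Tracer mass is
treated as stoichiometrically negligible for RBP consumption, keeping
the tracer subsystem linear in the dose.

## Inflammation forcings

Chronic inflammation sets U(43) to exactly half its basal value from
the onset day onward. Acute inflammation multiplies U(43) by

```
G(T) = p11·e^(−p1·T) + e^(−p2·T) + (p12 − e^(−p3·T) − e^(−p4·T))
```

with T the time since onset and G ≡ 1 before onset, so delayed onsets
translate the response exactly. Two exponentials shape the fall, two
the recovery; `p12` is the recovery plateau and `p11 = 2 − p12`
enforces G(0) = 1. The default parameters are the calibrated family
`p1 = p2 = 2·p3 = 2·p4` with `p3 = ln 2 / 1.25`, which gives an exact
50% nadir at day 1.25 and recovery to G(7) = 0.96. Calibration to
other shapes (`calibrate_g43`) is a bounded Nelder–Mead fit in log-rate
space scored on a 0.002-d grid; a nadir placed later than ~1.4 d cannot
be combined with ≥95% recovery by day 7 in this functional form, and
the calibrator raises when the shortfall exceeds 0.05.

## RID bookkeeping

"Stores" are the post-absorptive non-plasma pools: hepatocyte, storage
and small extravascular compartments (tracer 4+6+7, tracee 14+16+17);
plasma can be included via a build flag, and all RID quantities read
the same membership so Fa and SA<sub>s</sub> stay consistent. The
composite coefficient is computed both through its definition
(Fa · SA<sub>p</sub>/SA<sub>s</sub> with SA<sub>s</sub> = Fa/TBS) and
through the algebraic identity FaS = TBS·SA<sub>p</sub>; the two routes
must agree to 1e-10 or the computation aborts. Times before the tracer
reaches plasma are reported as missing, not zero. Predictions are made
in two coefficient modes: *time-variant* (validation: returns the model
stores identically) and *steady-state* (field practice: the mode in
which inflammation biases the estimate). The single-sample readout
defaults to day 4 after dosing, the conventional RID sampling time.

## Numerics

The integrator is classical fixed-step RK4 (default step 0.01 d, output
every 0.1 d) with delays handled by the method of steps: delayed inflows
are evaluated from a cubic-Hermite interpolated history of the full
state, which makes each delay an exact time shift rather than an
Erlang-chain approximation. The step must not exceed the shortest
delay. Before one delay time has elapsed, a delay releases its initial
content uniformly (zero when started empty, the steady through-flow
when equilibrium-loaded). History lookups are clamped at zero because
cubic interpolation can undershoot at sharp fronts (dose events).
States are clipped to zero when integrator ringing at tracer fronts
produces values above −1e-5; anything more negative raises an error as
a modeling fault. A cumulative-input state is integrated alongside the
pools so mass balance (total mass − input + sink content) closes to
integrator precision and is asserted in tests. Dose events and
perturbation onsets must fall on internal grid nodes.

The steady-state solver collapses delays to their termini, scales all
declared inputs by a common factor, and solves the linear flow balance
with the anchored compartment eliminated; delay-resident mass is
through-flow × DT. Control-law multipliers are exactly one at the
reference steady state, so an unperturbed simulation is flat to
round-off (drift < 1e-12 relative over 30 d in practice; tests assert
1e-6).

## The subject-2 replica

The published per-subject transfer coefficients are not available, so
the packaged replica is *defined* by the published anchors plus
response landmarks, fitted once and frozen
(`scripts/calibrate_replica.py`; achieved values in
`docs/calibration_residuals.json`). The steady-state anchors (plasma
pool 5 μmol, TBS 980 μmol, apo-RBP demand 14 μmol/d, 90% stellate
share, 74% absorption) are satisfied exactly by construction of the
deck; ten kinetic shape parameters (fast-pool sizes, absorption-chain
rates and delays, apo-RBP residence times) were fitted by bounded least
squares to the landmark features of the inflammation responses (plasma
ratio 0.76 at day 1 and nadir ~0.69; tracer ratio 0.68 at day 1 with a
mid-week peak ~1.5; SA<sub>p</sub> ratio maximum ~1.6; prediction
minima ~63% (onset day 0) and ~80% (onset day 3); chronic plasma ~55%
at day 10 with a late prediction plateau ~+10%).

Calibrated values worth noting: hepatocyte retinol ≈ 1.8 μmol
(residence ≈ 1.3 d), small pool ≈ 31 μmol exchanging ≈ 14 μmol/d with
plasma, apo-RBP residence 0.17 d (hepatocyte) and 0.12 d (stellate) —
fast pools, consistent with RBP's rapid turnover. Known structural
limitations: with irreversible loss only from the storage pool and
constant intake, the chronic plasma asymptote is exactly 50% of
baseline, so the day-10 value is ~53% rather than 55%; the chronic
prediction plateau settles at ~+5.6% rather than +10%; the chronic
mid-study prediction dip and the day-9-onset response are deeper than
the published curves. The apo-RBP pool sizes are a modeling choice
parameterized by mean residence time — no published values exist.

## The subject generator

`generate_subject` emulates the study population: healthy adults with
normal plasma retinol, low-to-high stores and varied absorption. It
draws physiological state variables — plasma pool 3–8 μmol, TBS
100–1500 μmol, absorption 0.50–0.90, plasma turnover, stellate share
0.80–0.95, hepatocyte residence 0.4–1.2 d, small-pool equilibration
0.8–2.5 d, apo-RBP residences bracketing the replica's — and constructs
the transfer coefficients so the steady state meets them exactly;
candidates whose steady state fails to solve cleanly are rejected and
redrawn (deterministic per seed). The small pool is sized by its
equilibration time, and hepatic residence is capped near one day, both
reflecting the fast peripheral exchange and rapid hepatic transit seen
in human tracer data; subjects outside those ranges would carry
multi-week echo modes that the study's healthy-subject models do not
show.

What the generator does *not* emulate: within-subject variation of
intake over time, children or vitamin A-depleted subjects, inflammation
effects on absorption (explored only through the explicit
reduced-absorption experiment), and biomarker (CRP/AGP) dynamics.
Passing tests therefore demonstrate the method's behavior under the
model's assumptions, not the variability of real field data.

## Design choices on open points

* Tracee delay elements are initialized with steady-state content —
  required for a flat baseline.
* The storage-mobilization control law applies to tracer and tracee
  alike (one multiplier per apo-RBP pool), keeping the two isotope
  forms kinetically identical.
* Fa excludes tracer still in absorptive components (gut, delays,
  chylomicron pool); after day 3 the difference is negligible because
  the absorption chain empties within hours.
* Holo-RBP leaves plasma by aggregate first-order clearance; whether
  retinol moving to extravascular pools carries RBP along is not
  resolved, and pool 45 is observational (it feeds nothing back).
* Chronic onset is an instantaneous step, not a ramp.

## Problem sizes

Default runs integrate ~25 state variables over 30 days at a 0.01-d
internal step with 0.1-d output (≈ 12,000 RK4 steps, ≈ 1 s per
scenario); the multi-subject sweeps use 20–30 generated subjects with
four scenarios each.
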