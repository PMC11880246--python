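# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `bilayerlab`, in the spirit of a methods appendix.

## Electrochemistry

### Conventions and constants

Units are fixed package-wide: mV, pA, pS, mM, ms, K. The two bilayer
chambers map as **out ≡ cis** (the side the protein is added to) and
**in ≡ trans**; membrane potential is cis minus trans. With 500 mM KCl on
the cis side, this orientation is the one under which a cation-selective
channel shows the measured *positive* reversal potential (~+53 mV), so it
is not a free choice.

Physical constants are CODATA values (F = 96 485.332 C/mol,
R = 8.314 463 J/mol/K). The default temperature is 298.15 K
(RT/F = 25.69 mV), always overridable per bath by either `temperature_K`
or `rt_over_f_mV`. The package's reference conditions use
**RT/F = 25.97 mV** (T ≈ 301.4 K): this is the unique thermal voltage under
which the two measured (reversal potential, permeability ratio) pairs on
the 500:50 mM KCl bath — (52.77 mV, 31.77) and (46.96 mV, 15.38) — are
simultaneously self-consistent, and the test suite verifies that
consistency numerically. The recording temperature itself was not reported.

Concentrations enter the equations as-is. No activity coefficients, no
liquid-junction correction, no surface-charge treatment; at 500 mM these
are real effects (the K⁺ activity-based equilibrium potential is closer to
50 mV than the 59.8 mV concentration-based Nernst value) and this is a
documented simplification, not an oversight.

### GHK equations

The monovalent GHK voltage equation is solved in closed form, and its
inversion for one unknown anion permeability (reference cation fixed at
P = 1) is algebraic: with u = exp(E·F/RT),

    P_an/P_cat = ([cat]_out − u·[cat]_in) / (u·[an]_out − [an]_in).

The divalent-capable equation is implicit in E (the Boltzmann factor u
appears on both sides). Design choices:

* **Anion terms are excluded by default** from the divalent equation,
  mirroring the form conventionally used for bi-ionic cation experiments;
  `include_anions=True` adds them in standard GHK positions with the same
  (1+u) weighting as the monovalent cations, so the equation still
  collapses exactly to the monovalent form when divalent concentrations
  vanish.
* **Root finding is bracketed bisection** on E ∈ [−500, +500] mV after a
  1000-point scan for sign changes. Zero crossings raise a no-solution
  error; multiple candidate roots raise an ambiguity error carrying every
  bracket. Bisection runs until the bracket is below the tolerance
  (default 1e-9 mV), which propagates to ~1e-11 relative error in an
  inverted ratio — comfortably inside the 1e-9 round-trip requirement the
  tests enforce. Robustness was preferred over Newton-type speed; a
  reversal-potential solve is microseconds either way.
* **Inversion for the divalent permeability** is the exact linear solve in
  P_div at fixed u. Both inversions re-evaluate the forward equation at the
  returned ratio and reject the result if it misses the input reversal
  potential by more than 1e-6 mV. Analytically-zero numerators are clamped
  when they land within 1e-12 relative of zero, so the boundary cases
  (pure-cation limit; monovalent-only reversal) return 0/∞ cleanly instead
  of failing on floating-point noise.

The measured K⁺/Ca²⁺ mixture figures (the wild-type mixture reversal
potential and the mutant's P_K/P_Ca = 1.73) could not be reproduced from
the divalent equation above with the stated solutions under any
orientation, temperature or anion-inclusion choice we tried (the attempts
span ≈0.94–1.64); the assumptions behind those reported values are
unstated, so the package makes no claim about them and they are not used
as reference values anywhere.

## Simulator

The generator emulates the statistical structure the analysis assumes:

* **Gating** is a continuous-time two-state Markov chain per channel
  (closed→open at k_open, open→closed at k_close), giving exponential
  dwell times and stationary open probability k_open/(k_open+k_close).
  Channels start in the stationary distribution so that time averages are
  unbiased from t = 0. Multiple channels are independent and identical;
  the path stores the aggregate open count.
* **Current** is ohmic: i = g(V − E_rev)/1000 pA with g in pS. E_rev can
  be given directly or derived from a bath via the GHK solvers.
* **Rendering** samples the ideal piecewise-constant current at the ADC
  rate (default 10 kHz), adds white Gaussian noise (default SD 0.8 pA),
  and applies a causal 4-pole Butterworth low-pass at 1 kHz. The hardware
  in this class of rig is a Bessel-type filter specified only as
  "1–2 kHz"; Butterworth order, cutoff and the noise SD are package
  choices, configurable per model. The filter state is initialized at the
  first sample value to avoid a spurious start-up transient.
* Gating is realized on the continuous time axis first and sampled second,
  so sub-sample openings can vanish at rendering — as in real acquisition.

Default gating rates in the packaged configs are k_open = 21.43 s⁻¹ and
k_close = 50 s⁻¹: stationary P_open = 0.3 (the order observed for these
channels) with 20 ms mean open dwells, long against both the 1.5 ms dead
time and the ~0.33 ms filter rise time, so filtering attenuates few events.

What the simulator does **not** model: baseline drift, 1/f and capacitance
noise, subconductance levels, rectification, voltage-dependent gating,
ligand modulation (including the Ca²⁺-dependent amplitude increase seen
experimentally, for which no functional form was reported), and bilayer
breakage artifacts. Passing recovery tests on these traces therefore shows
the estimator chain is correct and unbiased under its own assumptions; it
does not certify performance on drifting or rectifying recordings.

## Idealization

Half-amplitude threshold (threshold at baseline + 0.5 × signed unitary
amplitude), the field-standard criterion; the original analysis software's
criterion was not documented, so the standard one is used. Openings
shorter than the dead time (default 1.5 ms, matching the analysis rule the
package reproduces) are **merged into the flanking closed level** rather
than deleted: events keep tiling the record, and sub-dead-time openings do
not contribute to P_open. A symmetric closed-gap dead time exists but
defaults to 0 (off) — applying it was not part of the original rule.
Optional hysteresis is omitted in favor of the amplitude-histogram route
for noisy data.

The baseline (closed level) is the center of the dominant all-point
histogram peak, refined by recentering a symmetric window on its own mean
(fixed point: the peak center), with the window half-width adapting to
2.5× the local MAD-estimated noise SD. The adaptive width keeps the
estimator's statistical efficiency near that of a plain mean while still
excluding other conductance levels; the final estimate is free of the
half-bin quantization of a raw histogram mode.

## Amplitude histograms

All-point histograms use uniform bins (default width 0.05 pA — the
original bin width was unreported; configurable) anchored at the sample
minimum, so the count always sums to the number of samples. The fit is
deterministic nonlinear least squares of a two-Gaussian sum to the binned
counts — the same strategy as the commercial "Gauss fit" — rather than EM
on raw samples. Initialization takes the two tallest local maxima at least
0.5 pA apart; initial widths come from local second moments (floored at a
quarter bin so noiseless, delta-like histograms still fit). If no second
peak exists the call fails with a degenerate-fit error carrying the
single-component moments. Exactly two components are fitted: the traces
this targets show one closed and one open level; multi-level extensions
are out of scope. Component weights are the fitted areas as fractions of
the sample count, renormalized only if least squares pushes their sum
above 1. The "closed" label goes to the component nearer the baseline
(defaulting to the taller peak's position when no baseline is supplied,
correct whenever the channel is closed most of the time).

## I–V fits

Strictly linear (ohmic) fits, matching how slope conductances are reported
for these channels; rectifying models are out of scope. Ordinary least
squares by default, inverse-variance weighted on request, via statsmodels.
E_rev is the fitted line's x-intercept −b/a with its SE from the delta
method — the same way a reversal shift is read off an I–V plot, rather
than from a separate zero-current measurement. Two-point fits interpolate
exactly and report NaN uncertainties (zero residual degrees of freedom); a
slope within 1e-12 (relative to data scale) of zero raises a
reversal-undefined error. Duplicate-voltage points are pooled by inverse
variance when SEs are available, by the plain mean otherwise.

## Pipeline and reproducibility

One validated config (pydantic; all violations reported at once) drives
simulate-or-load → baseline → histogram fit → idealization → I–V →
optional GHK inversion. All randomness descends from one master seed
through `numpy.random.SeedSequence` spawns (per voltage, then gating vs
noise), so a config reproduces its report byte-for-byte; reports carry the
config hash, package version and seed, and no timestamps. Traces travel as
TSV + JSON sidecar, events as CSV, reports as JSON — text formats only.

### Packaged study conditions and problem sizes

The three shipped configs re-create the reported conditions at a size a
desk machine handles in seconds: five 60 s traces per condition at 10 kHz
(3×10⁶ samples per condition), P_open ≈ 0.3, noise SD 0.8 pA before the
1 kHz filter:

* `wt_kcl` — 500:50 mM KCl, true g = 27.37 pS, E_rev = +52.77 mV,
  voltages −50…+150 mV;
* `wt_ca` — 150:15 mM CaCl₂, true g = 59.55 pS, E_rev from the bath
  (Ca²⁺ Nernst, +29.90 mV at RT/F = 25.97 mV), voltages −50…+90 mV;
* `mutant_ca` — same bath, true g = 33.75 pS, voltages −60…+105 mV.

Voltage protocols span well over 100 mV, bracket E_rev from both sides,
and keep every unitary amplitude ≥ ~1.5 pA: after the 1 kHz filter the
noise SD is ≈0.36 pA, so the closed/open histogram peaks stay clearly
bimodal at every point (peak separation ≥ ~4 filtered SDs). Points closer
to E_rev would merge the peaks and defeat any two-Gaussian fit — the same
reason experimental I–V points cluster away from reversal. Under these
conditions the pipeline recovers the true conductances to within ~0.3%
across seeds, far inside the 5% the tests demand.

## Known limitations

* No missed-event (dead-time) correction of rate constants; P_open is the
  thresholded estimate, slightly biased low by ignored brief openings
  (≲0.3% of open time at the default rates).
* Gaussian amplitude fits ignore the beta-like broadening of heavily
  filtered brief events; with dwells ≫ filter rise time this bias is
  negligible, which the defaults ensure but pathological settings may not.
* The GHK machinery supports valences −1, +1, +2 only, one unknown
  permeability per inversion, and no anomalous mole-fraction effects.
* ABF/binary acquisition formats are not read; convert to TSV first.
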