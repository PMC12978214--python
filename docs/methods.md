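# Methods

This note documents the models, parameter choices and numerical decisions
behind `icenuc`, and what the synthetic-data experiments do and do not show
about real droplet-freezing data.

## Droplet-freezing assay model

A sample containing N_tot ice nucleators (INs) per mg is serially diluted
(10-fold steps) and dispensed as droplets of volume V_d (3 µl) at mass
concentration C_m(d) = C₀ / 10^d. The number of INs in a droplet at
dilution d is Poisson with mean λ_d = N_tot · C_m(d) · V_d (λ_d > 10⁹ is
rejected as unphysical). Each IN carries a characteristic freezing
temperature drawn from the underlying distribution P_u(T), modelled as a
mixture of p normalized Gaussians with weights cᵢ (Σcᵢ = 1), modes T_mode,i
and spreads sᵢ. On cooling, the droplet freezes at its warmest IN
temperature; droplets whose warmest IN is colder than the pure-water
background freeze there instead.

Fixed protocol parameters (instrument defaults): 96 droplets per dilution,
cooling range 0 to −30 °C, readout quantized to 0.1 °C, per-droplet
temperature uncertainty 0.2 °C (Gaussian, applied after the max over INs —
an instrument-level simplification rather than per-IN noise). The
background is a Gaussian at −24.5 ± 1.0 °C truncated above at −23 °C; only
its onset is experimentally constrained, so mean and spread are stand-ins
and configurable. Every simulation consumes a single integer seed;
identical seeds give bit-identical assays.

What the generator emulates: Poisson dilution statistics, order-statistics
of the warmest nucleator, censoring at the scan floor, background freezing,
quantization and instrument noise. What it does not: plate-layout or
liquid-handling effects, camera detection errors, IN aggregation kinetics
in the droplet, or day-to-day drift between replicates. Passing recovery
tests on these data therefore validates the inversion chain under its own
statistical assumptions, not robustness to systematic instrument artifacts.

## Vali spectra

The fraction of frozen droplets f_ice(T, d) is converted per dilution by
Vali's relation N_m = −ln(1 − f_ice)/(V_d · C_m), with the binomial
counting error σ_f = √(f(1−f)/n) propagated to
σ_Nm = σ_f / ((1−f) V_d C_m). Points with f = 0 (no information) and f = 1
(log divergence) are censored; overlapping dilutions are kept as separate
points. T₅₀ is the linear interpolation of the f_ice = 0.5 crossing.

Technical replicates of one sample can be pooled at the droplet level
(`pool_replicates`), mirroring the laboratory practice of running each
freezing experiment at least three times.

## Subpopulation decomposition

The cumulative spectrum of the mixture model is
N_m(T) = N_tot · Σᵢ cᵢ Φ((T_mode,i − T)/sᵢ). Fitting proceeds on the log₁₀
scale (spectra span decades):

1. **Preprocessing.** Points are filtered to an informative band: the
   implied frozen fraction must correspond to at least 5 expected droplets
   on each side (never narrower than 3%). Points just inside the censoring
   boundary enter the spectrum only on upward count fluctuations and carry
   a large conditional bias, so this filter is a bias control, not a
   cosmetic one. Duplicate temperatures across dilutions are collapsed by
   inverse-variance averaging of log₁₀ N_m; a monotone PCHIP spline maps
   the points onto a uniform 0.1 °C grid; a Savitzky–Golay filter
   (polynomial order 1, window 3 samples — the window is interpreted in
   grid samples) smooths the result. An order-1, window-3 filter is a
   3-point moving line fit: it reproduces straight lines exactly and keeps
   interior values inside the local data envelope (the two end samples
   extrapolate their windows and may graze it).
2. **Fitting.** For each candidate p, seeded differential evolution
   (best of 5 restarts, Sobol initialization, population 20·dim, up to 300
   generations, then local polish) minimizes the mean squared error between
   the model and the smoothed log₁₀ N_m over modes, log-spreads and simplex
   weights. The overall scale N_tot enters log₁₀ N_m additively, so its
   MSE-optimal value is concentrated out in closed form — this removes a
   normalization degeneracy that otherwise lets the optimizer park "dead"
   components outside the data window. Mode bounds default to the fitted
   data window (global bounds −25 to −2 °C), spreads to [0.05, 5] °C.
3. **Selection.** The lowest-MSE model over p = 1..p_max wins; components
   with weight < 0.01 are pruned, and components whose modes coincide
   within 0.1 °C are merged (they are a flat direction of the fit, not
   distinct subpopulations). Components are reported warmest-first.

**Fit window.** The default analysis window starts at the warm end of the
data and, for mode-recovery work, ends ~2–3 °C below the coldest expected
mode (−10 °C for the samples studied here): the spectrum's long cold
plateau carries only the already-concentrated-out N_tot and otherwise
dilutes the MSE's sensitivity to the mode structure. A conservative −20 °C
cut (clear of the −23 °C background) is used when the mode region is not
known in advance.

**Known limitation — instrument noise bias.** The ±0.2 °C per-droplet
temperature noise does not simply broaden the recovered spreads (to
√(s² + 0.2²)); because the Vali inversion is logarithmic and the noise acts
inside a per-droplet max over λ_d nucleators, high-λ dilutions inflate the
warm flank nonlinearly. In the infinite-droplet limit this shifts the
middle mode of the three-mode test mixture by about +0.4 °C. Recovery
experiments that validate the inversion machinery therefore sample
characteristic temperatures without instrument noise; decompositions of
noisy spectra should be read with a ~0.2–0.5 °C systematic warm-ward
uncertainty on interior modes. Measured performance of the shipped
configuration (three pooled replicates per experiment, noise-free
sampling): 38 of 40 independent experiments recover p = 3 and all three
modes of the −5.6/−6.5/−7.5 °C test mixture within ±0.3 °C.

## CNT model of finite-patch nucleation

An INpro aggregate is a flat rectangular patch, width W_n = n × 3.4 nm and
length L (19 nm or 25.3 nm solenoids), that binds ice as strongly as ice
itself: Δγ_bind = −2γ_sl(T), i.e. complete wetting, with line tension
τ = 10 pN on the ice–protein–water contact line.

Water thermodynamics: |Δμ_v|(T) = Δh_fv·ΔT/T_m − Δc_p,v·(ΔT − T·ln(T_m/T))
with Δh_fv = 3.06×10⁸ J/m³ and Δc_p,v = 2.0×10⁶ J/(m³·K);
γ_sl(T) = γ_m + (1.8×10⁻⁴ J/m²K)·(T − T_m). γ_m is the single calibratable
scale (default 3.08×10⁻² J/m²).

Two stages of the minimum free-energy path give two barriers; the larger
one limits nucleation:

* **Film spreading (ΔG*_A).** A circular ice film of one bilayer thickness
  (d₀ = 0.37 nm) spreads on the patch:
  ΔG_A(a) = −(|Δμ|d₀ + γ_sl)πa² + (γ_sl·d₀ + τ)2πa. The analytic maximum
  is capped where the film reaches the patch boundary. At moderate
  supercooling this barrier is ~10 k_BT — small.
* **Growth into bulk (ΔG*_B).** With the patch covered, the contact line
  pins at the perimeter and the nucleus bulges as a circular-segment ridge
  (chord W_n, bulge angle φ, radius r = W_n/(2 sin φ)) of length L closed
  by two half spherical caps of the same r and φ:
  ΔG_B(φ) = −|Δμ|·V(φ) + γ_sl·(A_lv(φ) − L·W_n − πW_n²/4), maximized over a
  2000-point φ-grid (a 10× finer grid changes barriers by < 0.5%). The
  reference term L·W_n + πW_n²/4 is the ice–liquid area of the flattened
  nucleus (rectangle plus the two end half-discs), so ΔG_B → 0 as φ → 0:
  the flat covered state is the zero of the path. This pinned-nucleus
  geometry is a declared reconstruction — the original algorithm's
  closed-form shape family is not published — so agreement beyond the
  calibrated tolerance is not guaranteed.

Because the pinned ridge spans the full patch length in one step (the
shape family has no partial-length nucleus), the saddle volume is large and
the limiting barrier falls extremely steeply with supercooling
(~10⁻¹⁸ J/K); T_het is therefore sharply defined and nearly independent of
the kinetic prefactor or the exact rate threshold.

T_het scans 0 to −46 °C (below which homogeneous nucleation takes over) in
0.1 °C steps and returns the warmest grid temperature where
J = A₀·exp(−ΔG*/k_BT) ≥ 10² s⁻¹, the rate matching crystallization at
1 °C/min cooling; the threshold is interpreted per aggregate. The kinetic
prefactor A₀ = 10²⁶ s⁻¹ is a typical CNT attachment scale; a 10× change
moves T_het by ≤ 0.5 °C because the barrier falls steeply with
supercooling. Halving the scan step changes T_het by at most one step.

**Calibration.** `calibrate` solves 1-D for γ_m (bracket
[0.015, 0.045] J/m²) so that an anchor surface reproduces an observed
freezing mode; the threshold crossing is interpolated off-grid and aimed a
hair warmer than the anchor so the quantized T_het lands exactly on it. If
the current model already reproduces the anchor within 0.05 °C the
calibration is a no-op. Calibrating the trimer-width 19-nm surface to
−7.5 °C gives γ_m = 0.0390 J/m², within the experimental range for the
ice–water interfacial free energy; all other aggregate predictions follow
with no further freedom.

## Sequence screening

Tandem repeats are called by period-identity autocorrelation: position i
matches position i+16, smoothed by a centered ~3-period window (symmetric
under sequence reversal, so annotations mirror exactly); maximal runs above
50% identity with ≥ 4 copies become blocks with majority-rule consensus
(ties alphabetical). This is a deliberate stand-in for an unspecified
"conserved region search": thresholds are configurable and phase-agnostic.
Motif scanning (TxT, SLT, SxLT, TQT, YGS; x = any residue) reports all
overlapping 0-based positions. Repeat logos are per-position frequency
matrices over full copies with information content log₂20 − entropy.
Cysteine profiling counts residues in terminal windows of 15% of sequence
length (floor). GC content excludes N bases from the denominator. RSCU for
a codon with k synonyms observed n_aa times in total is n_c/(n_aa/k); stop
codons are excluded, a terminal stop is trimmed, internal stops warn. No
group statistical test is bundled: per-gene tables feed downstream
comparison.

The synthetic sequence generator (`icenuc.sequences`, explicitly labelled
synthetic) builds proteins with the fungal INpro architecture — flexible
linker, two cysteines before a noisy 16-residue solenoid repeat array
bearing TQT/SLT/YGS motifs, six C-terminal cysteines — and reverse
translates them with a tunable GC bias to emulate donor- versus host-like
codon usage. These are structural stand-ins for testing; no natural
sequence is reproduced.

## Problem sizes and reproducibility

Simulated experiments use the instrument-scale protocol throughout (96
droplets × 5 dilutions; 3 pooled replicates where the protocol pools
replicates). Recovery statistics are measured over 20-seed batches; the
Vali round-trip coverage over 200 seeds. All stochastic stages derive
sub-seeds from one master seed via `numpy.random.SeedSequence`, and every
pipeline writes a manifest (config hash, sub-seeds, outputs) so a config
file fully determines all artifacts.
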