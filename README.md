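# icenuc

Statistics and physics of protein-driven ice nucleation: a Python package and
analysis pipeline for droplet-freezing assays of fungal ice-nucleating
proteins (INpros) and the classical-nucleation-theory (CNT) interpretation of
their activity.

Fungal species of the *Mortierellaceae* family secrete soluble, β-solenoid
INpros that multimerize into extended ice-binding surfaces and freeze water
at temperatures as warm as −5 to −8 °C. Linking the observed freezing
spectra of such samples to the size of the protein aggregates requires a
chain of quantitative steps, each implemented here as a tested module:

1. **`icenuc.assay`** — simulation of high-throughput droplet-freezing
   dilution series (96 droplets of 3 µl per 10-fold dilution, cooled 0 to
   −30 °C): per-droplet ice-nucleator counts are Poisson, each nucleator
   draws a characteristic temperature from a Gaussian-mixture distribution
   P_u(T), and droplets freeze at the warmest one (or at the pure-water
   background < −23 °C).
2. **`icenuc.spectra`** — fraction-frozen curves f_ice(T), the
   half-freezing temperature T₅₀, and the cumulative ice-nucleator spectrum
   via Vali's formula, N_m(T) = −ln(1 − f_ice)/(V_d·C_m), with binomial
   counting errors propagated by the delta method.
3. **`icenuc.hub`** — decomposition of a cumulative spectrum into Gaussian
   subpopulations: N_m(T) = N_tot · Σᵢ cᵢ Φ((T_mode,i − T)/sᵢ), fitted by
   seeded differential evolution on the log₁₀ scale after spline
   interpolation and Savitzky–Golay smoothing, with the component count
   selected by lowest mean squared error.
4. **`icenuc.cnt`** — heterogeneous ice-nucleation temperatures T_het of
   finite rectangular ice-binding patches (width W_n = n × 3.4 nm,
   length L) from a two-barrier CNT free-energy path: film spreading on the
   perfectly binding patch (Δγ_bind = −2γ_sl, line tension τ = 10 pN), then
   growth into bulk water from a contact line pinned at the patch
   perimeter. T_het is the warmest temperature at which the nucleation rate
   J = A₀·exp(−ΔG*/k_BT) reaches 10² s⁻¹.
5. **`icenuc.screen`** — sequence screening for INpro signatures:
   16-residue tandem repeats (period-identity autocorrelation), TxT / SLT /
   SxLT / TQT / YGS motif arrays, repeat logos, cysteine capping
   architecture, and GC / relative-synonymous-codon-usage (RSCU)
   composition statistics used as horizontal-gene-transfer evidence.
6. **`icenuc.workflows` / `icenuc.cli`** — seeded, provenance-tracked
   pipelines (`icenuc simulate|spectrum|decompose|nucleation|screen`).

The `analysis/` directory contains numbered drivers that run the full study
on synthetic data and write tables under `results/`.

## Worked example

Calibrate the one free scale of the CNT model (the ice–liquid interfacial
free energy at melting, γ_m) so that a trimer-width surface (10.2 × 19 nm)
freezes at the −7.5 °C mode observed for the least-active subpopulation,
then predict the rest of the aggregate series:

```bash
$ python analysis/04_nucleation_series.py
calibrated gamma_m = 0.039018 J/m^2 (trimer anchor -7.5 degC)
En_19nm: T_het(n=1..8) = [-18.5, -10.5, -7.5, -6.0, -5.0, -4.3, -3.8, -3.4] degC
Mo_25.3nm: T_het(n=1..8) = [-18.1, -10.1, -7.2, -5.7, -4.8, -4.1, -3.6, -3.3] degC
```

Reading: a single 19-nm INpro would only freeze water near −18 °C;
side-by-side aggregation warms T_het steeply (monomer → tetramer spans
12 °C) with diminishing returns, because widening the rectangle toward a
square shrinks the pinned-nucleus curvature penalty. Length matters far
less than width (≤ 0.4 °C between the 19 nm and 25.3 nm series at fixed n),
so warm freezing modes diagnose the aggregate width, i.e. the multimer
count: −7.5 °C ↔ trimers, −6.0 / −5.7 °C ↔ tetramers, −5.0 °C ↔ pentamers.

The spectrum side of the chain (simulate → invert → decompose):

```bash
$ python analysis/01_simulate_assays.py && python analysis/02_freezing_spectra.py
...
two_mode: T50(undiluted) = -5.0 degC, 687 spectrum points, N_m plateau ~ 9.43e+04/mg
three_mode: T50(undiluted) = -4.8 degC, 682 spectrum points, N_m plateau ~ 1.66e+05/mg
$ python analysis/03_decompose_spectra.py
two_mode: p = 2, modes [-5.89, -7.38] degC, MSE 2.45e-05
three_mode: p = 3, modes [-5.54, -6.06, -7.48] degC, MSE 4.52e-05
```

The two-mode sample (true modes −5.9 / −7.5 °C) is recovered almost
exactly; the three-mode sample shows the documented warm-ward bias of the
middle mode that the ±0.2 °C instrument noise imprints on the Vali
inversion (see `docs/methods.md`).

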