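# Methods

## Scope and model structure

`il15sim` couples two deterministic mass-action ODE systems for IL-15
receptor dynamics on NK cells to a threshold calculus for population
proliferation. The intermediate-affinity system describes quiescent cells
expressing only IL-15Rβγ; the high-affinity system adds IL-15Rα
upregulation on activated cells. Both live in a well-mixed culture of
N_tot = 25,000 cells in V_m = 200 µl; endosomal contents are per-cell and
well mixed in a total endosomal volume V_e = 1e-14 L.

Key structural assumptions:

* IL-15Rβ homodimers and common-γ limitation are ignored; the intermediate
  receptor is a single IL-15Rβγ species.
* Internalized receptors and complexes are lysosomally degraded (rate
  k_deg), never recycled; only free endosomal ligand recycles (k_rec).
  A degraded complex destroys its bound ligand.
* Bound receptor internalizes at k_int in place of — not in addition to —
  the constitutive k_endo.
* In the high-affinity model every synthesized IL-15Rα is instantaneously
  IL-15-bound (ligand excess, K_d ≈ 38 pM), so α synthesis directly
  produces the membrane ligand Λ = IL-15/IL-15Rα and no free-α species
  exists. Λ is not drawn from the media ligand pool, so the soluble-ligand
  conservation ledger covers only L, L_e, C_s, C_e and degraded
  intermediate complexes.
* Λ internalizes constitutively at k_endo, recycles at k_rec and is never
  degraded alone; the trimeric complex C_s′ traffics exactly like C_s.
  Trans-presentation of IL-15/IL-15Rα by other cells is out of scope.

## Parameters

Shared trafficking: k_endo = 0.42 h⁻¹, k_int = 2.4 h⁻¹, k_rec = 7.4 h⁻¹,
k_deg = 2.1 h⁻¹. Intermediate binding: k_f = 9.0e8 M⁻¹h⁻¹, k_r = 3.6 h⁻¹;
endosomal k_fe = 2.9e-2 M⁻¹h⁻¹, k_re = 29 h⁻¹. Synthesis: k_s (constitutive,
molecules/cell/h), k_syn = 1.2 h⁻¹ (complex-induced). High affinity:
k_f′ = 1.3e9 M⁻¹h⁻¹, k_r′ = 0.05 h⁻¹, k_fe′ = 4.0e-4 (per-molecule, see
below), k_re′ = 0.4 h⁻¹, k_syn′ = 1.5 h⁻¹. Membrane conversion factors
ξ_surf = 1.1e-9 and ξ_endo = 1.5e-8 M per molecule are consumed as
constants; the spherical-shell geometry behind them is not re-derived
because the underlying cell radius and bilayer thickness are not available.
Doses convert as 1 ng/ml ↔ 0.0667 nM via an effective molar mass of
15 kg/mol, reproducing the published dose table (2000 ng/ml ↔ 133 nM).

Design choices made where the design was genuinely open:

* **k_s = k_endo · 800 = 336 molecules/cell/h** (rather than the rounded
  3.6e2) so the unstimulated fixed point R_s = k_s/k_endo is exactly the
  observed 800 receptors/cell. The rounded value remains available via
  config and shifts steady states by ~7%.
* **Endosomal intermediate on-rate.** The tabulated k_fe = 2.9e-2 M⁻¹h⁻¹ is
  so small that endosomal rebinding is effectively off. An alternative
  preset (`kfe_from_kd_rule`) derives k_fe ≈ 9.1e8 M⁻¹h⁻¹ from the rule
  that endosomal pH weakens K_d eight-fold with k_re fixed. A regression
  test confirms the two presets move steady-state surface complexes by
  <1% — the surface solution is insensitive to endosomal binding because
  the endosome feeds back to the surface only through ligand recycling.
* **Endosomal Λ binding.** k_fe′ is printed with units h⁻¹ and is read as a
  per-molecule pseudo-association rate (flux k_fe′·Λ_e·R_e) with the
  membrane factor folded in; the explicit-ξ_endo molar reading is
  selectable (`kfe_p_mode="molar"`) and changes steady-state totals by <2%.
* **Mean division rate = 1/(2·t_div).** Per-cohort division rates spread
  approximately as a Gaussian from the fastest cohort (1/t_div) down to
  near zero, so the population mean is half the maximum. This closed form
  reproduces all four published rate values from their interdivision times.

## Numerics

Integration uses LSODA (stiff-capable) at rtol 1e-10 with per-component
absolute tolerances (1e-9 for molecule counts, 1e-22 for molar
concentrations) over a 48 h horizon (96 h for the high-affinity model,
whose α feedback settles more slowly); output grids carry 10 points/h.
Species are clipped of sub-tolerance negative round-off on output only,
never inside the derivative. Conservation ledgers (soluble ligand; β-
and α-subunit bookkeeping with cumulative synthesis/degradation
accumulators) hold to ~1e-11 relative in tests.

The intermediate steady state is solved algebraically with the media
ligand fixed at its dose value (depletion is <0.1% over 48 h at every
dose):

    C_s = k_f L R_s / (k_r + k_int),
    R_s = k_s / (k_f L + k_endo − (k_syn + k_r) k_f L / (k_r + k_int)),

requiring k_int > k_syn for a finite plateau C_s → k_s/(k_int − k_syn);
the three-species endosomal balance is then solved with `fsolve` from its
k_fe = 0 closed form. The high-affinity steady state is taken from
long-time integration (48 h, extended to 96 h when needed) because the
Λ feedback loop has no comparably simple closed form.

Steady-state classification: converged when every main species changes by
<1e-5 relative over the final 1 h window — looser than the integrator
tolerance because media ligand drifts at ~1e-6/h at low dose indefinitely;
diverging when surface complexes still grow super-linearly at the horizon
(window-over-window increments increasing), in which case species numbers
are reported as NaN rather than horizon artefacts. Sensitivity scans use
the factor grid {1/100, 1/33, 1/10, 1/3, 1, 3, 10, 33, 100}.

## Synthetic data

The generators emulate the statistical structure of the study's
observables, not the instruments:

* **Recruitment observations**: the thresholded recruitment curve plus
  additive Gaussian noise on the fraction scale, clipped to [0, 1].
  Replicate-level sd defaults to 0.05 — an assumption, chosen to produce
  single-digit-to-low-teens NRMSD typical of few-replicate flow-cytometry
  estimates; no error model is published.
* **Maximum division counts**: floor((t − τ)/t_div) with τ = 32 h, capped
  at 8 (CFSE dilution limit), optional ±1 miscount jitter.
* **CFSE profiles**: Gaussian cohort mixtures on a log2-intensity axis with
  unit (2-fold dilution) spacing, undivided cells excluded; cohort sd
  defaults to 0.05 of the spacing. The estimator smooths with a Gaussian of
  0.25 cohort-sd width, detects local maxima, and integrates peak areas
  between midpoints of adjacent peaks.

These generators do not emulate autofluorescence, spectral spillover,
cell-size-dependent dye partitioning, or inter-experiment batch effects;
passing recovery tests therefore demonstrates correctness of the inference
chain on data satisfying the model's own assumptions, not robustness to
real cytometry artefacts.

## Validation surfaces

The test suite checks: conservation ledgers; exact reduction of the
high-affinity system to the intermediate one at k_syn′ = 0; agreement of
algebraic and integrated steady states (<0.5%) across doses 3.9–2000
ng/ml; reproduction of the published steady-state complex numbers,
division-kinetics table and threshold constants; the sensitivity sign
structure, including the equivalence of 64× k_f at 25 ng/ml with
saturating stimulation and the loss of steady state at k_int/100;
threshold recovery within ±10% from noisy synthetic data; and
out-performance of the threshold-free recruitment model by the thresholded
one on thresholded truth in ≥95/100 seeded replicates.

## Known limitations

* The high-affinity totals run ~7–9% below the published per-dose values
  (e.g. 140 vs 154 complexes/cell at 9 ng/ml) and the intermediate plateau
  ~7% above (275 vs 257): the reconstruction reproduces the published
  network topology and constants, but residual differences suggest small
  unstated terms in the original formulation. All downstream quantities
  inherit these few-percent offsets when computed from model (rather than
  published) complex counts.
* Ligand-depletion regimes (very low dose in small volumes, or strongly
  upregulated synthesis) are outside the validated envelope.
* Recruitment predictions at t < 37.8 h precede the first observable
  division and should be treated as extrapolation; the published analysis
  itself notes over-prediction of recruitment at 75 ng/ml, and no
  correction is applied.
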