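# il15sim

Mechanistic modeling of IL-15 receptor dynamics on natural killer (NK)
cells, and of the proliferative response those dynamics drive.

NK-cell expansion during viral infection is controlled by IL-15. Quiescent
NK cells carry ~800 copies of the intermediate-affinity receptor IL-15Rβγ
(K_d ≈ 1 nM); once activated they upregulate the α subunit, whose
IL-15/IL-15Rα complex acts as a membrane-bound high-affinity ligand for
IL-15Rβγ. `il15sim` implements both regimes as mass-action ODE systems and
links their steady-state receptor occupancy to population proliferation
through a cumulative-stimulus threshold.

## The model

**Intermediate-affinity system** (quiescent cells). Species: free surface
receptor R_s, surface complex C_s, endosomal receptor/complex R_e, C_e,
media ligand L (M), free endosomal ligand L_e (M):

    dR_s/dt = k_s + k_syn C_s − k_f L R_s + k_r C_s − k_endo R_s
    dC_s/dt = k_f L R_s − (k_r + k_int) C_s
    dR_e/dt = k_endo R_s + k_re C_e − k_fe L_e R_e − k_deg R_e
    dC_e/dt = k_int C_s + k_fe L_e R_e − (k_re + k_deg) C_e

with media/endosomal ligand exchange through internalization, recycling
(k_rec) and degradation (k_deg destroys a complex together with its
ligand). Internalized receptors are lysosomally targeted, never recycled;
only free endosomal ligand returns to the medium.

**High-affinity system** (dividing cells) adds the trimeric complex C_s′
(IL-15/IL-15Rαβγ) and the membrane ligand Λ = IL-15/IL-15Rα, synthesized at
k_syn′(C_s + C_s′) — every α subunit is born IL-15-loaded because ligand is
in excess and α binds it with K_d ≈ 38 pM. Surface binding of Λ uses the
effective concentration ξ_surf·Λ_s.

**Proliferation calculus.** A cell commits to the cycle when its cumulative
surface-complex exposure C_s·t exceeds a threshold calibrated as
58.2 complexes/cell × 37.8 h ≈ 2198 complex·h/cell; complete population
recruitment requires 257 × 64 h ≈ 16448. Fractional recruitment is the
clipped momentum ratio (C_s·t − C_threshold)/16448. For dividing cells the
interdivision time is t_div = C_threshold / (C_s + C_s′) and the population
mean division rate is 1/(2·t_div).

The package also ships one-at-a-time parameter sensitivity scans, seeded
synthetic recruitment/CFSE data generators with ground truth, NRMSD
scoring, threshold recovery by least squares, and a `click` CLI
(`il15sim simulate|predict|scan|synthesize|evaluate|pipeline`).

## Worked example

```python
from il15sim import (Dose, steady_state_intermediate, steady_state_high_affinity,
                     total_surface_complexes, ThresholdModel, cell_cycle_threshold,
                     division_stats, fractional_recruitment)

ss = steady_state_intermediate(Dose(9.0))        # 9 ng/ml = 0.60 nM
print(round(ss.C_s, 1))                          # 57.3 surface complexes/cell

th = ThresholdModel()                            # published 2198 / 16448 calibration
print(round(fractional_recruitment(116.0, 64.0, th), 3))   # 0.318 recruited by 64 h

total = total_surface_complexes(steady_state_high_affinity(Dose(9.0)).species)
print(round(total, 1))                           # 140.1 total complexes/cell

stats = division_stats(9.0, 154.0, th)           # published complex count
print(round(stats.t_div, 1), round(stats.mean_rate, 3))     # 14.3 h, 0.035 /h
```

At 9 ng/ml the quiescent-cell model settles at ≈57 surface complexes per
cell; with α upregulation the same dose sustains ≈140 — a 2.7-fold signal
amplification that is strongest at low dose. A dividing cell holding 154
total complexes re-crosses the threshold every ≈14.3 h, i.e. a mean
population division rate of ≈0.035 h⁻¹.

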