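# adipoexo

Kinetic modelling of adrenergically stimulated adiponectin exocytosis in
white adipocytes.

Adiponectin is an adipocyte hormone whose circulating levels fall in
obesity and type-2 diabetes. Its release from 3T3-L1 adipocytes is
triggered by cAMP, augmented by Ca²⁺ and ATP, and — physiologically —
driven by catecholamines acting on β₃-adrenergic receptors (β₃AR).
Patch-clamp capacitance recordings measure the net rate of vesicle
exo-/endocytosis (ΔC/Δt, fF/s) in single cells while the pipette
dialyzes the cytosol with chosen cAMP/Ca²⁺/ATP concentrations and
agonists (epinephrine, or the β₃AR-selective CL 316243) are applied
extracellularly.

`adipoexo` implements a 14-state ODE model of this system and the full
analysis pipeline around it, for modellers who want to re-fit, probe, or
extend the published description:

* **model core** — receptor cycling (B ⇌ B_act → B_de), cAMP/Ca²⁺/ATP
  dynamics with first-order pipette exchange scaled by V_cell/V_pip, and
  vesicle trafficking (reserve → releasable → plasma membrane →
  exocytosis, plus Ca²⁺·cAMP-driven endocytosis). The measured rate is
  ŷ = k_scale·(v_exo − v_endo).
* **estimation** — the weighted least-squares cost
  `cost(θ) = Σ_t Σ_e ((y_{t,e} − ŷ_{t,e}(θ))/SEM_{t,e})²`, a χ² model
  test at N−1 degrees of freedom (one consumed by the analytically
  profiled scale k_scale), a peak-timing plausibility constraint, and a
  seeded multi-start global+local fitting pipeline in log₁₀ space.
* **uncertainty** — prediction bands by penalty-relaxed constrained
  optimization: min/max of any simulated quantity subject to
  `cost(θ) ≤ cost(θ*) + χ²(0.05, 1)`.
* **in-silico experiments** — β₃AR knockdown (the scale-free percent
  drop in peak exocytosis), internal-state reports, and single-cell →
  population scaling as fold over a reference secretion time.
* **synthetic data** — patch-clamp-like datasets (sparse 0–12 min
  grids, mean ± SEM from 4–15 replicates) generated from a known
  parameter set, so the whole pipeline is testable end to end.

## Worked example

```python
import adipoexo as ax

# chi-square acceptance limits used in the model test
print(round(ax.chi2_threshold(0.05, 24), 1))   # 36.4
print(round(ax.chi2_threshold(0.05, 6), 1))    # 12.6

# in-silico beta3AR knockdown, published optimal parameters
for fraction in (0.3, 0.6):
    r = ax.knockdown_inhibition(ax.TABLE1, ax.get_protocol("EPI5_ATP3"), fraction)
    print(f"{fraction:.0%} knockdown -> {r.inhibition_percent:.1f}% inhibition "
          f"(control peak at {r.control_peak_time:.2f} min)")
```

prints

```
36.4
12.6
30% knockdown -> 22.4% inhibition (control peak at 1.18 min)
60% knockdown -> 50.2% inhibition (control peak at 1.18 min)
```

A 30 % receptor loss costs only ~22 % of the peak exocytosis rate: the
response is buffered because the releasable vesicle pool, not receptor
number, limits the peak. Including 1.5 µM free Ca²⁺ in the pipette
buffers it further (≈7 %/21 % for the same knockdowns), since
Ca²⁺-dependent replenishment sustains the releasable pool.

The same model supports a full synthetic round trip:

```python
report = ax.recovery_experiment(ax.RecoveryConfig(seed=1))
print(report.fit.cost < report.fit.threshold)   # True: refit passes the chi-square test
print(report.fraction_within_3sem)              # 1.0: refit tracks the noise-free truth
```

A command-line interface mirrors the library
(`adipoexo fit / uncertainty / predict / generate`; see `--help`).

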