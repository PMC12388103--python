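# hsabind

Spectroscopic analysis of small-molecule binding to serum albumin.

Drug candidates circulate largely bound to human serum albumin (HSA), and
the strength and stoichiometry of that association controls free-drug
concentration, half-life and the feasibility of albumin-based nanocarriers.
The standard bench workflow measures HSA's intrinsic tryptophan/tyrosine
fluorescence while titrating in the drug, and reads binding parameters out
of a handful of classical transforms. `hsabind` implements that complete
inference chain as a tested library, together with a forward simulator that
generates every input data class with known ground truth, so the pipeline is
verifiable without instrument data.

## What it computes

- **Stern-Volmer quenching**: OLS fit of F₀/F = 1 + K_SV·[Q]; the
  bimolecular rate constant K_q = K_SV/τ₀ (τ₀ = 6.3 ns for HSA) and a
  mechanism call — *static* when K_q far exceeds the diffusion-limited
  dynamic ceiling (~1×10¹⁰ L·mol⁻¹·s⁻¹) and the intercept is consistent
  with 1, *mixed_flagged* when the intercept excludes 1.
- **Binding constant and stoichiometry**: double-log isotherm
  log₁₀((F₀−F)/F) = log₁₀K_b + n·log₁₀[Q], with a deterministic
  low-quench-point exclusion rule, and ΔG = −RT·ln K_b.
- **Job plot (continuous variation)**: signal maximum over the protein mole
  fraction χ at constant total concentration, parabola-refined; χmax = 0.5
  ⇒ 1:1 complex, χmax = 1/(n+1) ⇒ n:1.
- **Peak analytics**: λmax location with sub-grid parabolic interpolation,
  bathochromic/hypsochromic shift classification for UV and emission
  spectra, excitation-emission-matrix (EEM) peak picking with
  Rayleigh-scatter masking, and integer peak-reduction percentages.
- **Synthetic data**: titrations (exact Stern-Volmer law, or a 1:1
  equilibrium with the closed-form quadratic mass balance), Gaussian
  UV/emission bands, 2-D Gaussian EEMs with optional scatter ridges, and
  n:1 Job series — all seeded and bit-reproducible.

## Worked example

```python
import numpy as np
from hsabind import GroundTruth
from hsabind.synthetic import simulate_titration, simulate_job_series
from hsabind.quenching import stern_volmer_fit, classify_mechanism, double_log_fit
from hsabind.jobplot import find_job_maximum, stoichiometry_from_chi

truth = GroundTruth(kb=60.73e3, mode="stern_volmer", noise_sd_fraction=0.0)
series = simulate_titration(truth)          # 2 uM protein, 0-33 uM drug
fit = stern_volmer_fit(series)
print(f"K_sv = {fit.ksv:.4g} L/mol, K_q = {fit.kq/1e11:.2f}e11, "
      f"intercept = {fit.intercept:.2f}, mechanism = {classify_mechanism(fit).label}")

job = simulate_job_series(GroundTruth(kb=63.67e3),
                          mole_fractions=np.arange(0, 1.0001, 0.05))
chi_max, _ = find_job_maximum(job)
call = stoichiometry_from_chi(chi_max)
print(f"chi_max = {chi_max:.2f} -> {call.n_ratio} (ligand:protein)")
```

prints

```
K_sv = 6.073e+04 L/mol, K_q = 96.40e11, intercept = 1.00, mechanism = static
chi_max = 0.50 -> 1 (ligand:protein)
```

i.e. the fitted quenching constant recovers the generating 60.73×10³ L/mol,
the bimolecular rate (96.40×10¹¹ L·mol⁻¹·s⁻¹) sits three orders of
magnitude above the dynamic ceiling — static quenching via a ground-state
complex — and the continuous-variation maximum at χ = 0.5 identifies a 1:1
complex.

The `analysis/` directory holds the numbered drivers for the full study:
`01_simulate_datasets.py` generates titrations, spectra, EEMs and a Job
series for a weak-binder and a strong-binder scenario; `02`–`06` run the
quenching/binding fits, Job stoichiometry, UV/emission shifts, EEM
reductions and a seeded parameter-recovery study, writing their tables
under `results/`. A `hsabind` console script exposes the same operations on
CSV files (`hsabind simulate`, `sv-fit`, `binding-fit`, `job`,
`eem-compare`, `uv-shift`, `report`, `recover`).

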