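"""Fluorescence-quenching inference chain.

Stern-Volmer analysis (F0/F = 1 + K_SV·[Q]), the bimolecular quenching rate
constant K_q = K_SV/τ0 and its comparison with the diffusion-limited dynamic
ceiling (~1×10¹⁰ L·mol⁻¹·s⁻¹), the double-logarithmic binding isotherm
log10((F0−F)/F) = log10(K_b) + n·log10([Q]), and the standard Gibbs free
energy ΔG = −RT·ln(K_b).

[Q] is the total added quencher concentration (the titration is plotted
against added drug; no free-ligand correction is applied), and F0 is the
intensity at the zero-quencher point of the same series.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datamodel import (
    GAS_CONSTANT_J,
    BindingFit,
    FitDegenerateError,
    MechanismCall,
    QuenchFit,
    TitrationSeries,
    require_valid,
)

__all__ = [
    "DYNAMIC_QUENCHING_THRESHOLD",
    "stern_volmer_fit",
    "bimolecular_rate",
    "classify_mechanism",
    "double_log_fit",
    "gibbs_free_energy",
    "ksv_fold_ratio",
]

#: Diffusion-limited ceiling for dynamic (collisional) quenching,
#: L·mol⁻¹·s⁻¹. Apparent K_q far above it implies ground-state complex
#: formation (static quenching).
DYNAMIC_QUENCHING_THRESHOLD = 1.0e10


def _ols(x: np.ndarray, y: np.ndarray):
    """Ordinary least-squares line fit returning slope, intercept, their
    standard errors and R²; R² of a perfect fit is exactly 1."""
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    return res.slope, res.intercept, res.stderr, res.intercept_stderr, min(r2, 1.0)


def stern_volmer_fit(series: TitrationSeries, pin_intercept: bool = False) -> QuenchFit:
    """Fit F0/F versus [Q] by ordinary least squares over the positive-[Q]
    points.

    The intercept is free by default (an intercept away from 1 is itself a
    mechanistic diagnostic); ``pin_intercept=True`` instead fits the
    one-parameter line F0/F − 1 = K_SV·[Q] through the origin.
    """
    require_valid(series)
    q = series.quencher_concs
    f = series.intensities
    f0 = series.f0
    pos = q > 0
    n_used = int(pos.sum())
    if n_used < 3:
        raise FitDegenerateError(
            f"Stern-Volmer fit needs >= 3 positive-[Q] points, got {n_used}"
        )
    y = f0 / f[pos]
    x = q[pos]
    if pin_intercept:
        slope = float(np.sum(x * (y - 1.0)) / np.sum(x * x))
        resid = y - 1.0 - slope * x
        dof = max(n_used - 1, 1)
        slope_se = float(np.sqrt(np.sum(resid**2) / dof / np.sum(x * x)))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        intercept, intercept_se = 1.0, 0.0
    else:
        slope, intercept, slope_se, intercept_se, r2 = _ols(x, y)
    return QuenchFit(
        ksv=float(slope),
        ksv_se=float(slope_se),
        kq=bimolecular_rate(float(slope), series.tau0),
        intercept=float(intercept),
        intercept_se=float(intercept_se),
        r_squared=float(max(r2, 0.0)),
        n_points_used=n_used,
        tau0=series.tau0,
        label=series.label,
    )


def bimolecular_rate(ksv: float, tau0: float) -> float:
    """K_q = K_SV / τ0 (L·mol⁻¹·s⁻¹); exact arithmetic, no rounding."""
    if tau0 <= 0:
        raise ValueError("tau0 must be positive")
    return ksv / tau0


def classify_mechanism(
    fit: QuenchFit,
    threshold: float = DYNAMIC_QUENCHING_THRESHOLD,
    intercept_tol: float = 0.05,
) -> MechanismCall:
    """Classify the quenching mechanism from K_q and the SV intercept.

    static            — K_q above the dynamic ceiling AND the intercept
                        consistent with the theoretical value 1 (within the
                        relative tolerance, or 1 inside intercept ± 2·SE);
    mixed_flagged     — K_q above the ceiling but the intercept excludes 1
                        (possible combined static + dynamic quenching);
    dynamic_consistent — K_q at or below the ceiling.
    """
    kq_exceeds = fit.kq > threshold
    within_tol = abs(fit.intercept - 1.0) <= intercept_tol * max(1.0, abs(fit.intercept))
    brackets_one = (
        fit.intercept - 2.0 * fit.intercept_se
        <= 1.0
        <= fit.intercept + 2.0 * fit.intercept_se
    )
    intercept_ok = within_tol or brackets_one
    if not kq_exceeds:
        label = "dynamic_consistent"
    elif intercept_ok:
        label = "static"
    else:
        label = "mixed_flagged"
    return MechanismCall(
        label=label,
        kq_exceeds_threshold=kq_exceeds,
        intercept_within_tolerance=intercept_ok,
        threshold_used=threshold,
        tolerance_used=intercept_tol,
    )


def double_log_fit(
    series: TitrationSeries, min_quench_fraction: float = 0.02
) -> BindingFit:
    """Fit the double-log binding isotherm by OLS of log10((F0−F)/F) against
    log10([Q]); the intercept is log10(K_b), the slope the apparent number of
    binding sites n.

    Points with F0 − F ≤ 0 cannot enter the logarithm; points with a quench
    fraction (F0−F)/F0 below *min_quench_fraction* sit in the log blow-up
    regime where readout noise dominates and are excluded deterministically.
    Excluded indices (into the full series) are recorded on the result.
    """
    require_valid(series)
    q = series.quencher_concs
    f = series.intensities
    f0 = series.f0
    usable = np.zeros(q.size, dtype=bool)
    excluded: list[int] = []
    for i in range(q.size):
        if q[i] <= 0:
            continue
        if f0 - f[i] <= 0 or (f0 - f[i]) / f0 < min_quench_fraction:
            excluded.append(i)
        else:
            usable[i] = True
    n_used = int(usable.sum())
    if n_used < 3:
        raise FitDegenerateError(
            f"double-log fit needs >= 3 usable points, got {n_used} "
            f"(excluded {len(excluded)})"
        )
    x = np.log10(q[usable])
    y = np.log10((f0 - f[usable]) / f[usable])
    slope, intercept, _, _, r2 = _ols(x, y)
    kb = 10.0**intercept
    return BindingFit(
        log_kb=float(intercept),
        kb=float(kb),
        n_sites=float(slope),
        r_squared=float(max(r2, 0.0)),
        delta_g=gibbs_free_energy(kb, series.temperature),
        temperature=series.temperature,
        n_points_used=n_used,
        excluded_points=excluded,
        label=series.label,
    )


def gibbs_free_energy(kb: float, temperature: float) -> float:
    """ΔG = −R·T·ln(K_b) in kJ/mol (R = 8.314 J·mol⁻¹·K⁻¹); negative for
    K_b > 1 (spontaneous association)."""
    if kb <= 0:
        raise ValueError("kb must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return -GAS_CONSTANT_J * temperature * np.log(kb) / 1000.0


def ksv_fold_ratio(fit_a: QuenchFit, fit_b: QuenchFit) -> float:
    """Ratio K_SV(a) / K_SV(b) — the fold difference in quenching
    efficiency between two ligands."""
    if fit_b.ksv == 0:
        raise ValueError("denominator fit has zero ksv")
    return fit_a.ksv / fit_b.ksv
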