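"""Forward simulation of titrations, spectra, EEMs and Job series.

Emulates the reference experimental design — albumin at 2 µM titrated with
drug from 0 to 33 µM in 3 µM steps at 298.15 K, emission band near 338 nm,
UV bands near 211/280 nm, EEM peaks at ex/em 220/345 and 275/350, Job series
at constant total 2 µM — with known ground truth, so every downstream fit can
be scored against the parameters that generated its input.

All randomness is drawn from ``numpy.random.default_rng`` seeded from the
:class:`~hsabind.datamodel.GroundTruth`, so identical truth + design gives
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .datamodel import (
    DEFAULT_TAU0_S,
    DEFAULT_TEMPERATURE_K,
    EEM,
    AbsorptionSpectrum,
    EmissionSpectrum,
    GroundTruth,
    JobSeries,
    TitrationSeries,
)

__all__ = [
    "DESIGN_PROTEIN_CONC",
    "DESIGN_QUENCHER_GRID",
    "EEMPeak",
    "solve_complex_concentration",
    "simulate_titration",
    "titration_from_binding_law",
    "simulate_emission_spectrum",
    "simulate_uv_spectrum",
    "simulate_eem",
    "simulate_job_series",
    "default_eem_grids",
]

#: Protein concentration of the reference titration design (mol/L).
DESIGN_PROTEIN_CONC = 2.0e-6
#: Quencher grid of the reference design: 0–33 µM in 3 µM steps (mol/L).
DESIGN_QUENCHER_GRID = np.arange(0.0, 33.1e-6, 3.0e-6)


def solve_complex_concentration(
    protein_total: float, ligand_total: float, kb: float
) -> float:
    """Equilibrium 1:1 complex concentration [PL] for P + L ⇌ PL.

    Solves the mass balance Kb·(Pt−x)·(Lt−x) = x in closed form. The quadratic
    x² − (Pt+Lt+1/Kb)x + Pt·Lt = 0 has its physical root at

        x = (b − sqrt(b² − 4·Pt·Lt)) / 2,   b = Pt + Lt + 1/Kb,

    evaluated here as 2·Pt·Lt/(b + sqrt(b² − 4·Pt·Lt)) to avoid catastrophic
    cancellation when Kb·min(Pt,Lt) is small.

    Parameters are in mol/L (totals) and L/mol (kb); returns mol/L with
    0 ≤ [PL] ≤ min(Pt, Lt).
    """
    if protein_total < 0 or ligand_total < 0:
        raise ValueError("total concentrations must be non-negative")
    if kb <= 0:
        raise ValueError("kb must be positive")
    if protein_total == 0.0 or ligand_total == 0.0:
        return 0.0
    b = protein_total + ligand_total + 1.0 / kb
    disc = b * b - 4.0 * protein_total * ligand_total
    disc = max(disc, 0.0)
    x = 2.0 * protein_total * ligand_total / (b + math.sqrt(disc))
    return min(x, protein_total, ligand_total)


def _apply_noise(rng: np.random.Generator, values: np.ndarray, sd_fraction: float):
    """Multiplicative Gaussian noise, sd proportional to signal (shot-limited
    photomultiplier readout)."""
    if sd_fraction == 0.0:
        return values
    return values * (1.0 + sd_fraction * rng.standard_normal(values.shape))


def simulate_titration(
    truth: GroundTruth,
    protein_conc: float = DESIGN_PROTEIN_CONC,
    quencher_concs: np.ndarray | None = None,
    temperature: float = DEFAULT_TEMPERATURE_K,
    tau0: float = DEFAULT_TAU0_S,
    label: str = "",
) -> TitrationSeries:
    """Simulate a fluorescence titration under the truth's quenching model.

    mode "stern_volmer": F(Q) = F0 / (1 + Ksv·Q) with Ksv = truth.kb — the
    readout implied by an exactly linear Stern-Volmer plot.
    mode "equilibrium": F(Q) = F0·(1 − quench_efficiency·[PL]/Pt) with [PL]
    from :func:`solve_complex_concentration` — a partially dark ground-state
    complex.
    """
    if quencher_concs is None:
        quencher_concs = DESIGN_QUENCHER_GRID
    q = np.asarray(quencher_concs, dtype=float)
    if q.size == 0:
        raise ValueError("empty quencher concentration grid")
    if q[0] != 0.0 or np.any(np.diff(q) <= 0):
        raise ValueError("quencher grid must start at 0 and be strictly ascending")

    f0 = truth.f0_per_mol_protein * protein_conc
    if truth.mode == "stern_volmer":
        f = f0 / (1.0 + truth.kb * q)
    elif truth.mode == "equilibrium":
        pl = np.array(
            [solve_complex_concentration(protein_conc, lt, truth.kb) for lt in q]
        )
        f = f0 * (1.0 - truth.quench_efficiency * pl / protein_conc)
    else:
        raise ValueError(f"unknown simulation mode {truth.mode!r}")

    rng = np.random.default_rng(truth.seed)
    f = _apply_noise(rng, f, truth.noise_sd_fraction)
    return TitrationSeries(
        protein_conc=protein_conc,
        quencher_concs=q,
        intensities=f,
        temperature=temperature,
        tau0=tau0,
        label=label,
    )


def titration_from_binding_law(
    kb: float,
    n_sites: float,
    f0: float = 1000.0,
    quencher_concs: np.ndarray | None = None,
    protein_conc: float = DESIGN_PROTEIN_CONC,
    temperature: float = DEFAULT_TEMPERATURE_K,
    tau0: float = DEFAULT_TAU0_S,
    label: str = "",
) -> TitrationSeries:
    """Noise-free titration constructed so that (F0−F)/F = Kb·[Q]ⁿ holds
    exactly at every point, i.e. F = F0/(1 + Kb·Qⁿ).

    This is the inverse of the double-log isotherm and is used to test that
    the fit recovers (log10 Kb, n) to numerical precision.
    """
    if quencher_concs is None:
        quencher_concs = DESIGN_QUENCHER_GRID
    q = np.asarray(quencher_concs, dtype=float)
    f = f0 / (1.0 + kb * np.power(q, n_sites, where=q > 0, out=np.zeros_like(q)))
    f[q == 0] = f0
    return TitrationSeries(
        protein_conc=protein_conc,
        quencher_concs=q,
        intensities=f,
        temperature=temperature,
        tau0=tau0,
        label=label,
    )


def simulate_emission_spectrum(
    center: float,
    width: float,
    amplitude: float,
    grid: np.ndarray,
    excitation_wavelength: float = 295.0,
    label: str = "",
) -> EmissionSpectrum:
    """Gaussian emission band on *grid*; argmax falls on the grid point
    nearest *center*."""
    if width <= 0:
        raise ValueError("width must be positive")
    grid = np.asarray(grid, dtype=float)
    intensities = amplitude * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return EmissionSpectrum(
        excitation_wavelength=excitation_wavelength,
        wavelengths=grid,
        intensities=intensities,
        label=label,
    )


def simulate_uv_spectrum(
    peaks: list[tuple[float, float, float]],
    grid: np.ndarray,
    label: str = "",
) -> AbsorptionSpectrum:
    """Sum-of-Gaussians absorbance spectrum; *peaks* are (center nm, width nm,
    height) triples, e.g. the albumin backbone band at 211 nm plus the weak
    aromatic band at 280 nm."""
    if not peaks:
        raise ValueError("at least one peak is required")
    grid = np.asarray(grid, dtype=float)
    a = np.zeros_like(grid)
    for center, width, height in peaks:
        if width <= 0:
            raise ValueError("peak width must be positive")
        a += height * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return AbsorptionSpectrum(wavelengths=grid, absorbance=a, label=label)


@dataclass
class EEMPeak:
    """A 2-D Gaussian fluorescence band for EEM simulation."""

    ex: float
    em: float
    intensity: float
    ex_width: float = 12.0
    em_width: float = 15.0


def default_eem_grids() -> tuple[np.ndarray, np.ndarray]:
    """Reference scan grids: excitation 220–350 nm at 5 nm, emission
    220–500 nm at 5 nm."""
    return np.arange(220.0, 351.0, 5.0), np.arange(220.0, 501.0, 5.0)


def simulate_eem(
    peaks: list[EEMPeak],
    ex_grid: np.ndarray | None = None,
    em_grid: np.ndarray | None = None,
    scatter: bool = False,
    scatter_intensity: float = 5000.0,
    scatter_width: float = 6.0,
    label: str = "",
) -> EEM:
    """Sum of 2-D Gaussian bands on the excitation × emission grid.

    With ``scatter=True`` a first-order Rayleigh ridge (em ≈ ex) is added so
    peak-picking can be exercised against realistic scatter contamination.
    """
    if ex_grid is None or em_grid is None:
        dx, dm = default_eem_grids()
        ex_grid = dx if ex_grid is None else np.asarray(ex_grid, float)
        em_grid = dm if em_grid is None else np.asarray(em_grid, float)
    ex_grid = np.asarray(ex_grid, dtype=float)
    em_grid = np.asarray(em_grid, dtype=float)
    if np.any(np.diff(ex_grid) <= 0) or np.any(np.diff(em_grid) <= 0):
        raise ValueError("EEM grids must be strictly ascending")

    ex = ex_grid[:, None]
    em = em_grid[None, :]
    z = np.zeros((ex_grid.size, em_grid.size))
    for p in peaks:
        z += p.intensity * np.exp(
            -0.5 * (((ex - p.ex) / p.ex_width) ** 2 + ((em - p.em) / p.em_width) ** 2)
        )
    if scatter:
        z += scatter_intensity * np.exp(-0.5 * ((em - ex) / scatter_width) ** 2)
    return EEM(
        excitation_wavelengths=ex_grid,
        emission_wavelengths=em_grid,
        intensities=z,
        label=label,
    )


def _complex_concentration_n(
    protein_total: float, ligand_total: float, kbeta: float, n: int
) -> float:
    """Complex concentration for the single-step n:1 (ligand:protein)
    equilibrium P + nL ⇌ PLn, Kβ·(Pt−x)·(Lt−n·x)ⁿ = x.

    n = 1 uses the closed-form quadratic; n ≥ 2 brackets the root of the
    mass-balance residual on [0, min(Pt, Lt/n)].
    """
    if n == 1:
        return solve_complex_concentration(protein_total, ligand_total, kbeta)
    if protein_total == 0.0 or ligand_total == 0.0:
        return 0.0
    upper = min(protein_total, ligand_total / n)

    def residual(x: float) -> float:
        return kbeta * (protein_total - x) * (ligand_total - n * x) ** n - x

    if residual(upper) >= 0.0:  # saturating limit
        return upper
    return brentq(residual, 0.0, upper, xtol=1e-18, rtol=8.9e-16, maxiter=200)


def simulate_job_series(
    truth: GroundTruth,
    total_conc: float = 2.0e-6,
    mole_fractions: np.ndarray | None = None,
    signal_scale: float = 1.0e9,
    label: str = "",
) -> JobSeries:
    """Continuous-variation series at constant total concentration.

    At each protein mole fraction χ the totals are Pt = χ·T, Lt = (1−χ)·T and
    the noiseless signal is the equilibrium complex concentration (scaled by
    *signal_scale* to instrument-like magnitudes) — the static-quenching ΔF
    is proportional to the complex formed. Multiplicative noise as for
    titrations.
    """
    if truth.n_stoich < 1:
        raise ValueError("n_stoich must be >= 1")
    if mole_fractions is None:
        mole_fractions = np.linspace(0.0, 1.0, 21)
    chi = np.asarray(mole_fractions, dtype=float)
    if chi.size and (chi.min() < 0 or chi.max() > 1):
        raise ValueError("mole fractions must lie in [0, 1]")

    signal = np.array(
        [
            _complex_concentration_n(
                c * total_conc, (1.0 - c) * total_conc, truth.kb, truth.n_stoich
            )
            for c in chi
        ]
    )
    signal = signal * signal_scale
    rng = np.random.default_rng(truth.seed)
    signal = _apply_noise(rng, signal, truth.noise_sd_fraction)
    return JobSeries(
        total_conc=total_conc, mole_fractions=chi, signal=signal, label=label
    )
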