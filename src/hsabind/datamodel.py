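"""Domain types for spectroscopic binding analysis.

All concentrations are stored in mol/L, wavelengths in nm, temperatures in K,
lifetimes in s. Values printed in µM or 10³ L·mol⁻¹ by instruments or reports
are converted at the I/O boundary so fitting code never sees mixed units.

Each type carries its scientific invariants; :func:`validate` checks them and
returns a report without mutating or raising, while the I/O readers enforce
them on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Union

import numpy as np

__all__ = [
    "DEFAULT_TAU0_S",
    "DEFAULT_TEMPERATURE_K",
    "GAS_CONSTANT_J",
    "EmissionSpectrum",
    "AbsorptionSpectrum",
    "TitrationSeries",
    "QuenchFit",
    "MechanismCall",
    "BindingFit",
    "EEM",
    "PeakRecord",
    "ReductionRow",
    "JobSeries",
    "GroundTruth",
    "StoichiometryCall",
    "ValidationReport",
    "ValidationError",
    "FitDegenerateError",
    "validate",
]

#: Unquenched excited-state lifetime of the albumin Trp fluorophore (s).
DEFAULT_TAU0_S = 6.3e-9
#: Standard experimental temperature (K); free-energy arithmetic uses the
#: temperature stored on each series (298 K in the reference tables).
DEFAULT_TEMPERATURE_K = 298.15
#: Gas constant, J·mol⁻¹·K⁻¹.
GAS_CONSTANT_J = 8.314


class ValidationError(ValueError):
    """An object violates a domain invariant."""


class FitDegenerateError(RuntimeError):
    """Too few usable points, or a degenerate signal, for a requested fit."""


def _asarray(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class EmissionSpectrum:
    """Single-excitation fluorescence emission scan."""

    excitation_wavelength: float
    wavelengths: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = _asarray(self.wavelengths)
        self.intensities = _asarray(self.intensities)

    def invariant_violations(self) -> list[str]:
        v = []
        if self.wavelengths.size < 3:
            v.append("fewer than 3 wavelength points")
        if self.wavelengths.size != self.intensities.size:
            v.append("wavelength/intensity length mismatch")
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            v.append("wavelengths not strictly ascending")
        if not np.all(np.isfinite(self.intensities)):
            v.append("non-finite intensities")
        elif np.any(self.intensities < 0):
            v.append("negative intensities")
        return v


@dataclass
class AbsorptionSpectrum:
    """UV-Vis absorbance scan. Negative absorbances are flagged (baseline
    artifacts) but not rejected."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = _asarray(self.wavelengths)
        self.absorbance = _asarray(self.absorbance)

    def invariant_violations(self) -> list[str]:
        v = []
        if self.wavelengths.size < 3:
            v.append("fewer than 3 wavelength points")
        if self.wavelengths.size != self.absorbance.size:
            v.append("wavelength/absorbance length mismatch")
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            v.append("wavelengths not strictly ascending")
        if not np.all(np.isfinite(self.absorbance)):
            v.append("non-finite absorbance")
        elif np.any(self.absorbance < 0):
            v.append("flag: negative absorbance (baseline artifact)")
        return v


@dataclass
class TitrationSeries:
    """Fluorescence titration: quencher added stepwise to a fixed protein
    concentration; the intensity at ``quencher_concs[0] == 0`` defines F0.

    ``analysis_wavelength`` records where the readout was taken — a fixed
    wavelength in nm, the reference spectrum's λmax, or "integrated".
    """

    protein_conc: float
    quencher_concs: np.ndarray
    intensities: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE_K
    tau0: float = DEFAULT_TAU0_S
    analysis_wavelength: Union[float, str] = "lambda_max"
    label: str = ""

    def __post_init__(self) -> None:
        self.quencher_concs = _asarray(self.quencher_concs)
        self.intensities = _asarray(self.intensities)

    @property
    def f0(self) -> float:
        return float(self.intensities[0])

    def invariant_violations(self) -> list[str]:
        v = []
        q, f = self.quencher_concs, self.intensities
        if q.size == 0:
            return ["empty series"]
        if q.size != f.size:
            v.append("concentration/intensity length mismatch")
        if q[0] != 0.0:
            v.append("missing F0 point (first quencher concentration must be 0)")
        if np.any(q < 0):
            v.append("negative quencher concentration")
        if q.size >= 2 and not np.all(np.diff(q) > 0):
            v.append("quencher concentrations not strictly ascending")
        if not np.all(np.isfinite(f)):
            v.append("non-finite intensities")
        elif np.any(f <= 0):
            v.append("non-positive intensities")
        if self.tau0 <= 0:
            v.append("non-positive tau0")
        if self.protein_conc <= 0:
            v.append("non-positive protein concentration")
        return v


@dataclass
class QuenchFit:
    """Stern-Volmer regression result: F0/F = intercept + K_SV·[Q]."""

    ksv: float
    ksv_se: float
    kq: float
    intercept: float
    intercept_se: float
    r_squared: float
    n_points_used: int
    tau0: float = DEFAULT_TAU0_S
    label: str = ""

    def invariant_violations(self) -> list[str]:
        v = []
        if not np.isclose(self.kq, self.ksv / self.tau0, rtol=1e-12, atol=0.0):
            v.append("kq != ksv/tau0")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            v.append("r_squared outside [0, 1]")
        return v


@dataclass
class MechanismCall:
    """Quenching-mechanism classification from K_q and the SV intercept."""

    label: str  # static | dynamic_consistent | mixed_flagged
    kq_exceeds_threshold: bool
    intercept_within_tolerance: bool
    threshold_used: float
    tolerance_used: float

    def invariant_violations(self) -> list[str]:
        v = []
        if self.label == "static" and not (
            self.kq_exceeds_threshold and self.intercept_within_tolerance
        ):
            v.append("static call without both criteria satisfied")
        if self.label == "mixed_flagged" and not (
            self.kq_exceeds_threshold and not self.intercept_within_tolerance
        ):
            v.append("mixed_flagged call inconsistent with criteria")
        if self.label not in ("static", "dynamic_consistent", "mixed_flagged"):
            v.append(f"unknown label {self.label!r}")
        return v


@dataclass
class BindingFit:
    """Double-log binding isotherm result:
    log10((F0−F)/F) = log10(K_b) + n·log10([Q])."""

    log_kb: float
    kb: float
    n_sites: float
    r_squared: float
    delta_g: float
    temperature: float
    n_points_used: int
    excluded_points: list[int] = field(default_factory=list)
    label: str = ""

    def invariant_violations(self) -> list[str]:
        v = []
        if not np.isclose(self.kb, 10.0 ** self.log_kb, rtol=1e-12, atol=0.0):
            v.append("kb != 10**log_kb")
        if (self.delta_g < 0) != (self.kb > 1):
            v.append("delta_g sign inconsistent with kb")
        return v


@dataclass
class EEM:
    """Excitation-emission matrix; ``intensities[i, j]`` is the reading at
    ``excitation_wavelengths[i]`` / ``emission_wavelengths[j]``."""

    excitation_wavelengths: np.ndarray
    emission_wavelengths: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.excitation_wavelengths = _asarray(self.excitation_wavelengths)
        self.emission_wavelengths = _asarray(self.emission_wavelengths)
        self.intensities = np.asarray(self.intensities, dtype=float)

    def invariant_violations(self) -> list[str]:
        v = []
        nx, nm = self.excitation_wavelengths.size, self.emission_wavelengths.size
        if self.intensities.shape != (nx, nm):
            v.append(
                f"matrix shape {self.intensities.shape} does not match "
                f"grids ({nx}, {nm})"
            )
        for name, grid in (
            ("excitation", self.excitation_wavelengths),
            ("emission", self.emission_wavelengths),
        ):
            if grid.size >= 2 and not np.all(np.diff(grid) > 0):
                v.append(f"{name} wavelengths not strictly ascending")
        if not np.all(np.isfinite(self.intensities)):
            v.append("non-finite intensities")
        return v


@dataclass
class PeakRecord:
    """A located EEM peak (Peak 1: backbone+Trp band; Peak 2: Tyr/Trp band)."""

    peak_id: int
    ex: float
    em: float
    intensity: float
    interpolated: bool = False

    def invariant_violations(self) -> list[str]:
        if self.peak_id not in (1, 2):
            return [f"peak_id {self.peak_id} not in {{1, 2}}"]
        return []


@dataclass
class ReductionRow:
    """One row of the EEM reduction comparison (percent drop of a peak's
    intensity versus the drug-free reference, emission shift signed + = red)."""

    system_label: str
    molar_ratio: float
    peak_id: int
    intensity_ref: float
    intensity_test: float
    reduction_percent: int
    em_shift: float
    valid: bool = True

    def invariant_violations(self) -> list[str]:
        if not self.valid:
            return []
        expected = _round_half_away(
            100.0 * (self.intensity_ref - self.intensity_test) / self.intensity_ref
        )
        if self.reduction_percent != expected:
            return ["reduction_percent does not follow the rounding rule"]
        return []


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (the rule needed to
    reproduce the reference reduction table: 9.64→10, 8.84→9, 3.75→4)."""
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))


@dataclass
class JobSeries:
    """Continuous-variation series at constant total concentration.

    ``mole_fractions`` is the PROTEIN mole fraction χ = [P]/([P]+[L]); with
    this convention a 1:1 complex peaks at χ = 0.5 and an n:1 (ligand:protein)
    complex at χ = 1/(n+1).
    """

    total_conc: float
    mole_fractions: np.ndarray
    signal: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mole_fractions = _asarray(self.mole_fractions)
        self.signal = _asarray(self.signal)

    def invariant_violations(self) -> list[str]:
        v = []
        if self.total_conc <= 0:
            v.append("non-positive total concentration")
        chi = self.mole_fractions
        if chi.size != self.signal.size:
            v.append("mole-fraction/signal length mismatch")
        if chi.size and (chi.min() < 0 or chi.max() > 1):
            v.append("mole fractions outside [0, 1]")
        if chi.size >= 2 and not np.all(np.diff(chi) > 0):
            v.append("mole fractions not strictly ascending")
        return v


@dataclass
class StoichiometryCall:
    """Binding ratio inferred from the Job-plot maximum."""

    chi_max: float
    n_continuous: float
    n_ratio: Fraction | None  # ligand:protein, None if not snapped
    snapped: bool

    def invariant_violations(self) -> list[str]:
        return []


@dataclass
class GroundTruth:
    """Simulator parameter set, kept alongside generated data so fits can be
    scored against the generating truth.

    mode "stern_volmer": intensities follow F0/F = 1 + kb·[Q] exactly (kb is
    used as the quenching constant). mode "equilibrium": a 1:1 (or n:1)
    ground-state complex is formed with association constant kb and the
    complexed protein is dark in proportion to ``quench_efficiency``.
    """

    kb: float
    n_stoich: int = 1
    quench_efficiency: float = 1.0
    f0_per_mol_protein: float = 5.0e8
    noise_sd_fraction: float = 0.0
    seed: int = 0
    mode: str = "equilibrium"

    def invariant_violations(self) -> list[str]:
        v = []
        if self.kb <= 0:
            v.append("non-positive kb")
        if not (0.0 < self.quench_efficiency <= 1.0):
            v.append("quench_efficiency outside (0, 1]")
        if self.n_stoich < 1:
            v.append("n_stoich < 1")
        if self.noise_sd_fraction < 0:
            v.append("negative noise_sd_fraction")
        if self.mode not in ("stern_volmer", "equilibrium"):
            v.append(f"unknown mode {self.mode!r}")
        return v


@dataclass
class ValidationReport:
    passed: bool
    violations: list[str]

    def __bool__(self) -> bool:
        return self.passed


def validate(obj) -> ValidationReport:
    """Check an object's domain invariants; report-only, never mutates.

    Hard violations fail the report; messages prefixed ``"flag:"`` (e.g.
    negative absorbance baselines) are advisory and do not fail it.
    """
    try:
        violations = obj.invariant_violations()
    except AttributeError as exc:  # not a domain type
        raise TypeError(f"cannot validate object of type {type(obj).__name__}") from exc
    hard = [m for m in violations if not m.startswith("flag:")]
    return ValidationReport(passed=not hard, violations=violations)


def require_valid(obj) -> None:
    """Raise :class:`ValidationError` if *obj* fails validation (I/O boundary
    enforcement)."""
    report = validate(obj)
    if not report.passed:
        raise ValidationError(
            f"{type(obj).__name__} invalid: " + "; ".join(report.violations)
        )
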