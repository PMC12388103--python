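"""Peak finding and shift/reduction analytics for UV, emission and EEM data.

Covers λmax location with optional sub-grid parabolic refinement,
bathochromic/hypsochromic shift classification, EEM peak picking with
Rayleigh-scatter masking, and the peak-intensity reduction table comparing
drug-bound spectra against the drug-free reference.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from .datamodel import (
    EEM,
    AbsorptionSpectrum,
    EmissionSpectrum,
    PeakRecord,
    ReductionRow,
    _round_half_away,
)

__all__ = [
    "DEFAULT_PEAK_REGIONS",
    "find_lambda_max",
    "peak_shift",
    "eem_find_peaks",
    "reduction_table",
]

Spectrum = Union[EmissionSpectrum, AbsorptionSpectrum]

#: Search windows bracketing the two canonical albumin EEM peaks:
#: Peak 1 (backbone + Trp, near ex/em 220/345) and Peak 2 (Tyr/Trp,
#: near 275/350).
DEFAULT_PEAK_REGIONS: list[tuple[tuple[float, float], tuple[float, float]]] = [
    ((215.0, 235.0), (330.0, 360.0)),
    ((265.0, 290.0), (335.0, 365.0)),
]


def _spectrum_arrays(spectrum: Spectrum) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(spectrum, AbsorptionSpectrum):
        return spectrum.wavelengths, spectrum.absorbance
    return spectrum.wavelengths, spectrum.intensities


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through points i−1, i, i+1; falls back to the
    grid point at the window edge or when the parabola degenerates."""
    if i == 0 or i == x.size - 1:
        return float(x[i]), float(y[i])
    a, b, c = np.polyfit(x[i - 1 : i + 2], y[i - 1 : i + 2], 2)
    if a >= 0:  # not a maximum — flat or concave-up triple
        return float(x[i]), float(y[i])
    xv = -b / (2.0 * a)
    if not (x[i - 1] <= xv <= x[i + 1]):
        return float(x[i]), float(y[i])
    return float(xv), float(a * xv * xv + b * xv + c)


def find_lambda_max(
    spectrum: Spectrum,
    window: tuple[float, float] | None = None,
    interpolate: bool = False,
) -> tuple[float, float]:
    """Locate the wavelength of maximum signal inside *window*.

    Returns (λmax nm, signal at λmax). Ties are broken toward the shorter
    wavelength. With ``interpolate=True`` the grid argmax is refined by a
    3-point parabola, recovering band centers that fall between grid points.
    """
    wl, y = _spectrum_arrays(spectrum)
    if window is None:
        mask = np.ones(wl.size, dtype=bool)
    else:
        lo, hi = window
        mask = (wl >= lo) & (wl <= hi)
    if mask.sum() < 3:
        raise ValueError("window intersects fewer than 3 grid points")
    idx = np.flatnonzero(mask)
    sub_y = y[idx]
    j = int(np.argmax(sub_y))  # first occurrence == shortest wavelength
    if not interpolate:
        return float(wl[idx[j]]), float(sub_y[j])
    return _parabolic_refine(wl[idx], sub_y, j)


def peak_shift(
    reference: Spectrum,
    test: Spectrum,
    window: tuple[float, float] | None = None,
    interpolate: bool = True,
) -> tuple[float, str]:
    """Signed λmax displacement of *test* relative to *reference*.

    Δλ > 0 is a bathochromic (red) shift — increased polarity of the
    fluorophore microenvironment; Δλ < 0 hypsochromic (blue) — enhanced
    hydrophobicity; 0 is reported as "none".
    """
    lam_ref, _ = find_lambda_max(reference, window, interpolate)
    lam_test, _ = find_lambda_max(test, window, interpolate)
    delta = lam_test - lam_ref
    if delta > 0:
        cls = "bathochromic"
    elif delta < 0:
        cls = "hypsochromic"
    else:
        cls = "none"
    return float(delta), cls


def _scatter_mask(
    ex: np.ndarray, em: np.ndarray, halfwidth: float
) -> np.ndarray:
    """True where a cell lies on a first- or second-order Rayleigh scatter
    ridge (|em − k·ex| < halfwidth, k ∈ {1, 2})."""
    e = ex[:, None]
    m = em[None, :]
    return (np.abs(m - e) < halfwidth) | (np.abs(m - 2.0 * e) < halfwidth)


def eem_find_peaks(
    eem: EEM,
    regions: list[tuple[tuple[float, float], tuple[float, float]]] | None = None,
    mask_scatter: bool = False,
    scatter_halfwidth: float = 12.0,
) -> list[PeakRecord]:
    """Pick the maximum cell in each (excitation range, emission range)
    region, optionally ignoring Rayleigh-scatter ridges.

    Regions default to the two canonical albumin peaks. Ties break toward
    shorter wavelengths on both axes (row-major first occurrence).
    """
    if regions is None:
        regions = DEFAULT_PEAK_REGIONS
    if not regions:
        raise ValueError("at least one search region is required")
    ex, em, z = eem.excitation_wavelengths, eem.emission_wavelengths, eem.intensities
    scatter = _scatter_mask(ex, em, scatter_halfwidth) if mask_scatter else None
    records: list[PeakRecord] = []
    for peak_id, ((ex_lo, ex_hi), (em_lo, em_hi)) in enumerate(regions, start=1):
        ex_sel = np.flatnonzero((ex >= ex_lo) & (ex <= ex_hi))
        em_sel = np.flatnonzero((em >= em_lo) & (em <= em_hi))
        if ex_sel.size == 0 or em_sel.size == 0:
            raise ValueError(
                f"region {peak_id} ({ex_lo}-{ex_hi}/{em_lo}-{em_hi} nm) "
                "does not intersect the EEM grids"
            )
        sub = z[np.ix_(ex_sel, em_sel)].copy()
        if scatter is not None:
            sub[scatter[np.ix_(ex_sel, em_sel)]] = -np.inf
        i, j = np.unravel_index(int(np.argmax(sub)), sub.shape)
        records.append(
            PeakRecord(
                peak_id=peak_id,
                ex=float(ex[ex_sel[i]]),
                em=float(em[em_sel[j]]),
                intensity=float(z[ex_sel[i], em_sel[j]]),
            )
        )
    return records


def reduction_table(
    reference: EEM,
    tests: list[tuple[str, float, EEM]],
    regions: list[tuple[tuple[float, float], tuple[float, float]]] | None = None,
    mask_scatter: bool = False,
) -> list[ReductionRow]:
    """Peak-by-peak intensity reduction of each test EEM versus the
    drug-free reference.

    ``tests`` holds (system label, drug:protein molar ratio, EEM) triples
    sharing the reference's grids. Reduction percent is rounded to the
    nearest integer, halves away from zero; em_shift is the signed emission
    displacement of the test peak (+ = red). Rows with a non-positive
    reference intensity are flagged invalid rather than dropped.
    """
    ref_peaks = eem_find_peaks(reference, regions, mask_scatter)
    rows: list[ReductionRow] = []
    for label, ratio, test_eem in sorted(tests, key=lambda t: (t[0], t[1])):
        if not (
            np.array_equal(
                test_eem.excitation_wavelengths, reference.excitation_wavelengths
            )
            and np.array_equal(
                test_eem.emission_wavelengths, reference.emission_wavelengths
            )
        ):
            raise ValueError(f"EEM {label!r} does not share the reference grids")
        test_peaks = eem_find_peaks(test_eem, regions, mask_scatter)
        for ref_pk, test_pk in zip(ref_peaks, test_peaks):
            if ref_pk.intensity <= 0:
                rows.append(
                    ReductionRow(
                        system_label=label,
                        molar_ratio=ratio,
                        peak_id=ref_pk.peak_id,
                        intensity_ref=ref_pk.intensity,
                        intensity_test=test_pk.intensity,
                        reduction_percent=0,
                        em_shift=0.0,
                        valid=False,
                    )
                )
                continue
            pct = _round_half_away(
                100.0 * (ref_pk.intensity - test_pk.intensity) / ref_pk.intensity
            )
            rows.append(
                ReductionRow(
                    system_label=label,
                    molar_ratio=ratio,
                    peak_id=ref_pk.peak_id,
                    intensity_ref=ref_pk.intensity,
                    intensity_test=test_pk.intensity,
                    reduction_percent=pct,
                    em_shift=float(test_pk.em - ref_pk.em),
                )
            )
    return rows
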