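"""Continuous-variation (Job plot) stoichiometry analysis.

A Job series varies the protein mole fraction χ = [P]/([P]+[L]) at constant
total concentration; the complex signal peaks at χ = 1/(n+1) for an n:1
(ligand:protein) complex, so χmax = 0.5 identifies a 1:1 stoichiometry.

Convention: χ is the PROTEIN mole fraction (total = [protein] + [ligand],
protein listed first). Flipping the convention flips n to 1/n.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from .datamodel import FitDegenerateError, JobSeries, StoichiometryCall

__all__ = ["find_job_maximum", "stoichiometry_from_chi", "CANDIDATE_RATIOS"]

#: Small integer ligand:protein ratios the snapper considers.
CANDIDATE_RATIOS: list[Fraction] = [
    Fraction(1, 1),
    Fraction(1, 2),
    Fraction(2, 1),
    Fraction(1, 3),
    Fraction(3, 1),
]


def find_job_maximum(
    series: JobSeries, fit_halfwidth: int = 2
) -> tuple[float, float]:
    """Locate the signal maximum of a Job series.

    The grid argmax is refined by a least-squares parabola over
    ±*fit_halfwidth* neighbouring points (clipped at the grid edges), which
    is exact for the symmetric 1:1 case and robust on the 11–21 point grids
    typical of continuous-variation experiments. Returns (χmax clamped to
    [0, 1], refined signal maximum).
    """
    chi = np.asarray(series.mole_fractions, dtype=float)
    sig = np.asarray(series.signal, dtype=float)
    if chi.size < 5:
        raise FitDegenerateError("Job analysis needs at least 5 points")
    if np.all(sig == sig[0]):
        raise FitDegenerateError("degenerate Job series: signal is constant")
    order = np.argsort(chi)  # invariance under grid reversal
    chi, sig = chi[order], sig[order]
    i = int(np.argmax(sig))
    lo = max(i - fit_halfwidth, 0)
    hi = min(i + fit_halfwidth, chi.size - 1)
    if hi - lo < 2:
        return float(np.clip(chi[i], 0.0, 1.0)), float(sig[i])
    a, b, c = np.polyfit(chi[lo : hi + 1], sig[lo : hi + 1], 2)
    if a >= 0:
        return float(np.clip(chi[i], 0.0, 1.0)), float(sig[i])
    xv = -b / (2.0 * a)
    if not (chi[lo] <= xv <= chi[hi]):
        return float(np.clip(chi[i], 0.0, 1.0)), float(sig[i])
    return float(np.clip(xv, 0.0, 1.0)), float(a * xv * xv + b * xv + c)


def stoichiometry_from_chi(
    chi_max: float, ratio_tolerance: float = 0.05
) -> StoichiometryCall:
    """Convert the Job maximum to a binding ratio.

    The continuous estimate is n = (1−χmax)/χmax ligands per protein. If
    χmax lies within *ratio_tolerance* (in mole-fraction units) of the ideal
    position n/(n+1)... i.e. protein fraction 1/(n+1) of a small integer
    ratio, the call snaps to that ratio; otherwise the unsnapped continuous
    n is reported.
    """
    if not (0.0 < chi_max < 1.0):
        raise ValueError("chi_max must lie strictly inside (0, 1)")
    n_cont = (1.0 - chi_max) / chi_max
    best: Fraction | None = None
    best_dist = np.inf
    for ratio in CANDIDATE_RATIOS:
        chi_ideal = 1.0 / (1.0 + float(ratio))
        dist = abs(chi_max - chi_ideal)
        if dist < best_dist:
            best, best_dist = ratio, dist
    if best is not None and best_dist <= ratio_tolerance:
        return StoichiometryCall(
            chi_max=chi_max,
            n_continuous=n_cont,
            n_ratio=best,
            snapped=True,
        )
    return StoichiometryCall(
        chi_max=chi_max, n_continuous=n_cont, n_ratio=None, snapped=False
    )
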