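import numpy as np
import pytest

from hsabind.datamodel import GroundTruth
from hsabind.synthetic import DESIGN_QUENCHER_GRID


@pytest.fixture
def design_grid() -> np.ndarray:
    """Reference titration design: 0-33 uM quencher in 3 uM steps (mol/L)."""
    return DESIGN_QUENCHER_GRID.copy()


@pytest.fixture
def strong_binder_truth() -> GroundTruth:
    """Ground truth matching the stronger ligand's association constant."""
    return GroundTruth(kb=63.67e3, seed=17, mode="equilibrium")


def bisect_complex(pt: float, lt: float, kb: float, iters: int = 200) -> float:
    """Independent bisection oracle for the 1:1 mass balance
    Kb*(Pt-x)*(Lt-x) = x on [0, min(Pt, Lt)]."""
    lo, hi = 0.0, min(pt, lt)

    def residual(x: float) -> float:
        return kb * (pt - x) * (lt - x) - x

    if residual(hi) >= 0.0:
        return hi
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def ols_normal_equations(x: np.ndarray, y: np.ndarray):
    """Closed-form least-squares slope/intercept/R^2 from the normal
    equations, independent of the fitting path under test."""
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - intercept - slope * x
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, r2
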