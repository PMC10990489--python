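"""QI-FRET: intrinsic FRET and fluorophore separation in receptor dimers.

Quantitative imaging FRET measures, in each plasma-membrane-derived vesicle,
the FRET efficiency E together with the donor and acceptor fluorophore
concentrations.  When the receptor is constitutively dimeric (E independent
of total concentration), E depends only on the acceptor fraction

    xA = [acceptor] / ([donor] + [acceptor])

and on the intrinsic FRET of the dimer, E_tilde = E / xA — a structural
parameter set by the fluorophore separation.  Per-vesicle E_tilde values are
histogrammed and fitted with a Gaussian; the mean converts to a distance via
the Foerster equation

    E_tilde = 1 / (1 + (d / R0)^6)    <=>    d = R0 ((1 - E_tilde)/E_tilde)^(1/6)

with R0 the Foerster radius of the dye pair (53.1 Angstrom for eYFP/mCherry,
assuming free fluorophore rotation).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .bias import propagate_error
from .gaussfit import GaussianFit, fit_gaussian_histogram

__all__ = [
    "FretSummary",
    "ConcentrationTrend",
    "DEFAULT_R0_A",
    "acceptor_fraction",
    "intrinsic_fret",
    "fit_intrinsic_histogram",
    "separation_distance",
    "fret_from_distance",
    "check_concentration_independence",
    "summarize_vesicles",
]

#: Foerster radius of the eYFP/mCherry pair, Angstrom
DEFAULT_R0_A = 53.1
#: below this acceptor fraction, E/xA amplifies measurement noise unboundedly
DEFAULT_XA_MIN = 0.1
#: per-vesicle E_tilde outside this range is kept for the histogram but
#: excluded from distance conversion
E_TILDE_PHYSICAL = (0.0, 1.2)

VESICLE_COLUMNS = ["vesicle_id", "donor_conc", "acceptor_conc", "E"]


@dataclasses.dataclass
class FretSummary:
    condition: str
    n_vesicles: int
    n_excluded: int
    gaussian: GaussianFit
    e_tilde_mean: float
    se_e_tilde: float
    distance_A: float
    se_distance_A: float
    r0_A: float


@dataclasses.dataclass
class ConcentrationTrend:
    slope: float
    se_slope: float
    p: float
    constitutive: bool

    @property
    def flag(self) -> str:
        return "constitutive" if self.constitutive else "concentration-dependent"


def acceptor_fraction(donor_conc, acceptor_conc):
    """xA = acceptor / (donor + acceptor); errors if both are zero."""
    donor = np.asarray(donor_conc, dtype=float)
    acceptor = np.asarray(acceptor_conc, dtype=float)
    total = donor + acceptor
    if np.any(total <= 0):
        raise ValueError("donor + acceptor concentration must be positive")
    return acceptor / total


def intrinsic_fret(
    vesicles: pd.DataFrame, xa_min: float = DEFAULT_XA_MIN
) -> pd.DataFrame:
    """Add xA, E_tilde and an inclusion flag to a per-vesicle table.

    Vesicles with xA <= xa_min are excluded (reason recorded): dividing E by
    a tiny acceptor fraction turns measurement noise into arbitrarily large
    E_tilde values.
    """
    missing = [c for c in VESICLE_COLUMNS if c not in vesicles.columns]
    if missing:
        raise ValueError(f"vesicle table missing columns: {missing}")
    out = vesicles.copy()
    out["xA"] = acceptor_fraction(out["donor_conc"], out["acceptor_conc"])
    included = out["xA"] > xa_min
    out["E_tilde"] = np.where(included, out["E"] / out["xA"], np.nan)
    out["included"] = included
    out["exclusion_reason"] = np.where(included, "", f"xA <= {xa_min}")
    return out


def fit_intrinsic_histogram(
    e_tilde: np.ndarray,
    bin_width: float | None = None,
    n_cells: int | None = None,
    min_vesicles: int = 50,
) -> GaussianFit:
    """Gaussian fit of the per-vesicle intrinsic-FRET histogram."""
    values = np.asarray(e_tilde, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < min_vesicles:
        raise ValueError(f"need >= {min_vesicles} vesicles, got {values.size}")
    return fit_gaussian_histogram(values, bin_width=bin_width, n_cells=n_cells)


def separation_distance(e_tilde: float, r0: float = DEFAULT_R0_A) -> float:
    """Fluorophore separation d = R0 ((1 - E_tilde)/E_tilde)^(1/6)."""
    if not 0.0 < e_tilde < 1.0:
        raise ValueError("intrinsic FRET must lie strictly inside (0, 1)")
    if r0 <= 0:
        raise ValueError("R0 must be positive")
    return r0 * ((1.0 - e_tilde) / e_tilde) ** (1.0 / 6.0)


def fret_from_distance(d: float, r0: float = DEFAULT_R0_A) -> float:
    """Inverse Foerster relation: E_tilde = 1 / (1 + (d/R0)^6)."""
    if d <= 0 or r0 <= 0:
        raise ValueError("distance and R0 must be positive")
    return 1.0 / (1.0 + (d / r0) ** 6)


def check_concentration_independence(
    vesicles: pd.DataFrame,
    alpha: float = 0.05,
    min_vesicles: int = 20,
    min_fold_range: float = 3.0,
) -> ConcentrationTrend:
    """Test whether E depends on total receptor concentration.

    A constitutive dimer shows no trend of E with expression level (the
    monomer-dimer equilibrium is saturated); a significant positive slope
    indicates concentration-driven association instead.  OLS of E on total
    concentration with a t-test on the slope.
    """
    total = (
        vesicles["donor_conc"].to_numpy(dtype=float)
        + vesicles["acceptor_conc"].to_numpy(dtype=float)
    )
    e = vesicles["E"].to_numpy(dtype=float)
    if total.size < min_vesicles:
        raise ValueError(f"need >= {min_vesicles} vesicles")
    positive = total[total > 0]
    if positive.max() / positive.min() < min_fold_range:
        raise ValueError(
            f"concentration range must span >= {min_fold_range}-fold"
        )
    res = stats.linregress(total, e)
    return ConcentrationTrend(
        slope=float(res.slope),
        se_slope=float(res.stderr),
        p=float(res.pvalue),
        constitutive=bool(res.pvalue >= alpha),
    )


def summarize_vesicles(
    vesicles: pd.DataFrame,
    condition: str = "",
    r0: float = DEFAULT_R0_A,
    xa_min: float = DEFAULT_XA_MIN,
    bin_width: float | None = None,
) -> FretSummary:
    """Full per-condition summary: E_tilde Gaussian mean, SE and distance.

    The distance SE is propagated from the Gaussian mean's SE with the
    functional approach.
    """
    table = intrinsic_fret(vesicles, xa_min=xa_min)
    values = table.loc[table["included"], "E_tilde"].to_numpy(dtype=float)
    fit = fit_intrinsic_histogram(values, bin_width=bin_width)
    lo, hi = E_TILDE_PHYSICAL
    if not lo < fit.m < 1.0:
        raise ValueError(
            f"mean intrinsic FRET {fit.m:.3f} outside (0, 1); no distance defined"
        )
    distance = separation_distance(fit.m, r0=r0)
    se_d = propagate_error(
        lambda p: separation_distance(float(np.clip(p[0], 1e-9, 1 - 1e-9)), r0=r0),
        [fit.m],
        [fit.se_m],
        method="functional",
    )
    return FretSummary(
        condition=condition,
        n_vesicles=int(table["included"].sum()),
        n_excluded=int((~table["included"]).sum()),
        gaussian=fit,
        e_tilde_mean=fit.m,
        se_e_tilde=fit.se_m,
        distance_A=distance,
        se_distance_A=se_d,
        r0_A=r0,
    )
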