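"""Scaling and fitting of western-blot dose-response curves.

Band intensities from different gels are not on a common scale: each gel has
an unknown multiplicative factor (exposure, transfer efficiency, antibody
batch).  The scaling protocol makes curves globally comparable:

1. acquire >= 3 independent dose-response gels per ligand;
2. scale each gel's curve so its maximum band is 1 (``scale_within_gel``);
3. average the per-gel curves and reset the maximum mean to 1
   (``average_replicates``);
4. re-run the maximal samples of all ligands together on one "gluing gel";
5. average the gluing-gel lanes per ligand and normalize by the highest
   ligand average (``glue_coefficients``);
6. multiply each averaged curve by its ligand's coefficient
   (``glue_scale``) — the full agonist keeps max 1, partial agonists are
   scaled down accordingly.

Abundance-type readouts (receptor level, collagen content) decrease with
ligand; they are converted to loss curves with ``loss_transform`` (baseline
at zero ligand set to 1, loss = 1 - scaled value).

Scaled curves are fitted to a rectangular hyperbola (Hill equation with
coefficient fixed at 1)

    response(x) = x * Etop / (x + EC50)

after truncating each curve at the highest concentration whose response is
within 10% of the curve maximum (western-blot errors average 5-10%, and some
ligands show a genuine decline at high dose that the hyperbola cannot
describe).  The fit is Levenberg-Marquardt least squares, weighted by the
inverse square of the per-point SEM.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "HillFit",
    "hill",
    "validate_band_table",
    "scale_within_gel",
    "average_replicates",
    "glue_coefficients",
    "glue_scale",
    "loss_transform",
    "truncate_for_fit",
    "fit_hill",
    "fit_response_table",
]

#: long-format band-intensity table columns
BAND_COLUMNS = ["response_name", "ligand", "gel_id", "concentration_M", "replicate", "intensity"]
#: gluing-gel table columns
GLUE_COLUMNS = ["ligand", "replicate", "intensity"]

CURVE_KEY = ["response_name", "ligand"]
GEL_KEY = CURVE_KEY + ["gel_id"]

#: keep points whose mean response is within this fraction of the maximum
TRUNCATION_FRACTION = 0.10


def hill(x, etop, ec50):
    """Rectangular hyperbola: x*Etop/(x+EC50); passes through the origin."""
    x = np.asarray(x, dtype=float)
    return x * etop / (x + ec50)


@dataclasses.dataclass
class HillFit:
    """Best-fit efficacy/potency of one dose-response curve.

    The Hill coefficient is fixed at 1 and is not a parameter.  Standard
    errors come from the weighted-fit covariance scaled by reduced
    chi-square.
    """

    etop: float
    ec50: float
    se_etop: float = float("nan")
    se_ec50: float = float("nan")
    n_points: int = 0
    truncation_conc: float = float("nan")
    converged: bool = True
    weighted: bool = False

    @property
    def valid(self) -> bool:
        return self.converged and self.etop > 0 and self.ec50 > 0


def validate_band_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in BAND_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"band table missing columns: {missing}")
    if (table["concentration_M"] < 0).any():
        raise ValueError("negative ligand concentration")
    if (table["intensity"] < 0).any():
        raise ValueError("negative band intensity")
    return table


def scale_within_gel(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each gel's curve by its own maximum band intensity.

    Idempotent; errors on an all-zero gel.
    """
    table = validate_band_table(table).copy()

    def _scale(group: pd.DataFrame) -> pd.DataFrame:
        peak = group["intensity"].max()
        if peak <= 0:
            gel = group.name
            raise ValueError(f"gel {gel} has no positive band intensity")
        group = group.copy()
        group["intensity"] = group["intensity"] / peak
        return group

    out = (
        table.groupby(GEL_KEY, group_keys=False, sort=False)[table.columns]
        .apply(_scale)
        .reset_index(drop=True)
    )
    out.attrs["scale_state"] = "within_gel"
    return out


def _align_concentrations(values: np.ndarray, tol: float) -> np.ndarray:
    """Merge concentrations equal within relative tolerance onto one grid."""
    if tol <= 0:
        return values
    uniq = np.unique(values)
    groups: list[list[float]] = [[uniq[0]]]
    for c in uniq[1:]:
        ref = groups[-1][-1]
        if ref == 0:
            same = c == 0
        else:
            same = abs(c - ref) <= tol * ref
        if same:
            groups[-1].append(c)
        else:
            groups.append([c])
    mapping = {c: float(np.mean(g)) for g in groups for c in g}
    return np.array([mapping[c] for c in values])


def average_replicates(
    table: pd.DataFrame,
    align_tol: float = 0.01,
    renormalize: bool = True,
) -> pd.DataFrame:
    """Average within-gel-scaled curves over gels; mean +/- SEM per dose.

    Gels must share the concentration grid; concentrations within
    ``align_tol`` relative tolerance are merged, anything further apart on
    an otherwise-shared grid is left as its own dose.  With ``renormalize``
    the maximum mean is reset to 1 and the SEMs are scaled by the same
    factor.  A single gel yields SEM = NaN with a warning.
    """
    table = table.copy()
    rows = []
    for (response, ligand), group in table.groupby(CURVE_KEY, sort=False):
        group = group.copy()
        group["concentration_M"] = _align_concentrations(
            group["concentration_M"].to_numpy(dtype=float), align_tol
        )
        n_gels = group["gel_id"].nunique()
        if n_gels < 2:
            warnings.warn(
                f"{response}/{ligand}: single gel, SEM undefined", stacklevel=2
            )
        agg = (
            group.groupby("concentration_M")["intensity"]
            .agg(["mean", "sem", "count"])
            .reset_index()
            .rename(columns={"count": "n"})
        )
        if renormalize:
            factor = agg["mean"].max()
            if factor <= 0:
                raise ValueError(f"{response}/{ligand}: non-positive curve maximum")
            agg["mean"] = agg["mean"] / factor
            agg["sem"] = agg["sem"] / factor
        agg.insert(0, "ligand", ligand)
        agg.insert(0, "response_name", response)
        rows.append(agg)
    out = pd.concat(rows, ignore_index=True)
    out.attrs["scale_state"] = "averaged"
    return out


def glue_coefficients(glue: pd.DataFrame) -> pd.Series:
    """Per-ligand global scale factors from the gluing gel.

    The maximal-response samples of every ligand are re-run together on one
    gel; each ligand's lanes are averaged and divided by the highest ligand
    average, so the strongest ligand gets coefficient 1.
    """
    missing = [c for c in GLUE_COLUMNS if c not in glue.columns]
    if missing:
        raise ValueError(f"glue table missing columns: {missing}")
    means = glue.groupby("ligand")["intensity"].mean()
    return means / means.max()


def glue_scale(averaged: pd.DataFrame, glue: pd.DataFrame) -> pd.DataFrame:
    """Multiply each ligand's averaged curve by its gluing-gel coefficient."""
    coeff = glue_coefficients(glue)
    ligands = set(averaged["ligand"].unique())
    absent = ligands - set(coeff.index)
    if absent:
        raise ValueError(f"ligand(s) missing from glue table: {sorted(absent)}")
    out = averaged.copy()
    factors = out["ligand"].map(coeff)
    out["mean"] = out["mean"] * factors
    out["sem"] = out["sem"] * factors
    out.attrs["scale_state"] = "global"
    return out


def loss_transform(table: pd.DataFrame) -> pd.DataFrame:
    """Convert abundance curves to loss curves, per gel.

    The zero-ligand band is the baseline: it is set to 1, other bands are
    scaled accordingly, then loss = 1 - scaled value so loss at zero ligand
    is 0 and increases as abundance drops.
    """
    table = validate_band_table(table).copy()

    def _loss(group: pd.DataFrame) -> pd.DataFrame:
        base_rows = group[group["concentration_M"] == 0]
        if base_rows.empty:
            raise ValueError(f"gel {group.name}: missing zero-ligand baseline row")
        baseline = base_rows["intensity"].mean()
        if baseline <= 0:
            raise ValueError(f"gel {group.name}: non-positive baseline intensity")
        group = group.copy()
        group["intensity"] = 1.0 - group["intensity"] / baseline
        return group

    out = (
        table.groupby(GEL_KEY, group_keys=False, sort=False)[table.columns]
        .apply(_loss)
        .reset_index(drop=True)
    )
    out.attrs["scale_state"] = "loss"
    return out


def truncate_for_fit(
    conc: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, float]:
    """Index prefix keeping doses up to the last one within 10% of max(y).

    Returns (boolean keep-mask over the sorted input, truncation
    concentration).  ``conc`` must be strictly increasing.
    """
    conc = np.asarray(conc, dtype=float)
    y = np.asarray(y, dtype=float)
    if conc.size == 0:
        raise ValueError("empty dose-response curve")
    if conc.size != y.size:
        raise ValueError("conc and y must have the same length")
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    threshold = (1.0 - TRUNCATION_FRACTION) * np.max(y)
    last = int(np.max(np.nonzero(y >= threshold)[0]))
    keep = np.zeros(conc.size, dtype=bool)
    keep[: last + 1] = True
    return keep, float(conc[last])


def fit_hill(
    conc: np.ndarray,
    y: np.ndarray,
    sem: np.ndarray | None = None,
    truncation_conc: float = float("nan"),
    max_iterations: int = 100_000,
    error_model: str = "pooled_relative",
) -> HillFit:
    """Weighted Levenberg-Marquardt fit of the rectangular hyperbola.

    Weights are the inverse square of the per-point error.  How that error
    is obtained is the ``error_model``:

    pooled_relative (default)
        Blot noise is proportional to signal, so the relative error
        sqrt(mean((sem_i/y_i)^2)) is pooled over the curve and the point
        error is (pooled rel) * y_i, used as absolute sigma.  With only ~3
        gels the per-point SEMs are extremely noisy; pooling keeps the
        +/-2 SE intervals calibrated at ~95% where per-point weights drop
        to ~75% (and noisy weights also inflate the estimator variance).
    per_point
        Literal 1/sem_i^2 weights.  Zero/missing SEMs (the zero-dose
        baseline, single-gel doses) would get infinite weight; their SEM
        is replaced by the median positive SEM.  SEs are scaled by reduced
        chi-square.

    Without ``sem`` (or with no usable SEM) the fit is unweighted.  Needs
    >= 3 distinct nonzero concentrations.  Non-convergence and non-positive
    estimates are flagged, not raised.
    """
    conc = np.asarray(conc, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(conc[conc > 0]).size < 3:
        raise ValueError("need >= 3 distinct nonzero concentrations to fit")
    if error_model not in ("pooled_relative", "per_point"):
        raise ValueError("error_model must be 'pooled_relative' or 'per_point'")

    sigma = None
    absolute_sigma = False
    weighted = False
    if sem is not None:
        sem = np.asarray(sem, dtype=float).copy()
        usable = np.isfinite(sem) & (sem > 0) & (y > 0)
        if error_model == "pooled_relative" and usable.any():
            rel = float(np.sqrt(np.mean((sem[usable] / y[usable]) ** 2)))
            floor = rel * float(y[y > 0].min())
            sigma = np.where(y > 0, rel * y, floor)
            absolute_sigma = True
            weighted = True
        elif error_model == "per_point":
            bad = ~np.isfinite(sem) | (sem <= 0)
            good = sem[~bad]
            if good.size:
                sem[bad] = np.median(good)
                sigma = sem
                weighted = True

    etop0 = float(np.max(y))
    half = 0.5 * etop0
    ec50_0 = float(conc[conc > 0][np.argmin(np.abs(y[conc > 0] - half))])
    converged = True
    try:
        popt, pcov = curve_fit(
            hill,
            conc,
            y,
            p0=(etop0, ec50_0),
            sigma=sigma,
            absolute_sigma=absolute_sigma,
            method="lm",
            maxfev=max_iterations,
        )
        perr = np.sqrt(np.diag(pcov))
        if not np.all(np.isfinite(perr)):
            converged = False
    except RuntimeError:
        converged = False
        popt = (np.nan, np.nan)
        perr = (np.nan, np.nan)
    return HillFit(
        etop=float(popt[0]),
        ec50=float(popt[1]),
        se_etop=float(perr[0]),
        se_ec50=float(perr[1]),
        n_points=conc.size,
        truncation_conc=truncation_conc,
        converged=converged,
        weighted=weighted,
    )


def fit_response_table(
    averaged: pd.DataFrame, error_model: str = "pooled_relative"
) -> pd.DataFrame:
    """Truncate and fit every (response, ligand) curve of an averaged table.

    Returns a fits table with one row per curve (long format, CSV-ready).
    """
    rows = []
    for (response, ligand), group in averaged.groupby(CURVE_KEY, sort=False):
        group = group.sort_values("concentration_M")
        conc = group["concentration_M"].to_numpy(dtype=float)
        y = group["mean"].to_numpy(dtype=float)
        sem = group["sem"].to_numpy(dtype=float) if "sem" in group else None
        keep, trunc = truncate_for_fit(conc, y)
        fit = fit_hill(
            conc[keep],
            y[keep],
            sem[keep] if sem is not None else None,
            truncation_conc=trunc,
            error_model=error_model,
        )
        rows.append(
            {
                "response_name": response,
                "ligand": ligand,
                "etop": fit.etop,
                "se_etop": fit.se_etop,
                "ec50_M": fit.ec50,
                "se_ec50_M": fit.se_ec50,
                "n_points": fit.n_points,
                "truncation_conc_M": fit.truncation_conc,
                "converged": fit.converged,
                "weighted": fit.weighted,
            }
        )
    return pd.DataFrame(rows)
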