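"""Ligand-bias coefficients and their statistics.

A ligand's relative activity for a response is Etop/EC50 (efficacy over
potency).  The per-ligand transduction coefficient for a pair of responses is

    beta' = log10[ (Etop/EC50)_num / (Etop/EC50)_den ]

and the bias coefficient of a ligand against a reference ligand is the
difference of transduction coefficients,

    beta = beta'(ligand) - beta'(reference),

a delta-delta-log quantity: any common rescaling of a response across ligands
cancels, so beta is immune to the arbitrary units of each readout.  beta = 0
means both responses are engaged in the same proportion by both ligands;
beta != 0 means one ligand preferentially drives one of the responses.

Uncertainties are propagated from the Hill-fit standard errors by the
functional approach (one-at-a-time perturbation), by first-order
derivatives, or by Monte Carlo.  Significance of beta' differences across
ligands is assessed with a one-way ANOVA reconstructed from summary
statistics (mean, SEM, n).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .dose_response import HillFit

__all__ = [
    "BiasResult",
    "SummaryGroup",
    "AnovaResult",
    "SlopeComparison",
    "propagate_error",
    "beta_prime",
    "beta",
    "anova_summary",
    "compare_linear_slopes",
]

ERROR_METHODS = ("functional", "functional_symmetric", "derivative", "montecarlo")


@dataclasses.dataclass
class BiasResult:
    ligand: str
    reference: str
    response_num: str
    response_den: str
    beta: float
    se_beta: float
    beta_prime_ligand: float
    se_beta_prime_ligand: float
    beta_prime_reference: float
    se_beta_prime_reference: float
    method: str
    ordering_note: str = "numerator/denominator as given by caller; never inferred from labels"


@dataclasses.dataclass
class SummaryGroup:
    """Summary statistics of one group entering the ANOVA."""

    label: str
    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label}: need n >= 2")
        if self.sem <= 0:
            raise ValueError(f"group {self.label}: SEM must be positive")


@dataclasses.dataclass
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int


@dataclasses.dataclass
class SlopeComparison:
    slope1: float
    slope2: float
    t: float
    p: float
    df: int


def propagate_error(
    f: Callable[[np.ndarray], float],
    values: Sequence[float],
    ses: Sequence[float],
    method: str = "functional",
    n_draws: int = 100_000,
    seed: int | None = None,
) -> float:
    """Standard error of ``f(values)`` given per-parameter standard errors.

    functional
        One-at-a-time positive perturbation:
        SE = sqrt(sum_i [f(x + dx_i e_i) - f(x)]^2).
    functional_symmetric
        Same but with the symmetric difference [f(x+dx) - f(x-dx)]/2 per
        parameter; for strongly curved f (log at large relative error) this
        tracks the Monte Carlo answer where the one-sided variant
        under-estimates.
    derivative
        First-order propagation with central-difference partials:
        SE = sqrt(sum_i [df/dx_i * dx_i]^2).
    montecarlo
        Standard deviation of f over independent normal draws (seeded).
        Draws at which f is undefined (NaN) are dropped.
    """
    values = np.asarray(values, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if values.shape != ses.shape:
        raise ValueError("values and ses must have the same length")
    if method not in ERROR_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {ERROR_METHODS}")

    f0 = float(f(values))
    if not math.isfinite(f0):
        raise ValueError("f is undefined at the central values")

    if method == "functional":
        total = 0.0
        for i, dx in enumerate(ses):
            if dx == 0:
                continue
            x = values.copy()
            x[i] += dx
            fi = float(f(x))
            if not math.isfinite(fi):
                raise ValueError(f"f undefined when perturbing parameter {i}")
            total += (fi - f0) ** 2
        return math.sqrt(total)

    if method == "functional_symmetric":
        total = 0.0
        for i, dx in enumerate(ses):
            if dx == 0:
                continue
            xp, xm = values.copy(), values.copy()
            xp[i] += dx
            xm[i] -= dx
            fp, fm = float(f(xp)), float(f(xm))
            if not (math.isfinite(fp) and math.isfinite(fm)):
                raise ValueError(f"f undefined when perturbing parameter {i}")
            total += ((fp - fm) / 2.0) ** 2
        return math.sqrt(total)

    if method == "derivative":
        total = 0.0
        for i, dx in enumerate(ses):
            if dx == 0:
                continue
            h = 1e-6 * abs(values[i]) if values[i] != 0 else 1e-6 * dx
            xp, xm = values.copy(), values.copy()
            xp[i] += h
            xm[i] -= h
            deriv = (float(f(xp)) - float(f(xm))) / (2 * h)
            if not math.isfinite(deriv):
                raise ValueError(f"f undefined when perturbing parameter {i}")
            total += (deriv * dx) ** 2
        return math.sqrt(total)

    rng = np.random.default_rng(seed)
    draws = rng.normal(values, ses, size=(n_draws, values.size))
    out = np.array([f(d) for d in draws], dtype=float)
    out = out[np.isfinite(out)]
    if out.size < n_draws // 2:
        raise ValueError("f undefined at more than half of the Monte Carlo draws")
    return float(out.std())


def _check_fit(fit: HillFit, name: str) -> None:
    if not (fit.etop > 0 and fit.ec50 > 0):
        raise ValueError(f"{name}: Etop and EC50 must be positive")


def _log_activity_ratio(params: np.ndarray) -> float:
    """log10[(Etop_n/EC50_n) * (EC50_d/Etop_d)] with params packed as
    (Etop_n, EC50_n, Etop_d, EC50_d)."""
    en, cn, ed, cd = params
    if min(en, cn, ed, cd) <= 0:
        return float("nan")
    return math.log10(en / cn * cd / ed)


def beta_prime(
    fit_num: HillFit,
    fit_den: HillFit,
    method: str = "functional",
    seed: int | None = None,
) -> tuple[float, float]:
    """Transduction coefficient beta' and its propagated SE for one ligand."""
    _check_fit(fit_num, "numerator fit")
    _check_fit(fit_den, "denominator fit")
    values = [fit_num.etop, fit_num.ec50, fit_den.etop, fit_den.ec50]
    ses = [fit_num.se_etop, fit_num.se_ec50, fit_den.se_etop, fit_den.se_ec50]
    ses = [0.0 if not math.isfinite(s) else s for s in ses]
    value = _log_activity_ratio(np.asarray(values, dtype=float))
    se = propagate_error(_log_activity_ratio, values, ses, method=method, seed=seed)
    return value, se


def beta(
    ligand_fit_num: HillFit,
    ligand_fit_den: HillFit,
    reference_fit_num: HillFit,
    reference_fit_den: HillFit,
    ligand: str = "ligand",
    reference: str = "reference",
    response_num: str = "num",
    response_den: str = "den",
    method: str = "functional",
    seed: int | None = None,
) -> BiasResult:
    """Bias coefficient beta = beta'(ligand) - beta'(reference).

    The SE of beta combines all eight parameter uncertainties in a single
    propagation (not by adding the two beta' errors in quadrature, which
    would be equivalent only for independent first-order terms).
    """
    for fit, name in [
        (ligand_fit_num, "ligand numerator"),
        (ligand_fit_den, "ligand denominator"),
        (reference_fit_num, "reference numerator"),
        (reference_fit_den, "reference denominator"),
    ]:
        _check_fit(fit, name)

    def _beta(params: np.ndarray) -> float:
        return _log_activity_ratio(params[:4]) - _log_activity_ratio(params[4:])

    values = []
    ses = []
    for fit in (ligand_fit_num, ligand_fit_den, reference_fit_num, reference_fit_den):
        values += [fit.etop, fit.ec50]
        ses += [
            fit.se_etop if math.isfinite(fit.se_etop) else 0.0,
            fit.se_ec50 if math.isfinite(fit.se_ec50) else 0.0,
        ]
    bpl, se_bpl = beta_prime(ligand_fit_num, ligand_fit_den, method=method, seed=seed)
    bpr, se_bpr = beta_prime(
        reference_fit_num, reference_fit_den, method=method, seed=seed
    )
    value = _beta(np.asarray(values, dtype=float))
    se = propagate_error(_beta, values, ses, method=method, seed=seed)
    return BiasResult(
        ligand=ligand,
        reference=reference,
        response_num=response_num,
        response_den=response_den,
        beta=value,
        se_beta=se,
        beta_prime_ligand=bpl,
        se_beta_prime_ligand=se_bpl,
        beta_prime_reference=bpr,
        se_beta_prime_reference=se_bpr,
        method=method,
    )


def anova_summary(groups: Sequence[SummaryGroup]) -> AnovaResult:
    """One-way ANOVA reconstructed from per-group (mean, SEM, n).

    Between-group and within-group sums of squares are exactly those of the
    raw-data ANOVA, because SS_within = sum (n_i - 1) sd_i^2 with
    sd_i^2 = sem_i^2 * n_i.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups], dtype=float)
    variances = np.array([(g.sem**2) * g.n for g in groups], dtype=float)
    total_n = ns.sum()
    grand = float((ns * means).sum() / total_n)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * variances).sum())
    df_between = len(groups) - 1
    df_within = int(total_n) - len(groups)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f = math.inf if ms_between > 0 else 0.0
    else:
        f = ms_between / ms_within
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(f=float(f), p=p, df_between=df_between, df_within=df_within)


def compare_linear_slopes(
    x1: np.ndarray, y1: np.ndarray, x2: np.ndarray, y2: np.ndarray
) -> SlopeComparison:
    """Two-sided t-test on the difference of two OLS slopes.

    Residual variances are pooled over both regressions
    (df = n1 + n2 - 4); used for near-linear readouts such as viability or
    caspase activity versus ligand concentration.
    """
    x1, y1, x2, y2 = (np.asarray(a, dtype=float) for a in (x1, y1, x2, y2))
    for x, y in ((x1, y1), (x2, y2)):
        if x.size < 3 or x.size != y.size:
            raise ValueError("each series needs >= 3 (x, y) points")
        if np.ptp(x) == 0:
            raise ValueError("degenerate x: no spread")

    def _ols(x, y):
        sxx = float(((x - x.mean()) ** 2).sum())
        slope = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
        intercept = float(y.mean() - slope * x.mean())
        sse = float(((y - intercept - slope * x) ** 2).sum())
        return slope, sse, sxx

    b1, sse1, sxx1 = _ols(x1, y1)
    b2, sse2, sxx2 = _ols(x2, y2)
    df = x1.size + x2.size - 4
    pooled = (sse1 + sse2) / df
    se_diff = math.sqrt(pooled * (1.0 / sxx1 + 1.0 / sxx2))
    if se_diff == 0:
        t = 0.0 if b1 == b2 else math.inf * np.sign(b1 - b2)
    else:
        t = (b1 - b2) / se_diff
    p = float(2 * stats.t.sf(abs(t), df))
    return SlopeComparison(slope1=b1, slope2=b2, t=float(t), p=p, df=df)
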