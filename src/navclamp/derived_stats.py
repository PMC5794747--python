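"""Derived biophysical comparisons and group statistics.

Window current (the overlap of activation and availability), midpoint
shifts, density reductions, Arrhenius temperature-sensitivity fits with
ANCOVA slope comparison, unpaired t-tests, and mean +/- SEM group
summaries in the layout of the parameter tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .gating_model import GAS_CONSTANT_KCAL, VariantParams, boltzmann
from .trace_analysis import BoltzmannFit

__all__ = [
    "WindowResult",
    "ArrheniusFit",
    "GroupSummary",
    "window_curve",
    "window_fold_change",
    "v_shift",
    "percent_reduction",
    "arrhenius_fit",
    "ancova_slopes",
    "ttest_unpaired",
    "summarize",
    "significance_stars",
]

BoltzLike = Union[BoltzmannFit, tuple[float, float]]


@dataclass
class WindowResult:
    """Window-current open-probability curve and its area."""

    voltages: np.ndarray
    probability: np.ndarray
    area: float  # probability * mV
    peak_probability: float
    peak_voltage: float
    bounds: tuple[float, float]
    C: float


@dataclass
class ArrheniusFit:
    """Linear fit of ln(rate) against 1/T(K); Ea = -slope * R (kcal/mol)."""

    slope: float
    intercept: float
    Ea: float
    rates_by_T: dict[float, float]
    p_vs_reference: Optional[float] = None


def _v12_k(fit: BoltzLike) -> tuple[float, float]:
    if isinstance(fit, BoltzmannFit):
        return fit.v12, fit.k
    v12, k = fit
    return float(v12), float(k)


def window_curve(
    act: BoltzLike,
    inact: BoltzLike,
    C: float = 0.0,
    bounds: tuple[float, float] = (-150.0, 50.0),
    step: float = 0.1,
) -> WindowResult:
    """Open probability within the activation/availability overlap window.

    P(V) = 1/(1 + exp((V1/2act - V)/k_act)) * ((1 - C)/(1 + exp((V - V1/2inact)/k_inact)) + C)

    C is the persistent (non-inactivating) pedestal fraction; the default
    0 reflects the absence of persistent current.  The area is computed by
    trapezoid integration on the voltage grid.
    """
    if not 0.0 <= C <= 1.0:
        raise ValueError("pedestal C must lie in [0, 1]")
    av, ak = _v12_k(act)
    iv, ik = _v12_k(inact)
    V = np.arange(bounds[0], bounds[1] + step / 2, step)
    p = boltzmann(V, av, ak, "rising") * ((1.0 - C) * boltzmann(V, iv, ik, "falling") + C)
    idx = int(np.argmax(p))
    return WindowResult(
        voltages=V,
        probability=p,
        area=float(np.trapezoid(p, V)),
        peak_probability=float(p[idx]),
        peak_voltage=float(V[idx]),
        bounds=bounds,
        C=C,
    )


def window_fold_change(
    variant: WindowResult, reference: WindowResult, metric: str = "area"
) -> float:
    """Fold change of the window current, variant relative to reference.

    ``metric="area"`` (default) is the ratio of trapezoid areas;
    ``"peak"`` compares peak probabilities instead.
    """
    if variant.C != reference.C or variant.bounds != reference.bounds:
        raise ValueError("window results must share pedestal C and bounds")
    if metric == "area":
        if reference.area == 0:
            raise ZeroDivisionError("reference window area is zero")
        return variant.area / reference.area
    if metric == "peak":
        return variant.peak_probability / reference.peak_probability
    raise ValueError("metric must be 'area' or 'peak'")


def v_shift(mutant_v12: float, wt_v12: float) -> float:
    """Signed midpoint shift (mV), hyperpolarizing shifts negative."""
    return round(mutant_v12 - wt_v12, 1)


def percent_reduction(test: float, reference: float) -> int:
    """Percent reduction of test relative to reference, rounded to integer."""
    if reference == 0:
        raise ZeroDivisionError("reference quantity is zero")
    return int(round(100.0 * (1.0 - test / reference)))


def arrhenius_fit(
    taus_by_T: dict[float, float], reference: Optional[dict[float, float]] = None
) -> ArrheniusFit:
    """Energy of activation from time constants at several temperatures.

    Ordinary least squares of ln(1/tau) on 1/T(K); Ea = -slope * R in
    kcal/mol (positive when cooling slows the process).  If ``reference``
    is given, an ANCOVA slope comparison against it fills
    ``p_vs_reference``.
    """
    if len(taus_by_T) < 3:
        raise ValueError("need time constants at >= 3 temperatures")
    T = np.array(sorted(taus_by_T))
    inv_t = 1.0 / (T + 273.15)
    ln_rate = np.log([1.0 / taus_by_T[t] for t in T])
    slope, intercept = np.polyfit(inv_t, ln_rate, 1)
    p = None
    if reference is not None:
        a = [(1.0 / (t + 273.15), np.log(1.0 / tau)) for t, tau in taus_by_T.items()]
        b = [(1.0 / (t + 273.15), np.log(1.0 / tau)) for t, tau in reference.items()]
        p = ancova_slopes(a, b)
    return ArrheniusFit(
        slope=float(slope),
        intercept=float(intercept),
        Ea=float(-slope * GAS_CONSTANT_KCAL),
        rates_by_T={float(t): float(1.0 / taus_by_T[t]) for t in T},
        p_vs_reference=p,
    )


def ancova_slopes(
    group_a: Sequence[tuple[float, float]], group_b: Sequence[tuple[float, float]]
) -> float:
    """Slope-homogeneity test between two Arrhenius point clouds.

    Points are (1/T_K, ln rate) pairs.  Fits the pooled linear model
    ln_rate ~ invT * group and returns the p-value of the group x invT
    interaction term, the standard regression formulation of ANCOVA slope
    comparison.
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("need >= 3 points per group")
    df = pd.DataFrame(
        {
            "invT": [p[0] for p in group_a] + [p[0] for p in group_b],
            "y": [p[1] for p in group_a] + [p[1] for p in group_b],
            "group": [0] * len(group_a) + [1] * len(group_b),
        }
    )
    # center invT for numerical conditioning (1/T ~ 3.4e-3)
    df["x"] = (df["invT"] - df["invT"].mean()) * 1e3
    model = smf.ols("y ~ x * group", data=df).fit()
    return float(model.pvalues["x:group"])


def ttest_unpaired(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided unpaired Student's t-test p-value (equal variances)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.pvalue)


def significance_stars(p: float) -> str:
    """Asterisk notation at the 0.05 / 0.01 / 0.001 thresholds."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class GroupSummary:
    """Mean +/- SEM per variant and quantity, with WT comparisons."""

    table: pd.DataFrame  # index (variant, quantity); columns mean/sem/n/p_vs_ref/stars
    reference: str

    def mean(self, variant: str, quantity: str) -> float:
        return float(self.table.loc[(variant, quantity), "mean"])

    def sem(self, variant: str, quantity: str) -> float:
        return float(self.table.loc[(variant, quantity), "sem"])


def summarize(cells: pd.DataFrame, reference: str = "WT") -> GroupSummary:
    """Group summary of per-cell measurements.

    ``cells`` holds one row per cell with a ``variant`` column and one
    numeric column per measured quantity.  Produces mean, SEM (sd/sqrt(n),
    NaN for n=1), n, and the unpaired-t p-value against the reference
    variant with its star notation.
    """
    if cells.empty:
        raise ValueError("no cells to summarize")
    quantities = [c for c in cells.columns if c not in ("variant", "cell_id")]
    rows = []
    for variant, grp in cells.groupby("variant", sort=False):
        for q in quantities:
            vals = grp[q].dropna().to_numpy(dtype=float)
            n = len(vals)
            if n == 0:
                continue
            mean = float(np.mean(vals))
            sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
            p = np.nan
            if variant != reference and reference in set(cells["variant"]):
                ref_vals = cells.loc[cells["variant"] == reference, q].dropna()
                if n >= 2 and len(ref_vals) >= 2:
                    p = ttest_unpaired(vals, ref_vals)
            rows.append(
                {
                    "variant": variant,
                    "quantity": q,
                    "mean": mean,
                    "sem": sem,
                    "n": n,
                    "p_vs_ref": p,
                    "stars": significance_stars(p) if np.isfinite(p) else "",
                }
            )
    table = pd.DataFrame(rows).set_index(["variant", "quantity"])
    return GroupSummary(table=table, reference=reference)
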