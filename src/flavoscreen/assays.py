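"""Antioxidant assay analysis: % scavenging, 4PL IC50, FRAP, ANOVA/Tukey.

Radical-scavenging activity is the fractional absorbance drop of the
radical solution caused by the test compound:

    activity% = 100 * (A_control - A_sample) / A_control

Dose-response curves use the four-parameter logistic (4PL) model

    y(x) = d + (a - d) / (1 + (x / c)^b)

where ``a`` is the zero-dose response, ``d`` the infinite-dose asymptote,
``c`` the inflection concentration, and ``b`` a Hill-type slope. The IC50
is the 50%-activity crossing of the fitted curve (which equals ``c`` under
0/100 asymptotes), solved analytically. Replicates are fitted pooled; the
IC50 SD comes from per-replicate refits. FRAP reducing power is calibrated
against a Trolox standard line and reported as umol Trolox equivalents per
gram. Group comparisons use one-way ANOVA with Tukey's HSD post hoc test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DoseResponseSeries",
    "FourPLFit",
    "FrapResult",
    "AnovaTukeyResult",
    "DEFAULT_CONCENTRATIONS_UM",
    "percent_activity",
    "four_pl",
    "fit_four_pl",
    "estimate_ic50",
    "frap_trolox_equivalents",
    "anova_tukey",
]

#: Assay concentration series, uM.
DEFAULT_CONCENTRATIONS_UM: tuple[float, ...] = (3.125, 6.25, 12.5, 25.0, 50.0, 100.0)


@dataclass
class DoseResponseSeries:
    """Concentrations (uM) by replicate activity matrix for one compound."""

    compound: str
    concentrations: np.ndarray           # (n_conc,)
    activities: np.ndarray               # (n_conc, n_reps), percent
    truth: dict | None = None            # generator metadata, if synthetic

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.activities = np.atleast_2d(np.asarray(self.activities, dtype=float))
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if len(np.unique(self.concentrations)) < 2:
            raise ValueError("need at least 2 distinct concentrations")
        if self.activities.shape[0] != self.concentrations.size:
            raise ValueError("activities must have one row per concentration")

    @property
    def n_replicates(self) -> int:
        return self.activities.shape[1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, conc in enumerate(self.concentrations):
            for r in range(self.n_replicates):
                rows.append({
                    "compound": self.compound,
                    "concentration_um": conc,
                    "replicate": r + 1,
                    "activity_percent": self.activities[i, r],
                })
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, compound: str | None = None
                   ) -> "DoseResponseSeries":
        if compound is not None:
            df = df[df["compound"] == compound]
        else:
            compounds = df["compound"].unique()
            if len(compounds) != 1:
                raise ValueError("frame holds several compounds; pass one")
            compound = compounds[0]
        pivot = df.pivot_table(index="concentration_um", columns="replicate",
                               values="activity_percent")
        return cls(compound, pivot.index.to_numpy(), pivot.to_numpy())


@dataclass(frozen=True)
class FourPLFit:
    a: float           # zero-dose asymptote, %
    d: float           # infinite-dose asymptote, %
    c: float           # inflection concentration, uM
    b: float           # slope
    ic50: float        # uM; nan when the curve never crosses 50%
    ic50_sd: float     # uM; nan without replicate refits
    r_squared: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("inflection concentration must be positive")
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValueError("r_squared out of [0, 1]")


@dataclass(frozen=True)
class FrapResult:
    te_per_gram: float       # umol TE / g
    slope: float
    intercept: float
    calibration_r_squared: float


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame = field(repr=False)

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        hits = self.pairwise[self.pairwise["p_adj"] < alpha]
        return list(zip(hits["group1"], hits["group2"]))


def percent_activity(a_control: float, a_sample: float) -> float:
    """Radical-scavenging activity (%) from control and sample absorbances."""
    if a_control <= 0:
        raise ValueError("control absorbance must be positive")
    return 100.0 * (a_control - a_sample) / a_control


def four_pl(x, a: float, d: float, c: float, b: float):
    """Four-parameter logistic response at concentration(s) x."""
    x = np.asarray(x, dtype=float)
    return d + (a - d) / (1.0 + (x / c) ** b)


class FitError(RuntimeError):
    """4PL fit failed to converge or the data are degenerate."""


def _fit_pooled(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Bounded 4PL least squares from 5 deterministic starts; best SSE wins."""
    y_lo, y_hi = float(y.min()), float(y.max())
    if y_hi - y_lo < 1.0:
        raise FitError("degenerate dose-response data: activity range < 1%")
    x_lo, x_hi = float(x.min()), float(x.max())
    bounds = (
        [y_lo - 50.0, y_lo - 50.0, x_lo * 0.01, 0.1],
        [y_hi + 50.0, y_hi + 50.0, x_hi * 100.0, 20.0],
    )
    mid = np.sqrt(x_lo * x_hi)
    starts = [
        (y_lo, y_hi, mid, 1.0),
        (y_lo, y_hi, mid, 2.0),
        (y_lo, y_hi, x_lo, 0.5),
        (y_lo, y_hi, x_hi, 1.0),
        (y_lo, y_hi, np.median(np.unique(x)), 1.3),
    ]
    best: tuple[float, np.ndarray] | None = None
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                four_pl, x, y, p0=p0, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((four_pl(x, *popt) - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise FitError("4PL fit did not converge from any initialization")
    sse, popt = best
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 0.0
    return popt, max(0.0, min(1.0, r2))


def estimate_ic50(fit: FourPLFit | Sequence[float]) -> float:
    """Concentration at which the fitted 4PL curve crosses 50% activity.

    Solved in closed form: x = c * ((a - d) / (50 - d) - 1)^(1/b). Raises
    ``ValueError`` when 50% lies outside the open asymptote interval.
    """
    if isinstance(fit, FourPLFit):
        a, d, c, b = fit.a, fit.d, fit.c, fit.b
    else:
        a, d, c, b = fit
    lo, hi = min(a, d), max(a, d)
    if not (lo < 50.0 < hi):
        raise ValueError(
            f"fitted curve (asymptotes {a:.2f}, {d:.2f}) never crosses 50%"
        )
    ratio = (a - d) / (50.0 - d) - 1.0
    return float(c * ratio ** (1.0 / b))


def fit_four_pl(series: DoseResponseSeries) -> FourPLFit:
    """Fit the 4PL model to pooled replicates of a dose-response series.

    IC50 comes from the analytic 50% crossing of the pooled fit; its SD is
    the standard deviation of IC50s from per-replicate refits (nan if fewer
    than 2 replicates or any replicate refit fails to cross 50%).
    """
    if len(np.unique(series.concentrations)) < 4:
        raise ValueError("need at least 4 distinct concentrations for a 4PL fit")
    x = np.repeat(series.concentrations, series.n_replicates)
    y = series.activities.ravel()
    popt, r2 = _fit_pooled(x, y)
    a, d, c, b = popt
    try:
        ic50 = estimate_ic50((a, d, c, b))
    except ValueError:
        ic50 = float("nan")
    ic50_sd = float("nan")
    if series.n_replicates >= 2:
        rep_ic50s = []
        for r in range(series.n_replicates):
            try:
                p_r, _ = _fit_pooled(series.concentrations,
                                     series.activities[:, r])
                rep_ic50s.append(estimate_ic50(tuple(p_r)))
            except (FitError, ValueError):
                continue
        if len(rep_ic50s) >= 2:
            ic50_sd = float(np.std(rep_ic50s, ddof=1))
    return FourPLFit(a=float(a), d=float(d), c=float(c), b=float(b),
                     ic50=ic50, ic50_sd=ic50_sd, r_squared=r2)


def frap_trolox_equivalents(
    standards: Sequence[tuple[float, float]],
    sample_abs: float,
    mass_factor: float = 1.0,
) -> FrapResult:
    """Trolox-equivalent reducing power from a FRAP calibration line.

    ``standards`` are (Trolox concentration, absorbance) pairs; the sample
    TE concentration is inverted through the OLS line and divided by
    ``mass_factor`` (grams of sample per reaction) to give umol TE / g.
    """
    if len(standards) < 3:
        raise ValueError("need at least 3 calibration standards")
    if mass_factor <= 0:
        raise ValueError("mass_factor must be positive")
    conc = np.array([s[0] for s in standards], dtype=float)
    absorb = np.array([s[1] for s in standards], dtype=float)
    if np.allclose(conc, conc[0]):
        raise ValueError("calibration standards all at one concentration")
    reg = stats.linregress(conc, absorb)
    if reg.slope == 0:
        raise ValueError("degenerate calibration: zero slope")
    te_conc = (sample_abs - reg.intercept) / reg.slope
    return FrapResult(
        te_per_gram=float(te_conc / mass_factor),
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        calibration_r_squared=float(reg.rvalue**2),
    )


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    Pairwise adjusted p-values come from the studentized-range distribution.
    The pairwise table flags significance at 0.05 and 0.001.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(arr.size < 2 for arr in arrays):
        raise ValueError("every group needs at least 2 replicates")
    if all(np.var(arr) == 0 for arr in arrays):
        raise ValueError("zero within-group variance in all groups")
    f_stat, p_val = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    rows = []
    for i, j in combinations(range(len(labels)), 2):
        p_adj = float(hsd.pvalue[i, j])
        rows.append({
            "group1": labels[i],
            "group2": labels[j],
            "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
            "p_adj": p_adj,
            "significant_0.05": p_adj < 0.05,
            "significant_0.001": p_adj < 0.001,
        })
    return AnovaTukeyResult(
        f_statistic=float(f_stat),
        p_value=float(p_val),
        pairwise=pd.DataFrame(rows),
    )
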