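"""Power-law scaling of structural properties on species richness and
connectance, and per-web residual variation (RV).

Structural properties covary strongly with S and C, so raw cross-scale
comparisons confound sampling scale with diversity and complexity.  Each
property P is regressed on log10(S) and log10(C) across the whole web
collection:

* properties bounded in [0, 1] (fractions and similarity/clustering
  means) use a quasi-binomial GLM with a logit link, which respects the
  bounds without transforming zeros and ones;
* strictly positive unbounded properties use ordinary least squares of
  log10(P), i.e. an explicit power law ``P = 10^b0 * S^b1 * C^b2``.

Residual variation is ``observed - fitted`` on the property's natural
scale: negative RV means the scaling model overestimates the property
for that web.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

from .metrics import STRUCTURAL_PROPERTIES

#: Properties bounded in [0, 1]: logit-link quasi-binomial family.
BOUNDED_PROPERTIES = (
    "Top", "Int", "Bas", "Can", "Herb", "Omn", "Loop", "MaxSim", "Clust",
)
#: Strictly positive unbounded properties: log-log least squares.
POSITIVE_PROPERTIES = ("LinkSD", "GenSD", "VulSD", "TL", "Path")

DEFAULT_FAMILIES = {p: "binomial" for p in BOUNDED_PROPERTIES}
DEFAULT_FAMILIES.update({p: "loglinear" for p in POSITIVE_PROPERTIES})

_EPS = 1e-10  # clip for link-scale intercepts of degenerate constant fits


@dataclass
class PropertyFit:
    property: str
    family: str  # "binomial" | "loglinear"
    params: np.ndarray  # intercept, coef log10(S), coef log10(C)
    fitted: pd.Series  # fitted values on the natural scale, by row index
    n: int
    degenerate: bool = False


@dataclass
class ScalingFit:
    """One regression per property over a web collection."""

    fits: dict[str, PropertyFit]

    def coefficients_frame(self) -> pd.DataFrame:
        rows = [
            {
                "property": f.property,
                "family": f.family,
                "intercept": f.params[0],
                "coef_log10_S": f.params[1],
                "coef_log10_C": f.params[2],
                "n": f.n,
                "degenerate": f.degenerate,
            }
            for f in self.fits.values()
        ]
        return pd.DataFrame(rows)


def _design(df: pd.DataFrame) -> np.ndarray:
    x = np.column_stack(
        [np.ones(len(df)), np.log10(df["S"].to_numpy(float)),
         np.log10(df["C"].to_numpy(float))]
    )
    return x


def fit_scaling(
    df: pd.DataFrame,
    properties: tuple[str, ...] | None = None,
    families: dict[str, str] | None = None,
    min_webs: int = 10,
) -> ScalingFit:
    """Fit ``P ~ log10(S) + log10(C)`` for each property across webs.

    ``df`` needs columns ``S`` and ``C`` plus one column per property;
    rows with missing values are dropped per property.  Properties with
    fewer than ``min_webs`` usable rows are skipped with a warning.
    """
    if (df["S"] <= 0).any() or (df["C"] <= 0).any():
        raise ValueError("S and C must be positive")
    fam = dict(DEFAULT_FAMILIES)
    if families:
        fam.update(families)
    if properties is None:
        properties = tuple(
            p for p in df.columns if p in fam and p not in ("S", "C")
        )
    full_x = _design(df)
    if np.linalg.matrix_rank(full_x) < 3:
        raise ValueError("degenerate predictor matrix (S or C has no variation)")

    fits: dict[str, PropertyFit] = {}
    for prop in properties:
        family = fam.get(prop)
        if family is None:
            raise ValueError(f"no family known for property {prop!r}")
        y = pd.to_numeric(df[prop], errors="coerce")
        mask = y.notna().to_numpy()
        if family == "loglinear":
            mask &= (y > 0).fillna(False).to_numpy()
        n = int(mask.sum())
        if n < min_webs:
            warnings.warn(
                f"{prop}: only {n} usable webs (< {min_webs}); fit skipped",
                stacklevel=2,
            )
            continue
        yv = y.to_numpy(float)[mask]
        x = full_x[mask]
        idx = df.index[mask]
        if np.ptp(yv) == 0.0:
            const = yv[0]
            if family == "binomial":
                b0 = float(logit(np.clip(const, _EPS, 1 - _EPS)))
            else:
                b0 = float(np.log10(const))
            fits[prop] = PropertyFit(
                property=prop, family=family,
                params=np.array([b0, 0.0, 0.0]),
                fitted=pd.Series(const, index=idx), n=n, degenerate=True,
            )
            continue
        if family == "binomial":
            with warnings.catch_warnings():
                # continuous proportions are intended (quasi-binomial)
                warnings.simplefilter("ignore")
                res = sm.GLM(yv, x, family=sm.families.Binomial()).fit(scale="X2")
            fitted = pd.Series(res.predict(x), index=idx)
            params = np.asarray(res.params, dtype=float)
        elif family == "loglinear":
            res = sm.OLS(np.log10(yv), x).fit()
            fitted = pd.Series(10.0 ** res.fittedvalues, index=idx)
            params = np.asarray(res.params, dtype=float)
        else:
            raise ValueError(f"unknown family {family!r}")
        fits[prop] = PropertyFit(
            property=prop, family=family, params=params, fitted=fitted, n=n
        )
    return ScalingFit(fits=fits)


def predict(fit: ScalingFit, prop: str, S: float, C: float) -> float:
    """Fitted value of one property at given (S, C) on the natural scale."""
    f = fit.fits[prop]
    eta = float(f.params @ np.array([1.0, np.log10(S), np.log10(C)]))
    if f.family == "binomial":
        return float(expit(eta))
    return float(10.0 ** eta)


def residual_variation(fit: ScalingFit, df: pd.DataFrame) -> pd.DataFrame:
    """Observed minus fitted values, natural scale, per web and property.

    Rows excluded from a property's fit (missing or nonpositive values)
    get a missing RV.  Negative RV: the scaling model overestimates.
    """
    x = _design(df)
    out = {}
    for prop, f in fit.fits.items():
        obs = pd.to_numeric(df[prop], errors="coerce")
        eta = x @ f.params
        fitted = expit(eta) if f.family == "binomial" else 10.0 ** eta
        rv = obs - pd.Series(fitted, index=df.index)
        if f.family == "loglinear":
            rv[obs <= 0] = np.nan
        out[prop] = rv
    return pd.DataFrame(out, index=df.index)
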