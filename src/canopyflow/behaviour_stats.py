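"""Behavioural inference chain for per-minute fish counts.

Repeated one-minute counts from a continuous camera deployment are serially
correlated, so the chain is: (1) estimate autocorrelation per series and pick
a systematic thinning interval that brings the retained records inside the
white-noise 95% band; (2) exploratory median (50th-percentile) polynomial
quantile regression of the responses against water velocity; (3) formal GLMs
— a quasi-Poisson model for abundance (dispersion-scaled F tests) and a
binomial model for the water-column proportion (chi-square tests) — with
camera position and tide direction as crossed fixed factors; (4) Tukey HSD
pairwise contrasts among factor levels where a factor matters.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats
from statsmodels.tsa.stattools import acf as sm_acf

from .types import CAMERA_POSITIONS, TIDES, GlmResult

__all__ = [
    "acf_profile",
    "select_thinning_interval",
    "thin_table",
    "attach_velocity",
    "quantile_poly_fit",
    "QuantilePolyFit",
    "fit_abundance_glm",
    "fit_proportion_glm",
    "tukey_pairwise",
    "validate_count_table",
]

REQUIRED_COLUMNS = (
    "asu_id",
    "camera_position",
    "tide",
    "minute_index",
    "abundance",
    "watercolumn_count",
)

_RHS = (
    "C(tide, levels=tides) + C(camera_position, levels=positions) "
    "+ C(tide, levels=tides):C(camera_position, levels=positions)"
)
_TERMS = ("tide", "camera_position", "tide:camera_position")


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the count-table contract; returns the table unchanged."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    bad = table.index[table["watercolumn_count"] > table["abundance"]]
    if len(bad):
        raise ValueError(f"watercolumn_count exceeds abundance at rows {list(bad[:10])}")
    if (table["abundance"] < 0).any() or (table["watercolumn_count"] < 0).any():
        raise ValueError("counts must be non-negative")
    unknown_pos = set(table["camera_position"]) - set(CAMERA_POSITIONS)
    if unknown_pos:
        raise ValueError(f"unknown camera positions {sorted(unknown_pos)}; allowed: {CAMERA_POSITIONS}")
    unknown_tide = set(table["tide"]) - set(TIDES)
    if unknown_tide:
        raise ValueError(f"unknown tide labels {sorted(unknown_tide)}; allowed: {TIDES}")
    for _, grp in table.groupby(["asu_id", "camera_position"], sort=False):
        mi = grp["minute_index"].to_numpy()
        if np.any(np.diff(mi) <= 0):
            raise ValueError("minute_index must be strictly increasing within (asu_id, camera_position)")
    return table


# ---------------------------------------------------------------------------
# autocorrelation and thinning
# ---------------------------------------------------------------------------

def acf_profile(series: np.ndarray, max_lag: int) -> Tuple[np.ndarray, float]:
    """Sample autocorrelations at lags 1..max_lag with the white-noise band.

    Returns (acf values, half-width of the 95% band +-1.96/sqrt(n)).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) <= max_lag + 1:
        raise ValueError("series must be 1-d with length > max_lag + 1")
    if np.ptp(x) == 0:
        raise ValueError("ACF undefined for a constant series")
    vals = sm_acf(x, nlags=max_lag, fft=True)[1:]
    ci = 1.96 / np.sqrt(len(x))
    return vals, float(ci)


def select_thinning_interval(acf_values: np.ndarray, ci_halfwidth: float) -> int:
    """Systematic-retention interval implied by an ACF profile.

    Returns L + 1 for the smallest lag L at which the autocorrelation at L and
    every in-range multiple of L sits inside the 95% white-noise band — e.g.
    a series first acceptable at lag 4 is thinned by keeping every fifth
    record.
    """
    vals = np.asarray(acf_values, dtype=float)
    max_lag = len(vals)
    for lag in range(1, max_lag + 1):
        multiples = np.arange(lag, max_lag + 1, lag)
        if np.all(np.abs(vals[multiples - 1]) <= ci_halfwidth):
            return lag + 1
    raise ValueError("series too persistent: no acceptable lag within range")


def thin_table(table: pd.DataFrame, interval: int) -> pd.DataFrame:
    """Retain every ``interval``-th record within each (ASU, position) series.

    Records are taken at positions 0, interval, 2*interval, ... of each
    time-ordered group; ``interval`` = 1 is the identity.
    """
    if interval < 1:
        raise ValueError("interval must be >= 1")
    parts = []
    for _, grp in table.groupby(["asu_id", "camera_position"], sort=False):
        parts.append(grp.sort_values("minute_index").iloc[::interval])
    return pd.concat(parts).reset_index(drop=True)


def attach_velocity(
    table: pd.DataFrame,
    adcp: pd.DataFrame,
    bin_minutes: float = 10.0,
    time_column: str = "minute_index",
) -> pd.DataFrame:
    """Join each observation minute to its enclosing ADCP velocity bin.

    ``adcp`` needs columns ``bin_start`` (minutes) and ``velocity``; each
    observation joins the bin whose interval [bin_start, bin_start +
    bin_minutes) contains it.
    """
    adcp = adcp.sort_values("bin_start").reset_index(drop=True)
    starts = adcp["bin_start"].to_numpy(dtype=float)
    out = table.copy()
    pos = np.searchsorted(starts, out[time_column].to_numpy(dtype=float), side="right") - 1
    velocity = np.full(len(out), np.nan)
    valid = pos >= 0
    inside = valid.copy()
    inside[valid] = (
        out.loc[valid, time_column].to_numpy(dtype=float) - starts[pos[valid]]
    ) < bin_minutes
    velocity[inside] = adcp["velocity"].to_numpy()[pos[inside]]
    out["velocity"] = velocity
    return out


# ---------------------------------------------------------------------------
# median quantile polynomial regression
# ---------------------------------------------------------------------------

@dataclass
class QuantilePolyFit:
    """Polynomial quantile-regression fit (coefficients in ascending powers)."""

    coefficients: np.ndarray
    tau: float
    degree: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.vander(x, self.degree + 1, increasing=True) @ self.coefficients

    __call__ = predict


def quantile_poly_fit(
    x: np.ndarray, y: np.ndarray, degree: int = 2, tau: float = 0.5
) -> QuantilePolyFit:
    """Fit a global polynomial through the tau-th conditional quantile.

    Minimizes the check loss sum rho_tau(y - poly(x)); the default is the
    median quadratic used for the exploratory velocity relationships.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-d arrays")
    if len(np.unique(x)) < degree + 2:
        raise ValueError(f"need at least {degree + 2} distinct x values")
    design = np.vander(x, degree + 1, increasing=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.QuantReg(y, design).fit(q=tau)
    return QuantilePolyFit(coefficients=np.asarray(res.params), tau=tau, degree=degree)


# ---------------------------------------------------------------------------
# GLMs
# ---------------------------------------------------------------------------

def _design_env(table: pd.DataFrame) -> dict:
    return {"tides": list(TIDES), "positions": list(CAMERA_POSITIONS)}


def _sequential_formulas() -> Sequence[Tuple[str, str]]:
    base = "C(tide, levels=tides)"
    pos = "C(camera_position, levels=positions)"
    return [
        ("intercept", "1"),
        ("tide", base),
        ("camera_position", f"{base} + {pos}"),
        ("tide:camera_position", f"{base} + {pos} + {base}:{pos}"),
    ]


def _check_design(table: pd.DataFrame):
    for col, levels in (("tide", TIDES), ("camera_position", CAMERA_POSITIONS)):
        if table[col].nunique() < 2:
            raise ValueError(f"factor {col} needs >= 2 observed levels")


def _fit_glm_chain(table: pd.DataFrame, endog: np.ndarray, family) -> list:
    env = _design_env(table)
    fits = []
    for _, rhs in _sequential_formulas():
        if rhs == "1":
            x = np.ones((len(table), 1))
            info = None
        else:
            dm = patsy.dmatrix(rhs, {**env, **{c: table[c] for c in table.columns}},
                               return_type="dataframe")
            x = np.asarray(dm)
            info = dm.design_info
            if np.linalg.matrix_rank(x) < x.shape[1]:
                raise ValueError(f"rank-deficient design for terms '{rhs}' (aliased factor level)")
        fits.append((info, sm.GLM(endog, x, family=family).fit()))
    return fits


def _term_table(fits, family_label: str, dispersion: float) -> pd.DataFrame:
    full = fits[-1][1]
    rows = []
    names = [name for name, _ in _sequential_formulas()][1:]
    for (prev, cur), term in zip(zip(fits[:-1], fits[1:]), names):
        d_dev = prev[1].deviance - cur[1].deviance
        d_df = prev[1].df_resid - cur[1].df_resid
        if family_label == "quasipoisson":
            stat = (d_dev / d_df) / dispersion
            p = stats.f.sf(stat, d_df, full.df_resid)
            stat_type = "F"
        else:
            stat = d_dev
            p = stats.chi2.sf(stat, d_df)
            stat_type = "chi2"
        rows.append({"term": term, "df": int(d_df), "statistic": float(stat),
                     "statistic_type": stat_type, "p": float(p)})
    return pd.DataFrame(rows)


def _marginal_term_table(table, endog, family, family_label, dispersion, full_fit) -> pd.DataFrame:
    """Marginal (Type III) tests: sum-to-zero contrasts, each term's columns
    dropped from the full design."""
    env = _design_env(table)
    data = {**env, **{c: table[c] for c in table.columns}}
    base = "C(tide, Sum, levels=tides)"
    pos = "C(camera_position, Sum, levels=positions)"
    full_rhs = f"{base} + {pos} + {base}:{pos}"
    dm = patsy.dmatrix(full_rhs, data, return_type="dataframe")
    x_full = np.asarray(dm)
    term_cols = {
        name: dm.design_info.term_name_slices[name]
        for name in dm.design_info.term_names
        if name != "Intercept"
    }
    # map patsy term names onto the report labels in model order
    labels = dict(zip(term_cols.keys(), _TERMS))
    full = sm.GLM(endog, x_full, family=family).fit()
    rows = []
    for patsy_name, sl in term_cols.items():
        term = labels[patsy_name]
        keep = np.ones(x_full.shape[1], dtype=bool)
        keep[sl] = False
        red = sm.GLM(endog, x_full[:, keep], family=family).fit()
        d_dev = red.deviance - full.deviance
        d_df = red.df_resid - full.df_resid
        if family_label == "quasipoisson":
            stat = (d_dev / d_df) / dispersion
            p = stats.f.sf(stat, d_df, full.df_resid)
            stat_type = "F"
        else:
            stat = d_dev
            p = stats.chi2.sf(stat, d_df)
            stat_type = "chi2"
        rows.append({"term": term, "df": int(d_df), "statistic": float(stat),
                     "statistic_type": stat_type, "p": float(p)})
    return pd.DataFrame(rows)


def fit_abundance_glm(table: pd.DataFrame, tests: str = "sequential") -> GlmResult:
    """Quasi-Poisson GLM of abundance on tide, camera position and their
    interaction.

    Log link with variance = dispersion * mean; the dispersion is the Pearson
    chi-square of the full model divided by its residual df, and terms are
    tested with dispersion-scaled F statistics from the analysis of deviance
    (sequential by default, marginal drop-one on request).
    """
    validate_count_table(table)
    _check_design(table)
    y = table["abundance"].to_numpy(dtype=float)
    if not np.any(y > 0):
        raise ValueError("all-zero abundance response")
    family = sm.families.Poisson()
    fits = _fit_glm_chain(table, y, family)
    design_info, full = fits[-1]
    dispersion = float(full.pearson_chi2 / full.df_resid)
    if tests == "sequential":
        terms = _term_table(fits, "quasipoisson", dispersion)
    elif tests == "marginal":
        terms = _marginal_term_table(table, y, family, "quasipoisson", dispersion, full)
    else:
        raise ValueError("tests must be 'sequential' or 'marginal'")
    coefs = pd.DataFrame({
        "term": design_info.column_names,
        "estimate": np.asarray(full.params),
        "se": np.asarray(full.bse) * np.sqrt(dispersion),
    })
    return GlmResult(
        family="quasipoisson",
        terms=terms,
        dispersion=dispersion,
        coefficients=coefs,
        fit=full,
        design_info=design_info,
        data=table.reset_index(drop=True),
        test_type=tests,
    )


def fit_proportion_glm(table: pd.DataFrame, tests: str = "sequential") -> GlmResult:
    """Binomial GLM of the water-column proportion on tide and position.

    Logit link on (watercolumn_count, abundance - watercolumn_count); rows
    with zero abundance carry no information about the proportion and are
    dropped. Terms are tested with chi-square analysis of deviance.
    """
    validate_count_table(table)
    sub = table[table["abundance"] > 0].reset_index(drop=True)
    if sub.empty:
        raise ValueError("no rows with positive abundance")
    _check_design(sub)
    endog = np.column_stack([
        sub["watercolumn_count"].to_numpy(dtype=float),
        (sub["abundance"] - sub["watercolumn_count"]).to_numpy(dtype=float),
    ])
    family = sm.families.Binomial()
    fits = _fit_glm_chain(sub, endog, family)
    design_info, full = fits[-1]
    if np.any(np.abs(full.params) > 15):
        warnings.warn("possible separation: extreme logit coefficients", RuntimeWarning)
    if tests == "sequential":
        terms = _term_table(fits, "binomial", 1.0)
    elif tests == "marginal":
        terms = _marginal_term_table(sub, endog, family, "binomial", 1.0, full)
    else:
        raise ValueError("tests must be 'sequential' or 'marginal'")
    coefs = pd.DataFrame({
        "term": design_info.column_names,
        "estimate": np.asarray(full.params),
        "se": np.asarray(full.bse),
    })
    return GlmResult(
        family="binomial",
        terms=terms,
        dispersion=1.0,
        coefficients=coefs,
        fit=full,
        design_info=design_info,
        data=sub,
        test_type=tests,
    )


# ---------------------------------------------------------------------------
# Tukey HSD contrasts
# ---------------------------------------------------------------------------

def tukey_pairwise(result: GlmResult, factor: str = "camera_position") -> pd.DataFrame:
    """All pairwise level contrasts of ``factor`` with Tukey HSD adjustment.

    Contrasts are computed on the linear-predictor scale between
    equally-weighted cell means (each level's design row is the average of
    the full factorial grid rows at that level, so the other factor is
    averaged over). Adjusted p-values use the studentized-range distribution
    with the model's residual df.
    """
    if factor == "camera_position":
        levels = list(CAMERA_POSITIONS)
        other = ("tide", list(TIDES))
    elif factor == "tide":
        levels = list(TIDES)
        other = ("camera_position", list(CAMERA_POSITIONS))
    else:
        raise ValueError("factor must be 'tide' or 'camera_position'")
    if factor not in result.data.columns:
        raise ValueError(f"factor {factor} absent from model data")

    grid = pd.DataFrame(
        [(a, b) for a in levels for b in other[1]], columns=[factor, other[0]]
    )
    env = _design_env(result.data)
    (dm,) = patsy.build_design_matrices(
        [result.design_info], {**env, **{c: grid[c] for c in grid.columns}}
    )
    rows = np.asarray(dm)
    level_rows = {
        lev: rows[np.asarray(grid[factor] == lev)].mean(axis=0) for lev in levels
    }
    scale = result.dispersion if result.family == "quasipoisson" else 1.0
    cov = np.asarray(result.fit.cov_params()) * scale
    beta = np.asarray(result.fit.params)
    df_resid = float(result.fit.df_resid)
    k = len(levels)
    out = []
    for a, b in itertools.combinations(levels, 2):
        c = level_rows[a] - level_rows[b]
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        tval = est / se if se > 0 else np.inf
        p_adj = float(stats.studentized_range.sf(abs(tval) * np.sqrt(2.0), k, df_resid))
        out.append({"pair": f"{a} vs {b}", "estimate": est, "se": se,
                    "statistic": tval, "p_adj": min(max(p_adj, 0.0), 1.0)})
    contrasts = pd.DataFrame(out)
    result.contrasts = contrasts
    return contrasts
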