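"""CSF attribute tables and covariance/correlation analyses.

From fitted (or generating) CSF parameters, each observer-location cell
yields five attributes: peak-CS, peak-SF, bandwidth, cutoff-SF and
AULCSF.  Stacking 5 attributes x 3 locations gives a 15-column table
whose covariance structure carries the study's individual-level
questions: do attributes co-vary *across* locations (one observer's CSF
predicting their CSF elsewhere), and do attributes co-vary *within* a
location (observers' CSFs varying along a common axis)?

Analysis space: peak-CS, peak-SF and cutoff-SF enter the table as
log10 values; bandwidth (octaves) and AULCSF stay linear.  Covariances
are estimated with Schafer-Strimmer shrinkage (off-diagonal
correlations shrunk toward zero with analytically chosen intensity),
and correlation confidence intervals/p-values are propagated from the
MCMC posterior samples when a hierarchical fit is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import design
from .csf_core import LOG10_2
from .group_stats import fdr_adjust

__all__ = [
    "ATTRIBUTES",
    "MAIN_ATTRIBUTES",
    "build_attribute_table",
    "attribute_table_from_params",
    "attribute_tables_from_samples",
    "ShrunkCovariance",
    "shrinkage_covariance",
    "CorrelationReport",
    "correlation_report",
    "coefficient_of_variation",
    "cross_location_pairs",
    "within_location_pairs",
]

ATTRIBUTES = ("peak_cs", "peak_sf", "bandwidth", "cutoff_sf", "aulcsf")
#: Attributes of the main 9 x 9 sub-table.
MAIN_ATTRIBUTES = ("peak_cs", "peak_sf", "bandwidth")

#: Attributes stored on the log10 scale in the analysis table.
LOG_ATTRIBUTES = ("peak_cs", "peak_sf", "cutoff_sf")


def _attribute_columns(attributes=ATTRIBUTES) -> pd.MultiIndex:
    return pd.MultiIndex.from_tuples(
        [(a, loc) for a in attributes for loc in design.LOCATIONS],
        names=["attribute", "location"],
    )


def _attributes_from_log10(lc, lf, lw, sf_range):
    """Vectorised attribute computation from log10 parameter arrays.

    Returns (log10 cutoff-SF, AULCSF); cutoff is NaN when peak-CS < 1.
    Closed forms of the log-parabola are used so that thousands of
    posterior draws can be converted cheaply.
    """
    lc = np.asarray(lc, float)
    lf = np.asarray(lf, float)
    bw = 10.0 ** np.asarray(lw, float)
    with np.errstate(invalid="ignore"):
        log_cutoff = np.where(
            lc >= 0.0, lf + 0.5 * bw * np.sqrt(np.maximum(lc, 0.0) * LOG10_2), np.nan
        )
    w = bw * LOG10_2
    k = 4.0 * LOG10_2 / w**2
    r = np.sqrt(np.maximum(lc, 0.0) / k)
    lo = np.maximum(math.log10(sf_range[0]), lf - r)
    hi = np.minimum(math.log10(sf_range[1]), lf + r)
    span = np.maximum(hi - lo, 0.0)
    area = np.where(
        (lc > 0.0) & (span > 0.0),
        lc * span - k * ((hi - lf) ** 3 - (lo - lf) ** 3) / 3.0,
        0.0,
    )
    return log_cutoff, area


def attribute_table_from_params(
    params: pd.DataFrame,
    sf_range: tuple[float, float] = design.DEFAULT_SF_RANGE,
    attributes=ATTRIBUTES,
) -> pd.DataFrame:
    """Observers x (attribute, location) table from a tidy parameter frame.

    ``params`` needs columns observer_id, location, peak_cs, peak_sf,
    bandwidth_oct (linear scale) — e.g. the output of
    :func:`csfpolar.synthetic_data.sample_population` or an estimate
    frame.  Missing cells propagate as NaN.
    """
    lc = np.log10(params["peak_cs"].to_numpy(float))
    lf = np.log10(params["peak_sf"].to_numpy(float))
    lw = np.log10(params["bandwidth_oct"].to_numpy(float))
    log_cutoff, area = _attributes_from_log10(lc, lf, lw, sf_range)
    values = {
        "peak_cs": lc,
        "peak_sf": lf,
        "bandwidth": 10.0 ** lw,
        "cutoff_sf": log_cutoff,
        "aulcsf": area,
    }
    tidy = params[["observer_id", "location"]].copy()
    for a in attributes:
        tidy[a] = values[a]
    wide = tidy.set_index(["observer_id", "location"]).unstack("location")
    cols = _attribute_columns(attributes)
    wide.columns = wide.columns.set_names(["attribute", "location"])
    return wide.reindex(columns=cols)


def build_attribute_table(
    fit,
    sf_range: tuple[float, float] = design.DEFAULT_SF_RANGE,
    attributes=ATTRIBUTES,
) -> pd.DataFrame:
    """Attribute table from hierarchical-fit point estimates.

    ``fit`` is an :class:`csfpolar.hbm.HBMFit` (or any object with a
    ``point_estimates`` frame indexed by observer and location).  Under
    a fixed-bandwidth fit the three bandwidth columns of each row are
    identical by model structure.
    """
    frame = fit.point_estimates if hasattr(fit, "point_estimates") else fit
    tidy = frame.reset_index()[
        ["observer_id", "location", "peak_cs", "peak_sf", "bandwidth_oct"]
    ]
    return attribute_table_from_params(tidy, sf_range, attributes)


def attribute_tables_from_samples(
    fit,
    n_samples: int = 1000,
    sf_range: tuple[float, float] = design.DEFAULT_SF_RANGE,
    attributes=ATTRIBUTES,
) -> tuple[np.ndarray, pd.MultiIndex]:
    """Per-posterior-draw attribute tables for CI propagation.

    Thins the pooled test-level draws to ``n_samples`` evenly spaced
    samples and converts each to an observers x 15 attribute matrix.
    Returns ``(array of shape (samples, observers, columns), columns)``.
    """
    pooled = fit.pooled_theta()  # (S, I, 3, 3) log10
    idx = np.linspace(0, len(pooled) - 1, min(n_samples, len(pooled))).astype(int)
    sub = pooled[idx]
    lc, lf, lw = sub[..., 0], sub[..., 1], sub[..., 2]
    log_cutoff, area = _attributes_from_log10(lc, lf, lw, sf_range)
    values = {
        "peak_cs": lc, "peak_sf": lf, "bandwidth": 10.0 ** lw,
        "cutoff_sf": log_cutoff, "aulcsf": area,
    }
    blocks = [values[a][..., j] for a in attributes for j in range(3)]
    out = np.stack(blocks, axis=-1)  # (S, I, len(attributes)*3)
    return out, _attribute_columns(attributes)


@dataclass(eq=False)
class ShrunkCovariance:
    """Shrinkage covariance estimate and its analytic intensity."""

    matrix: pd.DataFrame
    intensity: float

    def to_numpy(self) -> np.ndarray:
        return self.matrix.to_numpy(float)


def shrinkage_covariance(table: pd.DataFrame | np.ndarray) -> ShrunkCovariance:
    """Schafer-Strimmer shrinkage of the sample covariance.

    Off-diagonal correlations are shrunk toward the diagonal target by
    the analytic optimal intensity ``lambda* = sum Var(r_ij) / sum
    r_ij^2`` (clipped to [0, 1]); variances are kept at their sample
    values.  The result is symmetric positive semi-definite and well
    conditioned even when columns outnumber rows.
    """
    if isinstance(table, pd.DataFrame):
        clean = table.dropna(axis=0)
        x = clean.to_numpy(float)
        cols = table.columns
    else:
        x = np.asarray(table, float)
        x = x[~np.isnan(x).any(axis=1)]
        cols = pd.RangeIndex(x.shape[1])
    n, p = x.shape
    if n < 3:
        raise ValueError("shrinkage covariance needs at least 3 complete rows")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0.0):
        # degenerate columns carry no correlation information; their
        # variance is kept and their correlations defined as zero
        sd_safe = np.where(sd == 0.0, 1.0, sd)
    else:
        sd_safe = sd
    xs = (x - x.mean(axis=0)) / sd_safe
    r = (xs.T @ xs) / (n - 1)
    w = xs[:, :, None] * xs[:, None, :]          # (n, p, p)
    var_r = n / (n - 1) ** 3 * ((w - w.mean(axis=0)) ** 2).sum(axis=0)
    off = ~np.eye(p, dtype=bool)
    denom = (r[off] ** 2).sum()
    lam = 1.0 if denom == 0.0 else float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))
    r_shrunk = r * (1.0 - lam)
    np.fill_diagonal(r_shrunk, 1.0)
    cov = r_shrunk * np.outer(sd, sd)
    np.fill_diagonal(cov, sd**2)
    return ShrunkCovariance(
        matrix=pd.DataFrame(cov, index=cols, columns=cols), intensity=lam,
    )


def _corr_from_cov(cov: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of a Pearson correlation with n observations."""
    r = np.clip(np.asarray(r, float), -0.9999999, 0.9999999)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


@dataclass(eq=False)
class CorrelationReport:
    """Correlation matrix plus per-pair inference.

    ``pairs`` has one row per tested coefficient: the point correlation
    (from the shrunk covariance), a percentile CI and the median
    two-sided p-value over MCMC-propagated samples (or the single
    analytic p-value when no samples are available), the BH-FDR
    adjusted p, and a significance flag at ``alpha``.
    """

    matrix: pd.DataFrame
    pairs: pd.DataFrame
    alpha: float


def correlation_report(
    cov: ShrunkCovariance | pd.DataFrame,
    attr_samples: np.ndarray | None = None,
    n_observers: int | None = None,
    alpha: float = 0.05,
    pairs: list[tuple] | None = None,
    ci_level: float = 0.95,
    observed_table: pd.DataFrame | np.ndarray | None = None,
) -> CorrelationReport:
    """Pearson correlations with CIs and significance from MCMC samples.

    ``cov`` is the (shrunk) attribute covariance; ``attr_samples`` the
    per-draw attribute tables from
    :func:`attribute_tables_from_samples`.  When no posterior samples
    are available, pass the observed attribute table instead
    (``observed_table``): p-values are then the analytic Pearson tests
    on the *unshrunk* sample correlations (the shrunk values would be
    conservative), and CIs are omitted.  Significance is declared when
    the median per-sample p-value, BH-FDR adjusted across the tested
    pairs, falls below ``alpha``.
    """
    mat = cov.matrix if isinstance(cov, ShrunkCovariance) else cov
    cols = list(mat.columns)
    if attr_samples is None and observed_table is not None:
        obs = (observed_table.to_numpy(float)
               if isinstance(observed_table, pd.DataFrame) else
               np.asarray(observed_table, float))
        attr_samples = obs[None, :, :]
    corr = pd.DataFrame(_corr_from_cov(mat.to_numpy(float)),
                        index=mat.index, columns=mat.columns)
    if pairs is None:
        pairs = [(cols[i], cols[j]) for i in range(len(cols))
                 for j in range(i + 1, len(cols))]
    if n_observers is None and attr_samples is not None:
        n_observers = attr_samples.shape[1]
    if n_observers is None:
        raise ValueError("n_observers is required to compute p-values")

    rows = []
    q = 0.5 * (1.0 - ci_level)
    for a, b in pairs:
        ia, ib = cols.index(a), cols.index(b)
        r_obs = float(corr.iloc[ia, ib])
        var_a = float(mat.iloc[ia, ia])
        var_b = float(mat.iloc[ib, ib])
        if var_a <= 0.0 or var_b <= 0.0 or not np.isfinite(r_obs):
            rows.append({"var_a": a, "var_b": b, "r": np.nan, "ci_lo": np.nan,
                         "ci_hi": np.nan, "p": np.nan, "defined": False})
            continue
        if attr_samples is not None:
            xa = attr_samples[:, :, ia]
            xb = attr_samples[:, :, ib]
            xa_c = xa - xa.mean(axis=1, keepdims=True)
            xb_c = xb - xb.mean(axis=1, keepdims=True)
            denom = np.sqrt((xa_c**2).sum(axis=1) * (xb_c**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                r_s = (xa_c * xb_c).sum(axis=1) / denom
            r_s = r_s[np.isfinite(r_s)]
            ci_lo, ci_hi = np.quantile(r_s, [q, 1.0 - q])
            p = float(np.median(_pearson_p(r_s, n_observers)))
        else:
            ci_lo = ci_hi = np.nan
            p = float(_pearson_p(r_obs, n_observers))
        rows.append({"var_a": a, "var_b": b, "r": r_obs, "ci_lo": ci_lo,
                     "ci_hi": ci_hi, "p": p, "defined": True})
    table = pd.DataFrame(rows)
    ok = table["defined"] & table["p"].notna()
    adj = np.full(len(table), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = fdr_adjust(table.loc[ok, "p"].to_numpy())
    table["p_adj"] = adj
    table["significant"] = table["p_adj"] < alpha
    return CorrelationReport(matrix=corr, pairs=table, alpha=alpha)


def cross_location_pairs(attribute: str) -> list[tuple]:
    """Column pairs testing one attribute across location pairs
    (the cross-location cells of the covariance schematic)."""
    locs = design.LOCATIONS
    return [((attribute, locs[i]), (attribute, locs[j]))
            for i in range(3) for j in range(i + 1, 3)]


def within_location_pairs(location: str, attributes=MAIN_ATTRIBUTES) -> list[tuple]:
    """Column pairs testing attribute couplings within one location
    (the within-location triangles of the covariance schematic)."""
    return [((attributes[i], location), (attributes[j], location))
            for i in range(len(attributes)) for j in range(i + 1, len(attributes))]


def coefficient_of_variation(
    table: pd.DataFrame, linear: bool = True, per_location: bool = False,
) -> pd.Series | pd.DataFrame:
    """Coefficient of variation (SD/mean) of each attribute.

    With ``linear=True`` the log10-stored attributes are exponentiated
    first so CVs compare attributes with different units on their
    natural scales.  Zero-mean columns yield NaN.
    """
    values = table.copy()
    if linear:
        for a in LOG_ATTRIBUTES:
            if a in values.columns.get_level_values("attribute"):
                values[a] = 10.0 ** values[a]
    if per_location:
        mean = values.mean(axis=0)
        sd = values.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = sd / mean.where(mean != 0.0)
        return cv.unstack("location")
    stacked = values.stack("location", future_stack=True)
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0, ddof=1)
    return (sd / mean.where(mean != 0.0)).reindex(
        [a for a in ATTRIBUTES if a in mean.index]
    )
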