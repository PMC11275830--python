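"""Permutation-based group statistics for polar-angle effects.

Location effects on each CSF attribute are tested with a one-way
repeated-measures ANOVA whose p-value comes from permuting location
labels within each observer, and with paired contrasts — HVA
(horizontal minus the vertical-meridian average), VMA (lower minus
upper vertical), and simple pairwise differences — whose p-values come
from within-observer sign flips.  Following the study's convention the
permutation p-value is the proportion of permuted statistics greater
than or equal to the observed one, floored at ``1/n_permutations``
(0.001 at the default 1000 permutations).  Effect sizes are partial
eta-squared for the ANOVA and Cohen's d for contrasts; families of
p-values are controlled with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import design

__all__ = [
    "PermutationConfig",
    "TestResult",
    "CONTRASTS",
    "permutation_rm_anova",
    "permutation_paired_contrast",
    "fdr_adjust",
    "run_location_tests",
]

#: Named location contrasts as weight vectors over
#: (horizontal, lower_vertical, upper_vertical).
CONTRASTS: dict[str, np.ndarray] = {
    "HVA": np.array([1.0, -0.5, -0.5]),
    "VMA": np.array([0.0, 1.0, -1.0]),
    "H_vs_LV": np.array([1.0, -1.0, 0.0]),
    "H_vs_UV": np.array([1.0, 0.0, -1.0]),
    "LV_vs_UV": np.array([0.0, 1.0, -1.0]),
}


@dataclass(frozen=True)
class PermutationConfig:
    """Permutation-test settings; the smallest reportable p is
    ``p_floor = 1/n_permutations`` (0.001 by default)."""

    n_permutations: int = 1000
    seed: int = 0
    p_floor: float | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.p_floor is None:
            object.__setattr__(self, "p_floor", 1.0 / self.n_permutations)


@dataclass(frozen=True)
class TestResult:
    """One permutation test: statistic, p, and effect size."""

    label: str
    statistic: float
    df: tuple
    p: float
    effect_size: float
    effect_name: str
    n_permutations: int = field(default=1000, repr=False)


def _location_matrix(table, attribute: str | None) -> np.ndarray:
    """Extract an observers x 3 matrix in canonical location order."""
    if isinstance(table, pd.DataFrame):
        if attribute is not None and isinstance(table.columns, pd.MultiIndex):
            sub = table[attribute]
        else:
            sub = table
        x = sub[list(design.LOCATIONS)].to_numpy(float)
    else:
        x = np.asarray(table, float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("expected an observers x 3-locations matrix")
    x = x[~np.isnan(x).any(axis=1)]
    if x.shape[0] < 3:
        raise ValueError("need at least 3 observers with complete rows")
    return x


def _rm_anova_f(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Repeated-measures F and partial eta-squared.

    ``x`` has shape (..., n, 3); the condition effect is tested against
    the condition-by-subject interaction with df (2, 2(n-1)).
    """
    n = x.shape[-2]
    grand = x.mean(axis=(-1, -2), keepdims=True)
    subj = x.mean(axis=-1, keepdims=True)
    cond = x.mean(axis=-2, keepdims=True)
    ss_cond = (n * (cond - grand) ** 2).sum(axis=(-1, -2))
    resid = x - subj - cond + grand
    ss_err = (resid**2).sum(axis=(-1, -2))
    df_cond = 2.0
    df_err = 2.0 * (n - 1)
    # degenerate cases (no variance at all) resolve to F = 0 rather than
    # 0/0; thresholds are relative to the total variability
    ss_tot = ((x - grand) ** 2).sum(axis=(-1, -2))
    eps = 1e-12 * (ss_tot + 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_cond / df_cond) / (ss_err / df_err)
        eta = ss_cond / (ss_cond + ss_err)
    f = np.where(ss_err <= eps, np.where(ss_cond <= eps, 0.0, np.inf), f)
    eta = np.where(ss_cond + ss_err <= eps, 0.0, eta)
    return f, eta


def _perm_p(null: np.ndarray, observed: float, cfg: PermutationConfig) -> float:
    exceed = int(np.sum(null >= observed))
    return max(exceed / cfg.n_permutations, cfg.p_floor)


def permutation_rm_anova(
    table, attribute: str | None = None,
    cfg: PermutationConfig = PermutationConfig(),
) -> TestResult:
    """One-way repeated-measures ANOVA with a within-observer permutation null.

    The observed F uses the standard within-subject decomposition with
    df (2, 2(n-1)); the null distribution relabels the three location
    values independently within each observer.  ``p`` is the proportion
    of permuted F at or above the observed F, floored at ``p_floor``;
    the effect size is partial eta-squared.
    """
    x = _location_matrix(table, attribute)
    n = x.shape[0]
    f_obs, eta = _rm_anova_f(x)
    rng = np.random.default_rng(cfg.seed)
    order = np.argsort(rng.random((cfg.n_permutations, n, 3)), axis=-1)
    perms = np.take_along_axis(np.broadcast_to(x, order.shape), order, axis=-1)
    f_null, _ = _rm_anova_f(perms)
    label = f"rm_anova[{attribute}]" if attribute else "rm_anova"
    return TestResult(
        label=label, statistic=float(f_obs), df=(2, 2 * (n - 1)),
        p=_perm_p(f_null, float(f_obs), cfg),
        effect_size=float(eta), effect_name="partial_eta_squared",
        n_permutations=cfg.n_permutations,
    )


def permutation_paired_contrast(
    table, attribute: str | None, contrast: str,
    cfg: PermutationConfig = PermutationConfig(),
) -> TestResult:
    """Paired location contrast with a sign-flip permutation null.

    ``contrast`` is one of ``HVA`` (horizontal minus vertical average),
    ``VMA`` (lower minus upper vertical), or a simple pairwise
    difference.  The statistic is the paired t of the per-observer
    contrast values; the null flips each observer's sign independently.
    One-sided exceedance (permuted t >= observed t) per the permutation
    convention above; Cohen's d is mean/SD of the contrast values.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected {sorted(CONTRASTS)}")
    x = _location_matrix(table, attribute)
    d = x @ CONTRASTS[contrast]
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        t_obs = np.inf if d.mean() > 0 else (-np.inf if d.mean() < 0 else 0.0)
        cohen = 0.0 if d.mean() == 0.0 else np.sign(d.mean()) * np.inf
    else:
        t_obs = d.mean() / (sd / np.sqrt(n))
        cohen = d.mean() / sd
    rng = np.random.default_rng(cfg.seed)
    signs = rng.integers(0, 2, size=(cfg.n_permutations, n)) * 2 - 1
    flipped = signs * d
    means = flipped.mean(axis=1)
    sds = flipped.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = means / (sds / np.sqrt(n))
        degenerate = np.where(means > 0, np.inf, np.where(means < 0, -np.inf, 0.0))
        t_null = np.where(sds == 0.0, degenerate, t_null)
    label = f"{contrast}[{attribute}]" if attribute else contrast
    return TestResult(
        label=label, statistic=float(t_obs), df=(n - 1,),
        p=_perm_p(t_null, float(t_obs), cfg),
        effect_size=float(cohen), effect_name="cohens_d",
        n_permutations=cfg.n_permutations,
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0.0) | (p > 1.0)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_location_tests(
    table: pd.DataFrame,
    attributes=None,
    contrasts=("HVA", "VMA", "H_vs_LV"),
    cfg: PermutationConfig = PermutationConfig(),
) -> pd.DataFrame:
    """Tidy table of location tests for each attribute.

    Runs the RM-ANOVA and the requested contrasts per attribute with
    independent permutation streams, then BH-FDR adjusts the contrast
    p-values within each attribute (one family per attribute).
    """
    if attributes is None:
        attributes = [a for a in table.columns.get_level_values("attribute").unique()]
    rows = []
    child_seeds = iter(np.random.SeedSequence(cfg.seed).generate_state(
        (1 + len(contrasts)) * len(attributes)
    ))
    for a in attributes:
        sub_cfg = PermutationConfig(cfg.n_permutations, int(next(child_seeds)) % (2**31))
        res = permutation_rm_anova(table, a, sub_cfg)
        rows.append({"attribute": a, "test": "rm_anova",
                     "statistic": res.statistic, "p": res.p,
                     "effect_size": res.effect_size, "effect_name": res.effect_name})
        contrast_ps = []
        for cname in contrasts:
            sub_cfg = PermutationConfig(cfg.n_permutations,
                                        int(next(child_seeds)) % (2**31))
            res = permutation_paired_contrast(table, a, cname, sub_cfg)
            rows.append({"attribute": a, "test": cname,
                         "statistic": res.statistic, "p": res.p,
                         "effect_size": res.effect_size,
                         "effect_name": res.effect_name})
            contrast_ps.append(res.p)
        adj = fdr_adjust(contrast_ps)
        for k in range(len(contrasts)):
            rows[-len(contrasts) + k]["p_adj"] = adj[k]
    out = pd.DataFrame(rows)
    if "p_adj" not in out.columns:
        out["p_adj"] = np.nan
    return out
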