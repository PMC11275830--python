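"""Bayesian Inference Procedure (BIP): independent grid-posterior CSF fits.

Each observer-location cell is fit on its own: the trial likelihood is
accumulated over a uniform grid spanning the standard prior boxes, and
the posterior mean/SD of each parameter (log10 space) summarises the
cell.  Across-observer summaries of these independent fits — the
population-level covariance of per-observer estimates and the
individual-level covariance of within-observer deviations — seed the
hierarchical model's Wishart priors.  Because every cell is scored
independently under a uniform prior, BIP uncertainty is an upper bound
the hierarchical model is expected to shrink.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design
from .csf_core import DEFAULT_PSYCHOMETRIC, PsychometricConfig, _p_correct_arrays
from .qcsf import PosteriorGrid

__all__ = ["BIPResult", "BIPSummary", "fit_bip", "summarize_bip"]

#: Default BIP grid resolution (finer than the adaptive-testing grid).
DEFAULT_BIP_GRID_SHAPE = (40, 40, 40)

#: Diagonal ridge added to degenerate covariance estimates before
#: they are used as Wishart expectations.
COV_RIDGE = 1e-6

_NODE_CHUNK = 16384


@dataclass(eq=False)
class BIPResult:
    """Per observer-location grid-posterior summaries.

    ``frame`` is indexed by (observer_id, location) and holds posterior
    means and SDs of (log10 peak-CS, log10 peak-SF, log10 bandwidth),
    the linear-scale point estimates, and the trial count.  Cells with
    no trials appear as all-NaN rows with ``n_trials == 0``.
    """

    frame: pd.DataFrame
    grid_shape: tuple[int, int, int]

    def stacked_estimates(self) -> pd.DataFrame:
        """Observers x 9 matrix of stacked (lc, lf, lbw) per location.

        Only observers with all three locations fit are kept.
        """
        cols = ["mean_log10_peak_cs", "mean_log10_peak_sf", "mean_log10_bandwidth"]
        wide = self.frame[cols].unstack("location")
        ordered = []
        for loc in design.LOCATIONS:
            for c in cols:
                ordered.append((c, loc))
        wide = wide.loc[:, ordered]
        return wide.dropna(axis=0)


@dataclass(eq=False)
class BIPSummary:
    """Across-observer summaries of independent BIP fits.

    ``location_means`` / ``location_sds`` are (3 locations x 3 params)
    in log10 space; ``sigma_bip`` is the 9x9 covariance of stacked
    per-observer estimates; ``phi_bip`` stacks one 3x3 individual-level
    covariance per location, computed from within-observer deviations
    around each observer's own across-location mean.
    """

    location_means: np.ndarray
    location_sds: np.ndarray
    sigma_bip: np.ndarray
    phi_bip: np.ndarray
    n_observers: int
    degenerate: list[str] = field(default_factory=list)


def _grid_for_bip(grid_shape: tuple[int, int, int]) -> PosteriorGrid:
    # margin 0: BIP point estimates must stay inside the prior support
    return PosteriorGrid.uniform(shape=grid_shape, peak_cs_margin=0.0)


def fit_bip(
    trials: pd.DataFrame,
    grid_shape: tuple[int, int, int] = DEFAULT_BIP_GRID_SHAPE,
    cfg: PsychometricConfig = DEFAULT_PSYCHOMETRIC,
) -> BIPResult:
    """Fit every observer-location cell with a uniform-prior grid posterior.

    The posterior over the grid is proportional to the product of trial
    likelihoods; the point estimate is the posterior mean in log10
    space.  Likelihood tables are shared across cells through the
    deduplicated stimulus set, so the whole cohort is fit in one pass.
    """
    grid = _grid_for_bip(grid_shape)
    trials = trials.reset_index(drop=True)
    observers = np.sort(trials["observer_id"].unique())

    # deduplicated stimulus table
    stim, stim_inv = np.unique(
        trials[["sf_cpd", "contrast"]].to_numpy(float), axis=0, return_inverse=True
    )
    n_stim = stim.shape[0]
    cells = [(int(o), loc) for o in observers for loc in design.LOCATIONS]
    cell_pos = {c: k for k, c in enumerate(cells)}
    trial_cell = np.array([
        cell_pos[(int(o), loc)]
        for o, loc in zip(trials["observer_id"], trials["location"])
    ])

    # counts of correct / incorrect responses per (stimulus, cell)
    resp = trials["response"].to_numpy(int)
    n1 = np.zeros((n_stim, len(cells)))
    n0 = np.zeros((n_stim, len(cells)))
    np.add.at(n1, (stim_inv, trial_cell), resp)
    np.add.at(n0, (stim_inv, trial_cell), 1 - resp)

    log_sf = np.log10(stim[:, 0])
    contrast = stim[:, 1]
    n_nodes = grid.n_nodes
    loglik = np.zeros((n_nodes, len(cells)))
    for start in range(0, n_nodes, _NODE_CHUNK):
        sl = slice(start, min(start + _NODE_CHUNK, n_nodes))
        p = _p_correct_arrays(
            log_sf[None, :], contrast[None, :],
            grid.node_log_peak_cs[sl, None], grid.node_log_peak_sf[sl, None],
            grid.node_bandwidth[sl, None],
            cfg.guess, cfg.lapse, cfg.slope,
        )
        loglik[sl] = np.log(p) @ n1 + np.log1p(-p) @ n0

    node_vals = np.stack([
        grid.node_log_peak_cs, grid.node_log_peak_sf,
        np.log10(grid.node_bandwidth),
    ])  # (3, nodes)

    rows = {}
    counts = np.bincount(trial_cell, minlength=len(cells))
    for k, (obs, loc) in enumerate(cells):
        if counts[k] == 0:
            rows[(obs, loc)] = dict.fromkeys(
                ("mean_log10_peak_cs", "mean_log10_peak_sf", "mean_log10_bandwidth",
                 "sd_log10_peak_cs", "sd_log10_peak_sf", "sd_log10_bandwidth",
                 "peak_cs", "peak_sf", "bandwidth_oct"), np.nan,
            ) | {"n_trials": 0}
            continue
        ll = loglik[:, k]
        w = np.exp(ll - ll.max())
        w /= w.sum()
        means = node_vals @ w
        sds = np.sqrt(np.maximum((node_vals - means[:, None]) ** 2 @ w, 0.0))
        rows[(obs, loc)] = {
            "mean_log10_peak_cs": means[0],
            "mean_log10_peak_sf": means[1],
            "mean_log10_bandwidth": means[2],
            "sd_log10_peak_cs": sds[0],
            "sd_log10_peak_sf": sds[1],
            "sd_log10_bandwidth": sds[2],
            "peak_cs": 10.0 ** means[0],
            "peak_sf": 10.0 ** means[1],
            "bandwidth_oct": 10.0 ** means[2],
            "n_trials": int(counts[k]),
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index = pd.MultiIndex.from_tuples(frame.index, names=["observer_id", "location"])
    return BIPResult(frame=frame, grid_shape=grid_shape)


def _ensure_pd(mat: np.ndarray, label: str, degenerate: list[str]) -> np.ndarray:
    mat = (mat + mat.T) / 2.0
    if np.linalg.eigvalsh(mat).min() < 1e-8:
        degenerate.append(label)
        mat = mat + COV_RIDGE * np.eye(mat.shape[0])
    return mat


def summarize_bip(result: BIPResult) -> BIPSummary:
    """Across-observer means, SDs, and covariance seeds from BIP fits.

    The population-level covariance ``sigma_bip`` is the sample
    covariance of the stacked (3 params x 3 locations) per-observer
    estimate vectors.  The individual-level covariance ``phi_bip[j]``
    is, per location, the covariance of each observer's deviation from
    their own across-location mean — a documented construction, since
    independent per-cell fits do not define it uniquely.  Degenerate
    matrices receive a diagonal ridge and are flagged.
    """
    stacked = result.stacked_estimates().to_numpy(float)
    n_obs = stacked.shape[0]
    if n_obs < 2:
        raise ValueError("summarize_bip needs at least 2 complete observers")
    per_loc = stacked.reshape(n_obs, 3, 3)  # (obs, location, param)

    location_means = per_loc.mean(axis=0)
    location_sds = per_loc.std(axis=0, ddof=1)

    degenerate: list[str] = []
    sigma = np.cov(stacked, rowvar=False, ddof=1)
    sigma = _ensure_pd(sigma, "sigma_bip", degenerate)

    dev = per_loc - per_loc.mean(axis=1, keepdims=True)
    phi = np.empty((3, 3, 3))
    for j, loc in enumerate(design.LOCATIONS):
        phi_j = np.cov(dev[:, j, :], rowvar=False, ddof=1)
        phi[j] = _ensure_pd(np.atleast_2d(phi_j), f"phi_bip[{loc}]", degenerate)

    return BIPSummary(
        location_means=location_means,
        location_sds=location_sds,
        sigma_bip=sigma,
        phi_bip=phi,
        n_observers=n_obs,
        degenerate=degenerate,
    )
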