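"""Synthetic observer populations and trial-level 2AFC response data.

The generator mirrors the statistical structure the hierarchical model
assumes: observer-level mean CSF parameters are drawn from a population
multivariate Gaussian over the stacked (3 parameters x 3 locations)
vector, per-location test parameters add individual-level Gaussian
noise, and trial responses are Bernoulli draws from the psychometric
function.  Population means encode the polar-angle asymmetries (HVA:
horizontal better than vertical; VMA: lower vertical better than upper
vertical), so every downstream stage — adaptive testing, per-observer
fits, the hierarchical model, covariance and permutation analyses — can
be exercised end to end on data whose ground truth is known.

Parameter space conventions: population/within covariances act on
(log10 peak-CS, log10 peak-SF, bandwidth-in-octaves) per location,
stacked location-major into 9-vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design
from .csf_core import DEFAULT_PSYCHOMETRIC, CSFParams, PsychometricConfig, _p_correct_arrays
from .qcsf import PosteriorGrid, StimulusLikelihoodTable, StimulusSpace, make_stimulus_space

__all__ = [
    "PopulationSpec",
    "TrialRecord",
    "TRIAL_COLUMNS",
    "default_study_spec",
    "sample_population",
    "simulate_session",
    "simulate_cohort",
    "make_cohort",
]

#: Canonical trial-table schema (the serialized CSV uses the same names).
TRIAL_COLUMNS = (
    "observer_id", "location", "test_id", "trial_index",
    "sf_cpd", "contrast", "response",
)

#: Parameter names in stacked order within one location block.
PARAM_NAMES = ("log10_peak_cs", "log10_peak_sf", "bandwidth_oct")


@dataclass(frozen=True)
class TrialRecord:
    """One 2AFC trial: stimulus, response, and its (i, j, k, m) indices."""

    observer_id: int
    location: str
    test_id: int
    trial_index: int
    sf_cpd: float
    contrast: float
    response: int


@dataclass(frozen=True, eq=False)
class PopulationSpec:
    """Generative description of an observer population.

    Attributes
    ----------
    location_means : (3, 3) array
        Per-location mean of (log10 peak-CS, log10 peak-SF, bandwidth in
        octaves), rows in :data:`csfpolar.design.LOCATIONS` order.
    population_cov : (9, 9) array
        Covariance of the stacked observer-level mean vector (location-
        major blocks of the three parameters).
    within_cov : (3, 3, 3) array
        Per-location individual-level (test-retest) covariance.
    n_observers : int
    shared_bandwidth : bool
        If true, each observer has a single bandwidth shared across
        locations (the translation-invariant CSF-shape regime).
    """

    location_means: np.ndarray
    population_cov: np.ndarray
    within_cov: np.ndarray
    n_observers: int = 28
    shared_bandwidth: bool = True

    def __post_init__(self) -> None:
        lm = np.asarray(self.location_means, dtype=float)
        pc = np.asarray(self.population_cov, dtype=float)
        wc = np.asarray(self.within_cov, dtype=float)
        if lm.shape != (3, 3):
            raise ValueError("location_means must be 3x3 (locations x params)")
        if pc.shape != (9, 9):
            raise ValueError("population_cov must be 9x9")
        if wc.shape != (3, 3, 3):
            raise ValueError("within_cov must be 3 stacked 3x3 matrices")
        for name, m in (("population_cov", pc),) + tuple(
            (f"within_cov[{j}]", wc[j]) for j in range(3)
        ):
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} is not symmetric")
            if np.linalg.eigvalsh(m).min() <= 0.0:
                raise ValueError(f"{name} is not positive definite")
        if self.n_observers < 1:
            raise ValueError("n_observers must be >= 1")
        object.__setattr__(self, "location_means", lm)
        object.__setattr__(self, "population_cov", pc)
        object.__setattr__(self, "within_cov", wc)

    @property
    def stacked_means(self) -> np.ndarray:
        """Population mean of the stacked 9-vector."""
        return self.location_means.ravel()


def _valid_correlation(corr: np.ndarray, floor: float = 1e-3) -> np.ndarray:
    """Project a symmetric matrix to the nearest unit-diagonal PD matrix.

    Eigenvalues are floored and the diagonal rescaled to 1; for the
    default constants the adjustment is negligible, the projection just
    guards hand-tuned structures against numerical indefiniteness.
    """
    vals, vecs = np.linalg.eigh((corr + corr.T) / 2.0)
    fixed = (vecs * np.maximum(vals, floor)) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def default_study_spec(
    n_observers: int = 28,
    hva_offset: float = 0.15,
    vma_offset: float = 0.10,
    shared_bandwidth: bool = True,
) -> PopulationSpec:
    """Population spec emulating the study cohort.

    28 observers, three locations at 6 deg eccentricity.  The location
    means encode the HVA/VMA ordering in log10 peak-CS (offsets of
    ``hva_offset`` between the horizontal and the vertical-meridian
    average, ``vma_offset`` between lower and upper vertical) and a
    smaller shift in log10 peak-SF; mean bandwidth is 2.9 octaves at all
    locations.  Off-diagonal structure follows the qualitative pattern
    the analyses probe: strong positive same-attribute correlations
    across locations, a peak-CS/peak-SF coupling at the horizontal
    meridian only, and negative bandwidth couplings everywhere.  These
    are synthetic calibration constants, not measured values.
    """
    mean_lc = 1.60  # grand mean log10 peak-CS
    lc = (mean_lc + 2.0 * hva_offset / 3.0,
          mean_lc - hva_offset / 3.0 + vma_offset / 2.0,
          mean_lc - hva_offset / 3.0 - vma_offset / 2.0)
    lf = (0.25, 0.18, 0.12)
    bw = (2.9, 2.9, 2.9)
    location_means = np.array([
        [lc[0], lf[0], bw[0]],
        [lc[1], lf[1], bw[1]],
        [lc[2], lf[2], bw[2]],
    ])

    sds = np.tile([0.18, 0.15, 0.35], 3)
    corr = np.eye(9)
    same_attr = {0: 0.7, 1: 0.7, 2: 0.8}   # lc, lf, bw across locations
    within = {(0, 1): (0.6, 0.0, 0.0),     # lc-lf: horizontal only
              (0, 2): (-0.3, -0.3, -0.3),  # lc-bw
              (1, 2): (-0.3, -0.3, -0.3)}  # lf-bw
    for j in range(3):
        for jj in range(3):
            for a in range(3):
                for b in range(3):
                    r, c = 3 * j + a, 3 * jj + b
                    if r == c:
                        continue
                    if a == b and j != jj:
                        corr[r, c] = same_attr[a]
                    elif j == jj:
                        key = (min(a, b), max(a, b))
                        corr[r, c] = within[key][j]
    corr = _valid_correlation(corr)
    population_cov = corr * np.outer(sds, sds)

    within_cov = np.stack([np.diag([0.08, 0.10, 0.15]) ** 2] * 3)
    return PopulationSpec(
        location_means=location_means,
        population_cov=population_cov,
        within_cov=within_cov,
        n_observers=n_observers,
        shared_bandwidth=shared_bandwidth,
    )


def sample_population(
    spec: PopulationSpec, seed: int | np.random.SeedSequence = 0
) -> pd.DataFrame:
    """Draw an observer cohort from a population spec.

    Returns a tidy frame with one row per observer-location holding the
    test-level CSF parameters (linear scale) alongside the observer-
    level means they were drawn from (``rho_*`` columns, generator
    space).  Deterministic under ``seed``; each observer consumes an
    independent substream so partial cohorts are reproducible.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in root.spawn(spec.n_observers)]
    chol_pop = np.linalg.cholesky(spec.population_cov)
    chol_within = [np.linalg.cholesky(spec.within_cov[j]) for j in range(3)]

    rows = []
    for i, rng in enumerate(streams, start=1):
        rho = spec.stacked_means + chol_pop @ rng.standard_normal(9)
        rho = rho.reshape(3, 3).copy()
        if spec.shared_bandwidth:
            rho[:, 2] = rho[:, 2].mean()
        shared_noise_bw = None
        for j, loc in enumerate(design.LOCATIONS):
            noise = chol_within[j] @ rng.standard_normal(3)
            theta = rho[j] + noise
            if spec.shared_bandwidth:
                # one test-level bandwidth per observer, copied across
                # locations; its noise is drawn once (location 0 stream)
                if shared_noise_bw is None:
                    shared_noise_bw = noise[2]
                theta[2] = rho[j, 2] + shared_noise_bw
            theta[2] = max(theta[2], 1e-3)  # bandwidth stays positive
            rows.append({
                "observer_id": i,
                "location": loc,
                "peak_cs": 10.0 ** theta[0],
                "peak_sf": 10.0 ** theta[1],
                "bandwidth_oct": theta[2],
                "rho_log10_peak_cs": rho[j, 0],
                "rho_log10_peak_sf": rho[j, 1],
                "rho_bandwidth_oct": rho[j, 2],
            })
    return pd.DataFrame(rows)


def _params_arrays(params_df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lc = np.log10(params_df["peak_cs"].to_numpy(float))
    lf = np.log10(params_df["peak_sf"].to_numpy(float))
    bw = params_df["bandwidth_oct"].to_numpy(float)
    return lc, lf, bw


def _simulate_cells(
    params_df: pd.DataFrame,
    n_trials: int,
    policy: str,
    space: StimulusSpace,
    cfg: PsychometricConfig,
    rng: np.random.Generator,
    grid: PosteriorGrid | None,
    table: StimulusLikelihoodTable | None,
) -> pd.DataFrame:
    """Lockstep session simulation for every row (cell) of ``params_df``.

    All cells advance one trial per step; under the qCSF policy they
    share one stimulus-likelihood table, and each cell threads its own
    posterior-weight vector.
    """
    n_cells = len(params_df)
    lc, lf, bw = _params_arrays(params_df)
    n_stim = space.n_stimuli

    if policy == "qcsf":
        if grid is None:
            grid = PosteriorGrid.uniform()
        if table is None:
            table = StimulusLikelihoodTable(grid, space, cfg)
        weights = np.tile(grid.weights, (n_cells, 1))
        p_table = table.p_correct
        # true correct-response probability of every cell at every stimulus
        p_true_all = _p_correct_arrays(
            table.stim_log_sf[None, :], table.stim_contrast[None, :],
            lc[:, None], lf[:, None], bw[:, None],
            cfg.guess, cfg.lapse, cfg.slope,
        )
    elif policy == "random":
        stim_log_sf = np.broadcast_to(
            np.log10(space.sfs)[:, None], (space.sfs.size, space.contrasts.size)
        ).ravel()
        stim_contrast = np.broadcast_to(
            space.contrasts[None, :], (space.sfs.size, space.contrasts.size)
        ).ravel()
        p_true_all = _p_correct_arrays(
            stim_log_sf[None, :], stim_contrast[None, :],
            lc[:, None], lf[:, None], bw[:, None],
            cfg.guess, cfg.lapse, cfg.slope,
        )
    else:
        raise ValueError(f"unknown policy {policy!r}; expected 'qcsf' or 'random'")

    sel = np.empty((n_trials, n_cells), dtype=np.int64)
    resp = np.empty((n_trials, n_cells), dtype=np.int8)
    cell_idx = np.arange(n_cells)
    for t in range(n_trials):
        if policy == "qcsf":
            eig = table.eig_all(weights)  # (n_cells, n_stim) via matmul
            chosen = np.argmax(eig, axis=1)
        else:
            chosen = rng.integers(0, n_stim, size=n_cells)
        p_true = p_true_all[cell_idx, chosen]
        r = (rng.random(n_cells) < p_true).astype(np.int8)
        sel[t] = chosen
        resp[t] = r
        if policy == "qcsf":
            like = p_table[:, chosen].T  # (n_cells, nodes)
            like = np.where(r[:, None] == 1, like, 1.0 - like)
            weights *= like
            weights /= weights.sum(axis=1, keepdims=True)

    sf_levels = np.broadcast_to(
        space.sfs[:, None], (space.sfs.size, space.contrasts.size)
    ).ravel()
    c_levels = np.broadcast_to(
        space.contrasts[None, :], (space.sfs.size, space.contrasts.size)
    ).ravel()
    frames = []
    for c in range(n_cells):
        row = params_df.iloc[c]
        frames.append(pd.DataFrame({
            "observer_id": int(row["observer_id"]),
            "location": row["location"],
            "test_id": 1,
            "trial_index": np.arange(1, n_trials + 1),
            "sf_cpd": sf_levels[sel[:, c]],
            "contrast": c_levels[sel[:, c]],
            "response": resp[:, c].astype(int),
        }))
    out = pd.concat(frames, ignore_index=True)
    if policy == "qcsf":
        out.attrs["final_weights"] = weights
        out.attrs["grid"] = grid
    return out


def simulate_session(
    params: CSFParams,
    n_trials: int,
    policy: str = "qcsf",
    space: StimulusSpace | None = None,
    cfg: PsychometricConfig = DEFAULT_PSYCHOMETRIC,
    seed: int = 0,
    observer_id: int = 1,
    location: str = "horizontal",
    grid: PosteriorGrid | None = None,
    table: StimulusLikelihoodTable | None = None,
) -> pd.DataFrame:
    """Simulate one observer-location session of ``n_trials`` 2AFC trials.

    ``policy='qcsf'`` places each trial at the EIG-maximising stimulus
    given the running grid posterior; ``policy='random'`` samples
    stimuli uniformly from the space.  Responses are Bernoulli draws
    from the psychometric function at the generating parameters.  Under
    the qCSF policy the final posterior weights are attached to the
    returned frame as ``df.attrs['final_weights']``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if space is None:
        space = make_stimulus_space()
    cell = pd.DataFrame([{
        "observer_id": observer_id,
        "location": location,
        "peak_cs": params.peak_cs,
        "peak_sf": params.peak_sf,
        "bandwidth_oct": params.bandwidth_oct,
    }])
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return _simulate_cells(cell, n_trials, policy, space, cfg, rng, grid, table)


def simulate_cohort(
    params_df: pd.DataFrame,
    n_trials: int = 150,
    policy: str = "qcsf",
    space: StimulusSpace | None = None,
    cfg: PsychometricConfig = DEFAULT_PSYCHOMETRIC,
    seed: int = 0,
    grid: PosteriorGrid | None = None,
) -> pd.DataFrame:
    """Simulate every observer-location session of a sampled cohort.

    ``params_df`` is the output of :func:`sample_population`.  Sessions
    run in lockstep sharing one precomputed likelihood table, which
    makes a 28 x 3 cohort of qCSF sessions tractable on one core.
    """
    if space is None:
        space = make_stimulus_space()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return _simulate_cells(params_df, n_trials, policy, space, cfg, rng, grid, None)


def make_cohort(
    spec: PopulationSpec | None = None,
    n_trials: int = 150,
    policy: str = "qcsf",
    seed: int = 0,
    space: StimulusSpace | None = None,
    cfg: PsychometricConfig = DEFAULT_PSYCHOMETRIC,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a cohort and simulate its sessions; returns (trials, truth).

    Two independent substreams of ``seed`` drive parameter sampling and
    response generation.
    """
    if spec is None:
        spec = default_study_spec()
    s_pop, s_trials = np.random.SeedSequence(seed).spawn(2)
    truth = sample_population(spec, seed=s_pop)
    rng = np.random.default_rng(s_trials)
    if space is None:
        space = make_stimulus_space()
    trials = _simulate_cells(truth, n_trials, policy, space, cfg, rng, None, None)
    return trials, truth
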