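"""Grid-based Bayesian CSF estimation and adaptive stimulus selection (qCSF).

The posterior over the three CSF parameters is maintained on a fixed
product grid in (log10 peak-CS, log10 peak-SF, bandwidth) space; each
trial multiplies the weights by the trial likelihood and renormalises.
The qCSF policy picks the next (SF, contrast) pair from a discrete
stimulus space by maximising the one-step expected information gain
(EIG, in bits): the expected reduction in posterior entropy over the
two possible 2AFC outcomes.

For speed, the per-node response probabilities for every stimulus in
the space can be precomputed once into a :class:`StimulusLikelihoodTable`
and shared across trials (and, in cohort simulations, across sessions).
EIG is then evaluated for all stimuli at once through the mutual
information identity ``I(theta; R) = H(R) - H(R | theta)``, which equals
the posterior-entropy-reduction definition exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from . import design
from .csf_core import (
    DEFAULT_PSYCHOMETRIC,
    PsychometricConfig,
    _p_correct_arrays,
)

__all__ = [
    "StimulusSpace",
    "make_stimulus_space",
    "PosteriorGrid",
    "StimulusLikelihoodTable",
    "update_posterior",
    "expected_information_gain",
    "select_next_stimulus",
]

#: Default grid resolution (log10 peak-CS x log10 peak-SF x bandwidth nodes).
DEFAULT_GRID_SHAPE = (30, 30, 20)

#: Extra headroom above the peak-CS prior ceiling for adaptive testing,
#: in log10 units, so strong observers do not pile up on the edge node.
PEAK_CS_GRID_MARGIN = 0.1


@dataclass(frozen=True, eq=False)
class StimulusSpace:
    """Discrete stimulus space: ordered contrast and SF levels."""

    contrasts: np.ndarray
    sfs: np.ndarray

    def __post_init__(self) -> None:
        for name in ("contrasts", "sfs"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.ndim != 1 or v.size < 1:
                raise ValueError(f"{name} must be a non-empty 1-D array")
            if np.any(v <= 0.0) or np.any(np.diff(v) <= 0.0):
                raise ValueError(f"{name} must be positive and strictly increasing")
        if np.any(self.contrasts > 1.0):
            raise ValueError("contrasts must not exceed 1")

    @property
    def n_stimuli(self) -> int:
        return self.contrasts.size * self.sfs.size

    def stimulus(self, index: int) -> tuple[float, float]:
        """(sf, contrast) of flat stimulus ``index`` (SF-major order)."""
        i_sf, i_c = divmod(index, self.contrasts.size)
        return float(self.sfs[i_sf]), float(self.contrasts[i_c])


def make_stimulus_space(
    n_contrasts: int = design.DEFAULT_N_CONTRASTS,
    c_range: tuple[float, float] = design.DEFAULT_CONTRAST_RANGE,
    n_sfs: int = design.DEFAULT_N_SFS,
    sf_range: tuple[float, float] = design.DEFAULT_SF_RANGE,
) -> StimulusSpace:
    """Log-evenly spaced stimulus space with both endpoints included.

    Defaults reproduce the study design: 60 contrasts spanning
    [0.001, 1] and 12 spatial frequencies spanning [0.5, 16] cpd.
    """
    if n_contrasts < 2 or n_sfs < 2:
        raise ValueError("need at least 2 levels per stimulus dimension")
    for lo, hi in (c_range, sf_range):
        if not (0.0 < lo < hi):
            raise ValueError(f"invalid range ({lo}, {hi})")
    return StimulusSpace(
        contrasts=np.geomspace(c_range[0], c_range[1], n_contrasts),
        sfs=np.geomspace(sf_range[0], sf_range[1], n_sfs),
    )


@dataclass(eq=False)
class PosteriorGrid:
    """Discrete joint posterior over (log10 peak-CS, log10 peak-SF, bandwidth).

    ``axes`` holds the three marginal grids — the first two on the log10
    scale, the third in octaves but log-spaced, so that uniform weights
    realise the uniform-in-log10 priors on all three parameters.
    ``weights`` is the flattened joint probability mass (C-order over the
    three axes) and sums to 1.
    """

    axis_log_peak_cs: np.ndarray
    axis_log_peak_sf: np.ndarray
    axis_bandwidth: np.ndarray
    weights: np.ndarray

    # flattened per-node parameter values, filled in __post_init__
    node_log_peak_cs: np.ndarray = field(init=False, repr=False)
    node_log_peak_sf: np.ndarray = field(init=False, repr=False)
    node_bandwidth: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        lc, lf, bw = np.meshgrid(
            self.axis_log_peak_cs, self.axis_log_peak_sf, self.axis_bandwidth,
            indexing="ij",
        )
        self.node_log_peak_cs = lc.ravel()
        self.node_log_peak_sf = lf.ravel()
        self.node_bandwidth = bw.ravel()
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.weights.size != self.node_bandwidth.size:
            raise ValueError("weights size does not match the grid")
        if np.any(self.weights < 0.0):
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"weights must sum to 1, got {total}")

    @classmethod
    def uniform(
        cls,
        shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
        log_peak_cs_range: tuple[float, float] | None = None,
        log_peak_sf_range: tuple[float, float] | None = None,
        log_bandwidth_range: tuple[float, float] | None = None,
        peak_cs_margin: float = PEAK_CS_GRID_MARGIN,
    ) -> "PosteriorGrid":
        """Uniform prior grid over the standard prior boxes.

        ``peak_cs_margin`` extends the top of the peak-CS axis beyond
        the prior box (adaptive-testing default); pass 0 for fits that
        must stay strictly inside the prior support.
        """
        if log_peak_cs_range is None:
            lo, hi = design.PRIOR_LOG10_PEAK_CS
            log_peak_cs_range = (lo, hi + peak_cs_margin)
        if log_peak_sf_range is None:
            log_peak_sf_range = design.PRIOR_LOG10_PEAK_SF
        if log_bandwidth_range is None:
            log_bandwidth_range = design.PRIOR_LOG10_BANDWIDTH
        n1, n2, n3 = shape
        axes = (
            np.linspace(*log_peak_cs_range, n1),
            np.linspace(*log_peak_sf_range, n2),
            10.0 ** np.linspace(*log_bandwidth_range, n3),
        )
        w = np.full(n1 * n2 * n3, 1.0 / (n1 * n2 * n3))
        return cls(axes[0], axes[1], axes[2], w)

    @property
    def n_nodes(self) -> int:
        return self.weights.size

    def copy(self) -> "PosteriorGrid":
        return PosteriorGrid(
            self.axis_log_peak_cs, self.axis_log_peak_sf, self.axis_bandwidth,
            self.weights.copy(),
        )

    def entropy(self) -> float:
        """Shannon entropy of the posterior weights, in bits."""
        return float(-xlogy(self.weights, self.weights).sum() / math.log(2.0))

    def response_probabilities(
        self, sf: float, contrast: float,
        cfg: PsychometricConfig = DEFAULT_PSYCHOMETRIC,
    ) -> np.ndarray:
        """Per-node probability of a correct response to (sf, contrast)."""
        return _p_correct_arrays(
            math.log10(sf), contrast,
            self.node_log_peak_cs, self.node_log_peak_sf, self.node_bandwidth,
            cfg.guess, cfg.lapse, cfg.slope,
        )

    def mean_log10(self) -> np.ndarray:
        """Posterior mean of (log10 peak-CS, log10 peak-SF, log10 bandwidth)."""
        w = self.weights
        return np.array([
            float(w @ self.node_log_peak_cs),
            float(w @ self.node_log_peak_sf),
            float(w @ np.log10(self.node_bandwidth)),
        ])

    def sd_log10(self) -> np.ndarray:
        """Posterior SD of the same three log10 quantities."""
        w = self.weights
        out = []
        for vals in (self.node_log_peak_cs, self.node_log_peak_sf,
                     np.log10(self.node_bandwidth)):
            m = w @ vals
            out.append(math.sqrt(max(w @ (vals - m) ** 2, 0.0)))
        return np.array(out)


class StimulusLikelihoodTable:
    """Precomputed correct-response probabilities, nodes x stimuli.

    Stimuli are ordered SF-major (all contrasts of the lowest SF first),
    so a flat ``argmax`` over the EIG vector breaks exact ties toward
    the lowest SF, then the lowest contrast.
    """

    def __init__(self, grid: PosteriorGrid, space: StimulusSpace,
                 cfg: PsychometricConfig = DEFAULT_PSYCHOMETRIC):
        self.space = space
        shape = (space.sfs.size, space.contrasts.size)
        stim_log_sf = np.broadcast_to(np.log10(space.sfs)[:, None], shape).ravel()
        stim_contrast = np.broadcast_to(space.contrasts[None, :], shape).ravel()
        self.stim_log_sf = stim_log_sf
        self.stim_contrast = stim_contrast
        # (nodes, n_sf * n_c)
        self.p_correct = _p_correct_arrays(
            stim_log_sf[None, :], stim_contrast[None, :],
            grid.node_log_peak_cs[:, None], grid.node_log_peak_sf[:, None],
            grid.node_bandwidth[:, None],
            cfg.guess, cfg.lapse, cfg.slope,
        )
        # Per-node binary response entropy (bits) for each stimulus.
        p = self.p_correct
        self.node_response_entropy = -(xlogy(p, p) + xlogy(1.0 - p, 1.0 - p)) / math.log(2.0)

    def eig_all(self, weights: np.ndarray) -> np.ndarray:
        """EIG (bits) of every stimulus for posterior ``weights``.

        Uses ``I(theta; R) = H(R) - H(R | theta)`` with the predictive
        probability ``p(R=1) = sum_theta w(theta) p(R=1 | theta)``.
        """
        w = np.asarray(weights, dtype=float)
        p1 = w @ self.p_correct
        h_marginal = -(xlogy(p1, p1) + xlogy(1.0 - p1, 1.0 - p1)) / math.log(2.0)
        h_conditional = w @ self.node_response_entropy
        return h_marginal - h_conditional


def update_posterior(
    grid: PosteriorGrid, sf: float, contrast: float, response: int,
    cfg: PsychometricConfig = DEFAULT_PSYCHOMETRIC,
) -> PosteriorGrid:
    """Bayes update of the grid posterior with one trial outcome.

    Returns a new grid with ``weights ~ prior * p(response | theta)``,
    renormalised.  A stimulus whose likelihood is constant over the grid
    (e.g. zero contrast) leaves the posterior unchanged.
    """
    if response not in (0, 1):
        raise ValueError(f"response must be 0 or 1, got {response!r}")
    like = grid.response_probabilities(sf, contrast, cfg)
    if response == 0:
        like = 1.0 - like
    new_w = grid.weights * like
    total = new_w.sum()
    if total <= 0.0:
        raise ValueError("degenerate update: likelihood annihilated all mass")
    return PosteriorGrid(
        grid.axis_log_peak_cs, grid.axis_log_peak_sf, grid.axis_bandwidth,
        new_w / total,
    )


def expected_information_gain(
    grid: PosteriorGrid, sf: float, contrast: float,
    cfg: PsychometricConfig = DEFAULT_PSYCHOMETRIC,
) -> float:
    """One-step expected information gain (bits) of testing (sf, contrast).

    ``EIG = H(prior) - sum_r p(r) H(posterior | r)``, the expected
    entropy reduction over the two 2AFC outcomes; non-negative and
    bounded by the prior entropy.
    """
    w = grid.weights
    like1 = grid.response_probabilities(sf, contrast, cfg)
    p1 = float(w @ like1)
    h_prior = grid.entropy()
    expected_h = 0.0
    for p_r, like in ((p1, like1), (1.0 - p1, 1.0 - like1)):
        if p_r <= 0.0:
            continue
        post = w * like / p_r
        expected_h += p_r * float(-xlogy(post, post).sum() / math.log(2.0))
    return h_prior - expected_h


def select_next_stimulus(
    grid: PosteriorGrid, space: StimulusSpace,
    cfg: PsychometricConfig = DEFAULT_PSYCHOMETRIC,
    table: StimulusLikelihoodTable | None = None,
) -> tuple[float, float]:
    """(sf, contrast) maximising EIG over the stimulus space.

    Deterministic: exact ties are broken toward the lowest SF, then the
    lowest contrast.  Pass a precomputed ``table`` (matching grid axes
    and space) to amortise the likelihood evaluation across trials.
    """
    if table is None:
        table = StimulusLikelihoodTable(grid, space, cfg)
    eig = table.eig_all(grid.weights)
    return space.stimulus(int(np.argmax(eig)))
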