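"""Deterministic core of the contrast sensitivity function (CSF).

The CSF is modeled as a log-parabola: on log10 axes, sensitivity is a
downward parabola with vertex at (log10 peak-SF, log10 peak-CS) whose
full width at half-maximum sensitivity is the bandwidth, expressed in
octaves.  A trial-level Weibull-family psychometric function links the
CSF to the probability of a correct response in a two-alternative
forced-choice (2AFC) task.  Derived attributes — the cutoff spatial
frequency (highest SF with sensitivity at least 1) and the area under
the log CSF (AULCSF) — summarise the "window of visibility".

Unit conventions
----------------
``bandwidth_oct`` is the FWHM in octaves (log2 frequency ratio).  The
log-parabola is evaluated on the log10 frequency axis, where one octave
spans ``log10(2)`` units, so the parabola uses ``w = bandwidth_oct *
log10(2)`` as its width parameter.  Internally (and everywhere sampling
happens) the three parameters are handled on the log10 scale; linear
values appear only at the API boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CSFParams",
    "PsychometricConfig",
    "DEFAULT_PSYCHOMETRIC",
    "NoSuprathresholdRange",
    "log_sensitivity",
    "p_correct",
    "cutoff_sf",
    "aulcsf",
]

LOG10_2 = math.log10(2.0)
_LN10 = math.log(10.0)


class NoSuprathresholdRange(ValueError):
    """Raised when peak sensitivity is below 1, so the CSF never crosses
    the sensitivity-1 line and the cutoff SF is undefined."""


@dataclass(frozen=True)
class CSFParams:
    """Parameters of one observer-location CSF (linear scale).

    Attributes
    ----------
    peak_cs : float
        Peak contrast sensitivity (inverse of the lowest detectable
        contrast at the best SF); dimensionless, > 0.
    peak_sf : float
        Spatial frequency of maximal sensitivity, in cycles per degree.
    bandwidth_oct : float
        Full width at half-maximum sensitivity, in octaves.
    """

    peak_cs: float
    peak_sf: float
    bandwidth_oct: float

    def __post_init__(self) -> None:
        for name in ("peak_cs", "peak_sf", "bandwidth_oct"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0.0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    @classmethod
    def from_log10(cls, log_peak_cs: float, log_peak_sf: float,
                   log_bandwidth: float) -> "CSFParams":
        """Build from the log10 representation used in sampling space."""
        return cls(10.0 ** log_peak_cs, 10.0 ** log_peak_sf, 10.0 ** log_bandwidth)

    def to_log10(self) -> tuple[float, float, float]:
        """(log10 peak-CS, log10 peak-SF, log10 bandwidth)."""
        return (
            math.log10(self.peak_cs),
            math.log10(self.peak_sf),
            math.log10(self.bandwidth_oct),
        )


@dataclass(frozen=True)
class PsychometricConfig:
    """Fixed non-CSF parameters of the 2AFC psychometric function.

    ``guess`` is the guessing rate g (0.5 for 2AFC), ``lapse`` the lapse
    rate lambda capping accuracy at 1 - lambda/2, and ``slope`` the
    Weibull slope beta.
    """

    guess: float = 0.5
    lapse: float = 0.04
    slope: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.guess < 1.0:
            raise ValueError(f"guess must be in [0, 1), got {self.guess}")
        if not 0.0 <= self.lapse < 1.0:
            raise ValueError(f"lapse must be in [0, 1), got {self.lapse}")
        if not self.slope > 0.0:
            raise ValueError(f"slope must be > 0, got {self.slope}")


DEFAULT_PSYCHOMETRIC = PsychometricConfig()


def _log_sensitivity_arrays(log10_sf, log_peak_cs, log_peak_sf, bandwidth_oct):
    """log10 sensitivity for array-valued parameters (broadcasting).

    Core formula, shared by the user-facing function and the grid code:
    ``log10 S = log10 peakCS - 4 log10(2) ((log10 sf - log10 peakSF)/w)^2``
    with ``w = bandwidth_oct * log10(2)``.
    """
    w = bandwidth_oct * LOG10_2
    return log_peak_cs - 4.0 * LOG10_2 * ((log10_sf - log_peak_sf) / w) ** 2


def log_sensitivity(sf, params: CSFParams):
    """log10 contrast sensitivity of the log-parabola CSF at ``sf`` (cpd).

    Symmetric in log frequency about ``peak_sf``; sensitivity falls to
    half its peak value exactly ``bandwidth_oct / 2`` octaves away from
    the peak on either side.
    """
    sf = np.asarray(sf, dtype=float)
    if np.any(sf <= 0.0) or not np.all(np.isfinite(sf)):
        raise ValueError("spatial frequency must be finite and > 0")
    lc, lf, _ = params.to_log10()
    out = _log_sensitivity_arrays(np.log10(sf), lc, lf, params.bandwidth_oct)
    return out if out.ndim else float(out)


def _p_correct_arrays(log10_sf, contrast, log_peak_cs, log_peak_sf,
                      bandwidth_oct, guess, lapse, slope):
    """Vectorised probability-correct with overflow guards.

    ``(c * S) ** beta`` is evaluated in log space and clipped so that
    extreme sensitivities neither overflow nor warn; ``contrast == 0``
    maps to the guessing rate exactly.
    """
    log_s = _log_sensitivity_arrays(log10_sf, log_peak_cs, log_peak_sf,
                                    bandwidth_oct)
    with np.errstate(divide="ignore"):
        t = slope * _LN10 * (np.log10(contrast) + log_s)
    x = np.exp(np.clip(t, -745.0, 700.0))
    return guess + (1.0 - guess - lapse / 2.0) * (-np.expm1(-x))


def p_correct(sf, contrast, params: CSFParams,
              cfg: PsychometricConfig = DEFAULT_PSYCHOMETRIC):
    """Probability of a correct 2AFC response at (``sf``, ``contrast``).

    ``p = g + (1 - g - lambda/2) (1 - exp(-(c S)^beta))`` with S the CSF
    sensitivity at ``sf``.  Monotone non-decreasing in contrast and in
    sensitivity; bounded in ``[g, 1 - lambda/2]``.
    """
    sf = np.asarray(sf, dtype=float)
    contrast = np.asarray(contrast, dtype=float)
    if np.any(sf <= 0.0) or not np.all(np.isfinite(sf)):
        raise ValueError("spatial frequency must be finite and > 0")
    if np.any(contrast < 0.0) or np.any(contrast > 1.0):
        raise ValueError("contrast must lie in [0, 1]")
    lc, lf, _ = params.to_log10()
    out = _p_correct_arrays(np.log10(sf), contrast, lc, lf,
                            params.bandwidth_oct, cfg.guess, cfg.lapse,
                            cfg.slope)
    return out if out.ndim else float(out)


def cutoff_sf(params: CSFParams) -> float:
    """Cutoff spatial frequency: the highest SF with sensitivity >= 1.

    Closed form for the upper root of ``log_sensitivity(sf) = 0``:
    ``log10 cutoff = log10 peakSF + (bandwidth/2) sqrt(log10(peakCS) * log10 2)``.
    Returns ``peak_sf`` itself when ``peak_cs == 1`` (the vertex touches
    the sensitivity-1 line) and raises :class:`NoSuprathresholdRange`
    when ``peak_cs < 1``.
    """
    lc, lf, _ = params.to_log10()
    if lc < 0.0:
        raise NoSuprathresholdRange(
            f"peak_cs={params.peak_cs} < 1: CSF never reaches sensitivity 1"
        )
    half_width = 0.5 * params.bandwidth_oct * math.sqrt(lc * LOG10_2)
    return 10.0 ** (lf + half_width)


def aulcsf(params: CSFParams, sf_lo: float = 0.5, sf_hi: float = 16.0) -> float:
    """Area under the log CSF over ``[sf_lo, sf_hi]`` cpd.

    Integrates ``max(log10 S(f), 0)`` against ``d(log10 f)`` — the log
    CSF truncated at sensitivity 1, so sub-threshold frequencies
    contribute nothing to the window of visibility.  The integrand is a
    clipped parabola, which is integrated in closed form over the
    intersection of the integration window with the suprathreshold
    interval.  Defaults cover the measured stimulus range 0.5-16 cpd.
    """
    if not (0.0 < sf_lo < sf_hi):
        raise ValueError(f"need 0 < sf_lo < sf_hi, got ({sf_lo}, {sf_hi})")
    a, u0, _ = params.to_log10()
    if a <= 0.0:
        return 0.0
    w = params.bandwidth_oct * LOG10_2
    k = 4.0 * LOG10_2 / w**2
    r = math.sqrt(a / k)
    lo = max(math.log10(sf_lo), u0 - r)
    hi = min(math.log10(sf_hi), u0 + r)
    if hi <= lo:
        return 0.0

    def antiderivative(u: float) -> float:
        return a * u - k * (u - u0) ** 3 / 3.0

    return antiderivative(hi) - antiderivative(lo)
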