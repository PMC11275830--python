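"""Study-design constants shared across the package.

The polar-angle locations, the stimulus ranges, and the uniform prior
boxes for the three CSF parameters (all on the log10 scale) are used by
the adaptive-testing grid, the per-observer Bayesian fits, and the
hierarchical model alike, so they live in one place.
"""

from __future__ import annotations

import math

#: Polar-angle locations at iso-eccentricity, in canonical order.
#: Left/right horizontal measurements are collapsed into ``horizontal``.
LOCATIONS: tuple[str, ...] = ("horizontal", "lower_vertical", "upper_vertical")

#: Number of locations (J).
N_LOCATIONS = len(LOCATIONS)

#: Uniform prior support for log10 peak contrast sensitivity.
PRIOR_LOG10_PEAK_CS: tuple[float, float] = (math.log10(10.0), math.log10(200.0))

#: Uniform prior support for log10 peak spatial frequency (cpd).
PRIOR_LOG10_PEAK_SF: tuple[float, float] = (math.log10(0.31), math.log10(3.16))

#: Uniform prior support for log10 bandwidth (octaves).
PRIOR_LOG10_BANDWIDTH: tuple[float, float] = (math.log10(1.58), math.log10(3.98))

#: The three prior boxes in (log10 peak-CS, log10 peak-SF, log10 bandwidth) order.
PRIOR_BOXES: tuple[tuple[float, float], ...] = (
    PRIOR_LOG10_PEAK_CS,
    PRIOR_LOG10_PEAK_SF,
    PRIOR_LOG10_BANDWIDTH,
)

#: Default stimulus space: contrast levels, log-evenly spaced.
DEFAULT_CONTRAST_RANGE: tuple[float, float] = (0.001, 1.0)
DEFAULT_N_CONTRASTS = 60

#: Default stimulus space: spatial frequencies in cpd, log-evenly spaced.
DEFAULT_SF_RANGE: tuple[float, float] = (0.5, 16.0)
DEFAULT_N_SFS = 12


def location_index(location: str) -> int:
    """Canonical 0-based index of a location name."""
    try:
        return LOCATIONS.index(location)
    except ValueError:
        raise ValueError(
            f"unknown location {location!r}; expected one of {LOCATIONS}"
        ) from None
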