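"""File formats and run configuration.

Everything is flat text: trials as CSV, parameters and reports as JSON,
MCMC samples as a long-format CSV (chain, iteration, parameter, value).
Indices are 1-based in files, matching the i/j/k/m notation of the
model; locations are encoded as strings.  Four-location files with
``left_horizontal`` / ``right_horizontal`` labels can be collapsed into
``horizontal`` at load time.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design
from .synthetic_data import TRIAL_COLUMNS

__all__ = [
    "read_trials",
    "write_trials",
    "write_truth",
    "read_truth",
    "RunConfig",
    "write_samples",
    "load_theta_samples",
]

_HORIZONTAL_ALIASES = {"left_horizontal", "right_horizontal"}


class TrialFormatError(ValueError):
    """Malformed trial CSV, with row/field diagnostics."""


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV with the canonical column order."""
    trials[list(TRIAL_COLUMNS)].to_csv(path, index=False)


def read_trials(path, collapse_horizontal: bool = False) -> pd.DataFrame:
    """Read and validate a trial CSV.

    With ``collapse_horizontal`` the left/right horizontal labels are
    merged into ``horizontal`` (the standard analysis convention);
    otherwise they are rejected as unknown.
    """
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise TrialFormatError(f"{path}: missing columns {sorted(missing)}")
    df = df[list(TRIAL_COLUMNS)].copy()
    if collapse_horizontal:
        df["location"] = df["location"].replace(
            {a: "horizontal" for a in _HORIZONTAL_ALIASES}
        )
    bad_loc = ~df["location"].isin(design.LOCATIONS)
    if bad_loc.any():
        row = int(df.index[bad_loc][0]) + 2  # header + 1-based
        raise TrialFormatError(
            f"{path}: line {row}: unknown location {df.loc[bad_loc.idxmax(), 'location']!r}"
        )
    for col, ok in (
        ("contrast", (df["contrast"] >= 0) & (df["contrast"] <= 1)),
        ("sf_cpd", df["sf_cpd"] > 0),
        ("response", df["response"].isin((0, 1))),
    ):
        if not ok.all():
            row = int(df.index[~ok][0]) + 2
            raise TrialFormatError(
                f"{path}: line {row}: invalid value in field {col!r}"
            )
    return df


def write_truth(truth: pd.DataFrame, path) -> None:
    """Ground-truth generator parameters as a JSON sidecar."""
    records = truth.to_dict(orient="records")
    Path(path).write_text(json.dumps({"observers": records}, indent=1))


def read_truth(path) -> pd.DataFrame:
    return pd.DataFrame(json.loads(Path(path).read_text())["observers"])


@dataclasses.dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run.

    Serialized alongside every run's outputs for provenance.  Override
    chain: dataclass defaults < YAML file < command-line flags.
    """

    seed: int = 0
    n_observers: int = 28
    n_trials: int = 150
    policy: str = "qcsf"
    variant: str = "fixed_bandwidth"
    profile: str = "desk"
    n_chains: int = 3
    n_samples: int = 2000
    burn_in: int | None = None
    adaptation: int | None = None
    shared_bandwidth: bool = True
    collapse_horizontal: bool = False

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def hbm_config(self):
        from .hbm import HBMConfig
        if self.profile == "paper-scale":
            base = HBMConfig.paper_scale(variant=self.variant, seed=self.seed,
                                         n_chains=self.n_chains,
                                         n_samples=self.n_samples)
        elif self.profile == "desk":
            base = HBMConfig(variant=self.variant, seed=self.seed,
                             n_chains=self.n_chains, n_samples=self.n_samples)
        else:
            raise ValueError(f"unknown profile {self.profile!r}")
        kw = {}
        if self.burn_in is not None:
            kw["burn_in"] = self.burn_in
        if self.adaptation is not None:
            kw["adaptation"] = self.adaptation
        return base.replace(**kw) if kw else base


_PARAM_NAMES = ("log10_peak_cs", "log10_peak_sf", "log10_bandwidth")


def write_samples(fit, path) -> None:
    """MCMC draws as long CSV: chain, iteration, parameter, value."""
    c, s, n_i, _, _ = fit.theta_samples.shape
    frames = []
    theta = fit.theta_samples.reshape(c, s, -1)
    names = [
        f"theta[{obs},{loc},{p}]"
        for obs in fit.observers for loc in design.LOCATIONS for p in _PARAM_NAMES
    ]
    chain_col = np.repeat(np.arange(1, c + 1), s)
    iter_col = np.tile(np.arange(1, s + 1), c)
    for k, name in enumerate(names):
        frames.append(pd.DataFrame({
            "chain": chain_col, "iteration": iter_col,
            "parameter": name, "value": theta[:, :, k].ravel(),
        }))
    for d in range(fit.mu_samples.shape[-1]):
        frames.append(pd.DataFrame({
            "chain": chain_col, "iteration": iter_col,
            "parameter": f"mu[{d}]", "value": fit.mu_samples[:, :, d].ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


class _SamplesView:
    """Minimal fit-like view over reloaded theta samples (pooled access)."""

    def __init__(self, theta: np.ndarray, observers: np.ndarray):
        self._theta = theta
        self.observers = observers

    def pooled_theta(self) -> np.ndarray:
        return self._theta


def load_theta_samples(path) -> _SamplesView:
    """Rebuild pooled test-level draws from a samples CSV."""
    df = pd.read_csv(path)
    theta = df[df["parameter"].str.startswith("theta[")].copy()
    pat = re.compile(r"theta\[(\d+),([a-z_]+),log10_(peak_cs|peak_sf|bandwidth)\]")
    parsed = theta["parameter"].str.extract(pat)
    theta["obs"] = parsed[0].astype(int)
    theta["loc"] = parsed[1].map(design.location_index)
    theta["par"] = parsed[2].map({"peak_cs": 0, "peak_sf": 1, "bandwidth": 2})
    observers = np.sort(theta["obs"].unique())
    obs_pos = {o: k for k, o in enumerate(observers)}
    n_c = theta["chain"].max()
    n_s = theta["iteration"].max()
    out = np.empty((n_c * n_s, len(observers), 3, 3))
    flat_idx = ((theta["chain"] - 1) * n_s + (theta["iteration"] - 1)).to_numpy()
    out[flat_idx, theta["obs"].map(obs_pos).to_numpy(),
        theta["loc"].to_numpy(), theta["par"].to_numpy()] = theta["value"].to_numpy()
    return _SamplesView(out, observers)
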