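"""Run configuration for the measurement pipeline.

Defaults reproduce the published analysis parameters: Gaussian smoothing
with sigma = 80 nm, a background threshold of 25 counts, a minimum spot
size of 10 voxels and an r^2 > 0.8 acceptance gate on the lateral
Gaussian fits.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Any, Optional

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    smoothing_sigma_nm: float = 80.0
    background_threshold_counts: float = 25.0
    min_spot_voxels: int = 10
    r2_accept: float = 0.8
    fit_window_halfwidth_voxels: int = 5
    dark_quantile: float = 0.10
    # "raw" fits amplitudes on the unsmoothed channel so pre-filtering does
    # not deflate brightness; "smoothed" is available for parity checks.
    fit_on: str = "raw"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        def _check(cond: bool, name: str, bound: str) -> None:
            if not cond:
                raise ValueError(
                    f"RunConfig.{name}={getattr(self, name)!r} out of range: must be {bound}"
                )

        _check(self.smoothing_sigma_nm > 0, "smoothing_sigma_nm", "> 0")
        _check(self.background_threshold_counts > 0, "background_threshold_counts", "> 0")
        _check(self.min_spot_voxels > 0, "min_spot_voxels", "> 0")
        _check(0 < self.r2_accept < 1, "r2_accept", "in (0, 1)")
        _check(self.fit_window_halfwidth_voxels >= 1, "fit_window_halfwidth_voxels", ">= 1")
        _check(0 < self.dark_quantile < 0.5, "dark_quantile", "in (0, 0.5)")
        _check(self.fit_on in ("raw", "smoothed"), "fit_on", "'raw' or 'smoothed'")

    def replace(self, **kwargs: Any) -> "RunConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def load_config(path: Optional[str | Path] = None, **overrides: Any) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML/JSON file plus overrides.

    With no file and no overrides the published defaults are returned.
    Keyword overrides win over file values. Unknown keys and out-of-range
    values raise ``ValueError`` naming the offending parameter.
    """
    values: dict[str, Any] = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping, got {type(loaded).__name__}")
        values.update(loaded)
    values.update(overrides)

    known = set(RunConfig.__dataclass_fields__)
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config parameter(s): {sorted(unknown)}")
    return RunConfig(**values)
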