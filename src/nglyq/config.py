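"""Layered run configuration: defaults < YAML file < explicit overrides.

Every tolerance and threshold used across the pipeline lives here so that
output headers can embed the effective configuration and runs are
reproducible from the header alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # tolerances (ppm unless noted)
    precursor_ppm: float = 10.0
    fragment_ppm: float = 20.0
    oxonium_ppm: float = 20.0
    envelope_ppm: float = 10.0
    s_score_tol_ppm: float = 200.0
    pair_rt_tol_min: float = 0.1

    # cascade thresholds
    m_score_floor: float = 0.5
    s_score_min: float = 98.0
    fdr: float = 0.01
    denoise_top: int = 200
    charges: tuple[int, ...] = (2, 3, 4, 5, 6)
    isotope_offset_recovery: int = 1  # +-k nucleons for mispicked monoisotope

    # quantitation
    tiq_rt_window_min: float = 2.0
    tiq_channel_ppm: float = 10.0
    n_top_isotopes: int = 3
    n_spectral_points: int = 3

    # cross-run comparison
    mbr_rt_window_min: float = 5.0
    cv_cutoff: float = 0.30
    fold_change_log2: float = 1.0

    seed: int = 0

    def __post_init__(self):
        self.charges = tuple(self.charges)
        if not (0 < self.fdr <= 1):
            raise ValueError("fdr must be in (0, 1]")
        if self.s_score_min < 0 or self.s_score_min > 100:
            raise ValueError("s_score_min must be within [0, 100]")
        for name in ("precursor_ppm", "fragment_ppm", "oxonium_ppm",
                     "envelope_ppm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["charges"] = list(self.charges)
        return d

    def header_line(self) -> str:
        return "#" + json.dumps({"config": self.to_dict()}, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_header(cls, line: str) -> "RunConfig":
        payload = json.loads(line.lstrip("#"))
        return cls.from_dict(payload["config"])


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Defaults, optionally updated from a YAML file, then from overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data.update(yaml.safe_load(fh) or {})
    data.update(overrides)
    return RunConfig.from_dict(data)
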