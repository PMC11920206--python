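"""Run configuration: every stage parameter in one serializable object.

A run's effective configuration is echoed into its output directory so any
result can be reproduced from the files alone; parameter provenance
(default / config file / command-line flag) is logged per key.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .regions import InvalidParameterError

log = logging.getLogger("fmscan")

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # locus / simulation
    scale: float = 100.0
    config: str = "FM-2"
    n_wt: int = 50
    n_fm_het: int = 0
    n_fm_hom: int = 50
    site_density: float = 1.0 / 200.0
    sfs_alpha: float | None = 0.3
    erosion_p: float = 0.9
    donor_divergence: float = 0.3
    seed: int = 0
    dup1_suppression_break: float | None = None
    dup2_ref_span: tuple[float, float] | None = None
    # observation
    depth: float = 30.0
    error_rate: float = 0.001
    het_lo: float = 0.2
    het_hi: float = 0.8
    # filtering & windows (window/step divided by scale when None)
    maf: float = 0.05
    max_missing: float = 0.9
    window_bp: int | None = None
    step_bp: int | None = None
    # site classes / bubble
    eps: float = 0.05
    tau: float = 0.5
    min_called: int = 20
    # CNV thresholds
    t1: float = 1.25
    t2: float = 1.75
    # breakpoint / LD
    lrt_threshold: float = 10.0
    contrast_threshold: float = 0.1

    def validate(self) -> "RunConfig":
        if not 0 < self.het_lo < self.het_hi < 1:
            raise InvalidParameterError("require 0 < het_lo < het_hi < 1")
        if not 0 < self.eps < 0.25:
            raise InvalidParameterError("eps must be in (0, 0.25)")
        if not 0 < self.t1 < self.t2:
            raise InvalidParameterError("require 0 < t1 < t2")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InvalidParameterError(
                f"unknown config key(s): {sorted(unknown)}")
        cfg = cls()
        for key, value in data.items():
            setattr(cfg, key, value)
            log.debug("config %s=%r (from %s)", key, value, path)
        for key, value in overrides.items():
            if value is not None:
                setattr(cfg, key, value)
                log.debug("config %s=%r (from flag)", key, value)
        if cfg.dup2_ref_span is not None:
            cfg.dup2_ref_span = tuple(cfg.dup2_ref_span)
        return cfg.validate()

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        if data.get("dup2_ref_span") is not None:
            data["dup2_ref_span"] = list(data["dup2_ref_span"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
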