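"""Run configuration: every analysis switch with its package default."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .karyotype import HETEROMORPHISM_THRESHOLD, PAIRING_WEIGHT
from .morphometrics import DEFAULT_THRESHOLDS


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration; defaults mirror the module-level conventions.

    The effective configuration is echoed into every report so results are
    reproducible from the report alone.
    """

    #: (label, lower arm-ratio bound) classification bins.
    thresholds: tuple[tuple[str, float], ...] = DEFAULT_THRESHOLDS
    #: include satellites in total chromosome length (TCL, CV_CL)?
    satellite_in_length: bool = True
    #: include satellites in the arm ratio / CA?
    satellite_in_ratio: bool = False
    #: relative CL difference above which homologs are heteromorphic.
    heteromorphism_threshold: float = HETEROMORPHISM_THRESHOLD
    #: arm-ratio weight in the pairing dissimilarity.
    pairing_weight: float = PAIRING_WEIGHT
    #: delta degrees of freedom of across-plate SDs (1 = sample SD).
    sd_ddof: int = 1
    #: output directory for report bundles.
    output_dir: str = "karyomorph_out"
    #: seed echoed into reports (simulation only; analysis is deterministic).
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = [list(t) for t in self.thresholds]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "thresholds" in d:
            d["thresholds"] = tuple((str(a), float(b)) for a, b in d["thresholds"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load overrides from a JSON key-value file."""
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
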