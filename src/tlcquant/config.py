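"""Declarative analysis configuration.

One flat record of every tunable threshold used by the pipeline, loadable
from a JSON or YAML file and hashable for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class AnalysisConfig:
    #: decode the input photo as gamma-encoded sRGB and linearize before
    #: densitometry; set False only for inputs already in linear intensity
    assume_srgb: bool = True
    #: downsample factor for plate detection
    detect_downsample: int = 4
    #: subsampling factor for the illumination fit
    fit_downsample: int = 4
    #: background model: "quartic" (15-term surface) or "constant"
    background_model: str = "quartic"
    #: re-fit the background once with above-threshold (spot) pixels
    #: excluded, removing their leverage on the surface
    refit_background: bool = True
    #: component filter: maximum bounding-box aspect ratio (and reciprocal)
    max_aspect: float = 3.0
    #: component filter: minimum area in pixels at a 12-megapixel plate,
    #: scaled proportionally with the actual plate area
    min_area: float = 25.0
    #: absolute lower bound for the scaled minimum area
    min_area_floor: int = 4
    #: fraction of disk pixels summed during spot integration
    top_fraction: float = 0.15
    #: maximum distance (px) between an annotation coordinate and a spot
    #: centre for them to be considered the same spot
    match_radius: float = 25.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data or {})
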