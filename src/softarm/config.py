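"""Plain-text (INI) configuration for the analysis pipeline.

Sections: [io] (dialect, zero_is_gap, max_gap_frames), [segments]
(proximal/distal marker-index triples), [classification] (posture
thresholds, degrees), [smoothing] (centered moving-average window in
frames; 0 or 1 disables). ``default_config_text()`` prints the defaults
the ``softarm config init`` command writes.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path

from .curvature import SegmentTriple

__all__ = ["Thresholds", "AnalysisConfig", "default_config_text"]


@dataclass(frozen=True)
class Thresholds:
    """Posture-classification thresholds, degrees.

    straight_kb_max: both segment chord angles below this -> nearly
    straight. nonplanar_min: |abduction| or |long-axis rotation| above
    this -> complex (non-planar) bending.
    """

    straight_kb_max: float = 15.0
    nonplanar_min: float = 30.0


@dataclass
class AnalysisConfig:
    dialect: str = "tsv"
    zero_is_gap: bool = False
    max_gap_frames: int = 0
    proximal: SegmentTriple = field(default_factory=lambda: SegmentTriple(0, 1, 2))
    distal: SegmentTriple = field(default_factory=lambda: SegmentTriple(2, 3, 4))
    thresholds: Thresholds = field(default_factory=Thresholds)
    smoothing_window: int = 0

    @classmethod
    def load(cls, path) -> "AnalysisConfig":
        parser = configparser.ConfigParser()
        parser.read_string(Path(path).read_text())
        cfg = cls()
        if parser.has_section("io"):
            io_ = parser["io"]
            cfg.dialect = io_.get("dialect", cfg.dialect)
            cfg.zero_is_gap = io_.getboolean("zero_is_gap", cfg.zero_is_gap)
            cfg.max_gap_frames = io_.getint("max_gap_frames", cfg.max_gap_frames)
        if parser.has_section("segments"):
            seg = parser["segments"]
            cfg.proximal = _parse_triple(seg.get("proximal", "0,1,2"))
            cfg.distal = _parse_triple(seg.get("distal", "2,3,4"))
        if parser.has_section("classification"):
            cls_ = parser["classification"]
            cfg.thresholds = Thresholds(
                straight_kb_max=cls_.getfloat("straight_kb_max", 15.0),
                nonplanar_min=cls_.getfloat("nonplanar_min", 30.0),
            )
        if parser.has_section("smoothing"):
            cfg.smoothing_window = parser["smoothing"].getint("window", 0)
        return cfg

    def save(self, path) -> None:
        Path(path).write_text(self.to_text())

    def to_text(self) -> str:
        t = self.thresholds
        return (
            "[io]\n"
            f"dialect = {self.dialect}\n"
            f"zero_is_gap = {str(self.zero_is_gap).lower()}\n"
            f"max_gap_frames = {self.max_gap_frames}\n"
            "\n[segments]\n"
            f"proximal = {','.join(map(str, self.proximal.indices))}\n"
            f"distal = {','.join(map(str, self.distal.indices))}\n"
            "\n[classification]\n"
            f"straight_kb_max = {t.straight_kb_max:g}\n"
            f"nonplanar_min = {t.nonplanar_min:g}\n"
            "\n[smoothing]\n"
            f"window = {self.smoothing_window}\n"
        )


def _parse_triple(text: str) -> SegmentTriple:
    parts = [int(p) for p in text.replace(" ", "").split(",")]
    if len(parts) != 3:
        raise ValueError(f"expected three indices, got {text!r}")
    return SegmentTriple(*parts)


def default_config_text() -> str:
    return AnalysisConfig().to_text()
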