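"""Core experimental-design and parameter types shared across the pipeline.

A 4-plex isobaric-tag (iTRAQ) experiment labels a common control with the
114 reporter channel and one tumor grade with each remaining channel
(115 = grade II, 116 = grade III, 117 = grade IV / GBM).  All quantitation
is pairwise tumor-channel / control-channel within a PSM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

CHANNELS = ("114", "115", "116", "117")
GRADES = ("II", "III", "IV")


@dataclass(frozen=True)
class ChannelDesign:
    """Assignment of reporter channels to conditions.

    Parameters
    ----------
    control_channel:
        Reporter channel carrying the pooled control sample.
    grade_channels:
        Mapping from tumor grade label to its reporter channel.
    """

    control_channel: str = "114"
    grade_channels: Mapping[str, str] = field(
        default_factory=lambda: {"II": "115", "III": "116", "IV": "117"}
    )

    def __post_init__(self) -> None:
        channels = [self.control_channel, *self.grade_channels.values()]
        if len(set(channels)) != len(channels):
            raise ValueError("control and grade channels must be distinct")
        if set(channels) != set(CHANNELS):
            raise ValueError(f"channels must be exactly {set(CHANNELS)}, got {set(channels)}")
        if self.control_channel in self.grade_channels.values():
            raise ValueError("exactly one control channel is required")

    @property
    def grades(self) -> tuple[str, ...]:
        return tuple(self.grade_channels)


@dataclass(frozen=True)
class CascadeParams:
    """Thresholds of the two-tier fold-change curation cascade.

    ``pre_fc`` is the provisional 1.3-fold gate applied first at the protein
    level and then to each supporting PSM ratio; ``final_fc`` is the 1.5-fold
    differential-expression call on the recomputed fold change, which must be
    supported by at least ``min_psms`` curated PSMs with a coefficient of
    variation below ``cv_max`` percent.  Down-regulation uses the reciprocal
    thresholds.
    """

    pre_fc: float = 1.3
    final_fc: float = 1.5
    cv_max: float = 40.0
    min_psms: int = 2
    min_unique_peptides_strict: int = 2

    def __post_init__(self) -> None:
        if not self.pre_fc >= 1.0:
            raise ValueError("pre_fc must be >= 1")
        if self.pre_fc > self.final_fc:
            raise ValueError("pre_fc must not exceed final_fc")
        if self.cv_max <= 0:
            raise ValueError("cv_max must be positive")
        if self.min_psms < 1:
            raise ValueError("min_psms must be >= 1")
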