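"""Editing-level quantification from Sanger chromatogram peak heights.

The editing level at a position is minor/(major+minor) peak height. Base
callers only report a minor peak whose height reaches a fraction (default
5%) of the major peak's, so levels below 5/(100+5) ~= 0.048 are not
observable: such measurements are censored and reported as level 0 with a
flag, matching the convention of drawing a detection line on bar graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import EdcallError


@dataclass(frozen=True)
class PeakPair:
    """Major and minor chromatogram peak heights (arbitrary fluorescence
    units) at one nucleotide position."""

    major_height: float
    minor_height: float

    def __post_init__(self):
        if self.major_height <= 0:
            raise EdcallError("major peak height must be positive")
        if self.minor_height < 0:
            raise EdcallError("minor peak height must be non-negative")
        if self.minor_height > self.major_height:
            raise EdcallError("minor peak height exceeds major peak height")


@dataclass(frozen=True)
class SangerLevel:
    level: float
    censored: bool  # True: below the chromatogram software's detection limit


def sanger_level(pp: PeakPair, rel_threshold: float = 0.05) -> SangerLevel:
    """Editing level minor/(major+minor); censored to 0 when the minor peak
    is below ``rel_threshold`` of the major peak.

    The smallest observable level is rel_threshold/(1+rel_threshold)
    (0.047619 ~= 0.048 at the default 5% software threshold).
    """
    if pp.minor_height / pp.major_height < rel_threshold:
        return SangerLevel(level=0.0, censored=True)
    return SangerLevel(
        level=pp.minor_height / (pp.major_height + pp.minor_height),
        censored=False)


def detection_threshold(rel_threshold: float = 0.05) -> float:
    """The smallest reportable editing level for a given software minor-peak
    threshold; 0.048 for the default 5%."""
    return rel_threshold / (1.0 + rel_threshold)


def replicate_mean(levels: list[SangerLevel],
                   include_censored: bool = True) -> float:
    """Mean editing level over replicates; censored replicates enter as 0
    when included (the default), or are dropped."""
    if include_censored:
        values = [lv.level for lv in levels]
    else:
        values = [lv.level for lv in levels if not lv.censored]
    if not values:
        raise EdcallError("no uncensored replicate levels to average")
    return sum(values) / len(values)
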