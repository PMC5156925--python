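"""Core record types shared by the IO layer and the site caller.

Coordinates are 1-based inclusive throughout the library; only BED output
converts to 0-based half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: (base, strand) keys used in BaseCallProfile counts; strand is the read
#: alignment direction ("+" forward, "-" reverse), not the transcribed strand.
BASES = ("A", "C", "G", "T")
STRANDS = ("+", "-")


class EdcallError(Exception):
    """Base class for errors raised by this package."""


class PileupParseError(EdcallError):
    """Malformed pileup input; message names the offending line."""


class ConfigError(EdcallError):
    """Inconsistent sample sheet / configuration."""


@dataclass
class BaseCallProfile:
    """Strand-resolved base-call counts at one genomic position.

    counts maps sample_id -> {(base, strand): n} where base is one of
    A/C/G/T and strand the read direction. Deletions, reference skips and
    N calls are excluded from the counts (they do not contribute to the
    A/C/G/T total that the filter cascade uses).
    """

    chrom: str
    pos: int  # 1-based
    ref_base: str
    counts: dict[str, dict[tuple[str, str], int]] = field(default_factory=dict)

    def total(self, sample_id: str) -> int:
        return sum(self.counts.get(sample_id, {}).values())

    def base_count(self, sample_id: str, base: str, strand: str | None = None) -> int:
        cells = self.counts.get(sample_id, {})
        if strand is None:
            return cells.get((base, "+"), 0) + cells.get((base, "-"), 0)
        return cells.get((base, strand), 0)

    def validate(self, reference: dict[str, str] | None = None) -> None:
        for sample, cells in self.counts.items():
            for (base, strand), n in cells.items():
                if base not in BASES or strand not in STRANDS or n < 0:
                    raise EdcallError(
                        f"invalid count cell {(base, strand)}={n} for sample {sample}"
                    )
        if reference is not None:
            refseq = reference.get(self.chrom)
            if refseq is not None and refseq[self.pos - 1] != self.ref_base:
                raise EdcallError(
                    f"ref_base {self.ref_base} at {self.chrom}:{self.pos} does not "
                    f"match reference {refseq[self.pos - 1]}"
                )


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    group: str  # "control" or "treated"
    aligner_id: str


class SampleSheet:
    """Sample metadata: group membership per sample, per aligner run."""

    GROUPS = ("control", "treated")

    def __init__(self, records: list[SampleRecord]):
        seen = set()
        for rec in records:
            if rec.group not in self.GROUPS:
                raise ConfigError(f"unknown group {rec.group!r} for {rec.sample_id}")
            key = (rec.sample_id, rec.aligner_id)
            if key in seen:
                raise ConfigError(f"duplicate (sample, aligner) pair {key}")
            seen.add(key)
        self.records = list(records)
        for group in self.GROUPS:
            if not self.samples(group):
                raise ConfigError(f"sample sheet has no {group} samples")

    def samples(self, group: str | None = None) -> list[str]:
        out = []
        for rec in self.records:
            if (group is None or rec.group == group) and rec.sample_id not in out:
                out.append(rec.sample_id)
        return out

    def aligners(self) -> list[str]:
        out = []
        for rec in self.records:
            if rec.aligner_id not in out:
                out.append(rec.aligner_id)
        return out

    def group_of(self, sample_id: str) -> str:
        for rec in self.records:
            if rec.sample_id == sample_id:
                return rec.group
        raise ConfigError(f"sample {sample_id!r} not in sample sheet")


@dataclass
class EditingSite:
    """A called RNA editing site.

    edit_level is the mean of the per-aligner treated-group means; levels are
    variant/(variant+ref) call-count ratios. filter_trace records every gate
    decision (name, passed) in cascade order and is not serialized.
    """

    chrom: str
    pos: int  # 1-based
    transcribed_strand: str  # "+", "-" or "." when unknown
    ref_base: str
    variant_base: str
    edit_type: str
    per_sample_levels: dict[str, float]
    per_aligner_mean_level: dict[str, float]
    edit_level: float
    p_value: float
    p_adjusted: float
    strand_bias_p: float | None = None
    filter_trace: list[tuple[str, bool]] = field(default_factory=list, compare=False)
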