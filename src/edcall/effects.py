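"""Gene-feature and codon-consequence classification of editing sites.

Given transcript models (exon structure plus CDS bounds on the genome) a
site is placed into one of: 5'UTR, exonic (CDS, with a translational
consequence), 3'UTR, ncRNA, intronic, untranscribed (within 1 kb of a
transcription start/end) or intergenic. CDS positions are translated with
the standard genetic code to classify the edit as synonymous, missense,
nonsense (gain of UAA/UAG/UGA) or stop-loss, and to produce the
conventional c.C751T / p.R251X change strings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq

from ._util import complement, revcomp
from .records import EdcallError

FEATURE_PRIORITY = ["exonic", "5'UTR", "3'UTR", "ncRNA", "intronic",
                    "untranscribed", "intergenic"]


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript; 1-based inclusive coordinates.

    ``exons`` are (start, end) pairs sorted along the genome regardless of
    strand; ``cds_start``/``cds_end`` are genomic bounds (cds_start <=
    cds_end) or None for non-coding transcripts.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self):
        self.exons = sorted(self.exons)
        prev_end = 0
        for s, e in self.exons:
            if s <= prev_end:
                raise EdcallError(
                    f"{self.transcript_id}: exons overlap or are unsorted")
            if e < s:
                raise EdcallError(f"{self.transcript_id}: exon end before start")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise EdcallError(f"{self.transcript_id}: partial CDS bounds")
        if self.cds_start is not None:
            if not (self.contains_exonic(self.cds_start)
                    and self.contains_exonic(self.cds_end)):
                raise EdcallError(
                    f"{self.transcript_id}: CDS bounds outside exons")

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def contains_exonic(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def cds_offset(self, pos: int) -> int:
        """0-based offset of a genomic position within the spliced CDS, in
        translation (strand) order."""
        segments = [(max(s, self.cds_start), min(e, self.cds_end))
                    for s, e in self.exons
                    if e >= self.cds_start and s <= self.cds_end]
        offset = 0
        if self.strand == "+":
            for s, e in segments:
                if s <= pos <= e:
                    return offset + (pos - s)
                offset += e - s + 1
        else:
            for s, e in reversed(segments):
                if s <= pos <= e:
                    return offset + (e - pos)
                offset += e - s + 1
        raise EdcallError(f"position {pos} not inside the CDS")

    def spliced_cds(self, genome: dict[str, str]) -> str:
        segments = [(max(s, self.cds_start), min(e, self.cds_end))
                    for s, e in self.exons
                    if e >= self.cds_start and s <= self.cds_end]
        seq = "".join(genome[self.chrom][s - 1:e] for s, e in segments)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class EffectCall:
    feature: str
    consequence: str | None = None  # synonymous | missense | nonsense | stop-loss
    cdna_change: str | None = None
    protein_change: str | None = None
    transcript_id: str | None = None
    overlaps: list[str] = field(default_factory=list)


def _feature_in_model(pos: int, model: TranscriptModel,
                      promoter_margin: int) -> str | None:
    if model.contains_exonic(pos):
        if not model.is_coding:
            return "ncRNA"
        if model.cds_start <= pos <= model.cds_end:
            return "exonic"
        upstream_of_cds = pos < model.cds_start
        if model.strand == "+":
            return "5'UTR" if upstream_of_cds else "3'UTR"
        return "3'UTR" if upstream_of_cds else "5'UTR"
    if model.tx_start <= pos <= model.tx_end:
        return "intronic"
    if (model.tx_start - promoter_margin <= pos < model.tx_start
            or model.tx_end < pos <= model.tx_end + promoter_margin):
        return "untranscribed"
    return None


def _consequence(site, model: TranscriptModel,
                 genome: dict[str, str]) -> tuple[str, str, str]:
    cds = model.spliced_cds(genome)
    if len(cds) % 3 != 0:
        raise EdcallError(
            f"{model.transcript_id}: CDS length {len(cds)} not divisible by 3")
    offset = model.cds_offset(site.pos)
    ref_c = site.ref_base if model.strand == "+" else complement(site.ref_base)
    var_c = (site.variant_base if model.strand == "+"
             else complement(site.variant_base))
    if cds[offset] != ref_c:
        raise EdcallError(
            f"{model.transcript_id}: cDNA base {cds[offset]} at offset "
            f"{offset} does not match site reference {ref_c}")
    codon_index = offset // 3
    within = offset % 3
    old_codon = cds[codon_index * 3:codon_index * 3 + 3]
    new_codon = old_codon[:within] + var_c + old_codon[within + 1:]
    old_aa = str(Seq(old_codon).translate())
    new_aa = str(Seq(new_codon).translate())
    old_aa = "X" if old_aa == "*" else old_aa
    new_aa = "X" if new_aa == "*" else new_aa
    if old_aa == new_aa:
        consequence = "synonymous"
    elif new_aa == "X":
        consequence = "nonsense"
    elif old_aa == "X":
        consequence = "stop-loss"
    else:
        consequence = "missense"
    cdna = f"c.{ref_c}{offset + 1}{var_c}"
    prot = f"p.{old_aa}{codon_index + 1}{new_aa}"
    return consequence, cdna, prot


def classify_site(site, models: Sequence[TranscriptModel],
                  genome: dict[str, str],
                  promoter_margin: int = 1000) -> EffectCall:
    """Classify one editing site against transcript models.

    When several transcripts overlap the site, the reported one is chosen by
    feature priority (CDS > UTR > ncRNA > intron > untranscribed), ties
    broken by lexicographic transcript id; every overlapping transcript is
    listed in ``overlaps``. Models whose CDS length is not a multiple of 3
    are rejected with a warning.
    """
    hits: list[tuple[str, TranscriptModel]] = []
    for model in models:
        if model.chrom != site.chrom:
            continue
        feature = _feature_in_model(site.pos, model, promoter_margin)
        if feature is not None:
            hits.append((feature, model))
    if not hits:
        return EffectCall(feature="intergenic")
    hits.sort(key=lambda fm: (FEATURE_PRIORITY.index(fm[0]),
                              fm[1].transcript_id))
    overlaps = [m.transcript_id for _, m in hits]
    for feature, model in hits:
        if feature != "exonic":
            return EffectCall(feature=feature,
                              transcript_id=model.transcript_id,
                              overlaps=overlaps)
        try:
            consequence, cdna, prot = _consequence(site, model, genome)
        except EdcallError as exc:
            warnings.warn(str(exc))
            continue
        return EffectCall(feature="exonic", consequence=consequence,
                          cdna_change=cdna, protein_change=prot,
                          transcript_id=model.transcript_id,
                          overlaps=overlaps)
    # every exonic model was rejected; fall back to the next feature if any
    non_exonic = [fm for fm in hits if fm[0] != "exonic"]
    if non_exonic:
        feature, model = non_exonic[0]
        return EffectCall(feature=feature, transcript_id=model.transcript_id,
                          overlaps=overlaps)
    return EffectCall(feature="unknown", overlaps=overlaps)


TALLY_ROWS = ["5'UTR", "exonic:synonymous", "exonic:missense",
              "exonic:nonsense", "exonic:stop-loss", "exonic:unknown",
              "ncRNA", "3'UTR", "intronic", "untranscribed", "intergenic",
              "unknown"]


def feature_tally(effect_calls: Iterable[EffectCall]) -> dict[str, int]:
    """Count effect calls in the shape of a gene-feature/consequence table."""
    tally = {row: 0 for row in TALLY_ROWS}
    for call in effect_calls:
        if call.feature == "exonic":
            key = f"exonic:{call.consequence or 'unknown'}"
        else:
            key = call.feature
        tally[key] = tally.get(key, 0) + 1
    return tally
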