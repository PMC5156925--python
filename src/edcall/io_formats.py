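"""Readers and writers: samtools-style pileup text, FASTA, sample sheets,
transcript tables, and the site-table outputs (TSV and BED6).

The pileup parser consumes single-sample, six-column `samtools mpileup`
output (chrom, 1-based position, reference base, depth, read bases, base
qualities). Mapping-quality filtering and read-pair overlap clipping are
assumed to have been applied upstream, before the pileup was produced.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, TextIO

from Bio import SeqIO

from .records import (
    BaseCallProfile,
    EditingSite,
    EdcallError,
    PileupParseError,
    SampleRecord,
    SampleSheet,
)

_BASE_CODES = set("ACGTacgt.,")
_SKIP_CODES = set("Nn*><")


def parse_pileup(
    stream: TextIO | str | os.PathLike,
    min_base_quality: int = 20,
    sample_id: str = "sample",
) -> list[BaseCallProfile]:
    """Decode a single-sample pileup into strand-resolved base-call counts.

    Base calls with Phred quality below ``min_base_quality`` are dropped.
    '.'/',' count toward the reference base on the forward/reverse read
    direction; upper/lower-case letters encode forward/reverse variant
    calls. Indel segments ('+n...'/'-n...'), read start ('^' plus mapping
    quality) and end ('$') markers are consumed without counting; 'N', '*'
    (deletion placeholder) and '>'/'<' (reference skips) are discarded but
    consume a quality character.
    """
    close = False
    if isinstance(stream, (str, os.PathLike)):
        stream = open(stream)
        close = True
    try:
        profiles = []
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split()
            if len(fields) != 6:
                raise PileupParseError(
                    f"line {lineno}: expected 6 fields, found {len(fields)}"
                )
            chrom, pos_s, ref, _depth, bases, quals = fields
            ref = ref.upper()
            counts: dict[tuple[str, str], int] = {}
            if bases == "*" and quals == "*":  # zero-depth placeholder
                bases = quals = ""
            i = qi = 0
            n = len(bases)
            try:
                while i < n:
                    c = bases[i]
                    if c == "^":
                        i += 2  # '^' is followed by mapping quality
                        continue
                    if c == "$":
                        i += 1
                        continue
                    if c in "+-":
                        i += 1
                        num = ""
                        while i < n and bases[i].isdigit():
                            num += bases[i]
                            i += 1
                        if not num:
                            raise PileupParseError(
                                f"line {lineno}: indel marker without length"
                            )
                        i += int(num)
                        continue
                    # every remaining symbol consumes one quality character
                    if qi >= len(quals):
                        raise IndexError
                    qual = ord(quals[qi]) - 33
                    qi += 1
                    i += 1
                    if c in _SKIP_CODES:
                        continue
                    if c not in _BASE_CODES:
                        raise PileupParseError(
                            f"line {lineno}: unexpected pileup symbol {c!r}"
                        )
                    if qual < min_base_quality:
                        continue
                    if c == ".":
                        base, strand = ref, "+"
                    elif c == ",":
                        base, strand = ref, "-"
                    elif c.isupper():
                        base, strand = c, "+"
                    else:
                        base, strand = c.upper(), "-"
                    if base == "N":
                        continue
                    counts[(base, strand)] = counts.get((base, strand), 0) + 1
            except IndexError:
                raise PileupParseError(
                    f"line {lineno}: base and quality strings disagree in length"
                ) from None
            if qi != len(quals):
                raise PileupParseError(
                    f"line {lineno}: base and quality strings disagree in length"
                )
            profiles.append(
                BaseCallProfile(chrom=chrom, pos=int(pos_s), ref_base=ref,
                                counts={sample_id: counts})
            )
        return profiles
    finally:
        if close:
            stream.close()


def write_pileup(profiles: Iterable[BaseCallProfile], path, sample_id: str,
                 quality_char: str = "I") -> None:
    """Serialize profiles for one sample as six-column pileup text.

    All calls are written at a single quality (default 'I', Phred 40) in the
    deterministic order ref+/ref-/variant bases alphabetically; this is the
    inverse of :func:`parse_pileup` for count data.
    """
    with open(path, "w") as fh:
        for prof in profiles:
            cells = prof.counts.get(sample_id, {})
            parts = []
            ref = prof.ref_base
            parts.append("." * cells.get((ref, "+"), 0))
            parts.append("," * cells.get((ref, "-"), 0))
            for base in "ACGT":
                if base == ref:
                    continue
                parts.append(base * cells.get((base, "+"), 0))
                parts.append(base.lower() * cells.get((base, "-"), 0))
            bases = "".join(parts)
            depth = len(bases)
            quals = quality_char * depth
            if depth == 0:
                bases = quals = "*"
            fh.write(f"{prof.chrom}\t{prof.pos}\t{ref}\t{depth}\t{bases}\t{quals}\n")


def merge_profiles(per_sample: dict[str, list[BaseCallProfile]]) -> list[BaseCallProfile]:
    """Merge single-sample profile lists into multi-sample profiles keyed by
    (chrom, pos); ref bases must agree across samples."""
    merged: dict[tuple[str, int], BaseCallProfile] = {}
    for sample_id, profiles in per_sample.items():
        for prof in profiles:
            key = (prof.chrom, prof.pos)
            if key not in merged:
                merged[key] = BaseCallProfile(prof.chrom, prof.pos, prof.ref_base, {})
            tgt = merged[key]
            if tgt.ref_base != prof.ref_base:
                raise EdcallError(
                    f"reference base mismatch at {prof.chrom}:{prof.pos}"
                )
            cells = dict(prof.counts.get(sample_id, prof.counts.get("sample", {})))
            tgt.counts[sample_id] = cells
    return [merged[k] for k in sorted(merged)]


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {name: sequence}; uppercased, U normalized to T."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise EdcallError(f"duplicate FASTA header {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper().replace("U", "T")
    return sequences


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --- sample sheet -----------------------------------------------------------

def read_sample_sheet(path) -> SampleSheet:
    """TSV with header sample_id, group, aligner_id."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sample_id", "group", "aligner_id"]
        if header != expected:
            raise EdcallError(f"sample sheet header must be {expected}, got {header}")
        for line in fh:
            if not line.strip():
                continue
            sample_id, group, aligner_id = line.rstrip("\n").split("\t")
            records.append(SampleRecord(sample_id, group, aligner_id))
    return SampleSheet(records)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\taligner_id\n")
        for rec in sheet.records:
            fh.write(f"{rec.sample_id}\t{rec.group}\t{rec.aligner_id}\n")


# --- site tables ------------------------------------------------------------

_SITE_COLUMNS = [
    "chrom", "pos", "transcribed_strand", "ref_base", "variant_base",
    "edit_type", "edit_level", "p_value", "p_adjusted", "strand_bias_p",
    "per_sample_levels", "per_aligner_mean_level",
]


def _check_sorted(sites: list[EditingSite]) -> None:
    keys = [(s.chrom, s.pos) for s in sites]
    if keys != sorted(keys):
        raise EdcallError("sites must be sorted by (chrom, pos)")


def _encode_map(d: dict[str, float]) -> str:
    return json.dumps(d, sort_keys=True)


def write_site_table(sites: list[EditingSite], path) -> None:
    """Tab-separated site table; one row per site, header names the columns.

    Per-sample and per-aligner level maps are serialized as JSON objects in
    single columns; the filter trace is not serialized.
    """
    _check_sorted(sites)
    with open(path, "w") as fh:
        fh.write("\t".join(_SITE_COLUMNS) + "\n")
        for s in sites:
            row = [
                s.chrom, str(s.pos), s.transcribed_strand, s.ref_base,
                s.variant_base, s.edit_type, repr(s.edit_level),
                repr(s.p_value), repr(s.p_adjusted),
                "NA" if s.strand_bias_p is None else repr(s.strand_bias_p),
                _encode_map(s.per_sample_levels),
                _encode_map(s.per_aligner_mean_level),
            ]
            fh.write("\t".join(row) + "\n")


def read_site_table(path) -> list[EditingSite]:
    sites = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _SITE_COLUMNS:
            raise EdcallError("unrecognized site-table header")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            sites.append(
                EditingSite(
                    chrom=f[0], pos=int(f[1]), transcribed_strand=f[2],
                    ref_base=f[3], variant_base=f[4], edit_type=f[5],
                    edit_level=float(f[6]), p_value=float(f[7]),
                    p_adjusted=float(f[8]),
                    strand_bias_p=None if f[9] == "NA" else float(f[9]),
                    per_sample_levels=json.loads(f[10]),
                    per_aligner_mean_level=json.loads(f[11]),
                )
            )
    return sites


def write_bed(sites: list[EditingSite], path) -> None:
    """BED6: 0-based half-open interval per site; score = 1000 x edit level."""
    _check_sorted(sites)
    with open(path, "w") as fh:
        for s in sites:
            score = int(round(1000 * s.edit_level))
            strand = s.transcribed_strand if s.transcribed_strand in "+-" else "."
            fh.write(
                f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{s.edit_type}\t{score}\t{strand}\n"
            )


# --- transcript tables ------------------------------------------------------

def read_transcript_table(path):
    """TSV with columns transcript_id, chrom, strand, exon_starts, exon_ends,
    cds_start, cds_end (1-based inclusive; 'NA' CDS for non-coding)."""
    from .effects import TranscriptModel

    models = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["transcript_id", "chrom", "strand", "exon_starts",
                    "exon_ends", "cds_start", "cds_end"]
        if header != expected:
            raise EdcallError(f"transcript table header must be {expected}")
        for line in fh:
            if not line.strip():
                continue
            tid, chrom, strand, starts, ends, cs, ce = line.rstrip("\n").split("\t")
            exons = list(zip((int(x) for x in starts.split(",") if x),
                             (int(x) for x in ends.split(",") if x)))
            models.append(
                TranscriptModel(
                    transcript_id=tid, chrom=chrom, strand=strand, exons=exons,
                    cds_start=None if cs == "NA" else int(cs),
                    cds_end=None if ce == "NA" else int(ce),
                )
            )
    return models


def write_transcript_table(models, path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tchrom\tstrand\texon_starts\texon_ends\t"
                 "cds_start\tcds_end\n")
        for m in models:
            starts = ",".join(str(s) for s, _ in m.exons)
            ends = ",".join(str(e) for _, e in m.exons)
            cs = "NA" if m.cds_start is None else str(m.cds_start)
            ce = "NA" if m.cds_end is None else str(m.cds_end)
            fh.write(f"{m.transcript_id}\t{m.chrom}\t{m.strand}\t{starts}\t"
                     f"{ends}\t{cs}\t{ce}\n")
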