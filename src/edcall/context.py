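"""Sequence-context statistics around edited cytidines.

Windows are 25 nt of transcript-strand RNA with the edited C as the 13th
(1-based) nucleotide; offsets run -12..+12 relative to that center. All
tallies operate on the RNA alphabet, so DNA input (T) and RNA input (U) are
never double-counted.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import revcomp, to_rna
from .records import EdcallError

RNA = ("A", "C", "G", "U")


class WindowError(EdcallError):
    """Window extraction failed (contig edge or non-C center)."""


@dataclass(frozen=True)
class FlankWindow:
    """A transcript-oriented RNA window centered on an edited C."""

    sequence: str
    chrom: str = ""
    pos: int = 0
    strand: str = "+"

    def __post_init__(self):
        if len(self.sequence) % 2 == 0:
            raise WindowError("window length must be odd")
        if self.center_base != "C":
            raise WindowError(
                f"window center must be C, found {self.center_base!r}")

    @property
    def center_index(self) -> int:
        """1-based index of the edited C (13 for the default 25-nt window)."""
        return len(self.sequence) // 2 + 1

    @property
    def center_base(self) -> str:
        return self.sequence[len(self.sequence) // 2]

    def at_offset(self, offset: int) -> str:
        """Base at a signed offset from the edited C (offset 0 = the C)."""
        i = len(self.sequence) // 2 + offset
        if not 0 <= i < len(self.sequence):
            raise IndexError(f"offset {offset} outside window")
        return self.sequence[i]


def extract_window(genome: dict[str, str], chrom: str, pos: int, strand: str,
                   width: int = 25) -> FlankWindow:
    """Cut a ``width``-nt window around the 1-based position ``pos`` and
    orient it to the transcribed strand (minus-strand sites are
    reverse-complemented); DNA T is rendered as U.

    Raises :class:`WindowError` when the window would run off the contig or
    the (transcript-sense) center base is not C.
    """
    if chrom not in genome:
        raise WindowError(f"unknown contig {chrom!r}")
    half = width // 2
    seq = genome[chrom]
    lo, hi = pos - half - 1, pos + half  # 0-based half-open
    if lo < 0 or hi > len(seq):
        raise WindowError(f"window at {chrom}:{pos} truncated by contig edge")
    window = seq[lo:hi].upper()
    if strand == "-":
        window = revcomp(window)
    elif strand != "+":
        raise WindowError(f"invalid strand {strand!r}")
    return FlankWindow(sequence=to_rna(window), chrom=chrom, pos=pos,
                       strand=strand)


def neighbor_distribution(windows: Iterable[FlankWindow],
                          offset: int = -1) -> dict[str, int]:
    """Counts of A/C/G/U at a signed offset from the edited C (default the
    immediate 5' neighbor)."""
    counts = Counter(w.at_offset(offset) for w in windows)
    if not counts:
        raise EdcallError("no windows supplied")
    return {b: counts.get(b, 0) for b in RNA}


def trinucleotide_contexts(windows: Iterable[FlankWindow]) -> dict[str, int]:
    """Counts of the RNA trinucleotide at offsets -2..0 (ending in the
    edited C)."""
    counts: Counter = Counter()
    for w in windows:
        tri = "".join(w.at_offset(o) for o in (-2, -1, 0))
        counts[tri] += 1
    return dict(counts)


def build_pfm(windows: Sequence[FlankWindow]) -> pd.DataFrame:
    """Position-frequency matrix: rows = offsets (-12..+12 for 25-nt
    windows), columns = A/C/G/U, each row summing to 1."""
    windows = list(windows)
    if not windows:
        raise EdcallError("PFM requires at least one window")
    width = len(windows[0].sequence)
    half = width // 2
    offsets = list(range(-half, half + 1))
    mat = np.zeros((width, 4))
    for w in windows:
        if len(w.sequence) != width:
            raise EdcallError("windows of mixed width")
        for i, base in enumerate(w.sequence):
            mat[i, RNA.index(base)] += 1
    mat /= len(windows)
    return pd.DataFrame(mat, index=offsets, columns=list(RNA))


def information_content(pfm: pd.DataFrame) -> pd.Series:
    """Per-position information content in bits: 2 - Shannon entropy."""
    p = pfm.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.nansum(np.where(p > 0, p * np.log2(p), 0.0), axis=1)
    return pd.Series(2.0 - ent, index=pfm.index, name="bits")


_TOKEN_RE = re.compile(r"\[([ACGUN]+)\]|([ACGUN])")


def parse_motif(motif: str) -> list[set[str]]:
    """Parse character-class motif notation (e.g. "[CGU]N[CU]C[AG]") into a
    list of allowed-base sets; N means any base."""
    tokens: list[set[str]] = []
    pos = 0
    for m in _TOKEN_RE.finditer(motif):
        if m.start() != pos:
            raise EdcallError(f"cannot parse motif {motif!r}")
        pos = m.end()
        cls = m.group(1) or m.group(2)
        tokens.append(set(RNA) if cls == "N" else set(cls))
    if pos != len(motif) or not tokens:
        raise EdcallError(f"cannot parse motif {motif!r}")
    return tokens


def match_motif(window: FlankWindow, motif: str = "[CGU]N[CU]C[AG]",
                start_offset: int = -3) -> bool:
    """Does the window match the motif at offsets ``start_offset`` onward?

    With the defaults the five motif positions cover offsets -3..+1 with the
    edited C fixed at offset 0.
    """
    tokens = parse_motif(motif)
    for i, allowed in enumerate(tokens):
        if window.at_offset(start_offset + i) not in allowed:
            return False
    return True


def per_position_matches(window: FlankWindow,
                         motif: str = "[CGU]N[CU]C[AG]",
                         start_offset: int = -3) -> list[bool]:
    tokens = parse_motif(motif)
    return [window.at_offset(start_offset + i) in allowed
            for i, allowed in enumerate(tokens)]
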