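"""Inverted-repeat (stem-loop) detection around edited cytidines.

Two search modes over the 25-nt window:

* :func:`find_inverted_repeat` — any pair of strictly reverse-complementary
  segments with the left arm entirely 5' of the edited C and the right arm
  entirely 3' of it (the general "flanking inverted repeat" question);
* :func:`call_loop_model` — the hairpin-loop model in which the edited C is
  the 3'-most nucleotide of the loop, i.e. the right arm starts immediately
  3' of the C and the loop (which ends at the C) is short; one unpaired
  (bulged) nucleotide inside an arm is tolerated and flagged.

Complementarity is strict Watson-Crick reverse complement: G.U wobble pairs
do not count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._util import revcomp, to_dna, to_rna
from .context import FlankWindow
from .records import EdcallError


@dataclass
class StemLoopCall:
    """A flanking inverted-repeat call; spans are 0-based half-open window
    coordinates. arm_length 0 means no repeat was found."""

    arm_length: int
    left_arm_span: tuple[int, int] | None = None
    right_arm_span: tuple[int, int] | None = None
    loop_length: int | None = None  # nt strictly between the arms
    interrupted: bool = False
    arm_sequence: str = ""  # left arm, RNA alphabet


def _window_seq(window) -> str:
    seq = window.sequence if isinstance(window, FlankWindow) else str(window)
    return to_dna(seq)


def find_inverted_repeat(window, min_arm: int = 3,
                         max_arm: int = 10) -> StemLoopCall:
    """Exhaustive search for the longest strict inverted-repeat pair flanking
    the center C.

    Ties at the maximal arm length are broken by the smallest loop (gap
    between the arms), then the most centrally balanced placement, then the
    left-most left arm; the tie-break affects spans only, never arm_length.
    """
    seq = _window_seq(window)
    c = len(seq) // 2
    best = None
    for arm in range(min(max_arm, c), min_arm - 1, -1):
        for i in range(0, c - arm + 1):          # left arm seq[i:i+arm], ends <= c-1
            left = seq[i:i + arm]
            target = revcomp(left)
            for j in range(c + 1, len(seq) - arm + 1):  # right arm starts >= c+1
                if seq[j:j + arm] != target:
                    continue
                loop = j - (i + arm)
                balance = abs((c - (i + arm - 1)) - (j - c))
                key = (loop, balance, i)
                if best is None or key < best[0]:
                    best = (key, i, j, arm)
        if best is not None:
            break
    if best is None:
        return StemLoopCall(arm_length=0)
    _, i, j, arm = best
    return StemLoopCall(
        arm_length=arm, left_arm_span=(i, i + arm),
        right_arm_span=(j, j + arm), loop_length=j - (i + arm),
        interrupted=False, arm_sequence=to_rna(seq[i:i + arm]))


def _one_bulge_match(longer: str, target: str) -> bool:
    """True if deleting exactly one nt from ``longer`` yields ``target``."""
    for d in range(len(longer)):
        if longer[:d] + longer[d + 1:] == target:
            return True
    return False


def call_loop_model(window, max_loop: int = 7, min_arm: int = 2,
                    max_arm: int = 10) -> StemLoopCall | None:
    """Hairpin-loop call with the edited C at the loop's 3' end.

    The right arm starts immediately 3' of the center C; the loop runs from
    just after the left arm up to and including the C, and must be 1..
    ``max_loop`` nt long. One unpaired nucleotide inside either arm is
    tolerated (``interrupted=True``); at equal paired arm length an
    uninterrupted call wins. Returns None when no arm pair exists.
    """
    seq = _window_seq(window)
    c = len(seq) // 2
    L = len(seq)
    best = None  # (arm, not interrupted, -loop) maximized
    for arm in range(min(max_arm, L - c - 1), min_arm - 1, -1):
        right = seq[c + 1:c + 1 + arm]
        if len(right) < arm:
            continue
        target = revcomp(right)
        for loop in range(1, max_loop + 1):
            left_end = c - loop  # inclusive index of last left-arm nt
            # uninterrupted: left arm of arm nt
            i = left_end - arm + 1
            if i >= 0 and seq[i:left_end + 1] == target:
                cand = (arm, 1, -loop,
                        StemLoopCall(arm, (i, left_end + 1),
                                     (c + 1, c + 1 + arm), loop, False,
                                     to_rna(seq[i:left_end + 1])))
                if best is None or cand[:3] > best[:3]:
                    best = cand
                continue
            # interrupted: one bulged nt in the left arm (arm+1 nt long)
            i2 = left_end - arm
            if i2 >= 0 and _one_bulge_match(seq[i2:left_end + 1], target):
                cand = (arm, 0, -loop,
                        StemLoopCall(arm, (i2, left_end + 1),
                                     (c + 1, c + 1 + arm), loop, True,
                                     to_rna(seq[i2:left_end + 1])))
                if best is None or cand[:3] > best[:3]:
                    best = cand
        # interrupted: bulge in the right arm (right arm arm+1 nt long)
        right_long = seq[c + 1:c + 2 + arm]
        if len(right_long) == arm + 1:
            for loop in range(1, max_loop + 1):
                left_end = c - loop
                i = left_end - arm + 1
                if i < 0:
                    continue
                left = seq[i:left_end + 1]
                if _one_bulge_match(right_long, revcomp(left)):
                    cand = (arm, 0, -loop,
                            StemLoopCall(arm, (i, left_end + 1),
                                         (c + 1, c + 2 + arm), loop, True,
                                         to_rna(left)))
                    if best is None or cand[:3] > best[:3]:
                        best = cand
        if best is not None and best[0] == arm:
            break  # shorter arms cannot beat the current maximal arm
    return best[3] if best is not None else None


def background_repeat_fraction(transcriptome: dict[str, str], n: int,
                               seed: int, min_arm: int = 4,
                               width: int = 25) -> float:
    """Fraction of ``n`` randomly sampled C-centered ``width``-nt windows
    from the transcriptome that carry a flanking inverted repeat of at least
    ``min_arm`` nt.

    Windows are sampled uniformly (with replacement) over all positions with
    a C at the center and the full window inside the sequence.
    """
    eligible: list[tuple[str, int]] = []
    half = width // 2
    for name, seq in transcriptome.items():
        s = to_dna(seq)
        for i in range(half, len(s) - half):
            if s[i] == "C":
                eligible.append((name, i))
    if not eligible:
        raise EdcallError("no eligible C-centered window in transcriptome")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(eligible), size=n)
    hits = 0
    for t in idx:
        name, i = eligible[t]
        w = to_dna(transcriptome[name])[i - half:i + half + 1]
        call = find_inverted_repeat(w, min_arm=min_arm, max_arm=10)
        if call.arm_length >= min_arm:
            hits += 1
    return hits / n


def repeat_length_histogram(calls: Iterable[StemLoopCall]) -> dict[int, int]:
    """Histogram of called arm lengths (0 = no repeat found)."""
    return dict(Counter(c.arm_length for c in calls))
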