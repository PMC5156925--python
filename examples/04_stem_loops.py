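"""Inverted repeats and hairpin loops flanking edited cytidines, and the
background repeat fraction in random windows."""

import numpy as np

from edcall.stemloop import (background_repeat_fraction, call_loop_model,
                             find_inverted_repeat, repeat_length_histogram)

window = "ACACGGCCATTCCTGGCCACACACA"  # edited C is the 13th nucleotide
call = find_inverted_repeat(window)
print(f"window {window}")
print(f"  maximal flanking inverted repeat: arm {call.arm_length} nt "
      f"({call.arm_sequence}), loop {call.loop_length} nt")

lm = call_loop_model(window)
print(f"  hairpin-loop model (C at loop 3' end): loop {lm.loop_length} / "
      f"arm {lm.arm_length}" + (" (interrupted)" if lm.interrupted else ""))

rng = np.random.default_rng(0)
windows = []
for _ in range(500):
    seq = "".join(rng.choice(list("ACGT"), size=25))
    windows.append(seq[:12] + "C" + seq[13:])
calls = [find_inverted_repeat(w) for w in windows]
hist = repeat_length_histogram(calls)
print("\narm-length histogram over 500 random windows:",
      dict(sorted(hist.items())))

transcriptome = {"tx": "".join(rng.choice(list("ACGT"), size=50_000))}
frac = background_repeat_fraction(transcriptome, n=2000, seed=1, min_arm=4)
print(f"background fraction of random C-centered windows with a >=4 nt "
      f"flanking repeat: {frac:.3f}")
print("\nEnrichment of long flanking repeats in edited sites relative to "
      "this background is the structural signature of deaminase targeting.")
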