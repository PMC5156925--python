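"""Small sequence helpers shared across modules."""

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")

DNA_BASES = ("A", "C", "G", "T")
RNA_BASES = ("A", "C", "G", "U")


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement; accepts DNA or RNA input, returns DNA alphabet."""
    return seq.translate(_COMPLEMENT)[::-1].replace("U", "T").replace("u", "t")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")
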