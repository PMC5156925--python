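"""Translational consequences of C>U edits on a toy coding transcript."""

from edcall.effects import TranscriptModel, classify_site, feature_tally
from edcall.records import EditingSite

# toy gene: 9 nt 5'UTR, 12 nt CDS (CAA CGG CCC ATG -> Q R P M), 9 nt 3'UTR
genome = {"chr1": "AAAAAAAAA" + "CAACGGCCCATG" + "AAAAAAAAA"}
model = TranscriptModel("NM_toy", "chr1", "+", [(1, 30)],
                        cds_start=10, cds_end=21)


def site(pos):
    return EditingSite("chr1", pos, "+", "C", "T", "C>U", {}, {},
                       0.2, 1e-9, 1e-7)


calls = []
for pos, label in [(10, "CAA codon, 1st base"),
                   (13, "CGG codon, 1st base"),
                   (18, "CCC codon, 3rd base"),
                   (5, "5' UTR"), (25, "3' UTR")]:
    c = classify_site(site(pos), [model], genome)
    calls.append(c)
    detail = ""
    if c.consequence:
        detail = f" -> {c.consequence} ({c.cdna_change}, {c.protein_change})"
    print(f"pos {pos:>3} ({label:<20}): {c.feature}{detail}")

print("\nfeature tally:",
      {k: v for k, v in feature_tally(calls).items() if v})
print("\nQ->stop (nonsense) and R->W (missense) reproduce the classic "
      "recoding patterns of C>U editing; third-position CCC edits are "
      "silent.")
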