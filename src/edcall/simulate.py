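"""Synthetic directional RNA-seq base-call data with known editing ground
truth.

The generator emulates the statistical structure the caller assumes: two
sample groups (controls and deaminase-expressing transfectants, three each
by default), editing present only in the treated group at beta-distributed
levels, zero-mean control background apart from sequencing miscalls on the
reference->variant channel, negative-binomial depth, balanced read
directions, and two aligner datasets derived from the same latent calls by
binomial thinning (mimicking the same reads mapped twice). A configurable
fraction of unedited positions receives direction-skewed variant calls in
the treated samples only — alignment-artifact mimics that the strand-bias
gate is meant to remove. Reference windows around edited cytidines embed
the deaminase-preferred sequence motif and a flanking inverted repeat with
configurable probabilities.

Everything is reproducible from the single seed; all randomness flows from
one generator consumed in a fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._util import complement, revcomp
from .io_formats import (write_fasta, write_pileup, write_sample_sheet,
                         write_transcript_table)
from .records import BaseCallProfile, EdcallError, SampleRecord, SampleSheet

#: fixed miscall channel: the variant base recorded for errors at each ref base
TRANSITION = {"C": "T", "G": "A", "A": "G", "T": "C"}


@dataclass
class SimulationConfig:
    n_positions: int = 2000
    fraction_edited: float = 0.10
    #: Beta(a, b) shape of true editing levels, linearly scaled to level_range
    level_beta: tuple[float, float] = (1.25, 8.75)
    level_range: tuple[float, float] = (0.04, 0.60)
    depth_mean: float = 80.0
    depth_dispersion: float = 10.0  # negative-binomial size parameter
    error_rate: float = 0.002       # ref->variant channel miscall probability
    other_base_error_rate: float = 0.0  # per other base; off by default
    strand_fraction: float = 0.5    # expected forward-read fraction
    strand_bias_artifact_fraction: float = 0.01  # of unedited positions
    aligner_jitter: float = 0.95    # per-aligner call retention probability
    level_icc: float = 0.002        # between-treated-sample level jitter
    n_control: int = 3
    n_treated: int = 3
    seed: int = 0
    chrom: str = "sim1"
    spacing: int = 25               # genomic distance between positions
    motif_fraction: float = 0.9     # edited sites given a motif context
    stemloop_fraction: float = 0.9  # edited sites given flanking arms
    aligner_ids: tuple[str, str] = ("aligner1", "aligner2")
    transcript_block: int = 100     # positions per simulated transcript

    def validate(self) -> None:
        probs = [self.fraction_edited, self.error_rate, self.strand_fraction,
                 self.strand_bias_artifact_fraction, self.aligner_jitter,
                 self.level_icc, self.motif_fraction, self.stemloop_fraction,
                 self.other_base_error_rate]
        if any(not 0 <= p <= 1 for p in probs):
            raise EdcallError("probability parameters must lie in [0, 1]")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise EdcallError("depth model parameters must be positive")
        if self.n_positions < 1 or self.n_control < 1 or self.n_treated < 1:
            raise EdcallError("need at least one position and sample per group")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["level_beta"] = list(self.level_beta)
        d["level_range"] = list(self.level_range)
        d["aligner_ids"] = list(self.aligner_ids)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("level_beta", "level_range", "aligner_ids"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class TruthRecord:
    pos: int
    is_edited: bool
    true_level: float
    transcribed_strand: str
    is_artifact: bool = False
    mean_depth: float = 0.0


class TruthTable:
    """Ground truth per simulated position, for recovery scoring."""

    def __init__(self, chrom: str, records: dict[int, TruthRecord]):
        self.chrom = chrom
        self.records = records

    def __getitem__(self, pos: int) -> TruthRecord:
        return self.records[pos]

    def __len__(self) -> int:
        return len(self.records)

    def edited_positions(self, level_min: float = 0.0,
                         depth_min: float = 0.0) -> set[int]:
        return {p for p, r in self.records.items()
                if r.is_edited and r.true_level >= level_min
                and r.mean_depth >= depth_min}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tis_edited\ttrue_level\tstrand\t"
                     "is_artifact\tmean_depth\n")
            for pos in sorted(self.records):
                r = self.records[pos]
                fh.write(f"{self.chrom}\t{pos}\t{int(r.is_edited)}\t"
                         f"{r.true_level!r}\t{r.transcribed_strand}\t"
                         f"{int(r.is_artifact)}\t{r.mean_depth!r}\n")

    @classmethod
    def read(cls, path) -> "TruthTable":
        records = {}
        chrom = ""
        with open(path) as fh:
            fh.readline()
            for line in fh:
                f = line.rstrip("\n").split("\t")
                chrom = f[0]
                records[int(f[1])] = TruthRecord(
                    pos=int(f[1]), is_edited=bool(int(f[2])),
                    true_level=float(f[3]), transcribed_strand=f[4],
                    is_artifact=bool(int(f[5])), mean_depth=float(f[6]))
        return cls(chrom, records)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    profiles_by_aligner: dict[str, list[BaseCallProfile]]
    sheet: SampleSheet
    truth: TruthTable
    genome: dict[str, str]
    transcripts: list = field(default_factory=list)


def _embed_context(sense: list[str], rng, motif: bool, stemloop: bool) -> None:
    """Rewrite a 25-nt transcript-sense window (list of DNA chars, center C
    at index 12) in place to carry the preferred motif and/or a flanking
    inverted repeat with the loop ending at the C."""
    c = 12
    if motif:
        # 5' neighbor composition follows the enrichment seen in edited sites
        sense[c - 3] = rng.choice(list("CGT"))
        sense[c - 1] = rng.choice(list("CTAG"), p=[0.87, 0.12, 0.005, 0.005])
        sense[c + 1] = rng.choice(list("AG"))
    sense[c] = "C"
    if stemloop:
        arm = int(rng.choice([3, 4, 5, 6], p=[0.25, 0.35, 0.25, 0.15]))
        loop = int(rng.choice([3, 4], p=[0.4, 0.6]))
        left = sense[c - loop - arm + 1:c - loop + 1]
        sense[c + 1:c + 1 + arm] = list(revcomp("".join(left)))


def _nb_depth(rng, cfg) -> int:
    p = cfg.depth_dispersion / (cfg.depth_dispersion + cfg.depth_mean)
    return max(1, int(rng.negative_binomial(cfg.depth_dispersion, p)))


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate base-call profiles for both aligners plus ground truth."""
    from .effects import TranscriptModel

    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_positions
    positions = [cfg.spacing * (i + 1) for i in range(n)]
    genome_len = cfg.spacing * (n + 1) + 13
    genome_arr = rng.choice(list("ACGT"), size=genome_len).tolist()

    # transcripts: consecutive blocks of positions, alternating strand
    transcripts = []
    for b in range(0, n, cfg.transcript_block):
        block = positions[b:b + cfg.transcript_block]
        strand = "+" if (b // cfg.transcript_block) % 2 == 0 else "-"
        transcripts.append(TranscriptModel(
            transcript_id=f"tx{b // cfg.transcript_block + 1:04d}",
            chrom=cfg.chrom, strand=strand,
            exons=[(max(1, block[0] - 12), min(genome_len, block[-1] + 12))]))
    strand_of = {}
    for m in transcripts:
        for pos in positions:
            if m.tx_start <= pos <= m.tx_end:
                strand_of.setdefault(pos, m.strand)

    n_edited = int(round(cfg.fraction_edited * n))
    edited = set(rng.choice(positions, size=n_edited, replace=False).tolist())
    null_positions = [p for p in positions if p not in edited]
    n_art = int(round(cfg.strand_bias_artifact_fraction * len(null_positions)))
    artifacts = set(rng.choice(null_positions, size=n_art,
                               replace=False).tolist()) if n_art else set()

    lo, hi = cfg.level_range
    a, b_shape = cfg.level_beta
    true_levels = {}
    for pos in sorted(edited):
        true_levels[pos] = float(lo + (hi - lo) * rng.beta(a, b_shape))
    artifact_levels = {pos: float(rng.uniform(0.06, 0.25))
                       for pos in sorted(artifacts)}

    # write edited/artifact reference bases and edited-site contexts
    for pos in sorted(edited | artifacts):
        strand = strand_of[pos]
        i = pos - 1
        if pos in edited:
            sense = [genome_arr[i - 12 + k] if strand == "+"
                     else complement(genome_arr[i + 12 - k])
                     for k in range(25)]
            _embed_context(sense, rng, rng.random() < cfg.motif_fraction,
                           rng.random() < cfg.stemloop_fraction)
            for k in range(25):
                if strand == "+":
                    genome_arr[i - 12 + k] = sense[k]
                else:
                    genome_arr[i + 12 - k] = complement(sense[k])
        else:
            genome_arr[i] = "C" if strand == "+" else "G"

    genome = {cfg.chrom: "".join(genome_arr)}

    controls = [f"ctrl{j + 1}" for j in range(cfg.n_control)]
    treated = [f"trt{j + 1}" for j in range(cfg.n_treated)]
    sheet = SampleSheet([SampleRecord(s, g, alg)
                         for alg in cfg.aligner_ids
                         for s, g in ([(c, "control") for c in controls]
                                      + [(t, "treated") for t in treated])])

    profiles = {alg: [] for alg in cfg.aligner_ids}
    truth_records = {}
    other_bases = {r: [x for x in "ACGT" if x not in (r, TRANSITION[r])]
                   for r in "ACGT"}
    for pos in positions:
        i = pos - 1
        ref = genome_arr[i]
        variant = TRANSITION[ref]
        is_edited = pos in edited
        is_artifact = pos in artifacts
        level = true_levels.get(pos, 0.0)
        depths = []
        per_aligner_counts = {alg: {} for alg in cfg.aligner_ids}
        for s in controls + treated:
            d = _nb_depth(rng, cfg)
            depths.append(d)
            if s in treated and is_edited:
                if cfg.level_icc > 0:
                    rho = cfg.level_icc
                    p_s = float(rng.beta(level * (1 - rho) / rho,
                                         (1 - level) * (1 - rho) / rho))
                else:
                    p_s = level
                p_var = p_s + (1 - p_s) * cfg.error_rate
            elif s in treated and is_artifact:
                p_var = artifact_levels[pos]
            else:
                p_var = cfg.error_rate
            k = int(rng.binomial(d, p_var))
            ref_n = d - k
            cells = {}
            if cfg.other_base_error_rate > 0 and ref_n > 0:
                for ob in other_bases[ref]:
                    e = int(rng.binomial(ref_n, cfg.other_base_error_rate))
                    e = min(e, ref_n)
                    ref_n -= e
                    if e:
                        ef = int(rng.binomial(e, cfg.strand_fraction))
                        cells[(ob, "+")] = ef
                        cells[(ob, "-")] = e - ef
            rf = int(rng.binomial(ref_n, cfg.strand_fraction))
            cells[(ref, "+")] = rf
            cells[(ref, "-")] = ref_n - rf
            if is_artifact and s in treated:
                vf = k  # direction-skewed artifact: all variant calls forward
            else:
                vf = int(rng.binomial(k, cfg.strand_fraction))
            if k:
                cells[(variant, "+")] = vf
                cells[(variant, "-")] = k - vf
            for alg in cfg.aligner_ids:
                thinned = {}
                for cell, count in cells.items():
                    kept = int(rng.binomial(count, cfg.aligner_jitter))
                    if kept:
                        thinned[cell] = kept
                per_aligner_counts[alg][s] = thinned
        for alg in cfg.aligner_ids:
            profiles[alg].append(BaseCallProfile(
                chrom=cfg.chrom, pos=pos, ref_base=ref,
                counts=per_aligner_counts[alg]))
        truth_records[pos] = TruthRecord(
            pos=pos, is_edited=is_edited, true_level=level,
            transcribed_strand=strand_of[pos], is_artifact=is_artifact,
            mean_depth=float(np.mean(depths)))

    return SimulatedDataset(config=cfg, profiles_by_aligner=profiles,
                            sheet=sheet,
                            truth=TruthTable(cfg.chrom, truth_records),
                            genome=genome, transcripts=transcripts)


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write pileups (one file per aligner x sample), reference FASTA,
    sample sheet, transcript table and truth table to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for alg, profs in ds.profiles_by_aligner.items():
        for s in ds.sheet.samples():
            p = outdir / f"{alg}.{s}.pileup"
            write_pileup(profs, p, sample_id=s)
            paths[f"pileup:{alg}:{s}"] = p
    write_fasta(ds.genome, outdir / "reference.fa")
    write_sample_sheet(ds.sheet, outdir / "samples.tsv")
    write_transcript_table(ds.transcripts, outdir / "transcripts.tsv")
    ds.truth.write(outdir / "truth.tsv")
    paths.update({"fasta": outdir / "reference.fa",
                  "samples": outdir / "samples.tsv",
                  "transcripts": outdir / "transcripts.tsv",
                  "truth": outdir / "truth.tsv"})
    return paths


@dataclass
class RecoveryScore:
    sensitivity: float
    fdr: float
    level_mae: float
    n_true_eligible: int
    n_called: int
    n_true_positive: int


def score_calls(called, truth: TruthTable, level_min: float = 0.0,
                depth_min: float = 0.0) -> RecoveryScore:
    """Confusion arithmetic for a call set against the simulation truth.

    Sensitivity is computed over truly edited positions with
    ``true_level >= level_min`` and ``mean_depth >= depth_min``; the false
    discovery rate and the mean absolute error of the editing level use all
    calls (FDR counts calls at positions that are not edited at any level).
    """
    called_pos = {s.pos for s in called}
    edited_all = truth.edited_positions()
    eligible = truth.edited_positions(level_min, depth_min)
    tp_eligible = called_pos & eligible
    sensitivity = len(tp_eligible) / len(eligible) if eligible else float("nan")
    fp = called_pos - edited_all
    fdr = len(fp) / len(called_pos) if called_pos else 0.0
    tp_all = called_pos & edited_all
    by_pos = {s.pos: s for s in called}
    if tp_all:
        mae = float(np.mean([abs(by_pos[p].edit_level
                                 - truth[p].true_level) for p in tp_all]))
    else:
        mae = float("nan")
    return RecoveryScore(sensitivity=sensitivity, fdr=fdr, level_mae=mae,
                         n_true_eligible=len(eligible),
                         n_called=len(called_pos),
                         n_true_positive=len(tp_all))
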