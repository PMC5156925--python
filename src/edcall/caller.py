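"""The step-wise filter cascade that turns two-group, two-aligner base-call
profiles into called RNA editing sites.

Gates, applied in order within each aligner dataset:

1. depth: every sample's A/C/G/T call total >= min_calls_per_sample and each
   group's mean total >= min_group_mean_depth;
2. candidate variant: some non-reference base for which every sample of at
   least one group has >= 1 call and a variation level >= 0.02, with group
   means >= 1.3 calls and >= 0.03 level;
3. other-base contamination: calls for bases other than reference and
   variant below 1% of all calls overall and <= 1 in every sample;
4. dispersion: (max - min)/mean of the six variation levels >= 2;
5. beta-binomial group test, Benjamini-Hochberg adjusted across all
   positions reaching this gate within the aligner, p_adjusted < alpha;
6. group specificity: control-group mean level exactly 0 and treated-group
   mean level >= min_treated_mean_level.

Then across aligners:

7. concordance: gates 1-6 pass independently in every aligner dataset with
   the same variant base;
8. strand bias: Fisher exact test of reference vs variant calls by read
   direction over the pooled treated samples (applied per aligner, only
   when both base-types have enough calls and one is direction-skewed);
9. final mean editing level (mean of per-aligner treated means) above
   final_min_edit_level.

Variation level is variant/(variant+reference) calls. Strict/non-strict
comparisons follow the thresholds as printed (e.g. ">0.05", ">=0.02").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from ._util import complement
from .records import BaseCallProfile, ConfigError, EditingSite, SampleSheet
from .stats import (VariationObservation, beta_binomial_test, bh_adjust,
                    fisher_exact_2x2)


@dataclass
class FilterThresholds:
    """Every numeric constant of the cascade; defaults follow the published
    analysis."""

    min_calls_per_sample: int = 6
    min_group_mean_depth: float = 9.0
    min_sample_variant_level: float = 0.02
    min_group_mean_variant_count: float = 1.3
    min_group_mean_variant_level: float = 0.03
    max_other_base_fraction: float = 0.01
    max_other_base_count_per_sample: int = 1
    min_range_over_mean: float = 2.0
    alpha_adjusted: float = 0.05
    min_treated_mean_level: float = 0.04
    final_min_edit_level: float = 0.05
    strand_min_calls_per_basetype: int = 8
    strand_minor_direction_fraction: float = 0.25
    strand_alpha: float = 0.05
    min_strand_call_agreement: float = 0.9  # read-direction strand inference

    def validate(self) -> None:
        for name in ("min_sample_variant_level", "min_group_mean_variant_level",
                     "max_other_base_fraction", "alpha_adjusted",
                     "min_treated_mean_level", "final_min_edit_level",
                     "strand_minor_direction_fraction", "strand_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("min_calls_per_sample", "min_group_mean_depth",
                     "min_group_mean_variant_count", "min_range_over_mean",
                     "max_other_base_count_per_sample"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterThresholds":
        th = cls(**d)
        th.validate()
        return th


GATES = ["depth", "candidate", "other_base", "dispersion", "group_test",
         "group_specificity", "concordance", "strand_bias", "final_level"]


@dataclass
class CallReport:
    """Sites plus the step-wise filtering table (survivors per gate)."""

    sites: list[EditingSite]
    gate_survivors: dict[str, int] = field(default_factory=dict)
    per_aligner_survivors: dict[str, dict[str, int]] = field(default_factory=dict)
    n_positions: int = 0


@dataclass
class _AlignerEval:
    passed: bool
    variant_base: str | None = None
    levels: dict[str, float] | None = None   # per sample
    treated_mean: float = math.nan
    p_value: float = math.nan
    p_adjusted: float = math.nan
    strand_counts: tuple[int, int, int, int] | None = None  # rf, rr, vf, vr
    fwd_fraction: float = math.nan
    trace: list[tuple[str, bool]] = field(default_factory=list)


def _candidate_variant(prof, samples_by_group, thresholds):
    """Return (variant_base, per-sample levels dict) or (None, None)."""
    ref = prof.ref_base
    best = None
    for base in "ACGT":
        if base == ref:
            continue
        ok = False
        for group, samples in samples_by_group.items():
            counts = [prof.base_count(s, base) for s in samples]
            levels = []
            for s, c in zip(samples, counts):
                denom = c + prof.base_count(s, ref)
                levels.append(c / denom if denom else 0.0)
            if (all(c >= 1 for c in counts)
                    and all(lv >= thresholds.min_sample_variant_level
                            for lv in levels)
                    and np.mean(counts) >= thresholds.min_group_mean_variant_count
                    and np.mean(levels) >= thresholds.min_group_mean_variant_level):
                ok = True
                break
        if ok:
            total = sum(prof.base_count(s, base)
                        for ss in samples_by_group.values() for s in ss)
            if best is None or total > best[1]:
                best = (base, total)
    if best is None:
        return None
    return best[0]


def _levels(prof, samples, variant):
    out = {}
    for s in samples:
        v = prof.base_count(s, variant)
        r = prof.base_count(s, prof.ref_base)
        out[s] = v / (v + r) if (v + r) else 0.0
    return out


def _eval_position(prof: BaseCallProfile, sheet: SampleSheet,
                   th: FilterThresholds) -> _AlignerEval:
    """Apply gates 1-4 for one aligner's profile; gate 5/6 need the cohort."""
    controls = sheet.samples("control")
    treated = sheet.samples("treated")
    all_samples = controls + treated
    ev = _AlignerEval(passed=False)

    totals = {s: prof.total(s) for s in all_samples}
    gate1 = (all(totals[s] >= th.min_calls_per_sample for s in all_samples)
             and np.mean([totals[s] for s in controls]) >= th.min_group_mean_depth
             and np.mean([totals[s] for s in treated]) >= th.min_group_mean_depth)
    ev.trace.append(("depth", gate1))
    if not gate1:
        return ev

    variant = _candidate_variant(
        prof, {"control": controls, "treated": treated}, th)
    ev.trace.append(("candidate", variant is not None))
    if variant is None:
        return ev
    ev.variant_base = variant

    ref = prof.ref_base
    other_total = 0
    grand_total = 0
    gate3 = True
    for s in all_samples:
        other = totals[s] - prof.base_count(s, ref) - prof.base_count(s, variant)
        if other > th.max_other_base_count_per_sample:
            gate3 = False
        other_total += other
        grand_total += totals[s]
    if grand_total and other_total / grand_total >= th.max_other_base_fraction:
        gate3 = False
    ev.trace.append(("other_base", gate3))
    if not gate3:
        return ev

    levels = _levels(prof, all_samples, variant)
    lv = np.array([levels[s] for s in all_samples])
    mean = lv.mean()
    # 1e-9 guard: the ratio is a derived float and symmetric data sits
    # exactly on the printed boundary
    gate4 = mean > 0 and ((lv.max() - lv.min()) / mean
                          >= th.min_range_over_mean - 1e-9)
    ev.trace.append(("dispersion", gate4))
    if not gate4:
        return ev

    ev.levels = levels
    ev.treated_mean = float(np.mean([levels[s] for s in treated]))
    rf = sum(prof.base_count(s, ref, "+") for s in treated)
    rr = sum(prof.base_count(s, ref, "-") for s in treated)
    vf = sum(prof.base_count(s, variant, "+") for s in treated)
    vr = sum(prof.base_count(s, variant, "-") for s in treated)
    ev.strand_counts = (rf, rr, vf, vr)
    fwd = sum(c for (b, st), c in
              ((k, v) for s in all_samples
               for k, v in prof.counts.get(s, {}).items()) if st == "+")
    tot = sum(prof.counts.get(s, {}).get((b, st), 0)
              for s in all_samples for b in "ACGT" for st in "+-")
    ev.fwd_fraction = fwd / tot if tot else math.nan
    ev.passed = True  # through gate 4; gates 5-6 applied by caller
    return ev


def strand_bias_gate(treated_counts: tuple[int, int, int, int],
                     thresholds: FilterThresholds | None = None):
    """Strand-bias gate on pooled treated counts (ref_fwd, ref_rev,
    var_fwd, var_rev).

    Returns (outcome, p) where outcome is "pass", "fail" or
    "not-applicable"; p is None when the test was not applied. The test is
    applied only when both base-types have >= strand_min_calls_per_basetype
    calls and at least one base-type draws < strand_minor_direction_fraction
    of its calls from one read direction; failure means Fisher p <
    strand_alpha.
    """
    th = thresholds or FilterThresholds()
    rf, rr, vf, vr = treated_counts
    ref_total, var_total = rf + rr, vf + vr
    if ref_total < th.strand_min_calls_per_basetype or \
            var_total < th.strand_min_calls_per_basetype:
        return "not-applicable", None
    skewed = (min(rf, rr) / ref_total < th.strand_minor_direction_fraction
              or min(vf, vr) / var_total < th.strand_minor_direction_fraction)
    if not skewed:
        return "not-applicable", None
    p = fisher_exact_2x2([[rf, rr], [vf, vr]])
    return ("fail" if p < th.strand_alpha else "pass"), p


def assign_edit_type(ref_base: str, variant_base: str,
                     transcribed_strand: str) -> str:
    """Report the edit in transcript (RNA) orientation; e.g. genomic G>A on a
    minus-strand transcript is C>U."""
    ref, var = ref_base.upper(), variant_base.upper()
    if transcribed_strand == "-":
        ref, var = complement(ref), complement(var)
    ref = "U" if ref == "T" else ref
    var = "U" if var == "T" else var
    return f"{ref}>{var}"


def _infer_strand(fwd_fraction: float, chrom: str, pos: int, transcripts,
                  min_agreement: float) -> str:
    if not math.isnan(fwd_fraction):
        if fwd_fraction >= min_agreement:
            return "+"
        if fwd_fraction <= 1 - min_agreement:
            return "-"
    if transcripts:
        strands = {m.strand for m in transcripts
                   if m.chrom == chrom and m.tx_start <= pos <= m.tx_end}
        if len(strands) == 1:
            return strands.pop()
    return "."


def call_sites(
    profiles_by_aligner: dict[str, Sequence[BaseCallProfile]],
    sheet: SampleSheet,
    thresholds: FilterThresholds | None = None,
    transcripts=None,
) -> list[EditingSite]:
    """Run the full cascade; see :func:`call_sites_report` for gate counts."""
    return call_sites_report(profiles_by_aligner, sheet, thresholds,
                             transcripts).sites


def call_sites_report(
    profiles_by_aligner: dict[str, Sequence[BaseCallProfile]],
    sheet: SampleSheet,
    thresholds: FilterThresholds | None = None,
    transcripts=None,
) -> CallReport:
    th = thresholds or FilterThresholds()
    th.validate()
    aligners = list(profiles_by_aligner)
    if len(aligners) != 2:
        import warnings
        warnings.warn(f"expected 2 aligner datasets, got {len(aligners)}; "
                      "concordance will require all provided aligners")
    controls = sheet.samples("control")
    treated = sheet.samples("treated")
    for alg, profiles in profiles_by_aligner.items():
        for prof in profiles:
            for s in prof.counts:
                if s not in controls + treated:
                    raise ConfigError(
                        f"sample {s!r} in {alg} profiles but not in sample sheet")

    # per-aligner evaluation through gate 6
    evals: dict[str, dict[tuple[str, int], _AlignerEval]] = {}
    per_aligner_survivors: dict[str, dict[str, int]] = {}
    ref_bases: dict[tuple[str, int], str] = {}
    for alg in aligners:
        evals[alg] = {}
        surv = {g: 0 for g in GATES[:6]}
        tested = []
        for prof in profiles_by_aligner[alg]:
            key = (prof.chrom, prof.pos)
            ref_bases[key] = prof.ref_base
            ev = _eval_position(prof, sheet, th)
            evals[alg][key] = ev
            for gate, ok in ev.trace:
                if ok:
                    surv[gate] += 1
                else:
                    break
            if ev.passed:
                obs_c = [VariationObservation(
                    prof.base_count(s, ev.variant_base),
                    prof.base_count(s, prof.ref_base)) for s in controls]
                obs_t = [VariationObservation(
                    prof.base_count(s, ev.variant_base),
                    prof.base_count(s, prof.ref_base)) for s in treated]
                res = beta_binomial_test(obs_c, obs_t)
                ev.p_value = res.p_value
                tested.append((key, ev))
        # BH across all positions reaching gate 5 within this aligner
        if tested:
            adj = bh_adjust([ev.p_value for _, ev in tested])
            for (key, ev), pa in zip(tested, adj):
                ev.p_adjusted = float(pa)
                gate5 = ev.p_adjusted < th.alpha_adjusted
                ev.trace.append(("group_test", gate5))
                if gate5:
                    surv["group_test"] += 1
                    control_mean = float(np.mean(
                        [ev.levels[s] for s in controls]))
                    gate6 = (control_mean == 0.0
                             and ev.treated_mean >= th.min_treated_mean_level)
                    ev.trace.append(("group_specificity", gate6))
                    if gate6:
                        surv["group_specificity"] += 1
                    else:
                        ev.passed = False
                else:
                    ev.passed = False
        per_aligner_survivors[alg] = surv

    # cross-aligner gates
    all_keys = sorted(set().union(*[set(evals[a]) for a in aligners])
                      if aligners else set())
    survivors = {g: 0 for g in GATES}
    for g in GATES[:6]:
        survivors[g] = min(per_aligner_survivors[a][g] for a in aligners) \
            if aligners else 0
    sites: list[EditingSite] = []
    for key in all_keys:
        evs = [evals[a].get(key) for a in aligners]
        if not all(ev is not None and ev.passed for ev in evs):
            continue
        variant_bases = {ev.variant_base for ev in evs}
        if len(variant_bases) != 1:
            continue
        survivors["concordance"] += 1
        variant = variant_bases.pop()
        trace = [("concordance", True)]

        strand_ps = []
        failed = False
        for ev in evs:
            outcome, p = strand_bias_gate(ev.strand_counts, th)
            if p is not None:
                strand_ps.append(p)
            if outcome == "fail":
                failed = True
        trace.append(("strand_bias", not failed))
        if failed:
            continue
        survivors["strand_bias"] += 1

        per_aligner_mean = {a: evals[a][key].treated_mean for a in aligners}
        edit_level = float(np.mean(list(per_aligner_mean.values())))
        # strict '>' as printed, with a 1e-9 guard against float artifacts
        # in the derived mean
        gate9 = edit_level > th.final_min_edit_level + 1e-9
        trace.append(("final_level", gate9))
        if not gate9:
            continue
        survivors["final_level"] += 1

        chrom, pos = key
        ref = ref_bases[key]
        fwd = float(np.nanmean([ev.fwd_fraction for ev in evs]))
        strand = _infer_strand(fwd, chrom, pos, transcripts,
                               th.min_strand_call_agreement)
        if strand in "+-":
            edit_type = assign_edit_type(ref, variant, strand)
        else:
            edit_type = f"{ref}>{variant}"
        per_sample = {}
        for s in controls + treated:
            per_sample[s] = float(np.mean([ev.levels[s] for ev in evs]))
        # per-site trace: per-aligner gate decisions then cross-aligner gates
        full_trace = []
        for a, ev in zip(aligners, evs):
            full_trace.extend([(f"{a}:{g}", ok) for g, ok in ev.trace])
        full_trace.extend(trace)
        sites.append(EditingSite(
            chrom=chrom, pos=pos, transcribed_strand=strand, ref_base=ref,
            variant_base=variant, edit_type=edit_type,
            per_sample_levels=per_sample,
            per_aligner_mean_level=per_aligner_mean, edit_level=edit_level,
            p_value=float(np.mean([ev.p_value for ev in evs])),
            p_adjusted=float(np.mean([ev.p_adjusted for ev in evs])),
            strand_bias_p=min(strand_ps) if strand_ps else None,
            filter_trace=full_trace,
        ))
    sites.sort(key=lambda s: (s.chrom, s.pos))
    n_positions = len(all_keys)
    return CallReport(sites=sites, gate_survivors=survivors,
                      per_aligner_survivors=per_aligner_survivors,
                      n_positions=n_positions)


@dataclass
class SiteSummary:
    n: int
    mean_level: float
    sd_level: float
    min_level: float
    max_level: float
    n_above_20pct: int
    n_above_30pct: int
    edit_type_counts: dict[str, int]


def summarize_sites(sites: Iterable[EditingSite]) -> SiteSummary:
    """Count sites, mean/SD/min/max of editing level, counts above 20% and
    30%, and the tally of edit types."""
    sites = list(sites)
    levels = np.array([s.edit_level for s in sites], dtype=float)
    types: dict[str, int] = {}
    for s in sites:
        types[s.edit_type] = types.get(s.edit_type, 0) + 1
    if len(sites) == 0:
        return SiteSummary(0, math.nan, math.nan, math.nan, math.nan, 0, 0, {})
    return SiteSummary(
        n=len(sites),
        mean_level=float(levels.mean()),
        sd_level=float(levels.std(ddof=1)) if len(sites) > 1 else 0.0,
        min_level=float(levels.min()),
        max_level=float(levels.max()),
        n_above_20pct=int((levels > 0.20).sum()),
        n_above_30pct=int((levels > 0.30).sum()),
        edit_type_counts=types,
    )
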