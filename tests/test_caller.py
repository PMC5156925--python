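"""The filter cascade: gate behavior, strand-bias gate, edit typing and
site summaries."""

import numpy as np
import pytest

from edcall.caller import (FilterThresholds, assign_edit_type, call_sites,
                           call_sites_report, strand_bias_gate,
                           summarize_sites)
from edcall.records import (BaseCallProfile, ConfigError, EditingSite,
                            SampleRecord, SampleSheet)

CONTROLS = ["ctrl1", "ctrl2", "ctrl3"]
TREATED = ["trt1", "trt2", "trt3"]
ALIGNERS = ["aln1", "aln2"]


def make_sheet(controls=CONTROLS, treated=TREATED, aligners=ALIGNERS):
    return SampleSheet([SampleRecord(s, g, a)
                        for a in aligners
                        for s, g in [(c, "control") for c in controls]
                        + [(t, "treated") for t in treated]])


def profile(pos=100, ref="C", variant="T", variant_counts=(0, 0, 0, 20, 20, 20),
            depth=100, chrom="chr1", var_fwd_fraction=0.5,
            other_counts=None):
    """Balanced-strand profile with given per-sample variant counts
    (controls first)."""
    counts = {}
    for s, v in zip(CONTROLS + TREATED, variant_counts):
        r = depth - v
        cells = {(ref, "+"): r // 2, (ref, "-"): r - r // 2}
        if v:
            vf = int(round(v * var_fwd_fraction))
            cells[(variant, "+")] = vf
            if v - vf:
                cells[(variant, "-")] = v - vf
        if other_counts and s in other_counts:
            base, n = other_counts[s]
            cells[(base, "+")] = n
        counts[s] = cells
    return BaseCallProfile(chrom, pos, ref, counts)


def run(profiles, thresholds=None, **kw):
    by_aligner = {a: profiles for a in ALIGNERS}
    return call_sites(by_aligner, make_sheet(), thresholds, **kw)


class TestCascade:
    def test_clean_edited_position_called(self):
        from edcall.effects import TranscriptModel
        tx = [TranscriptModel("t1", "chr1", "+", [(50, 150)])]
        sites = run([profile()], transcripts=tx)
        assert len(sites) == 1
        site = sites[0]
        assert site.edit_level == pytest.approx(0.20, abs=1e-9)
        assert site.edit_type == "C>U"
        assert site.p_adjusted < 0.05
        assert all(ok for _, ok in site.filter_trace)

    def test_treated_mean_below_threshold_rejected(self):
        sites = run([profile(variant_counts=(0, 0, 0, 3, 3, 3))])
        assert sites == []  # treated mean 0.03 < 0.04

    def test_nonzero_control_background_rejected(self):
        sites = run([profile(variant_counts=(2, 2, 2, 20, 20, 20))])
        assert sites == []  # control mean level > 0

    def test_low_depth_sample_rejected(self):
        p = profile()
        p.counts["ctrl2"] = {("C", "+"): 3, ("C", "-"): 2}  # 5 calls < 6
        assert run([p]) == []

    def test_low_group_mean_depth_rejected(self):
        p = profile(depth=8)  # all samples >=6 calls but group mean 8 < 9
        assert run([p]) == []

    def test_other_base_contamination_rejected(self):
        p = profile(other_counts={"trt1": ("G", 2)})  # >1 calls in a sample
        assert run([p]) == []

    def test_similar_levels_in_both_groups_rejected_by_dispersion(self):
        # all six samples at level 0.20: range/mean = 0 < 2
        sites = run([profile(variant_counts=(20, 20, 20, 20, 20, 20))])
        assert sites == []

    def test_discordant_aligners_rejected(self):
        signal = [profile()]
        blank = [profile(variant_counts=(0, 0, 0, 0, 0, 0))]
        sites = call_sites({"aln1": signal, "aln2": blank}, make_sheet())
        assert sites == []

    def test_final_level_gate_strictly_above_threshold(self):
        # treated level exactly 0.05 fails the strict > 0.05 final gate
        sites = run([profile(variant_counts=(0, 0, 0, 5, 5, 5))])
        assert sites == []

    def test_strand_skewed_variant_calls_rejected(self):
        sites = run([profile(var_fwd_fraction=1.0)])
        assert sites == []

    def test_unknown_sample_raises_config_error(self):
        p = profile()
        p.counts["mystery"] = {("C", "+"): 10}
        with pytest.raises(ConfigError, match="mystery"):
            run([p])

    def test_minus_strand_g_to_a_reports_c_to_u(self):
        from edcall.effects import TranscriptModel
        tx = [TranscriptModel("t1", "chr1", "-", [(50, 150)])]
        p = profile(ref="G", variant="A")
        sites = call_sites({a: [p] for a in ALIGNERS}, make_sheet(),
                           transcripts=tx)
        assert len(sites) == 1
        assert sites[0].transcribed_strand == "-"
        assert sites[0].edit_type == "C>U"

    def test_permuting_samples_within_group_is_invariant(self):
        p1 = profile(variant_counts=(0, 0, 0, 18, 22, 25))
        sites_a = run([p1])
        # same counts assigned to permuted sample names within each group
        p2 = profile(variant_counts=(0, 0, 0, 18, 22, 25))
        p2.counts = {"ctrl2": p1.counts["ctrl1"], "ctrl3": p1.counts["ctrl2"],
                     "ctrl1": p1.counts["ctrl3"], "trt3": p1.counts["trt1"],
                     "trt1": p1.counts["trt2"], "trt2": p1.counts["trt3"]}
        sites_b = run([p2])
        assert len(sites_a) == len(sites_b) == 1
        assert sites_a[0].edit_level == pytest.approx(sites_b[0].edit_level)
        assert sites_a[0].p_value == pytest.approx(sites_b[0].p_value,
                                                   rel=1e-6)

    def test_swapping_group_labels_mirrors_the_call(self):
        # editing lives in the treated group; relabel the groups and the
        # same position is called from the mirrored side
        p = profile()
        swapped = SampleSheet([
            SampleRecord(s, {"control": "treated",
                             "treated": "control"}[g], a)
            for a in ALIGNERS
            for s, g in [(c, "control") for c in CONTROLS]
            + (([(t, "treated") for t in TREATED]))])
        sites = call_sites({a: [p] for a in ALIGNERS}, swapped)
        # new 'treated' group (former controls) has zero variant level
        assert sites == []

    def test_gate_survivor_accounting(self):
        profiles = [profile(pos=100),
                    profile(pos=200, variant_counts=(0, 0, 0, 3, 3, 3)),
                    profile(pos=300, variant_counts=(0, 0, 0, 0, 0, 0))]
        report = call_sites_report({a: profiles for a in ALIGNERS},
                                   make_sheet())
        assert report.n_positions == 3
        assert report.gate_survivors["depth"] == 3
        assert report.gate_survivors["candidate"] == 2
        assert report.gate_survivors["final_level"] == len(report.sites) == 1


class TestStrandBiasGate:
    def test_balanced_counts_not_applicable(self):
        outcome, p = strand_bias_gate((50, 50, 10, 10))
        assert outcome == "not-applicable" and p is None

    def test_skewed_variant_calls_apply_fisher(self):
        from oracles import fisher_enumeration_p
        outcome, p = strand_bias_gate((50, 50, 20, 0))
        oracle = fisher_enumeration_p([[50, 50], [20, 0]])
        assert p == pytest.approx(oracle, rel=1e-9)
        assert outcome == ("fail" if oracle < 0.05 else "pass")

    def test_too_few_variant_calls_not_applicable(self):
        outcome, p = strand_bias_gate((50, 50, 7, 0))
        assert outcome == "not-applicable" and p is None

    def test_skewed_but_non_significant_passes(self):
        outcome, p = strand_bias_gate((6, 4, 8, 2))
        assert outcome == "pass" and p >= 0.05


class TestAssignEditType:
    @pytest.mark.parametrize("ref,var,strand,expected", [
        ("C", "T", "+", "C>U"),
        ("G", "A", "-", "C>U"),
        ("A", "G", "+", "A>G"),
        ("T", "C", "+", "U>C"),
    ])
    def test_transcript_orientation(self, ref, var, strand, expected):
        assert assign_edit_type(ref, var, strand) == expected


def _summary_site(level):
    return EditingSite("chr1", 1, "+", "C", "T", "C>U", {}, {}, level,
                       1e-9, 1e-7)


class TestSummarize:
    def test_counting_above_thresholds(self):
        s = summarize_sites([_summary_site(lv) for lv in (0.10, 0.25, 0.35)])
        assert (s.n, s.n_above_20pct, s.n_above_30pct) == (3, 2, 1)
        assert s.edit_type_counts == {"C>U": 3}

    def test_empty_list_flagged(self):
        s = summarize_sites([])
        assert s.n == 0 and np.isnan(s.mean_level)

    def test_mean_sd_agree_with_welford_oracle(self):
        rng = np.random.default_rng(6)
        levels = rng.uniform(0.05, 0.6, 200)
        s = summarize_sites([_summary_site(lv) for lv in levels])
        # independent single-pass Welford accumulation
        mean = 0.0
        m2 = 0.0
        for i, x in enumerate(levels, start=1):
            delta = x - mean
            mean += delta / i
            m2 += delta * (x - mean)
        sd = (m2 / (len(levels) - 1)) ** 0.5
        assert s.mean_level == pytest.approx(mean, abs=1e-12)
        assert s.sd_level == pytest.approx(sd, abs=1e-12)


class TestThresholdMonotonicity:
    def test_relaxing_thresholds_never_loses_sites(self):
        """Relaxing any single gate constant cannot shrink the call set on a
        fixed synthetic dataset."""
        from edcall.simulate import SimulationConfig, simulate_dataset
        ds = simulate_dataset(SimulationConfig(n_positions=150, seed=9))
        base = len(call_sites(ds.profiles_by_aligner, ds.sheet,
                              transcripts=ds.transcripts))
        relaxations = dict(min_calls_per_sample=0, min_group_mean_depth=0,
                           min_sample_variant_level=0.0,
                           min_group_mean_variant_count=0.0,
                           min_treated_mean_level=0.0,
                           final_min_edit_level=0.0,
                           min_range_over_mean=0.0,
                           max_other_base_count_per_sample=10 ** 6,
                           strand_alpha=0.0)
        for field, relaxed in relaxations.items():
            th = FilterThresholds(**{field: relaxed})
            n = len(call_sites(ds.profiles_by_aligner, ds.sheet, th,
                               transcripts=ds.transcripts))
            assert n >= base, f"relaxing {field} lost sites"
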