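"""Synthetic-data generator: determinism, noise structure, ground-truth
scoring and strand-bias-artifact behavior."""

import io

import numpy as np
import pytest

from edcall.caller import FilterThresholds, call_sites
from edcall.io_formats import write_pileup
from edcall.records import EdcallError, EditingSite
from edcall.simulate import (SimulationConfig, TruthRecord, TruthTable,
                             score_calls, simulate_dataset)


def _pileup_bytes(ds):
    import os
    import tempfile

    chunks = []
    for alg, profs in ds.profiles_by_aligner.items():
        for s in ds.sheet.samples():
            with tempfile.NamedTemporaryFile("r", suffix=".pu",
                                             delete=False) as fh:
                path = fh.name
            write_pileup(profs, path, sample_id=s)
            chunks.append(open(path).read())
            os.unlink(path)
    return "".join(chunks)


class TestDeterminism:
    def test_same_seed_byte_identical_pileups(self):
        cfg = SimulationConfig(n_positions=40, seed=123)
        a = _pileup_bytes(simulate_dataset(cfg))
        b = _pileup_bytes(simulate_dataset(SimulationConfig(n_positions=40,
                                                            seed=123)))
        assert a == b

    def test_different_seed_differs(self):
        a = _pileup_bytes(simulate_dataset(SimulationConfig(n_positions=40,
                                                            seed=1)))
        b = _pileup_bytes(simulate_dataset(SimulationConfig(n_positions=40,
                                                            seed=2)))
        assert a != b


class TestStructure:
    def test_null_configuration_produces_no_calls(self):
        cfg = SimulationConfig(n_positions=150, fraction_edited=0.0,
                               strand_bias_artifact_fraction=0.0, seed=5)
        ds = simulate_dataset(cfg)
        assert ds.truth.edited_positions() == set()
        sites = call_sites(ds.profiles_by_aligner, ds.sheet,
                           transcripts=ds.transcripts)
        assert len(sites) <= 1  # stochastically ~0 false calls

    def test_noise_free_limit(self):
        cfg = SimulationConfig(n_positions=60, error_rate=0.0,
                               level_range=(0.2, 0.2), level_icc=0.0,
                               depth_mean=100, strand_bias_artifact_fraction=0,
                               seed=7)
        ds = simulate_dataset(cfg)
        edited = ds.truth.edited_positions()
        assert edited
        controls = ds.sheet.samples("control")
        treated = ds.sheet.samples("treated")
        for alg, profs in ds.profiles_by_aligner.items():
            for prof in profs:
                variant = {"C": "T", "G": "A", "A": "G", "T": "C"}[prof.ref_base]
                for s in controls:
                    assert prof.base_count(s, variant) == 0
                if prof.pos in edited:
                    levels = []
                    for s in treated:
                        v = prof.base_count(s, variant)
                        r = prof.base_count(s, prof.ref_base)
                        levels.append(v / (v + r))
                    assert abs(np.mean(levels) - 0.2) < 0.1

    def test_control_level_converges_to_error_rate(self):
        # law of large numbers at high depth
        cfg = SimulationConfig(n_positions=60, fraction_edited=0.0,
                               strand_bias_artifact_fraction=0.0,
                               depth_mean=10000, depth_dispersion=50, seed=11)
        ds = simulate_dataset(cfg)
        v_total = r_total = 0
        for prof in ds.profiles_by_aligner["aligner1"]:
            variant = {"C": "T", "G": "A", "A": "G", "T": "C"}[prof.ref_base]
            for s in ds.sheet.samples("control"):
                v_total += prof.base_count(s, variant)
                r_total += prof.base_count(s, prof.ref_base)
        level = v_total / (v_total + r_total)
        assert level == pytest.approx(cfg.error_rate, rel=0.15)

    def test_reference_matches_profiles_and_truth_strands(self):
        ds = simulate_dataset(SimulationConfig(n_positions=50, seed=3))
        seq = ds.genome[ds.config.chrom]
        for prof in ds.profiles_by_aligner["aligner1"]:
            assert seq[prof.pos - 1] == prof.ref_base
            rec = ds.truth[prof.pos]
            if rec.is_edited:
                expected = "C" if rec.transcribed_strand == "+" else "G"
                assert prof.ref_base == expected

    def test_edited_windows_enriched_for_context(self):
        cfg = SimulationConfig(n_positions=300, motif_fraction=1.0,
                               stemloop_fraction=1.0, seed=13)
        ds = simulate_dataset(cfg)
        from edcall.context import extract_window, match_motif
        from edcall.stemloop import find_inverted_repeat
        motif_hits = arm_hits = n = 0
        for pos in sorted(ds.truth.edited_positions()):
            rec = ds.truth[pos]
            w = extract_window(ds.genome, cfg.chrom, pos,
                               rec.transcribed_strand)
            n += 1
            motif_hits += match_motif(w)
            arm_hits += find_inverted_repeat(w).arm_length >= 3
        assert n > 0
        assert arm_hits / n > 0.9
        assert motif_hits / n > 0.5  # arm embedding may overwrite the +1 base

    def test_invalid_config_rejected(self):
        with pytest.raises(EdcallError):
            SimulationConfig(fraction_edited=1.5).validate()
        with pytest.raises(EdcallError):
            SimulationConfig(depth_mean=-1).validate()


class TestScoring:
    def test_hand_counted_fixture(self):
        truth = TruthTable("c", {
            p: TruthRecord(p, p in {10, 20, 30}, 0.2 if p in {10, 20, 30}
                           else 0.0, "+", mean_depth=100.0)
            for p in range(10, 110, 10)})

        def fake_site(pos, level):
            return EditingSite("c", pos, "+", "C", "T", "C>U", {}, {}, level,
                               1e-9, 1e-7)

        called = [fake_site(10, 0.25), fake_site(20, 0.18),
                  fake_site(40, 0.1)]  # 2 TP, 1 FP, 1 FN(30)
        sc = score_calls(called, truth)
        assert sc.sensitivity == pytest.approx(2 / 3)
        assert sc.fdr == pytest.approx(1 / 3)
        assert sc.level_mae == pytest.approx((0.05 + 0.02) / 2)

    def test_perfect_and_empty_call_sets(self):
        truth = TruthTable("c", {10: TruthRecord(10, True, 0.3, "+",
                                                 mean_depth=80.0)})
        perfect = [EditingSite("c", 10, "+", "C", "T", "C>U", {}, {}, 0.3,
                               1e-9, 1e-7)]
        sc = score_calls(perfect, truth)
        assert (sc.sensitivity, sc.fdr, sc.level_mae) == (1.0, 0.0, 0.0)
        sc0 = score_calls([], truth)
        assert sc0.sensitivity == 0.0 and sc0.fdr == 0.0

    def test_eligibility_restriction(self):
        truth = TruthTable("c", {
            10: TruthRecord(10, True, 0.05, "+", mean_depth=100.0),
            20: TruthRecord(20, True, 0.30, "+", mean_depth=100.0),
            30: TruthRecord(30, True, 0.30, "+", mean_depth=20.0)})
        sc = score_calls([], truth, level_min=0.10, depth_min=50)
        assert sc.n_true_eligible == 1  # only pos 20 qualifies


class TestStrandBiasArtifacts:
    def test_gate_removes_artifacts_that_would_otherwise_be_called(self):
        cfg = SimulationConfig(n_positions=250, fraction_edited=0.0,
                               strand_bias_artifact_fraction=0.15, seed=17)
        ds = simulate_dataset(cfg)
        artifacts = {p for p, r in ds.truth.records.items() if r.is_artifact}
        assert artifacts
        with_gate = {s.pos for s in call_sites(
            ds.profiles_by_aligner, ds.sheet, transcripts=ds.transcripts)}
        no_gate_th = FilterThresholds(strand_alpha=0.0)  # never fails
        without_gate = {s.pos for s in call_sites(
            ds.profiles_by_aligner, ds.sheet, no_gate_th,
            transcripts=ds.transcripts)}
        assert len(without_gate & artifacts) > 0
        assert len(with_gate & artifacts) < len(without_gate & artifacts)
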