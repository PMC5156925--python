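"""Simulate a two-group, two-aligner RNA-seq base-call dataset and run the
full editing-site filter cascade on it.

Prints the step-wise filtering table (positions surviving each gate), the
recovery of the planted editing sites, and a summary of the called set.
"""

from edcall.caller import call_sites_report, summarize_sites
from edcall.simulate import SimulationConfig, score_calls, simulate_dataset

cfg = SimulationConfig(n_positions=400, seed=7)
ds = simulate_dataset(cfg)
print(f"simulated {cfg.n_positions} positions, "
      f"{len(ds.truth.edited_positions())} truly edited "
      f"(treated-group editing only; controls carry sequencing error at "
      f"rate {cfg.error_rate})\n")

report = call_sites_report(ds.profiles_by_aligner, ds.sheet,
                           transcripts=ds.transcripts)
print("gate                 survivors")
for gate, n in report.gate_survivors.items():
    print(f"{gate:<20} {n}")

score = score_calls(report.sites, ds.truth, level_min=0.10, depth_min=50)
print(f"\nsensitivity (level>=0.10, depth>=50): {score.sensitivity:.2f}")
print(f"false discovery rate:                 {score.fdr:.3f}")
print(f"editing-level mean absolute error:    {score.level_mae:.4f}")

s = summarize_sites(report.sites)
print(f"\ncalled {s.n} sites; mean level {s.mean_level:.3f} "
      f"(SD {s.sd_level:.3f}); {s.n_above_20pct} sites >20%; "
      f"edit types {s.edit_type_counts}")
print("\nEvery call is C>U in transcript orientation: the cascade requires "
      "zero control background, group significance, dual-aligner "
      "concordance and balanced read directions.")
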