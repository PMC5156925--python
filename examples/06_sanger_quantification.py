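"""Editing levels from Sanger chromatogram peak heights, with the
software's minor-peak detection limit."""

from edcall.sanger import (PeakPair, detection_threshold, replicate_mean,
                           sanger_level)

print(f"detection threshold at the 5% software limit: "
      f"{detection_threshold():.3f}\n")

for major, minor in [(100, 5), (100, 4), (100, 30), (1200, 430)]:
    r = sanger_level(PeakPair(major, minor))
    tag = "below detection (reported 0)" if r.censored else f"{r.level:.3f}"
    print(f"major {major:>5}, minor {minor:>3}  ->  level {tag}")

reps = [sanger_level(PeakPair(980, 310)), sanger_level(PeakPair(1050, 290)),
        sanger_level(PeakPair(1010, 20))]
print(f"\nreplicate mean incl. censored: {replicate_mean(reps):.3f}")
print(f"replicate mean excl. censored: "
      f"{replicate_mean(reps, include_censored=False):.3f}")
print("\nA minor peak below 5% of the major peak is invisible to the base "
      "caller, so levels under ~0.048 are censored rather than measured.")
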