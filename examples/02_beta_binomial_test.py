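"""The two-group beta-binomial test on variant/reference call counts.

Compares a control group with zero variant calls against a treated group
edited at ~20%, then shows a null comparison for contrast.
"""

from edcall.stats import beta_binomial_test

control = [(0, 100), (0, 120), (0, 90)]     # (variant, reference) calls
treated = [(20, 80), (25, 95), (18, 72)]

r = beta_binomial_test(control, treated)
print(f"edited site : p = {r.p_value:.2e}  group means = "
      f"({r.group_means[0]:.4f}, {r.group_means[1]:.4f})  "
      f"overdispersion rho = {r.overdispersion_estimate:.2e}")

null = beta_binomial_test([(5, 95), (6, 94), (4, 96)],
                          [(5, 95), (4, 96), (6, 94)])
print(f"null site   : p = {null.p_value:.3f}")

print("\nThe test is a likelihood-ratio test with a shared intraclass-"
      "correlation overdispersion; its statistic is Bartlett-corrected "
      "against a parametric bootstrap so that 3-vs-3 designs keep nominal "
      "type-I error.")
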