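"""Rank the contiguous and interlaced schemes with the bound metric.

Runs the study-2 pipeline at a small problem size: estimates the Bayesian
CRB design metric for both multi-illumination schemes, validates against the
Monte-Carlo MAP reconstruction error, and prints the comparison report with
half-sample error intervals.
"""

import pactoed as po

cfg = po.study_config(2, "desk", h_boundary=0.85, h_center=0.85,
                      n_transducers=32, n_times=40, dt=2e-7 * 184 / 40,
                      n_samples_bound=400, n_samples_cov=500,
                      n_trials_mse=20, seed=0)
result = po.run_study(cfg)

print("summary table (rows: schemes; columns: MSE and bound for m1, mu_a):")
print(result.table.round(4).to_string())
print()
report = po.compare_designs(result)
print(report.round(4).to_string(index=False))
print("ranking declared" if report.attrs["ranked"]
      else "half-sample intervals overlap: no ranking declared")
# the interlaced scheme carries the smaller mu_a metric in bound and MSE
# alike; at this demonstration sample size the bound estimator's upward
# Monte-Carlo bias can sit within a few percent of the MSE, so the strict
# information-inequality check lives in the test suite at larger N_s
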