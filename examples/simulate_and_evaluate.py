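"""Simulate a calibrated cohort and evaluate diagnostic performance.

Draws 600 lesions with three noisy readers, then scores each conspicuity
metric's ability to separate benign lesions or background parenchymal
enhancement (BPE) from malignancy: AUC with bootstrap CI, the
maximum-Youden threshold, and Fagan post-test probabilities.
"""

from cemquant import evaluate_all, simulate_cohort, summaries_to_frame
from cemquant.cohort import DEFAULT_PARAMS, SimulationParams

params = SimulationParams(classes=DEFAULT_PARAMS.classes,
                          n_lesions=600, seed=7)
cohort = simulate_cohort(params)
summaries = evaluate_all(cohort, n_boot=500, seed=7)
frame = summaries_to_frame(summaries)

cols = ["comparison", "metric", "auc", "auc_ci_lo", "auc_ci_hi",
        "threshold", "sensitivity_pct", "specificity_pct",
        "posttest_p_malignancy_pct"]
print(frame[cols].round(3).to_string(index=False))
print("\nCE_early carries the most discriminative signal by construction "
      "(the simulator separates class locations on the early view); the "
      "post-test probability is the Bayes update of the in-sample "
      "malignancy prevalence at the Youden threshold.")
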