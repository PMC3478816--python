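"""A small synthetic treadmill study with a table-style report.

Three pseudo-subjects walk at seven inclinations (30 strides each);
the report shows per-group mean +/- SD of the estimates, per-subject
RMSE and Pearson correlation with the true grade, and the pooled
global metrics (accuracy = mean error, precision = mean within-group
error SD).
"""

from gaitslope import (
    GaitScenario,
    build_report,
    estimate_slopes,
    simulate_recording,
)

SLOPES = (0.14, 0.10, 0.06, 0.02, -0.02, -0.05, -0.09)

runs = []
for s_idx, tilt_gain in enumerate((0.9, 1.0, 1.2), start=1):
    for k, slope in enumerate(SLOPES):
        scn = GaitScenario(slope=slope, n_strides=30, tilt_gain=tilt_gain,
                           seed=100 * s_idx + k)
        rec, _ = simulate_recording(scn)
        res = estimate_slopes(rec)
        res.meta["subject"] = f"s{s_idx}"
        res.meta["inclination"] = slope
        runs.append(res)

report = build_report(runs)
print(report.to_text())
print()
print("A Pearson r near 1 per subject means the method separates the "
      "grades; the global RMSE summarizes the per-stride error budget.")
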