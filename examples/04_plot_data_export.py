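"""Export predicted-versus-true-risk pairs for plotting.

Reproduces the data behind a calibration-style scatter: 500 randomly sampled
application subjects with their true generating risk and the model's
prediction (optionally jittered for display). Under the development
missingness mechanism, the zero-imputation model assigns every missing-P
subject the same probability (~0.2), visible as a horizontal band.
"""

from missshift import StudyConfig, export_plot_data, run_study

result = run_study(StudyConfig(seed=1))

sample = export_plot_data(result, scenario=1, method="zero",
                          sample_size=500, jitter=0.01, seed=9)
print(sample.head())
modal = sample["predicted"].round(6).mode()[0]
band = (sample["predicted"].round(6) == modal).sum()
print(
    f"\n{band} of {len(sample)} sampled subjects share the prediction "
    f"{modal:.3f} - the missing-P band."
)

sample4 = export_plot_data(result, scenario=4, method="zero", sample_size=500)
print(
    f"scenario 4: {sample4['predicted'].nunique()} distinct predicted value(s) "
    "- no discrimination left."
)
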