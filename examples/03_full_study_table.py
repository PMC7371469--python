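"""Run the full transportability study and print the performance table.

A model is developed under informative missingness and applied to a fresh
cohort under four deployment scenarios: (1) the same informative mechanism,
(2) no missing values, (3) a random half missing, (4) everything missing.
Each row reports mean prediction error against the generating risk (with SD),
RMSPE, c-statistic, Brier score and calibration-in-the-large; NA marks cells
where a strategy cannot be applied (nothing observed to average or donate).
"""

from missshift import StudyConfig, render_table, run_study

result = run_study(StudyConfig(n_dev=20_000, n_app=20_000, seed=1))
frame, text = render_table(result)
print(text)
print(
    "\nReading the table: zero/mean imputation beat the reference model only "
    "while the deployment\nmissingness mechanism matches development "
    "(scenario 1); once missingness becomes random\n(scenario 3) their "
    "discrimination collapses toward c = 0.5, and with everything missing\n"
    "(scenario 4) all predictions coincide, so c = 0.500 exactly."
)
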