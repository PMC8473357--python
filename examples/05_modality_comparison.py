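"""Why fuse? EMG-only vs accel-only vs fused pipelines on one cohort.

Acceleration reflects the current mechanical state, so accel-only models
recognise a mode change only after it happens (positive response time).
Muscle activation precedes movement, so EMG-bearing models see the change
coming.  Fusion keeps the EMG's early warning while the added channels
raise steady-state accuracy.
"""

from gaitfusion import ClassifierSpec
from gaitfusion.evaluation import PipelineConfig, run_modality_comparison, simulate_cohort

trials = simulate_cohort(2, 6, seed=1)
spec = ClassifierSpec("SVM", seed=1,
                      params={"c_grid": [1.0, 16.0, 256.0],
                              "g_grid": [2.0 ** -5, 2.0 ** -2, 2.0]})
df = run_modality_comparison(trials, spec, PipelineConfig(train_stride=100),
                             split_seed=1)
print(df.to_string(index=False))
print("\nmean_rt_ms < 0 only where EMG features are present: the 300 ms "
      "activation lead is invisible to the accelerometers.")
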