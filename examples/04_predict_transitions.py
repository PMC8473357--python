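"""End-to-end: train on steady-state data, predict the next mode early.

Simulates a small cohort of task-2 trials (stand-walk-stairs-walk-stand,
300 ms EMG activation lead), trains an SVM on steady-state feature rows of
five trials, and streams the held-out trial through the vote + legality
layer.  Negative response times mean the upcoming steady mode was named
before it began.
"""

from gaitfusion import ClassifierSpec
from gaitfusion.classifiers import split_trials
from gaitfusion.evaluation import PipelineConfig, evaluate_online, simulate_cohort
from gaitfusion.modes import LocomotionMode as M

trials = simulate_cohort(2, 6, seed=1)
train, test = split_trials(trials, seed=1)

spec = ClassifierSpec("SVM", seed=1,
                      params={"c_grid": [1.0, 16.0, 256.0],
                              "g_grid": [2.0 ** -5, 2.0 ** -2, 2.0]})
res = evaluate_online(train, test, spec, PipelineConfig(train_stride=100))

print(f"steady-state CA = {res['ca']:.2f} %   (SE {res['se_mean']:.2f} %, "
      f"SP {res['sp_mean']:.2f} %)")
print(f"predictive accuracy PA = {res['pa']:.1f} % over "
      f"{len(res['outcomes'])} transitions")
print(f"mean response time RT = {res['mean_rt_ms']:.1f} ms "
      f"(negative = predicted before onset)\n")
for o in res["outcomes"]:
    rt = f"{o.rt_ms:+8.1f} ms" if o.rt_ms is not None else "   missed"
    print(f"  -> {M(int(o.next_mode)).name:>2} at {o.onset_s:6.2f} s   RT {rt}")
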