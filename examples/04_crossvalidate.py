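"""Benchmark the classifier suite on lameness within one activity.

Each algorithm is evaluated by lameness-stratified 10-fold CV on the
standing windows of a moderate-effect flock.  The random forest is
typically the strongest, mirroring the method's intended deployment.
"""

import numpy as np

import ovinesense as ov
from ovinesense.classify import ALGORITHMS, ClassifierSpec, run_cv
from ovinesense.features import feature_table
from ovinesense.preprocess import window_recording

config = ov.SimulationConfig(recording_duration=600, n_lame=4, n_nonlame=4, rng_seed=4)
profiles = ov.default_profiles(config, effect_size=1.0, rng=np.random.default_rng(4))
windows = []
for rec in ov.generate_flock(config, profiles):
    windows.extend(window_recording(rec))
table = feature_table(windows, config.sampling_rate)
standing = table[table["activity"] == "standing"].reset_index(drop=True)

print(f"{len(standing)} standing windows, {standing['lame'].mean():.0%} lame")
print(f"{'algorithm':>10} {'accuracy':>9} {'precision':>10} {'recall':>7} {'F':>6} {'spec':>6}")
for algorithm in ALGORITHMS:
    result = run_cv(standing, None, ClassifierSpec(algorithm, seed=0), n_features=32, fold_seed=0)
    m = result.mean_metrics
    print(
        f"{algorithm:>10} {m.overall_accuracy:>9.3f} {m.precision:>10.3f} "
        f"{m.recall:>7.3f} {m.f_score:>6.3f} {m.specificity:>6.3f}"
    )
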