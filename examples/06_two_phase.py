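"""The two-phase prediction path: activity first, then lameness.

Phase 1 classifies each window's activity from the same 32 features;
phase 2 routes the window to the lameness model trained for that
activity.  On held-out sheep the end-to-end accuracy should sit close
to oracle-activity routing because the three activities are easy to
tell apart.
"""

import numpy as np

import ovinesense as ov
from ovinesense.classify import ClassifierSpec, fit_two_phase, two_phase_predict
from ovinesense.features import feature_table
from ovinesense.preprocess import window_recording

config = ov.SimulationConfig(recording_duration=600, n_lame=4, n_nonlame=4, rng_seed=6)
profiles = ov.default_profiles(config, effect_size=2.0, rng=np.random.default_rng(6))
windows = []
for rec in ov.generate_flock(config, profiles):
    windows.extend(window_recording(rec))
table = feature_table(windows, config.sampling_rate)

sheep = sorted(table["sheep_id"].unique())
train = table[table["sheep_id"].isin(sheep[::2])]
test = table[~table["sheep_id"].isin(sheep[::2])].reset_index(drop=True)

predictor = fit_two_phase(train, ClassifierSpec("RF", seed=0))
end_to_end = two_phase_predict(test, predictor)
oracle = two_phase_predict(test, predictor, oracle_activity=test["activity"].to_numpy())

truth = test["lame"].to_numpy()
activity_acc = np.mean(end_to_end["activity"].to_numpy() == test["activity"].to_numpy())
print(f"phase-1 activity accuracy:      {activity_acc:.3f}")
print(f"end-to-end lameness accuracy:   {np.mean(end_to_end['predicted_lame'] == truth):.3f}")
print(f"oracle-activity lameness accuracy: {np.mean(oracle['predicted_lame'] == truth):.3f}")
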