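"""Aggregate window predictions into sheep-level verdicts.

Each sheep's out-of-fold windows are summarised as a lame-window ratio;
the lame and sound groups are compared with the σ-difference
Δσ = (μ_lame − σ_lame) − (μ_nonlame + σ_nonlame) (positive iff the 1-SD
intervals separate), a Mann-Whitney U test, and the midpoint threshold
(μ_lame + μ_nonlame)/2 above which a sheep is declared lame.
"""

import numpy as np

import ovinesense as ov
from ovinesense.classify import ClassifierSpec, grouped_kfold, run_cv
from ovinesense.evaluate import evaluate_sheep_level
from ovinesense.features import feature_table
from ovinesense.preprocess import window_recording

config = ov.SimulationConfig(recording_duration=900, n_lame=6, n_nonlame=6, rng_seed=5)
profiles = ov.default_profiles(config, effect_size=1.5, rng=np.random.default_rng(5))
windows = []
for rec in ov.generate_flock(config, profiles):
    windows.extend(window_recording(rec))
table = feature_table(windows, config.sampling_rate)

for activity in ("walking", "standing", "lying"):
    sub = table[table["activity"] == activity].reset_index(drop=True)
    folds = grouped_kfold(sub["lame"], sub["sheep_id"], k=6, seed=0)
    result = run_cv(sub, None, ClassifierSpec("RF", seed=0), n_features=32, fold_assignment=folds)
    sep, verdicts, accuracy = evaluate_sheep_level(result.predictions)
    print(
        f"{activity:>9}: delta_sigma={sep.delta_sigma:+.3f}  threshold={sep.threshold:.3f}  "
        f"U={sep.mann_whitney_u:.0f} p={sep.p_value:.4f}  sheep accuracy={accuracy:.1f}%"
    )
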