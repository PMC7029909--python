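"""Simulate a small annotated flock and inspect its activity accounting.

Generates six sheep-day ear-tag recordings (three lame, three sound) at
16 Hz and prints how much time each sheep spent walking, standing and
lying.  Shares should sit near the default activity budget
(32 % / 37 % / 31 %).
"""

import ovinesense as ov

config = ov.SimulationConfig(recording_duration=900, n_lame=3, n_nonlame=3, rng_seed=1)
flock = ov.generate_flock(config)

print(f"{'sheep':>10} {'score':>5} {'lame':>5} {'walk %':>7} {'stand %':>8} {'lie %':>7}")
for rec in flock:
    spent = {"walking": 0.0, "standing": 0.0, "lying": 0.0}
    for start, end, activity, _ in rec.annotations:
        spent[activity] += end - start
    total = sum(spent.values())
    print(
        f"{rec.sheep_id:>10} {rec.lameness_score:>5} {str(rec.is_lame):>5} "
        f"{100 * spent['walking'] / total:>7.1f} {100 * spent['standing'] / total:>8.1f} "
        f"{100 * spent['lying'] / total:>7.1f}"
    )
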