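"""Reference accounting for the ear-tag field deployment this pipeline models.

The original deployment collected 23 sheep-day recordings (10 non-lame,
13 lame) at 16 Hz and retained 20 104 seven-second windows.  The raw
recordings are not publicly deposited; what is reproducible from the
published record is the sample accounting — per-behaviour window counts
for each lameness class — and the sheep-level verdict counts.  This
module stores those counts and recomputes every derived percentage from
them, so the arithmetic (not just the printed numbers) lives in code.
"""

from __future__ import annotations

import pandas as pd

from ovinesense.evaluate import sheep_level_accuracy

#: per-behaviour window counts by lameness class from the deployment
FIELD_WINDOW_COUNTS: dict[str, dict[str, int]] = {
    "walking": {"nonlame": 2974, "lame": 3370},
    "standing": {"nonlame": 3822, "lame": 3591},
    "lying": {"nonlame": 2271, "lame": 4076},
}

#: per-behaviour sheep-level verdicts: (correctly classified, assessed)
FIELD_SHEEP_VERDICTS: dict[str, tuple[int, int]] = {
    "walking": (16, 18),
    "standing": (12, 15),
    "lying": (11, 12),
}

#: flock composition of the deployment
FIELD_FLOCK = {"nonlame": 10, "lame": 13}


def behaviour_accounting(
    counts: dict[str, dict[str, int]] | None = None,
) -> pd.DataFrame:
    """Recompute the within-behaviour class percentages and totals.

    Returns one row per (behaviour, class) with the window count, the
    class share within the behaviour and the behaviour's share of all
    windows, each rounded to the 2-decimal reporting precision.
    """
    if counts is None:
        counts = FIELD_WINDOW_COUNTS
    grand_total = sum(sum(by_class.values()) for by_class in counts.values())
    if grand_total == 0:
        raise ValueError("accounting requires at least one window")
    rows = []
    for behaviour, by_class in counts.items():
        behaviour_total = sum(by_class.values())
        for cls, n in by_class.items():
            rows.append(
                {
                    "behaviour": behaviour,
                    "class": cls,
                    "n_windows": n,
                    "pct_within_behaviour": round(100.0 * n / behaviour_total, 2),
                    "behaviour_pct_of_total": round(100.0 * behaviour_total / grand_total, 2),
                }
            )
    frame = pd.DataFrame(rows)
    frame.attrs["grand_total"] = grand_total
    return frame


def total_windows(counts: dict[str, dict[str, int]] | None = None) -> int:
    """Grand total of retained windows across behaviours and classes."""
    if counts is None:
        counts = FIELD_WINDOW_COUNTS
    return sum(sum(by_class.values()) for by_class in counts.values())


def sheep_level_accuracies(
    verdicts: dict[str, tuple[int, int]] | None = None,
) -> dict[str, float]:
    """Sheep-level accuracy (percent) per behaviour from verdict counts."""
    if verdicts is None:
        verdicts = FIELD_SHEEP_VERDICTS
    return {
        behaviour: sheep_level_accuracy(correct, total)
        for behaviour, (correct, total) in verdicts.items()
    }
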