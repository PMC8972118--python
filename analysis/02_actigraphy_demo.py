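#!/usr/bin/env python
"""Actigraphy processing on synthetic wrist recordings.

Generates a day-long triaxial recording per demo subject with known rest,
movement and nonwear segments, then runs the full reduction — ENMO,
sliding-window nonwear scoring, 1-hour pre-beep averaging — and reports
how well the nonwear detector recovers the planted segments and which
pre-beep windows were excluded.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

import emanet as en  # noqa: E402

SEED = 2021
RESULTS = ROOT / "results" / "analysis"

# one waking day, 08:00-22:00, in seconds on the recording clock
DAY = 14 * 3600.0


def demo_profile(rng):
    """Random 14-hour day: mostly rest, two activity hours, one nonwear hour."""
    slots = ["rest"] * 11 + ["activity", "activity", "nonwear"]
    rng.shuffle(slots)
    segs = {"rest": [], "activity": [], "nonwear": []}
    for i, kind in enumerate(slots):
        segs[kind].append((i * 3600.0, (i + 1) * 3600.0))
    return en.AccelProfile(
        duration=DAY,
        rest_segments=segs["rest"],
        activity_segments=segs["activity"],
        nonwear_segments=segs["nonwear"],
    )


def main():
    RESULTS.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    rows = []
    hits = misses = false_flags = wear_windows = 0
    for s in range(10):
        prof = demo_profile(rng)
        sig = en.generate_raw_accel(prof, seed=SEED + s)
        enmo = en.compute_enmo(sig)
        scores = en.score_nonwear(sig)
        for start, score in zip(scores.window_start, scores.score):
            end = start + scores.window_length
            if any(a <= start and end <= b for a, b in prof.nonwear_segments):
                hits += score > 1
                misses += score <= 1
            elif any(a <= start and end <= b for a, b, k in prof.all_segments() if k != "nonwear"):
                wear_windows += 1
                false_flags += score > 1
        beeps = [3600.0 * (h + 1) for h in range(1, 14)]  # hourly beeps from 09:00
        for act in en.summarize_prebeep(enmo, scores, beeps, subject_id=f"demo_{s:02d}"):
            rows.append(
                {
                    "subject_id": act.subject_id,
                    "beep_s": act.timestamp,
                    "mean_enmo_mg": act.mean_enmo,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "prebeep_activity.csv", index=False)
    print(f"nonwear window sensitivity: {hits / (hits + misses):.3f}")
    print(f"wear window false-flag rate: {false_flags / wear_windows:.3f}")
    print(
        f"pre-beep values: {df['mean_enmo_mg'].notna().sum()} present, "
        f"{df['mean_enmo_mg'].isna().sum()} excluded (nonwear / low coverage)"
    )
    print(f"wrote {RESULTS / 'prebeep_activity.csv'}")


if __name__ == "__main__":
    main()
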