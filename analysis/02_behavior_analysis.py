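#!/usr/bin/env python
"""Classify the behavioral session and fit the escape psychometric.

Reads scratch/session/ (run 01_simulate_session.py first), classifies every
loom trial, enumerates spontaneous escapes and slow returns, compares
against ground truth, and fits the pooled logistic psychometric on a larger
simulated cohort (10 mice x 40 trials).  Tables go to results/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from escapekit import behavior as bh
from escapekit import core_io as cio
from escapekit.kinematics import compute_kinematics
from escapekit.synth import simulate_escape_outcomes

ROOT = Path(__file__).resolve().parents[1]
SESSION = ROOT / "scratch" / "session"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    geometry = cio.ArenaGeometry()
    track, _ = cio.read_keypoint_table(SESSION / "track.csv")
    events = cio.read_events(SESSION / "events.csv")
    truth = json.loads((SESSION / "ground_truth.json").read_text())
    kin = compute_kinematics(track, geometry)

    rows = []
    for _, ev in events.of_kind("loom").iterrows():
        trial = bh.classify_evoked_escape(kin, ev, geometry)
        trial.froze = bh.detect_freezing(kin, ev["onset_s"], ev["duration_s"])
        rows.append(trial.as_dict())
    trials = pd.DataFrame(rows)
    trials.to_csv(RESULTS / "behavior_trials.csv", index=False)

    want = pd.DataFrame(truth["behavior_trials"])
    agree = float(np.mean(trials["escaped"].to_numpy() == want["escaped"].to_numpy()))
    print(f"{len(trials)} loom trials classified; escape-label agreement with ground truth: {agree:.0%}")

    spont_prob, spont, n_app = bh.detect_spontaneous_escapes(kin, events, geometry)
    returns = bh.detect_non_escape_returns(kin, events)
    print(
        f"spontaneous escapes: {len(spont)}/{n_app} approaches "
        f"(truth {len(truth['spontaneous'])}/{truth['n_approaches_unstimulated']}); "
        f"slow returns: {len(returns)} (truth {len(truth['returns'])})"
    )

    prob = bh.escape_probability(trials.assign(mouse_id="m0"), ["mouse_id", "contrast"])
    prob.to_csv(RESULTS / "behavior_escape_probability.csv", index=False)

    # psychometric on a simulated cohort at the study's trial counts
    rng = np.random.default_rng(truth["seed"] + 10)
    cohort = simulate_escape_outcomes(-2.0, 0.05, (20.0, 40.0, 60.0, 98.0), 10, 40, rng)
    fit = bh.fit_psychometric(cohort)
    cs = np.array([20.0, 40.0, 60.0, 98.0])
    fitted = fit.predict(cs)
    true_p = 1 / (1 + np.exp(-(-2.0 + 0.05 * cs)))
    psy = pd.DataFrame({"contrast_pct": cs, "fitted_p": fitted, "true_p": true_p})
    psy.to_csv(RESULTS / "behavior_psychometric.csv", index=False)
    print("psychometric fit (10 mice x 40 trials):")
    for _, r in psy.iterrows():
        print(f"  c={r.contrast_pct:3.0f}%: fitted {r.fitted_p:.3f}  true {r.true_p:.3f}")
    print(f"max |fitted - true| = {np.max(np.abs(fitted - true_p)):.3f}")


if __name__ == "__main__":
    main()
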