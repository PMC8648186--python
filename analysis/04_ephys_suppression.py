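#!/usr/bin/env python
"""Quantify loom responses and optogenetic suppression in the recording.

Builds unit responsiveness profiles (loom / sound / laser, with the 2-SD
rules), the contrast-response curve normalized to the 99% no-laser
response, the population suppression index, and the class-wise spontaneous
suppression (visual-only vs sound-only), compared against the generator's
unit labels.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from escapekit import core_io as cio
from escapekit import ephys as ep

ROOT = Path(__file__).resolve().parents[1]
SESSION = ROOT / "scratch" / "session"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    ds = cio.read_spikes(
        SESSION / "spikes.times.npy",
        SESSION / "spikes.clusters.npy",
        SESSION / "spikes.cluster_table.csv",
    )
    trials = pd.read_csv(SESSION / "headfixed_trials.csv")
    truth = json.loads((SESSION / "ground_truth.json").read_text())
    looms = trials[trials["kind"] == "loom"]
    looms99 = looms[np.isclose(looms["contrast"], 0.99) & ~looms["laser"]]["onset_s"].to_numpy()
    sounds = trials.loc[trials["kind"] == "sound", "onset_s"].to_numpy()
    blanks = trials.loc[trials["kind"] == "laser_blank", "onset_s"].to_numpy()

    profiles = []
    for u in ds.units:
        p = ep.profile_unit(u, looms99, sound_onsets=sounds, blank_laser_onsets=blanks)
        profiles.append({**{k: v for k, v in p.__dict__.items()}, "unit_class": p.unit_class})
    units = pd.DataFrame(profiles)
    units["true_class"] = truth["unit_classes"]
    units.to_csv(RESULTS / "ephys_units.csv", index=False)
    expected = {
        "visual_only": "visual_only",
        "visual_sound": "visual",
        "sound_only": "sound_only",
        "unresponsive": "non_visual",
    }
    match = float(
        np.mean([c == expected[t] for c, t in zip(units["unit_class"], units["true_class"])])
    )
    print(f"{len(units)} units profiled; class agreement with generator labels: {match:.0%}")

    curve = ep.population_loom_curve(ds.units, looms)
    pd.DataFrame(
        {"contrast": curve.contrasts, "control": curve.control, "laser": curve.laser}
    ).to_csv(RESULTS / "ephys_loom_curve.csv", index=False)
    print("normalized contrast curve (control):",
          np.array2string(curve.control, precision=2))
    print("normalized contrast curve (laser):  ",
          np.array2string(curve.laser, precision=2))

    suppression = ep.population_laser_suppression(ds.units, looms)
    by_layer = ep.population_laser_suppression_by_layer(ds.units, looms)
    print(f"population suppression at 99% contrast: {suppression:.3f}")
    for layer, s in by_layer.items():
        print(f"  {layer}: {s:.3f}")

    quiet = [(a, a + 6.0) for a in looms["onset_s"].to_numpy() - 7.0]
    eligible = ep.filter_units_for_laser_analysis(ds.units, quiet)
    spont = {
        u.unit_id: ep.unit_laser_suppression_spontaneous(u, blanks) for u in eligible
    }
    units["suppression_spontaneous"] = units["unit_id"].map(spont)
    vis = units.loc[units["unit_class"] == "visual_only", "suppression_spontaneous"].dropna()
    aud = units.loc[units["unit_class"] == "sound_only", "suppression_spontaneous"].dropna()
    if len(vis) and len(aud):
        print(
            f"spontaneous suppression: visual-only median {vis.median():.3f} "
            f"(n={len(vis)}), sound-only median {aud.median():.3f} (n={len(aud)})"
        )
    summary = {
        "population_suppression": suppression,
        "by_layer": by_layer,
        "n_units_eligible_spontaneous": len(eligible),
    }
    (RESULTS / "ephys_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
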