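#!/usr/bin/env python
"""Generate the synthetic study dataset all downstream analyses consume.

Writes a freely-moving behavioral session (keypoint track + event log +
two-channel photometry), a head-fixed recording session (stimulus schedule +
sorted spikes), and a slice I-V table, together with the generator's ground
truth, under scratch/session/ (raw data, not part of the deliverable).
Problem sizes: a 30-min behavioral session, 20 recorded units over the full
25-block loom protocol, and 12 voltage-clamped cells.
"""

import json
import sys
from pathlib import Path

import numpy as np

from escapekit import core_io as cio
from escapekit import synth

OUT = Path(__file__).resolve().parents[1] / "scratch" / "session"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    geometry = cio.ArenaGeometry()

    bp = synth.BehaviorGenParams(session_length_s=1800.0, seed=SEED)
    track, events, truth = synth.generate_behavior(bp, geometry)
    cio.write_keypoint_table(OUT / "track.csv", track)
    cio.write_events(OUT / "events.csv", events)
    print(
        f"behavior: {bp.session_length_s:.0f}-s session, {len(truth.trials)} loom trials "
        f"({int(truth.trials['escaped'].sum())} escapes), "
        f"{len(truth.spontaneous)} spontaneous escapes, {len(truth.returns)} slow returns"
    )

    pp = synth.PhotometryGenParams(seed=SEED)
    rec, clean = synth.generate_photometry(
        track, events, pp, geometry, escape_onsets=truth.escape_onsets,
        rng=np.random.default_rng(SEED + 1),
    )
    cio.write_photometry(OUT / "photometry.h5", rec)
    np.save(OUT / "photometry_clean.npy", clean)
    print(f"photometry: {len(rec.timestamps)} samples at {rec.sample_rate:.0f} Hz")

    rng = np.random.default_rng(SEED + 2)
    prot = synth.headfixed_protocol(n_blocks=25, isi_s=8.0, rng=rng)
    specs = synth.make_population(20, rng, suppression=0.3)
    ds = synth.generate_spikes(prot, synth.EphysGenParams(units=specs, seed=SEED), rng=rng)
    cio.write_spikes(OUT / "spikes", ds)
    prot.to_csv(OUT / "headfixed_trials.csv", index=False)
    print(f"ephys: {len(ds.units)} units, {len(prot)} trials "
          f"({sum(s.unit_class == 'visual_only' for s in specs)} visual-only)")

    rng_iv = np.random.default_rng(SEED + 3)
    ivs = []
    for i in range(12):
        ivs.append(
            synth.generate_iv(
                float(rng_iv.uniform(0.5, 4.0)), float(rng_iv.normal(-70.0, 2.0)),
                np.array([-90.0, -80.0, -70.0, -50.0, -40.0]), 2.0, rng_iv,
                cell_id=f"cell{i}", layer=["superficial", "intermediate", "deep"][i % 3],
                mouse_id=f"m{i // 4}",
            )
        )
    cio.write_iv_table(OUT / "iv_cells.csv", ivs)
    print("slice: 12 cells, 5 holding potentials each")

    truth_payload = {
        "seed": SEED,
        "behavior_trials": truth.trials.to_dict("records"),
        "spontaneous": truth.spontaneous.to_dict("records"),
        "returns": truth.returns.to_dict("records"),
        "n_approaches_unstimulated": truth.n_approaches_unstimulated,
        "unit_classes": [s.unit_class for s in specs],
        "unit_suppression": [s.suppression for s in specs],
    }
    (OUT / "ground_truth.json").write_text(json.dumps(truth_payload, indent=2, default=float))
    print(f"all inputs written to {OUT}")


if __name__ == "__main__":
    main()
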