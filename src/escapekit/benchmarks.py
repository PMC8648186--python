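"""End-to-end benchmark measurements on generator ground truth.

Each function runs one slice of the pipeline at a calibrated problem size
and returns the quantities a reviewer would check: classifier fidelity,
psychometric recovery, artifact-correction quality, suppression recovery,
responsiveness-rule calibration, conductance recovery, and the behaviour of
the statistics policy.  The acceptance script and the acceptance tests both
drive these functions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from escapekit import behavior as bh
from escapekit import ephys as ep
from escapekit import photometry as ph
from escapekit import slice_iv as sl
from escapekit import stats as st
from escapekit import synth
from escapekit.core_io import ArenaGeometry, SpikeUnit
from escapekit.kinematics import compute_kinematics


# ---------------------------------------------------------------------------
# behavior classifier fidelity
# ---------------------------------------------------------------------------


def behavior_classifier_fidelity(
    n_trials: int = 200, noise_sd: float = 0.0, seed: int = 0
) -> float:
    """Fraction of scripted boundary-spanning trials whose classifier label
    (evoked escape / freeze / no-escape with eligibility, spontaneous escape,
    slow return) matches the generator's ground truth."""
    scens = synth.generate_trial_battery(n_trials, noise_sd=noise_sd, seed=seed)
    agree = 0
    for sc in scens:
        kin = compute_kinematics(sc.track, sc.geometry)
        got = bh.scenario_label(kin, sc.events, sc.geometry)
        agree += got == (sc.kind, sc.eligible, sc.label)
    return agree / len(scens)


# ---------------------------------------------------------------------------
# psychometric recovery
# ---------------------------------------------------------------------------


def psychometric_recovery(
    n_seeds: int = 20,
    seed0: int = 0,
    beta0: float = -2.0,
    beta1: float = 0.05,
    contrasts_pct: tuple[float, ...] = (20.0, 40.0, 60.0, 98.0),
    n_mice: int = 10,
    n_trials: int = 40,
) -> dict:
    """Logistic-fit recovery of the generative psychometric (p(40%) = 0.5).

    Returns per-seed max absolute error of fitted vs. true escape
    probability over the generated contrasts, and the count of seeds within
    0.10 everywhere.
    """
    cs = np.asarray(contrasts_pct)
    truth = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * cs)))
    errors = []
    for k in range(n_seeds):
        rng = np.random.default_rng(seed0 + k)
        df = synth.simulate_escape_outcomes(beta0, beta1, tuple(cs), n_mice, n_trials, rng)
        fit = bh.fit_psychometric(df)
        errors.append(float(np.max(np.abs(fit.predict(cs) - truth))))
    errors = np.asarray(errors)
    return {
        "max_errors": errors,
        "n_within_0p10": int(np.sum(errors < 0.10)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# photometry correction
# ---------------------------------------------------------------------------


def _explained_variance(y: np.ndarray, x: np.ndarray) -> float:
    x = (x - x.mean()) / x.std()
    return float(np.dot(y - y.mean(), x) ** 2 / len(y) ** 2)


def photometry_correction(
    gains: tuple[float, ...] = (0.5, 1.0, 2.0), seed: int = 0
) -> dict:
    """Artifact rejection of the isosbestic regression across channel gains.

    For each shared-artifact gain pair the session is generated, processed,
    and scored by (a) the residual artifact-explained variance in the
    corrected trace relative to the uncorrected one and (b) the correlation
    of the corrected trace with the generator's clean calcium signal.
    """
    geometry = ArenaGeometry()
    params = synth.BehaviorGenParams(session_length_s=900.0, seed=seed)
    track, events, truth = synth.generate_behavior(params, geometry)
    pairs = [(g, 1.0) for g in gains] + [(1.0, g) for g in gains if g != 1.0]
    frac_max, corr_min = 0.0, 1.0
    for k, (g_ca, g_iso) in enumerate(pairs):
        pp = synth.PhotometryGenParams(
            artifact_amp=1.5, gain_ca=g_ca, gain_iso=g_iso, seed=seed + k
        )
        rec, clean = synth.generate_photometry(
            track, events, pp, geometry, escape_onsets=truth.escape_onsets,
            rng=np.random.default_rng(seed + 100 + k),
        )
        trace, _ = ph.process_recording(rec)
        before = _explained_variance(rec.f_ca - rec.f_ca.mean(), rec.f_iso)
        after = _explained_variance(trace.dff, rec.f_iso)
        frac_max = max(frac_max, after / before)
        zc = (clean - clean.mean()) / clean.std()
        corr_min = min(corr_min, float(np.corrcoef(trace.zdff, zc)[0, 1]))
    # deterministic toy: a perfectly shared signal cancels exactly
    iso = np.sin(np.linspace(0, 80, 20000))
    dff, *_ = ph.isosbestic_correct(2.0 * iso, iso)
    return {
        "artifact_variance_fraction_max": frac_max,
        "corr_with_clean_min": corr_min,
        "toy_residual_max": float(np.max(np.abs(dff))),
    }


# ---------------------------------------------------------------------------
# luminance axis
# ---------------------------------------------------------------------------


def luminance_axis() -> dict:
    from escapekit.core_io import weber_contrast

    levels = np.array([1.0, 3.0, 9.0, 27.0, 81.0])
    mapped = ph.luminance_change(levels)
    return {
        "axis_error_max": float(np.max(np.abs(mapped - np.array([-2, -1, 0, 1, 2])))),
        "weber_at_background": float(weber_contrast(9.0)),
        "weber_at_black": float(weber_contrast(0.0)),
    }


# ---------------------------------------------------------------------------
# optogenetic suppression recovery
# ---------------------------------------------------------------------------


def suppression_recovery(
    n_seeds: int = 20,
    seed0: int = 0,
    true_suppression: float = 0.30,
    n_units: int = 20,
    n_trials_per_condition: int = 25,
) -> dict:
    """Per-mouse population-suppression estimates vs. the generative value,
    plus the visual_only / sound_only class separation in the spontaneous-
    suppression index."""
    estimates = []
    for k in range(n_seeds):
        rng = np.random.default_rng(seed0 + k)
        prot = synth.headfixed_protocol(
            n_blocks=n_trials_per_condition, contrasts=(0.99,), isi_s=8.0,
            n_sound=0, n_blank_laser=0, rng=rng,
        )
        specs = [
            synth.UnitGenSpec(
                baseline_hz=float(rng.uniform(5.0, 20.0)),
                unit_class="visual_only",
                loom_gain_hz=float(rng.uniform(25.0, 45.0)),
                suppression=true_suppression,
            )
            for _ in range(n_units)
        ]
        ds = synth.generate_spikes(prot, synth.EphysGenParams(units=specs), rng=rng)
        looms = prot[prot["kind"] == "loom"]
        estimates.append(ep.population_laser_suppression(ds.units, looms))
    estimates = np.asarray(estimates)

    # class separation: mixed population scored on blank-laser trials
    rng = np.random.default_rng(seed0 + 777)
    sep_suppression = 0.36
    prot = synth.headfixed_protocol(n_blocks=25, isi_s=8.0, n_sound=25, n_blank_laser=25, rng=rng)
    specs = [
        synth.UnitGenSpec(baseline_hz=float(rng.uniform(8.0, 18.0)), unit_class="visual_only",
                          suppression=sep_suppression)
        for _ in range(10)
    ] + [
        synth.UnitGenSpec(baseline_hz=float(rng.uniform(8.0, 18.0)), unit_class="sound_only",
                          suppression=0.0)
        for _ in range(10)
    ]
    ds = synth.generate_spikes(prot, synth.EphysGenParams(units=specs), rng=rng)
    looms99 = prot[(prot["kind"] == "loom") & np.isclose(prot["contrast"], 0.99) & ~prot["laser"]][
        "onset_s"
    ].to_numpy()
    sounds = prot[prot["kind"] == "sound"]["onset_s"].to_numpy()
    blanks = prot[prot["kind"] == "laser_blank"]["onset_s"].to_numpy()
    profiles = [
        ep.profile_unit(u, looms99, sound_onsets=sounds, blank_laser_onsets=blanks)
        for u in ds.units
    ]
    wanted = ["visual_only"] * 10 + ["sound_only"] * 10
    class_accuracy = float(np.mean([p.unit_class == w for p, w in zip(profiles, wanted)]))
    vis = np.median([p.suppression_spontaneous for p in profiles[:10]])
    aud = np.median([p.suppression_spontaneous for p in profiles[10:]])
    return {
        "median_estimate": float(np.median(estimates)),
        "true_suppression": true_suppression,
        "estimates": estimates,
        "class_accuracy": class_accuracy,
        "class_median_difference": float(vis - aud),
        "class_true_difference": sep_suppression,
    }


# ---------------------------------------------------------------------------
# responsiveness rule calibration (independent brute-force oracle)
# ---------------------------------------------------------------------------


def _brute_force_loom_rule(rng: np.random.Generator, baseline_hz: float, n_trials: int) -> bool:
    """Literal, loop-based re-implementation of the 2-SD / 200-ms rule on a
    freshly simulated stationary Poisson unit, written independently of the
    pipeline's vectorized code path.

    Spikes are counted into 10-ms base bins per trial; each 50-ms causal
    window on the 20-ms evaluation grid is the sum of five consecutive base
    bins (boundary ties have probability zero for continuous spike times).
    """
    onsets = [10.0 * (i + 1) for i in range(n_trials)]
    t_stop = onsets[-1] + 5.0
    n_spikes = rng.poisson(baseline_hz * t_stop)
    spikes = sorted(rng.uniform(0.0, t_stop, n_spikes).tolist())
    base = 0.01
    span_lo, n_base = -0.53, 103  # covers (-0.53, 0.50] around each onset
    lags = [(-0.48) + 0.02 * i for i in range(50)]  # (-0.48 .. 0.50]
    avg = [0.0] * len(lags)
    import bisect

    for onset in onsets:
        lo_t, hi_t = onset + span_lo, onset + span_lo + n_base * base
        seg = spikes[bisect.bisect_right(spikes, lo_t) : bisect.bisect_right(spikes, hi_t)]
        bins = [0] * n_base
        for s in seg:
            b = int((s - onset - span_lo) / base)
            if 0 <= b < n_base:
                bins[b] += 1
        for i, lag in enumerate(lags):
            end = int(round((lag - span_lo) / base))  # window = (end-5, end]
            avg[i] += sum(bins[end - 5 : end]) / 0.05
    avg = [a / n_trials for a in avg]
    pre = [a for a, lag in zip(avg, lags) if lag <= 0]
    post = [a for a, lag in zip(avg, lags) if lag > 0]
    mu = sum(pre) / len(pre)
    sd = (sum((p - mu) ** 2 for p in pre) / len(pre)) ** 0.5
    thresh = mu + 2.0 * max(sd, 1e-6)
    run = 0
    for a in post:
        run = run + 1 if a > thresh else 0
        if run >= 10:  # 10 consecutive 20-ms bins = 200 ms
            return True
    return False


def responsiveness_rule_calibration(
    n_seeds: int = 50,
    units_per_seed: int = 16,
    baseline_hz: float = 10.0,
    n_trials: int = 25,
    seed0: int = 0,
) -> dict:
    """Empirical false-positive rate of the loom-responsiveness rule on
    stationary Poisson units: pipeline implementation vs. the brute-force
    oracle, each on its own fresh simulations."""
    fp_pipeline = 0
    fp_oracle = 0
    n = n_seeds * units_per_seed
    for k in range(n_seeds):
        rng = np.random.default_rng(seed0 + k)
        rng_o = np.random.default_rng(100_000 + seed0 + k)
        for _ in range(units_per_seed):
            onsets = 10.0 * np.arange(1, n_trials + 1)
            t_stop = onsets[-1] + 5.0
            spikes = np.sort(rng.uniform(0.0, t_stop, rng.poisson(baseline_hz * t_stop)))
            unit = SpikeUnit(0, spikes, 800.0)
            fp_pipeline += ep.classify_loom_responsive(unit, onsets)
            fp_oracle += _brute_force_loom_rule(rng_o, baseline_hz, n_trials)
    return {
        "fp_rate_pipeline": fp_pipeline / n,
        "fp_rate_oracle": fp_oracle / n,
        "n_units_each": n,
    }


# ---------------------------------------------------------------------------
# conductance recovery
# ---------------------------------------------------------------------------


def conductance_recovery(n_seeds: int = 50, seed0: int = 0) -> dict:
    """Noiseless exactness, noisy recovery (5% relative noise, 5 holding
    potentials), and full-fit / fallback equivalence."""
    potentials = np.array([-90.0, -80.0, -70.0, -50.0, -40.0])
    rng = np.random.default_rng(seed0)
    clean = synth.generate_iv(2.0, -70.0, potentials, 0.0, rng)
    fit = sl.fit_conductance(clean)
    g_exact_err = abs(fit.g_ns - 2.0)
    e_exact_err = abs(fit.e_reversal_mv + 70.0)
    fb = sl.fallback_conductance(clean, -70.0)
    fallback_gap = abs(fb.g_ns - fit.g_ns)

    g_errs, e_errs = [], []
    for k in range(n_seeds):
        r = np.random.default_rng(seed0 + 1 + k)
        iv = synth.generate_iv(2.0, -70.0, potentials, 0.05 * 40.0, r)
        f = sl.fit_conductance(iv)
        g_errs.append(abs(f.g_ns - 2.0) / 2.0)
        e_errs.append(abs(f.e_reversal_mv + 70.0))
    return {
        "g_exact_error_ns": g_exact_err,
        "e_rev_exact_error_mv": e_exact_err,
        "fallback_gap_ns": fallback_gap,
        "g_relative_error_median": float(np.median(g_errs)),
        "e_rev_error_median_mv": float(np.median(e_errs)),
    }


# ---------------------------------------------------------------------------
# statistics policy
# ---------------------------------------------------------------------------

EXPECTED_TEST_TABLE = {
    ("paired", 2, "parametric"): "paired_t",
    ("paired", 2, "nonparametric"): "wilcoxon_signed_rank",
    ("unpaired", 2, "parametric"): "independent_t",
    ("unpaired", 2, "nonparametric"): "rank_sum",
    ("repeated", 3, "parametric"): "rm_anova_tukey",
    ("repeated", 3, "nonparametric"): "kruskal_wallis_dunn",
    ("unpaired", 3, "parametric"): "anova_tukey",
    ("unpaired", 3, "nonparametric"): "kruskal_wallis_dunn",
}


def stats_policy_check(n_seeds: int = 500, n: int = 20, seed0: int = 0) -> dict:
    """The selection table, cell by cell, plus the Shapiro-Wilk gate's
    rejection rate under normality at n = 20 (nominal 5%)."""
    correct = 0
    for (kind, groups, gate), expected in EXPECTED_TEST_TABLE.items():
        design = st.ComparisonDesign(
            paired=kind == "paired", n_groups=groups, repeated=kind == "repeated"
        )
        correct += st.select_test(design, gate) == expected
    rejections = 0
    for k in range(n_seeds):
        x = np.random.default_rng(seed0 + k).normal(0.0, 1.0, n)
        rejections += sps.shapiro(x).pvalue < 0.05
    return {
        "table_cells_correct": correct,
        "table_cells_total": len(EXPECTED_TEST_TABLE),
        "shapiro_rejection_rate": rejections / n_seeds,
    }
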