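"""Normality-gated statistics policy with per-animal aggregation.

Every comparison first aggregates repeated trials to one value per animal,
then gates on a Shapiro-Wilk normality test (p < 0.05 on any group, or on
the paired differences for paired designs, selects non-parametric tests).
The test mapping is fixed:

====================  ============================  =============================
design                parametric                    non-parametric
====================  ============================  =============================
paired, 2 groups      dependent t test              Wilcoxon signed-rank
unpaired, 2 groups    independent two-sample t      Wilcoxon rank-sum
repeated, >2 groups   RM one-way ANOVA + Tukey      Kruskal-Wallis + Dunn
unpaired, >2 groups   one-way ANOVA + Tukey         Kruskal-Wallis + Dunn
====================  ============================  =============================

Display statistics match the gate: mean +/- SEM for parametric data,
median +/- IQR for non-parametric data.  All tests are two-tailed.  Test
statistics themselves are delegated to scipy/statsmodels; this module owns
only gating, selection and aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonDesign:
    paired: bool
    n_groups: int
    repeated: bool = False

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ValueError("need at least two groups")
        if self.paired and self.n_groups != 2:
            raise ValueError("paired designs are two-group; use repeated for more")


def normality_gate(
    samples: list[np.ndarray], design: ComparisonDesign, alpha: float = SHAPIRO_ALPHA
) -> tuple[str, list[str]]:
    """Shapiro-Wilk gate: 'parametric' unless any tested set rejects
    normality.  Paired designs test the difference vector; unpaired and
    repeated multi-group designs test each group separately.  Groups with
    n < 3 force the non-parametric branch (flagged).
    """
    flags: list[str] = []
    if design.paired:
        a, b = (np.asarray(s, dtype=float) for s in samples)
        if len(a) != len(b):
            raise ValueError("paired design needs equal group sizes")
        tested = [a - b]
    else:
        tested = [np.asarray(s, dtype=float) for s in samples]
    for vec in tested:
        if len(vec) < 3:
            flags.append("n_below_3_nonparametric_fallback")
            return "nonparametric", flags
        if np.ptp(vec) == 0:
            flags.append("constant_sample_nonparametric_fallback")
            return "nonparametric", flags
        if sps.shapiro(vec).pvalue < alpha:
            return "nonparametric", flags
    return "parametric", flags


def select_test(design: ComparisonDesign, gate: str) -> str:
    """Map (design, gate) to the test identifier.  Pure function."""
    if gate not in ("parametric", "nonparametric"):
        raise ValueError("gate must be 'parametric' or 'nonparametric'")
    par = gate == "parametric"
    if design.paired:
        return "paired_t" if par else "wilcoxon_signed_rank"
    if design.n_groups == 2 and not design.repeated:
        return "independent_t" if par else "rank_sum"
    if design.repeated:
        return "rm_anova_tukey" if par else "kruskal_wallis_dunn"
    # >2 independent groups: one-way ANOVA + Tukey by symmetry with the
    # repeated-measures branch
    return "anova_tukey" if par else "kruskal_wallis_dunn"


def summarize(sample: np.ndarray, gate: str) -> tuple[float, float]:
    """(center, dispersion) matched to the gate: (mean, SEM) for parametric,
    (median, IQR with linear-interpolation quantiles) otherwise."""
    x = np.asarray(sample, dtype=float)
    if len(x) == 0:
        raise ValueError("empty sample")
    if gate == "parametric":
        sem = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
        return float(np.mean(x)), sem
    if len(x) == 1:
        return float(x[0]), 0.0
    q1, q3 = np.percentile(x, [25, 75])  # type-7 linear interpolation
    return float(np.median(x)), float(q3 - q1)


def per_animal_aggregate(
    trials: pd.DataFrame, value_col: str, animal_col: str = "mouse_id"
) -> pd.Series:
    """Mean across repeated trials within each animal; animals are the units
    of all downstream tests."""
    if animal_col not in trials.columns:
        raise KeyError(f"missing animal key {animal_col!r}")
    return trials.groupby(animal_col)[value_col].mean()


def run_comparison(
    samples: list[np.ndarray], design: ComparisonDesign
) -> dict:
    """Gate, select and execute the comparison; returns the gate, test id,
    statistic, p-value and per-group display summaries."""
    gate, flags = normality_gate(samples, design)
    test = select_test(design, gate)
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if test == "paired_t":
        stat, p = sps.ttest_rel(*arrays)
    elif test == "wilcoxon_signed_rank":
        stat, p = sps.wilcoxon(*arrays)
    elif test == "independent_t":
        stat, p = sps.ttest_ind(*arrays)
    elif test == "rank_sum":
        stat, p = sps.ranksums(*arrays)
    elif test == "rm_anova_tukey":
        from statsmodels.stats.anova import AnovaRM

        n = len(arrays[0])
        if any(len(a) != n for a in arrays):
            raise ValueError("repeated-measures design needs equal group sizes")
        long = pd.DataFrame(
            {
                "subject": np.tile(np.arange(n), len(arrays)),
                "condition": np.repeat(np.arange(len(arrays)), n),
                "value": np.concatenate(arrays),
            }
        )
        res = AnovaRM(long, "value", "subject", within=["condition"]).fit()
        stat = res.anova_table["F Value"].iloc[0]
        p = res.anova_table["Pr > F"].iloc[0]
    elif test == "anova_tukey":
        stat, p = sps.f_oneway(*arrays)
    elif test == "kruskal_wallis_dunn":
        stat, p = sps.kruskal(*arrays)
    else:  # pragma: no cover - mapping is exhaustive
        raise ValueError(f"unsupported test {test}")
    return {
        "gate": gate,
        "test": test,
        "statistic": float(stat),
        "p_value": float(p),
        "summaries": [summarize(a, gate) for a in arrays],
        "flags": flags,
    }
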