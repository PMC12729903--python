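"""Post-clustering statistical validation of recovery groups.

Given cluster labels, the module extracts the standard discriminative
kinematics per patient-week — peak hip extension (cycle minimum of the
flexion-positive hip angle), peak knee flexion in swing, peak ankle
dorsiflexion in terminal stance — and week-specific RMSE of each joint
against a normative reference trajectory, split by stance and swing phase
(stance is the first ~60% of the cycle).  Group differences in temporal
evolution are then tested with a two-way mixed ANOVA (group
between-subject, week within-subject), the interaction term being the
quantity of interest.  A noncentral-t power solver reproduces the a-priori
sample-size computation for the study design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .layout import ChannelLayout, CohortTensor

ANALYSIS_WEEKS = (2, 3, 4, 6, 8, 10, 12)  # final follow-up excluded by default


@dataclass(frozen=True)
class PhaseWindows:
    stance: slice
    swing: slice
    terminal_stance: slice


def phase_windows(points_per_cycle: int = 100) -> PhaseWindows:
    """Index windows: stance [0%, 60%), swing [60%, 100%), terminal stance [30%, 60%)."""
    if points_per_cycle < 10:
        raise ValueError("points_per_cycle must be >= 10")
    p = points_per_cycle
    s60 = int(round(0.6 * p))
    s30 = int(round(0.3 * p))
    return PhaseWindows(slice(0, s60), slice(s60, p), slice(s30, s60))


def extract_peaks(week_vector: np.ndarray, layout: ChannelLayout) -> dict[str, float]:
    """Peak kinematic features of one patient-week's 600-vector.

    Hip peak extension is the full-cycle minimum of the flexion-positive
    hip angle (extension is negative in this convention).
    """
    win = phase_windows(layout.points_per_cycle)
    hip = week_vector[layout.channel_slice("hip_angle")]
    knee = week_vector[layout.channel_slice("knee_angle")]
    ankle = week_vector[layout.channel_slice("ankle_angle")]
    return {
        "peak_hip_extension": float(hip.min()),
        "peak_knee_flexion_swing": float(knee[win.swing].max()),
        "peak_ankle_dorsiflexion_terminal_stance": float(ankle[win.terminal_stance].max()),
    }


def week_rmse(trajectory: np.ndarray, reference: np.ndarray) -> float:
    """Root mean squared deviation between two equal-length windows."""
    trajectory = np.asarray(trajectory, float)
    reference = np.asarray(reference, float)
    if trajectory.shape != reference.shape:
        raise ValueError("trajectory and reference lengths must agree")
    return float(np.sqrt(((trajectory - reference) ** 2).mean()))


def feature_table(
    cohort: CohortTensor,
    labels: np.ndarray,
    reference: np.ndarray | None = None,
    weeks: tuple[int, ...] = ANALYSIS_WEEKS,
    real_only: bool = True,
) -> pd.DataFrame:
    """Long-format kinematic feature table for statistical analysis.

    One row per (sample, week, feature).  ``reference`` is the normative
    600-vector used for the phase-split RMSE features; when omitted, RMSE
    features are skipped.  ``real_only`` restricts to provenance == real
    (clustered synthetic replicates are excluded from inference by
    default).
    """
    lay = cohort.layout
    win = phase_windows(lay.points_per_cycle)
    week_idx = [cohort.weeks.index(w) for w in weeks if w in cohort.weeks]
    rows = []
    prov = cohort.provenance or ["real"] * cohort.n_patients
    for i in range(cohort.n_patients):
        if real_only and prov[i] != "real":
            continue
        group = int(labels[i])
        for j in week_idx:
            if cohort.mask[i, j] != 1:
                continue
            vec = cohort.values[i, j]
            feats = extract_peaks(vec, lay)
            if reference is not None:
                for joint in ("hip", "knee", "ankle"):
                    sl = lay.channel_slice(f"{joint}_angle")
                    y, ref = vec[sl], reference[sl]
                    feats[f"rmse_{joint}_stance"] = week_rmse(y[win.stance], ref[win.stance])
                    feats[f"rmse_{joint}_swing"] = week_rmse(y[win.swing], ref[win.swing])
            for name, value in feats.items():
                rows.append(
                    {
                        "subject": cohort.patient_ids[i],
                        "group": group,
                        "week": cohort.weeks[j],
                        "feature": name,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class MixedAnovaResult:
    feature: str
    F_group: float
    p_group: float
    df_group: tuple[float, float]
    F_week: float
    p_week: float
    df_week: tuple[float, float]
    F_interaction: float
    p_interaction: float
    df_interaction: tuple[float, float]


def mixed_anova(table: pd.DataFrame, feature: str) -> MixedAnovaResult:
    """Two-way mixed ANOVA: group between-subject, week within-subject.

    Requires every subject in exactly one group with the same complete set
    of weeks (run after imputation).  Unbalanced group sizes are handled.
    """
    df = table[table["feature"] == feature] if "feature" in table else table
    if df.empty:
        raise ValueError(f"no rows for feature {feature!r}")
    groups_per_subject = df.groupby("subject")["group"].nunique()
    if (groups_per_subject > 1).any():
        bad = groups_per_subject[groups_per_subject > 1].index[0]
        raise ValueError(f"subject {bad} appears in more than one group")
    if df["group"].nunique() < 2:
        raise ValueError("need at least two groups")
    weeks_per_subject = df.groupby("subject")["week"].nunique()
    if (weeks_per_subject < 2).any():
        raise ValueError("every subject needs at least two weeks")
    if weeks_per_subject.nunique() > 1:
        raise ValueError("weeks must be balanced across subjects (impute first)")

    import pingouin as pg

    aov = pg.mixed_anova(
        data=df, dv="value", within="week", subject="subject", between="group",
        correction=False,
    )
    aov = aov.set_index("Source")

    def row(name):
        r = aov.loc[name]
        return float(r["F"]), float(r["p_unc"]), (float(r["DF1"]), float(r["DF2"]))

    fg, pg_, dg = row("group")
    fw, pw, dw = row("week")
    fi, pi, di = row("Interaction")
    return MixedAnovaResult(feature, fg, pg_, dg, fw, pw, dw, fi, pi, di)


def anova_table(features: pd.DataFrame) -> pd.DataFrame:
    """Mixed-ANOVA interaction summary for every feature in a table."""
    rows = []
    for feat in features["feature"].unique():
        res = mixed_anova(features, feat)
        rows.append(
            {
                "feature": feat,
                "F_interaction": res.F_interaction,
                "p_interaction": res.p_interaction,
                "F_group": res.F_group,
                "p_group": res.p_group,
                "F_week": res.F_week,
                "p_week": res.p_week,
            }
        )
    return pd.DataFrame(rows)


def power_of_n(n: int, d: float, alpha: float, design: str) -> float:
    """Two-tailed t-test power under the noncentral-t distribution."""
    if design == "paired":
        df = n - 1
        nc = d * np.sqrt(n)
    elif design == "independent":
        df = 2 * n - 2
        nc = d * np.sqrt(n / 2.0)
    else:
        raise ValueError("design must be 'paired' or 'independent'")
    if df < 1:
        return 0.0
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def required_sample_size(
    mean_diff: float,
    sd: float,
    alpha: float = 0.05,
    power: float = 0.95,
    design: str = "paired",
    n_max: int = 100000,
) -> int:
    """Smallest n with two-tailed t-test power >= target at d = mean_diff/sd.

    ``paired`` treats n as the number of subjects in a one-sample/paired
    design; ``independent`` returns the per-group n for a two-sample test.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if mean_diff == 0:
        raise ValueError("zero effect size: required n is unbounded")
    d = abs(mean_diff) / sd
    for n in range(2, n_max + 1):
        if power_of_n(n, d, alpha, design) >= power:
            return n
    raise RuntimeError("n_max exceeded without reaching the target power")


__all__ = [
    "ANALYSIS_WEEKS",
    "PhaseWindows",
    "phase_windows",
    "extract_peaks",
    "week_rmse",
    "feature_table",
    "MixedAnovaResult",
    "mixed_anova",
    "anova_table",
    "power_of_n",
    "required_sample_size",
]
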