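"""Behavioral statistics: 2x2 within-subject ANOVA and paired t-tests.

Mean correct RTs and error rates are analyzed in a repeated-measures
design with within-subject factors hand (left/right) and conflict
(conflict/non-conflict). With one degree of freedom per effect, each
main effect and the interaction reduce to a paired t-test on the
corresponding per-subject contrast score, with F = t^2 and partial eta
squared SS_effect / (SS_effect + SS_error) = t^2 / (t^2 + df). No
sphericity correction is applied (vacuous for 1-df effects).

Post-hoc paired t-tests are reported uncorrected, with a Bonferroni
column available for conservative reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "aggregate_behavior",
    "rm_anova_2x2",
    "paired_t",
]

_CELLS = [("left", False), ("left", True), ("right", False), ("right", True)]


@dataclass(frozen=True)
class AnovaResult:
    """One effect of the 2x2 repeated-measures ANOVA."""

    effect: str  # hand | conflict | interaction
    F: float
    df: tuple[int, int]
    p: float
    partial_eta_sq: float


def aggregate_behavior(trials: pd.DataFrame) -> pd.DataFrame:
    """Trial table -> one row per subject x hand x conflict cell.

    Expects columns subject, hand, conflict, rt_ms, correct. Mean RT is
    computed over correct trials only; the error rate over all trials.
    """
    grouped = trials.groupby(["subject", "hand", "conflict"])
    cells = grouped.apply(
        lambda g: pd.Series(
            {
                "mean_rt_ms": g.loc[g["correct"], "rt_ms"].mean(),
                "error_rate": 1.0 - g["correct"].mean(),
            }
        ),
        include_groups=False,
    ).reset_index()
    return cells


def _cell_matrix(table: pd.DataFrame, value_col: str) -> np.ndarray:
    """Subjects x 4 matrix in the fixed cell order; errors if incomplete."""
    subjects = sorted(table["subject"].unique())
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects")
    out = np.empty((len(subjects), 4))
    for i, subj in enumerate(subjects):
        sub = table[table["subject"] == subj]
        for j, (hand, conflict) in enumerate(_CELLS):
            sel = sub[(sub["hand"] == hand) & (sub["conflict"] == conflict)]
            if len(sel) != 1:
                raise ValueError(
                    f"subject {subj!r}: expected exactly one "
                    f"({hand}, conflict={conflict}) cell, got {len(sel)}"
                )
            out[i, j] = sel[value_col].iloc[0]
    return out


def rm_anova_2x2(table: pd.DataFrame, outcome: str = "rt") -> list[AnovaResult]:
    """Main effects of hand and conflict and their interaction.

    ``table`` holds one row per subject x cell with columns subject,
    hand, conflict and mean_rt_ms / error_rate; ``outcome`` selects
    which is analyzed.
    """
    col = {"rt": "mean_rt_ms", "error": "error_rate"}.get(outcome)
    if col is None:
        raise ValueError("outcome must be 'rt' or 'error'")
    y = _cell_matrix(table, col)  # columns: L-NC, L-C, R-NC, R-C
    n = y.shape[0]
    contrasts = {
        "hand": (y[:, 0] + y[:, 1] - y[:, 2] - y[:, 3]) / 2.0,
        "conflict": (-y[:, 0] + y[:, 1] - y[:, 2] + y[:, 3]) / 2.0,
        "interaction": (y[:, 0] - y[:, 1] - y[:, 2] + y[:, 3]) / 2.0,
    }
    results = []
    for effect, score in contrasts.items():
        t, df, p, _ = paired_t(score, np.zeros(n))
        f = t**2
        results.append(
            AnovaResult(
                effect=effect,
                F=float(f),
                df=(1, n - 1),
                p=float(p),
                partial_eta_sq=float(f / (f + (n - 1))) if np.isfinite(f) else 1.0,
            )
        )
    return results


def paired_t(
    a: np.ndarray, b: np.ndarray
) -> tuple[float, int, float, float]:
    """Classical paired t-test; returns (t, df, two-sided p, mean diff).

    Zero variance of the differences with a nonzero mean yields an
    infinite t (p = 0); zero variance with zero mean yields t = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of >= 2 pairs")
    d = a - b
    n = len(d)
    mean = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 1.0, 0.0
        return float(np.sign(mean) * np.inf), df, 0.0, float(mean)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p), float(mean)


def posthoc_tests(table: pd.DataFrame, outcome: str = "rt") -> pd.DataFrame:
    """Pairwise Simon-effect and hand-difference t-tests on cell means."""
    col = {"rt": "mean_rt_ms", "error": "error_rate"}[outcome]
    y = _cell_matrix(table, col)
    comparisons = {
        "simon_left_hand": (y[:, 1], y[:, 0]),
        "simon_right_hand": (y[:, 3], y[:, 2]),
        "hand_nonconflict": (y[:, 0], y[:, 2]),
        "hand_conflict": (y[:, 1], y[:, 3]),
    }
    rows = []
    for name, (a, b) in comparisons.items():
        t, df, p, diff = paired_t(a, b)
        rows.append({"comparison": name, "t": t, "df": df, "p": p,
                     "mean_diff": diff,
                     "p_bonferroni": min(1.0, p * len(comparisons))})
    return pd.DataFrame(rows)
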