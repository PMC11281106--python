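"""Aggregation to analysis cells and the mixed ANOVA with effect sizes.

Window-level feature values are averaged to one value per participant, day
and period (AM/PM; lunch windows excluded), yielding a 2 (group: pain-free
vs chronic spinal pain) x 6 (week: day 1/3/5 x AM/PM) mixed design. The
ANOVA decomposes sums of squares in the standard mixed-design way, tests
sphericity of the within factor with Mauchly's W, applies the
Greenhouse-Geisser df correction when sphericity is rejected at 0.05, and
reports partial eta squared

    np^2 = SS_effect / (SS_effect + SS_error-for-that-effect)

categorized as small (< 0.06), medium (0.06-0.14) or large (> 0.14).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class UnbalancedDesignError(ValueError):
    """Incomplete within-subject grid after listwise deletion."""


@dataclass(frozen=True)
class EffectResult:
    effect: str  # 'group', 'week', 'week_x_group'
    ss: float
    ss_error: float
    df1: float
    df2: float
    F: float
    p: float
    np2: float
    gg_applied: bool = False


@dataclass(frozen=True)
class MixedAnovaTable:
    feature: str
    direction: str
    effects: dict[str, EffectResult]
    epsilon_gg: float
    mauchly_w: float
    mauchly_p: float
    ss_total: float
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for eff in self.effects.values():
            rows.append(
                {
                    "feature": self.feature,
                    "direction": self.direction,
                    "effect": eff.effect,
                    "F": eff.F,
                    "df1": eff.df1,
                    "df2": eff.df2,
                    "p": eff.p,
                    "np2": eff.np2,
                    "category": effect_size_category(eff.np2) if np.isfinite(eff.np2) else "",
                }
            )
        return pd.DataFrame(rows)


def aggregate_cells(window_rows: pd.DataFrame) -> pd.DataFrame:
    """Average window-level features into participant x day x period cells.

    Expects tidy rows with columns participant, group, day, period, window,
    direction, feature, value. Lunch windows are excluded; a participant-day
    with no AM or no PM windows is flagged (listwise handling is left to the
    ANOVA stage).
    """
    df = window_rows[window_rows["period"].isin(["AM", "PM"])]
    if df.empty:
        warnings.warn("no non-lunch windows to aggregate", RuntimeWarning, stacklevel=2)
        return df.assign(value=[])
    cells = (
        df.groupby(
            ["participant", "group", "day", "period", "direction", "feature"],
            as_index=False,
            observed=True,
        )["value"]
        .mean()
    )
    return cells


def shapiro_wilk_screen(cells: pd.DataFrame) -> pd.DataFrame:
    """Shapiro-Wilk normality screen per feature x direction x group.

    Advisory only: no automatic nonparametric fallback. Constant samples are
    skipped and flagged.
    """
    rows = []
    for (feature, direction, group), sub in cells.groupby(
        ["feature", "direction", "group"], observed=True
    ):
        vals = sub["value"].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 3:
            rows.append(
                dict(feature=feature, direction=direction, group=group,
                     W=np.nan, p=np.nan, skipped=True, reason="n < 3")
            )
            continue
        if np.ptp(vals) == 0:
            rows.append(
                dict(feature=feature, direction=direction, group=group,
                     W=np.nan, p=np.nan, skipped=True, reason="constant")
            )
            continue
        w, p = stats.shapiro(vals)
        rows.append(
            dict(feature=feature, direction=direction, group=group,
                 W=float(w), p=float(p), skipped=False, reason="")
        )
    return pd.DataFrame(rows)


def _pivot_design(
    cells: pd.DataFrame, feature: str, direction: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Return (Y matrix subjects x K, group labels, within-level names)."""
    sub = cells[(cells["feature"] == feature) & (cells["direction"] == direction)].copy()
    if sub.empty:
        raise ValueError(f"no cells for feature={feature!r}, direction={direction!r}")
    sub["week"] = sub["day"].astype(str) + "_" + sub["period"].astype(str)
    levels = sorted(sub["week"].unique(), key=lambda s: (int(s.split("_")[0]), s.split("_")[1]))
    wide = sub.pivot_table(index=["participant", "group"], columns="week",
                           values="value", aggfunc="mean")
    wide = wide.reindex(columns=levels)
    complete = wide.dropna()
    dropped = sorted(set(wide.index.get_level_values(0)) - set(complete.index.get_level_values(0)))
    if dropped:
        raise UnbalancedDesignError(
            f"incomplete within-subject grid; dropped participants: {dropped}"
        )
    groups = np.asarray([g for _, g in complete.index])
    return complete.to_numpy(float), groups, levels


def greenhouse_geisser_epsilon(Y: np.ndarray, groups: np.ndarray) -> float:
    """GG epsilon from the pooled within-group covariance of the K levels."""
    S = _pooled_covariance(Y, groups)
    k = S.shape[0]
    # double-center the covariance matrix
    row = S.mean(axis=0, keepdims=True)
    col = S.mean(axis=1, keepdims=True)
    Sc = S - row - col + S.mean()
    num = np.trace(Sc) ** 2
    den = (k - 1) * np.sum(Sc**2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def _pooled_covariance(Y: np.ndarray, groups: np.ndarray) -> np.ndarray:
    k = Y.shape[1]
    S = np.zeros((k, k))
    dof = 0
    for g in np.unique(groups):
        Yg = Y[groups == g]
        if Yg.shape[0] < 2:
            continue
        S += np.cov(Yg.T, ddof=1) * (Yg.shape[0] - 1)
        dof += Yg.shape[0] - 1
    return S / max(dof, 1)


def mauchly_test(Y: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test on the orthonormal contrasts of the levels.

    Returns (W, p) using the chi-square approximation.
    """
    S = _pooled_covariance(Y, groups)
    k = S.shape[0]
    n = Y.shape[0] - np.unique(groups).size  # pooled error dof
    # orthonormal contrast basis (any full-rank set orthogonal to the mean)
    T = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]
    St = T.T @ S @ T
    eig = np.linalg.eigvalsh(St)
    eig = np.clip(eig, 1e-300, None)
    d = k - 1
    w = float(np.exp(np.sum(np.log(eig)) - d * np.log(np.mean(eig))))
    f = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * n)
    chi2 = -n * f * np.log(max(w, 1e-300))
    dof = d * (d + 1) // 2 - 1
    p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else 1.0
    return w, p


def mixed_anova(
    cells: pd.DataFrame,
    feature: str,
    direction: str,
    sphericity_correction: str = "auto",
) -> MixedAnovaTable:
    """Two-way mixed ANOVA: between factor group, within factor week.

    ``sphericity_correction``: 'auto' applies Greenhouse-Geisser dfs to the
    within effects when Mauchly's test rejects at 0.05; 'always' / 'never'
    force the respective behavior. Requires a complete balanced within grid
    per participant and at least 2 participants per group.
    """
    Y, groups, levels = _pivot_design(cells, feature, direction)
    uniq = np.unique(groups)
    if uniq.size < 2 or min((groups == g).sum() for g in uniq) < 2:
        raise ValueError("need at least 2 participants in each of 2+ groups")
    n, k = Y.shape
    grand = Y.mean()
    ss_total = float(np.sum((Y - grand) ** 2))

    if ss_total < 1e-300:
        eff = {
            name: EffectResult(name, 0.0, 0.0, np.nan, np.nan, np.nan, np.nan, 0.0)
            for name in ("group", "week", "week_x_group")
        }
        return MixedAnovaTable(feature, direction, eff, 1.0, 1.0, 1.0, 0.0, degenerate=True)

    subj_means = Y.mean(axis=1)
    ss_between_subj = k * float(np.sum((subj_means - grand) ** 2))
    ss_group = 0.0
    for g in uniq:
        m = groups == g
        ss_group += m.sum() * k * (subj_means[m].mean() - grand) ** 2
    ss_subj_within = ss_between_subj - ss_group

    time_means = Y.mean(axis=0)
    ss_week = n * float(np.sum((time_means - grand) ** 2))
    ss_inter = 0.0
    for g in uniq:
        m = groups == g
        cell = Y[m].mean(axis=0)
        ss_inter += m.sum() * float(
            np.sum((cell - subj_means[m].mean() - time_means + grand) ** 2)
        )
    ss_within = float(np.sum((Y - subj_means[:, None]) ** 2))
    ss_err_within = ss_within - ss_week - ss_inter

    g_count = uniq.size
    df_group, df_err_b = g_count - 1, n - g_count
    df_week, df_err_w = k - 1, (n - g_count) * (k - 1)
    df_inter = (g_count - 1) * (k - 1)

    w, p_sph = mauchly_test(Y, groups)
    eps = greenhouse_geisser_epsilon(Y, groups)
    if sphericity_correction == "always":
        apply_gg = True
    elif sphericity_correction == "never":
        apply_gg = False
    else:
        apply_gg = p_sph < 0.05

    def effect(name, ss, ss_err, df1, df2, corrected):
        e = eps if corrected else 1.0
        ms, ms_err = ss / df1, ss_err / df2
        F = ms / ms_err if ms_err > 0 else np.inf
        p = float(stats.f.sf(F, df1 * e, df2 * e))
        np2 = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
        return EffectResult(name, ss, ss_err, df1 * e, df2 * e, float(F), p,
                            float(np2), gg_applied=corrected)

    effects = {
        "group": effect("group", ss_group, ss_subj_within, df_group, df_err_b, False),
        "week": effect("week", ss_week, ss_err_within, df_week, df_err_w, apply_gg),
        "week_x_group": effect(
            "week_x_group", ss_inter, ss_err_within, df_inter, df_err_w, apply_gg
        ),
    }
    return MixedAnovaTable(
        feature=feature,
        direction=direction,
        effects=effects,
        epsilon_gg=eps,
        mauchly_w=w,
        mauchly_p=p_sph,
        ss_total=ss_total,
    )


def effect_size_category(np2: float) -> str:
    """Partial-eta-squared category: small < 0.06 <= medium <= 0.14 < large."""
    if not 0.0 <= np2 <= 1.0:
        raise ValueError(f"np2 must be in [0, 1], got {np2}")
    if np2 < 0.06:
        return "small"
    if np2 <= 0.14:
        return "medium"
    return "large"


def anova_report(
    cells: pd.DataFrame, sphericity_correction: str = "auto"
) -> pd.DataFrame:
    """Run the mixed ANOVA for every feature x direction and stack results."""
    frames = []
    for (feature, direction), _ in cells.groupby(["feature", "direction"], observed=True):
        try:
            tab = mixed_anova(cells, feature, direction, sphericity_correction)
        except (UnbalancedDesignError, ValueError):
            continue
        frames.append(tab.to_frame())
    if not frames:
        return pd.DataFrame(
            columns=["feature", "direction", "effect", "F", "df1", "df2", "p", "np2", "category"]
        )
    return pd.concat(frames, ignore_index=True)
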