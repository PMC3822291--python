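"""Test-retest consistency battery.

Genuine grapheme-colour synesthetes choose nearly the same colour for a
grapheme across sessions separated by weeks, while non-synesthetes asked
to fake the task drift toward the chance level of the palette. The
battery computes, per participant and script, the mean L*a*b* distance
between the session-1 and session-2 colour choices over all graphemes,
summarises each group (mean, SE, range), and compares synesthetes with
controls by Welch's unequal-variance two-tailed t-test with Bonferroni
correction across scripts.

Two degrees-of-freedom conventions are reported for the Welch test: the
Welch-Satterthwaite approximation, and the conservative min(n_A, n_B) - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .colorimetry import Palette, palette_chance_statistics

__all__ = [
    "RESPONSE_COLUMNS",
    "validate_responses",
    "retest_distances",
    "group_summary",
    "welch_t",
    "bonferroni",
    "WelchResult",
    "run_consistency_analysis",
]

RESPONSE_COLUMNS = ("participant", "group", "session", "script", "symbol", "color_name")


class CompletenessError(ValueError):
    """A participant is missing (session, grapheme) cells; message names gaps."""


def validate_responses(responses: pd.DataFrame, palette: Palette) -> None:
    """Schema checks shared by every consumer of a response table."""
    missing = set(RESPONSE_COLUMNS) - set(responses.columns)
    if missing:
        raise ValueError(f"response table lacks columns: {sorted(missing)}")
    bad_groups = set(responses["group"]) - {"synesthete", "control"}
    if bad_groups:
        raise ValueError(f"unknown participant groups: {sorted(bad_groups)}")
    bad_sessions = set(responses["session"]) - {1, 2}
    if bad_sessions:
        raise ValueError(f"sessions must be 1 or 2, got: {sorted(bad_sessions)}")
    unknown = sorted(set(responses["color_name"]) - set(palette.names))
    if unknown:
        raise ValueError(f"colour names not in palette: {unknown[:10]}")
    dup = responses.duplicated(subset=["participant", "session", "script", "symbol"])
    if dup.any():
        rows = responses.loc[dup, ["participant", "session", "symbol"]]
        raise ValueError(f"duplicated response cells:\n{rows.head(10)}")


def retest_distances(
    responses: pd.DataFrame,
    palette: Palette,
    script: str,
    exclude_no_color: bool = False,
) -> pd.Series:
    """Per-participant mean session-1 vs session-2 colour distance.

    For every participant with responses in ``script``, the L*a*b* distance
    between the colours chosen for each grapheme in the two sessions is
    averaged over graphemes. With ``exclude_no_color`` graphemes whose
    chosen colour is ``black`` in either session are dropped from the
    average (participants reporting "no synesthetic colour" were told to
    choose black); the number dropped is recorded in ``.attrs["n_excluded"]``.
    """
    validate_responses(responses, palette)
    sub = responses[responses["script"] == script]
    if sub.empty:
        raise ValueError(f"no responses for script {script!r}")
    wide = sub.pivot_table(
        index=["participant", "symbol"],
        columns="session",
        values="color_name",
        aggfunc="first",
    )
    for session in (1, 2):
        if session not in wide.columns:
            raise CompletenessError(
                f"no session-{session} responses at all for {script!r}"
            )
    gaps = wide[wide.isna().any(axis=1)]
    if not gaps.empty:
        raise CompletenessError(
            f"missing session responses for {script}: "
            f"{[tuple(i) for i in gaps.index[:10]]}"
        )
    symbols_per = sub.groupby(["participant", "session"])["symbol"].nunique()
    if symbols_per.nunique() != 1:
        raise CompletenessError(
            f"unequal grapheme coverage across participants/sessions for {script}"
        )
    n_excluded = 0
    if exclude_no_color:
        is_black = (wide == "black").any(axis=1)
        n_excluded = int(is_black.sum())
        wide = wide[~is_black]
    idx1 = np.array([palette.index_of(c) for c in wide[1]])
    idx2 = np.array([palette.index_of(c) for c in wide[2]])
    d = np.linalg.norm(palette.lab[idx1] - palette.lab[idx2], axis=1)
    out = (
        pd.Series(d, index=wide.index, name="retest_distance")
        .groupby(level="participant")
        .mean()
    )
    out.attrs["n_excluded"] = n_excluded
    return out


def group_summary(values: pd.Series | np.ndarray) -> dict:
    """Mean, standard error (n-1 SD), and observed range of a group."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty group")
    if v.size == 1:
        warnings.warn("single participant: SE undefined", stacklevel=2)
        se = None
    else:
        se = float(v.std(ddof=1) / np.sqrt(v.size))
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "se": se,
        "min": float(v.min()),
        "max": float(v.max()),
    }


@dataclass
class WelchResult:
    t: float
    df_welch: float
    df_min: int
    p_two_tailed: float          # at Welch-Satterthwaite df
    p_two_tailed_min_df: float   # at min(n_A, n_B) - 1 df
    p_bonferroni: float | None = None


def welch_t(group_a, group_b) -> WelchResult:
    """Welch's unequal-variance two-tailed t-test.

    t = (mean_A - mean_B) / sqrt(s_A^2/n_A + s_B^2/n_B). Degrees of freedom
    are reported both by the Welch-Satterthwaite approximation and by the
    conservative min(n) - 1 convention; two-tailed p-values accompany each.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df_w = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    df_min = min(a.size, b.size) - 1
    p_w = 2.0 * stats.t.sf(abs(t), df_w)
    p_min = 2.0 * stats.t.sf(abs(t), df_min)
    return WelchResult(float(t), float(df_w), int(df_min), float(p_w), float(p_min))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: min(1, p * m) elementwise.

    ``m`` defaults to the number of p-values supplied (one per script).
    """
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return np.minimum(1.0, p * m)


def run_consistency_analysis(
    responses: pd.DataFrame,
    palette: Palette,
    scripts: tuple[str, ...] = ("hiragana", "latin"),
    exclude_no_color: bool = False,
    df_convention: str = "min",
) -> dict:
    """Full genuineness battery over one or more scripts.

    Returns a report dict with, per script: per-group summaries of the
    test-retest distances, the palette chance level, and the Welch test of
    synesthetes vs controls. Bonferroni correction uses the number of
    scripts as the number of tests. ``df_convention`` selects which
    uncorrected p feeds the correction ("min" or "welch").
    """
    validate_responses(responses, palette)
    chance_mean, chance_sd = palette_chance_statistics(palette)
    report: dict = {
        "chance": {"mean": chance_mean, "sd": chance_sd},
        "scripts": {},
    }
    raw_ps = []
    for script in scripts:
        per = retest_distances(
            responses, palette, script, exclude_no_color=exclude_no_color
        )
        groups = responses.drop_duplicates("participant").set_index("participant")[
            "group"
        ]
        syn = per[groups.reindex(per.index) == "synesthete"]
        ctl = per[groups.reindex(per.index) == "control"]
        entry: dict = {
            "per_participant": per.to_dict(),
            "n_excluded_no_color": per.attrs.get("n_excluded", 0),
            "synesthetes": group_summary(syn) if len(syn) else None,
            "controls": group_summary(ctl) if len(ctl) else None,
        }
        if len(syn) >= 2 and len(ctl) >= 2:
            res = welch_t(syn, ctl)
            entry["welch"] = res
            raw_ps.append(
                res.p_two_tailed_min_df if df_convention == "min" else res.p_two_tailed
            )
        else:
            raise ValueError(
                f"cannot compare groups for {script!r}: need >= 2 synesthetes "
                f"and >= 2 controls"
            )
        report["scripts"][script] = entry
    corrected = bonferroni(raw_ps, m=len(scripts))
    for script, p_corr in zip(scripts, corrected):
        report["scripts"][script]["welch"].p_bonferroni = float(p_corr)
    return report
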