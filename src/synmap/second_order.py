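"""Second-order similarity mapping: binned regression of colour differences.

The second-order question is whether *differences* between two graphemes'
features predict *differences* between their synesthetic colours. For each
unordered grapheme pair the four colour-difference measures (L*a*b* colour
distance and the luminance, saturation and hue components) are averaged
across synesthetes; pairs are then sorted by mean colour distance and
grouped into equal-size bins (15 pairs per bin for the 1035 Hiragana
pairs -> 69 bins; 5 per bin for the 325 Latin pairs -> 65 bins), and the
bin means of the colour measures are regressed on the bin means of the
four grapheme predictors by ordinary least squares. Standardised
coefficients, VIF-based collinearity screening and a Pearson correlation
table accompany each fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .colorimetry import ACHROMATIC_CHROMA, Palette, circular_hue_difference
from .consistency import validate_responses
from .graphemes import (
    GibsonFeatures,
    GraphemeInventory,
    SimilarityNorms,
    predictor_table,
)

__all__ = [
    "MEASURES",
    "pair_color_measures",
    "BinnedTable",
    "sort_and_bin",
    "correlation_table",
    "vif",
    "RegressionResult",
    "fit_regression",
    "run_second_order_analysis",
    "format_report",
]

#: the four colour-difference measures, in reporting order
MEASURES = (
    "color_distance",
    "luminance_distance",
    "saturation_distance",
    "hue_distance",
)

DEFAULT_BIN_SIZE = {"hiragana": 15, "latin": 5}


def pair_color_measures(
    responses: pd.DataFrame,
    palette: Palette,
    inventory: GraphemeInventory,
    session: int = 1,
    group: str = "synesthete",
    hue_mode: str = "circular",
) -> pd.DataFrame:
    """Participant-averaged colour-difference measures for every grapheme pair.

    For each participant of ``group`` and each unordered pair of graphemes,
    the colour distance, luminance distance, saturation distance and hue
    distance between the two chosen colours (from ``session``) are
    computed, then averaged across participants. Returns one row per pair
    in canonical (position-ordered) pair order. ``.attrs["n_achromatic"]``
    counts (participant, pair) combinations where at least one colour was
    achromatic, for which the hue angle is 0 by convention.
    """
    validate_responses(responses, palette)
    sub = responses[
        (responses["script"] == inventory.script)
        & (responses["session"] == session)
        & (responses["group"] == group)
    ]
    if sub.empty:
        raise ValueError(
            f"no session-{session} {group} responses for {inventory.script!r}"
        )
    wide = sub.pivot_table(
        index="participant", columns="symbol", values="color_name", aggfunc="first"
    )
    missing = set(inventory.symbols) - set(wide.columns)
    if missing or wide.isna().any().any():
        raise ValueError(
            f"incomplete responses for {inventory.script}: "
            f"missing symbols {sorted(missing)[:10]} or empty cells"
        )
    wide = wide[inventory.symbols]
    idx = np.vectorize(palette.index_of)(wide.to_numpy())
    lab = palette.lab[idx]   # (participants, graphemes, 3)
    lch = palette.lch[idx]

    n = len(inventory)
    ii, jj = np.triu_indices(n, k=1)
    color = np.linalg.norm(lab[:, ii] - lab[:, jj], axis=2)
    lum = np.abs(lch[:, ii, 0] - lch[:, jj, 0])
    sat = np.abs(lch[:, ii, 1] - lch[:, jj, 1])
    dh = np.abs(lch[:, ii, 2] - lch[:, jj, 2])
    if hue_mode == "circular":
        hue = np.minimum(dh % 360.0, 360.0 - dh % 360.0)
    elif hue_mode == "linear":
        hue = dh
    else:
        raise ValueError(f"unknown hue_mode: {hue_mode!r}")

    achrom = lch[:, :, 1] < ACHROMATIC_CHROMA
    n_achromatic = int((achrom[:, ii] | achrom[:, jj]).sum())

    symbols = np.array(inventory.symbols)
    out = pd.DataFrame(
        {
            "symbol_a": symbols[ii],
            "symbol_b": symbols[jj],
            "color_distance": color.mean(axis=0),
            "luminance_distance": lum.mean(axis=0),
            "saturation_distance": sat.mean(axis=0),
            "hue_distance": hue.mean(axis=0),
        }
    )
    out.attrs["n_participants"] = len(wide)
    out.attrs["n_achromatic"] = n_achromatic
    return out


@dataclass
class BinnedTable:
    """Equal-size bins of grapheme pairs ordered by mean colour distance."""

    bins: pd.DataFrame          # one row per bin: means of measures & predictors
    assignment: pd.DataFrame    # the sorted pair table with a 'bin' column
    bin_size: int

    @property
    def n_bins(self) -> int:
        return len(self.bins)


def sort_and_bin(
    pairs: pd.DataFrame,
    bin_size: int,
    policy: str = "strict",
) -> BinnedTable:
    """Sort pairs by participant-averaged colour distance and bin them.

    Pairs are sorted ascending by ``color_distance`` (stable sort, so ties
    keep canonical pair order) and cut into consecutive chunks of
    ``bin_size``; the first bin holds the pairs most similar in colour.
    Per-bin means are taken over every numeric column. If the pair count
    is not divisible by ``bin_size``, ``policy="strict"`` raises and
    ``policy="drop_remainder"`` discards the trailing pairs with a warning.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n = len(pairs)
    remainder = n % bin_size
    if remainder:
        if policy == "drop_remainder":
            warnings.warn(
                f"dropping {remainder} pairs to make equal-size bins",
                stacklevel=2,
            )
        else:
            raise ValueError(
                f"{n} pairs not divisible by bin size {bin_size}; "
                f'use policy="drop_remainder" to truncate'
            )
    ordered = pairs.sort_values("color_distance", kind="stable").reset_index(drop=True)
    if remainder:
        ordered = ordered.iloc[: n - remainder].copy()
    ordered["bin"] = np.arange(len(ordered)) // bin_size
    numeric = ordered.select_dtypes(include="number").columns.difference(["bin"])
    bins = ordered.groupby("bin")[list(numeric)].mean().reset_index()
    return BinnedTable(bins=bins, assignment=ordered, bin_size=bin_size)


def correlation_table(
    binned: BinnedTable | pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations (and two-tailed p-values) among binned variables."""
    df = binned.bins if isinstance(binned, BinnedTable) else binned
    if len(df) < 3:
        raise ValueError("need at least 3 bins for correlations")
    r = pd.DataFrame(np.eye(len(columns)), index=columns, columns=columns)
    p = pd.DataFrame(np.zeros((len(columns), len(columns))), index=columns, columns=columns)
    for i, ci in enumerate(columns):
        for j, cj in enumerate(columns):
            if j <= i:
                continue
            x, y = df[ci], df[cj]
            if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
                warnings.warn(f"zero variance in {ci!r} or {cj!r}", stacklevel=2)
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(x, y)
            r.loc[ci, cj] = r.loc[cj, ci] = rij
            p.loc[ci, cj] = p.loc[cj, ci] = pij
    return r, p


def vif(data: BinnedTable | pd.DataFrame, predictors: list[str]) -> pd.Series:
    """Variance inflation factors via auxiliary regressions.

    VIF_j = 1 / (1 - R^2_j) where R^2_j comes from the OLS regression of
    predictor j on the remaining predictors (with intercept). Perfect
    collinearity yields ``inf``.
    """
    df = data.bins if isinstance(data, BinnedTable) else data
    if len(df) < len(predictors) + 2:
        raise ValueError("too few observations to estimate VIF")
    out = {}
    for j in predictors:
        others = [c for c in predictors if c != j]
        X = sm.add_constant(df[others].to_numpy(dtype=float))
        r2 = sm.OLS(df[j].to_numpy(dtype=float), X).fit().rsquared
        out[j] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class RegressionResult:
    """One OLS fit of a colour-difference measure on the four predictors."""

    dependent: str
    n_obs: int
    r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int
    p_overall: float
    coefficients: pd.DataFrame   # index: predictor; B, SE, beta, t, p, vif
    intercept: float

    def to_dict(self) -> dict:
        return {
            "dependent": self.dependent,
            "n_obs": self.n_obs,
            "r_squared": self.r_squared,
            "f_statistic": self.f_statistic,
            "df": [self.df_model, self.df_resid],
            "p_overall": self.p_overall,
            "intercept": self.intercept,
            "coefficients": self.coefficients.to_dict(orient="index"),
        }


def fit_regression(
    data: BinnedTable | pd.DataFrame,
    dv: str,
    predictors: list[str],
) -> RegressionResult:
    """OLS of one colour-difference measure on the grapheme predictors.

    Fit on bin means with an intercept. Standardised coefficients are
    beta_j = B_j * sd(x_j) / sd(y) using sample (n-1) standard deviations,
    identical to refitting on z-scored variables. Coefficient t-tests are
    two-tailed with N - k - 1 residual degrees of freedom.
    """
    df = data.bins if isinstance(data, BinnedTable) else data
    n, k = len(df), len(predictors)
    if n <= k + 1:
        raise ValueError(f"need more than {k + 1} observations, got {n}")
    X = df[predictors].to_numpy(dtype=float)
    y = df[dv].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X]))
    if rank < k + 1:
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0)
        dep = [
            predictors[i]
            for i in range(k)
            if np.any(np.abs(corr[i]) > 1 - 1e-10) or X[:, i].std() == 0
        ]
        raise ValueError(f"rank-deficient design; dependent columns: {dep}")
    model = sm.OLS(y, sm.add_constant(X)).fit()
    sx = X.std(axis=0, ddof=1)
    sy = y.std(ddof=1)
    coef = pd.DataFrame(
        {
            "B": model.params[1:],
            "SE": model.bse[1:],
            "beta": model.params[1:] * sx / sy,
            "t": model.tvalues[1:],
            "p": model.pvalues[1:],
        },
        index=predictors,
    )
    coef["vif"] = vif(df, predictors)
    return RegressionResult(
        dependent=dv,
        n_obs=n,
        r_squared=float(model.rsquared),
        f_statistic=float(model.fvalue),
        df_model=int(model.df_model),
        df_resid=int(model.df_resid),
        p_overall=float(model.f_pvalue),
        coefficients=coef,
        intercept=float(model.params[0]),
    )


def run_second_order_analysis(
    responses: pd.DataFrame,
    palette: Palette,
    inventories: dict[str, GraphemeInventory],
    norms: dict[str, SimilarityNorms] | None = None,
    features: GibsonFeatures | None = None,
    scripts: tuple[str, ...] = ("hiragana", "latin"),
    bin_sizes: dict[str, int] | None = None,
    hue_mode: str = "circular",
    shape_measure: str = "rated",
    session: int = 1,
) -> dict:
    """The full mapping pipeline for one or more scripts.

    Per script: participant-averaged pair colour measures (session-1
    synesthete data by default), predictor join, sorting + binning,
    correlation table, VIF screen, and one OLS regression per
    colour-difference measure. Returns a nested report dict; no
    multiple-testing correction is applied across the four regressions.
    """
    bin_sizes = {**DEFAULT_BIN_SIZE, **(bin_sizes or {})}
    report: dict = {"scripts": {}}
    for script in scripts:
        inv = inventories[script]
        measure = shape_measure if script == "latin" else "rated"
        preds = predictor_table(
            inv,
            norms=(norms or {}).get(script),
            features=features if measure == "gibson" else None,
            shape_measure=measure,
        )
        predictor_cols = [
            c for c in preds.columns if c not in ("symbol_a", "symbol_b")
        ]
        measures = pair_color_measures(
            responses, palette, inv, session=session, hue_mode=hue_mode
        )
        pairs = measures.merge(preds, on=["symbol_a", "symbol_b"], validate="1:1")
        binned = sort_and_bin(pairs, bin_sizes[script])
        all_cols = list(MEASURES) + predictor_cols
        r, p = correlation_table(binned, all_cols)
        entry = {
            "n_pairs": len(pairs),
            "n_bins": binned.n_bins,
            "bin_size": binned.bin_size,
            "n_achromatic_pairs": measures.attrs["n_achromatic"],
            "correlations": r,
            "correlation_p": p,
            "vif": vif(binned, predictor_cols),
            "regressions": {
                dv: fit_regression(binned, dv, predictor_cols) for dv in MEASURES
            },
            "binned": binned,
        }
        report["scripts"][script] = entry
    return report


def _stars(p: float) -> str:
    return "**" if p < 0.01 else ("*" if p < 0.05 else "")


def format_report(report: dict) -> str:
    """Plain-text tables (correlations, VIF, regressions) per script."""
    lines: list[str] = []
    for script, entry in report["scripts"].items():
        lines.append(f"=== {script} (N = {entry['n_bins']} bins of "
                     f"{entry['bin_size']} pairs) ===")
        lines.append("")
        lines.append("Correlations among binned variables "
                     "(* p < 0.05, ** p < 0.01):")
        r, p = entry["correlations"], entry["correlation_p"]
        cols = list(r.columns)
        for i, ci in enumerate(cols):
            cells = []
            for j in range(i):
                cells.append(f"{r.iloc[i, j]:+.2f}{_stars(p.iloc[i, j])}")
            lines.append(f"  {ci:<24}" + "  ".join(cells))
        lines.append("")
        lines.append("VIF: " + ", ".join(
            f"{k}={v:.2f}" for k, v in entry["vif"].items()))
        lines.append("")
        for dv, res in entry["regressions"].items():
            lines.append(
                f"{dv.upper()} [R^2 = {res.r_squared:.2f}, "
                f"F({res.df_model}, {res.df_resid}) = {res.f_statistic:.2f}, "
                f"p = {res.p_overall:.3g}]"
            )
            for name, row in res.coefficients.iterrows():
                lines.append(
                    f"  {name:<24} B = {row['B']:+9.3f} (SE {row['SE']:.3f})  "
                    f"beta = {row['beta']:+.3f}  t = {row['t']:+.2f}  "
                    f"p = {row['p']:.3g}{_stars(row['p'])}"
                )
            lines.append("")
    return "\n".join(lines)
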