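"""Agreement statistics between imaging techniques.

Kruskal-Wallis group comparison, OLS regression R², Bland-Altman bias
and limits of agreement, ICC with the low/good/excellent banding, and
the per-sample maximum percentage difference tables.  Paired data come
in long format: (sample_id, image_id, modality, metric, value); ND
entries are dropped pairwise with a logged count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "kruskal_wallis",
    "linear_r2",
    "bland_altman",
    "icc",
    "icc_band",
    "max_percent_diff",
    "paired_wide",
    "summarize_agreement",
]

LONG_COLUMNS = ["sample_id", "image_id", "modality", "metric", "value"]


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0  # all values identical: H degenerates to 0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def linear_r2(x, y) -> Tuple[float, float, float]:
    """OLS slope, intercept and R² (squared Pearson correlation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired finite values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    fit = sps.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def bland_altman(
    a, b, relative: bool = False
) -> Tuple[float, Tuple[float, float]]:
    """Mean difference (bias) and 95% limits of agreement for pairs (a, b).

    In relative mode differences are 100*(b - a)/a percent, using ``a``
    as the reference.  Limits are bias ± 1.96 * SD of the differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need >= 2 matched pairs")
    if relative:
        if np.any(a == 0):
            raise ValueError("zero reference values in relative mode")
        diff = 100.0 * (b - a) / a
    else:
        diff = b - a
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


def icc_band(value: float) -> str:
    """Agreement band: < 0.5 low, 0.5-0.75 good, > 0.75 excellent."""
    if value > 0.75:
        return "excellent"
    if value >= 0.5:
        return "good"
    return "low"


def icc(a, b, model: str = "ICC2") -> Tuple[float, str]:
    """Intraclass correlation of matched pairs, with its agreement band.

    Default model: two-way mixed/random effects, absolute agreement,
    single measurement (ICC2 in the Shrout-Fleiss naming used by
    pingouin); configurable via ``model``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need >= 3 matched pairs")
    import pingouin as pg

    n = a.size
    df = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["a", "b"], n),
            "score": np.concatenate([a, b]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(
            data=df, targets="target", raters="rater", ratings="score"
        )
    aliases = {
        "ICC1": {"ICC1", "ICC(1,1)"},
        "ICC2": {"ICC2", "ICC(A,1)"},   # two-way, absolute agreement, single
        "ICC3": {"ICC3", "ICC(C,1)"},
        "ICC1k": {"ICC1k", "ICC(1,k)"},
        "ICC2k": {"ICC2k", "ICC(A,k)"},
        "ICC3k": {"ICC3k", "ICC(C,k)"},
    }.get(model, {model})
    row = table.loc[table["Type"].isin(aliases)]
    if row.empty:
        raise ValueError(f"unknown ICC model {model!r}")
    value = float(row["ICC"].iloc[0])
    if np.isnan(value):  # zero error variance: perfect agreement
        value = 1.0 if np.allclose(a, b) else float("nan")
    return value, icc_band(value)


def max_percent_diff(reference, other) -> int:
    """Max over pairs of 100*|other - reference|/reference, integer %."""
    reference = np.asarray(reference, dtype=float)
    other = np.asarray(other, dtype=float)
    if reference.size == 0 or reference.size != other.size:
        raise ValueError("need >= 1 matched pair")
    if np.any(reference == 0):
        raise ValueError("zero reference value")
    return int(round(float(np.max(100.0 * np.abs(other - reference) / np.abs(reference)))))


# ---------------------------------------------------------------------------
# long-format table plumbing
# ---------------------------------------------------------------------------

def paired_wide(
    long_df: pd.DataFrame,
    reference_modality: str,
    other_modality: str,
    metric: Optional[str] = None,
) -> pd.DataFrame:
    """Pivot a long table into matched (reference, other) pairs.

    Rows with an ND/missing value on either side are dropped pairwise;
    the number of dropped pairs is recorded in ``df.attrs['n_dropped']``.
    """
    df = long_df.copy()
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"long table is missing columns {sorted(missing)}")
    if metric is not None:
        df = df[df["metric"] == metric]
    df["value"] = pd.to_numeric(
        df["value"].replace({"ND": np.nan, "nd": np.nan}), errors="coerce"
    )
    wide = df.pivot_table(
        index=["sample_id", "image_id", "metric"],
        columns="modality",
        values="value",
        aggfunc="first",
    ).reset_index()
    for mod in (reference_modality, other_modality):
        if mod not in wide.columns:
            raise ValueError(f"modality {mod!r} absent from table")
    complete = wide.dropna(subset=[reference_modality, other_modality])
    complete = complete.rename(
        columns={reference_modality: "reference", other_modality: "other"}
    )[["sample_id", "image_id", "metric", "reference", "other"]]
    complete.attrs["n_dropped"] = int(len(wide) - len(complete))
    return complete


def summarize_agreement(
    long_df: pd.DataFrame,
    reference_modality: str = "uCT",
    other_modality: str = "MRI",
) -> pd.DataFrame:
    """Per-metric agreement summary between two modalities.

    Columns: Kruskal-Wallis H/p, OLS slope/R², relative Bland-Altman
    bias (%), ICC and its band, and the overall max percentage
    difference with the reference modality as denominator.
    """
    rows = []
    for metric in sorted(long_df["metric"].unique()):
        pairs = paired_wide(long_df, reference_modality, other_modality, metric)
        ref, oth = pairs["reference"].values, pairs["other"].values
        entry = {"metric": metric, "n_pairs": len(pairs),
                 "n_dropped": pairs.attrs["n_dropped"]}
        if len(pairs) >= 2:
            h, p = kruskal_wallis([ref, oth])
            entry["kw_H"], entry["kw_p"] = h, p
            bias, (lo, hi) = bland_altman(ref, oth, relative=True)
            entry["ba_bias_pct"] = bias
            entry["ba_lo_pct"], entry["ba_hi_pct"] = lo, hi
            entry["max_diff_pct"] = max_percent_diff(ref, oth)
        if len(pairs) >= 3:
            slope, intercept, r2 = linear_r2(ref, oth)
            entry["ols_slope"], entry["ols_r2"] = slope, r2
            value, band = icc(ref, oth)
            entry["icc"], entry["icc_band"] = value, band
        rows.append(entry)
    return pd.DataFrame(rows)
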