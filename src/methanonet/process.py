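"""Functional process analysis.

Gas accumulation rates, the apparent carbon isotope fractionation factor
between CO2 and CH4 with methanogenic-pathway classification, qPCR group
statistics (ANOVA on log10 copy numbers with Duncan's multiple range
test) and volatile-fatty-acid summaries.

The fractionation factor alpha_app = (d13CO2 + 1000) / (d13CH4 + 1000)
discriminates the methanogenic pathway: values around 1.08 indicate CH4
produced exclusively from H2/CO2, values around 1.04 a mixture of
acetoclastic and hydrogenotrophic methanogenesis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .letters import compact_letter_display

log = logging.getLogger(__name__)

ALPHA_HYDRO_ANCHOR = 1.08
ALPHA_MIXED_ANCHOR = 1.04
#: midpoint of the two pathway anchors; >= threshold classifies as
#: hydrogenotrophic-dominant
PATHWAY_THRESHOLD = 0.5 * (ALPHA_HYDRO_ANCHOR + ALPHA_MIXED_ANCHOR)


def alpha_app(d13_co2, d13_ch4):
    """Apparent fractionation factor (d13CO2 + 10^3) / (d13CH4 + 10^3).

    Both deltas are per-mil values and must exceed -1000 (the physical
    lower bound of the delta scale).
    """
    co2 = np.asarray(d13_co2, dtype=float)
    ch4 = np.asarray(d13_ch4, dtype=float)
    if np.any(ch4 <= -1000.0) or np.any(co2 <= -1000.0):
        raise ValueError("delta 13C values must be > -1000 permil")
    out = (co2 + 1e3) / (ch4 + 1e3)
    return float(out) if out.ndim == 0 else out


def classify_pathway(alpha_series, window: int = 5,
                     threshold: float = PATHWAY_THRESHOLD) -> str:
    """Classify the terminal methanogenic pathway from an alpha_app series.

    The mean over the last ``window`` values is compared with the
    threshold (default 1.06): at or above -> "hydrogenotrophic-dominant",
    below -> "mixed".
    """
    arr = np.asarray(alpha_series, dtype=float)
    arr = arr[~np.isnan(arr)]
    if window < 1:
        raise ValueError("window must be >= 1")
    if arr.size == 0:
        raise ValueError("empty alpha_app series")
    terminal = arr[-window:]
    return "hydrogenotrophic-dominant" if terminal.mean() >= threshold else "mixed"


def terminal_alpha(alpha_series, window: int = 5) -> float:
    """Mean alpha_app over the final ``window`` time points."""
    arr = np.asarray(alpha_series, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("empty alpha_app series")
    return float(arr[-window:].mean())


@dataclass
class RateFit:
    slope: float       # amount per day
    intercept: float
    r_squared: float
    n: int


def accumulation_rate(times, amounts, window: slice | None = None) -> RateFit:
    """Ordinary least-squares accumulation rate over a time window.

    Fits amount = a + rate * t and reports the slope (amount/day),
    intercept and R^2.  Needs at least 3 points.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(amounts, dtype=float)
    if window is not None:
        t, y = t[window], y[window]
    if t.size < 3:
        raise ValueError(f"need >= 3 points for a rate fit, got {t.size}")
    res = stats.linregress(t, y)
    r2 = float(res.rvalue**2) if not np.isnan(res.rvalue) else 1.0 if np.allclose(
        y, y.mean()) else 0.0
    return RateFit(slope=float(res.slope), intercept=float(res.intercept),
                   r_squared=r2, n=int(t.size))


# ----------------------------------------------------------------------
# Duncan's multiple range test on log10 qPCR copy numbers
# ----------------------------------------------------------------------

def duncan_letters(values, group_labels, alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA plus Duncan's multiple range test.

    Group means are sorted; a pair whose ordered positions span p means
    is significant when its difference exceeds the critical range
    r_p = q*(alpha_p, p, df_err) * sqrt(MSE / n), with the Duncan
    protection level alpha_p = 1 - (1 - alpha)^(p-1) and q* the
    studentized range quantile.  Unbalanced designs use the harmonic
    mean group size (with a warning).  Returns a frame with group, n,
    mean and letters (shared letter = not significantly different).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("Duncan test needs at least 2 groups")
    sizes = {g: int((labels == g).sum()) for g in groups}
    tiny = [g for g, n in sizes.items() if n < 2]
    if tiny:
        raise ValueError(f"groups with a single replicate: {tiny}")

    means = {g: float(values[labels == g].mean()) for g in groups}
    n_tot = len(values)
    df_err = n_tot - len(groups)
    sse = sum(((values[labels == g] - means[g]) ** 2).sum() for g in groups)
    mse = sse / df_err if df_err > 0 else 0.0
    if len(set(sizes.values())) > 1:
        log.warning("unbalanced groups %s: using harmonic mean n", sizes)
        n_eff = len(groups) / sum(1.0 / n for n in sizes.values())
    else:
        n_eff = next(iter(sizes.values()))

    order = sorted(groups, key=lambda g: -means[g])
    sig_pairs: list[tuple] = []
    if mse > 0:
        se = np.sqrt(mse / n_eff)
        for i in range(len(order)):
            for j in range(i + 1, len(order)):
                span = j - i + 1
                alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
                crit = stats.studentized_range.ppf(1.0 - alpha_p, span, df_err) * se
                if means[order[i]] - means[order[j]] > crit:
                    sig_pairs.append((order[i], order[j]))
    letters = compact_letter_display(groups, sig_pairs, order=order)
    out = pd.DataFrame({"group": order,
                        "n": [sizes[g] for g in order],
                        "mean": [means[g] for g in order],
                        "letters": [letters[g] for g in order]})
    f_stat, p = stats.f_oneway(*[values[labels == g] for g in groups]) \
        if mse > 0 else (np.nan, 1.0)
    out.attrs["anova_F"] = float(f_stat)
    out.attrs["anova_p"] = float(p)
    return out


def qpcr_letters(measurements: pd.DataFrame, group_column: str = "treatment_code",
                 alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Duncan letter tables of log10 16S rRNA gene copies, one per domain.

    ``measurements`` needs columns domain, copies_per_g and the grouping
    column.  Copy numbers are log10-transformed before the ANOVA.
    """
    if (measurements["copies_per_g"] <= 0).any():
        raise ValueError("copy numbers must be positive for log transformation")
    out = {}
    for dom, sub in measurements.groupby("domain"):
        out[str(dom)] = duncan_letters(np.log10(sub["copies_per_g"].to_numpy()),
                                       sub[group_column].to_numpy(), alpha=alpha)
    return out


# ----------------------------------------------------------------------

def vfa_summary(vfa_table: pd.DataFrame, metadata: pd.DataFrame,
                accumulation_factor: float = 10.0) -> pd.DataFrame:
    """Per-treatment mean +/- SD of each acid with acetate accumulation flags.

    A treatment is flagged when its mean acetate exceeds
    ``accumulation_factor`` times the cross-treatment median (floored at
    a small positive value so an all-zero table yields no flags).
    """
    acids = [c for c in vfa_table.columns if c.endswith("_mM")]
    md = metadata.set_index("sample_id")
    tab = vfa_table.copy()
    tab["treatment_code"] = tab["sample_id"].map(md["treatment_code"])
    rows = []
    grouped = tab.groupby("treatment_code", sort=True)
    acetate_means = grouped["acetate_mM"].mean() if "acetate_mM" in acids else None
    median = float(np.median(acetate_means)) if acetate_means is not None else 0.0
    cutoff = accumulation_factor * max(median, 1e-9)
    for code, sub in grouped:
        row: dict = {"treatment_code": code, "n": len(sub)}
        for acid in acids:
            row[f"{acid}_mean"] = float(sub[acid].mean())
            row[f"{acid}_sd"] = float(sub[acid].std(ddof=1)) if len(sub) > 1 else 0.0
        row["acetate_accumulating"] = bool(
            acetate_means is not None and row.get("acetate_mM_mean", 0.0) > cutoff)
        rows.append(row)
    return pd.DataFrame(rows)


def alpha_table(isotopes: pd.DataFrame, window: int = 5,
                threshold: float = PATHWAY_THRESHOLD) -> pd.DataFrame:
    """Per-vessel alpha_app series reduced to a terminal mean + pathway label.

    ``isotopes`` is long format with sample_id, time_days, d13_co2,
    d13_ch4 columns (the generator's output or a read-in series).
    """
    rows = []
    for sample, sub in isotopes.groupby("sample_id", sort=True):
        sub = sub.sort_values("time_days")
        series = alpha_app(sub["d13_co2"].to_numpy(), sub["d13_ch4"].to_numpy())
        rows.append({
            "sample_id": sample,
            "treatment_code": sub["treatment_code"].iloc[0] if "treatment_code" in sub else "",
            "alpha_app_terminal": float(np.asarray(series)[-window:].mean()),
            "pathway": classify_pathway(series, window=window, threshold=threshold),
        })
    return pd.DataFrame(rows)
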