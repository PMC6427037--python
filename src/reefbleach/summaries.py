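"""Descriptive spatial and temporal summaries of the bleaching surveys.

Ecoregion-level z-scores of the significant covariates (with the >= 10
surveys inclusion rule), absolute-latitude bleaching prevalence bands, the
prevalence-vs-sampling-effort rank correlation, and the annual
bleaching-probability trend with Wilson confidence intervals.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.proportion import proportion_confint


def ecoregion_zscores(
    df: pd.DataFrame,
    covariates: list[str],
    min_surveys: int = 10,
    eco_col: str = "ecoregion",
) -> pd.DataFrame:
    """Per-ecoregion covariate anomalies in grand-standard-deviation units.

    For each covariate (typically those whose 95% CrI excluded zero in the
    fitted model), the ecoregion mean is expressed as the number of standard
    deviations from the covariate's mean across all retained ecoregions.
    Ecoregions with fewer than ``min_surveys`` surveys are excluded.
    """
    counts = df.groupby(eco_col).size()
    keep = counts.index[counts >= min_surveys]
    if len(keep) < 2:
        raise ValueError(
            f"only {len(keep)} ecoregion(s) with >= {min_surveys} surveys; "
            "z-scores need at least 2"
        )
    means = df[df[eco_col].isin(keep)].groupby(eco_col)[covariates].mean()
    out = pd.DataFrame(index=means.index)
    out["n_surveys"] = counts.loc[means.index]
    for cov in covariates:
        m = means[cov]
        sd = m.std(ddof=1)
        out[f"z_{cov}"] = 0.0 if sd == 0 else (m - m.mean()) / sd
    excluded = counts.index[counts < min_surveys].tolist()
    out.attrs["excluded_ecoregions"] = excluded
    return out


def latitude_profile(
    df: pd.DataFrame,
    band_width: float = 5.0,
    lat_col: str = "latitude",
    bleaching_col: str = "bleaching_pct",
) -> pd.DataFrame:
    """Bleaching prevalence and mean intensity by absolute-latitude band.

    Bands cover [0, ceil(max |lat|)] at ``band_width`` degrees. Empty bands
    are reported with n_surveys = 0 and NaN prevalence rather than dropped.
    """
    alat = df[lat_col].abs().to_numpy(dtype=float)
    top = float(np.ceil(alat.max() / band_width) * band_width)
    edges = np.arange(0.0, top + band_width / 2, band_width)
    idx = np.clip(np.digitize(alat, edges) - 1, 0, len(edges) - 2)
    bleached = (df[bleaching_col].to_numpy(dtype=float) > 0).astype(float)
    pct = df[bleaching_col].to_numpy(dtype=float)
    rows = []
    for b in range(len(edges) - 1):
        m = idx == b
        n = int(m.sum())
        rows.append(
            {
                "band_low": edges[b],
                "band_high": edges[b + 1],
                "n_surveys": n,
                "n_sites": int(df.loc[m, "site_id"].nunique()) if "site_id" in df else n,
                "prevalence": float(bleached[m].mean()) if n else np.nan,
                "mean_bleaching": float(pct[m].mean()) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def effort_correlation(profile: pd.DataFrame) -> tuple[float, float]:
    """Spearman rank correlation of prevalence vs sampling effort per band.

    Effort is the number of surveyed sites in the band. Returns (rho, p);
    with constant prevalence the correlation is undefined and (nan, nan) is
    returned with a warning.
    """
    bands = profile[profile["n_surveys"] > 0]
    if len(bands) < 4:
        raise ValueError(f"need >= 4 non-empty bands, got {len(bands)}")
    prev = bands["prevalence"].to_numpy()
    effort = bands["n_sites"].to_numpy(dtype=float)
    if np.allclose(prev, prev[0]) or np.allclose(effort, effort[0]):
        warnings.warn("constant prevalence or effort; Spearman rho undefined")
        return float("nan"), float("nan")
    rho, p = spearmanr(prev, effort)
    return float(rho), float(p)


def annual_trend(
    df: pd.DataFrame,
    bleaching_col: str = "bleaching_pct",
) -> pd.DataFrame:
    """Per-year bleaching probability with a Wilson 95% CI, plus the
    percent-bleaching quartiles and 95% range (boxplot-style).

    Years with no surveys are skipped. The probability is the fraction of
    surveys recording any bleaching.
    """
    if "year" in df.columns:
        years = df["year"].to_numpy()
    else:
        years = pd.DatetimeIndex(df["date"]).year.to_numpy()
    uyears = np.unique(years)
    if len(uyears) < 2:
        raise ValueError("annual trend needs surveys in >= 2 years")
    pct_all = df[bleaching_col].to_numpy(dtype=float)
    rows = []
    for y in uyears:
        m = years == y
        n = int(m.sum())
        pct = pct_all[m]
        nb = int((pct > 0).sum())
        lo, hi = proportion_confint(nb, n, alpha=0.05, method="wilson")
        q = np.percentile(pct, [2.5, 25, 50, 75, 97.5])
        rows.append(
            {
                "year": int(y),
                "n_surveys": n,
                "n_bleached": nb,
                "probability": nb / n,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "mean_bleaching": float(pct.mean()),
                "pct_q2.5": q[0],
                "pct_q25": q[1],
                "pct_median": q[2],
                "pct_q75": q[3],
                "pct_q97.5": q[4],
            }
        )
    return pd.DataFrame(rows)


def trend_slope(trend: pd.DataFrame) -> float:
    """OLS slope of the annual bleaching probability (per year)."""
    return float(np.polyfit(trend["year"], trend["probability"], 1)[0])
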