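"""Join, filter and standardize survey covariates for model fitting.

Reproduces the study's preprocessing rules: rows with missing environmental
covariates or an unmapped ecoregion are dropped (with the removal fraction
reported), pairs of covariates with |Pearson r| above a threshold (0.65 by
default) are pruned greedily, and every retained covariate is z-scored.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class EmptyTableError(ValueError):
    """All rows were removed during filtering."""


@dataclass
class AnalysisTable:
    """Model-ready survey table with standardized covariates.

    ``df`` holds one row per retained survey; covariate columns listed in
    ``covariate_names`` are standardized (mean 0, sd 1) with the original
    (mean, sd) kept in ``standardization_params`` so fitted coefficients can
    be back-transformed to per-unit effects.
    """

    df: pd.DataFrame
    covariate_names: list[str]
    standardization_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    dropped_covariates: list[dict] = field(default_factory=list)
    dropped_rows: dict = field(default_factory=dict)

    def back_transform(self, name: str, coef_std: float) -> float:
        """Effect per original covariate unit from a standardized-scale coefficient."""
        _, sd = self.standardization_params[name]
        return coef_std / sd

    def provenance(self) -> dict:
        return {
            "covariates": self.covariate_names,
            "standardization": {
                k: {"mean": m, "sd": s}
                for k, (m, s) in self.standardization_params.items()
            },
            "dropped_covariates": self.dropped_covariates,
            "dropped_rows": self.dropped_rows,
        }

    def save(self, csv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        self.df.to_csv(csv_path, index=False)
        if sidecar_path is not None:
            Path(sidecar_path).write_text(json.dumps(self.provenance(), indent=2, default=str))


def collinearity_prune(
    df: pd.DataFrame, covariate_names: list[str], threshold: float = 0.65
) -> tuple[list[str], list[dict]]:
    """Greedy pruning of collinear covariates.

    While any pair of retained covariates has |Pearson r| > ``threshold``,
    drop from the worst pair the member with the larger mean absolute
    correlation to all other retained covariates. Constant columns are
    excluded up front (their correlation is undefined). Each drop is recorded
    with the pair and correlation that triggered it.
    """
    if len(covariate_names) < 2 or len(df) < 3:
        raise ValueError("collinearity pruning needs >= 2 covariates and >= 3 rows")
    dropped: list[dict] = []
    retained = list(covariate_names)
    for name in list(retained):
        x = df[name].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            warnings.warn(f"covariate {name!r} is constant; excluded before pruning")
            retained.remove(name)
            dropped.append({"dropped": name, "partner": None, "r": None,
                            "reason": "constant column"})
    while len(retained) > 1:
        corr = df[retained].corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        acorr = np.abs(corr)
        i, j = np.unravel_index(np.argmax(acorr), acorr.shape)
        if acorr[i, j] <= threshold:
            break
        mean_i = acorr[i].sum() / (len(retained) - 1)
        mean_j = acorr[j].sum() / (len(retained) - 1)
        # drop the member more entangled with everything else; ties drop the
        # later column so the result is deterministic in column order
        if mean_i > mean_j:
            drop, keep = i, j
        elif mean_j > mean_i:
            drop, keep = j, i
        else:
            drop, keep = max(i, j), min(i, j)
        dropped.append(
            {
                "dropped": retained[drop],
                "partner": retained[keep],
                "r": float(corr[i, j]),
                "reason": f"|r| > {threshold}",
            }
        )
        retained.pop(drop)
    return retained, dropped


def drop_incomplete(
    df: pd.DataFrame,
    covariate_names: list[str],
    valid_ecoregions: set | None = None,
    ecoregion_col: str = "ecoregion",
) -> tuple[pd.DataFrame, dict]:
    """Remove rows with missing covariates or an unmapped ecoregion."""
    n0 = len(df)
    missing_mask = df[covariate_names].isna().any(axis=1)
    reasons = pd.Series("", index=df.index, dtype=object)
    reasons[missing_mask] = "missing covariate"
    if valid_ecoregions is not None and ecoregion_col in df.columns:
        outside = ~df[ecoregion_col].isin(valid_ecoregions)
        reasons[outside & (reasons == "")] = "outside ecoregion"
        missing_mask |= outside
    kept = df.loc[~missing_mask].copy()
    if len(kept) == 0:
        raise EmptyTableError("all rows removed by missing-data filtering")
    info = {
        "n_input": n0,
        "n_removed": int(missing_mask.sum()),
        "fraction_removed": float(missing_mask.mean()),
        "reasons": reasons[missing_mask].value_counts().to_dict(),
    }
    return kept, info


def standardize(
    df: pd.DataFrame, covariate_names: list[str]
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Z-score each covariate column (sample sd, ddof=1)."""
    out = df.copy()
    params: dict[str, tuple[float, float]] = {}
    for name in covariate_names:
        x = out[name].to_numpy(dtype=float)
        mean, sd = float(x.mean()), float(x.std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"covariate {name!r} is constant; cannot standardize")
        out[name] = (x - mean) / sd
        params[name] = (mean, sd)
    return out, params


def build_analysis_table(
    surveys: pd.DataFrame,
    covariates: pd.DataFrame | None,
    covariate_names: list[str],
    diversity: pd.DataFrame | None = None,
    prune_threshold: float = 0.65,
) -> AnalysisTable:
    """Full preprocessing chain: join -> drop incomplete -> prune -> standardize.

    ``surveys`` must carry site_id, date, ecoregion and bleaching_pct; if
    ``covariates`` is given it is joined on (site_id, date).
    """
    df = surveys.copy()
    if covariates is not None:
        join_cols = [c for c in covariates.columns
                     if c in ("site_id", "date") or c not in df.columns]
        df = df.merge(covariates[join_cols], on=["site_id", "date"], how="left")
    valid = (
        set(diversity["ecoregion"].tolist()) if diversity is not None else None
    )
    df, drop_info = drop_incomplete(df, covariate_names, valid_ecoregions=valid)
    retained, dropped_cov = collinearity_prune(df, covariate_names, prune_threshold)
    df, params = standardize(df, retained)
    return AnalysisTable(
        df=df,
        covariate_names=retained,
        standardization_params=params,
        dropped_covariates=dropped_cov,
        dropped_rows=drop_info,
    )
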