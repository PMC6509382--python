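"""Seasonal mixed-model comparisons of fidelity, overlap, sociality and area.

All responses are log-transformed (with a small offset because strengths
and overlap indices can be exactly zero) and modelled with Gaussian linear
mixed models fitted by REML: season as a fixed effect, with random
intercepts for year and for animal identity nested within herd. Four
models are run:

1. site fidelity (cross-year UDOI) ~ season, with the year pair as the
   year-level random effect;
2. spatial graph strength ~ season;
3. social graph strength ~ season x source, where source distinguishes the
   observed strength from the per-animal mean of the permutation null,
   paired within animal-season-year;
4. home-range area ~ season + observed social strength.

p-values use the normal approximation to the Wald t statistic (reported
with the method label ``t-as-z``). Near-singular random-effect variances
are tolerated and surfaced through the convergence flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

HR_OUTLIER_KM2 = 4000.0

RECORD_COLUMNS = ["animal_id", "herd", "season", "year", "kind", "value"]

RESPONSE_KINDS = (
    "fidelity_udoi",
    "spatial_strength",
    "social_strength_observed",
    "social_strength_null_mean",
    "hr_area_km2",
)


@dataclass
class ModelFit:
    """Fixed-effect table, variance components and fit diagnostics."""

    response: str
    formula: str
    coefficients: pd.DataFrame  # index: term; columns: estimate, se, t, p
    variance_components: dict[str, float]
    converged: bool
    n_obs: int
    p_method: str = "t-as-z"

    def coef(self, term: str) -> float:
        return float(self.coefficients.loc[term, "estimate"])


def half_min_positive(values) -> float:
    """Log offset: half the smallest positive value (0 if none positive)."""
    v = np.asarray(values, dtype=float)
    pos = v[v > 0]
    return float(pos.min() / 2.0) if len(pos) else 0.0


def log_transform(values, offset: float = 0.0):
    """log(value + offset); raises on negative input."""
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("log transform requires non-negative values")
    return np.log(v + offset)


def filter_outliers(
    records: pd.DataFrame, threshold: float = HR_OUTLIER_KM2
) -> pd.DataFrame:
    """Drop every record of animals with a summer home range > threshold.

    The rule keys on summer home-range area only, but removal is global:
    the animal leaves all seasons and all response kinds.
    """
    bad = records.loc[
        (records["kind"] == "hr_area_km2")
        & (records["season"] == "summer")
        & (records["value"] > threshold),
        "animal_id",
    ].unique()
    return records[~records["animal_id"].isin(bad)].reset_index(drop=True)


def fit_lmm(
    data: pd.DataFrame,
    formula: str,
    vc_cols: tuple[str, ...] = ("herd", "herd_id", "year"),
) -> ModelFit:
    """REML Gaussian LMM with variance-component random intercepts.

    ``vc_cols`` name grouping columns; each contributes a random intercept
    per level (the crossed-random-effects formulation with one trivial
    top-level group). ``herd_id`` (animal within herd) is derived from
    ``herd`` and ``animal_id`` if absent.
    """
    data = data.copy()
    if "herd_id" in vc_cols and "herd_id" not in data.columns:
        data["herd_id"] = data["herd"].astype(str) + ":" + data["animal_id"].astype(str)
    data["_all"] = 1
    response = formula.split("~")[0].strip()
    if response in data.columns and not np.isfinite(data[response].to_numpy(float)).all():
        raise ValueError(f"non-finite values in response {response!r}")

    # Variance components routinely sit on the zero boundary in these data;
    # when REML cannot even evaluate (singular profile), the component is
    # unidentifiable and fixed at 0 by dropping it, down to OLS (the exact
    # boundary solution with every random-effect variance at zero).
    res = None
    model = None
    active = list(vc_cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        while res is None:
            try:
                if active:
                    vcf = {c: f"0 + C({c})" for c in active}
                    model = smf.mixedlm(
                        formula, data, groups="_all", vc_formula=vcf, re_formula="0"
                    )
                    cand = model.fit(reml=True, method="lbfgs")
                else:
                    model = None
                    cand = smf.ols(formula, data).fit()
                if np.isfinite(np.asarray(cand.params)).all():
                    res = cand
                elif not active:
                    break
                else:
                    active.pop()
            except (np.linalg.LinAlgError, ValueError):
                if not active:
                    raise
                active.pop()

    if res is None:
        raise RuntimeError("no finite model fit obtained")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = pd.Series(res.fe_params if model is not None else res.params)
        se = pd.Series(res.bse_fe if model is not None else res.bse)
    tval = est / se
    pval = 2.0 * stats.norm.sf(np.abs(tval))
    coefs = pd.DataFrame({"estimate": est, "se": se, "t": tval, "p": pval})
    vcomp = {c: 0.0 for c in vc_cols}
    if model is not None:
        vc_names = list(getattr(model.exog_vc, "names", []) or [])
        vcomp.update(zip(vc_names, map(float, np.atleast_1d(res.vcomp))))
    vcomp["residual"] = float(res.scale)
    return ModelFit(
        response=response,
        formula=formula,
        coefficients=coefs,
        variance_components=vcomp,
        converged=bool(getattr(res, "converged", True)),
        n_obs=len(data),
    )


def assemble_records(
    social_summary: pd.DataFrame,
    spatial: pd.DataFrame,
    hr_areas: pd.DataFrame,
    fidelity: pd.DataFrame,
) -> pd.DataFrame:
    """Stack the four response tables into one long analysis-record table.

    ``social_summary`` is the ensemble's null summary (observed strength +
    null mean per animal-network); ``spatial`` and ``hr_areas`` are the
    strength and area tables; ``fidelity`` the cross-year UDOI table (its
    ``year_pair`` fills the year column).
    """
    frames = []
    base = ["animal_id", "herd", "season"]
    for kind, df, col in [
        ("social_strength_observed", social_summary, "strength"),
        ("social_strength_null_mean", social_summary, "null_mean"),
        ("spatial_strength", spatial, "strength"),
        ("hr_area_km2", hr_areas, "hr_area_km2"),
    ]:
        sub = df[base + ["year", col]].copy()
        sub["year"] = sub["year"].astype(str)
        sub = sub.rename(columns={col: "value"})
        sub["kind"] = kind
        frames.append(sub)
    if len(fidelity):
        sub = fidelity.rename(columns={"year_pair": "year", "udoi": "value"}).copy()
        sub["kind"] = "fidelity_udoi"
        frames.append(sub[base + ["year", "value", "kind"]])
    out = pd.concat(frames, ignore_index=True)
    return out[RECORD_COLUMNS]


def _prep(records: pd.DataFrame, kind: str, offset: float | None = None):
    sub = records[records["kind"] == kind].copy()
    if sub.empty:
        raise ValueError(f"no records of kind {kind!r}")
    if offset is None:
        offset = half_min_positive(sub["value"])
    sub["value"] = log_transform(sub["value"], offset)
    return sub, offset


def run_model_suite(records: pd.DataFrame) -> dict[str, ModelFit]:
    """Fit the four seasonal mixed models to a filtered record table."""
    fits: dict[str, ModelFit] = {}

    fid, _ = _prep(records, "fidelity_udoi")
    fits["fidelity"] = fit_lmm(fid, "value ~ season")  # year col is the pair

    spa, _ = _prep(records, "spatial_strength")
    fits["spatial_strength"] = fit_lmm(spa, "value ~ season")

    obs = records[records["kind"] == "social_strength_observed"]
    nul = records[records["kind"] == "social_strength_null_mean"]
    offset = half_min_positive(pd.concat([obs["value"], nul["value"]]))
    soc = pd.concat(
        [obs.assign(source="observed"), nul.assign(source="random")],
        ignore_index=True,
    )
    soc["value"] = log_transform(soc["value"], offset)
    fits["social_strength"] = fit_lmm(soc, "value ~ season * source")

    hr, _ = _prep(records, "hr_area_km2")
    obs2, _ = _prep(records, "social_strength_observed")
    obs2 = obs2.rename(columns={"value": "social_strength"})
    merged = hr.merge(
        obs2[["animal_id", "herd", "season", "year", "social_strength"]],
        on=["animal_id", "herd", "season", "year"],
        how="inner",
    )
    fits["hr_area"] = fit_lmm(merged, "value ~ season + social_strength")
    return fits


def model_summary_table(fits: dict[str, ModelFit]) -> pd.DataFrame:
    """Flat per-term summary across the model suite (beta, SE, t, p)."""
    rows = []
    for name, fit in fits.items():
        for term, row in fit.coefficients.iterrows():
            rows.append(
                {
                    "model": name,
                    "term": term,
                    "estimate": row["estimate"],
                    "se": row["se"],
                    "t": row["t"],
                    "p": row["p"],
                    "converged": fit.converged,
                }
            )
        for comp, var in fit.variance_components.items():
            rows.append(
                {
                    "model": name,
                    "term": f"var({comp})",
                    "estimate": var,
                    "se": np.nan,
                    "t": np.nan,
                    "p": np.nan,
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)
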