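"""Data-stream permutation null for proximity-based social networks.

The null model shuffles each animal's daily movement trajectories within a
season-year: calendar days are reassigned by a uniform random permutation
per animal, while the within-day fix sequence and times of day are kept
(a fix logged at 13:00 stays at 13:00 on its new date). This preserves
every animal's space use -- so home ranges and spatial networks are
untouched -- but decouples the temporal alignment between animals, erasing
any real-time coordination. Rebuilding rounds and PBSNs on each of the
shuffled datasets yields a null distribution of graph strength per animal,
and refitting the seasonal strength model per iteration yields a null
distribution of model coefficients.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import social
from .social import ASSOCIATION_DISTANCE, NETWORK_KEYS, _sri_matrix
from .telemetry import build_rounds

GROUP_KEYS = ["animal_id", "season", "year"]


def shuffle_days(fixes: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Permute calendar days independently per animal-season-year.

    Each animal's distinct dates within a season-year are reassigned by a
    uniform random permutation; times of day and within-day fix order are
    preserved. Spatial content of every day block is untouched.
    """
    out = fixes.copy()
    ts = out["timestamp"]
    dates = ts.dt.normalize()
    new_dates = dates.copy()
    keys = [k for k in GROUP_KEYS if k in out.columns] or ["animal_id"]
    for _, idx in out.groupby(keys, sort=False).indices.items():
        days = np.sort(dates.iloc[idx].unique())
        if len(days) == 1:
            warnings.warn("single-day trajectory: shuffle is the identity", stacklevel=2)
            continue
        perm = rng.permutation(len(days))
        mapping = dict(zip(days, days[perm]))
        new_dates.iloc[idx] = dates.iloc[idx].map(mapping)
    out["timestamp"] = new_dates + (ts - dates)
    return out.sort_values(["animal_id", "timestamp"], kind="stable").reset_index(
        drop=True
    )


@dataclass
class PermutationEnsemble:
    """Null strengths from ``n_iter`` day-shuffled network rebuilds.

    ``null_strengths`` is a long table with one row per iteration x network
    x animal; ``observed`` holds the unshuffled strengths in the same
    layout (without the iteration column).
    """

    n_iter: int
    seed: int
    threshold: float
    observed: pd.DataFrame
    null_strengths: pd.DataFrame
    networks: list = field(default_factory=list, repr=False)

    def null_summary(self) -> pd.DataFrame:
        """Observed strength with its null mean and percentile bounds."""
        g = self.null_strengths.groupby(NETWORK_KEYS + ["animal_id"])["strength"]
        summary = g.agg(
            null_mean="mean",
            null_lo=lambda s: s.quantile(0.025),
            null_hi=lambda s: s.quantile(0.975),
        ).reset_index()
        return self.observed.merge(summary, on=NETWORK_KEYS + ["animal_id"])

    def coverage(self) -> float:
        """Fraction of animals whose observed strength lies inside the null
        95 % band (quantile ties count as inside)."""
        s = self.null_summary()
        inside = (s["strength"] >= s["null_lo"]) & (s["strength"] <= s["null_hi"])
        return float(inside.mean())


def _network_arrays(rounds: pd.DataFrame):
    """Precompute per-network dense arrays for fast shuffled rebuilds.

    Within one herd-season-year, a fix's round is identified by (day index,
    time-of-day slot of its round). A day permutation only remaps the day
    index, so shuffled rounds are re-derived without re-running round
    assignment.
    """
    ids = sorted(rounds["animal_id"].unique())
    a_index = {a: j for j, a in enumerate(ids)}
    rt = rounds["round_time"]
    days = np.sort(rt.dt.normalize().unique())
    d_index = {d: i for i, d in enumerate(days)}
    tods = np.sort((rt - rt.dt.normalize()).unique())
    t_index = {t: i for i, t in enumerate(tods)}
    return {
        "ids": ids,
        "n_days": len(days),
        "n_slots": len(tods),
        "animal": rounds["animal_id"].map(a_index).to_numpy(),
        "day": rt.dt.normalize().map(d_index).to_numpy(),
        "slot": (rt - rt.dt.normalize()).map(t_index).to_numpy(),
        "xy": rounds[["x", "y"]].to_numpy(float),
    }


def _strengths_for_permutation(arr: dict, day_perm: np.ndarray, threshold: float):
    """Graph strengths after remapping each animal's days by ``day_perm``.

    ``day_perm`` has shape (n_animals, n_days): row a maps animal a's day i
    to day day_perm[a, i].
    """
    n = len(arr["ids"])
    r = arr["n_days"] * arr["n_slots"]
    rounds_idx = day_perm[arr["animal"], arr["day"]] * arr["n_slots"] + arr["slot"]
    pos = np.zeros((r, n, 2))
    present = np.zeros((r, n), dtype=bool)
    pos[rounds_idx, arr["animal"]] = arr["xy"]
    present[rounds_idx, arr["animal"]] = True
    w = _sri_matrix(pos, present, threshold)
    return np.where(np.isnan(w), 0.0, w).sum(axis=1), w


def run_ensemble(
    fixes: pd.DataFrame,
    n_iter: int = 1000,
    seed: int = 0,
    threshold: float = ASSOCIATION_DISTANCE,
    tolerance: str = "5min",
    keep_networks: bool = False,
) -> PermutationEnsemble:
    """Shuffle-and-rebuild null ensemble over all herd-season-year networks.

    For each iteration every animal's days are independently permuted, the
    rounds and PBSNs of every herd-season-year are rebuilt, and per-animal
    graph strengths recorded. ``fixes`` must be season-tagged.
    """
    rounds = build_rounds(fixes, tolerance)
    networks = social.build_pbsns(rounds, threshold=threshold)
    observed = social.strength_table(networks)

    root = np.random.SeedSequence(seed)
    null_rows = []
    kept = []
    for key, sub in rounds.groupby(NETWORK_KEYS, sort=True):
        arr = _network_arrays(sub)
        n_animals, n_days = len(arr["ids"]), arr["n_days"]
        # one substream per network so networks are order-insensitive
        key_hash = zlib.crc32(repr(key).encode())
        rng = np.random.default_rng(np.random.SeedSequence((seed, key_hash)))
        for it in range(n_iter):
            perms = np.argsort(rng.random((n_animals, n_days)), axis=1)
            s, w = _strengths_for_permutation(arr, perms, threshold)
            if keep_networks:
                kept.append({"key": key, "iteration": it, "ids": arr["ids"], "sri": w})
            null_rows.append(
                pd.DataFrame(
                    {
                        "iteration": it,
                        "herd": key[0],
                        "season": key[1],
                        "year": key[2],
                        "animal_id": arr["ids"],
                        "strength": s,
                    }
                )
            )
    null_strengths = pd.concat(null_rows, ignore_index=True)
    return PermutationEnsemble(
        n_iter=n_iter,
        seed=seed,
        threshold=threshold,
        observed=observed,
        null_strengths=null_strengths,
        networks=kept,
    )


def coefficient_null(
    ensemble: PermutationEnsemble,
    min_converged: float = 0.95,
) -> dict:
    """Null distribution of the seasonal strength-model coefficients.

    The seasonal mixed model (log strength ~ season, random intercepts for
    year and animal-within-herd) is refitted to every iteration's null
    strengths; the same model on the observed strengths gives the observed
    coefficients. A term is flagged nonrandom when its observed estimate
    falls outside the empirical 95 % interval of the null draws. The log
    offset is computed once from the observed strengths and reused across
    iterations so coefficients are comparable.
    """
    from . import inference

    offset = inference.half_min_positive(
        pd.concat(
            [ensemble.observed["strength"], ensemble.null_strengths["strength"]]
        )
    )
    if offset == 0.0:  # no association anywhere: any positive offset is neutral
        offset = 1.0

    def fit_season(df: pd.DataFrame) -> dict | None:
        data = df.copy()
        data["value"] = inference.log_transform(data["strength"], offset)
        fit = inference.fit_lmm(data, "value ~ season")
        # a boundary variance component is routine; only an unfittable
        # iteration (no finite estimates) is dropped
        if fit.coefficients.empty or not np.isfinite(
            fit.coefficients["estimate"].to_numpy()
        ).all():
            return None
        return fit.coefficients["estimate"].to_dict()

    observed_fit = fit_season(ensemble.observed)
    draws: dict[str, list[float]] = {}
    dropped = 0
    for _, sub in ensemble.null_strengths.groupby("iteration", sort=True):
        coefs = fit_season(sub)
        if coefs is None:
            dropped += 1
            continue
        for term, est in coefs.items():
            draws.setdefault(term, []).append(est)
    n_ok = ensemble.n_iter - dropped
    if n_ok < min_converged * ensemble.n_iter:
        raise RuntimeError(
            f"only {n_ok}/{ensemble.n_iter} null model fits converged"
        )
    out = {}
    for term, vals in draws.items():
        vals = np.asarray(vals)
        lo, hi = np.quantile(vals, [0.025, 0.975])
        obs = observed_fit[term] if observed_fit else np.nan
        out[term] = {
            "observed": obs,
            "draws": vals,
            "ci": (float(lo), float(hi)),
            "nonrandom": bool(obs < lo or obs > hi),
        }
    return out
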