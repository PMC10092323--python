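"""Bit-score decay model fitting and residual analysis.

The decay model says the bit-score of a homolog at genetic distance t from
the focal species is S(t) = L * exp(-R*t), with expected variance
sigma^2(t) = L * (1 - exp(-R*t)) * exp(-R*t). Parameters are estimated by a
double fit on the reference trait group ("present" bristle state):

1. ordinary (optionally weighted) least squares of ln S on t gives starting
   values (L0, R0);
2. Levenberg-Marquardt nonlinear least squares on the untransformed scores
   refines them, minimising sum_i w_i (S_i - L e^{-R t_i})^2 with
   w_i = 1 - p_miss_i when weighting is on.

Fits whose estimated similarity *increases* with distance are flagged
spurious and excluded downstream. Residuals (observed - predicted; negative
means less similar than expected) are computed for all species at t below a
trust horizon (default 0.7, the largest distance represented in the
reference group) and summarised per bristle state as within-OG medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

REFERENCE_STATE = "present"
DEFAULT_MIN_SPECIES = 5
DEFAULT_T_MAX = 0.7
# reference species all closer than this cannot identify R (near-collinear design)
MIN_T_SPREAD = 0.05


@dataclass(frozen=True)
class DecayModel:
    """Exponential bit-score decay with its binomial-style variance law."""

    L: float
    R: float

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("L must be > 0")

    def predict(self, t):
        return self.L * np.exp(-self.R * np.asarray(t, dtype=float))

    def sigma(self, t):
        decay = np.exp(-self.R * np.asarray(t, dtype=float))
        return np.sqrt(np.maximum(self.L * (1.0 - decay) * decay, 0.0))


@dataclass
class FitResult:
    og_id: str
    model: DecayModel | None
    n_used: int
    start_values: tuple[float, float] | None
    converged: bool
    spurious: bool
    weighted: bool
    skip_reason: str | None = None


@dataclass
class FitOptions:
    min_species: int = DEFAULT_MIN_SPECIES
    weighted: bool = False
    reference_state: str = REFERENCE_STATE
    t_max: float = DEFAULT_T_MAX
    exclude_p_miss_over: float | None = None  # robustness option; paper's check used 0.5


class FitError(ValueError):
    pass


def fit_log_linear(t, scores, weights=None) -> tuple[float, float]:
    """Starting values from (weighted) least squares of ln(score) on t.

    Returns (L0, R0) = (exp(intercept), -slope). Raises FitError on fewer
    than 2 distinct distances or nonpositive scores.
    """
    t = np.asarray(t, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if np.any(scores <= 0):
        raise FitError("log-linear step requires strictly positive scores")
    if len(np.unique(t)) < 2:
        raise FitError("need >= 2 distinct genetic distances")
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    y = np.log(scores)
    x = np.column_stack([np.ones_like(t), t])
    wx = x * w[:, None]
    beta = np.linalg.solve(x.T @ wx, wx.T @ y)
    return float(np.exp(beta[0])), float(-beta[1])


def fit_decay(
    og_scores: pd.DataFrame,
    traits: pd.DataFrame,
    options: FitOptions | None = None,
    og_id: str = "",
) -> FitResult:
    """Double-fit the decay model on reference-state species of one orthogroup.

    ``og_scores`` needs columns species_id, bitscore (missing = absent).
    Only reference-state species with observed positive scores enter the
    fit; OGs with fewer than ``min_species`` of them are skipped (reason
    recorded), as are near-collinear designs where all reference distances
    sit within MIN_T_SPREAD of zero.
    """
    opts = options or FitOptions()
    df = og_scores.merge(
        traits[["species_id", "bristle_state", "p_miss", "dist_to_focal"]],
        on="species_id",
        how="inner",
    )
    df = df[df["bristle_state"] == opts.reference_state]
    if opts.exclude_p_miss_over is not None:
        df = df[df["p_miss"] <= opts.exclude_p_miss_over]
    df = df[df["bitscore"].notna()]
    n_nonpos = int((df["bitscore"] <= 0).sum())
    if n_nonpos:
        logger.info("%s: dropping %d nonpositive scores before fitting", og_id, n_nonpos)
        df = df[df["bitscore"] > 0]

    def skipped(reason: str) -> FitResult:
        logger.info("%s: skipped (%s)", og_id, reason)
        return FitResult(og_id, None, len(df), None, False, False, opts.weighted, reason)

    if len(df) < opts.min_species:
        return skipped(f"too-few-species ({len(df)} < {opts.min_species})")

    t = df["dist_to_focal"].to_numpy(dtype=float)
    s = df["bitscore"].to_numpy(dtype=float)
    if t.max() < MIN_T_SPREAD:
        return skipped("unidentifiable-R (all reference distances near zero)")
    w = (1.0 - df["p_miss"].to_numpy(dtype=float)) if opts.weighted else None

    try:
        L0, R0 = fit_log_linear(t, s, w)
    except FitError as exc:
        return skipped(f"log-linear failure: {exc}")

    sigma = None if w is None else 1.0 / np.sqrt(w)
    try:
        popt, _ = curve_fit(
            lambda tt, L, R: L * np.exp(-R * tt),
            t,
            s,
            p0=[L0, R0],
            sigma=sigma,
            method="lm",
            maxfev=5000,
            ftol=1e-8,
            xtol=1e-8,
        )
        converged = True
    except RuntimeError:
        return FitResult(
            og_id, None, len(df), (L0, R0), False, False, opts.weighted, "non-convergence"
        )
    L_hat, R_hat = float(popt[0]), float(popt[1])
    spurious = R_hat < 0.0 or L_hat <= 0.0
    model = DecayModel(abs(L_hat) if L_hat != 0 else 1e-12, R_hat) if not spurious else None
    if spurious:
        logger.info("%s: spurious fit (similarity increases with distance)", og_id)
    return FitResult(
        og_id,
        model,
        len(df),
        (L0, R0),
        converged,
        spurious,
        opts.weighted,
        "spurious" if spurious else None,
    )


def residuals(
    fit: FitResult,
    held_out: pd.DataFrame,
    t_max: float = DEFAULT_T_MAX,
) -> pd.DataFrame:
    """Per-species residuals (observed - predicted) at distances below t_max.

    Rows require an observed score; species at t >= t_max are excluded
    because the model is not trusted when extrapolating beyond the reference
    group's distance range. Raises on spurious or unconverged fits.
    """
    if not fit.converged or fit.spurious or fit.model is None:
        raise FitError(f"{fit.og_id}: residuals undefined for an unusable fit")
    df = held_out[held_out["bitscore"].notna()].copy()
    df = df[df["dist_to_focal"] < t_max]
    df["residual"] = df["bitscore"].astype(float) - fit.model.predict(
        df["dist_to_focal"].to_numpy(dtype=float)
    )
    out = df[["species_id", "dist_to_focal", "residual"]].rename(
        columns={"dist_to_focal": "t"}
    )
    out.insert(0, "og_id", fit.og_id)
    return out.reset_index(drop=True)


def summarize_residuals(residual_rows: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Within-OG median residual per bristle state.

    States with no contributing species in an OG yield no row (missing,
    never zero).
    """
    df = residual_rows.merge(
        traits[["species_id", "bristle_state"]], on="species_id", how="left"
    )
    df = df[np.isfinite(df["residual"])]
    g = (
        df.groupby(["og_id", "bristle_state"], observed=True)["residual"]
        .agg(median_residual="median", n_species="size")
        .reset_index()
    )
    g["og_id"] = g["og_id"].astype("string")
    g["bristle_state"] = g["bristle_state"].astype("string")
    return g


def fit_all(
    scores: pd.DataFrame,
    traits: pd.DataFrame,
    options: FitOptions | None = None,
) -> list[FitResult]:
    """Fit every orthogroup in a long scores table; never raises per-OG."""
    opts = options or FitOptions()
    return [
        fit_decay(og_df, traits, opts, og_id=str(og))
        for og, og_df in scores.groupby("og_id", observed=True, sort=True)
    ]


def residuals_all(
    fits: list[FitResult],
    scores: pd.DataFrame,
    traits: pd.DataFrame,
    t_max: float = DEFAULT_T_MAX,
) -> pd.DataFrame:
    """Residual rows for every usable fit, joined with distances."""
    merged = scores.merge(
        traits[["species_id", "dist_to_focal"]], on="species_id", how="inner"
    )
    parts = []
    by_og = dict(tuple(merged.groupby("og_id", observed=True)))
    for fit in fits:
        if not fit.converged or fit.spurious or fit.og_id not in by_og:
            continue
        parts.append(residuals(fit, by_og[fit.og_id], t_max=t_max))
    if not parts:
        return pd.DataFrame(columns=["og_id", "species_id", "t", "residual"])
    out = pd.concat(parts, ignore_index=True)
    out["og_id"] = out["og_id"].astype("string")
    out["species_id"] = out["species_id"].astype("string")
    return out


def fits_table(fits: list[FitResult]) -> pd.DataFrame:
    rows = [
        (
            f.og_id,
            f.model.L if f.model is not None else np.nan,
            f.model.R if f.model is not None else np.nan,
            f.n_used,
            f.converged,
            f.spurious,
        )
        for f in fits
    ]
    df = pd.DataFrame(rows, columns=["og_id", "L", "R", "n_used", "converged", "spurious"])
    df["og_id"] = df["og_id"].astype("string")
    df["converged"] = df["converged"].astype("boolean")
    df["spurious"] = df["spurious"].astype("boolean")
    return df


def holdout_validate(
    scores: pd.DataFrame,
    traits: pd.DataFrame,
    options: FitOptions | None = None,
    holdout_fraction: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit on a retained subset of reference species, evaluate on the held-out rest.

    A single split of the reference-state species is drawn once (seeded) and
    applied to every orthogroup. With holdout_fraction = 0 this reduces to
    fit_decay on the full reference group and returns no rows. Returns
    held-out residual rows (og_id, species_id, t, residual).
    """
    opts = options or FitOptions()
    ref = traits[traits["bristle_state"] == opts.reference_state]
    ref_ids = sorted(ref.loc[ref["dist_to_focal"] > 0, "species_id"])
    n_hold = int(round(holdout_fraction * len(ref_ids)))
    if holdout_fraction < 0 or holdout_fraction >= 1:
        raise FitError("holdout_fraction must be in [0, 1)")
    if len(ref_ids) - n_hold < opts.min_species:
        raise FitError("holdout leaves fewer reference species than min_species")
    rng = np.random.default_rng(seed)
    held = set(rng.choice(ref_ids, size=n_hold, replace=False)) if n_hold else set()

    train_scores = scores[~scores["species_id"].isin(held)]
    fits = fit_all(train_scores, traits, opts)
    eval_scores = scores[scores["species_id"].isin(held)]
    return residuals_all(fits, eval_scores, traits, t_max=opts.t_max)
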