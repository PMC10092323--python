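"""Detection-probability calculations.

Converts an E-value threshold into a bit-score threshold via the
Karlin-Altschul relation E = m*n*2^(-S') and computes, per orthogroup, the
probability that a homolog at a reference genetic distance t* scores above
that threshold: P_detect = 1 - Phi((threshold - S(t*)) / sigma(t*)) under
the fitted decay model's mean and variance laws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DetectionConfig:
    evalue_threshold: float = 0.001
    db_size: int = 853_740_050  # residues in the original search database
    t_star: float = 0.7
    p_detect_cutoff: float = 0.90

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise InvalidConfigError("evalue_threshold must be > 0")
        if self.db_size < 1:
            raise InvalidConfigError("db_size must be >= 1")
        if self.t_star <= 0:
            raise InvalidConfigError("t_star must be > 0")
        if not (0.0 < self.p_detect_cutoff < 1.0):
            raise InvalidConfigError("p_detect_cutoff must be in (0, 1)")


def bitscore_threshold(evalue: float, query_len: int, db_len: int) -> float:
    """Bit-score at which an alignment's E-value equals ``evalue``.

    threshold = log2(m * n / E); no effective-length correction is applied
    to the m*n search-space product.
    """
    if evalue <= 0:
        raise InvalidConfigError("evalue must be > 0")
    if query_len < 1 or db_len < 1:
        raise InvalidConfigError("query and database lengths must be >= 1")
    return float(np.log2(query_len) + np.log2(db_len) - np.log2(evalue))


@dataclass(frozen=True)
class DetectabilityResult:
    og_id: str
    bitscore_threshold: float
    p_detect: float
    detectable: bool


def p_detect(fit, config: DetectionConfig, query_length: int) -> DetectabilityResult:
    """Detection probability for one fitted orthogroup at distance t*.

    The score at t* is Normal(S(t*), sigma(t*)); p_detect is the mass above
    the bit-score threshold. When sigma(t*) = 0 the deterministic limit
    applies: 1 if S(t*) > threshold else 0 (equality counts as undetected).
    Raises on unconverged or spurious fits.
    """
    if not fit.converged or fit.spurious:
        raise ValueError(f"{fit.og_id}: cannot compute p_detect for an unusable fit")
    thresh = bitscore_threshold(config.evalue_threshold, query_length, config.db_size)
    mu = fit.model.predict(config.t_star)
    sd = fit.model.sigma(config.t_star)
    if sd == 0.0:
        p = 1.0 if mu > thresh else 0.0
    else:
        p = float(norm.sf((thresh - mu) / sd))
    return DetectabilityResult(
        og_id=fit.og_id,
        bitscore_threshold=thresh,
        p_detect=p,
        detectable=p > config.p_detect_cutoff,
    )


def detectability_table(
    fits, config: DetectionConfig, query_lengths: dict[str, int]
) -> pd.DataFrame:
    """Compute p_detect for every usable fit; skips unconverged/spurious OGs."""
    rows = []
    for fit in fits:
        if not fit.converged or fit.spurious:
            continue
        res = p_detect(fit, config, query_lengths[fit.og_id])
        rows.append((res.og_id, res.bitscore_threshold, res.p_detect, res.detectable))
    df = pd.DataFrame(
        rows, columns=["og_id", "threshold_bits", "p_detect", "detectable"]
    )
    df["og_id"] = df["og_id"].astype("string")
    df["detectable"] = df["detectable"].astype("boolean")
    return df


def classify(
    detectability: pd.DataFrame,
    annotations: pd.DataFrame,
    cutoff: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition OGs by detectability and report per-category detectable fractions.

    Strict rule: detectable iff p_detect > cutoff. Returns (per-OG table
    with a recomputed 'detectable' column, per-category fraction table).
    """
    df = detectability.merge(annotations[["og_id", "category"]], on="og_id", how="left")
    if cutoff is not None:
        df = df.assign(detectable=(df["p_detect"] > cutoff).astype("boolean"))
    frac = (
        df.groupby("category", observed=True)["detectable"]
        .agg(n_ogs="size", n_detectable="sum")
        .reset_index()
    )
    frac["fraction_detectable"] = frac["n_detectable"] / frac["n_ogs"]
    return df, frac
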