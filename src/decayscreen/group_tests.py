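"""Nonparametric group comparisons of per-orthogroup summaries.

Kruskal-Wallis rank-sum tests (tie-corrected, chi-square approximation) for
overall differences between bristle states, and Dwass-Steele-Critchlow-
Fligner (DSCF) all-pairs tests for post hoc contrasts: each pair is
re-ranked jointly, the Wilcoxon rank-sum statistic is standardised with the
tie-corrected variance, and sqrt(2)*|z| is referred to the studentized-range
distribution with k groups and infinite degrees of freedom. A compact
letter display summarises the alpha-level pairwise decisions: groups
sharing no letter differ significantly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import kruskal, rankdata, studentized_range

logger = logging.getLogger(__name__)


class InvalidInputError(ValueError):
    pass


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p_value: float


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float  # standardized z for group_a's rank sum
    p_value: float


def kruskal_wallis(values, groups) -> KWResult:
    """Tie-corrected Kruskal-Wallis H with the chi-square(k-1) p-value.

    When every pooled observation is identical the tie correction degenerates;
    H is defined as 0 with p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise InvalidInputError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise InvalidInputError("every group needs at least one observation")
    if np.all(values == values[0]):
        return KWResult(0.0, len(labels) - 1, 1.0)
    h, p = kruskal(*samples)
    return KWResult(float(h), len(labels) - 1, float(p))


def _srange_sf(q: float, k: int) -> float:
    """Upper tail of the studentized range with k groups, infinite df."""
    if q <= 0:
        return 1.0
    return float(studentized_range.sf(q, k, np.inf))


def _pair_z(vi: np.ndarray, vj: np.ndarray) -> float:
    """Standardized Wilcoxon rank-sum statistic for group i within the pair (i, j)."""
    ni, nj = len(vi), len(vj)
    pooled = np.concatenate([vi, vj])
    ranks = rankdata(pooled)  # mid-ranks
    w = ranks[:ni].sum()
    n = ni + nj
    mean_w = ni * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var_w = ni * nj / 12.0 * (n + 1 - tie_term)
    if var_w <= 0:
        return 0.0
    return float((w - mean_w) / np.sqrt(var_w))


def compact_letters(groups: list[str], sig_pairs: set[frozenset[str]]) -> dict[str, str]:
    """Compact letter display: groups share a letter iff not significantly different.

    Letters are maximal cliques of the non-significance graph, ordered by
    first group membership.
    """
    g = nx.Graph()
    g.add_nodes_from(groups)
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            if frozenset((a, b)) not in sig_pairs:
                g.add_edge(a, b)
    cliques = sorted(
        (sorted(c, key=groups.index) for c in nx.find_cliques(g)),
        key=lambda c: [groups.index(x) for x in c],
    )
    letters = {grp: "" for grp in groups}
    for letter_idx, clique in enumerate(cliques):
        ch = chr(ord("a") + letter_idx)
        for grp in clique:
            letters[grp] += ch
    return letters


def dscf_allpairs(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """DSCF all-pairs comparisons with a compact letter display.

    Returns one row per unordered pair: group_a, group_b, z (rank-sum
    standardisation for group_a), p (studentized-range tail at sqrt(2)|z|),
    significant, plus the letters of both groups.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [str(g) for g in pd.unique(groups)]
    k = len(labels)
    if k < 2:
        raise InvalidInputError("need at least 2 groups")
    samples = {g: values[groups == g] for g in labels}
    for g, s in samples.items():
        if len(s) < 2:
            raise InvalidInputError(f"group {g!r} has fewer than 2 observations")

    rows = []
    sig = set()
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            z = _pair_z(samples[a], samples[b])
            p = _srange_sf(np.sqrt(2.0) * abs(z), k)
            if p < alpha:
                sig.add(frozenset((a, b)))
            rows.append((a, b, z, p))
    letters = compact_letters(labels, sig)
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_value"])
    df["significant"] = df["p_value"] < alpha
    df["letters_a"] = df["group_a"].map(letters)
    df["letters_b"] = df["group_b"].map(letters)
    return df


def compare_by_state(
    per_og: pd.DataFrame,
    metric: str,
    annotations: pd.DataFrame,
    adult_biased_only: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """KW + DSCF of a per-OG metric across bristle states within each annotation category.

    ``per_og`` needs columns og_id, bristle_state and the metric column.
    Strata with fewer than 2 represented states (or all-missing metric) are
    skipped with a logged reason. Returns a tidy table with one row per
    (category, bristle-state pair) plus the stratum-level H/df/p and letters.
    """
    ann = annotations[["og_id", "category"] + (["adult_biased"] if adult_biased_only else [])]
    df = per_og.merge(ann, on="og_id", how="inner")
    if adult_biased_only:
        df = df[df["adult_biased"].fillna(False).astype(bool)]
    df = df[np.isfinite(df[metric].astype(float))]

    out_rows = []
    for cat, sub in df.groupby("category", observed=True, sort=True):
        states = sub["bristle_state"].unique()
        if len(states) < 2 or any(
            (sub["bristle_state"] == s).sum() < 2 for s in states
        ):
            logger.info("stratum %s/%s skipped: fewer than 2 usable states", cat, metric)
            continue
        vals = sub[metric].to_numpy(dtype=float)
        grps = sub["bristle_state"].to_numpy()
        kw = kruskal_wallis(vals, grps)
        pairs = dscf_allpairs(vals, grps, alpha=alpha)
        letters = {}
        for _, r in pairs.iterrows():
            letters[r["group_a"]] = r["letters_a"]
            letters[r["group_b"]] = r["letters_b"]
        for _, r in pairs.iterrows():
            out_rows.append(
                (
                    str(cat),
                    metric,
                    kw.H,
                    kw.df,
                    kw.p_value,
                    r["group_a"],
                    r["group_b"],
                    r["z"],
                    r["p_value"],
                    letters[r["group_a"]],
                    letters[r["group_b"]],
                )
            )
    return pd.DataFrame(
        out_rows,
        columns=[
            "stratum",
            "metric",
            "H",
            "df",
            "p_overall",
            "group_a",
            "group_b",
            "z",
            "p_pairwise",
            "letters_a",
            "letters_b",
        ],
    )
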