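"""Synthetic phylogenies, trait states, and orthogroup score tables.

Emulates the data-generating assumptions behind the bit-score decay
analysis: an ultrametric species tree (root depth 1) with a handful of
convergent, irreversible trait shifts (present -> reduced/absent sperm
bristles); per-orthogroup decay parameters (L, R); Gaussian bit-score noise
with the decay model's variance law sigma^2(t) = L(1-e^{-Rt})e^{-Rt};
censoring of scores below the detection threshold; and per-species assembly
dropout (BUSCO-missing proportion).

Everything is driven by a single integer seed; identical configs give
byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm

from decayscreen.detect import bitscore_threshold

BRISTLE_STATES = ("present", "reduced", "absent")
DEFAULT_CATEGORIES = ("testis", "ovary", "tail", "ubiquitous")

# Self bit-score per residue used to convert L (bits) to an implied query
# length in residues (BLOSUM62 average self-score ~5.2 raw, lambda~0.267
# nats/unit => ~2 bits per residue).
BITS_PER_RESIDUE = 2.0

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class InvalidConfigError(ValueError):
    pass


def normalize_multipliers(obj) -> dict[tuple[str, str], float]:
    """Accept rate multipliers as {(state, category): m} or nested {state: {category: m}}."""
    out: dict[tuple[str, str], float] = {}
    for key, val in (obj or {}).items():
        if isinstance(key, tuple):
            out[key] = float(val)
        elif isinstance(val, dict):
            for cat, m in val.items():
                out[(str(key), str(cat))] = float(m)
        else:
            raise InvalidConfigError(
                "rate_multipliers must map (state, category) pairs or nest state -> category"
            )
    return out


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic run.

    L is drawn log-uniformly on ``L_range`` (bits), R log-uniformly on
    ``R_range`` (per unit genetic distance). ``rate_multipliers`` maps
    (bristle_state, category) to a multiplicative factor on R applied to
    species in that state; unset pairs default to 1. ``p_miss`` per species
    is Beta(``p_miss_beta``), emulating variable transcriptome completeness.
    Genetic distances to the focal species come from the time tree with
    per-edge log-normal rate multipliers (median ``gd_rate_median``,
    log-sd ``gd_rate_sigma``), mimicking the distinction between a time
    tree and substitution-scale distances.
    """

    n_species: int = 100
    focal_species: str | None = None  # default: first simulated tip
    birth_rate: float = 1.0
    death_rate: float = 0.0
    n_trait_shifts: int = 9
    derived_states: tuple[str, ...] = ("reduced", "absent")
    L_range: tuple[float, float] = (100.0, 2000.0)
    R_range: tuple[float, float] = (0.3, 5.0)
    rate_multipliers: dict[tuple[str, str], float] = field(default_factory=dict)
    p_miss_beta: tuple[float, float] = (2.0, 8.0)
    n_ogs_per_category: dict[str, int] = field(
        default_factory=lambda: {c: 25 for c in DEFAULT_CATEGORIES}
    )
    adult_biased_prob: float = 0.5
    gd_rate_median: float = 0.3
    gd_rate_sigma: float = 0.2
    detection_censor: bool = True
    evalue_threshold: float = 0.001
    db_size: int = 853_740_050
    gap_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 4:
            raise InvalidConfigError("n_species must be >= 4")
        if self.birth_rate <= 0 or self.death_rate < 0 or self.death_rate >= self.birth_rate:
            raise InvalidConfigError("need birth_rate > 0 and 0 <= death_rate < birth_rate")
        if not (0 < self.L_range[0] <= self.L_range[1]):
            raise InvalidConfigError("L_range must be positive and ordered")
        if not (0 < self.R_range[0] <= self.R_range[1]):
            raise InvalidConfigError("R_range must be positive and ordered")
        for (state, cat), mult in self.rate_multipliers.items():
            if state not in BRISTLE_STATES:
                raise InvalidConfigError(f"unknown bristle state {state!r}")
            if mult <= 0:
                raise InvalidConfigError(f"rate multiplier for {(state, cat)} must be > 0")
        for state in self.derived_states:
            if state not in ("reduced", "absent"):
                raise InvalidConfigError("derived states must be 'reduced' or 'absent'")
        if self.n_trait_shifts < 0:
            raise InvalidConfigError("n_trait_shifts must be >= 0")

    def multiplier(self, state: str, category: str) -> float:
        return self.rate_multipliers.get((state, category), 1.0)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _stage_rng(config: SimConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per pipeline stage
    return np.random.default_rng(np.random.SeedSequence([config.seed, stage]))


def _tip_label(i: int) -> str:
    return f"sp{i + 1:03d}"


def simulate_tree(config: SimConfig) -> dendropy.Tree:
    """Constant-rate birth-death tree conditioned on n extant tips, root depth 1.

    Pure-birth when death_rate is 0 (the default); with extinction the
    simulation restarts on total extinction. Tip depths are exactly 1 after
    rescaling (the tip edges absorb any floating-point slack).
    """
    config.validate()
    rng = _stage_rng(config, 0)
    b, d = config.birth_rate, config.death_rate
    n = config.n_species

    while True:  # restart on total extinction (impossible when d == 0)
        root = dendropy.Node()
        left, right = dendropy.Node(), dendropy.Node()
        root.add_child(left)
        root.add_child(right)
        active: list[tuple[dendropy.Node, float]] = [(left, 0.0), (right, 0.0)]
        now = 0.0
        extinct = False
        while len(active) < n:
            total_rate = (b + d) * len(active)
            now += rng.exponential(1.0 / total_rate)
            idx = int(rng.integers(len(active)))
            node, born = active.pop(idx)
            node.edge.length = now - born
            if rng.random() < b / (b + d):
                c1, c2 = dendropy.Node(), dendropy.Node()
                node.add_child(c1)
                node.add_child(c2)
                active.extend([(c1, now), (c2, now)])
            elif not active:
                extinct = True
                break
        if not extinct:
            break

    now += rng.exponential(1.0 / (b * n))  # final wait so no zero-length tips
    for node, born in active:
        node.edge.length = now - born

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    extant = {id(node) for node, _ in active}
    for i, (node, _) in enumerate(active):
        node.taxon = taxa.new_taxon(label=_tip_label(i))
    if len(extant) < sum(1 for _ in tree.leaf_node_iter()):  # prune extinct lineages
        tree.prune_leaves_without_taxa(suppress_unifurcations=True)
    # rescale to root depth 1, absorbing float slack into the tip edges
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += 1.0 - leaf.distance_from_root()
    return tree


def _focal_label(tree: dendropy.Tree, config: SimConfig) -> str:
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    focal = config.focal_species if config.focal_species is not None else _tip_label(0)
    if focal not in labels:
        raise InvalidConfigError(f"focal species {focal!r} is not a tip of the tree")
    return focal


def _focal_path_nodes(tree: dendropy.Tree, focal: str) -> set[int]:
    node = next(
        leaf for leaf in tree.leaf_node_iter() if leaf.taxon.label == focal
    )
    path = set()
    while node is not None:
        path.add(id(node))
        node = node.parent_node
    return path


def assign_traits(tree: dendropy.Tree, config: SimConfig) -> pd.DataFrame:
    """Place convergent, irreversible present->derived shifts and build the trait table.

    Shift edges are sampled without replacement from non-root edges off the
    focal lineage, rejecting edges nested inside (or containing) an already
    chosen one, so each derived clade is maximal and monophyletic. Distances
    to the focal species are patristic distances on an auxiliary
    substitutions tree (each edge times a log-normal rate). Columns:
    species_id, bristle_state, p_miss, dist_to_focal, weight.
    """
    config.validate()
    rng = _stage_rng(config, 1)
    focal = _focal_label(tree, config)
    focal_path = _focal_path_nodes(tree, focal)

    edges = [
        e
        for e in tree.preorder_edge_iter()
        if e.head_node is not tree.seed_node
        and id(e.head_node) not in focal_path
        and not e.head_node.is_leaf()  # shifts on internal edges: derived clades >= 2 tips
    ]
    n_internal_edges = len(edges)
    if config.n_trait_shifts > n_internal_edges:
        raise InvalidConfigError(
            f"{config.n_trait_shifts} trait shifts requested but only "
            f"{n_internal_edges} internal off-focal edges available"
        )

    def clade_tips(node) -> frozenset[str]:
        return frozenset(l.taxon.label for l in node.leaf_iter())

    chosen: list[frozenset[str]] = []
    states: list[str] = []
    order = rng.permutation(len(edges))
    for idx in order:
        if len(chosen) == config.n_trait_shifts:
            break
        tips = clade_tips(edges[idx].head_node)
        if any(tips <= c or c <= tips for c in chosen):
            continue
        chosen.append(tips)
        states.append(config.derived_states[int(rng.integers(len(config.derived_states)))])
    if len(chosen) < config.n_trait_shifts:
        raise InvalidConfigError(
            "could not place the requested number of non-nested trait shifts"
        )

    state_of = {leaf.taxon.label: "present" for leaf in tree.leaf_node_iter()}
    for tips, st in zip(chosen, states):
        for sp in tips:
            state_of[sp] = st

    # substitutions tree: each edge times an independent log-normal rate
    subs = {}  # tip label -> patristic distance to focal
    rates = {}
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            rates[id(edge)] = config.gd_rate_median * np.exp(
                config.gd_rate_sigma * rng.standard_normal()
            )
    pdm_tree = tree.clone(depth=1)
    for orig, clone in zip(tree.preorder_edge_iter(), pdm_tree.preorder_edge_iter()):
        if clone.length is not None:
            clone.length = orig.length * rates[id(orig)]
    pdm = pdm_tree.phylogenetic_distance_matrix()
    focal_taxon = next(
        t for t in pdm_tree.taxon_namespace if t.label == focal
    )
    for taxon in pdm_tree.taxon_namespace:
        subs[taxon.label] = 0.0 if taxon is focal_taxon else pdm.patristic_distance(
            focal_taxon, taxon
        )

    labels = sorted(state_of)
    a, bshape = config.p_miss_beta
    p_miss = {lab: float(rng.beta(a, bshape)) for lab in labels}
    p_miss[focal] = 0.0
    df = pd.DataFrame(
        {
            "species_id": pd.array(labels, dtype="string"),
            "bristle_state": pd.array([state_of[l] for l in labels], dtype="string"),
            "p_miss": [p_miss[l] for l in labels],
            "dist_to_focal": [subs[l] for l in labels],
        }
    )
    df["weight"] = 1.0 - df["p_miss"]
    return df


def _og_params(config: SimConfig, rng: np.random.Generator):
    """Yield (og_id, category, L, R, focal_len, adult_biased) deterministically."""
    i = 0
    for category in sorted(config.n_ogs_per_category):
        for _ in range(config.n_ogs_per_category[category]):
            i += 1
            lo, hi = config.L_range
            L = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            lo, hi = config.R_range
            R = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            focal_len = max(1, round(L / BITS_PER_RESIDUE))
            adult = bool(rng.random() < config.adult_biased_prob)
            yield f"OG{i:05d}", category, L, R, focal_len, adult


def decay_mean_sd(L: float, R: float, t: float) -> tuple[float, float]:
    """Expected bit-score and its standard deviation at genetic distance t."""
    decay = np.exp(-R * t)
    mu = L * decay
    var = L * (1.0 - decay) * decay
    return float(mu), float(np.sqrt(max(var, 0.0)))


def simulate_og_scores(
    tree: dendropy.Tree, traits: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate per-orthogroup bit-score tables under the decay model.

    Returns (scores, annotations, truth). Scores has one row per (OG,
    species); absent species carry a missing bitscore. Absence arises from
    assembly dropout (probability p_miss), censoring below the detection
    threshold (when enabled), and truncation of non-positive draws. The
    focal species is always present at score L. The truth table records
    every drawn parameter for recovery tests.
    """
    config.validate()
    if set(traits["species_id"]) != {l.taxon.label for l in tree.leaf_node_iter()}:
        raise InvalidConfigError("trait table does not cover the tree tips exactly")
    rng = _stage_rng(config, 2)
    focal = _focal_label(tree, config)

    sp = traits.sort_values("species_id")
    species = sp["species_id"].tolist()
    state = dict(zip(sp["species_id"], sp["bristle_state"]))
    tdist = dict(zip(sp["species_id"], sp["dist_to_focal"]))
    pmiss = dict(zip(sp["species_id"], sp["p_miss"]))

    score_rows, ann_rows, truth_rows = [], [], []
    for og_id, category, L, R, focal_len, adult in _og_params(config, rng):
        thresh = bitscore_threshold(config.evalue_threshold, focal_len, config.db_size)
        ann_rows.append((og_id, category, adult, focal_len))
        truth_rows.append(
            (
                og_id,
                category,
                L,
                R,
                focal_len,
                config.multiplier("present", category),
                config.multiplier("reduced", category),
                config.multiplier("absent", category),
            )
        )
        for s in species:
            if s == focal:
                score_rows.append((og_id, s, L))
                continue
            r_i = R * config.multiplier(str(state[s]), category)
            mu, sd = decay_mean_sd(L, r_i, tdist[s])
            obs = mu + sd * rng.standard_normal()
            dropped = rng.random() < pmiss[s]
            if obs <= 0.0 or dropped or (config.detection_censor and obs < thresh):
                score_rows.append((og_id, s, np.nan))
            else:
                score_rows.append((og_id, s, obs))

    scores = pd.DataFrame(score_rows, columns=["og_id", "species_id", "bitscore"])
    scores["og_id"] = scores["og_id"].astype("string")
    scores["species_id"] = scores["species_id"].astype("string")
    annotations = pd.DataFrame(
        ann_rows, columns=["og_id", "category", "adult_biased", "focal_len"]
    )
    annotations["og_id"] = annotations["og_id"].astype("string")
    annotations["category"] = annotations["category"].astype("string")
    annotations["adult_biased"] = annotations["adult_biased"].astype("boolean")
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "og_id",
            "category",
            "L",
            "R",
            "focal_len",
            "mult_present",
            "mult_reduced",
            "mult_absent",
        ],
    )
    truth["og_id"] = truth["og_id"].astype("string")
    truth["category"] = truth["category"].astype("string")
    return scores, annotations, truth


def uniform_rate_matrix(n_states: int = 20) -> np.ndarray:
    """Uniform-exchangeability rate matrix normalised to 1 substitution/site/unit."""
    q = np.ones((n_states, n_states)) / (n_states - 1)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _edge_state(edge, state_of: dict[str, str]) -> str:
    tips = {state_of[l.taxon.label] for l in edge.head_node.leaf_iter()}
    return tips.pop() if len(tips) == 1 else "present"


def simulate_og_alignments(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    config: SimConfig,
    rate_matrix: np.ndarray | None = None,
) -> tuple[dict[str, dict[str, str]], pd.DataFrame]:
    """Simulate gapped amino-acid alignments, one per orthogroup.

    Sites evolve independently under ``rate_matrix`` (default: uniform
    exchangeability over the 20 amino acids, equal frequencies). Each edge's
    substitution length is its time length times the OG's decay-rate draw
    times the trait multiplier for the edge's state. Non-focal residues are
    gapped out with probability ``gap_prob``; the focal sequence is ungapped.
    Returns ({og_id: {species: aligned_seq}}, params table).
    """
    config.validate()
    rng = _stage_rng(config, 3)
    focal = _focal_label(tree, config)
    q = uniform_rate_matrix() if rate_matrix is None else rate_matrix
    n_states = q.shape[0]
    state_of = dict(zip(traits["species_id"], traits["bristle_state"]))

    alignments: dict[str, dict[str, str]] = {}
    rows = []
    for og_id, category, L, R, focal_len, adult in _og_params(config, rng):
        n_sites = min(focal_len, 2000)  # cap alignment width for tractability
        root_seq = rng.integers(n_states, size=n_sites)
        seqs: dict[str, np.ndarray] = {}

        def evolve(node, seq):
            for child in node.child_nodes():
                st = _edge_state(child.edge, state_of)
                blen = child.edge.length * R * config.multiplier(str(st), category)
                if blen <= 0:
                    child_seq = seq.copy()
                else:
                    p = expm(q * blen)
                    cum = np.cumsum(p, axis=1)
                    u = rng.random(len(seq))
                    child_seq = np.array(
                        [np.searchsorted(cum[s], x) for s, x in zip(seq, u)]
                    )
                if child.is_leaf():
                    seqs[child.taxon.label] = child_seq
                else:
                    evolve(child, child_seq)

        evolve(tree.seed_node, root_seq)
        og_aln = {}
        for sp_label in sorted(seqs):
            chars = [AMINO_ACIDS[s % 20] for s in seqs[sp_label]]
            if sp_label != focal and config.gap_prob > 0:
                mask = rng.random(n_sites) < config.gap_prob
                chars = ["-" if m else c for c, m in zip(chars, mask)]
            og_aln[sp_label] = "".join(chars)
        alignments[og_id] = og_aln
        rows.append((og_id, category, L, R, focal_len, adult))

    params = pd.DataFrame(
        rows, columns=["og_id", "category", "L", "R", "focal_len", "adult_biased"]
    )
    return alignments, params
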