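"""End-to-end orchestration: simulate -> fit -> detect -> regress -> test -> report.

A single integer seed controls the whole run; stage-level seeds are derived
deterministically from it, so re-running with the same config gives
byte-identical outputs. Every stage consumes only the declared upstream
tables (the dialects defined in decayscreen.io) and per-OG skip reasons are
logged at INFO, because those filters (too-few-species, spurious,
all-present) are themselves results worth auditing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from decayscreen import __version__, io
from decayscreen.decay import FitOptions, fit_all, fits_table, residuals_all, summarize_residuals
from decayscreen.detect import DetectionConfig, classify, detectability_table
from decayscreen.group_tests import compare_by_state
from decayscreen.presence import (
    MCMCConfig,
    build_covariance,
    call_candidates,
    fit_presence_all,
    presence_fits_table,
)
from decayscreen.synthetic import (
    SimConfig,
    assign_traits,
    normalize_multipliers,
    simulate_og_scores,
    simulate_tree,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "fit", "detect", "regress", "test", "report")


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    min_species: int = 5
    t_max: float = 0.7
    weighted: bool = False
    exclude_p_miss_over: float | None = None
    evalue: float = 0.001
    db_size: int = 853_740_050
    t_star: float = 0.7
    p_detect_cutoff: float = 0.90
    mcmc_iterations: int = 13_000
    mcmc_burn_in: int = 3_000
    mcmc_thin: int = 10
    alpha: float = 0.05

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        idx = ALL_STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0] % (2**31))


def _config_hash(config: RunConfig) -> str:
    d = asdict(config)
    if "rate_multipliers" in d.get("sim", {}):
        d["sim"]["rate_multipliers"] = sorted(
            (list(k), v) for k, v in d["sim"]["rate_multipliers"].items()
        )
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in dependency order under ``config.out_dir``.

    Returns the run directory. Any stage failure writes a FAILED marker
    naming the stage and re-raises; completed outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": list(config.stages),
        "row_counts": {},
    }
    current_stage = "init"

    def table_out(df: pd.DataFrame, name: str, schema: str | None = None) -> None:
        io.write_table(df, out / f"{name}.tsv", schema)
        manifest["row_counts"][name] = int(len(df))

    try:
        if "simulate" in config.stages:
            current_stage = "simulate"
            sim_kwargs = {"seed": config.stage_seed("simulate"), **config.sim}
            if "rate_multipliers" in sim_kwargs:
                sim_kwargs["rate_multipliers"] = normalize_multipliers(
                    sim_kwargs["rate_multipliers"]
                )
            sim = SimConfig(**sim_kwargs)
            tree = simulate_tree(sim)
            io.write_tree(tree, out / "tree.nwk")
            traits = assign_traits(tree, sim)
            scores, annotations, truth = simulate_og_scores(tree, traits, sim)
            table_out(traits.drop(columns=["weight"]), "traits", "traits")
            table_out(scores, "scores", "scores")
            table_out(annotations, "annotations", "annotations")
            table_out(truth, "truth", "truth")

        needs_inputs = set(config.stages) & {"fit", "detect", "regress", "test", "report"}
        if needs_inputs:
            traits = io.read_table(out / "traits.tsv", "traits")
            traits["weight"] = 1.0 - traits["p_miss"]
            scores = io.read_table(out / "scores.tsv", "scores")
            annotations = io.read_table(out / "annotations.tsv", "annotations")

        if "fit" in config.stages:
            current_stage = "fit"
            opts = FitOptions(
                min_species=config.min_species,
                weighted=config.weighted,
                t_max=config.t_max,
                exclude_p_miss_over=config.exclude_p_miss_over,
            )
            fits = fit_all(scores, traits, opts)
            table_out(fits_table(fits), "fits", "fits")
            resid = residuals_all(fits, scores, traits, t_max=config.t_max)
            table_out(resid, "residuals", "residuals")
            table_out(
                summarize_residuals(resid, traits), "residual_summaries", "residual_summaries"
            )

        if "detect" in config.stages:
            current_stage = "detect"
            if "fit" not in config.stages:
                fits = _fits_from_table(io.read_table(out / "fits.tsv", "fits"))
            dconf = DetectionConfig(
                evalue_threshold=config.evalue,
                db_size=config.db_size,
                t_star=config.t_star,
                p_detect_cutoff=config.p_detect_cutoff,
            )
            qlen = dict(zip(annotations["og_id"], annotations["focal_len"]))
            detect = detectability_table(fits, dconf, qlen)
            table_out(detect, "detectability", "detectability")

        if "regress" in config.stages:
            current_stage = "regress"
            tree = io.read_tree(out / "tree.nwk")
            detect = io.read_table(out / "detectability.tsv", "detectability")
            cov = build_covariance(tree)
            detectable = sorted(detect.loc[detect["detectable"].fillna(False), "og_id"])
            mc = MCMCConfig(
                iterations=config.mcmc_iterations,
                burn_in=config.mcmc_burn_in,
                thin=config.mcmc_thin,
                seed=config.stage_seed("regress"),
            )
            pfits = fit_presence_all(scores, traits, cov, detectable, mc, t_max=config.t_max)
            table_out(presence_fits_table(pfits), "presence_fits", "presence_fits")
            table_out(call_candidates(pfits), "candidates")

        if "test" in config.stages:
            current_stage = "test"
            summaries = io.read_table(out / "residual_summaries.tsv", "residual_summaries")
            pfits_df = io.read_table(out / "presence_fits.tsv", "presence_fits")
            parts = [
                compare_by_state(
                    summaries, "median_residual", annotations, alpha=config.alpha
                ),
                compare_by_state(
                    pfits_df[pfits_df["fitted"].fillna(False)],
                    "post_mean",
                    annotations,
                    alpha=config.alpha,
                ),
            ]
            table_out(pd.concat(parts, ignore_index=True), "group_tests")

        if "report" in config.stages:
            current_stage = "report"
            _write_report(out, config)
            manifest["row_counts"]["report"] = int(
                len(pd.read_csv(out / "report.tsv", sep="\t"))
            )
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={current_stage}\nreason={exc}\n")
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def _fits_from_table(df: pd.DataFrame):
    from decayscreen.decay import DecayModel, FitResult

    fits = []
    for _, r in df.iterrows():
        usable = bool(r["converged"]) and not bool(r["spurious"]) and np.isfinite(r["L"])
        fits.append(
            FitResult(
                og_id=str(r["og_id"]),
                model=DecayModel(float(r["L"]), float(r["R"])) if usable else None,
                n_used=int(r["n_used"]),
                start_values=None,
                converged=bool(r["converged"]),
                spurious=bool(r["spurious"]),
                weighted=False,
            )
        )
    return fits


def _write_report(out: Path, config: RunConfig) -> None:
    """Consolidated report: detectable fractions, per-state residual medians, tests."""
    rows = []
    annotations = io.read_table(out / "annotations.tsv", "annotations")
    if (out / "detectability.tsv").exists():
        detect = io.read_table(out / "detectability.tsv", "detectability")
        _, frac = classify(detect, annotations)
        for _, r in frac.iterrows():
            rows.append(
                ("detectability", str(r["category"]), "fraction_detectable", r["fraction_detectable"])
            )
    if (out / "fits.tsv").exists():
        fits = io.read_table(out / "fits.tsv", "fits")
        n_conv = int(fits["converged"].fillna(False).sum())
        rows.append(("fits", "all", "n_converged", float(n_conv)))
        rows.append(("fits", "all", "n_spurious", float(fits["spurious"].fillna(False).sum())))
    if (out / "residual_summaries.tsv").exists():
        summ = io.read_table(out / "residual_summaries.tsv", "residual_summaries")
        merged = summ.merge(annotations[["og_id", "category"]], on="og_id")
        med = merged.groupby(["category", "bristle_state"], observed=True)[
            "median_residual"
        ].median()
        for (cat, st), v in med.items():
            rows.append(("median_residual", f"{cat}/{st}", "median_of_og_medians", float(v)))
    if (out / "group_tests.tsv").exists():
        gt = pd.read_csv(out / "group_tests.tsv", sep="\t")
        for (stratum, metric), sub in gt.groupby(["stratum", "metric"]):
            rows.append((f"kw_{metric}", str(stratum), "p_overall", float(sub["p_overall"].iloc[0])))
    if (out / "candidates.tsv").exists():
        cand = pd.read_csv(out / "candidates.tsv", sep="\t")
        rows.append(("candidates", "all", "n_candidates", float(cand["candidate"].sum())))
    report = pd.DataFrame(rows, columns=["section", "stratum", "key", "value"])
    report.to_csv(out / "report.tsv", sep="\t", index=False, float_format="%.10g")
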