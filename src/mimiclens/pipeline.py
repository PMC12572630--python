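"""End-to-end orchestration of the two analysis channels.

One config drives: synthetic specimen generation -> feature extraction ->
taxon similarity (S, Q, heatmap ordering, sympatric and all-pair Sankey
flows) -> 3D SNE embedding -> simulated survey (design, cohort, screening,
mean scores) -> cross-channel comparison.  A single master seed is fanned
out to per-stage substreams, and every tabular output embeds the config
hash so that reruns are verifiably byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from . import similarity as sim
from . import survey as surv
from .embedding import run_embedding
from .feature_extraction import (MorphometricExtractor, TrainerConfig,
                                 extract_features, split_dataset,
                                 train_extractor, evaluate_robustness)
from .synthetic_wings import generate_dataset, load_templates
from .taxa import default_templates

__all__ = ["PipelineConfig", "run_pipeline", "compare_channels",
           "latent_similarity_from_templates", "ChannelComparison"]

log = logging.getLogger("mimiclens")

_STAGES = ("data", "features", "similarity", "embedding", "survey", "report")


@dataclass
class PipelineConfig:
    templates_path: str | None = None   # None -> builtin 18-taxon system
    n_per_taxon: int = 5
    image_size: int = 256
    backend: str = "morphometric"       # morphometric | swav-mini
    feature_dim: int | None = None      # None -> backend native dimension
    split_ratios: tuple[float, float, float] = (8.0, 1.0, 1.0)
    embed_dim: int = 3
    embed_iters: int = 500
    embed_variant: str = "gaussian"
    n_respondents: int = 50
    noise_sd: float = 1.0
    careless_rate: float = 0.1
    n_control_sets: int = 1
    n_similar_sets: int = 2
    contradiction_threshold: int = 4
    swav: dict = field(default_factory=dict)   # TrainerConfig overrides
    out_dir: str = "mimiclens_out"
    seed: int = 0

    def __post_init__(self):
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        if self.backend not in ("morphometric", "swav-mini"):
            raise ValueError(f"unknown backend {self.backend!r}")

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths are execution details and
        are excluded, so reruns into different directories compare equal)."""
        d = asdict(self)
        d.pop("out_dir")
        d.pop("templates_path")
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _stage_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(_STAGES))
    return {name: int(c.generate_state(1)[0] % (2**31))
            for name, c in zip(_STAGES, children)}


def latent_similarity_from_templates(templates) -> dict[tuple[str, str], float]:
    """Cohort latent similarity for every mimic-model pair, set from the
    distance between the taxa's wing-pattern parameters.

    Distance mixes the white-spot count gap (dominant, as in the real
    system), the spot-size gap and the ground-colour gap; it maps onto the
    1-10 Likert scale with 10 = parameter-identical.
    """
    mimics = [t for t in templates if t.group == "mimic"]
    models = [t for t in templates if t.group == "model"]
    latent = {}
    for a in mimics:
        for b in models:
            d_spots = abs(a.n_white_spots - b.n_white_spots) / 4.0
            d_size = min(abs(a.spot_size - b.spot_size) / 0.08, 1.0)
            d_col = np.linalg.norm(np.subtract(a.ground_color, b.ground_color)) / 40.0
            dist = 0.6 * d_spots + 0.2 * d_size + 0.2 * min(d_col, 1.0)
            latent[(a.taxon_id, b.taxon_id)] = float(np.clip(
                1.0 + 9.0 * (1.0 - dist), 1.0, 10.0))
    return latent


@dataclass
class ChannelComparison:
    pairs: list[tuple[str, str]]
    computer_values: list[float]
    survey_values: list[float]
    spearman_rho: float


def compare_channels(flow_table: pd.DataFrame,
                     score_table: pd.DataFrame) -> ChannelComparison:
    """Spearman rank agreement between the computer-channel flow widths and
    the survey mean scores over their common mimic-model pairs."""
    merged = flow_table.merge(score_table, on=["mimic_taxon", "model_taxon"])
    if len(merged) < 3:
        raise ValueError(f"need >= 3 common pairs, got {len(merged)}")
    rho = float(spearmanr(merged["width"], merged["mean_score"]).statistic)
    return ChannelComparison(
        pairs=list(zip(merged["mimic_taxon"], merged["model_taxon"])),
        computer_values=merged["width"].tolist(),
        survey_values=merged["mean_score"].tolist(),
        spearman_rho=rho)


def _plot_heatmap(S: pd.DataFrame, order: list[str], path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    So = S.loc[order, order]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(So.to_numpy(), cmap="viridis", vmin=-1, vmax=1)
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=6)
    ax.set_yticks(range(len(order)), order, fontsize=6)
    fig.colorbar(im, label="cosine similarity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_embedding(coords: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 5))
    for taxon, grp in coords.groupby("taxon_id"):
        ax.scatter(grp["y1"], grp["y2"], label=taxon, s=14)
    ax.set_xlabel("y1")
    ax.set_ylabel("y2")
    ax.legend(fontsize=5, ncols=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str, **kw) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, float_format="%.12g", lineterminator="\n", **kw)


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run both channels end-to-end; returns {artifact name: file path}.

    Re-running with an identical config reproduces byte-identical tabular
    outputs.  Any stage failure aborts with the stage name in the message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    h = config.config_hash()
    artifacts: dict[str, str] = {}
    stage = "setup"
    t_all = time.time()
    try:
        # ---------------- data ------------------------------------------
        stage = "data"
        t0 = time.time()
        templates = (load_templates(config.templates_path)
                     if config.templates_path else default_templates())
        images, manifest = generate_dataset(
            templates, config.n_per_taxon, seed=seeds["data"],
            out_dir=out / "images", size=config.image_size)
        _write_csv(manifest, out / "manifest.csv", h, index=False)
        artifacts["manifest"] = str(out / "manifest.csv")
        log.info("stage data: %d images, %d taxa (%.1fs)",
                 len(images), len(templates), time.time() - t0)

        # ---------------- features --------------------------------------
        stage = "features"
        t0 = time.time()
        if config.backend == "morphometric":
            extractor = MorphometricExtractor()
        else:
            tc = TrainerConfig(seed=seeds["features"], **config.swav)
            extractor = train_extractor(images, tc)
        features = extract_features(images, extractor, D=config.feature_dim)
        _write_csv(features, out / "features.csv", h)
        artifacts["features"] = str(out / "features.csv")
        labels = manifest.set_index("specimen_id")["taxon_id"]
        split = split_dataset(manifest, config.split_ratios,
                              seed=seeds["features"])
        robustness = (evaluate_robustness(features, labels, split)
                      if split.test else float("nan"))
        log.info("stage features: %s -> %d dims, robustness %.3f (%.1fs)",
                 config.backend, features.shape[1], robustness,
                 time.time() - t0)

        # ---------------- similarity ------------------------------------
        stage = "similarity"
        t0 = time.time()
        profiles = sim.taxon_mean_features(features, manifest)
        S = sim.cosine_similarity_matrix(profiles)
        Q = sim.flow_transform(S)
        _write_csv(S, out / "similarity_S.csv", h)
        _write_csv(Q, out / "flow_Q.csv", h)
        _, leaf_order = sim.hierarchical_order(S)
        _write_csv(pd.DataFrame({"taxon_id": leaf_order}),
                   out / "heatmap_order.csv", h, index=False)
        groups = dict(zip(manifest["taxon_id"], manifest["group"]))
        sympatry = sim.sympatry_matrix({t.taxon_id: t.regions
                                        for t in templates})
        flows_sym = sim.sankey_flows(Q, groups, sympatry, "sympatric_only")
        flows_all = sim.sankey_flows(Q, groups, sympatry, "all_pairs")
        for name, fl in (("sympatric", flows_sym), ("all", flows_all)):
            p = out / f"flows_{name}.tsv"
            with open(p, "w") as fh:
                fh.write(f"# config_hash={h}\n")
                fl.to_csv(fh, sep="\t", index=False, float_format="%.12g",
                          lineterminator="\n")
            sim.flows_to_sankey_json(fl, out / f"sankey_{name}.json")
            artifacts[f"flows_{name}"] = str(p)
            artifacts[f"sankey_{name}"] = str(out / f"sankey_{name}.json")
        artifacts["similarity_S"] = str(out / "similarity_S.csv")
        artifacts["flow_Q"] = str(out / "flow_Q.csv")
        artifacts["heatmap_order"] = str(out / "heatmap_order.csv")
        log.info("stage similarity: %d taxa, %d sympatric flows (%.1fs)",
                 len(S), len(flows_sym), time.time() - t0)

        # ---------------- embedding -------------------------------------
        stage = "embedding"
        t0 = time.time()
        emb = run_embedding(features.to_numpy(), d=config.embed_dim,
                            n_iter=config.embed_iters,
                            variant=config.embed_variant,
                            seed=seeds["embedding"])
        coords = pd.DataFrame(
            emb.coordinates, index=features.index,
            columns=[f"y{i + 1}" for i in range(config.embed_dim)])
        coords.insert(0, "taxon_id", labels.reindex(coords.index))
        _write_csv(coords, out / "embedding.csv", h)
        _write_csv(pd.DataFrame({"iteration": np.arange(len(emb.kl_trace)),
                                 "kl": emb.kl_trace}),
                   out / "kl_trace.csv", h, index=False)
        artifacts["embedding"] = str(out / "embedding.csv")
        artifacts["kl_trace"] = str(out / "kl_trace.csv")
        log.info("stage embedding: n=%d, final KL %.4f (%.1fs)",
                 len(coords), emb.kl_trace[-1], time.time() - t0)

        # ---------------- survey ----------------------------------------
        stage = "survey"
        t0 = time.time()
        latent = latent_similarity_from_templates(templates)
        design = surv.design_questionnaire(
            sorted(latent), n_control_sets=config.n_control_sets,
            n_similar_sets=config.n_similar_sets, seed=seeds["survey"])
        model = surv.RespondentModel(latent_similarity=latent,
                                     noise_sd=config.noise_sd,
                                     careless_rate=config.careless_rate,
                                     seed=seeds["survey"])
        responses, careless = surv.simulate_responses(
            design, model, config.n_respondents)
        valid, report = surv.validate_responses(
            responses, design, config.contradiction_threshold)
        scores = surv.score_pairs(valid, design)
        _write_csv(responses, out / "survey_responses.csv", h, index=False)
        _write_csv(report.per_respondent, out / "survey_validation.csv", h)
        _write_csv(scores, out / "survey_scores.csv", h, index=False)
        with open(out / "survey_summary.json", "w") as fh:
            json.dump({"config_hash": h, **report.summary(),
                       "planted_careless": int(careless.sum())},
                      fh, indent=1, sort_keys=True)
        artifacts.update({
            "survey_responses": str(out / "survey_responses.csv"),
            "survey_validation": str(out / "survey_validation.csv"),
            "survey_scores": str(out / "survey_scores.csv"),
            "survey_summary": str(out / "survey_summary.json")})
        log.info("stage survey: %d collected, %d valid (%.1fs)",
                 report.collected, report.valid, time.time() - t0)

        # ---------------- report ----------------------------------------
        stage = "report"
        _plot_heatmap(S, leaf_order, out / "heatmap.png")
        _plot_embedding(coords, out / "embedding_scatter.png")
        artifacts["heatmap_png"] = str(out / "heatmap.png")
        artifacts["embedding_png"] = str(out / "embedding_scatter.png")
        comp = compare_channels(flows_all, scores)
        summary = {
            "config_hash": h,
            "n_taxa": len(S),
            "n_specimens": int(len(manifest)),
            "robustness": None if np.isnan(robustness) else round(robustness, 6),
            "channel_spearman_rho": round(comp.spearman_rho, 6),
            "survey_collected": report.collected,
            "survey_valid": report.valid,
            "final_kl": round(float(emb.kl_trace[-1]), 6),
        }
        with open(out / "report.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        artifacts["report"] = str(out / "report.json")
        log.info("pipeline complete: %d artifacts (%.1fs total)",
                 len(artifacts), time.time() - t_all)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return artifacts
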