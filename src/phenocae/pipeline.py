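"""End-to-end synthetic study pipeline and latent-configuration sweeps.

``run_pipeline`` chains every stage — simulate (or ingest), preprocess,
train CAE and vanilla AE, extract latents, compute vegetation indices,
disentanglement report, yield reports — writing each artifact plus the
resolved configuration next to the outputs so any report is reproducible
from its sidecar config and seed. One pipeline run handles exactly one
timepoint; multi-timepoint studies are multiple runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import imaging
from .cae import GroupLayout, LatentConfig, build_groups, save_checkpoint
from .disentangle import disentanglement_report
from .synthetic import SimulationConfig, SyntheticDataset, simulate_dataset, write_dataset
from .training import (TrainingConfig, extract_ae_latents, extract_latents,
                       latent_columns, train_ae, train_cae)
from .vegindex import vi_feature_table
from .yieldeval import experiment1, experiment2, experiment3

log = logging.getLogger("phenocae")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    latent: LatentConfig = field(default_factory=LatentConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    clip_k: float = 3.0
    run_disentanglement: bool = True
    run_yield: bool = True
    write_images: bool = False
    rank_fractions: tuple[float, ...] = (0.25, 0.5)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "sim" in raw and isinstance(raw["sim"], dict):
            sim = dict(raw["sim"])
            if "true_dims" in sim:
                sim["true_dims"] = tuple(sim["true_dims"])
            raw["sim"] = SimulationConfig(**sim)
        if "latent" in raw and isinstance(raw["latent"], dict):
            raw["latent"] = LatentConfig(**raw["latent"])
        if "training" in raw and isinstance(raw["training"], dict):
            raw["training"] = TrainingConfig(**raw["training"])
        if "rank_fractions" in raw:
            raw["rank_fractions"] = tuple(raw["rank_fractions"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=float))


def preprocess_dataset(dataset: SyntheticDataset, clip_k: float = 3.0):
    """Clip/normalize the dataset and return the pieces later stages need."""
    normalized, pre_stats, post_stats = imaging.preprocess(dataset.images, k=clip_k)
    clipped = imaging.clip_outliers(dataset.images, stats=pre_stats, k=clip_k)
    features = imaging.feature_matrix(normalized)
    return normalized, clipped, features, pre_stats, post_stats


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 dataset: SyntheticDataset | None = None) -> dict:
    """Execute every stage; returns a dictionary of the report payloads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)

    def stage(name):
        log.info("pipeline stage: %s", name)

    try:
        stage("simulate")
        if dataset is None:
            dataset = simulate_dataset(config.sim)
        timepoints = set(dataset.metadata["timepoint"].astype(str))
        if len(timepoints) > 1:
            raise ValueError(f"one run handles one timepoint, found {sorted(timepoints)}")
        if config.write_images:
            write_dataset(dataset, out / "dataset")
        else:
            dataset.metadata.to_csv(out / "metadata.csv", index=False)
            dataset.yields.to_csv(out / "yields.csv", index=False)

        stage("preprocess")
        _, clipped, features, pre_stats, post_stats = preprocess_dataset(
            dataset, clip_k=config.clip_k)

        stage("train")
        layout = GroupLayout(config.sim.n_environments, config.sim.n_replicates_per_env)
        grouped = build_groups(features, dataset.metadata, layout)
        if grouped.dropped_genotypes:
            log.warning("dropped incomplete genotype groups: %s", grouped.dropped_genotypes)
        cae_model, cae_history = train_cae(grouped, config.latent, layout, config.training)
        ae_model, ae_history = train_ae(features, config.latent, config.training)
        cae_history.to_csv(out / "cae_history.csv", index=False)
        ae_history.to_csv(out / "ae_history.csv", index=False)
        extra = {"channel_stats_mean": pre_stats.mean.tolist(),
                 "channel_stats_sd": pre_stats.sd.tolist(),
                 "clip_k": config.clip_k}
        save_checkpoint(cae_model, out / "cae.ckpt.npz", extra=extra)
        save_checkpoint(ae_model, out / "ae.ckpt.npz", extra=extra)

        stage("extract")
        cae_latents = extract_latents(cae_model, grouped)
        ae_latents = extract_ae_latents(ae_model, features, dataset.metadata)
        cae_latents.to_csv(out / "latents_cae.csv", index=False)
        ae_latents.to_csv(out / "latents_ae.csv", index=False)

        stage("vegetation-indices")
        vis = vi_feature_table(clipped)
        vis.to_csv(out / "vis.csv", index=False)

        reports: dict = {"history": {
            "cae_final_total": float(cae_history["total"].iloc[-1]),
            "ae_final_total": float(ae_history["total"].iloc[-1]),
        }}

        if config.run_disentanglement:
            stage("disentanglement")
            if config.sim.n_environments < 2:
                raise ValueError("disentanglement evaluation requires at least 2 environments")
            kept = cae_latents["plot_id"]
            raw_feat = features[dataset.metadata["plot_id"].isin(kept).to_numpy()]
            raw_env = dataset.metadata.loc[
                dataset.metadata["plot_id"].isin(kept), "environment_id"]
            reports["disentanglement"] = disentanglement_report(
                cae_latents, config.latent, raw_feat, raw_env)
            _write_json(reports["disentanglement"], out / "disentanglement_report.json")

        if config.run_yield:
            if dataset.yields is None or dataset.yields.empty:
                log.warning("no yield table available; skipping yield stages")
            else:
                stage("yield-evaluation")
                cols = latent_columns(config.latent)
                cae_feat = cae_latents[["plot_id", *cols]]
                ae_feat = ae_latents[["plot_id",
                                      *[f"z{i + 1}" for i in range(config.latent.d)]]]
                both = cae_feat.merge(vis, on="plot_id")
                tables = {"CAE": cae_feat, "AE": ae_feat, "VIs": vis, "CAE+VIs": both}
                meta = dataset.metadata[dataset.metadata["plot_id"].isin(cae_feat["plot_id"])]
                cv = experiment1(tables, dataset.yields, meta, seed=config.seed)
                overlaps = [
                    dataclasses.asdict(r)
                    for fr in config.rank_fractions
                    for r in experiment2(cae_feat, dataset.yields, meta,
                                         fraction=fr, seed=config.seed)
                ]
                heldout = sorted(meta["environment_id"].astype(str).unique())[-1]
                exp3 = experiment3(cae_feat, dataset.yields, meta, heldout,
                                   seed=config.seed)
                reports["yield"] = {
                    "experiment1": [r.summary() for r in cv],
                    "experiment2": overlaps,
                    "experiment3": exp3,
                }
                _write_json(reports["yield"], out / "yield_report.json")
    except Exception as err:  # re-raise with the failing stage's name
        raise RuntimeError(f"pipeline failed: {err}") from err
    return reports


def sweep_latent_configs(config: RunConfig, out_dir: str | Path,
                         latent_dims: list[tuple[int, int, int]]) -> pd.DataFrame:
    """Train/evaluate once per (zg, ze, zp) triple and tabulate the metrics."""
    if not latent_dims:
        raise ValueError("need at least one latent configuration")
    out = Path(out_dir)
    rows = []
    for zg, ze, zp in latent_dims:
        sub = dataclasses.replace(config, latent=LatentConfig(zg, ze, zp))
        reports = run_pipeline(sub, out / f"latent_{zg}-{ze}-{zp}")
        row = {"zg": zg, "ze": ze, "zp": zp,
               "cae_final_total": reports["history"]["cae_final_total"]}
        if "disentanglement" in reports:
            row["macro_env_silhouette"] = reports["disentanglement"]["macro_env_silhouette"]
            row["micro_env_silhouette"] = reports["disentanglement"]["micro_env_silhouette"]
            row["raw_silhouette"] = reports["disentanglement"]["raw_silhouette"]
        if "yield" in reports:
            for summary in reports["yield"]["experiment1"]:
                if summary["label"] == "CAE":
                    row["cae_mean_r2"] = summary["mean_r2"]
                    row["cae_mean_rmse"] = summary["mean_rmse"]
        rows.append(row)
    table = pd.DataFrame(rows)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "sweep.csv", index=False)
    return table
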