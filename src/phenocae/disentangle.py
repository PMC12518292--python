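"""Disentanglement evaluation: PCA projection and silhouette clustering.

The protocol mirrors the visual analysis used for the real trial: project
features to the first three principal components, then measure how well
points cluster by location (macro-environment) or by location x replicate
(micro-environment) with the silhouette score. The comparator is the same
pipeline run on raw flattened pixels.

The silhouette is computed on the 3 PCA coordinates with Euclidean
distance (matching the visual protocol); ``use_pca=False`` switches to the
full feature space. Singleton clusters are assigned s = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .cae import LatentConfig
from .training import latent_columns


@dataclass
class ProjectionResult:
    """Per-sample 3-D coordinates plus explained-variance ratios."""

    coords: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def cumulative_variance(self) -> float:
        return float(self.explained_variance_ratio.sum())


@dataclass
class SilhouetteReport:
    """Overall and per-label mean silhouettes for one labelling."""

    score: float
    per_label: dict[str, float]
    labels: list[str]

    @property
    def n_labels(self) -> int:
        return len(self.labels)


def pca_project(features: np.ndarray, n_components: int = 3) -> ProjectionResult:
    """Centered PCA with a fixed sign convention.

    Each component is flipped so its largest-magnitude loading is
    positive, making projections deterministic across runs/platforms.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    n, d = x.shape
    if n < n_components or d < n_components:
        raise ValueError(
            f"need at least {n_components} samples and dimensions, got {x.shape}"
        )
    if not np.any(x.var(axis=0) > 0):
        raise ValueError("degenerate input: zero variance in every dimension")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    flip = np.ones(n_components)
    for i in range(n_components):
        loading = pca.components_[i]
        if loading[np.argmax(np.abs(loading))] < 0:
            flip[i] = -1.0
    return ProjectionResult(coords=coords * flip,
                            explained_variance_ratio=pca.explained_variance_ratio_)


def silhouette(points: np.ndarray, labels) -> SilhouetteReport:
    """Euclidean silhouette with per-label means; singleton clusters get s = 0."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    if points.ndim == 1:
        points = points[:, None]
    if len(points) == 0:
        raise ValueError("empty input")
    if len(points) != len(labels):
        raise ValueError("points and labels must align")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 distinct labels")
    if np.allclose(points, points[0]):
        # All points identical: intra and inter distances vanish; by the
        # a >= b degenerate convention every sample scores 0.
        svals = np.zeros(len(points))
    else:
        svals = silhouette_samples(points, labels, metric="euclidean")
    per_label = {u: float(svals[labels == u].mean()) for u in uniq}
    return SilhouetteReport(score=float(svals.mean()), per_label=per_label, labels=uniq)


def _block(latents: pd.DataFrame, cols: list[str]) -> np.ndarray:
    missing = [c for c in cols if c not in latents.columns]
    if missing:
        raise ValueError(f"latent table is missing columns {missing}")
    return latents[cols].to_numpy(dtype=float)


def macro_env_silhouette(latents: pd.DataFrame, latent: LatentConfig,
                         mode: str = "ze", n_components: int = 3,
                         use_pca: bool = True) -> SilhouetteReport:
    """Location separation of the macro-environment latent block.

    ``mode="ze"`` (default): project the per-image Ze block to 3 PCs and
    score against environment labels. ``mode="mean_imputed"``: keep the
    full zg+ze+zp latent but replace the Zg and Zp columns by their
    dataset means (the "average over the genotype and micro-environment
    components" reading), so only Ze varies.
    """
    if latents["environment_id"].nunique() < 2:
        raise ValueError("macro-environment evaluation needs at least 2 environments")
    cols = latent_columns(latent)
    if mode == "ze":
        x = _block(latents, [c for c in cols if c.startswith("Ze")])
    elif mode == "mean_imputed":
        x = _block(latents, cols).copy()
        for i, c in enumerate(cols):
            if not c.startswith("Ze"):
                x[:, i] = x[:, i].mean()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pts = pca_project(x, n_components).coords if use_pca else x
    return silhouette(pts, latents["environment_id"].tolist())


def micro_env_silhouette(latents: pd.DataFrame, latent: LatentConfig,
                         n_components: int | None = 3,
                         use_pca: bool = True) -> SilhouetteReport:
    """Replicate-level separation of the Zp block (E*R classes).

    When Zp has fewer dimensions than the requested components the block
    is used as-is.
    """
    labels = (latents["environment_id"].astype(str) + "/"
              + latents["replicate_id"].astype(str)).tolist()
    if len(set(labels)) < 2:
        raise ValueError("micro-environment evaluation needs at least 2 classes")
    cols = [c for c in latent_columns(latent) if c.startswith("Zp")]
    x = _block(latents, cols)
    if use_pca and n_components is not None and x.shape[1] >= n_components:
        x = pca_project(x, n_components).coords
    return silhouette(x, labels)


def raw_baseline_silhouette(features: np.ndarray, environment_ids,
                            n_components: int = 3) -> SilhouetteReport:
    """The comparator: PCA(3) on raw flattened pixels, scored by location."""
    env = [str(e) for e in environment_ids]
    if len(set(env)) < 2:
        raise ValueError("raw baseline needs at least 2 environments")
    proj = pca_project(np.asarray(features, dtype=float), n_components)
    return silhouette(proj.coords, env)


def disentanglement_report(latents: pd.DataFrame, latent: LatentConfig,
                           raw_features: np.ndarray, raw_environment_ids,
                           mode: str = "ze") -> dict:
    """Full protocol: raw baseline vs macro (Ze) vs micro (Zp) silhouettes."""
    raw = raw_baseline_silhouette(raw_features, raw_environment_ids)
    macro = macro_env_silhouette(latents, latent, mode=mode)
    micro = micro_env_silhouette(latents, latent)
    cols = latent_columns(latent)
    proj = pca_project(_block(latents, [c for c in cols if c.startswith("Ze")]))
    return {
        "raw_silhouette": raw.score,
        "macro_env_silhouette": macro.score,
        "micro_env_silhouette": micro.score,
        "macro_minus_raw": macro.score - raw.score,
        "macro_per_environment": macro.per_label,
        "ze_explained_variance_ratio": proj.explained_variance_ratio.tolist(),
        "ze_cumulative_variance": proj.cumulative_variance,
        "mode": mode,
    }
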