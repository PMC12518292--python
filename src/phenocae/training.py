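"""Losses and training loops for the compositional and vanilla autoencoders.

The objective is two-part: a pixel reconstruction loss (mean squared
error) plus a *correlation loss* that penalizes the absolute Pearson
correlation between every pair of latent dimensions,

    corr_loss = sum_{i <= j} ( |CorrMat_ij| - I_ij )  =  sum_{i < j} |r_ij|,

computed across the images of a batch. Driving off-diagonal correlations
to zero is what pushes the genotype / macro-environment / micro-
environment blocks of the latent space to carry independent information.
The loss is differentiable (epsilon-guarded denominators; a zero-variance
column has r = 0 and contributes no gradient) and participates in the
gradients, not as a post-hoc penalty.

By default the correlation matrix spans the per-image assembled latents
(rows = images in the batch, columns = the zg+ze+zp dims), since that is
the representation consumed downstream; ``corr_mode="fused"`` instead
decorrelates the full fused vector across groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cae import AEModel, CAEModel, GroupLayout, GroupedData, LatentConfig

_EPS = 1e-8


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient r in [-1, 1].

    Returns 0.0 when either vector has zero variance (the convention used
    throughout the correlation loss).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("pearson expects 1-D vectors")
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 data points")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom <= _EPS:
        return 0.0
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def correlation_matrix(latents: np.ndarray) -> np.ndarray:
    """Column-wise Pearson matrix; zero-variance columns yield r = 0.

    This exact form is used for reported losses; the training gradient
    path uses an epsilon-guarded variant instead (see
    :func:`correlation_loss_grad`).
    """
    latents = np.asarray(latents, dtype=float)
    xc = latents - latents.mean(axis=0)
    ss = (xc * xc).sum(axis=0)
    denom = np.sqrt(np.where(ss > 0, ss, 1.0))
    xh = xc / denom
    return xh.T @ xh


def correlation_loss(latents: np.ndarray) -> float:
    """Sum of absolute off-diagonal correlations over unique pairs.

    Requires at least 3 rows (images); bounded by D*(D-1)/2.
    """
    latents = np.asarray(latents, dtype=float)
    if latents.ndim != 2:
        raise ValueError("latent batch must be a 2-D matrix")
    if latents.shape[0] < 3:
        raise ValueError("correlation loss needs at least 3 rows")
    corr = correlation_matrix(latents)
    iu = np.triu_indices(corr.shape[0], k=1)
    return float(np.abs(corr[iu]).sum())


def correlation_loss_grad(latents: np.ndarray, eps: float = _EPS):
    """Correlation loss and its gradient with respect to the latent matrix."""
    latents = np.asarray(latents)
    if latents.shape[0] < 3:
        raise ValueError("correlation loss needs at least 3 rows")
    xc = latents - latents.mean(axis=0)
    ss = (xc * xc).sum(axis=0)
    denom = np.sqrt(ss + eps)
    xh = xc / denom
    corr = xh.T @ xh
    sign = np.sign(corr)
    np.fill_diagonal(sign, 0.0)
    iu = np.triu_indices(corr.shape[0], k=1)
    loss = float(np.abs(corr[iu]).sum())
    # loss = 0.5 * sum_{i != j} |C_ij|; C = Xh' Xh  =>  dXh = Xh @ sign(C)_offdiag
    dxh = xh @ sign
    dxc = dxh / denom - xc * ((xc * dxh).sum(axis=0) / denom**3)
    dl = dxc - dxc.mean(axis=0)
    return loss, dl.astype(latents.dtype)


def reconstruction_loss(inputs: np.ndarray, reconstructions: np.ndarray) -> float:
    """Mean squared error over all elements."""
    inputs = np.asarray(inputs)
    reconstructions = np.asarray(reconstructions)
    if inputs.shape != reconstructions.shape:
        raise ValueError(f"shape mismatch: {inputs.shape} vs {reconstructions.shape}")
    diff = reconstructions - inputs
    return float(np.mean(diff * diff))


def total_loss(recon: float, corr: float, corr_weight: float) -> float:
    """Combined objective ``recon + corr_weight * corr`` (weight >= 0)."""
    if corr_weight < 0:
        raise ValueError("corr_weight must be nonnegative")
    return recon + corr_weight * corr


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings (seeded; all recorded in checkpoints)."""

    epochs: int = 200
    batch_groups: int = 8
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    corr_weight: float = 1.0
    corr_mode: str = "per_image"  # or "fused"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_groups < 1:
            raise ValueError("batch_groups must be >= 1")
        if self.corr_weight < 0:
            raise ValueError("corr_weight must be nonnegative")
        if self.corr_mode not in ("per_image", "fused"):
            raise ValueError(f"unknown corr_mode {self.corr_mode!r}")
        if self.optimizer != "adam":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def _make_optimizer(params, config: TrainingConfig):
    from .nn import Adam

    return Adam(params, lr=config.learning_rate)


def _cae_batch(model: CAEModel, xb: np.ndarray, config: TrainingConfig,
               update: bool):
    """One forward (and optionally backward) pass over a batch of groups."""
    b, n, f = xb.shape
    d = model.latent.d
    enc = model.encoder.forward(xb.reshape(b * n, f))
    fused = model.fusion.forward(enc.reshape(b, n * d))
    lat = fused[:, model._idx.T].transpose(0, 2, 1)  # (B, N, d)
    recon = model.decoder.forward(lat.reshape(b * n, d))
    x_flat = xb.reshape(b * n, f)
    rec_loss = reconstruction_loss(x_flat, recon)

    corr_val = 0.0
    d_lat_corr = None
    d_fused_corr = None
    if config.corr_weight > 0:
        if config.corr_mode == "per_image" and b * n >= 3:
            corr_val, grad = correlation_loss_grad(lat.reshape(b * n, d))
            d_lat_corr = config.corr_weight * grad
        elif config.corr_mode == "fused" and b >= 3:
            corr_val, grad = correlation_loss_grad(fused)
            d_fused_corr = config.corr_weight * grad

    if update:
        d_recon = (2.0 / recon.size) * (recon - x_flat).astype(model.dtype)
        d_lat = model.decoder.backward(d_recon)  # (B*N, d)
        if d_lat_corr is not None:
            d_lat = d_lat + d_lat_corr.astype(model.dtype)
        d_lat = d_lat.reshape(b, n, d)
        d_fused = np.zeros_like(fused)
        for j in range(n):
            d_fused[:, model._idx[j]] += d_lat[:, j, :]
        if d_fused_corr is not None:
            d_fused += d_fused_corr.astype(model.dtype)
        d_enc = model.fusion.backward(d_fused).reshape(b * n, d)
        model.encoder.backward(d_enc)
    return rec_loss, float(corr_val)


def evaluate_cae_losses(model: CAEModel, grouped: GroupedData,
                        config: TrainingConfig) -> dict[str, float]:
    """Loss components over the full dataset without updating weights."""
    rec, corr = _cae_batch(model, grouped.x.astype(model.dtype), config, update=False)
    return {"reconstruction": rec, "correlation": corr,
            "total": total_loss(rec, corr, config.corr_weight)}


def train_cae(grouped: GroupedData, latent: LatentConfig, layout: GroupLayout,
              config: TrainingConfig):
    """Train a CAE on complete genotype groups.

    Returns ``(model, history)`` where ``history`` has one row per epoch
    with the reconstruction and correlation components tracked separately.
    """
    if grouped.x.size == 0:
        raise ValueError("empty dataset")
    if grouped.layout != layout:
        raise ValueError("grouped data layout does not match the requested layout")
    n_groups, n, f = grouped.x.shape
    model = CAEModel(f, latent, layout, seed=config.seed)
    x = grouped.x.astype(model.dtype)
    opt = _make_optimizer(model.params, config)
    rng = np.random.default_rng(config.seed)
    rows = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n_groups)
        rec_sum = corr_sum = 0.0
        n_batches = 0
        for start in range(0, n_groups, config.batch_groups):
            xb = x[order[start:start + config.batch_groups]]
            rec, corr = _cae_batch(model, xb, config, update=True)
            opt.step()
            rec_sum += rec
            corr_sum += corr
            n_batches += 1
        rec_mean, corr_mean = rec_sum / n_batches, corr_sum / n_batches
        rows.append(dict(epoch=epoch, reconstruction=rec_mean, correlation=corr_mean,
                         total=total_loss(rec_mean, corr_mean, config.corr_weight)))
    return model, pd.DataFrame(rows)


def train_ae(features: np.ndarray, latent: LatentConfig, config: TrainingConfig,
             images_per_batch: int | None = None):
    """Train the vanilla autoencoder baseline on per-image vectors.

    The latent width is zg+ze+zp, matching the CAE's per-image latent.
    ``images_per_batch`` defaults to ``batch_groups * 10`` so batches carry
    a comparable number of images to CAE training.
    """
    features = np.asarray(features)
    if features.ndim != 2 or features.shape[0] == 0:
        raise ValueError("features must be a nonempty (n_images, width) matrix")
    n_images, f = features.shape
    batch = images_per_batch or config.batch_groups * 10
    model = AEModel(f, latent, seed=config.seed)
    x = features.astype(model.dtype)
    opt = _make_optimizer(model.params, config)
    rng = np.random.default_rng(config.seed)
    rows = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n_images)
        rec_sum, n_batches = 0.0, 0
        for start in range(0, n_images, batch):
            xb = x[order[start:start + batch]]
            _, recon = model.forward(xb)
            rec = reconstruction_loss(xb, recon)
            d_recon = (2.0 / recon.size) * (recon - xb).astype(model.dtype)
            model.encoder.backward(model.decoder.backward(d_recon))
            opt.step()
            rec_sum += rec
            n_batches += 1
        rec_mean = rec_sum / n_batches
        rows.append(dict(epoch=epoch, reconstruction=rec_mean, correlation=0.0,
                         total=rec_mean))
    return model, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Latent extraction
# ---------------------------------------------------------------------------

def latent_columns(latent: LatentConfig) -> list[str]:
    """Column names of the per-image disentangled latent (Zg*, Ze*, Zp*)."""
    return ([f"Zg{i + 1}" for i in range(latent.zg)]
            + [f"Ze{i + 1}" for i in range(latent.ze)]
            + [f"Zp{i + 1}" for i in range(latent.zp)])


def extract_latents(model: CAEModel, grouped: GroupedData) -> pd.DataFrame:
    """Per-image disentangled latents: one row per plot, deterministic order.

    Within a genotype group all rows share the Zg slice, and replicates of
    one environment share the Ze slice (exact equality, by construction).
    """
    layout = model.layout
    _, _, lat = model.forward_group(grouped.x.astype(model.dtype))
    cols = latent_columns(model.latent)
    rows = []
    for gi, gid in enumerate(grouped.genotype_ids):
        for j in range(layout.n_images):
            env = grouped.environment_ids[layout.env_of(j)]
            rows.append({
                "plot_id": grouped.plot_ids[gi, j],
                "genotype_id": gid,
                "environment_id": env,
                "replicate_id": j % layout.n_replicates + 1,
                **dict(zip(cols, lat[gi, j].astype(float))),
            })
    return pd.DataFrame(rows)


def extract_ae_latents(model: AEModel, features: np.ndarray,
                       metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-image latents of the vanilla autoencoder baseline."""
    features = np.asarray(features)
    if len(features) != len(metadata):
        raise ValueError("features and metadata must align row-wise")
    z, _ = model.forward(features.astype(model.dtype))
    cols = [f"z{i + 1}" for i in range(model.latent.d)]
    out = metadata[["plot_id", "genotype_id", "environment_id", "replicate_id"]].copy()
    for i, c in enumerate(cols):
        out[c] = z[:, i].astype(float)
    return out
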