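"""Compositional autoencoder (CAE) architecture and latent bookkeeping.

The CAE processes one *genotype group* at a time: the N = E*R chips of one
genotype across E environments and R replicates, ordered environment-major
(replicate minor). Each chip is encoded to a ``zg + ze + zp`` vector; the N
encodings are concatenated and passed through a single affine *fusion*
layer producing a partitioned vector

    [ Zg | Ze_1 ... Ze_E | Zp_1 ... Zp_N ]

of length ``zg + E*ze + N*zp``. Image at group position j (environment e,
micro index j) is then re-represented by the triple (Zg, Ze_e, Zp_j) —
so Zg is shared by the whole group and Ze_e by the replicates of one
environment — and decoded back to pixel space.

The vanilla autoencoder baseline uses the identical encoder/decoder with
no fusion, its latent width matched to ``zg + ze + zp`` for a fair
comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import MLP

#: Hidden widths of the encoder / decoder stacks. The decoder's first
#: hidden width (2024) is intentionally asymmetric to the encoder's.
ENCODER_HIDDEN = (2200, 2000, 1000)
DECODER_HIDDEN = (2024, 3000, 2200)


@dataclass(frozen=True)
class LatentConfig:
    """Latent dimension split: genotype (zg), per-environment macro (ze),
    per-image micro (zp). Default 6-6-1."""

    zg: int = 6
    ze: int = 6
    zp: int = 1

    def __post_init__(self) -> None:
        if min(self.zg, self.ze, self.zp) < 1:
            raise ValueError(f"latent dims must be >= 1, got {self}")

    @property
    def d(self) -> int:
        """Per-image latent width zg + ze + zp."""
        return self.zg + self.ze + self.zp


@dataclass(frozen=True)
class GroupLayout:
    """(E, R) group geometry with the fixed env-major, replicate-minor order.

    Group position ``j`` (0-based) maps to environment ``j // R`` and
    micro index ``j``; for R = 2 positions 2e, 2e+1 share environment e.
    """

    n_environments: int = 5
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if self.n_environments < 1 or self.n_replicates < 1:
            raise ValueError("E and R must be >= 1")

    @property
    def n_images(self) -> int:
        return self.n_environments * self.n_replicates

    def env_of(self, position: int) -> int:
        if not 0 <= position < self.n_images:
            raise ValueError(f"group position {position} out of range [0, {self.n_images})")
        return position // self.n_replicates

    def micro_of(self, position: int) -> int:
        if not 0 <= position < self.n_images:
            raise ValueError(f"group position {position} out of range [0, {self.n_images})")
        return position


def fused_length(latent: LatentConfig, layout: GroupLayout) -> int:
    """Width of the fused vector: zg + E*ze + N*zp."""
    return latent.zg + layout.n_environments * latent.ze + layout.n_images * latent.zp


def fused_indices(latent: LatentConfig, layout: GroupLayout, position: int) -> np.ndarray:
    """Column indices into the fused vector forming image ``position``'s latent.

    The slices are [Zg | Ze_e | Zp_j] with e, j from the layout.
    """
    e = layout.env_of(position)
    j = layout.micro_of(position)
    zg, ze, zp = latent.zg, latent.ze, latent.zp
    ze_start = zg + e * ze
    zp_start = zg + layout.n_environments * ze + j * zp
    return np.concatenate([
        np.arange(zg),
        np.arange(ze_start, ze_start + ze),
        np.arange(zp_start, zp_start + zp),
    ])


def index_matrix(latent: LatentConfig, layout: GroupLayout) -> np.ndarray:
    """(N, zg+ze+zp) matrix of fused-vector indices, one row per group position."""
    return np.stack([fused_indices(latent, layout, j) for j in range(layout.n_images)])


@dataclass
class DisentangledLatent:
    """Per-image latent triple sliced out of a fused vector."""

    zg: np.ndarray
    ze: np.ndarray
    zp: np.ndarray
    environment_index: int
    micro_index: int

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.zg, self.ze, self.zp])


def assemble_replicate_latent(
    fused: np.ndarray, position: int, latent: LatentConfig, layout: GroupLayout
) -> DisentangledLatent:
    """Slice the fused vector into (Zg, Ze_e, Zp_j) for one group position."""
    fused = np.asarray(fused)
    if fused.shape[-1] != fused_length(latent, layout):
        raise ValueError(
            f"fused vector of length {fused.shape[-1]}, expected {fused_length(latent, layout)}"
        )
    idx = fused_indices(latent, layout, position)
    zg, ze = latent.zg, latent.ze
    sliced = fused[..., idx]
    return DisentangledLatent(
        zg=sliced[..., :zg],
        ze=sliced[..., zg:zg + ze],
        zp=sliced[..., zg + ze:],
        environment_index=layout.env_of(position),
        micro_index=layout.micro_of(position),
    )


def make_encoder(input_dim: int, latent: LatentConfig, rng: np.random.Generator,
                 hidden: tuple[int, ...] = ENCODER_HIDDEN, dtype=np.float32) -> MLP:
    """SELU MLP ``input -> 2200 -> 2000 -> 1000 -> zg+ze+zp`` (linear output)."""
    widths = [input_dim, *hidden, latent.d]
    return MLP(widths, ["selu"] * len(hidden) + [None], rng, dtype=dtype)


def make_decoder(input_dim: int, latent: LatentConfig, rng: np.random.Generator,
                 hidden: tuple[int, ...] = DECODER_HIDDEN, dtype=np.float32) -> MLP:
    """SELU MLP ``zg+ze+zp -> 2024 -> 3000 -> 2200 -> input`` with sigmoid output."""
    widths = [latent.d, *hidden, input_dim]
    return MLP(widths, ["selu"] * len(hidden) + ["sigmoid"], rng, dtype=dtype)


class CAEModel:
    """Encoder + fusion + decoder operating on complete genotype groups."""

    kind = "cae"

    def __init__(self, input_dim: int, latent: LatentConfig, layout: GroupLayout,
                 seed: int = 0, encoder_hidden: tuple[int, ...] = ENCODER_HIDDEN,
                 decoder_hidden: tuple[int, ...] = DECODER_HIDDEN,
                 dtype=np.float32) -> None:
        rng = np.random.default_rng(seed)
        self.input_dim = int(input_dim)
        self.latent = latent
        self.layout = layout
        self.seed = int(seed)
        self.dtype = dtype
        self.encoder_hidden = tuple(encoder_hidden)
        self.decoder_hidden = tuple(decoder_hidden)
        self.encoder = make_encoder(input_dim, latent, rng, encoder_hidden, dtype)
        self.fusion = MLP([layout.n_images * latent.d, fused_length(latent, layout)],
                          [None], rng, dtype=dtype)
        self.decoder = make_decoder(input_dim, latent, rng, decoder_hidden, dtype)
        self._idx = index_matrix(latent, layout)

    # -- pieces -----------------------------------------------------------
    def encode(self, x: np.ndarray) -> np.ndarray:
        """Per-image encoding; accepts a vector or an (n, input_dim) batch."""
        x = np.asarray(x, dtype=self.dtype)
        single = x.ndim == 1
        out = self.encoder.forward(x[None, :] if single else x)
        return out[0] if single else out

    def fuse(self, latents: np.ndarray) -> np.ndarray:
        """Affine fusion of the N group encodings (ordered) into one vector."""
        latents = np.asarray(latents, dtype=self.dtype)
        single = latents.ndim == 2
        if single:
            latents = latents[None]
        if latents.shape[1] != self.layout.n_images or latents.shape[2] != self.latent.d:
            raise ValueError(
                f"expected (batch, {self.layout.n_images}, {self.latent.d}) encodings, "
                f"got {latents.shape}"
            )
        fused = self.fusion.forward(latents.reshape(latents.shape[0], -1))
        return fused[0] if single else fused

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Decode per-image latents; sigmoid output lies strictly in (0, 1)."""
        z = np.asarray(z, dtype=self.dtype)
        single = z.ndim == 1
        out = self.decoder.forward(z[None, :] if single else z)
        return out[0] if single else out

    # -- full group pass --------------------------------------------------
    def forward_group(self, x_group: np.ndarray):
        """Run complete groups through encode -> fuse -> assemble -> decode.

        ``x_group``: (N, input_dim) for one group or (B, N, input_dim) for a
        batch. Returns (reconstructions, fused, per-image latents) with
        matching leading dimensions.
        """
        x = np.asarray(x_group, dtype=self.dtype)
        single = x.ndim == 2
        if single:
            x = x[None]
        b, n, f = x.shape
        if n != self.layout.n_images:
            raise ValueError(f"group has {n} images, layout requires {self.layout.n_images}")
        if f != self.input_dim:
            raise ValueError(f"feature width {f}, expected {self.input_dim}")
        enc = self.encoder.forward(x.reshape(b * n, f))
        fused = self.fusion.forward(enc.reshape(b, n * self.latent.d))
        lat = fused[:, self._idx.T].transpose(0, 2, 1)  # (B, N, d)
        recon = self.decoder.forward(lat.reshape(b * n, self.latent.d)).reshape(b, n, f)
        if single:
            return recon[0], fused[0], lat[0]
        return recon, fused, lat

    @property
    def params(self):
        return self.encoder.params + self.fusion.params + self.decoder.params


class AEModel:
    """Vanilla per-image autoencoder baseline (same encoder/decoder stacks)."""

    kind = "ae"

    def __init__(self, input_dim: int, latent: LatentConfig, seed: int = 0,
                 encoder_hidden: tuple[int, ...] = ENCODER_HIDDEN,
                 decoder_hidden: tuple[int, ...] = DECODER_HIDDEN,
                 dtype=np.float32) -> None:
        rng = np.random.default_rng(seed)
        self.input_dim = int(input_dim)
        self.latent = latent
        self.seed = int(seed)
        self.dtype = dtype
        self.encoder_hidden = tuple(encoder_hidden)
        self.decoder_hidden = tuple(decoder_hidden)
        self.encoder = make_encoder(input_dim, latent, rng, encoder_hidden, dtype)
        self.decoder = make_decoder(input_dim, latent, rng, decoder_hidden, dtype)

    def forward(self, x: np.ndarray):
        """Per-image pass; returns ``(latent, reconstruction)``."""
        x = np.asarray(x, dtype=self.dtype)
        single = x.ndim == 1
        if single:
            x = x[None]
        z = self.encoder.forward(x)
        recon = self.decoder.forward(z)
        if single:
            return z[0], recon[0]
        return z, recon

    @property
    def params(self):
        return self.encoder.params + self.decoder.params


# ---------------------------------------------------------------------------
# Group assembly from datasets
# ---------------------------------------------------------------------------

@dataclass
class GroupedData:
    """Complete genotype groups as a dense (G, N, F) array plus identity grids."""

    x: np.ndarray  # (G, N, F)
    genotype_ids: list[str]
    plot_ids: np.ndarray  # (G, N) object array
    environment_ids: list[str]  # length E, in group (env-major) order
    layout: GroupLayout
    dropped_genotypes: list[str]


def build_groups(features: np.ndarray, metadata: pd.DataFrame,
                 layout: GroupLayout) -> GroupedData:
    """Arrange per-plot feature vectors into complete genotype groups.

    ``metadata`` must align row-wise with ``features`` and carry
    genotype_id / environment_id / replicate_id. Environments are ordered
    by sorted id; replicates by sorted replicate_id. Genotypes missing any
    (environment, replicate) cell are dropped (the fusion layer needs a
    fixed N) and reported in ``dropped_genotypes``.
    """
    features = np.asarray(features)
    if len(features) != len(metadata):
        raise ValueError("features and metadata must align row-wise")
    env_ids = sorted(metadata["environment_id"].astype(str).unique())
    if len(env_ids) != layout.n_environments:
        raise ValueError(
            f"metadata has {len(env_ids)} environments, layout expects {layout.n_environments}"
        )
    cell: dict[tuple[str, str, int], int] = {}
    for row_idx, row in enumerate(metadata.itertuples(index=False)):
        key = (str(row.genotype_id), str(row.environment_id), int(row.replicate_id))
        if key in cell:
            raise ValueError(f"duplicate plot cell {key}")
        cell[key] = row_idx

    groups, plot_grid, kept, dropped = [], [], [], []
    for gid in sorted(metadata["genotype_id"].astype(str).unique()):
        reps = sorted({int(r) for (g, _, r) in cell if g == gid})
        rows, plots, complete = [], [], True
        for env in env_ids:
            for r_pos in range(layout.n_replicates):
                if r_pos >= len(reps) or (gid, env, reps[r_pos]) not in cell:
                    complete = False
                    break
                idx = cell[(gid, env, reps[r_pos])]
                rows.append(idx)
                plots.append(str(metadata.iloc[idx]["plot_id"]))
            if not complete:
                break
        if complete:
            groups.append(features[rows])
            plot_grid.append(plots)
            kept.append(gid)
        else:
            dropped.append(gid)
    if not kept:
        raise ValueError("no complete genotype groups in the dataset")
    return GroupedData(
        x=np.stack(groups),
        genotype_ids=kept,
        plot_ids=np.array(plot_grid, dtype=object),
        environment_ids=env_ids,
        layout=layout,
        dropped_genotypes=dropped,
    )


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(model, path: str | Path, extra: dict | None = None) -> Path:
    """Persist a model (weights + configuration + seed) as an .npz container."""
    path = Path(path)
    header = {
        "version": CHECKPOINT_VERSION,
        "kind": model.kind,
        "input_dim": model.input_dim,
        "latent": [model.latent.zg, model.latent.ze, model.latent.zp],
        "seed": model.seed,
        "encoder_hidden": list(model.encoder_hidden),
        "decoder_hidden": list(model.decoder_hidden),
        "extra": extra or {},
    }
    arrays = {}
    stacks = {"encoder": model.encoder, "decoder": model.decoder}
    if model.kind == "cae":
        header["layout"] = [model.layout.n_environments, model.layout.n_replicates]
        stacks["fusion"] = model.fusion
    for name, mlp in stacks.items():
        for i, arr in enumerate(mlp.state()):
            arrays[f"{name}_{i}"] = arr
    np.savez(path, header=json.dumps(header), **arrays)
    return path


def load_checkpoint(path: str | Path):
    """Restore a model saved by :func:`save_checkpoint`.

    Returns ``(model, extra)`` where ``extra`` is the user dictionary
    stored alongside the weights.
    """
    with np.load(Path(path), allow_pickle=False) as npz:
        header = json.loads(str(npz["header"]))
        arrays = {k: npz[k] for k in npz.files if k != "header"}
    if header.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {header.get('version')}")
    latent = LatentConfig(*header["latent"])
    if header["kind"] == "cae":
        layout = GroupLayout(*header["layout"])
        model = CAEModel(header["input_dim"], latent, layout, seed=header["seed"],
                         encoder_hidden=tuple(header["encoder_hidden"]),
                         decoder_hidden=tuple(header["decoder_hidden"]))
        stacks = {"encoder": model.encoder, "fusion": model.fusion,
                  "decoder": model.decoder}
    elif header["kind"] == "ae":
        model = AEModel(header["input_dim"], latent, seed=header["seed"],
                        encoder_hidden=tuple(header["encoder_hidden"]),
                        decoder_hidden=tuple(header["decoder_hidden"]))
        stacks = {"encoder": model.encoder, "decoder": model.decoder}
    else:
        raise ValueError(f"unknown model kind {header['kind']!r}")
    for name, mlp in stacks.items():
        state = [arrays[f"{name}_{i}"] for i in range(len(mlp.state()))]
        mlp.load_state(state)
    return model, header.get("extra", {})
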