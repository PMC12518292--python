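"""Synthetic plot-level multispectral trial generator with known G/E/micro factors.

The generator emulates a replicated multi-location maize hybrid trial
imaged once by a high-resolution satellite: ``n_genotypes`` hybrids grown
in ``n_environments`` locations with ``n_replicates_per_env`` plots each,
every plot yielding one 12-bit, 6-band chip and one grain-yield record.

Generative model
----------------
Latent factors:

* genotype vectors ``g_k ~ N(0, I_dg)``;
* environment vectors ``e_l`` placed on a sphere of radius
  ``env_separation`` (seeded random directions), so one dial controls how
  separable locations are;
* per-plot micro vectors ``p_i ~ N(0, micro_sd^2 I_dp)`` — the only
  within-location source of image variation besides sensor noise.

Pixels: a fixed random linear map ``A`` mixes ``[g; e; p]`` into pixel
space, a low-frequency 2-D spatial pattern is added so chips are not
spatially constant, a logistic squash bounds the response, and the result
is scaled to the 12-bit range [0, 4095], rounded, perturbed with Gaussian
sensor noise and clipped back into range.

Yield (bu/ac): ``base + w_g.g + w_e.e + gxe * g'Me + noise`` — an additive
genotype effect, an additive location effect, a bilinear GxE interaction
and plot-level noise, all with fixed seeded coefficient draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .imaging import MAX_DN, PlotImage, read_plot_geotiff, write_plot_geotiff


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and noise structure of one simulated trial.

    Defaults mirror the real trial layout: 84 hybrids x 5 locations x 2
    replicates, 11 x 22 x 6 chips with 12-bit counts. Effect sizes are in
    bu/ac and chosen to resemble a replicated maize hybrid trial: genotype
    sd ~20 bu/ac, location effects of comparable order, a weaker GxE
    interaction and ~8 bu/ac plot noise.
    """

    n_genotypes: int = 84
    n_environments: int = 5
    n_replicates_per_env: int = 2
    image_width: int = 11
    image_height: int = 22
    image_channels: int = 6
    true_dims: tuple[int, int, int] = (6, 6, 2)  # (dg, de, dp)
    env_separation: float = 2.0
    pixel_noise_sd: float = 30.0  # DN on the 12-bit scale
    micro_sd: float = 0.3
    yield_noise_sd: float = 8.0  # bu/ac
    gxe_strength: float = 8.0
    genotype_effect: float = 20.0  # bu/ac
    env_effect: float = 12.0  # bu/ac per unit of environment coordinate
    base_yield: float = 180.0  # bu/ac
    timepoint: str = "TP1"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genotypes": self.n_genotypes,
            "n_environments": self.n_environments,
            "n_replicates_per_env": self.n_replicates_per_env,
            "image_width": self.image_width,
            "image_height": self.image_height,
            "image_channels": self.image_channels,
        }
        for name, value in counts.items():
            if int(value) < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if len(self.true_dims) != 3 or any(int(d) < 1 for d in self.true_dims):
            raise ValueError(f"true_dims must be three positive counts, got {self.true_dims}")
        for name in ("env_separation", "pixel_noise_sd", "micro_sd",
                     "yield_noise_sd", "gxe_strength"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n_images(self) -> int:
        return self.n_genotypes * self.n_environments * self.n_replicates_per_env

    @property
    def image_shape(self) -> tuple[int, int, int]:
        return (self.image_width, self.image_height, self.image_channels)


@dataclass
class SyntheticDataset:
    """Images plus sidecar tables produced by :func:`simulate_dataset`.

    ``metadata``: plot_id, genotype_id, environment_id, replicate_id,
    timepoint. ``yields``: plot_id, yield_bu_ac. ``factors``: the ground
    truth ``g*``, ``e*``, ``p*`` columns per plot.
    """

    images: list[PlotImage]
    metadata: pd.DataFrame
    yields: pd.DataFrame
    factors: pd.DataFrame
    config: SimulationConfig


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    return v / n if n > 0 else v


def environment_means(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Seeded directions on a sphere of radius ``env_separation``.

    One dial (the radius) then controls the pairwise separation of
    locations in factor space.
    """
    de = config.true_dims[1]
    dirs = rng.normal(size=(config.n_environments, de))
    dirs = np.apply_along_axis(_unit, 1, dirs)
    return config.env_separation * dirs


def _spatial_basis(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency per-channel 2-D pattern, flattened to pixel order."""
    w, h, c = config.image_shape
    x = np.linspace(0.0, np.pi, w)[:, None, None]
    y = np.linspace(0.0, np.pi, h)[None, :, None]
    ax = rng.normal(scale=0.5, size=(1, 1, c))
    ay = rng.normal(scale=0.5, size=(1, 1, c))
    pattern = ax * np.cos(x) + ay * np.cos(y)
    return np.broadcast_to(pattern, (w, h, c)).ravel(order="C")


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one full trial from the generative model (bit-reproducible per seed)."""
    rng = np.random.default_rng(config.seed)
    dg, de, dp = (int(d) for d in config.true_dims)
    d0 = dg + de + dp
    n_pix = int(np.prod(config.image_shape))

    # Fixed structural draws, in a frozen order so the seed pins everything.
    mix = rng.normal(size=(n_pix, d0)) / np.sqrt(d0)  # A
    offset = rng.normal(scale=0.1, size=n_pix)  # b
    spatial = _spatial_basis(config, rng)
    w_g = config.genotype_effect * _unit(rng.normal(size=dg))
    w_e = config.env_effect * _unit(rng.normal(size=de))
    gxe_mat = rng.normal(size=(dg, de)) / np.sqrt(dg * de)  # M
    env_mu = environment_means(config, rng)
    genos = rng.normal(size=(config.n_genotypes, dg))

    images: list[PlotImage] = []
    meta_rows, yield_rows, factor_rows = [], [], []
    micro_index = 0
    for k in range(config.n_genotypes):
        g = genos[k]
        for l in range(config.n_environments):
            e = env_mu[l]
            for r in range(config.n_replicates_per_env):
                micro_index += 1
                p = rng.normal(scale=config.micro_sd, size=dp) if config.micro_sd > 0 else np.zeros(dp)
                latent = np.concatenate([g, e, p])
                pre = mix @ latent + offset + spatial
                dn = np.round(MAX_DN / (1.0 + np.exp(-pre)))
                if config.pixel_noise_sd > 0:
                    dn = dn + rng.normal(scale=config.pixel_noise_sd, size=n_pix)
                dn = np.round(np.clip(dn, 0, MAX_DN))
                noise = rng.normal(scale=config.yield_noise_sd) if config.yield_noise_sd > 0 else 0.0
                y = (config.base_yield + w_g @ g + w_e @ e
                     + config.gxe_strength * float(g @ gxe_mat @ e) + noise)

                gid, eid = f"G{k + 1:03d}", f"E{l + 1}"
                plot_id = f"{gid}_{eid}_R{r + 1}"
                images.append(
                    PlotImage(
                        pixels=dn.reshape(config.image_shape, order="C"),
                        plot_id=plot_id,
                        genotype_id=gid,
                        environment_id=eid,
                        replicate_id=r + 1,
                        timepoint=config.timepoint,
                    )
                )
                meta_rows.append(
                    dict(plot_id=plot_id, genotype_id=gid, environment_id=eid,
                         replicate_id=r + 1, timepoint=config.timepoint)
                )
                yield_rows.append(dict(plot_id=plot_id, yield_bu_ac=float(y)))
                factor_rows.append(
                    dict(plot_id=plot_id,
                         **{f"g{i + 1}": g[i] for i in range(dg)},
                         **{f"e{i + 1}": e[i] for i in range(de)},
                         **{f"p{i + 1}": p[i] for i in range(dp)})
                )
    return SyntheticDataset(
        images=images,
        metadata=pd.DataFrame(meta_rows),
        yields=pd.DataFrame(yield_rows),
        factors=pd.DataFrame(factor_rows),
        config=config,
    )


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> Path:
    """Emit one TIFF per plot plus CSV metadata/yield/ground-truth tables."""
    directory = Path(directory)
    img_dir = directory / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    for im in dataset.images:
        write_plot_geotiff(im, img_dir / f"{im.plot_id}.tif")
    dataset.metadata.to_csv(directory / "metadata.csv", index=False)
    dataset.yields.to_csv(directory / "yields.csv", index=False)
    dataset.factors.to_csv(directory / "ground_truth.csv", index=False)
    with open(directory / "simulation_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(dataset.config), fh, sort_keys=False)
    return directory


def load_dataset(directory: str | Path) -> SyntheticDataset:
    """Read back a directory written by :func:`write_dataset`."""
    directory = Path(directory)
    metadata = pd.read_csv(directory / "metadata.csv")
    yields = pd.read_csv(directory / "yields.csv")
    factors_path = directory / "ground_truth.csv"
    factors = pd.read_csv(factors_path) if factors_path.exists() else pd.DataFrame()
    cfg_path = directory / "simulation_config.yaml"
    config = None
    if cfg_path.exists():
        with open(cfg_path) as fh:
            raw = yaml.safe_load(fh)
        raw["true_dims"] = tuple(raw["true_dims"])
        config = SimulationConfig(**raw)
    images = [
        read_plot_geotiff(directory / "images" / f"{plot_id}.tif")
        for plot_id in metadata["plot_id"]
    ]
    return SyntheticDataset(images=images, metadata=metadata, yields=yields,
                            factors=factors, config=config)
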