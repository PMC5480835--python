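"""End-to-end orchestration: images -> patches -> TICA -> atlas -> test.

One YAML-serializable config drives the whole experiment over a grid of
(patch size, undersampling factor) datasets; a manifest records every
derived seed, visual angle, artifact path and per-stage status, so any
figure or number is regenerable from the config plus the master seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import synthetic, sampling, tica, gabor, maps as rmaps, uniformity


def derive_seed(master: int, *keys) -> int:
    """Counter-style fan-out of the master seed, stable across runs."""
    ints = [int(master)] + [zlib.crc32(str(k).encode()) for k in keys]
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Full experiment description; round-trips through YAML."""

    outdir: str = "runs/out"
    seed: int = 0
    fs_base: float = 25.0
    image_source: dict = field(default_factory=lambda: dict(
        kind="synthetic", n_images=200, size=128, density=60))
    datasets: list = field(default_factory=lambda: [
        dict(N=16, factor=1), dict(N=20, factor=1),
        dict(N=32, factor=1), dict(N=50, factor=1),
        dict(N=32, factor=2), dict(N=50, factor=2),
        dict(N=32, factor=4), dict(N=50, factor=4)])
    T: int = 20000
    d_r: int | None = None
    pool_size: int = 5
    nonlinearity: str = "power"
    exponent: float = 0.5
    eps: float = 1e-3
    n_iter: int = 2000
    step: float = 0.1
    mae_threshold: float = 0.125
    K_list: list = field(default_factory=lambda: [4, 5, 6])
    n_real: int = 10000
    render: bool = True

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls(**yaml.safe_load(f))


def dataset_name(N: int, fs: float) -> str:
    return f"a{N / fs:.2f}_fs{fs:g}_N{N}"


def _load_images(cfg: RunConfig) -> synthetic.ImageEnsemble:
    src = cfg.image_source
    if src.get("kind", "synthetic") == "synthetic":
        return synthetic.gen_sparse_gabor_images(
            n_images=src.get("n_images", 200), size=src.get("size", 128),
            density=src.get("density", 60), fs=cfg.fs_base,
            f_range=tuple(src["f_range"]) if "f_range" in src else None,
            seed=derive_seed(cfg.seed, "images"))
    return synthetic.load_image_dir(src["path"], cfg.fs_base)


def run_dataset(cfg: RunConfig, ensemble: synthetic.ImageEnsemble,
                N: int, factor: int, outdir: Path) -> dict:
    """Run one (patch size, factor) dataset; returns its manifest entry."""
    ens = sampling.undersample(ensemble, factor)
    name = dataset_name(N, ens.fs)
    entry: dict = dict(name=name, N=N, fs=ens.fs, factor=factor,
                       visual_angle=rmaps.visual_angle(N, ens.fs),
                       status="ok", artifacts={}, seeds={}, tests=[])
    ddir = outdir / name
    ddir.mkdir(parents=True, exist_ok=True)
    try:
        seed_p = derive_seed(cfg.seed, name, "patches")
        entry["seeds"]["patches"] = seed_p
        data = sampling.extract_patches(ens, N, cfg.T, seed=seed_p)
        Z, wmodel = sampling.whiten(data, cfg.d_r)

        n = int(round(np.sqrt(wmodel.d_r)))
        topo = tica.build_topology(n, n, cfg.pool_size)
        nl = tica.NonlinearitySpec(cfg.nonlinearity, cfg.exponent, cfg.eps)
        seed_w = derive_seed(cfg.seed, name, "tica")
        entry["seeds"]["tica"] = seed_w
        model = tica.fit_tica(Z, topo, nl, n_iter=cfg.n_iter, step=cfg.step,
                              seed=seed_w)
        model.to_hdf5(ddir / "model.h5")
        wmodel.to_hdf5(ddir / "whitening.h5")
        entry["artifacts"]["model"] = str(ddir / "model.h5")

        rfs = tica.receptive_fields(model, wmodel)
        atlas = gabor.build_atlas(rfs, topo, ens.fs, cfg.mae_threshold)
        atlas.to_csv(ddir / "atlas.csv")
        entry["artifacts"]["atlas"] = str(ddir / "atlas.csv")
        entry["retained_units"] = len(atlas)
        entry["excluded_fraction"] = atlas.excluded_fraction

        reports = []
        for K in cfg.K_list:
            part = rmaps.orientation_partition(atlas, K)
            for b, ps in enumerate(part.members):
                rec = dict(K=K, bin=b, M=ps.M,
                           bin_center=float(part.centers[b]))
                if ps.M < 4:
                    rec["outcome"] = "skipped_too_few_points"
                else:
                    res = uniformity.uniformity_test(
                        ps, n_real=cfg.n_real,
                        seed=derive_seed(cfg.seed, name, "test", K, b))
                    rec.update(res.to_dict())
                reports.append(rec)
            if cfg.render and K == cfg.K_list[0]:
                rmaps.render_maps(atlas, part, ddir, prefix=f"{name}_K{K}",
                                  topology=topo)
        entry["tests"] = reports
        with open(ddir / "uniformity.json", "w") as f:
            json.dump(reports, f, indent=2)
        entry["artifacts"]["uniformity"] = str(ddir / "uniformity.json")
    except Exception as exc:  # record the failing stage, skip downstream
        entry["status"] = "failed"
        entry["error"] = f"{type(exc).__name__}: {exc}"
    return entry


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every dataset in the config; returns the artifact directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    ensemble = _load_images(cfg)
    manifest = dict(seed=cfg.seed, fs_base=cfg.fs_base,
                    visual_angles=[], datasets=[])
    for ds in cfg.datasets:
        entry = run_dataset(cfg, ensemble, int(ds["N"]), int(ds["factor"]),
                            outdir)
        manifest["datasets"].append(entry)
        manifest["visual_angles"].append(entry["visual_angle"])
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return outdir
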