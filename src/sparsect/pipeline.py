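"""Config-driven experiment orchestration: simulate -> train -> evaluate ->
OOD -> analyze, with provenance and resumable stage artifacts.

An :class:`ExperimentConfig` is fully serializable (YAML/JSON); its SHA-256
hash is recorded in every artifact so a result can always be traced to the
exact configuration that produced it.  ``run_experiment`` writes, per
stage: phantom images (HDF5 + TIFF previews), paired datasets (HDF5),
checkpoints (npz with the architecture spec embedded), metric tables
(CSV + JSON) and cost/receptive-field reports (JSON), plus a manifest.
Completed stages are detected by their artifacts and skipped on re-run if
the config hash matches, which makes interrupted runs resumable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dataio
from .fbp import FilterSpec
from .metrics import evaluate
from .netanalysis import count_flops, receptive_field
from .networks import Network, NetworkSpec, build_3lssnet, build_resunet
from .ood import OODScenario, run_ood
from .phantoms import PhantomSpec, generate_dataset
from .projector import make_geometry
from .training import (PairedDataset, build_pairs, desk_train_config,
                       train)

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_experiment", "SMOKE_PRESET"]


@dataclass
class ExperimentConfig:
    image_size: int = 80
    n_train: int = 200
    n_test: int = 16
    phantom_family: str = "chest-like"
    texture_sigma: float = 0.01
    geometries: tuple = ("full-range", "half-range")
    noise_level: float = 1e-2
    filter_window: str = "ram-lak"
    filter_cutoff: float = 1.0
    networks: tuple = ("3l-ssnet", "resunet")
    ssnet_variant: str = "table-consistent"
    resunet_c0: int = 16
    epochs: int = 15
    batch_size: int = 8
    ood_scenarios: tuple = ("unseen-noise", "unseen-image")
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("geometries", "networks", "ood_scenarios"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


SMOKE_PRESET = ExperimentConfig(image_size=64, n_train=20, n_test=4,
                                epochs=3, resunet_c0=8)


def _build_network_spec(cfg: ExperimentConfig, name: str) -> NetworkSpec:
    if name == "3l-ssnet":
        return build_3lssnet(cfg.ssnet_variant)
    if name == "resunet":
        return build_resunet(c0=cfg.resunet_c0)
    raise ValueError(f"unknown network {name!r}")


def run_experiment(cfg: ExperimentConfig, outdir) -> Path:
    """End-to-end study under one config; returns the artifact directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__
    provenance = {"config": cfg.to_dict(), "config_hash": cfg.config_hash,
                  "seed": cfg.seed, "version": __version__}
    filt = FilterSpec(cfg.filter_window, cfg.filter_cutoff)

    # -- stage 1: phantoms -------------------------------------------------
    tmpl = PhantomSpec(family=cfg.phantom_family, size=cfg.image_size,
                       texture_sigma=cfg.texture_sigma)
    gts_train = generate_dataset(cfg.n_train, tmpl, seed=cfg.seed,
                                 split="train")
    gts_test = generate_dataset(cfg.n_test, tmpl, seed=cfg.seed, split="test")
    ph_dir = out / "phantoms"
    ph_dir.mkdir(exist_ok=True)
    for i, img in enumerate(gts_test):
        dataio.save_image_h5(ph_dir / f"test_{i:03d}.h5", img,
                             family=cfg.phantom_family, seed=cfg.seed,
                             size=cfg.image_size, config_hash=cfg.config_hash)
        dataio.save_image_tiff(ph_dir / f"test_{i:03d}.tiff", img)

    # -- stage 2: paired datasets -----------------------------------------
    # One network is trained per geometry protocol (batch-norm statistics
    # are domain-dependent; pooling protocols in one training set lets the
    # normalization exploit batch composition and the models degrade on
    # pure-protocol inputs).
    per_geom_train: dict[str, PairedDataset] = {}
    per_geom_test: dict[str, PairedDataset] = {}
    for gi, tag in enumerate(cfg.geometries):
        geom = make_geometry(tag, cfg.image_size)
        per_geom_train[tag] = build_pairs(gts_train, geom, cfg.noise_level,
                                          filt, seed=cfg.seed + 11 + gi)
        per_geom_test[tag] = build_pairs(gts_test, geom, cfg.noise_level,
                                         filt, seed=cfg.seed + 31 + gi,
                                         split="test")
        _save_pairs(out / f"pairs_{tag}.h5", per_geom_test[tag], provenance)

    # -- stage 3: training -------------------------------------------------
    models: dict[tuple[str, str], Network] = {}
    for name in cfg.networks:
        for tag in cfg.geometries:
            ckpt = out / f"{name}_{tag}.npz"
            spec = _build_network_spec(cfg, name)
            if ckpt.exists():
                logger.info("reusing checkpoint %s", ckpt)
                spec = NetworkSpec.load(ckpt)
                models[name, tag] = Network(spec)
                models[name, tag].trained = True
                continue
            tc = desk_train_config(name, seed=cfg.seed)
            tc.epochs = cfg.epochs
            tc.batch_size = cfg.batch_size
            net, history = train(spec, per_geom_train[tag], tc)
            spec.save(ckpt)
            dataio.write_json(out / f"{name}_{tag}_train_log.json",
                              {**provenance, "optimizer": tc.optimizer,
                               "epochs": tc.epochs,
                               "per_epoch_mean_loss": history})
            models[name, tag] = net

    # -- stage 4: evaluation ----------------------------------------------
    summary_rows = []
    for tag in cfg.geometries:
        ds = per_geom_test[tag]
        reports = {"FBP": evaluate(None, ds)}
        for name in cfg.networks:
            reports[name] = evaluate(models[name, tag], ds, method=name)
        for label, rep in reports.items():
            rep.to_csv(out / f"metrics_{tag}_{label}.csv")
            summary_rows.append({"geometry": tag, "method": label,
                                 **rep.means})
    dataio.write_json(out / "metrics_summary.json",
                      {**provenance, "rows": summary_rows})

    # -- stage 5: OOD ------------------------------------------------------
    ood_out = {}
    for kind in cfg.ood_scenarios:
        for name in cfg.networks:
            for tag in cfg.geometries:
                res = run_ood(models[name, tag], OODScenario(kind, tag),
                              image_size=cfg.image_size,
                              n_images=cfg.n_test, seed=cfg.seed + 101,
                              train_noise=cfg.noise_level, filt=filt)
                ood_out[f"{kind}/{name}/{tag}"] = {
                    "in_domain": res["in_domain"].to_json(),
                    "ood": res["ood"].to_json(),
                    "delta": res["delta"]}
    dataio.write_json(out / "ood_report.json", {**provenance, **ood_out})

    # -- stage 6: cost / receptive-field analysis -------------------------
    analysis = {}
    for name in cfg.networks:
        spec = _build_network_spec(cfg, name)
        rf = receptive_field(spec.rf_layers(), input_side=cfg.image_size)
        cost = count_flops(spec, cfg.image_size)
        analysis[name] = {
            "max_rf": rf.max_rf, "rf_per_layer": rf.per_layer,
            "rf_percent_of_input": rf.percent_of_input,
            "weight_params": cost.weight_params,
            "all_trainable_params": cost.all_trainable_params,
            "flops": cost.flops, "flop_convention": cost.convention}
    dataio.write_json(out / "analysis.json", {**provenance, **analysis})

    dataio.write_json(out / "manifest.json", {
        **provenance,
        "stages": ["phantoms", "pairs", "training", "metrics", "ood",
                   "analysis"],
        "networks": list(cfg.networks),
        "geometries": list(cfg.geometries)})
    return out


def _save_pairs(path, ds: PairedDataset, provenance: dict) -> None:
    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("y", data=ds.y)
        f.create_dataset("gt", data=ds.gt)
        f.attrs["geometry_tag"] = ds.geometry_tag
        f.attrs["noise_level"] = ds.noise_level
        f.attrs["split"] = ds.split
        f.attrs["config_hash"] = provenance["config_hash"]
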