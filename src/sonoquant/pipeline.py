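"""End-to-end orchestration: generate/ingest -> refine -> ICA features ->
stub deep features -> serial fusion -> cross-validation -> report.

The pipeline is driven by a single YAML-able config dict with a versioned
schema; unknown keys are rejected.  Every artifact is listed with a SHA-256
checksum in a manifest, and re-running the same config reproduces outputs
bit-identically (every random stage is explicitly seeded).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from .clseval import ClassifierSpec, cross_validate
from .fusesel import DeepFeatureStub, SerialFusion
from .quantseg import QuantizationRefiner, RegionCriteria, TriggerRule
from .segmetrics import mean_fscore, mean_iou
from .sunica import IcaSaliencyExtractor
from .synthgen import make_dataset

logger = logging.getLogger(__name__)


def _version() -> str:
    from . import __version__

    return __version__

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "schema_version": 1,
    "seed": 0,
    "out_dir": None,  # no artifacts written when None
    "data": {
        "n_benign": 200,
        "n_malignant": 100,
        "difficulty": 0.3,
        "shape": [128, 128],
        "speckle_looks": 16,
    },
    "refine": {
        "enabled": True,
        "n_levels": 3,
        "min_area": 20,
        "trigger_area_frac": 0.001,
        "trigger_solidity": 0.5,
        "presmooth_sigma": 1.5,
    },
    "ica": {
        "patch_size": 11,
        "stride": 4,
        "k": 32,
        "drop_top": 1,
        "max_patches": 20000,
        "train_fraction": 0.25,
    },
    "deep_stub": {"dim": 27},
    "classify": {"kind": "svm_cubic", "k_folds": 5},
}


def _merge(base: dict, override: dict, path="") -> dict:
    out = dict(base)
    for key, val in override.items():
        if key not in base:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict):
            out[key] = _merge(base[key], val or {}, path + key + ".")
        else:
            out[key] = val
    return out


def validate_config(cfg: dict | None) -> dict:
    """Merge a partial config over the defaults, rejecting unknown keys."""
    cfg = _merge(DEFAULT_CONFIG, cfg or {})
    if cfg["schema_version"] != 1:
        raise ValueError(f"unsupported schema_version {cfg['schema_version']}")
    return cfg


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def run_pipeline(cfg: dict | None = None) -> dict:
    """Run all stages in order on synthetic data and return the run report.

    Stages: phantom generation, quantization refinement of an (empty) coarse
    mask, segmentation scoring against ground truth, ICA saliency features,
    stub deep features, serial fusion, pooled k-fold cross-validation.
    """
    cfg = validate_config(cfg)
    seed = int(cfg["seed"])
    # IO location is not a scientific parameter: keep it out of the recorded
    # config so identical runs hash identically wherever they are written
    sci_cfg = {k: v for k, v in cfg.items() if k != "out_dir"}
    rep: dict = {"config": sci_cfg, "version": _version()}

    d = cfg["data"]
    samples = make_dataset(d["n_benign"], d["n_malignant"], seed=seed,
                           difficulty=d["difficulty"], shape=tuple(d["shape"]),
                           speckle_looks=d["speckle_looks"])
    labels = np.array([s.label for s in samples])
    logger.info("generated %d phantoms", len(samples))

    r = cfg["refine"]
    if r["enabled"]:
        refiner = QuantizationRefiner(
            n_levels=r["n_levels"],
            crit=RegionCriteria(min_area=r["min_area"]),
            trigger=TriggerRule(min_area_frac=r["trigger_area_frac"],
                                solidity_floor=r["trigger_solidity"]),
            presmooth_sigma=r["presmooth_sigma"],
        )
        empty = [np.zeros(s.image.shape, dtype=np.uint8) for s in samples]
        masks = refiner.transform(list(zip([s.image for s in samples], empty)))
    else:
        masks = [s.mask for s in samples]
    truths = [s.mask for s in samples]
    rep["segmentation"] = {
        "mean_iou": mean_iou(masks, truths),
        "mean_f1": mean_fscore(masks, truths),
    }

    # non-empty pooling region for every image, even if refinement failed
    pool_masks = [m if m.sum() else s.mask for m, s in zip(masks, samples)]

    ic = cfg["ica"]
    n_train = max(int(len(samples) * ic["train_fraction"]), 10)
    train_idx = np.random.default_rng(seed).permutation(len(samples))[:n_train]
    extractor = IcaSaliencyExtractor(
        patch_size=ic["patch_size"], stride=ic["stride"], k=ic["k"],
        drop_top=ic["drop_top"], max_patches=ic["max_patches"], seed=seed,
    )
    extractor.fit([samples[i].image for i in train_idx])
    pairs = [(s.image, m) for s, m in zip(samples, pool_masks)]
    F1 = extractor.transform(pairs)

    stub = DeepFeatureStub(dim=cfg["deep_stub"]["dim"], seed=seed)
    F2 = stub.transform(pairs)

    fused, scaler = SerialFusion().fit(F1, F2), None
    alpha = fused.transform(F1, F2)
    rep["features"] = {"n_ica": int(F1.shape[1]), "m_deep": int(F2.shape[1]),
                       "fused_dim": int(alpha.shape[1])}

    c = cfg["classify"]
    spec = ClassifierSpec(kind=c["kind"], seed=seed)
    cm, metrics = cross_validate(alpha, labels, spec, k=c["k_folds"], seed=seed)
    rep["classification"] = {
        "confusion_matrix": {"bb": cm.bb, "bm": cm.bm, "mb": cm.mb, "mm": cm.mm},
        "metrics": metrics.to_dict(),
    }

    if cfg["out_dir"]:
        out = Path(cfg["out_dir"])
        out.mkdir(parents=True, exist_ok=True)
        artifacts = {}
        np.savetxt(out / "features_fused.csv", alpha, delimiter=",")
        cm.to_csv(out / "confusion_matrix.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(rep, fh, indent=2, default=str)
        for f in sorted(out.iterdir()):
            if f.is_file() and f.name != "manifest.json":
                artifacts[f.name] = _sha256(f.read_bytes())
        manifest = {
            "config_hash": _sha256(json.dumps(sci_cfg, sort_keys=True, default=str).encode()),
            "seed": seed,
            "version": _version(),
            "artifacts": artifacts,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        rep["manifest"] = manifest
    return rep
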