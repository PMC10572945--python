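"""End-to-end pipeline: simulate -> segment -> extract -> augment (train
side) -> train -> evaluate.

Every stage draws its randomness from seeds spawned deterministically from
the single pipeline seed, so one seed fixes every artifact.  When an output
directory is given, the feature stage writes its table plus a manifest keyed
by a hash of the configuration; a rerun with an unchanged configuration
reuses the cached table instead of re-segmenting.

Augmentation policy: the source method augments the whole corpus before
splitting, which would let augmented copies of one image straddle the
train/test boundary; here the 3:2 split is taken over *source* images and
only training sources contribute augmented variants, so reported test
accuracy is leakage-free.  For the named dihedral operations the joint
(intensity, local-mean, local-median) histogram is invariant, so segmenting
a rotated image yields the rotated ROI; the pipeline therefore augments the
segmented ROI rendering directly instead of re-running the threshold search
per variant.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import augment as aug
from . import evaluate as ev
from . import features as feat
from . import io as sio
from . import phantom as ph
from . import tsallis as ts
from .config import PipelineConfig
from .egnnn import EGNNN, EGNNNResults, GravConfig

log = logging.getLogger("sonomass")


@dataclass
class PipelineResult:
    """Artifacts of one full pipeline run."""

    config: PipelineConfig
    features: pd.DataFrame
    fit: EGNNNResults
    report: ev.ClassificationReport
    timings: dict[str, float] = field(default_factory=dict)

    def report_dict(self) -> dict:
        out = self.report.to_dict()
        out["seed"] = self.config.seed
        out["n_sources"] = int(self.features["source"].nunique())
        return out


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _rendering(img: np.ndarray, roi: np.ndarray, mode: str) -> np.ndarray:
    """Stage input handed to the curvelet decomposition."""
    if mode == "roi_mask":
        return (roi * 255).astype(np.uint8)
    if mode == "masked_image":
        return (img * roi).astype(np.uint8)
    if mode == "image":
        return np.asarray(img, dtype=np.uint8)
    raise ValueError(f"unknown feature input mode: {mode!r}")


def compute_feature_table(cfg: PipelineConfig) -> pd.DataFrame:
    """Simulate, segment, and extract curvelet radiomics.

    Returns one row per (source image, augmentation variant); variant 0 is
    the unaugmented rendering.  Columns: ``source``, ``variant``, ``label``,
    ``dice`` (against the phantom ground truth), then the named features.
    """
    t0 = time.time()
    base = ph.PhantomSpec(
        height=cfg.phantom.height,
        width=cfg.phantom.width,
        speckle_shape=cfg.phantom.speckle_shape,
        mass_contrast=cfg.phantom.mass_contrast,
    )
    dataset = ph.generate_dataset(
        cfg.phantom.n_per_class, base_spec=base, seed=cfg.seed
    )
    log.info("simulate: %d phantoms (%.1fs)", len(dataset), time.time() - t0)

    n_variants = cfg.augment.multiplier if cfg.augment.enabled else 1
    # one shared search seed: identical optimizer trajectories across images
    # keep threshold-placement variation out of the per-image features
    seg_seed = int(
        np.random.SeedSequence([cfg.seed, 2]).generate_state(1)[0] % (2**31)
    )
    t0 = time.time()
    rows = []
    names: list[str] = []
    mode = getattr(cfg.features, "input", "roi_mask")
    for idx, (img, mask, label) in enumerate(dataset):
        seed = seg_seed
        seg = ts.segment_image(
            img,
            ml=cfg.segment.ml,
            lam=cfg.segment.lam,
            k_q=cfg.segment.k_q,
            method=cfg.segment.method,
            budget=cfg.segment.budget,
            seed=seed,
            polarity=cfg.segment.polarity,
        )
        dice = 2.0 * np.sum(seg.roi_mask & mask) / max(
            seg.roi_mask.sum() + mask.sum(), 1
        )
        render = _rendering(img, seg.roi_mask, mode)
        if n_variants <= 8:
            variants = aug.dihedral_orbit(render)[:n_variants]
        else:
            variants = aug.augment_image(render, multiplier=n_variants, seed=seed)
        for v, arr in enumerate(variants):
            vec, names = feat.image_features(
                arr,
                size=cfg.features.size,
                n_coarse_angles=cfg.features.n_coarse_angles,
                normalize=cfg.features.normalize,
            )
            rows.append((idx, v, label, dice, vec))
    log.info(
        "segment+extract: %d sources x %d variants, %d features (%.1fs)",
        len(dataset), n_variants, len(names), time.time() - t0,
    )
    df = pd.DataFrame(np.vstack([r[4] for r in rows]), columns=names)
    df.insert(0, "dice", [r[3] for r in rows])
    df.insert(0, "label", [r[2] for r in rows])
    df.insert(0, "variant", [r[1] for r in rows])
    df.insert(0, "source", [r[0] for r in rows])
    return df


def train_and_evaluate(
    df: pd.DataFrame, cfg: PipelineConfig
) -> tuple[EGNNNResults, ev.ClassificationReport]:
    """3:2 split over sources, gravitational training, test-set report."""
    sources = sorted(df["source"].unique())
    src_train, src_test = ev.split_3_2(sources, seed=cfg.seed + 3)
    feat_cols = [c for c in df.columns if c not in ("source", "variant", "label", "dice")]
    train_df = df[df["source"].isin(src_train)]
    test_df = df[(df["source"].isin(src_test)) & (df["variant"] == 0)]
    x_train = train_df[feat_cols].to_numpy(dtype=float)
    y_train = train_df["label"].to_numpy()
    x_test = test_df[feat_cols].to_numpy(dtype=float)
    y_test = test_df["label"].to_numpy()
    class_names = [c for c in ph.CLASS_NAMES if c in set(df["label"])] or None

    tr = cfg.train
    if tr.tune:
        from .npoa import tune_egnnn

        sub_tr, sub_val = ev.split_3_2(range(len(x_train)), seed=cfg.seed + 4)
        hp, _ = tune_egnnn(
            x_train[sub_tr], y_train[sub_tr], x_train[sub_val], y_train[sub_val],
            budget=tr.tune_budget, seed=cfg.seed + 5,
        )
        log.info("tune: selected %s", hp)
        gcfg = GravConfig(
            c0=hp["c0"], beta=hp["beta"], population=hp["population"],
            iterations=tr.iterations, batch_size=tr.batch_size,
            learning_rate=tr.learning_rate, polish_epochs=tr.polish_epochs,
            n_polish=tr.n_polish, seed=cfg.seed + 6,
        )
        s_units = hp["s_units"] - hp["s_units"] % cfg.train.pool
    else:
        gcfg = GravConfig(
            c0=tr.c0, beta=tr.beta, population=tr.population,
            iterations=tr.iterations, batch_size=tr.batch_size,
            learning_rate=tr.learning_rate, polish_epochs=tr.polish_epochs,
            n_polish=tr.n_polish, seed=cfg.seed + 6,
        )
        s_units = tr.s_units

    model = EGNNN(x_train, y_train, s_units=s_units, pool=tr.pool,
                  class_names=class_names, output=tr.output)
    fit = model.fit(gcfg)
    scores = fit.scores(x_test)
    report = ev.report(
        y_test, fit.predict(x_test), scores=scores, class_names=model.class_names
    )
    return fit, report


def run_pipeline(
    cfg: PipelineConfig, out_dir: str | Path | None = None
) -> PipelineResult:
    """Run every stage; optionally persist artifacts with manifests."""
    timings: dict[str, float] = {}
    df = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        manifest_path = out_dir / "manifest.json"
        features_path = out_dir / "features.csv"
        if manifest_path.exists() and features_path.exists():
            manifest = sio.read_report(manifest_path)
            if manifest.get("config_hash") == _config_hash(cfg):
                log.info("resume: reusing cached feature table")
                df = sio.read_features(features_path)
    if df is None:
        t0 = time.time()
        df = compute_feature_table(cfg)
        timings["features"] = time.time() - t0
        if out_dir is not None:
            out_dir.mkdir(parents=True, exist_ok=True)
            df.to_csv(out_dir / "features.csv", index=False, float_format="%.12g")
            sio.write_report(
                out_dir / "manifest.json",
                {"config_hash": _config_hash(cfg), "n_rows": len(df)},
            )

    t0 = time.time()
    fit, report = train_and_evaluate(df, cfg)
    timings["train_evaluate"] = time.time() - t0
    result = PipelineResult(
        config=cfg, features=df, fit=fit, report=report, timings=timings
    )
    if out_dir is not None:
        sio.write_report(Path(out_dir) / "report.json", result.report_dict())
    return result
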