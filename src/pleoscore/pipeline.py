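"""End-to-end measurement and experiment runs.

``run_measure`` executes the five-stage measurement on a directory of
RGB tiles paired (by filename stem) with nucleus label masks: stain
unmixing -> per-nucleus geometry -> chromatin/hollow analysis -> feature
calculation -> HM scoring, writing one scored CSV row per nucleus.

``run_full_experiment`` reproduces the whole validation shape on
synthetic data: per-score feature quartile summaries, SVM-RBF
cross-validation metrics, and the feature-ablation grid.

Every CSV output starts with a comment line embedding the configuration
hash and seed, so reruns are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pleoscore import features as feat
from pleoscore import hm as hm_mod
from pleoscore import regions, stain
from pleoscore.evaluate import DEFAULT_ABLATION_SUBSETS, CVConfig, ablation, cross_validate_svm
from pleoscore.features import SizeParams
from pleoscore.hm import HMWeights

logger = logging.getLogger("pleoscore")

SCORED_COLUMNS = [
    "tile",
    "nucleus_id",
    "ar",
    "peri",
    "hol",
    "ep_size",
    "e_size",
    "e_shape",
    "e_appearance",
    "hm",
]


class PipelineError(RuntimeError):
    """A pipeline run could not produce any output."""


@dataclass
class PipelineConfig:
    tiles_dir: Path
    masks_dir: Path
    out_dir: Path
    corrected_masks_dir: Path | None = None  # expert-edited masks override
    size_params: SizeParams = field(default_factory=SizeParams)
    weights: HMWeights = field(default_factory=HMWeights)
    cv: CVConfig = field(default_factory=CVConfig)
    seed: int = 0
    i0: float = 255.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("tiles_dir", "masks_dir", "out_dir", "corrected_masks_dir"):
            if d[key] is not None:
                d[key] = str(d[key])
        return d


def config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    header = f"# pleoscore config_hash={config_hash(cfg)} seed={cfg.seed}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.10g")


def read_scored_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def measure_tile(
    rgb: np.ndarray,
    mask: regions.LabelMask,
    size_params: SizeParams = SizeParams(),
    weights: HMWeights = HMWeights(),
    i0: float = 255.0,
) -> list[tuple[regions.NucleusGeometry, feat.FeatureVector]]:
    """Measure and score every nucleus in one tile."""
    od = stain.rgb_to_od(rgb, i0=i0)
    basis = stain.estimate_stain_basis(od)
    h = stain.extract_h_channel(od, basis)
    geoms = []
    for nid in mask.nucleus_ids():
        geom = regions.region_geometry(mask, nid)
        chrom = regions.chromatin_map(h, mask, nid)
        geoms.append(geom.with_hol(regions.count_hollow(mask, nid, chrom)))
    scored = hm_mod.score_table(feat.featurize(geoms, size_params), weights)
    return list(zip(geoms, scored))


def run_measure(cfg: PipelineConfig) -> Path:
    """Measure every paired tile/mask and write the scored CSV."""
    import imageio.v3 as iio

    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    tiles = sorted(
        p for p in Path(cfg.tiles_dir).iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not tiles:
        raise PipelineError(f"no tiles found in {cfg.tiles_dir}")

    def mask_for(stem: str) -> Path | None:
        dirs = [cfg.masks_dir] if cfg.corrected_masks_dir is None else [
            cfg.corrected_masks_dir, cfg.masks_dir
        ]
        for d in dirs:
            for ext in (".tif", ".tiff", ".png"):
                p = Path(d) / f"{stem}{ext}"
                if p.exists():
                    return p
        return None

    rows = []
    n_done = 0
    for tile_path in tiles:
        mask_path = mask_for(tile_path.stem)
        if mask_path is None:
            logger.warning("no mask for tile %s; skipped", tile_path.name)
            continue
        rgb = iio.imread(tile_path)
        mask = regions.read_label_mask(mask_path)
        for geom, fv in measure_tile(rgb, mask, cfg.size_params, cfg.weights, cfg.i0):
            rows.append(
                {
                    "tile": tile_path.stem,
                    "nucleus_id": fv.nucleus_id,
                    "ar": geom.ar,
                    "peri": geom.peri,
                    "hol": geom.hol,
                    "ep_size": fv.ep_size,
                    "e_size": fv.e_size,
                    "e_shape": fv.e_shape,
                    "e_appearance": fv.e_appearance,
                    "hm": fv.hm,
                }
            )
        n_done += 1
    if n_done == 0:
        raise PipelineError("all tiles were skipped (no pairable masks)")
    df = pd.DataFrame(rows)
    out = cfg.out_dir / "scored.csv"
    _write_csv(df[SCORED_COLUMNS], out, cfg)
    logger.info("wrote %s (%d nuclei from %d tiles)", out, len(df), n_done)
    return out


def per_score_quartiles(scored: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Quartile summary (min/q1/median/q3/max) of each feature per score."""
    df = scored.copy()
    df["score"] = np.asarray(labels)
    rows = []
    for feature in ("e_size", "e_shape", "e_appearance", "hm"):
        for score, grp in df.groupby("score"):
            q = np.quantile(grp[feature], [0.0, 0.25, 0.5, 0.75, 1.0])
            rows.append(
                {
                    "feature": feature,
                    "score": score,
                    "min": q[0],
                    "q1": q[1],
                    "median": q[2],
                    "q3": q[3],
                    "max": q[4],
                }
            )
    return pd.DataFrame(rows)


def run_full_experiment(
    cfg: PipelineConfig,
    scored_csv: Path | None = None,
    labels_csv: Path | None = None,
) -> dict[str, Path]:
    """Metrics JSON + ablation CSV + per-score quartile CSV.

    Inputs are a scored CSV (from ``run_measure``) and a labels CSV with
    columns ``tile`` and ``score``; rows are joined on ``tile``.
    """
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    scored = read_scored_csv(scored_csv or cfg.out_dir / "scored.csv")
    labels_df = pd.read_csv(labels_csv or cfg.out_dir / "labels.csv", comment="#")
    merged = scored.merge(labels_df[["tile", "score"]], on="tile", how="inner")
    if merged.empty:
        raise PipelineError("no overlap between scored nuclei and labels")
    y = merged["score"].to_numpy()

    report = cross_validate_svm(merged[["hm"]], y, cfg.cv)
    metrics_path = cfg.out_dir / "metrics.json"
    payload = report.to_dict()
    payload["config_hash"] = config_hash(cfg)
    metrics_path.write_text(json.dumps(payload, indent=2, sort_keys=True))

    grid = ablation(merged, y, DEFAULT_ABLATION_SUBSETS, cfg.cv)
    ablation_path = cfg.out_dir / "ablation.csv"
    _write_csv(grid, ablation_path, cfg)

    quart = per_score_quartiles(merged, merged["score"])
    quartile_path = cfg.out_dir / "quartiles.csv"
    _write_csv(quart, quartile_path, cfg)

    return {
        "metrics": metrics_path,
        "ablation": ablation_path,
        "quartiles": quartile_path,
    }
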