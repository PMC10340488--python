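"""End-to-end segmentation pipeline over an image directory.

Composes the stages: handcrafted segmentation, optional deep inference,
AND-fusion, and metric evaluation against ground truth when available.
Stage outputs are cached under the run directory keyed by a content hash of
(input bytes, stage configuration), so re-running with the same inputs and
config skips completed stages; reports are written with sorted keys and no
timestamps, so identical runs produce byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .deepseg import LossParams, UNet, UNetSpec, predict_mask
from .ensemble import EnsembleConfig, fuse_masks
from .exceptions import ConfigError, StageError
from .handcrafted import SegConfig, segment_handcrafted
from .io import read_mask, read_rgb, write_mask, write_overlay
from .metrics import METRIC_NAMES, evaluate


@dataclass
class PipelineConfig:
    images_dir: Path
    out_dir: Path
    masks_dir: Path | None = None          # ground truth; enables evaluation
    model_path: Path | None = None         # trained U-Net; enables deep + fusion
    seg: SegConfig = field(default_factory=SegConfig)
    unet: UNetSpec = field(default_factory=UNetSpec)
    loss: LossParams = field(default_factory=LossParams)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    use_deep: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.images_dir = Path(self.images_dir)
        self.out_dir = Path(self.out_dir)
        if self.masks_dir is not None:
            self.masks_dir = Path(self.masks_dir)
        if self.use_deep and self.model_path is None:
            raise ConfigError("use_deep=True requires model_path (fusion needs a "
                              "trained deep model)")


def _hash(*parts: bytes | str) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p.encode() if isinstance(p, str) else p)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the pipeline; returns (and writes) the JSON-able run report."""
    images = sorted(p for p in config.images_dir.iterdir()
                    if p.suffix.lower() in (".png", ".tif", ".tiff", ".jpg", ".jpeg"))
    if not images:
        raise FileNotFoundError(f"no images found in {config.images_dir}")
    out = config.out_dir
    for sub in ("handcrafted", "deep", "fused", "overlays"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}

    model = None
    if config.use_deep:
        try:
            model = UNet.load(config.model_path, config.unet)
        except Exception as exc:
            raise StageError("load_model", exc) from exc

    seg_key = repr(config.seg)
    rows = []
    for path in images:
        raw = path.read_bytes()
        image = read_rgb(path)
        name = path.stem + ".png"

        hc_path = out / "handcrafted" / name
        key = _hash(raw, seg_key)
        if manifest.get(f"handcrafted/{name}") == key and hc_path.exists():
            hc_mask = read_mask(hc_path)
        else:
            hc_mask, _ = segment_handcrafted(image, config.seg)
            write_mask(hc_path, hc_mask)
            manifest[f"handcrafted/{name}"] = key

        final_mask = hc_mask
        if model is not None:
            deep_mask = predict_mask(model, image)
            write_mask(out / "deep" / name, deep_mask)
            final_mask = fuse_masks(hc_mask, deep_mask, config.ensemble)
            write_mask(out / "fused" / name, final_mask)
        write_overlay(out / "overlays" / name, image, final_mask)

        row: dict = {"image": name, "mask_pixels": int(final_mask.sum())}
        if config.masks_dir is not None:
            gt = read_mask(config.masks_dir / name)
            rep = evaluate(final_mask, gt)
            row.update({k: getattr(rep, k) for k in METRIC_NAMES})
        rows.append(row)

    report: dict = {
        "n_images": len(images),
        "mode": "ensemble" if model is not None else "handcrafted",
        "per_image": rows,
    }
    if config.masks_dir is not None:
        report["aggregate"] = {k: float(np.mean([r[k] for r in rows]))
                               for k in METRIC_NAMES}
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
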