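"""End-to-end orchestration: select atlases, register, fuse, evaluate.

The full run mirrors the three-stage multi-atlas design: a small subset of k
atlases is chosen from the library (uniform max–min selection by default,
which is target-independent), each selected atlas is registered to the target
and its mask propagated, and the warped pairs are fused into the final brain
mask by voxel-wise classification.

`run_alfa` drives the pipeline from manifests and a config file; `loocv` runs
the leave-one-out benchmark over a cohort, holding each subject out as the
target while the rest form the atlas library.  Both contain per-case failures:
one bad case is recorded and the run continues.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
import traceback
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas_selection import (DataVectorSet, SelectionResult, build_vectors,
                              select_most_similar, select_uniform)
from .evaluation import evaluate_case
from .fusion import FusionConfig, fuse, largest_component_postprocess
from .registration import BuiltinBackend, apply_transform
from .volumes import BinaryMask, Volume, read_mask, read_volume, write_volume

logger = logging.getLogger("alfa")

__all__ = ["RunConfig", "RunRecord", "run_alfa", "loocv",
           "extract_brain", "read_manifest", "write_manifest"]


@dataclass
class RunConfig:
    """Configuration of a full brain-extraction run."""

    atlas_manifest: str = ""
    targets: list[str] = field(default_factory=list)
    k: int = 3
    selection_strategy: str = "uas"  # uas | msas
    selection_metric: str = "l2"
    prealigned: bool = False
    registration_mode: str = "affine+nonlinear"
    registration_settings: dict = field(default_factory=dict)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    normalization: bool = True
    postprocess: bool = False
    output_dir: str = "alfa_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fus = raw.pop("fusion", {})
        cfg = cls(**raw)
        if isinstance(fus, dict):
            cfg.fusion = FusionConfig(**fus)
        return cfg

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunRecord:
    """Provenance of one pipeline run, serialized alongside its outputs."""

    config: dict
    version: str
    selection: dict | None = None
    timings_s: dict = field(default_factory=dict)
    case_outputs: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    failures: dict = field(default_factory=dict)

    def save(self, path: str) -> None:
        os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Manifests: plain tab-separated (id, image path[, mask path]) for diff-ability
# ---------------------------------------------------------------------------

def read_manifest(path: str) -> list[tuple[str, ...]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append(tuple(line.split("\t")))
    if not rows:
        raise ValueError(f"manifest {path} is empty")
    return rows


def write_manifest(rows: Sequence[Sequence[str]], path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


# ---------------------------------------------------------------------------
# In-memory pipeline core
# ---------------------------------------------------------------------------

def _make_backend(cfg: RunConfig) -> BuiltinBackend:
    return BuiltinBackend(**cfg.registration_settings)


def extract_brain(target: Volume,
                  library: Sequence[tuple[Volume, BinaryMask]],
                  k: int = 3,
                  strategy: str = "uas",
                  backend: BuiltinBackend | None = None,
                  registration_mode: str = "affine+nonlinear",
                  fusion_cfg: FusionConfig | None = None,
                  metric: str = "l2",
                  normalize: bool = True,
                  vectors: DataVectorSet | None = None,
                  postprocess: bool = False,
                  ) -> tuple[BinaryMask, SelectionResult]:
    """Segment one target from an atlas library; the in-memory pipeline core.

    The library is assumed roughly aligned for the purpose of atlas selection
    (vectors are compared on the native grids); registration then aligns the
    selected atlases precisely to the target before fusion.  A precomputed
    ``vectors`` set short-circuits vector building for repeated calls.
    """
    if len(library) < k:
        raise ValueError(f"library of {len(library)} atlases cannot supply k={k}")
    backend = backend or BuiltinBackend()
    fusion_cfg = fusion_cfg or FusionConfig(k=k)
    images = [img for img, _ in library]
    if vectors is None:
        vectors = build_vectors(images, prealigned=True, normalize=normalize)
    if strategy == "uas":
        sel = select_uniform(vectors, k, metric=metric)
    elif strategy == "msas":
        sel = select_most_similar(vectors, target, k, metric=metric,
                                  normalize=normalize)
    else:
        raise ValueError(f"unknown selection strategy {strategy!r}")
    by_id = {img.id: (img, msk) for img, msk in library}
    warped: list[tuple[Volume, BinaryMask]] = []
    for aid in sel.selected_ids:
        img, msk = by_id[aid]
        t = backend.register(img, target, mode=registration_mode)
        warped.append((apply_transform(t, img, target),
                       apply_transform(t, msk, target)))
    out = fuse(target, warped, fusion_cfg)
    if postprocess:
        out = largest_component_postprocess(out)
    return out, sel


# ---------------------------------------------------------------------------
# File-driven entry points
# ---------------------------------------------------------------------------

def _load_library(manifest: str) -> list[tuple[Volume, BinaryMask]]:
    lib = []
    for row in read_manifest(manifest):
        if len(row) < 3:
            raise ValueError(f"atlas manifest rows need (id, image, mask): {row}")
        sid, img_p, msk_p = row[0], row[1], row[2]
        img = read_volume(img_p)
        msk = read_mask(msk_p)
        img.id = sid
        msk.id = sid
        lib.append((img, msk))
    return lib


def run_alfa(cfg: RunConfig) -> RunRecord:
    """Run selection, registration and fusion for every configured target."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    record = RunRecord(config=cfg.snapshot(), version=__version__)
    os.makedirs(cfg.output_dir, exist_ok=True)
    t0 = time.perf_counter()
    library = _load_library(cfg.atlas_manifest)
    images = [img for img, _ in library]
    vectors = build_vectors(images, prealigned=True, normalize=cfg.normalization)
    record.timings_s["load_and_vectors"] = time.perf_counter() - t0
    backend = _make_backend(cfg)
    fusion_cfg = cfg.fusion
    for target_path in cfg.targets:
        case_t0 = time.perf_counter()
        try:
            target = read_volume(target_path)
            mask, sel = extract_brain(
                target, library, k=cfg.k, strategy=cfg.selection_strategy,
                backend=backend, registration_mode=cfg.registration_mode,
                fusion_cfg=fusion_cfg, metric=cfg.selection_metric,
                normalize=cfg.normalization, vectors=vectors,
                postprocess=cfg.postprocess)
            out_path = os.path.join(cfg.output_dir, f"{target.id}_brainmask.nii.gz")
            write_volume(mask, out_path)
            record.case_outputs[target.id] = out_path
            if record.selection is None:
                record.selection = dataclasses.asdict(sel)
        except Exception as exc:  # noqa: BLE001 - crash containment per case
            logger.error("case %s failed: %s", target_path, exc)
            record.failures[target_path] = traceback.format_exc(limit=3)
        finally:
            record.timings_s[os.path.basename(target_path)] = \
                time.perf_counter() - case_t0
    record.save(os.path.join(cfg.output_dir, "run_record.json"))
    return record


def loocv(cfg: RunConfig, cohort_manifest: str,
          library: Sequence[tuple[Volume, BinaryMask]] | None = None) -> pd.DataFrame:
    """Leave-one-out cross-validation over a cohort with reference masks.

    Each subject in turn is held out as the target; the remaining subjects
    form the atlas library from which k atlases are selected and fused.
    Returns one row of agreement metrics per subject.
    """
    if library is None:
        library = _load_library(cohort_manifest)
    backend = _make_backend(cfg)
    rows = []
    for i, (img, ref) in enumerate(library):
        rest = [p for j, p in enumerate(library) if j != i]
        try:
            mask, sel = extract_brain(
                img, rest, k=cfg.k, strategy=cfg.selection_strategy,
                backend=backend, registration_mode=cfg.registration_mode,
                fusion_cfg=cfg.fusion, metric=cfg.selection_metric,
                normalize=cfg.normalization, postprocess=cfg.postprocess)
            rep = evaluate_case(mask, ref, case_id=img.id)
            rows.append({"case_id": rep.case_id, "dice_pct": rep.dice_pct,
                         "hausdorff_mm": rep.hausdorff_mm,
                         "sensitivity_pct": rep.sensitivity_pct,
                         "specificity_pct": rep.specificity_pct,
                         "auto_volume_ml": rep.auto_volume_ml,
                         "ref_volume_ml": rep.ref_volume_ml,
                         "selected": ",".join(sel.selected_ids), "error": ""})
        except Exception as exc:  # noqa: BLE001 - crash containment per case
            logger.error("loocv case %s failed: %s", img.id, exc)
            rows.append({"case_id": img.id, "dice_pct": np.nan,
                         "hausdorff_mm": np.nan, "sensitivity_pct": np.nan,
                         "specificity_pct": np.nan, "auto_volume_ml": np.nan,
                         "ref_volume_ml": np.nan, "selected": "",
                         "error": str(exc)})
    return pd.DataFrame(rows)
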