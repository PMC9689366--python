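"""Cohort data model, manifest I/O, conditioning encoding and splitting.

A cohort is a collection of nodule growth annotations: one record per
(nodule, radiologist) pair, each holding the 32x32 baseline and
follow-up patches, the binary segmentation masks, the annotated longest
diameters D0/D1 in mm, the elapsed time between the two CT studies and
the pixel spacing.  Patches are stored on disk as 16-bit greyscale PNG
and referenced from a CSV manifest.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

PATCH_SIZE = 32
#: diameter increase (mm) above which radiological guidelines call growth
GROWTH_THRESHOLD_MM = 2.0
#: diameter cap (mm) used to normalise D0 into [0,1]; the conventional
#: nodule/mass boundary
D0_NORM_CAP_MM = 30.0
#: day boundaries of the ordinal time-to-predict bins (6/12/24/>24 months)
TIME_BIN_EDGES_DAYS = (183, 365, 730)

MANIFEST_COLUMNS = [
    "nodule_id",
    "annotator_id",
    "path_img_t0",
    "path_img_t1",
    "path_mask_t0",
    "path_mask_t1",
    "d0_mm",
    "d1_mm",
    "elapsed_days",
    "spacing_mm",
    "growth_label",
]


def derive_growth_label(d0_mm: float, d1_mm: float) -> int:
    """Growth label per the 2 mm guideline: 1 iff D1 - D0 > 2 mm (strict)."""
    if d0_mm < 0 or d1_mm < 0:
        raise ValueError("diameters must be non-negative")
    return int(d1_mm - d0_mm > GROWTH_THRESHOLD_MM)


def encode_conditioning(elapsed_days: int, d0_mm: float) -> tuple[float, float]:
    """Encode (time to predict, baseline diameter) as scalars in [0,1].

    The elapsed time is binned into the ordinal follow-up categories of
    radiological guidelines (<=6, 6-12, 12-24, >24 months) and mapped to
    {0, 1/3, 2/3, 1}; the baseline diameter is clamped at 30 mm and
    scaled to [0,1].
    """
    if elapsed_days < 1:
        raise ValueError("elapsed_days must be >= 1")
    if d0_mm <= 0:
        raise ValueError("d0_mm must be > 0")
    bin_index = int(np.searchsorted(TIME_BIN_EDGES_DAYS, elapsed_days))
    t_norm = bin_index / 3.0
    d_norm = min(d0_mm, D0_NORM_CAP_MM) / D0_NORM_CAP_MM
    return t_norm, d_norm


@dataclass
class GrowthRecord:
    """One radiologist's view of one nodule pair (T0 -> T1)."""

    nodule_id: str
    annotator_id: str
    image_t0: np.ndarray
    mask_t0: np.ndarray
    d0_mm: float
    elapsed_days: int
    spacing_mm: float
    image_t1: np.ndarray | None = None
    mask_t1: np.ndarray | None = None
    d1_mm: float | None = None
    growth_label: int | None = field(default=None)

    def __post_init__(self):
        if self.d1_mm is not None and self.growth_label is None:
            self.growth_label = derive_growth_label(self.d0_mm, self.d1_mm)
        self.validate()

    @property
    def growth_mm(self) -> float:
        return self.d1_mm - self.d0_mm

    def conditioning(self) -> tuple[float, float]:
        return encode_conditioning(self.elapsed_days, self.d0_mm)

    def validate(self):
        if self.d0_mm <= 0:
            raise ValueError(f"{self.nodule_id}/{self.annotator_id}: d0_mm must be > 0")
        if self.spacing_mm <= 0:
            raise ValueError(
                f"{self.nodule_id}/{self.annotator_id}: spacing_mm must be > 0"
            )
        if self.elapsed_days < 1:
            raise ValueError(
                f"{self.nodule_id}/{self.annotator_id}: elapsed_days must be >= 1"
            )
        for name in ("image_t0", "image_t1", "mask_t0", "mask_t1"):
            arr = getattr(self, name)
            if arr is None:
                continue
            if arr.shape != (PATCH_SIZE, PATCH_SIZE):
                raise ValueError(
                    f"{self.nodule_id}/{self.annotator_id}: {name} has shape "
                    f"{arr.shape}, expected {(PATCH_SIZE, PATCH_SIZE)}"
                )
        for name in ("image_t0", "image_t1"):
            arr = getattr(self, name)
            if arr is not None and (arr.min() < 0 or arr.max() > 1):
                raise ValueError(
                    f"{self.nodule_id}/{self.annotator_id}: {name} outside [0,1]"
                )
        for name in ("mask_t0", "mask_t1"):
            arr = getattr(self, name)
            if arr is not None and not np.isin(arr, (0, 1)).all():
                raise ValueError(
                    f"{self.nodule_id}/{self.annotator_id}: {name} not binary"
                )
        if self.d1_mm is not None:
            if self.d1_mm < 0:
                raise ValueError(
                    f"{self.nodule_id}/{self.annotator_id}: d1_mm must be >= 0"
                )
            expected = derive_growth_label(self.d0_mm, self.d1_mm)
            if self.growth_label is not None and int(self.growth_label) != expected:
                raise ValueError(
                    f"{self.nodule_id}/{self.annotator_id}: growth_label "
                    f"{self.growth_label} inconsistent with diameters "
                    f"(expected {expected})"
                )


@dataclass
class Cohort:
    records: list[GrowthRecord]

    def __post_init__(self):
        self.validate()

    @property
    def annotators(self) -> list[str]:
        return sorted({r.annotator_id for r in self.records})

    @property
    def nodule_ids(self) -> list[str]:
        return sorted({r.nodule_id for r in self.records})

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_nodule(self) -> dict[str, list[GrowthRecord]]:
        out: dict[str, list[GrowthRecord]] = {}
        for r in self.records:
            out.setdefault(r.nodule_id, []).append(r)
        return out

    def validate(self):
        seen = set()
        for r in self.records:
            key = (r.nodule_id, r.annotator_id)
            if key in seen:
                raise ValueError(f"duplicate (nodule, annotator) pair {key}")
            seen.add(key)
        for nid, recs in self.by_nodule().items():
            if not 1 <= len(recs) <= 3:
                raise ValueError(
                    f"nodule {nid} has {len(recs)} annotator records (expected 1-3)"
                )


# -- raster I/O --------------------------------------------------------

_U16_MAX = 65535


def _write_png16(path: Path, array: np.ndarray, is_mask: bool):
    if is_mask:
        data = (array.astype(np.uint16)) * _U16_MAX
    else:
        data = np.round(np.clip(array, 0, 1) * _U16_MAX).astype(np.uint16)
    Image.fromarray(data).save(path)  # uint16 -> 16-bit greyscale PNG


def _read_png16(path: Path, is_mask: bool) -> np.ndarray:
    try:
        img = Image.open(path)
        arr = np.asarray(img, dtype=np.float64)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"unreadable patch file {path}: {exc}") from exc
    if is_mask:
        return (arr > _U16_MAX / 2).astype(np.uint8)
    return arr / _U16_MAX


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> Path:
    """Write patches as 16-bit PNG plus a CSV manifest; returns manifest path."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "patches"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in cohort:
        stem = f"{r.nodule_id}_{r.annotator_id}"
        paths = {}
        for col, arr, is_mask in [
            ("path_img_t0", r.image_t0, False),
            ("path_img_t1", r.image_t1, False),
            ("path_mask_t0", r.mask_t0, True),
            ("path_mask_t1", r.mask_t1, True),
        ]:
            rel = f"patches/{stem}_{col[5:]}.png"
            if arr is not None:
                _write_png16(out_dir / rel, arr, is_mask)
                paths[col] = rel
            else:
                paths[col] = ""
        rows.append(
            {
                "nodule_id": r.nodule_id,
                "annotator_id": r.annotator_id,
                **paths,
                "d0_mm": r.d0_mm,
                "d1_mm": r.d1_mm if r.d1_mm is not None else "",
                "elapsed_days": r.elapsed_days,
                "spacing_mm": r.spacing_mm,
                "growth_label": r.growth_label if r.growth_label is not None else "",
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def load_manifest(path: str | os.PathLike) -> Cohort:
    """Load a cohort from a CSV manifest, validating every record.

    The growth label is recomputed from the stored diameters and checked
    against the manifest value; any mismatch, missing column, unreadable
    patch or shape violation raises with the offending row named.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"nodule_id": str, "annotator_id": str},
        float_precision="round_trip",
    )
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    base = path.parent
    records = []
    for i, row in df.iterrows():
        where = f"manifest row {i} ({row['nodule_id']}/{row['annotator_id']})"

        def read(col, is_mask, _row=row, _where=where):
            p = _row[col]
            if pd.isna(p) or p == "":
                return None
            return _read_png16(base / p, is_mask)

        try:
            rec = GrowthRecord(
                nodule_id=str(row["nodule_id"]),
                annotator_id=str(row["annotator_id"]),
                image_t0=read("path_img_t0", False),
                image_t1=read("path_img_t1", False),
                mask_t0=read("path_mask_t0", True),
                mask_t1=read("path_mask_t1", True),
                d0_mm=float(row["d0_mm"]),
                d1_mm=None if pd.isna(row["d1_mm"]) else float(row["d1_mm"]),
                elapsed_days=int(row["elapsed_days"]),
                spacing_mm=float(row["spacing_mm"]),
                growth_label=None
                if pd.isna(row["growth_label"])
                else int(row["growth_label"]),
            )
        except ValueError as exc:
            raise ValueError(f"{where}: {exc}") from exc
        if rec.image_t0 is None or rec.mask_t0 is None:
            raise ValueError(f"{where}: baseline image and mask are required")
        records.append(rec)
    return Cohort(records)


def split_by_nodule(
    cohort: Cohort, train_fraction: float, seed: int
) -> tuple[Cohort, Cohort]:
    """Leakage-free split: all records of a nodule land in the same set."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    ids = cohort.nodule_ids
    if len(ids) < 2:
        raise ValueError("need at least 2 unique nodules to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train_ids = {ids[i] for i in perm[:n_train]}
    train = [replace(r) for r in cohort if r.nodule_id in train_ids]
    test = [replace(r) for r in cohort if r.nodule_id not in train_ids]
    return Cohort(train), Cohort(test)
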