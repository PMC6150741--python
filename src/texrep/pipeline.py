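"""End-to-end orchestration: preprocess, extract the 46-feature panel, and
summarize test-retest repeatability per reader.

Feature extraction is error-isolated per feature class: a failure in one
family records NaN values and a flag for that family's features and the run
continues.  Under the default config every FeatureVector carries exactly the
46 registry features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, echo_config, load_config
from .errors import ValidationError
from .features.fractal import fractal_features
from .features.higher_order import (
    RUN_DIRECTIONS_2D,
    RUN_DIRECTIONS_3D,
    higher_order_features,
)
from .features.histogram import histogram_features
from .features.second_order import second_order_features
from .io import read_manifest, read_study, validate_pairing
from .preprocessing import preprocess
from .registry import ALL_FEATURES, FEATURE_CLASSES, feature_class
from .repeatability import summarize_repeatability
from .volume import ImageVolume, QuantizedVolume, RoiMask

logger = logging.getLogger("texrep")

#: output table index per feature class (global histogram first, GLZSM last)
TABLE_NUMBERS = {
    "histogram": 2,
    "fractal": 3,
    "glcm": 4,
    "gldm": 5,
    "ngtdm": 6,
    "glrl": 7,
    "glzsm": 8,
}


@dataclass
class FeatureVector:
    """Named feature values for one tumor volume, plus per-feature flags."""

    values: dict[str, float]
    flags: dict[str, str] = field(default_factory=dict)
    subject_id: str = ""
    reader_id: int = 1
    day: int = 1

    def __len__(self) -> int:
        return len(self.values)


def _selected_classes(config: dict) -> list[str]:
    sel = config["features"]["classes"]
    if sel == "all":
        return list(FEATURE_CLASSES)
    unknown = [c for c in sel if c not in FEATURE_CLASSES]
    if unknown:
        raise ValidationError(f"unknown feature classes: {unknown}")
    return list(sel)


def extract_all_features(
    volume: ImageVolume, mask: RoiMask, config: dict | None = None
) -> FeatureVector:
    """Run preprocessing and all selected feature classes on one study."""
    cfg = config or DEFAULT_CONFIG
    q = preprocess(
        volume,
        mask,
        filter_mode=cfg["filter"]["mode"],
        filter_scale_mm=cfg["filter"]["scale_mm"],
        n_bins=cfg["quantization"]["bins"],
    )
    return extract_from_quantized(q, cfg)


def extract_from_quantized(q: QuantizedVolume, config: dict | None = None) -> FeatureVector:
    cfg = config or DEFAULT_CONFIG
    classes = _selected_classes(cfg)
    geometry = cfg["texture"]["high_order_geometry"]
    distance = cfg["texture"]["distance"]
    values: dict[str, float] = {}
    flags: dict[str, str] = dict(q.flags)

    def run(cls_names: tuple[str, ...], func) -> None:
        try:
            result = func()
            values.update(result.values)
            flags.update(result.flags)
        except Exception as exc:  # error isolation: one family must not kill the run
            for cls in cls_names:
                for name in FEATURE_CLASSES[cls]:
                    values[name] = float("nan")
                    flags[name] = f"failed: {exc}"
            logger.warning("feature class %s failed: %s", "/".join(cls_names), exc)

    if "histogram" in classes:
        run(("histogram",), lambda: histogram_features(q))
    if "fractal" in classes:
        run(("fractal",), lambda: fractal_features(q))
    if "glcm" in classes or "gldm" in classes:
        run(("glcm", "gldm"), lambda: second_order_features(q, distance=distance))
    if any(c in classes for c in ("ngtdm", "glrl", "glzsm")):
        if geometry == "2d":
            kwargs = dict(
                neighborhood="8-in-plane",
                run_directions=RUN_DIRECTIONS_2D,
                connectivity=6,
            )
        else:
            kwargs = dict(
                neighborhood="26", run_directions=RUN_DIRECTIONS_3D, connectivity=26
            )
        run(("ngtdm", "glrl", "glzsm"), lambda: higher_order_features(q, **kwargs))
    ordered = {name: values[name] for name in ALL_FEATURES if name in values}
    return FeatureVector(values=ordered, flags=flags)


def features_to_long(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Long-format table: subject_id, reader_id, day, feature_name, value, flag."""
    rows = []
    for fv in vectors:
        for name, value in fv.values.items():
            rows.append(
                {
                    "subject_id": fv.subject_id,
                    "reader_id": fv.reader_id,
                    "day": fv.day,
                    "feature_name": name,
                    "value": value,
                    "flag": fv.flags.get(name, ""),
                }
            )
    return pd.DataFrame(rows)


def run_study(
    manifest: pd.DataFrame | str | Path,
    config: dict | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Extract features for every manifest row and build repeatability tables.

    Returns ``{"features": long_df, "repeatability": {reader_id: {table_no: df}}}``
    and, if ``out_dir`` is given, writes ``features.csv``, one
    ``repeatability_reader<k>/table<n>.csv`` per reader and feature class,
    and the resolved config.
    """
    cfg = config or load_config()
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    validate_pairing(manifest)
    vectors = []
    for row in manifest.itertuples(index=False):
        volume, mask = read_study(row.volume_path, row.mask_path)
        fv = extract_all_features(volume, mask, cfg)
        fv.subject_id, fv.reader_id, fv.day = str(row.subject_id), int(row.reader_id), int(row.day)
        vectors.append(fv)
    long_df = features_to_long(vectors)
    summary = summarize_repeatability(long_df)
    summary["feature_class"] = summary["feature_name"].map(feature_class)
    summary["table"] = summary["feature_class"].map(TABLE_NUMBERS)
    tables: dict[int, dict[int, pd.DataFrame]] = {}
    for reader, rgrp in summary.groupby("reader_id"):
        tables[int(reader)] = {
            int(t): tgrp.drop(columns=["table"]).reset_index(drop=True)
            for t, tgrp in rgrp.groupby("table")
        }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        echo_config(cfg, out_dir)
        long_df.to_csv(out_dir / "features.csv", index=False)
        for reader, by_table in tables.items():
            rdir = out_dir / f"repeatability_reader{reader}"
            rdir.mkdir(exist_ok=True)
            for t, df in by_table.items():
                df.to_csv(rdir / f"table{t}.csv", index=False)
    return {"features": long_df, "repeatability": tables, "summary": summary}
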