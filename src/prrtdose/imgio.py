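"""Reading and writing planar images, ROI masks, and tidy tables.

Count images travel as 16-bit TIFF (via ``tifffile``) or plain CSV
matrices; ROI label masks as integer-label TIFF/CSV plus a YAML name map.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .quantify import RoiSet

__all__ = [
    "write_count_image",
    "read_count_image",
    "write_roiset",
    "read_roiset",
    "write_samples_csv",
    "read_samples_csv",
]

SAMPLE_COLUMNS = ["source", "time_h", "fraction_ia", "sd"]


def write_count_image(path: str | Path, image: np.ndarray) -> None:
    """Write a count matrix as 16-bit TIFF or CSV, by file extension."""
    path = Path(path)
    if image.min() < 0:
        raise ValueError("count images must be non-negative")
    if path.suffix.lower() in (".tif", ".tiff"):
        if image.max() > np.iinfo(np.uint16).max:
            raise ValueError("counts exceed the 16-bit TIFF range")
        tifffile.imwrite(path, image.astype(np.uint16))
    else:
        np.savetxt(path, image.astype(np.int64), fmt="%d", delimiter=",")


def read_count_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path).astype(np.int64)
    return np.loadtxt(path, delimiter=",", dtype=np.int64)


def write_roiset(path_prefix: str | Path, roiset: RoiSet, fmt: str = "csv") -> None:
    """Write a label mask (<prefix>.labels.{csv,tif}) plus a YAML sidecar.

    Labels: 0 background-of-frame, 1 the background ROI, 2+ the sources in
    the YAML-listed order.  The whole-body mask (a superset of the sources)
    is stored as a separate mask file since it overlaps them.
    """
    prefix = Path(path_prefix)
    labels = np.zeros(roiset.background.shape, dtype=np.uint16)
    labels[roiset.background] = 1
    names = []
    wb = None
    for i, (name, mask) in enumerate(roiset.masks.items()):
        if name == "whole_body":
            wb = mask
            continue
        labels[mask] = len(names) + 2
        names.append(name)
    suffix = ".tif" if fmt == "tiff" else ".csv"
    _write_labels(prefix.with_suffix(".labels" + suffix), labels, fmt)
    if wb is not None:
        _write_labels(
            prefix.with_suffix(".wholebody" + suffix), wb.astype(np.uint16), fmt
        )
    meta = {
        "sources": names,
        "has_whole_body": wb is not None,
        "transmission": {k: float(v) for k, v in roiset.transmission.items()},
    }
    prefix.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def _write_labels(path: Path, arr: np.ndarray, fmt: str) -> None:
    if fmt == "tiff":
        tifffile.imwrite(path, arr.astype(np.uint16))
    else:
        np.savetxt(path, arr.astype(np.int64), fmt="%d", delimiter=",")


def read_roiset(path_prefix: str | Path) -> RoiSet:
    prefix = Path(path_prefix)
    meta = yaml.safe_load(prefix.with_suffix(".yaml").read_text())
    for suffix, fmt in ((".labels.csv", "csv"), (".labels.tif", "tiff")):
        p = prefix.with_suffix(suffix)
        if p.exists():
            labels = read_count_image(p)
            break
    else:
        raise FileNotFoundError(f"no label mask found for prefix {prefix}")
    masks: dict[str, np.ndarray] = {}
    for i, name in enumerate(meta["sources"]):
        masks[name] = labels == i + 2
    if meta.get("has_whole_body"):
        wb_path = prefix.with_suffix(".wholebody.tif" if fmt == "tiff" else ".wholebody.csv")
        masks["whole_body"] = read_count_image(wb_path) > 0
    return RoiSet(
        masks=masks,
        background=labels == 1,
        transmission=meta["transmission"],
    )


def write_samples_csv(path: str | Path, table: pd.DataFrame) -> None:
    """Write a tidy time-activity sample table (source, time_h, fraction_ia, sd)."""
    missing = set(SAMPLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"sample table missing columns {sorted(missing)}")
    table[SAMPLE_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_samples_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(SAMPLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"sample CSV missing columns {sorted(missing)}")
    return table.astype({"time_h": float, "fraction_ia": float, "sd": float})
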