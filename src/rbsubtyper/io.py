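"""Plain-text readers and writers for pipeline artifacts.

Matrices are TSV with the feature identifier in the first column and
sample identifiers in the header; segments are SEG-like TSV; regions are
BED (0-based half-open, converted to 1-based inclusive internally); gene
sets are GMT; configuration is YAML; everything else is JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
import pandas as pd
import yaml

from .cna import SEG_COLUMNS
from .matrix import OmicsMatrix

PathLike = Union[str, Path]


def write_matrix(matrix: OmicsMatrix, path: PathLike) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


def read_matrix(path: PathLike, omics: str) -> OmicsMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return OmicsMatrix(df, omics)


def write_segments(segments: pd.DataFrame, path: PathLike) -> None:
    segments[SEG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_segments(path: PathLike) -> pd.DataFrame:
    seg = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SEG_COLUMNS) - set(seg.columns)
    if missing:
        raise ValueError(f"segment table misses columns: {sorted(missing)}")
    return seg


def read_bed_regions(path: PathLike) -> pd.DataFrame:
    """BED regions (0-based half-open) -> 1-based inclusive region table."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      dtype={0: str})
    if bed.shape[1] < 3:
        raise ValueError("BED file needs chrom, start, end columns")
    names = (bed[3].astype(str) if bed.shape[1] > 3
             else pd.Series([f"region_{i}" for i in range(len(bed))]))
    out = pd.DataFrame({"chrom": bed[0],
                        "start": bed[1].astype(int) + 1,
                        "end": bed[2].astype(int)})
    out.index = pd.Index(names, name="region")
    return out


def read_gmt(path: PathLike) -> Dict[str, List[str]]:
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_json(obj, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.ndarray,)):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    if isinstance(o, pd.DataFrame):
        return o.to_dict()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_yaml(path: PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(obj: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def file_sha256(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
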