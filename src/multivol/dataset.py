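"""Dataset assembly: fit/validation split and the two training layouts.

The per-volume layout feeds one Schumacher-Hall regression per volume; the
long multi-volume layout codes every available volume of a stem as one row
(V, DBH, H, TX, d) where TX flags without-bark (1) vs with-bark (0) and d
is the merchantable top diameter (0 for total volume).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .scaling import TreeStem, StemVolumes
from .synthetic import REFERENCE_DIAMETERS

#: canonical columns of the long multi-volume record table
RECORD_COLUMNS = ("stem_id", "volume_label", "V", "DBH", "H", "TX", "d")

#: volume label -> (TX, d) coding
LABEL_CODING: dict[str, tuple[int, int]] = {
    "TVb": (0, 0), "TVw": (1, 0),
    "V5b": (0, 5), "V5w": (1, 5),
    "V10b": (0, 10), "V10w": (1, 10),
    "V15b": (0, 15), "V15w": (1, 15),
    "V20b": (0, 20), "V20w": (1, 20),
}

CODING_LABEL = {v: k for k, v in LABEL_CODING.items()}


@dataclass
class SplitDataset:
    """A stem-level random split: every record of a stem lands on one side."""

    fit_stems: set[str]
    validation_stems: set[str]
    fit_records: pd.DataFrame
    validation_records: pd.DataFrame

    def __post_init__(self) -> None:
        if self.fit_stems & self.validation_stems:
            raise ValueError("fit and validation stem sets overlap")


def split_stems(stem_ids: Sequence[str],
                records: Optional[pd.DataFrame] = None,
                fit_fraction: float = 0.7,
                fit_count: Optional[int] = None,
                seed: Optional[int] = None) -> SplitDataset:
    """Randomly split stems into fit and validation sets.

    The split is by stem: all multi-volume records of one stem share a side.
    ``fit_count`` overrides the rounded ``fit_fraction * n`` default, for
    reproducing an externally reported split size exactly.
    """
    stem_ids = list(dict.fromkeys(stem_ids))
    if len(stem_ids) < 2:
        raise ValueError("need at least two stems to split")
    if not 0.0 < fit_fraction < 1.0:
        raise ValueError("fit_fraction must be in (0, 1)")
    n_fit = int(round(fit_fraction * len(stem_ids))) if fit_count is None else int(fit_count)
    if not 0 < n_fit < len(stem_ids):
        raise ValueError("split leaves one side empty")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(stem_ids))
    fit = {stem_ids[i] for i in order[:n_fit]}
    val = {stem_ids[i] for i in order[n_fit:]}

    if records is None:
        records = pd.DataFrame(columns=list(RECORD_COLUMNS))
    fit_rec = records[records["stem_id"].isin(fit)].reset_index(drop=True)
    val_rec = records[records["stem_id"].isin(val)].reset_index(drop=True)
    return SplitDataset(fit, val, fit_rec, val_rec)


def expand_multivolume(volumes: Sequence[StemVolumes],
                       stems: Sequence[TreeStem] | Mapping[str, tuple[float, float]],
                       ) -> pd.DataFrame:
    """Long-format expansion: one (V, DBH, H, TX, d) row per available volume.

    ``stems`` supplies DBH and total height per stem, either as TreeStem
    objects or as a mapping stem_id -> (dbh_cm, height_m).  Rows whose
    merchantable diameter exceeds the stem's DBH (possible for a borderline
    stem whose butt swell crosses a limit below breast height) are rejected
    with a warning: the multi-volume model is undefined there.
    """
    if isinstance(stems, Mapping):
        meta = dict(stems)
    else:
        meta = {s.stem_id: (s.dbh_cm, s.total_height_m) for s in stems}

    rows = []
    dropped = 0
    for vol in volumes:
        labels = vol.available()
        if not labels:
            raise ValueError(f"stem {vol.stem_id} has no volumes")
        if vol.stem_id not in meta:
            raise KeyError(f"no DBH/H metadata for stem {vol.stem_id}")
        dbh, height = meta[vol.stem_id]
        for lab in labels:
            tx, d = LABEL_CODING[lab]
            if d > dbh:
                dropped += 1
                continue
            rows.append({"stem_id": vol.stem_id, "volume_label": lab,
                         "V": getattr(vol, lab), "DBH": dbh, "H": height,
                         "TX": tx, "d": d})
    if dropped:
        warnings.warn(f"dropped {dropped} records with top diameter d > DBH", stacklevel=2)
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


def subset_by_volume(records: pd.DataFrame, volume_label: str) -> pd.DataFrame:
    """Project the records of one volume label to (stem_id, V, DBH, H)."""
    if volume_label not in LABEL_CODING:
        raise ValueError(f"unknown volume label {volume_label!r}")
    sub = records.loc[records["volume_label"] == volume_label,
                      ["stem_id", "V", "DBH", "H"]].reset_index(drop=True)
    if sub.empty:
        warnings.warn(f"no records for volume {volume_label}", stacklevel=2)
    return sub


# ------------------------------------------------------------------- I/O

def _read_any(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def read_table(path: str | Path,
               column_map: Optional[Mapping[str, str] | str | Path] = None) -> pd.DataFrame:
    """Read a multi-volume record table from CSV or XLSX.

    ``column_map`` maps canonical names (V, DBH, H, TX, d, and optionally
    stem_id, volume_label) to the file's actual headers; it may be a dict or
    the path of a YAML file holding one.  Missing optional columns are
    reconstructed (volume_label from the TX/d coding; stem_id from the row
    index).
    """
    path = Path(path)
    df = _read_any(path)
    if column_map is not None:
        if isinstance(column_map, (str, Path)):
            column_map = yaml.safe_load(Path(column_map).read_text())
        rename = {actual: canonical for canonical, actual in column_map.items()}
        df = df.rename(columns=rename)
    required = ["V", "DBH", "H", "TX", "d"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing} after mapping")
    if "volume_label" not in df.columns:
        df["volume_label"] = [CODING_LABEL[(int(tx), int(d))]
                              for tx, d in zip(df["TX"], df["d"])]
    if "stem_id" not in df.columns:
        df["stem_id"] = [f"row{i}" for i in range(len(df))]
    return df[list(RECORD_COLUMNS)]


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".xlsx", ".xls"):
        records.to_excel(path, index=False)
    else:
        records.to_csv(path, index=False)


def read_stem_fixture(directory: str | Path) -> list[TreeStem]:
    """Read back the stems.csv / measurements.csv pair written by
    :func:`multivol.synthetic.write_fixture` (lossless round-trip)."""
    directory = Path(directory)
    headers = pd.read_csv(directory / "stems.csv", float_precision="round_trip")
    meas = pd.read_csv(directory / "measurements.csv", float_precision="round_trip")
    stems = []
    grouped = dict(tuple(meas.groupby("stem_id", sort=False)))
    for _, row in headers.iterrows():
        g = grouped[row["stem_id"]]
        measurements = list(zip(g["height_m"].astype(float),
                                g["diameter_bark_cm"].astype(float),
                                g["bark_thickness_cm"].astype(float)))
        ref = {d: float(row[f"h{d}"]) for d in REFERENCE_DIAMETERS
               if f"h{d}" in row and pd.notna(row[f"h{d}"])}
        stems.append(TreeStem(
            stem_id=str(row["stem_id"]), clone=str(row["clone"]),
            rotation=int(row["rotation"]), dbh_cm=float(row["dbh_cm"]),
            total_height_m=float(row["height_m"]),
            measurements=measurements, ref_heights=ref,
        ))
    return stems
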