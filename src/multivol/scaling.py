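"""Rigorous scaling (cubing) of felled stems.

Converts a stem's diameter/bark measurement series into its up-to-ten
volumes: total volume and merchantable volumes to top diameters of 5, 10,
15 and 20 cm (with bark), each with and without bark. Section volumes use
the Smalian formula, the tip above the 5 cm point is treated as a cone-like
half-section, and the minimum-log-length rule decides which merchantable
volumes exist for a given stem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: merchantable top diameters (cm), measured with bark
MERCHANTABLE_DIAMETERS = (5, 10, 15, 20)

#: volume column labels in canonical order
VOLUME_LABELS = (
    "TVb", "TVw",
    "V5b", "V5w",
    "V10b", "V10w",
    "V15b", "V15w",
    "V20b", "V20w",
)


@dataclass
class TreeStem:
    """One felled stem and its field measurement series.

    ``measurements`` is an ordered list of ``(height_m, diameter_bark_cm,
    bark_thickness_cm)`` triples starting at the cut height (~0.15 m) and
    ending at the point where the bark diameter reaches the 5 cm commercial
    minimum.  ``ref_heights`` maps the reference bark diameters (20, 15, 10
    and 5 cm) to the height at which each occurs, when the stem reaches that
    diameter at all; these are field-recorded heights and are used verbatim.
    """

    stem_id: str
    clone: str
    rotation: int
    dbh_cm: float
    total_height_m: float
    measurements: list[tuple[float, float, float]]
    ref_heights: dict[int, float] = field(default_factory=dict)

    def validate(self) -> None:
        if len(self.measurements) < 2:
            raise ValueError(f"stem {self.stem_id}: needs >=2 measurements")
        h = np.array([m[0] for m in self.measurements])
        d = np.array([m[1] for m in self.measurements])
        t = np.array([m[2] for m in self.measurements])
        if not np.all(np.diff(h) > 0):
            raise ValueError(f"stem {self.stem_id}: measurement heights not strictly increasing")
        if np.any(d <= 0):
            raise ValueError(f"stem {self.stem_id}: non-positive diameter")
        if np.any(2.0 * t >= d):
            raise ValueError(f"stem {self.stem_id}: bark thicker than radius")
        if self.total_height_m < h[-1]:
            raise ValueError(f"stem {self.stem_id}: total height below last measurement")

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[0] for m in self.measurements], dtype=float)

    @property
    def diameters_bark(self) -> np.ndarray:
        return np.array([m[1] for m in self.measurements], dtype=float)

    @property
    def bark_thickness(self) -> np.ndarray:
        return np.array([m[2] for m in self.measurements], dtype=float)

    @property
    def diameters_wood(self) -> np.ndarray:
        """Diameters without bark (bark diameter minus twice the thickness)."""
        return self.diameters_bark - 2.0 * self.bark_thickness


@dataclass
class StemVolumes:
    """The up-to-ten scaled volumes of one stem, in cubic meters.

    Merchantable volumes are ``None`` when the stem never reaches the top
    diameter or the resulting log would be shorter than the minimum length.
    """

    stem_id: str
    TVb: float = 0.0
    TVw: float = 0.0
    V5b: Optional[float] = None
    V5w: Optional[float] = None
    V10b: Optional[float] = None
    V10w: Optional[float] = None
    V15b: Optional[float] = None
    V15w: Optional[float] = None
    V20b: Optional[float] = None
    V20w: Optional[float] = None

    def as_dict(self) -> dict[str, Optional[float]]:
        return {lab: getattr(self, lab) for lab in VOLUME_LABELS}

    def available(self) -> list[str]:
        """Labels of the volumes this stem actually has."""
        return [lab for lab in VOLUME_LABELS if getattr(self, lab) is not None]


def sectional_area(d: float) -> float:
    """Cross-sectional area g (m^2) at diameter ``d`` (cm): g = pi d^2 / 40000."""
    if np.any(np.asarray(d) < 0):
        raise ValueError("negative diameter")
    return math.pi * d * d / 40000.0


def smalian_volume(d1: float, d2: float, length: float) -> float:
    """Smalian section volume: mean of the end areas times the length (m^3)."""
    if length <= 0:
        raise ValueError("non-positive section length")
    return length * (sectional_area(d1) + sectional_area(d2)) / 2.0


def tip_volume(d_at_5: float, tip_length: float) -> float:
    """Tip volume above the 5 cm point: half the sectional area times the tip length."""
    if tip_length < 0:
        raise ValueError("negative tip length")
    return sectional_area(d_at_5) / 2.0 * tip_length


def diameter_without_bark(d_bark: float, bark_thickness: float) -> float:
    """Diameter inside bark: bark diameter minus twice the bark thickness."""
    if 2.0 * bark_thickness >= d_bark:
        raise ValueError("bark thicker than stem radius")
    return d_bark - 2.0 * bark_thickness


def height_at_diameter(stem: TreeStem, d_target: float, bark: bool = True) -> Optional[float]:
    """Height (m) at which the stem tapers to ``d_target`` cm, or None.

    For with-bark targets that were recorded in the field (``ref_heights``),
    the recorded height is returned verbatim.  Otherwise the height is
    linearly interpolated between the two measurements bracketing the first
    downward crossing of the target diameter.  Returns ``None`` when the
    stem never reaches ``d_target``.
    """
    if bark and int(d_target) == d_target and int(d_target) in stem.ref_heights:
        return stem.ref_heights[int(d_target)]
    h = stem.heights
    diam = stem.diameters_bark if bark else stem.diameters_wood
    if d_target > diam.max():
        return None
    for i in range(len(h) - 1):
        if diam[i] >= d_target > diam[i + 1]:
            frac = (diam[i] - d_target) / (diam[i] - diam[i + 1])
            return float(h[i] + frac * (h[i + 1] - h[i]))
    # no downward crossing: target is at or below the last measured diameter
    if diam[-1] >= d_target:
        return float(h[-1])
    return None


def _interp_at(h: np.ndarray, v: np.ndarray, h0: float) -> float:
    """Linear interpolation of a measured series at height h0 (within range)."""
    return float(np.interp(h0, h, v))


def cube_stem(stem: TreeStem, min_log_length: float = 1.0) -> StemVolumes:
    """Cube one stem: Smalian sections + tip, with and without bark.

    Total volume sums all section volumes from the cut height to the 5 cm
    point plus the tip volume.  Merchantable volume to a top diameter d sums
    the sections up to the height where the with-bark diameter reaches d,
    splitting the containing section at that height; it is reported only
    when the resulting log (cut height to limit height) is at least
    ``min_log_length`` meters.  Without-bark volumes use the diameters
    inside bark over the same physical section boundaries.
    """
    stem.validate()
    h = stem.heights
    db = stem.diameters_bark
    t = stem.bark_thickness
    dw = stem.diameters_wood

    n = len(h)
    lengths = np.diff(h)
    sec_b = np.array([smalian_volume(db[i], db[i + 1], lengths[i]) for i in range(n - 1)])
    sec_w = np.array([smalian_volume(dw[i], dw[i + 1], lengths[i]) for i in range(n - 1)])
    cum_b = np.concatenate([[0.0], np.cumsum(sec_b)])
    cum_w = np.concatenate([[0.0], np.cumsum(sec_w)])

    tip_len = stem.total_height_m - h[-1]
    tip_b = tip_volume(db[-1], tip_len)
    tip_w = tip_volume(dw[-1], tip_len)

    vol = StemVolumes(stem_id=stem.stem_id)
    v5b = float(cum_b[-1])
    v5w = float(cum_w[-1])
    vol.TVb = v5b + tip_b
    vol.TVw = v5w + tip_w

    cut_height = h[0]
    # V5: the measurement series ends at the 5 cm (with bark) point by protocol,
    # so the merchantable stem to 5 cm is exactly the sum of the sections.
    if h[-1] - cut_height >= min_log_length:
        vol.V5b, vol.V5w = v5b, v5w

    def merch(cum: np.ndarray, diam: np.ndarray, hl: float) -> float:
        j = int(np.searchsorted(h, hl, side="right")) - 1
        j = min(max(j, 0), n - 2)
        d_hl = _interp_at(h, diam, hl)
        partial = smalian_volume(diam[j], d_hl, hl - h[j]) if hl > h[j] else 0.0
        return float(cum[j] + partial)

    for d_limit in (10, 15, 20):
        hl = height_at_diameter(stem, d_limit, bark=True)
        if hl is None or hl - cut_height < min_log_length:
            continue
        hl = min(hl, float(h[-1]))
        setattr(vol, f"V{d_limit}b", merch(cum_b, db, hl))
        setattr(vol, f"V{d_limit}w", merch(cum_w, dw, hl))
    return vol


def cube_stems(stems: Sequence[TreeStem], min_log_length: float = 1.0) -> list[StemVolumes]:
    return [cube_stem(s, min_log_length=min_log_length) for s in stems]


def volumes_to_frame(volumes: Sequence[StemVolumes]) -> pd.DataFrame:
    """One row per stem, absent volumes as NaN (empty cells in CSV)."""
    rows = [{"stem_id": v.stem_id, **{k: (np.nan if x is None else x) for k, x in v.as_dict().items()}}
            for v in volumes]
    return pd.DataFrame(rows, columns=["stem_id", *VOLUME_LABELS])
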