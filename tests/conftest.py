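"""Shared fixtures: analytic stem profiles and small synthetic datasets."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import multivol as mv
from multivol.synthetic import TrueStemProfile

#: fitted multi-volume coefficients used as the ground truth of simulation
#: studies: (b0, b1, b2, b3, b4)
MV_TRUE_BETA = (0.0001486, 1.0970, 1.3919, -2.5488, 0.1529)


def linear_taper_profile(d_base: float = 30.0, height: float = 20.0,
                         bark_fraction: float = 0.0) -> TrueStemProfile:
    """Cone: diameter falls linearly from d_base at h=0 to zero at the tip."""
    diameter = lambda h: max(d_base * (1.0 - h / height), 0.0)
    bark = lambda h: 0.5 * bark_fraction * diameter(h)
    return TrueStemProfile(diameter(1.3), height, diameter, bark)


def cylinder_stem(d: float = 20.0, heights=None, total_height: float = 12.0,
                  bark_thickness: float = 0.0) -> mv.TreeStem:
    heights = heights if heights is not None else [0.15, 1.3, 3.0, 5.0, 8.0]
    return mv.TreeStem(
        stem_id="cyl", clone="", rotation=1, dbh_cm=d, total_height_m=total_height,
        measurements=[(h, d, bark_thickness) for h in heights], ref_heights={})


def paraboloid_stem(d_base: float = 28.0, height: float = 20.0, n_points: int = 6,
                    ) -> tuple[mv.TreeStem, float]:
    """Quadratic paraboloid (d^2 linear in h) and its exact volume over the
    measured span: integral of g(h) = g_base * (1 - h/H)."""
    hs = np.linspace(0.15, 16.0, n_points)
    d_fn = lambda h: d_base * math.sqrt(1.0 - h / height)
    stem = mv.TreeStem(
        stem_id="par", clone="", rotation=1, dbh_cm=d_fn(1.3), total_height_m=height,
        measurements=[(float(h), d_fn(h), 0.0) for h in hs], ref_heights={})
    g_base = math.pi * d_base ** 2 / 40000.0
    exact = g_base * ((hs[-1] - hs[0]) - (hs[-1] ** 2 - hs[0] ** 2) / (2 * height))
    return stem, exact


def conic_frustum_volume(d1: float, d2: float, length: float) -> float:
    """Closed-form volume of a conic frustum (diameters in cm, length in m)."""
    return math.pi * length / 120000.0 * (d1 * d1 + d1 * d2 + d2 * d2)


def simulate_mv_records(n_stems: int, noise_cv: float, seed: int,
                        beta=MV_TRUE_BETA) -> pd.DataFrame:
    """Records drawn exactly from the multi-volume equation plus optional
    multiplicative log-normal noise; the independent data source for
    parameter-recovery and approximation-capacity studies."""
    rng = np.random.default_rng(seed)
    rows = []
    labels = {(0, 0): "TVb", (1, 0): "TVw", (0, 5): "V5b", (1, 5): "V5w",
              (0, 10): "V10b", (1, 10): "V10w", (0, 15): "V15b", (1, 15): "V15w",
              (0, 20): "V20b", (1, 20): "V20w"}
    made = 0
    while made < n_stems:
        dbh = rng.normal(17.0, 4.0)
        h = rng.normal(22.0, 3.0) + 0.5 * (dbh - 17.0)
        if dbh < 7.0 or h < 8.0:
            continue
        made += 1
        for d in (0, 5, 10, 15, 20):
            if d >= dbh:
                continue
            for tx in (0, 1):
                v = mv.mv_predict(beta, dbh, h, tx, d)
                if noise_cv > 0:
                    s = math.sqrt(math.log1p(noise_cv ** 2))
                    v *= rng.lognormal(-0.5 * s * s, s)
                rows.append({"stem_id": f"s{made}", "volume_label": labels[(tx, d)],
                             "V": v, "DBH": dbh, "H": h, "TX": tx, "d": d})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_stems() -> list[mv.TreeStem]:
    """~60 synthetic stems across the default populations."""
    with np.errstate(all="ignore"):
        return mv.simulate_stems(mv.default_populations(n_total=60, seed=11), seed=11)


@pytest.fixture(scope="session")
def small_records(small_stems) -> pd.DataFrame:
    vols = mv.cube_stems(small_stems)
    return mv.expand_multivolume(vols, small_stems)


@pytest.fixture(scope="session")
def small_split(small_stems, small_records) -> mv.SplitDataset:
    return mv.split_stems([s.stem_id for s in small_stems], small_records, seed=5)
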