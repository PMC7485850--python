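"""Synthetic eucalyptus stem populations and the field measurement protocol.

Generates virtual stems whose (DBH, total height) joint distribution matches
per-clone/rotation stand summaries, gives each stem a smooth variable-form
taper and a bark profile, and "measures" each stem the way a scaling crew
would: diameters with bark and bark thickness at the fixed lower heights
(0.15, 0.4, 0.7, 1.0, 1.3, 2.0 m) and then every two meters up to the 5 cm
with-bark commercial minimum, plus the heights at which the reference bark
diameters of 20, 15, 10 and 5 cm occur.

The taper family is a two-parameter variable-form power profile

    d(h) = DBH * X**(a + b*X),   X = (H - h) / (H - 1.3),

which equals the DBH at breast height, vanishes at the tip, and decreases
strictly with height above 1.3 m (and swells slightly below it).  Bark
thickness is a fraction of diameter that decays linearly with relative
height.  Neither the taper nor the bark model is estimated from data; they
exist only so that every downstream stage (cubing, dataset assembly, model
fitting) can run on realistic, fully controlled inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .scaling import TreeStem

#: fixed lower measurement heights (m) of the scaling protocol
PROTOCOL_BASE_HEIGHTS = (0.15, 0.4, 0.7, 1.0, 1.3, 2.0)
#: spacing (m) of measurements above 2 m
PROTOCOL_STEP = 2.0
#: reference bark diameters (cm) whose heights the crew records
REFERENCE_DIAMETERS = (20, 15, 10, 5)
#: with-bark commercial minimum diameter (cm) that ends the series
MIN_COMMERCIAL_DIAMETER = 5.0
BREAST_HEIGHT = 1.3


@dataclass
class TaperShape:
    """Parameters of the variable-form taper d = DBH * X**(a + b*X).

    ``exponent_sd`` adds stem-to-stem variation in ``a`` so that trees of
    identical DBH and H still differ in form (and hence in volume), as real
    stands do.
    """

    exponent: float = 0.75
    form: float = 0.12
    exponent_sd: float = 0.10


@dataclass
class PopulationConfig:
    """One clone x rotation population: moments of (DBH, H) plus stem-shape settings."""

    clone_label: str
    rotation: int
    n_stems: int
    dbh_mean_cm: float
    dbh_sd_cm: float
    height_mean_m: float
    height_sd_m: float
    dbh_height_correlation: float = 0.7
    taper_shape: TaperShape = field(default_factory=TaperShape)
    bark_fraction_at_base: float = 0.11
    bark_fraction_decay: float = 0.4
    noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stems < 1:
            raise ValueError("n_stems must be >= 1")
        if self.dbh_sd_cm < 0 or self.height_sd_m < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.dbh_height_correlation <= 1.0:
            raise ValueError("dbh_height_correlation must be in [0, 1]")
        if not 0.0 < self.bark_fraction_at_base < 0.3:
            raise ValueError("bark_fraction_at_base must be in (0, 0.3)")
        if isinstance(self.taper_shape, dict):
            self.taper_shape = TaperShape(**self.taper_shape)


# Per-clone/rotation stand summaries (DBH and height mean +- SD) of the four
# clones in the two rotations; used as the default simulated populations.
STAND_SUMMARIES: tuple[dict, ...] = (
    dict(clone_label="AEC0144", rotation=1, dbh_mean_cm=17.8, dbh_sd_cm=2.9, height_mean_m=23.5, height_sd_m=2.9),
    dict(clone_label="AEC0144", rotation=2, dbh_mean_cm=14.6, dbh_sd_cm=3.5, height_mean_m=23.7, height_sd_m=4.0),
    dict(clone_label="AEC0224", rotation=1, dbh_mean_cm=18.8, dbh_sd_cm=3.0, height_mean_m=24.1, height_sd_m=4.0),
    dict(clone_label="AEC0224", rotation=2, dbh_mean_cm=13.7, dbh_sd_cm=2.6, height_mean_m=18.3, height_sd_m=2.5),
    dict(clone_label="VM01", rotation=1, dbh_mean_cm=16.7, dbh_sd_cm=2.9, height_mean_m=19.9, height_sd_m=2.9),
    dict(clone_label="VM01", rotation=2, dbh_mean_cm=13.4, dbh_sd_cm=5.3, height_mean_m=17.9, height_sd_m=5.7),
    dict(clone_label="H77", rotation=1, dbh_mean_cm=20.6, dbh_sd_cm=5.3, height_mean_m=27.9, height_sd_m=3.0),
    dict(clone_label="H77", rotation=2, dbh_mean_cm=16.4, dbh_sd_cm=4.8, height_mean_m=19.2, height_sd_m=3.9),
)


def default_populations(n_total: int = 460, seed: int = 0, **overrides) -> list[PopulationConfig]:
    """The eight default clone x rotation populations, n_total stems split evenly."""
    k = len(STAND_SUMMARIES)
    base, extra = divmod(n_total, k)
    configs = []
    for i, summary in enumerate(STAND_SUMMARIES):
        configs.append(PopulationConfig(
            n_stems=base + (1 if i < extra else 0),
            seed=seed + i,
            **summary, **overrides,
        ))
    return configs


class TrueStemProfile:
    """Ground-truth continuous stem: diameter-with-bark and bark thickness vs height.

    Invariants: the diameter equals the DBH at 1.3 m, decreases strictly with
    height above 1.3 m, and is zero at the total height; twice the bark
    thickness is everywhere less than the diameter.
    """

    def __init__(self, dbh_cm: float, total_height_m: float,
                 diameter_fn: Callable[[float], float],
                 bark_fn: Callable[[float], float]):
        if dbh_cm <= 0 or total_height_m <= BREAST_HEIGHT:
            raise ValueError("need positive DBH and total height above 1.3 m")
        self.dbh_cm = float(dbh_cm)
        self.total_height_m = float(total_height_m)
        self._diameter_fn = diameter_fn
        self._bark_fn = bark_fn

    def diameter_with_bark(self, h: float) -> float:
        return self._diameter_fn(h)

    def bark_thickness(self, h: float) -> float:
        return self._bark_fn(h)

    @classmethod
    def power_taper(cls, dbh_cm: float, total_height_m: float,
                    shape: TaperShape = TaperShape(),
                    bark_fraction_at_base: float = 0.11,
                    bark_fraction_decay: float = 0.4) -> "TrueStemProfile":
        H = total_height_m
        a, b = shape.exponent, shape.form

        def diameter(h: float) -> float:
            x = (H - h) / (H - BREAST_HEIGHT)
            if x <= 0.0:
                return 0.0
            return dbh_cm * x ** (a + b * x)

        def bark(h: float) -> float:
            frac = bark_fraction_at_base * (1.0 - bark_fraction_decay * h / H)
            return 0.5 * diameter(h) * max(frac, 0.0)

        return cls(dbh_cm, total_height_m, diameter, bark)

    def height_at_bark_diameter(self, d_target: float,
                                min_height: float = 0.0) -> Optional[float]:
        """Height where the with-bark diameter equals d_target, or None.

        Searches the monotone region above breast height first; targets
        larger than the DBH are looked for in the butt below 1.3 m.
        """
        H = self.total_height_m
        f = lambda h: self.diameter_with_bark(h) - d_target
        if d_target <= self.dbh_cm:
            lo, hi = BREAST_HEIGHT, H - 1e-9
        else:
            if f(min_height) < 0:
                return None
            lo, hi = min_height, BREAST_HEIGHT
        if f(lo) < 0 or f(hi) > 0:
            return None
        root = brentq(f, lo, hi, xtol=1e-12)
        return float(root) if root >= min_height else None


def generate_population(config: PopulationConfig) -> list[TrueStemProfile]:
    """Draw ``n_stems`` ground-truth profiles from a correlated (DBH, H) distribution.

    (DBH, H) come from a bivariate normal with the configured moments and
    correlation, redrawn (truncated) until both are physically usable
    (DBH > 0, H > 2.0 m).  A warning is raised when more than 10% of the
    draws had to be discarded.
    """
    rng = np.random.default_rng(config.seed)
    rho = config.dbh_height_correlation
    cov = np.array([
        [config.dbh_sd_cm ** 2, rho * config.dbh_sd_cm * config.height_sd_m],
        [rho * config.dbh_sd_cm * config.height_sd_m, config.height_sd_m ** 2],
    ])
    mean = np.array([config.dbh_mean_cm, config.height_mean_m])

    profiles: list[TrueStemProfile] = []
    rejected = 0
    while len(profiles) < config.n_stems:
        dbh, height = mean + rng.multivariate_normal(np.zeros(2), cov)
        if dbh <= 0 or height <= 2.0:
            rejected += 1
            continue
        shape = TaperShape(
            exponent=max(config.taper_shape.exponent
                         + rng.normal(0.0, config.taper_shape.exponent_sd), 0.2),
            form=config.taper_shape.form,
            exponent_sd=0.0,
        )
        profiles.append(TrueStemProfile.power_taper(
            dbh, height, shape=shape,
            bark_fraction_at_base=config.bark_fraction_at_base,
            bark_fraction_decay=config.bark_fraction_decay,
        ))
    if rejected > 0.1 * config.n_stems:
        warnings.warn(
            f"population {config.clone_label}/{config.rotation}: "
            f"{rejected} draws truncated (> 10% of {config.n_stems})",
            stacklevel=2,
        )
    return profiles


def measure_stem(profile: TrueStemProfile, noise_cv: float = 0.0,
                 seed: Optional[int] = None, stem_id: str = "stem",
                 clone: str = "", rotation: int = 1,
                 cut_height: float = 0.15) -> TreeStem:
    """Apply the field protocol to a ground-truth profile.

    Measurement heights are the fixed lower set, then every 2 m, ending at
    the exact height where the (true) bark diameter reaches 5 cm.  Diameters
    and bark thicknesses receive independent multiplicative log-normal noise
    with coefficient of variation ``noise_cv``; the recorded reference
    heights (20/15/10/5 cm) are taken from the true profile.
    """
    h5 = profile.height_at_bark_diameter(MIN_COMMERCIAL_DIAMETER, min_height=cut_height)
    if h5 is None or profile.diameter_with_bark(cut_height) <= MIN_COMMERCIAL_DIAMETER:
        raise ValueError("degenerate taper: stem never reaches the 5 cm commercial diameter")

    heights = [h for h in PROTOCOL_BASE_HEIGHTS if h < h5]
    if cut_height != PROTOCOL_BASE_HEIGHTS[0]:
        heights[0] = cut_height
    g = PROTOCOL_BASE_HEIGHTS[-1] + PROTOCOL_STEP
    while g < h5:
        heights.append(g)
        g += PROTOCOL_STEP
    heights.append(h5)

    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        mu = -0.5 * sigma ** 2
        d_noise = rng.lognormal(mu, sigma, size=len(heights))
        t_noise = rng.lognormal(mu, sigma, size=len(heights))
    else:
        d_noise = t_noise = np.ones(len(heights))

    measurements = []
    for h, nd, nt in zip(heights, d_noise, t_noise):
        d = profile.diameter_with_bark(h) * nd
        t = profile.bark_thickness(h) * nt
        t = min(t, 0.499 * d)  # noise must not push bark past the radius
        measurements.append((float(h), float(d), float(t)))

    ref_heights = {}
    for d_ref in REFERENCE_DIAMETERS:
        hr = profile.height_at_bark_diameter(float(d_ref), min_height=cut_height)
        if hr is not None:
            ref_heights[d_ref] = hr

    return TreeStem(
        stem_id=stem_id, clone=clone, rotation=rotation,
        dbh_cm=profile.dbh_cm,
        total_height_m=profile.total_height_m,
        measurements=measurements, ref_heights=ref_heights,
    )


def simulate_stems(configs: Sequence[PopulationConfig] | PopulationConfig,
                   seed: Optional[int] = None) -> list[TreeStem]:
    """Generate, then measure, whole populations; skips (with a warning) the
    rare stems too small to reach the 5 cm commercial diameter."""
    if isinstance(configs, PopulationConfig):
        configs = [configs]
    master = np.random.SeedSequence(seed if seed is not None else configs[0].seed)
    stems: list[TreeStem] = []
    skipped = 0
    for ci, config in enumerate(configs):
        pop_seed = int(master.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        cfg = PopulationConfig(**{**asdict(config), "seed": pop_seed}) if seed is not None else config
        profiles = generate_population(cfg)
        meas_seeds = np.random.SeedSequence(cfg.seed + 1).generate_state(len(profiles))
        for i, (profile, mseed) in enumerate(zip(profiles, meas_seeds)):
            sid = f"{cfg.clone_label}_r{cfg.rotation}_{i:04d}"
            try:
                stems.append(measure_stem(
                    profile, noise_cv=cfg.noise_cv, seed=int(mseed % (2 ** 31)),
                    stem_id=sid, clone=cfg.clone_label, rotation=cfg.rotation,
                ))
            except ValueError:
                skipped += 1
    if skipped:
        warnings.warn(f"{skipped} stems never reached 5 cm and were skipped", stacklevel=2)
    return stems


# ---------------------------------------------------------------- fixtures

def write_fixture(stems: Sequence[TreeStem], directory: str | Path) -> None:
    """Write a stem-header CSV and a long measurement CSV; round-trips
    losslessly through :func:`multivol.dataset.read_stem_fixture`."""
    if not stems:
        raise ValueError("empty stem list")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header_rows = []
    meas_rows = []
    for s in stems:
        header_rows.append({
            "stem_id": s.stem_id, "clone": s.clone, "rotation": s.rotation,
            "dbh_cm": s.dbh_cm, "height_m": s.total_height_m,
            **{f"h{d}": s.ref_heights.get(d, np.nan) for d in REFERENCE_DIAMETERS},
        })
        for h, d, t in s.measurements:
            meas_rows.append({"stem_id": s.stem_id, "height_m": h,
                              "diameter_bark_cm": d, "bark_thickness_cm": t})
    # 17 significant digits: float64 round-trips exactly through the reader
    pd.DataFrame(header_rows).to_csv(directory / "stems.csv", index=False,
                                     float_format="%.17g")
    pd.DataFrame(meas_rows).to_csv(directory / "measurements.csv", index=False,
                                   float_format="%.17g")


def save_config(configs: Sequence[PopulationConfig], path: str | Path) -> None:
    payload = [asdict(c) for c in configs]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_config(path: str | Path) -> list[PopulationConfig]:
    payload = yaml.safe_load(Path(path).read_text())
    return [PopulationConfig(**entry) for entry in payload]
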