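"""End-to-end pipeline: simulate -> cube -> split -> fit -> train -> evaluate.

Every stochastic stage receives a seed derived deterministically from the
run's global seed, so a rerun with the same configuration reproduces every
output exactly.  Each stage writes its table or model file into the run
directory as it completes; a manifest records configuration, seeds, stage
timings and package versions.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import ann, dataset, evaluation, regression, scaling, synthetic

log = logging.getLogger("multivol")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    output_dir: str = "multivol_run"
    seed: int = 0
    # synthetic population (ignored when input tables are given)
    n_stems: int = 460
    noise_cv: float = 0.02
    # or: externally supplied record tables (skips simulate/cube/split)
    fit_table: Optional[str] = None
    validation_table: Optional[str] = None
    column_map: Optional[dict] = None
    # split
    fit_fraction: float = 0.7
    fit_count: Optional[int] = None
    # scaling
    min_log_length: float = 1.0
    # ann
    ann_trials: int = 200
    ann_max_hidden: int = 10
    ann_retain: int = 5
    ann_epochs: int = ann.DEFAULT_EPOCHS
    ann_learning_rate: float = ann.DEFAULT_LEARNING_RATE
    ann_momentum: float = ann.DEFAULT_MOMENTUM
    ann_margin: float = 0.1
    ann_validation_fraction: float = 0.25
    # evaluation
    alpha: float = 0.05
    t_test_mode: str = "paired"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ("simulate", "split", "fit_sh", "fit_mv", "ann")
    states = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(len(names))]
    return dict(zip(names, states))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {"config": asdict(config), "seeds": seeds,
                      "version": __version__, "stages": {}}
    t_all = time.perf_counter()

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            log.info("stage %s ...", name)
            try:
                result = fn()
            except Exception:
                manifest["stages"][name] = {"status": "failed"}
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
                log.exception("stage %s failed", name)
                raise
            manifest["stages"][name] = {
                "status": "ok", "seconds": round(time.perf_counter() - t0, 3)}
            return result
        return wrap

    if config.fit_table:
        fit_records = stage("load_fit")(
            lambda: dataset.read_table(config.fit_table, column_map=config.column_map))
        val_records = stage("load_validation")(
            lambda: dataset.read_table(config.validation_table, column_map=config.column_map))
    else:
        def simulate():
            pops = synthetic.default_populations(
                n_total=config.n_stems, seed=seeds["simulate"],
                noise_cv=config.noise_cv)
            stems = synthetic.simulate_stems(pops, seed=seeds["simulate"])
            synthetic.write_fixture(stems, out / "stems")
            return stems
        stems = stage("simulate")(simulate)

        def cube():
            vols = scaling.cube_stems(stems, min_log_length=config.min_log_length)
            scaling.volumes_to_frame(vols).to_csv(out / "volumes.csv", index=False)
            return vols
        volumes = stage("cube")(cube)

        records = stage("expand")(lambda: dataset.expand_multivolume(volumes, stems))

        def split():
            sp = dataset.split_stems([s.stem_id for s in stems], records,
                                     fit_fraction=config.fit_fraction,
                                     fit_count=config.fit_count,
                                     seed=seeds["split"])
            dataset.write_table(sp.fit_records, out / "records_fit.csv")
            dataset.write_table(sp.validation_records, out / "records_validation.csv")
            return sp
        sp = stage("split")(split)
        fit_records, val_records = sp.fit_records, sp.validation_records

    def fit_sh():
        fits = {}
        for label in scaling.VOLUME_LABELS:
            sub = dataset.subset_by_volume(fit_records, label)
            if len(sub) < 10:
                log.warning("volume %s: only %d fit records, skipped", label, len(sub))
                continue
            fits[label] = regression.fit_schumacher_hall(sub, volume_label=label,
                                                         seed=seeds["fit_sh"])
        regression.save_fits(fits, out / "sh_fits.json")
        return fits
    sh_fits = stage("fit_sh")(fit_sh)

    def fit_mv():
        fit = regression.fit_multivolume(fit_records, seed=seeds["fit_mv"])
        regression.save_fits({"multivolume": fit}, out / "mv_fit.json")
        return fit
    mv_fit = stage("fit_mv")(fit_mv)

    def train_ann():
        search = ann.architecture_search(
            fit_records, n_trials=config.ann_trials,
            max_hidden=config.ann_max_hidden, retain=config.ann_retain,
            validation_fraction=config.ann_validation_fraction,
            seed=seeds["ann"], epochs=config.ann_epochs,
            learning_rate=config.ann_learning_rate,
            momentum=config.ann_momentum, margin=config.ann_margin)
        ann.save_models([m for m, _ in search.retained], out / "ann_models.json")
        search.log.to_csv(out / "ann_search_log.csv", index=False)
        return search
    search = stage("train_ann")(train_ann)

    def evaluate():
        report = compare_strategies(sh_fits, mv_fit, [m for m, _ in search.retained],
                                    val_records, alpha=config.alpha,
                                    t_test_mode=config.t_test_mode)
        report.to_json(out / "report.json")
        report.to_csv(out / "report.csv")
        return report
    stage("evaluate")(evaluate)

    manifest["total_seconds"] = round(time.perf_counter() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def compare_strategies(sh_fits: dict[str, regression.SHFit],
                       mv_fit: regression.MVFit,
                       ann_models: list[ann.MLPModel],
                       validation_records: pd.DataFrame,
                       alpha: float = 0.05,
                       t_test_mode: str = "paired") -> evaluation.ValidationReport:
    """One report over the three strategies on an identical record set.

    Schumacher-Hall predicts each record with its own volume's equation
    (records of volumes with no fitted equation are excluded for all
    strategies, keeping the record sets identical); the multi-volume
    equation and the best ANN predict every record directly.
    """
    rec = validation_records[validation_records["volume_label"].isin(sh_fits)]
    rec = rec.reset_index(drop=True)
    if rec.empty:
        raise ValueError("no validation records covered by the fitted equations")

    sh_pred = np.empty(len(rec))
    for label, fit in sh_fits.items():
        mask = (rec["volume_label"] == label).to_numpy()
        if mask.any():
            sh_pred[mask] = regression.sh_predict(
                fit, rec.loc[mask, "DBH"], rec.loc[mask, "H"])
    mv_pred = regression.mv_predict(mv_fit, rec["DBH"], rec["H"], rec["TX"], rec["d"])
    best = ann_models[0]
    ann_pred = ann.predict_records(best, rec)

    return evaluation.evaluate_predictions(
        rec, {"schumacher_hall": sh_pred, "multivolume": mv_pred, "ann": ann_pred},
        alpha=alpha, t_test_mode=t_test_mode)
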