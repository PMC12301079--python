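"""Config-driven end-to-end run: simulate -> gamma -> ROC -> correlations
-> complexity, with a manifest that reproduces every output byte-identically.

A full run emulates the four experimental conditions of a two-device QA
study — {high-resolution planar, coarse cylindrical} x {cumulative,
field-by-field} — on synthetic cohorts that share delivery-error
realizations across the two detectors, and writes:

* ``qarecords.csv`` — one row per unit x device x criteria,
* ``roc_table.csv`` — AUC / optimal threshold / Mann-Whitney p per
  (device, mode, criteria, level),
* ``correlations.csv`` — Spearman permutation correlations between the
  GPRs of the two devices over all criteria pairs,
* ``complexity_vs_delta.csv`` + ``complexity_summary.json`` — MEFS/MSRA of
  simulated arcs against the isocenter dose deviation,
* ``manifest.json`` — the full configuration, seeds and versions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import (
    DEFAULT_LEVELS,
    ROCStudy,
    fraction_significant,
    spearman_permutation,
)
from .complexity import aperture_metrics
from .exceptions import UndefinedCorrelationError, ValidationError
from .gamma import STANDARD_CRITERIA, GammaCriteria
from .synthetic import CohortSpec, FieldModel, simulate_cohort, simulate_plan

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("psqa")

DETECTOR_TAGS = {"planar": "SM", "cylinder_unwrapped": "AC"}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full synthetic QA study run."""

    seed: int = 0
    out_dir: str = "psqa_run"
    n_cumulative: int = 20
    n_field: int = 46
    criteria: tuple[GammaCriteria, ...] = STANDARD_CRITERIA
    levels: tuple[float, ...] = DEFAULT_LEVELS
    shift_sd: float = 1.0
    scale_sd: float = 0.02
    noise_sd: float = 0.01
    coupling: float = 0.8
    delta_sd_percent: float = 2.5
    field_model: FieldModel = field(default_factory=FieldModel)
    n_perm: int = 10_000
    plan_n_cp: int = 24
    plan_n_pairs: int = 20
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.criteria:
            raise ValidationError("criteria list must be non-empty")
        if not all(0 < lv < 100 for lv in self.levels):
            raise ValidationError("levels must lie in (0, 100)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["criteria"] = [
            {"dd_percent": c.dd_percent, "dta_mm": c.dta_mm,
             "dose_threshold_percent": c.dose_threshold_percent,
             "normalization": c.normalization, "norm_dose": c.norm_dose}
            for c in self.criteria
        ]
        return d


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML/JSON RunConfig; unknown keys are rejected."""
    obj = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(obj) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "criteria" in obj:
        obj["criteria"] = tuple(GammaCriteria(**c) for c in obj["criteria"])
    if "field_model" in obj:
        obj["field_model"] = FieldModel(**obj["field_model"])
    if "levels" in obj:
        obj["levels"] = tuple(float(v) for v in obj["levels"])
    return RunConfig(**obj)


def _records_frame(records, device: str) -> pd.DataFrame:
    rows = []
    for rec in records:
        for crit, gpr in rec.gpr_by_criteria.items():
            rows.append(
                {
                    "unit_id": rec.unit_id, "device": device, "mode": rec.mode,
                    "criteria": crit, "gpr": gpr,
                    "d_calc": rec.d_calc, "d_meas": rec.d_meas,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full study; returns the paths of the written outputs."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- cohorts: two detectors sharing error realizations per mode --------
    cohorts = {}
    truths = {}
    for mode, n_units, seed_tag in (
        ("cumulative", config.n_cumulative, 1),
        ("field_by_field", config.n_field, 2),
    ):
        for detector in ("planar", "cylinder_unwrapped"):
            spec = CohortSpec(
                n_units=n_units, mode=mode,
                shift_sd=config.shift_sd, scale_sd=config.scale_sd,
                noise_sd=config.noise_sd, coupling=config.coupling,
                delta_sd_percent=config.delta_sd_percent,
                seed=config.seed * 1000 + seed_tag,
                detector=detector, field_model=config.field_model,
                criteria=config.criteria,
            )
            log.info("simulating %s cohort on %s detector (n=%d)",
                     mode, detector, n_units)
            records, truth = simulate_cohort(spec)
            device = DETECTOR_TAGS[detector]
            cohorts[(mode, device)] = records
            truths[(mode, device)] = truth

    qadf = pd.concat(
        [_records_frame(recs, device) for (mode, device), recs in cohorts.items()],
        ignore_index=True,
    )
    paths = {"qarecords": out / "qarecords.csv"}
    qadf.to_csv(paths["qarecords"], index=False)

    # -- ROC study per device ----------------------------------------------
    criteria_labels = [c.label for c in config.criteria]
    tables = []
    for device in sorted({d for (_, d) in cohorts}):
        records = [
            r for (mode, dev), recs in cohorts.items() if dev == device
            for r in recs
        ]
        study = ROCStudy(records, criteria_labels=criteria_labels,
                         levels=config.levels)
        table = study.fit().table
        table.insert(0, "device", device)
        tables.append(table)
    roc_table = pd.concat(tables, ignore_index=True)
    paths["roc_table"] = out / "roc_table.csv"
    roc_table.to_csv(paths["roc_table"], index=False)
    for device, sub in roc_table.groupby("device"):
        frac = fraction_significant(sub)
        for mode, pct in frac.items():
            log.info("%s %s: %.0f%% of AUCs significant", device, mode, pct)

    # -- cross-device GPR correlations (per mode, all criteria pairs) ------
    corr_rows = []
    for mode in ("cumulative", "field_by_field"):
        recs_a = cohorts[(mode, "AC")]
        recs_b = cohorts[(mode, "SM")]
        for ca in criteria_labels:
            x = [r.gpr_by_criteria[ca] for r in recs_a]
            for cb in criteria_labels:
                y = [r.gpr_by_criteria[cb] for r in recs_b]
                try:
                    c = spearman_permutation(
                        x, y, n_perm=config.n_perm, seed=config.seed
                    )
                    corr_rows.append(
                        {"mode": mode, "criteria_ac": ca, "criteria_sm": cb,
                         "r_s": c.r_s, "p_perm": c.p_perm, "n_perm": c.n_perm,
                         "defined": True}
                    )
                except UndefinedCorrelationError:
                    corr_rows.append(
                        {"mode": mode, "criteria_ac": ca, "criteria_sm": cb,
                         "r_s": np.nan, "p_perm": np.nan,
                         "n_perm": config.n_perm, "defined": False}
                    )
    paths["correlations"] = out / "correlations.csv"
    pd.DataFrame(corr_rows).to_csv(paths["correlations"], index=False)

    # -- aperture complexity vs isocenter deviation ------------------------
    comp_rows = []
    for mode, device in (("cumulative", "AC"), ("field_by_field", "AC")):
        truth = truths[(mode, device)]
        rng = np.random.default_rng(config.seed * 1000 + 7)
        for _, row in truth.iterrows():
            # lognormal spread of aperture sizes, clipped to the range the
            # 20-pair x 5-mm leaf bank can realize
            target = float(np.clip(np.exp(rng.normal(np.log(30.0), 0.35)),
                                   12.0, 45.0))
            seq = simulate_plan(
                config.plan_n_cp, config.plan_n_pairs, 5.0, target,
                seed=int(rng.integers(2**31)),
            )
            m = aperture_metrics(seq)
            comp_rows.append(
                {"mode": mode, "unit_id": row["unit_id"],
                 "mefs": m.mefs, "msra": m.msra,
                 "delta_percent": row["delta_percent"],
                 "abs_delta_percent": abs(row["delta_percent"])}
            )
    compdf = pd.DataFrame(comp_rows)
    paths["complexity"] = out / "complexity_vs_delta.csv"
    compdf.to_csv(paths["complexity"], index=False)
    comp_summary = {}
    for mode, sub in compdf.groupby("mode"):
        for metric in ("mefs", "msra"):
            try:
                c = spearman_permutation(
                    sub[metric], sub["abs_delta_percent"],
                    n_perm=config.n_perm, seed=config.seed,
                )
                comp_summary[f"{mode}.{metric}"] = {
                    "r_s": c.r_s, "p_perm": c.p_perm, "n_perm": c.n_perm}
            except UndefinedCorrelationError:
                comp_summary[f"{mode}.{metric}"] = None
    paths["complexity_summary"] = out / "complexity_summary.json"
    paths["complexity_summary"].write_text(
        json.dumps(comp_summary, indent=2, sort_keys=True) + "\n"
    )

    # -- manifest ----------------------------------------------------------
    config_dict = config.to_dict()
    config_dict.pop("out_dir")  # manifest must not depend on where it lives
    manifest = {
        "config": config_dict,
        "versions": {
            "psqa": __version__,
            "python": ".".join(map(str, sys.version_info[:3])),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": {k: p.name for k, p in paths.items()},
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True)
                                 + "\n")
    log.info("run complete: %d outputs in %s", len(paths), out)
    return paths
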