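"""Experiment orchestration: simulate groups, run the measurement stages,
compare groups, and write a reproducible report.

A YAML/dict config describes treatment groups per assay (for a simulated
three-arm fiber-alignment experiment: an untreated-like low-concentration
arm, a TGFb1-like high-anisotropy arm, and a TGFb1+FGF2-like arm near
control), the stages to run, and one master seed from which every
generator seed is derived, so a rerun with the same config is
bit-identical.

Config schema (all assay sections optional, stages pick what runs)::

    seed: 1
    out_dir: results/run
    stages: [align, zymo, morph, smafrac, contract, stats]
    fiber:
      n_images: 10
      params: {image_size_px: 256}        # FiberFieldParams overrides
      groups:                              # per-group overrides
        control:   {kappa: 1}
        TGFb1:     {kappa: 8}
        TGFb1+FGF2: {kappa: 2}
    zymo:
      n_images: 8
      params: {}                           # SpotStackParams overrides
      groups: {control: {n_spots: 4}, TGFb1: {n_spots: 16}}
    morph:
      n_images: 8
      params: {}                           # CellShapeParams overrides
      groups: {control: {n_arms: 0}, TGFb1: {n_arms: 5, arm_length_px: 90}}
      value: roundness                     # or mean_extension
    smafrac:
      n_images: 8
      nuclei_per_image: 100
      groups: {control: {p_positive: 0.1}, TGFb1: {p_positive: 0.6}}
    contract:
      n_images: 6
      params: {}                           # GelSeriesParams overrides
      groups: {control: {area_contraction_fraction: 0.1}}
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contraction as contr
from . import fiber_alignment as fa
from . import morphology as morph
from . import synthetic as syn
from . import zymography as zym
from .errors import ConfigValidationError
from .io import _jsonable
from .stats import compare_groups, summarize_groups

__all__ = ["run_pipeline", "load_config"]

logger = logging.getLogger("ecmquant")

_STAGES = ("simulate", "align", "zymo", "morph", "smafrac", "contract", "stats")
_STAGE_SECTION = {
    "align": "fiber",
    "zymo": "zymo",
    "morph": "morph",
    "smafrac": "smafrac",
    "contract": "contract",
}


def load_config(source) -> dict:
    if isinstance(source, dict):
        return source
    return yaml.safe_load(Path(source).read_text())


def _derived_seed(master: int, *key: int) -> int:
    """Stable child seed below 2**31 from the master seed and an index path."""
    return int(np.random.SeedSequence([int(master), *key]).generate_state(1)[0] % (2**31))


def _validate(config: dict) -> list[str]:
    stages = config.get("stages")
    if not stages:
        raise ConfigValidationError("config must list at least one stage")
    unknown = [s for s in stages if s not in _STAGES]
    if unknown:
        raise ConfigValidationError(f"unknown stages {unknown}; valid: {_STAGES}")
    if "seed" not in config:
        raise ConfigValidationError("config must set a seed")
    for stage in stages:
        section = _STAGE_SECTION.get(stage)
        if section and section not in config:
            raise ConfigValidationError(
                f"stage {stage!r} needs a {section!r} config section"
            )
        if section:
            groups = config[section].get("groups")
            if not groups:
                raise ConfigValidationError(f"section {section!r} defines no groups")
    return list(stages)


def _group_params(cls, base: dict, override: dict, seed: int):
    merged = {**base, **override, "seed": seed}
    valid = {f.name for f in dataclasses.fields(cls)}
    bad = set(merged) - valid
    if bad:
        raise ConfigValidationError(f"unknown {cls.__name__} fields {sorted(bad)}")
    return cls(**merged)


def _run_align(section: dict, master: int, stage_key: int) -> pd.DataFrame:
    base = dict(section.get("params", {}))
    n_images = int(section.get("n_images", 8))
    opts = {
        k: section[k]
        for k in ("step_deg", "window_deg", "tile", "smooth_sigma")
        if k in section
    }
    rows = []
    for gi, (label, override) in enumerate(sorted(section["groups"].items())):
        for ii in range(n_images):
            p = _group_params(
                syn.FiberFieldParams, base, override, _derived_seed(master, stage_key, gi, ii, 0)
            )
            ctrl_over = {**override, "kappa": 0.0, "mean_angle_deg": 0.0}
            pc = _group_params(
                syn.FiberFieldParams, base, ctrl_over, _derived_seed(master, stage_key, gi, ii, 1)
            )
            img, _ = syn.generate_fiber_image(p)
            ctrl, _ = syn.generate_fiber_image(pc)
            res = fa.fiber_alignment_pipeline(img, ctrl, **opts)
            rows.append(
                {
                    "group_label": label,
                    "image_id": f"{label}_{ii:02d}",
                    "value": res.alignment_index,
                    "peak_angle_deg": res.peak_angle_deg,
                }
            )
    return pd.DataFrame(rows)


def _run_zymo(section: dict, master: int, stage_key: int) -> pd.DataFrame:
    base = dict(section.get("params", {}))
    n_images = int(section.get("n_images", 8))
    threshold = section.get("threshold", "otsu")
    min_voxels = int(section.get("min_voxels", 5))
    rows = []
    for gi, (label, override) in enumerate(sorted(section["groups"].items())):
        for ii in range(n_images):
            p = _group_params(
                syn.SpotStackParams, base, override, _derived_seed(master, stage_key, gi, ii)
            )
            stack, _ = syn.generate_spot_stack(p)
            objs = zym.segment_objects(stack, threshold, min_voxels)
            res = zym.total_protease_activity(objs, stack)
            rows.append(
                {
                    "group_label": label,
                    "image_id": f"{label}_{ii:02d}",
                    "value": res.total_activity,
                    "n_objects": len(objs),
                }
            )
    return pd.DataFrame(rows)


def _run_morph(section: dict, master: int, stage_key: int) -> pd.DataFrame:
    base = dict(section.get("params", {}))
    n_images = int(section.get("n_images", 8))
    value_kind = section.get("value", "roundness")
    if value_kind not in ("roundness", "mean_extension", "max_extension"):
        raise ConfigValidationError(f"unknown morph value {value_kind!r}")
    rows = []
    for gi, (label, override) in enumerate(sorted(section["groups"].items())):
        for ii in range(n_images):
            p = _group_params(
                syn.CellShapeParams, base, override, _derived_seed(master, stage_key, gi, ii)
            )
            mask_img, _ = syn.generate_cell_mask(p)
            cell = morph.measure_cell(mask_img, threshold=0.5)
            value = {
                "roundness": cell.roundness,
                "mean_extension": cell.mean_extension_px,
                "max_extension": cell.max_extension_px,
            }[value_kind]
            rows.append(
                {"group_label": label, "image_id": f"{label}_{ii:02d}", "value": value}
            )
    return pd.DataFrame(rows)


def _run_smafrac(section: dict, master: int, stage_key: int) -> pd.DataFrame:
    n_images = int(section.get("n_images", 8))
    nuclei = int(section.get("nuclei_per_image", 100))
    rows = []
    for gi, (label, override) in enumerate(sorted(section["groups"].items())):
        table = syn.generate_count_table(
            n_images, nuclei, float(override["p_positive"]), _derived_seed(master, stage_key, gi)
        )
        frac = morph.percent_positive(table)
        for ii, pct in enumerate(frac.per_image_percent):
            rows.append(
                {"group_label": label, "image_id": f"{label}_{ii:02d}", "value": pct}
            )
    return pd.DataFrame(rows)


def _run_contract(section: dict, master: int, stage_key: int) -> pd.DataFrame:
    base = dict(section.get("params", {}))
    n_images = int(section.get("n_images", 6))
    rows = []
    for gi, (label, override) in enumerate(sorted(section["groups"].items())):
        for ii in range(n_images):
            p = _group_params(
                syn.GelSeriesParams, base, override, _derived_seed(master, stage_key, gi, ii)
            )
            baseline, followup, _ = syn.generate_gel_series(p)
            res = contr.measure_contraction(baseline, followup)
            rows.append(
                {
                    "group_label": label,
                    "image_id": f"{label}_{ii:02d}",
                    "value": res.percent_contraction,
                }
            )
    return pd.DataFrame(rows)


def _run_simulate(config: dict, master: int, out_dir: Path) -> list[str]:
    """Persist one synthetic exemplar per group and assay as TIFF plus a
    JSON ground-truth sidecar (the measurement stages regenerate in
    memory from derived seeds; this stage is for inspection and reuse)."""
    from .io import write_image, write_sidecar, write_stack

    sim_dir = out_dir / "simulated"
    sim_dir.mkdir(exist_ok=True)
    written: list[str] = []

    def _emit(path: Path, payload: dict):
        write_sidecar(path, payload)
        written.append(str(path))

    if "fiber" in config:
        base = dict(config["fiber"].get("params", {}))
        for gi, (label, override) in enumerate(sorted(config["fiber"]["groups"].items())):
            p = _group_params(syn.FiberFieldParams, base, override, _derived_seed(master, 100, gi))
            img, gt = syn.generate_fiber_image(p)
            path = sim_dir / f"fiber_{label}.tif"
            write_image(path, img)
            _emit(path, {"params": dataclasses.asdict(p), "ground_truth": gt})
    if "zymo" in config:
        base = dict(config["zymo"].get("params", {}))
        for gi, (label, override) in enumerate(sorted(config["zymo"]["groups"].items())):
            p = _group_params(syn.SpotStackParams, base, override, _derived_seed(master, 101, gi))
            stack, gt = syn.generate_spot_stack(p)
            path = sim_dir / f"zymo_{label}.tif"
            write_stack(path, stack)
            summary = [
                {k: v for k, v in spot.items() if k != "voxels"} for spot in gt
            ]
            _emit(path, {"params": dataclasses.asdict(p), "ground_truth": summary})
    if "morph" in config:
        base = dict(config["morph"].get("params", {}))
        for gi, (label, override) in enumerate(sorted(config["morph"]["groups"].items())):
            p = _group_params(syn.CellShapeParams, base, override, _derived_seed(master, 102, gi))
            img, gt = syn.generate_cell_mask(p)
            path = sim_dir / f"cell_{label}.tif"
            write_image(path, img)
            _emit(path, {"params": dataclasses.asdict(p), "ground_truth": gt})
    if "contract" in config:
        base = dict(config["contract"].get("params", {}))
        for gi, (label, override) in enumerate(sorted(config["contract"]["groups"].items())):
            p = _group_params(syn.GelSeriesParams, base, override, _derived_seed(master, 103, gi))
            b, f, gt = syn.generate_gel_series(p)
            for tag, img in (("baseline", b), ("followup", f)):
                path = sim_dir / f"gel_{label}_{tag}.tif"
                write_image(path, img)
                _emit(path, {"params": dataclasses.asdict(p), "ground_truth": gt})
    return written


_RUNNERS = {
    "align": _run_align,
    "zymo": _run_zymo,
    "morph": _run_morph,
    "smafrac": _run_smafrac,
    "contract": _run_contract,
}


def run_pipeline(config) -> dict:
    """Execute the configured stages and return the combined report dict.

    Per-stage per-image values land in ``<out_dir>/<stage>_values.csv``;
    the report (group summaries, comparisons, config echo) in
    ``report.json``; a parameter/seed log in ``run.log``.
    """
    config = load_config(config)
    stages = _validate(config)
    master = int(config["seed"])
    out_dir = Path(config.get("out_dir", "results/pipeline"))
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("pipeline start; seed=%d; stages=%s", master, stages)
    logger.info("config: %s", json.dumps(_jsonable(config), sort_keys=True))

    report: dict = {"seed": master, "stages": stages, "measurements": {}}
    values: dict[str, pd.DataFrame] = {}
    try:
        if "simulate" in stages:
            report["simulated_files"] = _run_simulate(config, master, out_dir)
            logger.info("simulate: wrote %d files", len(report["simulated_files"]))
        for si, stage in enumerate(s for s in stages if s in _RUNNERS):
            section = config[_STAGE_SECTION[stage]]
            df = _RUNNERS[stage](section, master, si)
            values[stage] = df
            df.to_csv(out_dir / f"{stage}_values.csv", index=False)
            logger.info("stage %s: %d measurements", stage, len(df))

        for stage, df in values.items():
            summaries = summarize_groups(df)
            entry = {
                "groups": [dataclasses.asdict(s) for s in summaries],
            }
            counts = df.groupby("group_label").size()
            if len(counts) >= 2 and (counts >= 2).all():
                cmpres = compare_groups(df)
                entry["comparison"] = {
                    "test_name": cmpres.test_name,
                    "statistic": cmpres.statistic,
                    "p_value": cmpres.p_value,
                    "pairwise": _jsonable(cmpres.pairwise)
                    if cmpres.pairwise is not None
                    else None,
                }
            report["measurements"][stage] = entry

        (out_dir / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
        logger.info("pipeline done")
    finally:
        logger.removeHandler(handler)
        handler.close()
    return report
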