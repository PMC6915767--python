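"""End-to-end orchestration: simulate → register → segment → reconstruct →
plaque proximity → colocalization → per-animal statistics.

Driven by a single config mapping (YAML on disk); every stage writes its
table so partial reruns are cheap, and a manifest records the config
hash, seed and package version. Rerunning with the same config and seed
reproduces every CSV byte for byte.
"""

from __future__ import annotations

import logging
import time
from dataclasses import fields as dc_fields
from pathlib import Path

import pandas as pd

from .coloc import coloc_rates, coloc_table
from .plaques import NEAR_FAR_CUTOFF_UM, classify_near_far, detect_plaques
from .puncta import filter_single_section, link_3d, punctum_density, puncta_table
from .registration import apply_transforms, estimate_shifts
from .segmentation import DEFAULT_METHODS, binarize_stack
from .stack_io import write_results, write_stack
from .stacks import ChannelStack
from .stats import aggregate_per_animal, mann_whitney_u
from .synthetic import SynthParams, generate_stack

log = logging.getLogger("arraytomo")

DEFAULT_CONFIG: dict = {
    "calibration": {"pixel_size_xy": 0.1, "section_thickness": 0.07},
    "channels": {"synaptic": ["synaptophysin", "PSD95"], "markers": ["tau", "abeta"]},
    "segmentation": {"methods": list(DEFAULT_METHODS), "min_object_px": 2},
    "coloc": {"threshold": 0.5},
    "plaque": {"core_channel": "thios", "pan_channel": "abeta",
               "near_cutoff_um": NEAR_FAR_CUTOFF_UM, "min_plaque_area_um2": 20.0},
    "stats": {"statistic": "median", "alternative": "two-sided"},
}


class ConfigError(ValueError):
    """Raised before any compute when the config is invalid."""


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults; reject structural problems."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    for section in ("calibration", "channels", "segmentation", "coloc", "plaque",
                    "stats"):
        merged = {**DEFAULT_CONFIG.get(section, {}), **(cfg.get(section) or {})}
        cfg[section] = merged
    cal = cfg["calibration"]
    for key in ("pixel_size_xy", "section_thickness"):
        if key not in cal or cal[key] is None:
            raise ConfigError(f"calibration.{key} is required")
        if not (float(cal[key]) > 0):
            raise ConfigError(f"calibration.{key} must be > 0")
    return cfg


def _synth_params(cfg: dict, overrides: dict, seed: int) -> SynthParams:
    block = {**(cfg.get("simulate", {}).get("params") or {}), **(overrides or {})}
    known = {f.name for f in dc_fields(SynthParams)}
    bad = set(block) - known
    if bad:
        raise ConfigError(f"unknown simulate.params keys: {sorted(bad)}")
    cal = cfg["calibration"]
    block.setdefault("pixel_size_xy", cal["pixel_size_xy"])
    block.setdefault("section_thickness", cal["section_thickness"])
    for key in ("field_size_px", "punctum_radius_xy", "nucleus_radius_um"):
        if key in block and isinstance(block[key], list):
            block[key] = tuple(block[key])
    if "plaque_spec" in block:
        block["plaque_spec"] = [((float(x), float(y)), float(cr), float(hr))
                                for (x, y), cr, hr in
                                (((s[0][0], s[0][1]), s[1], s[2])
                                 for s in block["plaque_spec"])]
    block["seed"] = seed
    return SynthParams(**block)


def analyze_stack(
    stack: ChannelStack,
    cfg: dict,
    animal_id: str,
    group: str,
) -> dict[str, pd.DataFrame]:
    """Run one animal's stack through registration → coloc; return tables."""
    seg = cfg["segmentation"]
    pl = cfg["plaque"]
    transforms = estimate_shifts(stack, cfg["channels"].get("reference"))
    reg = apply_transforms(stack, transforms)

    plaque_map = None
    if pl["core_channel"] in reg.channels:
        plaque_map = detect_plaques(
            reg, core_channel=pl["core_channel"],
            min_plaque_area_um2=pl["min_plaque_area_um2"],
            pan_channel=pl.get("pan_channel"))

    marker_masks = {
        m: binarize_stack(reg, m, methods=seg["methods"],
                          min_object_px=seg["min_object_px"])
        for m in cfg["channels"]["markers"] if m in reg.channels
    }

    punct_rows, dens_rows, coloc_frames = [], [], []
    for ch in cfg["channels"]["synaptic"]:
        if ch not in reg.channels:
            continue
        mask = binarize_stack(reg, ch, methods=seg["methods"],
                              min_object_px=seg["min_object_px"])
        puncta = filter_single_section(link_3d(mask))
        tab = puncta_table(puncta)
        if plaque_map is not None and plaque_map.n_plaques > 0:
            near_far = [
                classify_near_far(
                    plaque_map.distance_at(*p.centroid_um), pl["near_cutoff_um"])
                for p in puncta]
        else:
            near_far = ["far"] * len(puncta)
        tab["near_far"] = near_far
        tab.insert(0, "animal_id", animal_id)
        tab.insert(1, "group", group)
        punct_rows.append(tab)
        dens_rows.append({
            "animal_id": animal_id, "group": group, "channel": ch,
            "n_puncta": len(puncta),
            "density_per_um3": punctum_density(puncta, stack.volume_um3)
            if len(puncta) else 0.0,
        })
        strata = [{"near_far": nf} for nf in near_far]
        results = coloc_rates(puncta, marker_masks, strata,
                              threshold=cfg["coloc"]["threshold"])
        ct = coloc_table(results)
        ct.insert(0, "animal_id", animal_id)
        ct.insert(1, "group", group)
        ct["synaptic_channel"] = ch
        coloc_frames.append(ct)

    return {
        "puncta": pd.concat(punct_rows, ignore_index=True) if punct_rows
        else pd.DataFrame(),
        "density": pd.DataFrame(dens_rows),
        "coloc": pd.concat(coloc_frames, ignore_index=True) if coloc_frames
        else pd.DataFrame(),
    }


def group_stats(density: pd.DataFrame, coloc: pd.DataFrame, cfg: dict) -> pd.DataFrame:
    """Pairwise Mann-Whitney tests between groups on per-animal summaries."""
    alt = cfg["stats"]["alternative"]
    rows = []

    def _pairwise(per_animal: pd.DataFrame, value_col: str, metric: str):
        groups = sorted(per_animal["group"].unique())
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                a = per_animal.loc[per_animal["group"] == ga, value_col]
                b = per_animal.loc[per_animal["group"] == gb, value_col]
                if a.empty or b.empty:
                    continue
                res = mann_whitney_u(a, b, alternative=alt)
                rows.append({
                    "metric": metric, "group_a": ga, "group_b": gb,
                    "n_a": len(a), "n_b": len(b), "U": res.U, "p": res.p,
                    "method": res.method,
                })

    if not density.empty:
        for ch, sub in density.groupby("channel"):
            per_animal = sub.rename(columns={"density_per_um3": "value"})
            _pairwise(per_animal, "value", f"density::{ch}")
    if not coloc.empty:
        stat = cfg["stats"]["statistic"]
        sub = coloc.dropna(subset=["fraction"])
        for (ch, marker), tab in sub.groupby(["synaptic_channel", "marker"]):
            per_animal = aggregate_per_animal(
                tab, "fraction", stat, group_cols=["group"])
            _pairwise(per_animal, f"fraction_{stat}", f"coloc::{ch}::{marker}")
    return pd.DataFrame(rows, columns=["metric", "group_a", "group_b", "n_a",
                                       "n_b", "U", "p", "method"])


def run_pipeline(config: dict, out_dir, seed: int = 0,
                 write_stacks: bool = False) -> dict:
    """Execute the full synthetic pipeline described by ``config``.

    The ``simulate`` block defines groups (name → number of animals) and
    optional per-group parameter overrides; each animal gets a distinct
    sub-seed derived from ``seed``. Returns the result manifest.
    """
    cfg = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = cfg.get("simulate") or {"groups": {"control": 2}}
    groups: dict[str, int] = sim.get("groups", {"control": 2})
    overrides: dict = sim.get("group_overrides", {})

    all_tables: dict[str, list[pd.DataFrame]] = {"puncta": [], "density": [],
                                                 "coloc": []}
    sub_seed = seed
    for group, n_animals in groups.items():
        for a in range(int(n_animals)):
            sub_seed += 1
            animal_id = f"{group}_{a + 1}"
            t0 = time.time()
            params = _synth_params(cfg, overrides.get(group), sub_seed)
            stack, _truth = generate_stack(params)
            if write_stacks:
                write_stack(stack, out_dir / "stacks" / animal_id)
            if sim.get("simulate_only"):
                log.info("simulated %s in %.1fs", animal_id, time.time() - t0)
                continue
            tables = analyze_stack(stack, cfg, animal_id, group)
            for key in all_tables:
                all_tables[key].append(tables[key])
            log.info("stage=%s animal=%s took %.1fs", "analyze", animal_id,
                     time.time() - t0)

    out_tables = {k: (pd.concat(v, ignore_index=True) if v else pd.DataFrame())
                  for k, v in all_tables.items()}
    if not sim.get("simulate_only"):
        out_tables["stats"] = group_stats(out_tables["density"],
                                          out_tables["coloc"], cfg)
    manifest = write_results(out_tables, out_dir, config=cfg, seed=seed)
    return manifest
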