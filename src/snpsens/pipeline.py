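"""End-to-end experiment orchestration.

``run_experiment`` composes the full workflow over synthetic cohorts:
simulate target regions and a known-sites panel, draw per-individual
truth genotypes, simulate platform-specific coverage and allele counts
for each sample, downsample along the retention-fraction ladder, call
genotypes, build per-sample gold standards from the full data, and
derive every summary statistic: per-site sensitivity/specificity curves
and their threshold depths, overall estimated sensitivity versus mean
on-target depth with the 95% requirement, breadth requirements,
difficult-tile classification with the sequence-feature regression,
matched-platform concordance, grouped-versus-single calling accounting,
and the cost table. Fully deterministic under the master seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import derive_seed
from . import costs as costs_mod
from .concordance import compare_matched, grouped_vs_single, rare_variant_accounting
from .difficulty import DifficultyRules, classify_tiles, difficulty_regression
from .genotyper import CallerParams, call_sample, pooled_call
from .overall import (breadth_requirement, depth_requirement, distribution_from_depths,
                      overall_sensitivity)
from .regions_io import tile_targets, write_bed, write_vcf_calls
from .sensitivity import (build_gold_standard, matched_min_depth, min_depth_for,
                          per_site_sensitivity, specificity_curve, write_curve)
from .simulate import (AlleleModel, CoverageModel, DEFAULT_FRACTIONS, DepthProfile,
                       make_ladder, sample_allele_counts, simulate_coverage,
                       simulate_panel, simulate_regions, simulate_truth,
                       write_depth_table)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlatformSpec:
    """Coverage and allele-bias character of one sequencing platform."""

    mean_depth: float
    dispersion: float
    gc_bias_strength: float = 0.0
    failure_rate: float = 0.0
    ref_bias: float = 0.0
    error_rate: float = 0.01


#: WGS-like: homogeneous coverage, no capture bias. Exome-like: deeper on
#: average but overdispersed, GC-penalised, occasional probe failure, and
#: reference-biased at heterozygous sites.
DEFAULT_PLATFORMS = {
    "wgs": PlatformSpec(mean_depth=40.0, dispersion=50.0),
    "exome": PlatformSpec(mean_depth=80.0, dispersion=2.0, gc_bias_strength=2.0,
                          failure_rate=0.01, ref_bias=0.1),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions for one synthetic experiment."""

    n_regions: int = 625          # ~1e5 targeted bases at exon-scale lengths
    panel_density: float = 0.02   # known variant sites per targeted base
    n_samples: int = 6            # individuals per platform (matched across platforms)
    het_fraction: float = 0.4
    hom_alt_fraction: float = 0.2
    fractions: tuple = DEFAULT_FRACTIONS
    caller: CallerParams = field(default_factory=CallerParams)
    rules: DifficultyRules = field(default_factory=DifficultyRules)
    platforms: dict = field(default_factory=lambda: dict(DEFAULT_PLATFORMS))
    sensitivity_threshold: float = 0.95
    d_cap: int = 50
    min_bin_sites: int = 100
    seed: int = 0


def _simulate_platform(cfg: ExperimentConfig, name: str, spec: PlatformSpec,
                       targets: pd.DataFrame, truths: list[pd.DataFrame]) -> dict:
    """Per-sample profiles, read ladders, call ladders and gold standards."""
    samples = {}
    for i in range(cfg.n_samples):
        cov = CoverageModel(mean_depth=spec.mean_depth, dispersion=spec.dispersion,
                            gc_bias_strength=spec.gc_bias_strength,
                            failure_rate=spec.failure_rate,
                            seed=derive_seed(cfg.seed, name, i, "cov"))
        allele = AlleleModel(ref_bias=spec.ref_bias, error_rate=spec.error_rate,
                             seed=derive_seed(cfg.seed, name, i, "allele"))
        profile = simulate_coverage(targets, cov)
        reads = sample_allele_counts(truths[i], profile, allele)
        read_ladder = make_ladder(reads, cfg.fractions, derive_seed(cfg.seed, name, i, "reads"))
        call_ladder = {f: call_sample(r, cfg.caller) for f, r in read_ladder.items()}
        profile_ladder = make_ladder(profile, cfg.fractions,
                                     derive_seed(cfg.seed, name, i, "depthladder"))
        samples[f"{name}_s{i}"] = {
            "profile": profile, "reads": reads, "read_ladder": read_ladder,
            "call_ladder": call_ladder, "profile_ladder": profile_ladder,
        }
    return samples


def _platform_summary(cfg: ExperimentConfig, name: str, samples: dict,
                      panel: pd.DataFrame, tiles: pd.DataFrame) -> tuple[dict, dict]:
    """Curves, requirements and difficulty for one platform. Returns
    (summary section, artefacts for optional writing)."""
    golds = {}
    for sname, s in samples.items():
        gold, _ = build_gold_standard(s["call_ladder"][1.0], panel,
                                      min_gq=cfg.caller.min_gq_gold)
        golds[sname] = gold
    pairs = [(golds[sname], s["call_ladder"]) for sname, s in samples.items()]

    curve_het = per_site_sensitivity(pairs, "het", cfg.d_cap)
    curve_hom = per_site_sensitivity(pairs, "hom", cfg.d_cap)
    curve_spec = specificity_curve(pairs, cfg.d_cap)

    thr = cfg.sensitivity_threshold
    section = {
        "min_depth_het": min_depth_for(curve_het, thr, cfg.min_bin_sites),
        "min_depth_hom": min_depth_for(curve_hom, thr, cfg.min_bin_sites),
        "min_depth_specificity_99": min_depth_for(curve_spec, 0.99, cfg.min_bin_sites),
        "n_gold_sites": {s: len(g) for s, g in golds.items()},
    }

    # overall sensitivity ladder: pooled coverage distribution per fraction
    ladder_points = []
    breadth_profiles = []
    for f in sorted(cfg.fractions):
        depths = np.concatenate([s["profile_ladder"][f].df["depth"].to_numpy()
                                 for s in samples.values()])
        dist = distribution_from_depths(depths, cfg.d_cap)
        ladder_points.append((dist.mean, overall_sensitivity(curve_het, dist)))
        pooled = pd.concat([s["profile_ladder"][f].df for s in samples.values()],
                           ignore_index=True)
        breadth_profiles.append(DepthProfile(pooled))
    section["overall_ladder"] = [{"mean_depth": d, "overall_het_sensitivity": s}
                                 for d, s in ladder_points]
    section["depth_requirement"] = depth_requirement(ladder_points, thr)
    section["breadth_requirement_10x_90pct"] = breadth_requirement(breadth_profiles)

    # difficulty
    full_profiles = {sname: s["profile"] for sname, s in samples.items()}
    classified = classify_tiles(tiles, full_profiles, cfg.rules)
    counts = classified["difficulty"].value_counts().to_dict()
    section["difficulty_counts"] = {k: int(counts.get(k, 0))
                                    for k in ("difficult", "easy", "neither")}
    try:
        section["difficulty_regression"] = difficulty_regression(classified)
    except ValueError as exc:
        section["difficulty_regression"] = {"error": str(exc)}

    artefacts = {"curve_het": curve_het, "curve_hom": curve_hom,
                 "curve_specificity": curve_spec, "golds": golds,
                 "classified_tiles": classified}
    return section, artefacts


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full workflow; return (and optionally write) the summary."""
    t0 = time.time()
    targets = simulate_regions(cfg.n_regions, derive_seed(cfg.seed, "regions"))
    panel = simulate_panel(targets, cfg.panel_density, derive_seed(cfg.seed, "panel"))
    tiles = tile_targets(targets)
    log.info("stage=targets n_regions=%d n_bases=%d n_panel=%d",
             len(targets), int((targets['end'] - targets['start']).sum()), len(panel))

    truths = [simulate_truth(panel, cfg.het_fraction, cfg.hom_alt_fraction,
                             derive_seed(cfg.seed, "truth", i))
              for i in range(cfg.n_samples)]

    summary = {"seed": cfg.seed, "n_regions": len(targets),
               "n_targeted_bases": int((targets["end"] - targets["start"]).sum()),
               "n_panel_sites": len(panel), "platforms": {}}
    platform_data = {}
    artefacts = {}
    for name, spec in cfg.platforms.items():
        t = time.time()
        samples = _simulate_platform(cfg, name, spec, targets, truths)
        section, art = _platform_summary(cfg, name, samples, panel, tiles)
        summary["platforms"][name] = section
        platform_data[name] = samples
        artefacts[name] = art
        log.info("stage=platform name=%s n_samples=%d wall=%.1fs",
                 name, len(samples), time.time() - t)

    if {"wgs", "exome"} <= set(platform_data):
        summary["concordance"] = _concordance_section(cfg, platform_data, artefacts,
                                                      targets, panel)

    summary["costs"] = _cost_section()
    log.info("stage=done wall=%.1fs", time.time() - t0)

    if out_dir is not None:
        _write_outputs(Path(out_dir), cfg, targets, panel, platform_data,
                       artefacts, summary)
    return summary


def _concordance_section(cfg, platform_data, artefacts, targets, panel) -> dict:
    wgs, exo = platform_data["wgs"], platform_data["exome"]
    wnames, enames = list(wgs), list(exo)
    out = {}

    # matched-sample comparison: same individual, full calls, both platforms
    per_pair = []
    for i in range(cfg.n_samples):
        w, e = wgs[wnames[i]], exo[enames[i]]
        per_pair.append(compare_matched(e["call_ladder"][1.0], w["call_ladder"][1.0],
                                        targets, e["profile"], w["profile"]))
    def _mean_defined(key):
        vals = [p[key] for p in per_pair
                if not (isinstance(p[key], float) and np.isnan(p[key]))]
        return float(np.mean(vals)) if vals else None

    out["matched_full_calls"] = {k: _mean_defined(k)
                                 for k in per_pair[0] if k != "n_union"}
    out["matched_full_calls"]["n_union_mean"] = float(np.mean([p["n_union"] for p in per_pair]))

    # matched minimum-depth analysis on the first individual
    gw = artefacts["wgs"]["golds"][wnames[0]]
    ge = artefacts["exome"]["golds"][enames[0]]
    try:
        _, md = matched_min_depth(exo[enames[0]]["call_ladder"], wgs[wnames[0]]["call_ladder"],
                                  ge, gw)
        out["matched_min_depth_95"] = {"exome": md["A"], "wgs": md["B"]}
    except ValueError as exc:
        out["matched_min_depth_95"] = {"error": str(exc)}

    # grouped vs single calling, per platform, on the full data
    known_panel = panel[panel["maf"] >= 0.01] if "maf" in panel.columns else panel
    for name, samples in platform_data.items():
        reads = {s: d["reads"] for s, d in samples.items()}
        grouped_calls, _ = pooled_call(reads, cfg.caller)
        # single-sample mode applies the same discovery threshold to each
        # sample's own reads (pooled_call with a one-sample group)
        single_calls = {s: pooled_call({s: d["reads"]}, cfg.caller)[0][s]
                        for s, d in samples.items()}
        table = grouped_vs_single(grouped_calls, single_calls, artefacts[name]["golds"])
        out[f"grouped_vs_single_{name}"] = {
            "mean_additional_het": float(table["additional_het"].mean()),
            "mean_additional_hom": float(table["additional_hom"].mean()),
            "mean_mismatched": float(table["mismatched"].mean()),
        }
        first = list(samples)[0]
        out[f"rare_variants_{name}"] = rare_variant_accounting(
            grouped_calls[first], single_calls[first], known_panel, panel,
            min_gq=cfg.caller.min_gq_gold)
    return out


def _cost_section() -> dict:
    table = costs_mod.reference_cost_table()
    components = costs_mod.fit_cost_components(table)
    parity = costs_mod.parity_scan(components, [(1.0, 12.0), (2.0, 4.0)])
    return {
        "ratio_93_94_tier": costs_mod.cost_ratio_at_sensitivity(table, 1.0, 12.0),
        "ratio_98_99_tier": costs_mod.cost_ratio_at_sensitivity(table, 2.0, 4.0),
        "depth_exome_4_per_lane": costs_mod.depth_from_allocation(
            costs_mod.CostScenario("exome", costs_mod.exome_lane_yield(), samples_per_lane=4)),
        "depth_wgs_2_lanes": costs_mod.depth_from_allocation(
            costs_mod.CostScenario("wgs", costs_mod.wgs_lane_yield(), lanes_per_sample=2)),
        "fitted_components": components,
        "parity_multiplier_93_94": parity[0],
        "parity_multiplier_98_99": parity[1],
    }


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _write_outputs(out_dir: Path, cfg, targets, panel, platform_data,
                   artefacts, summary) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_bed(targets, out_dir / "targets.bed")
    for name, art in artefacts.items():
        write_curve(art["curve_het"], out_dir / f"curve_het_{name}.tsv", "het",
                    cfg.min_bin_sites)
        write_curve(art["curve_hom"], out_dir / f"curve_hom_{name}.tsv", "hom",
                    cfg.min_bin_sites)
        write_bed(art["classified_tiles"].rename(columns={"region_id": "name"}),
                  out_dir / f"tiles_{name}.bed", extra_cols=["difficulty"])
        profiles = {s: d["profile"] for s, d in platform_data[name].items()}
        write_depth_table(profiles, out_dir / f"depth_{name}.tsv")
        first = list(platform_data[name])[0]
        write_vcf_calls(platform_data[name][first]["call_ladder"][1.0],
                        out_dir / f"calls_full_{name}_{first}.vcf", sample=first)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(_jsonify(summary), fh, indent=2)
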