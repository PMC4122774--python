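"""Matched-platform call-set comparison and grouped-vs-single accounting.

Two call sets for the same individual (e.g. exome capture and WGS) are
compared over the targets they share: sites polymorphic in either set
are partitioned into matched-genotype, mismatched-genotype, only-A and
only-B categories (fractions over the union), with per-site depth
comparisons at the discordant sites to show whether dropouts track
coverage. Grouped-versus-single accounting quantifies what pooled
calling adds, overall and for rare variants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import DepthProfile

_KEYS = ["chrom", "pos", "ref", "alt"]
_POLY = ("RA", "AA")


def _polymorphic(calls: pd.DataFrame) -> pd.DataFrame:
    return calls[calls["genotype"].isin(_POLY)]


def _in_targets(calls: pd.DataFrame, targets: pd.DataFrame) -> pd.DataFrame:
    """Restrict calls to 1-based positions inside 0-based half-open targets."""
    if len(calls) == 0:
        return calls
    keep = np.zeros(len(calls), dtype=bool)
    pos0 = calls["pos"].to_numpy() - 1
    for chrom, grp in targets.groupby("chrom"):
        on_chrom = (calls["chrom"] == chrom).to_numpy()
        if not on_chrom.any():
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        idx = np.searchsorted(starts, pos0[on_chrom], side="right") - 1
        inside = (idx >= 0) & (pos0[on_chrom] < ends[np.maximum(idx, 0)])
        keep[np.flatnonzero(on_chrom)] = inside
    return calls[keep]


def compare_matched(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                    shared_targets: pd.DataFrame,
                    depths_a: DepthProfile, depths_b: DepthProfile) -> dict:
    """Concordance report for two call sets from one individual.

    Categories over the union of polymorphic sites within the shared
    targets: both polymorphic with matched / mismatched genotype,
    polymorphic only in A, only in B. At only-A sites the report adds
    the fraction with depth_A > depth_B and the fraction with zero depth
    in B (capture dropouts).
    """
    if len(shared_targets) == 0:
        raise ValueError("empty shared target set")
    poly_a = _in_targets(_polymorphic(calls_a), shared_targets)
    poly_b = _in_targets(_polymorphic(calls_b), shared_targets)
    merged = poly_a.merge(poly_b, on=_KEYS, how="outer", suffixes=("_a", "_b"),
                          indicator=True)
    n_union = len(merged)
    both = merged["_merge"] == "both"
    matched = both & (merged["genotype_a"] == merged["genotype_b"])
    mismatched = both & ~matched
    only_a = merged["_merge"] == "left_only"
    only_b = merged["_merge"] == "right_only"

    report = {"n_union": int(n_union)}
    if n_union:
        report.update(
            matched_genotype=float(matched.mean()),
            mismatched_genotype=float(mismatched.mean()),
            only_a=float(only_a.mean()),
            only_b=float(only_b.mean()),
        )
    else:
        report.update(matched_genotype=np.nan, mismatched_genotype=np.nan,
                      only_a=np.nan, only_b=np.nan)
    only_a_sites = merged.loc[only_a, _KEYS]
    if len(only_a_sites):
        da = depths_a.depth_at(only_a_sites["chrom"], only_a_sites["pos"])
        db = depths_b.depth_at(only_a_sites["chrom"], only_a_sites["pos"])
        report["only_a_depth_a_greater"] = float((da > db).mean())
        report["only_a_zero_depth_b"] = float((db == 0).mean())
    else:
        report["only_a_depth_a_greater"] = np.nan
        report["only_a_zero_depth_b"] = np.nan
    return report


def grouped_vs_single(group_calls: dict[str, pd.DataFrame],
                      single_calls: dict[str, pd.DataFrame],
                      gold: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-sample accounting of what grouped calling adds over single-sample.

    additional_het / additional_hom: sites polymorphic only in the
    grouped call set, stratified by the gold zygosity where the site is
    in the sample's gold standard (``additional_unknown`` otherwise).
    mismatched: polymorphic in both with different genotypes.
    """
    if set(group_calls) != set(single_calls):
        raise ValueError("grouped and single call sets cover different samples")
    rows = []
    for sample in group_calls:
        g = _polymorphic(group_calls[sample])
        s = _polymorphic(single_calls[sample])
        merged = g.merge(s, on=_KEYS, how="outer", suffixes=("_g", "_s"), indicator=True)
        additional = merged[merged["_merge"] == "left_only"]
        zyg = additional[_KEYS].merge(gold.get(sample, pd.DataFrame(columns=_KEYS + ["genotype"])),
                                      on=_KEYS, how="left")["genotype"]
        both = merged["_merge"] == "both"
        rows.append({"sample": sample,
                     "additional_het": int((zyg == "RA").sum()),
                     "additional_hom": int((zyg == "AA").sum()),
                     "additional_unknown": int((~zyg.isin(["RA", "AA"])).sum()),
                     "lost": int((merged["_merge"] == "right_only").sum()),
                     "mismatched": int((both & (merged["genotype_g"] != merged["genotype_s"])).sum())})
    return pd.DataFrame(rows)


def rare_variant_accounting(group_calls: pd.DataFrame, single_calls: pd.DataFrame,
                            known_panel: pd.DataFrame, freq_panel: pd.DataFrame,
                            maf_max: float = 0.01, min_gq: int = 60) -> dict:
    """Rare-variant gain/loss from grouped calling, one sample.

    A called site is *rare* when it is absent from the known-sites panel,
    present in the frequency panel at MAF strictly below ``maf_max``,
    polymorphic, and at GQ >= ``min_gq`` in the call set considered.
    gained% = 100 * |grouped-only rare| / |single rare|;
    lost%   = 100 * |single-only rare| / |single rare|.
    Percentages are None when the single-sample rare set is empty.
    """

    def rare(calls):
        poly = calls[(calls["genotype"].isin(_POLY)) & (calls["gq"] >= min_gq)]
        known = poly.merge(known_panel[_KEYS], on=_KEYS, how="left", indicator=True)
        novel = known[known["_merge"] == "left_only"].drop(columns="_merge")
        freq_cols = _KEYS + (["maf"] if "maf" in freq_panel.columns else [])
        in_freq = novel.merge(freq_panel[freq_cols], on=_KEYS, how="inner")
        if "maf" in in_freq.columns:
            in_freq = in_freq[in_freq["maf"] < maf_max]  # "less than" is strict
        return set(map(tuple, in_freq[_KEYS].itertuples(index=False)))

    rare_g, rare_s = rare(group_calls), rare(single_calls)
    n_single = len(rare_s)
    out = {"n_single_rare": n_single, "n_grouped_rare": len(rare_g),
           "n_gained": len(rare_g - rare_s), "n_lost": len(rare_s - rare_g)}
    if n_single == 0:
        out["gained_pct"] = None
        out["lost_pct"] = None
    else:
        out["gained_pct"] = 100.0 * out["n_gained"] / n_single
        out["lost_pct"] = 100.0 * out["n_lost"] / n_single
    return out
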