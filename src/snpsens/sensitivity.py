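"""Gold standards and per-site sensitivity/specificity versus mapped depth.

The per-site question: how many mapped reads directly over a known
variant site are needed to call its genotype correctly? The answer is
estimated empirically. Full-depth calls restricted to a known-sites
panel and filtered at GQ >= 60 define a per-sample gold standard; calls
from the downsampling ladder are then scored against that gold, pooling
(site, fraction, sample) observations and binning by the downsampled
per-site depth d. Sensitivity s(d) is the fraction of observations in
bin d whose called genotype equals the gold genotype exactly; a missing
call (including depth 0) is always incorrect.

Threshold crossings ("95% sensitivity is reached at ...X") are read off
after isotonic (monotone non-decreasing) smoothing of s(d), because raw
finite-bin curves are noisy; raw values are always kept alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

CURVE_COLS = ["depth", "n_sites", "n_correct", "sensitivity", "overflow"]

_ZYGOSITY_GENO = {"het": "RA", "hom": "AA"}


def build_gold_standard(full_calls: pd.DataFrame, panel: pd.DataFrame,
                        min_gq: int = 60) -> tuple[pd.DataFrame, int]:
    """Gold-standard genotypes from full-depth calls at panel sites.

    Keeps calls at panel positions with matching ref/alt alleles,
    non-missing genotype, and GQ >= min_gq. Returns (gold table with a
    genotype column, count of allele-mismatched panel positions).
    """
    merged = full_calls.merge(panel[["chrom", "pos", "ref", "alt"]],
                              on=["chrom", "pos"], how="inner",
                              suffixes=("", "_panel"))
    allele_match = (merged["ref"] == merged["ref_panel"]) & (merged["alt"] == merged["alt_panel"]) \
        if "ref_panel" in merged.columns else pd.Series(True, index=merged.index)
    n_mismatch = int((~allele_match).sum())
    kept = merged[allele_match & (merged["genotype"] != "missing") & (merged["gq"] >= min_gq)]
    gold = kept[["chrom", "pos", "ref", "alt", "genotype"]].reset_index(drop=True)
    return gold, n_mismatch


def sensitivity_observations(gold: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Score one call set against a gold standard.

    Returns one row per gold site: downsampled depth, gold genotype, and
    whether the call matches the gold exactly. Gold sites absent from
    the call table count as missing at depth 0.
    """
    merged = gold.merge(calls[["chrom", "pos", "ref", "alt", "genotype", "depth"]],
                        on=["chrom", "pos", "ref", "alt"], how="left",
                        suffixes=("_gold", ""))
    merged["depth"] = merged["depth"].fillna(0).astype(np.int64)
    merged["genotype"] = merged["genotype"].fillna("missing")
    merged["correct"] = merged["genotype"] == merged["genotype_gold"]
    return merged[["chrom", "pos", "depth", "genotype_gold", "genotype", "correct"]]


def curve_from_observations(obs: pd.DataFrame, d_cap: int = 50) -> pd.DataFrame:
    """Bin scored observations by depth into a sensitivity curve.

    Rows for d = 0..d_cap plus one overflow row (d > d_cap). Bins with
    no observations carry sensitivity NaN, never 0.
    """
    depth = obs["depth"].to_numpy(dtype=np.int64) if len(obs) else np.array([], dtype=np.int64)
    correct = obs["correct"].to_numpy(dtype=bool)
    binned = np.minimum(depth, d_cap + 1)
    n_sites = np.bincount(binned, minlength=d_cap + 2)
    n_correct = np.bincount(binned, weights=correct, minlength=d_cap + 2).astype(np.int64)
    with np.errstate(invalid="ignore"):
        sens = np.where(n_sites > 0, n_correct / np.maximum(n_sites, 1), np.nan)
    return pd.DataFrame({"depth": np.arange(d_cap + 2),
                         "n_sites": n_sites.astype(np.int64),
                         "n_correct": n_correct,
                         "sensitivity": sens,
                         "overflow": np.arange(d_cap + 2) > d_cap})


def per_site_sensitivity(pairs, zygosity: str, d_cap: int = 50,
                         include_full: bool = False) -> pd.DataFrame:
    """Pooled per-site sensitivity curve for one zygosity class.

    ``pairs`` is an iterable of (gold table, {fraction: calls}) — one
    entry per sample. Observations pool over samples and downsampling
    fractions; the p = 1.0 ladder entry is excluded by default because
    the gold standard derives from it.
    """
    if zygosity not in _ZYGOSITY_GENO:
        raise ValueError(f"zygosity must be 'het' or 'hom', got {zygosity!r}")
    want = _ZYGOSITY_GENO[zygosity]
    all_obs = []
    for gold, ladder in pairs:
        gold_z = gold[gold["genotype"] == want]
        for frac, calls in ladder.items():
            if not include_full and float(frac) == 1.0:
                continue
            all_obs.append(sensitivity_observations(gold_z, calls))
    if not all_obs or sum(len(o) for o in all_obs) == 0:
        import warnings
        warnings.warn(f"no gold sites with zygosity {zygosity!r}; empty curve")
        return curve_from_observations(
            pd.DataFrame({"depth": [], "correct": []}), d_cap)
    return curve_from_observations(pd.concat(all_obs, ignore_index=True), d_cap)


def specificity_curve(pairs, d_cap: int = 50, include_full: bool = False) -> pd.DataFrame:
    """1 - false-positive rate by depth at gold hom-ref sites.

    A false positive is a gold hom-ref observation called RA or AA;
    missing calls are not false positives. Returned in curve layout with
    ``sensitivity`` holding specificity and ``n_correct`` the non-FP count.
    """
    all_obs = []
    for gold, ladder in pairs:
        gold_rr = gold[gold["genotype"] == "RR"]
        for frac, calls in ladder.items():
            if not include_full and float(frac) == 1.0:
                continue
            obs = sensitivity_observations(gold_rr, calls)
            obs["correct"] = ~obs["genotype"].isin(["RA", "AA"])
            all_obs.append(obs)
    obs = pd.concat(all_obs, ignore_index=True) if all_obs else pd.DataFrame({"depth": [], "correct": []})
    return curve_from_observations(obs, d_cap)


def smooth_curve(curve: pd.DataFrame, min_bin_sites: int = 100) -> pd.DataFrame:
    """Isotonic (monotone non-decreasing) fit to the populated bins.

    Bins with fewer than ``min_bin_sites`` observations and the overflow
    bin are excluded from the fit; the returned copy carries a
    ``smoothed`` column (NaN where excluded).
    """
    out = curve.copy()
    use = (~curve["overflow"]) & (curve["n_sites"] >= min_bin_sites)
    out["smoothed"] = np.nan
    if use.sum() >= 1:
        x = curve.loc[use, "depth"].to_numpy(dtype=float)
        y = curve.loc[use, "sensitivity"].to_numpy(dtype=float)
        w = curve.loc[use, "n_sites"].to_numpy(dtype=float)
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        out.loc[use, "smoothed"] = iso.fit_transform(x, y, sample_weight=w)
    return out


def min_depth_for(curve: pd.DataFrame, threshold: float,
                  min_bin_sites: int = 100) -> int | None:
    """Smallest depth whose isotonically smoothed sensitivity reaches threshold.

    Returns None when the threshold is never reached within the capped
    bins (the overflow bin never qualifies).
    """
    if not 0.0 < threshold < 1.0 + 1e-12:
        raise ValueError(f"threshold={threshold} outside (0, 1]")
    smoothed = smooth_curve(curve, min_bin_sites)
    ok = smoothed["smoothed"] >= threshold - 1e-12
    if not ok.any():
        return None
    return int(smoothed.loc[ok, "depth"].iloc[0])


def write_curve(curve: pd.DataFrame, path, zygosity: str,
                min_bin_sites: int = 100) -> None:
    out = smooth_curve(curve, min_bin_sites)
    out.insert(0, "zygosity", zygosity)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Matched-sample minimum-depth analysis

def matched_min_depth(ladder_a: dict, ladder_b: dict,
                      gold_a: pd.DataFrame, gold_b: pd.DataFrame,
                      quantile: float = 0.95,
                      censored_in_denominator: bool = True):
    """Per-site minimum depth for a correct call on two matched platforms.

    Restricts to sites with identical alleles and genotypes in both
    platforms' gold standards. For each platform, scans the ladder in
    increasing fraction order and records the smallest downsampled depth
    at which the called genotype equals the shared gold genotype; sites
    never called correctly are censored (NaN).

    The summary reports, per platform, the smallest depth d such that at
    least ``quantile`` of sites have min-depth <= d. With
    ``censored_in_denominator`` (default, conservative) censored sites
    stay in the denominator; otherwise they are dropped.

    Returns (per-site table, {"A": depth|None, "B": depth|None}).
    """
    keys = ["chrom", "pos", "ref", "alt"]
    shared = gold_a.merge(gold_b, on=keys, suffixes=("_a", "_b"))
    shared = shared[shared["genotype_a"] == shared["genotype_b"]]
    if len(shared) == 0:
        raise ValueError("no shared gold sites with identical alleles and genotypes")
    gold = shared[keys].assign(genotype=shared["genotype_a"].to_numpy())

    def per_platform(ladder):
        dmin = np.full(len(gold), np.inf)
        for frac in sorted(ladder, key=float):
            if float(frac) == 1.0:
                continue
            obs = sensitivity_observations(gold, ladder[frac])
            d = obs["depth"].to_numpy(dtype=float)
            ok = obs["correct"].to_numpy(dtype=bool)
            cand = np.where(ok, d, np.inf)
            dmin = np.minimum(dmin, cand)
        return dmin

    dmin_a, dmin_b = per_platform(ladder_a), per_platform(ladder_b)
    table = gold.copy()
    table["d_min_a"] = np.where(np.isinf(dmin_a), np.nan, dmin_a)
    table["d_min_b"] = np.where(np.isinf(dmin_b), np.nan, dmin_b)

    def q_depth(dmin):
        vals = dmin if censored_in_denominator else dmin[np.isfinite(dmin)]
        if len(vals) == 0:
            return None
        finite = np.sort(vals[np.isfinite(vals)])
        n = len(vals)
        k = int(np.ceil(quantile * n))
        if k > len(finite):
            return None  # too many censored sites to ever reach the quantile
        return int(finite[k - 1])

    summary = {"A": q_depth(dmin_a), "B": q_depth(dmin_b)}
    return table, summary
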