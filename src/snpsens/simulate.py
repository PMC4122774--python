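"""Synthetic sequencing experiments: coverage fields, truth genotypes,
allele counts, and read downsampling.

The generator emulates the statistical structure of deep human
resequencing over exome-scale target regions, at the level the
downstream analyses consume — per-site mapped depth and per-site
ref/alt read counts — rather than individual reads:

* **Coverage** is a tile-level gamma-Poisson (negative binomial) field.
  Each tile of at most ``tile_size`` bases draws a rate multiplier from
  a Gamma(k, 1/k) distribution (mean 1); small k gives the heterogeneous,
  spiky coverage of capture-based exome sequencing, large k the
  near-Poisson homogeneity of WGS. An optional GC penalty
  ``exp(-gc_bias_strength * |gc - 0.5|)`` depresses coverage away from
  balanced base composition, and a ``failure_rate`` fraction of tiles
  captures nothing at all (probe failure). Per-base depths are Poisson
  around the tile rate.

* **Allele counts** at a known variant site with depth d: a heterozygote
  contributes alternate reads with probability
  ``0.5*(1-beta)`` before error, where ``beta`` is the reference-capture
  bias (preferential capture of reference-allele fragments); per-read
  sequencing error ``eps`` flips allele identity both ways. Homozygotes
  are Binomial(d, eps) or Binomial(d, 1-eps).

* **Downsampling** is independent per-read binomial thinning at
  retention fraction p, applied to ref and alt counts separately (and to
  bare depths for coverage-only analyses); a ladder of fractions
  0.1..0.9 plus the full data at 1.0 emulates a gradient of shallower
  sequencing runs.

All randomness flows from explicit integer seeds; substream seeds are
derived by stable hashing so that the same master seed reproduces every
output byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import check_fraction, check_positive, derive_seed
from .regions_io import make_panel, tile_targets

TRUTH_STATES = ("RR", "RA", "AA")


@dataclass(frozen=True)
class CoverageModel:
    """Tile-level gamma-Poisson coverage field parameters.

    mean_depth
        Expected per-base mapped depth (reads), before GC penalty and
        tile failures.
    dispersion
        Gamma shape k > 0. Var(depth)/mean ~ 1 + mean/k, so k -> inf is
        Poisson-homogeneous (WGS-like) and small k is overdispersed
        (capture-like).
    gc_bias_strength
        >= 0; per-tile depth multiplier exp(-strength * |gc - 0.5|).
    failure_rate
        Fraction in [0, 1] of tiles with zero capture.
    """

    mean_depth: float
    dispersion: float = 50.0
    gc_bias_strength: float = 0.0
    failure_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        check_positive("mean_depth", self.mean_depth)
        check_positive("dispersion", self.dispersion)
        if self.gc_bias_strength < 0:
            raise ValueError("gc_bias_strength must be >= 0")
        check_fraction("failure_rate", self.failure_rate, 0.0, 1.0)


@dataclass(frozen=True)
class AlleleModel:
    """Reference-capture bias and per-read error for allele-count draws.

    ref_bias
        beta in [0, 1): het alt-read probability before error is
        0.5*(1-beta). 0 for WGS-like data; positive for capture data.
    error_rate
        eps in [0, 0.5): probability a read reports the wrong allele.
    """

    ref_bias: float = 0.0
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        check_fraction("ref_bias", self.ref_bias, 0.0, 1.0, hi_open=True)
        check_fraction("error_rate", self.error_rate, 0.0, 0.5, hi_open=True)


def het_alt_probability(ref_bias: float, error_rate: float) -> float:
    """Probability an individual read at a het site reports the alt allele.

    Alt-origin fraction 0.5*(1-beta); error eps flips allele identity in
    both directions.
    """
    p_alt_origin = 0.5 * (1.0 - ref_bias)
    return p_alt_origin * (1.0 - error_rate) + (1.0 - p_alt_origin) * error_rate


class DepthProfile:
    """Per-site mapped depth for one sample over the targeted bases.

    Wraps a DataFrame with columns chrom, pos (1-based), depth (int >= 0)
    whose domain is exactly the targeted bases.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True)
        if (df["depth"] < 0).any():
            raise ValueError("negative depth")
        self.df = df.astype({"pos": np.int64, "depth": np.int64})
        self._index: pd.Index | None = None

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, DepthProfile) and self.df.equals(other.df)

    def mean_depth(self) -> float:
        """Mean on-target depth: average over all targeted bases, zeros included."""
        return float(self.df["depth"].mean()) if len(self.df) else 0.0

    def _site_index(self) -> pd.Index:
        if self._index is None:
            self._index = pd.MultiIndex.from_frame(self.df[["chrom", "pos"]])
        return self._index

    def depth_at(self, chrom, pos) -> np.ndarray:
        """Depths at 1-based (chrom, pos) pairs; raises if any site is off-target."""
        want = pd.MultiIndex.from_arrays([pd.Series(chrom, dtype=str),
                                          pd.Series(pos, dtype=np.int64)])
        locs = self._site_index().get_indexer(want)
        if (locs < 0).any():
            bad = want[locs < 0][0]
            raise KeyError(f"site {bad[0]}:{bad[1]} not in depth profile domain")
        return self.df["depth"].to_numpy()[locs]

    def thin(self, p: float, rng: np.random.Generator) -> "DepthProfile":
        out = self.df.copy()
        out["depth"] = rng.binomial(self.df["depth"].to_numpy(), p)
        return DepthProfile(out)


def targeted_positions(regions: pd.DataFrame) -> pd.DataFrame:
    """All targeted bases as (chrom, 1-based pos) rows, region order."""
    chroms, poss = [], []
    for row in regions.itertuples(index=False):
        n = row.end - row.start
        chroms.append(np.repeat(row.chrom, n))
        poss.append(np.arange(row.start + 1, row.end + 1, dtype=np.int64))
    if not chroms:
        return pd.DataFrame({"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64)})
    return pd.DataFrame({"chrom": np.concatenate(chroms), "pos": np.concatenate(poss)})


def simulate_coverage(regions: pd.DataFrame, model: CoverageModel,
                      tile_size: int = 100) -> DepthProfile:
    """Draw a per-base depth field over the target regions.

    Per tile: rate = mean_depth * Gamma(k, 1/k) * exp(-gc_bias*|gc-0.5|),
    zeroed for a failure_rate fraction of tiles; per-base depth is
    Poisson(rate). Regions without a gc column are treated as gc = 0.5
    (no penalty).
    """
    tiles = tile_targets(regions, tile_size)
    rng = np.random.default_rng(derive_seed(model.seed, "coverage"))
    lengths = (tiles["end"] - tiles["start"]).to_numpy()
    mult = rng.gamma(shape=model.dispersion, scale=1.0 / model.dispersion, size=len(tiles))
    gc = tiles["gc"].to_numpy(dtype=float) if "gc" in tiles.columns else np.full(len(tiles), 0.5)
    rate = model.mean_depth * mult * np.exp(-model.gc_bias_strength * np.abs(gc - 0.5))
    if model.failure_rate > 0:
        rate[rng.random(len(tiles)) < model.failure_rate] = 0.0
    per_base_rate = np.repeat(rate, lengths)
    depth = rng.poisson(per_base_rate)
    sites = targeted_positions(tiles[["chrom", "start", "end"]])
    sites["depth"] = depth
    return DepthProfile(sites)


def simulate_truth(panel: pd.DataFrame, het_fraction: float, hom_alt_fraction: float,
                   seed: int) -> pd.DataFrame:
    """Assign a true genotype to every panel site by independent categorical draw.

    Returns the panel with a ``genotype`` column in {RR, RA, AA};
    hom-ref probability is the remainder 1 - het - hom_alt.
    """
    check_fraction("het_fraction", het_fraction)
    check_fraction("hom_alt_fraction", hom_alt_fraction)
    if het_fraction + hom_alt_fraction > 1.0 + 1e-12:
        raise ValueError("het_fraction + hom_alt_fraction > 1")
    rng = np.random.default_rng(derive_seed(seed, "truth"))
    u = rng.random(len(panel))
    geno = np.where(u < het_fraction, "RA",
                    np.where(u < het_fraction + hom_alt_fraction, "AA", "RR"))
    out = panel.copy()
    out["genotype"] = geno
    return out


def sample_allele_counts(truths: pd.DataFrame, profile: DepthProfile,
                         model: AlleleModel) -> pd.DataFrame:
    """Draw per-site ref/alt read counts given truth genotypes and depths.

    hom-ref: alt ~ Binomial(d, eps); hom-alt: alt ~ Binomial(d, 1-eps);
    het: alt ~ Binomial(d, het_alt_probability(beta, eps)). ref = d - alt.
    """
    d = profile.depth_at(truths["chrom"], truths["pos"])
    geno = truths["genotype"].to_numpy()
    eps = model.error_rate
    p_alt = np.empty(len(truths))
    p_alt[geno == "RR"] = eps
    p_alt[geno == "AA"] = 1.0 - eps
    p_alt[geno == "RA"] = het_alt_probability(model.ref_bias, eps)
    rng = np.random.default_rng(derive_seed(model.seed, "alleles"))
    alt = rng.binomial(d, p_alt)
    out = truths[["chrom", "pos", "ref", "alt"]].copy()
    out["ref_count"] = d - alt
    out["alt_count"] = alt
    return out


def downsample(data, p: float, seed: int):
    """Binomially thin reads at retention fraction p (per-read independence).

    Accepts a SiteReads table (ref_count/alt_count thinned separately) or
    a DepthProfile (depth thinned). p = 1 returns an identical copy.
    """
    check_fraction("p", p)
    if p == 1.0:
        return DepthProfile(data.df.copy()) if isinstance(data, DepthProfile) else data.copy()
    rng = np.random.default_rng(derive_seed(seed, "thin", p))
    if isinstance(data, DepthProfile):
        return data.thin(p, rng)
    out = data.copy()
    out["ref_count"] = rng.binomial(data["ref_count"].to_numpy(), p)
    out["alt_count"] = rng.binomial(data["alt_count"].to_numpy(), p)
    return out


DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))


def make_ladder(data, fractions=DEFAULT_FRACTIONS, seed: int = 0) -> dict:
    """Downsampling ladder: {fraction: thinned data}, full data at 1.0."""
    fracs = [float(f) for f in fractions]
    if len(set(fracs)) != len(fracs):
        raise ValueError("duplicate downsampling fractions")
    return {f: downsample(data, f, derive_seed(seed, "ladder", f)) for f in sorted(fracs)}


# ---------------------------------------------------------------------------
# Study-condition generators: regions and known-site panels

def simulate_regions(n_regions: int, seed: int, mean_length: int = 160,
                     gc_mean: float = 0.46, gc_sd: float = 0.09,
                     repeat_fraction: float = 0.15, chrom: str = "chr1",
                     gap_mean: int = 2000) -> pd.DataFrame:
    """Generate a plausible exome-like target region set on one chromosome.

    Region lengths are geometric around ``mean_length`` (exon-scale,
    min 30 bp), separated by geometric gaps. GC is Gaussian around
    ``gc_mean`` clipped to [0.05, 0.95] — human coding exons average
    ~0.46 GC with a long right tail. A ``repeat_fraction`` of regions
    overlaps an annotated repeat; alignability is high (Beta(8,1)) for
    unique sequence and degraded for repeat-overlapping regions.
    """
    rng = np.random.default_rng(derive_seed(seed, "regions"))
    lengths = 30 + rng.geometric(1.0 / max(mean_length - 30, 1), n_regions)
    gaps = 50 + rng.geometric(1.0 / gap_mean, n_regions)
    starts = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(lengths[:-1])])
    gc = np.clip(rng.normal(gc_mean, gc_sd, n_regions), 0.05, 0.95)
    repeat = rng.random(n_regions) < repeat_fraction
    align = rng.beta(8, 1, n_regions)
    align[repeat] *= rng.beta(2, 2, repeat.sum())
    return pd.DataFrame({"chrom": chrom, "start": starts.astype(np.int64),
                         "end": (starts + lengths).astype(np.int64),
                         "gc": gc, "repeat": repeat, "alignability": align})


def simulate_panel(regions: pd.DataFrame, density: float, seed: int) -> pd.DataFrame:
    """Scatter known biallelic SNV sites over the targets at ``density`` per base.

    Minor allele frequencies are drawn from the neutral-ish 1/x site
    frequency spectrum truncated to [0.001, 0.5].
    """
    check_fraction("density", density, 0.0, 1.0, lo_open=True)
    rng = np.random.default_rng(derive_seed(seed, "panel"))
    sites = targeted_positions(regions)
    keep = rng.random(len(sites)) < density
    sites = sites[keep].reset_index(drop=True)
    nucs = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, len(sites))
    alt_idx = (ref_idx + rng.integers(1, 4, len(sites))) % 4
    lo, hi = np.log(0.001), np.log(0.5)
    maf = np.exp(rng.uniform(lo, hi, len(sites)))
    return make_panel(sites["chrom"], sites["pos"], nucs[ref_idx], nucs[alt_idx], maf=maf)


# ---------------------------------------------------------------------------
# Depth table I/O (GATK DepthOfCoverage-style TSV)

def write_depth_table(profiles: dict[str, DepthProfile], path) -> None:
    """Write per-site depths for several samples as a TSV (chrom, pos, one
    column per sample). All profiles must share the same site domain."""
    samples = list(profiles)
    domain = profiles[samples[0]].df[["chrom", "pos"]].reset_index(drop=True)
    out = domain.copy()
    for name in samples:
        df = profiles[name].df
        if not df[["chrom", "pos"]].reset_index(drop=True).equals(domain):
            raise ValueError(f"depth profile domain mismatch for sample {name!r}")
        out[name] = df["depth"].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_depth_table(path) -> dict[str, DepthProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    samples = [c for c in df.columns if c not in ("chrom", "pos")]
    return {name: DepthProfile(df[["chrom", "pos"]].assign(depth=df[name]))
            for name in samples}
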