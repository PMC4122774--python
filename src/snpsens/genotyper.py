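"""Biallelic diploid genotype-likelihood caller.

A deliberately small, analytically transparent caller: per-read error
eps, three genotype hypotheses {RR, RA, AA}, likelihoods

    L(RR) = eps^a (1-eps)^r
    L(RA) = 0.5^(r+a)
    L(AA) = eps^r (1-eps)^a

(shared combinatorial factor omitted), posterior proportional to
likelihood times a genotype prior, called genotype = argmax posterior,
and GQ = round(-10*log10(1 - max posterior)) capped. Zero depth yields
a "missing" call at GQ 0, which downstream sensitivity accounting
treats as an incorrect genotype.

Single-sample calling maps this over sites. Pooled (grouped) calling
first asks whether the site is polymorphic in the group — pooled alt
count against the Binomial(pooled depth, eps) upper tail — and only
then genotypes each sample; this is what lets reads from other samples
rescue a low-depth carrier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

GENOTYPE_ORDER = ("RR", "RA", "AA")  # argmax tie-break order


@dataclass(frozen=True)
class CallerParams:
    """Caller configuration.

    error_rate
        Per-read allele error eps in [0, 0.5).
    prior
        Prior over (RR, RA, AA); uniform by default so the analytic
        oracles stay clean. See :func:`gatk_like_prior` for a
        population-style alternative.
    gq_cap
        Maximum reported GQ (phred).
    min_gq_gold
        GQ threshold used when building gold standards from full data.
    """

    error_rate: float = 0.01
    prior: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    gq_cap: int = 99
    min_gq_gold: int = 60

    def __post_init__(self):
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError(f"error_rate={self.error_rate} outside [0, 0.5)")
        if abs(sum(self.prior) - 1.0) > 1e-12:
            raise ValueError("prior must sum to 1")
        if any(p < 0 for p in self.prior):
            raise ValueError("prior probabilities must be >= 0")


def gatk_like_prior(theta: float = 0.001) -> tuple[float, float, float]:
    """Population-style prior: P(RA)=theta, P(AA)=theta/2, rest hom-ref."""
    return (1.0 - 1.5 * theta, theta, theta / 2)


def _sxlogy(x: np.ndarray, y: float) -> np.ndarray:
    """x*log(y) with the convention 0*log(0) = 0 (eps = 0 is legal)."""
    from scipy.special import xlogy
    return xlogy(x, y)


def genotype_likelihoods(r, a, error_rate: float) -> np.ndarray:
    """Log-likelihoods (RR, RA, AA) for ref/alt read counts.

    Vectorised: scalar inputs give shape (3,), array inputs (n, 3).
    The shared binomial coefficient is omitted (it cancels in the
    posterior).
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValueError(f"error_rate={error_rate} outside [0, 0.5)")
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    a_arr = np.atleast_1d(np.asarray(a, dtype=float))
    if (r_arr < 0).any() or (a_arr < 0).any():
        raise ValueError("read counts must be >= 0")
    eps = error_rate
    ll = np.empty(np.broadcast(r_arr, a_arr).shape + (3,))
    ll[..., 0] = _sxlogy(a_arr, eps) + _sxlogy(r_arr, 1.0 - eps)
    ll[..., 1] = (r_arr + a_arr) * np.log(0.5)
    ll[..., 2] = _sxlogy(r_arr, eps) + _sxlogy(a_arr, 1.0 - eps)
    if np.isscalar(r) and np.isscalar(a):
        return ll[0]
    return ll


def genotype_posteriors(r, a, params: CallerParams) -> np.ndarray:
    """Normalised posterior triple(s) over (RR, RA, AA)."""
    ll = genotype_likelihoods(r, a, params.error_rate)
    logpost = ll + np.log(np.asarray(params.prior, dtype=float))
    logpost -= logpost.max(axis=-1, keepdims=True)
    post = np.exp(logpost)
    return post / post.sum(axis=-1, keepdims=True)


class GenotypeCall(NamedTuple):
    genotype: str
    gq: int
    depth: int
    ref_count: int
    alt_count: int


def _calls_from_counts(r: np.ndarray, a: np.ndarray, params: CallerParams):
    """Vectorised core: returns (genotype codes, gq) arrays."""
    post = genotype_posteriors(r, a, params)
    idx = post.argmax(axis=-1)  # first max wins: tie-break RR < RA < AA
    pmax = np.take_along_axis(post, idx[..., None], axis=-1)[..., 0]
    with np.errstate(divide="ignore"):
        gq = -10.0 * np.log10(np.maximum(1.0 - pmax, 1e-300))
    gq = np.minimum(np.round(gq), params.gq_cap).astype(np.int64)
    geno = np.array(GENOTYPE_ORDER, dtype=object)[idx]
    nodata = (np.asarray(r) + np.asarray(a)) == 0
    geno = np.where(nodata, "missing", geno)
    gq = np.where(nodata, 0, gq)
    return geno, gq


def call_genotype(r: int, a: int, params: CallerParams) -> GenotypeCall:
    """Call one site from ref/alt read counts."""
    geno, gq = _calls_from_counts(np.array([r]), np.array([a]), params)
    return GenotypeCall(str(geno[0]), int(gq[0]), int(r + a), int(r), int(a))


def call_sample(site_reads: pd.DataFrame, params: CallerParams) -> pd.DataFrame:
    """Call every site of a SiteReads table; site order preserved."""
    out = site_reads[["chrom", "pos", "ref", "alt"]].copy()
    r = site_reads["ref_count"].to_numpy()
    a = site_reads["alt_count"].to_numpy()
    if len(out) == 0:
        out["genotype"], out["gq"] = pd.Series(dtype=object), pd.Series(dtype=np.int64)
        out["depth"] = pd.Series(dtype=np.int64)
        out["ref_count"], out["alt_count"] = r, a
        return out
    geno, gq = _calls_from_counts(r, a, params)
    out["genotype"] = geno
    out["gq"] = gq
    out["depth"] = r + a
    out["ref_count"] = r
    out["alt_count"] = a
    return out


def pooled_call(sample_reads: dict[str, pd.DataFrame], params: CallerParams,
                alpha: float = 1e-4) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Grouped calling over samples sharing a site domain.

    A site is flagged polymorphic when the pooled alt count exceeds the
    Binomial(pooled depth, eps) upper tail at level ``alpha``. Samples
    are genotyped freely at flagged sites; at unflagged sites every
    sample is forced to RR (or missing at zero depth).

    Returns ({sample: calls}, site table with ``polymorphic`` flag).
    """
    samples = list(sample_reads)
    if not samples:
        raise ValueError("no samples")
    base = sample_reads[samples[0]][["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    for name in samples[1:]:
        if not sample_reads[name][["chrom", "pos", "ref", "alt"]].reset_index(drop=True).equals(base):
            raise ValueError(f"site domain mismatch for sample {name!r}")
    a_tot = sum(sample_reads[s]["alt_count"].to_numpy() for s in samples)
    n_tot = a_tot + sum(sample_reads[s]["ref_count"].to_numpy() for s in samples)
    # P(Bin(n_tot, eps) >= a_tot) < alpha, with a_tot = 0 never polymorphic
    tail = stats.binom.sf(a_tot - 1, np.maximum(n_tot, 1), params.error_rate)
    polymorphic = (a_tot > 0) & (tail < alpha)
    sites = base.copy()
    sites["pooled_depth"] = n_tot
    sites["pooled_alt"] = a_tot
    sites["polymorphic"] = polymorphic
    calls = {}
    for name in samples:
        df = call_sample(sample_reads[name], params)
        forced = ~polymorphic & (df["genotype"] != "missing")
        df.loc[forced, "genotype"] = "RR"
        calls[name] = df
    return calls, sites
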