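"""Independent oracles used by the test suite.

These deliberately avoid the library code paths they check: posterior
arithmetic is plain-float enumeration, isotonic regression is a direct
pool-adjacent-violators loop, and tile classification is a per-base
Python reimplementation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def posterior_oracle(r: int, a: int, eps: float, prior=(1 / 3, 1 / 3, 1 / 3)):
    """Normalised genotype posterior by direct arithmetic (no logs)."""
    lik = [(eps ** a) * ((1 - eps) ** r),
           0.5 ** (r + a),
           (eps ** r) * ((1 - eps) ** a)]
    post = [l * p for l, p in zip(lik, prior)]
    z = sum(post)
    return [x / z for x in post]


def call_oracle(r: int, a: int, eps: float, prior=(1 / 3, 1 / 3, 1 / 3), gq_cap: int = 99):
    """(genotype, gq) by direct posterior arithmetic; depth 0 is missing."""
    if r + a == 0:
        return "missing", 0
    post = posterior_oracle(r, a, eps, prior)
    idx = max(range(3), key=lambda i: (post[i], -i))  # first max wins
    pmax = post[idx]
    gq = min(round(-10.0 * math.log10(max(1.0 - pmax, 1e-300))), gq_cap)
    return ["RR", "RA", "AA"][idx], gq


def exact_call_probability(depth: int, p_alt: float, called: str, eps: float,
                           prior=(1 / 3, 1 / 3, 1 / 3)) -> float:
    """P(caller outputs ``called``) by enumerating all (r, a) splits at a depth."""
    total = 0.0
    for a in range(depth + 1):
        if call_oracle(depth - a, a, eps, prior)[0] == called:
            total += stats.binom.pmf(a, depth, p_alt)
    return total


def het_alt_prob_oracle(beta: float, eps: float) -> float:
    p = 0.5 * (1 - beta)
    return p * (1 - eps) + (1 - p) * eps


def pava_oracle(y, w):
    """Weighted isotonic (non-decreasing) fit by explicit block pooling.

    Each block is [mean, weight, n_points]; a violating adjacent pair is
    pooled into its weighted mean until the sequence is monotone.
    """
    blocks = []
    for yi, wi in zip(y, w):
        blocks.append([float(yi), float(wi), 1])
        while len(blocks) >= 2 and blocks[-2][0] > blocks[-1][0] + 1e-15:
            v1, w1, n1 = blocks.pop()
            v0, w0, n0 = blocks.pop()
            blocks.append([(v0 * w0 + v1 * w1) / (w0 + w1), w0 + w1, n0 + n1])
    out = []
    for val, _, n in blocks:
        out.extend([val] * n)
    return np.array(out)


def min_depth_oracle(depths, sens, counts, threshold, min_bin_sites):
    """Brute-force isotonic threshold crossing on a raw curve."""
    keep = [i for i, c in enumerate(counts) if c >= min_bin_sites]
    if not keep:
        return None
    y = [sens[i] for i in keep]
    w = [counts[i] for i in keep]
    fitted = pava_oracle(y, w)
    for d, f in zip([depths[i] for i in keep], fitted):
        if f >= threshold - 1e-12:
            return int(d)
    return None


def classify_oracle(tiles, depth_maps, per_base_min=15, frac_bases=0.5,
                    min_sample_frac=0.5):
    """Per-base Python reimplementation of tile difficulty classes.

    ``depth_maps`` is {sample: {(chrom, pos): depth}} with 1-based pos.
    """
    n = len(depth_maps)
    need = math.ceil(min_sample_frac * n)
    classes = []
    for tile in tiles.itertuples(index=False):
        positions = [(tile.chrom, p) for p in range(tile.start + 1, tile.end + 1)]
        fails = 0
        every_base_everywhere = True
        for dm in depth_maps.values():
            covered = [dm[pos] >= per_base_min for pos in positions]
            if sum(covered) / len(covered) < frac_bases:
                fails += 1
            if not all(covered):
                every_base_everywhere = False
        if fails >= need:
            classes.append("difficult")
        elif every_base_everywhere:
            classes.append("easy")
        else:
            classes.append("neither")
    return classes
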