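"""Overall estimated sensitivity: coverage distributions combined with
per-site sensitivity curves.

Per-site curves answer "how deep must this one site be?"; a sequencing
strategy is summarised instead by the *overall estimated sensitivity*

    S = sum_d P(d) * s(d)

where P(d) is the distribution of per-site depth over all targeted
bases (zeros included) and s(d) the per-site sensitivity. S relates
directly to the mean on-target depth d-bar of a run, which is what a
sequencing experiment actually buys, and so supports statements like
"95% overall heterozygous sensitivity needs a mean on-target depth of
40X on platform X but only 14X on platform Y": coverage heterogeneity,
not per-site behaviour, drives most of that gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .simulate import DepthProfile, targeted_positions


@dataclass(frozen=True)
class CoverageDistribution:
    """Histogram of per-site depth over targeted bases.

    ``p[d]`` for d = 0..d_cap, ``overflow`` the mass above d_cap,
    ``mean`` the mean on-target depth computed before capping, and
    ``n_bases`` the number of targeted bases.
    """

    p: np.ndarray
    overflow: float
    mean: float
    n_bases: int

    def __post_init__(self):
        total = float(self.p.sum() + self.overflow)
        if self.n_bases > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError(f"histogram mass {total} != 1")

    @property
    def d_cap(self) -> int:
        return len(self.p) - 1


def coverage_distribution(profile: DepthProfile, regions: pd.DataFrame,
                          d_cap: int = 50) -> CoverageDistribution:
    """Depth histogram over the targeted bases of ``regions``."""
    if len(regions) == 0:
        raise ValueError("empty region set")
    sites = targeted_positions(regions)
    depth = profile.depth_at(sites["chrom"], sites["pos"])
    return distribution_from_depths(depth, d_cap)


def distribution_from_depths(depth: np.ndarray, d_cap: int = 50) -> CoverageDistribution:
    depth = np.asarray(depth)
    if len(depth) == 0:
        raise ValueError("no targeted bases")
    counts = np.bincount(np.minimum(depth, d_cap + 1), minlength=d_cap + 2)
    p = counts / len(depth)
    return CoverageDistribution(p=p[: d_cap + 1], overflow=float(p[d_cap + 1]),
                                mean=float(depth.mean()), n_bases=len(depth))


def _imputed_sensitivity(curve: pd.DataFrame, d_cap: int) -> np.ndarray:
    """s(d) for d = 0..d_cap: raw where defined, isotonic interpolation at
    undefined interior bins, s(0) forced to 0."""
    body = curve[~curve["overflow"]]
    if body["depth"].max() < d_cap:
        raise ValueError(f"curve capped at {body['depth'].max()}, need d_cap={d_cap}")
    s = np.full(d_cap + 1, np.nan)
    s[body["depth"].to_numpy()[: d_cap + 1]] = body["sensitivity"].to_numpy()[: d_cap + 1]
    defined = np.flatnonzero(np.isfinite(s) & (np.arange(d_cap + 1) > 0))
    if len(defined) == 0:
        raise ValueError("sensitivity curve entirely undefined")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(defined.astype(float), s[defined],
            sample_weight=curve["n_sites"].to_numpy()[defined])
    missing = np.flatnonzero(~np.isfinite(s))
    if len(missing):
        s[missing] = iso.predict(missing.astype(float))
    s[0] = 0.0  # an uncovered site can never be called
    return s


def overall_sensitivity(curve: pd.DataFrame, dist: CoverageDistribution) -> float:
    """S = sum_d P(d) s(d); overflow depth mass uses s(d_cap)."""
    s = _imputed_sensitivity(curve, dist.d_cap)
    return float(np.dot(dist.p, s) + dist.overflow * s[dist.d_cap])


def depth_requirement(points, threshold: float) -> float | None:
    """Mean on-target depth at which overall sensitivity reaches threshold.

    ``points`` is a ladder of (mean_depth, S) pairs. S is made monotone
    non-decreasing in mean depth by isotonic adjustment, then the
    crossing is linearly interpolated between bracketing points.
    Upward extrapolation is refused: returns None when the threshold
    exceeds the adjusted maximum. A threshold already met at the
    smallest ladder point returns that point's mean depth (the true
    requirement may be lower; the ladder cannot resolve it).
    """
    pts = sorted((float(d), float(s)) for d, s in points)
    if len(pts) < 2:
        raise ValueError("need at least two ladder points")
    d = np.array([p[0] for p in pts])
    s = np.array([p[1] for p in pts])
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    s = iso.fit_transform(d, s)
    if threshold > s[-1] + 1e-12:
        return None
    idx = int(np.searchsorted(s, threshold))
    if idx == 0:
        return float(d[0])
    d0, d1, s0, s1 = d[idx - 1], d[idx], s[idx - 1], s[idx]
    if s1 == s0:
        return float(d0)
    if s0 == 0.0:
        # a zero lower bracket carries no crossing information (step-like
        # ladder); report the first point that actually meets the threshold
        return float(d1)
    return float(d0 + (threshold - s0) * (d1 - d0) / (s1 - s0))


def breadth_requirement(profiles, per_base_min: int = 10,
                        fraction_min: float = 0.9) -> float | None:
    """Mean on-target depth at which >= ``fraction_min`` of targeted bases
    reach ``per_base_min`` reads (breadth-of-coverage requirement).

    ``profiles`` is a ladder of DepthProfiles over the same targets.
    The (mean depth, covered fraction) points are interpolated the same
    way as :func:`depth_requirement`.
    """
    pts = []
    for prof in profiles:
        depth = prof.df["depth"].to_numpy()
        pts.append((prof.mean_depth(), float((depth >= per_base_min).mean())))
    return depth_requirement(pts, fraction_min)


def subset_sensitivity(subset_sites: pd.DataFrame, profile: DepthProfile,
                       curve: pd.DataFrame, d_cap: int = 50) -> float:
    """Overall sensitivity restricted to a site subset (e.g. disease loci).

    The coverage distribution is taken over the subset positions only
    (single-base targets); the per-site curve is shared.
    """
    if len(subset_sites) == 0:
        raise ValueError("empty site subset")
    depth = profile.depth_at(subset_sites["chrom"], subset_sites["pos"])
    return overall_sensitivity(curve, distribution_from_depths(depth, d_cap))
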