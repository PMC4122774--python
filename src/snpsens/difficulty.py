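"""Difficult/easy target-tile classification and its sequence correlates.

A tile (<= 100 bp target fragment) is *difficult* for a data set when,
in at least half of the samples' full alignments, fewer than 50% of its
bases reach 15X; it is *easy* when every base reaches 15X in every
sample. The number of samples in which a tile fails the coverage
criterion is then regressed (OLS, no interactions) on GC content,
repeat presence and alignability to ask how much of the difficulty is
explained by sequence composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simulate import DepthProfile


@dataclass(frozen=True)
class DifficultyRules:
    """Coverage thresholds defining difficult and easy tiles.

    A sample "fails" a tile when the fraction of tile bases at
    >= per_base_min reads is below frac_bases. Difficult: failed in at
    least min_sample_frac_difficult of samples (ceiling for odd n).
    Easy: every base >= per_base_min in every sample.
    """

    per_base_min: int = 15
    frac_bases: float = 0.5
    min_sample_frac_difficult: float = 0.5

    def __post_init__(self):
        for name in ("frac_bases", "min_sample_frac_difficult"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.per_base_min < 1:
            raise ValueError("per_base_min must be >= 1")


def classify_tiles(tiles: pd.DataFrame, profiles: dict[str, DepthProfile],
                   rules: DifficultyRules = DifficultyRules()) -> pd.DataFrame:
    """Classify each tile as difficult / easy / neither from full-depth profiles.

    Returns the tile table with ``n_samples_failing`` (samples in which
    the tile fails the coverage criterion) and ``difficulty`` columns.
    """
    if not profiles:
        raise ValueError("zero samples")
    n_samples = len(profiles)
    n_tiles = len(tiles)
    lengths = (tiles["end"] - tiles["start"]).to_numpy()
    tile_of_base = np.repeat(np.arange(n_tiles), lengths)

    chroms = np.repeat(tiles["chrom"].to_numpy(), lengths)
    pos = np.concatenate([np.arange(s + 1, e + 1)
                          for s, e in zip(tiles["start"], tiles["end"])]) if n_tiles else np.array([], dtype=np.int64)

    n_failing = np.zeros(n_tiles, dtype=np.int64)
    all_covered = np.ones(n_tiles, dtype=bool)
    for prof in profiles.values():
        depth = prof.depth_at(chroms, pos)
        covered = (depth >= rules.per_base_min).astype(np.int64)
        frac_cov = np.bincount(tile_of_base, weights=covered, minlength=n_tiles) / lengths
        n_failing += frac_cov < rules.frac_bases
        min_cov = np.ones(n_tiles)
        np.minimum.at(min_cov, tile_of_base, covered)
        all_covered &= min_cov >= 1

    need = math.ceil(rules.min_sample_frac_difficult * n_samples)
    difficult = n_failing >= need
    out = tiles.copy()
    out["n_samples_failing"] = n_failing
    out["difficulty"] = np.select([difficult, all_covered], ["difficult", "easy"], "neither")
    return out


def difficulty_regression(classified: pd.DataFrame) -> dict:
    """OLS of the per-tile failing-sample count on gc, repeat, alignability.

    Restricted to tiles failing in at least one sample. No interactions;
    intercept included. Returns coefficient estimates, two-sided
    p-values, adjusted R-squared and n.
    """
    df = classified[classified["n_samples_failing"] >= 1]
    predictors = ["gc", "repeat", "alignability"]
    missing = [c for c in predictors if c not in df.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    if len(df) < len(predictors) + 1 + 4:
        raise ValueError(f"only {len(df)} tiles fail in >= 1 sample; too few for regression")
    X = df[predictors].astype(float)
    _check_collinearity(X)
    y = df["n_samples_failing"].astype(float)
    if y.nunique() == 1:
        # degenerate response: zero slopes, nothing explained
        return {"coefficients": {"const": float(y.iloc[0]), "gc": 0.0,
                                 "repeat": 0.0, "alignability": 0.0},
                "p_values": {"const": 0.0, "gc": 1.0, "repeat": 1.0,
                             "alignability": 1.0},
                "adjusted_r_squared": 0.0,
                "n": int(len(y))}
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return {"coefficients": model.params.to_dict(),
            "p_values": model.pvalues.to_dict(),
            "adjusted_r_squared": float(model.rsquared_adj),
            "n": int(model.nobs)}


def _check_collinearity(X: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(X)), X.to_numpy()])
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        # name the offending pair(s) to make the error actionable
        corr = X.corr().abs()
        pairs = [(a, b) for i, a in enumerate(X.columns) for b in X.columns[i + 1:]
                 if corr.loc[a, b] > 1 - 1e-10]
        degenerate = [c for c in X.columns if X[c].nunique() <= 1]
        raise ValueError(f"perfectly collinear predictors: pairs={pairs}, constant={degenerate}")
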