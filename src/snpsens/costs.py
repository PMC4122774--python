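"""Lane-allocation depth model and cost-to-sensitivity economics.

Sequencing on a lane-based instrument (Illumina HiSeq-class) allocates
either whole lanes per sample (WGS) or multiplexes several samples per
lane (exome capture). Mean on-target depth is linear in lane share:

    WGS:    d_bar = Y * lanes_per_sample / G
    exome:  d_bar = (Y / samples_per_lane) * f_ot / T

with lane yield Y (mapped bases), genome size G, capture target size T
(default 65 Mbp, a SeqCap EZ v3-class kit) and on-target fraction f_ot
(default 0.60). Per-sample cost decomposes into library prep + capture
(exome only) + lane cost x lane share, and tables are normalised
against the cheapest exome configuration.

A published benchmark table of normalised costs and depths for seven
configurations ships as :func:`reference_cost_table`; printed totals do
not fit a single linear component model exactly (the underlying costing
inputs are unpublished), so ratio computations use the printed totals
and the least-squares component fit is reserved for the lane-cost
parity scan, with residuals reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import check_fraction, check_positive

GENOME_SIZE = 3.1e9
TARGET_SIZE = 65e6
ON_TARGET_FRACTION = 0.60


@dataclass(frozen=True)
class CostScenario:
    """One sequencing strategy: lane allocation plus cost components.

    Exactly one of lanes_per_sample (WGS) / samples_per_lane (exome)
    applies; ``lane_share`` is lanes consumed per sample either way.
    Monetary fields are in arbitrary consistent units.
    """

    method: str  # "wgs" | "exome"
    lane_yield: float  # mapped bases per lane
    lanes_per_sample: float | None = None
    samples_per_lane: float | None = None
    lane_cost: float = 1.0
    library_prep_cost: float = 0.0
    capture_cost: float = 0.0
    genome_size: float = GENOME_SIZE
    target_size: float = TARGET_SIZE
    on_target_fraction: float = ON_TARGET_FRACTION

    def __post_init__(self):
        if self.method not in ("wgs", "exome"):
            raise ValueError(f"method must be 'wgs' or 'exome', got {self.method!r}")
        check_positive("lane_yield", self.lane_yield)
        check_positive("genome_size", self.genome_size)
        check_positive("target_size", self.target_size)
        check_fraction("on_target_fraction", self.on_target_fraction, 0.0, 1.0, lo_open=True)
        if self.method == "wgs":
            if self.lanes_per_sample is None or self.lanes_per_sample <= 0:
                raise ValueError("wgs scenario needs lanes_per_sample > 0")
        else:
            if self.samples_per_lane is None or self.samples_per_lane <= 0:
                raise ValueError("exome scenario needs samples_per_lane > 0")
        if self.lane_cost < 0 or self.library_prep_cost < 0 or self.capture_cost < 0:
            raise ValueError("negative cost component")

    @property
    def lane_share(self) -> float:
        return self.lanes_per_sample if self.method == "wgs" else 1.0 / self.samples_per_lane


def depth_from_allocation(scenario: CostScenario) -> float:
    """Mean on-target depth implied by the lane allocation (linear model)."""
    if scenario.method == "wgs":
        return scenario.lane_yield * scenario.lanes_per_sample / scenario.genome_size
    per_sample_yield = scenario.lane_yield / scenario.samples_per_lane
    return per_sample_yield * scenario.on_target_fraction / scenario.target_size


def exome_lane_yield(anchor_depth: float = 22.0, anchor_samples_per_lane: float = 16.0,
                     target_size: float = TARGET_SIZE,
                     on_target_fraction: float = ON_TARGET_FRACTION) -> float:
    """Lane yield calibrated so the anchor exome configuration hits anchor_depth."""
    return anchor_depth * target_size * anchor_samples_per_lane / on_target_fraction


def wgs_lane_yield(anchor_depth: float = 11.0, anchor_lanes: float = 1.0,
                   genome_size: float = GENOME_SIZE) -> float:
    """Lane yield calibrated so the anchor WGS configuration hits anchor_depth."""
    return anchor_depth * genome_size / anchor_lanes


def cost_per_sample(scenario: CostScenario) -> float:
    """library prep + capture (exome only) + lane cost x lane share."""
    capture = scenario.capture_cost if scenario.method == "exome" else 0.0
    return scenario.library_prep_cost + capture + scenario.lane_cost * scenario.lane_share


def normalize_costs(rows: pd.DataFrame, base_method: str = "exome",
                    base_samples_per_lane: float = 16.0) -> pd.DataFrame:
    """Add a ``normalized_cost`` column scaled so the base row is 1.00."""
    is_base = (rows["method"] == base_method)
    if base_method == "exome":
        is_base &= rows["samples_per_lane"] == base_samples_per_lane
    if not is_base.any():
        raise ValueError("designated base scenario absent from table")
    base_cost = float(rows.loc[is_base, "cost"].iloc[0])
    out = rows.copy()
    out["normalized_cost"] = out["cost"] / base_cost
    return out


def reference_cost_table() -> pd.DataFrame:
    """Published benchmark: normalised cost and mean on-target depth for
    seven HiSeq-class configurations (costs normalised to exome at 16
    samples/lane; sensitivity is overall estimated heterozygous
    sensitivity in coding regions)."""
    rows = [
        ("wgs", 1.0, np.nan, 11, 94.0, 4.60),
        ("wgs", 2.0, np.nan, 22, 98.5, 8.79),
        ("exome", np.nan, 16.0, 22, 91.1, 1.00),
        ("exome", np.nan, 12.0, 29, 93.4, 1.09),
        ("exome", np.nan, 8.0, 44, 95.9, 1.28),
        ("exome", np.nan, 6.0, 58, 96.9, 1.46),
        ("exome", np.nan, 4.0, 88, 98.1, 1.63),
    ]
    return pd.DataFrame(rows, columns=["method", "lanes_per_sample", "samples_per_lane",
                                       "mean_on_target_depth", "sensitivity_pct",
                                       "normalized_cost"])


def _find_row(table: pd.DataFrame, method: str, lanes_per_sample=None,
              samples_per_lane=None) -> pd.Series:
    sel = table["method"] == method
    if lanes_per_sample is not None:
        sel &= table["lanes_per_sample"] == lanes_per_sample
    if samples_per_lane is not None:
        sel &= table["samples_per_lane"] == samples_per_lane
    if not sel.any():
        raise ValueError(f"no row for method={method}, lanes={lanes_per_sample}, "
                         f"samples/lane={samples_per_lane}")
    return table[sel].iloc[0]


def cost_ratio_at_sensitivity(table: pd.DataFrame, wgs_lanes_per_sample: float,
                              exome_samples_per_lane: float) -> float:
    """WGS cost over exome cost at a matched sensitivity tier, to one decimal."""
    wgs = _find_row(table, "wgs", lanes_per_sample=wgs_lanes_per_sample)
    exo = _find_row(table, "exome", samples_per_lane=exome_samples_per_lane)
    return round(float(wgs["normalized_cost"]) / float(exo["normalized_cost"]), 1)


def fit_cost_components(table: pd.DataFrame | None = None) -> dict:
    """Least-squares (fixed_exome, fixed_wgs, lane_cost) fit to a cost table.

    Model: cost = fixed(method) + lane_cost * lane_share, in normalised
    units. Residuals are returned per row; they are not negligible for
    the reference table (its underlying costing is not exactly linear).
    """
    if table is None:
        table = reference_cost_table()
    share = np.where(table["method"] == "wgs", table["lanes_per_sample"],
                     1.0 / table["samples_per_lane"])
    X = np.column_stack([(table["method"] == "exome").astype(float),
                         (table["method"] == "wgs").astype(float),
                         share])
    y = table["normalized_cost"].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return {"fixed_exome": float(beta[0]), "fixed_wgs": float(beta[1]),
            "lane_cost": float(beta[2]),
            "residuals": (y - X @ beta).tolist()}


def parity_scan(components: dict, tiers: list[tuple[float, float]],
                grid_step: float = 0.01) -> list[float | None]:
    """Break-even lane-cost multiplier per sensitivity tier.

    For each tier (wgs lanes/sample, exome samples/lane), scale the lane
    cost by m for both methods while holding fixed costs (library prep
    and exome capture) constant, and report the largest multiplier m on
    the grid (grid_step .. 1.0) at which WGS cost <= exome cost — the
    point below which whole-genome sequencing reaches cost parity. None
    when parity is not reached anywhere on the grid.
    """
    if not 0.0 < grid_step <= 1.0:
        raise ValueError("grid_step outside (0, 1]")
    grid = np.round(np.arange(grid_step, 1.0 + grid_step / 2, grid_step), 10)
    out = []
    for wgs_lanes, exome_spl in tiers:
        wgs_cost = components["fixed_wgs"] + grid * components["lane_cost"] * wgs_lanes
        exo_cost = components["fixed_exome"] + grid * components["lane_cost"] / exome_spl
        ok = wgs_cost <= exo_cost
        out.append(float(grid[ok][-1]) if ok.any() else None)
    return out
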