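"""Target regions, tiles, site panels, and the standard file formats.

Coordinate conventions
----------------------
Regions and tiles are 0-based half-open internally (BED convention).
Site positions in panels, depth tables and VCF are 1-based. Conversion
happens only inside the readers and writers in this module; no other
module converts coordinates.

Chromosome names are compared by exact string match: no ``chr`` prefix
normalisation. Functions that join two inputs on chromosome raise a
:class:`ChromosomeMismatchError` listing the offending names when the
two sets are disjoint.

Containers are plain :class:`pandas.DataFrame` objects with fixed
column sets (see ``REGION_COLS``, ``TILE_COLS``, ``PANEL_COLS``,
``CALL_COLS``), validated by the constructors here.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

#: Required region columns; gc / repeat / alignability are optional extras.
REGION_COLS = ["chrom", "start", "end"]
REGION_FEATURE_COLS = ["gc", "repeat", "alignability"]
TILE_COLS = ["region_id", "chrom", "start", "end"]
PANEL_COLS = ["chrom", "pos", "ref", "alt"]
CALL_COLS = ["chrom", "pos", "ref", "alt", "genotype", "gq", "depth",
             "ref_count", "alt_count"]

GENOTYPES = ("RR", "RA", "AA", "missing")
_NUCS = frozenset("ACGT")


class BedParseError(ValueError):
    pass


class ChromosomeMismatchError(ValueError):
    pass


def _chrom_sort_key(chroms: pd.Series) -> pd.Series:
    return chroms.astype(str)


def make_regions(chrom, start, end, gc=None, repeat=None, alignability=None) -> pd.DataFrame:
    """Build and validate a region table (sorted, non-overlapping not enforced)."""
    df = pd.DataFrame({"chrom": pd.Series(chrom, dtype=str),
                       "start": pd.Series(start, dtype=np.int64),
                       "end": pd.Series(end, dtype=np.int64)})
    if gc is not None:
        df["gc"] = np.asarray(gc, dtype=float)
    if repeat is not None:
        df["repeat"] = np.asarray(repeat, dtype=bool)
    if alignability is not None:
        df["alignability"] = np.asarray(alignability, dtype=float)
    validate_regions(df)
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def validate_regions(regions: pd.DataFrame) -> None:
    if (regions["start"] >= regions["end"]).any():
        bad = regions[regions["start"] >= regions["end"]].iloc[0]
        raise ValueError(f"inverted or empty interval {bad['chrom']}:{bad['start']}-{bad['end']}")
    if (regions["start"] < 0).any():
        raise ValueError("negative start coordinate")
    for col, lo, hi in [("gc", 0.0, 1.0), ("alignability", 0.0, 1.0)]:
        if col in regions.columns:
            v = regions[col].to_numpy(dtype=float)
            if np.any((v < lo) | (v > hi)):
                raise ValueError(f"{col} outside [{lo}, {hi}]")


def regions_overlap(regions: pd.DataFrame) -> bool:
    """True if any two regions on the same chromosome overlap."""
    df = regions.sort_values(["chrom", "start"])
    same = df["chrom"].to_numpy()[1:] == df["chrom"].to_numpy()[:-1]
    return bool(np.any(same & (df["start"].to_numpy()[1:] < df["end"].to_numpy()[:-1])))


def region_length(regions: pd.DataFrame) -> int:
    return int((regions["end"] - regions["start"]).sum())


def read_bed(path) -> pd.DataFrame:
    """Read a 3+ column BED file into a region table.

    Columns 4-6, when present and numeric/flag-like, are mapped to
    gc (col 4), repeat (col 5, 0/1) and alignability (col 6).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}: line {lineno}: expected >= 3 columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end ({start} >= {end})")
            row = {"chrom": parts[0], "start": start, "end": end}
            if len(parts) >= 4 and parts[3] != ".":
                row["gc"] = float(parts[3])
            if len(parts) >= 5 and parts[4] != ".":
                row["repeat"] = bool(int(parts[4]))
            if len(parts) >= 6 and parts[5] != ".":
                row["alignability"] = float(parts[5])
            rows.append(row)
    if not rows:
        return pd.DataFrame(columns=REGION_COLS)
    df = pd.DataFrame(rows)
    validate_regions(df)
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_bed(regions: pd.DataFrame, path, extra_cols=None) -> None:
    """Write regions as BED; optional feature columns appended in order."""
    cols = list(REGION_COLS)
    for col in (extra_cols if extra_cols is not None else REGION_FEATURE_COLS):
        if col in regions.columns:
            cols.append(col)
    out = regions[cols].copy()
    if "repeat" in out.columns:
        out["repeat"] = out["repeat"].astype(int)
    out.to_csv(path, sep="\t", header=False, index=False)


def merge_regions(regions: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or abutting intervals per chromosome."""
    if len(regions) == 0:
        return pd.DataFrame(columns=REGION_COLS)
    df = regions.sort_values(["chrom", "start"], kind="stable")
    out = []
    for chrom, grp in df.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=REGION_COLS).astype(
        {"start": np.int64, "end": np.int64})


def build_target_set(coding_regions: pd.DataFrame, flank: int = 50) -> pd.DataFrame:
    """Construct the analysis target set from raw coding intervals.

    Merge so every position appears once, extend each merged interval by
    ``flank`` bases on both sides (clipped at 0), and merge again.
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    if len(coding_regions) == 0:
        return pd.DataFrame(columns=REGION_COLS)
    merged = merge_regions(coding_regions)
    merged["start"] = np.maximum(merged["start"] - flank, 0)
    merged["end"] = merged["end"] + flank
    return merge_regions(merged)


def tile_targets(regions: pd.DataFrame, tile_size: int = 100) -> pd.DataFrame:
    """Partition each region left-to-right into tiles of at most ``tile_size`` bases.

    Full tiles first, then one remainder tile at the right edge if the
    region length is not a multiple of ``tile_size``. Feature columns
    (gc, repeat, alignability) are inherited from the parent region.
    """
    if tile_size < 1:
        raise ValueError(f"tile_size must be >= 1, got {tile_size}")
    feature_cols = [c for c in REGION_FEATURE_COLS if c in regions.columns]
    rows = []
    for region_id, row in regions.reset_index(drop=True).iterrows():
        edges = list(range(row["start"], row["end"], tile_size)) + [row["end"]]
        for s, e in zip(edges[:-1], edges[1:]):
            rec = {"region_id": region_id, "chrom": row["chrom"], "start": s, "end": e}
            for c in feature_cols:
                rec[c] = row[c]
            rows.append(rec)
    if not rows:
        return pd.DataFrame(columns=TILE_COLS + feature_cols)
    return pd.DataFrame(rows).astype({"start": np.int64, "end": np.int64})


def make_panel(chrom, pos, ref, alt, maf=None) -> pd.DataFrame:
    """Build and validate a known-sites panel (1-based positions, SNVs only)."""
    df = pd.DataFrame({"chrom": pd.Series(chrom, dtype=str),
                       "pos": pd.Series(pos, dtype=np.int64),
                       "ref": pd.Series(ref, dtype=str),
                       "alt": pd.Series(alt, dtype=str)})
    if maf is not None:
        df["maf"] = np.asarray(maf, dtype=float)
        if np.any((df["maf"] < 0) | (df["maf"] > 0.5)):
            raise ValueError("minor allele frequency outside [0, 0.5]")
    for col in ("ref", "alt"):
        bad = ~df[col].isin(list(_NUCS))
        if bad.any():
            raise ValueError(f"non-SNV {col} allele: {df.loc[bad, col].iloc[0]!r}")
    if (df["ref"] == df["alt"]).any():
        raise ValueError("ref == alt at some site")
    if df.duplicated(["chrom", "pos"]).any():
        dup = df[df.duplicated(["chrom", "pos"])].iloc[0]
        raise ValueError(f"duplicate panel position {dup['chrom']}:{dup['pos']}")
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def check_shared_chromosomes(a, b, what: str = "inputs") -> None:
    ca, cb = set(map(str, a)), set(map(str, b))
    if ca and cb and not (ca & cb):
        raise ChromosomeMismatchError(
            f"no shared chromosome names between {what}: "
            f"{sorted(ca)} vs {sorted(cb)}")


# ---------------------------------------------------------------------------
# VCF I/O (pysam)

_GT_TO_CODE = {(0, 0): "RR", (0, 1): "RA", (1, 0): "RA", (1, 1): "AA",
               (None, None): "missing", (None,): "missing"}
_CODE_TO_GT = {"RR": (0, 0), "RA": (0, 1), "AA": (1, 1), "missing": (None, None)}


def read_vcf_calls(path, sample: str | None = None) -> pd.DataFrame:
    """Read biallelic SNV genotype calls from a VCF into a call table.

    Multi-allelic and indel records are skipped; the count of skipped
    records is logged. GT ./. is retained as genotype "missing".
    """
    vcf = pysam.VariantFile(str(path))
    if sample is None:
        sample = list(vcf.header.samples)[0]
    rows = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.alts or ()) != 1 or len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            n_skipped += 1
            continue
        call = rec.samples[sample]
        gt = tuple(call.get("GT") or (None, None))
        geno = _GT_TO_CODE.get(gt)
        if geno is None:  # half-calls etc. treated as missing
            geno = "missing"
        ad = call.get("AD")
        ref_count, alt_count = (int(ad[0]), int(ad[1])) if ad is not None and ad[0] is not None else (0, 0)
        rows.append({"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": rec.alts[0],
                     "genotype": geno,
                     "gq": int(call.get("GQ") or 0),
                     "depth": int(call.get("DP") or 0),
                     "ref_count": ref_count, "alt_count": alt_count})
    vcf.close()
    if n_skipped:
        log.info("read_vcf_calls(%s): skipped %d multi-allelic/indel records", path, n_skipped)
    if not rows:
        return pd.DataFrame(columns=CALL_COLS)
    return pd.DataFrame(rows).astype({"pos": np.int64, "gq": np.int64, "depth": np.int64,
                                      "ref_count": np.int64, "alt_count": np.int64})


def write_vcf_calls(calls: pd.DataFrame, path, sample: str = "SAMPLE") -> None:
    """Write a call table as a single-sample VCF 4.2 with GT/GQ/DP/AD."""
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                                     ("Description", "Genotype")])
    header.add_meta("FORMAT", items=[("ID", "GQ"), ("Number", "1"), ("Type", "Integer"),
                                     ("Description", "Genotype quality")])
    header.add_meta("FORMAT", items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
                                     ("Description", "Read depth")])
    header.add_meta("FORMAT", items=[("ID", "AD"), ("Number", "R"), ("Type", "Integer"),
                                     ("Description", "Allele depths")])
    for chrom in pd.unique(calls["chrom"].astype(str)) if len(calls) else []:
        length = int(calls.loc[calls["chrom"] == chrom, "pos"].max()) + 1000
        header.contigs.add(chrom, length=length)
    header.add_sample(sample)
    out = pysam.VariantFile(str(path), "w", header=header)
    df = calls.sort_values(["chrom", "pos"], kind="stable")
    for row in df.itertuples(index=False):
        rec = out.new_record(contig=str(row.chrom), start=int(row.pos) - 1,
                             alleles=(str(row.ref), str(row.alt)))
        rec.samples[sample]["GT"] = _CODE_TO_GT[row.genotype]
        rec.samples[sample]["GQ"] = int(row.gq)
        rec.samples[sample]["DP"] = int(row.depth)
        rec.samples[sample]["AD"] = (int(row.ref_count), int(row.alt_count))
        out.write(rec)
    out.close()
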