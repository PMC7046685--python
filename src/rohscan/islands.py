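"""ROH islands: consensus regions where many individuals carry a ROH.

The per-SNP *support curve* counts, for each SNP of the map, how many
samples of a group have a ROH spanning it; dividing by the group size gives
the Manhattan-plot frequency track.  Islands are maximal blocks of
consecutive SNPs at or above a frequency threshold (20% in the usual
selection-signature convention), optionally merged across small gaps, and
are ranked by their peak frequency.  Per-breed frequencies at a set of
consensus regions use any-basepair overlap by default ("span" mode demands
that a single ROH cover the whole region).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

ISLAND_COLUMNS = ["chrom", "start_bp", "end_bp", "n_snps",
                  "peak_freq", "mean_freq", "group"]


def support_curve(segments: pd.DataFrame, variants: pd.DataFrame,
                  group_sample_ids) -> pd.DataFrame:
    """Per-SNP carrier counts and frequencies for one group of samples.

    Frequencies divide by the *group size* (all listed samples, carriers or
    not).  Segments of samples outside the group are ignored.
    """
    group_sample_ids = list(group_sample_ids)
    if not group_sample_ids:
        raise ValueError("empty group")
    group_size = len(group_sample_ids)
    pos = variants["pos_bp"].to_numpy(dtype=np.int64)
    chrom = variants["chrom"].to_numpy()
    n_snps = pos.size
    carriers = np.zeros(n_snps, dtype=np.int64)

    segs = segments[segments["sample_id"].isin(group_sample_ids)]
    for sid, sub in segs.groupby("sample_id", sort=False):
        covered = np.zeros(n_snps, dtype=bool)
        for row in sub.itertuples(index=False):
            on_chrom = np.flatnonzero(chrom == row.chrom)
            if on_chrom.size == 0:
                continue
            lo = on_chrom[0] + np.searchsorted(pos[on_chrom], row.start_bp, "left")
            hi = on_chrom[0] + np.searchsorted(pos[on_chrom], row.end_bp, "right")
            covered[lo:hi] = True
        carriers += covered
    return pd.DataFrame({
        "chrom": chrom, "pos_bp": pos,
        "n_carriers": carriers, "freq": carriers / group_size,
    })


def call_islands(curve: pd.DataFrame, min_freq: float = 0.20,
                 merge_gap_bp: int = 0, group: str = "all") -> pd.DataFrame:
    """Maximal runs of consecutive SNPs with frequency >= ``min_freq``.

    Runs on the same chromosome separated by at most ``merge_gap_bp``
    (default 0: no merging) are fused.  Returns one row per island with the
    :data:`ISLAND_COLUMNS` schema; may be empty.
    """
    out = []
    for chrom, sub in curve.groupby("chrom", sort=True):
        sub = sub.sort_values("pos_bp")
        pos = sub["pos_bp"].to_numpy(dtype=np.int64)
        freq = sub["freq"].to_numpy()
        hot = np.flatnonzero(freq >= min_freq)
        if hot.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(hot) > 1) + 1
        runs = [(r[0], r[-1]) for r in np.split(hot, breaks)]
        merged = [runs[0]]
        for s, e in runs[1:]:
            ps, pe = merged[-1]
            if pos[s] - pos[pe] <= merge_gap_bp:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        for s, e in merged:
            block = freq[s:e + 1]
            out.append({
                "chrom": int(chrom), "start_bp": int(pos[s]), "end_bp": int(pos[e]),
                "n_snps": int(e - s + 1), "peak_freq": float(block.max()),
                "mean_freq": float(block.mean()), "group": group,
            })
    return pd.DataFrame(out, columns=ISLAND_COLUMNS)


def top_islands(regions: pd.DataFrame, n: int = 20) -> pd.DataFrame:
    """The ``n`` highest-peak islands; ties break by (chrom, start_bp)."""
    if len(regions) < n:
        warnings.warn(f"only {len(regions)} islands available; returning all")
    ordered = regions.sort_values(
        ["peak_freq", "chrom", "start_bp"],
        ascending=[False, True, True], kind="mergesort",
    )
    return ordered.head(n).reset_index(drop=True)


def row_average(freqs) -> float:
    """Unweighted mean of per-breed frequencies for one consensus region."""
    freqs = np.asarray(list(freqs), dtype=float)
    if freqs.size == 0:
        raise ValueError("no frequencies to average")
    return float(freqs.mean())


def breed_frequencies_at(regions: pd.DataFrame, segments: pd.DataFrame,
                         breed_sizes: dict, mode: str = "any_overlap") -> pd.DataFrame:
    """Percent of each breed's samples with a ROH overlapping each region.

    ``mode="any_overlap"`` counts any shared base pair; ``mode="span"``
    requires one segment to cover the region end to end.  A breed with no
    overlapping carrier scores 0.  The ``average`` column is the unweighted
    mean across breeds.
    """
    if mode not in ("any_overlap", "span"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    breeds = list(breed_sizes)
    rows = []
    for reg in regions.itertuples(index=False):
        row = {"chrom": reg.chrom, "start_bp": reg.start_bp, "end_bp": reg.end_bp}
        for breed in breeds:
            segs = segments[(segments["breed"] == breed)
                            & (segments["chrom"] == reg.chrom)]
            if mode == "any_overlap":
                hit = segs[(segs["start_bp"] <= reg.end_bp)
                           & (segs["end_bp"] >= reg.start_bp)]
            else:
                hit = segs[(segs["start_bp"] <= reg.start_bp)
                           & (segs["end_bp"] >= reg.end_bp)]
            n_carriers = hit["sample_id"].nunique()
            row[breed] = 100.0 * n_carriers / breed_sizes[breed]
        row["average"] = row_average([row[b] for b in breeds])
        rows.append(row)
    return pd.DataFrame(rows)


def flank_region(chrom: int, start_bp: int, end_bp: int,
                 pad_bp: int = 2_000_000) -> tuple[int, int, int]:
    """Pad a region by ``pad_bp`` on both sides, clamping the left edge at 1."""
    return int(chrom), max(1, int(start_bp) - pad_bp), int(end_bp) + pad_bp


def flank_regions(regions: pd.DataFrame, pad_bp: int = 2_000_000) -> pd.DataFrame:
    """Vectorized :func:`flank_region` over an island table."""
    out = regions.copy()
    out["start_bp"] = np.maximum(1, regions["start_bp"].to_numpy() - pad_bp)
    out["end_bp"] = regions["end_bp"].to_numpy() + pad_bp
    return out
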