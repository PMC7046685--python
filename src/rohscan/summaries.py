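"""Descriptive ROH statistics: length classes, breed summaries, chromosome coverage.

ROH are grouped into the five conventional length classes 1-2, 2-4, 4-8,
8-16 and >16 Mb (half-open bins, so a 2.0 Mb run falls in 2-4), plus the
cumulative tiers >1 Mb and >8 Mb.  Breed summaries report the total segment
count (nROH), per-animal count mean +/- SD (MN_ROH), mean genome length and
percentage under ROH (MGL_ROH / MGP_ROH) and mean segment length (AL_ROH).
Chromosome coverage follows the two-step rule: sum ROH length (Mb) on the
chromosome, divide by the number of animals carrying at least one ROH
there, then divide by the chromosome length.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .inbreeding import AutosomeSpan

LENGTH_CLASSES = [("1-2", 1.0, 2.0), ("2-4", 2.0, 4.0), ("4-8", 4.0, 8.0),
                  ("8-16", 8.0, 16.0), (">16", 16.0, np.inf)]
CUMULATIVE_CLASSES = [(">1", 1.0), (">8", 8.0)]


def _class_stats(lengths_mb: np.ndarray, total_n: int, l_auto_mb: float,
                 label: str) -> dict:
    n = lengths_mb.size
    return {
        "length_class": label,
        "n_roh": int(n),
        "percent": 100.0 * n / total_n if total_n else 0.0,
        "mean_mb": float(lengths_mb.mean()) if n else np.nan,
        "sd_mb": float(lengths_mb.std(ddof=1)) if n > 1 else np.nan,
        "coverage_pct": 100.0 * float(lengths_mb.sum()) / l_auto_mb,
    }


def classify_lengths(segments: pd.DataFrame, span: AutosomeSpan,
                     by: str = "breed") -> pd.DataFrame:
    """Length-class table per group (default per breed).

    Rows: the five disjoint classes plus the cumulative >1 and >8 Mb tiers.
    A segment below 1 Mb violates the detector contract and is rejected.
    """
    if segments.empty:
        return pd.DataFrame(columns=[by, "length_class", "n_roh", "percent",
                                     "mean_mb", "sd_mb", "coverage_pct"])
    lengths_mb = segments["length_kb"].to_numpy() / 1000.0
    if (lengths_mb < 1.0).any():
        raise ValueError("segment shorter than 1 Mb present; not a valid detector output")
    l_auto_mb = span.l_auto_kb / 1000.0
    out = []
    for group, sub in segments.groupby(by, sort=True):
        lm = sub["length_kb"].to_numpy() / 1000.0
        total = lm.size
        for label, lo, hi in LENGTH_CLASSES:
            sel = lm[(lm >= lo) & (lm < hi)]
            out.append({by: group, **_class_stats(sel, total, l_auto_mb, label)})
        for label, lo in CUMULATIVE_CLASSES:
            sel = lm[lm >= lo]
            out.append({by: group, **_class_stats(sel, total, l_auto_mb, label)})
    return pd.DataFrame(out)


def breed_summary(segments: pd.DataFrame, samples: pd.DataFrame,
                  span: AutosomeSpan) -> pd.DataFrame:
    """Per-breed descriptive statistics.

    Animals with zero ROH contribute 0 to the per-animal count and length
    means; SD is the sample standard deviation (n-1).  Breeds present in
    ``samples`` but with zero animals are omitted with a warning.
    """
    l_auto_mb = span.l_auto_kb / 1000.0
    out = []
    for breed, sub in samples.groupby("breed", sort=True):
        if sub.empty:  # pragma: no cover - groupby never yields empty groups
            warnings.warn(f"breed {breed} has no samples; omitted")
            continue
        segs = segments[segments["breed"] == breed] if not segments.empty else segments
        counts = pd.Series(0, index=sub["sample_id"], dtype=float)
        lengths = pd.Series(0.0, index=sub["sample_id"])
        if not segs.empty:
            per_animal = segs.groupby("sample_id")["length_kb"].agg(["count", "sum"])
            counts.loc[per_animal.index] = per_animal["count"]
            lengths.loc[per_animal.index] = per_animal["sum"] / 1000.0
        n_roh = int(counts.sum())
        total_mb = float(lengths.sum())
        out.append({
            "breed": breed,
            "n_samples": len(sub),
            "n_roh": n_roh,
            "range_min": int(counts.min()),
            "range_max": int(counts.max()),
            "mn_roh_mean": float(counts.mean()),
            "mn_roh_sd": float(counts.std(ddof=1)) if len(counts) > 1 else np.nan,
            "mgl_roh_mb": float(lengths.mean()),
            "mgp_roh_pct": 100.0 * float(lengths.mean()) / l_auto_mb,
            "al_roh_mb": total_mb / n_roh if n_roh else np.nan,
        })
    return pd.DataFrame(out)


def chromosome_coverage(segments: pd.DataFrame, chrom_lengths_mb: dict,
                        denominator: str = "per_chrom") -> pd.DataFrame:
    """Per-chromosome ROH count, mean length and percent coverage.

    ``mean_roh_length_mb`` sums all ROH (Mb) on the chromosome and divides
    by the number of animals with at least one ROH there
    (``denominator="per_chrom"``, the default) or by the number of animals
    with any ROH genome-wide (``"genome_wide"``, for sensitivity analysis);
    ``percent_of_chrom`` divides that mean by the chromosome length.
    Chromosomes without ROH report zero.
    """
    if denominator not in ("per_chrom", "genome_wide"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    n_animals_total = segments["sample_id"].nunique() if not segments.empty else 0
    out = []
    for chrom, clen_mb in sorted(chrom_lengths_mb.items()):
        sub = segments[segments["chrom"] == chrom] if not segments.empty else segments
        if sub.empty:
            out.append({"chrom": chrom, "n_roh": 0,
                        "mean_roh_length_mb": 0.0, "percent_of_chrom": 0.0})
            continue
        total_mb = sub["length_kb"].sum() / 1000.0
        n_animals = (sub["sample_id"].nunique() if denominator == "per_chrom"
                     else n_animals_total)
        mean_mb = total_mb / n_animals
        out.append({"chrom": chrom, "n_roh": int(len(sub)),
                    "mean_roh_length_mb": float(mean_mb),
                    "percent_of_chrom": 100.0 * float(mean_mb) / clen_mb})
    return pd.DataFrame(out)
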