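"""Proportion tests and annotation-overlap counting for ROH islands.

Supports the comparison of trait-category annotation content (for example
QTL intervals labelled Health, Production, Reproduction, ...) between the
flanked ROH islands of two contrasting groups, via a two-sided pooled
two-proportion z test backed by a seeded Monte-Carlo version, and a
chi-square test of homogeneity of K proportions for per-breed island
frequencies.  Annotation coordinates are 1-based inclusive by default
(``bed_convention=True`` converts 0-based half-open input on load).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import chi2, norm

ANNOTATION_COLUMNS = ["chrom", "start_bp", "end_bp", "name", "category"]


def read_annotation_table(path, bed_convention: bool = False) -> pd.DataFrame:
    """Read a 5-column TSV/BED-like annotation file (chrom start end name category)."""
    df = pd.read_csv(path, sep="\t", header=None, names=ANNOTATION_COLUMNS,
                     comment="#")
    if bed_convention:
        df["start_bp"] = df["start_bp"] + 1  # 0-based half-open -> 1-based inclusive
    return df


def count_category_overlaps(flanked_islands: pd.DataFrame,
                            annotations: pd.DataFrame) -> tuple[dict, int]:
    """Count annotations overlapping >=1 flanked island, per category.

    Coordinates are 1-based inclusive on both sides; abutting intervals
    (annotation end == island start - 1) do not overlap.  An annotation
    overlapping several islands counts once, deduplicated by ``name``.
    Missing/empty categories are tallied under ``"other"`` with a warning.
    Returns (per-category counts, total).
    """
    trees: dict = {}
    for isl in flanked_islands.itertuples(index=False):
        trees.setdefault(isl.chrom, IntervalTree()).addi(
            int(isl.start_bp), int(isl.end_bp) + 1)  # half-open for the tree

    counts: Counter = Counter()
    seen = set()
    for ann in annotations.itertuples(index=False):
        if ann.name in seen:
            continue
        tree = trees.get(ann.chrom)
        if tree is None or not tree.overlap(int(ann.start_bp), int(ann.end_bp) + 1):
            continue
        seen.add(ann.name)
        category = ann.category
        if category is None or (isinstance(category, float) and np.isnan(category)) \
                or str(category).strip() == "":
            warnings.warn(f"annotation {ann.name!r} has no category; counted as 'other'")
            category = "other"
        counts[str(category)] += 1
    return dict(counts), sum(counts.values())


def category_percentages(counts: dict) -> dict:
    """Percent share of each category; requires a positive total."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("zero total count; percentages undefined")
    return {cat: 100.0 * c / total for cat, c in counts.items()}


@dataclass(frozen=True)
class ProportionTestResult:
    x1: int
    n1: int
    x2: int
    n2: int
    p1: float  # percent
    p2: float  # percent
    z: float
    p_continuous: float
    p_mc: float
    mc_reps: int
    seed: int | None


def two_proportion_test(x1: int, n1: int, x2: int, n2: int, *,
                        mc_reps: int = 5000, seed: int | None = None,
                        continuity: bool = False) -> ProportionTestResult:
    """Two-sided test that two binomial proportions are equal.

    ``p_continuous`` is the pooled-variance z test (equivalently the 1-df
    chi-square without continuity correction; ``continuity=True`` applies
    the Yates-style correction to the z statistic).  ``p_mc`` resamples both
    counts binomially under the pooled proportion and reports the add-one
    smoothed fraction of replicates with an absolute proportion difference
    at least as large as observed.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 <= x <= n:
            raise ValueError("counts must satisfy 0 <= x <= n")
    f1, f2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    diff = abs(f1 - f2)
    if se == 0:
        z = 0.0
    else:
        num = diff
        if continuity:
            num = max(0.0, diff - 0.5 * (1 / n1 + 1 / n2))
        z = num / se
    p_cont = float(min(1.0, 2 * norm.sf(abs(z))))

    rng = np.random.default_rng(seed)
    r1 = rng.binomial(n1, pooled, size=mc_reps) / n1
    r2 = rng.binomial(n2, pooled, size=mc_reps) / n2
    hits = int((np.abs(r1 - r2) >= diff - 1e-12).sum())
    p_mc = (1 + hits) / (1 + mc_reps)

    return ProportionTestResult(x1=x1, n1=n1, x2=x2, n2=n2,
                                p1=100.0 * f1, p2=100.0 * f2,
                                z=float(z if f1 >= f2 else -z),
                                p_continuous=p_cont, p_mc=float(p_mc),
                                mc_reps=mc_reps, seed=seed)


@dataclass(frozen=True)
class KProportionResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray


def k_proportion_test(xs, ns) -> KProportionResult:
    """Chi-square test of homogeneity of K proportions (K-1 df).

    The 2 x K table of successes/failures is tested against the pooled
    expectation; a warning is issued when any expected cell is below 5.
    For K = 2 the p-value equals the continuous two-proportion test's.
    """
    xs = np.asarray(xs, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if xs.shape != ns.shape or xs.ndim != 1 or xs.size < 2:
        raise ValueError("xs and ns must be equal-length vectors with K >= 2")
    if (ns <= 0).any():
        raise ValueError("all group sizes must be positive")
    if ((xs < 0) | (xs > ns)).any():
        raise ValueError("counts must satisfy 0 <= x <= n")
    observed = np.vstack([xs, ns - xs])
    pooled = xs.sum() / ns.sum()
    expected = np.vstack([ns * pooled, ns * (1 - pooled)])
    if (expected < 5).any():
        warnings.warn("expected cell count below 5; chi-square approximation is weak")
    k = xs.size
    if pooled in (0.0, 1.0):
        return KProportionResult(0.0, k - 1, 1.0, expected)
    stat = float(((observed - expected) ** 2 / expected).sum())
    return KProportionResult(stat, k - 1, float(chi2.sf(stat, k - 1)), expected)
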