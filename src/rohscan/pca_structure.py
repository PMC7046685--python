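"""Population structure from ROH incidence: PCA with Kaiser retention.

Each sample is coded 0/1 at a set of consensus ROH regions (carrier or not),
the region set being the most frequent regions above a carrier-frequency
floor (the study convention is the top 170 regions at >= 12.5%).  PCA of the
centered incidence matrix — equivalently an eigen-analysis of the samples'
cross-product relationship matrix, with which it shares its eigenstructure —
yields scores, loadings and per-region contributions; the Kaiser rule keeps
components whose eigenvalue exceeds the mean eigenvalue (the familiar
"> 1" rule when columns are standardized).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PCAResult:
    eigenvalues: np.ndarray          # descending, >= 0
    explained_pct: np.ndarray        # percent of total variance per component
    scores: pd.DataFrame             # samples x components
    loadings: pd.DataFrame           # regions x components
    contributions: pd.DataFrame      # percent, regions x components (cols sum to 100)
    k_retained: int


def build_incidence(segments: pd.DataFrame, regions: pd.DataFrame,
                    sample_ids, *, min_freq: float = 0.125,
                    top_n: int = 170) -> pd.DataFrame:
    """Binary sample x region carrier matrix over the selected regions.

    A cell is 1 when the sample has a ROH overlapping the region by at least
    one base pair.  Regions are filtered to carrier frequency >= ``min_freq``
    (computed over ``sample_ids``), ranked by frequency descending with a
    (chrom, start_bp) tie-break, and capped at ``top_n``.
    """
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise ValueError("no samples")
    segs = segments[segments["sample_id"].isin(sample_ids)]
    cells = np.zeros((len(sample_ids), len(regions)), dtype=np.int8)
    row_of = {sid: i for i, sid in enumerate(sample_ids)}
    labels = [f"chr{r.chrom}:{r.start_bp}-{r.end_bp}" for r in regions.itertuples(index=False)]
    for j, reg in enumerate(regions.itertuples(index=False)):
        hit = segs[(segs["chrom"] == reg.chrom)
                   & (segs["start_bp"] <= reg.end_bp)
                   & (segs["end_bp"] >= reg.start_bp)]
        for sid in hit["sample_id"].unique():
            cells[row_of[sid], j] = 1

    freq = cells.mean(axis=0)
    order = sorted(range(len(regions)),
                   key=lambda j: (-freq[j],
                                  regions["chrom"].iat[j], regions["start_bp"].iat[j]))
    keep = [j for j in order if freq[j] >= min_freq]
    if not keep:
        raise ValueError(f"no region reaches carrier frequency {min_freq}")
    if len(keep) < top_n:
        warnings.warn(f"only {len(keep)} regions pass the frequency filter "
                      f"(requested top {top_n}); returning all")
    keep = keep[:top_n]
    return pd.DataFrame(cells[:, keep], index=pd.Index(sample_ids, name="sample_id"),
                        columns=[labels[j] for j in keep])


def run_pca(incidence: pd.DataFrame, scale_mode: str = "center") -> PCAResult:
    """PCA of the incidence matrix via singular value decomposition.

    ``scale_mode`` is ``"center"`` (covariance PCA, the default) or
    ``"correlation"`` (columns standardized to unit variance).  Columns with
    zero variance are dropped with a warning.  Component signs are fixed by
    making each component's largest-magnitude loading positive.
    Contributions are ``100 * loading^2`` per component (the squared-cosine
    share of each region in the component), summing to 100.
    """
    if incidence.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = incidence.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance column(s)")
    if keep.sum() < 2:
        raise ValueError("fewer than 2 informative columns")
    x = x[:, keep]
    cols = incidence.columns[keep]
    xc = x - x.mean(axis=0)
    if scale_mode == "correlation":
        xc = xc / sd[keep]
    elif scale_mode != "center":
        raise ValueError(f"unknown scale_mode {scale_mode!r}")

    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    n = x.shape[0]
    eigenvalues = s ** 2 / (n - 1)
    loadings = vt.T
    scores = u * s

    # reproducible component orientation
    for k in range(loadings.shape[1]):
        imax = np.argmax(np.abs(loadings[:, k]))
        if loadings[imax, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1

    total = eigenvalues.sum()
    explained = 100.0 * eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    contrib = 100.0 * loadings ** 2
    comp_ix = [f"PC{k + 1}" for k in range(len(eigenvalues))]
    return PCAResult(
        eigenvalues=eigenvalues,
        explained_pct=explained,
        scores=pd.DataFrame(scores, index=incidence.index, columns=comp_ix),
        loadings=pd.DataFrame(loadings, index=cols, columns=comp_ix),
        contributions=pd.DataFrame(contrib, index=cols, columns=comp_ix),
        k_retained=kaiser_retain(eigenvalues),
    )


def kaiser_retain(eigenvalues) -> int:
    """Number of eigenvalues strictly above the mean eigenvalue.

    With correlation scaling the mean is 1, recovering the classic "keep
    eigenvalues > 1" rule.  All-equal eigenvalues retain nothing (warned).
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        raise ValueError("no eigenvalues")
    k = int((ev > ev.mean()).sum())
    if k == 0:
        warnings.warn("all eigenvalues equal; Kaiser rule retains no component")
    return k


def top_contributing_loci(pca: PCAResult, m: int) -> pd.DataFrame:
    """Regions ranked by contribution over the retained components.

    The ranking score is the contribution of each region to each retained
    component weighted by that component's explained-variance percentage, so
    a region loading on PC1 outranks an equal loading on a later component.
    Returns the top ``m`` (all, if ``m`` exceeds the region count) with their
    scores.
    """
    k = max(pca.k_retained, 1)
    weights = pca.explained_pct[:k]
    score = (pca.contributions.iloc[:, :k] * weights).sum(axis=1) / weights.sum()
    ranked = score.sort_values(ascending=False, kind="mergesort")
    return ranked.head(min(m, len(ranked))).rename("contribution_score").to_frame()
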