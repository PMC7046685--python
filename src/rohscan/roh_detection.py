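"""Detect runs of homozygosity (ROH) per sample and chromosome.

Two detectors are provided.  :func:`detect_roh_sliding` reproduces the
PLINK-style scan: a window of ``window_snp`` SNPs slides one SNP at a time,
a window is called homozygous when it holds at most ``window_het_max``
heterozygous and ``window_missing_max`` missing calls, and a SNP is
run-eligible when the fraction of windows overlapping it that are homozygous
reaches ``window_hit_threshold`` (the denominator is the number of windows
actually overlapping the SNP, which shrinks near chromosome ends).  Maximal
stretches of run-eligible SNPs, split at inter-SNP gaps above ``max_gap_kb``,
are emitted when they satisfy the SNP-count, length and density thresholds.

:func:`detect_roh_consecutive` is a window-free scan in the style of
detectRUNS' consecutive-runs method: the genome is read SNP by SNP,
accumulating a candidate run while the *run-level* heterozygote and missing
allowances and the gap rule hold; when an allowance would be exceeded the
candidate is closed at the last valid SNP and scanning restarts after the
violating call (at the violating SNP for a pure gap break).  The two
detectors intentionally differ in where the het/missing allowance applies:
per window (sliding) versus per run (consecutive).

Coordinates are 1-based inclusive base pairs of the first/last SNP in the
run; ``length_kb = (end_bp - start_bp + 1) / 1000``.

:func:`brute_force_runs` is a deliberately naive re-implementation of the
sliding definition (literal per-window loops, exhaustive maximality check)
kept as an independent oracle for testing; it refuses large inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, HET, MISSING

ROH_COLUMNS = ["sample_id", "breed", "chrom", "start_bp", "end_bp",
               "n_snps", "length_kb", "detector"]


@dataclass(frozen=True)
class ROHParams:
    """Sliding-window detector thresholds (defaults follow common
    PLINK practice for high-density bovine arrays)."""

    window_snp: int = 50
    window_het_max: int = 1
    window_missing_max: int = 5
    window_hit_threshold: float = 0.05
    min_snp: int = 100
    min_length_kb: float = 1000.0
    max_gap_kb: float = 1000.0
    min_density_kb_per_snp: float = 50.0

    def __post_init__(self):
        if min(self.window_snp, self.window_het_max + 1, self.window_missing_max + 1,
               self.min_snp) <= 0 or min(self.min_length_kb, self.max_gap_kb,
                                         self.min_density_kb_per_snp) <= 0:
            raise ValueError("ROHParams fields must be positive")
        if not 0 < self.window_hit_threshold <= 1:
            raise ValueError("window_hit_threshold must be in (0, 1]")


@dataclass(frozen=True)
class ConsecutiveParams:
    """Window-free (consecutive-runs) detector thresholds."""

    min_snp: int = 100
    min_length_kb: float = 1000.0
    max_gap_kb: float = 1000.0
    max_het_in_run: int = 1
    max_missing_in_run: int = 5

    def __post_init__(self):
        if min(self.min_snp, self.max_het_in_run + 1, self.max_missing_in_run + 1) <= 0 \
                or min(self.min_length_kb, self.max_gap_kb) <= 0:
            raise ValueError("ConsecutiveParams fields must be positive")


def _empty_result() -> pd.DataFrame:
    return pd.DataFrame({
        "sample_id": pd.Series(dtype=object),
        "breed": pd.Series(dtype=object),
        "chrom": pd.Series(dtype=np.int64),
        "start_bp": pd.Series(dtype=np.int64),
        "end_bp": pd.Series(dtype=np.int64),
        "n_snps": pd.Series(dtype=np.int64),
        "length_kb": pd.Series(dtype=float),
        "detector": pd.Series(dtype=object),
    })


def _finalize(rows: list, detector: str) -> pd.DataFrame:
    if not rows:
        return _empty_result()
    df = pd.DataFrame(rows, columns=ROH_COLUMNS[:-1])
    df["detector"] = detector
    df = df.sort_values(["sample_id", "chrom", "start_bp"], kind="mergesort")
    return df.reset_index(drop=True)


def _chrom_blocks(gm: GenotypeMatrix):
    """Yield (chrom, snp index slice) per chromosome, in map order."""
    chrom = gm.variants["chrom"].to_numpy()
    if chrom.size == 0:
        return
    boundaries = np.flatnonzero(np.diff(chrom)) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [chrom.size]))
    for s, e in zip(starts, stops):
        yield int(chrom[s]), slice(s, e)


def _eligible_snps(het: np.ndarray, mis: np.ndarray, params: ROHParams) -> np.ndarray:
    """Vectorized per-SNP run-eligibility, all samples at once.

    ``het``/``mis`` are boolean arrays of shape (samples, snps) for one
    chromosome; returns an equally shaped boolean eligibility matrix.
    """
    ns, n = het.shape
    w = min(params.window_snp, n)
    nw = n - w + 1
    zeros = np.zeros((ns, 1), dtype=np.int32)
    ch = np.concatenate((zeros, het.cumsum(axis=1, dtype=np.int32)), axis=1)
    cm = np.concatenate((zeros, mis.cumsum(axis=1, dtype=np.int32)), axis=1)
    win_het = ch[:, w:] - ch[:, :-w]
    win_mis = cm[:, w:] - cm[:, :-w]
    hom_win = (win_het <= params.window_het_max) & (win_mis <= params.window_missing_max)
    cw = np.concatenate((zeros, hom_win.cumsum(axis=1, dtype=np.int32)), axis=1)

    # SNP j is overlapped by windows lo..hi; away from chromosome ends that
    # is exactly w windows, which a shifted difference of cumsums covers.
    num = np.empty((ns, n), dtype=np.int32)
    den = np.empty(n, dtype=np.int32)
    j = np.arange(n)
    interior = (j >= w - 1) & (j <= nw - 1)
    if interior.any():
        num[:, w - 1:nw] = cw[:, w:nw + 1] - cw[:, :nw - w + 1]
        den[w - 1:nw] = w
    edge = np.flatnonzero(~interior)
    if edge.size:
        lo = np.maximum(0, edge - w + 1)
        hi = np.minimum(edge, nw - 1)
        num[:, edge] = cw[:, hi + 1] - cw[:, lo]
        den[edge] = hi - lo + 1
    return (num / den[None, :]) >= params.window_hit_threshold


def _emit_eligible_runs(eligible, pos, params: ROHParams):
    """Split eligible stretches at large gaps and apply segment filters."""
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return
    gap_bp = params.max_gap_kb * 1000.0
    breaks = np.flatnonzero(
        (np.diff(idx) > 1) | ((pos[idx[1:]] - pos[idx[:-1]]) > gap_bp)
    ) + 1
    for run in np.split(idx, breaks):
        s, e = run[0], run[-1]
        n_snps = int(e - s + 1)
        length_kb = (pos[e] - pos[s] + 1) / 1000.0
        if (n_snps >= params.min_snp
                and length_kb >= params.min_length_kb
                and length_kb / n_snps <= params.min_density_kb_per_snp):
            yield int(s), int(e), n_snps, float(length_kb)


def detect_roh_sliding(gm: GenotypeMatrix, params: ROHParams | None = None) -> pd.DataFrame:
    """PLINK-style sliding-window ROH scan.

    Returns one row per emitted segment with columns
    ``sample_id, breed, chrom, start_bp, end_bp, n_snps, length_kb, detector``,
    sorted by (sample_id, chrom, start_bp).  Deterministic.
    """
    params = params or ROHParams()
    rows = []
    pos_all = gm.variants["pos_bp"].to_numpy(dtype=np.int64)
    sample_ids = gm.samples["sample_id"].to_numpy()
    breeds = gm.samples["breed"].to_numpy()
    for chrom, sl in _chrom_blocks(gm):
        pos = pos_all[sl]
        block = gm.calls[:, sl]
        eligible = _eligible_snps(block == HET, block == MISSING, params)
        for i in range(gm.n_samples):
            for s, e, n_snps, length_kb in _emit_eligible_runs(eligible[i], pos, params):
                rows.append((sample_ids[i], breeds[i], chrom,
                             int(pos[s]), int(pos[e]), n_snps, length_kb))
    return _finalize(rows, "sliding")


def detect_roh_consecutive(gm: GenotypeMatrix,
                           params: ConsecutiveParams | None = None) -> pd.DataFrame:
    """Window-free SNP-by-SNP ROH scan with run-level allowances.

    Restart rule: when a heterozygous (or missing) call would push the run
    over its allowance the candidate closes at the previous SNP and the scan
    restarts just after the violating call; a gap violation closes the
    candidate and restarts at the current SNP (the SNP itself is unobjectionable).
    Runs may begin or end on a tolerated heterozygous/missing call.
    """
    params = params or ConsecutiveParams()
    rows = []
    pos_all = gm.variants["pos_bp"].to_numpy(dtype=np.int64)
    gap_bp = params.max_gap_kb * 1000.0

    def close(i, sid, breed, chrom, pos, s, e):
        if e < s:
            return
        n_snps = e - s + 1
        length_kb = (pos[e] - pos[s] + 1) / 1000.0
        if n_snps >= params.min_snp and length_kb >= params.min_length_kb:
            rows.append((sid, breed, chrom, int(pos[s]), int(pos[e]),
                         int(n_snps), float(length_kb)))

    for chrom, sl in _chrom_blocks(gm):
        pos = pos_all[sl]
        n = pos.size
        for i in range(gm.n_samples):
            calls = gm.calls[i, sl]
            sid = gm.samples["sample_id"].iat[i]
            breed = gm.samples["breed"].iat[i]
            s = 0
            het_c = mis_c = 0
            j = 0
            while j < n:
                if j > s and pos[j] - pos[j - 1] > gap_bp:
                    close(i, sid, breed, chrom, pos, s, j - 1)
                    s, het_c, mis_c = j, 0, 0
                c = calls[j]
                if c == HET and het_c + 1 > params.max_het_in_run:
                    close(i, sid, breed, chrom, pos, s, j - 1)
                    s, het_c, mis_c = j + 1, 0, 0
                elif c == MISSING and mis_c + 1 > params.max_missing_in_run:
                    close(i, sid, breed, chrom, pos, s, j - 1)
                    s, het_c, mis_c = j + 1, 0, 0
                else:
                    het_c += c == HET
                    mis_c += c == MISSING
                j += 1
            if s < n:
                close(i, sid, breed, chrom, pos, s, n - 1)
    return _finalize(rows, "consecutive")


_BRUTE_FORCE_MAX_SNPS = 2000


def brute_force_runs(gm: GenotypeMatrix, params: ROHParams | None = None) -> pd.DataFrame:
    """Naive re-derivation of the sliding-window definition (test oracle).

    Eligibility is computed with literal per-window loops and segments by
    exhaustive candidate enumeration plus a containment-based maximality
    filter.  Quadratic; refuses panels above ~2,000 SNPs.
    """
    params = params or ROHParams()
    if gm.n_variants > _BRUTE_FORCE_MAX_SNPS:
        raise ValueError(
            f"brute_force_runs is a test oracle; refusing {gm.n_variants} SNPs "
            f"(limit {_BRUTE_FORCE_MAX_SNPS})"
        )
    rows = []
    pos_all = gm.variants["pos_bp"].to_numpy(dtype=np.int64)
    gap_bp = params.max_gap_kb * 1000.0
    for chrom, sl in _chrom_blocks(gm):
        pos = pos_all[sl]
        n = pos.size
        w = min(params.window_snp, n)
        n_win = n - w + 1
        for i in range(gm.n_samples):
            calls = gm.calls[i, sl]
            hom_win = []
            for ws in range(n_win):
                window = calls[ws:ws + w]
                n_het = int((window == HET).sum())
                n_mis = int((window == MISSING).sum())
                hom_win.append(n_het <= params.window_het_max
                               and n_mis <= params.window_missing_max)
            eligible = []
            for j in range(n):
                covering = [hom_win[ws] for ws in range(n_win)
                            if ws <= j <= ws + w - 1]
                frac = sum(covering) / len(covering)
                eligible.append(frac >= params.window_hit_threshold)

            # all candidate stretches whose SNPs are eligible with gaps in bound
            candidates = []
            for s in range(n):
                if not eligible[s]:
                    continue
                e = s
                while (e + 1 < n and eligible[e + 1]
                       and pos[e + 1] - pos[e] <= gap_bp):
                    e += 1
                candidates.append((s, e))
            maximal = [
                (s, e) for (s, e) in candidates
                if not any(s2 <= s and e <= e2 and (s2, e2) != (s, e)
                           for (s2, e2) in candidates)
            ]
            for s, e in maximal:
                n_snps = e - s + 1
                length_kb = (pos[e] - pos[s] + 1) / 1000.0
                if (n_snps >= params.min_snp
                        and length_kb >= params.min_length_kb
                        and length_kb / n_snps <= params.min_density_kb_per_snp):
                    rows.append((gm.samples["sample_id"].iat[i],
                                 gm.samples["breed"].iat[i], chrom,
                                 int(pos[s]), int(pos[e]), int(n_snps),
                                 float(length_kb)))
    return _finalize(rows, "sliding")


def validate_segments(segments: pd.DataFrame, params: ROHParams | None = None) -> None:
    """Assert the per-segment invariants; raises ``AssertionError`` on violation."""
    params = params or ROHParams()
    if segments.empty:
        return
    assert (segments["end_bp"] >= segments["start_bp"]).all()
    assert (segments["n_snps"] >= params.min_snp).all()
    assert (segments["length_kb"] >= params.min_length_kb).all()
    assert (segments["length_kb"] / segments["n_snps"]
            <= params.min_density_kb_per_snp).all()
    for (_, _), sub in segments.groupby(["sample_id", "chrom"], sort=False):
        sub = sub.sort_values("start_bp")
        assert (sub["start_bp"].to_numpy()[1:] > sub["end_bp"].to_numpy()[:-1]).all(), \
            "overlapping segments for one sample on one chromosome"
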