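"""Genomic inbreeding coefficients from ROH segments and genotype counts.

Two estimators are provided, mirroring the standard SNP-array pair:

* ``F_ROH(t) = L_ROH(t) / L_AUTO`` — total length of an individual's ROH at
  least ``t`` kb long, divided by the autosomal genome length covered by the
  SNP map (per chromosome, last minus first SNP position).  Reported at the
  conventional thresholds of 1 Mb (ancient plus recent autozygosity) and
  8 Mb (recent autozygosity only).  The length threshold is inclusive: a
  segment of exactly ``t`` kb counts, so detector output at minimum length
  1000 kb is wholly contained in the ">1 Mb" tier.
* ``F_HOM = (O - E) / (N - E)`` — observed minus expected homozygous call
  count over nonmissing minus expected, the PLINK ``--het`` method-of-moments
  estimator.  Expected homozygosity at locus j is ``1 - 2 p q * T/(T-1)``
  with ``p`` the cohort allele frequency and ``T`` the cohort's nonmissing
  allele count; the ``T/(T-1)`` factor unbiases the 2pq plug-in so a cohort
  drawn exactly at Hardy-Weinberg equilibrium averages F_HOM ~ 0
  (``unbiased=False`` gives the plain plug-in).  F_HOM may be negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_io import GenotypeMatrix, HET, HOM_A, HOM_B, MISSING


@dataclass(frozen=True)
class AutosomeSpan:
    """SNP-covered autosomal length, total and per chromosome, in kb."""

    l_auto_kb: float
    per_chrom_kb: dict

    def __post_init__(self):
        if self.l_auto_kb <= 0:
            raise ValueError("l_auto_kb must be positive")


def autosome_span(variants: pd.DataFrame) -> AutosomeSpan:
    """Per-chromosome SNP-map span (last minus first position, kb) and total.

    Chromosomes with fewer than two SNPs carry no span and are excluded with
    a warning.
    """
    per_chrom = {}
    for chrom, sub in variants.groupby("chrom", sort=True):
        if len(sub) < 2:
            warnings.warn(f"chromosome {chrom} has <2 SNPs; excluded from autosome span")
            continue
        pos = sub["pos_bp"]
        per_chrom[int(chrom)] = float(pos.max() - pos.min()) / 1000.0
    if not per_chrom:
        raise ValueError("no chromosome with >=2 SNPs; autosome span undefined")
    return AutosomeSpan(l_auto_kb=float(sum(per_chrom.values())), per_chrom_kb=per_chrom)


def f_roh(segments_for_sample: pd.DataFrame, span: AutosomeSpan,
          min_len_kb: float = 1000.0) -> float:
    """Fraction of the SNP-covered autosome in ROH of length >= ``min_len_kb``."""
    if span.l_auto_kb <= 0:
        raise ValueError("autosome span must be positive")
    if segments_for_sample.empty:
        return 0.0
    lengths = segments_for_sample["length_kb"]
    return float(lengths[lengths >= min_len_kb].sum() / span.l_auto_kb)


def _allele_freq_b(calls: np.ndarray) -> np.ndarray:
    """Cohort frequency of allele B per variant (nonmissing calls only)."""
    nh = (calls == HET).sum(axis=0)
    nb = (calls == HOM_B).sum(axis=0)
    nonmiss = (calls != MISSING).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(nonmiss > 0, (2 * nb + nh) / (2 * nonmiss), np.nan)


def f_hom(gm: GenotypeMatrix, sample_id, *, by_breed: bool = False,
          unbiased: bool = True) -> float:
    """Excess-homozygosity inbreeding coefficient for one sample."""
    series = f_hom_all(gm, by_breed=by_breed, unbiased=unbiased)
    if sample_id not in series.index:
        raise KeyError(f"unknown sample {sample_id!r}")
    return float(series.loc[sample_id])


def f_hom_all(gm: GenotypeMatrix, *, by_breed: bool = False,
              unbiased: bool = True) -> pd.Series:
    """F_HOM for every sample, indexed by sample_id.

    Allele frequencies (and the expected-homozygosity correction) are taken
    from the whole analysis cohort, or per breed when ``by_breed`` is set.
    """
    out = np.full(gm.n_samples, np.nan)
    groups = (gm.samples.groupby("breed").indices.items() if by_breed
              else [("__all__", np.arange(gm.n_samples))])
    for _, rows in groups:
        rows = np.asarray(rows)
        block = gm.calls[rows]
        p = _allele_freq_b(block)
        het_exp = 2.0 * p * (1.0 - p)
        if unbiased:
            t = 2.0 * (block != MISSING).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                het_exp = het_exp * np.where(t > 1, t / (t - 1.0), np.nan)
        exp_hom_per_locus = 1.0 - het_exp

        nonmiss = block != MISSING
        obs_hom = ((block == HOM_A) | (block == HOM_B)).sum(axis=1)
        n_loci = nonmiss.sum(axis=1)
        exp_hom = np.where(nonmiss, exp_hom_per_locus[None, :], 0.0).sum(axis=1)
        for k, i in enumerate(rows):
            if n_loci[k] == 0:
                raise ValueError(
                    f"sample {gm.samples['sample_id'].iat[i]!r} has no nonmissing loci"
                )
            out[i] = (obs_hom[k] - exp_hom[k]) / (n_loci[k] - exp_hom[k])
    return pd.Series(out, index=gm.samples["sample_id"].to_numpy(), name="f_hom")


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D vectors with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("rank correlation undefined for zero-variance input")
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


def inbreeding_records(gm: GenotypeMatrix, segments: pd.DataFrame,
                       span: AutosomeSpan,
                       thresholds_kb: tuple[float, float] = (1000.0, 8000.0),
                       **f_hom_kwargs) -> pd.DataFrame:
    """Per-sample table: sample_id, breed, f_roh at each threshold, f_hom.

    Samples without any ROH get f_roh 0 at every threshold.
    """
    fhom = f_hom_all(gm, **f_hom_kwargs)
    by_sample = dict(tuple(segments.groupby("sample_id", sort=False))) if not segments.empty else {}
    empty = segments.iloc[0:0]
    rows = []
    for srow in gm.samples.itertuples(index=False):
        segs = by_sample.get(srow.sample_id, empty)
        rec = {"sample_id": srow.sample_id, "breed": srow.breed}
        for t in thresholds_kb:
            rec[f"f_roh_gt{t / 1000:g}"] = f_roh(segs, span, t)
        rec["f_hom"] = float(fhom.loc[srow.sample_id])
        rows.append(rec)
    return pd.DataFrame(rows)


def inbreeding_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-breed mean +/- SD of each coefficient plus Spearman correlations
    of every f_roh column with f_hom (sample SD, n-1)."""
    value_cols = [c for c in records.columns if c.startswith("f_roh") or c == "f_hom"]
    out = []
    for breed, sub in records.groupby("breed", sort=True):
        row = {"breed": breed, "n": len(sub)}
        for c in value_cols:
            row[f"{c}_mean"] = sub[c].mean()
            row[f"{c}_sd"] = sub[c].std(ddof=1)
        for c in value_cols:
            if c == "f_hom":
                continue
            try:
                row[f"r_{c}_f_hom"] = spearman_correlation(sub[c], sub["f_hom"])
            except ValueError:
                row[f"r_{c}_f_hom"] = np.nan
        out.append(row)
    return pd.DataFrame(out)
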