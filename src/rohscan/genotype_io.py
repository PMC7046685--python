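"""Read, write and quality-filter PLINK-format SNP genotype panels.

Genotype calls are held as an ``int8`` matrix of shape (samples, variants)
using the codes :data:`HOM_A` (0), :data:`HET` (1), :data:`HOM_B` (2) and
:data:`MISSING` (-1).  Which physical allele counts as "A" is a per-variant
bookkeeping choice (first allele observed in the input, or column 5 of a BIM
file); every downstream computation in this package only distinguishes
homozygous / heterozygous / missing, so the coding choice is immaterial.

Quality control follows standard SNP-array practice for autosomal data:
non-autosomal variants are dropped first, then samples with too much
missingness, then variants failing call rate, minor allele frequency and a
Hardy-Weinberg exact test, in that order, each statistic recomputed on the
surviving set.  Thresholds are *exclusive at the boundary*: a variant with
call rate exactly 0.90 or MAF exactly 0.05 is removed (retention requires
CR > min_call_rate and MAF > min_maf), and HWE removal triggers at
p <= hwe_p_threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

HOM_A: int = 0
HET: int = 1
HOM_B: int = 2
MISSING: int = -1

VARIANT_COLUMNS = ["chrom", "vid", "pos_bp", "a1", "a2"]
SAMPLE_COLUMNS = ["sample_id", "breed", "group"]

#: PLINK non-autosomal chromosome codes for cattle-style inputs.
_CHROM_CODES = {"X": 30, "Y": 31, "XY": 32, "MT": 33, "M": 33}


class PlinkFormatError(ValueError):
    """Raised when a PED/MAP or BED/BIM/FAM file violates the format."""


class QCEmptyError(RuntimeError):
    """Raised when quality control removes every sample.

    The partially filled :class:`QCReport` is attached as ``.report``.
    """

    def __init__(self, message: str, report: "QCReport"):
        super().__init__(message)
        self.report = report


@dataclass(frozen=True)
class QCParams:
    """Thresholds for marker and sample filtering.

    ``min_call_rate``, ``min_maf`` are exclusive lower bounds for retention;
    ``hwe_p_threshold`` is the exact-test p at or below which a variant is
    removed; ``max_sample_missing`` is the per-sample missing fraction above
    which a sample is removed.
    """

    min_call_rate: float = 0.90
    min_maf: float = 0.05
    hwe_p_threshold: float = 0.001
    max_sample_missing: float = 0.10

    def __post_init__(self):
        for name in ("min_call_rate", "min_maf", "hwe_p_threshold", "max_sample_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    n_samples_removed: int = 0
    n_snps_removed_callrate: int = 0
    n_snps_removed_maf: int = 0
    n_snps_removed_hwe: int = 0
    n_snps_removed_nonautosomal: int = 0
    overall_genotyping_rate: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


@dataclass
class GenotypeMatrix:
    """A sample x variant panel of diploid genotype codes.

    Attributes
    ----------
    samples
        DataFrame with columns ``sample_id``, ``breed``, ``group``.
    variants
        DataFrame with columns ``chrom``, ``vid``, ``pos_bp``, ``a1``, ``a2``,
        sorted by (chrom, pos_bp).
    calls
        ``int8`` array, shape (n_samples, n_variants).
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self):
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(self.samples) and (self.samples["breed"].astype(str) == "").any():
            raise ValueError("breed labels must be non-empty")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sort_variants(self) -> "GenotypeMatrix":
        """Return a copy with variants sorted by (chrom, pos_bp), calls permuted."""
        order = np.lexsort((self.variants["pos_bp"].to_numpy(),
                            self.variants["chrom"].to_numpy()))
        return GenotypeMatrix(
            samples=self.samples.copy(),
            variants=self.variants.iloc[order].reset_index(drop=True),
            calls=self.calls[:, order],
        )

    def canonical_codes(self) -> np.ndarray:
        """Calls with hom orientation normalized to the first-observed allele.

        At each variant, if the first non-missing call is hom-B the two
        homozygote codes are swapped so that the first observed allele is
        allele A.  This is the orientation :func:`read_plink_text` produces;
        het/missing calls are unaffected.  Useful for comparing panels that
        took different routes through text serialization.
        """
        calls = self.calls.copy()
        if calls.size == 0:
            return calls
        nonmiss = calls != MISSING
        first = np.argmax(nonmiss, axis=0)
        has_any = nonmiss.any(axis=0)
        flip = has_any & (calls[first, np.arange(calls.shape[1])] == HOM_B)
        cols = np.flatnonzero(flip)
        block = calls[:, cols]
        swapped = block.copy()
        swapped[block == HOM_A] = HOM_B
        swapped[block == HOM_B] = HOM_A
        calls[:, cols] = swapped
        return calls

    def subset(self, sample_mask=None, variant_mask=None) -> "GenotypeMatrix":
        s = slice(None) if sample_mask is None else np.asarray(sample_mask)
        v = slice(None) if variant_mask is None else np.asarray(variant_mask)
        return GenotypeMatrix(
            samples=self.samples.loc[s] if sample_mask is not None else self.samples.copy(),
            variants=self.variants.loc[v] if variant_mask is not None else self.variants.copy(),
            calls=self.calls[np.ix_(np.flatnonzero(sample_mask) if sample_mask is not None
                                    else np.arange(self.n_samples),
                                    np.flatnonzero(variant_mask) if variant_mask is not None
                                    else np.arange(self.n_variants))],
        )


def _parse_chrom(token: str) -> int:
    token = token.strip()
    if token in _CHROM_CODES:
        return _CHROM_CODES[token]
    try:
        return int(token)
    except ValueError:
        raise PlinkFormatError(f"unrecognized chromosome identifier {token!r}") from None


# ---------------------------------------------------------------------------
# PED/MAP text format
# ---------------------------------------------------------------------------

def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read a PLINK PED/MAP pair into a :class:`GenotypeMatrix`.

    The first allele observed at each variant (scanning samples in file
    order, left allele then right) becomes allele ``a1``; ``0`` denotes a
    missing allele and any genotype containing it is coded missing.  Variants
    are sorted by (chrom, pos_bp) on load, with calls permuted to match.
    """
    map_rows = []
    for line in Path(map_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise PlinkFormatError(f"MAP line must have 4 columns, got {len(parts)}")
        map_rows.append((_parse_chrom(parts[0]), parts[1], int(parts[3])))
    m = len(map_rows)

    sample_rows = []
    allele_cols = []
    for line in Path(ped_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise PlinkFormatError(
                f"PED line has {len(parts)} fields; expected {6 + 2 * m} for {m} variants"
            )
        sample_rows.append((parts[1], parts[0], parts[0]))  # sample_id, breed=FID, group=FID
        allele_cols.append(parts[6:])

    n = len(sample_rows)
    alleles = np.array(allele_cols, dtype=object).reshape(n, m, 2) if n else \
        np.empty((0, m, 2), dtype=object)

    calls = np.full((n, m), MISSING, dtype=np.int8)
    a1_list, a2_list = [], []
    for j in range(m):
        a = alleles[:, j, 0]
        b = alleles[:, j, 1]
        miss = (a == "0") | (b == "0")
        interleaved = np.empty(2 * n, dtype=object)
        interleaved[0::2] = a
        interleaved[1::2] = b
        seen = pd.unique(interleaved[np.repeat(~miss, 2)])
        if len(seen) > 2:
            raise PlinkFormatError(
                f"variant {map_rows[j][1]!r} has {len(seen)} distinct alleles"
            )
        a1 = seen[0] if len(seen) > 0 else "A"
        a2 = seen[1] if len(seen) > 1 else ("B" if a1 != "B" else "A2")
        a1_list.append(a1)
        a2_list.append(a2)
        ok = ~miss
        hom = ok & (a == b)
        calls[hom & (a == a1), j] = HOM_A
        calls[hom & (a == a2), j] = HOM_B
        calls[ok & (a != b), j] = HET

    samples = pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS)
    variants = pd.DataFrame(
        {"chrom": [r[0] for r in map_rows], "vid": [r[1] for r in map_rows],
         "pos_bp": [r[2] for r in map_rows], "a1": a1_list, "a2": a2_list}
    )
    return GenotypeMatrix(samples, variants, calls).sort_variants()


def write_plink_text(gm: GenotypeMatrix, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` and ``<prefix>.map``; returns the two paths."""
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")

    with open(map_path, "w") as fh:
        for row in gm.variants.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.vid}\t0\t{row.pos_bp}\n")

    a1 = gm.variants["a1"].astype(str).to_numpy()
    a2 = gm.variants["a2"].astype(str).to_numpy()
    with open(ped_path, "w") as fh:
        for i, srow in enumerate(gm.samples.itertuples(index=False)):
            c = gm.calls[i]
            left = np.where(c == HOM_B, a2, a1)
            right = np.where(c == HOM_A, a1, a2)
            left = np.where(c == MISSING, "0", left)
            right = np.where(c == MISSING, "0", right)
            genos = " ".join(x for pair in zip(left, right) for x in pair)
            fh.write(f"{srow.breed} {srow.sample_id} 0 0 0 -9 {genos}\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# BED/BIM/FAM binary format
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B])
# 2-bit code (per pair of bits, little-endian within byte) -> genotype code
_BED_DECODE = np.array([HOM_A, MISSING, HET, HOM_B], dtype=np.int8)
_BED_ENCODE = {HOM_A: 0, MISSING: 1, HET: 2, HOM_B: 3}


def read_plink_binary(bed_path, bim_path, fam_path) -> GenotypeMatrix:
    """Read a SNP-major PLINK BED/BIM/FAM triple.

    Bit pairs decode as 00 -> hom a1, 01 -> missing, 10 -> het,
    11 -> hom a2; four samples are packed per byte, least-significant pair
    first, with per-variant padding when the sample count is not a multiple
    of four.
    """
    fam_rows = []
    for line in Path(fam_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise PlinkFormatError("FAM line must have 6 columns")
        fam_rows.append((parts[1], parts[0], parts[0]))
    samples = pd.DataFrame(fam_rows, columns=SAMPLE_COLUMNS)
    n = len(samples)

    bim_rows = []
    for line in Path(bim_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise PlinkFormatError("BIM line must have 6 columns")
        bim_rows.append((_parse_chrom(parts[0]), parts[1], int(parts[3]), parts[4], parts[5]))
    variants = pd.DataFrame(bim_rows, columns=VARIANT_COLUMNS)
    m = len(variants)

    raw = Path(bed_path).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise PlinkFormatError("not a PLINK BED file (bad magic bytes)")
    if len(raw) < 3 or raw[2] == 0x00:
        raise PlinkFormatError("sample-major BED files (mode byte 0x00) are unsupported")
    if raw[2] != 0x01:
        raise PlinkFormatError(f"unknown BED mode byte {raw[2]:#04x}")

    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * bytes_per_variant:
        raise PlinkFormatError(
            f"BED payload of {body.size} bytes does not match "
            f"{m} variants x {bytes_per_variant} bytes"
        )
    if m:
        packed = body.reshape(m, bytes_per_variant)
        shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
        codes2 = (packed[:, :, None] >> shifts[None, None, :]) & 0x3
        codes2 = codes2.reshape(m, 4 * bytes_per_variant)[:, :n]
        calls = _BED_DECODE[codes2].T
    else:
        calls = np.empty((n, 0), dtype=np.int8)
    return GenotypeMatrix(samples, variants, calls).sort_variants()


def write_plink_binary(gm: GenotypeMatrix, prefix) -> tuple[Path, Path, Path]:
    """Write ``<prefix>.bed/.bim/.fam`` (SNP-major); returns the three paths."""
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")

    with open(fam_path, "w") as fh:
        for row in gm.samples.itertuples(index=False):
            fh.write(f"{row.breed} {row.sample_id} 0 0 0 -9\n")
    with open(bim_path, "w") as fh:
        for row in gm.variants.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.vid}\t0\t{row.pos_bp}\t{row.a1}\t{row.a2}\n")

    n, m = gm.n_samples, gm.n_variants
    bytes_per_variant = (n + 3) // 4
    enc = np.zeros((m, 4 * bytes_per_variant), dtype=np.uint8)
    code_map = np.zeros(4, dtype=np.uint8)
    for call, bits in _BED_ENCODE.items():
        code_map[call % 4] = bits  # MISSING (-1) -> index 3
    if m:
        enc[:, :n] = code_map[gm.calls.T % 4]
    packed = (
        enc.reshape(m, bytes_per_variant, 4)
        << np.array([0, 2, 4, 6], dtype=np.uint8)[None, None, :]
    ).sum(axis=2, dtype=np.uint8)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        fh.write(packed.tobytes())
    return bed_path, bim_path, fam_path


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Two-sided exact Hardy-Weinberg test (Wigginton-style, no mid-p).

    Conditional on the observed allele counts, the probability of every
    possible heterozygote count is computed and the p-value is the summed
    probability of all counts no more likely than the observed one.

    Returns a p-value in (0, 1]; a monomorphic table gives 1.0 exactly.
    """
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_a + n_het + n_hom_b
    if n == 0:
        raise ValueError("all genotype counts are zero")
    rare = 2 * min(n_hom_a, n_hom_b) + n_het
    return _hwe_exact_from_allele_counts(n, rare, n_het)


@lru_cache(maxsize=65536)
def _hwe_exact_from_allele_counts(n: int, rare: int, obs_het: int) -> float:
    if rare == 0:
        return 1.0
    common = 2 * n - rare
    hets = np.arange(rare % 2, min(rare, common) + 1, 2)
    # log P(h | n, rare) up to a common constant
    logp = (
        hets * np.log(2.0)
        - gammaln((rare - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((common - hets) / 2 + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, obs_het)]
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_chisq_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """1-df chi-square HWE test (no continuity correction); exact test alternative."""
    n = n_hom_a + n_het + n_hom_b
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * n_hom_a + n_het) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_hom_a, n_het, n_hom_b], dtype=float)
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, 1))


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def _genotype_counts(calls: np.ndarray):
    """Per-variant (n_hom_a, n_het, n_hom_b, n_missing) for an int8 call block."""
    na = (calls == HOM_A).sum(axis=0)
    nh = (calls == HET).sum(axis=0)
    nb = (calls == HOM_B).sum(axis=0)
    nm = (calls == MISSING).sum(axis=0)
    return na, nh, nb, nm


def apply_qc(
    gm: GenotypeMatrix,
    params: QCParams | None = None,
    *,
    max_autosome: int = 29,
    hwe_scope: str = "within_breed",
    hwe_method: str = "exact",
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter a genotype panel; returns the filtered panel and a report.

    Filter order is fixed: (1) non-autosomal variants, (2) samples with
    missing fraction > ``max_sample_missing``, (3) variants by call rate,
    then MAF, then HWE, each recomputed on the surviving samples.

    ``hwe_scope`` is ``"within_breed"`` (a variant is removed if it fails in
    any breed) or ``"pooled"``.  Applying QC twice is a no-op.
    """
    params = params or QCParams()
    report = QCReport()

    chrom = gm.variants["chrom"].to_numpy()
    autosomal = (chrom >= 1) & (chrom <= max_autosome)
    report.n_snps_removed_nonautosomal = int((~autosomal).sum())
    gm = gm.subset(variant_mask=autosomal)

    if gm.n_variants:
        miss_frac = (gm.calls == MISSING).mean(axis=1)
    else:
        miss_frac = np.zeros(gm.n_samples)
    keep_samples = miss_frac <= params.max_sample_missing
    report.n_samples_removed = int((~keep_samples).sum())
    if not keep_samples.any():
        raise QCEmptyError("quality control removed every sample", report)
    gm = gm.subset(sample_mask=keep_samples)
    n = gm.n_samples

    na, nh, nb, nm = _genotype_counts(gm.calls)
    call_rate = (n - nm) / n if n else np.zeros(gm.n_variants)
    keep = call_rate > params.min_call_rate
    report.n_snps_removed_callrate = int((~keep).sum())

    nonmiss = np.maximum(n - nm, 1)
    p_b = (2 * nb + nh) / (2 * nonmiss)
    maf = np.minimum(p_b, 1 - p_b)
    fail_maf = keep & ~(maf > params.min_maf)
    report.n_snps_removed_maf = int(fail_maf.sum())
    keep &= ~fail_maf

    test = hwe_exact_test if hwe_method == "exact" else hwe_chisq_test
    cached = _hwe_exact_from_allele_counts if hwe_method == "exact" else None

    def hwe_p(block_calls, idx):
        a, h, b, _ = _genotype_counts(block_calls[:, idx])
        out = np.ones(idx.size)
        for k in range(idx.size):
            tot = int(a[k] + h[k] + b[k])
            if tot == 0:
                continue
            if cached is not None:
                rare = 2 * int(min(a[k], b[k])) + int(h[k])
                out[k] = cached(tot, rare, int(h[k]))
            else:
                out[k] = test(int(a[k]), int(h[k]), int(b[k]))
        return out

    candidates = np.flatnonzero(keep)
    if candidates.size:
        fail_hwe = np.zeros(candidates.size, dtype=bool)
        if hwe_scope == "pooled":
            pvals = hwe_p(gm.calls, candidates)
            fail_hwe = pvals <= params.hwe_p_threshold
        elif hwe_scope == "within_breed":
            for breed in gm.samples["breed"].unique():
                rows = (gm.samples["breed"] == breed).to_numpy()
                pvals = hwe_p(gm.calls[rows], candidates)
                fail_hwe |= pvals <= params.hwe_p_threshold
        else:
            raise ValueError(f"unknown hwe_scope {hwe_scope!r}")
        report.n_snps_removed_hwe = int(fail_hwe.sum())
        keep[candidates[fail_hwe]] = False

    gm = gm.subset(variant_mask=keep)
    if gm.calls.size:
        report.overall_genotyping_rate = float((gm.calls != MISSING).mean())
    else:
        report.overall_genotyping_rate = 1.0
    return gm, report
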