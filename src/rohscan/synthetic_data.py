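"""Synthetic SNP-array panels with known planted autozygosity.

The generator lays down a jittered SNP map over a configurable autosome set,
draws breed-specific allele frequencies from a Beta prior, samples baseline
genotypes at Hardy-Weinberg equilibrium within breed, and then *plants*
homozygous-by-descent tracts directly: per animal, tract counts per length
class are Poisson, lengths uniform within the class bounds, placements
uniform without overlap (rejection sampling with a retry bound).  Inside a
tract the genotype is homozygous for an allele drawn by frequency, except
for rare heterozygote "errors"; uniform missingness is applied last.
Island regions can be planted so that an exact-count random subset
(``round(fraction * group size)``) of a group carries a tract spanning the
island.  Tracts are planted directly rather than produced by a pedigree
process because every analysis downstream depends only on tract length and
frequency structure, and direct planting yields exact per-sample truth.

Everything is reproducible from ``SimConfig.seed``: one
``numpy.random.Generator`` drives the whole simulation in a fixed draw order.

The default SNP spacing (mean 6 kb) emulates a high-density bovine array, on
which the canonical detector thresholds (100 SNPs and 1 Mb minimum) are
mutually consistent: 1 Mb of map carries ~170 SNPs.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, HET, HOM_A, HOM_B, MISSING, SAMPLE_COLUMNS
from .inbreeding import AutosomeSpan

#: ROH length classes (Mb) used for tract planting: 1-2, 2-4, 4-8, 8-16, >16.
CLASS_BOUNDS_MB = ((1.0, 2.0), (2.0, 4.0), (4.0, 8.0), (8.0, 16.0), (16.0, 32.0))

_PLACEMENT_RETRIES = 1000


@dataclass(frozen=True)
class BreedConfig:
    """One breed: cohort size, allele-frequency prior and planted-tract rates.

    ``tract_rate_per_class`` is the expected number of planted tracts per
    animal in each of the five length classes of :data:`CLASS_BOUNDS_MB`.
    """

    name: str
    n_samples: int
    tract_rate_per_class: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    allele_freq_beta: tuple = (2.0, 2.0)
    group: str = "all"

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if len(self.tract_rate_per_class) != len(CLASS_BOUNDS_MB):
            raise ValueError("tract_rate_per_class must have one rate per length class")
        if any(r < 0 for r in self.tract_rate_per_class):
            raise ValueError("tract rates must be non-negative")
        if min(self.allele_freq_beta) <= 0:
            raise ValueError("Beta prior parameters must be positive")


@dataclass(frozen=True)
class IslandSpec:
    """A planted shared-ROH region carried by a fixed fraction of a group."""

    chrom: int
    start_bp: int
    end_bp: int
    group: str
    carrier_fraction: float

    def __post_init__(self):
        if self.end_bp <= self.start_bp:
            raise ValueError("island end must exceed start")
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    breeds: tuple
    chrom_lengths_bp: tuple
    snp_spacing_bp: tuple = (6000, 2000)  # (mean, +/- jitter)
    het_error_rate_in_tract: float = 0.001
    missing_rate: float = 0.01
    islands: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if not self.breeds:
            raise ValueError("at least one breed required")
        if any(l <= 0 for l in self.chrom_lengths_bp):
            raise ValueError("chromosome lengths must be positive")
        mean, jitter = self.snp_spacing_bp
        if mean <= 0 or jitter < 0 or jitter >= mean:
            raise ValueError("snp spacing must satisfy 0 <= jitter < mean")
        for rate in (self.het_error_rate_in_tract, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        for isl in self.islands:
            if not 1 <= isl.chrom <= len(self.chrom_lengths_bp):
                raise ValueError(f"island chromosome {isl.chrom} outside the genome")


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-sample tracts and per-island carriers."""

    tracts: dict            # sample_id -> list of (chrom, start_bp, end_bp)
    island_carriers: list   # one list of sample_ids per SimConfig.islands entry

    def tract_lengths_kb(self, sample_id) -> np.ndarray:
        if sample_id not in self.tracts:
            raise KeyError(f"unknown sample {sample_id!r}")
        return np.array([(e - s + 1) / 1000.0 for _, s, e in self.tracts[sample_id]])


def truth_f_roh(truth: SyntheticTruth, sample_id, min_len_kb: float,
                span: AutosomeSpan) -> float:
    """Analytic F_ROH from planted tracts at a length threshold (inclusive)."""
    lengths = truth.tract_lengths_kb(sample_id)
    return float(lengths[lengths >= min_len_kb].sum() / span.l_auto_kb)


def _snp_positions(rng, chrom_lengths_bp, spacing):
    mean, jitter = spacing
    all_chrom, all_pos = [], []
    for ci, length in enumerate(chrom_lengths_bp, start=1):
        est = int(length // max(mean - jitter, 1)) + 8
        steps = rng.integers(mean - jitter, mean + jitter + 1, size=est)
        pos = np.cumsum(steps)
        pos = pos[pos <= length]
        all_chrom.append(np.full(pos.size, ci, dtype=np.int64))
        all_pos.append(pos.astype(np.int64))
    return np.concatenate(all_chrom), np.concatenate(all_pos)


def _place_tract(rng, length_bp, chrom_lengths_bp, occupied, chrom_probs):
    """Place one tract uniformly without overlapping this sample's tracts."""
    for _ in range(_PLACEMENT_RETRIES):
        ci = int(rng.choice(len(chrom_lengths_bp), p=chrom_probs)) + 1
        l_chrom = chrom_lengths_bp[ci - 1]
        if length_bp >= l_chrom:
            continue
        start = int(rng.integers(1, l_chrom - length_bp + 1))
        end = start + length_bp - 1
        spans = occupied.setdefault(ci, [])
        k = bisect_left(spans, (start, end))
        if k > 0 and spans[k - 1][1] >= start:
            continue
        if k < len(spans) and spans[k][0] <= end:
            continue
        insort(spans, (start, end))
        return ci, start, end
    raise RuntimeError(
        f"could not place a {length_bp} bp tract after {_PLACEMENT_RETRIES} tries; "
        "tract demand likely exceeds chromosome capacity"
    )


def simulate_panel(config: SimConfig) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Generate a genotype panel plus its planted truth.  Fully seeded."""
    rng = np.random.default_rng(config.seed)
    chrom, pos = _snp_positions(rng, config.chrom_lengths_bp, config.snp_spacing_bp)
    m = pos.size

    sample_rows = []
    for bc in config.breeds:
        for k in range(bc.n_samples):
            sample_rows.append((f"{bc.name}_{k:02d}", bc.name, bc.group))
    samples = pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS)
    n = len(samples)
    sample_ids = samples["sample_id"].to_numpy()

    # breed allele frequencies (frequency of allele A) and HWE baseline calls
    calls = np.empty((n, m), dtype=np.int8)
    freq_a = {}
    row0 = 0
    for bc in config.breeds:
        a, b = bc.allele_freq_beta
        p = rng.beta(a, b, size=m)
        freq_a[bc.name] = p
        u = rng.random((bc.n_samples, m), dtype=np.float32)
        t1 = (p * p).astype(np.float32)
        t2 = t1 + (2 * p * (1 - p)).astype(np.float32)
        block = np.full((bc.n_samples, m), HOM_B, dtype=np.int8)
        block[u < t2[None, :]] = HET
        block[u < t1[None, :]] = HOM_A
        calls[row0:row0 + bc.n_samples] = block
        row0 += bc.n_samples

    # island carriers: exact-count random subsets per group
    tracts: dict = {sid: [] for sid in sample_ids}
    occupied: dict = {sid: {} for sid in sample_ids}
    island_carriers = []
    for isl in config.islands:
        in_group = samples if isl.group == "all" else samples[samples["group"] == isl.group]
        if in_group.empty:
            raise ValueError(f"island group {isl.group!r} matches no samples")
        n_carriers = int(round(isl.carrier_fraction * len(in_group)))
        chosen = sorted(rng.choice(in_group["sample_id"].to_numpy(), size=n_carriers,
                                   replace=False)) if n_carriers else []
        island_carriers.append(list(chosen))
        for sid in chosen:
            spans = occupied[sid].setdefault(isl.chrom, [])
            k = bisect_left(spans, (isl.start_bp, isl.end_bp))
            if (k > 0 and spans[k - 1][1] >= isl.start_bp) or \
                    (k < len(spans) and spans[k][0] <= isl.end_bp):
                raise ValueError("planted islands overlap for one sample; adjust config")
            insort(spans, (isl.start_bp, isl.end_bp))
            tracts[sid].append((isl.chrom, isl.start_bp, isl.end_bp))

    # random tracts per animal and length class
    lengths_arr = np.asarray(config.chrom_lengths_bp, dtype=float)
    chrom_probs = lengths_arr / lengths_arr.sum()
    breed_of = dict(zip(sample_ids, samples["breed"]))
    for bc in config.breeds:
        for sid in sample_ids[samples["breed"].to_numpy() == bc.name]:
            lengths_bp = []
            for rate, (lo_mb, hi_mb) in zip(bc.tract_rate_per_class, CLASS_BOUNDS_MB):
                if rate == 0:
                    continue
                count = int(rng.poisson(rate))
                lengths_bp.extend(
                    (rng.uniform(lo_mb, hi_mb, size=count) * 1e6).astype(np.int64))
            # longest first: long tracts need large free gaps, so place them
            # while the chromosome is still mostly empty
            for length_bp in sorted(lengths_bp, reverse=True):
                ci, s, e = _place_tract(rng, int(length_bp), config.chrom_lengths_bp,
                                        occupied[sid], chrom_probs)
                tracts[sid].append((ci, s, e))

    # overwrite genotypes inside tracts: homozygous, with rare het errors
    chrom_offsets = {}
    for ci in range(1, len(config.chrom_lengths_bp) + 1):
        idx = np.flatnonzero(chrom == ci)
        chrom_offsets[ci] = (idx[0], idx[-1] + 1) if idx.size else (0, 0)
    for i, sid in enumerate(sample_ids):
        p = freq_a[breed_of[sid]]
        for ci, s, e in tracts[sid]:
            off, stop = chrom_offsets[ci]
            cpos = pos[off:stop]
            lo = off + np.searchsorted(cpos, s, "left")
            hi = off + np.searchsorted(cpos, e, "right")
            k = hi - lo
            if k <= 0:
                continue
            hom = np.where(rng.random(k) < p[lo:hi], HOM_A, HOM_B).astype(np.int8)
            if config.het_error_rate_in_tract > 0:
                hom[rng.random(k) < config.het_error_rate_in_tract] = HET
            calls[i, lo:hi] = hom
        tracts[sid] = sorted(tracts[sid])

    if config.missing_rate > 0:
        calls[rng.random((n, m), dtype=np.float32) < config.missing_rate] = MISSING

    variants = pd.DataFrame({
        "chrom": chrom,
        "vid": [f"snp{c}_{p}" for c, p in zip(chrom, pos)],
        "pos_bp": pos, "a1": "A", "a2": "B",
    })
    gm = GenotypeMatrix(samples, variants, calls)
    return gm, SyntheticTruth(tracts=tracts, island_carriers=island_carriers)


def emulate_study_profile(seed: int = 0) -> SimConfig:
    """A canned seven-breed cohort shaped like a small Bos indicus survey.

    Four dairy/dual-utility breeds (~25-45 expected ROH per animal), one
    draft breed (~64, the most autozygous), one dual and one dwarf breed
    whose planted tracts are long-ROH enriched (>8 Mb classes carry ~70% of
    its tract length).  Per-class rates follow the length-class mixes
    typical of such surveys; group-specific islands are planted so that
    island and structure analyses have recoverable signal.  Genome: eight
    150 Mb autosomes at ~6 kb SNP spacing (a scaled-down autosome set; see
    the methods note).
    """
    breeds = (
        BreedConfig("dairy_sw", 13, (13.2, 5.0, 3.1, 2.0, 1.3), group="dairy"),
        BreedConfig("dairy_tp", 17, (13.6, 4.2, 3.9, 3.2, 1.6), group="dairy"),
        BreedConfig("dairy_gr", 15, (22.8, 10.2, 6.1, 3.2, 3.1), group="dairy"),
        BreedConfig("dual_hr", 18, (14.1, 5.4, 3.4, 2.3, 1.1), group="dairy"),
        BreedConfig("draft_kg", 16, (25.5, 15.6, 13.2, 7.0, 2.3), group="draft"),
        BreedConfig("dual_og", 17, (21.6, 11.2, 6.3, 3.9, 2.0), group="dual"),
        BreedConfig("dwarf_vc", 16, (11.8, 4.6, 3.3, 3.5, 3.5), group="dwarf"),
    )
    islands = (
        IslandSpec(1, 40_000_000, 43_000_000, "dairy", 0.5),
        IslandSpec(2, 60_000_000, 63_000_000, "draft", 0.6),
        IslandSpec(3, 30_000_000, 33_000_000, "dwarf", 0.6),
        IslandSpec(4, 80_000_000, 82_500_000, "all", 0.35),
    )
    return SimConfig(
        breeds=breeds,
        chrom_lengths_bp=tuple([150_000_000] * 8),
        snp_spacing_bp=(6000, 2000),
        het_error_rate_in_tract=0.001,
        missing_rate=0.01,
        islands=islands,
        seed=seed,
    )
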