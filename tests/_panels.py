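"""Small genotype-panel builders shared across test modules."""

import numpy as np
import pandas as pd

from rohscan.genotype_io import GenotypeMatrix, HOM_A, HET, HOM_B, MISSING


def make_gm(calls, pos=None, chrom=None, breeds=None, groups=None):
    """Build a GenotypeMatrix from a raw call array (samples x snps)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 10_000
    pos = np.asarray(pos, dtype=np.int64)
    if chrom is None:
        chrom = np.ones(m, dtype=np.int64)
    else:
        chrom = np.broadcast_to(np.asarray(chrom, dtype=np.int64), (m,)).copy()
    if breeds is None:
        breeds = ["breed1"] * n
    if groups is None:
        groups = list(breeds)
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "breed": breeds, "group": groups,
    })
    variants = pd.DataFrame({
        "chrom": chrom, "vid": [f"v{i}" for i in range(m)],
        "pos_bp": pos, "a1": "A", "a2": "B",
    })
    return GenotypeMatrix(samples, variants, calls)


def random_roh_panel(rng, n_snps=500, n_samples=2, n_tracts=(0, 3),
                     het_rate_in_tract=0.01, missing_rate=0.005):
    """A single-chromosome panel of HWE-like noise with planted hom tracts."""
    pos = np.cumsum(rng.integers(3000, 9000, size=n_snps))
    calls = rng.choice(
        [HOM_A, HET, HOM_B], p=[0.35, 0.35, 0.30], size=(n_samples, n_snps)
    ).astype(np.int8)
    for i in range(n_samples):
        for _ in range(rng.integers(n_tracts[0], n_tracts[1] + 1)):
            s = int(rng.integers(0, max(1, n_snps - 150)))
            ln = int(min(rng.integers(80, 320), n_snps - s))
            calls[i, s:s + ln] = np.where(
                rng.random(ln) < 0.5, HOM_A, HOM_B)
            calls[i, s:s + ln][rng.random(ln) < het_rate_in_tract] = HET
    calls[rng.random(calls.shape) < missing_rate] = MISSING
    return make_gm(calls, pos=pos)
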