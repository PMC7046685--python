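"""Quality control and ROH detection on a small simulated panel.

Simulates two 15-animal breeds with planted autozygous tracts, applies the
standard SNP-array filters (call rate > 0.90, MAF > 0.05, HWE exact
p > 0.001, sample missingness <= 10%), and runs both ROH detectors.
"""

import rohscan

cfg = rohscan.SimConfig(
    breeds=(rohscan.BreedConfig("breedA", 15, (8.0, 4.0, 2.0, 1.0, 0.3)),
            rohscan.BreedConfig("breedB", 15, (4.0, 2.0, 1.0, 0.5, 0.1))),
    chrom_lengths_bp=(100_000_000, 80_000_000),
    seed=42,
)
gm, truth = rohscan.simulate_panel(cfg)
print(f"simulated panel: {gm.n_samples} samples x {gm.n_variants} SNPs")

gm_qc, report = rohscan.apply_qc(gm)
print(f"QC: removed {report.n_samples_removed} samples; "
      f"{report.n_snps_removed_callrate} SNPs by call rate, "
      f"{report.n_snps_removed_maf} by MAF, {report.n_snps_removed_hwe} by HWE; "
      f"genotyping rate {report.overall_genotyping_rate:.4f}")

sliding = rohscan.detect_roh_sliding(gm_qc)
consecutive = rohscan.detect_roh_consecutive(gm_qc)
print(f"sliding-window detector: {len(sliding)} ROH; "
      f"consecutive-runs detector: {len(consecutive)} ROH")
print("\nfirst segments (sample, chrom, span, SNPs, length):")
print(sliding.head(5).to_string(index=False))
# Each row is one run of homozygosity: a stretch of one animal's genome with
# essentially no heterozygous calls, interpreted as autozygosity when >= 1 Mb.
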