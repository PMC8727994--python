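"""Expected power of QTL detection for a concrete BSA-seq design.

A haploid (yeast-like) population of 1500 segregants, balanced quarter
pools, and a minor QTL explaining 3% of the phenotypic variance.
"""

from bsadesign import DesignPoint, afd_stats, detection_power

design = DesignPoint.make("H", h2=0.03, n=1500, p=0.25, gamma=1.0, u=3.93)
stats = afd_stats(design)
power = detection_power(design).power

print(f"expected pool allele frequencies: fH={stats.mu_fH:.4f} fL={stats.mu_fL:.4f}")
print(f"expected AFD between pools:       {stats.mu_delta_f:+.4f}")
print(f"significance threshold (|AFD|):   {stats.T_plus:.4f}")
print(f"power of detection:               {power:.4f}")
print()
print("The H pool is depleted of the low-trait parent's allele, so the")
print("expected AFD is negative; its magnitude (0.22) comfortably exceeds")
print("the genome-wise threshold (0.14), giving near-certain detection.")
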