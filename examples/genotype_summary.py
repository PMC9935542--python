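"""Hardy-Weinberg genotype arithmetic for a biallelic risk variant.

Summarizes genotype counts of a schizophrenia cohort genotyped for a GRIN2A
SNP: the C-allele frequency, the observed genotype fractions and the
fractions expected under Hardy-Weinberg equilibrium.
"""

from connsig import summarize_genotypes

counts = {"TT": 76, "TC": 59, "CC": 11}
s = summarize_genotypes(counts)

print(f"cohort size:          {s.n}")
print(f"C-allele frequency:   {s.allele_freq_c_pct}%")
print(f"observed genotypes:   {s.rounded_pct('observed')}")
print(f"HWE expected:         {s.rounded_pct('expected')}")
print()
print(
    "The observed and HWE-expected genotype fractions agree to within a few\n"
    "tenths of a percent, i.e. the cohort shows no deviation from random\n"
    "mating at this locus."
)
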