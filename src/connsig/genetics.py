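"""Genotype summary arithmetic for a biallelic SNP.

Genotypes are coded by the count of the minor (risk) C-allele: TT = 0,
TC = 1, CC = 2.  Under Hardy-Weinberg equilibrium with C-allele frequency
``p`` the expected genotype proportions are ``q**2, 2*p*q, p**2`` with
``q = 1 - p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = ["GenotypeSummary", "summarize_genotypes", "GENOTYPES"]

GENOTYPES = ("TT", "TC", "CC")


@dataclass(frozen=True)
class GenotypeSummary:
    """Observed and Hardy-Weinberg-expected genotype frequencies.

    Attributes
    ----------
    counts
        Genotype -> non-negative count.
    n
        Total number of genotyped subjects.
    allele_freq_c
        Frequency of the C allele, ``(n_TC + 2 n_CC) / (2 N)``.
    observed_freq
        Genotype -> observed fraction (sums to 1).
    hwe_expected_freq
        Genotype -> HWE-expected fraction ``(q^2, 2pq, p^2)``.
    """

    counts: Mapping[str, int]
    n: int
    allele_freq_c: float
    observed_freq: Mapping[str, float] = field(repr=False)
    hwe_expected_freq: Mapping[str, float] = field(repr=False)

    def rounded_pct(self, which: str = "observed", ndigits: int = 1) -> dict[str, float]:
        """Frequencies as percentages rounded for display (default 0.1%)."""
        src = {
            "observed": self.observed_freq,
            "expected": self.hwe_expected_freq,
        }[which]
        return {g: round(100.0 * src[g], ndigits) for g in GENOTYPES}

    @property
    def allele_freq_c_pct(self) -> float:
        return round(100.0 * self.allele_freq_c, 1)


def summarize_genotypes(counts: Mapping[str, int]) -> GenotypeSummary:
    """Summarize genotype counts: allele frequency, observed and HWE fractions.

    Parameters
    ----------
    counts
        Mapping with keys ``TT``, ``TC``, ``CC`` (missing keys count as 0).

    Raises
    ------
    ValueError
        If any count is negative or all counts are zero ("empty cohort").
    """
    c = {g: int(counts.get(g, 0)) for g in GENOTYPES}
    if any(v < 0 for v in c.values()):
        raise ValueError("genotype counts must be non-negative")
    n = sum(c.values())
    if n == 0:
        raise ValueError("empty cohort: all genotype counts are zero")

    p = (c["TC"] + 2 * c["CC"]) / (2 * n)  # C-allele frequency
    q = 1.0 - p
    observed = {g: c[g] / n for g in GENOTYPES}
    expected = {"TT": q * q, "TC": 2.0 * p * q, "CC": p * p}
    return GenotypeSummary(
        counts=c,
        n=n,
        allele_freq_c=p,
        observed_freq=observed,
        hwe_expected_freq=expected,
    )
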