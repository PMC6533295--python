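"""Forensic diversity statistics for Y-STR haplotype data.

For a population of N males, with allele frequencies :math:`p_{ai}` at one
locus and haplotype frequencies :math:`p_{hi}` over a marker set:

.. math::

    GD = \\frac{N}{N-1}\\Bigl(1 - \\sum_i p_{ai}^2\\Bigr), \\qquad
    HD = \\frac{N}{N-1}\\Bigl(1 - \\sum_i p_{hi}^2\\Bigr), \\qquad
    MP = \\sum_i p_{hi}^2 .

GD is Nei's unbiased gene diversity per locus; HD is the same estimator
applied to whole haplotypes; MP (random match probability) is the chance
two males drawn with replacement share a haplotype. Discrimination
capacity DC is the number of distinct haplotypes divided by N.

Frequencies come from direct counting. At multi-copy loci (and at
single-copy loci with a duplicated-allele pattern) the countable unit is
the whole allelic combination, not the individual allele.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .profiles import PopulationSample, haplotype_key, subset_sample

__all__ = [
    "FrequencyTable",
    "HaplotypeSpectrum",
    "allele_frequencies",
    "gene_diversity",
    "haplotype_spectrum",
    "match_probability",
    "haplotype_diversity",
    "discrimination_capacity",
    "forensic_report",
]


@dataclass(frozen=True)
class FrequencyTable:
    """Direct-count frequencies of alleles (or allelic combinations) at one locus."""

    locus: str
    counts: Mapping[str, int]
    N: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.N:
            raise ValueError("counts must sum to N")

    @property
    def frequencies(self) -> dict[str, float]:
        return {k: c / self.N for k, c in self.counts.items()}


@dataclass(frozen=True)
class HaplotypeSpectrum:
    """Multiplicity spectrum: how many distinct haplotypes occur m times.

    This is the sufficient statistic for MP, HD and DC: each haplotype seen
    m times contributes (m/N)^2 to MP regardless of its identity.
    """

    spectrum: Mapping[int, int]

    def __post_init__(self) -> None:
        for m, k in self.spectrum.items():
            if m < 1 or k < 1:
                raise ValueError(f"invalid spectrum entry {m}: {k}")

    @property
    def N(self) -> int:
        return sum(m * k for m, k in self.spectrum.items())

    @property
    def n_haplotypes(self) -> int:
        return sum(self.spectrum.values())

    @property
    def n_unique(self) -> int:
        return self.spectrum.get(1, 0)


def allele_frequencies(sample: PopulationSample, locus: str) -> FrequencyTable:
    """Direct-count frequency table at `locus`.

    The key of each entry is the allele string (``"19.2"``), or the
    comma-joined combination for multi-allele calls (``"13,18"``); null
    calls count under the key ``"NULL"``.
    """
    if locus not in sample.panel.loci:
        raise KeyError(f"locus {locus!r} not in panel")
    counts = Counter(
        "NULL" if p.call(locus).is_null else str(p.call(locus))
        for p in sample.profiles
    )
    return FrequencyTable(locus, dict(counts), sample.N)


def _sum_sq(freqs: Sequence[float]) -> float:
    return sum(f * f for f in freqs)


def gene_diversity(freq: FrequencyTable) -> float:
    """Nei's unbiased gene diversity GD = N/(N-1) (1 - sum p^2)."""
    if freq.N < 2:
        raise ValueError("gene diversity needs N >= 2")
    n = freq.N
    return n / (n - 1) * (1.0 - _sum_sq(list(freq.frequencies.values())))


def haplotype_spectrum(
    sample: PopulationSample, subset: Sequence[str] | None = None
) -> HaplotypeSpectrum:
    """Group profiles by haplotype identity on `subset` loci; return the spectrum."""
    keys = Counter(haplotype_key(p, subset) for p in sample.profiles)
    return HaplotypeSpectrum(dict(Counter(keys.values())))


def match_probability(spec: HaplotypeSpectrum) -> float:
    """MP = sum over haplotypes of (m/N)^2 = sum_m spectrum[m] (m/N)^2."""
    n = spec.N
    if n < 1:
        raise ValueError("empty spectrum")
    return sum(k * (m / n) ** 2 for m, k in spec.spectrum.items())


def haplotype_diversity(spec: HaplotypeSpectrum) -> float:
    """HD = N/(N-1) (1 - MP)."""
    n = spec.N
    if n < 2:
        raise ValueError("haplotype diversity needs N >= 2")
    return n / (n - 1) * (1.0 - match_probability(spec))


def discrimination_capacity(spec: HaplotypeSpectrum) -> float:
    """DC = distinct haplotypes / N."""
    return spec.n_haplotypes / spec.N


def forensic_report(
    samples: Sequence[PopulationSample],
    subsets: Sequence[str] = ("MHT", "EHT", "PPY12", "YFILER", "YFILER_PLUS"),
    *,
    per_locus_gd: bool = False,
) -> pd.DataFrame:
    """One row per population x marker subset with the forensic parameters.

    Columns: population, subset, N, n_haplotypes, n_unique, fraction_unique,
    MP, HD, DC (raw doubles; round for display). With ``per_locus_gd`` a
    ``GD_<locus>`` column is added per subset locus.
    """
    rows = []
    for sample in samples:
        for name in subsets:
            sub = subset_sample(sample, name)
            spec = haplotype_spectrum(sub)
            row = {
                "population": sample.name,
                "subset": name,
                "N": sub.N,
                "n_haplotypes": spec.n_haplotypes,
                "n_unique": spec.n_unique,
                "fraction_unique": spec.n_unique / sub.N,
                "MP": match_probability(spec),
                "HD": haplotype_diversity(spec),
                "DC": discrimination_capacity(spec),
            }
            if per_locus_gd:
                for locus in sub.panel.loci:
                    row[f"GD_{locus}"] = gene_diversity(
                        allele_frequencies(sub, locus)
                    )
            rows.append(row)
    return pd.DataFrame(rows)
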