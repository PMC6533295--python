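"""Synthetic Y-STR data with the statistical structure the analyses assume.

Two generators:

* :func:`simulate_populations` — populations diverging from a common
  founder haplotype under the single-step symmetric stepwise mutation
  model (SMM): each mutation shifts an allele by exactly one repeat, up
  or down with equal probability. Genealogy is star-like: a population
  founder sits ``divergence_generations`` below the common ancestor, and
  each sampled male hangs ``within_generations`` below his population
  founder. This is a test harness that produces the repeat-number
  variance structure Rst responds to, not a demographic model.

* :func:`spectrum_constrained_dataset` — a population whose haplotype
  multiplicity spectrum matches a requested spectrum exactly (haplotypes
  distinct by construction), reproducing printed sufficient statistics
  such as "166 unique haplotypes and three duplicated haplotypes".

Rapidly mutating loci default to a mutation rate an order of magnitude
above the other loci, mirroring their published per-meiosis rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np

from .forensic import HaplotypeSpectrum
from .panels import MarkerPanel, RM_LOCI, YFILER_PLUS_PANEL
from .profiles import AlleleCall, PopulationSample, Profile

__all__ = [
    "SimulationConfig",
    "FOUNDER_HAPLOTYPE",
    "simulate_populations",
    "spectrum_constrained_dataset",
    "inject_artifacts",
]

#: Modal Yfiler Plus alleles (repeat units) used as the default founder.
FOUNDER_HAPLOTYPE: dict[str, tuple[float, ...]] = {
    "DYS19": (15,), "DYS385": (13, 18), "DYS389I": (13,), "DYS389II": (29,),
    "DYS390": (24,), "DYS391": (10,), "DYS392": (13,), "DYS393": (13,),
    "DYS438": (10,), "DYS439": (12,), "DYS437": (14,), "DYS456": (15,),
    "DYS458": (17,), "DYS635": (21,), "DYS448": (19,), "YGATAH4": (12,),
    "DYS576": (18,), "DYS627": (21,), "DYS460": (10,), "DYS449": (29,),
    "DYS518": (38,), "DYS570": (17,), "DYS481": (23,), "DYF387S1": (36, 38),
    "DYS533": (11,),
}

#: Typical single-locus Y-STR mutation rate per meiosis.
DEFAULT_RATE = 2.5e-3
#: Rapidly mutating loci run an order of magnitude hotter.
RM_RATE = 1.2e-2


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the SMM population simulator.

    ``divergence_generations`` gives, per population, the branch length in
    generations between the common ancestor and that population's
    founder; ``within_generations`` the star-tip depth below the founder
    (controls within-population diversity). Artifact rates are
    per-profile-per-locus probabilities applied to single-copy loci
    (restricted to ``artifact_loci`` when given).
    """

    n_samples: tuple[int, ...] = (50, 50)
    divergence_generations: tuple[int, ...] = (100, 100)
    within_generations: int = 150
    panel: MarkerPanel = YFILER_PLUS_PANEL
    mutation_rates: Mapping[str, float] = field(default_factory=dict)
    default_rate: float = DEFAULT_RATE
    rm_rate: float = RM_RATE
    duplicated_rate: float = 0.0
    null_rate: float = 0.0
    intermediate_rate: float = 0.0
    artifact_loci: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_samples) != len(self.divergence_generations):
            raise ValueError("one divergence time per population required")
        if not self.panel.loci:
            raise ValueError("panel has no loci")
        for r in (self.duplicated_rate, self.null_rate, self.intermediate_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("artifact rates must be in [0, 1]")
        if any(g < 0 for g in self.divergence_generations) \
                or self.within_generations < 0:
            raise ValueError("generations must be >= 0")

    def rate(self, locus: str) -> float:
        if locus in self.mutation_rates:
            return self.mutation_rates[locus]
        return self.rm_rate if locus in RM_LOCI else self.default_rate


def _mutate(values: tuple[int, ...], generations: int, rate: float,
            rng: np.random.Generator) -> tuple[int, ...]:
    """Evolve one call for `generations` under the single-step SMM.

    Each copy accumulates Binomial(generations, rate) mutations; the net
    displacement is a sum of independent +/-1 steps (in whole repeats).
    Alleles reflect at 1 repeat so they stay positive.
    """
    out = []
    for v in values:
        k = rng.binomial(generations, rate)
        if k:
            ups = rng.binomial(k, 0.5)
            v = v + 10 * (2 * ups - k)
            if v < 10:
                v = 20 - v  # reflect at one repeat
        out.append(v)
    return tuple(out)


def _founder_calls(panel: MarkerPanel) -> dict[str, tuple[int, ...]]:
    calls = {}
    for locus in panel.loci:
        reps = FOUNDER_HAPLOTYPE.get(locus)
        if reps is None:
            reps = (13, 16) if panel.is_multicopy(locus) else (13,)
        calls[locus] = tuple(int(round(r * 10)) for r in reps)
    return calls


def simulate_populations(
    config: SimulationConfig,
) -> tuple[list[PopulationSample], dict]:
    """Simulate diverging populations; returns samples plus a truth log."""
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    ancestor = _founder_calls(panel)
    samples = []
    truth: dict = {"populations": [], "seed": config.seed,
                   "within_generations": config.within_generations}
    for pop_idx, (n, div) in enumerate(
        zip(config.n_samples, config.divergence_generations)
    ):
        pop_name = f"POP{pop_idx + 1}"
        founder = {
            l: _mutate(v, div, config.rate(l), rng) for l, v in ancestor.items()
        }
        profiles = []
        for i in range(n):
            calls = {
                l: AlleleCall(
                    _mutate(v, config.within_generations, config.rate(l), rng)
                )
                for l, v in founder.items()
            }
            profiles.append(
                Profile(f"{pop_name}_{i + 1:04d}", pop_name, calls, panel)
            )
        sample = PopulationSample(pop_name, tuple(profiles))
        sample = inject_artifacts(sample, config, rng=rng)
        samples.append(sample)
        truth["populations"].append({
            "name": pop_name, "n": n, "divergence_generations": div,
        })
    return samples, truth


def inject_artifacts(
    sample: PopulationSample,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> PopulationSample:
    """Seeded injection of genotyping artifacts into single-copy calls.

    Per profile and eligible locus: with ``duplicated_rate`` the call
    gains a second allele one repeat up (a duplicated single-copy
    pattern), with ``null_rate`` it becomes a null, with
    ``intermediate_rate`` it becomes an x.2 microvariant. At most one
    artifact per call; rates of zero leave the sample untouched.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if not (config.duplicated_rate or config.null_rate or config.intermediate_rate):
        return sample
    panel = sample.panel
    eligible = [
        l for l in panel.loci
        if not panel.is_multicopy(l)
        and (config.artifact_loci is None or l in config.artifact_loci)
    ]
    new_profiles = []
    for p in sample.profiles:
        calls = dict(p.calls)
        for locus in eligible:
            u = rng.random()
            call = calls[locus]
            if call.is_null or len(call.values) != 1:
                continue
            v = call.values[0]
            if u < config.duplicated_rate:
                calls[locus] = AlleleCall((v, v + 10))
            elif u < config.duplicated_rate + config.null_rate:
                calls[locus] = AlleleCall.null()
            elif u < (config.duplicated_rate + config.null_rate
                      + config.intermediate_rate):
                calls[locus] = AlleleCall((v - v % 10 + 2,))
        new_profiles.append(dc_replace(p, calls=calls))
    return PopulationSample(sample.name, tuple(new_profiles))


def spectrum_constrained_dataset(
    spectrum: HaplotypeSpectrum | Mapping[int, int],
    panel: MarkerPanel = YFILER_PLUS_PANEL,
    seed: int = 0,
    name: str = "POP",
) -> PopulationSample:
    """A population whose haplotype multiplicity spectrum is exactly `spectrum`.

    Distinct haplotypes are enumerated by offsetting two high-variability
    counter loci from the founder haplotype, so distinctness holds by
    construction; profile order is a seeded shuffle.
    """
    if not isinstance(spectrum, HaplotypeSpectrum):
        spectrum = HaplotypeSpectrum(dict(spectrum))
    rng = np.random.default_rng(seed)
    n_hap = spectrum.n_haplotypes
    base = _founder_calls(panel)
    c1, c2 = panel.loci[-1], panel.loci[0]  # counter loci for enumeration
    if panel.is_multicopy(c1) or panel.is_multicopy(c2):
        single = [l for l in panel.loci if not panel.is_multicopy(l)]
        if len(single) < 2:
            raise ValueError("panel needs two single-copy loci for enumeration")
        c1, c2 = single[0], single[-1]
    span = 60
    if n_hap > span * span:
        raise ValueError(f"spectrum requests {n_hap} haplotypes; max {span * span}")
    haplotypes = []
    for i in range(n_hap):
        calls = dict(base)
        calls[c1] = (100 + 10 * (i % span),)
        calls[c2] = (100 + 10 * (i // span),)
        haplotypes.append(calls)
    multiplicities = []
    for m, k in sorted(spectrum.spectrum.items()):
        multiplicities.extend([m] * k)
    rng.shuffle(multiplicities)
    profiles = []
    idx = 0
    for h, m in zip(haplotypes, multiplicities):
        for _ in range(m):
            idx += 1
            profiles.append(Profile(
                f"{name}_{idx:04d}", name,
                {l: AlleleCall(v) for l, v in h.items()}, panel,
            ))
    order = rng.permutation(len(profiles))
    profiles = [profiles[i] for i in order]
    profiles = [
        dc_replace(p, sample_id=f"{name}_{i + 1:04d}")
        for i, p in enumerate(profiles)
    ]
    return PopulationSample(name, tuple(profiles))
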