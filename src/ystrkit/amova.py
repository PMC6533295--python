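"""AMOVA-based pairwise population distances for Y-STR haplotypes.

Analysis of molecular variance (Excoffier-Smouse-Quattro) partitions the
squared inter-individual distances into among- and within-population
variance components; the among fraction

.. math::

    \\Phi_{ST} = \\frac{\\sigma^2_{among}}{\\sigma^2_{among} + \\sigma^2_{within}}

is the population distance. Two inter-profile metrics are supported:

* ``IDENTITY`` — 0/1 haplotype mismatch; the resulting Phi is the
  frequency-based Fst analog computed by Arlequin on haplotype data.
* ``SQUARED_REPEAT`` — sum over loci of the squared repeat-number
  difference; the resulting Phi is the microsatellite Rst analog used by
  the YHRD AMOVA tool, which weights mismatches by mutational distance
  under the stepwise mutation model.

Significance comes from permuting profiles between the two populations
and recounting how often the permuted Phi reaches the observed one.

The user-facing surface follows the model/results pattern:
``PairwiseAmova(samples, model=DistanceModel.rst()).fit(permutations=999,
seed=1)`` returns a :class:`PairwiseAmovaResults` with the Phi matrix,
p-values, the filter provenance and a ``summary()`` table.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import Flag, PopulationSample, Profile, haplotype_key

__all__ = [
    "DistanceKind",
    "IntermediatePolicy",
    "DistanceModel",
    "VarianceComponents",
    "filter_for_distance",
    "profile_distance",
    "distance_matrix",
    "amova_two_group",
    "PairwiseAmova",
    "PairwiseAmovaResults",
    "pairwise_matrix",
]


class DistanceKind(str, enum.Enum):
    IDENTITY = "IDENTITY"
    SQUARED_REPEAT = "SQUARED_REPEAT"


class IntermediatePolicy(str, enum.Enum):
    """How microvariant alleles (19.2) enter the repeat-difference metric."""

    FRACTIONAL = "FRACTIONAL"        # 19.2 - 19 counts as 0.2 repeats
    EXCLUDE_LOCUS = "EXCLUDE_LOCUS"  # drop loci carrying any microvariant


@dataclass(frozen=True)
class DistanceModel:
    """Configuration of the inter-profile distance underlying Phi.

    ``include_multicopy`` only affects ``SQUARED_REPEAT``: repeat
    differences are undefined for allele multisets, so the multi-copy
    loci are excluded there by default (they always participate in
    ``IDENTITY`` through their combination keys). ``dys389_adjust``
    subtracts DYS389I from DYS389II before differencing, since DYS389II
    is conventionally reported as the combined fragment.
    """

    kind: DistanceKind = DistanceKind.SQUARED_REPEAT
    intermediate_policy: IntermediatePolicy = IntermediatePolicy.FRACTIONAL
    dys389_adjust: bool = False
    include_multicopy: bool = False

    @classmethod
    def rst(cls, **kw) -> "DistanceModel":
        return cls(kind=DistanceKind.SQUARED_REPEAT, **kw)

    @classmethod
    def fst(cls, **kw) -> "DistanceModel":
        return cls(kind=DistanceKind.IDENTITY, **kw)


def filter_for_distance(
    samples: Sequence[PopulationSample],
) -> tuple[list[PopulationSample], list[dict]]:
    """Drop profiles with duplicated single-copy alleles or null alleles.

    These artifacts have no defined repeat distance, so they are removed
    before any Phi computation (they still count in the diversity
    statistics). Returns the filtered samples and a provenance log; a
    population left empty is an error.
    """
    log: list[dict] = []
    filtered: list[PopulationSample] = []
    for sample in samples:
        kept = []
        for p in sample.profiles:
            reasons = []
            if p.flags & Flag.DUPLICATED_SINGLE_COPY:
                reasons.append("DUPLICATED_SINGLE_COPY")
            if p.flags & Flag.NULL_ALLELE:
                reasons.append("NULL_ALLELE")
            if reasons:
                log.append({"population": sample.name,
                            "sample_id": p.sample_id,
                            "reasons": reasons})
            else:
                kept.append(p)
        if not kept:
            raise ValueError(
                f"population {sample.name!r} has no profiles left after filtering"
            )
        filtered.append(PopulationSample(sample.name, tuple(kept)))
    return filtered, log


def _included_loci(
    profiles: Sequence[Profile],
    model: DistanceModel,
    subset: Sequence[str] | None,
) -> list[str]:
    """Loci entering the SQUARED_REPEAT sum, resolved once per dataset."""
    panel = profiles[0].panel
    loci = list(panel.loci if subset is None else subset)
    if not model.include_multicopy:
        loci = [l for l in loci if not panel.is_multicopy(l)]
    if model.intermediate_policy is IntermediatePolicy.EXCLUDE_LOCUS:
        loci = [
            l for l in loci
            if not any(p.call(l).is_intermediate for p in profiles)
        ]
    return loci


def _repeat_value(profile: Profile, locus: str, model: DistanceModel) -> float:
    call = profile.call(locus)
    if call.is_null or len(call.values) != 1:
        raise ValueError(
            f"profile {profile.sample_id}: locus {locus} has "
            f"{len(call.values)} alleles; apply filter_for_distance first"
        )
    value = call.values[0] / 10.0
    if model.dys389_adjust and locus == "DYS389II":
        value -= profile.call("DYS389I").values[0] / 10.0
    return value


def _locus_sq_diff(a: Profile, b: Profile, locus: str, model: DistanceModel) -> float:
    """Squared repeat difference at one locus; multi-copy loci compare
    their sorted copies position-wise."""
    if a.panel.is_multicopy(locus):
        va, vb = a.call(locus).values, b.call(locus).values
        if not va or not vb:
            raise ValueError(f"null call at multi-copy locus {locus}")
        if len(va) != len(vb):
            raise ValueError(
                f"copy-number mismatch at {locus}: {len(va)} vs {len(vb)}"
            )
        return sum(((x - y) / 10.0) ** 2 for x, y in zip(va, vb))
    return (_repeat_value(a, locus, model) - _repeat_value(b, locus, model)) ** 2


def profile_distance(
    a: Profile,
    b: Profile,
    model: DistanceModel,
    subset: Sequence[str] | None = None,
) -> float:
    """Squared distance between two males under the configured metric."""
    if model.kind is DistanceKind.IDENTITY:
        return 0.0 if haplotype_key(a, subset) == haplotype_key(b, subset) else 1.0
    loci = _included_loci((a, b), model, subset)
    return sum(_locus_sq_diff(a, b, l, model) for l in loci)


def distance_matrix(
    profiles: Sequence[Profile],
    model: DistanceModel,
    subset: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Symmetric squared-distance matrix over `profiles`.

    For ``SQUARED_REPEAT`` the included loci are resolved once for the
    whole set (so every pair uses the same loci, as AMOVA requires) and
    returned alongside the matrix; for ``IDENTITY`` the subset itself is
    returned.
    """
    n = len(profiles)
    d = np.zeros((n, n))
    if model.kind is DistanceKind.IDENTITY:
        keys = [haplotype_key(p, subset) for p in profiles]
        for i in range(n):
            for j in range(i + 1, n):
                if keys[i] != keys[j]:
                    d[i, j] = d[j, i] = 1.0
        loci = list(profiles[0].panel.loci if subset is None else subset)
        return d, loci
    loci = _included_loci(profiles, model, subset)
    panel = profiles[0].panel
    single = [l for l in loci if not panel.is_multicopy(l)]
    vals = np.array(
        [[_repeat_value(p, l, model) for l in single] for p in profiles]
    )
    diff = vals[:, None, :] - vals[None, :, :]
    d = np.einsum("ijk,ijk->ij", diff, diff)
    for l in loci:  # multi-copy loci (only present with include_multicopy)
        if panel.is_multicopy(l):
            for i in range(n):
                for j in range(i + 1, n):
                    step = _locus_sq_diff(profiles[i], profiles[j], l, model)
                    d[i, j] += step
                    d[j, i] += step
    return d, loci


@dataclass(frozen=True)
class VarianceComponents:
    """Two-level AMOVA decomposition for one population pair."""

    ssd_total: float
    ssd_within: float
    msd_among: float
    msd_within: float
    n_prime: float
    sigma2_among: float
    sigma2_within: float
    phi_st: float
    group_sizes: tuple[int, ...]

    @property
    def ssd_among(self) -> float:
        return self.ssd_total - self.ssd_within


def _amova_from_matrix(
    d: np.ndarray, groups: np.ndarray, sizes: np.ndarray
) -> VarianceComponents:
    n = d.shape[0]
    k = len(sizes)
    # SSD from squared distances: SSD = sum_{i<j} d_ij / n over the group
    ssd_total = d[np.triu_indices(n, k=1)].sum() / n
    ssd_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(groups == g)
        sub = d[np.ix_(idx, idx)]
        ssd_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    msd_among = (ssd_total - ssd_within) / (k - 1)
    msd_within = ssd_within / (n - k)
    n_prime = (n - (sizes**2).sum() / n) / (k - 1)
    sigma2_among = (msd_among - msd_within) / n_prime
    sigma2_within = msd_within
    denom = sigma2_among + sigma2_within
    phi = 0.0 if denom == 0 else sigma2_among / denom
    return VarianceComponents(
        ssd_total, ssd_within, msd_among, msd_within, n_prime,
        sigma2_among, sigma2_within, phi, tuple(int(s) for s in sizes),
    )


def amova_two_group(
    pop_a: PopulationSample,
    pop_b: PopulationSample,
    model: DistanceModel,
    subset: Sequence[str] | None = None,
) -> VarianceComponents:
    """Variance components and Phi-st for one population pair."""
    if pop_a.N < 2 or pop_b.N < 2:
        raise ValueError("each population needs at least 2 profiles")
    profiles = list(pop_a.profiles) + list(pop_b.profiles)
    d, _ = distance_matrix(profiles, model, subset)
    groups = np.array([0] * pop_a.N + [1] * pop_b.N)
    return _amova_from_matrix(d, groups, np.array([pop_a.N, pop_b.N]))


@dataclass
class PairwiseAmovaResults:
    """Fitted pairwise AMOVA: Phi estimates, permutation p-values, provenance.

    ``phi`` clamps negative Phi estimates to zero (the reporting
    convention); the raw estimates stay in ``phi_raw``.
    """

    populations: list[str]
    phi_raw: pd.DataFrame
    pvalues: pd.DataFrame
    components: dict[tuple[str, str], VarianceComponents]
    model: DistanceModel
    loci_used: dict[tuple[str, str], list[str]]
    filter_log: list[dict]
    permutations: int
    seed: int | None

    @property
    def phi(self) -> pd.DataFrame:
        return self.phi_raw.clip(lower=0.0)

    def summary(self) -> str:
        lines = []
        kind = "Rst (squared repeat difference)" \
            if self.model.kind is DistanceKind.SQUARED_REPEAT \
            else "Fst (haplotype identity)"
        lines.append("Pairwise AMOVA results")
        lines.append("=" * 62)
        lines.append(f"Distance metric:      {kind}")
        lines.append(f"Populations:          {len(self.populations)}")
        lines.append(f"Permutations:         {self.permutations}")
        lines.append(f"Seed:                 {self.seed}")
        lines.append(f"Profiles filtered:    {len(self.filter_log)}")
        lines.append("-" * 62)
        lines.append(f"{'pair':<28}{'Phi_st':>10}{'p-value':>12}{'n':>10}")
        for i, a in enumerate(self.populations):
            for b in self.populations[i + 1:]:
                comp = self.components[(a, b)]
                phi = max(comp.phi_st, 0.0)
                p = self.pvalues.loc[a, b]
                n = sum(comp.group_sizes)
                lines.append(f"{a + ' vs ' + b:<28}{phi:>10.4f}{p:>12.4g}{n:>10d}")
        lines.append("=" * 62)
        return "\n".join(lines)


class PairwiseAmova:
    """Pairwise AMOVA model over two or more population samples.

    Parameters
    ----------
    samples
        Population samples sharing one marker panel.
    model
        The distance configuration (default: Rst / squared repeat).
    subset
        Optional locus subset (e.g. the Yfiler loci); default all panel loci.
    apply_filter
        Remove profiles with duplicated or null alleles first (the standard
        practice for repeat-based distances); the removals are logged on
        the results object.
    """

    def __init__(
        self,
        samples: Sequence[PopulationSample],
        model: DistanceModel | None = None,
        subset: Sequence[str] | None = None,
        apply_filter: bool = True,
    ) -> None:
        if len(samples) < 2:
            raise ValueError("need at least two populations")
        self.model = model if model is not None else DistanceModel.rst()
        self.subset = list(subset) if subset is not None else None
        if apply_filter:
            self.samples, self.filter_log = filter_for_distance(samples)
        else:
            self.samples, self.filter_log = list(samples), []

    def fit(
        self, permutations: int = 999, seed: int | None = None
    ) -> PairwiseAmovaResults:
        """Estimate Phi for every pair, with label-permutation p-values.

        The p-value uses the add-one estimator
        ``(1 + #{permuted Phi >= observed}) / (permutations + 1)``,
        permuting profile-to-population assignments within the pair.
        """
        if permutations < 0:
            raise ValueError("permutations must be >= 0")
        rng = np.random.default_rng(seed)
        names = [s.name for s in self.samples]
        phi = pd.DataFrame(0.0, index=names, columns=names)
        pvals = pd.DataFrame(np.nan, index=names, columns=names)
        comps: dict[tuple[str, str], VarianceComponents] = {}
        loci_used: dict[tuple[str, str], list[str]] = {}
        for i, sa in enumerate(self.samples):
            for sb in self.samples[i + 1:]:
                profiles = list(sa.profiles) + list(sb.profiles)
                d, loci = distance_matrix(profiles, self.model, self.subset)
                sizes = np.array([sa.N, sb.N])
                groups = np.array([0] * sa.N + [1] * sb.N)
                comp = _amova_from_matrix(d, groups, sizes)
                comps[(sa.name, sb.name)] = comp
                loci_used[(sa.name, sb.name)] = loci
                phi.loc[sa.name, sb.name] = comp.phi_st
                phi.loc[sb.name, sa.name] = comp.phi_st
                if permutations:
                    hits = 0
                    perm_groups = groups.copy()
                    for _ in range(permutations):
                        rng.shuffle(perm_groups)
                        c = _amova_from_matrix(d, perm_groups, sizes)
                        if c.phi_st >= comp.phi_st:
                            hits += 1
                    p = (1 + hits) / (permutations + 1)
                else:
                    p = np.nan
                pvals.loc[sa.name, sb.name] = p
                pvals.loc[sb.name, sa.name] = p
        return PairwiseAmovaResults(
            populations=names,
            phi_raw=phi,
            pvalues=pvals,
            components=comps,
            model=self.model,
            loci_used=loci_used,
            filter_log=self.filter_log,
            permutations=permutations,
            seed=seed,
        )


def pairwise_matrix(
    samples: Sequence[PopulationSample],
    model: DistanceModel | None = None,
    permutations: int = 999,
    seed: int | None = None,
    subset: Sequence[str] | None = None,
    apply_filter: bool = True,
) -> PairwiseAmovaResults:
    """Functional convenience wrapper around :class:`PairwiseAmova`."""
    return PairwiseAmova(samples, model, subset, apply_filter).fit(
        permutations=permutations, seed=seed
    )
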