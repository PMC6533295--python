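"""Core domain objects: allele calls, per-male profiles, population samples.

Y-STR alleles are repeat numbers, possibly with a microvariant fraction
(e.g. ``19.2`` = 19 full repeats plus 2 bases). To avoid float-equality
hazards every allele is stored internally as an integer number of tenths
of a repeat (``19.2`` -> 192). Multi-copy loci and duplicated alleles at
single-copy loci are both represented as a sorted multiset of such values
in one :class:`AlleleCall`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .panels import MarkerPanel

__all__ = [
    "AlleleCall",
    "Flag",
    "Profile",
    "PopulationSample",
    "parse_allele_token",
    "format_allele",
    "haplotype_key",
    "subset_sample",
]

NULL_TOKENS = ("", "-")


class Flag(enum.Flag):
    """Quality-control flags recomputable from the calls themselves."""

    NONE = 0
    DUPLICATED_SINGLE_COPY = enum.auto()
    NULL_ALLELE = enum.auto()
    INTERMEDIATE_ALLELE = enum.auto()


def parse_allele_token(token: str) -> int:
    """Parse one allele designation to internal tenths-of-a-repeat units.

    Accepts integers (``"13"``) and one-decimal microvariants (``"19.2"``);
    the microvariant digit must be 0-3 and the repeat count in (0, 100).
    """
    tok = token.strip()
    try:
        if "." in tok:
            whole, frac = tok.split(".")
            if len(frac) != 1:
                raise ValueError
            value = int(whole) * 10 + int(frac)
        else:
            value = int(tok) * 10
    except ValueError:
        raise ValueError(f"non-numeric allele token {token!r}") from None
    if not 0 < value < 1000:
        raise ValueError(f"allele {token!r} outside the plausible (0, 100) range")
    if value % 10 > 3:
        raise ValueError(
            f"allele {token!r}: microvariant digit must be .0-.3"
        )
    return value


def format_allele(value: int) -> str:
    """Inverse of :func:`parse_allele_token` (``192`` -> ``"19.2"``)."""
    whole, frac = divmod(value, 10)
    return str(whole) if frac == 0 else f"{whole}.{frac}"


@dataclass(frozen=True)
class AlleleCall:
    """The allele multiset observed at one locus for one male.

    ``values`` are tenths-of-a-repeat integers, sorted ascending; an empty
    tuple means the locus failed to amplify (null allele).
    """

    values: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(sorted(self.values)))
        for v in self.values:
            if not 0 < v < 1000:
                raise ValueError(f"allele value {v} out of range")
            if v % 10 > 3:
                raise ValueError(f"allele value {v}: microvariant digit must be 0-3")

    @classmethod
    def from_strings(cls, tokens: Iterable[str]) -> "AlleleCall":
        return cls(tuple(parse_allele_token(t) for t in tokens))

    @classmethod
    def null(cls) -> "AlleleCall":
        return cls(())

    @property
    def is_null(self) -> bool:
        return not self.values

    @property
    def is_intermediate(self) -> bool:
        return any(v % 10 for v in self.values)

    @property
    def repeats(self) -> tuple[float, ...]:
        """Allele designations as floats (display/distance use)."""
        return tuple(v / 10 for v in self.values)

    def __str__(self) -> str:
        return ",".join(format_allele(v) for v in self.values) if self.values else "-"


@dataclass(frozen=True)
class Profile:
    """One male's multi-locus Y-STR genotype."""

    sample_id: str
    population: str
    calls: Mapping[str, AlleleCall]
    panel: MarkerPanel

    def __post_init__(self) -> None:
        extra = set(self.calls) - set(self.panel.loci)
        if extra:
            raise ValueError(f"calls at loci outside the panel: {sorted(extra)}")

    @property
    def flags(self) -> Flag:
        """QC flags, recomputed from the calls on every access."""
        f = Flag.NONE
        for locus, call in self.calls.items():
            if call.is_null:
                f |= Flag.NULL_ALLELE
            elif len(call.values) >= 2 and not self.panel.is_multicopy(locus):
                f |= Flag.DUPLICATED_SINGLE_COPY
            if call.is_intermediate:
                f |= Flag.INTERMEDIATE_ALLELE
        return f

    def call(self, locus: str) -> AlleleCall:
        try:
            return self.calls[locus]
        except KeyError:
            raise KeyError(
                f"profile {self.sample_id}: no call at locus {locus}"
            ) from None

    def restrict(self, loci: Sequence[str], panel: MarkerPanel | None = None) -> "Profile":
        """Profile restricted to `loci` (flags recompute on the restriction)."""
        sub_panel = panel if panel is not None else self.panel.restrict(loci)
        calls = {l: self.call(l) for l in sub_panel.loci}
        return replace(self, calls=calls, panel=sub_panel)


def haplotype_key(profile: Profile, subset: Sequence[str] | None = None) -> str:
    """Deterministic haplotype identity string on a locus subset.

    Loci appear in panel order joined by ``|``; within a locus the allele
    values are ascending and ``,``-joined; a null call becomes the literal
    token ``NULL``. Two profiles get equal keys iff their genotypes agree
    (as multisets) on every subset locus.
    """
    loci = profile.panel.loci if subset is None else subset
    order = {l: i for i, l in enumerate(profile.panel.loci)}
    missing = [l for l in loci if l not in profile.calls]
    if missing:
        raise KeyError(
            f"profile {profile.sample_id}: missing loci {missing}"
        )
    fields = []
    for locus in sorted(loci, key=order.__getitem__):
        call = profile.calls[locus]
        fields.append("NULL" if call.is_null else str(call))
    return "|".join(fields)


@dataclass(frozen=True)
class PopulationSample:
    """A named population: the unit the diversity formulas' N refers to."""

    name: str
    profiles: tuple[Profile, ...]

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError(f"population {self.name!r} has no profiles")
        panels = {id(p.panel) for p in self.profiles}
        if len({tuple(p.panel.loci) for p in self.profiles}) > 1:
            raise ValueError(f"population {self.name!r} mixes marker panels")
        del panels

    @property
    def N(self) -> int:
        return len(self.profiles)

    @property
    def panel(self) -> MarkerPanel:
        return self.profiles[0].panel


def subset_sample(sample: PopulationSample, subset_name: str) -> PopulationSample:
    """Restrict every profile to a named panel subset (e.g. ``"YFILER"``)."""
    loci = sample.panel.subset_loci(subset_name)
    sub_panel = sample.panel.restrict(loci)
    return PopulationSample(
        sample.name, tuple(p.restrict(loci, panel=sub_panel) for p in sample.profiles)
    )
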