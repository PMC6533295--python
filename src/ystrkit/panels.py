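"""Marker panel definitions for forensic Y-STR kits.

A :class:`MarkerPanel` is an ordered list of locus names together with the
subset of loci that are multi-copy (amplified from duplicated Y regions and
therefore yielding an unordered allele multiset per male), plus a family of
named, nested subsets corresponding to the historical forensic kits:

=============  =======  ==================================================
subset         markers  definition
=============  =======  ==================================================
MHT               9     minimal haplotype (DYS19, DYS385a/b, DYS389I/II,
                        DYS390, DYS391, DYS392, DYS393)
EHT              11     extended haplotype = MHT + DYS438, DYS439
PPY12            12     PowerPlex Y = EHT + DYS437
YFILER           17     Yfiler kit = PPY12 + DYS456, DYS458, DYS635,
                        DYS448, YGATAH4
YFILER_PLUS      27     Yfiler Plus kit = Yfiler + DYS576, DYS627, DYS460,
                        DYS449, DYS518, DYS570, DYS481, DYF387S1a/b, DYS533
=============  =======  ==================================================

Marker counts treat each copy of a multi-copy locus (DYS385a/b,
DYF387S1a/b) as one marker, which is why 25 named loci give 27 markers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MarkerPanel",
    "YFILER_PLUS_PANEL",
    "SUBSET_NAMES",
    "RM_LOCI",
    "load_panel_tsv",
]

#: Canonical nesting order of the named subsets, smallest first.
SUBSET_NAMES = ("MHT", "EHT", "PPY12", "YFILER", "YFILER_PLUS")

#: Rapidly mutating loci (per-meiosis mutation rate above 1e-2).
RM_LOCI = frozenset(
    {"DYF387S1", "DYS449", "DYS518", "DYS570", "DYS576", "DYS627"}
)


def _canon_locus(name: str) -> str:
    """Canonical locus name: uppercase, no spaces/hyphens, a/b copy suffix merged."""
    n = name.strip().upper().replace(" ", "").replace("-", "").replace("_", "")
    if n.startswith("YGATA"):
        n = "YGATAH4"
    # merge per-copy column names (DYS385a / DYS385b -> DYS385)
    for stem in ("DYS385", "DYF387S1"):
        if n in (stem + "A", stem + "B"):
            return stem
    return n


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered set of Y-STR loci with multi-copy annotation and nested subsets.

    Parameters
    ----------
    loci
        Locus names in reporting order. Multi-copy loci appear once under
        their stem name (``DYS385``, not ``DYS385a``/``DYS385b``).
    multicopy
        The subset of `loci` carrying two marker copies.
    named_subsets
        Map from subset name (e.g. ``"YFILER"``) to its locus list, ordered
        consistently with `loci`.
    """

    loci: tuple[str, ...]
    multicopy: frozenset[str]
    named_subsets: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("panel loci must be unique")
        unknown = self.multicopy - set(self.loci)
        if unknown:
            raise ValueError(f"multicopy loci not in panel: {sorted(unknown)}")
        for name, subset in self.named_subsets.items():
            extra = set(subset) - set(self.loci)
            if extra:
                raise ValueError(f"subset {name} has unknown loci {sorted(extra)}")

    def is_multicopy(self, locus: str) -> bool:
        return locus in self.multicopy

    def n_markers(self, loci: Sequence[str] | None = None) -> int:
        """Number of markers (multi-copy loci count twice)."""
        loci = self.loci if loci is None else loci
        return sum(2 if l in self.multicopy else 1 for l in loci)

    def subset_loci(self, subset_name: str) -> tuple[str, ...]:
        """Locus list for a named subset (case-insensitive)."""
        key = subset_name.strip().upper()
        try:
            return tuple(self.named_subsets[key])
        except KeyError:
            raise KeyError(
                f"unknown panel subset {subset_name!r}; "
                f"known: {sorted(self.named_subsets)}"
            ) from None

    def restrict(self, loci: Iterable[str]) -> "MarkerPanel":
        """A new panel keeping only `loci` (panel order preserved)."""
        keep = {_canon_locus(l) for l in loci}
        new_loci = tuple(l for l in self.loci if l in keep)
        missing = keep - set(new_loci)
        if missing:
            raise KeyError(f"loci not in panel: {sorted(missing)}")
        subsets = {
            name: tuple(l for l in ls if l in keep)
            for name, ls in self.named_subsets.items()
        }
        return MarkerPanel(new_loci, self.multicopy & keep, subsets)

    def resolve(self, name: str) -> str:
        """Canonicalize a locus name and check panel membership."""
        canon = _canon_locus(name)
        if canon not in set(self.loci):
            raise KeyError(f"unknown locus column {name!r}")
        return canon


def _build_yfiler_plus() -> MarkerPanel:
    mht = (
        "DYS19", "DYS385", "DYS389I", "DYS389II",
        "DYS390", "DYS391", "DYS392", "DYS393",
    )
    eht = mht + ("DYS438", "DYS439")
    ppy12 = eht + ("DYS437",)
    yfiler = ppy12 + ("DYS456", "DYS458", "DYS635", "DYS448", "YGATAH4")
    yfiler_plus = yfiler + (
        "DYS576", "DYS627", "DYS460", "DYS449", "DYS518",
        "DYS570", "DYS481", "DYF387S1", "DYS533",
    )
    subsets = {
        "MHT": mht,
        "EHT": eht,
        "PPY12": ppy12,
        "YFILER": yfiler,
        "YFILER_PLUS": yfiler_plus,
    }
    return MarkerPanel(
        loci=yfiler_plus,
        multicopy=frozenset({"DYS385", "DYF387S1"}),
        named_subsets=subsets,
    )


#: Built-in 27-marker Yfiler Plus panel (25 named loci, 2 multi-copy).
YFILER_PLUS_PANEL = _build_yfiler_plus()


def load_panel_tsv(path: str | Path) -> MarkerPanel:
    """Load a user panel definition.

    The TSV needs columns ``locus``, ``multicopy`` (0/1) and ``subsets``
    (comma-separated subset names the locus belongs to).
    """
    loci: list[str] = []
    multicopy: set[str] = set()
    membership: dict[str, list[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"locus", "multicopy", "subsets"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"panel TSV must have columns {sorted(required)}")
        for row in reader:
            locus = _canon_locus(row["locus"])
            loci.append(locus)
            if row["multicopy"].strip() in ("1", "true", "True", "yes"):
                multicopy.add(locus)
            for sub in row["subsets"].split(","):
                sub = sub.strip().upper()
                if sub:
                    membership.setdefault(sub, []).append(locus)
    subsets = {k: tuple(v) for k, v in membership.items()}
    return MarkerPanel(tuple(loci), frozenset(multicopy), subsets)
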