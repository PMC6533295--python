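"""Reading, validating and writing YHRD-style Y-STR genotype tables.

The on-disk format is a TSV with a header row ``SampleID<TAB>Population``
followed by one column per locus, and one data row per male. Cells hold
comma-joined allele designations (``"13,18"`` at a multi-copy locus,
``"19.2"`` for a microvariant); an empty cell or ``-`` is a null allele.
Per-copy column pairs (``DYS385a``/``DYS385b``) are accepted on input and
merged into the locus' allele multiset.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Sequence, TextIO

from .panels import MarkerPanel, YFILER_PLUS_PANEL
from .profiles import (
    AlleleCall,
    Flag,
    NULL_TOKENS,
    PopulationSample,
    Profile,
    parse_allele_token,
)

__all__ = ["read_genotype_table", "write_genotype_table", "validation_summary"]


def _parse_cell(cell: str, *, row: int, locus: str) -> list[int]:
    cell = cell.strip()
    if cell in NULL_TOKENS:
        return []
    values = []
    for token in cell.split(","):
        try:
            values.append(parse_allele_token(token))
        except ValueError as exc:
            raise ValueError(f"row {row}, locus {locus}: {exc}") from None
    return values


def read_genotype_table(
    path: str | Path | TextIO,
    panel: MarkerPanel = YFILER_PLUS_PANEL,
) -> list[PopulationSample]:
    """Parse a genotype TSV into one :class:`PopulationSample` per population.

    Locus columns are matched case-insensitively against the panel; an
    unrecognised column, a non-numeric allele token or a repeated SampleID
    is an error. Populations are returned in order of first appearance.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError("empty genotype table")

    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 3 or header[0].strip().lower() != "sampleid" \
            or header[1].strip().lower() != "population":
        raise ValueError(
            "header must start with SampleID<TAB>Population followed by locus columns"
        )
    # map each column index to its canonical locus (a/b copies share a locus)
    col_locus: list[str] = []
    for col in header[2:]:
        col_locus.append(panel.resolve(col))  # raises naming the column

    seen_ids: set[str] = set()
    by_pop: dict[str, list[Profile]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.rstrip("\n").split("\t")
        if len(cells) != len(header):
            raise ValueError(
                f"row {lineno}: {len(cells)} fields, expected {len(header)}"
            )
        sample_id, population = cells[0].strip(), cells[1].strip()
        if not sample_id or not population:
            raise ValueError(f"row {lineno}: empty SampleID or Population")
        if sample_id in seen_ids:
            raise ValueError(f"row {lineno}: duplicate SampleID {sample_id!r}")
        seen_ids.add(sample_id)

        merged: dict[str, list[int]] = {}
        null_seen: dict[str, bool] = {}
        for locus, cell in zip(col_locus, cells[2:]):
            values = _parse_cell(cell, row=lineno, locus=locus)
            merged.setdefault(locus, []).extend(values)
            null_seen[locus] = null_seen.get(locus, False) or not values
        calls = {}
        for locus, values in merged.items():
            # a locus split over a/b columns is null only if every column was
            if not values and null_seen[locus]:
                calls[locus] = AlleleCall.null()
            else:
                calls[locus] = AlleleCall(tuple(values))
        profile = Profile(sample_id, population, calls, panel)
        by_pop.setdefault(population, []).append(profile)

    return [PopulationSample(name, tuple(ps)) for name, ps in by_pop.items()]


def write_genotype_table(
    samples: Sequence[PopulationSample],
    path: str | Path | TextIO,
) -> None:
    """Serialize populations back to the TSV format `read_genotype_table` reads.

    Round trip: reading the written file reproduces the samples (including
    recomputed QC flags), since the cell syntax is lossless.
    """
    if not samples:
        raise ValueError("no populations to write")
    panel = samples[0].panel
    for s in samples[1:]:
        if tuple(s.panel.loci) != tuple(panel.loci):
            raise ValueError("all populations must share one panel")
    rows = ["\t".join(["SampleID", "Population", *panel.loci])]
    for sample in samples:
        for p in sample.profiles:
            cells = [str(p.calls[l]) if l in p.calls else "-" for l in panel.loci]
            rows.append("\t".join([p.sample_id, p.population, *cells]))
    text = "\n".join(rows) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text)


def validation_summary(samples: Sequence[PopulationSample]) -> dict:
    """Per-population QC summary: sample counts and flag tallies."""
    out = {}
    for sample in samples:
        tally = Counter()
        flagged = []
        for p in sample.profiles:
            f = p.flags
            for flag in (Flag.DUPLICATED_SINGLE_COPY, Flag.NULL_ALLELE,
                         Flag.INTERMEDIATE_ALLELE):
                if f & flag:
                    tally[flag.name] += 1
            if f != Flag.NONE:
                flagged.append({"sample_id": p.sample_id,
                                "flags": [fl.name for fl in Flag if fl and f & fl]})
        out[sample.name] = {
            "N": sample.N,
            "n_flagged": len(flagged),
            "flag_counts": dict(tally),
            "flagged_profiles": flagged,
        }
    return out
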