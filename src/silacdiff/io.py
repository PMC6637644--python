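"""Reading, filtering, and writing protein-group quantification tables.

The upstream input is a MaxQuant-style ``proteinGroups`` export: one row per
inferred protein group, tab-separated with a header, carrying a SILAC ratio
column per comparison ("Ratio H/M normalized" or "Ratio H/L normalized") and
"+"-flagged contaminant/reverse columns.  A :class:`QuantTable` holds the
measurements of one comparison in one biological replicate — the population
over which z-scores are later computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, NoQuantifiableProteinsError

logger = logging.getLogger(__name__)

#: Channel schemes supported by the triple-label design: the heavy channel is
#: always the co-cultured condition, divided by medium or light mono-culture.
CHANNEL_SCHEMES = ("heavy_over_medium", "heavy_over_light")

#: Default column mapping following MaxQuant 1.5-era header conventions.
#: The ratio column is selected by the channel scheme.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "accession": "Majority protein IDs",
    "gene_name": "Gene names",
    "description": "Protein names",
    "ratio_heavy_over_medium": "Ratio H/M normalized",
    "ratio_heavy_over_light": "Ratio H/L normalized",
    "contaminant": "Potential contaminant",
    "reverse": "Reverse",
}


@dataclass(frozen=True)
class ProteinRecord:
    """One protein group's measurement in one comparison/replicate."""

    accession: str
    gene_name: str
    description: str
    ratio: float | None  # positive raw SILAC ratio, or None when missing
    is_contaminant: bool = False
    is_reverse: bool = False

    def __post_init__(self) -> None:
        if not self.accession:
            raise InputError("protein record requires a non-empty accession")
        if self.ratio is not None and not (np.isfinite(self.ratio) and self.ratio > 0):
            raise InputError(
                f"ratio for {self.accession} must be finite and > 0, got {self.ratio!r}"
            )


@dataclass
class QuantTable:
    """Protein-level ratios of one comparison for one biological replicate."""

    records: list[ProteinRecord]
    comparison: str
    replicate: str
    channel_scheme: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.channel_scheme not in CHANNEL_SCHEMES:
            raise ConfigurationError(
                f"unknown channel scheme {self.channel_scheme!r}; "
                f"expected one of {CHANNEL_SCHEMES}"
            )
        accessions = [r.accession for r in self.records]
        if len(set(accessions)) != len(accessions):
            dupes = sorted({a for a in accessions if accessions.count(a) > 1})
            raise InputError(f"duplicate accessions in table: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Return the records as a DataFrame (ratio as float, NaN = missing)."""
        return pd.DataFrame(
            {
                "accession": [r.accession for r in self.records],
                "gene_name": [r.gene_name for r in self.records],
                "description": [r.description for r in self.records],
                "ratio": [np.nan if r.ratio is None else r.ratio for r in self.records],
                "is_contaminant": [r.is_contaminant for r in self.records],
                "is_reverse": [r.is_reverse for r in self.records],
            }
        )


@dataclass
class GeneSetCollection:
    """Named gene/protein sets for over-representation testing."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] | None = None
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise InputError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def _scheme_for_comparison(comparison: str) -> str:
    """Infer the channel scheme from a comparison label like 'KG1a H/M'."""
    label = comparison.upper().replace(" ", "")
    if "H/M" in label:
        return "heavy_over_medium"
    if "H/L" in label:
        return "heavy_over_light"
    raise ConfigurationError(
        f"cannot infer channel scheme from comparison label {comparison!r}; "
        "expected it to contain 'H/M' or 'H/L'"
    )


def _flagged(cell: object) -> bool:
    # MaxQuant marks contaminant/reverse rows with "+"; tolerate variants —
    # any non-empty cell other than "0" counts as flagged.
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return False
    text = str(cell).strip()
    return text not in ("", "0", "nan")


def _parse_ratio(cell: object) -> float | None:
    try:
        value = float(cell)
    except (TypeError, ValueError):
        return None
    if not np.isfinite(value) or value <= 0:
        return None
    return value


def read_protein_groups(
    path: str | Path,
    comparison: str,
    replicate: str,
    column_map: Mapping[str, str] | None = None,
    channel_scheme: str | None = None,
) -> QuantTable:
    """Read a tab-separated protein-groups table into a :class:`QuantTable`.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    comparison
        Comparison label, e.g. ``"KG1a H/M"``; used to select the ratio
        column unless ``channel_scheme`` is given explicitly.
    replicate
        Replicate identifier (e.g. ``"rep1"``).
    column_map
        Overrides for :data:`DEFAULT_COLUMN_MAP` (logical name → header).

    Unparsable or non-positive ratio cells become missing values; rows are
    never dropped here (that is :func:`filter_quality`'s job) and row order
    is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input table not found: {path}")
    scheme = channel_scheme or _scheme_for_comparison(comparison)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    ratio_key = f"ratio_{scheme}"

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {
        "accession": cmap["accession"],
        "ratio": cmap[ratio_key],
    }
    optional = {
        "gene_name": cmap["gene_name"],
        "description": cmap["description"],
        "contaminant": cmap["contaminant"],
        "reverse": cmap["reverse"],
    }
    for logical, header in required.items():
        if header not in df.columns:
            raise ConfigurationError(
                f"mapped column for {logical!r} ({header!r}) not present in {path.name}"
            )

    records: list[ProteinRecord] = []
    for _, row in df.iterrows():
        raw_acc = str(row[required["accession"]]).strip()
        # multi-accession groups ("P1;P2"): the first accession is canonical
        accession = raw_acc.split(";")[0].strip()
        description = (
            str(row[optional["description"]]).strip()
            if optional["description"] in df.columns
            else ""
        )
        if ";" in raw_acc:
            description = f"{description} [group: {raw_acc}]".strip()
        gene = (
            str(row[optional["gene_name"]]).split(";")[0].strip()
            if optional["gene_name"] in df.columns
            else ""
        )
        records.append(
            ProteinRecord(
                accession=accession,
                gene_name=gene,
                description=description,
                ratio=_parse_ratio(row[required["ratio"]]),
                is_contaminant=_flagged(row.get(optional["contaminant"])),
                is_reverse=_flagged(row.get(optional["reverse"])),
            )
        )
    logger.info(
        "read %d protein groups from %s (%s, %s)", len(records), path.name, comparison, replicate
    )
    return QuantTable(
        records=records,
        comparison=comparison,
        replicate=str(replicate),
        channel_scheme=scheme,
        provenance=str(path),
    )


def filter_quality(table: QuantTable) -> QuantTable:
    """Drop contaminant/reverse entries and records without a ratio.

    Decoy (reversed-sequence) and known-contaminant rows exist upstream for
    search-engine FDR control and must not enter the population statistics.
    Idempotent; never alters a ratio value.
    """
    kept = [
        r
        for r in table.records
        if not r.is_contaminant and not r.is_reverse and r.ratio is not None
    ]
    n_contam = sum(r.is_contaminant for r in table.records)
    n_reverse = sum(r.is_reverse and not r.is_contaminant for r in table.records)
    n_missing = len(table.records) - len(kept) - n_contam - n_reverse
    logger.info(
        "filter_quality(%s/%s): kept %d of %d (removed %d contaminant, %d reverse, %d missing-ratio)",
        table.comparison,
        table.replicate,
        len(kept),
        len(table.records),
        n_contam,
        n_reverse,
        n_missing,
    )
    if not kept:
        raise NoQuantifiableProteinsError(
            f"no quantifiable proteins remain in {table.comparison}/{table.replicate}"
        )
    return replace(table, records=kept)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT gene-set file (name, description, members… per line)."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(
                    f"{path.name}:{lineno}: GMT line needs name, description and "
                    f"at least one member ({len(fields)} fields found)"
                )
            name, description = fields[0], fields[1]
            if name in sets:
                raise InputError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            members = frozenset(m.strip() for m in fields[2:] if m.strip())
            if not members:
                raise InputError(f"{path.name}:{lineno}: set {name!r} has no members")
            sets[name] = members
            descriptions[name] = description
    if not sets:
        raise InputError(f"{path.name}: no gene sets found")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_table(records: pd.DataFrame | Iterable[Mapping], path: str | Path) -> None:
    """Write a result table as tab-separated text with a header row.

    Ratios and statistics are rendered at full float precision (``repr``
    round-trip), so read-after-write reproduces the values exactly.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False, float_format=None)


def write_quant_table(table: QuantTable, path: str | Path) -> None:
    """Export a QuantTable in the same protein-groups dialect read_protein_groups reads."""
    ratio_col = (
        "Ratio H/M normalized"
        if table.channel_scheme == "heavy_over_medium"
        else "Ratio H/L normalized"
    )
    df = pd.DataFrame(
        {
            "Majority protein IDs": [r.accession for r in table.records],
            "Gene names": [r.gene_name for r in table.records],
            "Protein names": [r.description for r in table.records],
            ratio_col: [
                "" if r.ratio is None else repr(r.ratio) for r in table.records
            ],
            "Potential contaminant": ["+" if r.is_contaminant else "" for r in table.records],
            "Reverse": ["+" if r.is_reverse else "" for r in table.records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
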