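"""Reading organism records and building per-genome property profiles.

GenBank flat files are the preferred input: one protein per CDS feature,
taking the ``/translation`` qualifier when present and otherwise re-translating
the feature's nucleotide span with the bacterial/plastid genetic code
(NCBI translation table 11), honoring strand and ``join()`` coordinates.
Amino-acid FASTA is supported as a fallback, one record per entry.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .properties import (
    FEATURES,
    GeneStats,
    PropertyTable,
    UnscorableProteinError,
    score_protein,
)

__all__ = [
    "ProteinRecord",
    "GenomeProfile",
    "InputError",
    "EmptyProfileError",
    "RIBOSOMAL_PATTERN",
    "read_proteins",
    "classify_ribosomal",
    "profile_genome",
    "profile_to_frame",
]

logger = logging.getLogger(__name__)

#: Genetic code used when a CDS lacks /translation (bacterial/plastid code).
TRANSLATION_TABLE = 11

# Ribosomal identity is taken from the annotation alone, via this single
# pattern: either the phrase "ribosomal protein" or an rps/rpl/rpm-style
# gene-name token (e.g. rpsL, rpl12, rpmA).  "ribosomal RNA" does not match.
RIBOSOMAL_PATTERN = re.compile(
    r"ribosomal\s+protein|\b(?:rps|rpl|rpm)[A-Za-z0-9]{1,3}\b", re.IGNORECASE
)


class InputError(ValueError):
    """The input file is unreadable or contains no usable records."""


class EmptyProfileError(ValueError):
    """No protein in the record set could be scored."""


@dataclass
class ProteinRecord:
    """One coding gene's translated product plus annotation metadata."""

    gene_id: str
    product: str
    sequence: str
    is_ribosomal: bool
    source_id: str = ""


@dataclass
class GenomeProfile:
    """Aligned per-gene records and property statistics for one organism."""

    organism_id: str
    role: str  # "symbiont" or "relative"
    records: list[ProteinRecord]
    stats: list[GeneStats]
    table_name: str
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.role not in ("symbiont", "relative"):
            raise ValueError(f"role must be 'symbiont' or 'relative', got {self.role!r}")
        if len(self.records) != len(self.stats):
            raise ValueError("records and stats must be aligned")

    def __len__(self) -> int:
        return len(self.records)


def classify_ribosomal(record: ProteinRecord) -> bool:
    """True iff the product annotation identifies a ribosomal protein.

    The decision depends only on the annotation string, never on the
    sequence; an empty product cannot assert ribosomal identity and
    returns False.
    """
    return bool(RIBOSOMAL_PATTERN.search(record.product))


def _unique_gene_id(base: str, seen: dict[str, int]) -> str:
    # Duplicate locus tags get _2, _3, ... suffixes rather than aborting.
    count = seen.get(base, 0) + 1
    seen[base] = count
    return base if count == 1 else f"{base}_{count}"


def _extract_cds(
    seqrecord, index: int, seen_ids: dict[str, int], skipped: list[tuple[str, str]]
) -> ProteinRecord | None:
    feature = seqrecord.features[index]
    quals = feature.qualifiers
    base_id = (
        quals.get("locus_tag", [None])[0]
        or quals.get("protein_id", [None])[0]
        or f"cds_{index}"
    )
    if "pseudo" in quals or "pseudogene" in quals:
        skipped.append((base_id, "pseudo"))
        return None
    product = quals.get("product", [""])[0]
    translation = quals.get("translation", [None])[0]
    if translation is not None:
        sequence = translation.strip().upper().rstrip("*")
    else:
        try:
            nt = feature.extract(seqrecord.seq)
            sequence = str(nt.translate(table=TRANSLATION_TABLE)).rstrip("*")
            logger.debug(
                "re-translated %s with table %d", base_id, TRANSLATION_TABLE
            )
        except Exception as exc:  # malformed single feature: skip, never fatal
            skipped.append((base_id, f"translation failed: {exc}"))
            return None
    if not sequence:
        skipped.append((base_id, "empty translation"))
        return None
    record = ProteinRecord(
        gene_id=_unique_gene_id(base_id, seen_ids),
        product=product,
        sequence=sequence,
        is_ribosomal=False,
        source_id=seqrecord.id,
    )
    record.is_ribosomal = classify_ribosomal(record)
    return record


def read_proteins(
    path: str | Path,
    format: str = "genbank",
    *,
    skipped: list[tuple[str, str]] | None = None,
) -> list[ProteinRecord]:
    """Extract one :class:`ProteinRecord` per coding gene from a file.

    Parameters
    ----------
    path:
        GenBank flat file (.gb/.gbk/.gbff) or amino-acid FASTA (.faa/.fasta).
    format:
        ``"genbank"`` or ``"fasta"``.
    skipped:
        Optional list that collects ``(gene_id, reason)`` for every CDS
        feature dropped (pseudo genes, failed translations); its length is
        the ``n_skipped`` accounting for the file.

    Output order follows file feature order; gene ids are locus tag, else
    protein id, else a running ``cds_<i>`` index, deduplicated with numeric
    suffixes.
    """
    path = Path(path)
    if format not in ("genbank", "fasta"):
        raise ValueError(f"format must be 'genbank' or 'fasta', got {format!r}")
    if not path.exists():
        raise InputError(f"input file does not exist: {path}")
    drop_log: list[tuple[str, str]] = skipped if skipped is not None else []
    records: list[ProteinRecord] = []
    seen_ids: dict[str, int] = {}
    try:
        parsed = list(SeqIO.parse(str(path), format))
    except Exception as exc:
        raise InputError(f"could not parse {path} as {format}: {exc}") from exc
    if format == "fasta":
        for entry in parsed:
            description = entry.description
            # product = description minus the leading id token
            product = description[len(entry.id):].strip() if description else ""
            record = ProteinRecord(
                gene_id=_unique_gene_id(entry.id, seen_ids),
                product=product,
                sequence=str(entry.seq).upper().rstrip("*"),
                is_ribosomal=False,
                source_id=path.stem,
            )
            record.is_ribosomal = classify_ribosomal(record)
            if not record.sequence:
                drop_log.append((record.gene_id, "empty sequence"))
                continue
            records.append(record)
        if not records:
            raise InputError(f"no FASTA entries with sequence in {path}")
        return records
    n_cds = 0
    for seqrecord in parsed:
        for i, feature in enumerate(seqrecord.features):
            if feature.type != "CDS":
                continue
            n_cds += 1
            record = _extract_cds(seqrecord, i, seen_ids, drop_log)
            if record is not None:
                records.append(record)
    if n_cds == 0:
        raise InputError(f"no CDS features found in {path}")
    for gene_id, reason in drop_log:
        logger.debug("skipped %s (%s) in %s", gene_id, reason, path.name)
    if not records:
        raise InputError(f"every CDS feature in {path} was skipped")
    return records


def profile_genome(
    records: list[ProteinRecord],
    table: PropertyTable,
    organism_id: str,
    role: str,
    n_skipped: int = 0,
) -> GenomeProfile:
    """Score every record and return the aligned :class:`GenomeProfile`.

    Unscorable proteins (zero residues with table entries) are dropped from
    both collections and logged; if nothing remains an
    :class:`EmptyProfileError` is raised.
    """
    kept_records: list[ProteinRecord] = []
    stats: list[GeneStats] = []
    for record in records:
        try:
            stats.append(score_protein(record.sequence, table, gene_id=record.gene_id))
        except (UnscorableProteinError, ValueError) as exc:
            logger.debug("dropped unscorable protein %s: %s", record.gene_id, exc)
            continue
        kept_records.append(record)
    if not stats:
        raise EmptyProfileError(f"no scorable protein in {organism_id}")
    return GenomeProfile(
        organism_id=organism_id,
        role=role,
        records=kept_records,
        stats=stats,
        table_name=table.name,
        n_skipped=n_skipped,
    )


def profile_to_frame(profile: GenomeProfile) -> pd.DataFrame:
    """Per-gene statistics table (one row per retained gene)."""
    rows = []
    for record, stat in zip(profile.records, profile.stats):
        row = {
            "organism_id": profile.organism_id,
            "role": profile.role,
            "gene_id": record.gene_id,
            "product": record.product,
            "is_ribosomal": record.is_ribosomal,
            "length": stat.length,
            "n_scored": stat.n_scored,
        }
        for feature in FEATURES:
            row[f"mean_{feature}"] = stat.value_for(feature)
        rows.append(row)
    return pd.DataFrame(rows)
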