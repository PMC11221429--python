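"""Amino-acid property lookup tables and per-protein mean scoring.

Every downstream statistic in this package is a *within-table* comparison
(symbiont minus relative under one fixed scale), so the absolute choice of
standard scale does not affect direction-of-difference results.  The packaged
default ships one standard published value set; any user table with the same
layout can be substituted.
"""

from __future__ import annotations

import importlib.resources
from collections import Counter
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "CANONICAL_RESIDUES",
    "FEATURES",
    "PropertyTable",
    "GeneStats",
    "TableValidationError",
    "UnscorableProteinError",
    "load_property_table",
    "score_protein",
]

#: The 20 canonical amino acids, alphabetical by one-letter code.
CANONICAL_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: Feature names understood throughout the package.
FEATURES: tuple[str, ...] = ("hydrophobicity", "amino_pka", "carboxyl_pka")

_DEFAULT_RESOURCE = "aa_properties.tsv"


class TableValidationError(ValueError):
    """A property table failed validation (missing/duplicate/bad-value row)."""


class UnscorableProteinError(ValueError):
    """A protein sequence contained zero residues with table entries."""


@dataclass(frozen=True)
class PropertyTable:
    """Immutable per-residue lookup of hydrophobicity and terminal-group pKa.

    Attributes
    ----------
    name:
        Short identifier of the scale set (recorded in every output so runs
        are self-describing).
    hydrophobicity:
        One-letter residue code -> dimensionless hydropathy value.
    amino_pka, carboxyl_pka:
        Residue -> pKa of the alpha-amino / alpha-carboxyl group (pH units).
    provenance:
        Free-text citation of the source chart.
    """

    name: str
    hydrophobicity: Mapping[str, float]
    amino_pka: Mapping[str, float]
    carboxyl_pka: Mapping[str, float]
    provenance: str = ""

    def values_for(self, feature: str) -> Mapping[str, float]:
        """Return the residue->value map for one of :data:`FEATURES`."""
        if feature not in FEATURES:
            raise ValueError(
                f"unknown feature {feature!r}; expected one of {FEATURES}"
            )
        return getattr(self, feature)


@dataclass(frozen=True)
class GeneStats:
    """Per-protein mean property values.

    ``length`` counts every symbol of the input sequence; ``n_scored`` counts
    only residues that had table entries (stops and non-canonical codes are
    excluded from the means and from ``n_scored`` but still count in
    ``length``).
    """

    gene_id: str
    mean_hydrophobicity: float
    mean_amino_pka: float
    mean_carboxyl_pka: float
    length: int
    n_scored: int

    def value_for(self, feature: str) -> float:
        if feature not in FEATURES:
            raise ValueError(
                f"unknown feature {feature!r}; expected one of {FEATURES}"
            )
        return getattr(self, f"mean_{feature}")


def _validate_column(name: str, values: dict[str, float], is_pka: bool) -> None:
    seen = set(values)
    expected = set(CANONICAL_RESIDUES)
    missing = expected - seen
    if missing:
        raise TableValidationError(
            f"column {name!r} is missing residue(s): {', '.join(sorted(missing))}"
        )
    extra = seen - expected
    if extra:
        raise TableValidationError(
            f"column {name!r} has non-canonical residue row(s): "
            f"{', '.join(sorted(extra))}"
        )
    for residue, value in values.items():
        if not (value == value and abs(value) != float("inf")):
            raise TableValidationError(
                f"column {name!r}, residue {residue!r}: non-finite value {value!r}"
            )
        if is_pka and not (0.0 < value < 14.0):
            raise TableValidationError(
                f"column {name!r}, residue {residue!r}: pKa {value} "
                "outside the open interval (0, 14)"
            )


def _parse_table_text(text: str, name: str, provenance: str) -> PropertyTable:
    hydro: dict[str, float] = {}
    amino: dict[str, float] = {}
    carboxyl: dict[str, float] = {}
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if not header_seen:
            expected = ["residue", "hydrophobicity", "amino_pka", "carboxyl_pka"]
            if [f.strip() for f in fields] != expected:
                raise TableValidationError(
                    f"line {lineno}: header must be {expected!r}, got {fields!r}"
                )
            header_seen = True
            continue
        if len(fields) != 4:
            raise TableValidationError(
                f"line {lineno}: expected 4 tab-separated fields, got {len(fields)}"
            )
        residue = fields[0].strip().upper()
        if residue in hydro:
            raise TableValidationError(f"line {lineno}: duplicate residue {residue!r}")
        try:
            h, a, c = (float(fields[i]) for i in (1, 2, 3))
        except ValueError as exc:
            raise TableValidationError(
                f"line {lineno}: non-numeric value in row for residue {residue!r}"
            ) from exc
        hydro[residue] = h
        amino[residue] = a
        carboxyl[residue] = c
    if not header_seen:
        raise TableValidationError("table file contains no header line")
    _validate_column("hydrophobicity", hydro, is_pka=False)
    _validate_column("amino_pka", amino, is_pka=True)
    _validate_column("carboxyl_pka", carboxyl, is_pka=True)
    return PropertyTable(
        name=name,
        hydrophobicity=MappingProxyType(dict(hydro)),
        amino_pka=MappingProxyType(dict(amino)),
        carboxyl_pka=MappingProxyType(dict(carboxyl)),
        provenance=provenance,
    )


def load_property_table(source: str | None = None) -> PropertyTable:
    """Load a per-residue property table.

    Parameters
    ----------
    source:
        Path to a tab-separated file with header
        ``residue\\thydrophobicity\\tamino_pka\\tcarboxyl_pka`` ('#' comment
        lines permitted).  When omitted, the packaged default value set is
        used (normalized pH-7 hydrophobicity; standard alpha-amino and
        alpha-carboxyl pKa reference values).

    Raises
    ------
    TableValidationError
        On missing or duplicate residue rows, non-numeric values, or pKa
        values outside (0, 14); the message names the offending row.
    """
    if source is None:
        text = (
            importlib.resources.files("endosym.data")
            .joinpath(_DEFAULT_RESOURCE)
            .read_text(encoding="utf-8")
        )
        return _parse_table_text(
            text,
            name="aa_properties_v1",
            provenance=(
                "Normalized hydrophobicity at pH 7 (Monera et al. 1995) and "
                "standard alpha-amino/alpha-carboxyl pKa reference-chart values"
            ),
        )
    with open(source, encoding="utf-8") as handle:
        text = handle.read()
    return _parse_table_text(text, name=str(source), provenance=f"user file {source}")


def score_protein(
    sequence: str, table: PropertyTable, gene_id: str = ""
) -> GeneStats:
    """Mean hydrophobicity and amino/carboxyl pKa over a protein's residues.

    Each mean is the arithmetic mean of the table value over exactly the
    residues present in the table.  Stop symbols (``*``) and residues without
    table entries (X, B, Z, J, U, O, ...) are excluded from the means and from
    ``n_scored`` but counted in ``length``.  Whitespace is stripped and case
    is normalized before scoring.

    Residue contributions are accumulated by residue *count* (one dot product
    of the 20 counts with the 20 table values), which makes the result exactly
    invariant under any permutation of the sequence.

    Raises
    ------
    ValueError
        If the sequence is empty after stripping whitespace.
    UnscorableProteinError
        If no residue has a table entry; the caller decides whether to skip
        or abort.
    """
    seq = "".join(sequence.split()).upper()
    if not seq:
        raise ValueError("empty protein sequence")
    counts = Counter(seq)
    hydro = table.hydrophobicity
    n_scored = sum(count for residue, count in counts.items() if residue in hydro)
    if n_scored == 0:
        raise UnscorableProteinError(
            f"protein {gene_id or sequence[:10]!r}: no residue has a table entry"
        )
    # accumulate in canonical residue order so the result is exactly
    # independent of the residue order of the input
    sums = {feature: 0.0 for feature in FEATURES}
    for residue in CANONICAL_RESIDUES:
        count = counts.get(residue)
        if not count:
            continue
        for feature in FEATURES:
            sums[feature] += count * table.values_for(feature)[residue]
    return GeneStats(
        gene_id=gene_id,
        mean_hydrophobicity=sums["hydrophobicity"] / n_scored,
        mean_amino_pka=sums["amino_pka"] / n_scored,
        mean_carboxyl_pka=sums["carboxyl_pka"] / n_scored,
        length=len(seq),
        n_scored=n_scored,
    )
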