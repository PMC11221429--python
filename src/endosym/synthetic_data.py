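"""Synthetic paired proteomes with programmed property shifts.

Stands in for downloaded genome records: generates symbiont/relative proteome
pairs whose amino-acid compositions are biased so that the symbiont member
has a controllable shift in mean hydrophobicity and/or mean amino pKa
(including the zero-shift null).  The composition bias is an exponential
tilt ``p_i proportional to base_i * exp(lambda * v_i)`` with the tilt
parameter solved so the composition's expected feature value moves by the
requested amount; this keeps compositions strictly positive and gives a
smooth one-parameter control of the target expectation.

Residues are drawn i.i.d. from the composition, so per-gene residue counts
are multinomial; :func:`simulate_pair_gene_means` exploits this to draw
per-gene mean statistics directly from the identical distribution without
materializing sequences, which makes large replicate calibrations cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .properties import CANONICAL_RESIDUES, FEATURES, PropertyTable
from .seq_io import ProteinRecord

__all__ = [
    "DEFAULT_COMPOSITION",
    "RIBOSOMAL_HYDRO_OFFSET",
    "SyntheticConfig",
    "AttainabilityError",
    "bias_composition",
    "generate_pair",
    "simulate_pair_gene_means",
    "write_fixture",
]

# Average amino-acid frequencies of well-annotated proteomes (Swiss-Prot
# release statistics), alphabetical by one-letter code; used as the
# free-living baseline composition.
DEFAULT_COMPOSITION = np.array(
    [
        0.0825, 0.0138, 0.0546, 0.0672, 0.0386, 0.0707, 0.0227, 0.0591,
        0.0580, 0.0965, 0.0241, 0.0406, 0.0474, 0.0393, 0.0553, 0.0665,
        0.0536, 0.0685, 0.0110, 0.0292,
    ]
)
DEFAULT_COMPOSITION = DEFAULT_COMPOSITION / DEFAULT_COMPOSITION.sum()

#: Hydrophobicity offset (table units) applied to the composition that
#: ribosomal genes are drawn from, in both genomes.  Ribosomal proteins are
#: cytosolic and well spread, hence less hydrophobic than the average gene.
RIBOSOMAL_HYDRO_OFFSET = -10.0

_MIN_GENE_LENGTH = 30


class AttainabilityError(ValueError):
    """The requested expectation shift lies outside the attainable range."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic symbiont/relative pair.

    Shifts are applied to the symbiont member; the relative draws from
    ``base_composition`` unchanged.  ``hydro_shift`` is in the hydrophobicity
    table's (dimensionless) units, ``pka_shift`` in pH units.
    """

    n_genes_symbiont: int = 500
    n_genes_relative: int = 500
    length_mean: float = 300.0
    length_sd: float = 150.0
    base_composition: np.ndarray = field(
        default_factory=lambda: DEFAULT_COMPOSITION.copy()
    )
    hydro_shift: float = 0.0
    pka_shift: float = 0.0
    ribosomal_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (20,):
            raise ValueError("base_composition must be a 20-vector")
        if np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("base_composition must be nonnegative and sum to 1")
        if self.n_genes_symbiont < 1 or self.n_genes_relative < 1:
            raise ValueError("gene counts must be positive")
        if not 0.0 <= self.ribosomal_fraction <= 1.0:
            raise ValueError("ribosomal_fraction must lie in [0, 1]")
        object.__setattr__(self, "base_composition", comp)


def _feature_vector(table: PropertyTable, feature: str) -> np.ndarray:
    values = table.values_for(feature)
    return np.array([values[aa] for aa in CANONICAL_RESIDUES], dtype=float)


def _tilt(base: np.ndarray, v: np.ndarray, lam: float) -> np.ndarray:
    # stable exponential tilt; renormalized to a probability vector
    w = base * np.exp(lam * v - np.max(lam * v))
    return w / w.sum()


def bias_composition(
    base: np.ndarray,
    table: PropertyTable,
    feature: str,
    target_shift: float,
) -> tuple[np.ndarray, float]:
    """Tilt a composition so its expected feature value moves by ``target_shift``.

    Returns ``(composition, achieved_shift)``; the achieved shift is the
    realized expectation difference (within 1e-6 of the target).  A target
    beyond the attainable range — the expectation is bounded by the min/max
    residue value on the support of ``base`` — raises
    :class:`AttainabilityError` stating the feasible interval.
    """
    base = np.asarray(base, dtype=float)
    if not math.isfinite(target_shift):
        raise ValueError("target_shift must be finite")
    v = _feature_vector(table, feature)
    e0 = float(base @ v)
    if target_shift == 0.0:
        return base.copy(), 0.0
    support = base > 0
    lo = float(v[support].min() - e0)
    hi = float(v[support].max() - e0)
    if not lo < target_shift < hi:
        raise AttainabilityError(
            f"target shift {target_shift:+g} for {feature} is outside the "
            f"attainable open interval ({lo:+.6g}, {hi:+.6g})"
        )

    def gap(lam: float) -> float:
        return float(_tilt(base, v, lam) @ v) - e0 - target_shift

    # gap is monotone increasing in lam; expand the bracket until it straddles 0
    scale = 1.0 / max(1.0, float(np.ptp(v)))
    lo_lam, hi_lam = -scale, scale
    while gap(lo_lam) > 0:
        lo_lam *= 2.0
    while gap(hi_lam) < 0:
        hi_lam *= 2.0
    lam = brentq(gap, lo_lam, hi_lam, xtol=1e-12, rtol=8.9e-16)
    composition = _tilt(base, v, lam)
    achieved = float(composition @ v) - e0
    return composition, achieved


def _pair_compositions(
    config: SyntheticConfig, table: PropertyTable
) -> dict[str, np.ndarray]:
    """Main and ribosomal compositions for both members, plus the truth record."""
    base = config.base_composition
    v_hydro = _feature_vector(table, "hydrophobicity")
    v_pka = _feature_vector(table, "amino_pka")
    comp_sym, _ = bias_composition(base, table, "hydrophobicity", config.hydro_shift)
    # second tilt targets the final amino-pKa expectation relative to base,
    # compensating whatever the first tilt did to it
    residual = config.pka_shift - (float(comp_sym @ v_pka) - float(base @ v_pka))
    comp_sym, _ = bias_composition(comp_sym, table, "amino_pka", residual)
    rib_rel, _ = bias_composition(base, table, "hydrophobicity", RIBOSOMAL_HYDRO_OFFSET)
    rib_sym, _ = bias_composition(
        comp_sym, table, "hydrophobicity", RIBOSOMAL_HYDRO_OFFSET
    )
    return {
        "relative": base.copy(),
        "symbiont": comp_sym,
        "relative_ribosomal": rib_rel,
        "symbiont_ribosomal": rib_sym,
    }


def _truth_record(
    config: SyntheticConfig,
    table: PropertyTable,
    comps: dict[str, np.ndarray],
    n_rib_sym: int,
    n_rib_rel: int,
) -> dict:
    """Programmed and achieved shifts; 'achieved' is the exact expected
    per-gene mean difference of the generated mixture populations."""
    f_sym = n_rib_sym / config.n_genes_symbiont
    f_rel = n_rib_rel / config.n_genes_relative
    achieved = {}
    main_shift = {}
    for feature in FEATURES:
        v = _feature_vector(table, feature)
        e_sym = (1 - f_sym) * float(comps["symbiont"] @ v) + f_sym * float(
            comps["symbiont_ribosomal"] @ v
        )
        e_rel = (1 - f_rel) * float(comps["relative"] @ v) + f_rel * float(
            comps["relative_ribosomal"] @ v
        )
        achieved[feature] = e_sym - e_rel
        main_shift[feature] = float((comps["symbiont"] - comps["relative"]) @ v)
    return {
        "programmed": {
            "hydrophobicity": config.hydro_shift,
            "amino_pka": config.pka_shift,
        },
        "achieved": achieved,
        "main_composition_shift": main_shift,
        "ribosomal_hydro_offset": RIBOSOMAL_HYDRO_OFFSET,
        "ribosomal_counts": {"symbiont": n_rib_sym, "relative": n_rib_rel},
        "table_name": table.name,
        "seed": config.seed,
    }


def _draw_lengths(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    """Truncated (redrawn) normal lengths, rounded, minimum 30 residues."""
    out = np.empty(n, dtype=np.int64)
    pending = np.arange(n)
    while pending.size:
        draw = np.rint(rng.normal(mean, sd, size=pending.size)).astype(np.int64)
        ok = draw >= _MIN_GENE_LENGTH
        out[pending[ok]] = draw[ok]
        pending = pending[~ok]
    return out


def _draw_sequences(
    rng: np.random.Generator, lengths: np.ndarray, composition: np.ndarray
) -> list[str]:
    """i.i.d. residue draws for a batch of genes sharing one composition."""
    total = int(lengths.sum())
    letters = np.frombuffer(CANONICAL_RESIDUES.encode(), dtype=np.uint8)
    indices = rng.choice(20, size=total, p=composition)
    flat = letters[indices]
    bounds = np.cumsum(lengths)[:-1]
    return [chunk.tobytes().decode() for chunk in np.split(flat, bounds)]


def _genome_records(
    rng: np.random.Generator,
    config: SyntheticConfig,
    role: str,
    main_comp: np.ndarray,
    rib_comp: np.ndarray,
) -> tuple[list[ProteinRecord], int]:
    n = config.n_genes_symbiont if role == "symbiont" else config.n_genes_relative
    n_rib = int(round(config.ribosomal_fraction * n))
    lengths = _draw_lengths(rng, n, config.length_mean, config.length_sd)
    rib_seqs = _draw_sequences(rng, lengths[:n_rib], rib_comp) if n_rib else []
    other_seqs = _draw_sequences(rng, lengths[n_rib:], main_comp) if n_rib < n else []
    prefix = "SYM" if role == "symbiont" else "REL"
    records = []
    for i, seq in enumerate(rib_seqs + other_seqs):
        ribosomal = i < n_rib
        product = (
            f"50S ribosomal protein L{i + 1}" if ribosomal else "hypothetical protein"
        )
        records.append(
            ProteinRecord(
                gene_id=f"{prefix}_{i + 1:04d}",
                product=product,
                sequence=seq,
                is_ribosomal=ribosomal,
                source_id=role,
            )
        )
    return records, n_rib


def generate_pair(
    config: SyntheticConfig, table: PropertyTable
) -> tuple[list[ProteinRecord], list[ProteinRecord], dict]:
    """Generate one symbiont/relative proteome pair plus its truth record.

    The relative draws residues i.i.d. from ``base_composition``; the
    symbiont from the composition tilted for the hydrophobicity shift and
    then for the amino-pKa shift (each achieved shift re-measured and
    reported in the truth record).  A ``ribosomal_fraction`` of genes in each
    genome is annotated as ribosomal and drawn from a composition
    additionally tilted toward lower hydrophobicity.  All randomness flows
    from one generator seeded with ``config.seed``: identical config gives
    byte-identical output.  An infeasible shift raises
    :class:`AttainabilityError` before anything is generated.
    """
    comps = _pair_compositions(config, table)  # raises on infeasible shifts
    rng = np.random.default_rng(config.seed)
    symbiont, n_rib_sym = _genome_records(
        rng, config, "symbiont", comps["symbiont"], comps["symbiont_ribosomal"]
    )
    relative, n_rib_rel = _genome_records(
        rng, config, "relative", comps["relative"], comps["relative_ribosomal"]
    )
    truth = _truth_record(config, table, comps, n_rib_sym, n_rib_rel)
    return symbiont, relative, truth


def simulate_pair_gene_means(
    config: SyntheticConfig,
    table: PropertyTable,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict]:
    """Per-gene mean statistics for one pair, without building sequences.

    Residues are i.i.d. draws, so a gene's residue counts are multinomial
    and its mean property value is ``counts @ v / length``; sampling the
    counts directly yields per-gene means with exactly the distribution that
    :func:`generate_pair` followed by scoring produces.  Used for large
    replicate calibrations (null rejection rates, coverage studies).
    """
    comps = _pair_compositions(config, table)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    vectors = {feature: _feature_vector(table, feature) for feature in FEATURES}
    out: list[dict[str, np.ndarray]] = []
    for role in ("symbiont", "relative"):
        n = config.n_genes_symbiont if role == "symbiont" else config.n_genes_relative
        n_rib = int(round(config.ribosomal_fraction * n))
        lengths = _draw_lengths(rng, n, config.length_mean, config.length_sd)
        counts = np.empty((n, 20), dtype=np.int64)
        if n_rib:
            counts[:n_rib] = rng.multinomial(lengths[:n_rib], comps[f"{role}_ribosomal"])
        if n_rib < n:
            counts[n_rib:] = rng.multinomial(lengths[n_rib:], comps[role])
        means = {
            feature: counts @ v / lengths for feature, v in vectors.items()
        }
        out.append(means)
    n_rib_sym = int(round(config.ribosomal_fraction * config.n_genes_symbiont))
    n_rib_rel = int(round(config.ribosomal_fraction * config.n_genes_relative))
    truth = _truth_record(config, table, comps, n_rib_sym, n_rib_rel)
    return out[0], out[1], truth


# --- fixture writing ---------------------------------------------------------

def _back_translation_map() -> dict[str, str]:
    """First (lexicographically smallest) codon per residue, genetic code 11."""
    forward = CodonTable.unambiguous_dna_by_id[11].forward_table
    best: dict[str, str] = {}
    for codon, aa in sorted(forward.items()):
        best.setdefault(aa, codon)
    return best


def write_fixture(
    records: list[ProteinRecord],
    organism_id: str,
    format: str,
    directory: str | Path = ".",
) -> Path:
    """Write records as an amino-acid FASTA or a minimal GenBank flat file.

    GenBank mode back-translates each peptide with genetic code 11 (first
    codon per residue; nucleotide realism is irrelevant, only parse-ability
    and strand handling are exercised), places every second CDS on the minus
    strand, and carries the exact peptide in ``/translation`` so a round trip
    through the reader reproduces the input sequences.
    """
    if not records:
        raise ValueError("write_fixture requires at least one record")
    if format not in ("fasta", "genbank"):
        raise ValueError(f"format must be 'fasta' or 'genbank', got {format!r}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if format == "fasta":
        path = directory / f"{organism_id}.faa"
        entries = [
            SeqRecord(Seq(r.sequence), id=r.gene_id, description=r.product)
            for r in records
        ]
        SeqIO.write(entries, str(path), "fasta")
        return path

    codon_of = _back_translation_map()
    spacer = "ACGTACGTAC"
    genome_parts: list[str] = []
    features: list[SeqFeature] = []
    position = 0
    for i, record in enumerate(records):
        cds = "".join(codon_of[aa] for aa in record.sequence) + "TAA"
        strand = -1 if i % 2 else +1
        segment = cds if strand == +1 else str(Seq(cds).reverse_complement())
        start, end = position, position + len(segment)
        features.append(
            SeqFeature(
                FeatureLocation(start, end, strand=strand),
                type="CDS",
                qualifiers={
                    "locus_tag": [record.gene_id],
                    "product": [record.product],
                    "transl_table": [str(11)],
                    "translation": [record.sequence],
                },
            )
        )
        genome_parts.append(segment)
        genome_parts.append(spacer)
        position = end + len(spacer)
    name = "".join(ch if ch.isalnum() else "_" for ch in organism_id)[:16]
    seqrecord = SeqRecord(
        Seq("".join(genome_parts)),
        id=name,
        name=name,
        description=f"synthetic proteome fixture for {organism_id}",
        annotations={"molecule_type": "DNA", "topology": "linear"},
        features=features,
    )
    path = directory / f"{organism_id}.gbk"
    SeqIO.write(seqrecord, str(path), "genbank")
    return path
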