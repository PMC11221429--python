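import numpy as np
import pytest

from endosym.properties import GeneStats, load_property_table
from endosym.seq_io import GenomeProfile, ProteinRecord


@pytest.fixture(scope="session")
def table():
    return load_property_table()


def make_profile(organism_id, role, sequences=None, stats=None, table=None,
                 ribosomal=None):
    """Build a GenomeProfile either from raw sequences (scored with the
    table) or from pre-cooked GeneStats values."""
    from endosym.seq_io import profile_genome

    if sequences is not None:
        ribosomal = ribosomal or [False] * len(sequences)
        records = [
            ProteinRecord(
                gene_id=f"g{i}",
                product="50S ribosomal protein L1" if rib else "hypothetical protein",
                sequence=seq,
                is_ribosomal=rib,
                source_id=organism_id,
            )
            for i, (seq, rib) in enumerate(zip(sequences, ribosomal))
        ]
        return profile_genome(records, table, organism_id, role)
    records = [
        ProteinRecord(
            gene_id=s.gene_id, product="", sequence="A", is_ribosomal=False,
            source_id=organism_id,
        )
        for s in stats
    ]
    return GenomeProfile(
        organism_id=organism_id, role=role, records=records, stats=list(stats),
        table_name="test",
    )


def stats_from_values(values, feature="hydrophobicity"):
    """GeneStats whose chosen feature takes the given per-gene values."""
    out = []
    for i, v in enumerate(values):
        fields = {
            "mean_hydrophobicity": 0.0,
            "mean_amino_pka": 9.0,
            "mean_carboxyl_pka": 2.0,
        }
        fields[f"mean_{feature}"] = float(v)
        out.append(GeneStats(gene_id=f"g{i}", length=10, n_scored=10, **fields))
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240620)


def write_structural_manifest(directory):
    """Seven FASTA pairs engineered so exactly one of the 14 comparisons
    (pair 7's amino pKa) disagrees with the predicted directions; pairs 1
    and 2 share a merge group.  Returns the manifest path."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    agree_sym = ["F" * 40 + "M" * 10] * 5          # hydrophobic, low amino pKa
    agree_rel = ["G" * 40 + "S" * 10] * 5          # hydrophilic, higher pKa
    discord_sym = ["C" * 40 + "P" * 10] * 5        # hydrophobic but HIGH pKa
    discord_rel = ["G" * 50] * 5
    rows = ["pair_id\tsymbiont_path\tsymbiont_label\trelative_path\trelative_label\tgroup\tnotes"]
    for i in range(1, 8):
        sym_seqs = discord_sym if i == 7 else agree_sym
        rel_seqs = discord_rel if i == 7 else agree_rel
        sym_path = directory / f"sym{i}.faa"
        rel_path = directory / f"rel{i}.faa"
        sym_path.write_text(
            "".join(f">s{i}_{j} hypothetical protein\n{s}\n" for j, s in enumerate(sym_seqs))
        )
        rel_path.write_text(
            "".join(f">r{i}_{j} hypothetical protein\n{s}\n" for j, s in enumerate(rel_seqs))
        )
        group = "spheroid" if i in (1, 2) else ""
        rows.append(f"p{i}\t{sym_path.name}\tS{i}\t{rel_path.name}\tR{i}\t{group}\t")
    manifest = directory / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
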