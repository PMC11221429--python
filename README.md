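# endosym

Comparative hydropathy and pKa analysis of endosymbiont and organelle
genomes versus their free-living relatives.

## The problem

As endosymbionts coevolve with their hosts toward becoming integrated
organelles, their genomes erode — genes are lost or transferred to the host
nucleus — and the retained subset is biased. Two per-protein features track
retention: genes encoding proteins with **higher mean hydrophobicity**
(hard-to-import proteins resist relocation) and **lower mean α-amino pKa**
are preferentially kept in the symbiont/organelle genome. `endosym` turns
that comparison into a tested, reusable pipeline for anyone with genome
records of a symbiont and a free-living relative: molecular evolution and
symbiosis researchers who want to score new partnerships as they are
sequenced.

## The statistic

For each protein with residues r₁…r_L and a per-residue lookup v(·), the
score is the mean over scorable residues, x̄ = (1/n) Σ v(rᵢ), computed for
three scales: a hydrophobicity index and the α-amino and α-carboxyl pKa.
Each genome is summarized by the unweighted mean of x̄ over its genes. For a
partnership *j*, the direction of Δⱼ = (symbiont mean − relative mean) is
compared with the predicted sign (+ for hydrophobicity, − for amino pKa);
with k agreements among n comparisons, significance against the
no-difference null is the exact binomial upper tail

    P(B ≥ k),  B ~ Binomial(n, 1/2),

evaluated in rational arithmetic (e.g. P(B ≥ 13 | n = 14) = 15/16384
≈ 9.2 × 10⁻⁴). Partnerships that reflect the same evolutionary case can be
merged via a manifest group; a merged group counts as one observation,
agreeing only if unanimous. Whole proteomes enter each comparison, so no
per-pair test is (or should be) computed — pairs contribute effect sizes
and directions; inference lives at the partnership level.

A synthetic proteome-pair generator (exponential tilting of an amino-acid
composition toward programmed hydrophobicity/pKa shifts, with a ribosomal
sub-population and GenBank/FASTA fixture writers) makes every stage of the
pipeline testable without downloading anything.

## Worked example

Generate three synthetic partnerships with programmed shifts
(+8 hydrophobicity units, −0.1 pH units amino pKa), then run the full
analysis:

```python
from endosym import SyntheticConfig, generate_pair, load_property_table, write_fixture

table = load_property_table()
rows = ["pair_id\tsymbiont_path\tsymbiont_label\trelative_path\trelative_label\tgroup\tnotes"]
for i in range(1, 4):
    cfg = SyntheticConfig(n_genes_symbiont=300, n_genes_relative=300,
                          hydro_shift=8.0, pka_shift=-0.1, seed=i)
    sym, rel, truth = generate_pair(cfg, table)
    sp = write_fixture(sym, f"sym{i}", "genbank", ".")
    rp = write_fixture(rel, f"rel{i}", "fasta", ".")
    rows.append(f"p{i}\t{sp.name}\tS{i}\t{rp.name}\tR{i}\t\t")
open("manifest.tsv", "w").write("\n".join(rows) + "\n")
```

```sh
$ endosym --outdir out --seed 1 run manifest.tsv
sign test: k=6 n=6 p=0.0156
out
```

All six comparisons (3 pairs × 2 features) agree with the predicted
directions, and P(B ≥ 6 | n = 6) = 1/2⁶ = 0.0156. The output directory
contains `per_gene.tsv` (every gene's means), `pairs.tsv`, `signtest.tsv`,
`correlation.tsv`, `stratified.tsv` (ribosomal vs non-ribosomal strata),
`figure.png` (paired boxplots with jittered gene points) and
`run_metadata.json` (table provenance, versions, seeds, skip counts). The
first data row of `pairs.tsv`:

```
symbiont_id  relative_id  feature         symbiont_mean  relative_mean  difference  predicted_sign  agrees
S1           R1           hydrophobicity  26.8896        21.7785        5.1110      1               True
```

The measured +5.11 hydrophobicity difference sits near the generator's
achieved shift for this configuration (the sequential pKa tilt pulls the
realized hydrophobicity shift somewhat below the programmed +8; the
generator's truth record reports the achieved value, here +5.40, and the
difference is within sampling error of it).

To analyze real partnerships, fetch the accessioned GenBank records
yourself, list them in a manifest, and run the same command; the per-pair
agreement table makes any headline k-of-n count fully auditable. Subcommands
`score`, `compare`, `signtest`, `simulate` and `figure` expose the
individual stages; `--table` swaps in a custom property table.

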