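# Methods

## The question and the statistic

As an endosymbiotic relationship matures toward an integrated organelle, the
symbiont genome erodes: genes are lost outright or transferred to the host
nucleus. The genes that *stay* are not a random sample. Two per-protein
features have been found to track retention propensity: mean residue
hydrophobicity (retained proteins tend to be more hydrophobic, plausibly
because hydrophobic proteins are hard to import back into the compartment if
encoded elsewhere) and mean α-amino pKa (retained proteins tend to have
lower values, possibly reflecting compartmental pH and the chemistry of
peptide-bond formation).

This package implements the comparative form of that test. For each
partnership — one endosymbiont or organelle genome paired with a free-living
relative — it scores every encoded protein, averages each feature over genes
(unweighted: each gene counts once regardless of length, matching gene-level
distribution displays), and records the *direction* of the
symbiont-minus-relative difference for each feature. Because the entire
proteome of each genome is used, there is no within-pair sampling noise to
model; each pair contributes an effect size and a direction, nothing more.
Inference happens at the partnership level: if hydrophobicity and amino pKa
carry no signal, each direction is a fair coin, so the count k of agreements
with the predicted directions (+ for hydrophobicity, − for amino pKa) among
n comparisons follows Binomial(n, 1/2), and the reported p-value is the
exact upper tail P(B ≥ k), evaluated in rational arithmetic.

Ties (a difference of exactly zero) count as disagreements — conservative
for the one-sided alternative, and measure-zero for real data. Partnerships
that arguably reflect the same evolutionary case (e.g. two closely related
spheroid-body symbioses) can be merged via a manifest group: a merged group
contributes a single Bernoulli observation, agreeing only if unanimous
(again conservative; disagreement otherwise). The α-carboxyl pKa is computed
and exported for every gene but excluded from the headline sign test, since
no retention direction is predicted for it; `compare_pair` therefore demands
an explicit `predicted_sign` before it will judge carboxyl-pKa agreement.

## Scoring

A protein's score for a feature is the arithmetic mean of a per-residue
lookup value over exactly the residues present in the table. Stop symbols
(`*`) and non-canonical codes (X, B, Z, J, U, O) are excluded from the mean
and from `n_scored` — skipping, not imputing, because imputation would
inject invented values — but still count toward `length`. There is no
minimum-length filter: a protein is unscorable only when *zero* residues
have table entries.

The packaged default table (`data/aa_properties.tsv`, version-stamped and
provenance-stamped) uses the normalized hydrophobicity index at pH 7
(Monera et al. 1995; Gly = 0, Phe = 100) and standard reference-chart values
for the free amino acids' α-amino and α-carboxyl pKa. Both scales are the
ones tabulated on common amino-acid reference charts. The choice of pH-7
over pH-2 hydrophobicity is documented here precisely because published
chart sources carry both columns; every output records the table name, so a
run is self-describing and any user-supplied table with the same layout can
be swapped in. All downstream statistics are within-table comparisons, so
direction-of-difference results are invariant to any consistent standard
choice.

Numerically, scoring accumulates per-residue contributions grouped by
residue, iterated in canonical residue order (one dot product of 20 counts
with 20 values in double precision). This makes the result exactly
invariant under permutation of the sequence — an invariant the test suite
asserts bitwise — and agrees with a naive residue-by-residue loop to well
below 1e-12 for any protein of realistic length. No compensated summation
is used; at < 10^5 residues the rounding error is orders of magnitude below
the tolerances that matter.

## Sequence ingestion

GenBank CDS extraction prefers the annotation's own `/translation`
qualifier; only when it is absent is the nucleotide span extracted
(strand-aware, `join()`-aware, via Biopython) and translated with NCBI
genetic code 11, the bacterial/plastid code appropriate for
bacteria-derived symbionts and organelles, trimming one terminal stop.
Features marked `pseudo`, or whose translation fails, are skipped and
counted (`n_skipped`), each with a logged reason; a malformed feature is
never fatal, but a file with zero usable CDS features is. Gene identifiers
follow the precedence locus_tag > protein_id > `cds_<index>`, with duplicate
locus tags suffixed `_2`, `_3`, … so per-gene joins stay stable.
Coordinates are stored half-open 0-based internally (Biopython's
convention), converted once at parse time.

Ribosomal identity comes from annotation alone — one documented regular
expression matching either the phrase "ribosomal protein" or an
rps/rpl/rpm-style gene-name token, case-insensitively. A gene with no
product annotation is classified non-ribosomal: the classifier defaults to
False because an empty annotation cannot assert ribosomal identity. This is
a documented package choice, not an inference about upstream pipelines.

## The synthetic-genome-pair generator

Real inputs are accessioned genome records, which the pipeline consumes
from local files; testing instead uses generated pairs whose ground truth
is known. The generator emulates the relevant features of those records:
proteome sizes of 50–2,000 genes (default 500 per genome), lengths from a
truncated normal (default mean 300, SD 150, minimum 30 residues — typical
bacterial protein lengths), a baseline amino-acid composition taken from
average well-annotated proteome frequencies (Swiss-Prot release
statistics), a ribosomal fraction (default 0.10) of genes annotated
"50S ribosomal protein L<i>" and drawn from a composition tilted 10
hydrophobicity units lower (ribosomal proteins are cytosolic and
comparatively hydrophilic), and programmed symbiont shifts in mean
hydrophobicity and mean amino pKa.

The shift mechanism is exponential tilting: p_i ∝ base_i · exp(λ v_i) with
v the residue value vector, λ solved by monotone one-dimensional
root-finding (Brent) so the tilted composition's expectation moves by the
requested amount, to within 1e-6. Tilting keeps compositions strictly
positive and gives a smooth one-parameter control; a target beyond the
attainable range (the expectation is bounded by the extreme residue values
on the support) raises an error stating the feasible interval. The two
shifts are applied sequentially — hydrophobicity first, then a compensating
amino-pKa tilt targeting the final pKa expectation — rather than jointly
moment-matched; the second tilt slightly perturbs the first feature's
expectation, which is why the truth record reports *achieved* shifts
(exact expectations of the realized mixture of main and ribosomal
compositions) alongside the programmed ones, and all recovery tests compare
against the achieved values.

Residues are drawn i.i.d. from the composition, so a gene's residue counts
are multinomial and its mean property value is `counts · v / length`.
`simulate_pair_gene_means` samples the counts directly and yields per-gene
means with *exactly* the distribution of generate-then-score, at a small
fraction of the cost; large replicate calibrations (the 2,000-replicate
null study) use this route, while everything that exercises sequence
handling (round trips, the 200-replicate recovery study) generates real
sequences and scores them through the full pipeline.

What the generator does not emulate: codon usage, GC content, synteny,
annotation noise, and — deliberately — phylogenetic correlation between
pairs. Real partnerships share ancestry, so the binomial null treats as
independent observations that are not fully independent; the generator's
pairs actually are independent. Passing calibration tests therefore
validates the machinery and the statistic's behavior under its stated
assumptions, not the biological independence of real partnerships.

GenBank fixtures are written with back-translated nucleotide spans (first
codon per residue under code 11 — nucleotide realism is irrelevant; only
parse-ability matters), every second CDS on the minus strand to exercise
strand handling, and the exact peptide in `/translation`, so a
generate → write → read → score round trip reproduces per-gene statistics
bit-for-bit.

## Calibration and problem sizes

The shipped studies use 500 genes per genome with 200 replicates for shift
recovery (programmed +0.3 hydrophobicity, −0.15 pH units amino pKa; a
replicate passes when both measured differences fall within 3 standard
errors of the achieved shifts) and 2,000 replicates of a 7-pair × 2-feature
null sign test (rejection threshold α = 10⁻³, expected rejection rate
= P(B ≥ 13) ≈ 9.2 × 10⁻⁴). These sizes put the Monte Carlo error of both
rates well below the margins being asserted while keeping a full run of the
suite and the acceptance script in the low minutes on a single core.

## Known limitations

- Pearson's r² is used for the gene-by-gene feature correlation (the
  conventional reading of r²); Spearman is not exposed. The choice is
  recorded in the correlation output metadata.
- The regression model that *predicts* retention indices from these
  features is out of scope; this package tests direction agreement only.
- Reproducing published per-organism distributions and the real 13/14
  agreement count requires the accessioned genome records; the pipeline
  runs on such user-fetched files and its per-pair agreement table makes
  the count auditable, but no network access is attempted.
- Eukaryotic nuclear gene models (introns, GFF+FASTA pairing) are not
  parsed; inputs are GenBank flat files or amino-acid FASTA.
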