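# dicistro

Comparative-genomics toolkit for small dicistronic picorna-like RNA
viruses of insects (SINV-3/APV/KFV-like genomes): ~10-kb polyadenylated
positive-sense genomes with two long ORFs, in which the structural
proteins are expressed both from the genomic RNA and from a
3'-coterminal subgenomic RNA (sgRNA), and a capsid-extension protein is
made by −1 programmed ribosomal frameshifting at the ORF1/ORF2 overlap.

The package is aimed at virologists and comparative genomicists who want
to run, on their own genomes and alignments, the sequence analyses that
establish this expression strategy:

* **Synonymous-site conservation profiling** (`dicistro.syncon`): NG86
  synonymous opportunities per codon; per-window observed vs expected
  synonymous change under a global neutral rate p̂ = Σobs/Σsites, with a
  one-tailed Poisson depletion p-value P(X ≤ obs_w | p̂·sites_w) over a
  sliding window (default 25 codons).  Depleted windows flag overlapping
  elements (sgRNA promoters, overlapping genes, RNA structures).
* **ORF/frameshift scanning** (`dicistro.orfscan`): stop maps in the
  three forward frames, stop-to-stop and AUG-to-stop ORFs, slippery
  heptamers of the X_XXY_YYZ class (e.g. U_UUA_AAC) with codon-phase
  checking, ORF-overlap cassettes rendered with ORF1 phasing
  (U_GAU_UUA_AAC_UGA), and Kozak-like start-context calls (strong iff
  purine at −3 or G at +4).
* **Repeat statistics and sgRNA 5'-end inference** (`dicistro.repeats`):
  maximal exact repeats, the chance probability C(L−k+1,2)·4⁻ᵏ of a
  k-mer repeat in an L-nt genome, Hamming comparison of near-exact
  duplicates, and ungapped similarity scans of internal windows against
  the genomic 5' terminus, each hit implying an sgRNA length
  L − start + 1.
* **Product/mass bookkeeping** (`dicistro.products`): translation,
  transframe fusion assembly across the slippery site (0-frame through
  XXY, resume in the −1 frame at YYY), average masses (residues + one
  water), and cleavage arithmetic (fragments sum to precursor + one
  water per cut).
* **Synthetic data** (`dicistro.synthetic_data`): seeded generators of
  diverged CDS pairs with logged substitutions and of toy dicistronic
  genomes with fully known planted features, so every stage is testable
  offline.
* **Pipeline + CLI** (`dicistro.pipeline`, `dicistro` command):
  per-genome annotation reports (JSON/GFF3/TSV/peptide FASTA) and
  per-alignment conservation profiles.

## Worked example

The analysis drivers under `analysis/` are thin narrative scripts over
the library.  `analysis/03_annotate_toy_genome.py` builds a miniature
dicistronic genome with known planted features and runs the full
annotation:

```text
$ python analysis/03_annotate_toy_genome.py
genome toy_genome_seed0: 1321 nt (config 535a5c3bcbed)
  planted ORF1 (92, 814) frame 1; recovered ORFs: [((41, 814), 1)]
  slippery heptamer at 805 (planted 805), cassette (802, 814) rendered U_GAU_UUA_AAC_UGA (offset -1)
  exact repeat (13, 36) x (652, 675) (24 nt), chance probability 2.99e-09
  terminal match at 640 identity 0.972 -> implied sgRNA length 682 nt (planted start 640, length 682)
  first AUGs on toy sgRNA: [(679, 'weak', '+2'), (737, 'weak', 'ORF'), (753, 'weak', '+1')]
  product nonframeshift: 25 aa, 2.9 kDa
  product transframe: 176 aa, 20.0 kDa
  transframe product consistent with planted peptide: True
```

Reading the output: the scanner found the planted −1 frameshift cassette
in phase with ORF1 and rendered it with ORF1 codon phasing; the 24-nt
exact repeat occurs once in the 5' UTR and once inside ORF1 (its chance
probability in a genome this size is ~3×10⁻⁹, so it would not occur by
accident); the internal near-duplicate of the genomic 5' terminus marks
the toy sgRNA start at nt 640, implying a 682-nt sgRNA; and the product
catalog contains the non-frameshift product and the transframe fusion
with their average masses.  On a real 10386-nt genome the same machinery
reports, e.g., a chance probability of 1.9×10⁻⁷ for a 24-nt repeat and
an implied sgRNA length of 3735 nt for a terminal match at nt 6652
(`analysis/04_repeat_statistics.py` prints the first of these).

`analysis/02_syncon_calibration.py` measures the depletion statistic's
behaviour on 200 neutral and 50 planted-window simulated alignments
(tables in `results/`): the discrete Poisson lower tail is conservative
(pooled fraction of p<0.05 windows ≈ 0.014 under the null), and a fully
suppressed 50-codon window is detected with ratio ≈ 0 and localized to
within about half a scan window.

Genome FASTAs are annotated from the shell:

```bash
dicistro annotate --fasta genome.fa --min-orf 100 --kmin 20 \
    --window 35 --min-identity 0.7 --out outdir/
dicistro syncon --alignment aligned_cds.fa --window 25 --out outdir/
dicistro synth --spec batch.cfg --out fixtures/
```

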