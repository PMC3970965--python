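# Methods

`dicistro` implements the comparative-genomics toolkit used to dissect the
gene-expression strategy of small dicistronic picorna-like RNA viruses of
insects (SINV-3-, APV- and KFV-like genomes): two long ORFs on a ~10-kb
polyadenylated positive-sense genome, structural proteins expressed both
from the genomic RNA and from a 3'-coterminal subgenomic RNA (sgRNA), and
a capsid-extension protein made by −1 programmed ribosomal frameshifting
at the ORF1/ORF2 junction.  This note records the models, the parameters
that matter, and the design choices made where the design was open.

## Coordinates and alphabets

All public coordinates are 1-based inclusive, matching GenBank feature
tables, so printed genome positions can be used directly.  Sequences are
canonicalized internally to DNA (`U → T`, upper case); RNA spelling is a
rendering concern (phased cassette strings are printed with `U`).  IUPAC
ambiguity codes are accepted in input but treated as mismatches by every
comparison operation — a deliberately conservative default: an ambiguous
base can never support a repeat, a terminal match, or a synonymous-site
count.

## Synonymous-site conservation (`syncon`)

Overlapping functional elements — sgRNA promoters, overlapping genes,
frameshift-stimulatory structures — constrain nucleotide choice at codon
positions that are otherwise free to vary, so a local deficit of
synonymous change between two homologous coding sequences flags such
elements.  The statistic:

1. **Opportunity.** Each sense codon's synonymous-site count follows
   NG86-style enumeration: at each codon position, the fraction of the
   three single-nucleotide changes that preserve the amino acid,
   summed over positions (changes creating stops count as
   nonsynonymous).  E.g. TTT → 1/3, CTC → 1, ATG → 0.
2. **Counting.** For each reference codon and each unordered sequence
   pair whose codons are gap-free, unambiguous, non-stop and encode the
   *same* amino acid, the observed count is the number of differing
   nucleotide positions and the opportunity is the mean of the two
   codons' site counts.  Pairs encoding different amino acids are
   excluded entirely rather than path-counted: this discards some true
   synonymous changes (multi-hit codons), i.e. it biases the test
   *against* finding depletion, which is the conservative direction for
   a depletion screen.
3. **Null and p-value.** A single global synonymous rate per site,
   p̂ = Σobs/Σsites, is estimated from the whole alignment.  For a
   sliding window (default 25 codons, step 1; 15 codons available), the
   expected count is exp_w = p̂·sites_w and the depletion p-value is the
   one-tailed Poisson probability P(X ≤ obs_w).  Poisson rather than
   binomial because opportunities are fractional; windows are full-width
   only and windows without opportunity are omitted.
4. **Multiple sequences** are handled by summing over all unordered
   pairs, ignoring phylogenetic non-independence.  For two-sequence
   comparisons (the APV/RAAV-style case this package targets)
   pair-summation is exact; for larger alignments the p-values are
   optimistic and should be read as ranking scores.  A phylogeny-aware
   null is out of scope.

### Calibration behaviour (measured, `analysis/02_syncon_calibration.py`)

Under the default neutral study conditions (3000-codon pairs, per-lineage
synonymous rate 0.25/site, nonsynonymous rate 0.03/site, giving measured
pairwise p̂ ≈ 0.38 and ~13% amino-acid divergence), the pooled fraction of
windows with p < 0.05 over 200 seeded replicates is **0.014**, not 0.05:
with window expectations around exp_w ≈ 6, the discrete Poisson lower
tail can only realize achieved levels on a sawtooth well below the
nominal level.  The test is therefore *valid but conservative* at these
window means; p-values should be read as upper bounds on the false-alarm
rate, not as uniformly distributed under the null.

Power: with a planted 50-codon window in which synonymous change is fully
suppressed (multiplier 0) at pairwise p̂ ≈ 0.30 (per-lineage rate 0.20 on
600-codon pairs), the minimum-p window falls within ±25 codons of the
planted center in ~90% of replicates and within ±13 codons in ~50%; the
ratio inside the planted window drops to ~0 with p < 0.01.  The dip is
thus reliably *detected and localized to within about half a scan
window*; sharper localization is limited by zero-count windows that
partially overlap the planted element, an intrinsic property of sliding
fixed-width windows.

## ORF scanning and the frameshift cassette (`orfscan`)

Scanning is forward-strand only (these are positive-sense genomes, and
the published analyses use the three forward frames).  Frames are
labelled 0/1/2 by the offset mod 3 of the first codon base from position
1.  `stop_to_stop` ORFs are runs of sense codons between consecutive
in-frame stops, with the terminal stop included in the coordinates (so
ORFs and leftover stops exactly partition each frame) but excluded from
translation; `aug_to_stop` anchors each run at its first AUG.

The −1 frameshift motif class is X_XXY_YYZ with homopolymeric XXX,
YYY ∈ {AAA, UUU} and Z ≠ G — covering the canonical U_UUA_AAC cassette of
these viruses while excluding motifs they never use; the YYY set is
configurable.  A hit is *in phase* when its first base is the third base
of a codon of the designated ORF, so the 0-frame reads `…_XXY_YYZ_…`.
The junction convention for the transframe product is tandem-slippage
re-pairing: translate the 0-frame through XXY, resume in the −1 frame at
YYY (one nucleotide read twice).  Alternative conventions shift the
fusion by at most one residue; the choice is a single constant.

The natural ORF1/ORF2 overlap of these genomes is printed as the 13-nt
cassette `U_GAU_UUA_AAC_UGA`, whose first three bases are themselves the
−1-frame stop bounding the extended ORF2.  Because `stop_to_stop` ORFs
include only their terminal stop, the raw intersection of ORF1 with the
extended ORF2 is 10 nt; `extend_orf_upstream` pulls in the immediate
upstream bounding stop, and the pipeline uses it when forming the
cassette so the full 13-nt rendering is reported.

Start-codon (Kozak-like) context: the call is **strong** iff the −3 base
is a purine (A/G) *or* the +4 base is G, else **weak** — the disjunctive
rule, since A at −3 alone is treated as strong in this literature.  The
−3/+4 bases are reported so stricter rules can be applied downstream.
AUGs too close to a sequence edge are flagged (call `None`), not errors.

## Repeats and sgRNA 5'-end inference (`repeats`)

Calicivirus-like sgRNA promoters recapitulate the genomic 5' end, so an
internal (near-)duplicate of the genomic 5' terminus marks the sgRNA
start, and its position implies the sgRNA length (genome length −
internal start + 1, excluding the poly(A) tail's variable part).

* **Exact repeats**: all maximal (left/right-inextensible) repeated
  substring pairs of length ≥ k, by k-mer seeding plus extension —
  genomes here are ≤ ~11 kb, so quadratic worst cases are acceptable and
  suffix structures are not used.  Trailing poly(A) runs (≥ 10 A's) are
  masked by default because homopolymer tails generate spurious repeats.
* **Chance probability**: the expected number of identical unordered
  k-mer position pairs in an i.i.d. uniform 4-letter sequence,
  C(L−k+1, 2)·4⁻ᵏ, capped at 1 — a Bonferroni-style bound.  For a 24-nt
  repeat in a 10386-nt genome this evaluates to 1.9×10⁻⁷.
* **Terminal similarity**: ungapped identity between the genomic
  5'-terminal window and every internal window; no indels are modelled,
  matching how such terminal alignments are inspected in practice.  The
  scan reports candidates only; it does not adjudicate single-nucleotide
  offsets that only 5' RACE can settle.

## Protein products and masses (`products`)

Products are assembled from coding segments (region + frame); the
transframe product has two segments meeting at the slippery site.
Masses are **average** (not monoisotopic): sum of standard average
residue masses plus one water (18.02 Da), N-terminal methionine
retained, no post-translational modifications — appropriate for gel-scale
(kDa, one decimal) comparisons.  Cleavage takes an explicit list of
inter-residue sites and labels; the package annotates flanking residues
(e.g. `Q|M`, the picorna-like protease signature) but never asserts a
site the user did not supply, because such sites are typically not
definitively localized.  Mass bookkeeping is exact: fragments of a
precursor sum to the precursor mass plus one water per cut.

## Synthetic data (`synthetic_data`)

The generators define the study conditions for every offline test.

**Diverged CDS pairs.**  An ancestor is drawn codon-uniform over the 61
sense codons; each lineage receives per-codon Poisson numbers of
synonymous and nonsynonymous substitutions with NG86 opportunities
evaluated on the ancestral codon, applied sequentially with
re-classification after each event; stops are never created; every event
is logged (position, bases, class), and replaying the log onto the
ancestor reproduces each descendant exactly.  Defaults — 3000 codons,
synonymous rate 0.25/site/lineage, nonsynonymous 0.03/site/lineage —
emulate a full dicistronic polyprotein alignment between two viruses at
~13% pairwise amino-acid divergence with substantial synonymous
divergence.  Power runs use 600-codon pairs at synonymous rate
0.20/lineage, which delivers measured pairwise p̂ ≈ 0.30.  Back-mutation
bookkeeping is omitted (rates ≪ 1); alignments are gap-free; codon usage
is uniform.  Real alignments add indels, codon bias and rate
heterogeneity, so passing tests demonstrate correctness of the counting
and calibration machinery, not robustness to alignment error.

**Toy dicistronic genomes.**  A miniature genome with the SINV-3
architecture at recorded coordinates: a 91-nt 5' UTR whose first 36 nt
recur internally (with a configurable number of mismatches) as the toy
sgRNA 5' end; a 24-nt exact repeat occupying the 3' end of that terminal
window (so the repeat's second copy rides inside the duplicate, as in
the natural genome); ORF1 ending in the exact cassette
`U_GAU_UUA_AAC_UGA`; an extended −1-frame ORF2; a poly(A) tail.
Construction is by rejection sampling with derived seeds until the
planted features are exactly recoverable: no splice-induced premature
stops, repeat maximality respected (a mismatch is forced immediately
5' of the repeat copy and the bases after both copies differ), and no
accidental in-phase slippery heptamer upstream of the ORF1 stop.  With
zero mismatches the two terminal windows merge into a single longer
maximal repeat, and the truth annotation records that merged repeat.
Everything the generator plants — coordinates, heptamer, cassette
rendering, expected transframe peptide — is returned as the truth
oracle.

## Pipeline and reproducibility

`annotate_genome` runs orfscan → repeats → products and cross-links the
stages (slippery site → overlap cassette; best terminal match → sgRNA
start → AUG survey → designated structural-protein start).  On the sgRNA,
the designated start is the first ORF1-frame AUG at or downstream of the
inferred sgRNA 5' end.  Reports serialize to JSON/GFF3/TSV with a config
hash recorded in every output; identical config and input give
byte-identical outputs.  All randomness in the package flows through
explicit integer seeds (NumPy `default_rng` / `SeedSequence`).

## Known limitations

* The depletion null is a single-rate Poisson screen, not the
  phylogeny-aware method used in the antecedent literature; absolute
  p-value traces from that method are not reproducible here, only the
  qualitative depletion signal.
* The discrete lower-tail p-value is conservative at small window
  expectations (see calibration above).
* No reverse-strand analysis, no indel-aware terminal similarity, no
  frameshift-efficiency or RNA-structure prediction, no protease
  specificity prediction.
* Repeat significance is computed for exact repeats only; near-exact
  duplicates are compared (Hamming) but not assigned probabilities.
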