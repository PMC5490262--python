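# Methods

## Classification model

A gene is reduced to the spliced CDS of one canonical transcript — the
isoform with the longest CDS, ties broken by the lexicographically smallest
transcript id so outputs are deterministic. Junction offsets count the
spliced-CDS nucleotides strictly upstream of each internal exon–exon
junction, in translation orientation; UTR-containing exon structure is not
modelled, because the positional rules are evaluated on coding-sequence
coordinates. All coordinates are held 0-based half-open internally (GTF is
read as 1-based inclusive, BED12 as 0-based half-open), so only one
arithmetic convention exists in the code.

Wild-type pre-filters remove genes that cannot be classified sensibly:
an in-frame stop before the final codon (`wt_ptc`), a CDS not starting with
ATG (`no_start`), a CDS whose final in-frame codon is not a stop, including
non-codon-multiple lengths (`no_stop`), and gene identifiers mapping to
more than one locus (`duplicate_id`).

Mutation-level filters mirror standard somatic practice: splice/UTR/
intergenic variant classes are excluded; any mutation whose genomic
footprint is not fully inside a single CDS exon is excluded as
splice-proximal (insertions must have both flanking bases in one exon);
records whose reference allele disagrees with the extracted CDS are
dropped; exact duplicate annotations (same gene, sample, position and
alleles) are collapsed on genomic identity, while distinct mutations of one
gene in one sample are all retained. MAF alleles are taken as
forward-strand and reverse-complemented onto minus-strand genes. Insertions
use the MAF flanking convention: `cds_pos` is the base after which the new
bases sit, in translation orientation.

For each kept mutation the CDS is edited, and junction offsets strictly
downstream of the edit move by `len(alt) − len(ref)`; offsets are
recomputed rather than reused because the mature mutant transcript, not the
wild type, is what the ribosome and the exon-junction complexes see. The
ORF is then relocated: the most upstream start codon anywhere in the
mutated sequence (default start set {ATG}; alternative initiators can be
added via `NmdConfig.start_codons`), followed by an in-frame triplet walk
to the first stop (TAA/TAG/TGA). A stop is premature iff its third base is
not the final base of the mutated sequence; this makes silent and
normal-stop variants non-PTC without special-casing. Start-codon loss with
a rescue ORF is handled by the same relocation and flagged
`start_relocated`; no stop at all is flagged `nonstop`.

### Distance conventions and thresholds

`d_start` is measured first-base-of-start to first-base-of-PTC;
`d_junction` from the base after the PTC's third base to the last junction.
Both rules are strict inequalities: elicit requires `d_junction > 50` and
`d_start > 200` (and ≥ 2 exons). The thresholds are configuration keys
(`junction_min_bp`, `start_min_bp`) since the junction bound is sometimes
quoted as 50–54 nt.

A consequence worth noting: because the PTC is found by in-frame scanning
from the start codon, `d_start` is always a multiple of 3 under these
conventions. Exact boundary behaviour at 200 vs 201 is therefore pinned on
the rule predicate directly, and the sequence-level boundary fixtures use
the nearest codon-aligned distances 174 and 198 (escape) versus 201
(elicit); 174 mirrors the characteristic near-miss failure mode of
PTCs falling just short of the start-proximity rule.

Multiple mutations of one gene in one sample are classified independently
against the wild-type CDS by default; an opt-in combined mode applies them
jointly in descending coordinate order (one call per gene+sample).
Overlapping edits within one sample are not supported in combined mode.

## Expression statistics

The background for a gene × cancer is the expression of that gene in
same-cancer samples (restricted to the same expression cluster when labels
exist) with no somatic mutation of any class in the gene and a thresholded
copy-number call of 0; backgrounds smaller than `min_n` (default 8) are
reported undefined rather than used. REV uses midranks, so REV ∈ (0,1] and
is uniform on {k/(n+1)} under the null; low REV = low expression. Group
comparisons report both group medians and their ratio, a Mann–Whitney p
(exact for small tie-free groups, normal approximation with tie correction
otherwise) and a Welch t-test, with degenerate (zero-variance) inputs
flagged instead of tested.

The z-score uses pooled midranks: `U_mut = rank_sum(mut) − N2(N2+1)/2`,
`z = U_mut/(N1·N2)`; `U_wt + U_mut = N1·N2` exactly, and z equals the
tie-corrected win probability P(mut > wt) + ½P(mut = wt) (verified against
brute-force pair counting to 1e−12). The mutant-group U (not min(U1,U2)) is
used so that low z always means depressed mutant expression. Tier bounds
are inclusive on the left: z ≤ 0.3 sensitive, ≤ 0.4 intermediate, else
insensitive; genes with fewer than three elicit mutants are discarded with
a reason.

## Cohort analyses

Hypermutation labels are strict: > 1,000 filtered mutations is hyper,
< 100 non-hyper, the band between is excluded from enrichment. Per-gene
enrichment compares NMD-elicit counts against silent-class counts (Silent,
3'UTR, 5'UTR, Intron, RNA) between strata. The normalised ratio is a double
quotient with ½ pseudo-counts — each stratum's elicit:silent quotient is
first divided by the cohort-wide totals of each mutation type in that
stratum — which cancels global negative selection against NMD-elicit
mutations; the raw 2×2 counts are always emitted so alternative
normalisations can be recomputed. Fisher's exact test is two-sided (the
standard choice for an enrichment screen), BH-adjusted across genes.
Mutation events are counted by default; a sample-level mode
(`count_samples=True`) counts distinct mutated samples instead.

Gene-set over-representation is a one-sided hypergeometric upper tail per
GMT set against the analysed universe, BH-adjusted across sets. TSG burden
is the per-cancer fraction of samples with ≥ 1 NMD-elicit call in a listed
TSG (each sample counted once). Deletion co-occurrence builds a per-gene
2×2 of elicit-mutation presence × deletion presence over the CNV-profiled
samples (deletion = thresholded CNV ≤ −1 by default, −2 for deep-only) and
compares REV of elicit mutants with versus without a co-deletion by
one-sided Mann–Whitney, flagging degenerate strata.

## Synthetic data

The generators emulate: multi-exon genes (1–6 coding exons of 90–300 nt)
with clean ORFs placed on individual contigs with random introns and
flanks, both strands; a mutation catalogue mixing nonsense SNVs (20%),
frameshift deletions/insertions (15% each), in-frame deletions (10%),
missense (15%), silent (20%) and start-loss (5%) events across 60 samples;
and log2-scale expression with gene means ~ Normal(8, 2) and noise SD 1.0,
in which NMD-elicit mutants are shifted down by `nmd_effect_size` SD units
(default 2 — a strong but realistic NMD knockdown on log2 scale).
Ground-truth classes come from `oracle_classify`, a deliberately naive
re-implementation (string edit, linear scan, direct rule checks) sharing no
code with the classifier. Targeted boundary genes probe each rule edge, and
planted filter cases (excluded class, reference mismatch, duplicate,
junction-spanning deletion, intronic record) exercise every exclusion path.
A single seed drives fixed, documented RNG substreams, so all outputs are
byte-reproducible.

What the simulations do **not** model: realistic mutational signatures and
hotspots, UTRs and alternative splicing, allele-specific expression,
tumour purity, expression-cluster structure, or MSI beyond a boolean label.
Passing tests therefore demonstrate algorithmic correctness of the rules,
coordinate arithmetic and statistics — not calling performance on real
tumour data, where annotation quality and transcript-model mismatch
dominate.

The hypermutation cohort generator draws per-gene Poisson counts (null
means 24 elicit / 48 silent per stratum, identical ratios; planted genes
get a fold increase of elicit events in the hyper stratum only) and sizes
the strata (10 hyper, 320 non-hyper samples) so hyper samples exceed 1,000
events and non-hyper ones stay under 100. These means give the Fisher test
a planted-table z of roughly 5, so a 5× enrichment is reliably detectable
at FDR < 0.05 among ~200 genes without being trivial.

## Problem sizes and numerical choices

The test and acceptance workloads use desk-scale sizes chosen to make the
statistical checks well conditioned: 1,200 random mutations for oracle
parity; 100 genes × 10 mutants with ~140-sample backgrounds for REV null
calibration (estimator SD ≈ 0.01 against the ±0.03 acceptance band);
200 genes for z calibration and effect recovery; three seeded cohorts for
enrichment recovery. Fisher/BH primitives are checked exhaustively on all
2×2 tables with total ≤ 30 plus a seeded sample of larger tables with all
margins ≤ 30. Ties use midranks everywhere; p-values of 2×2 tables use
scipy's exact conditional enumeration; BH is statsmodels' step-up. The
pyfaidx `.fai` index is refreshed on genome rewrite to avoid stale-index
reads.

## Known limitations

- One canonical transcript per gene: consequence calls on minority isoforms
  are out of scope.
- The 50-nt rule is a heuristic for exon-junction-complex displacement;
  last-exon-proximal PTC biology (e.g. long 3'UTR-triggered NMD) is not
  modelled.
- `delins` records are modelled as delete-then-insert at one position.
- Combined-sample mode assumes non-overlapping edits.
- Expression validation assumes log-scale values with approximately
  gene-wise unimodal backgrounds; copy-number is consumed only as GISTIC-
  style thresholded integers.
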