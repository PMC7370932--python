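# Methods

This note documents the models, rules and numerical choices implemented in
`erf_survey`, what the synthetic generators emulate, and the known
limitations.

## Family identification

The AP2/ERF superfamily is partitioned by domain architecture:

| architecture | family |
|---|---|
| ≥ 2 AP2 domains | AP2 |
| any B3 domain | RAV |
| exactly one AP2, `AAEIRD` inside the domain | ERF |
| exactly one AP2, no `AAEIRD` | DREB |
| no AP2 | other |

The rules are applied in that order, so a protein with two AP2 domains and
a B3 is labelled AP2 (such proteins are eliminated from the single-domain
funnel either way).

Two hit sources feed the same decision tree:

- **Domain-table path.** A whitespace/tab-delimited per-domain table (the
  de-facto profile-HMM dialect; only protein id, domain name, E-value and
  envelope coordinates are consumed, with a configurable column map).
  Rows with E ≥ 1e-5 are dropped — the inequality is strict, matching the
  usual survey threshold literally.
- **Internal consensus detector.** A position-class scorer over the
  21-residue ERF/DREB core window
  `GVR[RQK]RPWG[KR][WYF]AAEIRDPA[KR][KG][AGV]`.  The six AAEIRD positions
  are scored as wildcards so DREB-type domains (which differ exactly
  there) are detected by the same profile; the score is the fraction of
  the 15 constrained positions matched, hits need ≥ 0.8 (default), and
  overlapping windows are resolved greedily by score.  Under a uniform
  background the expected number of matched constrained positions in a
  random window is 1.2, so the false-positive rate at the default
  threshold is negligible (measured < 1% per 300-aa protein; in practice
  zero at 2,000 proteins).

The ERF/DREB discrimination then checks for the literal 6-mer `AAEIRD`
within the hit span ± 3 residues.  The slack absorbs envelope-coordinate
variation between detectors; it is configurable.

**Limitation:** B3 has no internal sequence detector (no usable consensus
is available at this level of description), so RAV calls require the
domain-table path.  Internal-path recovery statistics are therefore
reported over non-RAV proteins; on the table path all families are
recovered exactly on planted data.

Proteins with partial domains are admitted whenever the hit clears the
score threshold; partialness is not an exclusion criterion.

## EAR census and physicochemistry

The EAR repression motif is matched as the regex `[LF]DLN[LF].P`, all
overlapping occurrences reported.

Molecular weight (average masses), GRAVY (Kyte–Doolittle mean) and pI are
computed via Biopython's ProtParam, whose pI routine bisects the
net-charge curve under the Bjellqvist pKa set — the same constants ExPASy
uses, including the terminal-residue-specific N/C-terminal pKas.  An
independent fine-grid charge scan (step 0.001 pH, implemented separately
in `erf_survey.oracles`) agrees with the bisection within 0.01 pH on
random peptides.  `X` residues contribute nothing to mass, charge or
hydropathy and flag the result approximate; length still counts them.

## Phylogeny and grouping

- Pairwise alignment: global Needleman–Wunsch with affine gaps
  (BLOSUM62, open −10, extend −0.5) via Biopython's PairwiseAligner;
  optimal scores are verified against an exhaustive alignment-enumeration
  oracle on small inputs.
- Distances: p-distance (mismatch fraction over gap-free columns).
  A Poisson-type correction is deliberately not applied; at within-family
  divergences the ranking is unchanged and p-distances keep NJ input
  non-negative.
- Neighbor joining: Saitou–Nei Q-criterion, ties broken to the smallest
  (i, j) index pair, branch lengths from the standard formulas with
  negative estimates clamped to zero (flagged on the tree).  On additive
  matrices NJ provably recovers the generating topology; this is tested
  against an exhaustive least-squares topology search (all (2n−5)!!
  topologies, non-negative LS branch fit) for n ≤ 6 and against generator
  truth for 1,000 random 4–8 taxon matrices.
- Bootstrap: the multiple alignment is a center-star approximation (star
  = sequence with maximal summed pairwise score; "once a gap, always a
  gap" merge).  Columns are resampled with replacement, NJ is rebuilt per
  replicate, and support is the fraction of replicates containing each
  internal bipartition.  A user-supplied MSA can replace the center-star
  step.  All-identical inputs are reported unresolved rather than given
  arbitrary support.
- Group transfer: a query takes a group by **clade evidence** when its
  smallest bipartition side containing any reference holds references of
  one group only with support ≥ 0.5 (no numeric cutoff is standard; 0.5
  is the package default and configurable), otherwise by **nearest
  reference** in patristic distance, ties to the lexicographically first
  reference id and flagged.  Trees without bootstrap values treat clades
  as fully supported.

## Promoter cis-elements

Promoters are the 2,000 bp upstream of the annotated gene start (strand
aware; truncated with a warning at contig edges, empty at position 1).
Scanning is exact IUPAC-consensus matching on both strands, overlaps and
nestings all counted, minus-strand hits reported at the plus-strand start
coordinate.  The default dictionary carries the eight
literature-sequenced consensi (Sp1 `GGGCGG`, G-box `CACGTC`, MBS `CAACTG`,
ABRE `ACGTG`, LTR `CCGAAA`, ARE `AAACCA`, DRE core `RCCGAC`, GCC-box
`AGCCGCC`) tagged `source=literature`, plus PlantCARE-style curated entries for
O2-site (`GATGAYRTGR`) and as-1 (`TGACG`) tagged `source=curated` and
overridable — the curated two complete the customary nine-element promoter
panel but their exact consensi are not fixed by the survey literature.
Note the G-box is carried as `CACGTC` (the literal the survey literature
prints) although the canonical plant G-box is `CACGTG`; users can override
the dictionary.

Consensi overlap: e.g. a planted G-box `CACGTC` contains `CACGT`, the
reverse complement of ABRE's first five bases, so one element's insertion
can imply another element's hit.  The generator's truth accounts for this
(below).

## Duplication and Ka/Ks

Pairs are classified **tandem** when on one chromosome with at most five
intervening family genes or within 100 kb, else **segmental**; both knobs
are configurable (these defaults follow common gene-family-survey
practice; the underlying pair list is an input, not a synteny
computation).

Ka/Ks is Nei–Gojobori (1986):

- Sites: each codon position contributes 1 site split by the fraction of
  its one-step changes that are synonymous.  Changes that create a stop
  codon are excluded from the denominator, so S + N = 3 × codons exactly.
- Differences: averaged over all minimal substitution pathways between the
  two codons; pathways passing through a stop are excluded and the
  weights renormalised (if every pathway is blocked, all minimal pathways
  are used).
- Correction: Jukes–Cantor d = −¾ ln(1 − 4p/3), reported undefined with a
  reason when p ≥ ¾; the ratio is undefined when Ks = 0.

An independent exhaustive-pathway oracle (separate code path built on
`itertools.permutations` and Biopython translation) reproduces the
implementation exactly on all 4,096 ordered codon pairs.

## Expression rules

- **Expressed:** condition-mean FPKM < 1 ⇒ not expressed (strictly below;
  a mean of exactly 1 is expressed).
- **Tissue specificity:** top condition mean ≥ 1 and ≥ 2× the runner-up;
  ties go to the lexicographically first condition and are flagged.
- **DE:** log10((mean_t + 1)/(mean_c + 1)); up when ≥ log10 2, down when
  ≤ −log10 2.  The pseudocount of 1 FPKM prevents division by zero and
  matches the log10(x+1) heatmap transform; DE is a property of condition
  means only — no replicate-level test and no multiple-testing correction
  is applied, mirroring the fold-change-only criterion, and this should
  be kept in mind when interpreting DE counts.
- **qPCR:** per-replicate ΔCt = Ct_target − Ct_reference; ΔΔCt against
  the control-condition mean; RQ = 2^−ΔΔCt; two-sided Welch t-test on
  replicate ΔCt values (a pooled-variance flag restores the classical
  form), stars at 0.05 and 0.01.

## Synthetic data and what passing tests show

All generators are pure functions of (parameters, seed); identical seeds
give bit-identical output.  Backgrounds are reject-resampled against the
motif set in play (EAR + AAEIRD for proteins, the cis dictionary for DNA),
which makes planted counts exact truth rather than expected truth.  For
promoters, cross-element implications of a planted literal (see above) are
deterministic and included in the recorded truth; the generator asserts
that no hit is attributable to background.  Defaults mirror the survey's
stated conditions: 2-kb promoters, three expression replicates per
condition and six qPCR replicates, fold-10 tissue elevation, fold-4
planted DE genes against the two-fold criterion, log-normal FPKM baselines
(median 20, ln-sd 1) with 0.2 ln-sd replicate noise, and 0.1-cycle Ct
noise.  CDS pairs mutate each codon position at most once, with
synonymous/non-synonymous substitution proportions set by the
Jukes–Cantor forward map of the targets, so the NG86 estimate is unbiased
for them.

The 76-member **stand-in ERF set** is constructed, not downloaded: every
member carries one AP2 core with AAEIRD; exactly the 14 designated members
(ZmERF7, -21, -22, -26, -32, -33, -34, -46, -47, -58, -63, -64, -65, -76)
carry an EAR heptamer; the named members pin the length extremes (183 and
1,425 aa); and two members' residue compositions are grid-designed against
the package's own Bjellqvist calculator to hit pI 4.44 and 10.46 (all
others screened into a strictly interior band).  The published survey
counts 14 EAR carriers in its results while its discussion says 17; the
enumerated list has 14 members and the stand-in follows the enumeration.
Passing the census/extremes checks therefore demonstrates that the
scanners and calculators reproduce the planted facts through the full
FASTA round trip — not that the original deposited sequences were
re-analysed, which would require the original data and annotation release.
Genome-scale counts of the original survey (191 HMM hits, 157
single-domain proteins, 76 ERFs / 81 DREBs, 21 segmental pairs, stress DE
counts) depend on a specific proteome release and external databases and
are intentionally not asserted anywhere.

The generators do not emulate: empirical amino-acid composition (uniform
background by default; configurable), intron evolution or real chromosome
structure, read-level RNA-seq noise, or alignment uncertainty in real
families (synthetic families are nearly alignment-free by construction).
Recovery rates on synthetic data are therefore upper bounds on real-data
behaviour.

## Problem sizes

Default verification scales — 2,000-protein proteome, 500 promoters,
1,000 NJ matrices (4–8 taxa), all 4,096 codon pairs, 500-gene expression
matrix, 200 bootstrap replicates in the drivers (1,000 remains the CLI
default for real trees) — were chosen so the whole suite and the
acceptance script each complete in well under a minute while keeping every
recovery estimate's sampling error far from its threshold.
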