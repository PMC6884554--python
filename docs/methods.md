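# Methods notes

## Model and assumptions

`colocnet` operationalizes "guilt by proxy": if a genomic region is
consistently close in 3D nuclear space to regions harbouring genes with an
established phenotype association, it is a candidate for involvement in
the same phenotype. The evidence base is (i) inter-chromosomal Hi-C
contact frequencies (close in 3D ⇔ high contact frequency), (ii) Capture
Hi-C promoter–enhancer and promoter–promoter interactions defining each
seed gene's regulatory footprint, and (iii) GWAS summary statistics used
only for annotation, never for network construction. The method assumes
the contact data are already KR-balanced (vectors supplied alongside raw
counts), that the Capture tables are pre-filtered for significance at the
source (binomial test, BH FDR < 0.05 — no further filtering is applied),
and that all inputs share one genome assembly (no lift-over is performed).

## Coordinate and binning conventions

Coordinates are 1-based inclusive throughout; BED input is converted at
the reader boundary. Bin labels are 1-based: position p falls in bin
⌊(p−1)/bin_size⌋+1, so chr22:38,800,001–43,700,000 is bins 389–437 at
100 kb. An interval partially covering a bin claims the whole bin.
Amalgamation merges runs of consecutive claimed bins and never crosses a
chromosome (regions are physical DNA segments). Contact pairs are
canonicalized lexicographically by (chromosome, bin); note this is a
dictionary order (chr10 < chr2), used only as a storage key.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `bin_size` | 100 kb | inter-chromosomal grid; eQTL binning uses 10 kb / 100 kb / 1 Mb by SNP–target distance |
| `threshold` | 64 | normalized-count cut-off defining a *strong* contact (inclusive, ≥) |
| `top_fraction` | 0.0005 | alternative quantile mode: smallest threshold retaining ≤ 0.05% of records (ties resolve toward fewer records); documents how an absolute threshold like 64 arises |
| `strong_p_cut` | 1e-6 | eQTL p-value defining a "strong" eQTL signal in cell-line scoring |
| `significance` | 5e-8 | GWAS genome-wide significance, strict `<` |
| `promiscuity_fraction` | 0.1 | a node whose strong-contact partners cover more than this fraction of all genomic bins is reported as promiscuous |
| `min_community_size` | 40 | communities larger than this are re-clustered once into subcommunities |

Exactly one of `threshold` / `top_fraction` is active per run. Edge
weights store the maximum fragment-pair normalized count (inter) or the
Capture support count (intra) but are metadata only: degree and
communities are computed on the unweighted graph, consistent with the
first-neighbour construction.

## Design choices where the design was open

* **d = 1 Mb eQTL pairs** are assigned to the 1 Mb scale (the distance
  rule's strict inequalities leave the boundary open).
* **Concordance 2×2 table**: rows are strong vs weaker-nonzero contact
  over *observed* contact bin-pairs, columns eQTL-occupied vs not. Both
  reported metrics are computed: the fraction of pairs on any nonzero
  contact, and the p ≤ 1e-6 fraction among pairs on strong contacts
  (the ranking criterion; Fisher p breaks ties).
* **Promoter identity** comes from the Capture bait annotation — the
  capture design defines promoters; enhancer fragments are merged per
  gene, not genome-wide. A regulatory region shared by two guilty genes
  is shared, with both memberships recorded.
* **Extension merges adjacent bins wholesale**: an added bin adjacent to
  an original node merges into that node, preserving node class and gene
  membership (novel provenance is kept per constituent bin in
  `novel_bins`); a run of added bins bridging two original nodes merges
  them. This keeps region identity counts stable under extension.
* **Isolated nodes** (no inter or intra edge) are reported and excluded
  before extension; one extension round only (first nearest neighbours).
* **Blacklisting**: blacklist intervals remove nodes plus incident
  edges. The promiscuity detector only *reports*; the pipeline can be
  configured (`auto_blacklist_promiscuous`) to blacklist reported nodes,
  mirroring the manual removal of artifact regions such as a bin that
  contacts nearly every other bin.
* **Community detection** is agglomerative greedy modularity
  maximization (Clauset–Newman–Moore): merge the connected community
  pair with maximal ΔQ = e_ij/m − d_i·d_j/(2m²) while ΔQ > 0. Ties break
  on the lexicographically smallest community-label pair (a community's
  label is its smallest member id), making results order-independent and
  fully deterministic. Non-adjacent communities never merge, so
  components are respected exactly. Different greedy implementations can
  split large real networks into slightly different community counts;
  the tests pin behaviour on structures where the optimum is provably
  unique (verified against exhaustive partition enumeration) and against
  an independent library implementation on unambiguous structures.
* **Gene-to-node assignment**: a gene straddling two (necessarily
  non-adjacent) nodes is assigned to both with an ambiguity flag; SNPs
  are point features and land in at most one node. Chromosome X SNPs are
  accepted but flagged, since GWAS panels often exclude chrX while chrX
  regions can still be network nodes.

## Numerical choices

Fisher's one-sided exact test sums the hypergeometric upper tail in
log-space (`gammaln` + `logsumexp`), so enrichments with p far below
float underflow remain comparable via their log (`log=True`); it matches
exact rational enumeration to 1e-12 on every 2×2 table with N ≤ 60.
Modularity uses the standard Σ_c [l_c/m − (d_c/2m)²] form; the
incremental ΔQ of each greedy merge agrees with from-scratch
recomputation to 1e-9. The quantile threshold returns the smallest
*observed* value whose ≥-count is within the allowance, or the next
float above the maximum when even the maximal ties exceed it (degenerate
all-equal input retains nothing). Records touching an unmappable bin
(NaN or non-positive KR factor) are excluded as a state, not an error.
Empty inputs (empty bin set, empty blacklist) are identities; empty
contact sets and all-zero tables are errors.

## What the synthetic generator emulates — and what it does not

The default scenario is 3 chromosomes × 10 Mb at 100 kb bins (30,000
inter-chromosomal bin pairs, all recorded with geometric-tailed
background counts, geometric p = 0.35). Two modules of five bins each,
spread 2+2+1 across the chromosomes, interact strongly across
chromosomes with probability 0.9 within a module and 0.02 between
modules — 16 eligible cross-chromosome pairs, i.e. ≈ 14.4 expected
strong records, ≈ 0.05% of records, matching the strong-contact tail the
method presumes. Each module bin houses one guilty gene whose Capture
footprint stays inside its bin; same-chromosome module genes are tied by
promoter–promoter interactions (intra links). Two isolated guilty genes
are planted with a hard guarantee (background counts capped below
threshold on their bins), one promiscuous hub bin contacts ~90% of
other-chromosome bins (excluded from the tail self-check, as an analyst
removes such artifact regions before analysis), two bins per chromosome
are unmappable (NaN factors), and six genome-wide-significant SNPs sit in
module bins. The eQTL tables plant cell-line-specific concordance:
low-p pairs land on strong contacts with probability 0.61 / 0.10 / 0.098
for the three cell lines and 0.05 otherwise, chosen analytically so the
expected strong-eQTL fractions approximate an 84% vs 46% split
(bin-sharing at the coarse 1 Mb scale dilutes the observed fractions
somewhat; the ranking margin remains large). One RNG stream per file
type derives from the master seed, so bundles are byte-reproducible and
adding a file type never perturbs existing ones.

Passing the planted-recovery tests therefore shows the pipeline
correctly *propagates* strong-contact structure into communities, recalls
truly contact-free regions, flags promiscuous artifacts, and ranks
concordant cell lines — under a clean generative model. It does not show
robustness to real-data pathologies: copy-number-driven contact bias,
translocations, distance-dependent intra-chromosomal decay, LD structure
among SNPs, or assembly mismatches are not simulated. Problem sizes
(300 bins, 12 guilty genes, 400 eQTL pairs, 20 seeds) were chosen as the
smallest at which the planted effects are statistically unambiguous.

## Known limitations

* Inter-chromosomal evidence only for network edges; intra-chromosomal
  co-location enters solely through Capture-derived links.
* KR factors are inputs; the package does not re-balance raw matrices,
  and only text dumps are parsed (no `.hic`/`.cool`).
* Whether the 0.05% quantile should be computed per chromosome pair or
  genome-wide is ambiguous in general; it is computed genome-wide here.
* The ORA is a generic hypergeometric test over user-supplied gene sets;
  it does not query GO/DAVID or model gene length / LD biases.
* One extension round; k-hop neighbourhoods and weighted or
  Louvain/Leiden community detection are out of scope.
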