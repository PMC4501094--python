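# Methods

This note documents the models, rules and numerical choices behind
`trfscape`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the procedure was genuinely open.

## The tRF model

A tRNA-derived fragment is treated as an *exact* contiguous fragment of
a mature tRNA. Mature sequences are constructed as the strand-resolved,
intron-spliced genomic gene body plus the post-transcriptional `CCA`
tail; all mapping is exact substring search with no mismatches or gaps.
This replaces heuristic alignment deliberately: the acceptance criterion
for a tRF is a perfect match, and exact search is deterministic,
parameter-free, and checkable against a brute-force oracle (the test
suite does exactly that). A hook exists for plugging in an external
aligner, off by default.

**CCA handling.** Because the tail is appended during maturation and is
absent from eukaryotic genomic tRNA loci, a read that ends in `CCA` and
aligns flush to a gene's 3′ terminus is a valid tRF even though it
matches no genomic locus. Since our mature sequences already carry the
tail, such reads are ordinary exact matches to the mature sequence; any
hit ending at the mature 3′ end is flagged `cca_masked`. Partial tails
(`C`, `CC`) are ordinary internal matches and are never flagged.

**Compartment precedence.** Reads are matched to the mitochondrial
compartment first; any mitochondrial occurrence (tRNA or not) claims
the read and only mito-unmapped reads are considered against nuclear
contigs. This mirrors the step order of the original extraction
procedure and resolves cross-compartment multi-mapping deterministically.

**Ambiguity filters** (nuclear calls): (a) reads that also occur at a
non-tRNA genomic locus are dropped; (b) reads whose only parents carry
polymorphic sites are dropped; (c) reads matching tRNA genes of two or
more distinct anticodons are dropped. Reads matching several isodecoder
subtypes of one anticodon are kept with all parents and counted once per
anticodon. Two readings were open here and are fixed as follows:

- *"tRNA region"* for filter (a) means the interval of **any** annotated
  tRNA gene, including genes later removed by curation (pseudo,
  polymorphic, contig-end). Only occurrences outside all annotated tRNA
  loci count as "other genomic regions" — a read should not be punished
  for matching a locus the curator merely filtered. A read antisense to
  a tRNA counts as a non-tRNA occurrence, since tRFs are fragments of
  the sense mature transcript.
- Mitochondrial candidates are exempt from filter (a) by default (the
  published footnotes annotate only nuclear rows); within-mitochondrial
  multi-anticodon reads are still dropped. Both behaviours are
  toggleable (`mito_other_genomic_filter`).
- For filter (b), a read with at least one non-polymorphic parent keeps
  its non-polymorphic parents rather than being removed outright.

## Catalog curation

tRNAscan-SE tabular output is parsed directly (begin > end rows become
minus-strand genes with normalized intervals; a trailing note column may
mark `pseudo` or `polymorphic`). Nuclear gene sets from the eukaryotic
and bacterial search modes are intersected by locus: a gene is kept when
its eukaryotic COVE bit score strictly exceeds the bacterial one, and
loci found only by the eukaryotic search are kept (the score rule is a
comparison and is only applicable where both exist). Mitochondrial genes
come from the organellar search mode and bypass this comparison.
Curation then removes pseudogenes, genes within `edge_margin` (default
5 nt — no published value exists; configurable) of a contig boundary,
and genes with polymorphic sites. Polymorphism is recognised from the
annotation note, or detected as two genes at overlapping loci (or
sharing a gene id) with unequal sequences — "genes containing polymeric
site(s)" in the source material is read as a typo for *polymorphic*
sites, the only self-consistent interpretation given the table footnote
wording. All interfaces use 1-based inclusive coordinates.

The anticodon's position on the mature sequence is recomputed by taking
the occurrence of the anticodon triplet closest to a hint position
(default 33, the canonical cloverleaf position used by the toy gene
model) or, lacking a hint, closest to the sequence midpoint.

## Region classification

With anticodon loop `[a−2, a+2 .. ]` (7 nt centred on the anticodon) and
an anticodon stem of `stem_width` = 5 bp, a span is classified in fixed
decision order: 5′ half (5′-anchored, 3′ terminus inside the loop),
3′ half (3′-anchored, 5′ terminus inside the loop), 5′ end (5′-anchored,
ends before the loop), 3′ end (3′-anchored, starts after the loop), AC
stem-loop (unanchored, within the stem-loop window ± `window_slack`),
else *other* — reported, never dropped. Anchoring tolerances default to
`t5 = t3 = 2` nt (published alignments group variants starting a few
nucleotides inside the terminus with the terminal classes; no exact
value is stated, so these are configuration, not claims). The decision
order guarantees exactly one label per span, verified exhaustively in
the tests.

A geometric consequence worth noting: with the default 7-nt loop, 5-bp
stem and 3-nt slack, the AC stem-loop window admits spans of at most
23 nt, so no read in the 25–45 nt analysis window can receive that label
under default tolerances. The label is reachable for shorter spans (the
classifier itself is length-agnostic) or wider windows; the synthetic
generator therefore plants only the four anchored classes by default
and raises a configuration error if asked to plant AC stem-loop
fragments that cannot satisfy the read-length window.

The per-anticodon **main region** reports every category holding at
least `main_region_fraction` = 25 % of the group's reads, most abundant
first, joined with " and " (ties broken by the fixed category order
5′ half, 5′ end, 3′ half, 3′ end, AC stem-loop). The 25 % threshold
reproduces the one- and two-label styles of the published table on
plausible mixtures; it is scale-invariant by construction.

## Expression profiling

Libraries are normalized with two spike-in RNAs. The published source
states only that two spikes were used; the arithmetic chosen here
anchors each stage's spike sum to the geometric mean of all six sums
(`factor_s = K / spikesum_s`), which is scale-free, symmetric across
stages, and preserves within-stage count ratios exactly. Alternative
anchors would differ only by a global constant.

Coverage profiles sum normalized counts of covering tRFs per mature
position (CCA included). The top-variant heatmap divides each variant's
normalized stage counts by the row maximum (all-zero rows stay zero and
are flagged). Rows are ordered by agglomerative average-linkage
clustering with distance 1 − uncentered correlation, the default
similarity of the Cluster 3.0 program the original analysis used;
centered Pearson is a config option. All-zero rows are treated as
mutually identical and orthogonal to everything else.

Developmental trends are a coarse operationalization of three
qualitative classes: *egg-enriched* when the egg value exceeds 50 % of
the total (evaluated first), else *increasing*/*decreasing* when the
Spearman rank correlation of the six stage values against stage index
reaches ±0.8, else *other*. The thresholds are package configuration,
not published values.

## The synthetic study

The generator emulates the study design, not its sequences: six stage
libraries; toy tRNA genes of 70–76 nt mature length with the anticodon
at mature positions 33–35 (making the region map unambiguous and the
classifier exhaustively testable); 6 mitochondrial + 14 nuclear
anticodon families, nuclear families with 2 isodecoder subtypes that
share their 5′ half and differ near the 3′ end; 10⁴ fragment reads by
default, allocated per family/stage/region by largest-remainder rounding
so planted totals are exact integers. Complications planted with full
ground truth: one decoy locus (an exact unannotated copy of a tRNA body,
followed by a non-C base so CCA-tailed reads cannot extend into it); one
polymorphic-flagged gene family; two spike-ins at stage-dependent counts
(so factors are nontrivial); 5 % pure-noise reads; and reads destined
for each filter — `N`-containing, mean-quality-12, shorter than 25 nt,
longer than 45 nt, and unique sequences with pooled count 4. Gene
flanks are patched so a CCA-terminated read can never coincidentally
continue into intergenic sequence, keeping truth bookkeeping exact.

Per-anticodon stage trends are planted in *normalized* space (raw counts
are derived by dividing by the known spike factors): increasing series
grow 2.5-fold per stage, egg-enriched series put 60 % of reads in the
egg stage, and decreasing series fall 1.7-fold per stage — a decreasing
series steeper than 2-fold would place more than half its reads in the
egg stage and thus *be* egg-enriched under the precedence rule above, so
the gentler fold keeps the planted classes mutually exclusive.

What the generator does **not** emulate: sequencing substitution errors,
tRNA-modification-induced misincorporation, miRNA/piRNA populations,
realistic tRNA secondary structure beyond the anticodon region, gene
families with near-identical paralogs across anticodons, or adapter
artifacts. Passing the planted-truth tests therefore demonstrates the
correctness of the calling logic and bookkeeping, not robustness to
base-calling noise — by design, since the method itself is exact
matching after quality filtering.

## Problem sizes and determinism

The default synthetic study (20 anticodon families, ~10⁴ fragment
reads, ~65 k raw reads across six libraries) runs the full pipeline in a
few seconds; the brute-force oracle comparison uses 200 random instances
of ~8 genes and 40–90 unique reads each, chosen so naive enumeration
stays fast while covering every ambiguity rule. All randomness flows
from a single integer seed through `numpy.random.default_rng`; reads and
catalogs are processed in sorted order, so identical configurations
produce byte-identical text outputs, and the run manifest records the
seed and a hash of the scientific parameters (paths excluded).

## Known limitations

- Exact matching means a single sequencing error or modification-induced
  misread loses the read; quantities are therefore lower bounds in real
  data.
- The mitochondrial reannotation of the original study was manual; the
  catalog accepts an override/annotation table rather than reproducing
  it.
- Multi-parent tRFs report the span of their first (lexicographic)
  parent in single-span outputs; per-parent spans are retained
  internally and in alignments.
- 18–24 nt fragments are out of scope (unreliable to place on tRNA
  families); the length window is configurable but the region geometry
  assumes fragments long enough to anchor.
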