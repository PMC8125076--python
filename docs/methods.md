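# Methods

`motukit` implements a genome-resolved inference chain for collections of
metagenome-assembled genomes (MAGs), single-amplified genomes (SAGs) and
isolate genomes: species-level clustering by average nucleotide identity
(ANI), incompleteness-aware core/accessory pangenome partitioning,
competitive-mapping abundance profiling across metagenome samples,
marker-gene trait matrices, and biogeographic classification. This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic-data tests do and do not establish.

## ANI estimation and mOTU clustering

**Estimator.** Each genome is reduced to its set of canonical k-mers
(k = 21 by default; canonical = lexicographic minimum of a k-mer and its
reverse complement, so strand is irrelevant; windows containing non-ACGT
symbols are skipped). For two genomes with k-mer Jaccard similarity
J = |A∩B|/|A∪B|, the MinHash distance transform

    D = −(1/k) · ln( 2J / (1+J) ),        ANI = 100 · (1 − D)

estimates per-base divergence under a Poisson model of independent
substitutions. J = 0 is floored to ANI = 0. Full k-mer sets are used by
default — draft genomes at the scales this package targets are small
enough that sketching buys nothing; a fixed-size bottom sketch
(`sketch_size`) is available for large inputs. On substitution-only
simulated pairs of 100 kb at true identity 96–99.5%, the estimate is
within ±0.5 percentage points of the realised Hamming identity
(verified in the test suite; the transform's small-J bias and k-mer
non-independence are the residual error sources). The estimator is not a
re-implementation of any fragment-mapping ANI tool; externally computed
five-column ANI TSVs can be imported instead, with directed duplicates
symmetrised by their arithmetic mean (the field's tools report slightly
asymmetric values; the mean is a documented choice).

**Clustering.** Genomes with completeness ≥ 70% and contamination ≤ 5%
are *seeds*; pairs of seeds with ANI strictly above 95% are edges, and
connected components (singletons included) are the mOTUs. Genomes with
completeness in [50%, 70%) and contamination ≤ 5% are *recruited* into
the component containing a seed they exceed the ANI threshold with; if
several components qualify, the one with the highest mean ANI to its
seed members wins, ties broken by the component's lexicographically
smallest seed id (final mOTU ids are only assigned afterwards — by
decreasing member count, then smallest member id — so the tie-break is
keyed on the cluster's smallest seed, which is deterministic and
order-independent). Everything else, including recruit-range genomes
with no qualifying link, is retained as *excluded* with a reason code
(`low_completeness`, `high_contamination`, `unrecruited`), never
silently dropped. "Above 95%" is strict by default (`strict_above`
exposes ≥ for sensitivity checks). The representative of each mOTU is
its most complete seed member, ties broken by lowest contamination, then
id. Connected components are computed with networkx; an exhaustive
union-find is kept as an independent oracle in the tests.

## Core/accessory partitioning

The model and its fitting are described in the `pangenome` module
docstring; in brief, for genomes of completeness c_i a gene's 0/1
profile is scored under "core" (shown with probability c_i) versus
"accessory" (shown with the genome's accessory carriage probability p_i
= observed accessory genes in genome i / distinct accessory clusters in
the mOTU), and the assignment is iterated to a fixed point starting from
genes whose frequency is at least the mean completeness. Choices worth
recording:

* **Clamp ε = 1e-3** on all probabilities keeps log-likelihoods finite
  for "100% complete" genomes; it also sets the per-absence penalty for
  the core hypothesis at ln(ε) ≈ −6.9.
* **Initialisation at mean completeness** couples the starting core set
  to data quality instead of a fixed 50% frequency cut.
* **Oscillation guard**: assignments are hashed per iteration; if a
  cycle is detected, the lexicographically smallest assignment in the
  cycle (genes ordered by label, so input order is irrelevant) is
  returned with `converged=False`, together with the likelihoods its
  predecessor produced, so `assignment == (loglik_core >
  loglik_accessory)` holds in every returned object.
* **Completeness re-estimation** (off by default — input completeness
  is treated as authoritative) re-derives c_i after each pass as the
  fraction of current core genes genome i shows.
* **Unobserved genes are never classified.** A gene absent from every
  member is reported "absent": absence across all MAGs and SAGs of the
  cluster is treated as evidence of true absence, distinct from an
  accessory call. All-zero rows are rejected by the model constructor
  and filtered by `from_dataframe`.
* **Contamination is not modelled**; with contamination capped at 5% by
  the clustering tier its effect on the likelihood is second-order.
  Known limitation.
* **Near-universal genes stay core.** For a gene present in N−1 of N
  genomes the likelihood ratio prefers core whenever
  (N−1)·ln((1−ε)/p) > ln((1−p)/ε) — at carriage p = 0.3 this happens
  for any N > 6 *even when every genome is essentially complete*. This
  is a deliberate property of the ratio rule, and it is exactly what
  makes recovery of planted core genes exact at completeness 0.999
  (some core genes always drop out of one genome); the flip side is
  that the partition does not reduce to the naive presence-in-all
  indicator on all matrices in the complete-genome limit, only in the
  dense-carriage / small-N regime where the inequality cannot fire.

On planted pangenomes (20 genomes, completeness 0.9, 1000 core + 1000
accessory genes at frequency 0.3) the classifier's core/accessory F1
exceeds 0.95 on every tested seed, and recovery is exact at
completeness 0.999. The functional form is a reconstruction of a
published one-sentence decision rule; byte-level equivalence with any
external pangenome software is not claimed.

## Abundance profiles and occupancy

Each metagenome is subsampled (uniform, without replacement) to
1,000,000 reads by default; libraries below the target are used whole
with a warning. Reads are matched at **100% identity**, read strictly:
the read must be a full-length exact substring of a genome or its
reverse complement — no mismatches, no clipping. Matching is seeded by
the read's first canonical 31-mer against an index of all genome
31-mers, followed by exact substring verification, so the criterion is
implemented precisely rather than through a mapper's scoring heuristics.
Only genomes with a mOTU assignment are indexed: excluded genomes do not
compete for reads.

A read matching one mOTU counts 1; a read matching k > 1 mOTUs counts
1/k to each (the deterministic, conservation-preserving default;
`discard` and seeded `random` policies exist because the behaviour of
the original mapping pipeline for such reads is not documented). Counts
are exact `Fraction`s, so per-sample mOTU abundances plus the unmapped
fraction sum to 1 exactly, not merely to rounding. Relative abundance is
count / subsample size; occupancy is the unweighted arithmetic mean over
all of a site's samples (zeros included), and presence is called at mean
abundance ≥ 0.03% (0.0003), boundary inclusive.

## Traits and biogeography

Marker hits are filtered at query coverage ≥ 80% and identity ≥ 50%
(≥ 80% for PsaA), all comparisons inclusive; coverage from 12-column
alignment tables is computed against the *query* length. A marker absent
from every member genome is "absent"; otherwise its presence profile is
scored with the mOTU's fitted likelihood rule and carriage
probabilities (`classify_profile`), so the trait matrix and the
pangenome partition cannot disagree.

Biogeography unions two evidence channels — member-genome origins and
occupancy-present sites — through a caller-supplied site → region →
country → continent hierarchy (no geography is hardcoded):
≥ 2 continents ⇒ cosmopolitan; all evidence within one region (hence
also one site when only one is seen) ⇒ endemic; otherwise regional; no
evidence ⇒ unknown. The three-level scheme with explicit rules replaces
narrative categories; "endemic" deliberately covers both
single-lake and single-region confinement.

## Synthetic communities

The generator plants: species pangenomes (core set carried by every
member; accessory-pool genes carried independently at a configurable
frequency, default 0.3); genome degradation (each true gene retained
with probability = completeness; contamination adds
Binomial(n_true_genes, rate) genes drawn from the other species' pools);
sequences (one random ancestor per species, each member mutated at
per-base rate (100 − within_ani)/200 so member pairs sit near the
target within-species identity, default 98%; species ancestors are
independent, giving between-species identity far below any threshold);
and single-end 150-base reads drawn i.i.d. from planted abundances,
uniform position and strand, substitution errors at a configurable rate
(default 0). The unplanted remainder of each sample comes from a
background sequence rejection-checked to share no canonical 31-mers
with any genome, so unmapped fractions are meaningful. Completeness and
contamination are per-genome inputs (default 0.9 and 0 in the community
generator); no distribution over genome quality is assumed.

What this does *not* emulate: indels and rearrangements, read-quality
profiles, chimeras, paired-end structure, assembly and binning error,
shared accessory genes between species, or uneven coverage. Passing
tests therefore establish correctness of the inference chain under its
own model assumptions — substitution-only divergence and exact-match
reads — not robustness to real-data artefacts like indel-rich
alignments (where an exact-substring criterion is far stricter than a
mapper's 100%-identity filter) or mis-binned contigs.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; per-species and per-sample streams are
derived from the top seed plus a CRC of the label, so outputs are
reproducible and independent of dict ordering. The test and acceptance
workloads use desk-scale instances chosen to make the statistical
assertions sharp but cheap: 100 kb genomes for ANI calibration and the
5-species × 8-genome clustering recovery; 2000-gene × 20-genome
matrices for classifier recovery; 125,000-read libraries subsampled to
100,000 for abundance recovery (the library is built at exactly the
planted composition so the subsample is the randomness under test);
30 kb genomes and 8000-read samples for the end-to-end biogeography
runs.
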