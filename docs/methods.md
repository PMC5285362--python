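# Methods

This note documents the models, algorithms and numerical choices behind
`exomir`, the parameters that matter, and what the synthetic-data tests do
and do not demonstrate.

## Problem setting

Small RNA-seq libraries routinely contain reads whose sequence belongs to a
species other than the sequenced host. Two explanations compete: genuine
cross-species RNA transfer (diet, infection, symbiosis) and contamination
introduced during sample handling or sequencing. The pipeline (i) separates
host-attributable reads from the rest, (ii) identifies residual reads that
are exact copies of known mature miRNAs from other species, and (iii)
accumulates the statistical evidence needed to tell the two explanations
apart.

## Host filtering

A read is host-derived iff it aligns full-length to some window of some
host reference, on either strand, with at most `max_mismatch`
substitutions (no indels). The default bound is **1**: the relaxed bounds
customary for expression mapping (2 mismatches) are exactly what lets
host-near exogenous sequences — and conversely, exogenous-near host loci —
cross the line (see the similarity scan below).

**Matcher.** References are indexed by every k-mer (default k = 9, forward
strand). A query of length L is split into `max_mismatch + 1` disjoint
blocks; by pigeonhole, any alignment within the bound leaves at least one
block mismatch-free, so the first k-mer of each block is used as an exact
seed and each candidate diagonal is verified by direct Hamming count.
Reverse-strand hits are found by querying the read's reverse complement
against the forward index — the hit set is identical to indexing both
strands at half the memory. Configuration requires
`floor(min_read_len / (max_mismatch+1)) >= k` (18 nt reads, bound 1, k = 9
at the defaults); when a caller asks for a bound the seeds cannot
guarantee — e.g. scanning a 21 nt mature at 2 mismatches — the matcher
falls back to an exhaustive vectorized scan over every reference window,
so results are exact at every bound, only slower. `N` never matches
anything, in query or reference.

Reference layers (genome, transcripts, ncRNA, hairpins) are merged into
one index: removal is independent of layer order, and per-layer
attribution is reported separately for annotation only. Transcript
sequences cover splice-junction reads the genome cannot.

**Order of operations.** Host filtering precedes exogenous matching, so a
read within one mismatch of the host *and* identical to an exogenous
mature is classified host. This deliberately reproduces the suppression of
host-similar exogenous matures (the miR156 situation); the
`host_similarity_scan` surfaces such sequences explicitly (all full-length
occurrences within a relaxed bound, default 2, both strands, 0-based
forward-strand offsets).

## Exogenous classification

Residual reads hit the catalog only on **exact, full-length, forward**
sequence identity after U→T normalization: mature miRNAs are
single-stranded, so a read matching only a mature's reverse complement is
not that miRNA. Catalog entries of the host species are removed *before*
matching — "exogenous" is structural, not a post-hoc filter. When one
sequence is carried by matures of several exogenous species, every species
is credited with the full count and the co-attributed species are recorded
(`shared_with`); an optional fractional mode (1/n per species) exists for
sensitivity analysis. Quantification is RPM = count / T × 10⁶ where T is
the dataset's **total** input read count; T is fixed before any filtering
and is never shrunk by it, keeping the denominator comparable across
pipeline stages.

## Aggregation

- Frequency value: F_ij = Σ_k S_ijk / T_k × 10⁹ over the datasets of a
  source group, species i × miRNA family j, with S summed over a family's
  mature variants. The 10⁹ scale (RPM × 1000) is kept as defined; for a
  single dataset every cell reduces to rpm × 1000 exactly, which the tests
  assert at 1e-9 relative tolerance.
- Families are derived from miRBase identifiers: strip species prefix,
  then a `-5p`/`-3p` arm suffix, then one trailing lowercase variant
  letter (`osa-miR156a → miR156`, `ebv-miR-BART1-5p → miR-BART1`). Numeric
  locus suffixes (`-1`, `-2`) are retained — collapsing them would need
  per-family curation the identifier alone cannot support.
- Supporting number: datasets containing the miRNA at ≥ `min_count` reads
  (default 1; no abundance threshold). Matrix orderings: by family name,
  by species name, or by descending marginal frequency on both axes.

## Comparison

Presence-set overlap is 100·|A∩B|/|A∪B| at miRNA-id granularity (family
granularity optional). Correlation vectors are keyed by the **union** of
observed ids with 0 for absences and transformed log2(RPM+1): union keying
lets shared absence structure contribute, and the log tames heavy-tailed
abundances; both choices are switchable (`intersection`, `raw`). Pearson r
is computed by `scipy.stats.pearsonr`, whose p-value is the exact
two-sided t-transform with |union|−2 df; a seeded permutation p-value is
available for small unions. Groups are merged by summing counts and
library sizes before recomputing RPM (not by averaging RPM), preserving
the frequency formula's additive structure. A pair is `intra_study` iff
the groups share a study identifier. A constant vector makes r undefined
and raises rather than returning 0.

## Provenance scoring

Three raw features per miRNA, reported alongside the label so users can
re-threshold without recomputation:

1. recurrence: supporting number and number of distinct studies;
2. host spread: the clades/kingdoms of the hosts it appears in;
3. coverage ratio: 100 × (distinct matures of the source species observed
   anywhere) / (matures of that species in the catalog).

Default thresholds: `candidate_genuine` requires ≥ 2 independent studies,
coverage ≥ 50%, and plausible spread; spread is implausible at > 2 host
kingdoms or any blacklisted source→host kingdom route (plant, animal or
fungi miRNAs observed in bacterial or protist libraries — no trophic or
infective path). `likely_contamination` on implausible spread, or on
coverage below threshold despite a supporting number ≥ 5. Everything else
is `ambiguous`. The thresholds are package defaults (the underlying
features are qualitative); they reproduce the canonical worked judgments —
a rice-like miRNA seen in human, worm and *E. coli* at ~6% source coverage
is contamination; an EBV-like set seen only in human lymphoid samples from
two studies at ~86% coverage is a genuine candidate — and all are exposed
as parameters/CLI flags.

## Synthetic data generator

`simulate.generate_world` builds, deterministically from one seed: a random
host genome (default 20 kb) with planted pre-miRNA hairpins (mature + 8 nt
loop + reverse-complement), transcript windows of that genome, a mature
catalog over the host plus configurable exogenous species, taxonomy and
metadata tables. Exogenous matures are rejection-sampled to have **no**
full-length window within 1 mismatch of any host reference, except matures
explicitly planted as host-similar, which get `copies` near-copies at
exactly `mismatches` substitutions written into the genome (transcript
windows avoid those intervals so the copy count is exact over the full
reference set). One mature can be configured to carry an identical
sequence under two species codes (the miR168a situation).

`simulate_dataset` draws reads by a seeded multinomial over host genome
windows (18–24 nt, either strand), verbatim spiked matures, and noise
rejection-sampled ≥ 2 mismatches from host windows and catalog matures.
Reads are error-free by default (exact matching then recovers every spiked
count exactly, which the tests assert); an optional per-base substitution
rate exercises the exact-match sensitivity cliff.

**Default study conditions:** six datasets of 20,000 reads in two studies;
host proportion 0.90; study-level spike tables shared across a study's
datasets, with proportions spanning 5×10⁻³ … 1.5×10⁻⁴ (dominant
contaminants in public libraries reach percent-level RPM; most sit far
lower — the ~2-decade spread is what makes abundance profiles informative
for correlation); three exogenous species (rice, maize, EBV), one
osa/zma-shared sequence, one plant mature planted host-similar at 2
mismatches × 2 copies. Read totals are desk-scale stand-ins for the
multi-million-read libraries of real studies; every assertion made on them
(exact recovery, conservation, contrast direction) is scale-free.

**What passing tests do not show.** The generator has uniform base
composition, no expression distribution shape, no adapter/ligation/PCR
bias, no platform error profile, and its noise is constructed to be
unambiguous. Tests therefore demonstrate correctness of the algorithms
(exact bookkeeping, conservation laws, bound-exact matching), not
robustness to the messiness of real libraries — in real data the
exact-match rule makes detection conservative (isomiRs and sequencing
errors are missed, not misassigned).

## Numerical and degenerate-input choices

- Alphabet normalized once at load (uppercase, U→T); all comparisons in DNA
  space. Reads with characters outside {A,C,G,T,N} are parse errors.
- RPM with T = 0 raises; classifying an empty library warns and returns an
  empty profile.
- `shared_fraction` of two empty profiles is undefined (raises), not 0 or
  100.
- Ranking ties (equal supporting numbers) break lexicographically by id;
  all outputs are deterministic under permutation of input profiles.
- Frequency matrices use exact float accumulation in pandas; the n = 1
  closed form agrees to 1e-9 relative.
- Seed derivation for per-dataset simulation: `(seed·100003 + i·7919 + 1)
  mod (2³¹−1)`, keeping all derived seeds in 32-bit range.

## Limitations

- No gapped alignment: a host read spanning an unrepresented junction with
  an indel escapes filtering (mitigated by the transcript layer, as in
  standard practice).
- Exact matching ignores isomiRs and non-templated additions; counts are
  lower bounds on the underlying miRNA abundance.
- The clade blacklist quantifies "evolutionary distance" only coarsely; it
  is a configurable artifact decision, not a phylogenetic model.
- Multi-attribution inflates per-species counts for conserved families by
  design; use `shared_with`/fractional mode when a deduplicated view is
  needed.
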