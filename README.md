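# exomir

Detection and provenance analysis of **exogenous miRNAs** (xenomiRs) in small
RNA sequencing datasets.

Nearly every deep-sequenced small-RNA library contains reads from organisms
other than the host — plant miRNAs in human plasma, viral miRNAs in B-cell
lines, rice miR168a in *E. coli*. Whether such reads reflect genuine
cross-species RNA transfer or laboratory contamination is contested, and the
answer matters: unrecognized contaminants distort expression estimates and
have driven bold biological claims. `exomir` implements a complete pipeline
for finding these reads and judging their provenance, aimed at researchers
re-analyzing public small RNA-seq data.

## Method

1. **Host filtering ("map and remove").** Reads are matched against layered
   host references (genome, transcripts, ncRNAs, pre-miRNA hairpins) with a
   self-contained matcher: a read is host-derived iff it aligns full-length,
   substitutions only, on either strand, within *m* mismatches (default
   *m* = 1) of any reference window. The matcher uses a k-mer seed index
   with a pigeonhole guarantee and is exact at every bound.
2. **Exogenous classification.** Residual reads are matched **exactly**
   (full length, forward strand) against a mature-miRNA catalog classified
   by source species and kingdom (miRBase-style identifiers). Hits are
   quantified as RPM = count / T × 10⁶ against the library size T and
   labeled `same_kingdom` / `other_kingdom` relative to the host. Sequences
   identical across species (e.g. miR168a in many plants) credit every
   species, with the sharing recorded.
3. **Aggregation.** Across datasets *k* = 1..*n* of a source group, the
   frequency value of source species *i* and miRNA family *j* is

   &nbsp;&nbsp;&nbsp;&nbsp;F<sub>ij</sub> = Σ<sub>k</sub> S<sub>ijk</sub> / T<sub>k</sub> × 10⁹

   where S<sub>ijk</sub> is the read count for (*i*, *j*) in dataset *k*.
   The *supporting number* of a miRNA is the number of datasets in which it
   is detected.
4. **Comparison.** Pairs/groups of profiles are compared by presence-set
   overlap (100·|A∩B|/|A∪B|) and Pearson correlation of log2(RPM+1)
   vectors, labeled intra- vs inter-study. Systematic **intra**-study
   sharing is the signature of process contamination.
5. **Provenance scoring.** Each exo-miRNA is labeled
   `likely_contamination` / `candidate_genuine` / `ambiguous` from three
   features: recurrence across independent studies, the evolutionary spread
   of the hosts it appears in (a plant miRNA in both mammal and bacterial
   libraries has no plausible common route), and the *coverage ratio* — the
   percentage of the source species' cataloged matures observed at all. A
   relaxed-bound similarity scan additionally flags exogenous matures lying
   within 2 mismatches of the host genome, which a loose mapping policy
   would silently absorb.

A fully deterministic synthetic-data generator (host genome with planted
hairpins, spiked exogenous matures, rejection-sampled noise, complete ground
truth) drives the test suite end to end.

## Worked example

```sh
python examples/01_simulate_and_detect.py
```

simulates a six-dataset study (human host, rice/maize/EBV spikes) and runs
dataset `d1` through the pipeline:

```
dataset d1: 20000 reads total
  host-filtered: 18054 reads (17463 unique)
  residual:      1946 reads, 1767 unassigned
  exogenous hits (count = reads exactly equal to the mature):
    osa-miR101   other_kingdom  count=89   rpm=  4450.0  truth=89
    osa-miR102   other_kingdom  count=36   rpm=  1800.0  truth=36
    ...
    zma-miR101   other_kingdom  count=89   rpm=  4450.0  truth=shared
```

Every spiked count equals the simulator's truth exactly; `zma-miR101` is
credited because it carries the identical sequence as `osa-miR101`
(multi-attribution). `examples/03_compare_studies.py` then shows the
contamination signature on the same study — mean intra-study r = +0.92
versus mean inter-study r = −0.54 with 100% vs ~21% shared fractions — and
`examples/04_provenance_scoring.py` prints the provenance labels and the
planted two-mismatch host-similarity hits.

The same stages are available as a CLI for file-based use:

```sh
exomir simulate --seed 1 --outdir sim/
exomir run --reads sim/d1.fastq --dataset-id d1 --host-species hsa \
    --host-ref all=sim/host_references.fa --matures sim/mature_catalog.fa \
    --taxonomy sim/taxonomy.tsv --out d1.tsv
exomir compare d1.tsv d4.tsv --metadata sim/metadata.tsv --out cmp.tsv
```

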