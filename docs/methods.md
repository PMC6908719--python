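# Methods

## The analysis model

`pepgo` implements a peptide-centric quantification of community
function and taxonomy from shotgun metaproteomics spectral counts.

**GO propagation.** Let P be the set of retained peptides in a run and
c(p) the spectral count of peptide p. Each peptide carries a GO set
G(p): the union over its matched proteins of their annotated terms,
closed under ancestors (is_a and, by default, part_of edges). The count
of term t in the run is

    n(t) = Σ_{p : t ∈ G(p)} c(p)

Each peptide contributes once per term regardless of how many matched
proteins carry the term or how many DAG paths reach it — this is the
point of peptide-centric counting: protein inference and double
counting never enter. Counts are therefore monotone: n(parent) ≥
n(child), and n at an aspect root is at most the run total N (the sum
of all retained bacterial peptides' counts, including peptides whose
proteins carry no GO terms).

**Taxonomy.** Each peptide's taxon is the LCA of its matched proteins'
top-hit taxa (one precomputed top hit per protein; the package never
re-ranks homology hits). Reporting is at class rank: the LCA is rolled
up to its class ancestor; when that fails (no taxon, LCA above class,
or no class on the path) the spectra land in the reserved
`Unclassified` bucket. Peptides whose LCA lies outside the Bacteria
subtree — and, by default, peptides with no taxon at all — are removed
before any denominator is formed (`keep_untaxed` reverses the latter).

**Enrichment between runs.** Tested family = terms with nonzero count
in either run (size m). Effect size is the add-one (Laplace) corrected
log2 fold change; add-one is applied to both the count and the total of
each run, which keeps zero counts finite and makes the statistic
antisymmetric under swapping runs. Significance uses the pooled
two-sample z-test of proportions without continuity correction (its z²
is exactly the 1-df chi-square statistic on the 2×2 table, which the
tests use as an oracle); p-values are Bonferroni-corrected with
multiplier m. Only terminal terms — members of the tested set with no
strict descendant also in the tested set — can be called significant:
an ancestor's count is (at least) the sum of its descendants', so
testing it alongside them is redundant. Correcting over the observed
family rather than the whole ontology, and judging terminality against
the observed set, are deliberate dialect choices; both alternatives
are exposed (`terminal_mode="ontology"`).

**Rates of change and the permutation test.** A ratio matrix holds per
row (GO term or class) and per day the fraction of the run's spectra
assigned to that row. The per-row rate is the *mean* of per-interval
absolute slopes |Δv|/Δd — a per-day quantity; the sentence "sum of the
absolute differences divided by the days between time points" admits a
sum-of-interval-rates reading too, so `rate_mode="sum"` exposes it. The
default day grid for rate analysis is {0, 1, 6}. The test statistic is
the difference in group-mean rates between the functional and the
taxonomic matrix. The null is built by pooling all rows and reassigning
group labels without replacement (`perm_mode="rows"`, 10,000
replicates by default); the alternative reading — shuffling time points
within rows — is implemented as `perm_mode="within-row"`. The
two-sided p-value uses the add-one estimator
(1 + #{|null| ≥ |observed|}) / (n_perm + 1), so its floor is
1/(n_perm+1) ≈ 1e-4 at the default and it is exactly reproducible from
the seed. Missing time points (a compromised sample, say) are handled
by dropping the column; interval lengths adjust automatically and
nothing is interpolated.

**Concordance.** Peptide class abundances vs. a 16S OTU class table:
vectors aligned on the label union (Unclassified excluded, missing
classes zero-filled), sample Pearson r with the t-distribution p-value
on n−2 df, pooling class × time-point pairs per experiment (so n counts
pairs, not classes). Rare-class display filtering (e.g. ">1%") is
presentation-only and off by default (`min_fraction`).

## Matching

Peptide-to-protein matching is exact substring search under I/L
equivalence (isobaric residues are indistinguishable in the MS data;
a flag disables the folding). The matcher concatenates normalized
protein sequences with a sentinel and answers queries by repeated
`str.find`; an unmatched peptide is reported, retained in the
annotation table, and excluded from all downstream counts.

## The synthetic-data generator

`SimConfig` defaults define the study conditions:

| parameter | default | meaning |
| --- | --- | --- |
| n_classes | 6 | bacterial classes (under 2 phyla, plus 1 eukaryote branch) |
| n_proteins | 300 | metagenome proteins, 1–4 leaf GO annotations each |
| n_go_terms | 60 | GO terms across 3 aspect roots |
| n_peptides | 2000 | unique peptides, substrings (8–15 aa) of their source proteins |
| total_spectra_per_run | 20,000 | one multinomial draw per run |
| days | 0, 1, 6, 10 | sampled time points, two treatments (om / control) |
| n_spiked / spike_log2_range | 6 / (2.2, 3.8) | spiked terminal terms, sign-balanced |
| spike_ramp_days | 1.0 | spike effect realized by day 1, then held |
| lca_ambiguity_rate | 0.15 | peptides planted verbatim across classes (LCA above class) |
| nonbacterial_rate | 0.02 | peptides from the eukaryote branch |

Design choices worth knowing:

* **Spike semantics.** A drift d means a carrier-weight multiplier of
  2^(d·min(day, ramp)). Letting a per-day drift compound through day 10
  would multiply weights by >2^20 and make the spiked term consume the
  run; a ramp-and-hold profile instead matches bloom-type responses
  where the largest changes occur within the first interval and
  persist.
* **Marker terms.** Auto-chosen spiked terms are reserved leaf terms
  carried only by dedicated single-annotation proteins, so spiking one
  term induces no effect on any other terminal term. Explicit
  `spiked_terms` lists skip this machinery.
* **Compositional balance.** Proportions are compositional: a one-sided
  spike inflates the run total and drags every null term's proportion
  down, which at 20,000 spectra is itself detectable. Default spikes
  therefore alternate sign, each up/down pair shares a taxonomic class,
  and the down-carrier base weights are scaled so the pair's net weight
  change is zero. Consequences: null-term proportions are constant
  across days, and the class composition is constant up to sampling
  noise — the generated world has fast functional change over a quiet
  taxonomy, and `truth_eval`'s specificity measures false positives
  rather than real compositional side effects.
* **Ambiguity and removal.** Ambiguous peptides are planted verbatim
  into a host protein of a different class (plants never overwrite a
  region carrying another peptide's only copy); their LCA lands above
  class rank and they populate the Unclassified bucket. 16S truth
  tables use the *organism* (source-protein) class, so concordance is
  computed against a source that sees through peptide-level ambiguity,
  as real amplicon data would.

What the generator does **not** emulate: spectrum-level noise and FDR
(counts arrive as a clean 1%-FDR-style PSM table), peptide
detectability and length biases, protein abundance correlation
structure, run-to-run technical variation beyond multinomial sampling,
and sequence homology between proteins (sequences are i.i.d. random, so
accidental peptide sharing is essentially absent). Passing tests
therefore demonstrate correctness and calibration of the statistics
under the stated sampling model, not robustness to search-engine
artifacts or homology-driven ambiguity in real data.

## Numerical and degenerate-input choices

* Proportion test: returns 1.0 when the pooled proportion is 0 or 1;
  z-tests are vectorized over terms.
* Enrichment results sort by corrected p, ties broken by GO id
  (deterministic output files).
* `row_rate` requires ≥2 strictly increasing days; ratio cells must lie
  in [0, 1].
* Empty runs, zero-count terms asked for proportions, unmatched
  manifests, and cyclic ontologies/taxonomies raise typed errors that
  the CLI maps to exit codes 2 (input) and 3 (integrity).
* GO ids on proteins that are absent from the ontology are dropped with
  a warning rather than failing the run (ontology slims are common).
* Ranks outside the canonical 8-rank set collapse to "no rank" and are
  skipped during rollup, so intermediate ranks never block class-level
  reporting.

## Problem sizes used in the shipped tests and acceptance script

Oracle-equivalence checks run 100 random instances per operation
(DAGs ≤ 50 terms, trees ≤ 200 nodes). Calibration uses 200 null run
pairs at the default 20,000 spectra and 220 permutation-test datasets
at 400 permutations; recovery uses 10–15 replicate studies at full
default size. The whole suite completes in well under a minute; these
sizes were chosen so the statistical assertions have comfortable
margins while iteration stays fast.

## Known limitations

* The LCA uses top hits only; proteins with wrong top hits propagate
  their error silently (no hit re-scoring is in scope).
* Bonferroni over the observed family is conservative when counts are
  propagated (ancestor counts are strongly dependent on descendants).
* The permutation test treats rows as exchangeable units; rows of the
  functional matrix are not independent of each other (terms share
  peptides), which the row-label null ignores — the same caveat applies
  to any row-level permutation of propagated data.
* `Unclassified` is excluded from taxonomic rate rows and from
  concordance; analyses dominated by unresolvable peptides will look
  artificially quiet at class level.
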