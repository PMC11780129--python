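# Methods

## Nick detection model

A single-strand nick prevents any native molecule of that strand from
spanning the break, so strand-specific read depth collapses there while
three controls stay normal: the opposite native strand, and both strands of
the amplified (WGA) sample. `detect_drops` operationalizes this as a
per-position test on each strand *s*:

    native_depth_s(x)   <= max(tau_abs, tau_rel * median_s)      (depleted)
    native_depth_o(x)   >= min_other_strand * median_o           (other strand intact)
    control_depth_s(x)  >= min_control * control_median_s        (WGA intact)

Marked positions within `merge_gap` bp merge into intervals; intervals
touching the first or last 200 bp are discarded because the physical ends
of a linear genome produce coverage cliffs of their own. Defaults:
`tau_abs = 2` reads and `tau_rel = 0.05` ("near-zero" rather than strictly
zero, tolerating rare read-through or chimeric molecules),
`min_other_strand = min_control = 0.5`, `merge_gap = 5`,
`min_callable_median = 10` (below which calling errors out rather than
guessing). Both strands are tested symmetrically: assembly orientation is
arbitrary, so the depleted strand is reported, not assumed. The nick point
estimate is the interval midpoint; the exact nick base within the motif is
not identified.

`associate_motif_hits` pairs intervals and motif occurrences greedily by
ascending midpoint distance within a 50 bp window, each hit used at most
once; ties break on coordinates, making the matching deterministic.

## Motif model

Motifs are IUPAC degenerate patterns. Scanning uses overlapped regular
expression search on the forward sequence with the pattern and its
IUPAC-aware reverse complement; overlapping occurrences count separately,
ambiguous genome bases never match, and the genome is treated as linear
(no origin wraparound). The chance expectation under an i.i.d. base model
is per strand

    E = (L - k + 1) * prod_i sum_{b in code_i} p(b)

with `p` either uniform (0.25 each) or the genome's own A/C/G/T fractions
computed ignoring ambiguous bases. For `WACTRTGAC` (k = 9, 4 concrete
k-mers) on a 45,228 bp genome with uniform composition this gives
E = 45,220 · 4/4⁹ = 0.690 ≈ 0.7 per strand. Whether the window count should
be L or L − k + 1 is immaterial at genome scale; both are exposed
(`count_full_length`), as is a both-strands variant (2E). The per-genome
summary statistic is the *net strand difference* |n₊ − n₋|, reported as an
absolute value because strand labels are not comparable across independent
assemblies.

### Consensus finder

`consensus_from_sites` stands in for a motif-discovery tool on nick-site
windows, but is deterministic: for k from `k_max` down to `k_min`, each
k-mer of the first window serves as an anchor; every other window
contributes its minimum-Hamming-distance k-mer, the choices are refined
against the column base-frequency profile (two iterations suffice for
planted sites — this resolves chance Hamming ties in favour of the mutually
consistent k-mer set), and the aligned columns merge into IUPAC codes. A
candidate is valid when every column has at most 2 alternative bases and at
most `max_degenerate_cols = 3` columns are degenerate at all (without this
cap any two windows would merge into a vacuous all-ambiguous pattern).
Ranking is longest k, then fewest degenerate columns, then lexicographic.
"No consensus" is an explicit result, not an error. This is not a PWM/EM
discovery method and will not find motifs that require mismatch-tolerant
or variable-gap models.

## wGRR

wGRR(A,B) = Σ over bidirectional best hits of identity / min(|A|,|B|).
Protein pairs are aligned globally (Biopython PairwiseAligner, BLOSUM62,
gap open 11 / extend 1); identity defaults to identical pairs over all
alignment columns including gaps, with a `shorter`-sequence denominator as
an option because the convention varies between wGRR implementations. BBH
pairs must pass 35% identity and 50% coverage (aligned span over the
shorter sequence) — common practice where no single standard exists.
Clustering is average-linkage on 1 − wGRR with a user-set cut (flat
clusters at distance 1 − cut); all-vs-all alignment is O(n²) pairwise DPs
and is intended for desk scale (≲100 genomes × ~100 proteins).

## Positional statistics

Genomes are reverse-complemented (when terL is on the minus strand) and
rotated so the unique CDS whose product contains "terminase large subunit"
starts at 0 on the plus strand. Rotation treats coordinates as circular for
bookkeeping although the molecules are linear; a CDS that would span the
new origin cannot be represented as a single linear interval and is dropped
with a warning (the synthetic generator rotates at intergenic points, so
this never happens in the test data). Motif positions use the hit's central
base: relative genome position = midpoint / L; CDS-relative position =
offset of the midpoint from the start codon over CDS length, measured
5'→3' on the CDS strand and clamped to [0, 1]. Whether a hit is "inside" a
CDS is decided by any-overlap by default (matching the "at least partly
within" reading), with a midpoint mode available; hits spanning two CDS go
to the one containing more of the hit, ties to the smaller start. Coding
density is the fraction of bases under the CDS interval union.

## Synthetic data

The generators' defaults are the study conditions the package is tested
under, not tuning knobs:

- **Nicked genome** — 45,228 bp, GC 0.525, 13 `WACTRTGAC` occurrences
  planted on the minus strand at jittered, ≥500 bp-spaced positions ≥500 bp
  from the ends, concrete variants drawn uniformly from the 4-mer expansion;
  one nick at each planted motif's central base. Chance background
  occurrences of the motif are found by scanning and recorded in the truth.
- **Reads** — lengths ~N(4000, 2000²) truncated at 200 bp, strand uniform,
  drawn per strand until 50× per-strand coverage; molecule intervals are
  sampled before clipping at the termini so end coverage stays flat, as it
  is for real linear molecules whose fragments abut the physical ends.
  Native molecules on the nicked strand are cut at every nick they span.
  Each cut end additionally loses `nick_end_loss = 25` bp, emulating the
  terminal-base loss of real nicked molecules — without some terminal loss
  the two cut fragments would jointly cover every base and no depth trough
  would exist at all. Reads carry no sequencing errors by default (nick
  calling consumes only coordinates); uniform substitution noise is
  available for I/O realism, and a read-through probability models nicks
  that are not fully penetrant. Alignments are emitted as coordinate-sorted
  SAM with exact full-match CIGARs.
- **Annotation** — gene lengths ~N(900, 150) bp and exponential gaps,
  rescaled so the CDS union hits the target coding density (default 0.89)
  to within rounding; strand switches come in runs; one gene is labelled
  "terminase large subunit".
- **Family** — 10 clade + 10 outgroup genomes of 20 kb, 12 proteins of
  120 aa each, descending from a shared ancestral set by i.i.d.
  substitution with per-genome retention √0.9 (within-clade pairwise
  identity ≈ 0.9) and a clade ancestor mutated to 0.2 identity
  (between-clade ≈ 0.18). Clade genomes get Uniform(8, 12) same-strand
  motifs planted at 52–95% of the terL-oriented genome; outgroup genomes
  get Poisson(0.7) occurrences on random strands — 0.7 being the chance
  expectation for a 45 kb genome. Each emitted genome is randomly flipped
  and rotated (recorded in the truth) so reorientation is genuinely
  exercised. Protein evolution has no indels, keeping identity targets
  analytic; family sizes are desk-scale choices so the all-vs-all
  alignment stays cheap.

What passing tests on these simulations do *not* show: robustness to
mapping artifacts, ONT homopolymer errors, chimeric reads, repeats,
partially nicked populations, or annotation errors — the simulators model
none of these beyond the optional substitution and read-through knobs.

## Numerical and design choices

- Internal coordinates are 0-based half-open throughout; GFF3 is converted
  at the boundary (1-based inclusive), BED is written 0-based half-open.
- Mapping quality 0 reads are kept by default (small non-repetitive
  genomes; long-read single-end data, strand from the orientation flag).
- Depth from alignments uses difference-array accumulation; verified in
  tests against a per-read per-base counting loop.
- Hierarchical clustering labels are renumbered by first-member appearance
  and leaf order is exported, so outputs are deterministic.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give byte-identical output bundles, and report tables carry their
  resolved parameters in `#` headers with no timestamps.

## Known limitations

- The nick base within the motif is not resolved; calls report intervals
  and distances only.
- Circularly permuted genomes with genes spanning the terL rotation point
  lose those genes from the positional table (warned, not silent).
- The expectation model is i.i.d.; genomes with strong local composition
  bias will deviate from it.
- wGRR values depend on the identity convention and BBH thresholds; both
  are configurable but defaults were chosen once, as stated above.
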