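# Methods

This note documents the models, defaults, and numerical choices behind
`tcrscreen`, and what the synthetic-data tests do and do not demonstrate.

## Germline model and coordinates

Segments are stored with 0-based, half-open coordinates. `anchor_offset`
points at the first base of the conserved anchor codon — the cysteine near
the 3' end of a V gene, or the phenylalanine/tryptophan of the F/W-G-X-G
motif in a J gene — and is validated on load. The CDR3 **junction** is
defined IMGT-style as the interval from the first base of the V anchor codon
through the last base of the J anchor codon, inclusive of both anchors. The
junction *owns* both anchor codons: in stitching, the germline V contributes
up to (excluding) its anchor and the germline J from just after its anchor,
which prevents double-counting at the boundaries.

The bundled reference (`data/germline_synthetic.*`) is a **synthetic**
IMGT-like fixture generated once by `scripts/make_germline_fixture.py`:
4 V (48-nt leader + 180-nt body + anchor + 15-nt germline tail, 228 nt
total) and 3 J (21-nt trimmable head + anchor + 24-nt F/W-G-X-G region)
per chain, one TRBD (12 nt), and one 120-nt constant region per chain.
Sequences are random stop-free codons screened to contain none of the four
cloning sites; V tails and J motifs use CASS/CAV- and FGXG-style codons so
junction translations look realistic. Gene names follow IMGT nomenclature
but the sequences are not IMGT alleles. An allele-collapsing flag
(`collapse_alleles`) strips `*NN` suffixes when loading real references;
the default keeps names verbatim.

## Repertoire and read simulation

Each chain is assembled as trimmed V + N-insert (+ trimmed D + N-insert for
β) + trimmed J. Defaults, chosen to give human-plausible junction length and
diversity at desk scale:

| parameter | default | meaning |
|---|---|---|
| `trim_mean` | 2.5 nt | geometric (support 0,1,2,…) exonucleolytic trimming per segment end |
| `n_insert_mean` | 5 nt | Poisson N-nucleotide insertion length per junction |
| `abundance_exponent` | 1.0 | Zipf exponent of clone frequencies (0 = uniform control) |
| `productive_frac` | 1.0 | fraction of clones resampled until in-frame and stop-free |
| `chimera_rate` / `residual_chimera_rate` | 0.9 / 0.02 | mispairing probability with suppression PCR off / on |
| `read_length` / `error_profile` | 300 / Q30 | 2×300 MiSeq geometry; per-base substitution rate 10^(−Q/10) |

Junctions are resampled until in frame and stop-free; trims are clipped so
anchors survive, with a bounded retry budget. Clones are additionally forced
to have pairwise-distinct CDR3β junctions at both the nucleotide and
amino-acid level, so that amino-acid clone tracking has an unambiguous
ground truth. Abundances are normalized Zipf weights over clone rank.

Suppression PCR is modeled as a single effective rate, not hybridization
kinetics: each emitted amplicon is chimeric with probability
`chimera_rate` (suppression off) or `residual_chimera_rate` (on), in which
case its α and β are drawn independently from the abundance distribution. A
chimeric draw that picks the same clone twice counts as correctly paired,
so the expected mispaired fraction has the closed form `rate · (1 − Σ aᵢ²)`.
Note that the *correctly-paired* fraction without suppression is bounded
below by `1 − rate`, so the benefit of suppression is quantified as the
fold-reduction of the **mispaired** fraction (complete elimination at
residual rate 0).

Activation sorting draws presort counts from `multinomial(depth, a)` and
sorted counts from the renormalized weights `a·F` (designated specific
clones, activation factor F > 1) and `a·B` (background retention B ≤ 1,
default 1). The closed-form expected enrichment ratio of a specific clone is
therefore `F / (F·S + B·(1−S))` with `S = Σ specific abundance` — note the
renormalization: strongly abundant designated clones *lower* their own
expected ratio, which is why desk-scale screens designate mid-rank clones.

Paired-end emission writes R1 as the first `read_length` bases of the
β-first linked amplicon and R2 as the reverse complement of its last
`read_length` bases (mate orientation and linker are configuration inputs;
the default 30-nt linker carries the SpeI and MluI swap sites). β-only mode
emits one merged read spanning the ~450-bp β recovery amplicon. Errors are
substitution-only by default — MiSeq indel rates are low and indels would
confound the frame-based productivity logic that the tests exercise.

## Quality filtering and demultiplexing

A read is kept iff bases with Phred ≥ `q_threshold` (default 20, i.e. 99%
accuracy) make up at least `min_fraction` (default 0.5) of its length; both
boundaries are inclusive, `N` bases never count as passing, and under the
default pair policy both mates must pass. The per-sample index barcode is an
exact-prefix match by default; barcodes within `max_mismatches` of each
other are rejected as a configuration error, and ties go to the
undetermined bin.

## Annotation

Segments are assigned by semi-global alignment (end gaps free on both
sequences) with +1/−1 match/mismatch and affine gaps −4/−1 (a run of length
L costs 4 + (L−1)); both orientations are tried and the better combined
V+J score wins, with ties broken by lexicographically smallest gene name
for determinism. Acceptance thresholds default to V ≥ 50, J ≥ 15 — roughly
half the available V coverage on the shorter (α) mate and a third of the J
length, low enough that only non-TCR sequence is rejected. Anchor codons
are mapped through the alignment and must fall gap-free inside one aligned
block; reads failing any step carry a machine-readable exclusion reason and
annotated + excluded always reconciles to the input count. D segments are
never called: downstream keys use CDR3 + V/J identity only. Identical read
sequences are annotated once (amplicon libraries are highly redundant); the
memoization is exact, not approximate.

## Clonotyping

Percent identity between CDR3β nucleotide sequences is computed from the
optimal end-gap-free global alignment: columns inside leading/trailing gap
runs of either sequence are excluded ("ignoring terminal gaps"), internal
gap columns count toward the denominator but never as matches. A fast path
returns the Hamming identity for equal-length pairs with ≤ 3 mismatches;
this equals the alignment identity exactly, because rescuing ≤ 3 mismatches
would cost at least two gap runs (≥ 8) for a gain of ≤ 6. One consequence
of the end-gap-free definition is that a clean truncation scores identity
1.0 regardless of length difference.

Greedy clustering is fully specified for order independence: clonotypes are
visited by decreasing total read count (ties by lexicographic CDR3β), and
each joins the first centroid in creation order reaching the 96% threshold,
else founds a new cluster; member-vs-centroid identity is asserted on every
run. Clusters with fewer than 2 reads (totaled across the library's
samples; a per-sample option exists) are removed, and surviving clusters
sharing a centroid CDR3β amino-acid sequence merge into one tracked clone.
Because clustering is intentionally tolerant, truth clones whose junctions
are genuinely ≥ 96% identical (same V/J, near-identical N regions) can
collapse into one tracked clone; at the default simulation settings this
affects at most a few clones in 300 and is the same homology-collapsing
behavior expected of the screening analysis on real repertoires.

## Enrichment

Frequencies use the per-sample filtered-read totals. A clone absent from
the presort gets pseudo-frequency `0.5 / presort_total` and an explicit
`presort_absent` flag rather than an infinite ratio. A hit requires a ratio
*strictly* greater than the 10-fold threshold **and** ≥ 2 sorted reads —
the read guard extends the pipeline's general aversion to singleton
evidence to the hit call. No significance test is attached to the ratio;
the screen is a ranking, not an inference procedure.

## Construct design

The cassette is AgeI · modified β leader · β V(D)J + Cβ 5' part · SpeI ·
Cβ remainder · P2A · modified α leader (carrying MluI) · α V(D)J + Cα ·
stop · BstBI, a single ORF from the β start codon to the α stop. Recognition
sequences (AgeI ACCGGT, BstBI TTCGAA, MluI ACGCGT, SpeI ACTAGT — all
palindromic 6-cutters, checked against a standard enzyme reference) ship as
a built-in registry. Leaders, Cβ remainder and linker are synthetic config
fixtures (`data/cassette_elements_synthetic.yaml`); the P2A is the canonical
teschovirus-derived sequence. Assembly enforces: each site exactly once,
ORF stop-free to the terminal stop, P2A in frame. Chains whose junctions
happen to contain a cloning site fail assembly and are counted by the
repertoire-loss estimator; on the synthetic fixture roughly 1–3% of clones
are lost this way (junction-adjacent novel sequence is the only place sites
can arise, since the fixture germline is screened site-free).

Silent-site design enumerates every placement of the recognition sequence,
rewrites exactly the differing bases, and accepts a placement iff every
altered codon stays synonymous (edits in codons incomplete within the
region are never accepted as silent); results rank by (edits, offset). This
direct construction is provably the minimal-edit design per placement and
is cross-checked against exhaustive synonymous-codon enumeration in tests.

Blocking oligos are a seeded random nonsense tail (default 20 nt) joined to
the reverse complement of the chain's 3' terminal region; tails must share
no 8-mer — on either strand — with the terminal regions, the linker, or
each other, removing the sequence homology that drives overlap-extension
mispairing while leaving linked amplicons untouched.

## Problem sizes and determinism

Desk-scale study points used by the test suite and the acceptance script:
clone recovery at 300 clones × 30,000 read pairs × Q40 with suppression on;
enrichment recovery at activation factor 25, three designated mid-rank
clones (abundances ≥ 5×10⁻³) × depth 50,000 × 10 sort replicates; chimera
checks at depth 10,000 with 3-binomial-SD tolerances; the demo screen at
150 clones × 10,000 reads per sample. Every stochastic component consumes a
`numpy` generator seeded from one top-level seed through distinct
`SeedSequence` streams, so identical parameters give byte-identical FASTQ
and identical manifests.

## What the synthetic tests do not show

The generator emulates clone skew, junctional diversity, chimera formation,
sort enrichment, and Phred-dependent substitution error. It does not model
PCR amplification bias, per-cycle quality decay, indels, droplet
co-occupancy, allele-level germline variation, or cross-sample index
hopping; and with 4 V × 3 J synthetic segments per chain, V/J assignment is
far easier than against the full IMGT gene set. Passing recovery tests
therefore demonstrate correctness of the pipeline's logic under its own
stated error model, not benchmark performance on real MiSeq libraries —
real-data runs use the same entry points with an IMGT reference and
deposited FASTQ.
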