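# Methods

## Candidate regions

Bacterial translation initiation is controlled at the ribosome binding
site (RBS); trans-acting small RNAs typically repress translation by
pairing across it. `mirabind` therefore restricts the search to a
window anchored at each CDS start: `upstream` nt strictly before the
first base of the start codon plus `downstream` nt beginning with (and
including) that base. The defaults (15, 20) give a 35-nt candidate
sequence. The two offsets are independent configuration parameters
because the RBS literature quotes both (−15…+20) and (−20…+15) style
extents; either reading is one config edit away.

Only CDSs strictly longer than `min_cds_len` (default 150 nt) are
screened, a conservative guard against annotation artifacts on very
short ORFs. Windows are reported in transcript orientation (reverse
complemented for minus-strand CDSs), so position 0 of the window is the
5'-most base of the mRNA fragment. Windows that would run off a contig
edge are clipped and flagged rather than dropped — contigs from
metagenome-assembled genomes are fragmented, and discarding edge genes
would silently bias per-genome counts. Windows containing N are dropped
(pairing with N is undefined) with a logged count.

For accessibility scoring each window is extended by `extension`
(default 150) nt on **each** flank, clipped at contig bounds; the
window's offset inside the extended sequence is tracked so duplex
coordinates can be mapped into folding coordinates exactly.

Internally all coordinates are 0-based half-open; GFF3's 1-based
inclusive convention is converted only at the file boundary.

## Hybridization model

The duplex stage finds the intermolecular minimum-free-energy
configuration of the full mature miRNA against a candidate window: an
antiparallel chain of base pairs (G:C, A:U/T, G:U/T wobble; T and U are
interchangeable pairing partners so DNA windows pair directly with RNA
miRNAs) optionally interrupted by bulges and internal loops. No
intramolecular pairs are allowed at this stage. The energy of a
configuration is

```
E = Σ pair energies + e_stack · (#adjacent pair columns) + Σ loop penalties
```

with an affine loop cost (open + ext per additional unpaired base;
a gap on one side is a bulge, on both sides an internal loop). The
dynamic program is exact over this model (O(n²m²), with predecessor
tie-breaks resolved nearest-first so outputs are deterministic), and a
configuration needs at least two pairs and negative energy to be
reported. One best hit per (miRNA, window) pair is kept; ties resolve
to the smallest target start, then the configuration with more pairs.

### Energy table

The table is deliberately simple and lives entirely in `EnergyParams`,
so a full nearest-neighbour table could be substituted. The defaults
are

| parameter | value (kcal/mol) |
|---|---|
| e_GC / e_AU / e_GU | −2.0 / −1.5 / −0.5 |
| e_stack (per adjacent pair) | −1.0 |
| bulge / internal loop open | +10.0 |
| bulge / internal loop extension (per nt) | +4.0 |
| helix initiation (folding model only) | +10.0 |
| RT | 0.6163 (310.15 K) |

The calibration principle: stability must be concentrated in
*contiguous* helices. During development we measured that tables with
strong per-pair intrinsic energies and cheap loops (e.g. pairs at
−3/−2/−1 with internal-loop open at +2) let random 35-nt windows reach
−33 kcal/mol on average against a random 22-nt miRNA — every window
would pass a −20 kcal/mol screen, because isolated pairs scattered
across 1×1 loops accumulate energy that no real duplex would have.
With the stiff loop penalties above, a random miRNA×window pair scores
−13.5 on average (≈3 % of pairs cross −20), while a perfect 22-nt
complementary site scores ≈ −58 to −78 depending on GC content. The
widely used −20 kcal/mol cutoff is therefore meaningful under this
table at the packaged window size, which is the property the screen
needs; absolute energies are *not* comparable to Turner-parameter
tools, and the cutoffs should be re-calibrated if the table is swapped.

### Significance

Best-hit energies of a fixed query against fixed-length sequences
follow extreme-value statistics. For each (miRNA, window) pair the null
is built explicitly: the window is dinucleotide-shuffled
(Altschul–Erickson Eulerian-walk shuffle, preserving exact dinucleotide
composition and hence local stacking propensity) `null_shuffles`
(default 200) times, the best duplex score x = −ΔG is computed for each
shuffle (0 when no duplex exists), and a Gumbel distribution is fitted
by the method of moments (β = s·√6/π, μ = x̄ − γβ). The reported
p-value is `1 − exp(−exp(−(x−μ)/β))`; the add-one empirical rank
p-value `(r+1)/(n+1)` is reported alongside but does not gate the
filter. A degenerate null (all scores identical) forces p = 1 with a
warning. Null streams are keyed by (run seed, miRNA id, genome id, CDS
id) via a CRC-mixed seed sequence, so results are independent of
iteration order and byte-reproducible for a fixed seed.

An optional seed constraint (positions `seed_start…seed_end`, 1-based
on the mature miRNA) requires those positions to be paired in the hit;
it is off by default — bacterial-style regulation does not respect the
eukaryotic seed convention, so the full mature sequence is used.

## Accessibility

A site buried in stable mRNA structure must first be melted out. The
opening energy is computed from two partition functions over nested
secondary structures of the extended window:

```
ΔG_open = G_constrained − G_ensemble = RT · ln(Z / Z_unpaired) ≥ 0
```

`Z_unpaired` sums only structures in which every base of the duplex
footprint (the hit's target interval mapped into the extended window)
is unpaired; the constraint can only remove structures, so ΔG_open is
non-negative by construction and the final score composes exactly:
ΔG_total = ΔG_duplex + ΔG_open.

The folding model uses the same pair energies and stacking bonus as the
duplex stage plus a helix-initiation penalty charged once per maximal
helix. Initiation is what keeps the two stages commensurable: without
it, an isolated pair is worth its full pair energy, random 300-nt
contexts accumulate tens of kcal/mol of spurious "structure", and
opening even a site buried under a perfect stem could never cost more
than the duplex gains — structural decoys would be undetectable in
principle. Because the number of maximal helices equals pairs minus
stacked pairs, the penalty folds into the same recursion (pair′ =
pair + init, stack′ = stack − init), and the McCaskill-style O(n³) DP
is run in log space (no under/overflow for any window length). The
minimum hairpin loop is 3 nt; pseudoknots are out of scope.

Extended windows longer than 400 nt (possible only under non-default
configs) are trimmed symmetrically around the site with a warning to
bound the cubic cost.

## Filter cascade and outputs

A hit becomes a prediction iff p < `pval_cutoff` (0.01) **and**
ΔG_duplex < `mfe_cutoff` (−20) **and** ΔG_total < `dg_total_cutoff`
(−15), all strict. Accessibility is computed only for hits passing the
first two tests (the fold is the expensive stage); a surviving hit with
no accessibility score is a pipeline error, never silently kept.
Filtering is a pure row-wise function: permuting input rows permutes
output rows, and tightening any threshold can only shrink the output.

Outputs: the comprehensive table, summaries grouped by miRNA and by
genome with distinct-count semantics (a miRNA hitting 2 genes in 1
genome counts n_genomes = 1, n_genes = 2), top-20 rankings with
lexicographic tie-breaks, a candidate-window FASTA for debugging, and a
run manifest (all parameters, SHA-256 of every input, tool version).

## Comparative analysis

When metadata defines ≥ 2 groups, predictions are partitioned by group
and exact set overlaps are computed for miRNAs, genes and species-level
taxa: for every non-empty subset S of groups, the region holds elements
present in all groups of S and absent elsewhere, so region counts sum
to the union size for any number of groups (the classical 2- and
3-group Venn figures are the special cases). Species labels come from
the metadata taxonomy string (the `s__` field when GTDB-prefixed, else
the last semicolon-separated field); genomes without a species label
are excluded from taxon overlaps with a warning.

Cross-genome gene identity is genuinely ill-defined for MAGs. The
convention here — `gene_name` when present, else the lower-cased
`product` string, else the genome-local CDS id (never shared) — is the
single most consequential labelling choice in the comparative stage and
is deliberately surfaced in both docs and logs. miRNA labels are
compared verbatim; comparing across host species requires the user to
harmonize names first.

## Differential function abundance

Each genome is one sample; its predicted target genes are mapped to
functions through the user-supplied table (one gene may carry several
functions, e.g. at different hierarchy levels). Function counts are
normalized within-sample to relative abundances (samples with no
annotated target genes are dropped with a warning). Functions are kept
when their mean relative abundance across all samples is ≥
`min_rel_abundance` (0.01), they are present in ≥ `min_prevalence`
(20 %) of all samples, and they occur in every group being compared.
Whether the abundance threshold applies per sample or to the
cross-sample mean is a judgment call; the mean is used because a
per-sample rule interacts badly with small per-genome gene sets.

Surviving functions are tested with the two-sided Wilcoxon rank-sum
test: exact null enumeration when the combined sample size is ≤ 12 and
tie-free, otherwise the normal approximation with tie and continuity
corrections (the branch used is recorded per function). P-values are
Benjamini–Hochberg adjusted; effect size is
log₂((mean_A + ε)/(mean_B + ε)) with pseudocount ε = 10⁻⁶ and groups
ordered alphabetically (recorded in the output header). A function is
significant iff adjusted p ≤ `alpha` (0.05) and |log₂FC| > `lfc_min`
(1). A looser profile (prevalence > 0.05, adjusted p < 0.1) matching
published large-scale usage ships as `REAL_DATA_PROFILE`.

## Synthetic fixtures

The generator emulates the pipeline's real inputs at desk scale:
uniform-composition contigs (4 kb, 4 CDSs of 300 nt, one on the minus
strand) carrying CDSs with valid start/stop codons, stop-free frames,
an in-frame stop guard just upstream of each candidate window and an
upstream region free of in-frame start codons — so the naive six-frame
ORF caller rediscovers ≥ 90 % of planted CDSs exactly. Mature miRNAs
are 22 nt (canonical length) at GC ≈ 0.55, which puts a perfect helix
near −60 kcal/mol, far below the −20 screen.

Sites are planted as the reverse complement of a miRNA written in
transcript orientation; decoy classes each defeat exactly one stage:
`cds_interior` (200 nt into the CDS, outside any window), `intergenic`
(clear of every window by at least the extension), `mismatched_k`
(k evenly spaced positions mutated to bases that can neither
Watson–Crick nor wobble pair; the demo uses k = 10, which leaves no
helix segment longer than ~2 pairs), and `hairpin` (a site carrying two
mismatches to the miRNA whose *exact* complement is planted as an arm
8 nt upstream in the extended context: the perfect intramolecular stem
outcompetes the interrupted duplex, so ΔG_open pushes ΔG_total above
−15). The two-mismatch detail matters: for a perfectly complementary
site, duplex and stem share the same pairs, and the duplex always wins
by the initiation penalty — a fully perfect buried site is not
rejectable under this model family, so the structural decoy is defined
with the asymmetry that makes the physics discriminate.

Generation is constructive: after assembly the generator re-scores
every planted truth with the package's own engines and enforces margins
(true sites and the hairpin's duplex clear the MFE cutoff by ≥ 2
kcal/mol; the mismatched decoy misses it by ≥ 2; the hairpin's ΔG_total
misses its cutoff by ≥ 2), and any non-planted (miRNA, window) pair
that crosses the MFE cutoff by chance (≈3 % of random pairs) triggers a
deterministic, bounded resample of that contig's background. Fixtures
are byte-identical under a fixed seed (default 7 for the demo spec);
per-genome streams are keyed by (seed, genome id, attempt).

The Poisson count simulator for the statistics stage plants shifted
functions at a smaller baseline (20 vs 100 expected counts) so that a
4-fold count shift survives within-sample renormalization with
|log₂FC| ≈ 1.7.

What the fixtures do **not** emulate: real genome composition and codon
bias, operon structure and leaderless transcripts, annotation noise,
miRNA families with shared seeds, and cross-genome gene homology beyond
identical generator-assigned names. Passing the planted-recovery tests
therefore demonstrates that the machinery is correct and calibrated
under its own model — not that the energy model predicts in vivo
interactions; like the tools it emulates, the pipeline is a
hypothesis-generating instrument.

## Problem sizes and numerics

The packaged demo (6 genomes × 4 CDSs × 5 miRNAs, 200-shuffle nulls)
runs the full pipeline in well under a minute; oracle test batteries
use miRNA ≤ 8 / window ≤ 12 for duplex enumeration and length ≤ 12 for
structure enumeration, where exhaustive search is exact and fast.
Partition functions are evaluated in log space with `logaddexp`
accumulation (observed agreement with enumeration ≈ 1e−15 absolute);
opening energies are clamped at 0 against representation error. The
duplex and folding kernels are numba-compiled with a transparent
pure-Python fallback of identical semantics.

## Known limitations

- The energy model is a calibrated simplification: rankings and
  pass/fail decisions are meaningful relative to its own null; absolute
  kcal/mol values are not transferable to ViennaRNA/RNAhybrid scales.
- One best site per (miRNA, window); suboptimal sites are not reported.
- Gene identity across genomes relies on annotation strings.
- The Wilcoxon exact branch requires tie-free data; heavily tied
  abundance vectors always take the corrected normal approximation.
- No operon/UTR awareness: windows are purely coordinate-anchored.
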