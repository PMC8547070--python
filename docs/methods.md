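# Methods

This note documents the models, conventions and parameter choices behind
`fruitsplice`, and what the synthetic-data experiments do and do not show.

## Coordinates and event definitions

All internal coordinates are 0-based, half-open; GTF and junction-table I/O
(1-based, inclusive; junction tables carry the first and last intron base)
convert at the boundary, so interval arithmetic never handles off-by-ones.

Events are defined locally, from pairwise comparison of exon chains within
a gene:

* **IR** — a transcript reads through an intron (d, a) of another
  transcript within a single exon whose outer boundaries equal the spliced
  form's flanking exon boundaries. The exact-outer-boundary requirement
  prevents alternative first/last exons from being mistaken for retention.
* **ES** — a cassette exon with flanking introns (d₁, s) and (e, a₂) in
  one form and the direct junction (d₁, a₂) in the other.
* **A5SS / A3SS** — two introns share one boundary and differ at the
  other; the shorter-intron form must be exonic across the whole
  alternative region (this excludes spurious calls arising from
  skipping-junction pairs). Donor/acceptor labels are assigned relative to
  the transcription direction, so they are strand-aware.

Events are deduplicated by (type, coordinates). Membership is
compatibility-based: every isoform of the gene carrying the inclusion- or
exclusion-defining introns (or, for IR, a read-through exon) joins the
respective set; isoforms compatible with neither form are excluded from
the PSI denominator. Inclusion conventions — IR: intron retained; ES: exon
included; A5SS/A3SS: the longer-exon (shorter-intron) form — fix the sign
of ΔPSI.

## PSI, occurrence and differential splicing

Per sample, PSI = ΣTPM(inclusion) / ΣTPM(inclusion ∪ exclusion), NA when
the denominator is zero. Stage PSI is the arithmetic mean of non-NA
replicate PSIs (the simplest symmetric aggregation; per-sample occurrence
is also available and is what the profile builder uses). An event occurs
at a stage when stage PSI ∈ [0.05, 0.95] (inclusive); a stage-specific
event occurs at exactly one of the two stages. Events with NA stage PSI
are treated as not occurring there.

Differential splicing uses ΔPSI = mean PSI(ripe) − mean PSI(immature) and
an empirical null built from within-stage between-replicate |PSI|
differences, pooled across events within total-abundance quantile bins
(one bin per ~100 events, at most 10); the p-value is the +1-smoothed rank
of |ΔPSI| in its bin's null. Gates: p < 0.05 and |ΔPSI| > 0.1. No multiple
-testing correction is applied by default (the gates above are the
decision rule); the machinery returns raw p-values so a user can apply
one.

## Transcriptome filter cascade

Per stage, in order: junction support → expression → class code →
single-exon; then the stage merge. The support rule for a novel junction
(one absent from the reference introns, strand-aware) is KEEP iff
(rep1 ≥ 4 AND rep2 ≥ 4) OR (rep1 ≥ 10 OR rep2 ≥ 10) — the unique reading
of the removal clause under which (4,4) and (0,10) survive and (3,9) does
not. Junctions missing from the support table count as zero and are
logged. Expression requires TPM strictly greater than 1 in both
replicates of the stage, at transcript level. Class codes are a minimal
subset of the conventional vocabulary: "=" (identical intron chain, or
identical coordinates for single-exon transcripts), "x" (antisense exonic
overlap), "s" (antisense intronic overlap), "o" (any other same-strand
overlap, kept), "u" (no overlap), with precedence = > x > s > o > u;
only u/x/s drive removal. Single-exon transcripts survive only on an
exact reference match. The merge groups multi-exon transcripts by intron
chain (single-exon by exact coordinates) and keeps the greatest summed
exon length — transcript length in the RNA sense, not genomic span — with
lexicographic id as the deterministic tie-break. The filter order is not
forced by the definitions; the suite checks that reordering class-code and
expression filters leaves the final set unchanged on the synthetic bundle.

## Orthology

Single-copy orthogroups pass through. In multi-copy orthogroups,
cross-species pairs must be reciprocal best hits (bit score, ties by
e-value then id) *and* synteny-supported — the strict AND combination,
chosen to favour precision for downstream conservation claims (an OR mode
exists). Connected components with at most one gene per species become
tuples; violating components are dropped and logged. Partial tuples are
kept and flagged, since pairwise conservation does not need all species.

## Conserved AS

Each event is represented by its characteristic junction(s): the retained
intron for IR, the skipping junction for ES, and both alternative
junctions for A5SS/A3SS (a match on either suffices). Flanks walk outward
along the exon chain of a transcript carrying the junction, collecting up
to 300 bp of exonic sequence per side (possibly across several exons),
oriented in the transcription direction; events yielding under 30 bp on a
side are excluded and logged.

The default scorer is an exact local nucleotide alignment (match +1,
mismatch −1, gap open −2, gap extend −1). A flank pair matches when the
optimal alignment spans ≥ 30 columns **and** ≥ 50 % of the shorter flank,
with column identity ≥ 0.7. The coverage requirement exists because a
local aligner applied to distantly related sequence finds short
high-identity excursions that would otherwise qualify; the identity
threshold was set so that flank pairs descending from a common ancestor at
≤ 0.15 substitutions per lineage always match while pairs at ≥ 0.3 (and
unrelated sequence) never do — measured over hundreds of simulated pairs.
Both flanks of a pair must match (the conservative reading; a single-flank
mode is not offered). An adapter accepts precomputed external
translated-search hits in tabular form in place of the built-in scorer.

Two events are linked iff same type, genes co-orthogroup, and both flanks
match; clusters are connected components. A species' conserved-event count
(the counts-matrix semantics) counts its events with at least one
cross-species link, so species rows sum to the grand total and the
percentage columns are shares of that total. A cluster is highly conserved
when its species set equals the full configured species set.

## Profiles and statistics

Profiles are per-sample binary vectors over the orthologue index: bit i is
set when any event of the i-th orthologue's gene has per-sample PSI in the
occurrence window (per-sample, not stage-mean — both rules coexist and are
named in outputs). All-zero orthologues are dropped before distances.
Binary distance is d = (b + c)/(a + b + c) with both-zero positions
carrying no signal; two all-zero vectors get d = 0, logged. Clustering is
agglomerative (complete linkage by default — robust to chaining on binary
distances; single/average available); species-coherence holds when cutting
at one cluster per species reproduces the species partition exactly.

Fisher's exact test (two-sided, probability-mass rule) and the Wilcoxon
rank-sum test (exact for min(n, m) ≤ 10 without ties, otherwise normal
approximation with midrank-tie and continuity corrections) are delegated
to scipy behind validated wrappers; the test suite checks both against
exhaustive enumeration oracles. The stage contrast of occurrence counts is
built as an (occurs, does-not-occur) × (immature, ripe) table over
detected events.

## Synthetic data generator

The generator emulates the four-species, two-stage, two-replicate study
design. Per orthogroup it draws one shared gene architecture — 4–8 exons
of 120–400 bp, introns 80–2000 bp, uniform — which supports the 30–300 bp
flank rule and the intron-length comparison; orthologous genes share
architecture but not (in general) sequence or strand. Genomes are i.i.d.
uniform nucleotides, except genes carrying planted conserved events, whose
region is copied from a per-orthogroup ancestor and mutated per species at
`flank_divergence` (each base substituted with that probability); this
guarantees planted conserved flanks are detectable at low divergence while
non-planted flanks stay unrelated.

Planting is count-deterministic: round(frac × N) orthogroups are chosen
without replacement for conserved events (species subsets of ≥ 2 drawn per
cluster), then for AS events among the rest, then for stage-specificity
among those — so a config determines its planted counts exactly, while
event types remain random draws from `event_mix` (default IR 0.40,
A3SS 0.25, A5SS 0.20, ES 0.15, the plant-typical skew). IR events retain
the gene's shortest intron, making retained introns stochastically shorter
than background, as the intron-length test expects. Stage-specific events
set PSI 0.5 in the "on" stage and 0.99 (or 0.01) in the other — one value
inside and one outside the occurrence window by construction; conserved
events get equal PSI in both stages (no stage bias). In the
`profile_mode="species"` condition each AS orthogroup is spliced in one
species only (species-dominant signal, the observed regime);
`"stage"` plants the same stage-specific event in every species
(stage-dominant, used to show the clustering analysis discriminates).

Quantification draws a gene depth `tpm_depth × LogNormal(0, 0.4)`
(default depth 100 TPM) and splits it between inclusion and exclusion
isoforms by the true PSI, jittered per replicate on the logit scale with
sd `psi_noise_sd` (default 0.05); a per-sample lognormal scale multiplies
both isoforms so that recomputed PSI is exactly the jittered value — with
zero noise, PSI is recoverable to floating-point precision.

Artefact transcripts are planted in four flavours matching the four
filters — a skip isoform whose novel junction gets failing read counts; a
same-chain isoform at 0.5/0.8 TPM; intergenic ("u"), antisense-exonic
("x") and antisense-intronic ("s") transcripts with well-supported
junctions and good TPM so that only the class filter removes them; and an
unmatched single-exon transcript — cycling flavours until the configured
fraction is reached. Separately, a few event-free genes get a
stage-restricted longer variant of the same intron chain to exercise the
keep-longer merge. Every transcript's expected fate and removal reason is
recorded in the manifest.

Orthology tables mirror the design: one gene per species per orthogroup
(a configurable fraction gets a second copy in one species), BLAST-style
hits with within-orthogroup scores well above noise hits (which all fall
outside the 1e-10 cut-off), and complete synteny support for the true
pairs. A homolog map assigns ripening-pathway symbols to a sample of AS
genes for the stage-specific join.

The study design is fixed at two stages and two replicates (the junction
rule and differential test require exactly two replicates); configs
requesting otherwise are rejected explicitly.

**What passing tests do and do not show.** The generator produces clean
splice junctions, exact TPMs and complete annotations; it does not model
read-level noise, assembly fragmentation, overlapping genes, paralogous
interference in quantification, or incomplete orthology. Recovery rates
of 100 % on synthetic bundles therefore validate the pipeline's logic and
conventions, not its robustness to real assembly artefacts beyond the
planted flavours.

## Problem sizes and numerical choices

Synthetic experiments default to 48 orthogroups plus 8 species-specific
genes per species (~450 kb genome per species), which exercises every code
path while keeping a full four-species pipeline run around two seconds;
the acceptance script uses this size, 500 oracle genes, and 50 seeded
bundles for the clustering-coherence rate. Species-coherence is reliable
at this size; markedly smaller bundles (~24 orthogroups) leave too few
informative orthologues for the species signal to dominate in every seed.
All randomness flows from one seeded generator; bundle writing is
byte-deterministic (sorted iteration everywhere). PSI tables are written
at 12 significant digits so round-tripping preserves the 1e-9 recovery
guarantee. Degenerate cases are explicit: empty exon chains, mixed-strand
genes, NaN distances and empty samples raise; zero PSI denominators give
NA; all-zero profile pairs give distance 0 with a log line.

## Known limitations

* Only the four main AS types are handled; mutually exclusive exons and
  alternative first/last exons are out of scope by design.
* The differential-splicing null is a documented stand-in with the same
  decision gates as the original tool chain's script; its p-values are
  empirical ranks, not analytic.
* The built-in flank scorer is nucleotide-level; a translated search can
  be substituted through the tabular-hits adapter.
* The pipeline assumes the two-stage, two-replicate design throughout.
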