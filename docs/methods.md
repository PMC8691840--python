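# Methods

This note documents the models and procedures implemented in `knockin`,
the parameter defaults and why they were chosen, what the synthetic-data
generators emulate, and the known limitations.

## Donor design

A knock-in donor is `left_arm + linker5 + tag + linker3 + right_arm`. The
tag ORF is stripped of its leading ATG and trailing stop codon regardless
of terminus (knock-in cassettes must fuse in frame on both sides); the
assembled block must be a multiple of 3 with no in-frame stop, and the
simulated HDR allele is checked for stops across both junctions in the
gene's frame. Coordinates are 0-based half-open internally; everything
reported to the user is 1-based.

* **Homology arms**: slices of the locus window abutting the insertion
  junction. Lengths outside 30–40 bp warn but do not fail — the range is a
  protocol recommendation, not a hard constraint, and exploration should
  be possible. Asymmetric arm lengths are supported.
* **Guide scan**: exhaustive SpCas9 NGG scan on both strands; the blunt cut
  is placed 3 bp 5′ of the PAM (`start+17` on the protospacer strand).
  Ranking is by distance of the cut site to the insertion junction only;
  activity and off-target scoring are deliberately out of scope (they are
  served well by dedicated web tools and would make the design
  non-deterministic).
* **Donor primers**: forward = left arm + first *k* nt of the cassette
  block; reverse = reverse-complement of (last *k* nt + right arm); both
  flagged 5′-biotinylated. *k* defaults to 18–25 nt, chosen to put the
  annealing segment's GC fraction inside 40–60 % (closest achievable
  otherwise, ties to the shorter primer). No nearest-neighbour Tm model is
  used: the GC rule is deterministic and testable, which matters more here
  than thermodynamic precision.
* **Genotyping primers** sit strictly outside the donor footprint so a
  single PCR distinguishes alleles: the knock-in amplicon exceeds the
  wild-type amplicon by exactly the cassette-block length. Primer start
  positions are chosen by the same GC rule within the available flanks.
* **Molarity**: `nM = ng/µl × 10⁶ / (L × 650)`, with 650 g·mol⁻¹·bp⁻¹ the
  mean double-stranded base-pair mass (documented constant, overridable).
* **In-silico PCR** finds the longest exact 3′-terminal match (≥ 15 nt) of
  each primer on the template, requires uniqueness, and concatenates
  tails + template core. It serves as the oracle that donor and genotyping
  primers reproduce the intended products.
* The injection-mix recipe (sgRNA 15–20, Cas9 mRNA 150, donor 8–10 ng/µl)
  is carried as metadata with range checks only.

## Integration-site calling and copy number

Real libraries enter as SAM from a production aligner (QNAME, FLAG, RNAME,
POS, MAPQ, CIGAR, mate fields, SEQ are used; secondary/supplementary
records are dropped). The built-in mapper exists only so the synthetic
path is self-contained: exact 31-mer seeding with up to 4 seed offsets per
orientation, ungapped extension, isolated mismatches tolerated as
sequencing errors, and a run of ≥2 mismatches within 8 bp treated as the
start of a foreign (clipped) segment. MAPQ is 60 for a unique best
placement, 0 on ties. This is adequate for low-error simulated reads and
is *not* a general-purpose aligner (no gapped alignment, no base
qualities, no pair rescue).

Calling proceeds as:

1. **Anchor pairs** — both mates mapped with MAPQ ≥ 20 and exactly one on
   an insert contig. The host mate's orientation gives the junction side
   (forward mate → junction to its right → "left" side).
2. **Clustering** — single linkage of anchor host positions per (insert,
   contig, side) with gap ≤ 500 bp; clusters with < 3 supporting pairs are
   not called but surfaced in a diagnostics list, because weakly supported
   partial insertions are a real observation that the caller should report
   rather than adjudicate.
3. **Calls** — nearest left/right clusters within 1 kb pair into one call;
   unpaired clusters yield one-sided flagged calls.
4. **Coordinate** — the modal soft-clip boundary near the cluster pair,
   with each clipped segment located inside the known insert sequence
   first: if the junction carries microhomology the aligner over-extends
   into the insert and shifts the raw boundary by the homology length, so
   the probe offset is subtracted back. With ≥1 split read the reported
   1-based left-junction base is exact on error-free junctions; without
   split reads the midpoint of the innermost anchor bounds is used. The
   reported coordinate denotes the last host base left of the insert (the
   left-junction base), a convention that must be documented because
   "integration coordinate" is otherwise ambiguous.
5. **Copy number** — `depth_ratio` = mean aligned depth on the insert
   contig / mean host depth. Pooled F1 heterozygotes carry the insert on
   one haplotype, expectation 0.5; thresholds 0.25/0.75 are symmetric
   around it and > 3 SD away at ≥ 14× over a ≥ 700-bp insert, which is the
   coverage regime of a typical verification run (14–24×, 150-bp
   paired-end reads). Ratios > 0.75 class as multi-copy/concatemer,
   < 0.25 as partial/low-support.

Defaults (cluster window 500 bp, pairing window 1 kb, min support 3, MAPQ
≥ 20, min clip 8 bp, probe 20 nt) are all configurable.

## Sanger junction classification

The observed read is aligned to the expected HDR allele semi-globally
(match +1, mismatch −1, gap open −2, gap extend −1; end gaps on the
expected allele free, so flanking context beyond the read never counts as
an edit). Inserted segments are tested for exact substring identity to a
homology arm (arms passed explicitly, or a ±60 bp window around the edit
otherwise); a hit of ≥ 8 bp gives `partial_duplication` with the matched
part as `dup_seq` and the remainder as `ins_seq`; otherwise
`small_insertion`. Pure target-side gaps give `deletion`; mixed or
mismatch-only differences give `complex`; equality over the compared span
gives `precise`. Edit positions are reported relative to a caller-supplied
feature anchor (start-codon first base, or first base after the stop), and
`coding_affected` is computed against the caller's coding interval.
Duplication detection requires *exact* identity because the documented
events are exact arm duplications; near-duplications fall through to
`small_insertion`.

## PCNA cell-cycle classifier

Inputs are a single-channel TIFF stack and a per-frame circular ROI (the
nucleus track). ROI tracking is an input, not computed — nuclei are tracked
manually in practice and automated tracking is out of scope.

* **Intensity trace**: mean ROI intensity per frame, normalized by the
  first tracked frame (scale-invariant; a multiplicative change of
  illumination leaves `I_norm` unchanged).
* **Width trace**: histogram of ROI pixel values per frame over the global
  movie range (so widths are comparable across frames), 64 bins by
  default; the width is the span between the extreme bins whose count
  reaches 5 % of the modal bin count. 64 bins (not the 8-bit display
  convention of 256) because a nucleus of a few hundred pixels needs
  several counts per occupied bin for the occupancy threshold to be
  meaningful; with 256 bins the threshold degenerates to min–max and the
  statistic becomes an extreme-value estimator. Bin count, range and
  occupancy fraction are configurable; the estimator is validated through
  its monotonicity in pixel dispersion and through change-point recovery,
  since no canonical definition of "distribution width" exists for this
  assay.
* **Speckles**: local maxima of the lightly smoothed frame (σ = 1 px)
  exceeding the ROI level by 2 robust SDs, with prominence ≥ 3 robust SDs
  above the ROI median and pairwise separation ≥ 2 px. Median/MAD
  statistics are used so the bright foci being counted do not inflate
  their own threshold, and statistics are computed on an eroded ROI
  interior so the nucleus-to-background falloff at the rim does not
  either.
* **S/G2 transition**: argmax of the width trace after a 3-frame moving
  mean; ties resolve to the earliest frame.
* **M onset**: earliest frame sitting ≥ 30 % (relative) below some frame
  at most 3 frames earlier. The drop is relative to the earlier value so
  the rule is invariant to how high the trace has risen by G2.
* **Segmentation**, rules in order: frames ≥ M onset are M; frames from
  the S/G2 point to M onset are G2; frames before it with positive
  Theil–Sen slope (5-frame sliding window) are S, late S where ≥ 3
  speckles; non-dividing tracks with overall negative robust slope are G1
  throughout; the rest unclassified. Isolated single-frame disagreements
  are majority-filled so each phase forms a contiguous run. If M onset
  precedes the S/G2 estimate the segmentation is still emitted with a
  warning flag.

Times are carried in minutes (default 20-min frame interval); outputs
report both frame indices and minutes.

## Synthetic data

Three generators, all driven by a single `numpy` Generator seeded from the
run seed, with the full parameter set and planted truth echoed in a
`SimTruth` record; identical seed + parameters reproduce outputs byte for
byte.

* **Loci**: i.i.d. bases at a target GC with one centred clean ORF
  (internal in-frame stops recoded).
* **Read libraries**: FR paired-end fragments, Normal(400, 40) insert
  sizes, 150-bp reads, i.i.d. substitution errors (default 0.1 %),
  constant Q37 qualities — the error model is substitution-only by design;
  indel and quality-profile realism is out of scope. `depth` is the total
  depth summed over alleles, so a heterozygote at 20× sequences each
  haplotype at ~10×, which is what the copy-number logic assumes.
  Knock-in alleles are built by splicing 1–n tandem cassette copies at the
  junction; het keeps one wild-type allele. Default experiment scale
  follows the verification regime the caller targets: 100-kb host, 714-bp
  insert, 20×.
* **Nucleus movies**: 16-bit 64×64 frames, static centred circular nucleus
  (radius 16 px); mean intensity decays exponentially in G1 (2 %/frame),
  rises linearly through S (2 % of base/frame), plateaus in G2, and falls
  by 60 % over 2 frames at M. Pixel texture is a partially persistent
  (AR(1), ρ = 0.5) random field whose dispersion ramps quadratically to a
  peak of 180 intensity units at the programmed S/G2 frame and narrows
  over ~8 frames after it — replication-driven heterogeneity grows fastest
  near the transition. Six replication foci (Gaussian puncta, σ 1.2 px,
  amplitude 800) brighten linearly through late S, are maximal exactly at
  the S/G2 frame, and disassemble over the first five G2 frames, so the
  total pixel dispersion genuinely peaks at the programmed transition.
  The default dividing-cell schedule starts in S (22 frames S, 12 late S,
  13 G2, 6 M at 20-min intervals): dividing-cell traces begin with the
  PCNA rise, while G1 cells are modelled as separate non-dividing decay
  tracks. Additive Gaussian noise (SD 30) is applied everywhere.

What the movie generator does **not** emulate: nucleus movement and shape
change, photobleaching, out-of-focus drift, neighbouring cells, or optical
PSF blur. Passing phase-recovery tests therefore demonstrates that the
classifier's rules are correct and robust to pixel noise and texture — not
that they are robust to every imaging artefact of a live embryo.

## Problem sizes and numerical choices

The replicated experiments run 100 seeded libraries (100-kb host for
integration calling; 50-kb host for the concatemer arm, since the depth
ratio is host-size independent) and 100 seeded movies; per-replicate
sub-seeds are derived from the run seed by a fixed affine map modulo
2³¹−1. Ties are always broken deterministically (lowest coordinate, then
'+' strand for guides; earliest frame for change points; smallest boundary
for modal split coordinates), and all pipelines are pure functions of
their inputs and configuration — no hidden randomness.

## Known limitations

* The naive mapper assumes low-error short reads and forward-orientation
  inserts; reverse-orientation integrations lose the microhomology
  correction (their clip probes do not match the insert forward strand)
  and fall back to raw clip boundaries.
* Full SV discovery (deletions, inversions, host–host translocations),
  duplicate marking and base-quality handling are out of scope; the caller
  answers one question — where did the known insert integrate, and in how
  many copies.
* The junction classifier reports one edit cleanly; stacked edits at one
  junction classify as `complex` and need manual review.
* Copy-number classes assume a pooled-heterozygote library; homozygous
  single copies produce ratios near 1 and intentionally class as
  multi-copy-or-concatemer — the class names the signal, not the cause.
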