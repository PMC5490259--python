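# Methods

## Problem setting

Ancient-DNA libraries from long-extinct species yield short (~30–100 bp),
damaged fragments, heavily diluted by environmental and human
contamination. The standard reconstruction route — mapping to a
conspecific reference — is unavailable when the nearest living relatives
diverged tens of millions of years ago (mitochondrial divergence 10–20 %).
Iterative bait mapping bridges that gap: each round's consensus becomes the
next round's reference, so the reference walks from the bait toward the
sampled organism. The cost is a real risk of reference bias and of
spuriously recruited reads; the pipeline's design is therefore built
around masking anything not supported by an overwhelming, reproducible
majority, across several baits and several mapping stringencies at once.

## Synthetic study design

The simulator generates every input the pipeline consumes, so the whole
chain is testable against known truth:

* **Truth genome** — i.i.d. bases on a circle, default 16 500 bp at 40 %
  GC (mammal-mitogenome scale and composition). Deliberately featureless:
  any mapping ambiguity observed in tests is produced by the mapper, not
  planted by the generator.
* **Bait references** — the truth genome passed through a one-off
  substitution process (each site mutates with probability *d* to a random
  other base) plus Poisson(λ = indel_rate·L) indel events of 1–3 bp.
  Defaults: four baits at *d* = 10, 12, 15, 18 % and indel_rate
  0.001/bp (~16 events per bait) — the scale separating taxa that split
  on the order of 50 Myr ago, which is the regime this method exists for.
* **Reads** — fragment starts uniform on the circle (sampled on the
  doubled sequence, coordinates reduced modulo L); lengths lognormal with
  mean 60 / sd 15, clipped at the 31 bp floor the pipeline enforces on
  input; strand uniform. The endogenous read count is
  round(depth·L/mean_length), giving ~11 000 reads at the 40× default.
* **Damage** — single-strand-library convention: C→T on the read-sense
  sequence at **both** ends, with probability δ·γ^k at distance k from the
  end (defaults δ5 = δ3 = 0.3, γ = 0.9; a `library="ds"` flag switches the
  3′ end to G→A). Uniform base-call error (default 0.1 %) is applied after
  damage. These rates are at the severe end of what degraded material
  shows, which makes the zero-error acceptance check a worst-case test.
* **Contaminant** — 2 % of reads drawn from an unrelated random genome
  (44 % GC, human-mitochondrion-like), undamaged by default (modern
  contamination assumption).

Every stochastic step takes an explicit integer seed; identical
configuration and seed reproduce the read set byte for byte.

What the generator does **not** emulate: real mitochondrial repeat
structure and the control region's hypervariability, heteroplasmy,
nuclear-mitochondrial inserts (numts), quality-score information, PCR
duplicates, and contaminants homologous to the target. Passing tests
therefore certify the algorithmic chain, not performance on any particular
real library.

## The mapper

Seed-and-extend, deterministic, circular:

* Exact 13-mer seeds at non-overlapping read offsets, looked up in a
  sorted k-mer table over one rotation of the doubled reference. For the
  grid's thresholds (≤ 6 %) the pigeonhole bound 0.06 < 1/13 guarantees a
  damaged-but-acceptable read always retains a clean seed.
* Candidates are scored ungapped (vectorised mismatch count). Any
  candidate with ≥ 1 mismatch is also scored gapped (edlib, unit costs,
  ≤ 3 indel bases within a ±3 window); the gapped encoding is taken only
  when it strictly reduces the total number of edits, and gapped results
  whose CIGAR begins or ends in an indel are rejected — a terminal indel
  is a degenerate re-encoding of a terminal mismatch and would erase
  exactly the damage signal the QC stage measures.
* Indels are normalised to their leftmost equivalent placement before
  entering the pileup, so equivalent alignments vote on the same column
  regardless of where each read happens to start.
* Acceptance: n_mismatch/read_length ≤ m and n_indel_bases ≤ 3. Fewest
  mismatches wins among placements, then fewest indel bases, then the
  leftmost coordinate; equal-score placements at non-overlapping loci
  reject the read outright — no arbitrary placement, ever.

### Iteration

Map all reads → rebuild the working reference as a plain per-position
majority (ties and uncovered positions keep the previous base) → remap.
Indels in the working sequence are edited only on a ≥ 95 % supermajority
of at least 4 reads spanning the site with ≥ 4 aligned bases on each side.
The margin matters: reads barely overlapping an indel cannot express it
(the aligner absorbs it into terminal columns) and would otherwise dilute
the supermajority; the low absolute floor matters too, because an
unhealed frame defect in a coverage trough locks in a permanent local
misassembly, while four independent reads agreeing on the same indel by
error is implausible. The loop stops when neither the recruited read-id
set nor the working sequence changes (a stable read set alone can hide a
pending edit), or after `max_iters` (default 20) passes; non-convergence
is recorded on the assembly and is not fatal — a partially converged cell
simply contributes less coverage.

At the strictest mismatch values (0–1 %) against deeply diverged baits,
recruitment cannot bootstrap at all (no read matches a 10–18 %-diverged
sequence nearly exactly) and those cells converge empty. This is expected
and harmless: an all-N layer constrains nothing downstream.

## Consolidation

* **Coverage corridor.** One **study-wide** mean depth — taken from the
  best-recruiting assembly, which is the closest available stand-in for
  "the depth this library actually provides" — feeds
  (⌊0.8·x̄⌋, ⌊2.0·x̄⌋) for *every* cell. Using each cell's own mean would
  shrink the corridor of a starved low-stringency cell toward 1×, letting
  single damaged reads produce called bases; measured on synthetic data,
  exactly that happened before the rule was fixed study-wide.
* **Stage 1.** Per position, with spanning count = base calls + deletion
  calls: outside the corridor → N; deletion fraction ≥ 95 % → position
  removed; modal-base fraction ≥ 95 % (inclusive — "a minimum of 95 %"
  reads naturally as ≥) → that base; anything else, including ties → N.
  Deletion calls sit in the denominator on purpose: a position where 5 %
  of spanning reads delete the base is not a 100 %-agreement position. A
  junction carrying > 5 % insertion evidence masks both flanking
  positions, for the same reason in the other direction.
* **Stages 2–3.** Center-star multiple alignment (match +1, mismatch −1,
  gap −2, N matches anything at 0; banded DP, band = |Δlength| + 32),
  then per column: no A/C/G/T call → N; a gap coexisting with a call → N
  (length disagreement *is* disagreement); two distinct bases → N;
  otherwise the agreed base. N is **missing data**, not a variant: a
  column {A, N, N, A} yields A. Treating N as a conflicting call would
  throw away precisely the coverage information the grid exists to pool.
* **Guide-driven alignment.** Masked consensuses carry no alignment
  information inside N runs, and the N-wildcard scoring would let
  segments slide there — cross-layer misalignment then *fabricates*
  mosaic bases (observed, and independently confirmed with MAFFT, before
  the fix). The stage 2–3 alignments are therefore computed on fully
  informative *guide* strings — each consensus's working reference
  restricted to its frame — and the masked strings are projected through
  them. Where a cell called a base, its working sequence is
  read-corrected, so guides agree exactly in all well-recruited regions.
* **Frame-hazard masking.** A call asserted only by layers whose own
  pairwise alignment to the center frame needed an indel nearby is
  masked: inside such a neighbourhood (hazard marks closer than 40×8
  columns merged into one span, then widened by 8 columns) the projected
  column of a sparse call can slide by up to the indel width. Calls
  anchored by the center layer, or by any layer whose frame locally
  agrees with the center, are kept. In converged regions the frames
  agree exactly and the rule costs nothing; overall it masks about one
  extra percentage point of positions.

## Authentication and validation

* **Identity windows**: 500 bp / 50 bp step on the shared degapped,
  N-free column frame of the final consensus against each comparison
  sequence. A contaminant-derived block surfaces as a local spike of
  identity toward the contaminant track and a dip toward every bait.
* **Damage profile**: terminal C→T frequency per distance from each read
  end, measured against the mapped reference, reverse-strand alignments
  complemented back to read sense. QC mapping uses a deliberately
  permissive 10 % threshold (`QC_MISMATCH`): at the strict assembly
  thresholds, heavily damaged reads are preferentially rejected, which
  measurably deflates the terminal rate (0.27 observed for a simulated
  0.30 at 6 %; unbiased at 10 %).
* **Stop-codon scan**: vertebrate mitochondrial code; codons containing N
  are unevaluable and counted separately; genes whose length is not a
  multiple of 3 are flagged and scanned over complete codons.
* **Harness**: the final grid consensus is compared with a single-pass
  direct-mapping consensus against the truth genome (same filters, no
  iteration). The pipeline passes only at zero mismatches — and zero
  mismatches against the truth itself.
* **Retrospective screen**: fraction of a read set accepted against the
  final consensus (N filled with a placeholder base, so masked regions
  simply reject reads — a conservative lower bound).

## Numerical and interface choices

* Coordinates 0-based half-open internally, 1-based inclusive in all
  user-facing files; circular positions reduced modulo length; reads may
  span the origin (sampled and mapped on the doubled sequence).
* Alignments export as SAM (NM = mismatch count, the quantity the mapper
  thresholds); pileups, grid reports, identity tracks, damage profiles
  and gene annotations as TSV; run configuration as YAML that round-trips
  losslessly and is written next to every run's outputs.
* Default problem sizes (16.5 kb, ~11 k reads, 28 grid cells) run the full
  study in a few minutes on one CPU; unit tests use 2–8 kb genomes.

## Known limitations

* Inside a coverage trough flanked by unresolved bait indels, the
  homology register of the few surviving calls relative to an external
  sequence is genuinely underdetermined — different optimal alignments
  pair them with different columns. Frame-hazard masking removes almost
  all such calls; across seven full-scale synthetic studies, six showed
  zero disagreements with truth under every comparison tried (including
  MAFFT re-alignment), and one retained a single register-ambiguous
  column out of ~13 000 called. A consumer aligning the final FASTA sees
  the masked trough as an N run either way.
* The recruited-read set is not guaranteed monotone across iterations on
  noisy data (a working-sequence edit can re-rank a read's placements);
  in practice recruitment grows monotonically on noise-free data, which
  is what the property test asserts.
* The damage profile measures mapped reads only; at strict thresholds the
  mapped subset is biased against damage. Use the QC threshold (10 %) for
  measurement, the grid thresholds for reconstruction.
* `endogenous_fraction` counts aligner-accepted reads; against a heavily
  masked consensus it under-reports by design (screening favours false
  negatives over false positives).
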