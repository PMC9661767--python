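# Methods

## The inference problem

Reverse transcription over a folded RNA G-quadruplex terminates at the
structure's 3′ edge when the quadruplex is stabilised (K⁺ buffer) and reads
through when it is not (Li⁺). Sequencing both conditions turns rG4 mapping
into a per-position two-sample count problem: at transcript position *i*,
among the `n_c(i)` deduplicated template-strand reads covering *i* in
condition *c*, `s_c(i)` have their 5′ end exactly at *i*. The package tests
whether the K⁺ stop rate `s_K/n_K` exceeds the Li⁺ rate.

## The caller

For each position with `n_K ≥ min_cov` (default 16 — the coverage level
below which stall evidence becomes too noisy to call reliably) and `n_Li >
0`, a one-sided exact conditional test (Fisher) is applied to the 2×2 table
`[s_K, n_K−s_K; s_Li, n_Li−s_Li]`. Positions with `n_Li = 0` are skipped
and flagged rather than tested. p-values are Benjamini–Hochberg adjusted
across **all** tested positions of the run; a position is called stalled
when the adjusted p ≤ α (default 0.05) *and* the empirical K⁺ rate strictly
exceeds the Li⁺ rate. The test is pluggable (`CallerConfig.test`:
`fisher`, `barnard`, `boschloo`); the conditional test was chosen as the
transparent, replicate-free default — it is conservative for small counts,
which the type-I simulations confirm. Whether stall excess should instead
be measured against a transcript-wide background rather than local
read-through is a genuinely open modelling question; the local 2×2
read-through contrast is this package's declared choice.

Called positions at most `merge_gap` nt apart (default 1) merge into one
RTS site — an rG4 stalls RT at its 3′-most G ("position 0") and/or the
next base ("+1"), so the typical site is 1–2 nt wide. Singleton positions
become 1-nt sites. Replicates are called independently; the *consensus*
list keeps sites of the first replicate rediscovered (span distance < 5 nt,
strict) in every other, and *union* lists are plain interval merges.

## Structural classification

Each site anchors a pattern search at offsets 0 and +1 (candidate motif 3′
ends `site.start − offset`), scanning a 50-nt window upstream — 50 nt is
the conventional window from earlier quadruplex-profiling work, wide enough
for any pattern the taxonomy admits (max ~38 nt). Classes are tried in
priority order, first match wins:

| class | pattern | group |
|---|---|---|
| canonical | G≥3 (N₁₋₇ G≥3)×3 | canonical |
| long_loop | four G≥3 tracts, exactly one loop 8–12 nt | non-canonical |
| bulge | four tracts, one interrupted by a 1–7 nt non-G bulge (≥3 Gs total) | non-canonical |
| two_quartet | G≥2 (N₁₋₇ G≥2)×3 | variant |
| g_triplex | G≥3 (N₁₋₇ G≥3)×2 | variant |
| others | none of the above | Others |

"Others" sites fail the minimum quadruplex/triplex requirement and are
treated as false positives. The canonical→variant grouping used in reports
is configuration, not biology: which subclasses count as "non-canonical"
versus "variant" is a reporting convention, and the map can be overridden
in `ClassTaxonomy.grouping`. All pattern parameters (tract minima, loop
and bulge ranges, window, anchor offsets) are config-exposed. The regex
implementation is cross-checked in the tests against an independent
recursive tract-placement enumerator.

## The simulator

The generator emulates the statistical structure the analysis assumes, at
desk scale:

* **Transcriptome** — 30 transcripts of 1.0–1.6 kb (defaults), log-normal
  relative abundances (μ=1.0, σ=0.8 on the log scale) normalised to TPM.
  Background sequence has G-runs capped below two, so *no* background locus
  can satisfy any class pattern; planted motifs are the only true signal.
  28 motifs (10 canonical, 5 long-loop, 5 bulged, 5 two-quartet, 3
  G-triplex) are planted non-overlapping, ≥ 80 nt apart, with G-free
  flanks so each planted span is exactly the maximal pattern match.
* **Molecules** — a fragment of ~N(250, 50) nt (the protocol's target
  fragment size) is cut uniformly from a transcript drawn ∝ TPM × length.
  Under K⁺, a fragment wholly containing a planted motif stalls with the
  class's θ (canonical 0.9, long-loop/bulge 0.7, two-quartet/G-triplex 0.4
  with a per-replicate jitter of SD 0.05 — variant-class stalling is the
  most stochastic); the stop lands at position 0 with probability 0.6,
  else at +1. Otherwise (and always under Li⁺) a background
  per-position stall rate ε = 10⁻³ applies geometrically from the fragment
  3′ end; most reads run through to the fragment 5′ end.
* **Protocol bias** — each molecule is accepted with probability
  proportional to a weight on the transcript base at its stop position:
  A=0.65 (others ≈0.117) for the hairpin-adapter protocol ("1.0"), A=0.35
  (others ≈0.217) for the dU-adapter protocol ("2.0"). Acceptance
  sampling is the minimal mechanism that reproduces the observed read-5′
  compositions without modelling ligation chemistry.
* **Library complexity and duplicates** — the library is a finite pool of
  `complexity_per_ng × input_ng` unique molecules (160/ng default), each
  carrying a PCR weight `1 + Poisson(λ)` with λ scaled by PCR cycles;
  sequencing draws `depth` read pairs (default 25 000) multinomially over
  the weights. Duplicate fraction and saturation behaviour emerge from
  pool size versus depth: at the defaults the 100-ng library loses ~40 %
  of reads to deduplication, and complexity ordering by input is
  guaranteed. Copies of one molecule share UMI (10 random nt on the 5′
  end of mate 1; the tag is abstract — its biochemical location is not
  modelled) and coordinates.
* **Fates** — adapter-only (5 %), unalignable (10 %) and multi-mapping
  (10 %) labels are assigned per read so yield accounting can run without a
  trimmer or aligner; the simulator emits the aligned-read table those
  tools would have produced, which is why ~75 % of raw reads survive to
  the uniquely-aligned stage.

What the simulator does **not** model: sequencing errors (hence exact-match
UMI dedup; a 1-mismatch directional mode exists for real data but is
off by default), multi-exon genome coordinates, polyA-selection chemistry,
strand ambiguity (everything is template-strand, `+`), or inter-molecular
quadruplexes. Passing tests therefore demonstrate correctness of the
inference machinery under the stated generative model, not robustness to
alignment artefacts or chemistry noise in real libraries.

## Adapter chemistry model

The 5′ dU adapter is 44 nt with deoxyuridine at position 24, a 5′
phosphate (required of the downstream ligation partner) and a 3′ C3
spacer (which is why it cannot ligate to itself). USER II scission is
modelled as a length-conserving nick immediately 5′ of each dU, the dU
staying on the 3′ fragment — the unique placement consistent with both the
23/21 split of the free adapter and the 85/21 split of the 106-nt ligated
product. (Chemically the enzyme excises the uracil base, but band sizes
are printed on the nick model, so that is what is implemented.) The
ligated product is cDNA(5′)→adapter(3′), forced by the fragment arithmetic
and by which end carries the phosphate. The cDNA mimic is 40 random nt
plus the 22-nt 3′-adapter sequence = 62 nt. Gel metrics follow the five
ratio formulas; ratios pushed outside [0, 100] by noisy band intensities
are clipped and flagged, since the formulas assume ideal densitometry.

## Numerical and design choices

* Coordinates are 0-based half-open transcript coordinates throughout;
  BED6 strand is always `+`; FASTQ is Phred+33; gzip members are written
  with mtime 0 so identical runs are byte-identical.
* Dedup keys on (transcript, strand, stop, UMI) — the stop position is the
  information-bearing coordinate for stall analysis; fragment ends are not
  part of the key. Representative = first read in lexicographic id order.
* Saturation curves use nested subsampling (one permutation, prefixes),
  making curves non-decreasing by construction, as in a real depth
  titration of a single flowcell.
* Site agreement uses strict `< 5 nt` between nearest span boundaries
  (overlap = distance 0); the distance anchor (boundaries, not centres) is
  a declared convention. Guideline TPM bands are half-open [4,8), [8,16),
  [16,∞) so the shared printed endpoints resolve upward.
* Coverage regression runs on log10 coverage — site coverages span orders
  of magnitude, and slope/intercept are only interpretable on that scale.
* All randomness descends from one seed; libraries derive child seeds from
  (seed, condition, replicate), so adding a replicate never perturbs
  existing ones.

## Problem sizes

Default study: 30 transcripts (~39 kb), 4 libraries × 25 000 read pairs,
~32 000 tested positions per replicate pair. Type-I simulations use 20
motif-free studies of 5 transcripts × 3 000 read pairs. These sizes give
stable statistics (null called fraction ≈ 0, canonical recovery at ≥ 32×
coverage = 100 % across seeds tried) while a full pipeline run stays
under ten seconds.

## Known limitations

* The exact conditional test is conservative at low counts; power at the
  16× coverage gate is adequate for θ ≥ 0.7 but two-quartet/G-triplex
  motifs (θ ≈ 0.4) are recovered less reliably — mirroring the lower
  replicate reproducibility of variant motifs in real data.
* Consensus anchoring on the first list makes `consensus()` asymmetric by
  construction (agreed-pair *counts* are symmetric).
* The SAM path for real data is untested against any public dataset; the
  aligned-read TSV is the supported interchange format.
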