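# Methods

## Scope and model

`xlms3` implements an MS2–MS3 search for MS-cleavable cross-linkers. The
underlying physical model: a cross-linked peptide pair (masses m_A, m_B)
carries one intact linker, so the MS1 precursor neutral mass is
m_A + m_B + M_intact. During MS2 the linker cleaves asymmetrically, leaving a
short-arm or long-arm remnant on each peptide; each peptide therefore
produces a light/heavy peak *doublet* spaced by
(M_long − M_short)/z. MS3 scans fragment individual doublet peaks and
contain ordinary b/y ions of one arm-modified peptide.

Built-in reagents (sulfoxide NHS esters, reactive toward lysine side chains
and protein N-termini):

| reagent | short arm | long arm | doublet Δ (Da) | intact (Da) |
|---|---|---|---|---|
| DSSO  | alkene C3H2O (54.0106) | thiol C3H2OS (85.9826) | 31.9721 | 158.0038 |
| DSBSO | alkene C3H2O (54.0106) | C8H12O4S2 (236.0177)   | 182.0071 | 308.0388 |

The intact mass equals short + long + H2O, consistent with sulfoxide C–S
cleavage chemistry. Alternative cleavage products (e.g. water loss,
thiol↔sulfenic interconversion) are supported as per-arm mass deltas in the
YAML cross-linker config; the shipped built-ins default to an empty product
list, and only single products are enumerated per arm (no stacking).

## Doublet detection and deisotoping

For each charge z in 1..`max_charge` (default 4) and each allowed product
delta, peak pairs spaced by (Δ + δ_product)/z within the fragment tolerance
(default 20 ppm) are annotated as doublets. A light/heavy intensity-ratio
band (default 0.1–10) suppresses pairings of unrelated peaks; this band is
this package's own plausibility filter, since detector-level peak-quality
heuristics are instrument-specific. When the MS1 precursor charge is known
and at least two doublets are present, doublet pairs are cross-checked
against the precursor-sum identity m_A + m_B + M_intact ≈ M_precursor.
Alpha/beta roles are assigned by ascending doublet m/z (alpha = lowest).

Charge inference looks for ≥2 consecutive isotope-envelope members spaced
1.00336/z above the peak and returns the largest consistent z; with no
envelope, charges 1..4 are enumerated downstream. Deisotoping walks the
envelope down to its lowest member and then estimates the monoisotopic m/z
by averaging mz_k − k·1.00336/z over all envelope members — averaging
reduces the centroiding error roughly by √(envelope length), which in
practice decides whether the adjusted mass falls inside the candidate
tolerance. Neutral masses use a proton mass of 1.00728 Da.

## MS3 mapping

An MS3 scan is assigned to a doublet peak iff it was recorded 0–5 min
(default, one-sided) after the MS2 scan, shares the MS1 precursor m/z within
the precursor tolerance (default 10 ppm), and its selected precursor m/z
matches the doublet peak or one of the first four envelope members. Ties go
to the closer peak, then to the lower-m/z doublet. MS3 scans triggered on
co-isolated non-doublet peaks are excluded — searching them would mostly
produce false positives. The cross-linker-free peptide mass of an assigned
MS3 is `mono_neutral − arm − δ_product`; non-positive results reject the
assignment.

## Candidate generation and scoring

Proteins (targets plus whole-protein reversed `REV_` decoys) are digested
with trypsin (cleave after K/R unless before P), ≤2 missed cleavages, length
5–30, mass 400–6000 Da, fixed carbamidomethyl-C (+57.02146). A peptide's
cross-link sites are its reactive residues, except a C-terminal K when the
peptide is not protein C-terminal (a linker-blocked lysine would not have
been cleaved); protein N-termini count when the reagent is amine-reactive.

The fragment-match scorer is a binomial-tail score, chosen because the
commercial engines used with this workflow are closed and the downstream
logic only needs an order-preserving match-quality score: with n theoretical
b/y ions (charges 1..2, arm mass added to site-containing ions), k of them
matched, and per-ion random-match probability p = 2·w·N_peaks/span (w =
tolerance half-width at the spectrum midpoint), the score is
−10·log10 P(X ≥ k), X ~ Binomial(n, p), and 0 when k = 0. It is monotone in
k and anti-monotone in the tolerance width.

Each MS2 spectrum is also scored directly (the MS2-supplement path, on by
default): this identifies the partner peptide when only one side has MS3
evidence and adds an extra supporting scan otherwise. The linear prefilter
scores every MS2 spectrum against unmodified linear peptides at its
precursor mass and removes scans whose best linear hit reaches target–decoy
q ≤ 0.01 before any doublet search.

## Pooling, boosting, assembly, validation

All PSMs of one candidate (sequence, site, arm, decoy status) across an MS2
scan chain are pooled; with n unique supporting scans the boosted score is
max(scores)·(1 + p/100)^(n−1), p default 20. This form satisfies the two
anchor behaviors — p = 0 leaves the max unchanged and p = 100 doubles it per
additional scan — and uses only the maximum score and n; lower-ranked scores
do not contribute beyond counting their scans.

CSMs pair the best hits of two distinct doublet pairs of one MS2 scan,
choosing the combination with the highest min-score that passes the
precursor-sum check; the lower-m/z pair is alpha. CSM score = min of the two
boosted scores; decoy class TT/TD/DD from the two candidates. CSMs of the
same unordered (sequence, site) pair form one cross-link with score = max of
its CSMs and the decoy class of its best CSM.

Validation is two-step: target–decoy thresholding at the CSM level (default
1%), grouping of survivors, thresholding again at the cross-link level
(default 1%). The estimator is max(0, TD − DD)/TT — DD pairs estimate the
rate at which TD pairs arise by chance; the alternative (TD + DD)/TT
convention would be more conservative. Thresholds treat score ties as one
block (all in or all out), so a decoy tied with targets keeps those targets
out. Decoy cross-links are dropped from the final report.

Post-processing: `validated_group_fdr` computes the groupwise experimentally
validated FDR, (#inter-group + #non-library)/#total, on the accepted list;
`entrapment_filter` repeatedly removes the lowest-scoring cross-link while
the fraction containing an entrapment-flagged peptide is ≥ 1% (default).
Both run after, never instead of, target–decoy validation.

## Synthetic libraries and simulated runs

The generator emulates groupwise synthetic peptide-library benchmarks:
random tryptic-like peptides (length 8–16, exactly one internal lysine as
the link site, C-terminal K/R, no other K/R/P, masses pairwise distinct by
≥10 mDa), partitioned into groups of 6–10; all intra-group site pairs are
admissible true cross-links, so the generator's own truth set has a
validated FDR of exactly 0.

A simulated run samples intra-group cross-links (default 20 from a
30-peptide library) and emits per cross-link: one MS1 scan, one MS2 scan at
precursor charge 4 containing both doublets (charge 2, 3-member envelopes
with 1.0/0.7/0.35 intensity ratios), stub-modified b/y fragments of both
peptides, and 30 uniform noise peaks; plus 2 MS3 scans per doublet pair
(alternating light/heavy arm) with linear fragments of that peptide, RT
offsets uniform in (0, 2] min. Fragment ions are present with probability
0.7, intensities are log-normal, and m/z values carry Gaussian jitter with
σ = tolerance/3. Optional knobs emit linear-bait MS2 spectra (for the
prefilter) and co-isolation artifacts (MS3 triggered on a random non-doublet
peak). Everything is deterministic given (library, params, seed).

What the simulator does **not** model: chromatographic peak shapes and
co-elution, correlated intensity structure, missed monoisotopic selection
beyond the envelope, FAIMS/ion mobility, real instrument noise spectra, and
real library sequences. Passing the end-to-end benchmark therefore shows the
search logic is correct and calibrated under these idealized conditions, not
that identification rates transfer to real acquisitions.

## Problem sizes and numerical choices

The default test/benchmark scale — 30 peptides, 20 sampled cross-links, 2
MS3 per doublet, 30 noise peaks, 20 simulation seeds — keeps a full
benchmark run under ten seconds while leaving every pipeline stage
non-trivially exercised; it mirrors the structure (not the size) of real
synthetic-library benchmarks. Degenerate inputs are defined: empty mzML
reads as an empty collection; MSn scans without precursors are skipped and
counted; an empty FASTA is fatal; an empty CSM list validates to empty
results; the validated group FDR of an empty cross-link list is 0 with a
warning. Duplicate m/z peaks are merged by intensity sum on read; retention
times are normalized to minutes.

## Known limitations

- Only one CSM (the best-scoring doublet-pair combination) is reported per
  MS2 scan; chimeric spectra with two co-isolated cross-links are not split.
- A single detected doublet pair cannot form a CSM; the partner peptide is
  only inferred through its own doublet (no precursor-difference fallback).
- Variable modifications (e.g. Met oxidation) are not searched; only fixed
  modifications are applied.
- The binomial scorer ignores peak intensities; intensity-aware scoring
  would likely sharpen the target/decoy separation.
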