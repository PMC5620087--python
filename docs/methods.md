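# Methods

## Scope and model

`copurify` implements the post-search half of a spectral-counting AP-MS
(affinity-purification mass spectrometry) workflow. The input is a set
of MudPIT-style runs, each a table of peptide-spectrum matches (PSMs)
carrying SEQUEST-type scores, searched against a protein database that
contains one shuffled decoy per target entry. The output is a merged
protein × run NSAF matrix and, when a bait accession is given, the set
of proteins whose abundance profiles tightly co-cluster with the bait —
the candidate complex.

The stages, in order:

1. **PSM retention.** A PSM is kept iff DeltCn ≥ 0.08, XCorr ≥ a
   charge-dependent minimum (1.8 / 2.0 / 3.0 for 1+ / 2+ / 3+), Sp rank
   ≤ 10, peptide length ≥ 7, and both peptide termini tryptic. All
   thresholds are inclusive ("at least"/"maximum" read as ≥/≤). Charges
   above 3 fall back to the charge-3 threshold — a conservative
   extension, configurable. The tryptic test uses the same
   proline-suppressed trypsin rule as the in-silico digest (cleave
   after K/R, not before P; protein termini always qualify).
2. **Target-decoy FDR.** Spectral FDR = 2·(decoy spectra)/(total
   spectra)·100; protein FDR = (decoy proteins)/(total proteins)·100.
   The factor-2 asymmetry is deliberate and kept exactly as the two
   estimators are conventionally displayed. A PSM counts as a decoy hit
   only if *every* protein it maps to is a decoy. FDR is reported, not
   used as a cutoff: retention is score-threshold-based and the
   achieved FDR characterizes it. The dispersion quoted next to the
   pooled spectral FDR is the across-run sample standard deviation of
   per-run spectral FDRs.
3. **Protein inference.** PSMs pooled over all runs of the sample are
   tallied per protein; a protein is retained with ≥ 2 distinct
   peptides, or 1 peptide with ≥ 2 spectra. Proteins whose peptide set
   is a proper subset of another's are removed; proteins with identical
   peptide sets are merged into one group reported under the
   lexicographically smallest accession (determinism; the choice of
   merging rather than dropping ties is ours). Shared-peptide spectra
   count toward every mapped protein — whole counts, no fractional
   splitting. Coverage is the union of all occurrences of each peptide
   in the protein sequence, 1-based inclusive coordinates.
4. **NSAF.** NSAF_i = (SpC_i/L_i) / Σ_k (SpC_k/L_k) per run, summing
   over that run's retained proteins; decoys are excluded from the
   denominator by default (including them only perturbs reported
   abundances; a flag restores them). Proteins undetected in a run get
   NSAF 0 downstream — treated as absence, not missingness.
5. **Merging and background removal.** Per-run NSAF vectors merge into
   a protein × run matrix (union of accessions, structural zeros,
   manifest column order). Control subtraction defaults to
   *mean-dominates*: a protein is removed when its mean NSAF over
   negative-control runs is ≥ its mean over bait runs; the strict
   *any-presence* mode removes anything ever seen in a control. The
   subtraction rule is this package's own (the upstream convention is
   only that control runs are analyzed alongside bait runs).
   Condition intersection then keeps proteins detected (NSAF > 0) in at
   least one run — configurable via `min_runs_per_condition` — of
   every condition group.
6. **Clustering and complex calling.** Protein rows are z-scored,
   pairwise distances are 1 − Pearson r, and agglomeration uses average
   linkage. Correlation distance is the right default here because
   co-complex members share profile *shape* across runs and conditions
   even at severalfold stoichiometry differences. Rows are sorted by
   accession before clustering so results are invariant under input
   row order; constant rows get the maximal distance 2 (logged) rather
   than poisoning the correlation matrix. `extract_bait_cluster` walks
   the bait leaf's ancestor chain and returns the largest cluster with
   ≤ `max_size` members (default 10). The pipeline additionally passes
   `max_cluster_height = 0.5`: members must join the bait's cluster at
   merge height ≤ 0.5, i.e. average correlation r ≥ 0.5. This is the
   quantitative reading of "tightly clustering" — without it, the pure
   size bound absorbs sparsely detected background proteins whose
   correlation estimates over a few dozen runs are dominated by chance
   (they attach to the bait's cluster one leaf at a time at merge
   heights 0.6–1.0, versus ≤ 0.2 for genuine co-complex members).

## Decoy construction and digestion

Decoys are uniform random permutations of whole target sequences
(length and residue composition preserved), prefixed `shuffled_`. A
whole-sequence shuffle is the simplest reading of "randomized"
decoys; a tryptic-site-preserving variant is a known alternative and
the CLI reserves a flag name for it, but it is not implemented. Each
decoy's permutation stream is derived from the global seed plus a CRC
of the accession, so decoy databases are reproducible and independent
of database order. Digestion cleaves after K/R except before P, with
configurable missed cleavages and a minimum length; N-terminal
methionine is not treated specially.

## The synthetic experiment generator

The generator emulates a two-condition immunopurification study at
desk scale. Defaults and their rationale:

| parameter | default | why |
|---|---|---|
| complex | bait 1550 aa + partners 480/490/330 aa at 1:1:1:3 molar | a large scaffold-sized bait, two deacetylase-sized partners, one WD40-sized partner in threefold excess; fixed realistic lengths keep the length-normalization of NSAF well conditioned |
| conditions / runs | 2 conditions, 11 and 12 bait runs | the emulated design: low/high salt groups of MudPIT analyses |
| control runs | 12 | matched negative-control purifications |
| background | 300 proteins, lengths U(100, 2000), molar abundance log-normal(ln 0.02, 0.8) relative to bait | hundreds of nonspecific binders spanning ~2 orders of magnitude of abundance |
| contaminant overlap | 0.8 | fraction of background present in bait *and* control runs at equal abundance; the remaining 20 % is bait-only, split between "sticky" contaminants present in all conditions and condition-specific ones |
| bait depth | 50 expected bait spectra/run | enough counting depth that a 3× stoichiometry is measurable per run |
| elution-pool recovery | 1.0 / 0.45 / 0.15 for E1, E2–3, E4–7 | the first peptide elution yields far more complex than the pooled late elutions; this systematic factor (times a log-normal capture noise, σ = 0.5) applies to complex members only and is what makes co-complex NSAF profiles co-vary across runs — NSAF's per-run normalization cancels any factor shared by all proteins, so without it co-complex correlation collapses toward chance level |
| run depth noise | log-normal σ = 0.25 | loading/chromatography variation shared by all proteins of a run |
| decoy PSM rate | 7 × 10⁻⁴ | each passing PSM independently becomes a decoy hit with this probability, so the expected spectral FDR is 2 × 0.07 % = 0.14 % |
| sub-threshold fraction | 0.1 | extra PSMs violating exactly one retention rule each, exercising the filter |

Spectral counts are Poisson with mean
`depth_scale · molar_i · (observable peptides of i) · run factors`,
where observable peptides are the distinct fully-tryptic ≥ 7-mers of
the zero-missed-cleavage digest — the same retention rule the filter
applies. Passing scores are drawn uniformly above the thresholds
(XCorr in [threshold, threshold + 2], DeltCn in [0.08, 0.4], Sp rank
1–10); score *realism* is not modeled, only filter correctness.
Everything derives from one `numpy` generator stream, so a seed fixes
the emitted files byte-for-byte.

What the generator does **not** emulate: peptide detectability
differences (ionization efficiency, missed cleavages, modifications),
shared peptides between homologous proteins, score distributions with
realistic overlap between correct and incorrect matches, saturation of
spectral counting at high abundance, and run-order or batch effects.
Tests passing on this generator therefore demonstrate that the
*computational* pipeline is correct under the stated statistical
model, not that the thresholds themselves are optimal for real
instrument data.

## Numerical choices

- NSAF vectors sum to 1 within 1e-9; the report writer stores floats at
  full `repr` precision so write→read round-trips are exact.
- Correlation distances are symmetrized and clipped at 0 to absorb
  floating-point round-off; constant rows get distance 2.0 with a
  logged warning.
- Ties in identical-peptide-set merging, matrix row order, and
  clustering input order are all broken lexicographically by accession.
- Per-entry decoy shuffling uses `seed ⊕ crc32(accession)` streams so
  shuffles are order-independent.

## Problem sizes

The shipped tests and the acceptance script run the full design (35
runs, ~600 database entries, ~15 000 PSMs per experiment) over 10–20
seeded replicates; a single experiment plus pipeline takes well under
a second, the complete suite a few seconds.

## Known limitations

- The subset-removal implementation is O(n²) in retained proteins —
  fine for thousands, not for hundreds of thousands.
- `mean-dominates` control subtraction compares raw NSAF means; at low
  counting depth, proteins with expected counts ≪ 1 per run can leak
  past it by Poisson chance. The reproducibility knob
  (`min_runs_per_condition`) and the cluster tightness bound are the
  provided mitigations.
- Protein-level FDR on desk-scale synthetic data is far below what a
  deep real experiment would show, because scattered single-spectrum
  decoy hits rarely survive the two-peptide evidence rule.
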