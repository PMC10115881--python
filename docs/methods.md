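# Methods

## The screen's generative model

The synthetic pooled screen treats selection as a per-peptide
multiplicative survival weight. Baseline library composition is drawn once
per screen from a symmetric Dirichlet, f ~ Dirichlet(α·1), α = 1 by
default — the simplest exchangeable model for a pooled lentiviral library
transduced at low multiplicity of infection, where every cell carries one
peptide and clone abundances scatter widely but without structure. The
pre-selection sample is T0 ~ Multinomial(D, f) and the selected sample is
Multinomial(D, f·e / Σ f·e), where e_i = 1 for neutral peptides and
e_i = `enrichment_factor` for the planted protective peptides. Depth D is
10⁶ reads per sample by default and column sums equal D exactly.

Defaults (library ≈ 5,000 peptides, 10 planted, 50-fold enrichment,
D = 10⁶) are the design point used throughout the tests and the acceptance
script. The source publication does not state the screen's sequencing
depth or survivor fraction, so D and e are declared package defaults: e is
chosen so planted peptides sit unambiguously (≈ 5.5 log2 units) above the
resampling noise of neutral peptides, and D gives neutral peptides ≈ 200
expected reads, enough for the abundance floor to be meaningful.

What the generator deliberately does not model: PCR amplification bias,
sequencing substitution errors inside the coding window, and cell-growth
dynamics during selection. Passing tests therefore demonstrate that the
readout/scoring machinery is correct and calibrated for multinomial
resampling noise — not that the thresholds are optimal for real screens,
where index hopping, jackpot clones and PCR noise widen the null.

## Reads and quality

Synthetic reads are `upstream-flank + coding + downstream-flank`, one read
per counted molecule, with the fixed one-codon-per-residue table (most
common human codon per residue); since the screen uses the peptide itself
as the barcode, codon degeneracy carries no information and is omitted.
Decoding nevertheless translates with the full standard genetic code, so
stop codons and corrupted windows are detected and tallied as unmatched.

The quality filter keeps reads with arithmetic mean per-base Phred
strictly greater than 30 (integer-score averaging, not error-probability
averaging). The generator draws per-base qualities around a per-class mean
(37 for passing reads, 22 for failing reads) and clips them to ≥ 31
respectively ≤ 30, which makes the pass/fail dichotomy exact: QC tallies
equal the generated fail counts and round-trip tests are deterministic.
Peptide matching is exact; mismatch rescue of sequencing errors is out of
scope.

## Enrichment score and thresholds

score = log2((f_sel + α)/(f_T0 + α)) on normalized frequencies
(counts-per-million, S = 10⁶), with α = 0.5·S/sample-total per sample —
half a read in each sample's own units. The score is antisymmetric under
swapping samples and finite everywhere. Hit thresholds are score ≥ 3
(an 8-fold frequency gain) and ≥ 100 selected reads; both are package
defaults, declared rather than derived, since the original analysis
thresholded only implicitly (survivor sequencing is itself the selection).
Hits are *reported* ranked by selected-sample reads, matching the
"most abundant hit" convention, but recovery of planted peptides is a
property of the score ordering: a planted peptide whose baseline frequency
happens to be small can rank below abundant neutral peptides by raw reads
while still scoring far above them.

## Interface mapping and ranking

Peptide-to-interface placement is an exhaustive Hamming scan of every
length-k window of every interface segment, keeping windows with ≤ 3
mismatches; per segment the minimum-distance window is flagged best
(leftmost on ties). Sequence identity is (k − mismatches)/k, and ranking
uses the integer mismatch count directly (same ordering, exact
arithmetic). Disease-GO sharing is the intersection count
|pd_terms ∩ ann(partner₁) ∩ ann(partner₂)| — "shared by the mapped
proteins" read as terms common to both partners; the union reading was
rejected because it rewards one well-annotated partner regardless of the
other. The full sort key is (mismatches ↑, shared terms ↓, complex id,
partner, offset), a total order independent of input permutation. The
original workflow's visual discarding of crystal-packing contacts is
replaced by the declared geometric parameters below plus the rank report;
there is no human-in-the-loop step.

Interface segments derive from coordinates by: residue is interfacial iff
any heavy atom is within 5.0 Å of any heavy atom of the partner chain;
maximal runs with single-residue gaps bridged and length ≥ 5 become
segments. 5 Å heavy-atom contact and a 5-residue minimum are conventional
interface-definition values; both are parameters. Coordinates are 1-based
inclusive in all reported offsets, 0-based half-open internally.

## FP binding fits

Saturation: Y = Bmax·Xʰ/(Kdʰ+Xʰ) + Background, fitted by
Levenberg–Marquardt on all replicate points with initialization
Background = min Y, Bmax = max Y − min Y, Kd = X nearest the half-range
response, h = 1 — robust for monotone curves. The probe is held at 50 nM,
far below Kd, so total receptor approximates free receptor and the
ligand-depletion quadratic model is unnecessary. The Hill check fits both
variants and reports h ± SE plus an extra-sum-of-squares F statistic; the
primary parameters quoted are always from the h = 1 fit.

Competition: the exact mass-balance system for receptor R, probe L
(dissociation constant Kd) and competitor C (Ki) reduces to a single
strictly increasing function of free R with a unique root on [0, R_tot],
located by Brent's method at 1e-14 relative tolerance; species totals are
conserved to better than 1e-10. Ki is fitted on a log10 scale (its SE is
mapped back by the delta method); Bmax and Background are co-fitted unless
fixed — the zero-competitor reading can pin Background, and both modes are
supported, fitted being the default. IC50 is the numerically located
midpoint between the fitted zero-competitor response and Background; under
the competitive model IC50 ≥ Ki always, and in the dilute regime
(L, R ≪ Kd, R ≪ Ki) the fit reproduces the Cheng–Prusoff relation
Ki = IC50/(1 + L/Kd) to within 5%.

A fit is flagged non-identifiable when the fitted Ki exceeds the top
tested concentration or the fitted displacement span across the tested
range is under 3 residual standard deviations (a flat curve also admits a
degenerate "fully displaced" optimum); the result then reports the top
concentration as a lower bound on Ki, the conventional "Ki > 30 µM"-style
statement.

Concentration defaults mirror the assay design: probe 50 nM, 12-point 1:1
dilution from 30 µM, receptor constant at 1 µM in competition, 5
replicates, Gaussian noise of 2 mp (typical plate-reader scatter).

## Degenerate inputs and tie-breaks

Fits never raise on non-convergence; they return a flagged result with the
initialization values and NaN standard errors. Ranks break read-count ties
lexicographically by peptide sequence. An empty proteome yields an empty
library with a warning; proteins shorter than k or with ambiguous residues
(X/B/Z/…) in the C-terminal k-mer are skipped and logged. Zero-total
samples make normalization raise, naming the sample.

## Problem sizes

Tests and the acceptance script run the screen at a ≈ 5,000-peptide
library and depth 10⁶ (the end-to-end FASTQ path processes 2×10⁶ reads in
well under a minute); FP fits use 60 points (12 concentrations × 5
replicates); property suites use randomized instances of a few dozen
elements with fixed seeds. These sizes exercise every code path at the
pipeline's design point while keeping the whole suite fast.

## Known limitations

- The hit thresholds are calibrated to the synthetic design point, not
  learned; real screens need replicate-aware count models (e.g.,
  negative-binomial shrinkage) that are deliberately out of scope.
- Interface fixtures stand in for a curated PDB interface library;
  biological-vs-crystal contact discrimination is only as good as the
  cutoff/min-run parameters.
- The competition model assumes one binding site and pure competition; it
  cannot express allosteric or partial displacement.
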