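# Methods

## Panel and layout

The packaged catalogue (`data/panel.tsv`) holds 39 mutations in seven genes
(7 BRAF, 12 NRAS, 9 KIT, 3 GNAQ, 2 GNA11, 4 MAP2K1, 2 MAP2K2), organised in
11 locus groups that mirror the assay's multiplex amplicons: BRAF-600,
NRAS-12/13, NRAS-61, KIT-557/559, KIT-576, KIT-642, KIT-816, GNAQ-209,
GNA11-209, MAP2K1-121/124 and MAP2K2-57/60. Each group carries one
wild-type probe; every probe is spotted twice; four marker spots occupy the
grid corners. The default geometry (10×12 grid, 20 px pitch, 6 px spot
radius) is a package convention — the physical chip's drop coordinates are
not modelled — and is fully configurable; capacity is checked as
2×(mutations + groups) + 4 ≤ rows×cols.

HGVS c. strings are parsed by a small grammar covering substitutions,
deletion–insertions (both `del..ins..` and `NN>NN` spellings) and
insertions; coordinates are 1-based CDS on the coding strand, codon *c*
spanning 3c−2..3c. Protein labels are validated by applying the cDNA change
to a packaged ±12 nt coding-strand context window and translating the
affected codon (Biopython's standard table). The target codons in
`data/codon_contexts.json` are forced by the panel's own reference and
alternate amino acids; flanking bases are synthetic filler except for the
well-established BRAF 596–604 stretch, and are never read by validation.

## Forward model

**Clamp PCR.** Product per locus group after `cycles` rounds:
`mut = min(cap, f·N0·(1+eff_mut)^cycles)`,
`wt = min(cap, (1−f)·N0·(1+eff_wt_clamped)^cycles)`,
with f the mutant template fraction and N0 the template input. No published
kinetics exist for the clamp, so the simplest monotone two-efficiency model
is used. Defaults: N0 = 10⁴ copies, 35 cycles (the assay's thermal
program), eff_mut = 0.9, eff_wt_clamped = 0.2, cap = 10¹². Any
eff_wt_clamped < eff_mut enriches mutant over wild type at every fraction —
the property the clamp exists for; the cap expresses reagent saturation.

**Hybridization.** Probe signal = gain · Σ_allele w(probe, allele) ·
product(allele) + B̄, with w = 1 for the matched allele and `crosshyb` =
0.05 for other alleles of the same group (0 across groups — different
amplicons). B̄ = 600 is the measured chip background including the camera
dark current I₀ = 100; both are in arbitrary camera units. Spot noise is
multiplicative log-normal with CV 10% (standard array noise structure),
drawn independently for the two duplicates; marker spots are fixed at
30 000 counts. The nested asymmetric second-round PCR and Cy5-dUTP
incorporation are absorbed into the single `gain` parameter.

**Calibration.** The only quantitative constraint the assay publishes is
its 0.5% limit of detection, so `gain` = 2.6×10⁻⁹ units/copy is set so that
the noiseless J of the spiked probe is ≈2.5 at 0.5% mutant fraction
(passing the J ≥ 2 criterion with ~4σ of headroom under 10% spot noise) and
≈1.7 at 0.25% (failing it; the probability of a spurious pass is ~10⁻³ per
replicate). Signal magnitudes at each dilution are a package convention —
the published sensitivity figure is graphical only.

**Rendering.** Spots are drawn as anti-aliased disks (1 px edge roll-off)
on a uniform background B̄, plus additive Gaussian pixel noise (sd 20), then
rounded and clipped to 16 bits. The disk interior mean equals the assigned
intensity before pixel noise, which is what makes the noiseless
render→quantify round trip testable to 2%.

## Image analysis

Gridding smooths the image (σ = 1 px), detects bright peaks, assigns the
four corner-most peaks to the layout's marker spots, refines them by
intensity centroid, and least-squares-fits an affine transform from nominal
to detected coordinates; the RMS marker residual is reported and residuals
above 2 px flag every spot `weak-marker`. Fewer than four detectable
markers is a hard gridding error.

Quantification is GenePix-like: I_m = mean over the interior disk (0.6×
nominal radius); B_m = median over a 1.2–1.8× annulus excluding pixels
within one radius of neighbouring spot centres; saturation is flagged when
>1% of interior pixels sit at the bit-depth maximum. The interior/annulus
extents and the median background are package conventions (the instrument
software's internals are not published); they were chosen for robustness to
neighbour bleed, not tuned to any outcome. I₀ is taken from acquisition
metadata (the simulator records it in each truth sidecar); the fallback —
mean of the darkest 1% of pixels — is crude because a fluorescing chip may
have no truly dark region, and is only a last resort.

## Calling

J = (I_m − I₀)/(B_m − I₀) per spot; duplicates averaged per probe
(QC-failed duplicates dropped, probes with both duplicates failed excluded);
per-group max-normalization for display. The decision rule calls the
maximal-J mutant probe among those with J_mut > J_wt and J_mut ≥ `min_sbr`
(default 2). The assay's printed criterion divides J by a raw background
intensity, which is dimensionally inconsistent since J is already the
background ratio; it is read here as J_mut ≥ 2, preserving the printed
constant and the evident intent. Exact ties between qualifying probes are
no-calls (the rule does not adjudicate them), as is a failed wild-type
probe — the no-call criterion for dim chips is a package convention.
Variants with no probe on the chip are invisible by construction; the
caller never emits off-panel verdicts. Two mutated genes among
BRAF/NRAS/KIT/GNAQ/GNA11 in one sample raise a warning (these drivers are
near-mutually exclusive in melanoma), while MAP2K1/2 plus BRAF is expected
and silent.

LoD policy `"all"` (default) demands detection in every replicate;
`"majority"` in more than half. False calls at 0% make the LoD undefined
(an error), detection nowhere reports "> max fraction tested".

## Cohort reconstruction and statistics

Per-patient data for the 253-melanoma cohort are not deposited; the
packaged reconstruction (`load_reference_cohort`) is synthetic and is built
to reproduce the published marginals exactly: per-variant biochip counts,
177/253 biochip-positive and 76 wild type, the six sequencing-only rare
variants in the combined calls (134 BRAF any-method), the sex and subtype
margins, and the published contingencies (BRAF by sex 85/140 vs 46/97;
NRAS nodular vs superficial 7/43 vs 0/24). The published per-gene counts
sum to 188 gene hits over 177 mutation-positive patients, which forces 11
two-gene patients although only the 2 BRAF+MAP2K1 co-occurrences are
described; the reconstruction places the remainder on BRAF+KIT (6) and
BRAF+GNAQ (3), the pairings least constrained by the published exclusivity
statements. Ages are drawn deterministically from the published group
means/SDs and are plausible rather than real. Conclusions about the real
cohort beyond these printed marginals cannot be drawn from this table.

Association tests build the 2×2 table excluding missing covariates
pairwise and default to the two-sided Fisher exact test; χ² with and
without Yates continuity correction and the Mann–Whitney U (for age) are
selectable, since which test produced each published p-value is not stated
per comparison. Method concordance is exact call-set equality; arbitration
labels each discordant sample `confirms-A/B/neither` by exact match with
the arbiter call, `neither` covering rare off-panel variants. Cell lines
are flagged and excluded from patient-sample counts on request.

## Synthetic-data scope

The generators emulate clamp enrichment, within-group cross-hybridization,
duplicate-spot noise, pixel noise, grid placement, the dilution design and
cohort genotype frequencies. They do not emulate FFPE damage artifacts,
multiplex primer interactions, hybridization thermodynamics, spatial
intensity gradients, or spot morphology defects — so green tests show the
algorithms are correct under the stated noise model, not that the assay
performs identically on degraded clinical material.

## Problem sizes and determinism

The default simulated image is 213×253 px (10×12 grid); a full 24-chip
dilution series simulates, renders, grids, quantifies and calls in a few
seconds. All stochastic stages consume seeds derived from one master seed
via `numpy` seed sequences and record them in truth manifests, so every
artifact is reproducible byte-for-byte.

## Known limitations

* The clamp model is phenomenological; efficiencies are not fitted to any
  measured amplification curve.
* The dark-current fallback estimator biases J when no dark region exists.
* One wild-type probe per group is assumed; the chip's true probe count per
  locus is not published.
* The cohort table is a reconstruction (see above), not patient data.
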