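# Methods

`nociscreen` reimplements, as a tested pipeline, the computational layers of
a kinase-substrate study in nociceptive sensory neurons: an in-silico screen
for Cdk5 phosphorylation sites in nociceptor-enriched proteins, a
single-cell coexpression analysis, ratiometric calcium-imaging responder
classification, and a lickometer aversion metric. This note records the
models, parameter choices and their rationale, what the synthetic generators
do and do not emulate, and known limitations.

## Substrate screen (`seqscreen`)

Cdk5 is a proline-directed Ser/Thr kinase; its substrate consensus is
(S/T)PX(K/H/R) — acceptor Ser/Thr, obligate Pro at +1, any residue at +2,
basic/His at +3. Ankyrin repeats frequently carry a T/SxxH tetrapeptide
whose acceptor coincides with the consensus whenever +3 is His, so both
patterns are scanned and sites matching both are labelled `both`.

Decisions:

- **Coordinates** are 1-based inclusive everywhere in sequence space,
  matching how phospho-sites are named (T101, S449, ...). Zero-based
  arithmetic is internal only.
- **Overlapping matches are all reported** and never deduplicated; the scan
  uses a zero-width lookahead so adjacent acceptors both appear.
- **`X` residues** never satisfy a determinative pattern position (acceptor,
  +1 Pro, +3 basic/His) and contribute 0 to PSSM scores; the +2 wildcard
  tolerates `X`.
- **Topology filtering is conservative**: only sites demonstrably inside
  annotated transmembrane or extracellular segments are removed. Sites at
  unannotated positions are kept and labelled `unknown`, because a missing
  annotation is not evidence of inaccessibility. The filter is idempotent.
- **PSSM weights are an input** (TSV of offset x residue covering −4..+5
  around the acceptor), not a built-in: published Cdk5 matrices are cited
  from prior work rather than printed, so shipping one would mean inventing
  numbers. An all-zero matrix ships for plumbing tests. Offsets that fall
  off a sequence end contribute 0.
- **Assay windows** are the residues acceptor−3 .. acceptor+6: a 10-mer with
  the acceptor at window position 4 and the obligate proline at 5. This
  reproduces all six packaged decapeptide substrates exactly; windows
  clipped by a sequence end are flagged truncated rather than padded.
- The "highly expressed in the nociceptor lineage" restriction is a gene
  set computed by `coexpr.expressed_gene_set` (mean FPKM over a cell group
  ≥ threshold), not a fold-enrichment rule, since no enrichment cutoff is
  defined for it.

## Single-cell coexpression (`coexpr`)

Expression is binarized at **5 FPKM, inclusive** (≥); the threshold is a
parameter everywhere it appears. Prevalence is the percent of cells
positive for a gene; the coexpression fraction from A to B is the percent
of A-positive cells that are also B-positive — deliberately asymmetric
(e.g. "100% of TRPA1+ neurons express Cdk5" does not imply the converse).
A pair with zero conditioning-positive cells has an undefined fraction,
reported as NaN with a warning rather than 0.

The network edge rule is our own definition, exposed as configuration: an
edge joins A and B when the *mutual* conditional fraction
min(coexpr(A→B), coexpr(B→A)) reaches the edge threshold, with that minimum
(on [0, 1]) as the weight. The minimum makes the rule symmetric and means a
rare gene nested inside a common one does not create an edge on the strength
of the rare gene's side alone. Exports are edge-list TSV and GraphML.

Missing values are rejected at ingestion, never imputed; FPKM computation
from reads is upstream of this package.

## Calcium imaging (`caimaging`)

The Fura-2 response is the 340/380 excitation ratio, sampled every 2 s by
default (any uniform interval is accepted). The relative trace divides the
ratio by the mean of the **five frames immediately preceding the first drug
application**; the amplitude fold for a stimulus is the maximum of the
relative trace from application onset to the end of its washout.

**Responder cutoff.** The cutoff is mean + 3 sample SD (ddof = 1) of the
non-responsive peak distribution; with peaks of mean 1.00 and SD 0.05 this
is 1.15-fold, the default. The comparison is inclusive (fold ≥ cutoff). How
the non-responsive population is delimited in the first place is not
something the rule itself defines, so the function simply takes the peaks
it is given; callers may supply them directly or take the sub-cutoff mode
of a provisional split.

**Desensitization.** A strong low-dose response that never washes out makes
the high-dose amplitude uninterpretable. The high dose is excluded when the
pre-onset level has not recovered below
baseline + `recovery_fraction` x (low-dose peak − baseline), with
`recovery_fraction` = 0.5 as our operationalization of "partial recovery"
(configurable). The exclusion applies **only when the preceding window held
an actual response** (previous peak ≥ cutoff): on a flat trace the recovery
requirement sits inside the noise floor and the bare rule would flag ~10%
of non-responders on noise alone. Excluded calls report no amplitude but
are still classified from the peak in their own window.

**Per-mouse aggregation.** %responders = 100 x responders / KCl responders,
computed per mouse; KCl (30 mM, final application) marks the excitable
population. By default the numerator is gated to neurons that themselves
responded to KCl, which keeps the percentage within [0, 100]; the ungated
variant is available behind a flag. A mouse with zero KCl responders yields
NaN with a warning. Group statistics (`group_compare`: two-sided unpaired
Student t or one-way ANOVA) always operate on per-animal values — the
animal, never the neuron, is the sampling unit.

**Calibration.** Ratio-to-[Ca2+]i conversion uses the standard Grynkiewicz
relation [Ca2+] = Kd·β·(R − Rmin)/(Rmax − R), strictly increasing on
[Rmin, Rmax) and erroring at saturation; Kd defaults to 224 nM (Fura-2 at
37 °C). It is optional and off the classification path, which operates on
relative folds throughout.

## Behavior (`behavior`)

Aversion is licking under agonist as a percent of baseline: 100 x mean
agonist-session licks / mean water-session licks, **normalized per animal
before averaging** within genotype (pooling sessions across animals would
let high-licking animals dominate). The baseline is the mean over all water
sessions (configurable to the last k). Values above 100 are meaningful —
reduced aversion. The concentration grid defaults to 1, 10, 100, 1000 µM.
With two genotypes each concentration gets an unpaired t-test against the
reference genotype; with one genotype the table still builds and the test
columns carry a notice.

## Synthetic data (`synthetic`)

Generators are seeded (`numpy` Generator); identical configuration gives
byte-identical output files, and every generator writes a ground-truth
table so recovery is checkable exactly.

- **Proteomes**: background residues uniform over the 20 canonical amino
  acids (a frequency-weighted background would change per-residue hit rates
  but not the scanner's correctness; uniform keeps planted-count accounting
  exact). Planted motifs are written at recorded positions ≥ 15 residues
  apart with a topology segment of the requested kind around each; any
  background position that would by chance complete a consensus or T/SxxH
  match is mutated to alanine, so the truth table is exhaustive, not
  probabilistic.
- **TRPA1 scaffold**: a *synthetic* 1125-residue stand-in carrying the six
  published assay windows at the published acceptor positions (T101, T134,
  S242, T416, S449, T485) inside an annotated cytoplasmic region 1–605,
  plus two decoy consensus sites (unannotated linker at 650, transmembrane
  at 800) so the topology filter is actually exercised. One window (T485)
  is an assay decapeptide with its acceptor Ser changed to Thr to keep the
  published acceptor residue. It is **not** the real TRPA1 sequence; the
  census code path runs unchanged on the real translated GenBank protein
  when the user supplies it.
- **Single-cell matrices**: block-structured positivity with per-gene
  fractions, optional nested pairs (sub ⊆ sup positivity, giving exact 100%
  conditional fractions), dropout that thins positives independently
  (expected prevalence x (1 − dropout)), positive FPKM ≥ threshold
  (shifted exponential) and negative FPKM below it.
- **Fura-2 traces**: a two-population mixture — responders with peak fold
  ~ N(1.45, 0.10) (within the reported 1.3–1.6 band), non-responders with
  peak fold ~ N(1.00, 0.05) — on a default schedule of 30 s low dose,
  washout, 30 s high dose, washout, terminal KCl, at 2 s sampling. Neuron
  counts per mouse default to round(N(31, 7)) ≥ 1, matching the reported
  per-animal yields. Transients are exponential rise (τ = 5 s) / decay
  (τ = 20 s) scaled so the windowed maximum equals the planted peak;
  kinetics are configurable since only sampling and application duration
  are specified by the design being emulated. Desensitized responders keep
  their low-dose plateau (no decay) and skip the high dose. Additive
  Gaussian noise, SD 0.005. One measurement caveat: a windowed *maximum*
  cannot fall much below baseline, so the sub-1.0 half of the planted
  non-responder peak distribution is truncated in trace-level measurements;
  moment-recovery tests for the 3-SD rule therefore use the truth-table
  peak draws, while classification tests use the measured traces (the
  truncation is far below the 1.15 cutoff and does not affect calls).
- **Lick sessions**: Poisson counts, water at the baseline mean and agonist
  at baseline x planted-percent/100, 5 sessions per condition, 4 animals
  per genotype by default.

What the generators do **not** emulate: photobleaching, motion artifacts or
ROI segmentation; bursty single-cell count noise (dropout is a plain
Bernoulli thinning of a planted mask, not a count model); session-order or
habituation effects in licking. Passing recovery tests therefore
demonstrates correctness of the analysis chain under its stated model, not
robustness to those real-data artifacts.

## Problem sizes in the test suite

The suite exercises scanner/oracle equivalence on 1,000 random 200-mers,
responder-fraction recovery at 0.2/0.4/0.6 with 200 neurons over 20 seeds
per fraction, prevalence recovery at 10,000 cells, and t-test type-I error
under the null at n = 7 per group over 10,000 replicates — sizes chosen so
binomial/Monte-Carlo error is small against the tolerances being checked
while the whole suite stays interactive (tens of seconds).

## Known limitations

- The screen scores sites only when a PSSM is supplied; no stringency
  percentile calibration (as in web-service predictors) is attempted.
- Topology must be provided; the package does not predict membrane
  topology.
- The network edge rule is one reasonable definition among several
  (thresholded correlation or joint-count rules are alternatives); it is a
  parameter, not a claim.
- `group_compare` implements the two classical parametric tests only, on
  per-animal summaries; hierarchical models pooling neurons within animals
  are out of scope.
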