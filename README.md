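# nociscreen

Analytics for identifying and validating substrates of the neuronal kinase
Cdk5 in pain-sensing (nociceptive) neurons, and for the downstream
functional assays used to test them. The package covers four stages that
are usually scattered across ad-hoc scripts:

1. **Substrate screen** — scan protein sequences for the Cdk5 consensus
   motif (S/T)PX(K/H/R) and the ankyrin-repeat T/SxxH tetrapeptide, score
   sites with a user-supplied position-specific scoring matrix, drop sites
   inside annotated transmembrane/extracellular segments (inaccessible to a
   cytosolic kinase), restrict to genes expressed in a nociceptor lineage,
   and extract the 10-residue assay window (acceptor at position 4,
   obligate proline at 5) used in peptide kinase assays.
2. **Single-cell coexpression** — binarize FPKM matrices at a positivity
   threshold (5 FPKM, inclusive), compute per-gene prevalence and
   asymmetric conditional coexpression fractions
   (100 × |A⁺∧B⁺| / |A⁺|), and build a coexpression network whose edges
   require a mutual conditional fraction above a threshold.
3. **Calcium imaging** — turn ratiometric Fura-2 recordings (340/380 nm,
   2 s sampling) into responder calls: baseline-normalize to the five
   pre-stimulus frames, measure the peak fold per stimulus window, classify
   responders at the cutoff mean + 3 SD of the non-responsive peaks
   (1.15-fold for peaks ~ N(1.00, 0.05)), exclude desensitized high-dose
   windows, and report per-mouse %responders normalized to the KCl-excitable
   population. Group tests (unpaired t / one-way ANOVA) use the mouse as
   the unit.
4. **Behavior** — lickometer aversion as percent-of-baseline licking per
   animal across an agonist concentration series.

A seeded synthetic-data module generates fixtures with ground-truth tables
for every stage, so the full pipeline is testable without any downloads.
See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Scan the six packaged decapeptide substrates of mouse TRPA1 (the
10-residue windows around its ankyrin-domain phospho-acceptor candidates):

```bash
nociscreen screen \
  --fasta "$(python -c 'from nociscreen.data import trpa1_peptides_path as p; print(p())')" \
  --out screen/candidates.tsv
# 6 candidate sites -> screen/candidates.tsv
```

```text
protein_id   acceptor_pos  acceptor_res  motif_class  window  peptide10   ...
TRPA1_pep1   4             T             both         TPLH    YGNTPLHCAA
TRPA1_pep2   4             S             both         SPLH    NMMSPLHIAV
```

Each peptide yields exactly one consensus site with the acceptor at window
position 4, and every site is labelled `both` — the (S/T)PLH windows
satisfy the kinase consensus and the ankyrin T/SxxH tetrapeptide at once.

Simulate a 7-mouse Fura-2 experiment (responder fraction 0.4, peak fold
~ N(1.45, 0.10) against non-responders ~ N(1.00, 0.05)) and classify it:

```bash
nociscreen simulate --kind traces --seed 7 --out-dir sim
nociscreen ca --traces sim/traces.csv --schedule sim/schedule.csv --out-prefix ca/run
```

`ca/run_mouse_summary.tsv` (abridged):

```text
mouse_id  n_neurons  n_kcl_responders  pct_responders_AITC_low  mean_fold_AITC_low
mouse00   31         28                21.4                     1.460
mouse01   34         32                31.2                     1.443
mouse02   32         30                46.7                     1.445
...
mouse06   38         34                44.1                     1.450
```

`n_kcl_responders` is each mouse's excitable denominator;
`pct_responders_AITC_low` is the percentage of those neurons responding to
the low agonist dose (scattered around the planted 40%, binomially), and
`mean_fold_AITC_low` is the mean peak amplitude over responders, sitting at
the planted 1.45-fold. Per-neuron calls, including desensitization
exclusions for the high dose, are in `ca/run_calls.tsv`, and every output
directory carries a `manifest.json` sufficient to rerun the stage.

The same stages are importable directly
(`nociscreen.seqscreen.screen_proteome`, `nociscreen.coexpr.build_network`,
`nociscreen.caimaging.analyze_traces`, ...).

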