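# quantcore

Desk-scale core of a quantitative proteomics pipeline: SDRF-driven experiment
routing, multi-engine PSM consensus scoring, layered target-decoy FDR control
(PSM, peptide, picked protein), label-free / isobaric / IBAQ protein
quantification, and — the centrepiece — merging protein lists from many
datasets under a globally re-estimated FDR using *stand-in decoys*.

## Who this is for

Computational proteomics researchers who want the bespoke statistical stages
of a large-scale reanalysis pipeline as an importable, testable Python library
plus a small CLI: no search engines, no raw-spectrum processing, no workflow
engine.  Input and output are plain tabular formats (SDRF, TSV PSM tables,
FASTA, mzTab, MSstats/Triqler exports), and a synthetic-data module generates
every input with known ground truth, so the whole pipeline can be validated
on a laptop.

## The statistics at the core

**Posterior error probabilities.** PSM scores are modelled as a two-component
Gaussian mixture (the PeptideProphet lineage) fitted by EM; decoy scores
initialise the incorrect component.  `PEP(s) = π₀f₀(s) / (π₀f₀(s) + (1−π₀)f₁(s))`.

**Consensus.** Candidates from multiple search engines are combined per
spectrum by averaging per-engine PEPs; an engine that searched the spectrum
but did not report a candidate contributes PEP = 1.

**Target-decoy q-values.** At every score threshold,
`FDR = #decoys at-or-above / #targets at-or-above` (capped at 1), with the
q-value the cumulative minimum from the worst score upward.  Protein-level
FDR uses the *picked* strategy: each target competes with its decoy
counterpart and only the better-scoring member of the pair is counted.

**Stand-in decoy merging.** Protein inference tools report q-values but often
no explicit decoys, so their lists cannot be pooled under a common FDR.  For
the k-th target of a q-sorted list, the package injects stand-in decoys so the
cumulative decoy count is `d_k = round_half_up(q_k · k)` — making the
decoy/target ratio at every rank encode the nominal q-value.  Merged across
datasets (keeping each protein's lowest-q observation, keeping every decoy),
each target's q-value is re-estimated as the ratio of decoys to targets
scoring as well or better, and the combined build is filtered at a strict
adjusted FDR (q̂ < 0.01).

## Worked example

```python
import quantcore as qc

# a hand-checkable target-decoy instance: target scores {10,9,7,5,3},
# decoy scores {8,4}
q = qc.target_decoy_qvalues(
    [(10, False), (9, False), (7, False), (5, False), (3, False),
     (8, True), (4, True)]
)
print(q[:5])          # [0.   0.   0.25 0.25 0.4 ]

# stand-in decoy injection: targets with q = {0.0, 0.1, 0.2}
lst = qc.inject_standin_decoys([("a", 0.0), ("b", 0.1), ("c", 0.2)], "DS1")
print([(e.accession, e.q) for e in lst.decoys()])
# [('DECOY_STANDIN_DS1_1', 0.2)]   -> one decoy per three targets ~ q = 0.2

# merge + re-estimate reproduces the nominal q-values up to rounding
build = qc.reestimate_qvalues(qc.merge_protein_lists([lst]))
print([round(t.adjusted_q, 3) for t in build.targets])   # [0.0, 0.0, 0.333]
```

An end-to-end synthetic run (simulate → score → consensus → FDR → inference →
quantification, compared against the generator's ground truth):

```python
report = qc.end_to_end(qc.SimulationConfig(seed=3, n_proteins=200))
print(report["psm_fdp"])        # 0.0030  (realized FDP at 1% PSM FDR)
print(report["protein_fdp"])    # 0.0071  (realized FDP at 1% picked FDR)
print(report["ibaq_spearman"])  # 0.97    (IBAQ vs true abundance)
```

The same stages are exposed as a CLI (`quantcore simulate / design / score /
infer / quant / merge / export / qc`); run `quantcore --help`.

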