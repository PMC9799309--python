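# metox

**In-silico assessment of methionine oxidation liability in antibody
variable regions.**

Methionine side chains in the variable (Fv) region of therapeutic
monoclonal antibodies are prone to oxidation to the sulfoxide form;
when the affected residue sits in or near a CDR this can abolish
antigen binding, so flagging liable sites early in developability
assessment matters. Solvent exposure of the side chain predicts
oxidation well for surface methionines but fails for partially buried
ones — notably those at the end of the CDR-H3 loop. `metox` computes
four solvent-environment descriptors per methionine from a structure
and/or a conformational ensemble with explicit waters, and applies
threshold rules to flag oxidation-prone residues:

| descriptor | definition |
|---|---|
| sSASA | Shrake–Rupley solvent-accessible surface area of the Met side chain on the static structure, reported absolute (Å²) and relative (% of the residue's maximum allowed area) |
| dSASA | the same area averaged over ensemble frames |
| WCN | 2-shell water coordination number — mean number of water molecules within 6 Å of the side-chain sulfur (SD) over frames |
| #OH | mean number of Ser/Thr/Tyr side-chain hydroxyl groups within the same 6 Å shell |

Decision rules (defaults): SASA-based methods flag a site when the
relative side-chain SASA exceeds 15%; the WCN method when at least 6
waters populate the shell; and the combined **WCN-OH** rule when

> WCN > 6, **or** WCN > 0.1 and #OH > 1.5.

The second condition captures buried methionines whose oxidation is
mediated by hydrogen-bonding hydroxyl groups of neighbouring polar side
chains rather than by bulk water — the class the exposure-only methods
miss. Predictions are evaluated against observed oxidation with
confusion matrices (residue-resolved labels at a ≥ 5% oxidation level,
or count-matched per-molecule events), sensitivity/specificity with
bootstrap errors, and semiquantitative correlations (R², Pearson,
Spearman).

## Worked example

A synthetic fixture generator produces solvated methionine probes with
exactly known shell counts (no downloads needed). The `buried_ensemble`
fixture is a caged — hence solvent-inaccessible — methionine visited by
a transient water in 1 of 4 frames and permanently coordinated by two
serine hydroxyls:

```sh
metox make-fixtures fixtures --seed 1
metox analyze fixtures/buried_ensemble.pdb -o descriptors.tsv
metox classify descriptors.tsv -o predictions.tsv
```

`descriptors.tsv` (comment header omitted):

```text
molecule_id  chain  residue_label  sSASA_abs  sSASA_rel  dSASA_abs  dSASA_rel  WCN   OH   n_frames
molecule     H      100            0.0        0.0        0.0        0.0        0.25  2.0  4
```

The side chain has zero accessible area and averages only 0.25 shell
waters, so the exposure-based methods and the plain WCN rule all call
it safe — but with WCN 0.25 > 0.1 and #OH 2.0 > 1.5 the WCN-OH rule
flags it, as the classify log shows:

```text
INFO metox: events for molecule: {'ssasa': 0, 'dsasa': 0, 'wcn': 0, 'wcn_oh': 1}
```

With an observed table (`molecule_id  chain  residue_label  ox_percent`),
`metox evaluate predictions.tsv observed.tsv -o metrics.tsv` prints the
confusion matrix per method (TP FN on the first row, FP TN on the
second) and writes sensitivity/specificity with bootstrap errors.

The library mirrors the CLI: `parse_structure`/`parse_ensemble`,
`select_methionines`, `ensemble_descriptors`, `classify_table`,
`confusion_from_labels`/`confusion_from_event_counts`,
`bootstrap_errors`, and `load_reference_tables` for the packaged datasets.

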