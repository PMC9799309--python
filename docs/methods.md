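# Methods

## Model and procedure

The package operationalises a water-mediated picture of methionine
oxidation: the rate-limiting charge separation in the oxidant (e.g.
H₂O₂ or an alkyl hydroperoxide) is stabilised by a hydrogen-bond
network around the sulfur, supplied either by shell waters or — for
partially buried side chains — by hydroxyl groups of nearby Ser, Thr
and Tyr side chains. Accordingly each methionine is characterised by
the occupancy of a 6 Å sphere around its side-chain sulfur (SD) and by
the solvent accessibility of the side chain, and a site is called
oxidation-prone by simple threshold rules on these descriptors.

Inputs are PDB structures (a multi-model file is treated as a
conformational ensemble over a fixed topology; DCD/XTC trajectories are
accepted with a PDB topology). The package consumes ensembles, it does
not generate them: molecular-dynamics sampling, homology modelling and
protonation are upstream of its scope.

### Descriptors

* **Shell counts.** WCN counts water molecules, #OH counts Ser OG /
  Thr OG1 / Tyr OH oxygens within the shell; each group is represented
  by its oxygen so results are independent of hydrogen presence and no
  molecule is double-counted. Membership uses a closed ball (≤); the
  boundary case is measure-zero in real data but must be deterministic.
  With a periodic box, distances follow the minimum-image convention
  (orthorhombic boxes only); a box edge below twice the shell radius is
  rejected because the shell would overlap its own image. Ensemble
  values are unweighted arithmetic means of per-frame integer counts —
  no burn-in is discarded, on the assumption that input trajectories
  are pre-equilibrated.
* **SASA.** Shrake–Rupley quadrature: every atom is inflated by the
  probe radius (1.4 Å, a water molecule) and covered with a
  golden-spiral lattice of test points (default 960/atom; quadrature
  error on totals is ~0.1–0.5%, and halving/quadrupling the point count
  moves fixture totals by <2%). The side-chain area is the sum over CB,
  CG, SD, CE (plus side-chain hydrogens if present), computed in the
  context of all protein atoms with every water stripped: SASA is a
  property of the protein surface, whereas the shell counts explicitly
  measure solvent. Van der Waals radii are a conventional element-keyed
  set (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å…), configurable.
* **Relative SASA.** Absolute areas are reported next to percentages of
  a per-residue maximum-allowed area (Tien et al. theoretical
  normalisation; MET 224.4 Å², empirical set available). Because the
  normalisation constant is a convention, both absolute and relative
  values are always emitted; values above 100% are flagged, not
  clipped.

### Classification

Defaults: relative SASA > 15% (strict) for sSASA/dSASA; WCN ≥ 6 for the
plain water-coordination rule; WCN > 6 or (WCN > 0.1 and #OH > 1.5),
all strict, for WCN-OH. The ≥ in the plain WCN rule ("at least 6")
versus the strict > of WCN-OH condition 1 is a deliberate asymmetry
mirroring how each rule is stated; the two differ only at WCN exactly
6, and both operators are configurable. The four flags are computed
independently; thresholds are configuration, not fitted — no threshold
optimisation is performed here.

### Evaluation

Residue-resolved observations are binarised at a ≥ 5% measured
oxidation level. When only per-segment event counts are known, counts
are matched within each molecule (TP = min(observed, predicted), the
excess becoming FN or FP, untouched methionines TN) — the unique
assignment consistent with treating every methionine as one outcome.
Sensitivity and specificity are TP/(TP+FN) and TN/(TN+FP); undefined
ratios are reported as NaN with the replicate dropped and counted,
never imputed. Bootstrap errors resample the per-methionine outcomes
(or the per-molecule count tuples, for segment data) with replacement,
50 replicates by default, under a logged seed (default 20221229).
Semiquantitative agreement between a descriptor and oxidation levels is
reported as OLS R², Pearson r and Spearman ρ.

A note on bootstrap magnitudes: with ~9 positive outcomes among 46, the
replicate-to-replicate spread of sensitivity is analytically ≈
sqrt(p(1−p)·E[1/n₊]) ≈ 0.11; resampling units coarser or finer than
that cannot reach the ~0.05 sometimes quoted for such data, which would
require resampling the underlying trajectory frames. The package
reports the deterministic ratio and the bootstrap mean side by side and
makes no attempt to force agreement between them.

## Synthetic fixtures

The generator builds an idealised methionine (standard bond lengths,
approximate tetrahedral angles) and places water oxygens and minimal
Ser/Thr/Tyr stubs at controlled SD distances: "inside" atoms in
[2.8 Å, shell − 0.05 Å], "outside" atoms beyond shell + 0.05 Å, so the
≤/< convention can never flip a fixture's truth, with a global 2.4 Å
minimum separation. Ensembles translate selected waters (or hydroxyl
stubs) between a fixed inside and outside pose per frame, so per-frame
counts follow the schedule exactly while the topology stays constant.
An optional cage fills the region around the side chain with carbon
atoms by rejection sampling, producing genuinely buried geometries
(side-chain SASA ≈ 0) without touching the shell counts.

These fixtures emulate *bookkeeping*, not physics: water positions are
not Boltzmann-distributed, hydroxyl stubs are truncated residues, and
the cage is not a folded protein. Passing tests therefore demonstrate
that counting, averaging, surface quadrature and classification are
correct on unambiguous geometry — they do not validate the biological
accuracy of the thresholds, which comes from the packaged evaluation
datasets.

## Packaged datasets and problem sizes

Three checksummed tables ship with the package: the 14-antibody
segment-level evaluation (46 methionines), the 11-row crystal-structure
worked example, and the 26-methionine residue-resolved internal
dataset. The acceptance script and tests run entirely on these tables
and on generated fixtures (tens of atoms, tens of frames); descriptor
property checks use ~100–120 randomised geometries per run.

## Design choices and limitations

* Altloc resolution keeps the highest-occupancy conformer, ties to the
  alphabetically first identifier; selenomethionine is treated as
  methionine with SE in the SD role (both configurable).
* Crystallographic waters in an input structure can be kept (default)
  or stripped via `--strip-input-waters`; keeping them means a static
  analysis counts ordered waters toward WCN.
* Only orthorhombic boxes are supported; triclinic input is an error
  rather than a silent approximation.
* Static single-frame input degenerates cleanly: dSASA equals sSASA and
  WCN/#OH are the static counts — but single-structure WCN is a poor
  stand-in for the ensemble average the rules were tuned on.
* Whether "water within 6 Å" is judged by the oxygen position or by any
  atom of the molecule is a representation choice; the oxygen
  convention used here is recorded and configurable only through the
  water-residue selection, not per-atom.
* Thresholds were tuned (upstream of this package) on small datasets;
  the 15% SASA cut in particular is sensitive to the choice of
  maximum-area normalisation and radii set, which is why both are
  explicit configuration and absolute areas are always reported.
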