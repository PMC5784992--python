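# cytosar

Classification SAR models of human cell-line cytotoxicity for drug-like
compounds: given a small-molecule structure, predict a ranked profile of
the tumour and normal cell lines it is likely to be cytotoxic against.

Screening compounds against panels of cell lines is expensive; curated
bioactivity databases (ChEMBL-style IC50/GI50/%-inhibition tables)
already contain the results of millions of such experiments. `cytosar`
turns such a table into one binary classifier per cell line and lets
you query new structures, the way ligand-based activity-spectrum
predictors are used in early drug discovery and repositioning.

## Method

**Descriptors.** A molecule is represented by its unique set of
*multilevel neighbourhood of atoms* (MNA) strings of levels 1 and 2,
built on the hydrogen-complete graph. The level-0 label of an atom is
`-X` (acyclic) or `X` (ring); level *k* wraps the sorted level-(k−1)
strings of all bonded neighbours: ethanol's oxygen gives `-O(-C-H)` at
level 1 and `-O(-C(-C-H-H-O)-H(-O))` at level 2. Bond orders and
stereochemistry never appear, so stereoisomers are equivalent. Only
admissible structures are modelled: single neutral covalent component,
≥ 3 carbons, bond orders 1–3 after kekulization, MW < 1250 Da.

**Model.** For cell line *a* with corpus counts N, N_a, N_d, N_ad and
smoothing c > 0,

    P(a|d) = (N_ad + c·P₀) / (N_d + c),   P₀ = N_a / N
    B = sin( mean_i arcsin(2·P(a|dᵢ) − 1) )   over known descriptors dᵢ

Compounds not labelled active for a line count as inactive for it
(global-inactive convention). Leave-one-out scores are computed
analytically by decrementing the held-out compound's counts — exactly
equal to a refit without it — and calibrate the probabilities
**Pa**(B) = fraction of active LOO scores ≤ B and **Pi**(B) = fraction
of inactive LOO scores ≥ B. Profiles are ranked by Pa − Pi. Model
quality is the Mann–Whitney ROC AUC under LOO and 20-fold CV; only cell
lines with LOO AUC > 0.8 are kept.

**Training-set curation.** IC50/IG50 < 10,000 nM or inhibition > 50%
⇒ active (strict boundaries; one-sided relations that cannot decide the
threshold are discarded); compound–cell-line pairs with both active and
inactive records are excluded; cell lines need ≥ 3 actives and ≥ 10
explicitly tested inactives and can be dropped via a misidentified-line
exclusion list.

## Worked example

`examples/03_train_and_predict.py` trains on a 200-compound synthetic
panel with one marker-driven cell line (SIG-1, actives carry a carboxyl
marker) and one random line (RND-1), then ranks benzoic acid:

```
cell line   B        Pa     Pi
SIG-1      +0.159  0.900  0.007
RND-1      -0.865  0.714  0.306
```

The query carries SIG-1's marker: its score B sits above 90% of SIG-1's
training actives (Pa = 0.900) and above almost all inactives
(Pi = 0.007), so SIG-1 tops the Pa − Pi ranking. For the random line
the same structure scores low and the Pa/Pi gap shrinks accordingly.

`examples/04_cross_validate.py` runs the standard 500-compound recovery
panel: the three marker-driven lines reach LOO AUC ≈ 0.87 (matching the
panel's Bayes ceiling — see `docs/methods.md`), the two random lines
stay near chance, and AUC-threshold selection retains exactly the
marker-driven lines.

All other capabilities have similar narrative scripts under
`examples/`, and the same flows are available from the shell via the
`cytosar` CLI (`validate`, `descriptors`, `build-dataset`, `train`,
`cv`, `predict`, `summarize`, `make-fixtures`).

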