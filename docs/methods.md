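# Methods

`logfeat` turns heterogeneous protein-annotation snapshots — assembly
stoichiometry/symmetry records, domain-interface residue lists,
biomolecular-condensate (LLPS) annotations, GO/PO records, TF motif
and binding-site data — into mixed categorical feature tables, and
runs a bagged random-forest classification protocol and post-hoc
association analyses over them. This note documents the models,
conventions, defaults, and the limits of what the synthetic tests
demonstrate.

## Reduced alphabets and trimer profiles

Amino acids are collapsed into five groups by side-chain polarity and
charge: `P` (R, K, S, T — positive or polar uncharged), `N` (D, E, N,
Q — negative or polar uncharged), `H` (A, V, I, L, M — hydrophobic),
`R` (F, W, Y — ring structures) and `S` (C, G, P, H — special
properties). IUPAC DNA, including ambiguity codes, collapses to four:
`G`, `Z` = {R, S, K, B, D, V}, `X` = {A, C, T, Y, W, M, H}, `N`.
Profiles are sliding-window trimer counts (step 1), so a length-L
sequence has exactly max(0, L − 2) windows; densified vectors have
|groups|³ entries (125 protein, 64 DNA) in lexicographic order over
the declared group order — the published enumeration is elided with an
ellipsis, so the order is a package convention. Group membership is a
parameter (`AlphabetSpec`): depending on the proteins under study one
may, for instance, give each of C, G, H, P its own group. The default
protein alphabet rejects non-canonical letters (U, B, Z, X) with a
positional error rather than silently skipping them.

Conserved ligand-binding motif families are profiled as the mean of
per-member normalized trimer vectors; mean (rather than sum) keeps
profiles comparable across families of different size, and the
aggregation is a parameter of `motif_profile`.

Nucleotide-containing cofactors are grouped by moiety composition
(R ribose/ribitol, B nucleobase, P phosphate, F flavin,
N nicotinamide, S sulfur, T thiamine, O other) into 11 codes. The
24-ligand assignment shipped in `data/ligand_groups.yaml` is a
documented default derived from standard cofactor chemistry (e.g.
NAD(H) = ribose + base + phosphate + nicotinamide → RBPN; FMN has no
nucleobase → RPF); it is deliberately editable because the grouping
is a modelling choice, not a measurement.

## Assembly taxonomy and oligomerization features

A cluster's stoichiometry string (`A2BC` = two copies of chain A, one
each of B and C) and point-group token (`C1`, `C2`, `D3`) determine:

* composition — *homo* (one distinct chain letter) vs *hetero*;
* state — *monomer* (C1 with one chain copy), *oligomer* (rotational
  order ≥ 2), *single* (an order-1 assembly of several chains; the
  canonical case is C1 from multiple sequences such as C1-A2BC, and we
  extend the same reading to asymmetric homo multi-copy clusters like
  C1-A2, which the source taxonomy leaves unclassified).

The "symmetry number" is read as the integer suffix of the point-group
token (C2 → 2, D3 → 3); an option doubles dihedral groups (D3 → 6
subunits) for users who want subunit counts instead of rotational
order.

All clusters observed for one protein fold into a composite
oligomerization-type label. The label grammar is deterministic and
invertible: `composition + front-obligacy + states + back-obligacy`,
where states appear in (monomer, single, oligomer) order, the front
and back obligacy tokens attach to the first and last state (a single
observed obligacy prints on both sides; two obligacies tied to the
same states print moderate-first). A protein whose every cluster is
C1-A1 is the crystallographic monomer, labelled `CMA`; labels
covering a hetero C1 multi-chain cluster carry a `C1_` prefix. The
printed exemplars of this label family are not mutually consistent in
token order, so the grammar here is the package's own, fixed by a
truth table shipped with the tests and reproducing the canonical
example `homo_obligate_monomer_oligomer_moderate`.

The 19-feature assembly summary (counts and fractions of
compositions, states and obligacy levels; maxima and means of
symmetry order and chain-copy totals; distinct-symmetry/stoichiometry
counts; CMA presence) is a fixed reduction of the raw per-cluster
variables; the original reduction recipe is not published, so the
selection aims at covering the quantities the downstream comparisons
reuse (notably the maximum symmetry order).

## Interface fragments and cluster comparison

Interface residue positions (1-based, strictly increasing per side)
split into *fragments*: maximal runs in which consecutive kept
positions have at most 3 missing residues between them (a gap of
exactly 3 does not split; 4 does — "larger than 3" read strictly).

Entries sharing an unordered domain pair divide into a non-redundant
cluster (each architecture member occurs once, Dom1–Dom2) and a
redundant cluster (a repeated member, Dom1–Dom2–Dom1). Thirteen
per-entry measures are compared across the two clusters — interacting
domain/motif counts, interface residue counts per side and total,
fragment count and length statistics, inter-fragment gaps, and the
assembly module's maximum-symmetry value — with per-cluster means,
standard deviations and membership sizes, plus a one-way ANOVA (F, p)
per measure. The ANOVA is run without a normality screen by design:
the magnitude of the between-cluster difference is the quantity of
interest and no non-parametric statistic reports it the same way;
reports should therefore carry a normality caveat. Only the first
four measures are named by the source description; the remaining
slots are the package's choice and are kept configurable. Degenerate
input (both clusters constant and equal) reports F = 0, p = 1;
an empty cluster marks the ANOVA not-applicable rather than erroring.

Region mapping tiles each protein exactly into domain spans and their
complement (interdomain regions), 1-based inclusive internally;
position-borne annotations (PTM sites, glycosylation) attach by
containment, protein-global ones (GRAVY, pI, locations) to every
region. Overlapping domain annotations keep the longer span and log
the discard — the source is silent on overlaps.

## LLPS features

The condensate vocabulary is the 40-term list (nucleoli, P bodies,
stress granules, …) in snake_case; `others` is a real category. A
protein's LLPS type is its sorted, `|`-joined condensate set, so the
key is order-free and the number of distinct types is bounded by the
number of proteins. Frequency matrices (domains, functional types,
or domain dimers × LLPS types) are additive over protein partitions.
Domain dimers are unordered pairs of distinct Pfams within a protein,
counted once per pair; a self-pair counts only when the Pfam occurs
at least twice. Partial matching marks a protein whose Pfam set is a
strict subset of a larger molecule's and reports the largest such
molecule's Pfam count (motivated by hetero-oligomers and factors that
evolved from several genes).

The 13 special flags cover nine named domain properties (RNA-binding
domain, DNA-binding domain, DMI participation, low complexity,
disorder, repeats, coiled coil, phosphorylation site, active site)
plus four configurable slots defaulting to transmembrane helix,
signal peptide, domain linker and glycosylation — the full list of
thirteen is not published, and the defaults, drawn from the
physicochemical property list, are declared gap-fillers. A flag whose
evidence table is absent reports `unknown`, never a silent `False`.

## GO/PO features

Annotation records match a five-category lexicon through four word
lists: signaling terms, 34 major GO terms, regulatory-role words
(enhancer, suppressor, chaperon(e), activator, …) and the database's
own qualifier vocabulary (matched verbatim). Matching is whole-word
and case-insensitive on the concatenated term name + qualifier. The
per-gene vector has 10 frequency features; duplicates count by
default (frequency semantics) with a dedupe flag. The exact 34-term
and signaling lists are not published; the YAML defaults are
GO-slim-style stand-ins and should be replaced for release-specific
work.

## Binding-site mapping

All interval arithmetic is 0-based half-open internally; BED enters
unchanged, GFF3 converts at the I/O edge. Introns are the exon
complement within the gene span; UTRs, when absent, are inferred as
exon minus CDS (logged); upstream/downstream windows default to
2,000 bp each and are strand-aware (upstream = 5′ of the TSS). A site
counts toward every feature interval it overlaps by ≥ 1 bp and may
hit several features and genes; zero-length overlap never counts, and
adjacent intervals share no position. Sites on chromosomes absent
from the models go to an unmapped bucket. The engine (interval trees)
is tested against a naive all-pairs oracle.

## Classification protocol

Numeric array variables become categoricals by direct mapping or by
clustering (k-means, Gaussian-mixture EM, or a Dirichlet-process
mixture as the density-based option); cluster labels are
`cluster_0…` by descending size with deterministic tie-breaks.
Duplicate rows are removed (non-redundant data); singleton classes
are dropped on request before any stratified scheme, which otherwise
refuses them with a pointer to that step. Training folds are
rebalanced by stratified resampling with replacement to uniform class
mass, or by subsampling majority classes to `max_spread` × the
minority size (default spread 1). The classifier is a random forest
of 100 bootstrapped trees over one-hot-encoded categoricals (one-hot
chosen for portability across implementations); unseen levels at
predict time map to an explicit `__unseen__` bucket; probability
argmax ties break to the lexicographically smallest class. Trees are
exportable as readable text.

Evaluation schemes: stratified 10-fold CV, a single stratified 66/34
split, and a stratified 1/10 holdout intended to be persisted.
Rebalancing and conversion fitting happen inside each training fold
only — a dedicated test verifies the per-fold path is the one that
runs. Reports carry accuracy, per-class precision/recall/F1, the
confusion matrix and the per-instance class-probability table (rows
sum to 1 within 1e-9), and are byte-identical under a fixed seed.

## Association analysis

FAMD standardizes continuous columns and enters each categorical
level as a centered indicator weighted by 1/√(level frequency), so a
continuous column contributes inertia 1 and an L-level categorical
L − 1; eigenvalues therefore sum to (#continuous) + Σ(L − 1), and
per-dimension variable contributions sum to 100%. On all-continuous
input the coordinates coincide with correlation-matrix PCA (tested to
1e-8). Constant columns are dropped with a warning.

The association matrix dispatches on types: Pearson r for
numeric–numeric, Cramér's V (no bias correction) for
categorical–categorical, and the correlation ratio η for mixed pairs.
η is directional — it measures how much of the numeric variance the
categorical explains — and is written into both cells with that
orientation documented. A `corr > 0.6` reporting screen is available
as a flag (default 0.6).

The hotspot search grows conjunctive rules greedily: each node tries
every `variable = level` extension and expands the top `branching`
(default 3) by target-class confidence, requiring support ≥
`min_support` of the target-class mass (default 0.3), strict
confidence improvement, and depth ≤ `max_depth` (default 3). The
defaults mirror customary settings for this rule-search family; none
are published for this use.

## Synthetic data

`generate_bundle` writes a schema-conformant miniature of every
source table with referential integrity across files and one seeded
generator for all randomness (same config ⇒ byte-identical bundle).
It emulates schemas and join structure, *not* the marginal
distributions of real databases: domain, condensate and symmetry
assignments are uniform-ish, sequences are i.i.d. letters, and class
labels derived from it are only as predictable as its features allow.
Passing tests therefore demonstrate correctness of the machinery and
the protocol, not real-data accuracy.

`inject_signal` samples labeled tables from the joint law
p(class, features) ∝ exp(effect · scale · #level-matches): the class
is drawn first, then each informative feature's level from a
multinomial with log-odds shifted by effect × scale toward the
class-linked level, which by symmetry gives the class those same
additive shifts conditionally on the features. The default scale 4.0
makes effect = 1 near-deterministic per feature (a strength-1 binary
feature predicts a 2-class label with ≈ 0.98 accuracy) and effect = 0
exactly independent. Class-fraction presets reproduce the tiny-class
regime (sub-percent classes) to exercise singleton-drop and
stratification errors.

Problem sizes used by the tests and the acceptance script — n = 600
instances, 4 classes, 3 informative + 5 noise features for parameter
recovery; 120-protein bundles for end-to-end runs; 1,000-sequence /
1,000-interval oracle sweeps — were chosen as the smallest scales at
which the statistical checks are stable.

## Known limitations

* Word lists, the 24→11 ligand map, the four unnamed special flags
  and the non-named interface-comparison slots are stand-in defaults;
  all are editable configs, and conclusions drawn from the defaults
  inherit their arbitrariness.
* The composite-label grammar is a package convention fixed by a
  truth table; other tools may order tokens differently.
* No real database parsers (the released flat files of the upstream
  resources are out of scope); readers accept schema-conformant
  TSV/GAF/BED/GFF3/FASTA snapshots.
* The correlation-ratio entries make the association matrix only
  block-symmetric in interpretation, though numerically symmetric by
  construction.
* ANOVA p-values are reported under an explicit normality caveat.
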