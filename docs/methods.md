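# Methods

## Peptide model

A peptide is an ordered list of monomer ids per chain plus explicit
connections. Monomers are capped small molecules (free amine, free
acid) with labelled attachment points in the HELM convention: R1 on the
backbone amine (hydrogen leaving group), R2 on the backbone acid
(hydroxyl leaving group), R3 on a side chain where present (the
side-chain carboxyls of Asp/Glu). Assembly condenses successive R2–R1
pairs within a chain and any explicit connections, deleting the acid
hydroxyl while the amine loses one implicit hydrogen — one water per
bond. Consequences used as test oracles:

* linear n-mer mass = Σ monomer masses − (n−1)·H₂O;
* head-to-tail cycles remove n·H₂O and leave no free termini;
* a gamma-glutamyl dipeptide is an exact-mass isomer of its
  backbone-linked counterpart.

D-amino acids are distinct monomer ids (`dL`, `dF`, `dW`), not flags.
Gamma-glutamyl/aspartyl peptides keep the canonical E/D monomer and an
explicit R3→R1 connection (the Glu/Asp sits in its own HELM polymer).
Esters and acyl modifications are terminal cap monomers (`OMe`, `Lac`,
`Succ`, `Ac`); ionic salt adducts (e.g. hydrochlorides) are *not*
modelled — a known limitation of the cap representation. Pyroglutamate
is a terminal monomer exposing only R2 (its ring nitrogen is an amide).

Residue count excludes the pure caps (`Ac`, `Lac`, `Succ`, `OMe`) and
counts everything else, including pGlu. The shipped library holds the
20 canonical L-amino acids plus 13 extension monomers covering the
modification classes that occur in taste-annotated collections; user
libraries are merged at load time with user entries taking precedence.

## Notations

Extended FASTA: one-letter codes, `(D)-X` for D-residues, bracket
tokens from a fixed module-level table (`[pGlu]`, `[Nle]`, `[Nva]`,
`[Orn]`, `[M(O)]`, `[pS]`, `[Ac]`, `[Lac]`, `[Succ]`, `[OMe]`), a
`cyclo(...)` wrapper, and a `gE-`/`gD-` (also `γE-`/`γD-`) prefix for
gamma linkages. The bracket convention is standard practice; the token
inventory itself is this package's documented choice, since no
canonical inventory exists. Bracket tokens may appear at any sequence
position; N-terminal caps are written before, C-terminal caps after
the residue letters.

HELM v2 is supported for PEPTIDE polymers with explicit connections
(`PEPTIDE1,PEPTIDE1,3:R2-1:R1`); an optional trailing `V2.0` section is
accepted. BILN uses hyphen-separated ids with paired `(index,Rgroup)`
bond suffixes, emitted digit-only (`A(1,1)-P-G(1,2)`) and accepted in
either digit or `R`-labelled form. Emission is canonical — chains in
input order, connections sorted — so output strings are bit-stable and
round trips are exact. Three-letter→one-letter conversion uses
Biopython's IUPAC table.

## Q value and the Ney rule

Q = ΣΔf/n, the mean free energy of transfer of side chains from
ethanol to water (cal/mol), over the Ney (1971)/Tanford Δf table. The
source material prints only derived Q values, so the shipped table is
validated at import time against five fixed points — Q(WW)=3000,
Q(Q)=−100, Q(GE)=275, Q(GF)=1325, Q(RRPPPFFF)=2151 — which jointly pin
down Δf for G, E, F, W, Q and the combination 2R+3P+3F = 17,210
cal/mol. These checks require Pro = 2600 cal/mol and reject the 2620
variant found in some textbooks. Asn (−10) and Cys (1420) are not
constrained by the fixed points and follow common tabulations.

Printed Q values are integers; computed values are reals rounded
half-away-from-zero (17,210/8 = 2151.25 → 2151). The rule is applied
strictly: values above 1400 cal/mol are likely bitter, below 1300
likely nonbitter, and boundary values (exactly 1300 or 1400) fall in
the indeterminate band, matching the strict reading of "over"/"below".
Q is undefined for modified residues and the scorer rejects them;
modified records are excluded (with reasons) from the Q/length plane.

## Descriptors

ExactMW is the monoisotopic mass. Two independent routes must agree to
1e-4 Da: RDKit `ExactMolWt` on the assembled graph, and a residue-mass
table fast path for canonical sequences (cross-checked against
pyteomics in the tests). Quoted integer masses in collection reports
follow *truncation* of the monoisotopic sum — G → 75 Da (75.032),
RRPPPFFF → 1062 Da (1062.576), the 56-mer → 6357 Da (6357.265) —
which `printed_mw` implements; note 1062.576 would *round* to 1063, so
truncation is the only convention consistent with all three quoted
values. SlogP is the Wildman–Crippen atom-additive logP delegated to
RDKit, computed on neutral structures (uncharged termini and side
chains, matching descriptor computation on drawn structures); the
glycine value −0.9703 is frozen as a reference point. Peptides are
located in two planes: (Q, length) for canonical records and
(SlogP, ExactMW) for all records.

## Synthetic collection

The generator's defaults are the study conditions: 570 bitter and 423
nonbitter records including 213 modified peptides (cyclic 59,
salts/esters 26, pyroglutamyl 14, gamma-Glu/Asp 57, Nle/Nva 14, other
43). Group-wise bitter counts (44/8/4/7/14/15, 92 total) reproduce the
reported fractions: cyclic 74.6% bitter, Nle/Nva 100%, gamma-Glu/Asp
12.3%.

Sequence lengths follow P(1) = 0.08 and a geometric tail from the mode
at 2 with ratio 0.80 (dipeptide fraction ≈ 0.18, matching the real
dipeptide counts 107/570 and 71/423), truncated at the class maxima 49
(bitter) and 56 (nonbitter). Residues are drawn from class-conditional
frequencies — bitter over-samples F, G, I, L, P, R, V, W, Y and
nonbitter over-samples A, D, E, M, S, T, with Pro most frequent in
both — and candidate sequences are accepted through a Q-logistic label
law, p(accept | bitter) = σ(k·(Q − 1350)) with k = 0.0025 per cal/mol,
so the bitter/nonbitter separation is present by construction but
blurs near the rule thresholds, as in real sensory data. Increasing k
sharpens the separation (a tested monotone response). Sequences are
unique within a dataset.

BTTs attach to 60% of bitter records as a two-band log-uniform
mixture: with probability 0.86 in [0.002, 10) mmol/L, else in
[10, 519] — reproducing the reported "86% below 10 mmol/L" marginal.
Receptor annotations are sparse (5% of bitter records, 1–3 receptors
from the 12-receptor peptide-sensitive vocabulary); 3% of records are
flagged as sensory-conflicting. Modified records are canonical
backbones transformed by their group's defining operation
(cyclization, caps, pGlu, gamma linkage, Nle/Nva or other
substitutions), so they exercise every notation path.

What the generator does **not** emulate: real amino-acid
autocorrelation within sequences (residues are i.i.d. given class and
length), food-source structure beyond a categorical field, the exact
per-peptide content of any curated collection, and any BTT–Q
dependence (thresholds are drawn independently of the sequence).
Passing tests therefore demonstrate that the analysis machinery is
correct and that it recovers structure the generator plants — not that
the Q rule performs at any particular level on real peptides.

## Numerical and design choices

* One numpy `default_rng(seed)` stream per generated dataset; no
  global state. Identical seeds give byte-identical record tables.
* Rejection sampling for the label law caps at 200 tries per record,
  then takes the best candidate seen — termination is guaranteed for
  any configuration.
* Analysis operations are order-invariant and conserve counts;
  exclusions are enumerated (id + reason), never silent.
* Threshold partitions use strict inequality for "above"; unlabelled
  (not-tested) points are counted separately so the conservation law
  still holds.
* Enrichment fractions for empty sides are NaN rather than an error.
* The logP density thresholds (−0.20, −1.90) and BTT band edges (1,
  10, 100 mmol/L) are configuration values, not constants — they are
  dataset-dependent in origin.
* Default problem sizes: the shipped analysis drivers and tests run on
  one 993-record dataset (plus 10 seeds for the correlation property),
  which keeps the full suite under a minute while leaving every
  distributional check well-powered.

## Known limitations

* No 3D structure: conformers, chirality-dependent effects,
  intramolecular hydrogen bonds are out of scope, so SlogP and Q are
  coarse for long peptides.
* No charge-state or pKa modelling; masses and logP assume neutral
  molecules.
* HELM support covers PEPTIDE polymers only (no RNA/CHEM types,
  hydrogen-bond pairing, or polymer groups).
* Q cannot be extended to modified residues without new Δf values,
  which this package deliberately does not invent.
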