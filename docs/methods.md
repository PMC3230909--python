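# Methods

## Problem

Targeted mass-spectrometry assays (SRM/MRM) for phosphorylation
stoichiometry need, for every monitored site, a proteolytic peptide that
contains the site, has a workable length, and avoids residues that
complicate synthesis or ionisation. When a study monitors tens of sites
across many proteins, choosing the enzyme — or small enzyme panel — that
produces such peptides for *every* site is a combinatorial chore. This
package simulates digests for a registry of proteases and chemical
cleavage reagents, scores per-site coverage, and proposes a minimal
enzyme panel.

## Cleavage model

Each enzyme is a single regular-expression recognition pattern over the
20-letter amino-acid alphabet plus an integer **distance to cleavage
point**. Positions are 1-based. A match starting at residue `p`
contributes the bond `b = p + d − 1`, where bond `b` is the peptide bond
between residues `b` and `b+1`; bonds landing on a terminus (`b = 0` or
`b = L`) are silently dropped. For the pattern `WKP`, `d = 0` cuts
before the W and `d = 1` between W and K. Every start position is probed
independently (`re.match` at each offset), so overlapping motifs — e.g.
consecutive lysines under a `K` rule — each cut; lookbehinds still see
the full upstream context. Specificity exceptions (trypsin's suppressed
cleavage before proline, pepsin's positional preferences) are encoded
with lookaround constructs inside the one pattern per enzyme.

The bundled registry transcribes the published PeptideCutter
specificities for 34 enzymes and reagents. The registry is a plain XML
(or JSON) data file; users can edit, subset, or replace it.

A **two-enzyme digest** is modelled as a simultaneous double digest: the
union of the two single digests' bond sets, with no ordering. General
missed-cleavage enumeration (0..k skipped cuts) is deliberately not
modelled; the only missed-cleavage mechanism is phosphorylation
adjacency, below.

## Phosphorylation-aware cleavage

A phosphoryl group adjacent to a cleavage site can sterically block the
protease, so the cut is missed and the site survives inside a longer
peptide. In phospho-aware mode (default on) every bond flanking a
modified residue at position `s` — both `s − 1` and `s` — is removed
from the final bond set before peptides are formed. Suppressing both
flanking bonds is the conservative reading of "adjacent"; the operation
is exposed separately (`suppress_phospho_adjacent`) so a one-sided
variant is a trivial wrapper. Suppression is idempotent and only ever
removes bonds.

## Peptide properties

* **Masses** are monoisotopic: sum of residue masses + water
  (18.0105647 Da), plus one HPO3 increment (79.9663309 Da) per modified
  residue for the phospho form. The residue table is a bundled,
  editable JSON file.
* **m/z** = `(M + z·m_proton) / z` with `m_proton = 1.00727647` Da,
  reported for both forms at the predicted charge.
* **Charge** is the protonation-site count `1 + #(K, R, H)` — the
  N-terminus plus basic side chains. This is a naming convention for
  the report, not an electrospray model, and is isolated so a smarter
  predictor can replace it.
* **Hydrophobic percentage** counts residues in {A, V, L, I, M, F, W}
  over peptide length, to one decimal. This is the unique classical
  hydrophobic set consistent with both bundled reference peptides
  (RMNCSPTSQI → 20.0 via M, I; MKTF → 50.0 via M, F).
* **Retention time** uses an additive linear model: intercept plus one
  coefficient per residue occurrence, blind to modifications. The
  default coefficient file ships the classical Guo–Mant–Hodges C18/pH-2
  set with intercept 0; absolute predictions are only meaningful after
  refitting intercept and coefficients to a specific gradient, which is
  why the table is data, not code.
* **Highlighting** renders each modified residue as ` [X] ` with doubled
  spaces collapsed, e.g. `MK [T] F`, `RMNC [S] PT [S] QI`.

## Filtering and qualification

Two per-peptide predicates screen digest output: a length window
(default 5–30 residues) and an exclusion list of problematic residues
(default M and C — oxidation-prone / cysteine-chemistry-prone). Both are
pure predicates, so filtering is idempotent and order-independent. A
target site is **covered** when some passing peptide spans it (1-based
inclusive bounds). An enzyme **qualifies** for an experiment when it
covers all target sites (`require_all_sites`) or at least one (default —
partial panels are useful when sites are far apart). An optional strict
mode asks for all sites inside one single peptide
(`sites_in_single_peptide`); it is not the default because distant sites
(e.g. a kinase's S473 and T308 equivalents) make it vacuously empty.

## Combination and enzyme selection

Per-experiment results merge into an enzymes × (experiment, site)
coverage matrix; covered cells carry the covering peptide's sequence.
"Most appropriate combination of enzymes" is formalised as
minimum-cardinality set cover over matrix rows, solved greedily: pick
the row covering the most still-uncovered columns, break ties by
lexicographically smallest label, stop when nothing improves. Greedy is
within `1 + ln(n)` of optimal and is verified against an exhaustive
oracle on all random matrices up to 10×10 in the test suite. Columns no
enzyme can cover are returned explicitly as residual, never dropped.
The cardinality objective is pluggable in principle (a quality-weighted
scorer would slot into the same loop); cardinality is the default
because nothing in the problem statement weights peptide quality.

## Synthetic data

`generate_fixture` builds i.i.d. random sequences over the 20-letter
alphabet, plants literal cleavage motifs at recorded non-overlapping
positions, and marks phosphosites on existing S/T/Y residues, all from
one integer seed, returning a ground-truth manifest. Tests use it for
engine-vs-manifest cross-checks and for a structural analog of a
nine-protein / 52-site study panel (sequence length 360, the default
5–30 / no-M,C / phospho-aware parameter set), which must come out as a
52-column matrix end-to-end. These sequences deliberately lack real
amino-acid composition bias, domain structure, and phosphosite
clustering in disordered regions — passing tests demonstrate engine
correctness (coordinates, tiling, coverage accounting), not biological
realism of coverage rates.

## Numerical and degenerate-input choices

Mass comparisons use a 5e-4 Da tolerance (report formatting is 5
decimals); percentages are rounded to one decimal, retention times to
two. An experiment with zero target sites qualifies vacuously. An empty
bond set yields the whole protein as one peptide. Registry iteration
order is file order, and every export is deterministic given inputs and
seed; nothing reads the clock or locale.

## Known limitations

* Cleavage rules are binary patterns; no kinetics, efficiency, or
  semi-specific cleavage.
* Charge and retention predictions are deliberately simple conventions;
  treat them as sortable heuristics, not instrument-grade predictions.
* No proteotypicity check against a background proteome and no
  fragment-ion (transition) lists — the output is candidate peptides,
  not a finished instrument method.
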