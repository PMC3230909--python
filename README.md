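# srmdigest

In-silico enzymatic protein digestion for designing SRM/MRM
(selected/multiple reaction monitoring) assays, with a focus on
phosphorylation-site monitoring.

Quantifying phosphorylation stoichiometry by targeted LC-MS/MS requires,
for every monitored site, a proteolytic peptide that contains the site,
sits in a practical length range, and avoids problematic residues.
Finding the protease — or minimal pair/panel of proteases — that
achieves this for dozens of sites across many proteins is tedious to do
by hand. `srmdigest` simulates digests for 34 PeptideCutter-derived
enzyme and chemical-cleavage specificities (single enzymes or pairwise
combinations), suppresses cleavages next to phosphorylated residues
(the *missed cleavage* effect: a phosphoryl group adjacent to a cut
site can block the protease), filters candidate peptides, reports their
physicochemical properties, and selects a minimal covering enzyme panel.

## Model in brief

* Each enzyme is one regular-expression pattern plus an integer
  *distance to cleavage point* `d`: a match starting at residue `p`
  (1-based) cuts the bond `b = p + d − 1` between residues `b` and
  `b+1`. For pattern `WKP`, `d = 0` cuts before W, `d = 1` between W
  and K.
* A pairwise digest is the union of the two enzymes' bond sets.
* Phospho-aware mode removes both bonds flanking each modified residue
  before peptides are formed.
* Peptide masses are monoisotopic; the phospho form adds
  79.96633 Da (HPO3) per site; m/z = (M + z·1.00727646) / z at a
  predicted charge of 1 + #(K,R,H).
* Panel selection is greedy minimum set cover over the
  enzymes × (protein, site) coverage matrix, with uncoverable sites
  reported explicitly.

See `docs/methods.md` for the full model, parameter meanings, and
limitations.

## Worked example

Generate a reproducible synthetic two-protein panel with four
phosphosites, then ask which enzymes cover them:

```sh
srmdigest fixture --seed 8 --n-proteins 2 --length 180 --n-sites 4 --out-dir demo
cat > demo/run.json <<'EOF'
{
  "fasta": "proteins.fasta",
  "sites": "sites.tsv",
  "enzymes": ["Trypsin", "LysC", "Glutamyl endopeptidase", "Asp-N endopeptidase"],
  "experiments": [
    {"name": "exp-SYN001", "record": "SYN001"},
    {"name": "exp-SYN002", "record": "SYN002"}
  ]
}
EOF
srmdigest batch --config demo/run.json --out-dir demo/out
```

This prints one log line per digest and a summary:

```
[exp-SYN001] Trypsin: 10 peptides, 3 passed filters, 0/2 sites covered, qualified=False
[exp-SYN001] Asp-N endopeptidase: 13 peptides, 6 passed filters, 2/2 sites covered, qualified=True
[exp-SYN002] Asp-N endopeptidase: 16 peptides, 3 passed filters, 2/2 sites covered, qualified=True
...
4 target sites, 4 coverable; selected enzymes: Asp-N endopeptidase
```

Each line reports how many peptides the digest produced, how many
survived the default filters (length 5–30, no M or C), and how many of
the experiment's target sites those survivors cover. Here Asp-N
endopeptidase alone yields filter-passing peptides spanning all four
sites, so the greedy selector proposes a one-enzyme panel.
`demo/out/matrix.csv` holds the full Y/N coverage matrix:

```
"Enzyme","SYN001:15","SYN001:43","SYN002:74","SYN002:90"
"Asp-N endopeptidase","Y","Y","Y","Y"
"Glutamyl endopeptidase","N","N","N","N"
...
```

and `demo/out/datasheet_*.json` carries the per-peptide detail blocks
(coordinates, highlighted sequence such as `MK [T] F`, phospho and
non-phospho monoisotopic masses and m/z, percent hydrophobic residues,
predicted retention time).

The same pipeline is available as a library:

```python
from srmdigest import DigestParams, Experiment, PhosphoSiteSet, load_rules, run_experiment

exp = Experiment(
    name="demo", protein_id="P1",
    sequence="GGARMNCSPTSQIGG",
    target_sites=PhosphoSiteSet({8: "S", 11: "S"}, sequence="GGARMNCSPTSQIGG"),
    params=DigestParams(len_min=1, len_max=40, excluded_residues=frozenset()),
)
results = run_experiment(exp, load_rules().subset(["Proteinase K"]))
peptide, props = results[0].peptides[1]
print(peptide.sequence, props.mass_phospho, props.highlighted)
# RMNCSPTSQI 1295.4440752062999 RMNC [S] PT [S] QI
```

## Layout

| Path | Contents |
| --- | --- |
| `src/srmdigest/rules.py` | enzyme rule registry, XML/JSON rule files |
| `src/srmdigest/digest.py` | cleavage-site finding, phospho suppression, peptide generation |
| `src/srmdigest/props.py` | masses, m/z, charge, hydrophobicity, retention time, highlighting |
| `src/srmdigest/filters.py` | length/residue filters, site coverage, qualification |
| `src/srmdigest/experiment.py` | batch runs, coverage matrix, greedy panel selection, exports |
| `src/srmdigest/io.py` | FASTA, sites TSV, XML report dialect, run configs |
| `src/srmdigest/fixtures.py` | seeded synthetic panels with ground-truth manifests |
| `src/srmdigest/cli.py` | `srmdigest digest / batch / rules / fixture` |
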