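# ssrobust

Quantifying the mutational robustness of protein secondary-structure
elements: are alpha helices harder to destroy by sequence change than
beta strands, and if so, why?

## The scientific problem

When homologous protein domains diverge in sequence, their residues do
not lose their local conformation at equal rates: helix (H) residues
tend to stay helical across much larger sequence distances than strand
(E) residues, and coil (C) is the least stable of all. A candidate
mechanism is **contact density**: helices make more short-range
residue-residue contacts than strands at comparable burial, and contacts
constrain which substitutions a site tolerates. The same asymmetry shows
up in human missense variation - variants that break secondary structure
are disproportionately pathogenic and destabilizing.

`ssrobust` implements the full analysis chain for this question over
structural alignments of diverged domain pairs, plus a synthetic-data
generator with known ground truth so that every statistical claim the
pipeline makes can be tested against the generating process.

## What is in the box

| module | contents |
| --- | --- |
| `ssrobust.structio` | PDB / DSSP / structure-alignment / SCOP-classification readers and writers, domain and alignment containers |
| `ssrobust.structcalc` | secondary-structure assignment from backbone H-bonds (Kabsch-Sander energies), Shrake-Rupley accessible surface area, RSA normalization against extended Gly-X-Gly, residue contact maps (0.25 A surface-gap rule) |
| `ssrobust.align_metrics` | alignment filtering (TM-score, length, family, numbering), percent identity, per-class secondary-structure similarity, indel frequency, similarity-binned aggregation, per-residue conservation tables |
| `ssrobust.stats` | ANCOVA (group + covariate F-test), two-proportion tests with exact small-count fallback, Holm-Bonferroni / Benjamini-Hochberg corrections, Wilson intervals, contact-regression residue subsetting, logistic predictor importance |
| `ssrobust.mutation_variant` | point-mutant discovery between near-identical sequences (k-mer prefilter, global alignment, spacing and dedup rules), missense-variant stratification by RSA / PolyPhen-2 bins, ddG comparisons |
| `ssrobust.synthetic_data` | ideal backbone geometries (helix, twist-free strand, antiparallel hairpin, coil), diverged-domain-pair generator with class-dependent flip rates and contact damping, mutant sequence sets, logistic variant cohorts - all with recorded ground truth |
| `ssrobust.pipeline` / `ssrobust.cli` | end-to-end report bundles and the `ssrobust` command-line wrapper |

## Worked example

Annotate an ideal 15-residue alpha helix from raw coordinates:

```python
from ssrobust.structcalc import annotate_domain
from ssrobust.synthetic_data import make_ideal_structure

helix = make_ideal_structure("helix", 15)
for res, a in zip(helix.residues, annotate_domain(helix)):
    print(res.number, a.ss3, round(a.asa, 1), a.n_contacts)
```

Interior residues are assigned `H` from the i -> i+4 hydrogen-bond
ladder and carry 7-8 contacts; chain ends relax to coil (run
`python examples/01_annotate_ideal_structures.py` for the full table):

```
 res ss3     asa    rsa contacts    mcd
   1   C   120.1  1.055        4   2.50
   2   H    83.9  0.738        5   2.20
   ...
   8   H    64.0  0.563        8   2.50
   ...
  15   C   121.5  1.068        4   2.50
```

Run the comparative analysis on 200 simulated diverged pairs
(`python examples/02_comparative_report.py`); the output below is the
script's actual print-out:

```
per-class secondary-structure retention (10-20% window):
ss3  retained     n  fraction    ci_lo    ci_hi
  C      6378 11641  0.547891 0.538836 0.556915
  E     11742 13263  0.885320 0.879785 0.890632
  H     12944 13396  0.966259 0.963065 0.969185
helix vs strand proportion test: {'p_value': 1.44e-140, 'method': 'z', 'diff': 0.0809}

after contact-regression subsetting (helix below / strand above their class lines):
ss3  retained    n  fraction
  E      6078 6689  0.908656
  H      6433 6698  0.960436

ANCOVA retention ~ class + RSA (10-30% window):
  F = 764.76, p = 5.04e-166, RSA slope = -0.076, n = 27072
```

Helix residues retain their conformation more often than strand
residues at matched sequence divergence; selecting contact-poor helix
residues and contact-rich strand residues narrows the gap - the
contact-density mechanism at work.

The other example scripts cover the mutant scan
(`03_mutant_scan.py`), variant stratification
(`04_variant_stratification.py`) and the RSA-versus-contacts predictor
comparison (`05_predictor_importance.py`). The same capabilities are
exposed on the command line:

```bash
ssrobust annotate structure.pdb
ssrobust report --n-pairs 200 --outdir results/report
ssrobust scan-mutants sequences.fasta
ssrobust simulate --what variants --n 5000 --outdir sim
ssrobust variants sim/variants.tsv --outdir results/variants
```

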