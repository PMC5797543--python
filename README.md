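# neomhc

Tumor-specific missense mutations can create *neoepitopes*: short peptides
that an HLA class I molecule displays on the cell surface and that CD8+
T cells can recognise, while the unmutated *self* peptide is ignored or
excluded from binding. `neomhc` is a toolkit for the two computational
halves of that problem:

1. **Variant → neoepitope pipeline.** Somatic SNVs annotated with
   per-caller status, allele fraction, mate-specific read support, RNA
   coverage and gene expression are pushed through a three-stage filter
   chain (caller consensus → OxoG/read-provenance artifacts → expression),
   translated into 2n−1-mer mutant contexts for n = 9, 10, 15, enumerated
   into every n-mer containing the mutation, scored against HLA alleles
   through a pluggable predictor, filtered at a 5% percentile rank, paired
   with their self counterparts, and grouped into ImmunoActive Regions
   (IARs) ranked by best binder, expression, allele promiscuity, and
   9/10-mer overlap support.

2. **Structure-based peptide/HLA screening.** Starting from a
   peptide/MHC-I template complex, the heavy chain is trimmed to the α1/α2
   groove domain, the groove is defined as every heavy-chain residue
   within 3.5 Å of the peptide, target HLA sequences are threaded onto the
   fixed backbone (side chains rebuilt from a bundled rotamer library at
   mismatches), groove + peptide side chains are repacked by seeded
   simulated annealing, and the binding energy

   ΔE = E(complex) − E(MHC) − E(peptide)

   is averaged over the 10 lowest-energy models of a 100-model pool per
   allele. A polyAla mock groove is the negative control. Downstream
   analytics include BLOSUM62 identity landscapes, Kullback–Leibler
   sequence logos of groove residues among good binders, RMSD/SASA/BSA/
   contact/3₁₀-helix structure metrics, theoretical peptide masses, and
   Boltzmann sigmoid melting-curve (DSF) fits.

The energy model is a deliberately simple, documented physics score
(softened Lennard-Jones, hydrogen bonds, screened Coulomb, burial
penalty); all conclusions drawn from it are **ordinal** (which complex
scores better), never absolute energies. See `docs/methods.md`.

## Worked example

Every input class can be synthesised, so the full pipeline runs with no
external data:

```bash
# 40 variants with planted artifacts -> filter chain
neomhc simulate variants --seed 3 --n 40 --out v.vcf --truth truth.tsv
neomhc filter-variants --vcf v.vcf --out kept.vcf --audit audit.tsv
# -> "kept 24/40 variants"; audit.tsv names the failing stage per variant

# idealised peptide/MHC micro-groove and a small allele family
neomhc simulate groove --out groove.pdb
neomhc simulate alleles --seed 2 --ref-seq TTTTTLSYLLSYLLSYLLSYL \
    --n-alleles 3 --out alleles.fasta
neomhc --seed 11 thread --template groove.pdb --alleles alleles.fasta \
    --n-models 10 --top-k 3 --out screen.tsv
```

`screen.tsv` then contains (energies in model energy units; lower binds
better):

```
allele      mean_delta_e  sd_delta_e  n_models  top_k  status
allele-001  -31.86        0.00        10        3      scored
allele-002  -27.16        0.02        10        3      scored
allele-003  -27.04        0.39        10        3      scored
polyAla     -15.73        0.39        10        3      scored
```

The allele identical to the template groove (allele-001) binds best, the
two mutated family members bind less well, and the polyAla mock groove is
clearly the worst — the expected control ordering. A theoretical peptide
mass for an LC–MS check:

```bash
$ neomhc mass --seq AQDIYRASY
1086.17
```

Library use mirrors the CLI; for example the nonamer/decamer windows of
an ALK-kinase-like R→Q substitution:

```python
>>> from neomhc.windows import windows_for_mutation
>>> ws = windows_for_mutation("MGWGMARDIYRASYYHKL", 7, "Q", 9)
>>> [(w.seq, w.self_seq) for w in ws if w.seq == "AQDIYRASY"]
[('AQDIYRASY', 'ARDIYRASY')]
```

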