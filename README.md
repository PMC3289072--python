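# dnagroove

Knowledge-based prediction of where — and in which orientation — DNA binds
on a protein structure.

Given a set of training protein–DNA complexes, `dnagroove` learns:

1. **Residue propensities** — the fraction of each amino-acid type found
   within 4.5 Å of DNA;
2. **Reference frames** — the three atoms of each type contacting the most
   bases within 4 Å, defining a canonical residue-local coordinate system;
3. **Geometric models** — for each (amino acid, base) pair, the cloud of
   base positions observed around that residue type, stored in its local
   frame (up to 20 × 4 = 80 models).

On a query protein (bound or unbound), the pipeline then:

* filters a conserved-residue list to solvent-exposed residues
  (RSA > 0.25, internal Shrake–Rupley),
* clusters them at atom level (average linkage, 11 Å stop, majority vote
  per residue) and keeps clusters whose summed propensity beats the
  size × mean-propensity expectation — these are the **DNA-binding units
  (DBUs)**,
* predicts the groove tangent direction of each DBU by PCA over three
  representative atoms per residue (top contact atom, CA, C),
* predicts base locations by mapping the geometric models into query
  coordinates, scoring candidates with a Gaussian density normalized per
  amino-acid type, removing protein-core positions (CA-based burial score
  with a 2 Å clash stop), and greedily selecting diverse placements
  (pairwise RMSD > 5 Å), highest density first.

Predictions can be scored against a reference complex: distance to the
closest base centroid (failure beyond 6 Å), undirected angle to the
phosphate-chord groove tangent (success at cosine > 0.9), and residue-level
precision/sensitivity.

A synthetic-fixture generator (`dnagroove.fixtures`) builds idealized
B-DNA duplexes with planted residue clusters and known ground-truth groove
tangents, so the whole pipeline is testable without any external data.

## CLI

```bash
# generate a synthetic complex with ground truth
dnagroove fixture --out scratch/fix.pdb --n-bp 16 --n-dbus 1

# build a knowledgebase from a directory of complex PDB files
dnagroove kb build --train-dir scratch/ --out scratch/kb

# rank DNA-binding units on a query structure
dnagroove dbu find --pdb scratch/fix.pdb --kb scratch/kb

# full pipeline: DBUs -> orientation -> base locations (+ evaluation)
dnagroove predict --pdb scratch/fix.pdb --kb scratch/kb \
    --reference scratch/fix.pdb --topk 1 --out scratch/pred.tsv

# score a prediction TSV against a reference complex
dnagroove evaluate --pred scratch/pred.tsv --ref scratch/fix.pdb
```

Conserved residues default to `--conserved all`; pass a text file with one
`chain:resseq` per line to restrict to an external conservation prediction.

## Notes on modeling choices

* The exact functional bodies of the density and core scores are realized
  as Gaussian kernel sums (unit peak; widths 2 Å and 5 Å) behind single
  swappable functions; the propensity is the plain binding fraction, with
  an odds-ratio variant available on `PropensityTable`.
* Whether DNA backbone atoms count toward the 4 Å base contacts is
  configurable (`base_moiety_only`); the default includes the whole
  nucleotide.
* The 11 Å clustering stop is implemented as a dendrogram cut: merges are
  applied in ascending linkage order and stop at the first merge whose
  average linkage exceeds the threshold.
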