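# titinkit

Sequence and structure analysis of the titin-kinase (TK) region — the
vertebrate pseudokinase near titin's C-terminus, flanked by its N-terminal
linker (NL) and C-terminal regulatory domain (CRD).

TK is a pseudokinase: its ATP pocket carries a θxK motif (θ a bulky
hydrophobic residue, usually M, instead of the canonical small A/V of AxK)
and its magnesium-binding slot an ExG motif (instead of DFG).  The flanking
tails contribute the rest of the signature — an [N/L]YD anchor in the NL, an
[R/K]H[R/K]RYY motif in CRD helix αR1, an R-7x-R motif in helix αR2, and a
small residue at position −2 of R-7x-R that packs into the ATP pocket
against θ and completes the catalytic spine.  Teleost fish carry two titin
genes (*ttna*/*ttnb*) from the teleost genome duplication, and their TK
domains segregate cleanly by isoform and by fish clade
(neoteleostei/non-neoteleostei), which makes TK a usable proxy for
classifying full titin genes.

`titinkit` implements that analysis as a tested pipeline, for sequence
analysts and structural biologists working on sarcomeric kinases:

- **seq_io** — FASTA reading/writing with label tags, three-pass curation
  (keyword exclusion, exact-duplicate removal, partial-sequence removal by
  reference-anchor coverage);
- **align** — affine-gap global alignment (BLOSUM62, gap open 10 / extend
  0.5, free terminal gaps), percent identity over mutually aligned columns,
  within/across-group identity summaries;
- **simmap** — the pairwise-similarity map: raw alignment scores are
  normalised to correlation-like coefficients
  `r_ij = s_ij / sqrt(s_ii · s_jj)`, embedded spectrally
  (`x_i(d) = sqrt(λ_d) · v_d(i)`, dimensions ordered by eigenvalue, so
  earlier dimensions carry the more prominent divergences), and classified
  into isoform/clade clusters with labelled anchor sequences;
- **motifs** — reference-anchored motif extraction (θxK, DFG/ELG slot, P+1,
  glycine-rich loop template, [N/L]YD, αR1, R-7x-R, position −2), per-group
  residue frequency tables and the θ ↔ −2 2×2 covariation (Haldane-corrected
  odds ratio, φ association);
- **structure** — PDB/mmCIF parsing (gemmi), Kabsch/SVD superposition with
  reflection guard, per-residue Cα deviations, functional-group distances
  (e.g. the K68–E83 open-conformation gap), spine contiguity checks;
- **synth** — a family simulator with implanted group-specific motif tables
  and known truth, plus rigid-transformed noisy coordinate pairs, so every
  stage is testable without downloads.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from titinkit import assign_and_classify, build_similarity, embed
from titinkit.synth import SimConfig, default_anchor_ids, simulate_families

sset, truth = simulate_families(SimConfig(seed=17))   # 5 groups × 20 seqs
emb = embed(build_similarity(sset))
asn = assign_and_classify(emb, default_anchor_ids(truth))
true = [truth.groups[i] for i in emb.ids]
pred = [asn.clusters[i] for i in emb.ids]
print(adjusted_rand_score(true, pred))
```

Running `python examples/01_simulate_and_classify.py` prints:

```
simulated 100 sequences in 5 groups of 20
eigenvalue spectrum: 56.8, 17.0, 15.1, 3.9, 3.0
adjusted Rand index vs truth: 1.000  (1.0 = perfect recovery)
isoform split in dimension 2, clade split in dimension 5: the deeper a/b divergence surfaces first
```

The leading eigenvalue is the shared-similarity axis (all TK regions are
homologous); the following dimensions separate mammals from fish, isoform
*a* from *b*, and the fish clades.  An adjusted Rand index of 1.0 means the
anchor-oriented classification reproduces the generator's five groups
exactly, and the isoform split appearing in an earlier dimension than the
clade split mirrors the fact that the gene-duplication divergence is deeper
than the clade divergence.

The other examples cover motif frequency tables and covariation
(`02_motif_frequencies.py`), structure superposition
(`03_structure_superposition.py`) and curation plus identity summaries
(`04_curation_and_identity.py`).  A thin CLI exposes the same stages:
`titinkit simulate|curate|identity|map|motifs|struct --help`.

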