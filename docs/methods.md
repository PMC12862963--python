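# Methods

This note documents the models, conventions and design choices behind
`titinkit`, in the order of the pipeline.

## Scoring and alignment conventions

All similarity and identity values derive from optimal global pairwise
alignment with affine gaps (Needleman–Wunsch with Gotoh's extension, via
Bio.Align.PairwiseAligner).  Defaults: BLOSUM62; gap open 10, gap extend
0.5 (a gap of length L costs `open + (L−1)·extend`); terminal gaps free.
Free terminal gaps suit TK-region constructs of unequal trimming: a
sequence missing a few NL or CRD residues should not pay gap penalties at
the ends.  The ambiguity code X scores 0 against every residue and never
counts as identical.

Percent identity is computed over columns where both sequences are non-gap.
This denominator is robust to trimming differences but differs from
aligner-specific conventions by up to ±1–2 points; exact printed identity
values from other tools should be compared with that in mind.  Traceback
ties are resolved deterministically, and the two input sequences are
aligned in a canonical (lexicographic) order internally so that identity is
exactly symmetric; for essentially unrelated sequences the identity of an
optimal alignment remains tie-dependent in principle, which is why the
column-map stage refuses alignments below an identity floor rather than
interpreting them.

## The pairwise-similarity map

For a sequence set, raw global alignment scores `s_ij` (including
self-scores `s_ii`) are transformed to correlation-like coefficients
`r_ij = s_ij / sqrt(s_ii · s_jj)`, giving a symmetric matrix with unit
diagonal; a non-positive self-score is an error (the scheme cannot
normalise).  `r` is clipped at 1 to guard floating-point overshoot for
identical sequences.

The embedding is the spectral solution: eigendecomposition of `r`,
coordinates `x_i(d) = sqrt(λ_d) · v_d(i)` over the top-k positive
eigenvalues.  Dot products `x_i · x_j` approximate `r_ij`, and dimensions
are ordered by non-increasing eigenvalue, so earlier dimensions carry the
more prominent divergences.  The unit diagonal is part of the fitting
objective, and the reported reconstruction error is
`Σ_{i≤j} (x_i·x_j − r_ij)²`; including the diagonal is what makes the error
non-increasing in k (Eckart–Young) — an off-diagonal-only error is not
monotone under spectral truncation.  An optional least-squares polish of
the same objective is kept only when it does not increase the error.
Eigenvector signs are fixed deterministically (largest-magnitude coordinate
positive) and re-oriented by labelled anchors during classification.

**Default dimensionality k = 5.**  A five-group family (mammal + isoform
a/b × two fish clades) spans four independent between-group contrasts in
addition to the shared-similarity axis that dominates dimension 1.  With
k = 4 the smallest contrast (the clade split of one isoform) has no axis
left and classification degrades measurably; k = 5 carries all five groups.

Classification uses one of two methods.  *nearest-centroid* (default, and
required when mammals are included): each sequence joins the nearest
anchor-defined centroid in dimensions 2..k.  *sign-quadrant* (fish-only
four-group maps): anchors orient the isoform and clade dimensions (isoform
*a* and neoteleostei on the negative side, matching the published axis
convention), and calls are read off coordinate signs.  Anchors of one label
falling on both sides of the chosen dimension raise an ambiguity error.
Anchor sequences always recover their own labels.

## Reference annotation and motif extraction

The annotation frame is the medaka ttnb (medTKb) construct: parent-protein
residue M27887 is local residue 1, the NL spans ~1–33, the kinase domain
follows, and the CRD ends at residue 355.  Anchors (local numbering):
glycine-rich loop 45–50, θxK at 66–68 (θ=M66, catalytic K68), helix-αC
glutamate E83, R-spine L87/L98/H157/L180, C-spine
V53/M66/I120/I165/V166/Y167/L224/L228, hinge acids D119/D122, catalytic
aspartate D159, ELG slot 179–181, P+1 position 202, YD motif 12–13 with
contacts E43/S116/R170, CRD αR1 motif at 300–305, position −2 at 328 and
the R-7x-R arginines at 330/338.  For human TK (PDB 4JNW frame) the
tabulated anchors are the known positions D144, R146, Q167, Y170, Y187 and
R323.

The shipped default reference carries a **synthetic backbone**: random
residues with the canonical anchor residues implanted at the annotated
positions (`references.synthetic_reference`).  It supports column mapping,
simulation and testing; it is not the biological medTKb sequence, which can
be supplied to `medtkb_annotation(sequence=...)` when available.

Sequences are mapped onto the reference by one global alignment per
sequence; each reference position maps to a query position or a gap, and
an alignment identity below 25% (or with no aligned columns) raises an
unmappable error instead of producing nonsense motif calls.  Anchored
features (θ, DFG slot, P+1, gly-loop window, −2 fallback) are read off
mapped columns.  Pattern features are scanned within the mapped NL/CRD
windows of the query itself: `[NL]YD` (falling back to a bare `YD` with its
preceding residue), `[RK]H[RK]RYY`, and `R-7x-R` (an R, any seven residues,
an R; first match wins and multiple matches are flagged).  Position −2 is
the residue two positions before the first R of the matched R-7x-R — the
A328/R330 convention — falling back to the anchored column when no pattern
matches.  Absence is recorded as `None`, never guessed.

Residue classes: θ bulky = {M,L,I,F}; small = {G,A,S,T}; large (at −2) =
{L,I,V,M,F}.  V is deliberately not "small": at position −2 valine is
tallied separately.  The glycine-rich loop is reported as the literal 6-mer
plus the best-matching template among GxGxxG, RxGxxG and Ax[C/S]xxG (the
templates are mutually exclusive in their first position).

Group frequency tables report counts and percentages per (group, feature,
value) over resolved sequences only, with per-feature exclusion counts; the
percentages per feature sum to 100 within rounding.  The θ↔−2 covariation
is a 2×2 contingency (θ bulky/not × −2 small/not) with a
Haldane-corrected (+0.5) odds ratio when a cell is zero and association
φ = sqrt(χ²/n) ∈ [0,1]; an empty margin (e.g. an all-TK set, where every θ
is bulky) leaves the association undefined and flagged rather than forced.

## Structure comparison

Coordinate files (PDB/mmCIF) are parsed with gemmi into a light model
keeping author numbering and insertion codes; for alternate locations the
highest-occupancy conformer is kept; waters and ligands are retained but
flagged non-polymer.

Superposition is the least-squares rigid-body fit (Kabsch): SVD of the
cross-covariance of centred coordinates with the reflection guard
(`det(U) = +1` always, verified on mirrored inputs), translation from the
centroids.  `rmsd²` equals the mean of squared per-pair deviations exactly.
Fewer than 3 pairs or a collinear point set raises a degeneracy error.
When no correspondence is supplied, chains are paired by sequence-aligning
their one-letter sequences and keeping aligned non-gap columns whose
residues both carry the named atom (default Cα); no outlier trimming is
applied.

Functional-group ("lateral group") distances default to the
terminal-charged-atoms rule — minimum distance between the terminal charged
atoms of the two residues (lysine NZ; glutamate OE1/OE2; aspartate OD1/OD2;
arginine NE/NH1/NH2; histidine ND1/NE2) — with a closest-heavy-sidechain
rule as the alternative.  Distances are reported per chain copy and
aggregated as mean ± half-range across copies (the interpretation used for
two-copy crystal forms).  Missing side-chain atoms yield an unresolved
flag, never a fabricated distance.

Spine contiguity: for an ordered residue list, the minimum side-chain
heavy-atom distance of each consecutive pair; contiguous iff every link is
within the cutoff (default 5.5 Å, a generous van-der-Waals contact
distance).  An optional completion contact reports e.g. the CRD −2 residue
against the θ column that closes the catalytic spine.

## The family simulator

`simulate_families` emulates the study conditions: five groups (mammal,
a/neoteleostei, a/non-neoteleostei, b/neoteleostei, b/non-neoteleostei)
evolved on the fixed tree root → (mammal, fish), fish → (a, b),
isoform → (neoteleostei, non-neoteleostei), with per-site substitution
probabilities per branch and a terminal per-sequence rate.  Defaults:
root 0.30, isoform 0.22, clade 0.09, terminal 0.02.  These were chosen
once so that (i) the isoform split is strictly deeper than the clade
split, and (ii) expected identity levels mirror the reported ranges —
within-cluster ≈ 96%, cross-isoform ≈ 57–78%, mammal-vs-fish at the lower
end of that range.  Substitutions draw uniformly from the position's
background alphabet (draws may coincide with the current residue, so the
realised change rate is `rate · (1 − 1/|A|)`).

After mutation, every anchor column is overwritten: fixed anchors from the
canonical reference residues; variable anchors sampled from the group's
motif table.  The default tables carry the reported per-group percentages:
θ methionine content 98.5 / 98.9 / 100 / 40 / 77.4% (mammal, a-neo, b-neo,
a-non-neo, b-non-neo; the remainder split over L/I/F in their overall
8.7 : 0.6 : 2.6 proportions), ExG vs DxG (D in 17.6% of a-neo and 6.7% of
a-non-neo), P+1 tyrosine (96.4 / 28.6 / 46.7% in mammal / a-neo /
a-non-neo; absent in b), the shared −2 composition (76.8% A, 15.2% S/T,
4.8% G, 1.5% V, 0.4% E), the [N/L]YD preceding residue (73.8% N), and
group-specific gly-loop templates (GxGxxG in mammal and b, RxGxxG in
a-non-neo, Ax[C/S]xxG in a-neo).

The simulation's annotation frame is its own root sequence with the
canonical anchors implanted (`truth.reference`) — every emitted sequence is
homologous to it, exactly as the real sets are homologous to the medTKb
reference.  Group sizes default to 20 per group, which keeps the
O(n²)-alignment similarity map fast enough for multi-seed closure studies;
`study_config()` uses the real per-group sizes (139/91/100/60/62, 452
total).

Two deliberate simplifications, and what they imply for the tests: the
background alphabet excludes Y in the NL window and R/H in the CRD window,
so that the implanted [N/L]YD, αR1 and R-7x-R occurrences are the first
pattern matches — real TK sequences satisfy this through conservation, but
a uniform random background would create confounding matches in a sizeable
fraction of simulations and corrupt the −2 read-off.  And there is no indel
process by default (an optional rate exists to stress the column mapper),
so anchored columns stay aligned; passing tests therefore demonstrate
recovery under substitution divergence, not robustness to extensive
insertion/deletion variation or to non-homologous contamination.

`simulate_structure_pair` emits a Cα-trace-like random walk (3.8 Å steps)
and a rigid-transformed copy with isotropic Gaussian noise σ per
coordinate; the expected post-superposition RMSD is
`σ · sqrt((3n − 6)/n)`, the rigid fit absorbing six degrees of freedom.

## Statistical conventions in the acceptance checks

Implanted-motif recovery is checked in two parts: extraction must
reproduce the implanted residue counts exactly (the pipeline is
deterministic given the sequences), and the implanted counts must lie
within exact binomial intervals of the generator probabilities.  Because
~80 (group, feature, residue) combinations are checked simultaneously, the
interval level is Šidák-adjusted so the family-wise level is 99% — at a
per-comparison 99% level, at least one chance failure would be expected in
most runs.  Single-frequency checks elsewhere use the plain 99% interval.

## Reproducing the published values

The checks against published numbers (medTKb vs human TK identity 62.5%;
Cα RMSD ≈ 1.10 Å between the medTKb structure and the human TK segment;
NCS RMSD ≈ 0.284 Å between the two copies; K68–E83 ≈ 4.92 ± 0.17 Å;
per-group motif percentages of the curated 452-sequence set) require the
deposited inputs, which are not redistributable inside this repository.
To run them, place under `data/external/`:

- `medtkb_region.fasta` — NCBI XP_023806503, residues 27887–28241;
- `human_tk_region.fasta` — UniProtKB Q8WZ42, residues 32150–32491;
- `9qj2.pdb` — PDB entry 9QJ2;
- `6ygn_tk_segment.pdb` — the TK region extracted from PDB entry 6YGN;
- `sm1_tk_sequences.fasta` — the curated TK sequence set with group labels
  as header tags.

Without these files the corresponding tests fail with an explanatory
message; all synthetic-data checks run self-contained.

## Known limitations

- The similarity map is O(n²) in alignment calls; sets beyond ~1000
  sequences need score-only batching or sub-sampling.
- The spectral embedding is fit to the correlation transform of raw global
  alignment scores; score normalisations other than `s_ij/sqrt(s_ii s_jj)`
  (e.g. bit scores) would shift coordinates, though not the qualitative
  cluster structure.
- Column mapping uses one pairwise alignment per sequence rather than a
  progressive multiple alignment; for the highly similar within-family
  sequences this is equivalent in practice, but column assignments near
  long indels can differ from an MSA.
- The human TK annotation ships as anchor positions only; full human-frame
  motif extraction needs the real sequence.
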