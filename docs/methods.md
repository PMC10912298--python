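# Methods

This note documents the models, numerical choices and limitations behind
`gpcrclade`, in the order the pipeline runs.

## Similarity graph and seeded extraction

Pairwise similarity is exact Smith–Waterman (BLOSUM62, gap open 11,
extend 1) via Biopython's `PairwiseAligner`; at catalogue sizes of a few
hundred receptors there is no need for a heuristic search engine.
Significance uses the Karlin–Altschul formula `E = K·m·n·exp(−λS)` with
the gapped BLOSUM62 constants λ = 0.267, K = 0.041 and `m·n` the product
of the two sequence lengths, which makes E symmetric in sequence order.
For the E-value regimes that matter here (E ≪ 1) E-values and P-values
are interchangeable. Edges are kept at `E ≤ 1e-50` by default — strict
enough that two unrelated 300-residue proteins (typical best local score
well under 200, E around 1e-20 at worst for compositionally biased 7TM
sequences) never connect, while members of one receptor family at a few
percent divergence connect with E below 1e-100.

"Clustered with the seeds" is formalized as connected-component
membership in the thresholded graph. The force-directed layout
(attraction along edges proportional to −log₁₀E with an E-value floor of
1e-180, uniform repulsion ∝ 1/(d²+ε), step size decaying linearly to
zero over 10,000 rounds, three dimensions, seeded uniform start) is kept
strictly for visualization: its force constants and cooling schedule are
declared defaults, not a claim of equivalence to any published layout
engine, and no decision downstream depends on coordinates.

## 7TM topology

Two routes produce the per-residue O / TM1–7 / I segmentation:

* **Annotation ingest** reads the three-line per-record dialect used by
  transmembrane predictors (header, sequence, label string over
  {O,M,I}, with lowercase and B/S folded into O). This is the intended
  route whenever predictions from a dedicated tool are available, and it
  is the route the end-to-end validation uses.
* **Built-in prediction** is a classical hydropathy segmenter: windowed
  Kyte–Doolittle mean (window 19, clipped at the ends), TM-core
  candidates at mean ≥ 1.5, candidate runs merged across gaps < 3,
  boundaries refined by extending each run outward while the raw
  per-residue hydropathy stays positive (cores systematically undershoot
  helix ends because a window-19 mean needs ~14 in-helix residues),
  runs that touch after extension coalesced, then length-filtered to
  15–35 residues with over-long runs trimmed symmetrically about their
  hydropathy peak. X scores 0.

A map is accepted only with exactly seven helices; sides are then
assigned by alternation from an extracellular N-terminus (the class-A
convention — predictions violating alternation are re-labeled from this
rule). Non-7TM records are excluded from phylogeny with a flag, since
they cannot be trimmed to a comparable span. Coordinates are 1-based
inclusive throughout.

The hydropathy route recovers planted helix boundaries exactly at zero
divergence (property-tested at ±2 residues over 200 simulated
receptors). Its known limitation: at a few percent sequence divergence,
substitutions that flip the hydropathy sign of boundary-adjacent
residues shift individual boundaries by 1–3 residues and occasionally
split a helix core; on the synthetic study at 3% codon divergence this
costs roughly 10% of records their 7TM acceptance and pushes ~10% of DRY
loci outside the motif scan. This is inherent to single-scale hydropathy
segmentation, which is why external predictions are preferred when
available.

## Motif extraction

All three motifs are anchored to the topology, with small scans that
absorb boundary error:

* **DRY locus** — candidate window of 3 residues ending at the last
  residue of TM3; offsets −3..+3 are scored (+1 for D/E at position 1,
  +2 for the near-universal R at position 2, +1 for an aromatic W/Y/F/H
  at position 3) and the best window wins (ties: smaller |offset|, then
  more N-terminal). If nothing scores, the anchored window is returned
  flagged low-confidence. DRYxxx is the 6-mer from the same start.
* **CWxP** — scan TM6 for C..P three apart; the match whose C is nearest
  the TM6 midpoint wins (ties: more extracellular). No match means the
  motif is not discernible — a genuine biological state for the GnRHR
  clade — and the 6-mer centred on the TM6 midpoint is reported instead,
  mirroring how a fallback junction sequence is tabulated for that
  clade. The midpoint anchor approximates the canonical mid-TM6
  position without adopting a generic residue-numbering scheme.
* **NPxxY** — scan TM7 for [N|D]P··[Y|F]; the match nearest the
  cytoplasmic end wins; the fallback is the 5-mer ending two residues
  before that end.

Windows that leave the sequence are reported `Truncated`; motifs
containing X count as undetermined. Both are excluded from diversity
percentages and counted separately. The diversity table is per-position
residue percentages on the 0–100 scale over the three DRY-locus columns;
the headline statistics are %R at position 2 and %aromatic at position 3.

## Codon graph and explainability

The 20×20 minimum nucleotide Hamming distance matrix is enumerated over
all codon pairs of the standard genetic code (translation table 1, stop
codons excluded). A motif variant is single-nucleotide explainable when
every position deviating from the canonical motif has distance exactly 1.
The rule is deliberately **per codon position**, not per motif: a
two-position variant like ERF arises from two independent
single-nucleotide events in two different codons, and the published
variant list and its arithmetic (40.8 + 32.7 = 73.5) only cohere under
this reading. Tests witness reachability explicitly by constructing the
codon pairs. No codon-usage weighting or transition/transversion
asymmetry is modelled; the package exposes distances and the binary
classification, not substitution probabilities.

## Alignment, distances, trees

The progressive aligner uses fractional-common-3-mer guide distances
(`1 − shared/min(count)`), a UPGMA guide tree (scipy average linkage),
and profile–profile Needleman–Wunsch with affine gaps (BLOSUM62, open
10, extend 0.5; column scores are frequency-vector bilinear forms, gap
symbols scoring 0 against everything). Degapping any output row returns
its input — a tested invariant. The aligner substitutes for a
general-purpose MSA tool on the grounds that downstream conclusions rest
on deep, well-separated clades that survive aligner choice; externally
aligned FASTA can be imported instead.

Distances are p-distances with pairwise deletion (gap or X in either
sequence skips the site for that pair; a pair with no comparable sites
is an error); a Poisson correction `−ln(1−p)` sits behind a flag.
Neighbor joining follows Saitou–Nei: join the pair minimizing
`Q(i,j) = (r−2)d(i,j) − R_i − R_j`, with exact ties broken by the
lexicographically smallest pair of subtree labels (a subtree is labelled
by its smallest leaf). Because float evaluation order breaks Q's exact
symmetry at the ulp level, the argmin scans the upper triangle only.
Negative branch-length estimates are clamped to zero with the deficit
moved to the sister branch. NJ is exact on additive matrices
(property-tested: 50/50 random 12-taxon trees, and cross-checked against
scikit-bio's implementation on noisy matrices).

Bootstrap resamples alignment columns with replacement; the support of
each internal edge of the point-estimate tree is the percentage of
replicate trees containing that split (1000 replicates by default).
Tree comparison uses unrooted nontrivial splits: Robinson–Foulds is the
size of their symmetric difference (cross-checked against dendropy).

## Clade partitioning and labelling

NJ output is unrooted with an arbitrary basal trifurcation, so clades
are defined on splits, not on subtrees of the stored root: every
internal edge with bootstrap support ≥ 90 nominates its smaller leaf
side (≥ 2 leaves) as a candidate clade, and candidates are accepted
greedily by decreasing size subject to disjointness, making each
accepted clade maximal. Uncovered leaves become singletons flagged
`unplaced`. The support default of 90 reflects the observed structure of
receptor superfamily trees: within-clade edges carry near-100 supports
while the deep edges between clades are weak (54 and 34 in the
motivating dataset).

A clade containing exactly one distinct seed label inherits it; a
seedless clade is labelled `novel:<modal DRYxxx>`; conflicting seeds
yield `conflict` plus a flag (conflicts are data, not exceptions).
Colors come from a fixed palette in clade-size order. Congruence between
the clade partition and any categorical labelling is reported as
per-clade purity (modal category frequency) and the adjusted Rand index
— a deliberate formalization of what is otherwise a by-eye judgement,
chosen so the claim "motifs compartmentalize into clades" is assertable.
The ARI is undefined for a single effective clade; that case is flagged,
not raised.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes
about real receptor catalogues:

* **Architecture** — N-terminus 25 (out), seven 23-residue TM helices,
  12-residue loops alternating in/out, C-terminus 20 (in). Loops and
  termini draw from hydrophilic residues {D,E,K,R,N,Q,S,T,G,P}, helices
  from hydrophobic {A,I,L,V,F,M} (all Kyte–Doolittle-positive, so
  planted boundaries are detectable; W is negative on that scale and is
  excluded from the random fill, though it occurs inside motifs).
* **Motif placement** — DRYxxx opens ICL2 (the TM3/ICL2 union: D and R
  are strongly hydrophilic and cannot sit inside a hydropathy-detectable
  helix tail); CWxP sits with C at the TM6 midpoint (or the 6-residue
  fallback centred there for the CWxP-less template); NPxxY sits inside
  TM7 ending nine residues before its cytoplasmic end — deep enough
  that the windowed mean clears the core threshold through the motif's
  hydrophilic residues with ~3σ margin even for the weakest template.
* **Templates** — the eight clade templates default to the published
  modal triplets (GnRHR DRHEAV/—(TNTPYV)/NPFIY, CrzR DRFTAV/CWTP/NPIIY,
  RPCHR DRYFAV/CWTP/NPIVY, ACPR1 DRYFAV/CWTP/NPIIY, ACPR2
  DRYFAI/CWTP/NPLVY, VR1 DRARAV/CWSP/NPWIY, VR2 DRYQVI/CSAP/NPWIF,
  CCAPR DRYDAI/CWSP/NPIIY).
* **Evolution** — codons are drawn uniformly among synonyms; each family
  member independently accumulates Poisson(rate × CDS length)
  single-nucleotide substitutions (uniform position and alternative
  base) on a star phylogeny; substitutions creating stops are redrawn,
  keeping lengths fixed. Motif codons are exempt by default, emulating
  the purifying selection that keeps the triplets constant within real
  clades; switching protection off yields the mechanistic
  explainability experiment. A star topology within clades is
  sufficient for clade separability and keeps the generator analyzable;
  the clade-ancestor level provides the deep-split structure.
* **Decoys** — same architecture, fresh random residues everywhere
  (their motif loci are whatever the random fill produces),
  rejection-sampled to < 30% identity against every clade seed: close
  enough to pass topology, far too diverged to cross the cluster
  threshold.
* **Defaults** — 8 clades × 8 members, 40 decoys, rate 0.03/site: about
  6% protein divergence from the ancestor, i.e. tight clades separated
  by essentially random inter-clade distances, which is the regime the
  clade-annotation problem lives in.

What the generator does **not** emulate: indels (alignment gaps are
exercised in dedicated aligner tests only), codon-usage bias,
within-clade tree structure, length variation among real termini, and
homology *between* clades — real GnRH-superfamily clades share ancestry
and cluster together against the class-A background, whereas synthetic
clades are mutually unrelated. Passing end-to-end tests therefore
demonstrates that the machinery recovers planted structure under
realistic noise, not that it resolves the harder gradations of real
catalogues.

## Validation setup and problem sizes

The end-to-end validation runs the pipeline on the generator's own
output, reading the generator's topology annotation file (the
external-predictor route) — matching a workflow in which topologies come
from a dedicated predictor, and keeping motif recovery independent of
hydropathy-segmentation noise, which is assessed separately. Problem
sizes: the full synthetic study (104 records, two 1000-replicate
bootstrapped trees) completes in about a minute on one CPU; NJ
exactness uses 50 random 12-taxon trees; the explainability simulation
uses 1000-member families. The acceptance script threads one seed
through every random draw, so each run is reproducible end to end.

Two statistics are worth flagging honestly. The mechanistic
explainability rate at 0.01 substitutions/site has mean ≈ 99.7% but a
heavy-ish lower tail (two distinct hits in one DRY codon produce
inexplainable deviants at ~0.3% conditional rate, and only ~60 deviants
arise per 1000 members), so single-run values as low as ~97% occur; the
pooled-family unit test has the statistical power the single-run check
lacks. And the clade-purity/ARI results under the predict-topology route
(rather than annotation ingest) degrade by roughly 10% for the reasons
given under *7TM topology*.
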