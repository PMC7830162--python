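# Methods

This note documents the models, rules and numerical choices behind
`phazscan`: what each stage computes, which knobs matter, what the synthetic
benchmark does and does not emulate, and where the design was genuinely open.

## 1. The candidate screen

### Model

Extracellular PHA depolymerases are secreted serine hydrolases of the
alpha/beta-hydrolase superfamily. Their diagnostic sequence features, in
N-to-C order, are: an oxyanion pocket; a pentapeptide "lipase box"
containing the catalytic serine; and the remaining catalytic-triad residues,
aspartate then histidine, downstream of the box. The screen is a
conjunction of five tests per protein:

1. *secreted*: a signal-peptide call for the protein id (SignalP 4.1 short
   format or a generic 2–3-column TSV);
2. *fold*: any domain hit whose signature id is in the configured fold set
   (defaults `SSF53474`, `G3DSA:3.40.50.1820`) or whose description contains
   an "alpha/beta hydrolase" keyword — config data, to be checked against
   current InterPro rather than treated as ground truth;
3. *oxyanion pocket* and 4. *lipase box*: at least one occurrence of a
   library pattern of each role;
5. *triad and order*: some (oxyanion, box) pair with a completing triad such
   that `oxyanion.end < box.start` (strictly upstream, non-overlapping) and
   Ser < Asp < His.

### Pattern language and library

Patterns use uppercase literals, `X` (wildcard) and `[..]` groups; commas in
groups are decorative. An `X` *residue* in a sequence satisfies only
wildcard positions — an unknown residue never certifies a literal
constraint. The default library is `src/phazscan/data/patterns.yaml`:
oxyanion `PXXXXHG` and `HGC`; lipase boxes `GXSXG`, `AHSMGV`,
`A[I,T]S[S,T]G`, `AHSXG`, and `GHSXH`. `GHSXH` is tagged
"observed-variant": it is the triacylglycerol-lipase-like box carried by the
*Vibrio* candidate lipase precursors, which none of the four classical
depolymerase boxes matches. Both oxyanion variants are kept even though the
strong empirical signal is for `PXXXXHG`; the screen only needs one to hit.

### Numerical/tie-break choices

- **Coordinates** are 1-based inclusive everywhere.
- **Search region** defaults to the mature sequence (from the cleavage site)
  since the features belong to the secreted enzyme; full-sequence mode is
  available because the choice is not forced by the data.
- **Triad selection** is sequence-only: the leftmost Asp after the box, then
  the leftmost His after that Asp. The biologically correct triad residues
  can only be pinned by structural alignment, so all valid (Asp, His) pairs
  are counted in `n_alternative_pairs` and reported.
- **Candidate chain selection**: boxes are tried leftmost-first; for each,
  the nearest upstream oxyanion is paired. The first combination with a
  valid triad and correct order is reported. For failing proteins a
  best-effort feature set (leftmost box with a triad, else leftmost box;
  nearest oxyanion) is still recorded so that every decoy's failing flag is
  inspectable.
- **Classification** keys off the matched pattern: `AHSXG`/`AHSMGV`/
  `A[I,T]S[S,T]G` → `AHSXG-type` (depolymerase-like), `GHSXH` →
  `GHSXH-type` (lipase-like), `GXSXG` → `GXSXG-type`, anything else
  `other`.

### Toy signal-peptide fallback

Disabled by default and never a SignalP substitute: a protein with no call
is accepted as secreted only if residue 1 is Met, a Lys/Arg occurs in
residues 1–5, and some run of ≥8 residues within residues 3–35 has mean
Kyte–Doolittle hydropathy ≥1.5 (minimal n/h/c-region architecture). The
predicted first mature residue is the window end + 5, capped at 45. It
exists so the pipeline can run end-to-end on bare FASTA in demonstrations.

## 2. PHA-cycle profiling

### Catalog

Sixteen gene functions: the 12 columns of the reference gene-content matrix
(phaA/bktB EC 2.3.1.9/2.3.1.16; fabG 1.1.1.100; fadB 4.2.1.17 + 1.1.1.35;
hbd 1.1.1.157; phaB 1.1.1.36; phaC; phaY_e 3.1.1.22; phaZ_e/phaZ_i
3.1.1.75/76; bdh 1.1.1.30; aacS 6.2.1.16; scoA/scoB 2.8.3.5) plus four
alternate-route functions (phaJ 4.2.1.119; phaG; hpd 1.1.1.59; hibdh
1.1.1.31). A feature matches by exact EC (a `-` in a catalog EC is a
one-field wildcard) or by lowercase name keyword.

Two functions are **keyword-gated**: phaC and phaG carry incomplete EC
classes (2.3.1.-, 2.4.1.-) that would swallow unrelated acyl/glycosyl
transferases (2.3.1.- alone matches the ketothiolase), so a name keyword is
required and any EC present must agree with the gated prefix. A
keyword-matching feature with *no* EC still counts, since annotation rows
frequently omit ECs.

Localization: a depolymerase feature is extracellular only if its linked
protein has a secreted signal-peptide call, else intracellular — absence of
evidence for secretion is read as intracellular, the same inference used
when curating the reference matrix. An oligomer hydrolase without a
secreted call is not counted as `phaY_e`. scoAB requires both a
"subunit A" and a "subunit B" matching feature.

### Rule set

```
monomer_supply          = (phaA_bktB AND (fabG|fadB|hbd|phaB)) OR phaJ OR phaG
biosynthesis_complete   = monomer_supply AND phaC
depoly_extracellular    = phaZ_e OR phaY_e
monomer_oxidation       = yes if bdh|hpd; partial_3C if only hibdh; else no
coa_activation          = aacS OR scoAB
intracellular_utilization = (monomer_oxidation == yes) AND coa_activation
full_intracellular_cycle  = biosynthesis_complete AND phaZ_i AND intracellular_utilization
```

`hibdh` never grants utilization: 3-hydroxyisobutyrate dehydrogenase acts on
3-carbon monomers with a K_M one to two orders of magnitude above its
natural substrate, so it is reported as `partial_3C` only. The rule set is
monotone: adding a gene can never revoke a capability (property-tested).

### Reference matrix

`src/phazscan/data/table4_gene_matrix.tsv` transcribes the published
33-genome presence/absence table verbatim (✓/–), including the footnoted
*R. sphaeroides* 2.4.1 entry: a depolymerase deposited as extracellular
whose protein has no predicted signal peptide. The tick is kept in the
matrix; pathway calling treats that entry as not extracellular
(`NO_SP_FOOTNOTE`), consistent with the signal-peptide-based localization
rule above. Keyword lists are best-effort reconstructions of annotation
vocabulary and are config-editable; the matrix itself is boolean, so
profiling it does not depend on them.

## 3. Feature report and similarity

Feature windows take `flank = 5` residues (configurable) on each side of the
oxyanion, box, Asp and His spans, clipped at the termini with the window
start adjusted.

Pairwise similarity is computed on a local alignment with affine gaps
(BLOSUM62, gap open 11, extend 1; a gap of length k costs
`open + (k-1)·extend`). `pct_identity` is identical columns over all
alignment columns; `pct_similarity` is positive-scoring columns over all
columns, gap columns in the denominator — the common BLASTP "positives"
notion. Identical-residue columns always count as similar even where the
matrix scores a letter non-positively against itself (e.g. `X`). Inputs are
canonically ordered before aligning so tie-broken optimal alignments cannot
break symmetry. The metric and parameters are explicit config because the
published 85.2% candidate similarity came from a gene-clustering workflow
whose alignment settings are unstated; with different positives definitions
the number can shift by a few points. If no positive-scoring local alignment
exists at all, the result is reported as 0% over an alignment of length 0.

## 4. Synthetic benchmark

### What it emulates

Per protein: a signal peptide (Met + 2 charged residues + 12 hydrophobic
residues + `AQA` cleavage motif, 18 residues, matching the generic
signal-peptide call emitted alongside), then a mature region of 250–450
background residues with the conserved features planted in order with ≥10
residues between them (`flank_min`), and a covering alpha/beta-hydrolase
domain row. Background residues are drawn uniformly with P, H, G, S, D
down-weighted 20% to reduce accidental motif seeds. Defaults: 20 candidates
and 20 decoys per class (7 classes, 160 proteins), seed 42.

Each decoy class violates exactly one criterion — no signal peptide, no
fold row, one missing feature, or inverted oxyanion/box order — and
satisfies all others. Downstream of a planted lipase box the background
contains no Asp/His, so the planted triad is the only resolvable one
(`n_alternative_pairs == 1`) and the missing-Asp/His classes stay missing.
After assembly every protein is re-screened; if background chance produced
an unintended outcome (an accidental box or oxyanion completing or breaking
a chain) the protein is resampled, up to 100 attempts, so emitted truth is
exact. All output is a pure function of the config; identical seeds give
byte-identical files.

### What passing does and does not show

The benchmark validates the *logic* of the screen: filter conjunction,
order checking, coordinate bookkeeping, exact truth recovery. It does not
emulate real proteome statistics — homologous families, compositional bias,
genuinely ambiguous triads, or signal peptides that fool predictors — so
perfect precision/recall here says nothing about SignalP's or InterProScan's
error rates on real data, which the screen inherits wholesale.

The annotation-set generator inverts the profiler by construction: for any
gene-content profile it emits features that trigger exactly the requested
functions (both sco subunits; secreted stubs for extracellular entries),
which is property-tested as a round-trip identity over random profiles.

## 5. Known limitations

- The screen is motif-presence logic, not a statistical model: no
  position-specific scoring, no HMMs, no structure. Proteins with
  non-canonical feature spacing will be missed by design.
- Triad identification is sequence-order-only; `n_alternative_pairs`
  quantifies but does not resolve the ambiguity.
- Profiler keyword lists cannot reproduce any specific annotation
  pipeline's vocabulary; EC matching is the reliable path.
- The published 85.2% similarity between the two *Vibrio* candidate
  proteins cannot be recomputed here because the deposited sequences are not
  distributable with the package; the aligner itself is validated against an
  independent dynamic-programming oracle instead.
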