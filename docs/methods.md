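# Methods

## The screen

The screening funnel treats fusion detection as a set-intersection problem.
Two datasets are assembled per proteome: proteins with α-domain (Class I
terpene synthase) evidence and proteins with γβ-didomain (Class II
diterpene cyclase) evidence. A protein in both datasets whose most
N-terminal γβ region ends before its most C-terminal α region starts is a
DCS candidate (γβα order, the arrangement shared by plant tridomain terpene
synthases). Using the outermost hits makes the order test conservative:
fragmented sub-hits of one domain cannot fake a fusion. Proteins with both
domain classes in any other arrangement are reported as
`DCS_ATYPICAL_ORDER` rather than silently mis-called.

Domain evidence comes from one of two providers:

- **External rows.** HMMER3 `--domtblout` tables for the α profiles
  (PF03936, PF19086, PF06330; per-domain e-value ≤ 10⁻³) and the two SHC
  profiles that capture the γβ-didomain (PF13249 N-terminal, PF13243
  C-terminal). Envelope coordinates are used: envelopes bound the homology
  region, which is the conservative interval for an order test. A γβ hit is
  only emitted when both profile types fire on the same protein, spanning
  their combined extent; sub-hits of one class are merged when separated by
  ≤ 30 residues (tolerates split hits of one domain). The γβ HMM stage has
  no published cutoff distinct from the α stage, so it defaults to the same
  10⁻³ (configurable, `gb_evalue_cutoff`). The downstream confirmation
  steps of a web-based screen (conserved-domain lookup at 10⁻², blastp
  against a reference DTC at 10⁻⁴) are carried as configuration metadata
  only; their role — removing squalene–hopene cyclases (SHCs), which share
  the γβ fold and the DxDD motif — is played by the relatedness filter
  `closer_to_group` (mean alignment distance to DTC references vs. SHC
  references; ties removed as SHC, the conservative direction).
- **Internal scanner.** Position-probability profiles built from the three
  packaged templates (α, γβ, SHC) with a flat 1/20 pseudocount, scored as
  summed log₂ odds against a uniform background, slid at stride 1. The
  per-class threshold is 60 % of the profile's self-match score; at that
  fraction a random sequence scores far below threshold (expected ≈ −0.78
  bits/position vs. +3.39 for a match) and 1000 random 300-mers produce
  zero hits, while instances at ≥ 85 % template identity score ≈ 80 % of
  self and are always found. The scanner is a desk-scale stand-in for the
  external searches: the package's substance is the classification on top
  of hits, not profile-HMM inference, which is explicitly out of scope.

## Motif engine

Motif notation is compiled position-wise: an uppercase letter is an exact
residue, `x` a wildcard, `(A/B/C)` a set. `x` matches the unknown residue
X; exact positions do not. Scanning reports every window whose full span
lies inside the motif's region constraint — the γβ region for DxDD (and the
LHS/PNV dyad contexts), the α region for DDxxD, NSE, their aberrant
variants and PIx. When domain hits exist they define the regions; otherwise
the sequence midpoint splits it (a fallback only, the pipeline always has
hits for proteins it classifies as candidates).

Class II status is INTACT iff a DxDD hit lies in the γβ region. Class I is
INTACT iff canonical DDxxD and NSE hits co-occur in the α region with DDxxD
upstream and a start-to-start separation of 80–220 residues. The spacing
window is a package choice: a single α-domain places the two metal-binding
motifs roughly one domain-length apart, and the packaged template uses 140;
the window brackets that generously and is configurable. Aberrantly spaced
DDxxx(D/E), the NGxxSxxxE variant, or a canonical pair with out-of-window
spacing give ABERRANT — present but unlikely to support Class I catalysis,
which is why `predicted_bifunctional` requires INTACT on both classes.
When canonical and aberrant motifs co-occur, canonical wins: the intact
configuration is the catalytically relevant one.

## Constructs and active-site rules

Candidates are split at the γβ hit end by default; `MIDLINKER` uses the
midpoint of the inter-domain gap and `EXPLICIT:n` reproduces externally
determined boundaries (guarded to [γβ end − 20, α start − 1] to prevent
nonsense splits). Splitting is exact: the two parts always concatenate back
to the parent. Mutations are anchored to motif occurrences rather than raw
coordinates, so a recipe like "first aspartate of DDxxD → Ala" (the Class I
knockout) transfers across homologs; labels record the absolute 1-based
position (D610A style).

Active-site sites are transferred from an annotated reference by global
pairwise alignment; a site aligned to a gap is absent, and the local
context (His inside an LHS match, Asn inside PNV, plant-type Ile inside
PIx) is re-verified on the query. The bacterial-type key position is
defined as plant-type Ile − 4 (one helical turn). The packaged reference is
a **synthetic** annotated CPS–KS stand-in
(`data/synthetic_csedcs_like.fasta` + sidecar TSV) with the dyad at
187/253, Class I motifs at 610/750 and the key isoleucines at 726/730 — the
annotation geometry of the characterized cyanobacterial fusion enzyme on a
synthetic backbone, since real sequences are not shipped.

Product prediction is an annotation lookup, not a mechanistic model: a
seven-row rule table over the finite state space {Class I knockout, dyad
His→A, dyad Asn→A, bacterial-type Ile→T, plant-type Ile→T} × Class I
status, with mutually exclusive conditions (verified by exhaustive
enumeration) and a flagged `no_rule` default. Ordered product lists encode
major/minor only; relative proportions are not modeled. Enzymes outside the
CPS–KS lineage carry free-text product annotations, not rules, because no
transferable residue→product mapping exists for them.

## Alignment and trees

The aligner is affine-gap global (Gotoh) over profiles; a single sequence
is a one-row profile, so the pairwise and profile–profile cases share one
DP. A gap of length k costs `open + k·extend` (defaults: BLOSUM62, open 10,
extend 0.5 on the half-bit scale); gap-to-gap transitions between the two
insertion states are allowed (they are optimal under strongly negative
mismatch scores) and traceback ties deterministically prefer substitution
over a gap in the first profile over a gap in the second. Progressive MSA
merges profiles in the order of a neighbor-joining guide tree built from
3-mer count cosine distances, children visited in lexicographic order of
their smallest leaf — fully deterministic.

Distances are Poisson-corrected, d = −ln(1 − p), with pairwise deletion of
gap columns (keeps short toy alignments informative) and a cap at d = 5
near saturation; a pair with no comparable columns is an error, not a
silent zero. Neighbor joining uses the standard Q criterion with ties
broken by the lexicographically smallest cluster-label pair and negative
branch estimates clamped to zero; it is exact on additive matrices, which
the test suite exploits as its oracle (path-sum matrices of random trees).
Bootstrap supports count, over seeded column-resampling replicates, how
often each bipartition of the full-data tree recurs. NJ with Poisson
distances deliberately replaces maximum-likelihood inference: at desk scale
the claims under test are topology-level (monophyly, bipartition support),
not branch-support values of a particular ML run, and ML model fitting is
out of scope.

## Synthetic proteomes

The generator emulates the six classes the screen must separate. Three
fixed templates are packaged: a 300-residue α template (DDxxD at 60, NSE at
200 — spacing 140, inside the Class I window — and the key-Ile/PIx context
at 250/253), a 500-residue γβ template (LHS at 110, PNV at 180, DxDD at
380) and a 500-residue SHC template sharing only the DxDD motif on an
unrelated random backbone. Template backbones, linkers and substitutions
are drawn from a 17-letter alphabet excluding D, H and N, so no
aspartate-rich or dyad motif can arise by chance outside the planted
positions and truth labels stay valid; motif positions themselves are
mutation-locked. Background proteins are uniform over all 20 residues
(their chance motifs are harmless because they carry no domain hits).

Instances are drawn hierarchically: each class has a seeded ancestor
mutated from its template at the full divergence rate (1 − identity,
default identity 0.9), and instances mutate from that ancestor at half the
rate. This gives within-class similarity exceeding between-class
similarity, so distance trees recover planted classes as clades — the
synthetic analogue of the observation that the α-parts of functional
fusion proteins cluster together. Without the hierarchy all α-derived
classes would be statistically exchangeable and no clade structure would
exist to test.

The default composition is the canonical 50-protein screen (5 intact + 2
aberrant fusions, 10 α-only, 10 γβ-only, 3 SHC decoys, 20 background),
sized so the full pipeline, including trees, runs in about a second. What
passing tests show: interval logic, motif classification, order rules,
split/mutation algebra and clade recovery are correct on sequences whose
ground truth is known exactly. What they do not show: detection power on
real profile–HMM score distributions, compositional bias, indel evolution
or domain-boundary ambiguity in real proteomes — the generator plants exact
substitutional divergence only, and the internal scanner's thresholds are
calibrated to these templates, not to Pfam models.

## Numerical and reporting choices

Coordinates are 1-based inclusive everywhere. Prevalence percentages are
rounded half-up to two decimals, with trailing zeros trimmed at ≥ 1 %
("0.03%" but "10%"). Newick output carries branch lengths at 6 significant
digits and integer supports as internal labels; labels containing Newick
metacharacters are single-quoted. E-value cutoffs are applied per hit with
no global false-discovery correction, mirroring a fixed-cutoff screen.
De-duplication keeps the first of identical (id, sequence) pairs and
rejects conflicting duplicates; one-strain-per-species selection is the
caller's responsibility. All randomness (generator, bootstrap) flows from
explicit integer seeds; repeated runs write byte-identical reports.

## Known limitations

The internal scanner is not a profile HMM and its scores are not
comparable to HMMER bit scores; real screens should ingest external
per-domain tables. The product rule table is valid only for the CPS–KS
lineage it was derived from. The synthetic CPS–KS reference is a geometric
stand-in, not a real sequence. Bootstrap supports on toy alignments
saturate quickly and should not be read as statements about real-data
robustness.
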