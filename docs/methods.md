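# Methods

## Glycan representation and identity

Glycans are rooted ordered trees: the reducing-end residue is the root and
every edge carries a linkage (anomer α/β/undetermined, donor carbon fixed
by the residue — C2 for Neu5Ac, C1 otherwise — and an acceptor carbon in
2/3/4/6/8 or undetermined).  The protein or peptide is never modelled:
O-glycan structures are rooted at the reducing-end GalNAc, N-glycans at
the innermost GlcNAc.  Trees are ordered internally, but all equality,
deduplication and dictionary keying go through `canonical_string`, which
sorts sibling subtrees by (acceptor position, anomer, recursive canonical
string).  Two trees differing only in sibling order therefore collapse to
one species, while any difference in residue, anomer or position —
including determined versus undetermined — keeps species distinct.  An
undetermined linkage equals only another undetermined linkage under
canonicalisation, but acts as a wildcard during motif matching; this keeps
partially resolved MS-annotated structures usable as inputs without
letting them merge with resolved ones.

Residue positions are addressed by paths from the root rather than array
indices, so a site reference survives serialisation and structural edits.
`attach`/`remove` are value-semantic (they return a new glycan and never
mutate the input); the occupancy rule is one child per (acceptor position,
anomer) pair.

Two text notations are supported.  The linear notation is the condensed
form used in the glycobiology literature (`Gal(b1,3)[GlcNAc(b1,6)]GalNAc`,
Greek or Latin anomer letters accepted); the writer is deterministic, so
write→parse is the identity on structure.  GlycoCT condensed is emitted
with RES/LIN sections only (no REP/ALT), N-acetyl groups as substituent
entries, and undetermined positions as `-1`; this dialect covers every
structure the package handles and is what gets embedded in SBML species
annotations.

## Enzyme records and matching semantics

`GTEnz`/`GHEnz` records carry the specificity fields listed in the README.
Three matching semantics are worth spelling out:

* `targetBranch` is a linear chain anchored at the acted-on residue and
  read toward the reducing end.  Matching is *prefix* matching — the chain
  must match the ancestor path but need not reach the root — with an
  optional `to_root` flag for enzymes that act only at the reducing end
  (the core α1,6-fucosyltransferase uses it).  Prefix semantics lets one
  record such as "Gal(b1,4)GlcNAc" pin a sialyltransferase to type-2
  LacNAc at any depth, while full chains pin GnT isoenzymes to specific
  antennae.
* `substNAResidue` is global (the residue anywhere in the substrate blocks
  the enzyme); `substNABranch` and `substMinStruct` are anchored at the
  reducing end (the motif root must align with the substrate root, extra
  branches allowed).  These scopes are exactly what the two biological
  uses need: galactose capping blocks GnTs wherever the galactose sits,
  whereas the bisecting-GlcNAc block is a property of the core chain.
* One optional field extends the canonical set: `acceptor_context`, a
  motif matched downward into the acted-on residue's own subtree.  It
  exists for α1,3-fucosyltransferase VII, whose requirement — the acceptor
  GlcNAc's own galactose must already be α2,3-sialylated — is a property
  of the acceptor's descendants and is expressible neither as an ancestor
  chain nor as a global motif (a global motif would licence fucosylation
  of the unsialylated inner GlcNAc of an extended polylactosamine chain).

A glycosidase's `linkFG` may hold several linkages.  They are interpreted
as an *ordered preference*: sites are taken from the first linkage class
with any match.  For α-mannosidase II (α1,3 before α1,6) this produces the
single trimming path M5Gn → M4Gn → M3Gn — the behaviour required to
reproduce the published five-enzyme network exactly; an unordered
disjunction would generate two Man4 isomers and a 16-species network.
This mirrors the enzyme's known kinetic preference.

The built-in database holds 12 glycosyltransferases and 2 glycosidases:
GnT I–V, ManI, ManII, GalT (lower-antenna-restricted), GalT-IV
(unrestricted LacNAc synthase), B3GnT, ST3Gal-I/II (core-1), ST3Gal-IV
(type-2 LacNAc; alternative name SiaT), FT-VII and the core
fucosyltransferase FUT8 (`FucT`).  Gal appears in `substNAResidue` of
GnT II–V, GnT III and ManII, so one galactosylation event freezes
antennary processing; GnT II additionally requires the fully trimmed
6-arm (two `substNABranch` motifs), and GnT IV/V require the GnT II
product (`substMinStruct`).  EC numbers and names are static records.
Databases round-trip through a one-stanza-per-enzyme text format with
glycan-valued fields in linear notation.

## Network inference

Forward inference is a worklist fixed point: every enzyme is applied to
every frontier species; products depend only on their substrate, so a
frontier-only sweep is exact.  `max_iter` (default 50) bounds the rounds
and sets a `truncated` flag when hit — pools containing B3GnT + a
galactosyltransferase extend polylactosamine indefinitely and never reach
a fixed point.  Reverse inference applies substrate inference backward and
finally prunes to species that actually reach an input product.  Every
reverse candidate is forward-checked, so reverse inference never proposes
a substrate the enzyme could not convert; with glycosidases in the pool
the backward search is open-ended (hydrolysis substrates are larger than
their products, and mannoses can be re-attached indefinitely), so an
optional `max_size` caps candidate residue counts.

Connection inference takes each of the m(m−1)/2 unordered input pairs,
designates the initial substrate by the pool's net direction (smaller
glycan for pure-transferase pools, larger for pure-glycosidase pools, both
attempted for mixed pools), runs bounded backward search from the
designated product (intermediates may not exceed the product's residue
count nor drop below the substrate's — this guarantees termination), and
keeps exactly the species and reactions lying on some substrate→product
chain.  The union over pairs is consolidated by canonical string; reaction
identity is the (substrate, product, enzyme) triple, so two enzymes
catalysing the same conversion yield two parallel edges.

## Graph analysis

`path_finding` is a recursive depth-first enumeration of all simple
directed paths, returned as alternating species/reaction sequences;
parallel enzyme-labelled edges are distinct path steps.  It is tested
against an independent exhaustive enumeration (networkx) on random
multigraphs.

`subnet_by_num_del` enumerates all C(n_deletable, k) deletions of k
non-protected species exhaustively (a seeded random-sampling mode exists
for large networks), drops incident reactions, and evaluates a
configurable constraint set.  For the O-glycan case study the constraint
set is: the deletion strands no orphan species (a candidate that would
need isolated-species cleanup is invalid rather than silently pruned); the
start glycan is present and every surviving species is reachable from it
(the subset pathway "starts with" the core-2 trisaccharide in the strong
sense); at least one sialyl-Lewis-X product survives; and every in-silico
intermediate remains both the substrate and the product of at least one
reaction.  Under these rules the number of valid subset pathways over
k = 1..10 is 10, 47, 137, 276, 406, 455, 413, 331, 246, 159 — a unimodal
profile peaking at k = 6.  Weaker readings (pruning orphans instead of
rejecting them, or not requiring reachability) shift the peak to 7–9; the
constraint set is explicit in the API so either reading can be run.

## Case-study fixtures

Case 1 ships the core-2 trisaccharide plus twelve PSGL-1-type O-glycans:
the mono- and disialylated core-2 forms, the sialyl-Lewis-X carriers, the
di- and tri-LacNAc-extended 6-arm forms.  Figure cartoons, not machine
files, are the ultimate source of such rosters, so the transcription is
validated by over-constraint: the five enzyme activities must reproduce
20 species, 28 reactions, 7 intermediates and the k = 6 subset-sweep
maximum simultaneously, which no single-glycan transcription error
survives.  Case 2 is fully determined (one seed, six enzyme records).
Case 3 is explicitly a *synthetic stand-in*: the original roster derives
from external MALDI-TOF annotation of CHO-cell spectra and cannot be
reconstructed from printed material, so the bundled 17 structures lie
along the nine-enzyme biosynthetic routes and are exercised at smoke level
only (network completes, exports, start connects to the largest species,
all species masses fall in the configured 1400–3300 Th window).  Passing
Case-3 tests demonstrates the machinery runs end to end, not that the
published network size is reproduced.

## MS processing

`ms_process` implements the four-step method.  (1) Background adjustment:
the baseline is a morphological opening (moving minimum then moving
maximum, window 501 points) of a lightly pre-smoothed trace, followed by a
201-point moving average; pre-smoothing stops isolated detector zeros from
capturing the minimum, and the opening stops single deep noise excursions
from denting the baseline.  (2) Normalisation to max = 100.  (3) Noise
removal: 5-point moving-average smoothing, then zeroing below
median + `snr_threshold` (default 3) × a robust noise level (1.4826 × MAD
of the smoothed trace — peaks are sparse, so the median tracks the
baseline region).  (4) Peak finding: `scipy.signal.find_peaks` with the
same height floor (never below `min_height`, default 1 normalised unit),
a prominence floor of `snr_threshold` × noise, and a minimum width of 5
grid points (peaks narrower than the modelled resolution are noise);
centroids are intensity-weighted over the FWHM window.

The synthetic generator places Gaussian peaks (σ = 0.15 Th on a 0.05 Th
grid) at theoretical composition m/z values over a sloping baseline with
seeded Gaussian noise, and returns the ground-truth table.  It emulates a
reflectron MALDI-TOF profile's peak shapes and dynamic range but not
isotope envelopes, adduct heterogeneity, or chemical-noise structure —
so the recall/FDR tests certify the processing chain against idealised
truth, not performance on real spectra.  Composition annotation
enumerates the bounded Hex/HexNAc/dHex/NeuAc lattice (defaults 12/8/4/4)
and reports candidates within `tol_ppm` of each centroid; masses are
monoisotopic from atomic masses, default permethylated [M+Na]+ (e.g.
Hex5HexNAc2 at m/z 1579.78).  The electron mass is included in adduct
masses.

## Numerical and design notes

* Determinism: all inference output is sorted by canonical string; the
  acceptance metrics are fully deterministic and the only random machinery
  (synthetic spectra, random-structure generators, subset sampling) is
  driven by explicit seeds.
* Degenerate inputs: an empty enzyme pool returns the seeds unchanged; a
  single-residue product yields an empty reverse network; an all-zero
  spectrum yields an empty peak list; an unconnectable glycan pair
  contributes nothing (not an error).
* SBML export is Level 2 Version 4 with the glycan's GlycoCT embedded
  under `<glycoct xmlns="http://www.eurocarbdb.org/recommendations/encoding">
  <sugar version="1.0"><residues>…</residues><linkages>…</linkages></sugar>`
  in each species annotation; species ids are truncated SHA-1 hashes of
  the canonical string (`gly_…`), enzymes are boundary modifier species
  plus a reaction attribute.  The writer is produced with lxml and checked
  structurally; no external schema validation is performed.
* Known limitations: no repeating-unit or underdetermined-topology
  glycans; no compartmentalised (ER/Golgi-ordered) inference; no kinetics
  (rate constants are user concerns downstream of the exported SBML); no
  isotope-pattern deconvolution or charge-state inference; monosaccharide
  alphabet limited to the eight residues of mammalian N-/O-glycans.
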