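# glyconet

Automated construction and analysis of glycosylation reaction networks.

Cellular glycosylation is carried out by families of glycosyltransferases
(which add one monosaccharide from a sugar-nucleotide donor per reaction)
and glycosidases (which trim one residue per reaction).  Because glycans
are branched and many enzymes accept overlapping substrates, the reaction
network behind even a modest set of observed glycans is large, and building
it by hand is slow and error-prone.  `glyconet` is for systems
glycobiologists who want that network built, analysed and exported
automatically: it encodes enzyme substrate specificity in machine-readable
records and derives every reaction from them.

## The model

A glycan is a rooted tree of residues (Glc, Gal, Man, GlcNAc, GalNAc, Fuc,
Neu5Ac, Xyl); the root is the reducing end, edges are typed linkages such
as β1,4.  An enzyme record (`GTEnz` for transferases, `GHEnz` for
hydrolases, both under the generic `Enz`/`TfEnz`/`HlEnz` hierarchy) stores:

* `resfuncgroup`, `linkFG` — the residue and linkage formed or broken
  (obligatory; a glycosidase may list several linkages in order of
  preference, e.g. α-mannosidase II cleaves Manα1,3 then Manα1,6);
* `resAtt2FG`, `linkAtt2FG` — the attachment residue and its own linkage;
* `targetBranch` — the chain from the acted-on residue toward the
  reducing end (pins an enzyme to one antenna);
* `substNAResidue`, `substNABranch` — residues/motifs whose presence
  blocks the enzyme (e.g. the bisecting GlcNAc chain
  GlcNAcβ1,4Manβ1,4GlcNAcβ1,4GlcNAc blocks ManII and GnT II/IV/V;
  galactosylation blocks further GnT action);
* `substMinStruct` — a motif the substrate must already carry (e.g.
  GnT IV/V require the GnT II product).

Single-reaction inference is three steps: check the enzyme can act, find
the modifiable residues, build one product per site.  On top of it sit
**forward** network inference (fixed point of product inference from seed
glycans), **reverse** inference (substrate inference from products), and
**connection** inference (for every pair among *m* observed glycans —
*m*(*m*−1)/2 pair analyses — enumerate all reaction chains linking them,
then consolidate, deduplicating species by a canonical tree string).
Pathways are graphs (species = nodes, reactions = edges): depth-first
all-paths search, subset-network generation by species deletion, and
isolated-species cleanup support in-silico knockout analysis.  Networks
export to SBML (glycan structure embedded as GlycoCT in each species
annotation) and to DOT/GraphML.  An MS module reads raw MALDI-TOF traces,
applies four-step peak processing (background adjustment, normalisation,
noise removal, peak finding) and assigns monoisotopic permethylated
compositions to centroids, so networks can be synthesised from glycomics
profiles.

## Worked example

The classic N-glycan antennary-processing system, starting from
GlcNAcMan5GlcNAc2 (M5Gn):

```python
import glyconet as gn

db = gn.builtin_database()          # 12 glycosyltransferases + 2 glycosidases
m5gn = gn.parse_linear(
    "GlcNAc(b1,2)Man(a1,3)[Man(a1,3)[Man(a1,6)]Man(a1,6)]"
    "Man(b1,4)GlcNAc(b1,4)GlcNAc"
)

print(gn.infer_products(db["ManII"], m5gn, name="ManII")[0])
pw5 = gn.forward_network([m5gn], ["GnTII", "GnTIII", "GnTIV", "GnTV", "ManII"], db=db)
pw6 = gn.forward_network([m5gn], ["GnTII", "GnTIII", "GnTIV", "GnTV", "ManII", "GalT"], db=db)
print(pw5)
print(pw6)
```

prints

```
[ManII] Man(a1,6)[Man(a1,3)]Man(a1,6)[GlcNAc(b1,2)Man(a1,3)]Man(b1,4)GlcNAc(b1,4)GlcNAc -| Man(a1,6)Man(a1,6)[GlcNAc(b1,2)Man(a1,3)]Man(b1,4)GlcNAc(b1,4)GlcNAc
Pathway(14 species, 14 reactions)
Pathway(28 species, 28 reactions)
```

The first line is the ManII trimming step M5Gn → M4Gn (hydrolysis of the
α1,3-linked mannose on the 6-arm).  With five enzymes the fixed point is
the 14-species / 14-reaction antennary network (hybrid intermediates, the
complex GnGn → tri- → tetra-antennary lattice, and a bisected dead-end
copy of each); adding galactosyltransferase doubles it to 28/28 because
every species gains exactly one lower-antenna galactosylated successor, on
which all GnTs and ManII are blocked.

The O-glycan case: connecting the core-2 trisaccharide (glycan 0) with
twelve observed sialylated/fucosylated core-2 glycans under five enzyme
activities (GalT-IV, B3GnT, ST3Gal-I/II, ST3Gal-IV, FT-VII):

```python
case1 = gn.case1_inputs()
pw = gn.connection_network(list(case1.glycans), list(case1.enzyme_names), db=db)
print(pw, pw.pair_analyses)           # Pathway(20 species, 28 reactions) 78
```

yields 20 species and 28 reactions from 78 pair analyses — the 13 inputs
plus 7 in-silico intermediates, each of which is both produced and
consumed.  `path_finding` then returns the 6 six-step routes from the
core-2 start to the extended sialyl-Lewis-X glycan 9.

A CLI mirrors the library:

```sh
glyconet enzyme show GnTII
glyconet network forward m5gn.glycoct --enzymes GnTII,GnTIII,GnTIV,GnTV,ManII --out fig.sbml
glyconet ms process --in raw.msd --out peaks.tsv
```

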