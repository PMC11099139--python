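# Methods

`patentchem` profiles patent-derived compound libraries the way a
medicinal-chemistry group would triage a large screening deck: parse the
compound-to-patent map, deduplicate, compute physicochemical descriptors,
classify drug-likeness, reduce to scaffolds, screen interference alerts,
and cross-reference into external compound databases. This note records
the models, conventions and design choices behind each stage, and what the
synthetic corpus does and does not establish about real data.

## Ingest model

A map dump is tab-separated text (optionally gzipped), one row per
annotation event. The dump dialect is not standardized, so the column
layout is a configurable `ColumnMap`; the default order is (accession,
SMILES, InChIKey, corpus frequency, patent id, publication date, field
code). Section field codes default to 1..6 =
description/claims/abstract/title/image/molfile and are likewise
overridable.

Patent identifiers follow the SCPN grammar `COUNTRY-SERIAL-KIND` with a
two-letter jurisdiction, a 7–11 digit serial and a kind code
(letter + optional digit). Kind codes group by their leading letter:
A = filed application, B = granted patent; S (design), E (reissue) and
P (plant) documents are grouped as "other", and any unenumerated letter
falls back to "other" with a logged warning.

Validation is drop-only: rows with a malformed SCPN, an InChIKey that is
not `[A-Z]{14}-[A-Z]{10}-[A-Z]`, an unusable date or an unknown section
code are counted by reason and never repaired, so a load is exactly
reproducible from the report. Rows before 2015 are excluded by default
because the older legacy dump format lacks the patent linkage this
pipeline depends on. The application year is taken from the year component
of the dump's date column; whether that date is a filing or publication
date is a property of the dump, not of this package.

Deduplication is keyed on the full InChIKey: patents and annotation
sources are unioned, the representative SMILES is first-seen, and
`first_year` is the minimum application year. Promiscuity (distinct patent
documents per compound) is binned as 1, 2–4, 5–1000 and >1000 — the two
regimes of interest being compounds cited in fewer than five documents and
the heavy >1000 tail.

## Drug-likeness

Structures are desalted before any descriptor work: among
carbon-containing fragments the one with most heavy atoms is kept (ties:
higher molecular weight, then lexicographically smallest canonical
SMILES). No neutralization or tautomer canonicalization is applied — the
desalting step is deliberately minimal so that classification operates on
what the dump actually contains.

Descriptors (RDKit): molecular weight; Wildman–Crippen cLogP; Lipinski
hydrogen-bond counts (HBA = N+O atoms, HBD = NH/OH donor atoms); Ertl
TPSA; rotatable bonds; SSSR ring count; and tetrahedral stereocenters
counted with unassigned centers included. The "stereoisomers" column of
the yearly summary is therefore a stereocenter count, not an enumerated
stereoisomer count — the two readings differ and the former is the
well-defined, conformation-free choice.

Classification applies, in order:

* **extended Ro5** — MW ≤ 500, cLogP ≤ 5, HBD ≤ 5, HBA ≤ 10, plus the
  Veber criteria TPSA < 140 Å² and NRotB < 12. The rule is a strict
  conjunction (zero violations tolerated); the permissive
  one-violation-allowed reading is available only as an explicit,
  logged rule-set override.
* **bRo5** — 500 < MW < 3000 Da with at least one property beyond the
  extended bounds: cLogP > 7.5 or < 0, HBD > 5, HBA > 10, TPSA > 200,
  NRotB > 20.
* **neither** otherwise.

Boundary conventions are exactly as printed above: ≤ on the Lipinski
thresholds, strict < on the Veber ones, strict inequalities throughout
bRo5. The MW thresholds force Ro5 and bRo5 to be mutually exclusive
(MW = 500 lies on the Ro5 side only), which the test suite proves over
10,000 random descriptor vectors including the boundaries.

## Scaffolds

The Bemis–Murcko scaffold is the ring systems plus connecting linkers
with side chains pruned, retaining heteroatoms and bond orders — not the
carbon-skeleton graph framework, which collapses chemically distinct ring
systems together. Atoms attached to a retained ring/linker atom through a
double bond (e.g. a ring carbonyl oxygen, a linker C=O) are retained;
whole side chains ending in such groups are pruned. Acyclic molecules
have no scaffold and are reported as a separate count rather than an
empty-string scaffold row.

Scaffold identity is canonical-SMILES string equality. The test suite
checks the implementation against an independent brute-force oracle that
prunes the molecular graph directly (iteratively delete terminal non-ring
atoms, then restore multiply-bonded neighbors of the surviving skeleton).

Novelty is computed within the loaded corpus only: a scaffold is "new" in
the first year any parent compound cites it and "known" in every later
year it recurs, so the new counts sum to the distinct scaffold count and
the earliest corpus year has zero known scaffolds. Section attribution
counts a scaffold toward every annotation source among its parents;
because of multi-attribution those percentages jointly exceed 100%, so
the share over scaffold–section pairs (which sums to 100%) is reported
alongside.

## PAINS screening

The built-in catalog is the published three-family PAINS set as compiled
in RDKit's FilterCatalog (A: 16, B: 55, C: 409 — 480 patterns). Matching
is a substructure query on the desalted parent with aromaticity
perceived; one compound may fire many alerts, per-alert counts are
distinct compounds (never occurrences), and screening is monotone under
catalog union. User catalogs are two-column (name, SMARTS) files;
an uncompilable pattern aborts the load naming its line. Corpus-level
alert counts depend on the catalog revision, so they are treated as
descriptive output, not as reference values.

## Cross-referencing

Compounds map into external resources by exact match of the full
27-character InChIKey. Connectivity-block (first 14 characters) matching
would conflate stereoisomers and is deliberately not used; the property
tests verify that altering a single stereo-block or protonation-flag
character breaks the match. Resources are plain TSVs
(`inchikey[, max_phase][, status]`), keeping the stage deterministic and
offline. Numeric max-phase codes map to named stages through an explicit
table (default: −1 unknown, 0 preclinical, 1–3 phases, 4 approved)
because the preclinical/unknown boundary is a vocabulary convention, not
a fact about the data. A compound annotated approved on one side and
withdrawn (or mid-trial) on the other is counted in both tables and
flagged as a conflict rather than silently resolved.

## Synthetic corpus

The generator emits corpora whose ground truth is planted, not sampled:

* **Class membership** — molecules are assembled from label-specific
  template pools (decorated small rings for Ro5; polyol chains for bRo5;
  greasy alkanes or small polar amide chains for "neither") and accepted
  only if the package's own classifier assigns the requested label
  (bounded rejection sampling, 100 tries). Class counts follow
  largest-remainder rounding of the configured fractions, so recovery is
  exact, not statistical.
* **PAINS injections** — a configured fraction of molecules (default 4%)
  carries one of three grafted motifs (catechol, azo-aryl, quinone),
  each verified at generation time to fire the catalog; every clean
  molecule is verified to miss the entire catalog. The recovered flagged
  fraction therefore equals the injection rate exactly.
* **Promiscuity** — per-compound patent counts follow a discrete
  truncated power law, default exponent 2.5 with a cap of 1,500. With
  these defaults ~95% of compounds sit below 5 documents, matching the
  promiscuity regime reported for real patent corpora; the >1000 bin is
  reachable but rare at n = 2000.
* **Patents and sections** — SCPNs use globally unique serials,
  countries weighted US/EP/WO/JP ≈ 57/27/15/1, filed kinds dominating
  granted, and US-only design/reissue/plant codes. Years are uniform
  over 2015–2022. Annotation sources are drawn per compound–patent pair
  from marginals echoing the observed dominance of images (~48%) and
  descriptions (~28%), with at least one source forced.
* **Resources** — membership is an exact deterministic selection of
  round(fraction × n) compounds per resource (defaults 0.9 / 0.3 / 0.05
  for the PubChem-, ChEMBL- and DrugBank-like tables) via seeded
  permutations, plus a few decoy keys per resource that exist nowhere in
  the corpus. Clinical phases and approval statuses are planted by
  largest remainder over the configured distributions; a drugbank-
  approved compound that is also chembl-planted is promoted to the
  approved phase so the two annotations can never contradict.

Everything derives from one seeded NumPy generator; identical
configurations reproduce every emitted file byte for byte.

What the generator does **not** emulate: real structural diversity (a few
dozen template families versus millions of real scaffolds), Markush
enumeration, realistic SMILES noise or invalid rows, correlated
section/phase structure, and real corpus scale. Passing the recovery
tests therefore demonstrates that the pipeline's bookkeeping — parsing,
deduplication, classification thresholds, set algebra, counting — is
exact, not that the package reproduces any statistic of the real
SureChEMBL dump, whose headline values depend on ~10M compounds and
specific external database versions.

## Problem sizes and numerics

The study corpus used by the analysis drivers, the acceptance script and
the end-to-end tests is n = 2,000 compounds (≈ 4,600 dump rows), chosen
as the smallest size at which every planted structure (class split,
overlap regions, promiscuity tail, per-year novelty) is well populated;
generation takes ~15 s and the full pipeline ~7 s on one CPU. Percentage
shares are never rounded internally and only at serialization
(2 decimals). Ranking ties break lexicographically (InChIKey for
compounds, canonical SMILES for scaffolds) so all orderings are total and
deterministic. Empty inputs yield schema-valid zero outputs throughout.

## Known limitations

* Lipinski-convention HBA/HBD counts differ from pharmacophore-based
  definitions; compounds near the HBA/HBD thresholds can change class
  under other conventions (selectable via the rule-set, logged).
* The desalter keeps the largest organic fragment; genuinely mixed
  organic salts (two large organic ions) resolve by the tie-break rather
  than by charge analysis.
* cLogP is an atomic-contribution estimate; published experimental LogP
  values can differ by more than a log unit for large natural products.
* Heparin-like polydisperse polymers have no single representative
  structure and are outside the exemplar panel.
* The SCPN serial/kind grammar is enforced as documented; dumps with
  nonconforming legacy identifiers are dropped (and counted), not
  recovered.
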