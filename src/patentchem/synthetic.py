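"""Synthetic patent-compound corpora with exact, known ground truth.

The generator emits a map dump in the ingest dialect together with
resource tables and a ground-truth JSON, so every downstream stage can be
checked against planted values:

* drug-likeness class membership is guaranteed per molecule by rejection
  sampling against the package's own classifier;
* PAINS-flagged molecules are built by grafting catalog-matching motifs
  (catechol, azo-aryl, quinone) and verified to hit; clean molecules are
  verified to miss the entire catalog;
* cross-resource membership, clinical phases and approval statuses are
  planted by exact deterministic selection (largest-remainder rounding,
  seeded shuffles), never Bernoulli draws;
* per-compound patent counts follow a discrete truncated power law whose
  defaults put ~95% of compounds below 5 documents, the promiscuity regime
  observed in real patent corpora.

Everything is driven by one seeded NumPy generator: the same configuration
produces byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem

from .alerts import AlertDefinition, load_catalog, screen
from .druglikeness import DruglikenessLabel, classify, compute_descriptors
from .errors import GeneratorError
from .ingest import DEFAULT_SECTION_CODES, SectionSource

logger = logging.getLogger(__name__)

_SECTION_CODE_OF = {v: k for k, v in DEFAULT_SECTION_CODES.items()}

#: Default per-source annotation probabilities (per compound-patent pair),
#: echoing the observed dominance of images and descriptions.
DEFAULT_SECTION_MARGINALS: Mapping[SectionSource, float] = {
    SectionSource.TITLE: 0.01,
    SectionSource.ABSTRACT: 0.03,
    SectionSource.DESCRIPTION: 0.28,
    SectionSource.CLAIMS: 0.12,
    SectionSource.IMAGE: 0.48,
    SectionSource.MOLFILE: 0.15,
}

DEFAULT_PHASE_DISTRIBUTION: Mapping[str, float] = {
    "unknown": 0.016,
    "preclinical": 0.90,
    "phase1": 0.015,
    "phase2": 0.025,
    "phase3": 0.024,
    "approved": 0.02,
}

DEFAULT_STATUS_DISTRIBUTION: Mapping[str, float] = {
    "approved": 0.40,
    "investigational": 0.58,
    "withdrawn": 0.02,
}

_PHASE_TO_CODE = {
    "unknown": -1,
    "preclinical": 0,
    "phase1": 1,
    "phase2": 2,
    "phase3": 3,
    "approved": 4,
}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic corpus."""

    n_compounds: int = 2000
    years: tuple[int, int] = (2015, 2022)
    class_fractions: tuple[float, float, float] = (0.55, 0.16, 0.29)  # ro5/bro5/neither
    section_marginals: dict = field(
        default_factory=lambda: dict(DEFAULT_SECTION_MARGINALS)
    )
    promiscuity_alpha: float = 2.5
    promiscuity_max: int = 1500
    resource_overlaps: dict = field(
        default_factory=lambda: {"pubchem": 0.9, "chembl": 0.3, "drugbank": 0.05}
    )
    phase_distribution: dict = field(
        default_factory=lambda: dict(DEFAULT_PHASE_DISTRIBUTION)
    )
    status_distribution: dict = field(
        default_factory=lambda: dict(DEFAULT_STATUS_DISTRIBUTION)
    )
    pains_rate: float = 0.04
    seed: int = 0

    def validate(self) -> None:
        if self.n_compounds < 0:
            raise GeneratorError("n_compounds must be >= 0")
        if self.years[0] > self.years[1]:
            raise GeneratorError("years range is inverted")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise GeneratorError("class_fractions must sum to 1")
        for f in self.class_fractions:
            if not 0.0 <= f <= 1.0:
                raise GeneratorError("class fractions must lie in [0, 1]")
        for name, f in self.resource_overlaps.items():
            if not 0.0 <= f <= 1.0:
                raise GeneratorError(f"overlap for {name!r} outside [0, 1]")
        if not 0.0 <= self.pains_rate <= 1.0:
            raise GeneratorError("pains_rate outside [0, 1]")
        for dist, label in (
            (self.phase_distribution, "phase_distribution"),
            (self.status_distribution, "status_distribution"),
        ):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise GeneratorError(f"{label} must sum to 1")
        if not self.section_marginals or sum(self.section_marginals.values()) <= 0:
            raise GeneratorError("section_marginals must have positive mass")
        for p in self.section_marginals.values():
            if not 0.0 <= p <= 1.0:
                raise GeneratorError("section marginals must lie in [0, 1]")
        if self.promiscuity_alpha <= 1.0:
            raise GeneratorError("promiscuity_alpha must exceed 1")
        if self.promiscuity_max < 1:
            raise GeneratorError("promiscuity_max must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["years"] = list(self.years)
        d["class_fractions"] = list(self.class_fractions)
        d["section_marginals"] = {
            s.value if isinstance(s, SectionSource) else str(s): p
            for s, p in self.section_marginals.items()
        }
        return d


def largest_remainder(fractions: Sequence[float], total: int) -> list[int]:
    """Integer counts summing to ``total`` that best honour the fractions."""
    raw = [f * total for f in fractions]
    counts = [int(np.floor(x)) for x in raw]
    short = total - sum(counts)
    order = sorted(
        range(len(fractions)), key=lambda i: (-(raw[i] - counts[i]), i)
    )
    for i in order[:short]:
        counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# molecule construction
# ---------------------------------------------------------------------------

_RO5_CORES = (
    "c1ccc({0})cc1",
    "c1cc({0})ccc1{1}",
    "c1cc({0})cc({1})c1",
    "c1c({0})cc({1})cc1{2}",
    "c1ccnc({0})c1",
    "C1CCC({0})CC1",
    "C1CC({0})CCC1{1}",
    "C1CCOC({0})C1",
    "c1ccc2cc({0})ccc2c1",
    "c1ccc2cc({0})c({1})cc2c1",
    "C(c1ccccc1)c1ccc({0})cc1",
)

_RO5_SUBSTITUENTS = (
    "C", "CC", "CCC", "CCCC", "CC(C)C", "O", "OC", "OCC", "F", "Cl", "Br",
    "C#N", "CO", "CCO", "C(=O)OC", "C(=O)NC", "C(C)=O", "S(C)(=O)=O",
    "C(F)(F)F", "CCN(C)C",
    # ring-bearing substituents so the corpus spans a realistic scaffold space
    "c1ccccc1", "C1CCCCC1", "c1ccco1", "c1cccs1", "c1cccnc1", "C1CCOCC1",
    "Cc1ccccc1", "CC1CCCCC1",
)

_POLYOL_UNITS = ("C(O)", "C(CO)", "CC(O)")
_POLYOL_PREFIXES = ("OC", "OCC", "C1CCOC(C1)", "c1ccccc1C(O)")
_GREASY_UNITS = ("C", "C(C)", "CC")

#: PAINS injection motifs, attached through a single bond.  Each key is the
#: attachment fragment appended to an aliphatic carbon chain; every grafted
#: molecule is verified to fire the corresponding catalog family.
PAINS_MOTIFS: Mapping[str, str] = {
    "catechol": "c1ccc(O)c(O)c1",
    "azo": "c1ccc(/N=N/c2ccccc2)cc1",
    "quinone": "C1=CC(=O)C=CC1=O",
}

_pains_catalog_cache: list[AlertDefinition] | None = None


def _pains_catalog() -> list[AlertDefinition]:
    global _pains_catalog_cache
    if _pains_catalog_cache is None:
        _pains_catalog_cache = load_catalog("pains")
    return _pains_catalog_cache


def _alkyl(rng: np.random.Generator, units: Sequence[str], n_units: int) -> str:
    return "".join(rng.choice(units) for _ in range(n_units))


def _propose(label: DruglikenessLabel, rng: np.random.Generator) -> str:
    """One random clean candidate SMILES for the requested class."""
    if label is DruglikenessLabel.RO5:
        core = _RO5_CORES[rng.integers(len(_RO5_CORES))]
        subs = [
            _RO5_SUBSTITUENTS[rng.integers(len(_RO5_SUBSTITUENTS))]
            for _ in range(core.count("{"))
        ]
        return core.format(*subs)
    if label is DruglikenessLabel.BRO5:
        prefix = _POLYOL_PREFIXES[rng.integers(len(_POLYOL_PREFIXES))]
        chain = _alkyl(rng, _POLYOL_UNITS, int(rng.integers(18, 36)))
        return prefix + chain + "CO"
    # NEITHER: either a greasy chain (cLogP violation at MW <= 500) or a
    # small highly polar amide chain (TPSA violation at MW <= 500).
    if rng.random() < 0.7:
        prefix = "c1ccccc1" if rng.random() < 0.3 else "C"
        chain = _alkyl(rng, _GREASY_UNITS, int(rng.integers(10, 18)))
        return prefix + chain + "C"
    units = _alkyl(rng, ("CNC(=O)", "C(C)NC(=O)"), int(rng.integers(4, 7)))
    return "NC(=O)" + units + _alkyl(rng, ("C", "C(C)"), int(rng.integers(1, 4)))


_POLAR_SUBS = ("O", "OC", "F", "Cl", "C#N", "CO", "OCC", "C(=O)NC", "S(C)(=O)=O")


def _propose_injected(
    label: DruglikenessLabel, motif: str, rng: np.random.Generator
) -> str:
    """One random PAINS-grafted candidate for the requested class."""
    fragment = PAINS_MOTIFS[motif]
    if label is DruglikenessLabel.RO5:
        if motif == "azo":
            # keep the grafted azo-biaryl inside Ro5 logP via a polar para
            # substituent and at most a short alkyl tail
            sub = _POLAR_SUBS[int(rng.integers(len(_POLAR_SUBS)))]
            tail = _alkyl(rng, ("C", "CC"), int(rng.integers(0, 2)))
            return tail + f"c1ccc(/N=N/c2ccc({sub})cc2)cc1"
        tail = _alkyl(rng, ("C", "C(C)", "CC"), int(rng.integers(1, 7)))
        return tail + fragment
    if label is DruglikenessLabel.BRO5:
        chain = "OC" + _alkyl(rng, _POLYOL_UNITS, int(rng.integers(16, 30)))
        return chain + "C" + fragment
    tail = _alkyl(rng, _GREASY_UNITS, int(rng.integers(8, 16)))
    return "C" + tail + fragment


def make_molecule(
    label: DruglikenessLabel,
    rng: np.random.Generator,
    pains_motif: str | None = None,
    max_tries: int = 100,
) -> str:
    """A valid SMILES whose computed descriptors carry the requested label.

    With ``pains_motif`` set ("catechol", "azo" or "quinone") the molecule
    additionally contains the grafted motif and fires at least one PAINS
    alert; without it the molecule matches no catalog pattern.  Bounded
    rejection sampling against the classifier (and the catalog) enforces
    both guarantees; exceeding ``max_tries`` raises
    :class:`GeneratorError` naming the label.
    """
    catalog = _pains_catalog()
    for _ in range(max_tries):
        smiles = (
            _propose_injected(label, pains_motif, rng)
            if pains_motif is not None
            else _propose(label, rng)
        )
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if classify(compute_descriptors(canonical)) is not label:
            continue
        n_hits = len(screen(canonical, catalog))
        if pains_motif is not None and n_hits == 0:
            continue
        if pains_motif is None and n_hits > 0:
            continue
        return canonical
    raise GeneratorError(
        f"could not build a {label.value} molecule"
        + (f" with motif {pains_motif}" if pains_motif else "")
        + f" in {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# corpus assembly
# ---------------------------------------------------------------------------

_COUNTRIES = ("US", "EP", "WO", "JP")
_COUNTRY_P = (0.57, 0.27, 0.15, 0.01)
_US_KINDS = ("A1", "A2", "B1", "B2", "E1", "P1", "S1")
_US_KIND_P = (0.45, 0.15, 0.30, 0.07, 0.015, 0.01, 0.005)
_NON_US_KINDS = ("A1", "A2", "B1", "B2")
_NON_US_KIND_P = (0.50, 0.15, 0.28, 0.07)


@dataclass
class CorpusPaths:
    """Locations of the files one generator run produced."""

    map_file: Path
    resource_files: dict[str, Path]
    ground_truth_file: Path


def _power_law_counts(
    rng: np.random.Generator, n: int, alpha: float, kmax: int
) -> np.ndarray:
    ks = np.arange(1, kmax + 1, dtype=float)
    p = ks ** (-alpha)
    p /= p.sum()
    return rng.choice(np.arange(1, kmax + 1), size=n, p=p)


def _promiscuity_bins(counts: Sequence[int]) -> dict[str, int]:
    bins = {"1": 0, "2-4": 0, "5-1000": 0, ">1000": 0}
    for c in counts:
        if c == 1:
            bins["1"] += 1
        elif c <= 4:
            bins["2-4"] += 1
        elif c <= 1000:
            bins["5-1000"] += 1
        else:
            bins[">1000"] += 1
    return bins


def _random_fake_inchikey(rng: np.random.Generator) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    pick = lambda k: "".join(letters[i] for i in rng.integers(0, 26, size=k))
    return f"{pick(14)}-{pick(10)}-{pick(1)}"


def generate_corpus(config: SyntheticConfig, out_dir: str | Path) -> CorpusPaths:
    """Generate the map dump, resource tables and ground-truth JSON.

    See the module docstring for the guarantees.  Files are written with
    sorted, fully deterministic content: rerunning with the same
    configuration reproduces them byte for byte.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n = config.n_compounds
    labels_order = (
        DruglikenessLabel.RO5,
        DruglikenessLabel.BRO5,
        DruglikenessLabel.NEITHER,
    )

    class_counts = largest_remainder(config.class_fractions, n)
    n_inject = int(round(n * config.pains_rate))
    inject_counts = largest_remainder(config.class_fractions, n_inject)
    # never inject more than a class holds
    for i in range(3):
        inject_counts[i] = min(inject_counts[i], class_counts[i])
    motif_names = sorted(PAINS_MOTIFS)

    compounds: list[dict] = []
    seen_keys: set[str] = set()
    motif_cursor = 0
    for label, n_class, n_inj in zip(labels_order, class_counts, inject_counts):
        for j in range(n_class):
            motif = None
            if j < n_inj:
                motif = motif_names[motif_cursor % len(motif_names)]
                motif_cursor += 1
            for attempt in range(200):
                smiles = make_molecule(label, rng, pains_motif=motif)
                inchikey = Chem.MolToInchiKey(Chem.MolFromSmiles(smiles))
                if inchikey not in seen_keys:
                    break
            else:
                raise GeneratorError(
                    f"could not draw a fresh {label.value} molecule after 200 tries"
                )
            seen_keys.add(inchikey)
            compounds.append(
                {
                    "label": label.value,
                    "smiles": smiles,
                    "inchikey": inchikey,
                    "pains_motif": motif,
                }
            )

    # stable accession ids in generation order
    for idx, comp in enumerate(compounds):
        comp["schembl_id"] = f"SCHEMBL{100000 + idx}"

    # patents: unique serials, power-law counts per compound
    patent_counts = (
        _power_law_counts(rng, n, config.promiscuity_alpha, config.promiscuity_max)
        if n
        else np.array([], dtype=int)
    )
    serial_counter = 10000000
    y0, y1 = config.years
    sections_sorted = sorted(config.section_marginals, key=lambda s: _SECTION_CODE_OF[s])
    marg = np.array([config.section_marginals[s] for s in sections_sorted])
    rows: list[tuple] = []
    for comp, k in zip(compounds, patent_counts):
        patents = []
        for _ in range(int(k)):
            country = rng.choice(_COUNTRIES, p=_COUNTRY_P)
            kinds, kp = (
                (_US_KINDS, _US_KIND_P) if country == "US" else (_NON_US_KINDS, _NON_US_KIND_P)
            )
            kind = rng.choice(kinds, p=kp)
            year = int(rng.integers(y0, y1 + 1))
            date = f"{year:04d}-{int(rng.integers(1, 13)):02d}-{int(rng.integers(1, 29)):02d}"
            scpn = f"{country}-{serial_counter}-{kind}"
            serial_counter += 1
            draw = rng.random(len(sections_sorted))
            chosen = [s for s, u, p in zip(sections_sorted, draw, marg) if u < p]
            if not chosen:
                chosen = [sections_sorted[rng.choice(len(sections_sorted), p=marg / marg.sum())]]
            patents.append({"scpn": scpn, "year": year, "date": date, "sections": chosen})
        comp["patents"] = patents
        comp["n_patents"] = int(k)
        comp["first_year"] = min(p["year"] for p in patents) if patents else None
        union: set[SectionSource] = set()
        for p in patents:
            union.update(p["sections"])
        comp["sections"] = sorted(s.value for s in union)
        for p in patents:
            for s in sorted(p["sections"], key=lambda s: _SECTION_CODE_OF[s]):
                rows.append(
                    (
                        comp["schembl_id"],
                        comp["smiles"],
                        comp["inchikey"],
                        str(int(k)),
                        p["scpn"],
                        p["date"],
                        str(_SECTION_CODE_OF[s]),
                    )
                )

    map_file = out_dir / "map_dump.tsv"
    header = "SCHEMBL_ID\tSMILES\tInChIKey\tFrequency\tPatent_ID\tPublication_Date\tField"
    with open(map_file, "w", newline="\n") as fh:
        fh.write(header + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")

    # resources: exact deterministic planting
    resource_files: dict[str, Path] = {}
    memberships: dict[str, list[int]] = {}
    for res_name in sorted(config.resource_overlaps):
        frac = config.resource_overlaps[res_name]
        m = int(round(frac * n))
        members = sorted(rng.permutation(n)[:m].tolist())
        memberships[res_name] = members
        for idx in members:
            compounds[idx].setdefault("resources", []).append(res_name)
    for comp in compounds:
        comp.setdefault("resources", [])
        comp["max_phase"] = None
        comp["status"] = None

    # clinical phases on the chembl-like resource
    if "chembl" in memberships and memberships["chembl"]:
        members = memberships["chembl"]
        phases = sorted(config.phase_distribution)
        counts = largest_remainder(
            [config.phase_distribution[p] for p in phases], len(members)
        )
        shuffled = [members[i] for i in rng.permutation(len(members))]
        pos = 0
        for phase, cnt in zip(phases, counts):
            for idx in shuffled[pos : pos + cnt]:
                compounds[idx]["max_phase"] = phase
            pos += cnt

    # approval statuses on the drugbank-like resource
    if "drugbank" in memberships and memberships["drugbank"]:
        members = memberships["drugbank"]
        statuses = sorted(config.status_distribution)
        counts = largest_remainder(
            [config.status_distribution[s] for s in statuses], len(members)
        )
        shuffled = [members[i] for i in rng.permutation(len(members))]
        pos = 0
        for status, cnt in zip(statuses, counts):
            for idx in shuffled[pos : pos + cnt]:
                compounds[idx]["status"] = status
            pos += cnt
        # an approved drug cannot sit below the approved phase
        for comp in compounds:
            if (
                comp["status"] == "approved"
                and "chembl" in comp["resources"]
            ):
                comp["max_phase"] = "approved"

    for res_name in sorted(config.resource_overlaps):
        path = out_dir / f"resource_{res_name}.tsv"
        resource_files[res_name] = path
        members = memberships.get(res_name, [])
        n_decoys = max(3, len(members) // 10) if n else 0
        decoys = []
        while len(decoys) < n_decoys:
            key = _random_fake_inchikey(rng)
            if key not in seen_keys:
                decoys.append(key)
        entries = []
        for idx in members:
            comp = compounds[idx]
            phase = comp["max_phase"] if res_name == "chembl" else None
            status = comp["status"] if res_name == "drugbank" else None
            entries.append((comp["inchikey"], phase, status))
        entries.extend((key, None, None) for key in decoys)
        entries.sort(key=lambda e: e[0])
        with open(path, "w", newline="\n") as fh:
            fh.write("inchikey\tmax_phase\tstatus\n")
            for key, phase, status in entries:
                phase_code = "" if phase is None else str(_PHASE_TO_CODE[phase])
                fh.write(f"{key}\t{phase_code}\t{status or ''}\n")

    # ground-truth aggregates (independent simple tallies)
    region_counts: dict[str, int] = {}
    for comp in compounds:
        key = "+".join(sorted(comp["resources"])) or "none"
        region_counts[key] = region_counts.get(key, 0) + 1
    phase_counts: dict[str, int] = {}
    for comp in compounds:
        if "chembl" in comp["resources"]:
            phase = comp["max_phase"] or "unknown"
            phase_counts[phase] = phase_counts.get(phase, 0) + 1
    status_counts: dict[str, int] = {}
    for comp in compounds:
        if comp["status"] is not None:
            status_counts[comp["status"]] = status_counts.get(comp["status"], 0) + 1
    truth = {
        "config": config.to_dict(),
        "compounds": [
            {
                "schembl_id": c["schembl_id"],
                "inchikey": c["inchikey"],
                "smiles": c["smiles"],
                "label": c["label"],
                "pains_motif": c["pains_motif"],
                "n_patents": c["n_patents"],
                "first_year": c["first_year"],
                "years": sorted({p["year"] for p in c["patents"]}),
                "sections": c["sections"],
                "resources": sorted(c["resources"]),
                "max_phase": c["max_phase"],
                "status": c["status"],
            }
            for c in compounds
        ],
        "aggregates": {
            "n_compounds": n,
            "n_rows": len(rows),
            "class_counts": {
                label.value: count for label, count in zip(labels_order, class_counts)
            },
            "flagged_count": sum(1 for c in compounds if c["pains_motif"]),
            "promiscuity_bins": _promiscuity_bins([c["n_patents"] for c in compounds]),
            "region_counts": dict(sorted(region_counts.items())),
            "exclusive_count": region_counts.get("none", 0),
            "per_resource_counts": {
                name: len(m) for name, m in sorted(memberships.items())
            },
            "phase_counts": dict(sorted(phase_counts.items())),
            "status_counts": dict(sorted(status_counts.items())),
            "multi_source_count": sum(
                1 for c in compounds if len(c["sections"]) >= 2
            ),
        },
    }
    ground_truth_file = out_dir / "ground_truth.json"
    with open(ground_truth_file, "w", newline="\n") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")

    logger.info(
        "generated corpus: %d compounds, %d rows, %d resources",
        n, len(rows), len(resource_files),
    )
    return CorpusPaths(
        map_file=map_file,
        resource_files=resource_files,
        ground_truth_file=ground_truth_file,
    )
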