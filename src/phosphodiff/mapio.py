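"""Reading curated CellDesigner-flavored SBML signaling maps.

A curated map stores its biochemistry in standard SBML Level 2 elements
(species, reactions) and its graphical/biological detail — including
phosphorylated modification residues on proteins — in the CellDesigner
extension namespace.  Literature provenance is attached to reactions as
PMID strings in notes.  This module parses maps into a light container,
summarizes them (optionally as a deduplicated union across maps), and
audits the concordance of their phosphosite inventory against a
reference site database.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
CELLDESIGNER_NS = "http://www.sbml.org/2001/ns/celldesigner"
PMID_RE = re.compile(r"PMID[:\s]*(\d+)")
RESIDUE_RE = re.compile(r"^([STY])(\d+)?$")

_KNOWN_CD_TAGS = {
    "extension", "listOfProteins", "protein", "listOfModificationResidues",
    "modificationResidue", "speciesIdentity", "class", "proteinReference",
    "state", "listOfModifications", "modification",
}


@dataclass
class Reaction:
    id: str
    reactants: list[str]
    products: list[str]
    modifiers: list[str]
    pmids: set[int]


@dataclass
class SignalingMap:
    """Parsed map content: species, reactions and the phosphosite inventory."""

    species: list[tuple[str, str, str]]          # (id, name, compartment)
    reactions: list[Reaction]
    phosphosites: list[tuple[str, str, int | None]]  # (protein, residue, position)
    source: str = ""
    dangling_ids: list[str] = field(default_factory=list)


@dataclass
class MapSummary:
    n_species: int
    n_reactions: int
    n_publications: int
    n_phosphosites: int
    n_ser_thr: int
    n_tyr: int
    n_proteins_with_sites: int
    n_positionless: int = 0

    def as_dict(self) -> dict:
        return dict(vars(self))


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def parse_celldesigner_sbml(path) -> SignalingMap:
    """Parse an SBML file carrying the CellDesigner extension.

    Species and reactions come from the standard SBML elements;
    phosphosites from extension modification residues whose state is
    "phosphorylated" (residue names like ``S235``, or a bare residue
    letter when the position is not curated).  PMIDs are pulled from
    reaction notes/annotation text.  Files without the extension
    namespace degrade gracefully to an empty phosphosite inventory.
    """
    tree = etree.parse(str(path))  # raises XMLSyntaxError with line info
    root = tree.getroot()
    level = root.get("level")
    if level is not None and not str(level).startswith("2"):
        logger.warning("%s: SBML level %s outside 2.x; best-effort parse", path, level)
    model = next((c for c in root if _local(c.tag) == "model"), None)
    if model is None:
        raise ValueError(f"{path}: no <model> element")

    def find_list(parent, name):
        el = next((c for c in parent.iter() if _local(c.tag) == name), None)
        return list(el) if el is not None else []

    # extension: protein definitions with modification residues
    residues: dict[tuple[str, str], tuple[str, str, int | None]] = {}
    protein_names: dict[str, str] = {}
    n_unknown = 0
    for el in model.iter():
        tag = _local(el.tag)
        if el.tag.startswith("{" + CELLDESIGNER_NS + "}") and tag not in _KNOWN_CD_TAGS:
            n_unknown += 1
    for prot in (el for el in model.iter("{%s}protein" % CELLDESIGNER_NS)):
        pid = prot.get("id", "")
        pname = prot.get("name", pid)
        protein_names[pid] = pname
        for res in prot.iter("{%s}modificationResidue" % CELLDESIGNER_NS):
            m = RESIDUE_RE.match(res.get("name", "").strip())
            if m:
                residues[(pid, res.get("id", ""))] = (
                    pname, m.group(1), int(m.group(2)) if m.group(2) else None
                )
    if n_unknown:
        logger.info("%s: ignored %d unknown extension elements", path, n_unknown)

    # species
    species: list[tuple[str, str, str]] = []
    phospho: list[tuple[str, str, int | None]] = []
    seen_sites: set[tuple[str, str, int | None]] = set()
    species_list = next(
        (c for c in model if _local(c.tag) == "listOfSpecies"), None
    )
    for sp in (list(species_list) if species_list is not None else []):
        if _local(sp.tag) != "species":
            continue
        sid = sp.get("id", "")
        species.append((sid, sp.get("name", sid), sp.get("compartment", "")))
        pref = next((e.text for e in sp.iter("{%s}proteinReference" % CELLDESIGNER_NS)), None)
        for mod in sp.iter("{%s}modification" % CELLDESIGNER_NS):
            if mod.get("state") != "phosphorylated":
                continue
            key = (pref or "", mod.get("residue", ""))
            if key in residues:
                site = residues[key]
                if site not in seen_sites:
                    seen_sites.add(site)
                    phospho.append(site)

    # reactions
    species_ids = {s[0] for s in species}
    reactions: list[Reaction] = []
    dangling: list[str] = []
    reaction_list = next((c for c in model if _local(c.tag) == "listOfReactions"), None)
    for rx in (list(reaction_list) if reaction_list is not None else []):
        if _local(rx.tag) != "reaction":
            continue
        parts: dict[str, list[str]] = {"listOfReactants": [], "listOfProducts": [],
                                       "listOfModifiers": []}
        for child in rx:
            name = _local(child.tag)
            if name in parts:
                for sr in child:
                    ref = sr.get("species", "")
                    parts[name].append(ref)
                    if ref not in species_ids:
                        dangling.append(ref)
        text = " ".join(
            t for el in rx.iter()
            if _local(el.tag) in ("notes", "body", "p", "annotation") and (t := el.text)
        )
        pmids = {int(m) for m in PMID_RE.findall(text or "")}
        reactions.append(Reaction(
            id=rx.get("id", ""), reactants=parts["listOfReactants"],
            products=parts["listOfProducts"], modifiers=parts["listOfModifiers"],
            pmids=pmids,
        ))
    if dangling:
        logger.warning("%s: %d reaction participants reference undeclared species: %s",
                       path, len(dangling), sorted(set(dangling))[:5])
    if not residues and not protein_names:
        logger.warning("%s: no CellDesigner extension content; phosphosite inventory empty", path)
    return SignalingMap(species=species, reactions=reactions, phosphosites=phospho,
                        source=str(path), dangling_ids=dangling)


def map_summary(maps: SignalingMap | Sequence[SignalingMap]) -> MapSummary:
    """Summarize one map, or the deduplicated union of several.

    Union mode deduplicates species by (name, compartment), reactions by
    id, phosphosites by (protein, residue, position) and PMIDs by value.
    """
    if isinstance(maps, SignalingMap):
        maps = [maps]
    species = {(name, comp) for m in maps for (_sid, name, comp) in m.species}
    reactions = {rx.id for m in maps for rx in m.reactions}
    pmids = {p for m in maps for rx in m.reactions for p in rx.pmids}
    sites = {s for m in maps for s in m.phosphosites}
    positioned = {s for s in sites if s[2] is not None}
    positionless = sites - positioned
    n_st = sum(1 for s in sites if s[1] in ("S", "T"))
    n_y = sum(1 for s in sites if s[1] == "Y")
    return MapSummary(
        n_species=len(species),
        n_reactions=len(reactions),
        n_publications=len(pmids),
        n_phosphosites=len(sites),
        n_ser_thr=n_st,
        n_tyr=n_y,
        n_proteins_with_sites=len({s[0] for s in sites}),
        n_positionless=len(positionless),
    )


def map_concordance(
    m: SignalingMap | Sequence[SignalingMap], ref: pd.DataFrame
) -> dict:
    """Audit how many map phosphosites exist in a reference site table.

    A positioned map site (protein, residue, position) is "found" when
    some reference record matches by case-folded gene or protein name
    plus residue and position.  Positionless sites are excluded from the
    denominator and tallied separately.
    """
    if isinstance(m, SignalingMap):
        maps = [m]
    else:
        maps = list(m)
    sites = {s for mm in maps for s in mm.phosphosites}
    positioned = sorted(s for s in sites if s[2] is not None)
    n_positionless = len(sites) - len(positioned)
    if n_positionless:
        logger.info("map_concordance: %d positionless sites excluded from denominator",
                    n_positionless)
    ref_keys = set()
    for rec in ref.to_dict("records") if len(ref) else []:
        res = str(rec.get("residue", "")).upper()
        pos = rec.get("position", None)
        if not res or pos is None or int(pos) < 1:
            continue
        for name_col in ("gene", "protein"):
            name = str(rec.get(name_col, "")).casefold()
            if name:
                ref_keys.add((name, res, int(pos)))
    missing = [s for s in positioned
               if (s[0].casefold(), s[1], int(s[2])) not in ref_keys]
    n_found = len(positioned) - len(missing)
    return {
        "n_map_sites": len(positioned),
        "n_found": n_found,
        "n_missing": len(missing),
        "n_positionless": n_positionless,
        "concordance": n_found / len(positioned) if positioned else float("nan"),
        "missing": missing,
    }
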