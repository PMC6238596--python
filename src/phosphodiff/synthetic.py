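"""Synthetic study generator: all pipeline inputs with known ground truth.

Emulates a three-condition (control / acute / chronic stimulation)
isobaric-labeling phosphoproteomics experiment: protein-level reporter
signal-to-noise, phosphopeptide S/N tied to the parent protein with
planted per-group chronic-vs-acute shifts, localization scores, a
reference phosphosite database overlapping the MS sites at a controlled
fraction (plus decoys and cross-species rows), kinase-substrate
annotations with heavy-tailed kinase usage, a functional-group table, a
term-annotation file and a miniature CellDesigner-SBML map fixture.
Every emitted phosphosite has exactly one ground-truth row, so each
downstream stage can be validated without external data.

Default scale mirrors the emulated study: ~7,500 quantified proteins,
~1,850 phosphoproteins, triplicate channels per condition, 90.3% of MS
sites present in the reference database, and per-channel log2 noise
calibrated so that ~96.5% of null sites keep |differential| <= 1.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import matching
from .matching import explode_multisite

logger = logging.getLogger(__name__)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Functional modules of the curated signaling map used as group labels.
DEFAULT_GROUPS = (
    "RNA binding and translation",
    "MAPK cascade",
    "mTOR signaling",
    "calcium signaling",
    "cytoskeleton dynamics",
    "transcription and cell cycle",
    "small GTPase signaling",
    "endocytosis and degradation",
)

GROUP_PALETTE = (
    "#e41a1c", "#377eb8", "#4daf4a", "#984ea3",
    "#ff7f00", "#a65628", "#f781bf", "#999999",
)

#: Sites-per-protein distribution over 1..10: 73.6% of phosphoproteins
#: carry 1-3 sites and the mean (~3.1) puts ~5,750 sites on the default
#: 1,847 phosphoproteins, the scale of the emulated study.
DEFAULT_SITES_PER_PROTEIN = {
    1: 0.38, 2: 0.21, 3: 0.146, 4: 0.03, 5: 0.03,
    6: 0.04, 7: 0.05, 8: 0.05, 9: 0.035, 10: 0.029,
}


class ConfigurationError(ValueError):
    """A SimulationConfig field is invalid."""


class GenerationError(RuntimeError):
    """Inconsistent inputs passed between generation stages."""


@dataclass
class SimulationConfig:
    """Parameters of the simulated study.  All randomness flows from ``seed``."""

    seed: int = 0
    n_proteins: int = 7528
    n_phosphoproteins: int = 1847
    sites_per_protein_dist: dict[int, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_SITES_PER_PROTEIN))
    n_replicates_per_condition: int = 3
    conditions: tuple[str, ...] = ("control", "acute", "chronic")
    baseline_log_abundance_sd: float = 1.5
    #: per-channel multiplicative noise, sd in log2 units; 0.58 makes the
    #: null chronic-vs-acute differential sd ~0.47, i.e. ~96.5% within +-1
    noise_sd_log2: float = 0.58
    protein_effect_sd_log2: float = 0.25
    acute_effect_sd_log2: float = 0.8
    group_labels: tuple[str, ...] = DEFAULT_GROUPS
    group_effects: dict[str, float] = dc_field(default_factory=dict)
    #: sites per functional group; None scatters groups over a fraction of peptides
    sites_per_group: int | None = None
    frac_sites_grouped: float = 0.30
    frac_sites_in_reference: float = 0.903
    frac_matched_with_kinase: float = 0.066
    n_kinases: int = 408
    n_decoy_reference_sites: int = 5000
    frac_below_localization_threshold: float = 0.05
    frac_multisite_peptides: float = 0.08
    frac_reference_cross_species: float = 0.03
    frac_reference_renamed_accession: float = 0.03
    # map fixture
    map_n_species: int = 20
    map_n_reactions: int = 12
    map_n_phosphosites: int = 8
    map_n_pmids: int = 6
    map_frac_tyr: float = 40.0 / 189.0

    def __post_init__(self) -> None:
        counts = {
            "n_proteins": self.n_proteins,
            "n_phosphoproteins": self.n_phosphoproteins,
            "n_replicates_per_condition": self.n_replicates_per_condition,
            "n_kinases": self.n_kinases,
        }
        for name, v in counts.items():
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigurationError(f"{name} must be a count >= 1, got {v!r}")
        fractions = {
            "frac_sites_in_reference": self.frac_sites_in_reference,
            "frac_matched_with_kinase": self.frac_matched_with_kinase,
            "frac_below_localization_threshold": self.frac_below_localization_threshold,
            "frac_multisite_peptides": self.frac_multisite_peptides,
            "frac_sites_grouped": self.frac_sites_grouped,
            "frac_reference_cross_species": self.frac_reference_cross_species,
            "frac_reference_renamed_accession": self.frac_reference_renamed_accession,
            "map_frac_tyr": self.map_frac_tyr,
        }
        for name, v in fractions.items():
            if not (0.0 <= float(v) <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v!r}")
        if self.n_phosphoproteins > self.n_proteins:
            raise ConfigurationError("n_phosphoproteins cannot exceed n_proteins")
        if len(self.conditions) < 2:
            raise ConfigurationError("need at least 2 conditions")
        dist = self.sites_per_protein_dist
        if not dist or any(k < 1 or k > 10 for k in dist) or any(p < 0 for p in dist.values()):
            raise ConfigurationError("sites_per_protein_dist must be over 1..10 with p >= 0")
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise ConfigurationError("sites_per_protein_dist probabilities must sum to 1")
        for g in self.group_effects:
            if g not in self.group_labels:
                raise ConfigurationError(f"group_effects key {g!r} not in group_labels")
        for name in ("baseline_log_abundance_sd", "noise_sd_log2",
                     "protein_effect_sd_log2", "acute_effect_sd_log2"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @property
    def sample_columns(self) -> list[str]:
        return [f"{c}_{r + 1}" for c in self.conditions
                for r in range(self.n_replicates_per_condition)]

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator per operation, all derived from ``seed``."""
        return np.random.default_rng([int(self.seed) & 0x7FFFFFFF, stream])


def _protein_ids(config: SimulationConfig) -> list[str]:
    width = len(str(config.n_proteins))
    return [f"P{i:0{width}d}" for i in range(1, config.n_proteins + 1)]


def generate_protein_quant(config: SimulationConfig) -> pd.DataFrame:
    """Protein-level S/N matrix: one row per protein, columns = samples.

    value = 2^(baseline + condition effect + channel noise), a
    log-normal draw, so rows are strictly positive (no all-zero rows).
    The control condition has no protein-level effect; acute/chronic
    expression shifts are drawn per protein.
    """
    rng = config.rng(1)
    ids = _protein_ids(config)
    n = config.n_proteins
    baseline = 7.0 + rng.normal(0.0, config.baseline_log_abundance_sd, size=n)
    effects = np.zeros((n, len(config.conditions)))
    if config.protein_effect_sd_log2 > 0:
        effects[:, 1:] = rng.normal(0.0, config.protein_effect_sd_log2,
                                    size=(n, len(config.conditions) - 1))
    cols = config.sample_columns
    noise = (rng.normal(0.0, config.noise_sd_log2, size=(n, len(cols)))
             if config.noise_sd_log2 > 0 else np.zeros((n, len(cols))))
    values = np.empty((n, len(cols)))
    for j, col in enumerate(cols):
        ci = config.conditions.index(col.rpartition("_")[0])
        values[:, j] = 2.0 ** (baseline + effects[:, ci] + noise[:, j])
    df = pd.DataFrame(values, index=pd.Index(ids, name="analyte_id"), columns=cols)
    logger.info("generate_protein_quant: %d proteins x %d samples", n, len(cols))
    return df


def _random_flank(rng: np.random.Generator, residue: str) -> str:
    aa = rng.choice(AMINO_ACIDS, size=15)
    aa[7] = residue.lower()
    return "".join(aa)


def generate_phospho_quant(
    config: SimulationConfig, proteins: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Phosphopeptide S/N plus site records and the ground-truth table.

    Each peptide's S/N is the parent protein's realized S/N times a
    site-specific condition multiplier (acute effect alpha, plus the
    planted group shift delta on chronic channels) times channel noise;
    protein normalization downstream therefore cancels protein
    expression changes exactly up to measurement noise.  A configured
    minority of peptides carries two sites (one quant row for both), and
    a configured fraction of localization scores falls at or below the
    confidence threshold of 13.

    Returns ``(quant, sites, truth)``: quant indexed by peptide_id over
    sample columns; sites with peptide_id / accession / gene / organism
    / residue / position / ascore / flank (multi-site fields
    slash-joined); truth with one row per individual site.
    """
    rng = config.rng(2)
    ids = _protein_ids(config)
    missing = [i for i in ids if i not in proteins.index]
    if missing:
        raise GenerationError(f"protein table missing parent accessions, e.g. {missing[:3]}")
    phospho_prots = sorted(rng.choice(ids, size=config.n_phosphoproteins, replace=False))

    ks = np.array(sorted(config.sites_per_protein_dist))
    ps = np.array([config.sites_per_protein_dist[k] for k in ks], dtype=float)
    n_sites_per = rng.choice(ks, size=len(phospho_prots), p=ps)

    # build peptides: list of (accession, gene, [(res, pos, flank)...], below_flag)
    # sites-per-protein counts describe the confidently localized sites;
    # below-threshold peptides are emitted on top so the post-filter scale
    # matches the configured one
    f_below = config.frac_below_localization_threshold
    extra_rate = f_below / (1.0 - f_below) if f_below < 1.0 else 0.0
    peptides = []
    for acc, n_sites in zip(phospho_prots, n_sites_per):
        gene = "G" + acc[1:]
        n_extra = int(rng.binomial(int(n_sites), extra_rate)) if extra_rate else 0
        n_total = int(n_sites) + n_extra
        length = min(2000, 100 + n_total * int(rng.integers(40, 180)))
        positions = np.sort(rng.choice(np.arange(1, length + 1), size=n_total,
                                       replace=False))
        residues = rng.choice(["S", "T", "Y"], size=n_total, p=[0.80, 0.165, 0.035])
        sites = [(str(r), int(p), _random_flank(rng, str(r)))
                 for r, p in zip(residues, positions)]
        below_idx = set(rng.choice(n_total, size=n_extra, replace=False)) if n_extra else set()
        kept_sites = [s for i, s in enumerate(sites) if i not in below_idx]
        low_sites = [s for i, s in enumerate(sites) if i in below_idx]
        i = 0
        while i < len(kept_sites):
            if (len(kept_sites) - i >= 2
                    and rng.random() < config.frac_multisite_peptides):
                peptides.append((acc, gene, kept_sites[i:i + 2], False))
                i += 2
            else:
                peptides.append((acc, gene, kept_sites[i:i + 1], False))
                i += 1
        for s in low_sites:
            peptides.append((acc, gene, [s], True))

    order = rng.permutation(len(peptides))
    # group assignment at the peptide level (all sites of a peptide share quant)
    groups = ["unclassified"] * len(peptides)
    if config.sites_per_group is not None:
        want = {g: config.sites_per_group for g in config.group_labels}
        for idx in order:
            if peptides[idx][3]:  # below-threshold peptides stay unclassified
                continue
            for g in config.group_labels:
                if want[g] > 0:
                    groups[idx] = g
                    want[g] -= len(peptides[idx][2])
                    break
        short = {g: w for g, w in want.items() if w > 0}
        if short:
            logger.warning("generate_phospho_quant: groups short of target sizes: %s", short)
    else:
        for idx in order:
            if rng.random() < config.frac_sites_grouped:
                groups[idx] = str(rng.choice(config.group_labels))

    cols = config.sample_columns
    cond_of = [c.rpartition("_")[0] for c in cols]
    quant = np.empty((len(peptides), len(cols)))
    site_rows, truth_rows = [], []
    for i, ((acc, gene, sites, below), group) in enumerate(zip(peptides, groups)):
        alpha = rng.normal(0.0, config.acute_effect_sd_log2) if config.acute_effect_sd_log2 else 0.0
        delta = float(config.group_effects.get(group, 0.0))
        mult = {config.conditions[0]: 0.0}
        mult[config.conditions[1]] = alpha
        if len(config.conditions) > 2:
            mult[config.conditions[2]] = alpha + delta
        noise = (rng.normal(0.0, config.noise_sd_log2, size=len(cols))
                 if config.noise_sd_log2 > 0 else np.zeros(len(cols)))
        parent = proteins.loc[acc, cols].to_numpy(dtype=float)
        quant[i] = parent * 2.0 ** (np.array([mult.get(c, 0.0) for c in cond_of]) + noise)
        ascore = float(rng.uniform(2.0, 13.0)) if below else float(rng.uniform(13.5, 60.0))
        pep_id = f"pep{i + 1:05d}"
        site_rows.append({
            "peptide_id": pep_id, "accession": acc, "gene": gene, "organism": "mouse",
            "residue": "/".join(s[0] for s in sites),
            "position": "/".join(str(s[1]) for s in sites),
            "ascore": ascore,
            "flank": "/".join(s[2] for s in sites),
        })
        for res, pos, flank in sites:
            truth_rows.append({
                "site_key": matching.site_key(acc, res, pos),
                "peptide_id": pep_id, "accession": acc, "gene": gene,
                "residue": res, "position": pos, "flank": flank,
                "group": group, "acute_effect": alpha, "differential": delta,
                "ascore": ascore, "below_threshold": below,
            })

    pep_ids = [r["peptide_id"] for r in site_rows]
    quant_df = pd.DataFrame(quant, index=pd.Index(pep_ids, name="analyte_id"), columns=cols)
    sites_df = pd.DataFrame(site_rows)
    truth_df = pd.DataFrame(truth_rows)
    logger.info("generate_phospho_quant: %d peptides carrying %d sites on %d proteins",
                len(sites_df), len(truth_df), len(phospho_prots))
    return quant_df, sites_df, truth_df


def _zipf_weights(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def generate_reference_db(
    config: SimulationConfig, sites: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Reference site dataset + kinase-substrate dataset for the MS sites.

    Each individual MS site enters the reference with probability
    ``frac_sites_in_reference``.  Small configured fractions of the
    in-reference rows are recorded under a human/rat accession (only
    reachable through the sequence-window tier) or under a renamed
    accession with the same gene (reachable through the gene tier);
    decoy sites absent from the MS data pad the database.  In-reference
    sites gain >=1 kinase with probability ``frac_matched_with_kinase``;
    kinase usage is Zipf-weighted so few kinases dominate, as in curated
    databases.  Returns ``(reference, kinase_substrate, membership)``
    where membership records per-site truth (in_reference, kinases).
    """
    rng = config.rng(3)
    if "is_multisite" not in sites.columns:
        sites = explode_multisite(sites)
    kin_labels = [f"KIN{i:04d}" for i in range(1, config.n_kinases + 1)]
    kin_w = _zipf_weights(config.n_kinases)

    ref_rows, ks_rows, member_rows = [], [], []
    for rec in sites.to_dict("records"):
        acc, gene = str(rec["accession"]), str(rec["gene"])
        res, pos = str(rec["residue"]), int(rec["position"])
        flank = str(rec.get("flank", ""))
        in_ref = rng.random() < config.frac_sites_in_reference
        kinases: list[str] = []
        if in_ref:
            organism = "mouse"
            ref_acc = acc
            u = rng.random()
            if u < config.frac_reference_cross_species:
                organism = str(rng.choice(["human", "rat"]))
                ref_acc = "H" + acc
            elif u < (config.frac_reference_cross_species
                      + config.frac_reference_renamed_accession):
                ref_acc = "ALT" + acc
            ref_rows.append({
                "gene": gene, "protein": gene.capitalize(), "accession": ref_acc,
                "organism": organism, "residue": res, "position": pos, "flank": flank,
            })
            if rng.random() < config.frac_matched_with_kinase:
                n_kin = 2 if rng.random() < 0.1 else 1
                kinases = sorted(set(
                    str(k) for k in rng.choice(kin_labels, size=n_kin, p=kin_w)))
                for kin in kinases:
                    ks_rows.append({
                        "kinase": kin, "kinase_organism": "mouse",
                        "substrate": gene.capitalize(), "substrate_accession": ref_acc,
                        "substrate_gene": gene, "substrate_organism": organism,
                        "substrate_residue": res, "substrate_position": pos,
                        "flank": flank,
                    })
        member_rows.append({
            "site_key": matching.site_key(acc, res, pos),
            "in_reference": in_ref, "kinases": ";".join(kinases),
        })

    for i in range(config.n_decoy_reference_sites):
        res = str(rng.choice(["S", "T", "Y"], p=[0.80, 0.165, 0.035]))
        pos = int(rng.integers(1, 2000))
        row = {
            "gene": f"DG{i:05d}", "protein": f"Dg{i:05d}", "accession": f"D{i:05d}",
            "organism": str(rng.choice(["mouse", "human", "rat"], p=[0.5, 0.35, 0.15])),
            "residue": res, "position": pos, "flank": _random_flank(rng, res),
        }
        ref_rows.append(row)
        if rng.random() < config.frac_matched_with_kinase:
            kin = str(rng.choice(kin_labels))  # uniform: decoys spread kinase coverage
            ks_rows.append({
                "kinase": kin, "kinase_organism": "mouse", "substrate": row["protein"],
                "substrate_accession": row["accession"], "substrate_gene": row["gene"],
                "substrate_organism": row["organism"], "substrate_residue": res,
                "substrate_position": pos, "flank": row["flank"],
            })

    ref_df = pd.DataFrame(
        ref_rows, columns=["gene", "protein", "accession", "organism",
                           "residue", "position", "flank"])
    ks_df = pd.DataFrame(
        ks_rows, columns=["kinase", "kinase_organism", "substrate",
                          "substrate_accession", "substrate_gene",
                          "substrate_organism", "substrate_residue",
                          "substrate_position", "flank"])
    member_df = pd.DataFrame(member_rows)
    logger.info("generate_reference_db: %d reference rows (%d from MS sites), %d kinase rows",
                len(ref_df), int(member_df["in_reference"].sum()), len(ks_df))
    return ref_df, ks_df, member_df


def generate_map_fixture(config: SimulationConfig, path) -> str:
    """Write a miniature CellDesigner-SBML map with configured counts.

    ``map_n_species`` species, ``map_n_reactions`` reactions whose notes
    carry ``map_n_pmids`` distinct PMIDs (round-robin over reactions, so
    every PMID appears), and ``map_n_phosphosites`` phosphorylated
    modification residues spread over protein-backed species with a
    ``map_frac_tyr`` share of tyrosines.  Parseable by
    :mod:`phosphodiff.mapio`; round-trips to exactly these counts.
    """
    rng = config.rng(4)
    if config.map_n_pmids > 0 and config.map_n_reactions < 1:
        raise ConfigurationError("map PMIDs require at least one reaction")
    n_sp, n_rx = config.map_n_species, config.map_n_reactions
    n_sites, n_pmids = config.map_n_phosphosites, config.map_n_pmids

    n_tyr = int(round(n_sites * config.map_frac_tyr))
    residues = ["Y"] * n_tyr + [str(rng.choice(["S", "T"], p=[0.75, 0.25]))
                                for _ in range(n_sites - n_tyr)]
    rng.shuffle(residues)
    positions = rng.choice(np.arange(1, 1200), size=n_sites, replace=False) if n_sites else []

    # spread sites over protein-backed species, <=4 per protein
    n_prot = max(1, -(-n_sites // 4)) if n_sites else 0
    n_prot = min(n_prot, n_sp) or (1 if n_sites else 0)
    if n_sites and n_prot == 0:
        raise ConfigurationError("map phosphosites require at least one species")
    prot_sites: list[list[tuple[str, int]]] = [[] for _ in range(n_prot)]
    for i in range(n_sites):
        prot_sites[i % n_prot].append((residues[i], int(positions[i])))

    cd = "celldesigner"
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<sbml xmlns="http://www.sbml.org/sbml/level2/version4" '
        f'xmlns:{cd}="http://www.sbml.org/2001/ns/celldesigner" level="2" version="4">',
        '<model id="synthetic_map">',
        "<annotation>",
        f"<{cd}:extension>",
        f"<{cd}:listOfProteins>",
    ]
    for p, psites in enumerate(prot_sites):
        lines.append(f'<{cd}:protein id="pr{p + 1}" name="MAPPROT{p + 1}">')
        lines.append(f"<{cd}:listOfModificationResidues>")
        for j, (res, pos) in enumerate(psites):
            lines.append(
                f'<{cd}:modificationResidue id="rs{p + 1}_{j + 1}" name="{res}{pos}"/>')
        lines.append(f"</{cd}:listOfModificationResidues>")
        lines.append(f"</{cd}:protein>")
    lines += [f"</{cd}:listOfProteins>", f"</{cd}:extension>", "</annotation>",
              '<listOfCompartments><compartment id="cytosol"/></listOfCompartments>',
              "<listOfSpecies>"]
    for s in range(n_sp):
        sid = f"s{s + 1}"
        if s < n_prot:
            lines.append(f'<species id="{sid}" name="MAPPROT{s + 1}" compartment="cytosol">')
            lines.append(f"<annotation><{cd}:extension><{cd}:speciesIdentity>")
            lines.append(f"<{cd}:class>PROTEIN</{cd}:class>")
            lines.append(f"<{cd}:proteinReference>pr{s + 1}</{cd}:proteinReference>")
            lines.append(f"<{cd}:state><{cd}:listOfModifications>")
            for j in range(len(prot_sites[s])):
                lines.append(
                    f'<{cd}:modification residue="rs{s + 1}_{j + 1}" state="phosphorylated"/>')
            lines.append(f"</{cd}:listOfModifications></{cd}:state>")
            lines.append(f"</{cd}:speciesIdentity></{cd}:extension></annotation>")
            lines.append("</species>")
        else:
            lines.append(f'<species id="{sid}" name="SP{s + 1}" compartment="cytosol"/>')
    lines.append("</listOfSpecies>")
    lines.append("<listOfReactions>")
    pmids = [10000000 + int(x) for x in rng.choice(np.arange(1, 9 * 10**6), size=n_pmids,
                                                   replace=False)] if n_pmids else []
    rx_pmids: list[list[int]] = [[] for _ in range(n_rx)]
    for i, pm in enumerate(pmids):
        rx_pmids[i % n_rx].append(pm)
    for r in range(n_rx):
        a = int(rng.integers(1, n_sp + 1))
        b = int(rng.integers(1, n_sp + 1))
        note = " ".join(f"PMID: {pm}" for pm in rx_pmids[r])
        lines.append(f'<reaction id="re{r + 1}">')
        if note:
            lines.append(f'<notes><body xmlns="http://www.w3.org/1999/xhtml">{note}</body></notes>')
        lines.append(f'<listOfReactants><speciesReference species="s{a}"/></listOfReactants>')
        lines.append(f'<listOfProducts><speciesReference species="s{b}"/></listOfProducts>')
        lines.append("</reaction>")
    lines += ["</listOfReactions>", "</model>", "</sbml>"]
    text = "\n".join(lines) + "\n"
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(text)
    return str(path)


# --- file emission ---------------------------------------------------------

REFERENCE_PREAMBLE = (
    "Synthetic phosphorylation-site dataset (generated fixture)\n"
    "For pipeline testing only; column dialect mirrors curated site databases\n"
    "\n"
)
KS_PREAMBLE = (
    "Synthetic kinase-substrate dataset (generated fixture)\n"
    "For pipeline testing only\n"
    "\n"
)


def reference_to_dialect(ref: pd.DataFrame) -> pd.DataFrame:
    """Convert an internal reference-site table to the TSV dialect columns."""
    return pd.DataFrame({
        "GENE": ref["gene"], "PROTEIN": ref["protein"], "ACC_ID": ref["accession"],
        "ORGANISM": ref["organism"],
        "MOD_RSD": [f"{r}{int(p)}-p" for r, p in zip(ref["residue"], ref["position"])],
        "SITE_+/-7_AA": ref["flank"],
    })


def ks_to_dialect(ks: pd.DataFrame) -> pd.DataFrame:
    """Convert an internal kinase-substrate table to the TSV dialect columns."""
    return pd.DataFrame({
        "KINASE": ks["kinase"], "KIN_ORGANISM": ks["kinase_organism"],
        "SUBSTRATE": ks["substrate"], "SUB_ACC_ID": ks["substrate_accession"],
        "SUB_GENE": ks["substrate_gene"], "SUB_ORGANISM": ks["substrate_organism"],
        "SUB_MOD_RSD": [f"{r}{int(p)}" for r, p in
                        zip(ks["substrate_residue"], ks["substrate_position"])],
        "SITE_+/-7_AA": ks["flank"],
    })


def group_color_table(config: SimulationConfig) -> dict[str, str]:
    return {g: GROUP_PALETTE[i % len(GROUP_PALETTE)]
            for i, g in enumerate(config.group_labels)}


def simulate_all(config: SimulationConfig, outdir) -> dict[str, str]:
    """Generate and write every pipeline input; returns a path map.

    Files: protein_quant.tsv, phospho_quant.tsv, reference_sites.tsv,
    kinase_substrates.tsv, groups.tsv, terms.gmt, map.sbml.xml,
    truth.tsv.  Identical config + seed reproduces all files
    byte-identically.
    """
    os.makedirs(outdir, exist_ok=True)
    proteins = generate_protein_quant(config)
    phospho, sites, truth = generate_phospho_quant(config, proteins)
    ref, ks, member = generate_reference_db(config, sites)
    truth = truth.merge(member, on="site_key", how="left")

    paths = {k: os.path.join(outdir, v) for k, v in {
        "protein_quant": "protein_quant.tsv", "phospho_quant": "phospho_quant.tsv",
        "reference_sites": "reference_sites.tsv", "kinase_substrates": "kinase_substrates.tsv",
        "groups": "groups.tsv", "terms": "terms.gmt", "map": "map.sbml.xml",
        "truth": "truth.tsv",
    }.items()}

    proteins.round(4).to_csv(paths["protein_quant"], sep="\t")
    pq = sites.merge(phospho.round(4), left_on="peptide_id", right_index=True)
    pq.to_csv(paths["phospho_quant"], sep="\t", index=False)

    with open(paths["reference_sites"], "wt", encoding="utf-8") as fh:
        fh.write(REFERENCE_PREAMBLE)
        reference_to_dialect(ref).to_csv(fh, sep="\t", index=False)
    with open(paths["kinase_substrates"], "wt", encoding="utf-8") as fh:
        fh.write(KS_PREAMBLE)
        ks_to_dialect(ks).to_csv(fh, sep="\t", index=False)

    colors = group_color_table(config)
    grp = truth[truth["group"] != "unclassified"]
    pd.DataFrame({
        "key": grp["site_key"], "level": "site", "group": grp["group"],
        "color": [colors[g] for g in grp["group"]],
    }).to_csv(paths["groups"], sep="\t", index=False)

    rng = config.rng(5)
    with open(paths["terms"], "wt", encoding="utf-8") as fh:
        for g in config.group_labels:
            members = sorted(set(grp.loc[grp["group"] == g, "accession"]))
            if members:
                fh.write("\t".join([g, "functional module"] + members) + "\n")
        all_accs = sorted(set(truth["accession"]))
        for i in range(5):  # decoy terms: random protein sets
            members = sorted(rng.choice(all_accs, size=min(30, len(all_accs)), replace=False))
            fh.write("\t".join([f"random_term_{i + 1}", "decoy"] + list(members)) + "\n")

    generate_map_fixture(config, paths["map"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    logger.info("simulate_all: wrote %d files to %s", len(paths), outdir)
    return paths


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain dict (e.g. parsed TOML)."""
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown simulation config fields: {sorted(unknown)}")
    d = dict(d)
    for tup_field in ("conditions", "group_labels"):
        if tup_field in d:
            d[tup_field] = tuple(d[tup_field])
    if "sites_per_protein_dist" in d:
        d["sites_per_protein_dist"] = {int(k): float(v)
                                       for k, v in d["sites_per_protein_dist"].items()}
    return SimulationConfig(**d)
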