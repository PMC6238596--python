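"""End-to-end orchestration: quant -> match -> group stats -> network.

``run_pipeline`` sequences the full analysis from TSV inputs to stage
outputs plus a reproducibility manifest (config snapshot, input
checksums, per-stage row counts, version, seed, timestamps).  Any stage
failure aborts with the stage name; the partial manifest is still
written.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from . import groupstats, mapio, matching, network, quant

logger = logging.getLogger(__name__)

META_COLUMNS = ["peptide_id", "accession", "gene", "organism", "residue",
                "position", "ascore", "flank"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Declarative description of one analysis run."""

    protein_quant: str
    phospho_quant: str
    reference_sites: str
    kinase_substrates: str
    outdir: str
    groups: str | None = None
    terms: str | None = None
    map_files: list[str] = field(default_factory=list)
    conditions: tuple[str, str, str] = quant.CONDITIONS
    localization_threshold: float = quant.LOCALIZATION_THRESHOLD
    outlier_cutoff: float = groupstats.DEFAULT_OUTLIER_CUTOFF
    outlier_field: str = "differential"
    ks_mode: str = "asymptotic"
    n_perm: int = 999
    min_group_size: int = groupstats.DEFAULT_MIN_GROUP_SIZE
    bh_alpha: float = 0.05
    ms_organism: str = "mouse"
    seed: int = 0

    def validate(self) -> None:
        for name in ("localization_threshold", "outlier_cutoff", "bh_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.conditions) != 3:
            raise ValueError(f"need exactly 3 condition labels, got {self.conditions}")
        if self.ks_mode not in ("asymptotic", "permutation"):
            raise ValueError(f"unknown ks_mode {self.ks_mode!r}")
        required = ["protein_quant", "phospho_quant", "reference_sites", "kinase_substrates"]
        optional = ["groups", "terms"]
        for name in required + optional:
            path = getattr(self, name)
            if name in required and path is None:
                raise ValueError(f"config is missing required input {name!r}")
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"{name}: no such file {path!r}")
        for p in self.map_files:
            if not os.path.exists(p):
                raise FileNotFoundError(f"map file not found: {p!r}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def read_phospho_table(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a phospho quant TSV into site metadata and the S/N matrix."""
    df = pd.read_csv(path, sep="\t", dtype={"position": str, "residue": str})
    meta_cols = [c for c in META_COLUMNS if c in df.columns]
    for col in ("peptide_id", "accession", "residue", "position"):
        if col not in df.columns:
            raise ValueError(f"{path}: phospho table missing column {col!r}")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    meta = df[meta_cols].copy()
    m = df.set_index("peptide_id")[sample_cols].astype(float)
    m.index.name = "analyte_id"
    return meta, m


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Stages run in order quant -> match -> group_stats -> network_export;
    all outputs and ``manifest.json`` are written under
    ``config.outdir``.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "inputs": {},
        "stages": {},
        "notes": [
            "channel layout: simulated <condition>_<replicate> design; the plex-to-"
            "condition mapping of the emulated study is not public and is an assumption",
        ],
        "started_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    for name in ("protein_quant", "phospho_quant", "reference_sites",
                 "kinase_substrates", "groups", "terms"):
        path = getattr(config, name)
        if path:
            manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}
    for p in config.map_files:
        manifest["inputs"].setdefault("maps", []).append({"path": str(p), "sha256": _sha256(p)})

    out = lambda fname: os.path.join(config.outdir, fname)  # noqa: E731
    stage = "quant"
    try:
        protein_raw = quant.read_quant_tsv(config.protein_quant)
        meta, phospho_raw = read_phospho_table(config.phospho_quant)
        kept_meta, discarded = quant.localization_filter(meta, config.localization_threshold)
        protein_rel = quant.relative_abundance(protein_raw)
        phospho_rel = quant.relative_abundance(phospho_raw.loc[kept_meta["peptide_id"]])
        pep2prot = dict(zip(kept_meta["peptide_id"], kept_meta["accession"]))
        normalized, flags = quant.normalize_to_protein(phospho_rel, protein_rel, pep2prot)
        collapsed = quant.condition_collapse(normalized)
        pep_diff = quant.compute_differentials(collapsed, config.conditions)

        exploded = matching.explode_multisite(kept_meta)
        exploded["site_key"] = [matching.site_key(a, r, p) for a, r, p in
                                zip(exploded["accession"], exploded["residue"],
                                    exploded["position"])]
        site_diff = pep_diff.loc[exploded["peptide_id"]].set_axis(
            pd.Index(exploded["site_key"].tolist(), name="site_key"))
        site_diff = site_diff[~site_diff.index.duplicated()]
        site_diff.to_csv(out("site_differentials.tsv"), sep="\t", index_label="site_key")
        manifest["stages"]["quant"] = {
            "peptides_in": int(len(meta)),
            "peptides_kept": int(len(kept_meta)),
            "peptides_filtered": int(len(discarded)),
            "proteins_quantified": int(len(protein_rel)),
            "peptides_unnormalized": int((flags == "unnormalized").sum()),
            "sites_after_explode": int(len(exploded)),
            "sites_with_contrasts": int(site_diff["differential"].notna().sum()),
        }

        stage = "match"
        reference = matching.read_reference_sites(config.reference_sites)
        ks_table = matching.read_kinase_substrates(config.kinase_substrates)
        policy = matching.MatchPolicy(ms_organism=config.ms_organism)
        report = matching.match_sites(exploded, reference, policy)
        annotated, kin_summary = matching.annotate_kinases(report, ks_table)
        matching.write_match_report(report, out("match_report.tsv"), out("match_summary.json"))
        annotated.to_csv(out("annotated_sites.tsv"), sep="\t", index=False)
        spp = matching.sites_per_protein_summary(exploded)
        manifest["stages"]["match"] = {
            "sites_in": report.n_total,
            "sites_matched": report.n_matched,
            "sites_unmatched": report.n_unmatched,
            "matched_fraction": report.matched_fraction,
            "tier_counts": {str(k): v for k, v in sorted(report.tier_counts.items())},
            "fraction_proteins_1_to_3_sites": spp["fraction_1_to_3"],
            **kin_summary,
        }

        stage = "group_stats"
        diffs = site_diff["differential"] if config.outlier_field == "differential" \
            else site_diff[config.outlier_field]
        outliers = groupstats.select_outliers(site_diff, config.outlier_cutoff,
                                              config.outlier_field)
        pd.DataFrame({
            "site_key": outliers.keys,
            "direction": ["up"] * len(outliers.up) + ["down"] * len(outliers.down),
        }).to_csv(out("outliers.tsv"), sep="\t", index=False)
        stats_block = {
            "outliers_up": len(outliers.up),
            "outliers_down": len(outliers.down),
            "fraction_inside_cutoff": outliers.fraction_inside,
        }
        colors: dict[str, str] = {}
        if config.groups:
            gtable = groupstats.read_group_table(config.groups)
            if "color" in gtable.columns:
                colors = dict(zip(gtable["group"], gtable["color"]))
            assignments = groupstats.assign_groups(list(site_diff.index), gtable)
            scan = groupstats.group_ks_scan(
                diffs, assignments, mode=config.ks_mode, n_perm=config.n_perm,
                seed=config.seed, min_size=config.min_group_size)
            scan.to_csv(out("group_ks.tsv"), sep="\t", index=False)
            stats_block["groups_tested"] = int(len(scan))
            stats_block["groups_significant"] = int((scan["q_value"] < config.bh_alpha).sum())
        else:
            assignments = pd.Series("unclassified", index=site_diff.index)
        kin_scan = groupstats.kinase_ks_scan(
            diffs, annotated, mode=config.ks_mode, n_perm=config.n_perm,
            seed=config.seed + 1, min_size=config.min_group_size)
        kin_scan.to_csv(out("kinase_ks.tsv"), sep="\t", index=False)
        stats_block["kinases_tested"] = int(len(kin_scan))
        if config.terms:
            terms = groupstats.read_gmt(config.terms)
            background = sorted({k.split("|")[0] for k in site_diff.index})
            foreground = sorted({k.split("|")[0] for k in outliers.keys})
            enrich = groupstats.hypergeometric_enrichment(foreground, background, terms)
            enrich.to_csv(out("enrichment.tsv"), sep="\t", index=False)
            stats_block["terms_tested"] = int(len(enrich))
            stats_block["terms_significant"] = int((enrich["q_value"] < config.bh_alpha).sum())
        manifest["stages"]["group_stats"] = stats_block

        stage = "map_audit"
        if config.map_files:
            maps = [mapio.parse_celldesigner_sbml(p) for p in config.map_files]
            summary = mapio.map_summary(maps)
            conc = mapio.map_concordance(maps, reference)
            with open(out("map_summary.json"), "wt", encoding="utf-8") as fh:
                json.dump({"summary": summary.as_dict(),
                           "concordance": {k: v for k, v in conc.items() if k != "missing"}},
                          fh, indent=2, sort_keys=True)
                fh.write("\n")
            manifest["stages"]["map_audit"] = {
                "n_species": summary.n_species, "n_reactions": summary.n_reactions,
                "n_phosphosites": summary.n_phosphosites,
                "concordance": conc["concordance"],
            }

        stage = "network_export"
        genes = dict(zip(exploded["accession"], exploded.get("gene", exploded["accession"])))
        net = network.build_network(annotated, site_diff, assignments, colors, genes)
        network.export_sif(net, out("network.sif"))
        network.export_graphml(net, out("network.graphml"))
        network.export_attribute_tables(net, config.outdir)
        manifest["stages"]["network_export"] = {
            "n_nodes": net.number_of_nodes(), "n_edges": net.number_of_edges(),
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest(manifest, out("manifest.json"))
        raise PipelineError(stage, str(exc)) from exc

    manifest["finished_at"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    _write_manifest(manifest, out("manifest.json"))
    logger.info("run_pipeline: complete; outputs in %s", config.outdir)
    return manifest


def _write_manifest(manifest: dict, path: str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def config_from_toml(path, **overrides) -> AnalysisConfig:
    """Load the ``[analysis]`` table of a TOML file into an AnalysisConfig."""
    import tomllib
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    section = doc.get("analysis", doc)
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"{path}: unknown analysis config fields {sorted(unknown)}")
    section = dict(section)
    section.update({k: v for k, v in overrides.items() if v is not None})
    if "conditions" in section:
        section["conditions"] = tuple(section["conditions"])
    return AnalysisConfig(**section)
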