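"""Cross-referencing MS phosphosites with a curated site database.

Matches each MS-observed phosphosite (protein accession, residue,
1-based position) against a PhosphoSitePlus-dialect phosphorylation-site
dataset, then annotates matched sites with kinases from the
kinase-substrate dataset.  Matching is tiered, first hit wins:

  tier 1  (normalized accession, residue, position), same organism
  tier 2  (case-folded gene symbol, residue, position), same organism
  tier 3  exact +/-7 flanking-window string, any organism

Accession normalization strips isoform ("-2") and version (".1")
suffixes; cross-species curation is only reachable through the
sequence-window tier.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

MOD_RSD_RE = re.compile(r"^([STY])(\d+)(?:-p)?$")
_ACC_SUFFIX_RE = re.compile(r"(-\d+|\.\d+)$")

SITE_COLUMNS = ["peptide_id", "accession", "gene", "organism", "residue", "position"]


def normalize_accession(acc: str) -> str:
    """Strip isoform ("-2") and version (".1") suffixes from an accession."""
    return _ACC_SUFFIX_RE.sub("", str(acc).strip())


def site_key(accession: str, residue: str, position: int) -> str:
    return f"{accession}|{residue}{int(position)}"


@dataclass
class MatchPolicy:
    """Which tiers run, and the organism of the MS data."""

    tiers: Sequence[int] = (1, 2, 3)
    ms_organism: str = "mouse"

    def __post_init__(self) -> None:
        bad = [t for t in self.tiers if t not in (1, 2, 3)]
        if bad:
            raise ValueError(f"unknown matching tiers: {bad}")


@dataclass
class MatchReport:
    """Result of the tiered site merge.

    ``matches`` has one row per matched MS site (ms_key, ref_key, tier);
    ``unmatched`` lists the MS keys with no hit in any enabled tier.
    """

    n_total: int
    matches: pd.DataFrame
    unmatched: list[str]
    duplicate_reference_keys: int = 0
    tier_counts: dict[int, int] = field(default_factory=dict)

    @property
    def n_matched(self) -> int:
        return len(self.matches)

    @property
    def n_unmatched(self) -> int:
        return len(self.unmatched)

    @property
    def matched_fraction(self) -> float:
        return self.n_matched / self.n_total if self.n_total else float("nan")

    def summary(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_matched": self.n_matched,
            "n_unmatched": self.n_unmatched,
            "matched_fraction": self.matched_fraction,
            "tier_counts": {str(k): v for k, v in sorted(self.tier_counts.items())},
            "duplicate_reference_keys": self.duplicate_reference_keys,
        }


def explode_multisite(records: pd.DataFrame) -> pd.DataFrame:
    """Expand multi-site phosphopeptide isoforms into one row per site.

    A quantified isoform can carry several phosphorylated residues
    (encoded as slash-separated ``residue``/``position`` fields, e.g.
    ``S/S`` at ``235/236``); each constituent site inherits the
    isoform's quant linkage (``peptide_id``).  Singleton records pass
    through unchanged.
    """
    rows = []
    for rec in records.to_dict("records"):
        residues = str(rec["residue"]).split("/")
        positions = str(rec["position"]).split("/")
        if len(residues) != len(positions):
            raise ValueError(
                f"peptide {rec.get('peptide_id')!r}: {len(residues)} residues but "
                f"{len(positions)} positions"
            )
        flanks = str(rec.get("flank", "")).split("/")
        if len(flanks) != len(residues):
            flanks = [rec.get("flank", "")] * len(residues)
        for res, pos, flank in zip(residues, positions, flanks):
            res = res.strip().upper()
            try:
                ipos = int(pos)
            except ValueError:
                raise ValueError(
                    f"peptide {rec.get('peptide_id')!r}: malformed position {pos!r}"
                ) from None
            if res not in ("S", "T", "Y"):
                raise ValueError(f"peptide {rec.get('peptide_id')!r}: residue {res!r} not in S/T/Y")
            if ipos < 1:
                raise ValueError(f"peptide {rec.get('peptide_id')!r}: position {ipos} < 1")
            new = dict(rec)
            new["residue"] = res
            new["position"] = ipos
            if "flank" in rec:
                new["flank"] = flank
            new["is_multisite"] = len(residues) > 1
            rows.append(new)
    out = pd.DataFrame(rows, columns=list(records.columns) + ["is_multisite"])
    if len(out):
        out["position"] = out["position"].astype(int)
    return out


def _ref_index(ref: pd.DataFrame, keycols: list[str]) -> tuple[dict, int]:
    """First-occurrence lookup for a tier; returns (index, duplicate count)."""
    index: dict = {}
    dups = 0
    for i, key in enumerate(zip(*(ref[c] for c in keycols))):
        if key in index:
            dups += 1
        else:
            index[key] = i
    return index, dups


def match_sites(
    ms: pd.DataFrame, ref: pd.DataFrame, policy: MatchPolicy | None = None
) -> MatchReport:
    """Tiered, first-hit-wins merge of MS sites into the reference dataset.

    ``ms`` needs columns accession/gene/residue/position (organism and
    flank optional); ``ref`` is a parsed reference-site table (see
    :func:`read_reference_sites`).  Every MS site appears exactly once in
    the report, either matched (with the winning tier) or unmatched.
    """
    policy = policy or MatchPolicy()
    ms = ms.reset_index(drop=True)
    ref = ref.reset_index(drop=True)

    n_dups = 0
    tier_lookups: dict[int, dict] = {}
    if len(ref):
        r_acc = ref["accession"].map(normalize_accession)
        r_res = ref["residue"].str.upper()
        r_pos = ref["position"].astype(int)
        r_org = ref["organism"].str.casefold()
        if 1 in policy.tiers:
            idx, d = _ref_index(
                pd.DataFrame({"a": r_acc, "r": r_res, "p": r_pos, "o": r_org}),
                ["a", "r", "p", "o"],
            )
            tier_lookups[1] = idx
            n_dups += d
        if 2 in policy.tiers:
            idx, d = _ref_index(
                pd.DataFrame(
                    {"g": ref["gene"].astype(str).str.casefold(), "r": r_res, "p": r_pos, "o": r_org}
                ),
                ["g", "r", "p", "o"],
            )
            tier_lookups[2] = idx
            n_dups += d
        if 3 in policy.tiers and "flank" in ref.columns:
            flanks = ref["flank"].astype(str)
            idx, d = _ref_index(pd.DataFrame({"f": flanks}), ["f"])
            idx.pop(("",), None)
            idx.pop(("nan",), None)
            tier_lookups[3] = idx
            n_dups += d
    if n_dups:
        logger.info("match_sites: %d duplicate reference keys (first occurrence used)", n_dups)

    org = policy.ms_organism.casefold()
    matches = []
    unmatched = []
    tier_counts: dict[int, int] = {}
    for rec in ms.to_dict("records"):
        acc = normalize_accession(rec["accession"])
        res = str(rec["residue"]).upper()
        pos = int(rec["position"])
        ms_org = str(rec.get("organism", policy.ms_organism)).casefold()
        key = site_key(rec["accession"], res, pos)
        hit = None
        for tier in policy.tiers:
            lookup = tier_lookups.get(tier)
            if not lookup:
                continue
            if tier == 1:
                probe = (acc, res, pos, ms_org if ms_org else org)
            elif tier == 2:
                probe = (str(rec.get("gene", "")).casefold(), res, pos, ms_org)
            else:
                flank = str(rec.get("flank", "") or "")
                if not flank:
                    continue
                probe = (flank,)
            i = lookup.get(probe)
            if i is not None:
                ref_rec = ref.iloc[i]
                hit = (key, site_key(ref_rec["accession"], ref_rec["residue"], ref_rec["position"]), tier)
                break
        if hit is None:
            unmatched.append(key)
        else:
            matches.append(hit)
            tier_counts[hit[2]] = tier_counts.get(hit[2], 0) + 1

    report = MatchReport(
        n_total=len(ms),
        matches=pd.DataFrame(matches, columns=["ms_key", "ref_key", "tier"]),
        unmatched=unmatched,
        duplicate_reference_keys=n_dups,
        tier_counts=tier_counts,
    )
    logger.info(
        "match_sites: %d/%d matched (%.1f%%), %d unmatched",
        report.n_matched, report.n_total, 100 * report.matched_fraction if report.n_total else 0.0,
        report.n_unmatched,
    )
    return report


def annotate_kinases(report: MatchReport, ks: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Attach kinase sets from the kinase-substrate dataset to matched sites.

    A kinase annotates a site when its substrate key (accession,
    residue, position) equals the site's matched reference key.  Returns
    the per-site table (ms_key, ref_key, tier, kinases as a sorted
    semicolon-joined string) and a summary with the distinct kinase
    count, annotated-site count and annotated-protein count.
    """
    by_key: dict[str, set[str]] = {}
    for rec in ks.to_dict("records"):
        key = site_key(
            normalize_accession(rec["substrate_accession"]),
            str(rec["substrate_residue"]).upper(),
            int(rec["substrate_position"]),
        )
        by_key.setdefault(key, set()).add(str(rec["kinase"]))

    annotated = report.matches.copy()
    kin_sets = []
    for ref_key in annotated["ref_key"] if len(annotated) else []:
        acc, respos = ref_key.split("|")
        norm_key = site_key(normalize_accession(acc), respos[0], int(respos[1:]))
        kin_sets.append(by_key.get(norm_key, set()))
    annotated["kinases"] = [";".join(sorted(s)) for s in kin_sets]

    with_kin = annotated[annotated["kinases"] != ""] if len(annotated) else annotated
    distinct = set()
    for s in kin_sets:
        distinct |= s
    proteins = {k.split("|")[0] for k in with_kin["ms_key"]} if len(with_kin) else set()
    summary = {
        "n_kinases": len(distinct),
        "n_annotated_sites": len(with_kin),
        "n_annotated_proteins": len(proteins),
    }
    logger.info(
        "annotate_kinases: %(n_kinases)d kinases on %(n_annotated_sites)d sites "
        "(%(n_annotated_proteins)d proteins)", summary,
    )
    return annotated, summary


def sites_per_protein_summary(sites: pd.DataFrame) -> dict:
    """Per-protein phosphosite counts, histogram, and the 1-3-site fraction."""
    if not len(sites):
        return {"per_protein": {}, "histogram": {}, "fraction_1_to_3": float("nan"),
                "n_proteins": 0, "n_sites": 0}
    uniq = sites.drop_duplicates(subset=["accession", "residue", "position"])
    counts = uniq.groupby("accession").size()
    hist = counts.value_counts().sort_index()
    frac = float((counts <= 3).mean())
    return {
        "per_protein": counts.to_dict(),
        "histogram": {int(k): int(v) for k, v in hist.items()},
        "fraction_1_to_3": frac,
        "n_proteins": int(len(counts)),
        "n_sites": int(len(uniq)),
    }


# --- PhosphoSitePlus-dialect I/O -------------------------------------------

REFERENCE_COLUMNS = {
    "GENE": "gene", "PROTEIN": "protein", "ACC_ID": "accession",
    "ORGANISM": "organism", "MOD_RSD": "mod_rsd", "SITE_+/-7_AA": "flank",
}
KS_COLUMNS = {
    "KINASE": "kinase", "KIN_ORGANISM": "kinase_organism", "SUBSTRATE": "substrate",
    "SUB_ACC_ID": "substrate_accession", "SUB_GENE": "substrate_gene",
    "SUB_ORGANISM": "substrate_organism", "SUB_MOD_RSD": "sub_mod_rsd",
    "SITE_+/-7_AA": "flank",
}


def _read_dialect_tsv(path, colmap: dict, required: list[str]) -> pd.DataFrame:
    """Read a reference-dialect TSV, tolerating a preamble before the header."""
    skip = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            fields = line.rstrip("\n").split("\t")
            if all(c in fields for c in required):
                skip = i
                break
            if i > 5:
                raise ValueError(f"{path}: header row with columns {required} not found in preamble")
    df = pd.read_csv(path, sep="\t", skiprows=skip, dtype=str).fillna("")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df.rename(columns=colmap)


def _parse_mod_rsd(df: pd.DataFrame, col: str, path) -> pd.DataFrame:
    res, pos, bad = [], [], 0
    for v in df[col]:
        m = MOD_RSD_RE.match(str(v).strip())
        if m:
            res.append(m.group(1))
            pos.append(int(m.group(2)))
        else:
            res.append(None)
            pos.append(-1)
            bad += 1
    df = df.assign(residue=res, position=pos)
    if bad:
        logger.warning("%s: %d rows with unparseable modified-residue field dropped", path, bad)
        df = df[df["residue"].notna()]
    df["position"] = df["position"].astype(int)
    return df


def read_reference_sites(path) -> pd.DataFrame:
    """Parse a phosphorylation-site dataset TSV (reference dialect).

    Accepts up to a 3-line preamble before the header; MOD_RSD entries
    like ``S235-p`` are split into residue and 1-based position.
    """
    df = _read_dialect_tsv(path, REFERENCE_COLUMNS, ["ACC_ID", "MOD_RSD"])
    return _parse_mod_rsd(df, "mod_rsd", path)


def read_kinase_substrates(path) -> pd.DataFrame:
    """Parse a kinase-substrate dataset TSV (reference dialect)."""
    df = _read_dialect_tsv(path, KS_COLUMNS, ["KINASE", "SUB_ACC_ID", "SUB_MOD_RSD"])
    df = _parse_mod_rsd(df, "sub_mod_rsd", path)
    return df.rename(columns={"residue": "substrate_residue", "position": "substrate_position"})


def write_match_report(report: MatchReport, tsv_path, json_path=None) -> None:
    """Write per-site match rows as TSV and the count summary as JSON."""
    rows = report.matches.copy()
    un = pd.DataFrame({"ms_key": report.unmatched, "ref_key": "", "tier": ""})
    pd.concat([rows, un], ignore_index=True).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "wt", encoding="utf-8") as fh:
            json.dump(report.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")
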