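"""Isobaric quantitation: relative abundance, localization filtering,
protein normalization and condition contrasts.

The quantitative unit is the analyte (a protein or a phosphopeptide
isoform) measured as reporter-ion signal-to-noise (S/N) across labeled
sample channels.  Channels are named ``<condition>_<replicate>`` (e.g.
``control_1``).  Relative abundance rescales each analyte's S/N row to
sum to 100; phosphopeptide values are then divided by the relative
abundance of the parent protein so that changes in protein expression do
not masquerade as phosphorylation changes.  Contrasts are log2 fold
changes of the stimulated conditions against control, plus the
chronic-vs-acute differential.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default condition order: unstimulated control, bolus short-term ligand
#: stimulation, sustained autocrine ligand expression.
CONDITIONS: tuple[str, str, str] = ("control", "acute", "chronic")

#: Localization-score cutoff: scores strictly greater than this are
#: considered confidently localized (corresponds to P < 0.05).
LOCALIZATION_THRESHOLD: float = 13.0


def design_from_columns(columns: Iterable[str]) -> dict[str, str]:
    """Map ``<condition>_<replicate>`` sample labels to their condition."""
    design = {}
    for col in columns:
        cond, sep, _rep = str(col).rpartition("_")
        if not sep or not cond:
            raise ValueError(f"sample label {col!r} is not of the form <condition>_<replicate>")
        design[col] = cond
    return design


def relative_abundance(m: pd.DataFrame) -> pd.DataFrame:
    """Rescale each analyte's S/N row so that it sums to 100.

    Rows whose sum is 0 carry no quantitative information and are
    dropped (the count is logged).  Negative values are invalid S/N and
    raise a ``ValueError`` naming the offending analyte and sample.
    """
    if m.shape[1] < 1:
        raise ValueError("quant matrix has no sample columns")
    values = m.to_numpy(dtype=float)
    neg = np.argwhere(np.nan_to_num(values, nan=0.0) < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"negative signal-to-noise for analyte {m.index[i]!r} in sample {m.columns[j]!r}"
        )
    row_sums = np.nansum(values, axis=1)
    zero = row_sums == 0
    if zero.any():
        logger.info("relative_abundance: dropped %d zero-sum analyte rows", int(zero.sum()))
    kept = m.loc[~zero]
    out = kept.div(kept.sum(axis=1, skipna=True), axis=0) * 100.0
    return out


def localization_filter(
    sites: pd.DataFrame, threshold: float = LOCALIZATION_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition phosphosite records by localization confidence.

    ``kept`` holds records with ``ascore`` strictly greater than
    *threshold*; everything else (including records with a missing
    score) goes to ``discarded`` with a ``reason`` column.  The
    partition is exhaustive and disjoint.
    """
    if "ascore" not in sites.columns:
        raise ValueError("site table lacks an 'ascore' column")
    score = pd.to_numeric(sites["ascore"], errors="coerce")
    missing = score.isna()
    keep = score > threshold
    kept = sites.loc[keep].copy()
    discarded = sites.loc[~keep].copy()
    discarded["reason"] = np.where(
        missing.loc[~keep], "missing_score", "at_or_below_threshold"
    )
    logger.info(
        "localization_filter: kept %d, discarded %d (threshold %g)",
        len(kept), len(discarded), threshold,
    )
    return kept, discarded


def normalize_to_protein(
    phospho: pd.DataFrame,
    protein: pd.DataFrame,
    site_to_protein: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Divide phosphopeptide relative abundance by the parent protein's.

    Returns the normalized matrix and a per-analyte flag Series:
    ``"normalized"`` when the parent protein was quantified,
    ``"unnormalized"`` when it was not (those rows are carried forward
    with their raw relative abundances).  A protein relative abundance
    of 0 in a sample makes that sample's normalized value missing.
    """
    flags = pd.Series("normalized", index=phospho.index, dtype=object)
    out = phospho.copy().astype(float)
    n_zero = 0
    for pep in phospho.index:
        acc = site_to_protein.get(pep)
        if acc is None or acc not in protein.index:
            flags.loc[pep] = "unnormalized"
            continue
        denom = protein.loc[acc, phospho.columns].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = phospho.loc[pep].to_numpy(dtype=float) / denom
        zero_mask = denom == 0
        if zero_mask.any():
            ratio[zero_mask] = np.nan
            n_zero += int(zero_mask.sum())
        out.loc[pep] = ratio
    if n_zero:
        logger.info("normalize_to_protein: %d sample values set missing (protein S/N of 0)", n_zero)
    n_unnorm = int((flags == "unnormalized").sum())
    if n_unnorm:
        logger.info("normalize_to_protein: %d analytes carried forward unnormalized", n_unnorm)
    return out, flags


def condition_collapse(
    m: pd.DataFrame, design: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Collapse replicate channels to one value per condition.

    The per-condition value is the arithmetic mean over that condition's
    non-missing replicate channels; a condition with no non-missing
    channel for an analyte is missing (logged).
    """
    if design is None:
        design = design_from_columns(m.columns)
    conditions: list[str] = []
    for col in m.columns:
        cond = design[col]
        if cond not in conditions:
            conditions.append(cond)
    collapsed = pd.DataFrame(index=m.index, columns=conditions, dtype=float)
    for cond in conditions:
        cols = [c for c in m.columns if design[c] == cond]
        collapsed[cond] = m[cols].mean(axis=1, skipna=True)
    n_missing = int(collapsed.isna().sum().sum())
    if n_missing:
        logger.info("condition_collapse: %d condition values missing (no usable replicate)", n_missing)
    return collapsed


def compute_differentials(
    collapsed: pd.DataFrame, conditions: Sequence[str] = CONDITIONS
) -> pd.DataFrame:
    """Compute log2 contrasts per analyte from collapsed condition values.

    Columns of the result: ``log2fc_acute`` = log2(acute/control),
    ``log2fc_chronic`` = log2(chronic/control) and ``differential`` =
    log2(chronic/acute), computed as the difference of the two
    vs-control contrasts so the identity ``differential =
    log2fc_chronic - log2fc_acute`` holds exactly.  Analytes with any
    nonpositive or missing condition value get missing contrasts.
    """
    control, acute, chronic = conditions
    for cond in conditions:
        if cond not in collapsed.columns:
            raise ValueError(f"unknown or absent condition label {cond!r}")
    vals = collapsed[list(conditions)].to_numpy(dtype=float)
    ok = np.all(np.isfinite(vals) & (vals > 0), axis=1)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("compute_differentials: %d analytes with nonpositive/missing values -> missing contrasts", n_bad)
    with np.errstate(divide="ignore", invalid="ignore"):
        la = np.where(ok, np.log2(vals[:, 1] / vals[:, 0]), np.nan)
        lc = np.where(ok, np.log2(vals[:, 2] / vals[:, 0]), np.nan)
    return pd.DataFrame(
        {"log2fc_acute": la, "log2fc_chronic": lc, "differential": lc - la},
        index=collapsed.index,
    )


def read_quant_tsv(path) -> pd.DataFrame:
    """Read a quant table (TSV, analyte_id first column, samples after)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_quant_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or "analyte_id")
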