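"""Functional-group statistics on site-level contrasts.

Sites are classified into functional groups (pathway modules from a
curated signaling map); each group's distribution of chronic-vs-acute
differentials is compared against the complement with a two-sample
Kolmogorov-Smirnov test, and outlier proteins are tested for term
over-representation with the hypergeometric distribution.  P-values
within a scan are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"
DEFAULT_MIN_GROUP_SIZE = 5
DEFAULT_OUTLIER_CUTOFF = 1.0


def assign_groups(site_keys: Sequence[str], table: pd.DataFrame) -> pd.Series:
    """Assign each site to one functional group.

    *table* has columns ``key``, ``level`` ("protein" or "site"),
    ``group`` (and optionally ``color``).  A site-level assignment for a
    specific site wins over a protein-level one for its protein; keys
    with no assignment resolve to ``"unclassified"``.  Conflicting
    duplicate assignments for one key raise a ``ValueError``.
    """
    prot_map: dict[str, str] = {}
    site_map: dict[str, str] = {}
    conflicts = []
    for rec in table.to_dict("records") if len(table) else []:
        level = str(rec.get("level", "protein")).lower()
        target = site_map if level == "site" else prot_map
        key = str(rec["key"])
        grp = str(rec["group"])
        if key in target and target[key] != grp:
            conflicts.append(key)
        target[key] = grp
    if conflicts:
        raise ValueError(f"conflicting duplicate group assignments for keys: {sorted(set(conflicts))}")

    out = {}
    for sk in site_keys:
        protein = sk.split("|")[0]
        out[sk] = site_map.get(sk, prot_map.get(protein, UNCLASSIFIED))
    return pd.Series(out, name="group")


@dataclass
class OutlierSet:
    """Sites whose chosen contrast strictly exceeds the cutoff in magnitude."""

    up: list[str]
    down: list[str]
    cutoff: float
    field: str
    fraction_inside: float

    @property
    def keys(self) -> list[str]:
        return self.up + self.down


def select_outliers(
    differentials: pd.DataFrame,
    cutoff: float = DEFAULT_OUTLIER_CUTOFF,
    field: str = "differential",
) -> OutlierSet:
    """Select sites with |contrast| strictly above *cutoff*.

    The boundary is exclusive: a contrast of exactly +-cutoff is not an
    outlier.  ``fraction_inside`` reports the share of sites with a
    finite contrast in [-cutoff, +cutoff].
    """
    if field not in differentials.columns:
        raise ValueError(f"unknown contrast field {field!r}; have {list(differentials.columns)}")
    vals = pd.to_numeric(differentials[field], errors="coerce")
    finite = vals[np.isfinite(vals)]
    up = list(finite.index[finite > cutoff])
    down = list(finite.index[finite < -cutoff])
    inside = float((finite.abs() <= cutoff).mean()) if len(finite) else float("nan")
    logger.info(
        "select_outliers(%s, |x|>%g): %d up, %d down, %.1f%% inside",
        field, cutoff, len(up), len(down), 100 * inside if len(finite) else float("nan"),
    )
    return OutlierSet(up=up, down=down, cutoff=cutoff, field=field, fraction_inside=inside)


# --- Kolmogorov-Smirnov ----------------------------------------------------

def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """sup_t |ECDF_x(t) - ECDF_y(t)| over the pooled sample points.

    Right-continuous ECDFs evaluated at the pooled sorted unique points;
    ties therefore contribute a single evaluation point.
    """
    pooled = np.unique(np.concatenate([x, y]))
    fx = np.searchsorted(np.sort(x), pooled, side="right") / len(x)
    fy = np.searchsorted(np.sort(y), pooled, side="right") / len(y)
    return float(np.max(np.abs(fx - fy)))


def ks_two_sample(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "asymptotic",
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Two-sample KS test returning (D, p).

    Asymptotic p uses the Kolmogorov distribution at sqrt(ne)*D with
    effective size ne = |x||y|/(|x|+|y|); permutation p is the
    add-one-smoothed tail frequency of D under random relabelings.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    d = _ks_statistic(x, y)
    if mode == "asymptotic":
        ne = len(x) * len(y) / (len(x) + len(y))
        p = float(min(1.0, special.kolmogorov(np.sqrt(ne) * d)))
    elif mode == "permutation":
        if n_perm < 100:
            logger.warning("ks_two_sample: n_perm=%d is small; p-values will be coarse", n_perm)
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([x, y])
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if _ks_statistic(perm[: len(x)], perm[len(x):]) >= d - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm)
    else:
        raise ValueError(f"unknown KS mode {mode!r}")
    return d, p


@dataclass
class GroupTestResult:
    group: str
    n_in: int
    n_out: int
    D: float
    p_value: float
    q_value: float = field(default=float("nan"))


def _scan(
    values: pd.Series,
    membership: Mapping[str, Sequence[str]],
    mode: str,
    n_perm: int,
    seed: int | None,
    min_size: int,
    what: str,
) -> pd.DataFrame:
    vals = pd.to_numeric(values, errors="coerce")
    vals = vals[np.isfinite(vals)]
    results = []
    rng = np.random.default_rng(seed)
    for label in sorted(membership):
        keys = [k for k in membership[label] if k in vals.index]
        x = vals.loc[keys].to_numpy() if keys else np.array([])
        y = vals.drop(index=keys, errors="ignore").to_numpy()
        if len(x) < min_size or len(y) < 1:
            logger.info("%s scan: %r skipped (n_in=%d < %d)", what, label, len(x), min_size)
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1)) if mode == "permutation" else None
        d, p = ks_two_sample(x, y, mode=mode, n_perm=n_perm, seed=sub_seed)
        results.append(GroupTestResult(group=label, n_in=len(x), n_out=len(y), D=d, p_value=p))
    if not results:
        logger.warning("%s scan: no group reached the minimum size", what)
        return pd.DataFrame(columns=["group", "n_in", "n_out", "D", "p_value", "q_value"])
    q = multipletests([r.p_value for r in results], method="fdr_bh")[1]
    for r, qi in zip(results, q):
        r.q_value = float(qi)
    df = pd.DataFrame([vars(r) for r in results]).sort_values(
        ["p_value", "group"], kind="mergesort"
    ).reset_index(drop=True)
    return df


def group_ks_scan(
    differentials: pd.Series,
    groups: pd.Series,
    mode: str = "asymptotic",
    n_perm: int = 999,
    seed: int | None = None,
    min_size: int = DEFAULT_MIN_GROUP_SIZE,
    include_unclassified: bool = False,
    pairwise: bool = False,
) -> pd.DataFrame:
    """KS scan of each functional group against its complement.

    ``differentials`` is a site-keyed Series of contrast values;
    ``groups`` a site-keyed Series of group labels.  Groups below
    *min_size* are skipped (logged).  BH adjustment is applied across
    the tested groups; results sorted by p.  With ``pairwise=True``, all
    group pairs are tested instead of group-vs-complement.
    """
    labels = groups.loc[groups.index.intersection(differentials.index)]
    if not include_unclassified:
        labels = labels[labels != UNCLASSIFIED]
    membership = {g: list(idx) for g, idx in labels.groupby(labels).groups.items()}
    if len(membership) < 2:
        raise ValueError("need at least 2 groups for a scan")
    if not pairwise:
        return _scan(differentials, membership, mode, n_perm, seed, min_size, "group")
    # pairwise mode: each pair of groups tested head-to-head
    vals = pd.to_numeric(differentials, errors="coerce")
    results = []
    rng = np.random.default_rng(seed)
    for ga, gb in combinations(sorted(membership), 2):
        x = vals.loc[[k for k in membership[ga] if np.isfinite(vals.get(k, np.nan))]].to_numpy()
        y = vals.loc[[k for k in membership[gb] if np.isfinite(vals.get(k, np.nan))]].to_numpy()
        if len(x) < min_size or len(y) < min_size:
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1)) if mode == "permutation" else None
        d, p = ks_two_sample(x, y, mode=mode, n_perm=n_perm, seed=sub_seed)
        results.append({"group": f"{ga} vs {gb}", "n_in": len(x), "n_out": len(y),
                        "D": d, "p_value": p})
    if not results:
        return pd.DataFrame(columns=["group", "n_in", "n_out", "D", "p_value", "q_value"])
    df = pd.DataFrame(results)
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values(["p_value", "group"], kind="mergesort").reset_index(drop=True)


def kinase_ks_scan(
    differentials: pd.Series,
    annotated: pd.DataFrame,
    mode: str = "asymptotic",
    n_perm: int = 999,
    seed: int | None = None,
    min_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> pd.DataFrame:
    """KS scan per kinase: its substrate sites against all other sites.

    ``annotated`` is the kinase-annotated match table (columns
    ``ms_key`` and semicolon-joined ``kinases``); a site with several
    kinases contributes to each kinase's substrate set.
    """
    membership: dict[str, list[str]] = {}
    for rec in annotated.to_dict("records") if len(annotated) else []:
        for kin in str(rec.get("kinases", "")).split(";"):
            if kin:
                membership.setdefault(kin, []).append(rec["ms_key"])
    if not membership:
        logger.warning("kinase_ks_scan: no kinase-annotated sites")
        return pd.DataFrame(columns=["group", "n_in", "n_out", "D", "p_value", "q_value"])
    return _scan(differentials, membership, mode, n_perm, seed, min_size, "kinase")


# --- Over-representation ---------------------------------------------------

def hypergeometric_enrichment(
    foreground: Sequence[str],
    background: Sequence[str],
    terms: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of terms.

    For each term with K background members, p = P(X >= k) where X ~
    Hypergeom(N=|background|, K, n=|foreground|) and k is the number of
    foreground members.  Terms with K = 0 are skipped; BH q across
    tested terms.  The foreground must be a subset of the background.
    """
    fg = set(foreground)
    bg = set(background)
    stray = fg - bg
    if stray:
        raise ValueError(f"foreground proteins absent from background: {sorted(stray)}")
    N, n = len(bg), len(fg)
    rows = []
    for term in sorted(terms):
        members = set(terms[term]) & bg
        K = len(members)
        if K == 0:
            continue
        k = len(members & fg)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p_value": min(1.0, p)})
    if not rows:
        return pd.DataFrame(columns=["term", "k", "K", "n", "N", "p_value", "q_value"])
    df = pd.DataFrame(rows)
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)


def read_group_table(path) -> pd.DataFrame:
    """Read a group-assignment TSV (key, level, group[, color])."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("key", "level", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: group table missing column {col!r}")
    return df


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT term-annotation file: term <TAB> description <TAB> members..."""
    terms: dict[str, list[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for i, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{i}: GMT line needs term, description, >=1 member")
            terms[fields[0]] = [f for f in fields[2:] if f]
    return terms
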