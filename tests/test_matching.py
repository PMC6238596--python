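"""Multisite explosion, tiered site matching, kinase annotation, dialect I/O."""

import numpy as np
import pandas as pd
import pytest

from phosphodiff import matching
from phosphodiff.matching import (
    MatchPolicy,
    annotate_kinases,
    explode_multisite,
    match_sites,
    normalize_accession,
    sites_per_protein_summary,
)

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _flank(rng, res):
    s = rng.choice(AA, size=15)
    s[7] = res.lower()
    return "".join(s)


def _random_instance(rng, n_ms, n_ref, n_shared):
    """Random MS/reference tables with a controlled overlap and edge cases."""
    ms_rows, ref_rows = [], []
    for i in range(n_ms):
        res = str(rng.choice(["S", "T", "Y"]))
        ms_rows.append({
            "peptide_id": f"p{i}", "accession": f"A{i:03d}", "gene": f"g{i:03d}",
            "organism": "mouse", "residue": res, "position": int(rng.integers(1, 400)),
            "flank": _flank(rng, res),
        })
    shared = rng.choice(n_ms, size=min(n_shared, n_ms), replace=False)
    for i in shared:
        r = dict(ms_rows[i])
        kind = rng.integers(0, 4)
        row = {"gene": r["gene"], "protein": r["gene"], "accession": r["accession"],
               "organism": "mouse", "residue": r["residue"], "position": r["position"],
               "flank": r["flank"]}
        if kind == 1:      # version-suffixed accession: still tier 1 after normalization
            row["accession"] = r["accession"] + ".2"
        elif kind == 2:    # renamed accession, same gene: tier 2
            row["accession"] = "X" + r["accession"]
        elif kind == 3:    # cross-species record: only the window tier can hit
            row["accession"] = "H" + r["accession"]
            row["organism"] = "human"
            row["gene"] = r["gene"].upper()
        ref_rows.append(row)
    for j in range(n_ref - len(ref_rows)):
        res = str(rng.choice(["S", "T", "Y"]))
        ref_rows.append({"gene": f"dg{j}", "protein": f"dg{j}", "accession": f"D{j:03d}",
                         "organism": str(rng.choice(["mouse", "human"])),
                         "residue": res, "position": int(rng.integers(1, 400)),
                         "flank": _flank(rng, res)})
    return pd.DataFrame(ms_rows), pd.DataFrame(ref_rows)


def brute_force_match(ms, ref, tiers=(1, 2, 3), ms_organism="mouse"):
    """All-pairs oracle applying the tier rules site by site."""
    out = {}
    for _, m in ms.iterrows():
        acc = normalize_accession(m["accession"])
        res, pos = m["residue"].upper(), int(m["position"])
        org = str(m.get("organism", ms_organism)).casefold()
        hit = None
        for tier in tiers:
            for ri, r in ref.iterrows():
                r_org = str(r["organism"]).casefold()
                if tier == 1 and (normalize_accession(r["accession"]), r["residue"].upper(),
                                  int(r["position"]), r_org) == (acc, res, pos, org):
                    hit = (ri, tier)
                elif tier == 2 and (str(r["gene"]).casefold(), r["residue"].upper(),
                                    int(r["position"]), r_org) == (
                                        str(m.get("gene", "")).casefold(), res, pos, org):
                    hit = (ri, tier)
                elif tier == 3 and str(m.get("flank", "")) and \
                        str(r.get("flank", "")) == str(m.get("flank", "")):
                    hit = (ri, tier)
                if hit:
                    break
            if hit:
                break
        out[matching.site_key(m["accession"], res, pos)] = hit
    return out


class TestExplodeMultisite:
    def test_two_site_isoform_shares_peptide_id(self):
        rec = pd.DataFrame([{"peptide_id": "p1", "accession": "A1", "gene": "g1",
                             "residue": "S/S", "position": "235/236"}])
        out = explode_multisite(rec)
        assert len(out) == 2
        assert set(out["peptide_id"]) == {"p1"}
        assert list(out["position"]) == [235, 236]
        assert out["is_multisite"].all()

    def test_singletons_pass_through(self):
        rec = pd.DataFrame([{"peptide_id": "p1", "accession": "A1", "gene": "g1",
                             "residue": "Y", "position": "88"}])
        out = explode_multisite(rec)
        assert len(out) == 1 and out.loc[0, "position"] == 88
        assert not out.loc[0, "is_multisite"]

    def test_output_count_equals_sum_of_sites(self, rng):
        rows = []
        expected = 0
        for i in range(100):
            k = int(rng.integers(1, 4))
            expected += k
            rows.append({"peptide_id": f"p{i}", "accession": f"A{i}", "gene": f"g{i}",
                         "residue": "/".join(["S"] * k),
                         "position": "/".join(str(10 + j) for j in range(k))})
        assert len(explode_multisite(pd.DataFrame(rows))) == expected

    @pytest.mark.parametrize("residue,position", [
        ("S/S", "10"), ("S", "x"), ("B", "10"), ("S", "0"),
    ])
    def test_malformed_records_raise(self, residue, position):
        rec = pd.DataFrame([{"peptide_id": "p1", "accession": "A1", "gene": "g1",
                             "residue": residue, "position": position}])
        with pytest.raises(ValueError):
            explode_multisite(rec)


class TestMatchSites:
    def test_empty_reference_leaves_all_unmatched(self, rng):
        ms, _ = _random_instance(rng, 5, 0, 0)
        report = match_sites(ms, pd.DataFrame(columns=["accession", "gene", "organism",
                                                       "residue", "position", "flank"]))
        assert report.n_matched == 0
        assert report.n_unmatched == report.n_total == 5

    def test_equals_brute_force_oracle_on_random_instances(self):
        """Tiered matcher reproduces the all-pairs oracle partition (50 seeds)."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n_ms = int(rng.integers(5, 40))
            n_ref = int(rng.integers(5, 60))
            ms, ref = _random_instance(rng, n_ms, n_ref, int(rng.integers(0, n_ms)))
            report = match_sites(ms, ref)
            oracle = brute_force_match(ms, ref)
            got = {k: t for k, _rk, t in report.matches.itertuples(index=False)}
            oracle_matched = {k: ht[1] for k, ht in oracle.items() if ht}
            assert got == oracle_matched, f"seed {seed}"
            assert set(report.unmatched) == {k for k, ht in oracle.items() if not ht}

    def test_partition_exactness(self, rng):
        ms, ref = _random_instance(rng, 30, 40, 15)
        report = match_sites(ms, ref)
        assert report.n_matched + report.n_unmatched == report.n_total == len(ms)
        assert len(set(report.matches["ms_key"]) | set(report.unmatched)) == len(ms)

    def test_tier_monotonicity(self, rng):
        """Adding tiers never loses matches; removing tier 3 never gains."""
        ms, ref = _random_instance(rng, 40, 60, 25)
        full = match_sites(ms, ref, MatchPolicy(tiers=(1, 2, 3)))
        no3 = match_sites(ms, ref, MatchPolicy(tiers=(1, 2)))
        only1 = match_sites(ms, ref, MatchPolicy(tiers=(1,)))
        assert only1.n_matched <= no3.n_matched <= full.n_matched

    def test_idempotence_on_matched_output(self, rng):
        ms, ref = _random_instance(rng, 30, 40, 20)
        first = match_sites(ms, ref)
        matched_keys = set(first.matches["ms_key"])
        ms_matched = ms[[matching.site_key(a, r, p) in matched_keys
                         for a, r, p in zip(ms["accession"], ms["residue"], ms["position"])]]
        second = match_sites(ms_matched, ref)
        assert second.n_unmatched == 0
        pairs1 = set(map(tuple, first.matches[["ms_key", "ref_key"]].to_numpy()))
        pairs2 = set(map(tuple, second.matches[["ms_key", "ref_key"]].to_numpy()))
        assert pairs2 <= pairs1 and len(pairs2) == len(ms_matched)

    def test_accession_normalization_strips_suffixes(self):
        assert normalize_accession("P12345-2") == "P12345"
        assert normalize_accession("P12345.1") == "P12345"
        assert normalize_accession("P12345") == "P12345"


class TestAnnotateKinases:
    def _report(self):
        matches = pd.DataFrame({"ms_key": ["A1|S10", "A2|T20"],
                                "ref_key": ["A1|S10", "A2|T20"], "tier": [1, 1]})
        return matching.MatchReport(n_total=2, matches=matches, unmatched=[])

    def test_empty_kinase_dataset_gives_empty_sets(self):
        annotated, summary = annotate_kinases(
            self._report(), pd.DataFrame(columns=["kinase", "substrate_accession",
                                                  "substrate_residue", "substrate_position"]))
        assert (annotated["kinases"] == "").all()
        assert summary == {"n_kinases": 0, "n_annotated_sites": 0, "n_annotated_proteins": 0}

    def test_one_kinase_per_site_saturates(self):
        ks = pd.DataFrame([
            {"kinase": "K1", "substrate_accession": "A1", "substrate_residue": "S",
             "substrate_position": 10},
            {"kinase": "K2", "substrate_accession": "A2", "substrate_residue": "T",
             "substrate_position": 20},
        ])
        annotated, summary = annotate_kinases(self._report(), ks)
        assert summary["n_annotated_sites"] == 2
        assert summary["n_kinases"] == 2
        assert list(annotated["kinases"]) == ["K1", "K2"]

    def test_multiple_kinases_joined_sorted(self):
        ks = pd.DataFrame([
            {"kinase": "KB", "substrate_accession": "A1", "substrate_residue": "S",
             "substrate_position": 10},
            {"kinase": "KA", "substrate_accession": "A1", "substrate_residue": "S",
             "substrate_position": 10},
        ])
        annotated, _ = annotate_kinases(self._report(), ks)
        assert annotated.loc[0, "kinases"] == "KA;KB"


class TestSitesPerProtein:
    def test_hand_counted_histogram(self):
        sites = pd.DataFrame({
            "accession": ["A", "B", "C", "C", "C", "C"],
            "residue": ["S"] * 6, "position": [1, 1, 1, 2, 3, 4],
        })
        out = sites_per_protein_summary(sites)
        assert out["histogram"] == {1: 2, 4: 1}
        assert out["fraction_1_to_3"] == pytest.approx(2 / 3)

    def test_empty_input(self):
        out = sites_per_protein_summary(pd.DataFrame(columns=["accession", "residue",
                                                              "position"]))
        assert out["histogram"] == {} and out["n_proteins"] == 0

    def test_counts_match_oracle_on_simulated_sites(self, rng):
        n_per = {f"A{i}": int(rng.integers(1, 8)) for i in range(30)}
        rows = [{"accession": a, "residue": "S", "position": p + 1}
                for a, k in n_per.items() for p in range(k)]
        out = sites_per_protein_summary(pd.DataFrame(rows))
        assert out["per_protein"] == n_per
        assert out["fraction_1_to_3"] == pytest.approx(
            sum(1 for v in n_per.values() if v <= 3) / len(n_per))


class TestDialectIO:
    def test_reference_roundtrip_with_preamble(self, tmp_path):
        path = tmp_path / "ref.tsv"
        path.write_text(
            "some preamble line\nanother line\n\n"
            "GENE\tPROTEIN\tACC_ID\tORGANISM\tMOD_RSD\tSITE_+/-7_AA\n"
            "Rps6\tRps6\tP62754\tmouse\tS235-p\tAKRRRLssLRASTSK\n"
            "Eif4b\tEif4b\tQ8BGD9\tmouse\tS422-p\tERSRTGSesSQTGTS\n"
        )
        ref = matching.read_reference_sites(path)
        assert len(ref) == 2
        assert list(ref["residue"]) == ["S", "S"]
        assert list(ref["position"]) == [235, 422]

    def test_unparseable_mod_rsd_dropped(self, tmp_path):
        path = tmp_path / "ref.tsv"
        path.write_text(
            "GENE\tPROTEIN\tACC_ID\tORGANISM\tMOD_RSD\tSITE_+/-7_AA\n"
            "G1\tG1\tA1\tmouse\tS10-p\tAAAAAAAsAAAAAAA\n"
            "G2\tG2\tA2\tmouse\tK48-ub\tAAAAAAAkAAAAAAA\n"
        )
        ref = matching.read_reference_sites(path)
        assert len(ref) == 1 and ref.iloc[0]["accession"] == "A1"

    def test_missing_required_column_raises(self, tmp_path):
        path = tmp_path / "ref.tsv"
        path.write_text("GENE\tORGANISM\nx\tmouse\n")
        with pytest.raises(ValueError, match="ACC_ID|header"):
            matching.read_reference_sites(path)

    def test_kinase_substrate_parsing(self, tmp_path):
        path = tmp_path / "ks.tsv"
        path.write_text(
            "KINASE\tKIN_ORGANISM\tSUBSTRATE\tSUB_ACC_ID\tSUB_GENE\tSUB_ORGANISM\t"
            "SUB_MOD_RSD\tSITE_+/-7_AA\n"
            "mTOR\tmouse\tRps6\tP62754\tRps6\tmouse\tS235\tAKRRRLssLRASTSK\n"
        )
        ks = matching.read_kinase_substrates(path)
        assert ks.iloc[0]["substrate_residue"] == "S"
        assert ks.iloc[0]["substrate_position"] == 235
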