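"""Curation chain: parsing, filter semantics, replicate handling, pIC50."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ache_qsar.curation import (
    ActivityRecord,
    CurationConfigError,
    assign_activity_class,
    curate,
    deduplicate_replicates,
    drop_missing_smiles,
    drop_qualified_or_missing,
    filter_endpoint,
    filter_units,
    from_pic50,
    read_activity_table,
    standardize_structure,
    to_pic50,
)


def rec(cid="C1", smiles="CCO", endpoint="IC50", qualifier="=", value=100.0, unit="nM"):
    return ActivityRecord(cid, smiles, endpoint, qualifier, value, unit)


class TestReadActivityTable:
    def test_toy_csv_with_blank_cell(self, toy_raw_table):
        records = read_activity_table(toy_raw_table)
        assert len(records) == 5
        assert sum(r.value_missing for r in records) == 1
        assert [r.compound_id for r in records] == ["C1", "C2", "C3", "C4", "C5"]

    def test_header_only_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("compound_id,smiles,endpoint,qualifier,value,unit\n")
        assert read_activity_table(path) == []

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("compound_id,smiles,endpoint,qualifier,value\nC1,CCO,IC50,=,1\n")
        with pytest.raises(CurationConfigError, match="unit"):
            read_activity_table(path)

    def test_chembl_dialect_maps_headers(self, tmp_path):
        path = tmp_path / "chembl.tsv"
        path.write_text(
            "CMPD_CHEMBLID\tCANONICAL_SMILES\tSTANDARD_TYPE\tRELATION\tSTANDARD_VALUE\tSTANDARD_UNITS\n"
            "CHEMBL1\tCCO\tIC50\t=\t42\tnM\n"
        )
        (r,) = read_activity_table(path, dialect="chembl")
        assert r.compound_id == "CHEMBL1" and r.value == 42.0 and r.unit == "nM"

    def test_malformed_numeric_becomes_missing(self, tmp_path):
        path = tmp_path / "mal.csv"
        path.write_text("compound_id,smiles,endpoint,qualifier,value,unit\nC1,CCO,IC50,=,abc,nM\n")
        (r,) = read_activity_table(path)
        assert r.value_missing


class TestFilters:
    def test_endpoint_mixed(self):
        records = [rec(endpoint="IC50")] * 3 + [rec(endpoint="Ki")] * 2
        assert len(filter_endpoint(records)) == 3

    def test_endpoint_none_left(self):
        assert filter_endpoint([rec(endpoint="Ki")] * 4) == []

    def test_qualifier_and_missing_dropped(self):
        records = [rec(), rec(qualifier="<"), rec(value=math.nan), rec(qualifier="")]
        kept = drop_qualified_or_missing(records)
        assert len(kept) == 2
        assert all(not r.value_missing and r.qualifier in ("=", "") for r in kept)

    def test_all_exact_unchanged(self):
        records = [rec(cid=f"C{i}") for i in range(4)]
        assert drop_qualified_or_missing(records) == records

    def test_unit_filter_keeps_nm_only(self):
        records = [rec(unit="nM")] * 3 + [rec(unit="uM")] * 2
        assert len(filter_units(records)) == 3
        assert filter_units(records, unit="uM") == [rec(unit="uM")] * 2


class TestDeduplicateReplicates:
    def test_singleton_kept(self):
        (c,) = deduplicate_replicates([rec(value=100.0)])
        assert c.compound_id == "C1" and c.pic50 == pytest.approx(7.0)

    def test_concordant_pair_aggregated_by_mean_pic50(self):
        # 10 nM and 100 nM -> pIC50 {8, 7}, sample SD 0.7071 < 2 -> mean 7.5
        (c,) = deduplicate_replicates([rec(value=10.0), rec(value=100.0)])
        assert c.pic50 == pytest.approx(7.5)
        assert c.ic50_nM == pytest.approx(from_pic50(7.5))

    def test_discordant_pair_dropped_entirely(self):
        # 1 nM vs 100 uM -> pIC50 {9, 4}, SD 3.54 >= 2
        assert deduplicate_replicates([rec(value=1.0), rec(value=1e5)]) == []

    def test_nm_scale_alternative(self):
        # values 10 and 100 nM: nM-scale SD = 63.6 >= 2 -> dropped on that scale
        records = [rec(value=10.0), rec(value=100.0)]
        assert deduplicate_replicates(records, sd_scale="nM") == []
        assert len(deduplicate_replicates(records, sd_scale="pic50")) == 1

    def test_nonpositive_value_rejected_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = deduplicate_replicates([rec(value=0.0), rec(cid="C2", value=10.0)])
        assert [c.compound_id for c in out] == ["C2"]
        assert "non-positive" in caplog.text

    def test_bad_scale_rejected(self):
        with pytest.raises(ValueError, match="sd_scale"):
            deduplicate_replicates([rec()], sd_scale="molar")


class TestPic50:
    @pytest.mark.parametrize("ic50,expected", [(1.0, 9.0), (1000.0, 6.0), (50.0, 7.30103)])
    def test_known_values(self, ic50, expected):
        assert to_pic50(ic50) == pytest.approx(expected, abs=1e-5)

    @given(st.floats(min_value=1e-3, max_value=1e9))
    @settings(derandomize=True, max_examples=50)
    def test_round_trip(self, ic50):
        assert from_pic50(to_pic50(ic50)) == pytest.approx(ic50, rel=1e-9)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            to_pic50(bad)


class TestActivityClass:
    @pytest.mark.parametrize(
        "pic50,expected",
        [
            (to_pic50(500.0), "active"),  # IC50 = 500 nM < 1 uM
            (6.0, "intermediate"),  # boundary is upper-exclusive
            (5.0, "intermediate"),
            (to_pic50(50_000.0), "inactive"),  # IC50 = 50 uM
            (9.2, "active"),
            (3.0, "inactive"),
        ],
    )
    def test_bounds(self, pic50, expected):
        assert assign_activity_class(pic50) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            assign_activity_class(math.nan)


class TestStandardize:
    def test_salt_strip_keeps_largest_organic_fragment(self):
        assert standardize_structure("CCO.[Na+].[Cl-]") == "CCO"

    def test_idempotent_on_canonical_neutral(self):
        smi = standardize_structure("c1ccccc1CCN")
        assert standardize_structure(smi) == smi

    def test_glycine_hydrochloride_loses_chlorine(self):
        out = standardize_structure("C(C(=O)O)N.Cl")
        assert "Cl" not in out
        assert out == standardize_structure("NCC(=O)O")

    def test_unparseable_raises(self):
        with pytest.raises(ValueError, match="unparseable"):
            standardize_structure("not-a-smiles(((")


class TestFullChain:
    def _records_from_curated(self, df):
        return [
            ActivityRecord(str(r.compound_id), str(r.smiles), "IC50", "=", float(r.ic50_nM), "nM")
            for r in df.itertuples()
        ]

    def test_chain_is_idempotent_on_its_own_output(self):
        from ache_qsar.synthetic import SynthSpec, gen_activity_table
        from ache_qsar.curation import ActivityRecord

        spec = SynthSpec(n_compounds=80, replicate_rate=0.3, qualifier_rate=0.2,
                         missing_rate=0.1, missing_smiles_rate=0.05,
                         noisy_replicate_rate=0.1, unit_mix={"nM": 0.8, "uM": 0.2}, seed=3)
        records_df, _ = gen_activity_table(spec)
        records = [
            ActivityRecord(r.compound_id, r.smiles, r.endpoint, r.qualifier,
                           float(r.value) if r.value else math.nan, r.unit)
            for r in records_df.itertuples()
        ]
        df1, _ = curate(records)
        df2, _ = curate(self._records_from_curated(df1))
        pd.testing.assert_frame_equal(df1.reset_index(drop=True), df2.reset_index(drop=True))

    @pytest.mark.parametrize("seed", [0, 7, 19])
    def test_monotone_shrinkage_and_log_consistency(self, seed):
        from ache_qsar.synthetic import SynthSpec, gen_activity_table
        from ache_qsar.curation import ActivityRecord

        spec = SynthSpec(n_compounds=60, replicate_rate=0.4, qualifier_rate=0.25,
                         missing_rate=0.15, missing_smiles_rate=0.1,
                         noisy_replicate_rate=0.2, unit_mix={"nM": 0.7, "uM": 0.3}, seed=seed)
        records_df, truth = gen_activity_table(spec)
        records = [
            ActivityRecord(r.compound_id, r.smiles, r.endpoint, r.qualifier,
                           float(r.value) if r.value else math.nan, r.unit)
            for r in records_df.itertuples()
        ]
        df, log = curate(records)
        for _, ri, ro, _ in log.stages:
            assert ro <= ri
        # generator bookkeeping is the oracle for the final survivor set
        expected = truth[truth.survives]
        assert set(df.compound_id) == set(expected.compound_id)
        got = df.set_index("compound_id").pic50
        want = expected.set_index("compound_id").expected_pic50
        assert np.allclose(got.loc[want.index], want, atol=1e-4)
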