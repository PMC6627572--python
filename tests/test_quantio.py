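"""Quantification I/O: top-3 aggregation, fold changes, table round trips."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from btpp.design import design_from_columns, parse_sample_label
from btpp.quantio import (
    TableFormatError,
    aggregate_top3,
    compute_fold_changes,
    load_published_targets,
    read_abundance_table,
    read_results_table,
    write_abundance_table,
    write_results_table,
)
from btpp.simdata import SimulationConfig, simulate_study


def peptide_frame(rows):
    return pd.DataFrame(rows, columns=["peptide", "accession", "sample", "area"])


class TestAggregateTop3:
    def test_mean_of_three_largest(self):
        table = peptide_frame(
            [(f"PEP{i}", "P1", "vehicle_1_37", a) for i, a in enumerate([10.0, 5.0, 8.0, 2.0])]
        )
        out = aggregate_top3(table)
        assert out.loc["P1", "vehicle_1_37"] == pytest.approx((10 + 8 + 5) / 3)

    def test_fewer_than_three_peptides_uses_available(self):
        out = aggregate_top3(peptide_frame([("PEP0", "P1", "vehicle_1_37", 4.0)]))
        assert out.loc["P1", "vehicle_1_37"] == pytest.approx(4.0)

    def test_counts_flag_contributing_peptides(self):
        table = peptide_frame(
            [("A", "P1", "s", 1.0), ("B", "P1", "s", 2.0), ("C", "P2", "s", 3.0)]
        )
        _, counts = aggregate_top3(table, return_counts=True)
        assert counts.loc["P1", "s"] == 2 and counts.loc["P2", "s"] == 1

    def test_brute_force_oracle_small_table(self):
        rng = np.random.default_rng(0)
        rows = []
        for acc, sample in itertools.product(["P1", "P2"], ["vehicle_1_37", "compound_2_67"]):
            for i in range(rng.integers(1, 6)):
                rows.append((f"{acc}_{sample}_{i}", acc, sample, float(rng.uniform(0, 100))))
        table = peptide_frame(rows)
        out = aggregate_top3(table)
        for acc, sample in itertools.product(["P1", "P2"], ["vehicle_1_37", "compound_2_67"]):
            areas = sorted(
                (r[3] for r in rows if r[1] == acc and r[2] == sample), reverse=True
            )[:3]
            assert out.loc[acc, sample] == pytest.approx(sum(areas) / len(areas))

    def test_negative_area_rejected(self):
        with pytest.raises(TableFormatError, match="negative"):
            aggregate_top3(peptide_frame([("A", "P1", "s", -1.0)]))

    def test_empty_table_rejected(self):
        with pytest.raises(TableFormatError):
            aggregate_top3(peptide_frame([]))

    @given(
        st.lists(st.floats(0.0, 1e6, allow_nan=False), min_size=1, max_size=8),
        st.floats(1.0, 1e3),
    )
    @settings(max_examples=60, deadline=None)
    def test_permutation_invariant_and_monotone(self, areas, bump):
        base = peptide_frame(
            [(f"PEP{i}", "P1", "s", a) for i, a in enumerate(areas)]
        )
        shuffled = base.sample(frac=1.0, random_state=1)
        v1 = aggregate_top3(base).loc["P1", "s"]
        v2 = aggregate_top3(shuffled).loc["P1", "s"]
        assert v1 == pytest.approx(v2)
        # raising the largest area can never lower the abundance
        bumped = base.copy()
        bumped.loc[bumped["area"].idxmax(), "area"] += bump
        assert aggregate_top3(bumped).loc["P1", "s"] >= v1


class TestFoldChanges:
    def test_reference_profile_example(self, design):
        profile = [1e6, 8e5, 5e5, 2.5e5, 1e5, 6e4, 5e4]
        data = {}
        for cond, rep in design.experiments():
            for t, v in zip(design.gradient, profile):
                data[design.sample_label(cond, rep, t)] = [v]
        abundance = pd.DataFrame(data, index=["P1"])
        fc, exclusions = compute_fold_changes(abundance, design)
        got = fc.loc["P1", design.experiment_labels(design.vehicle, 1)].to_numpy(float)
        np.testing.assert_allclose(got, [1, 0.8, 0.5, 0.25, 0.1, 0.06, 0.05])
        assert exclusions.empty

    def test_constant_profile_gives_unit_fold_changes(self, design):
        abundance = pd.DataFrame(
            {label: [3.0] for label in design.sample_labels()}, index=["P1"]
        )
        fc, _ = compute_fold_changes(abundance, design)
        assert (fc.loc["P1"] == 1.0).all()

    def test_zero_reference_flags_experiment_unusable(self, design):
        abundance = pd.DataFrame(
            {label: [2.0] for label in design.sample_labels()}, index=["P1"]
        )
        abundance.loc["P1", design.sample_label(design.vehicle, 1, 37.0)] = 0.0
        fc, exclusions = compute_fold_changes(abundance, design)
        assert fc.loc["P1", design.experiment_labels(design.vehicle, 1)].isna().all()
        assert fc.loc["P1", design.experiment_labels(design.treatment, 1)].notna().all()
        assert len(exclusions) == 1
        assert exclusions.iloc[0]["reason"] == "reference_zero"

    def test_scale_invariance(self, design):
        truth, abundance, des = simulate_study(SimulationConfig(n_proteins=30, seed=41))
        fc1, _ = compute_fold_changes(abundance, des)
        fc2, _ = compute_fold_changes(abundance * 37.5, des)
        pd.testing.assert_frame_equal(fc1, fc2)


class TestTableIO:
    def test_abundance_round_trip(self, tmp_path):
        truth, abundance, design = simulate_study(
            SimulationConfig(n_proteins=25, missing_rate=0.1, seed=43)
        )
        path = tmp_path / "abundance.tsv"
        write_abundance_table(abundance, path)
        back, design_back = read_abundance_table(path)
        pd.testing.assert_frame_equal(abundance, back, check_exact=False, rtol=1e-9)
        assert design_back.sample_labels() == design.sample_labels()

    def test_duplicate_accession_reported_with_row(self, tmp_path, design):
        df = pd.DataFrame(
            {label: [1.0, 2.0] for label in design.sample_labels()},
            index=pd.Index(["P1", "P1"], name="accession"),
        )
        path = tmp_path / "dup.tsv"
        write_abundance_table(df, path)
        with pytest.raises(TableFormatError, match="row 3"):
            read_abundance_table(path)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("protein\tvehicle_1_37\nP1\t1.0\n")
        with pytest.raises(TableFormatError, match="accession"):
            read_abundance_table(path)

    def test_incomplete_design_rejected(self, tmp_path):
        path = tmp_path / "bad2.tsv"
        path.write_text("accession\tvehicle_1_37\tvehicle_1_42\nP1\t1.0\t0.5\n")
        with pytest.raises(TableFormatError):
            read_abundance_table(path)

    def test_results_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {
                "accession": ["P1"],
                "protein_name": ["Example"],
                "tm_control_1": [45.74],
                "tm_treatment_1": [47.16],
                "tm_control_2": [45.32],
                "tm_treatment_2": [49.00],
                "p_value": [0.0385],
            }
        )
        path = tmp_path / "results.tsv"
        write_results_table(df, path)
        back = read_results_table(path)
        pd.testing.assert_frame_equal(df, back)


class TestPublishedTables:
    def test_btpp_table_has_nine_targets(self):
        table = load_published_targets("bTPP")
        assert len(table) == 9
        row = table.set_index("accession").loc["P08865"]
        assert row["tm_control_1"] == pytest.approx(45.74)
        assert row["tm_treatment_2"] == pytest.approx(49.00)
        assert row["p_value"] == pytest.approx(0.0385)

    def test_tpp_table_has_nineteen_targets(self):
        table = load_published_targets("TPP")
        assert len(table) == 19
        assert set(table["accession"]).issuperset({"Q00341", "P60709", "Q9Y696"})

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            load_published_targets("CETSA")


class TestSampleLabels:
    def test_parse_round_trip(self, design):
        for cond, rep in design.experiments():
            for t in design.gradient:
                label = design.sample_label(cond, rep, t)
                assert parse_sample_label(label) == (cond, rep, t)

    def test_design_reconstruction(self, design):
        rebuilt = design_from_columns(design.sample_labels())
        assert rebuilt.sample_labels() == design.sample_labels()

    def test_malformed_label_rejected(self):
        with pytest.raises(ValueError):
            parse_sample_label("vehicle37")
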