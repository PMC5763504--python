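"""Series Matrix parsing, preprocessing, tensor assembly and validation tests."""

import numpy as np
import pandas as pd
import pytest

from tdfe.geo import (
    DURATIONS,
    REST_PERIODS,
    TABLE_REPLICATES,
    TISSUES,
    ExpressionMatrix,
    SampleRecord,
    StudyDesign,
    assemble_tensor,
    filter_probes,
    parse_series_matrix,
    run_ptsd_analysis,
    standardize_samples,
    ttest_combinations,
)
from tdfe.geo import testable_combinations as design_combinations
from conftest import MEASURED_CELLS, planted_study, write_series_matrix


def _matrix(values, probes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    probes = probes or [f"P{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(data=pd.DataFrame(values, index=probes, columns=samples))


class TestParseSeriesMatrix:
    def test_fixture_round_trips_values_exactly(self, tmp_path, rng):
        probes = ["A_51_P1", "A_51_P2", "A_51_P3"]
        specs = [
            ("GSM1", "AY", "10 days", "24 hours", "control"),
            ("GSM2", "AY", "10 days", "24 hours", "stress"),
            ("GSM3", "heart", "5 days", "1.5 weeks", "control"),
            ("GSM4", "heart", "5 days", "1.5 weeks", "stress"),
        ]
        values = np.round(rng.normal(size=(3, 4)), 4)
        path = tmp_path / "m.txt"
        write_series_matrix(path, probes, specs, values)
        matrix, design = parse_series_matrix(path)
        assert matrix.probes == probes
        assert np.array_equal(matrix.data.to_numpy(), values)
        assert len(design) == 4
        rec = design.by_sample()["GSM3"]
        assert (rec.tissue, rec.duration, rec.rest, rec.treatment) == (8, 2, 1, 1)

    def test_sample_without_tissue_label_is_reported(self, tmp_path, rng):
        probes = ["A_51_P1"]
        specs = [("GSM1", "AY", "10 days", "24 hours", "control"),
                 ("GSM2", "AY", "10 days", "24 hours", "stress")]
        path = tmp_path / "m.txt"
        write_series_matrix(path, probes, specs, rng.normal(size=(1, 2)))
        text = path.read_text().replace("tissue: amygdala\"\t\"tissue: amygdala",
                                        "tissue: amygdala\"\t\"organ unknown")
        path.write_text(text)
        with pytest.raises(ValueError, match="GSM2"):
            parse_series_matrix(path)

    def test_missing_table_markers(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text("!Series_title\t\"x\"\n")
        with pytest.raises(ValueError, match="table_begin"):
            parse_series_matrix(path)

    def test_replicate_counts_per_cell(self, tmp_path, rng):
        probes = ["A_51_P1"]
        specs = [("GSM%d" % i, "HC", "5 days", "24 hours", "stress")
                 for i in range(1, 4)]
        path = tmp_path / "m.txt"
        write_series_matrix(path, probes, specs, rng.normal(size=(1, 3)))
        _, design = parse_series_matrix(path)
        assert design.replicate_counts() == {(2, 2, 2, 2): 3}
        assert [r.replicate for r in design.records] == [1, 2, 3]


class TestFilterProbes:
    def test_removes_exactly_prefixed_probes(self):
        m = _matrix(np.zeros((3, 2)), probes=["EA001", "A_51_P100", "EA_x"])
        out = filter_probes(m)
        assert out.probes == ["A_51_P100"]

    def test_case_sensitive(self):
        m = _matrix(np.zeros((2, 2)), probes=["ea001", "EA002"])
        assert filter_probes(m).probes == ["ea001"]

    def test_empty_prefix_guarded(self):
        m = _matrix(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="allow_empty_prefix"):
            filter_probes(m, prefix="")
        assert filter_probes(m, prefix="", allow_empty_prefix=True).probes == []

    def test_counts_partition(self, rng):
        probes = [("EA" if rng.random() < 0.3 else "A_") + str(i) for i in range(50)]
        m = _matrix(rng.normal(size=(50, 3)), probes=probes)
        kept = filter_probes(m)
        n_ea = sum(p.startswith("EA") for p in probes)
        assert len(kept.probes) + n_ea == 50


class TestStandardizeSamples:
    def test_closed_form_column(self):
        m = _matrix(np.array([[1.0], [2.0], [3.0]]).reshape(3, 1))
        out = standardize_samples(m).data.to_numpy().ravel()
        assert np.allclose(out, [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_idempotent(self, rng):
        m = _matrix(rng.normal(size=(40, 5)))
        once = standardize_samples(m)
        twice = standardize_samples(once)
        assert np.allclose(once.data.to_numpy(), twice.data.to_numpy(), atol=1e-12)

    def test_moments_on_random_columns(self, rng):
        m = standardize_samples(_matrix(rng.normal(2.0, 3.0, size=(60, 100))))
        v = m.data.to_numpy()
        assert np.abs(v.mean(axis=0)).max() < 1e-12
        assert np.abs(v.std(axis=0, ddof=0) - 1.0).max() < 1e-12

    def test_constant_column_rejected(self):
        m = _matrix(np.column_stack([np.arange(4.0), np.full(4, 2.0)]))
        with pytest.raises(ValueError, match="constant"):
            standardize_samples(m)


class TestAssembleTensor:
    def _design(self, records):
        return StudyDesign(records=tuple(SampleRecord(*r) for r in records))

    def test_replicates_averaged(self):
        m = _matrix(np.array([[1.0, 3.0]]), samples=["a", "b"])
        design = self._design([("a", 1, 1, 1, 1, 1), ("b", 1, 1, 1, 1, 2)])
        t = assemble_tensor(m, design)
        assert t.values[0, 0, 0, 0, 0] == 2.0

    def test_missing_cells_exact_zero(self):
        m = _matrix(np.array([[1.0, 2.0]]), samples=["a", "b"])
        design = self._design([("a", 1, 1, 1, 1, 1), ("b", 2, 1, 1, 1, 1)])
        t = assemble_tensor(m, design)
        # the unmeasured 5-day/6-week slice is zero-filled
        assert np.all(t.values[:, :, :, 1, 2] == 0.0)
        assert t.mode_names == ("gene", "treatment", "tissue", "duration", "rest")
        assert t.shape == (1, 2, 10, 2, 3)

    def test_matches_group_by_average_oracle(self, rng):
        n_p, specs = 6, []
        cols = []
        for i in range(30):
            specs.append((f"s{i}", rng.integers(1, 3), rng.integers(1, 11),
                          rng.integers(1, 3), rng.integers(1, 4), 1))
            cols.append(rng.normal(size=n_p))
        m = _matrix(np.column_stack(cols), samples=[s[0] for s in specs])
        design = self._design(specs)
        t = assemble_tensor(m, design)
        frame = m.data.T
        meta = pd.DataFrame(specs, columns=["s", "j1", "j2", "j3", "j4", "rep"])
        for (j1, j2, j3, j4), group in meta.groupby(["j1", "j2", "j3", "j4"]):
            expected = frame.loc[group["s"]].mean(axis=0).to_numpy()
            assert np.allclose(t.values[:, j1 - 1, j2 - 1, j3 - 1, j4 - 1], expected)

    def test_uncovered_sample_rejected(self):
        m = _matrix(np.zeros((1, 2)), samples=["a", "b"])
        design = self._design([("a", 1, 1, 1, 1, 1)])
        with pytest.raises(ValueError, match="b"):
            assemble_tensor(m, design)

    def test_standardize_before_averaging_is_order_sensitive(self):
        """The pipeline standardizes samples before replicate averaging;
        averaging raw replicates with unequal scales then standardizing the
        averaged tensor cell-wise gives a different tensor."""
        m = _matrix(np.array([[1.0, 10.0], [2.0, 30.0], [3.0, 20.0]]),
                    samples=["a", "b"])
        design = self._design([("a", 1, 1, 1, 1, 1), ("b", 1, 1, 1, 1, 2)])
        pipeline = assemble_tensor(standardize_samples(m), design)
        raw_avg = assemble_tensor(m, design)
        cell_p = pipeline.values[:, 0, 0, 0, 0]
        cell_r = raw_avg.values[:, 0, 0, 0, 0]
        cell_r_std = (cell_r - cell_r.mean()) / cell_r.std(ddof=0)
        assert not np.allclose(cell_p, cell_r_std)


class TestRunPtsdAnalysis:
    def test_end_to_end_on_planted_study(self, series_matrix_file):
        path, probes, specs, signal = series_matrix_file
        matrix, design = parse_series_matrix(path)
        matrix = standardize_samples(filter_probes(matrix))
        tensor = assemble_tensor(matrix, design)
        result, info = run_ptsd_analysis(tensor, threshold=0.01)
        # the treatment-difference vector has opposite-sign entries
        assert info["l1_treatment"] >= 1
        assert len(info["omega"]) == 3
        assert info["n_selected"] == len(result.selected)
        # planted responders dominate the selection
        if result.selected:
            hits = sum(p in signal for p in result.selected)
            assert hits / len(result.selected) > 0.5

    def test_treatment_contrast_finds_opposite_sign_vector(self, series_matrix_file):
        from tdfe.tensor import find_contrast_vector, hosvd

        path, *_ = series_matrix_file
        matrix, design = parse_series_matrix(path)
        tensor = assemble_tensor(standardize_samples(filter_probes(matrix)), design)
        decomp = hosvd(tensor)
        l1 = find_contrast_vector(decomp, "treatment", (1.0, -1.0))
        col = decomp.factors[tensor.mode_index("treatment")][:, l1 - 1]
        assert col[0] * col[1] < 0

    def test_requires_five_modes(self, rng):
        from tdfe.tensor import DenseTensor

        t = DenseTensor(rng.normal(size=(4, 2)), ("gene", "treatment"),
                        (tuple("abcd"), ("control", "stress")))
        with pytest.raises(ValueError, match="five-mode"):
            run_ptsd_analysis(t)

    def test_deterministic(self, series_matrix_file):
        path, *_ = series_matrix_file
        matrix, design = parse_series_matrix(path)
        tensor = assemble_tensor(standardize_samples(filter_probes(matrix)), design)
        r1, i1 = run_ptsd_analysis(tensor)
        r2, i2 = run_ptsd_analysis(tensor)
        assert i1 == i2
        assert r1.selected == r2.selected


class TestTtestCombinations:
    def test_identical_groups_give_null_result(self, rng):
        probes = [f"A_{i}" for i in range(5)]
        specs, cols = [], []
        base = rng.normal(size=(5, 3))
        for tissue in ("AY", "HC"):
            for treatment in ("control", "stress"):
                for r in range(3):
                    specs.append((f"GSM{tissue}{treatment}{r}", tissue,
                                  "10 days", "24 hours", treatment))
                    cols.append(base[:, r])  # same values in both groups
        m = _matrix(np.column_stack(cols), probes=probes,
                    samples=[s[0] for s in specs])
        design = StudyDesign(records=tuple(
            SampleRecord(s[0],
                         1 if s[4] == "control" else 2,
                         TISSUES.index(s[1]) + 1,
                         DURATIONS.index(s[2]) + 1,
                         REST_PERIODS.index(s[3]) + 1)
            for s in specs))
        out = ttest_combinations(m, design, probes)
        assert np.allclose(out["t"], 0.0)
        assert np.allclose(out["p_raw"], 1.0)

    def test_single_shifted_combination_detected(self, rng):
        """Only the combination with the planted shift is significant; a
        permutation test on the same data agrees."""
        probes, specs, values, signal = planted_study(
            seed=3, n_probes=60, n_signal=60, effect=0.0,
            tissue_subset=("AY", "HC"), replicates=5,
        )
        meta = pd.DataFrame(specs, columns=["s", "tissue", "dur", "rest", "trt"])
        shift_cols = ((meta["tissue"] == "AY") & (meta["dur"] == "10 days")
                      & (meta["rest"] == "24 hours") & (meta["trt"] == "stress"))
        values = values.copy()
        values[:, shift_cols.to_numpy()] += 4.0
        m = _matrix(values, probes=probes, samples=[s[0] for s in specs])
        design = StudyDesign(records=tuple(
            SampleRecord(s[0], 1 if s[4] == "control" else 2,
                         TISSUES.index(s[1]) + 1, DURATIONS.index(s[2]) + 1,
                         REST_PERIODS.index(s[3]) + 1)
            for s in specs))
        out = ttest_combinations(m, design, probes, threshold=0.01)
        sig = out[out["significant"]]
        assert len(sig) == 1
        assert sig.iloc[0]["tissue"] == "AY"
        assert sig.iloc[0]["rest"] == "24 hours"

        # permutation oracle on the significant combination
        ctrl = meta[(meta.tissue == "AY") & (meta.dur == "10 days")
                    & (meta.rest == "24 hours") & (meta.trt == "control")]["s"]
        trt = meta[shift_cols]["s"]
        a = m.data[list(ctrl)].mean(axis=0).to_numpy()
        b = m.data[list(trt)].mean(axis=0).to_numpy()
        obs = b.mean() - a.mean()
        pooled = np.concatenate([a, b])
        perm_rng = np.random.default_rng(0)
        more_extreme = sum(
            abs(np.diff([p[: len(a)].mean(), p[len(a):].mean()])[0]) >= abs(obs)
            for p in (perm_rng.permutation(pooled) for _ in range(500))
        )
        assert (more_extreme + 1) / 501 < 0.05

    def test_combination_with_one_group_empty_skipped(self, rng):
        probes = ["A_1"]
        specs = [("g1", "AY", "10 days", "24 hours", "control"),
                 ("g2", "AY", "10 days", "24 hours", "control")]
        m = _matrix(rng.normal(size=(1, 2)), probes=probes,
                    samples=["g1", "g2"])
        design = StudyDesign(records=(
            SampleRecord("g1", 1, 1, 1, 2), SampleRecord("g2", 1, 1, 1, 2)))
        out = ttest_combinations(m, design, probes)
        assert len(out) == 0

    def test_paired_by_probe_variant(self, series_matrix_file):
        path, probes, *_ = series_matrix_file
        matrix, design = parse_series_matrix(path)
        matrix = standardize_samples(matrix)
        out = ttest_combinations(matrix, design, probes, mode="paired-by-probe")
        assert {"t", "p_raw", "p_adjusted", "significant"} <= set(out.columns)
        assert len(out) > 0

    def test_empty_probe_list_rejected(self, rng):
        m = _matrix(rng.normal(size=(2, 2)))
        with pytest.raises(ValueError, match="non-empty"):
            ttest_combinations(m, StudyDesign(records=()), [])


class TestStudyDesignTable:
    def test_forty_testable_combinations(self):
        combos = design_combinations()
        assert len(combos) == 40
        assert len(set(combos)) == 40

    def test_table_covers_all_tissues_with_four_cells(self):
        assert set(TABLE_REPLICATES) == set(TISSUES)
        for cells in TABLE_REPLICATES.values():
            assert len(cells) == 4
            for (dur, rest) in cells:
                assert dur in DURATIONS and rest in REST_PERIODS
        # the unmeasured cells are absent: 6 weeks never follows 5 days
        for cells in TABLE_REPLICATES.values():
            assert ("5 days", "6 weeks") not in cells
        assert [c for c in TABLE_REPLICATES["AY"]] == MEASURED_CELLS

    def test_design_code_ranges_enforced(self):
        with pytest.raises(ValueError, match="tissue"):
            StudyDesign(records=(SampleRecord("x", 1, 11, 1, 1),))
        with pytest.raises(ValueError, match="treatment"):
            StudyDesign(records=(SampleRecord("x", 3, 1, 1, 1),))
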