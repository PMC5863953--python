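import io

import numpy as np
import pandas as pd
import pytest

from hapticdyad.config import DEG, RAD2DEG, SimConfig
from hapticdyad.synthetic_data import (HapticTrackingRecord, S1_COLUMNS,
                                       generate_dyad_dataset, read_s1,
                                       read_s2, s1_to_outcomes, write_s1,
                                       write_s2)


@pytest.fixture(scope="module")
def small_table(cfg, haptic_model):
    return generate_dyad_dataset(3, "neuromechanical", seed=4, cfg=cfg,
                                 haptic_noise=haptic_model, n_per_block=5)


class TestGenerator:
    def test_layout_and_positivity(self, small_table):
        assert list(small_table.columns) == S1_COLUMNS
        assert (small_table[S1_COLUMNS[:4]] > 0).all().all()
        assert small_table["dyad"].nunique() == 3

    def test_fixed_seed_reproducible_file(self, cfg, haptic_model, tmp_path):
        a = generate_dyad_dataset(2, "goal_integration", seed=9, cfg=cfg,
                                  haptic_noise=haptic_model, n_per_block=5)
        b = generate_dyad_dataset(2, "goal_integration", seed=9, cfg=cfg,
                                  haptic_noise=haptic_model, n_per_block=5)
        pa, pb = tmp_path / "a.txt", tmp_path / "b.txt"
        write_s1(a, pa)
        write_s1(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_equal_skill_centers_relative_error_at_zero(self, cfg,
                                                        haptic_model):
        df = generate_dyad_dataset(3, "goal_integration", seed=2, cfg=cfg,
                                   skill_band_deg=(3.0, 3.0),
                                   haptic_noise=haptic_model, n_per_block=5)
        out = s1_to_outcomes(df)
        assert abs(out["delta_p"].mean()) < 0.1

    def test_order_constant_within_dyad(self, small_table):
        assert (small_table.groupby("dyad")["order"].nunique() == 1).all()

    def test_rejects_too_few_dyads(self, cfg):
        with pytest.raises(ValueError):
            generate_dyad_dataset(1, "neuromechanical", seed=0, cfg=cfg)


class TestTrialPairIO:
    def test_round_trip_lossless(self, small_table, tmp_path):
        p = tmp_path / "pairs.txt"
        write_s1(small_table, p)
        back = read_s1(p)
        assert np.allclose(back.to_numpy(), small_table.to_numpy())

    @pytest.mark.parametrize("n_cols", [18, 20])
    def test_rejects_wrong_column_count(self, small_table, tmp_path, n_cols):
        arr = small_table.to_numpy()
        if n_cols < arr.shape[1]:
            arr = arr[:, :n_cols]
        else:
            arr = np.column_stack([arr, arr[:, 0]])
        p = tmp_path / "bad.txt"
        np.savetxt(p, arr, delimiter="\t")
        with pytest.raises(ValueError, match="columns"):
            read_s1(p)

    def test_rejects_non_numeric_cells(self, small_table, tmp_path):
        p = tmp_path / "bad.txt"
        write_s1(small_table, p)
        text = p.read_text().replace(
            text_first_number(p.read_text()), "abc", 1)
        p.write_text(text)
        with pytest.raises(ValueError):
            read_s1(p)

    def test_rejects_unit_inconsistent_stiffness(self, small_table, tmp_path):
        bad = small_table.copy()
        # stiffness accidentally written in Nm/rad instead of Nm/deg
        bad["stiffness_nm_deg"] = bad["stiffness_nm_deg"] * RAD2DEG
        p = tmp_path / "bad.txt"
        write_s1(bad, p)
        with pytest.raises(ValueError, match="stiffness"):
            read_s1(p)

    def test_whitespace_delimiters_accepted(self, small_table, tmp_path):
        p = tmp_path / "pairs.txt"
        write_s1(small_table, p)
        spaced = p.read_text().replace("\t", "   ")
        p2 = tmp_path / "spaced.txt"
        p2.write_text(spaced)
        back = read_s1(p2)
        assert len(back) == len(small_table)


def text_first_number(text):
    return text.split()[0]


class TestOutcomes:
    def test_hand_built_row_metrics(self):
        row = {c: 1.0 for c in S1_COLUMNS}
        row.update({"solo_error_1": 2.0, "solo_error_2": 4.0,
                    "conn_error_1": 1.0, "conn_error_2": 2.0,
                    "solo_effort_1": 1.0, "conn_effort_1": 1.5,
                    "solo_effort_2": 2.0, "conn_effort_2": 1.0,
                    "stiffness_nm_deg": 17.2 * DEG, "dyad": 1, "order": 0})
        out = s1_to_outcomes(pd.DataFrame([row], columns=S1_COLUMNS))
        s1 = out[out.subject == 1].iloc[0]
        assert s1["delta_c"] == pytest.approx(1 - 1.0 / 2.0)
        assert s1["delta_p"] == pytest.approx(1 - 4.0 / 2.0)
        assert s1["E"] == pytest.approx(0.5)
        assert s1["kappa"] == pytest.approx(np.log10(17.2))
        assert s1["block_level"] == "hard"

    def test_two_rows_per_pair(self, small_table):
        out = s1_to_outcomes(small_table)
        assert len(out) == 2 * len(small_table)


class TestHapticTrackingIO:
    def make_record(self):
        errors = np.repeat([[3.0], [1.5], [0.8]], 5, axis=0) * np.ones((1, 8))
        stiff = np.repeat([[0.3 * DEG], [1.7 * DEG], [17.2 * DEG]],
                          5, axis=0) * np.ones((1, 8))
        return HapticTrackingRecord(errors_deg=errors,
                                    stiffness_nm_deg=stiff)

    def test_round_trip(self, tmp_path):
        rec = self.make_record()
        p = tmp_path / "haptic.txt"
        write_s2(rec, p)
        back = read_s2(p)
        assert np.allclose(back.errors_deg, rec.errors_deg)
        assert np.allclose(back.stiffness_nm_deg, rec.stiffness_nm_deg)
        assert back.errors_deg.shape[1] == 8

    def test_rejects_wrong_row_count(self, tmp_path):
        p = tmp_path / "bad.txt"
        np.savetxt(p, np.ones((29, 8)))
        with pytest.raises(ValueError, match="30 rows"):
            read_s2(p)

    def test_rejects_nonconstant_stiffness_blocks(self, tmp_path):
        rec = self.make_record()
        arr = np.vstack([rec.errors_deg, rec.stiffness_nm_deg])
        arr[17, 0] = 99.0
        p = tmp_path / "bad.txt"
        np.savetxt(p, arr)
        with pytest.raises(ValueError, match="constant"):
            read_s2(p)

    def test_mean_error_by_stiffness(self):
        rec = self.make_record()
        means = rec.mean_error_by_stiffness()
        assert means[0.3] == pytest.approx(3.0)
        assert means[17.2] == pytest.approx(0.8)
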