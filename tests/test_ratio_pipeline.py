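"""Orientation, normalization, replicate pooling and sentinel substitution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lysoenrich as le
from lysoenrich.errors import DegenerateInputError, DesignError, LysoEnrichError
from lysoenrich.ratio_pipeline import (
    EXTREME_HIGH,
    EXTREME_LOW,
    HIGH,
    LOW,
    MISSING,
    NONE,
    VALID,
)


def make_records(simple_design, ratios_by_protein):
    """ratios_by_protein: pid -> list of 4 H/L ratios (None = missing)."""
    records = []
    for pid, values in ratios_by_protein.items():
        for rep, v in enumerate(values, start=1):
            records.append(
                le.QuantRecord(
                    protein_id=pid, cell_line="L1", replicate=rep,
                    ratio_heavy_over_light=v,
                )
            )
    return records


class TestOrientRatios:
    def test_heavy_channel_keeps_ratio_light_inverts(self, simple_design):
        records = [
            le.QuantRecord("P1", "L1", 3, ratio_heavy_over_light=4.0),  # heavy
            le.QuantRecord("P1", "L1", 1, ratio_heavy_over_light=4.0),  # light
        ]
        oriented = le.orient_ratios(records, simple_design)
        by_rep = oriented.set_index("replicate")["sc_ratio"]
        assert by_rep[3] == 4.0
        assert by_rep[1] == 0.25

    def test_reported_sentinel_passes_through(self, simple_design):
        records = [
            le.QuantRecord("P1", "L1", 1, reported_spions_over_control=100.0),
        ]
        oriented = le.orient_ratios(records, simple_design)
        assert oriented["sc_ratio"].iloc[0] == 100.0

    def test_hl_sentinel_swaps_direction_in_light_replicate(self, simple_design):
        records = [
            le.QuantRecord("P1", "L1", 1, ratio_heavy_over_light=100.0),  # light
            le.QuantRecord("P2", "L1", 3, ratio_heavy_over_light=100.0),  # heavy
        ]
        oriented = le.orient_ratios(records, simple_design)
        by_pid = oriented.set_index("protein_id")["sc_ratio"]
        assert by_pid["P1"] == 0.01  # SPIONs-channel empty -> low code
        assert by_pid["P2"] == 100.0

    def test_unknown_replicate_is_design_error(self, simple_design):
        records = [le.QuantRecord("P1", "L1", 9, ratio_heavy_over_light=2.0)]
        with pytest.raises(DesignError):
            le.orient_ratios(records, simple_design)


class TestBuildRatioMatrix:
    def test_median_normalization_arithmetic(self, simple_design):
        # one replicate column with ratios (1, 2, 4): log2 (0, 1, 2),
        # median 1 -> normalized (-1, 0, 1)
        records = [
            le.QuantRecord(p, "L1", 3, ratio_heavy_over_light=v)
            for p, v in (("A", 1.0), ("B", 2.0), ("C", 4.0))
        ]
        matrix = le.build_ratio_matrix(
            le.orient_ratios(records, simple_design), simple_design
        )
        values = matrix.cells.set_index("protein_id")["log2_value"]
        assert values["A"] == -1.0 and values["B"] == 0.0 and values["C"] == 1.0

    def test_centred_column_unchanged(self, simple_design):
        records = [
            le.QuantRecord(p, "L1", 3, ratio_heavy_over_light=v)
            for p, v in (("A", 0.5), ("B", 1.0), ("C", 2.0))
        ]
        matrix = le.build_ratio_matrix(
            le.orient_ratios(records, simple_design), simple_design
        )
        values = matrix.cells.set_index("protein_id")["log2_value"]
        assert values["A"] == -1.0 and values["B"] == 0.0 and values["C"] == 1.0

    def test_sentinel_excluded_from_normalization_median(self, simple_design):
        # column (2, 100, 8): sentinel excluded -> log2 (1, -, 3), median 2
        records = [
            le.QuantRecord(p, "L1", 3, ratio_heavy_over_light=v)
            for p, v in (("A", 2.0), ("B", 100.0), ("C", 8.0))
        ]
        matrix = le.build_ratio_matrix(
            le.orient_ratios(records, simple_design), simple_design
        )
        cells = matrix.cells.set_index("protein_id")
        assert cells.loc["A", "log2_value"] == -1.0
        assert cells.loc["C", "log2_value"] == 1.0
        assert cells.loc["B", "status"] == EXTREME_HIGH
        assert np.isnan(cells.loc["B", "log2_value"])

    def test_statuses(self, simple_design):
        records = [
            le.QuantRecord("A", "L1", 3, ratio_heavy_over_light=2.0),
            le.QuantRecord("B", "L1", 3, reported_spions_over_control=0.01),
            le.QuantRecord("C", "L1", 3, ratio_heavy_over_light=None),
        ]
        matrix = le.build_ratio_matrix(
            le.orient_ratios(records, simple_design), simple_design
        )
        status = matrix.cells.set_index("protein_id")["status"]
        assert status["A"] == VALID
        assert status["B"] == EXTREME_LOW
        assert status["C"] == MISSING

    def test_nonpositive_ratio_rejected(self, simple_design):
        records = [le.QuantRecord("A", "L1", 3, ratio_heavy_over_light=-2.0)]
        with pytest.raises(LysoEnrichError, match="nonpositive"):
            le.build_ratio_matrix(
                le.orient_ratios(records, simple_design), simple_design
            )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_per_replicate_median_is_zero(self, seed):
        design = le.StudyDesign(
            cell_lines=("L1",),
            replicates_per_line=4,
            channel_of_spions={("L1", r): ("light" if r <= 2 else "heavy")
                               for r in range(1, 5)},
        )
        rng = np.random.default_rng(seed)
        records = []
        for i in range(rng.integers(5, 30)):
            for rep in range(1, 5):
                if rng.random() < 0.2:
                    continue
                records.append(
                    le.QuantRecord(
                        f"P{i}", "L1", rep,
                        ratio_heavy_over_light=float(
                            2.0 ** rng.normal(0, 1.5)
                        ),
                    )
                )
        if not records:
            return
        matrix = le.build_ratio_matrix(le.orient_ratios(records, design), design)
        valid = matrix.cells[matrix.cells["status"] == VALID]
        for _, column in valid.groupby("replicate"):
            med = float(column["log2_value"].median())
            assert med == 0.0 or abs(med) < 1e-12


class TestPoolReplicates:
    def pool(self, simple_design, ratios):
        records = make_records(simple_design, ratios)
        matrix = le.build_ratio_matrix(
            le.orient_ratios(records, simple_design), simple_design
        )
        return le.pool_replicates(matrix, simple_design)

    def test_min_valid_replicates_filter(self, simple_design):
        design = le.StudyDesign(
            cell_lines=("L1",), replicates_per_line=4,
            channel_of_spions={("L1", r): "heavy" for r in range(1, 5)},
        )
        # medians are computed per replicate over one protein -> normalized
        # to 0; use several proteins so normalization is meaningful
        ratios = {
            "KEEP": [2.0, 2.0, 2.0, None],   # 3 valid -> kept
            "DROP": [2.0, 2.0, None, None],  # 2 valid -> dropped
            "REF1": [1.0, 1.0, 1.0, 1.0],
            "REF2": [4.0, 4.0, 4.0, 4.0],
        }
        records = make_records(design, ratios)
        matrix = le.build_ratio_matrix(le.orient_ratios(records, design), design)
        pooled = le.pool_replicates(matrix, design)
        assert set(pooled.table["protein_id"]) == {"KEEP", "REF1", "REF2"}
        assert pooled.drop_log["protein_id"].tolist() == ["DROP"]
        assert "n_valid=2 < 3" in pooled.drop_log["reason"].iloc[0]
        keep = pooled.table.set_index("protein_id").loc["KEEP"]
        assert keep["n_valid"] == 3

    def test_even_count_median_is_mean_of_middle_pair(self):
        design = le.StudyDesign(
            cell_lines=("L1",), replicates_per_line=4,
            channel_of_spions={("L1", r): "heavy" for r in range(1, 5)},
        )
        # P has per-replicate normalized values (0, 1, 2, 3) once centred
        # against a large symmetric background; directly check the pooled
        # median convention on a crafted matrix instead
        cells = pd.DataFrame(
            {
                "cell_line": ["L1"] * 4,
                "protein_id": ["P"] * 4,
                "replicate": [1, 2, 3, 4],
                "status": [VALID] * 4,
                "log2_value": [0.0, 1.0, 2.0, 3.0],
            }
        )
        pooled = le.pool_replicates(
            le.RatioMatrix(cells=cells, design=design), design
        )
        assert pooled.table["x_log2"].iloc[0] == 1.5

    def test_extreme_classification_and_mixed_fallback(self):
        design = le.StudyDesign(
            cell_lines=("L1",), replicates_per_line=4,
            channel_of_spions={("L1", r): "heavy" for r in range(1, 5)},
        )
        cells = []
        spec = {
            "ALLHIGH": [EXTREME_HIGH] * 4,
            "ALLLOW": [EXTREME_LOW] * 3 + [MISSING],
            "MIXED": [VALID, VALID, VALID, EXTREME_HIGH],  # finite wins
            "TOOFEW": [EXTREME_HIGH, EXTREME_HIGH, MISSING, MISSING],
        }
        for pid, statuses in spec.items():
            for rep, s in enumerate(statuses, start=1):
                cells.append(
                    {
                        "cell_line": "L1", "protein_id": pid, "replicate": rep,
                        "status": s,
                        "log2_value": 0.5 if s == VALID else np.nan,
                    }
                )
        pooled = le.pool_replicates(
            le.RatioMatrix(cells=pd.DataFrame(cells), design=design), design
        )
        table = pooled.table.set_index("protein_id")
        assert table.loc["ALLHIGH", "extreme"] == HIGH
        assert table.loc["ALLLOW", "extreme"] == LOW
        assert table.loc["MIXED", "extreme"] == NONE
        assert table.loc["MIXED", "x_log2"] == 0.5
        assert "TOOFEW" in set(pooled.drop_log["protein_id"])

    def test_pooling_invariant_to_row_order(self, simple_design):
        ratios = {
            f"P{i}": [float(2.0 ** (i % 3)), 1.0, 4.0, None] for i in range(8)
        }
        records = make_records(simple_design, ratios)
        a = le.pooled_ratios_from_records(records, simple_design)
        b = le.pooled_ratios_from_records(records[::-1], simple_design)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestSubstituteExtremes:
    def build(self, extremes):
        rows = [
            {"cell_line": "L1", "protein_id": "A", "x_log2": -2.1,
             "n_valid": 4, "extreme": NONE},
            {"cell_line": "L1", "protein_id": "B", "x_log2": 3.4,
             "n_valid": 4, "extreme": NONE},
            {"cell_line": "L1", "protein_id": "C", "x_log2": 0.2,
             "n_valid": 4, "extreme": NONE},
        ]
        for pid, tag in extremes:
            rows.append(
                {"cell_line": "L1", "protein_id": pid, "x_log2": np.nan,
                 "n_valid": 0, "extreme": tag}
            )
        return le.PooledRatios(table=pd.DataFrame(rows))

    def test_high_gets_max_low_gets_min_tags_kept(self):
        pooled = self.build([("H1", HIGH), ("H2", HIGH), ("L", LOW)])
        out = le.substitute_extremes(pooled).table.set_index("protein_id")
        assert out.loc["H1", "x_log2"] == 3.4
        assert out.loc["H2", "x_log2"] == 3.4
        assert out.loc["L", "x_log2"] == -2.1
        assert out.loc["H1", "extreme"] == HIGH
        assert out.loc["L", "extreme"] == LOW

    def test_all_extreme_is_degenerate(self):
        table = pd.DataFrame(
            [{"cell_line": "L1", "protein_id": "H", "x_log2": np.nan,
              "n_valid": 0, "extreme": HIGH}]
        )
        with pytest.raises(DegenerateInputError):
            le.substitute_extremes(le.PooledRatios(table=table))


class TestLabelSwitchSymmetry:
    def test_inverting_ratios_and_flipping_design_is_bit_identical(self):
        design = le.StudyDesign(
            cell_lines=("L1", "L2"), replicates_per_line=4,
            channel_of_spions={(line, r): ("light" if r <= 2 else "heavy")
                               for line in ("L1", "L2") for r in range(1, 5)},
        )
        rng = np.random.default_rng(11)
        records, flipped = [], []
        for i in range(40):
            for line in ("L1", "L2"):
                for rep in range(1, 5):
                    if rng.random() < 0.15:
                        continue
                    if rng.random() < 0.05:
                        hl = 100.0
                        inv = 0.01
                    else:
                        # integer powers of two are exactly invertible, so
                        # the symmetry can be asserted bitwise
                        hl = float(2.0 ** int(rng.integers(-6, 7)))
                        inv = 1.0 / hl
                    records.append(
                        le.QuantRecord(f"P{i}", line, rep,
                                       ratio_heavy_over_light=hl)
                    )
                    flipped.append(
                        le.QuantRecord(f"P{i}", line, rep,
                                       ratio_heavy_over_light=inv)
                    )
        a = le.pooled_ratios_from_records(records, design)
        b = le.pooled_ratios_from_records(flipped, design.flipped())
        pd.testing.assert_frame_equal(a.table, b.table)
        pd.testing.assert_frame_equal(a.drop_log, b.drop_log)
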