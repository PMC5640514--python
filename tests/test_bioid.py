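"""Bait normalization, ±DOX ratios, and the myotube-enrichment filter."""

import numpy as np
import pandas as pd
import pytest

from myonuc.bioid import (QuantTable, bait_normalize, candidate_set,
                          dox_ratio, enrichment_filter, identification_gate,
                          ratio_table, read_quant_table, threshold_sweep,
                          write_quant_table)


def small_table(bait_vals=(100.0, 100.0, 100.0, 100.0, 100.0, 100.0)):
    """Two proteins + bait, 1 replicate would be too small: use 3 reps,
    both states, biotin-only controls."""
    cols, data = [], {}
    i = 0
    for state in ("myoblast", "myotube"):
        for rep in (1, 2, 3):
            cols.append((state, "noDOX_biotin", rep))
            cols.append((state, "DOX_biotin", rep))
    rows = {
        "A": [10, 100, 10, 100, 10, 100, 10, 400, 10, 400, 10, 400],
        "B": [20, 200, 20, 200, 20, 200, 20, 200, 20, 200, 20, 200],
        "BAIT": [1, bait_vals[0], 1, bait_vals[1], 1, bait_vals[2],
                 1, bait_vals[3], 1, bait_vals[4], 1, bait_vals[5]],
    }
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=pd.MultiIndex.from_tuples(
                                    cols, names=["cell_state", "treatment",
                                                 "replicate"])).astype(float)
    return QuantTable(df, "BAIT")


class TestBaitNormalize:
    def test_equal_bait_is_identity(self):
        qt = small_table()
        out = bait_normalize(qt)
        pd.testing.assert_frame_equal(out.data, qt.data)

    def test_two_sample_factors_go_to_geometric_mean(self):
        cols = pd.MultiIndex.from_tuples(
            [("myotube", "DOX_biotin", 1), ("myotube", "DOX_biotin", 2)],
            names=["cell_state", "treatment", "replicate"])
        df = pd.DataFrame([[100.0, 200.0], [50.0, 50.0]],
                          index=["BAIT", "X"], columns=cols)
        out = bait_normalize(QuantTable(df, "BAIT"))
        ref = np.sqrt(100.0 * 200.0)
        assert out.normalization["reference"] == pytest.approx(ref, rel=1e-12)
        f = out.normalization["factors"]
        assert f[("myotube", "DOX_biotin", 1)] == pytest.approx(np.sqrt(2.0))
        assert f[("myotube", "DOX_biotin", 2)] == pytest.approx(1 / np.sqrt(2.0))
        # bait now equal in all +DOX samples
        bait = out.data.loc["BAIT"]
        assert np.allclose(bait, ref)

    def test_non_bait_ratios_scale_by_factor_ratio(self):
        cols = pd.MultiIndex.from_tuples(
            [("myotube", "DOX_biotin", 1), ("myotube", "DOX_biotin", 2)],
            names=["cell_state", "treatment", "replicate"])
        df = pd.DataFrame([[100.0, 200.0], [60.0, 30.0]],
                          index=["BAIT", "X"], columns=cols)
        out = bait_normalize(QuantTable(df, "BAIT"))
        before = 60.0 / 30.0
        after = out.data.loc["X"].iloc[0] / out.data.loc["X"].iloc[1]
        assert after == pytest.approx(before * (np.sqrt(2) / (1 / np.sqrt(2))))

    def test_zero_bait_errors_with_sample_name(self):
        qt = small_table(bait_vals=(100, 0.0, 100, 100, 100, 100))
        with pytest.raises(ValueError, match="BAIT"):
            bait_normalize(qt)

    def test_column_scale_invariance_of_ratios(self):
        """Scaling any +DOX column is absorbed by bait normalization: all
        ratios shift by one protein-independent constant (the geometric-mean
        reference moves), so ratio-of-ratios are exactly invariant."""
        qt = small_table()
        scaled = qt.data.copy()
        col = ("myotube", "DOX_biotin", 2)
        scaled[col] = scaled[col] * 7.5
        r1 = ratio_table(bait_normalize(qt))
        r2 = ratio_table(bait_normalize(QuantTable(scaled, "BAIT")))
        const = (r2 / r1).to_numpy()
        assert np.allclose(const, const.flat[0])
        ror1 = r1["myotube"] / r1["myoblast"]
        ror2 = r2["myotube"] / r2["myoblast"]
        pd.testing.assert_frame_equal(ror1, ror2)


class TestDoxRatio:
    def test_equal_abundance_ratio_near_one(self):
        qt = small_table()
        r = dox_ratio(qt, "B", "myotube", 1, pseudocount=0.0)
        assert r == pytest.approx(10.0)  # 200/20: +DOX biotin over control

    def test_plain_arithmetic(self):
        qt = small_table()
        assert dox_ratio(qt, "A", "myoblast", 2, pseudocount=0.0) == \
            pytest.approx(10.0)

    def test_absent_denominator_uses_pseudocount(self):
        qt = small_table()
        qt.data.loc["A", ("myotube", "noDOX_biotin", 1)] = np.nan
        r = dox_ratio(qt, "A", "myotube", 1)
        assert np.isfinite(r) and r > 10.0  # large but finite

    def test_absent_protein_gives_nan_not_exception(self):
        qt = small_table()
        assert np.isnan(dox_ratio(qt, "ZZZ", "myotube", 1))


class TestEnrichmentFilter:
    def _ratios(self, ror_by_protein):
        """Build a ratio frame whose myoblast ratios are 1."""
        reps = [1, 2, 3]
        cols = pd.MultiIndex.from_tuples(
            [(s, r) for s in ("myoblast", "myotube") for r in reps],
            names=["cell_state", "replicate"])
        rows = {p: [1.0] * 3 + list(v) for p, v in ror_by_protein.items()}
        return pd.DataFrame.from_dict(rows, orient="index", columns=cols)

    def test_two_of_three_rule(self):
        rec = enrichment_filter(self._ratios({"p": (2.0, 3.0, 0.5)}),
                                fold_threshold=1.0)
        assert bool(rec.loc["p", "pass"])

    def test_one_of_three_fails(self):
        rec = enrichment_filter(self._ratios({"p": (0.9, 0.9, 5.0)}),
                                fold_threshold=1.0)
        assert not bool(rec.loc["p", "pass"])

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        ror = {f"p{i}": tuple(np.exp(rng.normal(0, 1, 3))) for i in range(200)}
        ratios = self._ratios(ror)
        sizes = [int(enrichment_filter(ratios, t)["pass"].sum())
                 for t in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_sweep_reports_monotone_curve(self):
        rng = np.random.default_rng(1)
        ratios = self._ratios(
            {f"p{i}": tuple(np.exp(rng.normal(0, 1, 3))) for i in range(100)})
        sweep = threshold_sweep(ratios, [1.0, 2.0, 4.0])
        assert list(sweep["n_candidates"]) == \
            sorted(sweep["n_candidates"], reverse=True)

    def test_bait_not_a_candidate(self):
        rec = enrichment_filter(self._ratios({"p": (4.0, 4.0, 4.0),
                                              "BAIT": (9.0, 9.0, 9.0)}),
                                fold_threshold=1.0, bait_id="BAIT")
        assert not bool(rec.loc["BAIT", "pass"])
        assert "BAIT" not in candidate_set(rec)


class TestIdentificationGate:
    @pytest.mark.parametrize("flags,kept", [
        ((True, True, False), True),
        ((True, False, False), False),
        ((True, True, True), True),
    ])
    def test_truth_table(self, flags, kept):
        ident = pd.DataFrame([flags], index=["p"], columns=[1, 2, 3])
        assert (("p" in identification_gate(ident)) is kept)


class TestIO:
    def test_roundtrip(self, tmp_path):
        qt = small_table()
        path = tmp_path / "quant.csv"
        write_quant_table(qt, path)
        back = read_quant_table(path, "BAIT")
        pd.testing.assert_frame_equal(back.data, qt.data,
                                      check_names=False)
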