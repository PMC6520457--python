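"""CPM normalization, log2 fold changes, gene scores, tests and ECDF."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pairedscreen.io_quant import CountMatrix, make_library
from pairedscreen.scoring import (
    NormalizedMatrix,
    ScoringError,
    ecdf,
    gene_score,
    gene_test,
    lfc_from_counts,
    normalize_cpm,
    sgrna_lfc,
)

from .oracles import t_pvalue_numeric


def _counts(data: dict, meta: list[tuple]) -> CountMatrix:
    counts = pd.DataFrame(data)
    counts.index = pd.Index([f"s{i}" for i in range(len(counts))], name="sgrna_id")
    samples = pd.DataFrame(
        meta, columns=["sample_id", "cell_line", "day", "replicate"]
    ).set_index("sample_id")
    return CountMatrix(counts=counts, samples=samples)


def _spacer(i: int, length: int = 20) -> str:
    """Distinct deterministic ACGT k-mer per index (base-4 encoding)."""
    bases = "ACGT"
    return "".join(bases[(i // (4**k)) % 4] for k in range(length))


def _lfc_frame(values_by_sgrna: dict[str, float], cell_line="KMM", day=21) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sgrna_id": list(values_by_sgrna),
            "cell_line": cell_line,
            "day": day,
            "lfc": list(values_by_sgrna.values()),
        }
    )


class TestNormalizeCpm:
    def test_one_sample_scales_to_per_million(self):
        cm = _counts({"x": [1, 3]}, [("x", "MM", 1, 1)])
        norm = normalize_cpm(cm)
        assert norm.cpm["x"].tolist() == [250000.0, 750000.0]

    @given(st.lists(st.integers(0, 10_000), min_size=2, max_size=20).filter(lambda v: sum(v) > 0))
    def test_cpm_sums_to_one_million(self, values):
        cm = _counts({"x": values}, [("x", "MM", 1, 1)])
        norm = normalize_cpm(cm)
        assert norm.cpm["x"].sum() == pytest.approx(1e6, rel=1e-6)

    def test_all_zero_sample_is_an_error_naming_it(self):
        cm = _counts({"x": [1, 2], "y": [0, 0]}, [("x", "MM", 1, 1), ("y", "MM", 4, 1)])
        with pytest.raises(ScoringError, match="y"):
            normalize_cpm(cm)

    def test_nonpositive_pseudocount_rejected(self):
        cm = _counts({"x": [1, 2]}, [("x", "MM", 1, 1)])
        with pytest.raises(ScoringError):
            normalize_cpm(cm, pseudocount=0)


def _tidy(lfc: pd.DataFrame, cell_line, day) -> pd.Series:
    sub = lfc[(lfc["cell_line"] == cell_line) & (lfc["day"] == day)]
    return sub.set_index("sgrna_id")["lfc"]


class TestSgrnaLfc:
    def _norm(self, cpm: dict, pseudocount: float) -> tuple[NormalizedMatrix, pd.DataFrame]:
        frame = pd.DataFrame(cpm)
        frame.index = pd.Index([f"s{i}" for i in range(len(frame))], name="sgrna_id")
        samples = pd.DataFrame(
            {
                "sample_id": list(cpm),
                "cell_line": "MM",
                "day": [1, 21][: len(cpm)] if len(cpm) <= 2 else [1] + [21] * (len(cpm) - 1),
                "replicate": 1,
            }
        ).set_index("sample_id")
        return NormalizedMatrix(cpm=frame, pseudocount=pseudocount), samples

    def test_equal_cpm_gives_zero(self):
        norm, samples = self._norm({"d1": [10.0, 20.0], "d21": [10.0, 20.0]}, 0.5)
        lfc = _tidy(sgrna_lfc(norm, samples), "MM", 21)
        assert lfc.tolist() == [0.0, 0.0]

    def test_thirtytwo_fold_drop_is_minus_five(self):
        norm, samples = self._norm({"d1": [32.0, 10.0], "d21": [1.0, 10.0]}, 1e-12)
        lfc = _tidy(sgrna_lfc(norm, samples), "MM", 21)
        assert lfc.iloc[0] == pytest.approx(-5.0, abs=1e-9)

    def test_pseudocount_forces_zero_over_zero_to_zero(self):
        norm, samples = self._norm({"d1": [0.0, 5.0], "d21": [0.0, 5.0]}, 0.5)
        lfc = _tidy(sgrna_lfc(norm, samples), "MM", 21)
        assert lfc.iloc[0] == 0.0

    def test_reference_day_lfc_identically_zero(self, small_screen):
        lfc = lfc_from_counts(small_screen.counts)
        ref = lfc[lfc["day"] == 1]
        assert (ref["lfc"] == 0).all()

    def test_replicates_averaged_on_cpm_scale(self):
        frame = pd.DataFrame({"d1": [10.0], "t_r1": [10.0], "t_r2": [30.0]})
        frame.index = pd.Index(["s0"], name="sgrna_id")
        samples = pd.DataFrame(
            {
                "sample_id": ["d1", "t_r1", "t_r2"],
                "cell_line": "MM",
                "day": [1, 21, 21],
                "replicate": [1, 1, 2],
            }
        ).set_index("sample_id")
        norm = NormalizedMatrix(cpm=frame, pseudocount=1e-12)
        lfc = _tidy(sgrna_lfc(norm, samples), "MM", 21)
        assert lfc.iloc[0] == pytest.approx(1.0)  # mean(10, 30)/10 = 2

    def test_missing_reference_day_is_an_error(self):
        norm, samples = self._norm({"d1": [1.0], "d21": [2.0]}, 0.5)
        with pytest.raises(ScoringError, match="reference day 2"):
            sgrna_lfc(norm, samples, reference_day=2)

    def test_median_centering_zeroes_the_per_day_median(self, small_screen):
        lfc = lfc_from_counts(small_screen.counts, center="median")
        for (_, day), sub in lfc.groupby(["cell_line", "day"]):
            assert np.median(sub["lfc"]) == pytest.approx(0.0, abs=1e-12)

    def test_raw_and_centered_differ_by_a_per_day_constant(self, small_screen):
        raw = lfc_from_counts(small_screen.counts)
        centered = lfc_from_counts(small_screen.counts, center="median")
        delta = raw["lfc"] - centered["lfc"]
        spread = pd.DataFrame({"cell_line": raw["cell_line"], "day": raw["day"], "d": delta})
        assert (spread.groupby(["cell_line", "day"])["d"].std() < 1e-12).all()


class TestGeneScore:
    def _library(self, n=3):
        ids = [f"s{i}" for i in range(n)] + ["nt"]
        spacers = [_spacer(i) for i in range(n + 1)]
        frame = pd.DataFrame(
            {
                "sgrna_id": ids,
                "gene_id": ["g"] * n + ["non-targeting"],
                "spacer": spacers,
            }
        )
        return make_library(frame)

    def test_mean_of_sgrna_lfcs(self):
        lib = self._library()
        lfc = _lfc_frame({"s0": -1.0, "s1": -2.0, "s2": -3.0, "nt": 0.0})
        out = gene_score(lfc, lib)
        assert out.loc[out["gene_id"] == "g", "cs"].iloc[0] == -2.0
        assert out.loc[out["gene_id"] == "g", "n_sgrna"].iloc[0] == 3

    def test_all_zero_lfcs_give_zero_score(self):
        lib = self._library()
        out = gene_score(_lfc_frame({"s0": 0.0, "s1": 0.0, "s2": 0.0}), lib)
        assert out["cs"].iloc[0] == 0.0

    def test_controls_excluded_from_gene_scores(self):
        lib = self._library()
        out = gene_score(_lfc_frame({"s0": -1.0, "s1": -1.0, "s2": -1.0, "nt": -9.0}), lib)
        assert set(out["gene_id"]) == {"g"}

    def test_uniform_depletion_gives_negative_score(self):
        """A gene whose guides all drop out scores negative (sign convention)."""
        lfc = _lfc_frame({"s0": -3.0, "s1": -2.5, "s2": -4.0})
        out = gene_score(lfc, self._library())
        assert (out["cs"] < 0).all()

    def test_linearity_under_scaling(self):
        lib = self._library()
        base = {"s0": -1.2, "s1": 0.4, "s2": 2.0}
        cs1 = gene_score(_lfc_frame(base), lib)["cs"].iloc[0]
        cs3 = gene_score(_lfc_frame({k: 3 * v for k, v in base.items()}), lib)["cs"].iloc[0]
        assert cs3 == pytest.approx(3 * cs1)

    def test_gene_with_no_lfc_rows_dropped_with_warning(self, caplog):
        frame = pd.DataFrame(
            {
                "sgrna_id": ["s0", "x0"],
                "gene_id": ["g", "ghost"],
                "spacer": ["ACGTACGTACGTACGTACGT", "TGCATGCATGCATGCATGCA"],
            }
        )
        lib = make_library(frame)
        with caplog.at_level("WARNING"):
            out = gene_score(_lfc_frame({"s0": -1.0}), lib)
        assert "ghost" in caplog.text
        assert set(out["gene_id"]) == {"g"}


class TestGeneTest:
    def _fit(self, values, method="t", controls=None):
        ids = [f"s{i}" for i in range(len(values))]
        rows = dict(zip(ids, values))
        genes = ["g"] * len(values)
        if controls is not None:
            for i, v in enumerate(controls):
                rows[f"nt{i}"] = v
            ids += [f"nt{i}" for i in range(len(controls))]
            genes += ["non-targeting"] * len(controls)
        spacers = [_spacer(i) for i in range(len(ids))]
        lib = make_library(pd.DataFrame({"sgrna_id": ids, "gene_id": genes, "spacer": spacers}))
        return gene_test(_lfc_frame(rows), lib, method=method)

    def test_zero_variance_nonzero_mean_is_certain(self):
        out = self._fit([-2.0, -2.0, -2.0])
        assert out["pvalue"].iloc[0] == 0.0

    def test_zero_variance_zero_mean_is_uninformative(self):
        out = self._fit([0.0, 0.0, 0.0])
        assert out["pvalue"].iloc[0] == 1.0

    def test_single_sgrna_gets_p_one_with_warning(self):
        with pytest.warns(UserWarning, match="single sgRNA"):
            out = self._fit([-3.0])
        assert out["pvalue"].iloc[0] == 1.0

    def test_textbook_case_matches_numeric_oracle(self):
        values = [-1.0, 0.5, -0.2]
        out = self._fit(values)
        assert out["pvalue"].iloc[0] == pytest.approx(t_pvalue_numeric(values), abs=1e-9)

    def test_t_pvalues_match_numeric_oracle_on_random_cases(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(2, 7))
            values = rng.normal(rng.normal(0, 1), rng.uniform(0.2, 2.0), size=n).tolist()
            out = self._fit(values)
            assert out["pvalue"].iloc[0] == pytest.approx(
                t_pvalue_numeric(values), abs=1e-9
            )

    def test_ks_against_controls(self):
        out = self._fit([-5.0, -5.2, -4.8], method="ks", controls=[0.0, 0.1, -0.1, 0.05, -0.02])
        assert 0 <= out["pvalue"].iloc[0] < 0.2
        null = self._fit([0.0, 0.1, -0.1], method="ks", controls=[0.0, 0.1, -0.1, 0.05, -0.02])
        assert null["pvalue"].iloc[0] > 0.5

    def test_ks_without_controls_is_an_error(self):
        with pytest.raises(ScoringError, match="control"):
            self._fit([-1.0, -2.0], method="ks")

    def test_unknown_method_rejected(self):
        with pytest.raises(ScoringError, match="method"):
            self._fit([-1.0, -2.0], method="wilcoxon")

    def test_bh_adjustment_adds_qvalues_no_smaller_than_p(self, small_screen):
        from pairedscreen.scoring import score_screen

        scored = score_screen(small_screen.counts, small_screen.library, adjust="bh")
        assert "qvalue" in scored.columns
        assert (scored["qvalue"] >= scored["pvalue"] - 1e-12).all()


class TestEcdf:
    def test_three_point_curve(self):
        lfc = _lfc_frame({"s0": -1.0, "s1": 0.0, "s2": 1.0})
        curve = ecdf(lfc, "KMM", 21)
        assert curve["value"].tolist() == [-1.0, 0.0, 1.0]
        assert curve["fraction"].tolist() == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_reference_day_is_a_step_at_zero(self, small_screen):
        lfc = lfc_from_counts(small_screen.counts)
        curve = ecdf(lfc, "MM", 1)
        assert (curve["value"] == 0).all()
        assert curve["fraction"].iloc[-1] == 1.0

    def test_translation_equivariance(self):
        values = {"s0": -1.5, "s1": 0.3, "s2": 2.0, "s3": 0.3}
        base = ecdf(_lfc_frame(values), "KMM", 21)
        shifted = ecdf(_lfc_frame({k: v - 0.7 for k, v in values.items()}), "KMM", 21)
        assert shifted["value"].tolist() == pytest.approx((base["value"] - 0.7).tolist())
        assert shifted["fraction"].tolist() == base["fraction"].tolist()

    def test_empty_selection_is_an_error(self):
        with pytest.raises(ScoringError):
            ecdf(_lfc_frame({"s0": 0.0}), "nope", 21)

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=40))
    def test_fractions_nondecreasing_and_reach_one(self, values):
        lfc = _lfc_frame({f"s{i}": v for i, v in enumerate(values)})
        curve = ecdf(lfc, "KMM", 21)
        fracs = curve["fraction"].to_numpy()
        assert (np.diff(fracs) >= 0).all()
        assert fracs[0] == pytest.approx(1 / len(values))
        assert fracs[-1] == pytest.approx(1.0)
        assert (np.diff(curve["value"].to_numpy()) >= 0).all()
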