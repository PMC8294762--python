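"""Peak annotation, target selection, expression matching and KS shift."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ribodrop import de, shift, sim
from ribodrop.errors import AnalysisError


def make_peaks(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


def make_models(rows):
    return pd.DataFrame(rows, columns=["gene", "region", "chrom", "start", "end", "strand"])


def brute_force_hits(peaks, models):
    """All-pairs interval-overlap oracle (half-open, strand-aware)."""
    hits = []
    for pi, p in peaks.iterrows():
        for _, m in models.iterrows():
            if p["chrom"] != m["chrom"]:
                continue
            if max(p["start"], m["start"]) >= min(p["end"], m["end"]):
                continue
            if p["strand"] != "." and m["strand"] != "." and p["strand"] != m["strand"]:
                continue
            hits.append((pi, m["gene"], m["region"]))
    return sorted(hits)


class TestAnnotatePeaks:
    def test_simple_overlap(self):
        peaks = make_peaks([("chr1", 100, 150, "+")])
        models = make_models([("geneA", "cds", "chr1", 120, 200, "+")])
        hits = shift.annotate_peaks(peaks, models)
        assert list(hits.itertuples(index=False)) == [(0, "geneA", "cds")]

    def test_half_open_boundary_no_overlap(self):
        peaks = make_peaks([("chr1", 100, 120, "+")])
        models = make_models([("geneA", "cds", "chr1", 120, 200, "+")])
        assert shift.annotate_peaks(peaks, models).empty

    def test_strand_rules(self):
        models = make_models([("geneA", "cds", "chr1", 0, 100, "+")])
        assert shift.annotate_peaks(make_peaks([("chr1", 10, 20, "-")]), models).empty
        assert len(shift.annotate_peaks(make_peaks([("chr1", 10, 20, ".")]), models)) == 1
        assert len(shift.annotate_peaks(make_peaks([("chr1", 10, 20, "+")]), models)) == 1

    def test_matches_brute_force_oracle(self, rng):
        labels = ["five_prime_utr", "cds", "three_prime_utr", "intron"]
        for _ in range(20):
            peaks = make_peaks(
                [
                    (f"chr{rng.integers(1, 3)}", s := int(rng.integers(0, 900)),
                     s + int(rng.integers(1, 120)), rng.choice(["+", "-", "."]))
                    for _ in range(20)
                ]
            )
            models = make_models(
                [
                    (f"gene{g}", rng.choice(labels), f"chr{rng.integers(1, 3)}",
                     s := int(rng.integers(0, 900)), s + int(rng.integers(1, 250)),
                     rng.choice(["+", "-"]))
                    for g in range(10)
                ]
            )
            hits = shift.annotate_peaks(peaks, models)
            got = sorted(hits.itertuples(index=False, name=None))
            assert got == brute_force_hits(peaks, models)

    def test_malformed_interval_reports_row(self):
        peaks = make_peaks([("chr1", 100, 150, "+"), ("chr1", 60, 50, "+")])
        models = make_models([("geneA", "cds", "chr1", 0, 100, "+")])
        with pytest.raises(AnalysisError, match="row 1"):
            shift.annotate_peaks(peaks, models)


class TestSelectTargetGenes:
    def setup_method(self):
        self.hits = pd.DataFrame(
            {"peak": [0, 1, 2], "gene": ["gA", "gB", "gB"],
             "region": ["intron", "cds", "intron"]}
        )

    def test_mature_only_drops_intron_only_genes(self):
        assert shift.select_target_genes(self.hits, "mature_only") == {"gB"}

    def test_any_keeps_intron_only_genes(self):
        assert shift.select_target_genes(self.hits, "any") == {"gA", "gB"}

    def test_empty_peaks_empty_set(self):
        assert shift.select_target_genes(self.hits.iloc[:0], "mature_only") == set()


class TestExpressionMatching:
    @staticmethod
    def _de(base_means, z=None):
        n = len(base_means)
        return pd.DataFrame(
            {"gene": [f"g{i}" for i in range(n)], "baseMean": base_means,
             "log2FC": 0.0, "SE": 1.0, "p": 0.5, "padj": 0.5,
             "z": z if z is not None else np.zeros(n)}
        )

    def test_window_is_strict(self):
        # log10 base means: 2.0 (below), 2.5 (boundary), 3.0 (inside),
        # 4.25 (boundary), 3.5 (inside, non-target)
        table = self._de(
            [10**2.0, 10**2.5, 10**3.0, 10**4.25, 10**3.5], z=[1, 2, 3, 4, 5]
        )
        tz, nz = shift.expression_matched_sets(table, {"g0", "g1", "g2", "g3"})
        np.testing.assert_array_equal(tz, [3.0])  # strict bounds exclude the rest
        np.testing.assert_array_equal(nz, [5.0])

    def test_nontarget_inside_window(self):
        table = self._de([10**3.0, 10**3.5], z=[1, 2])
        tz, nz = shift.expression_matched_sets(table, {"g0"})
        np.testing.assert_array_equal(nz, [2.0])

    def test_empty_set_raises(self):
        table = self._de([10**3.0])
        with pytest.raises(AnalysisError, match="non-target"):
            shift.expression_matched_sets(table, {"g0"})


def ks_oracle(x, y):
    """O(n^2) pooled-grid ECDF oracle for the KS statistic."""
    pooled = sorted(list(x) + list(y))
    best = 0.0
    for v in pooled:
        fx = sum(1 for u in x if u <= v) / len(x)
        fy = sum(1 for u in y if u <= v) / len(y)
        best = max(best, abs(fx - fy))
    return best


class TestKsTwoSample:
    def test_identical_samples(self):
        d, p = shift.ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_samples(self):
        d, _ = shift.ks_two_sample([0, 0, 0], [1, 1, 1])
        assert d == 1.0

    def test_small_example(self):
        d, _ = shift.ks_two_sample([1, 2], [1.5, 3])
        assert d == 0.5

    def test_empty_rejected(self):
        with pytest.raises(AnalysisError):
            shift.ks_two_sample([], [1.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        x=st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=30),
        y=st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=30),
    )
    def test_matches_oracle_with_ties(self, x, y):
        d, _ = shift.ks_two_sample(x, y)
        assert d == pytest.approx(ks_oracle(x, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=80)
        y = rng.normal(0.5, 1.0, size=60)
        d0, _ = shift.ks_two_sample(x, y)
        for f in (np.exp, np.arctan, lambda v: v**3):
            d1, _ = shift.ks_two_sample(f(x), f(y))
            assert d1 == pytest.approx(d0, abs=1e-12)


class TestCumulativeShift:
    def test_identical_distributions_no_shift(self):
        z = np.linspace(-2, 2, 50)
        table = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(100)], "baseMean": 1000.0,
             "log2FC": 0.0, "SE": 1.0, "p": 0.5, "padj": 0.5,
             "z": np.concatenate([z, z])}
        )
        result, curves = shift.cumulative_shift(table, {f"g{i}" for i in range(50)})
        assert result.D == 0.0
        assert result.direction == "none"
        assert set(curves) == {"targets", "nontargets"}

    def test_planted_depletion_detected(self):
        cm, truth = sim.simulate_counts(sim.SimCountConfig(target_log2fc=-1.0, seed=21))
        table = de.nb_wald_test(cm)
        targets = set(truth.loc[truth["is_target"], "gene"])
        result, _ = shift.cumulative_shift(table, targets)
        assert result.direction == "down" and result.p < 0.05

    def test_window_removes_abundance_confound(self):
        # plant the depletion only on genes above the expression window and
        # define targets as exactly those genes: after windowing the targets
        # that remain are unshifted, so no spurious shift is called
        rng = np.random.default_rng(0)
        n = 2000
        log_bm = rng.uniform(2.6, 4.2, n)
        high = rng.random(n) < 0.2
        log_bm[high] = rng.uniform(4.5, 5.5, high.sum())
        z = rng.normal(size=n)
        z[high] -= 2.0
        # a thin slice of targets stays inside the window, unshifted
        in_window_targets = rng.random(n) < 0.05
        targets = {f"g{i}" for i in range(n) if high[i] or in_window_targets[i]}
        table = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(n)], "baseMean": 10.0**log_bm,
             "log2FC": 0.0, "SE": 1.0, "p": 0.5, "padj": 0.5, "z": z}
        )
        result, _ = shift.cumulative_shift(table, targets)
        assert result.direction == "none"

    def test_ecdf_curve_steps(self):
        curve = shift.ecdf_curve([3.0, 1.0, 2.0])
        np.testing.assert_allclose(curve["value"], [1, 2, 3])
        np.testing.assert_allclose(curve["ecdf"], [1 / 3, 2 / 3, 1.0])
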