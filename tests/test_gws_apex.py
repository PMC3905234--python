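"""Quantile-rank curves, loess projection, apex estimation and GWS calls."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from mugwas import gws_apex
from mugwas.gws_apex import (QRCurve, call_study_gws, estimated_curve,
                             expected_quantiles, genome_curves, loess_quadratic,
                             project_curve, wg_apex)


class TestExpectedQuantiles:
    def test_known_values(self):
        assert expected_quantiles(1)[0] == pytest.approx(-np.log10(0.5), abs=1e-12)
        e10 = expected_quantiles(10)
        assert e10[-1] == pytest.approx(-np.log10(0.05), abs=1e-12)
        assert np.all(np.diff(e10) > 0)

    def test_uniform_simulation_hugs_expected(self):
        rng = np.random.default_rng(0)
        n = 100_000
        s = np.sort(-np.log10(rng.random(n)))
        # away from the extreme tail the empirical curve tracks expectation
        gap = np.abs(s[: int(0.99 * n)] - expected_quantiles(n)[: int(0.99 * n)])
        assert gap.max() < 0.05


class TestLoess:
    def test_exact_on_linear_data(self):
        x = np.linspace(0, 4, 200)
        y = 0.7 * x + 0.2
        assert np.allclose(loess_quadratic(x, y), y, atol=1e-6)

    def test_exact_on_quadratic_data(self):
        x = np.linspace(0, 2, 150)
        y = 1 + x - 0.3 * x**2
        assert np.allclose(loess_quadratic(x, y), y, atol=1e-6)

    def test_constant_data(self):
        x = np.linspace(0, 1, 60)
        assert np.allclose(loess_quadratic(x, np.full(60, 2.5)), 2.5, atol=1e-9)

    def test_linear_in_response(self):
        rng = np.random.default_rng(3)
        x = np.sort(rng.random(120))
        y = rng.random(120)
        f1 = loess_quadratic(x, y)
        f2 = loess_quadratic(x, y + 1.7)
        assert np.allclose(f2, f1 + 1.7, atol=1e-6)

    def test_matches_r_loess_smooth(self, tmp_path):
        """Independent oracle: R stats::loess, degree 2, gaussian family."""
        rng = np.random.default_rng(7)
        x = np.sort(rng.random(150)) * 3
        y = x + rng.normal(0, 0.2, 150)
        np.savetxt(tmp_path / "xy.csv", np.column_stack([x, y]), delimiter=",")
        script = textwrap.dedent(f"""
            d <- read.csv("{tmp_path}/xy.csv", header=FALSE)
            fit <- loess(V2 ~ V1, data=d, span=0.4, degree=2,
                         family="gaussian", surface="direct")
            write.csv(fitted(fit), "{tmp_path}/fit.csv", row.names=FALSE)
        """)
        (tmp_path / "fit.R").write_text(script)
        try:
            subprocess.run(["Rscript", str(tmp_path / "fit.R")], check=True,
                           capture_output=True, timeout=120)
        except (FileNotFoundError, subprocess.SubprocessError):
            pytest.skip("Rscript unavailable")
        r_fit = pd.read_csv(tmp_path / "fit.csv")["x"].to_numpy()
        ours = loess_quadratic(x, y, span=0.4)
        # same smoother family; small differences from weight windowing
        assert np.max(np.abs(ours - r_fit)) < 0.08


class TestProjectCurve:
    def test_diagonal_identity_untruncated(self):
        n = 500
        s = expected_quantiles(n)  # s exactly on the diagonal
        curve = project_curve(s)
        assert curve.n_truncated == 0
        assert curve.apex == pytest.approx(s[-1], abs=0.05)

    def test_constant_values(self):
        curve = project_curve(np.full(100, 2.0))
        assert np.allclose(curve.fitted, 2.0, atol=1e-9)
        assert curve.apex == pytest.approx(2.0, abs=1e-9)
        assert curve.n_truncated == 0

    def test_inflated_top_values_truncated(self):
        n = 500
        clean = expected_quantiles(n)
        inflated = clean.copy()
        inflated[-5:] += np.array([2.0, 2.5, 3.0, 3.5, 4.0])
        curve = project_curve(inflated)
        clean_curve = project_curve(clean)
        assert curve.n_truncated >= 5
        assert curve.apex == pytest.approx(clean_curve.apex, abs=0.3)

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        s = np.sort(-np.log10(rng.random(300)))
        c1 = project_curve(s)
        c2 = project_curve(s + 1.25)
        assert c2.n_truncated == c1.n_truncated
        assert np.allclose(c2.fitted, c1.fitted + 1.25, atol=1e-6)
        assert c2.apex == pytest.approx(c1.apex + 1.25, abs=1e-6)

    def test_few_values_degenerate(self):
        curve = project_curve(np.array([0.1, 0.5, 3.0]))
        assert curve.degenerate
        assert curve.apex == 3.0


class TestWGApex:
    def _curve(self, apex, deviation, n_truncated=0):
        return QRCurve(np.zeros(1), np.zeros(1), np.zeros(1), n_truncated,
                       apex, deviation)

    def test_identical_chromosomes_give_common_apex(self):
        curves = {str(c): self._curve(3.3, 0.1) for c in range(1, 13)}
        est = wg_apex(curves)
        assert est.wg_apex == pytest.approx(3.3)

    def test_sex_chromosomes_never_selected(self):
        curves = {str(c): self._curve(3.0, 0.1) for c in range(1, 12)}
        curves["X"] = self._curve(9.0, 0.0)
        est = wg_apex(curves)
        assert "X" not in est.selected
        assert est.wg_apex == pytest.approx(3.0)

    def test_high_deviation_chromosome_excluded(self):
        curves = {str(c): self._curve(3.0 + 0.01 * c, 0.1) for c in range(1, 12)}
        curves["12"] = self._curve(8.0, 2.5)   # signal chromosome
        est = wg_apex(curves, n_select=10)
        assert "12" not in est.selected
        assert est.wg_apex < 3.2

    def test_fewer_autosomes_than_n_select_warns(self):
        curves = {str(c): self._curve(2.0, 0.1) for c in range(1, 4)}
        with pytest.warns(UserWarning, match="autosomes"):
            est = wg_apex(curves, n_select=10)
        assert len(est.selected) == 3

    def test_wg_apex_within_selected_range(self):
        rng = np.random.default_rng(0)
        curves = {str(c): self._curve(float(3 + rng.random()), float(rng.random()))
                  for c in range(1, 23)}
        est = wg_apex(curves)
        sel = est.per_chromosome[est.per_chromosome["selected"]]
        assert sel["apex"].min() <= est.wg_apex <= sel["apex"].max()


class TestEstimatedCurve:
    def test_no_replacement_when_all_below_apex(self):
        rng = np.random.default_rng(1)
        s = np.sort(-np.log10(rng.random(200)))
        curve = estimated_curve(s, wg_apex_value=s.max() + 1.0)
        assert curve.n_truncated == 0

    def test_single_outlier_replaced(self):
        n = 300
        s = expected_quantiles(n)
        s[-1] += 5.0
        curve = estimated_curve(s, wg_apex_value=expected_quantiles(n)[-1])
        assert curve.n_truncated >= 1
        assert curve.apex <= expected_quantiles(n)[-1] + 0.1

    def test_constant_at_apex_level(self):
        curve = estimated_curve(np.full(100, 2.0), wg_apex_value=2.0)
        assert np.allclose(curve.fitted, 2.0, atol=1e-9)
        assert curve.n_truncated == 0


class TestCallStudyGWS:
    def _results(self, s_values, chrom="1", lo=None, hi=None):
        n = len(s_values)
        return pd.DataFrame({
            "chrom": [chrom] * n,
            "pos": [(i + 1) * 1000 for i in range(n)],
            "rsid": [f"rs{i}" for i in range(n)],
            "s": s_values,
            "best_width": [2] * n,
            "polarity": ["++"] * n,
            "window_lo": lo if lo is not None else list(range(n)),
            "window_hi": hi if hi is not None else [i + 1 for i in range(n)],
        })

    def _apex(self, value):
        from mugwas.gws_apex import ApexEstimate
        return ApexEstimate(per_chromosome=pd.DataFrame(), wg_apex=value)

    def test_all_below_apex_no_regions(self):
        sig, regions = call_study_gws(self._results([1.0, 2.0, 1.5]), self._apex(3.0))
        assert len(sig) == 0 and len(regions) == 0

    def test_overlapping_windows_merge_to_one_region(self):
        res = self._results([5.0, 6.0], lo=[0, 1], hi=[2, 3])
        sig, regions = call_study_gws(res, self._apex(3.0))
        assert len(regions) == 1
        assert regions["s"].iloc[0] == 6.0
        assert regions["n_loci"].iloc[0] == 2

    def test_disjoint_windows_stay_separate(self):
        res = self._results([5.0, 6.0], lo=[0, 10], hi=[2, 12])
        _, regions = call_study_gws(res, self._apex(3.0))
        assert len(regions) == 2

    def test_flagged_loci_excluded_from_calls(self):
        res = self._results([5.0, 6.0], lo=[0, 10], hi=[2, 12])
        res["single_snp_driven"] = [False, True]
        _, regions = call_study_gws(res, self._apex(3.0))
        assert len(regions) == 1
        assert regions["s"].iloc[0] == 5.0
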