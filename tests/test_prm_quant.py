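import math

import numpy as np
import pytest

from pirprm.crosslink_model import enumerate_transitions, make_pair
from pirprm.mzml_io import Ms2Scan, write_prm_mzml
from pirprm.prm_quant import (
    ChromatogramTrace,
    MatchOptions,
    QuantResult,
    extract_prm_chromatograms,
    integrate_peak,
    quantify_pairs,
    response_curve,
    silac_ratios,
)


def trace(rt, y, name="t1", pair="p"):
    return ChromatogramTrace(pair, name, np.asarray(rt, float), np.asarray(y, float))


def gaussian_trace(height=1e5, sigma=0.05, apex=2.0, step=0.01, span=6.0):
    rt = np.arange(apex - span * sigma, apex + span * sigma + step / 2, step)
    return trace(rt, height * np.exp(-0.5 * ((rt - apex) / sigma) ** 2))


class TestIntegratePeak:
    def test_unit_triangle_area(self):
        tr = trace([0.0, 0.5, 1.0], [0.0, 1.0, 0.0])
        area, apex = integrate_peak(tr)
        assert area == pytest.approx(0.5)
        assert apex == 0.5

    def test_gaussian_area_matches_analytic(self):
        h, sigma = 2.5e4, 0.04
        area, _ = integrate_peak(gaussian_trace(height=h, sigma=sigma))
        assert area == pytest.approx(h * sigma * math.sqrt(2 * math.pi), rel=0.01)

    def test_area_scales_linearly(self):
        tr = gaussian_trace()
        doubled = trace(tr.rt, 2 * tr.intensity)
        a1, _ = integrate_peak(tr)
        a2, _ = integrate_peak(doubled)
        assert a2 == pytest.approx(2 * a1, rel=1e-12)

    def test_all_zero_trace_flagged(self):
        area, apex = integrate_peak(trace([0, 1, 2], [0, 0, 0]))
        assert area == 0.0 and apex is None

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            integrate_peak(trace([0, 1], [1, 1]))

    def test_explicit_bounds_restrict_area(self):
        tr = gaussian_trace(apex=2.0, sigma=0.05)
        full, _ = integrate_peak(tr)
        half, _ = integrate_peak(tr, rt_bounds=(2.0, 3.0))
        assert half == pytest.approx(full / 2, rel=0.02)

    def test_window_stability_one_step(self):
        """Widening the auto bounds by one sampling step moves the area < 2%."""
        tr = gaussian_trace(height=1e5, sigma=0.05, step=0.01)
        from pirprm.prm_quant import _auto_bounds

        left, _, right = _auto_bounds(tr.rt, tr.intensity)
        area, _ = integrate_peak(tr)
        wide_lo = tr.rt[max(left - 1, 0)]
        wide_hi = tr.rt[min(right + 1, len(tr.rt) - 1)]
        wider, _ = integrate_peak(tr, rt_bounds=(wide_lo, wide_hi))
        assert abs(wider - area) / area < 0.02


def write_single_pair_run(path, pair, transitions, offset_ppm=0.0, n_scans=9):
    """A tiny run with a triangular elution of every transition."""
    scans = []
    for i in range(n_scans):
        shape = max(0.0, 1.0 - abs(i - n_scans // 2) / (n_scans // 2))
        mzs = np.array([t.product_mz * (1 + offset_ppm * 1e-6) for t in transitions])
        scans.append(
            Ms2Scan(
                rt_min=1.0 + 0.02 * i,
                isolation_target_mz=900.0,
                precursor_charge=pair.precursor_charge,
                mz=mzs,
                intensity=np.full(len(mzs), 1000.0 * shape + 1.0),
            )
        )
    write_prm_mzml(scans, path)


class TestExtraction:
    @pytest.fixture()
    def small_pair(self):
        return make_pair("AAKLR", 3, "GGKGR", 3, charge=3)

    def test_traces_share_rt_grid(self, tmp_path, small_pair):
        trans = enumerate_transitions(small_pair)
        path = tmp_path / "run.mzML"
        write_single_pair_run(path, small_pair, trans)
        traces = extract_prm_chromatograms(path, trans, {small_pair.pair_name: 900.0})
        assert len(traces) == len(trans)
        grids = {tuple(tr.rt) for tr in traces}
        assert len(grids) == 1 and len(traces[0].rt) == 9

    def test_off_tolerance_peak_gives_zero(self, tmp_path, small_pair):
        trans = enumerate_transitions(small_pair)
        path = tmp_path / "run.mzML"
        write_single_pair_run(path, small_pair, trans, offset_ppm=25.0)
        opts = MatchOptions(ppm_tol=10.0, abs_floor=0.0)
        traces = extract_prm_chromatograms(
            path, trans, {small_pair.pair_name: 900.0}, opts
        )
        # 25 ppm off at 10 ppm tolerance: nothing matches
        assert all(not np.any(tr.intensity > 0) for tr in traces)

    def test_overlapping_windows_share_scans(self, tmp_path, small_pair):
        trans = enumerate_transitions(small_pair)
        path = tmp_path / "run.mzML"
        write_single_pair_run(path, small_pair, trans)
        fake = [t for t in trans][:1]
        prec = {small_pair.pair_name: 900.0, "other/3/light": 900.5}
        renamed = [
            type(t)(
                pair_name="other/3/light", kind=t.kind, ordinal=t.ordinal,
                product_charge=t.product_charge, product_mz=t.product_mz,
                product_name=t.product_name,
            )
            for t in fake
        ]
        traces = extract_prm_chromatograms(path, trans + renamed, prec,
                                           MatchOptions(isolation_window=3.0))
        by_pair = {}
        for tr in traces:
            by_pair.setdefault(tr.pair_name, tr)
        assert by_pair["other/3/light"].source_scans == by_pair[small_pair.pair_name].source_scans

    def test_missing_precursor_mapping_rejected(self, tmp_path, small_pair):
        trans = enumerate_transitions(small_pair)
        path = tmp_path / "run.mzML"
        write_single_pair_run(path, small_pair, trans)
        with pytest.raises(ValueError, match="no precursor m/z"):
            extract_prm_chromatograms(path, trans, {})


class TestQuantifyPairs:
    def make_traces(self, areas, pair="p"):
        out = []
        for i, scale in enumerate(areas):
            tr = gaussian_trace(height=scale, sigma=0.05, apex=2.0)
            tr.pair_name = pair
            tr.product_name = f"t{i}"
            out.append(tr)
        return out

    def test_total_is_sum_of_transitions(self, fig2_pair):
        traces = self.make_traces([1e5, 5e4, 2e4], pair=fig2_pair.pair_name)
        (res,) = quantify_pairs(traces, [fig2_pair])
        assert res.total_area == pytest.approx(sum(res.transition_areas.values()))
        assert len(res.transition_areas) == 3

    def test_single_transition_total(self, fig2_pair):
        traces = self.make_traces([1e5], pair=fig2_pair.pair_name)
        (res,) = quantify_pairs(traces, [fig2_pair])
        assert res.total_area == pytest.approx(res.transition_areas["t0"])

    def test_shuffling_transitions_leaves_total_unchanged(self, fig2_pair):
        traces = self.make_traces([1e5, 5e4, 2e4, 1e4], pair=fig2_pair.pair_name)
        (a,) = quantify_pairs(traces, [fig2_pair])
        (b,) = quantify_pairs(list(reversed(traces)), [fig2_pair])
        assert a.total_area == pytest.approx(b.total_area)

    def test_no_signal_pair_flagged_not_dropped(self, fig2_pair):
        tr = trace([0, 1, 2], [0, 0, 0], pair=fig2_pair.pair_name)
        (res,) = quantify_pairs([tr], [fig2_pair])
        assert "no_signal" in res.flags and res.total_area == 0.0

    def test_intensity_scaling_scales_totals_exactly(self, fig2_pair):
        traces = self.make_traces([1e5, 3e4], pair=fig2_pair.pair_name)
        scaled = [trace(tr.rt, 3.0 * tr.intensity, tr.product_name, tr.pair_name)
                  for tr in traces]
        (a,) = quantify_pairs(traces, [fig2_pair])
        (b,) = quantify_pairs(scaled, [fig2_pair])
        assert b.total_area == pytest.approx(3.0 * a.total_area, rel=1e-12)


def qr(total, pair="p"):
    return QuantResult(pair_name=pair, transition_areas={"t": total},
                       total_area=total, apex_rt=2.0, normalized_area=total)


class TestResponseCurve:
    def test_exact_line(self):
        levels = {x: [qr(2.0 * x)] for x in (100, 200, 500, 1000)}
        slope, intercept, r2 = response_curve(levels)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_constant_response(self):
        levels = {x: [qr(7.0)] for x in (100, 200, 500)}
        slope, _, r2 = response_curve(levels)
        assert slope == 0.0 and r2 == 0.0

    def test_replicates_averaged(self):
        levels = {x: [qr(2 * x - 5), qr(2 * x + 5)] for x in (100, 200, 500)}
        slope, _, r2 = response_curve(levels)
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            response_curve({100: [qr(1)], 200: [qr(2)]})


class TestSilacRatios:
    def test_equal_channels_give_zero(self):
        assert silac_ratios(qr(100.0), qr(100.0)) == pytest.approx(0.0)

    def test_fourfold_light_gives_two(self):
        assert silac_ratios(qr(400.0), qr(100.0)) == pytest.approx(2.0)

    def test_channel_swap_negates(self):
        a, b = qr(331.0), qr(97.0)
        assert silac_ratios(a, b) == pytest.approx(-silac_ratios(b, a))

    def test_control_normalization(self):
        assert silac_ratios(qr(400.0), qr(100.0), control_log2=2.0) == pytest.approx(0.0)

    def test_zero_heavy_is_undefined(self):
        assert silac_ratios(qr(100.0), qr(0.0)) is None


class TestRatioRecovery:
    def test_programmed_ratios_recovered_under_noise(self):
        """On 200 simulated light/heavy trace pairs with CV 10% multiplicative
        noise, the estimated log2 ratio is within 0.2 of truth for >= 95%."""
        rng = np.random.default_rng(42)
        n_ok = 0
        n_pairs = 200
        for i in range(n_pairs):
            rho = float(rng.uniform(0.25, 4.0))
            log_sigma = math.sqrt(math.log(1.0 + 0.10**2))
            rt = np.arange(1.7, 2.3, 0.01)
            shape = np.exp(-0.5 * ((rt - 2.0) / 0.05) ** 2)
            noise = lambda: np.exp(rng.normal(-0.5 * log_sigma**2, log_sigma, len(rt)))
            light = trace(rt, 1e5 * rho * shape * noise(), pair="L")
            heavy = trace(rt, 1e5 * shape * noise(), pair="H")
            (lr,) = quantify_pairs([light], [])
            (hr,) = quantify_pairs([heavy], [])
            est = silac_ratios(lr, hr)
            if est is not None and abs(est - math.log2(rho)) <= 0.2:
                n_ok += 1
        assert n_ok / n_pairs >= 0.95
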