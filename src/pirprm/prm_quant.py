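"""PRM quantification of cross-linked peptide pairs.

From a PRM run (mzML, centroided MS2) the quantifier extracts one ion
chromatogram per transition, integrates peak areas over a shared per-pair
window, and reports the quantities the method is built around:

* per-transition and summed (total) chromatographic peak areas,
* dilution-series response curves (ordinary least squares, R² as the
  squared Pearson correlation of the level means),
* SILAC light/heavy log2 ratios, optionally normalized to a control
  condition so the control sits at zero by construction.

Scan-to-pair assignment reproduces the instrument's behaviour: an MS2 scan
contributes to a pair iff its isolation target lies within half the
isolation window of the pair's precursor m/z (3 m/z window by default, with
a 1 m/z narrow preset). Overlapping windows therefore share scans; this is
reported, not corrected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .crosslink_model import CrossLinkedPair, Transition
from .mzml_io import iter_ms2_scans

logger = logging.getLogger(__name__)

__all__ = [
    "MatchOptions",
    "ChromatogramTrace",
    "QuantResult",
    "extract_prm_chromatograms",
    "integrate_peak",
    "quantify_pairs",
    "response_curve",
    "silac_ratios",
]


@dataclass(frozen=True)
class MatchOptions:
    """Tolerances controlling scan and peak matching.

    ``isolation_window``: full width (m/z) of the precursor isolation
    window; 3 m/z matches the wide-window instrument method, 1 m/z the
    narrow preset. ``ppm_tol`` / ``abs_floor``: a product peak matches a
    transition when within max(ppm_tol ppm, abs_floor m/z) of its m/z.
    """

    isolation_window: float = 3.0
    ppm_tol: float = 10.0
    abs_floor: float = 0.005
    smooth: bool = False  # optional 5-point moving average before integration

    def mz_tol(self, mz: float) -> float:
        return max(mz * self.ppm_tol * 1e-6, self.abs_floor)


@dataclass
class ChromatogramTrace:
    """Extracted ion chromatogram of one transition of one pair."""

    pair_name: str
    product_name: str
    rt: np.ndarray  # minutes, strictly increasing
    intensity: np.ndarray
    source_scans: int = 0

    def smoothed(self) -> np.ndarray:
        if len(self.intensity) < 5:
            return self.intensity
        kernel = np.ones(5) / 5.0
        return np.convolve(self.intensity, kernel, mode="same")


@dataclass
class QuantResult:
    """Quantitative readout for one pair in one run."""

    pair_name: str
    transition_areas: Dict[str, float]
    total_area: float
    apex_rt: Optional[float]
    normalized_area: Optional[float] = None
    light_heavy_log2: Optional[float] = None
    r_squared: Optional[float] = None
    flags: Tuple[str, ...] = ()


def extract_prm_chromatograms(
    mzml_path,
    transitions: Sequence[Transition],
    precursor_mz_by_pair: Mapping[str, float],
    match_opts: MatchOptions = MatchOptions(),
) -> List[ChromatogramTrace]:
    """Extract per-transition chromatograms from a PRM mzML run.

    ``precursor_mz_by_pair`` carries the targeted precursor m/z per pair
    (as written in the isolation list). Scans with no matching product peak
    contribute intensity 0 so that all of a pair's traces share one RT
    grid.
    """
    by_pair: Dict[str, List[Transition]] = {}
    for t in transitions:
        by_pair.setdefault(t.pair_name, []).append(t)
    unknown = set(by_pair) - set(precursor_mz_by_pair)
    if unknown:
        raise ValueError(f"no precursor m/z supplied for pairs: {sorted(unknown)}")

    half = match_opts.isolation_window / 2.0
    rt_acc: Dict[str, List[float]] = {p: [] for p in by_pair}
    int_acc: Dict[str, List[List[float]]] = {p: [] for p in by_pair}

    for scan in iter_ms2_scans(mzml_path):
        for pname, trans in by_pair.items():
            if abs(scan.isolation_target_mz - precursor_mz_by_pair[pname]) > half:
                continue
            rt_acc[pname].append(scan.rt_min)
            row = []
            for t in trans:
                tol = match_opts.mz_tol(t.product_mz)
                sel = np.abs(scan.mz - t.product_mz) <= tol
                row.append(float(scan.intensity[sel].sum()))
            int_acc[pname].append(row)

    traces: List[ChromatogramTrace] = []
    for pname, trans in by_pair.items():
        rts = np.asarray(rt_acc[pname])
        mat = np.asarray(int_acc[pname]).reshape(len(rts), len(trans))
        order = np.argsort(rts, kind="stable")
        rts, mat = rts[order], mat[order]
        for j, t in enumerate(trans):
            traces.append(
                ChromatogramTrace(
                    pair_name=pname,
                    product_name=t.product_name,
                    rt=rts,
                    intensity=mat[:, j],
                    source_scans=len(rts),
                )
            )
    return traces


def _auto_bounds(rt: np.ndarray, y: np.ndarray) -> Tuple[int, int, int]:
    """(left, apex, right) indices: extend from the apex until intensity
    drops below 1% of apex or a local minimum below 5% of apex."""
    apex = int(np.argmax(y))
    top = y[apex]
    lo_cut, min_cut = 0.01 * top, 0.05 * top
    # the stopping point is included so the trapezoid reaches the baseline
    left = apex
    while left > 0:
        nxt = y[left - 1]
        left -= 1
        if nxt < lo_cut:
            break
        if nxt < min_cut and left - 1 >= 0 and y[left - 1] > nxt:
            break
    right = apex
    n = len(y)
    while right < n - 1:
        nxt = y[right + 1]
        right += 1
        if nxt < lo_cut:
            break
        if nxt < min_cut and right + 1 < n and y[right + 1] > nxt:
            break
    return left, apex, right


def integrate_peak(
    trace: ChromatogramTrace,
    rt_bounds: Optional[Tuple[float, float]] = None,
    smooth: bool = False,
) -> Tuple[float, Optional[float]]:
    """Trapezoidal peak area (intensity x minutes) and apex RT.

    With explicit ``rt_bounds`` integrates within them; otherwise bounds
    are chosen automatically around the global maximum. An all-zero trace
    yields area 0 with an undefined apex.
    """
    if len(trace.rt) < 3:
        raise ValueError(f"trace {trace.product_name}: need at least 3 points")
    y = trace.smoothed() if smooth else trace.intensity
    if not np.any(y > 0):
        return 0.0, None
    if rt_bounds is not None:
        sel = (trace.rt >= rt_bounds[0]) & (trace.rt <= rt_bounds[1])
        if sel.sum() < 2:
            return 0.0, None
        area = float(np.trapezoid(y[sel], trace.rt[sel]))
        apex = float(trace.rt[sel][np.argmax(y[sel])])
        return area, apex
    left, apex_i, right = _auto_bounds(trace.rt, y)
    area = float(np.trapezoid(y[left : right + 1], trace.rt[left : right + 1]))
    return area, float(trace.rt[apex_i])


def quantify_pairs(
    traces: Sequence[ChromatogramTrace],
    pairs: Sequence[CrossLinkedPair],
    top_n: int = 3,
    normalizer: float = 1.0,
    smooth: bool = False,
) -> List[QuantResult]:
    """Integrate all of each pair's transitions over a shared window.

    The window is derived from the pair's ``top_n`` most intense
    transitions: automatic bounds on their summed trace, centred on the
    consensus apex. Total area is the sum over transitions; the normalized
    area divides by ``normalizer``.
    """
    known = {p.pair_name for p in pairs}
    by_pair: Dict[str, List[ChromatogramTrace]] = {}
    for tr in traces:
        by_pair.setdefault(tr.pair_name, []).append(tr)

    results: List[QuantResult] = []
    for pname in sorted(by_pair):
        group = by_pair[pname]
        flags: List[str] = []
        if pname not in known:
            flags.append("unknown_pair")
        usable = [tr for tr in group if len(tr.rt) >= 3 and np.any(tr.intensity > 0)]
        if not usable:
            results.append(
                QuantResult(
                    pair_name=pname,
                    transition_areas={tr.product_name: 0.0 for tr in group},
                    total_area=0.0,
                    apex_rt=None,
                    normalized_area=0.0,
                    flags=tuple(flags + ["no_signal"]),
                )
            )
            continue
        ranked = sorted(usable, key=lambda tr: float(tr.intensity.max()), reverse=True)
        top = ranked[: max(1, top_n)]
        summed = ChromatogramTrace(
            pair_name=pname,
            product_name="__sum__",
            rt=top[0].rt,
            intensity=np.sum([tr.intensity for tr in top], axis=0),
        )
        y = summed.smoothed() if smooth else summed.intensity
        left, apex_i, right = _auto_bounds(summed.rt, y)
        bounds = (float(summed.rt[left]), float(summed.rt[right]))
        areas: Dict[str, float] = {}
        for tr in group:
            area, _ = integrate_peak(tr, rt_bounds=bounds, smooth=smooth)
            areas[tr.product_name] = area
        total = float(sum(areas.values()))
        results.append(
            QuantResult(
                pair_name=pname,
                transition_areas=areas,
                total_area=total,
                apex_rt=float(summed.rt[apex_i]),
                normalized_area=total / normalizer,
                flags=tuple(flags),
            )
        )
    return results


def response_curve(
    results_by_level: Mapping[float, Sequence[QuantResult]],
) -> Tuple[float, float, float]:
    """Fit normalized total area vs. level; returns (slope, intercept, R²).

    Levels are e.g. injection amounts (ng); each maps to the replicate
    results of one pair at that level. The fit is ordinary least squares on
    the replicate means; R² is the squared Pearson correlation of those
    mean points. Requires at least 3 levels with varying x.
    """
    levels = sorted(results_by_level)
    if len(levels) < 3:
        raise ValueError("response curve needs at least 3 levels")
    x = np.asarray(levels, dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in level values")
    y = np.asarray(
        [np.mean([r.normalized_area for r in results_by_level[lv]]) for lv in levels]
    )
    if np.allclose(y, y[0]):
        # flat response: slope 0 and, by convention, no explained variance
        return 0.0, float(y[0]), 0.0
    slope, intercept, r_value, _, _ = stats.linregress(x, y)
    return float(slope), float(intercept), float(r_value**2)


def silac_ratios(
    light: QuantResult,
    heavy: QuantResult,
    control_log2: Optional[float] = None,
) -> Optional[float]:
    """log2(light/heavy) total-area ratio, optionally control-normalized.

    With ``control_log2`` given, returns the difference so the control
    condition reads 0 by construction. A zero or missing heavy total is
    undefined (None); callers should carry the flag forward.
    """
    if heavy.total_area <= 0 or light.total_area <= 0:
        logger.warning(
            "pair %s: non-positive channel total (light=%g heavy=%g); ratio undefined",
            light.pair_name, light.total_area, heavy.total_area,
        )
        return None
    ratio = math.log2(light.total_area / heavy.total_area)
    if control_log2 is not None:
        ratio -= control_log2
    return ratio
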