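"""Chromatographic-domain verification: CWT peak picking, coelution testing,
and area-based re-evaluation of the isotopologue rules.

The peak picker follows the centWave idea: a Mexican-hat continuous wavelet
transform over a log-spaced scale grid covering the allowed peak-width range,
ridge lines linked across scales, peak boundaries found by descending from
the apex to the nearest local minima, and areas by trapezoidal integration.
A feature is accepted only when every required isotopologue has a
chromatographic peak coeluting with X (pairwise Pearson correlation over the
X peak window above the threshold) and the rule set also holds on the peak
areas — a strictly stronger check than the scan-level one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msdata import EIC, Run, extract_eic
from .rules import RuleSet, Verdict, evaluate_on_intensities, expected_mz
from .screening import FeatureCandidate

__all__ = ["ChromPeak", "Feature", "pick_peaks", "coelution_r", "verify_feature"]


@dataclass
class ChromPeak:
    """A detected chromatographic peak on one EIC."""

    apex_rt: float
    bounds: tuple[float, float]
    area: float
    apex_intensity: float
    snr: float
    apex_index: int
    bound_indices: tuple[int, int]


@dataclass
class Feature:
    """A chromatographically verified isotopologue-pattern hit."""

    x_mz: float
    apex_rt: float
    peaks: dict[int, ChromPeak]  # offset -> peak (required offsets only)
    coelution_r: float
    verdict: Verdict

    @property
    def x_peak(self) -> ChromPeak:
        return self.peaks[0]

    @property
    def areas(self) -> dict[int, float]:
        return {nu: p.area for nu, p in self.peaks.items()}


def _mexican_hat(points: int, scale: float) -> np.ndarray:
    """Mexican-hat (Ricker) wavelet sampled on ``points`` points."""
    x = (np.arange(points) - (points - 1) / 2.0) / scale
    return (2.0 / (np.sqrt(3.0) * np.pi**0.25)) * (1.0 - x**2) * np.exp(-(x**2) / 2.0)


def _cwt(signal: np.ndarray, scales: np.ndarray) -> np.ndarray:
    rows = np.empty((scales.size, signal.size))
    for i, scale in enumerate(scales):
        width = min(signal.size, int(np.ceil(10 * scale)) | 1)
        kernel = _mexican_hat(width, scale)
        rows[i] = np.convolve(signal, kernel, mode="same") / np.sqrt(scale)
    return rows


def _local_maxima(row: np.ndarray) -> np.ndarray:
    if row.size < 3:
        return np.array([], dtype=int)
    inner = (row[1:-1] > row[:-2]) & (row[1:-1] >= row[2:]) & (row[1:-1] > 0)
    return np.flatnonzero(inner) + 1


def _link_ridges(coeffs: np.ndarray, scales: np.ndarray) -> list[list[tuple[int, int]]]:
    """Link per-scale CWT maxima into ridge lines, largest scale first."""
    ridges: list[list[tuple[int, int]]] = []  # each: list of (scale_idx, pos)
    active: list[list[tuple[int, int]]] = []
    for si in range(scales.size - 1, -1, -1):
        maxima = list(_local_maxima(coeffs[si]))
        window = max(2, int(np.ceil(scales[si])))
        next_active: list[list[tuple[int, int]]] = []
        for ridge in active:
            _, last_pos = ridge[-1]
            near = [m for m in maxima if abs(m - last_pos) <= window]
            if near:
                best = min(near, key=lambda m: abs(m - last_pos))
                maxima.remove(best)
                ridge.append((si, best))
                next_active.append(ridge)
            else:
                ridges.append(ridge)
        for m in maxima:  # start new ridges from unclaimed maxima
            next_active.append([(si, m)])
        active = next_active
    ridges.extend(active)
    return ridges


def _descend(signal: np.ndarray, apex: int) -> tuple[int, int]:
    """Walk downhill from the apex to the nearest local minima (or zero)."""
    left = apex
    while left > 0 and signal[left - 1] < signal[left] and signal[left] > 0:
        left -= 1
    right = apex
    while right < signal.size - 1 and signal[right + 1] < signal[right] and signal[right] > 0:
        right += 1
    return left, right


def _fwhm_width(rt: np.ndarray, signal: np.ndarray, apex: int, lb: int, ub: int) -> float:
    """Gaussian-equivalent full width (4 sigma) from the half-maximum crossings."""
    base = min(signal[lb], signal[ub])
    half = base + (signal[apex] - base) / 2.0
    left_rt = rt[lb]
    for i in range(apex, lb, -1):
        if signal[i - 1] <= half <= signal[i]:
            frac = (half - signal[i - 1]) / max(signal[i] - signal[i - 1], 1e-30)
            left_rt = rt[i - 1] + frac * (rt[i] - rt[i - 1])
            break
    right_rt = rt[ub]
    for i in range(apex, ub):
        if signal[i + 1] <= half <= signal[i]:
            frac = (signal[i] - half) / max(signal[i] - signal[i + 1], 1e-30)
            right_rt = rt[i] + frac * (rt[i + 1] - rt[i])
            break
    fwhm = right_rt - left_rt
    return 4.0 * fwhm / 2.3548200450309493  # FWHM -> 4 sigma


def _noise_level(signal: np.ndarray, lb: int, ub: int, halo: int) -> float:
    lo = max(0, lb - halo)
    hi = min(signal.size, ub + 1 + halo)
    outside = np.concatenate([signal[lo:lb], signal[ub + 1:hi]])
    if outside.size == 0:
        return 1.0
    mad = np.median(np.abs(outside - np.median(outside)))
    return max(1.4826 * mad, 1.0)


def pick_peaks(
    eic: EIC,
    min_width: float = 5.0,
    max_width: float = 25.0,
    snr_min: float = 3.0,
    n_scales: int = 10,
    min_ridge_length: int = 3,
) -> list[ChromPeak]:
    """Detect chromatographic peaks on an EIC via Mexican-hat CWT ridges.

    ``min_width``/``max_width`` bound the accepted peak width in seconds
    (a peak's width is taken as 4 sigma of its Gaussian-equivalent shape,
    estimated from the half-maximum crossings). Peaks outside the width
    bounds or below ``snr_min`` (apex over the MAD-based local noise outside
    the peak) are rejected. Areas are trapezoidal integrals between the
    boundary minima.
    """
    if min_width >= max_width:
        raise ValueError("min_width must be < max_width")
    signal = eic.intensity
    rt = eic.rt
    if signal.size < 5 or not np.any(signal > 0):
        return []
    dt = float(np.median(np.diff(rt)))
    if (signal.size - 1) * dt < min_width:
        return []

    # scales in scan points, spanning sigma = width/4 over the allowed range
    scales = np.unique(
        np.clip(
            np.geomspace(min_width / 4.0 / dt, max_width / 4.0 / dt, n_scales),
            1.0,
            max(1.0, signal.size / 3.0),
        )
    )
    coeffs = _cwt(signal, scales)
    ridges = _link_ridges(coeffs, scales)

    peaks: dict[int, ChromPeak] = {}
    halo = int(np.ceil(3 * max_width / dt))
    for ridge in ridges:
        if len(ridge) < min(min_ridge_length, scales.size):
            continue
        si, pos = max(ridge, key=lambda sp: coeffs[sp[0], sp[1]])
        if coeffs[si, pos] <= 0:
            continue
        # refine the apex on the raw trace near the ridge position
        span = max(1, int(np.ceil(scales[si])))
        lo = max(0, pos - span)
        hi = min(signal.size, pos + span + 1)
        apex = lo + int(np.argmax(signal[lo:hi]))
        if signal[apex] <= 0:
            continue
        lb, ub = _descend(signal, apex)
        if ub - lb < 2:
            continue
        width = _fwhm_width(rt, signal, apex, lb, ub)
        if not (min_width <= width <= max_width):
            continue
        noise = _noise_level(signal, lb, ub, halo)
        snr = float(signal[apex]) / noise
        if snr < snr_min:
            continue
        area = float(np.trapezoid(signal[lb:ub + 1], rt[lb:ub + 1]))
        if area <= 0:
            continue
        if apex in peaks:  # several ridges can converge on one apex
            continue
        peaks[apex] = ChromPeak(
            apex_rt=float(rt[apex]),
            bounds=(float(rt[lb]), float(rt[ub])),
            area=area,
            apex_intensity=float(signal[apex]),
            snr=snr,
            apex_index=apex,
            bound_indices=(lb, ub),
        )
    return sorted(peaks.values(), key=lambda p: p.apex_rt)


def coelution_r(
    eic_a: EIC,
    eic_b: EIC,
    window: tuple[float, float] | None = None,
) -> float:
    """Pearson correlation of two EICs restricted to an rt window.

    Both EICs must be sampled on the same scan grid. Zero variance in either
    trace yields NaN, which callers treat as a coelution failure.
    """
    if eic_a.rt.size != eic_b.rt.size or not np.allclose(eic_a.rt, eic_b.rt):
        raise ValueError("EICs must share the same scan grid")
    mask = np.ones(eic_a.rt.size, dtype=bool)
    if window is not None:
        mask = (eic_a.rt >= window[0]) & (eic_a.rt <= window[1])
    if mask.sum() < 4:
        raise ValueError("correlation window must contain at least 4 points")
    a = eic_a.intensity[mask]
    b = eic_b.intensity[mask]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _coeluting_peak(peaks: list[ChromPeak], x_peak: ChromPeak) -> ChromPeak | None:
    """The most intense peak whose apex lies within the X peak bounds."""
    inside = [p for p in peaks if x_peak.bounds[0] <= p.apex_rt <= x_peak.bounds[1]]
    if not inside:
        return None
    return max(inside, key=lambda p: p.apex_intensity)


def verify_feature(
    run: Run,
    candidate: FeatureCandidate,
    ruleset: RuleSet,
    eic_ppm: float = 5.0,
    min_width: float = 5.0,
    max_width: float = 25.0,
    snr_min: float = 3.0,
    r_min: float = 0.85,
) -> tuple[list[Feature], list[str]]:
    """Verify a scan-level candidate in the chromatographic domain.

    EICs are extracted at the expected m/z of every rule-referenced offset,
    peaks are picked, and each X peak in the candidate's rt window is judged
    independently (isomers yield separate features): every required offset
    needs a peak whose apex falls within the X peak bounds, all pairwise
    Pearson correlations of the coelution-checked traces over the X peak
    window must reach ``r_min``, and the rule set must hold on the peak
    areas (forbidden offsets contribute the area of a coeluting peak, or 0).

    Returns ``(features, rejection_reasons)``.
    """
    pad = 2.0 * max_width
    span = run.rt_span
    window = (max(span[0], candidate.rt_window[0] - pad), min(span[1], candidate.rt_window[1] + pad))
    charge = ruleset.charge

    eics: dict[int, EIC] = {}
    peaklists: dict[int, list[ChromPeak]] = {}
    for nu in sorted(ruleset.referenced_offsets):
        eic = extract_eic(run, expected_mz(candidate.mean_mz, nu, charge), eic_ppm, window)
        eics[nu] = eic
        peaklists[nu] = pick_peaks(eic, min_width, max_width, snr_min)

    accept_lo = candidate.rt_window[0] - max_width / 2.0
    accept_hi = candidate.rt_window[1] + max_width / 2.0
    x_peaks = [p for p in peaklists[0] if accept_lo <= p.apex_rt <= accept_hi]
    if not x_peaks:
        return [], [f"no chromatographic peak for X at m/z {candidate.mean_mz:.4f}"]

    required = sorted(ruleset.required_offsets)
    forbidden = sorted(ruleset.forbidden_offsets)
    coelution_set = sorted(ruleset.coelution_offsets & ruleset.required_offsets)

    features: list[Feature] = []
    rejections: list[str] = []
    for x_peak in x_peaks:
        matched: dict[int, ChromPeak] = {0: x_peak}
        missing = None
        for nu in required:
            if nu == 0:
                continue
            peak = _coeluting_peak(peaklists[nu], x_peak)
            if peak is None:
                missing = nu
                break
            matched[nu] = peak
        if missing is not None:
            rejections.append(
                f"no coeluting chromatographic peak for X{missing:+d} "
                f"(X apex {x_peak.apex_rt:.1f} s)"
            )
            continue

        # pairwise coelution over the X peak window
        min_r = 1.0
        bad_pair = None
        for i, nu_a in enumerate(coelution_set):
            for nu_b in coelution_set[i + 1:]:
                try:
                    r = coelution_r(eics[nu_a], eics[nu_b], x_peak.bounds)
                except ValueError:
                    r = float("nan")
                if not np.isfinite(r) or r < r_min:
                    bad_pair = (nu_a, nu_b, r)
                    break
                min_r = min(min_r, r)
            if bad_pair:
                break
        if bad_pair:
            nu_a, nu_b, r = bad_pair
            rejections.append(
                f"coelution failure between X{nu_a:+d} and X{nu_b:+d} "
                f"(r = {r:.3f} < {r_min}) at {x_peak.apex_rt:.1f} s"
            )
            continue

        areas: dict[int, float | None] = {nu: matched[nu].area for nu in matched}
        for nu in forbidden:
            peak = _coeluting_peak(peaklists[nu], x_peak)
            areas[nu] = peak.area if peak is not None else 0.0

        verdict = evaluate_on_intensities(ruleset, areas)
        if not verdict.passed:
            rejections.append(
                f"area re-check failed at {x_peak.apex_rt:.1f} s: {verdict.reason}"
            )
            continue
        features.append(
            Feature(
                x_mz=candidate.mean_mz,
                apex_rt=x_peak.apex_rt,
                peaks=matched,
                coelution_r=min_r,
                verdict=verdict,
            )
        )
    return features, rejections
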