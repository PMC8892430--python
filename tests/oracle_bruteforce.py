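"""Independent brute-force oracle for the standard-tracer scan screen.

Deliberately naive and self-contained: it re-derives every rule check from
the method's stated constants (1e5 / 5e4 counts, 5 % absence tolerance,
10-300 % and 10-200 % windows, ±10 % ratio constancy, ±5 ppm lookup) with
exhaustive linear scans over all centroids, sharing no code with the
package's screening path.
"""

DELTA_C = 1.0033548378


def _best_in_window(mzs, intensities, target, ppm=5.0):
    tol = target * ppm * 1e-6
    hits = [
        (mz, inten)
        for mz, inten in zip(mzs, intensities)
        if abs(mz - target) <= tol
    ]
    if not hits:
        return None
    top = max(inten for _, inten in hits)
    contenders = [h for h in hits if h[1] == top]
    return min(contenders, key=lambda h: abs(h[0] - target))


def _standard_pattern_ok(intensity_of):
    """Apply the standard-tracer rule constants to an offset->intensity map."""
    x = intensity_of(0)
    if x is None or x < 1e5:
        return False
    for nu in (2, 4):
        value = intensity_of(nu)
        if value is None or value < 5e4:
            return False
    for nu in (1, 3):
        value = intensity_of(nu)
        if value is None or value <= 0:
            return False
    for nu in (-1, -2):
        value = intensity_of(nu) or 0.0
        if value > 0.05 * x:
            return False
    i1, i2, i3, i4 = (intensity_of(nu) for nu in (1, 2, 3, 4))
    for num, den, lo, hi in (
        (i2, x, 0.10, 3.00),
        (i4, i2, 0.10, 3.00),
        (i1, x, 0.10, 2.00),
        (i1, i2, 0.10, 2.00),
        (i3, i2, 0.10, 2.00),
        (i3, i4, 0.10, 2.00),
    ):
        if not (lo <= num / den <= hi):
            return False
    r_first = (x + i2) / i1
    r_second = (i2 + i4) / i3
    if abs(r_first - r_second) / min(r_first, r_second) > 0.10:
        return False
    return True


def bruteforce_standard_screen(run, ppm=5.0):
    """Every (scan, centroid) pair that satisfies the standard rule constants.

    Returns a set of (scan_index, x_mz) tuples.
    """
    found = set()
    for scan in run.scans:
        mzs = list(scan.mz)
        intensities = list(scan.intensity)
        for x_mz, x_int in zip(mzs, intensities):

            def intensity_of(nu, x_mz=x_mz, x_int=x_int):
                if nu == 0:
                    return x_int
                hit = _best_in_window(mzs, intensities, x_mz + nu * DELTA_C, ppm)
                return None if hit is None else hit[1]

            if _standard_pattern_ok(intensity_of):
                found.add((scan.scan_index, x_mz))
    return found


def random_tiny_run(rng, max_scans=5, max_centroids=50):
    """A small random run mixing pure noise with planted near-patterns.

    Planted patterns draw satellite intensities around the compliant ranges
    so that both pass and fail outcomes occur; jitter stays within ±3 ppm so
    lookup windows are exercised.
    """
    import numpy as np

    from tracerscreen.msdata import MassSpectrum, Run

    n_scans = int(rng.integers(1, max_scans + 1))
    scans = []
    for index in range(n_scans):
        mzs = list(rng.uniform(100.0, 900.0, size=int(rng.integers(3, 25))))
        intensities = list(10 ** rng.uniform(3.0, 6.5, size=len(mzs)))
        for _ in range(int(rng.integers(0, 3))):
            x_mz = float(rng.uniform(150.0, 800.0))
            x_int = 10 ** float(rng.uniform(4.7, 6.5))
            rel = {
                1: float(rng.uniform(0.02, 0.5)),
                2: float(rng.uniform(0.05, 3.5)),
                3: float(rng.uniform(0.02, 0.5)),
                4: float(rng.uniform(0.02, 3.5)),
            }
            if rng.uniform() < 0.5:  # half the plants obey ratio constancy
                rel[3] = rel[2] * (1 + rel[2]) / (1 + rel[2]) * rel[1] / (1.0)
                rel[3] = (rel[2] + rel[2] * rel[4]) * rel[1] / (1 + rel[2])
            for nu, fraction in rel.items():
                jitter = 1.0 + float(rng.uniform(-3e-6, 3e-6))
                mzs.append((x_mz + nu * DELTA_C) * jitter)
                intensities.append(x_int * fraction)
            if rng.uniform() < 0.3:  # sometimes violate the absence rule
                mzs.append(x_mz - DELTA_C)
                intensities.append(x_int * float(rng.uniform(0.01, 0.2)))
            mzs.append(x_mz)
            intensities.append(x_int)
        order = np.argsort(mzs)
        mz_arr = np.asarray(mzs)[order]
        int_arr = np.asarray(intensities)[order]
        keep = np.concatenate([[True], np.diff(mz_arr) > 1e-6])
        scans.append(
            MassSpectrum(
                scan_index=index,
                rt=float(index),
                polarity="+",
                ms_level=1,
                mz=mz_arr[keep][:max_centroids],
                intensity=int_arr[keep][:max_centroids],
            )
        )
    return Run(sample_id="tiny", scans=scans, polarity="+")
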