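"""Ground-truthed synthetic LC-HRMS runs with planted tracer-incorporation
isotopologue patterns, decoys, and noise; plus the theoretical incorporation
pattern model itself.

The incorporation model
-----------------------
A metabolite built from ``n_units`` C2 extension units incorporates each
unit from the tracer pool with probability ``q``, so the number of
tracer-derived units is Binomial(n_units, q) and the even-offset envelope of
the pattern follows that distribution: a staircase for small ``q``
(q < 1/(n_units+1)) and a hill shape otherwise — both occur in practice.

The odd-offset satellites arise from single isotopic defects: natural heavy
isotopes in the light carbon pool and the isotopic impurity of the labelled
pool. Because these defect rates are constant molecule properties, the model
places each odd isotopologue proportional to the sum of its two even
neighbours, ``I(2m+1) = delta * (I(2m) + I(2m+2))``, with one defect rate

    delta = ( (1 - tracer_purity) * 2 * n_units * q
              + background_defect * (n_carbons - 2 * n_units * q) ) / 2

(``background_defect`` is the natural 13C abundance in the standard
approach and the residual 12C content of the global label in the reversed
approach). This makes the diagnostic odd/even ratio
``(I(2m) + I(2m+2)) / I(2m+1) = 1/delta`` exactly independent of the number
of incorporated units — the constancy the ratio rules exploit. Physically
the up- and down-defect contributions weight the two even neighbours
slightly differently; the symmetric idealization is deliberate and is
discussed in the methods documentation.

In the reversed approach all offsets are negated: the principal isotopologue
is the fully labelled species and tracer incorporation shifts mass downward.
"""

from __future__ import annotations

import base64
import io
from dataclasses import dataclass, field
from math import comb

import numpy as np
from pyteomics import mass as pyteomics_mass

from .msdata import MassSpectrum, Run
from .rules import expected_mz

__all__ = [
    "IncorporationModel",
    "PlantedCompound",
    "SyntheticTruth",
    "DECOY_VIOLATIONS",
    "theoretical_pattern",
    "pattern_probabilities",
    "mirrored_model",
    "max_extension_units",
    "generate_run",
    "write_mzxml",
    "write_truth_tsv",
]


@dataclass(frozen=True)
class IncorporationModel:
    """Parameters of the tracer-incorporation isotopologue pattern.

    n_units:
        Number of C2 extension units in the carbon skeleton (k).
    q:
        Probability that an extension unit is tracer-derived.
    tracer_purity:
        Per-carbon isotopic purity of the tracer's labelled carbons.
    nat_13c:
        Natural 13C abundance of the light carbon pool (standard approach).
    n_carbons:
        Total carbon count of the ion.
    direction:
        'standard' (heavy tracer, light background, offsets X+nu) or
        'reversed' (light tracer, heavy background, offsets X-nu).
    label_purity:
        Per-carbon purity of the global label (reversed approach only).
    """

    n_units: int
    q: float
    n_carbons: int
    tracer_purity: float = 0.99
    nat_13c: float = 0.0107
    direction: str = "standard"
    label_purity: float = 0.99

    def __post_init__(self):
        if self.direction not in ("standard", "reversed"):
            raise ValueError("direction must be 'standard' or 'reversed'")
        for name in ("q", "tracer_purity", "nat_13c", "label_purity"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.n_carbons < 2 * self.n_units:
            raise ValueError("n_carbons must be >= 2 * n_units")

    @property
    def sign(self) -> int:
        return 1 if self.direction == "standard" else -1

    @property
    def defect_rate(self) -> float:
        """Single-defect probability delta feeding the odd-offset satellites.

        The expected number of isotopic defects per molecule is
        ``lambda = eps_tracer * (tracer carbons) + eps_background * (other
        carbons)``; the probability of carrying a defect is the Poisson
        ``1 - exp(-lambda)``, split evenly between the two mass directions,
        so delta stays below 1/2 (hence odd satellites below the mean of
        their even neighbours) for every parameterization.
        """
        tracer_carbons = 2.0 * self.n_units * self.q
        background_carbons = self.n_carbons - tracer_carbons
        eps_tracer = 1.0 - self.tracer_purity
        eps_background = self.nat_13c if self.direction == "standard" else 1.0 - self.label_purity
        expected_defects = eps_tracer * tracer_carbons + eps_background * background_carbons
        return 0.5 * -np.expm1(-expected_defects)


def pattern_probabilities(model: IncorporationModel) -> dict[int, float]:
    """Exact pattern as a probability distribution over signed offsets (sums to 1)."""
    k, q = model.n_units, model.q
    staircase = np.array([comb(k, m) * q**m * (1.0 - q) ** (k - m) for m in range(k + 1)])
    delta = model.defect_rate
    raw: dict[int, float] = {}
    for m in range(k + 1):
        raw[2 * m] = raw.get(2 * m, 0.0) + staircase[m]
    for m in range(k):
        odd = delta * (staircase[m] + staircase[m + 1])
        if odd > 0.0:
            raw[2 * m + 1] = odd
    total = sum(raw.values())
    sign = model.sign
    return {sign * off: value / total for off, value in raw.items() if value > 0.0}


def theoretical_pattern(model: IncorporationModel) -> dict[int, float]:
    """Relative isotopologue intensities, most intense isotopologue = 1."""
    probs = pattern_probabilities(model)
    top = max(probs.values())
    return {off: value / top for off, value in probs.items()}


def mirrored_model(model: IncorporationModel) -> IncorporationModel:
    """The same incorporation statistics viewed from the opposite approach.

    Mirroring swaps which carbon pool is labelled: the background defect rate
    of one direction becomes that of the other, so the mirrored pattern is
    the original with all offsets negated.
    """
    if model.direction == "standard":
        return IncorporationModel(
            n_units=model.n_units,
            q=model.q,
            n_carbons=model.n_carbons,
            tracer_purity=model.tracer_purity,
            nat_13c=model.nat_13c,
            direction="reversed",
            label_purity=1.0 - model.nat_13c,
        )
    return IncorporationModel(
        n_units=model.n_units,
        q=model.q,
        n_carbons=model.n_carbons,
        tracer_purity=model.tracer_purity,
        nat_13c=1.0 - model.label_purity,
        direction="standard",
        label_purity=model.label_purity,
    )


def max_extension_units(formula: str) -> int:
    """Number of C2 extension units that fit into a molecular formula."""
    try:
        composition = pyteomics_mass.Composition(formula=formula)
    except Exception as exc:
        raise ValueError(f"malformed molecular formula {formula!r}") from exc
    carbons = composition.get("C", 0)
    if carbons < 2:
        raise ValueError(f"formula {formula!r} has fewer than 2 carbon atoms")
    return carbons // 2


# ---------------------------------------------------------------------------
# Run generation
# ---------------------------------------------------------------------------

#: Recognized single-rule decoy violations.
DECOY_VIOLATIONS = (
    "missing_isotopolog",   # a required odd satellite is removed
    "forbidden_isotopolog", # a signal appears at a forbidden offset (10% of X)
    "ratio_violation",      # the first odd satellite is inflated threefold
    "low_intensity",        # the whole pattern is scaled below the X threshold
    "shifted_satellite",    # the first even satellite elutes 15 s late
    "narrow_satellite",     # the first odd satellite elutes at half the width
)


@dataclass
class PlantedCompound:
    """One compound planted into a synthetic run (compliant or decoy)."""

    x_mz: float
    rt_apex: float
    model: IncorporationModel
    peak_sigma: float = 3.0  # seconds
    height: float = 1e6  # apex intensity of the most intense isotopologue
    decoy_violation: str | None = None
    name: str = ""

    def __post_init__(self):
        if self.decoy_violation is not None and self.decoy_violation not in DECOY_VIOLATIONS:
            raise ValueError(f"unknown decoy violation {self.decoy_violation!r}")

    @property
    def compliant(self) -> bool:
        return self.decoy_violation is None


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic study: compounds plus reproducibility seed."""

    compounds: list[PlantedCompound]
    seed: int
    rt_span: tuple[float, float] = (0.0, 600.0)

    @property
    def expected_hits(self) -> list[PlantedCompound]:
        return [c for c in self.compounds if c.compliant]

    @property
    def decoys(self) -> list[PlantedCompound]:
        return [c for c in self.compounds if not c.compliant]


_EMIT_FLOOR = 1.0  # counts; below this a centroid is not written


def _compound_centroids(
    compound: PlantedCompound,
    t: float,
    rng: np.random.Generator,
    mz_noise_ppm: float,
    intensity_noise_cv: float,
    rt_shift: float,
    mz_shift_ppm: float,
) -> list[tuple[float, float]]:
    pattern = theoretical_pattern(compound.model)
    sign = compound.model.sign
    violation = compound.decoy_violation
    sigma = compound.peak_sigma
    apex = compound.rt_apex + rt_shift
    scale = 1.0

    if violation == "low_intensity":
        scale = 0.03
    if violation == "missing_isotopolog":
        pattern = {nu: v for nu, v in pattern.items() if nu != sign * 3}
    if violation == "ratio_violation":
        pattern = dict(pattern)
        if sign * 1 in pattern:
            pattern[sign * 1] *= 3.0
    if violation == "forbidden_isotopolog":
        pattern = dict(pattern)
        pattern[-sign * 1] = 0.10 * pattern.get(0, 1.0)

    centroids: list[tuple[float, float]] = []
    base_amp = np.exp(-((t - apex) ** 2) / (2.0 * sigma**2))
    for nu, rel in pattern.items():
        amp = base_amp
        if violation == "shifted_satellite" and nu == sign * 2:
            amp = np.exp(-((t - apex - 15.0) ** 2) / (2.0 * sigma**2))
        elif violation == "narrow_satellite" and nu == sign * 1:
            amp = np.exp(-((t - apex) ** 2) / (2.0 * (sigma / 2.0) ** 2))
        value = compound.height * scale * rel * amp
        if intensity_noise_cv > 0:
            value *= float(np.exp(rng.normal(0.0, intensity_noise_cv)))
        if value < _EMIT_FLOOR:
            continue
        mz = expected_mz(compound.x_mz, nu, 1) * (1.0 + mz_shift_ppm * 1e-6)
        if mz_noise_ppm > 0:
            mz *= 1.0 + float(rng.normal(0.0, mz_noise_ppm * 1e-6))
        centroids.append((mz, value))
    return centroids


def generate_run(
    truth: SyntheticTruth,
    scan_interval: float = 0.5,
    mz_noise_ppm: float = 0.0,
    intensity_noise_cv: float = 0.0,
    n_noise_peaks_per_scan: int = 0,
    noise_mz_range: tuple[float, float] = (150.0, 900.0),
    sample_id: str = "synthetic",
    polarity: str = "+",
    rt_shift: float = 0.0,
    mz_shift_ppm: float = 0.0,
    seed: int | None = None,
) -> Run:
    """Simulate a centroided full-scan run containing the planted compounds.

    Each compound contributes Gaussian chromatographic peaks at the expected
    isotopologue m/z positions with its theoretical pattern intensities;
    decoys apply their stated single-rule violation. ``rt_shift`` (seconds)
    and ``mz_shift_ppm`` emulate between-sample drift for bracketing studies.
    Deterministic for a fixed seed (default: the truth's seed).
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    lo, hi = truth.rt_span
    times = np.arange(lo, hi + scan_interval / 2.0, scan_interval)
    scans: list[MassSpectrum] = []
    for index, t in enumerate(times):
        centroids: list[tuple[float, float]] = []
        for compound in truth.compounds:
            if abs(t - (compound.rt_apex + rt_shift)) > 8.0 * compound.peak_sigma + 20.0:
                continue
            centroids.extend(
                _compound_centroids(
                    compound, float(t), rng, mz_noise_ppm, intensity_noise_cv,
                    rt_shift, mz_shift_ppm,
                )
            )
        for _ in range(n_noise_peaks_per_scan):
            centroids.append(
                (
                    float(rng.uniform(*noise_mz_range)),
                    float(rng.uniform(1e3, 4.5e4)),
                )
            )
        centroids.sort()
        # merge split centroids closer than 1 micro-Dalton to keep m/z strictly ascending
        merged: list[tuple[float, float]] = []
        for mz, inten in centroids:
            if merged and mz - merged[-1][0] < 1e-6:
                merged[-1] = (merged[-1][0], merged[-1][1] + inten)
            else:
                merged.append((mz, inten))
        mzs = np.array([c[0] for c in merged])
        intens = np.array([c[1] for c in merged])
        scans.append(
            MassSpectrum(
                scan_index=index,
                rt=float(t),
                polarity=polarity,
                ms_level=1,
                mz=mzs,
                intensity=intens,
            )
        )
    return Run(sample_id=sample_id, scans=scans, polarity=polarity)


# ---------------------------------------------------------------------------
# mzXML output
# ---------------------------------------------------------------------------

def _encode_peaks(mz: np.ndarray, intensity: np.ndarray, precision: int) -> str:
    dtype = ">f4" if precision == 32 else ">f8"
    interleaved = np.empty(2 * mz.size, dtype=dtype)
    interleaved[0::2] = mz
    interleaved[1::2] = intensity
    return base64.b64encode(interleaved.tobytes()).decode("ascii")


def write_mzxml(run: Run, path: str, precision: int = 32) -> None:
    """Write a minimal valid indexed mzXML file (centroided MS1 scans).

    ``precision`` selects 32- or 64-bit network-order peak encoding.
    """
    if precision not in (32, 64):
        raise ValueError("precision must be 32 or 64")
    buffer = io.StringIO()
    buffer.write('<?xml version="1.0" encoding="ISO-8859-1"?>\n')
    buffer.write(
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">\n'
    )
    buffer.write(f' <msRun scanCount="{len(run.scans)}">\n')
    offsets: list[tuple[int, int]] = []
    for scan in run.scans:
        offsets.append((scan.scan_index + 1, len(buffer.getvalue().encode("utf-8"))))
        low = f"{scan.mz.min():.6f}" if scan.mz.size else "0"
        high = f"{scan.mz.max():.6f}" if scan.mz.size else "0"
        buffer.write(
            f'  <scan num="{scan.scan_index + 1}" msLevel="1" '
            f'peaksCount="{scan.mz.size}" polarity="{scan.polarity}" '
            f'retentionTime="PT{scan.rt!r}S" lowMz="{low}" highMz="{high}" '
            f'totIonCurrent="{scan.tic!r}">\n'
        )
        payload = _encode_peaks(scan.mz, scan.intensity, precision)
        buffer.write(
            f'   <peaks precision="{precision}" byteOrder="network" '
            f'contentType="m/z-int" compressionType="none" '
            f'compressedLen="0">{payload}</peaks>\n'
        )
        buffer.write("  </scan>\n")
    buffer.write(" </msRun>\n")
    index_offset = len(buffer.getvalue().encode("utf-8"))
    buffer.write(' <index name="scan">\n')
    for num, offset in offsets:
        buffer.write(f'  <offset id="{num}">{offset}</offset>\n')
    buffer.write(" </index>\n")
    buffer.write(f" <indexOffset>{index_offset}</indexOffset>\n")
    buffer.write("</mzXML>\n")
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write(buffer.getvalue())


def write_truth_tsv(truth: SyntheticTruth, path: str) -> None:
    """Write the planted-compound ground truth table next to the run files."""
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write(
            "name\tx_mz\trt_apex_s\tpeak_sigma_s\theight\tdirection\t"
            "n_units\tq\tn_carbons\tdecoy_violation\texpected_verdict\n"
        )
        for c in truth.compounds:
            handle.write(
                f"{c.name}\t{c.x_mz:.6f}\t{c.rt_apex:.2f}\t{c.peak_sigma:.2f}\t"
                f"{c.height:.3g}\t{c.model.direction}\t{c.model.n_units}\t"
                f"{c.model.q}\t{c.model.n_carbons}\t{c.decoy_violation or ''}\t"
                f"{'hit' if c.compliant else 'reject'}\n"
            )
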