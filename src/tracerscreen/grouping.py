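"""Cross-sample bracketing, metabolite-level convolution, peak-area
reintegration, and TSV reporting.

Features detected independently in several runs are merged ("bracketed")
when they agree in m/z and retention time; co-eluting, correlated brackets
are connected into feature groups (ions of one metabolite); samples in which
a bracketed compound was not detected get their areas reintegrated from the
raw EIC over the consensus peak bounds.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromatography import Feature, coelution_r
from .msdata import Run, extract_eic
from .rules import expected_mz

__all__ = [
    "SampleEntry",
    "BracketedFeature",
    "FeatureGroup",
    "bracket",
    "convolute",
    "reintegrate",
    "write_results_tsv",
    "read_results_tsv",
]


@dataclass
class SampleEntry:
    """Per-sample content of a bracket: a detected feature or reintegrated areas."""

    feature: Feature | None
    areas: dict[int, float | None]
    flag: str  # 'detected' | 'reintegrated' | 'missing'


@dataclass
class BracketedFeature:
    consensus_mz: float
    consensus_rt: float  # seconds
    per_sample: dict[str, SampleEntry]

    @property
    def detected_samples(self) -> list[str]:
        return [s for s, e in self.per_sample.items() if e.flag == "detected"]

    @property
    def consensus_bounds(self) -> tuple[float, float]:
        bounds = [e.feature.x_peak.bounds for e in self.per_sample.values() if e.feature]
        if not bounds:
            raise ValueError("bracket has no detected member")
        return float(np.mean([b[0] for b in bounds])), float(np.mean([b[1] for b in bounds]))


@dataclass
class FeatureGroup:
    group_id: int
    members: list[BracketedFeature]
    annotations: list[str] = field(default_factory=list)


def _feature_weight(feature: Feature) -> float:
    return sum(p.area for p in feature.peaks.values())


def bracket(
    features_by_sample: dict[str, list[Feature]],
    rt_tol: float = 6.0,
    mz_ppm: float = 5.0,
) -> list[BracketedFeature]:
    """Merge corresponding features across samples.

    Greedy centroid-based merging in deterministic order (descending summed
    isotopologue area): the strongest unassigned feature seeds a bracket and
    collects, from every sample, the closest unassigned feature within
    ``rt_tol`` seconds and ``mz_ppm`` of the seed. Each sample contributes at
    most one feature per bracket.
    """
    pool: list[tuple[str, Feature]] = [
        (sample, feat) for sample, feats in features_by_sample.items() for feat in feats
    ]
    pool.sort(key=lambda sf: (-_feature_weight(sf[1]), sf[0], sf[1].x_mz, sf[1].apex_rt))
    assigned = [False] * len(pool)
    brackets: list[BracketedFeature] = []
    for i, (seed_sample, seed) in enumerate(pool):
        if assigned[i]:
            continue
        assigned[i] = True
        members: dict[str, tuple[int, Feature]] = {seed_sample: (i, seed)}
        for j, (sample, feat) in enumerate(pool):
            if assigned[j] or sample in members:
                continue
            if abs(feat.apex_rt - seed.apex_rt) > rt_tol:
                continue
            if abs(feat.x_mz - seed.x_mz) / seed.x_mz * 1e6 > mz_ppm:
                continue
            prev = members.get(sample)
            members[sample] = (j, feat)
        for sample, (j, feat) in members.items():
            assigned[j] = True
        per_sample = {
            sample: SampleEntry(feature=feat, areas=dict(feat.areas), flag="detected")
            for sample, (_, feat) in members.items()
        }
        brackets.append(
            BracketedFeature(
                consensus_mz=float(np.mean([f.x_mz for _, f in members.values()])),
                consensus_rt=float(np.mean([f.apex_rt for _, f in members.values()])),
                per_sample=per_sample,
            )
        )
    brackets.sort(key=lambda b: (b.consensus_mz, b.consensus_rt))
    return brackets


def convolute(
    brackets: list[BracketedFeature],
    runs: dict[str, Run],
    r_min: float = 0.85,
    rt_tol: float = 6.0,
    eic_ppm: float = 5.0,
) -> list[FeatureGroup]:
    """Group co-eluting, correlated brackets into metabolite-level groups.

    Two brackets are connected when their consensus retention times differ by
    at most ``rt_tol`` seconds and their X EICs correlate with Pearson r >=
    ``r_min`` over the union of their peak bounds in at least one shared
    sample. Connected components become feature groups.
    """
    n = len(brackets)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i in range(n):
        for j in range(i + 1, n):
            bi, bj = brackets[i], brackets[j]
            if abs(bi.consensus_rt - bj.consensus_rt) > rt_tol:
                continue
            shared = sorted(set(bi.detected_samples) & set(bj.detected_samples) & set(runs))
            for sample in shared:
                run = runs[sample]
                lo = min(bi.consensus_bounds[0], bj.consensus_bounds[0])
                hi = max(bi.consensus_bounds[1], bj.consensus_bounds[1])
                eic_i = extract_eic(run, bi.consensus_mz, eic_ppm, (lo, hi))
                eic_j = extract_eic(run, bj.consensus_mz, eic_ppm, (lo, hi))
                try:
                    r = coelution_r(eic_i, eic_j)
                except ValueError:
                    continue
                if np.isfinite(r) and r >= r_min:
                    union(i, j)
                    break

    components: dict[int, list[BracketedFeature]] = {}
    for i, b in enumerate(brackets):
        components.setdefault(find(i), []).append(b)
    groups = [
        FeatureGroup(group_id=gid, members=members)
        for gid, members in enumerate(
            sorted(components.values(), key=lambda ms: (ms[0].consensus_rt, ms[0].consensus_mz)),
            start=1,
        )
    ]
    return groups


def reintegrate(
    bracket_: BracketedFeature,
    runs: dict[str, Run],
    eic_ppm: float = 5.0,
    charge: int = 1,
) -> BracketedFeature:
    """Fill areas for samples in which the bracket was not detected.

    For every sample without a detected feature, the X and satellite EICs are
    integrated over the consensus peak bounds and flagged 'reintegrated'.
    Detected members are never altered. Samples whose run is unavailable get
    areas of None and the flag 'missing'.
    """
    offsets: set[int] = set()
    for entry in bracket_.per_sample.values():
        offsets.update(entry.areas)
    if not offsets:
        offsets = {0}
    lo, hi = bracket_.consensus_bounds
    for sample, run in runs.items():
        if sample in bracket_.per_sample and bracket_.per_sample[sample].flag == "detected":
            continue
        if run is None:
            bracket_.per_sample[sample] = SampleEntry(
                feature=None, areas={nu: None for nu in sorted(offsets)}, flag="missing"
            )
            continue
        areas: dict[int, float | None] = {}
        for nu in sorted(offsets):
            try:
                eic = extract_eic(run, expected_mz(bracket_.consensus_mz, nu, charge), eic_ppm, (lo, hi))
                areas[nu] = float(np.trapezoid(eic.intensity, eic.rt))
            except ValueError:
                areas[nu] = None
        bracket_.per_sample[sample] = SampleEntry(feature=None, areas=areas, flag="reintegrated")
    return bracket_


def write_results_tsv(groups: list[FeatureGroup], path: str, charge: int = 1) -> pd.DataFrame:
    """Write the result matrix: one row per bracketed feature.

    Columns: group id, consensus m/z, consensus rt (minutes), charge, then
    per sample one flag column and one area column per isotopologue offset.
    UTF-8, Unix newlines, tab separators, '.' decimal point. Returns the
    DataFrame that was written.
    """
    samples: list[str] = sorted(
        {s for g in groups for b in g.members for s in b.per_sample}
    )
    offsets: list[int] = sorted(
        {nu for g in groups for b in g.members for e in b.per_sample.values() for nu in e.areas}
    )
    rows = []
    for group in groups:
        for b in group.members:
            row: dict[str, object] = {
                "group_id": group.group_id,
                "mz": round(b.consensus_mz, 6),
                "rt_min": round(b.consensus_rt / 60.0, 4),
                "charge": charge,
            }
            for sample in samples:
                entry = b.per_sample.get(sample)
                row[f"{sample}.flag"] = entry.flag if entry else "missing"
                for nu in offsets:
                    value = entry.areas.get(nu) if entry else None
                    row[f"{sample}.area_X{nu:+d}"] = "" if value is None else round(value, 2)
            rows.append(row)
    columns = ["group_id", "mz", "rt_min", "charge"]
    for sample in samples:
        columns.append(f"{sample}.flag")
        columns.extend(f"{sample}.area_X{nu:+d}" for nu in offsets)
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")
    return frame


def read_results_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
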