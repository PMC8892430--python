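"""Scan-level pattern search and time-aware clustering of surviving signals.

Every centroid of every MS1 scan is provisionally treated as the principal
isotopologue X of a pattern; the rule-referenced satellite positions are
looked up within the intra-scan mass accuracy and the rule set is evaluated
on the resulting intensity map. Survivors are clustered on X m/z
(complete-linkage, dendrogram cut at the inter-scan mass deviation so that
cluster diameter is bounded) and each m/z cluster is split on scan-index
gaps, so non-coeluting isomers end up in separate candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .msdata import MassSpectrum, Run, lookup
from .rules import RuleSet, expected_mz

__all__ = ["ScanCandidate", "FeatureCandidate", "screen_run", "screen_scan", "cluster_candidates"]


@dataclass
class ScanCandidate:
    """A single-scan X signal whose satellites satisfied the rule set."""

    scan_index: int
    rt: float
    x_mz: float
    x_intensity: float
    matched: dict[int, tuple[float, float]]  # offset -> (mz, intensity)


@dataclass
class FeatureCandidate:
    """A group of scan candidates: one putative chromatographic feature."""

    mean_mz: float
    rt_window: tuple[float, float]
    members: list[ScanCandidate]

    @property
    def scan_range(self) -> tuple[int, int]:
        idx = [m.scan_index for m in self.members]
        return min(idx), max(idx)


def screen_scan(
    scan: MassSpectrum,
    ruleset: RuleSet,
    intra_ppm: float = 5.0,
) -> list[ScanCandidate]:
    """Evaluate the rule set with every centroid of one scan as putative X."""
    offsets = sorted(ruleset.referenced_offsets)
    min_x = ruleset.min_x_intensity
    candidates: list[ScanCandidate] = []
    for i in range(scan.mz.size):
        x_int = float(scan.intensity[i])
        if x_int < min_x:  # cannot pass the rule that implies this bound
            continue
        x_mz = float(scan.mz[i])
        intensities: dict[int, float | None] = {}
        matched: dict[int, tuple[float, float]] = {}
        for nu in offsets:
            if nu == 0:
                intensities[0] = x_int
                matched[0] = (x_mz, x_int)
                continue
            hit = lookup(scan, expected_mz(x_mz, nu, ruleset.charge), intra_ppm)
            if hit is None:
                intensities[nu] = None
            else:
                intensities[nu] = hit[1]
                matched[nu] = hit
        if ruleset.evaluate(intensities).passed:
            candidates.append(
                ScanCandidate(
                    scan_index=scan.scan_index,
                    rt=scan.rt,
                    x_mz=x_mz,
                    x_intensity=x_int,
                    matched=matched,
                )
            )
    return candidates


def screen_run(run: Run, ruleset: RuleSet, intra_ppm: float = 5.0) -> list[ScanCandidate]:
    """Scan-level pattern search over all MS1 scans of a run."""
    if not run.scans:
        raise ValueError("cannot screen an empty run")
    candidates: list[ScanCandidate] = []
    for scan in run.scans:
        candidates.extend(screen_scan(scan, ruleset, intra_ppm))
    return candidates


def cluster_candidates(
    candidates: list[ScanCandidate],
    inter_ppm: float = 8.0,
    max_scan_gap: int = 3,
    min_members: int = 3,
) -> list[FeatureCandidate]:
    """Group scan candidates into putative features.

    Complete-linkage agglomerative clustering on log(m/z) with the dendrogram
    cut at ``inter_ppm * 1e-6`` bounds each cluster's relative m/z diameter
    by the inter-scan mass deviation. Each m/z cluster is then split wherever
    consecutive members are more than ``max_scan_gap`` scans apart, and
    groups with fewer than ``min_members`` members are discarded (a real
    chromatographic peak spans several consecutive scans).

    The result is invariant under permutation of the input order.
    """
    if not candidates:
        return []
    ordered = sorted(candidates, key=lambda c: (c.x_mz, c.scan_index, -c.x_intensity))
    log_mz = np.array([[np.log(c.x_mz)] for c in ordered])
    if len(ordered) == 1:
        labels = np.array([1])
    else:
        tree = linkage(log_mz, method="complete")
        labels = fcluster(tree, t=inter_ppm * 1e-6, criterion="distance")

    features: list[FeatureCandidate] = []
    for label in np.unique(labels):
        members = [c for c, l in zip(ordered, labels) if l == label]
        members.sort(key=lambda c: (c.scan_index, c.x_mz))
        # split on scan gaps
        chunk: list[ScanCandidate] = [members[0]]
        chunks: list[list[ScanCandidate]] = []
        for cand in members[1:]:
            if cand.scan_index - chunk[-1].scan_index > max_scan_gap:
                chunks.append(chunk)
                chunk = [cand]
            else:
                chunk.append(cand)
        chunks.append(chunk)
        for group in chunks:
            scans = {c.scan_index for c in group}
            if len(scans) < min_members:
                continue
            features.append(
                FeatureCandidate(
                    mean_mz=float(np.mean([c.x_mz for c in group])),
                    rt_window=(min(c.rt for c in group), max(c.rt for c in group)),
                    members=group,
                )
            )
    features.sort(key=lambda f: (f.mean_mz, f.rt_window))
    return features
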