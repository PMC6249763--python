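"""Marker filtering cascade for GBS genotypes of a full-sib population.

Stages, applied in order:

1. depth masking — calls with read depth outside [depth_min, depth_max]
   (inclusive) become missing;
2. alphabet masking — calls outside the marker's segregation-class alphabet
   become missing;
3. missing/integrity removal — a marker is removed when its missing-call
   count exceeds ``max_missing_individuals`` or its non-missing fraction
   falls below ``min_integrity`` (two independent rules, OR-joined);
4. segregation-distortion removal — Pearson chi-square against the class's
   Mendelian ratio (1:1 or 1:2:1), no continuity correction, removal at
   p < distortion_alpha;
5. redundancy reduction — at most ``max_snps_per_scaffold`` markers per
   scaffold, chosen nearest to evenly spaced targets over the occupied span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CLASS_ALPHABET, MISSING_CALL, GenotypeMatrix

EXPECTED_RATIOS = {
    "lmxll": {"lm": 1, "ll": 1},
    "nnxnp": {"nn": 1, "np": 1},
    "hkxhk": {"hh": 1, "hk": 2, "kk": 1},
}


@dataclass
class QcParams:
    depth_min: int = 5
    depth_max: int = 1500
    max_missing_individuals: int = 10
    min_integrity: float = 0.95
    distortion_alpha: float = 0.05
    max_snps_per_scaffold: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.min_integrity <= 1:
            raise ValueError("min_integrity must be in (0, 1]")
        if self.depth_min > self.depth_max:
            raise ValueError("depth_min > depth_max")
        if not 0 < self.distortion_alpha < 1:
            raise ValueError("distortion_alpha must be in (0, 1)")


@dataclass
class QcReport:
    n_input: int = 0
    removed_missing: list[str] = field(default_factory=list)
    removed_distorted: list[str] = field(default_factory=list)
    removed_redundant: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    chi_square: pd.DataFrame | None = None  # marker_id, chi2, p

    def counts(self) -> dict[str, int]:
        return {
            "input": self.n_input,
            "removed_missing_or_integrity": len(self.removed_missing),
            "removed_distorted": len(self.removed_distorted),
            "removed_redundant": len(self.removed_redundant),
            "retained": len(self.retained),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mid in self.retained:
            rows.append((mid, "retained"))
        for mid in self.removed_missing:
            rows.append((mid, "missing_or_integrity"))
        for mid in self.removed_distorted:
            rows.append((mid, "distorted"))
        for mid in self.removed_redundant:
            rows.append((mid, "redundant"))
        df = pd.DataFrame(rows, columns=["marker_id", "status"]).set_index("marker_id")
        if self.chi_square is not None:
            df = df.join(self.chi_square, how="left")
        return df.reset_index()


def depth_mask(matrix: GenotypeMatrix, params: QcParams | None = None) -> GenotypeMatrix:
    """Mask calls whose depth lies outside the inclusive [depth_min, depth_max]."""
    params = params or QcParams()
    out = matrix.copy()
    bad = (out.depths < params.depth_min) | (out.depths > params.depth_max)
    out.calls = out.calls.mask(bad, MISSING_CALL)
    return out


def alphabet_mask(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Mask calls outside their marker's segregation-class alphabet."""
    out = matrix.copy()
    calls = out.calls.to_numpy(dtype=object)
    for i, seg in enumerate(out.classes):
        allowed = set(CLASS_ALPHABET[seg]) | {MISSING_CALL}
        row = calls[i]
        calls[i] = np.where(np.isin(row, list(allowed)), row, MISSING_CALL)
    out.calls = pd.DataFrame(calls, index=out.calls.index, columns=out.calls.columns)
    return out


def chi_square_segregation(counts: dict[str, int], seg_class: str) -> tuple[float, float]:
    """Pearson chi-square of observed class counts against the Mendelian
    expectation (1:1 for testcross classes, 1:2:1 for hk×hk); df = classes-1."""
    ratios = EXPECTED_RATIOS[seg_class]
    observed = np.array([counts.get(c, 0) for c in ratios], dtype=float)
    total = observed.sum()
    if total == 0:
        raise ValueError("zero total count")
    weights = np.array(list(ratios.values()), dtype=float)
    expected = total * weights / weights.sum()
    chi2, p = stats.chisquare(observed, expected)
    return float(chi2), float(p)


def missing_and_integrity_filter(
    matrix: GenotypeMatrix, params: QcParams | None = None
) -> tuple[list[str], list[str]]:
    """Split markers into (retained, removed) by the missing-count and
    integrity rules; expects a depth-masked matrix."""
    params = params or QcParams()
    n = matrix.n_offspring
    missing = (matrix.calls == MISSING_CALL).sum(axis=1)
    integrity = (n - missing) / n
    removed_mask = (missing > params.max_missing_individuals) | (
        integrity < params.min_integrity
    )
    removed = list(matrix.calls.index[removed_mask])
    retained = list(matrix.calls.index[~removed_mask])
    return retained, removed


def reduce_redundancy(positions: pd.Series, k: int = 5) -> list[str]:
    """Pick at most k markers "equally distributed" over one scaffold.

    positions: marker_id -> scaffold bp.  Targets are k evenly spaced points
    from the first to the last occupied position (inclusive endpoints); each
    target takes its nearest not-yet-selected marker, ties toward the lower
    position.  Returns ids in position order.
    """
    positions = positions.sort_values(kind="mergesort")
    if len(positions) <= k:
        return list(positions.index)
    pos = positions.to_numpy(dtype=float)
    ids = list(positions.index)
    lo, hi = pos[0], pos[-1]
    targets = np.linspace(lo, hi, k)
    chosen: list[int] = []
    for t in targets:
        best = None
        for i in range(len(pos)):
            if i in chosen:
                continue
            d = abs(pos[i] - t)
            if best is None or d < best[0] - 1e-12:
                best = (d, i)
            # ties keep the earlier (lower-position) candidate
        chosen.append(best[1])
    chosen.sort()
    return [ids[i] for i in chosen]


def run_qc(matrix: GenotypeMatrix, params: QcParams | None = None) -> tuple[GenotypeMatrix, QcReport]:
    """The full cascade; returns the filtered matrix and a per-rule report."""
    params = params or QcParams()
    report = QcReport(n_input=matrix.n_markers)

    masked = alphabet_mask(depth_mask(matrix, params))

    retained, removed = missing_and_integrity_filter(masked, params)
    report.removed_missing = removed
    masked = _subset(masked, retained)

    chi_rows = []
    keep: list[str] = []
    for mid in masked.calls.index:
        seg = masked.classes[mid]
        row = masked.calls.loc[mid]
        counts = row[row != MISSING_CALL].value_counts().to_dict()
        if sum(counts.values()) == 0:
            report.removed_distorted.append(mid)
            continue
        chi2, p = chi_square_segregation(counts, seg)
        chi_rows.append((mid, chi2, p))
        if p < params.distortion_alpha:
            report.removed_distorted.append(mid)
        else:
            keep.append(mid)
    report.chi_square = pd.DataFrame(
        chi_rows, columns=["marker_id", "chi2", "p"]
    ).set_index("marker_id")
    masked = _subset(masked, keep)

    if masked.positions is not None and len(keep):
        selected: list[str] = []
        for _scaffold, grp in masked.positions.groupby("scaffold", sort=True):
            selected.extend(
                reduce_redundancy(grp["pos"], k=params.max_snps_per_scaffold)
            )
        selected_set = set(selected)
        report.removed_redundant = [m for m in keep if m not in selected_set]
        keep = [m for m in keep if m in selected_set]
        masked = _subset(masked, keep)

    report.retained = keep
    return masked, report


def _subset(matrix: GenotypeMatrix, ids: list[str]) -> GenotypeMatrix:
    return GenotypeMatrix(
        matrix.calls.loc[ids],
        matrix.depths.loc[ids],
        matrix.classes.loc[ids],
        None if matrix.positions is None else matrix.positions.loc[ids],
    )
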