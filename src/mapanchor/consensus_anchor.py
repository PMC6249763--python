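"""Weighted multi-map consensus anchoring of scaffolds into chromosomes.

Given several per-population linkage maps, each with a reliability weight,
the anchorer assigns every scaffold to the chromosome (linkage group) with
the largest weighted marker support, derives a weighted consensus position,
and searches for the scaffold ordering that maximizes the collinearity
objective

    J(order) = sum_k  w_k * rho_k,

where rho_k is the Spearman rank correlation between map k's marker cM
positions and the marker order induced by the scaffold ordering.  Scaffolds
with two or more markers at distinct positions are additionally oriented by
the weighted sign of their within-scaffold bp-vs-cM correlation; everything
else stays strandless ("?").  Unanchorable scaffolds go to chromosome 0.

The ordering search is exact (full enumeration) for small chromosome groups
and a deterministic steepest-ascent pairwise-swap hill-climb seeded by the
consensus positions otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneticMap, ScaffoldSet

EXACT_ENUMERATION_LIMIT = 8


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("spearman_rho needs two equal-length vectors of size >= 2")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass
class ScaffoldAnchor:
    scaffold: str
    chrom: int  # 0 = unplaced
    order_index: int | None = None
    orientation: str = "?"
    n_markers_total: int = 0
    n_markers_per_map: dict[str, int] = field(default_factory=dict)
    consensus_pos: float | None = None  # normalized 0..1 along the chromosome


@dataclass
class AnchorPlan:
    anchors: list[ScaffoldAnchor]

    def __post_init__(self) -> None:
        self._index = {a.scaffold: a for a in self.anchors}
        for chrom, group in self.by_chromosome().items():
            if chrom == 0:
                continue
            idx = sorted(a.order_index for a in group)
            if idx != list(range(len(group))):
                raise ValueError(f"chromosome {chrom}: order indices not contiguous")

    def __getitem__(self, scaffold: str) -> ScaffoldAnchor:
        return self._index[scaffold]

    def __contains__(self, scaffold: str) -> bool:
        return scaffold in self._index

    def by_chromosome(self) -> dict[int, list[ScaffoldAnchor]]:
        out: dict[int, list[ScaffoldAnchor]] = {}
        for a in self.anchors:
            out.setdefault(a.chrom, []).append(a)
        for chrom, group in out.items():
            if chrom != 0:
                group.sort(key=lambda a: a.order_index)
        return out

    def ordered_scaffolds(self, chrom: int) -> list[str]:
        return [a.scaffold for a in self.by_chromosome().get(chrom, [])]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.anchors:
            rows.append((
                a.scaffold, a.chrom,
                a.order_index if a.order_index is not None else ".",
                a.orientation, a.n_markers_total,
                round(a.consensus_pos, 6) if a.consensus_pos is not None else ".",
            ))
        return pd.DataFrame(rows, columns=[
            "scaffold", "chrom", "order_index", "orientation",
            "n_markers", "consensus_pos",
        ])


@dataclass
class MapConcordance:
    """Spearman rho between each individual map's marker order and the
    consensus, per (map, linkage group)."""

    rows: pd.DataFrame  # map, lg, n_markers, rho (NaN when undefined)

    def to_frame(self) -> pd.DataFrame:
        return self.rows


# ---------------------------------------------------------------------------
# chromosome assignment


def assign_chromosome(scaffold: str, maps: list[GeneticMap]) -> int:
    """Chromosome with the largest sum of (map weight x marker count); 0 on a
    tie or when no map places the scaffold."""
    scores: dict[int, float] = {}
    for gmap in maps:
        for pl in gmap.scaffold_placements(scaffold):
            scores[pl.lg] = scores.get(pl.lg, 0.0) + gmap.weight
    if not scores:
        return 0
    best = max(scores.values())
    winners = [lg for lg, s in scores.items() if s == best]
    return winners[0] if len(winners) == 1 else 0


# ---------------------------------------------------------------------------
# consensus positions


def _lg_span(gmap: GeneticMap, lg: int) -> tuple[float, float]:
    cms = [pl.cm for pl in gmap.lg_placements(lg)]
    return (min(cms), max(cms)) if cms else (0.0, 0.0)


def consensus_positions(
    scaffolds: list[str], chrom: int, maps: list[GeneticMap]
) -> dict[str, float]:
    """Weighted mean of per-map normalized scaffold positions.

    Per map, a scaffold's position is the mean cM of its markers on the
    assigned LG, normalized by the LG span to [0,1] (0.5 for degenerate
    zero-span LGs); the consensus is the weight-averaged position over the
    maps that place the scaffold.
    """
    out: dict[str, float] = {}
    spans = {gmap.name: _lg_span(gmap, chrom) for gmap in maps}
    for scaffold in scaffolds:
        num = 0.0
        den = 0.0
        for gmap in maps:
            cms = [pl.cm for pl in gmap.scaffold_placements(scaffold) if pl.lg == chrom]
            if not cms:
                continue
            lo, hi = spans[gmap.name]
            pos = (float(np.mean(cms)) - lo) / (hi - lo) if hi > lo else 0.5
            num += gmap.weight * pos
            den += gmap.weight
        out[scaffold] = num / den if den else 0.5
    return out


# ---------------------------------------------------------------------------
# ordering


class _GroupObjective:
    """Precomputed evaluator of J = sum_k w_k rho_k for one chromosome group.

    For each map the group's markers are frozen into (scaffold index,
    within-scaffold bp, cM rank) arrays so evaluating a candidate ordering is
    a rank computation plus a Pearson on ranks.
    """

    def __init__(self, scaffolds: list[str], chrom: int, maps: list[GeneticMap]):
        self.scaffolds = list(scaffolds)
        index = {s: i for i, s in enumerate(self.scaffolds)}
        self.maps = []
        for gmap in maps:
            scaf_idx = []
            pos = []
            cm = []
            for pl in gmap.placements:
                if pl.lg == chrom and pl.scaffold in index:
                    scaf_idx.append(index[pl.scaffold])
                    pos.append(pl.pos)
                    cm.append(pl.cm)
            if len(cm) < 2:
                continue
            cm_rank = stats.rankdata(cm, method="average")
            if np.ptp(cm_rank) == 0:
                continue
            self.maps.append((
                gmap.weight,
                np.asarray(scaf_idx),
                np.asarray(pos, dtype=float),
                cm_rank - cm_rank.mean(),
            ))

    def __call__(self, order: list[str]) -> float:
        rank_of = np.empty(len(self.scaffolds), dtype=float)
        for r, s in enumerate(order):
            rank_of[self.scaffolds.index(s)] = r
        total = 0.0
        for w, scaf_idx, pos, cm_rank_c in self.maps:
            induced = stats.rankdata(rank_of[scaf_idx] * 1e12 + pos,
                                     method="average")
            induced_c = induced - induced.mean()
            denom = np.sqrt((induced_c ** 2).sum() * (cm_rank_c ** 2).sum())
            if denom > 0:
                total += w * float((induced_c * cm_rank_c).sum() / denom)
        return total


def ordering_objective(order: list[str], chrom: int, maps: list[GeneticMap]) -> float:
    """J = sum_k w_k * rho_k for a candidate scaffold ordering.

    Marker rank along the chromosome is induced by (position of the marker's
    scaffold in the ordering, within-scaffold bp); maps with fewer than two
    markers in the group, or a degenerate rho, contribute zero.
    """
    return _GroupObjective(order, chrom, maps)(order)


def order_scaffolds(
    scaffolds: list[str], chrom: int, maps: list[GeneticMap],
    method: str = "auto",
) -> list[str]:
    """Ordering maximizing J; exact for <= EXACT_ENUMERATION_LIMIT scaffolds,
    otherwise consensus-position sort + steepest-ascent pairwise-swap
    hill-climb.  Deterministic tie-break by scaffold id.  ``method`` can force
    "exact" or "hillclimb"."""
    if method not in ("auto", "exact", "hillclimb"):
        raise ValueError(f"unknown ordering method {method!r}")
    pos = consensus_positions(scaffolds, chrom, maps)
    start = sorted(scaffolds, key=lambda s: (pos[s], s))
    if len(scaffolds) <= 1:
        return start
    objective = _GroupObjective(sorted(scaffolds), chrom, maps)
    use_exact = (method == "exact"
                 or (method == "auto" and len(scaffolds) <= EXACT_ENUMERATION_LIMIT))
    if use_exact:
        best_order = None
        best_j = -np.inf
        for perm in itertools.permutations(sorted(scaffolds)):
            j = objective(list(perm))
            if j > best_j + 1e-12:
                best_j = j
                best_order = list(perm)
        return best_order

    current = start
    current_j = objective(current)
    improved = True
    while improved:
        improved = False
        best_swap = None
        best_j = current_j
        for i in range(len(current) - 1):
            for j in range(i + 1, len(current)):
                cand = current.copy()
                cand[i], cand[j] = cand[j], cand[i]
                cj = objective(cand)
                if cj > best_j + 1e-12:
                    best_j = cj
                    best_swap = (i, j)
        if best_swap is not None:
            i, j = best_swap
            current[i], current[j] = current[j], current[i]
            current_j = best_j
            improved = True
    return current


# ---------------------------------------------------------------------------
# orientation


def orient_scaffold(scaffold: str, chrom: int, maps: list[GeneticMap]) -> str:
    """Sign of the weighted within-scaffold bp-vs-cM correlation: "+", "-",
    or "?" when undefined (fewer than 2 markers at distinct bp and cM, or an
    exactly balanced signal)."""
    total = 0.0
    supported = False
    for gmap in maps:
        pls = [pl for pl in gmap.scaffold_placements(scaffold) if pl.lg == chrom]
        if len(pls) < 2:
            continue
        bps = np.array([pl.pos for pl in pls], dtype=float)
        cms = np.array([pl.cm for pl in pls], dtype=float)
        if len(set(bps)) < 2 or len(set(cms)) < 2:
            continue
        rho = stats.spearmanr(bps, cms).statistic
        if np.isfinite(rho):
            total += gmap.weight * rho
            supported = True
    if not supported or total == 0.0:
        return "?"
    return "+" if total > 0 else "-"


# ---------------------------------------------------------------------------
# the full plan


def build_anchor_plan(
    scaffolds: ScaffoldSet | list[str], maps: list[GeneticMap]
) -> AnchorPlan:
    """Assign, position, order and orient every scaffold.

    Markers on a scaffold's losing linkage group (when maps disagree on the
    chromosome) are excluded from positioning and orientation.
    """
    ids = scaffolds.ids() if isinstance(scaffolds, ScaffoldSet) else list(scaffolds)
    # include scaffolds that appear only in maps (no sequence provided)
    mapped = {pl.scaffold for gmap in maps for pl in gmap.placements}
    all_ids = list(dict.fromkeys(list(ids) + sorted(mapped - set(ids))))

    anchors: dict[str, ScaffoldAnchor] = {}
    groups: dict[int, list[str]] = {}
    for sid in all_ids:
        chrom = assign_chromosome(sid, maps)
        per_map = {
            gmap.name: len([pl for pl in gmap.scaffold_placements(sid)
                            if chrom == 0 or pl.lg == chrom])
            for gmap in maps
        }
        per_map = {k: v for k, v in per_map.items() if v}
        anchors[sid] = ScaffoldAnchor(
            scaffold=sid,
            chrom=chrom,
            n_markers_total=sum(per_map.values()),
            n_markers_per_map=per_map,
        )
        if chrom != 0:
            groups.setdefault(chrom, []).append(sid)

    for chrom, group in sorted(groups.items()):
        pos = consensus_positions(group, chrom, maps)
        order = order_scaffolds(group, chrom, maps)
        for idx, sid in enumerate(order):
            a = anchors[sid]
            a.order_index = idx
            a.consensus_pos = pos[sid]
            a.orientation = orient_scaffold(sid, chrom, maps)

    return AnchorPlan([anchors[sid] for sid in all_ids])


# ---------------------------------------------------------------------------
# concordance with individual maps


def compare_maps(plan: AnchorPlan, maps: list[GeneticMap]) -> MapConcordance:
    """Spearman rho between each map's marker cM order and the consensus
    marker order, per (map, LG); NaN when fewer than two shared markers."""
    rows = []
    for gmap in maps:
        for lg in gmap.linkage_groups():
            cms = []
            induced = []
            for pl in gmap.lg_placements(lg):
                if pl.scaffold not in plan:
                    continue
                a = plan[pl.scaffold]
                if a.chrom != lg or a.order_index is None:
                    continue
                within = pl.pos if a.orientation != "-" else -pl.pos
                cms.append(pl.cm)
                induced.append(a.order_index * 10**12 + within)
            if len(cms) >= 2:
                rho = float(stats.spearmanr(cms, induced).statistic)
            else:
                rho = float("nan")
            rows.append((gmap.name, lg, len(cms), rho))
    return MapConcordance(
        pd.DataFrame(rows, columns=["map", "lg", "n_markers", "rho"])
    )
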