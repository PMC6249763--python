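"""Pseudo-chromosome construction from an anchor plan, plus assembly and
linkage-map summary statistics.

Scaffolds assigned to a chromosome are concatenated in plan order with a
spacer of N bases (default 100) between consecutive scaffolds; "-" scaffolds
are reverse-complemented, "?" scaffolds enter forward but keep "?" in the
AGP.  Chromosome length therefore equals the scaffold-length sum plus
gap_len * (n_scaffolds - 1).  Unplaced (chromosome 0) scaffolds remain
separate records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus_anchor import AnchorPlan
from .io_formats import AgpRow, GeneticMap, ScaffoldSet

DEFAULT_GAP_LEN = 100

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AssemblyBundle:
    """Pseudo-chromosome sequences, their AGP, and marker projections."""

    chrom_sequences: dict[str, str | None]
    chrom_lengths: dict[str, int]
    agp: list[AgpRow]
    scaffold_counts: dict[str, int]
    scaffold_bp: dict[str, int]
    unplaced: list[str] = field(default_factory=list)
    marker_projections: pd.DataFrame | None = None  # marker_id, chrom, chrom_pos

    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def total_scaffold_bp(self) -> int:
        return sum(self.scaffold_bp.values())


def build_pseudochromosomes(
    plan: AnchorPlan,
    scaffolds: ScaffoldSet,
    gap_len: int = DEFAULT_GAP_LEN,
    maps: list[GeneticMap] | None = None,
    chrom_prefix: str = "chr",
) -> AssemblyBundle:
    """Concatenate anchored scaffolds into pseudo-chromosomes.

    Works in length-only mode when the ScaffoldSet carries no sequences (the
    AGP and all lengths are still produced).  Raises KeyError when the plan
    references a scaffold missing from the set.
    """
    by_chrom = plan.by_chromosome()
    chrom_sequences: dict[str, str | None] = {}
    chrom_lengths: dict[str, int] = {}
    scaffold_counts: dict[str, int] = {}
    scaffold_bp: dict[str, int] = {}
    agp: list[AgpRow] = []
    placements: dict[str, tuple[str, int, str]] = {}  # scaffold -> (chrom, offset, orient)

    for chrom in sorted(c for c in by_chrom if c != 0):
        name = f"{chrom_prefix}{chrom}"
        parts: list[str] = []
        cursor = 1
        part_no = 0
        n_scaf = 0
        bp_sum = 0
        have_seq = True
        for anchor in by_chrom[chrom]:
            if anchor.scaffold not in scaffolds:
                raise KeyError(f"scaffold {anchor.scaffold!r} missing from scaffold set")
            rec = scaffolds[anchor.scaffold]
            if n_scaf > 0 and gap_len > 0:
                part_no += 1
                agp.append(AgpRow(name, cursor, cursor + gap_len - 1, part_no,
                                  "N", gap_length=gap_len))
                parts.append("N" * gap_len)
                cursor += gap_len
            part_no += 1
            agp.append(AgpRow(name, cursor, cursor + rec.length - 1, part_no,
                              "W", component_id=rec.id, component_beg=1,
                              component_end=rec.length,
                              orientation=anchor.orientation))
            placements[rec.id] = (name, cursor, anchor.orientation)
            if rec.sequence is None:
                have_seq = False
            elif anchor.orientation == "-":
                parts.append(revcomp(rec.sequence))
            else:
                parts.append(rec.sequence)
            cursor += rec.length
            n_scaf += 1
            bp_sum += rec.length
        chrom_lengths[name] = cursor - 1
        chrom_sequences[name] = "".join(parts) if have_seq else None
        scaffold_counts[name] = n_scaf
        scaffold_bp[name] = bp_sum

    unplaced = [a.scaffold for a in by_chrom.get(0, [])]
    bundle = AssemblyBundle(
        chrom_sequences=chrom_sequences,
        chrom_lengths=chrom_lengths,
        agp=agp,
        scaffold_counts=scaffold_counts,
        scaffold_bp=scaffold_bp,
        unplaced=unplaced,
    )
    if maps:
        bundle.marker_projections = project_markers(placements, scaffolds, maps)
    return bundle


def project_markers(
    placements: dict[str, tuple[str, int, str]],
    scaffolds: ScaffoldSet,
    maps: list[GeneticMap],
) -> pd.DataFrame:
    """Project map markers through scaffold placements onto chromosome
    coordinates (1-based)."""
    rows = []
    for gmap in maps:
        for pl in gmap.placements:
            if pl.scaffold not in placements:
                continue
            chrom, offset, orient = placements[pl.scaffold]
            length = scaffolds[pl.scaffold].length
            if orient == "-":
                chrom_pos = offset + (length - pl.pos)
            else:
                chrom_pos = offset + pl.pos - 1
            rows.append((pl.marker_id, gmap.name, chrom, chrom_pos))
    return pd.DataFrame(rows, columns=["marker_id", "map", "chrom", "chrom_pos"])


def rebuild_from_agp(agp: list[AgpRow], scaffolds: ScaffoldSet) -> dict[str, str]:
    """Reconstruct object sequences from AGP rows + component sequences
    (cross-validation path for the builder)."""
    objects: dict[str, list[tuple[int, str]]] = {}
    for row in agp:
        if row.component_type == "N":
            objects.setdefault(row.object_id, []).append(
                (row.object_beg, "N" * row.gap_length))
        else:
            seq = scaffolds[row.component_id].sequence
            if seq is None:
                raise ValueError(f"no sequence for component {row.component_id!r}")
            piece = seq[row.component_beg - 1: row.component_end]
            if row.orientation == "-":
                piece = revcomp(piece)
            objects.setdefault(row.object_id, []).append((row.object_beg, piece))
    return {
        obj: "".join(p for _s, p in sorted(parts))
        for obj, parts in objects.items()
    }


# ---------------------------------------------------------------------------
# assembly statistics (consensus-map summary)


def markers_per_mb(n_markers: int, total_bp: int) -> float:
    """Physical marker density, one decimal."""
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    return round(n_markers / (total_bp / 1e6), 1)


def genome_fraction_pct(part_bp: int, genome_bp: int, decimals: int = 2) -> float:
    """Partition size as a percentage of the genome."""
    if genome_bp < part_bp:
        raise ValueError("partition larger than genome")
    return round(100.0 * part_bp / genome_bp, decimals)


def n50_l50(lengths: list[int]) -> tuple[int, int]:
    """N50 length and L50 count: smallest k and the length of the k-th piece
    (descending) whose cumulative sum reaches half the total."""
    if not lengths:
        return 0, 0
    lengths = sorted(lengths, reverse=True)
    half = sum(lengths) / 2.0
    cum = 0
    for i, ln in enumerate(lengths, start=1):
        cum += ln
        if cum >= half:
            return ln, i
    return lengths[-1], len(lengths)


def assembly_stats(
    bundle: AssemblyBundle,
    plan: AnchorPlan,
    scaffolds: ScaffoldSet,
    maps: list[GeneticMap],
    genome_total_bp: int | None = None,
) -> pd.DataFrame:
    """Anchored / oriented / unanchored partition summary: unique marker
    counts, markers per Mb, N50 and L50, scaffold counts by marker class,
    total bases and percentage of the genome."""
    anchored = [a for a in plan.anchors if a.chrom != 0]
    oriented = [a for a in anchored if a.orientation in "+-"]
    unanchored = [a for a in plan.anchors if a.chrom == 0]

    if genome_total_bp is None:
        genome_total_bp = scaffolds.total_bp()

    def marker_ids(group):
        ids = set()
        members = {a.scaffold for a in group}
        for gmap in maps:
            for pl in gmap.placements:
                if pl.scaffold in members:
                    ids.add(pl.marker_id)
        return ids

    def partition_row(label, group):
        members = {a.scaffold for a in group}
        lengths = [scaffolds[s].length for s in members if s in scaffolds]
        total = sum(lengths)
        if genome_total_bp < total:
            raise ValueError("genome_total_bp smaller than partition bases")
        markers = marker_ids(group)
        n50, l50 = n50_l50(lengths)
        by_count = {1: 0, 2: 0, 3: 0, "4+": 0}
        for a in group:
            c = a.n_markers_total
            if c >= 4:
                by_count["4+"] += 1
            elif c >= 1:
                by_count[c] += 1
        return {
            "partition": label,
            "markers_unique": len(markers),
            "markers_per_mb": markers_per_mb(len(markers), total) if total else float("nan"),
            "n50_bp": n50,
            "l50": l50,
            "n_scaffolds": len(group),
            "scaffolds_1_marker": by_count[1],
            "scaffolds_2_marker": by_count[2],
            "scaffolds_3_marker": by_count[3],
            "scaffolds_4plus_marker": by_count["4+"],
            "total_bases": total,
            "pct_of_genome": genome_fraction_pct(total, genome_total_bp),
            "avg_scaffold_bp": int(round(total / len(group))) if group else 0,
        }

    return pd.DataFrame([
        partition_row("anchored", anchored),
        partition_row("oriented", oriented),
        partition_row("not_anchored", unanchored),
    ])


# ---------------------------------------------------------------------------
# linkage-map statistics


@dataclass
class MapStats:
    per_lg: pd.DataFrame  # lg, n_markers, length_cm, avg_cm, max_gap_cm, gaps
    totals: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return self.per_lg


def map_stats(gmap: GeneticMap, gap_thresholds: tuple[float, float] = (5.0, 10.0)) -> MapStats:
    """Per-LG marker count, cM length (max - min), average spacing
    (length / marker count, one decimal), max adjacent gap and counts of gaps
    above the thresholds."""
    rows = []
    for lg in gmap.linkage_groups():
        cms = sorted(pl.cm for pl in gmap.lg_placements(lg))
        length = cms[-1] - cms[0]
        gaps = np.diff(cms) if len(cms) > 1 else np.array([0.0])
        rows.append({
            "lg": lg,
            "n_markers": len(cms),
            "length_cm": round(length, 1),
            "avg_cm": round(length / len(cms), 1),
            "max_gap_cm": round(float(gaps.max()), 1),
            f"gaps_gt_{gap_thresholds[0]:g}cm": int((gaps > gap_thresholds[0]).sum()),
            f"gaps_gt_{gap_thresholds[1]:g}cm": int((gaps > gap_thresholds[1]).sum()),
        })
    per_lg = pd.DataFrame(rows)
    total_markers = int(per_lg["n_markers"].sum())
    total_length = float(per_lg["length_cm"].sum())
    totals = {
        "n_markers": total_markers,
        "length_cm": round(total_length, 1),
        "avg_cm": round(total_length / total_markers, 1) if total_markers else float("nan"),
        "max_gap_cm": float(per_lg["max_gap_cm"].max()) if len(per_lg) else 0.0,
        f"lgs_with_gap_gt_{gap_thresholds[0]:g}cm": int(
            (per_lg[f"gaps_gt_{gap_thresholds[0]:g}cm"] > 0).sum()),
        f"lgs_with_gap_gt_{gap_thresholds[1]:g}cm": int(
            (per_lg[f"gaps_gt_{gap_thresholds[1]:g}cm"] > 0).sum()),
    }
    return MapStats(per_lg=per_lg, totals=totals)


def average_spacing_cm(n_markers: int, length_cm: float) -> float:
    """Mean inter-marker spacing by the length / marker-count convention,
    rounded to one decimal."""
    if n_markers <= 0:
        raise ValueError("marker count must be positive")
    return round(length_cm / n_markers, 1)
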