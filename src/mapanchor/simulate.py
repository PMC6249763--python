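"""Synthetic data generator for an F1 outcross anchoring study.

Emulates the statistical structure of a genotyping-by-sequencing experiment
on a full-sib (CP) population: a fragmented genome of 17 chromosomes, markers
of the three CP segregation classes (lm×ll, nn×np, hk×hk), overdispersed read
depths with missingness, noisy per-population map estimates, and two
phenotype-pooled bulks segregating at one causal locus.

The crossover model places an independent recombination event in each
marker interval with probability given by the inverse Kosambi function of the
interval's cM length; chiasma interference is not simulated beyond what the
Kosambi distance itself encodes (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    CLASS_ALPHABET,
    MISSING_CALL,
    GeneticMap,
    GenotypeMatrix,
    MapPlacement,
    PoolDepthTable,
    ScaffoldRecord,
    ScaffoldSet,
)

DEFAULT_SEED = 42
DEFAULT_CLASS_MIX = {"lmxll": 0.40, "nnxnp": 0.42, "hkxhk": 0.18}
DEFAULT_DEPTH_MEAN = 30.0
DEFAULT_DEPTH_DISPERSION = 0.3


# ---------------------------------------------------------------------------
# Kosambi mapping function


def kosambi_cm(r: float) -> float:
    """Map distance in cM for recombination fraction r: d = 25 ln((1+2r)/(1-2r))."""
    if not 0 <= r < 0.5:
        raise ValueError(f"recombination fraction {r} outside [0, 0.5)")
    return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))


def kosambi_r(d: float) -> float:
    """Inverse Kosambi: recombination fraction for a distance of d cM.

    r = tanh(2d/100)/2; approaches 0.5 as d grows.
    """
    if d < 0:
        raise ValueError(f"negative map distance {d}")
    return 0.5 * math.tanh(d / 50.0)


def _kosambi_r_vec(d: np.ndarray) -> np.ndarray:
    return 0.5 * np.tanh(np.asarray(d, dtype=float) / 50.0)


# ---------------------------------------------------------------------------
# truth layout


@dataclass
class MarkerTruth:
    marker_id: str
    chrom: int
    genome_pos: int  # 1-based bp on the chromosome
    true_cm: float
    seg_class: str
    phase: tuple[int, int]  # per-parent linkage phase bits
    scaffold: str = ""
    scaffold_pos: int = 0


@dataclass
class TruthLayout:
    """Ground truth for parameter-recovery tests."""

    chromosomes: list[tuple[int, int]]  # (chrom_id, length bp)
    scaffold_truth: list[tuple[str, int, int, str]]  # (scaffold, chrom, start bp, orientation)
    marker_truth: list[MarkerTruth] = field(default_factory=list)
    causal_locus: tuple[int, int, float] | None = None  # (chrom, genome_pos, true_cm)

    def markers_on(self, chrom: int) -> list[MarkerTruth]:
        return sorted(
            (m for m in self.marker_truth if m.chrom == chrom),
            key=lambda m: m.genome_pos,
        )

    def scaffold_of(self, scaffold_id: str) -> tuple[str, int, int, str]:
        for st in self.scaffold_truth:
            if st[0] == scaffold_id:
                return st
        raise KeyError(scaffold_id)

    def true_order(self, chrom: int) -> list[str]:
        """Scaffold ids on a chromosome in genomic order."""
        return [s for s, c, start, _o in sorted(self.scaffold_truth, key=lambda t: t[2])
                if c == chrom]


def simulate_genome(
    n_chrom: int = 17,
    chrom_len: int = 1_000_000,
    n_scaffolds: int = 170,
    seed: int = DEFAULT_SEED,
    markers_per_chrom: int = 60,
    cm_per_mb: float = 4.0,
    min_scaffold_len: int = 1000,
    with_sequence: bool = True,
    causal_chrom: int | None = None,
) -> tuple[TruthLayout, ScaffoldSet]:
    """Fragment ``n_chrom`` chromosomes of ``chrom_len`` bp into scaffolds and
    scatter markers with a linear bp→cM relation of ``cm_per_mb``.

    Scaffolds tile each chromosome exactly; roughly half are assigned a "-"
    true orientation so orientation recovery is non-trivial.
    """
    if n_scaffolds < n_chrom:
        raise ValueError("need at least one scaffold per chromosome")
    rng = np.random.default_rng(seed)

    # distribute scaffolds over chromosomes: one each, remainder multinomial
    counts = np.ones(n_chrom, dtype=int)
    extra = n_scaffolds - n_chrom
    if extra:
        counts += rng.multinomial(extra, np.full(n_chrom, 1.0 / n_chrom))
    if (counts * min_scaffold_len > chrom_len).any():
        raise ValueError("chrom_len too small to host the requested scaffolds")

    chromosomes = [(c + 1, chrom_len) for c in range(n_chrom)]
    scaffold_truth: list[tuple[str, int, int, str]] = []
    records: list[ScaffoldRecord] = []
    marker_truth: list[MarkerTruth] = []

    scaffold_no = 0
    for chrom_id, length in chromosomes:
        k = int(counts[chrom_id - 1])
        # k-1 internal breakpoints leaving >= min_scaffold_len per piece
        if k > 1:
            cuts = np.sort(rng.choice(
                np.arange(1, length // min_scaffold_len), size=k - 1, replace=False
            )) * min_scaffold_len
        else:
            cuts = np.array([], dtype=int)
        bounds = np.concatenate(([0], cuts, [length]))
        for i in range(k):
            scaffold_no += 1
            sid = f"scf{scaffold_no:04d}"
            start = int(bounds[i]) + 1
            slen = int(bounds[i + 1] - bounds[i])
            orient = "+" if rng.random() < 0.5 else "-"
            scaffold_truth.append((sid, chrom_id, start, orient))
            seq = None
            if with_sequence:
                seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=slen)])
            records.append(ScaffoldRecord(sid, slen, seq))

        positions = np.sort(rng.choice(np.arange(1, length + 1),
                                       size=markers_per_chrom, replace=False))
        class_names = list(DEFAULT_CLASS_MIX)
        class_probs = np.array([DEFAULT_CLASS_MIX[c] for c in class_names])
        for j, pos in enumerate(positions):
            seg = class_names[rng.choice(len(class_names), p=class_probs)]
            marker_truth.append(MarkerTruth(
                marker_id=f"m{chrom_id:02d}_{j + 1:04d}",
                chrom=chrom_id,
                genome_pos=int(pos),
                true_cm=float(pos) / 1e6 * cm_per_mb,
                seg_class=seg,
                phase=(int(rng.integers(0, 2)), int(rng.integers(0, 2))),
            ))

    truth = TruthLayout(chromosomes, scaffold_truth, marker_truth, None)
    _attach_marker_scaffolds(truth)

    if causal_chrom is None:
        causal_chrom = min(5, n_chrom)
    causal_pos = chrom_len // 2
    truth.causal_locus = (causal_chrom, causal_pos, causal_pos / 1e6 * cm_per_mb)
    return truth, ScaffoldSet(records)


def _attach_marker_scaffolds(truth: TruthLayout) -> None:
    """Resolve each marker's owning scaffold and 1-based within-scaffold bp,
    respecting the scaffold's true orientation."""
    by_chrom: dict[int, list[tuple[str, int, int, str]]] = {}
    lengths: dict[str, int] = {}
    ordered = sorted(truth.scaffold_truth, key=lambda t: (t[1], t[2]))
    for i, (sid, chrom, start, orient) in enumerate(ordered):
        nxt = [t for t in ordered[i + 1:] if t[1] == chrom]
        end = (nxt[0][2] - 1) if nxt else dict(truth.chromosomes)[chrom]
        lengths[sid] = end - start + 1
        by_chrom.setdefault(chrom, []).append((sid, start, end, orient))
    for m in truth.marker_truth:
        for sid, start, end, orient in by_chrom[m.chrom]:
            if start <= m.genome_pos <= end:
                offset = m.genome_pos - start + 1
                m.scaffold = sid
                m.scaffold_pos = offset if orient == "+" else lengths[sid] - offset + 1
                break


# ---------------------------------------------------------------------------
# F1 cross genotypes


def _draw_depths(rng: np.random.Generator, shape: tuple[int, int],
                 mean: float, dispersion: float) -> np.ndarray:
    """Overdispersed (negative binomial) read depths with the given mean;
    dispersion is the NB alpha, var = mean + alpha * mean^2."""
    if dispersion <= 0:
        return rng.poisson(mean, size=shape)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=shape)


def simulate_cross(
    truth: TruthLayout,
    n_offspring: int = 345,
    class_mix: dict[str, float] | None = None,
    missing_rate: float = 0.05,
    depth_params: tuple[float, float] = (DEFAULT_DEPTH_MEAN, DEFAULT_DEPTH_DISPERSION),
    seed: int = DEFAULT_SEED,
    error_rate: float = 0.0,
) -> GenotypeMatrix:
    """Generate offspring genotype calls for the markers in ``truth``.

    Gametes follow a Markov recombination process along each chromosome with
    inter-marker switch probability kosambi_r(dcm).  Calls obey the CP class
    semantics (lm×ll → lm/ll 1:1; nn×np → nn/np 1:1; hk×hk → hh/hk/kk 1:2:1).
    ``class_mix`` is accepted for API symmetry with genome simulation but the
    realized class of each marker is fixed in ``truth``.
    """
    del class_mix  # classes come from the truth layout
    rng = np.random.default_rng(seed)
    mean_depth, dispersion = depth_params

    marker_ids: list[str] = []
    classes: list[str] = []
    rows: list[np.ndarray] = []
    positions: list[tuple[str, int]] = []

    for chrom_id, _len in truth.chromosomes:
        markers = truth.markers_on(chrom_id)
        if not markers:
            continue
        cms = np.array([m.true_cm for m in markers])
        # maternal and paternal gamete haplotypes
        hap_m = _markov_haplotypes(rng, cms, n_offspring)
        hap_p = _markov_haplotypes(rng, cms, n_offspring)
        for i, m in enumerate(markers):
            gm = hap_m[i] ^ m.phase[0]  # 1 => carries the "variant" allele
            gp = hap_p[i] ^ m.phase[1]
            if m.seg_class == "lmxll":
                call = np.where(gm == 1, "lm", "ll")
            elif m.seg_class == "nnxnp":
                call = np.where(gp == 1, "np", "nn")
            else:  # hkxhk
                dose = gm + gp
                call = np.array(["hh", "hk", "kk"], dtype=object)[dose]
            marker_ids.append(m.marker_id)
            classes.append(m.seg_class)
            positions.append((m.scaffold, m.scaffold_pos))
            rows.append(np.asarray(call, dtype=object))

    calls = np.vstack(rows) if rows else np.empty((0, n_offspring), dtype=object)

    if error_rate > 0 and calls.size:
        err = rng.random(calls.shape) < error_rate
        for i, seg in enumerate(classes):
            alphabet = CLASS_ALPHABET[seg]
            repl = np.array(alphabet, dtype=object)[
                rng.integers(0, len(alphabet), size=calls.shape[1])
            ]
            calls[i] = np.where(err[i], repl, calls[i])

    depths = _draw_depths(rng, calls.shape, mean_depth, dispersion)
    if missing_rate > 0 and calls.size:
        mask = rng.random(calls.shape) < missing_rate
        calls = np.where(mask, MISSING_CALL, calls)

    offspring = [f"off{j + 1:03d}" for j in range(n_offspring)]
    idx = pd.Index(marker_ids, name="marker_id")
    return GenotypeMatrix(
        calls=pd.DataFrame(calls, index=idx, columns=offspring),
        depths=pd.DataFrame(depths, index=idx, columns=offspring),
        classes=pd.Series(classes, index=idx, name="seg_class"),
        positions=pd.DataFrame(positions, index=idx, columns=["scaffold", "pos"]),
    )


def _markov_haplotypes(rng: np.random.Generator, cms: np.ndarray,
                       n_offspring: int) -> np.ndarray:
    """0/1 haplotype indicator per marker x offspring for one parent."""
    n_mark = len(cms)
    hap = np.empty((n_mark, n_offspring), dtype=np.int8)
    hap[0] = rng.integers(0, 2, size=n_offspring)
    if n_mark > 1:
        rec_p = _kosambi_r_vec(np.diff(cms))
        switches = (rng.random((n_mark - 1, n_offspring)) < rec_p[:, None]).astype(np.int8)
        hap[1:] = switches
        hap = np.cumsum(hap, axis=0, dtype=np.int64) % 2
    return hap.astype(np.int8)


# ---------------------------------------------------------------------------
# per-population map estimates


def true_map(truth: TruthLayout, name: str = "truth", weight: float = 1.0,
             seg_classes: tuple[str, ...] | None = None,
             marker_fraction: float = 1.0,
             seed: int = DEFAULT_SEED) -> GeneticMap:
    """The noise-free map implied by the truth layout (LG = chromosome)."""
    rng = np.random.default_rng(seed)
    placements = []
    for m in truth.marker_truth:
        if seg_classes and m.seg_class not in seg_classes:
            continue
        if marker_fraction < 1.0 and rng.random() > marker_fraction:
            continue
        placements.append(MapPlacement(m.marker_id, m.chrom, m.true_cm,
                                       m.scaffold, m.scaffold_pos))
    return GeneticMap(name=name, weight=weight, placements=placements)


def perturb_map(
    gmap: GeneticMap,
    jitter_cm: float = 0.0,
    swap_rate: float = 0.0,
    drop_rate: float = 0.0,
    misassign_rate: float = 0.0,
    seed: int = DEFAULT_SEED,
) -> GeneticMap:
    """Model map-estimation error: Gaussian cM jitter, local adjacent-marker
    swaps, random marker drops, and optional LG misassignment."""
    for rate, label in ((swap_rate, "swap_rate"), (drop_rate, "drop_rate"),
                        (misassign_rate, "misassign_rate")):
        if not 0 <= rate <= 1:
            raise ValueError(f"{label} outside [0,1]")
    rng = np.random.default_rng(seed)
    placements = [MapPlacement(p.marker_id, p.lg, p.cm, p.scaffold, p.pos)
                  for p in gmap.placements]

    if drop_rate > 0:
        placements = [p for p in placements if rng.random() >= drop_rate]
    if jitter_cm > 0:
        for p in placements:
            p.cm = max(0.0, p.cm + float(rng.normal(0.0, jitter_cm)))
    if swap_rate > 0:
        by_lg: dict[int, list[MapPlacement]] = {}
        for p in placements:
            by_lg.setdefault(p.lg, []).append(p)
        for lg_pls in by_lg.values():
            lg_pls.sort(key=lambda p: (p.cm, p.marker_id))
            i = 0
            while i < len(lg_pls) - 1:
                if rng.random() < swap_rate:
                    a, b = lg_pls[i], lg_pls[i + 1]
                    a.cm, b.cm = b.cm, a.cm
                    i += 2  # non-overlapping swaps
                else:
                    i += 1
    if misassign_rate > 0:
        from .io_formats import N_LINKAGE_GROUPS
        for p in placements:
            if rng.random() < misassign_rate:
                p.lg = int(rng.integers(1, N_LINKAGE_GROUPS + 1))
    return GeneticMap(name=gmap.name, weight=gmap.weight, placements=placements)


# ---------------------------------------------------------------------------
# bulked-segregant pools


def simulate_bulks(
    truth: TruthLayout,
    n_snps_per_chrom: int = 1000,
    mean_depth: float = 20.0,
    seed: int = DEFAULT_SEED,
) -> PoolDepthTable:
    """Two-bulk allele depths segregating at the causal locus (dominant model).

    For a SNP at recombination fraction r from the causal locus the expected
    alt-allele frequency is (1-r)/2 in the carrier pool and r/2 in the
    non-carrier pool, so E[d(SNP-index)] = (1-2r)/2; unlinked chromosomes use
    r = 0.5 (both pools 0.25, expected delta 0).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if truth.causal_locus is None:
        raise ValueError("truth layout has no causal locus")
    rng = np.random.default_rng(seed)
    causal_chrom, _causal_pos, causal_cm = truth.causal_locus

    # bp->cM rate inferred from marker truth (linear by construction)
    rates = [m.true_cm / m.genome_pos * 1e6 for m in truth.marker_truth
             if m.genome_pos > 0]
    cm_per_mb = float(np.median(rates)) if rates else 4.0

    recs = []
    for chrom_id, length in truth.chromosomes:
        pos = np.sort(rng.choice(np.arange(1, length + 1),
                                 size=min(n_snps_per_chrom, length), replace=False))
        if chrom_id == causal_chrom:
            d_cm = np.abs(pos / 1e6 * cm_per_mb - causal_cm)
            r = _kosambi_r_vec(d_cm)
        else:
            r = np.full(len(pos), 0.5)
        freq1 = (1.0 - r) / 2.0  # carrier pool
        freq2 = r / 2.0
        dp1 = rng.poisson(mean_depth, size=len(pos))
        dp2 = rng.poisson(mean_depth, size=len(pos))
        alt1 = rng.binomial(dp1, freq1)
        alt2 = rng.binomial(dp2, freq2)
        recs.append(pd.DataFrame({
            "chrom": f"chr{chrom_id}",
            "pos": pos,
            "ref1": dp1 - alt1, "alt1": alt1,
            "ref2": dp2 - alt2, "alt2": alt2,
        }))
    return PoolDepthTable(pd.concat(recs, ignore_index=True))
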