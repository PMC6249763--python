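"""Published summary statistics of the pear 'Dangshansuli' (DS) v1.1
chromosome-level assembly and its underlying genetic maps.

These tables are inputs for worked examples and cross-checks: given only the
printed per-chromosome scaffold counts and scaffold-length sums, the builder
must reproduce the printed pseudo-chromosome lengths, and the partition
accounting must reproduce the printed percentages.
"""

from __future__ import annotations

# Per pseudo-chromosome: (number of scaffolds, summed scaffold length in bp,
# published pseudo-chromosome length in bp).
DS_V11_CHROMOSOMES: dict[str, tuple[int, int, int]] = {
    "Chr1": (38, 17_741_026, 17_744_726),
    "Chr2": (46, 21_235_622, 21_240_122),
    "Chr3": (54, 26_905_313, 26_910_613),
    "Chr4": (57, 22_557_600, 22_563_200),
    "Chr5": (60, 26_919_162, 26_925_062),
    "Chr6": (42, 20_808_669, 20_812_769),
    "Chr7": (51, 23_073_416, 23_078_416),
    "Chr8": (39, 17_213_204, 17_217_004),
    "Chr9": (48, 22_543_132, 22_547_832),
    "Chr10": (64, 26_037_640, 26_043_940),
    "Chr11": (75, 31_663_329, 31_670_729),
    "Chr12": (47, 20_526_746, 20_531_346),
    "Chr13": (42, 19_240_341, 19_244_441),
    "Chr14": (60, 21_933_695, 21_939_595),
    "Chr15": (71, 39_101_076, 39_108_076),
    "Chr16": (47, 20_394_842, 20_399_442),
    "Chr17": (57, 22_680_450, 22_686_050),
}

# Consensus-map partitions: unique markers, scaffold count, total bases.
DS_V11_PARTITIONS = {
    "anchored": {"markers": 7757, "scaffolds": 898, "bases": 400_575_263},
    "oriented": {"markers": 7455, "scaffolds": 793, "bases": 378_731_939},
    "not_anchored": {"markers": 106, "scaffolds": 1284, "bases": 107_975_332},
}

# MH (Mantianhong x Hongxiangsu) map totals.
MH_MAP = {"markers": 2606, "length_cm": 1846.6, "total_bases": 351_322_567}

# Red/green skin locus scan: the two top-0.5% subintervals (bp lengths) and
# the five scaffold pieces (1-based inclusive scaffold coordinates).
QTL_SUBINTERVALS_BP = (900_000, 1_200_000)
QTL_SCAFFOLD_PIECES = {
    "NW_008988126.1": (188_765, 968_163),
    "NW_008988141.1": (1, 120_502),
    "NW_008988091.1": (1_156_306, 1_193_985),
    "NW_008988243.1": (1, 620_203),
    "NW_008988130.1": (1, 542_018),
}


def split_lengths(total_bp: int, n: int) -> list[int]:
    """Deterministically split a summed scaffold length into n positive
    pieces (used to rebuild length-only scaffold inventories from published
    per-chromosome counts and sums)."""
    if n < 1 or total_bp < n:
        raise ValueError("cannot split")
    base, rem = divmod(total_bp, n)
    return [base + 1] * rem + [base] * (n - rem)


def length_only_inventory():
    """AnchorPlan + length-only ScaffoldSet reproducing the published
    per-chromosome scaffold counts and scaffold-length sums."""
    from .consensus_anchor import AnchorPlan, ScaffoldAnchor
    from .io_formats import ScaffoldRecord, ScaffoldSet

    anchors = []
    records = []
    for idx, (chrom_name, (n, scaf_bp, _pub_len)) in enumerate(
            DS_V11_CHROMOSOMES.items(), start=1):
        for j, length in enumerate(split_lengths(scaf_bp, n)):
            sid = f"{chrom_name}_scf{j + 1:03d}"
            records.append(ScaffoldRecord(sid, length))
            anchors.append(ScaffoldAnchor(sid, chrom=idx, order_index=j,
                                          orientation="?"))
    return AnchorPlan(anchors), ScaffoldSet(records)
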