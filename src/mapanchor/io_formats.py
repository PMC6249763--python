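"""Readers and writers for the on-disk formats the pipeline touches.

All on-disk coordinates are 1-based inclusive.  TSV dialect: tab-separated,
"." for missing fields, UTF-8.  Every reader/writer pair round-trips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

N_LINKAGE_GROUPS = 17

IUPAC_DNA = set("ACGTRYSWKMBDHVNacgtryswkmbdhvn")

# genotype call alphabets per segregation class of a full-sib (CP) cross
SEG_CLASSES = ("lmxll", "nnxnp", "hkxhk")
CLASS_ALPHABET = {
    "lmxll": ("lm", "ll"),
    "nnxnp": ("nn", "np"),
    "hkxhk": ("hh", "hk", "kk"),
}
MISSING_CALL = "--"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# scaffolds / FASTA


@dataclass
class ScaffoldRecord:
    id: str
    length: int
    sequence: str | None = None


@dataclass
class ScaffoldSet:
    """A set of assembly scaffolds; sequences are optional (length-only mode)."""

    records: list[ScaffoldRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise FormatError(f"duplicate scaffold id {rec.id!r}")
            seen.add(rec.id)
            if rec.length <= 0:
                raise FormatError(f"scaffold {rec.id!r} has non-positive length")
            if rec.sequence is not None and len(rec.sequence) != rec.length:
                raise FormatError(
                    f"scaffold {rec.id!r}: length {rec.length} != sequence "
                    f"length {len(rec.sequence)}"
                )
        self._index = {rec.id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self._index

    def __getitem__(self, scaffold_id: str) -> ScaffoldRecord:
        return self._index[scaffold_id]

    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def total_bp(self) -> int:
        return sum(rec.length for rec in self.records)


def read_fasta(path: str | Path) -> ScaffoldSet:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"empty FASTA record {rec.id!r}")
        bad = set(seq) - IUPAC_DNA
        if bad:
            warnings.warn(
                f"record {rec.id!r} contains non-IUPAC characters {sorted(bad)}; retained"
            )
        records.append(ScaffoldRecord(rec.id, len(seq), seq))
    return ScaffoldSet(records)


def write_fasta(scaffolds: ScaffoldSet | Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    if isinstance(scaffolds, ScaffoldSet):
        items = [(rec.id, rec.sequence) for rec in scaffolds.records]
    else:
        items = list(scaffolds)
    seq_records = []
    for name, seq in items:
        if seq is None:
            raise FormatError(f"scaffold {name!r} has no sequence to write")
        seq_records.append(SeqRecord(Seq(seq), id=name, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# genetic maps


@dataclass
class MapPlacement:
    marker_id: str
    lg: int
    cm: float
    scaffold: str
    pos: int  # 1-based bp on the scaffold


@dataclass
class GeneticMap:
    """One population's linkage map with an integration weight.

    Placements are kept sorted by (lg, cm, marker_id).
    """

    name: str
    weight: float
    placements: list[MapPlacement] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise FormatError(f"map {self.name!r}: weight must be positive")
        seen: set[str] = set()
        for pl in self.placements:
            if pl.marker_id in seen:
                raise FormatError(
                    f"map {self.name!r}: duplicate marker id {pl.marker_id!r}"
                )
            seen.add(pl.marker_id)
            if not (1 <= pl.lg <= N_LINKAGE_GROUPS):
                raise FormatError(
                    f"map {self.name!r}: marker {pl.marker_id!r} linkage group "
                    f"{pl.lg} outside 1..{N_LINKAGE_GROUPS}"
                )
            if not (pl.cm >= 0 and pl.cm == pl.cm and pl.cm != float("inf")):
                raise FormatError(
                    f"map {self.name!r}: marker {pl.marker_id!r} has invalid cM {pl.cm}"
                )
            if pl.pos < 1:
                raise FormatError(
                    f"map {self.name!r}: marker {pl.marker_id!r} scaffold pos "
                    f"{pl.pos} < 1"
                )
        self.placements.sort(key=lambda p: (p.lg, p.cm, p.marker_id))

    def __len__(self) -> int:
        return len(self.placements)

    def linkage_groups(self) -> list[int]:
        return sorted({pl.lg for pl in self.placements})

    def lg_placements(self, lg: int) -> list[MapPlacement]:
        return [pl for pl in self.placements if pl.lg == lg]

    def scaffold_placements(self, scaffold: str) -> list[MapPlacement]:
        return [pl for pl in self.placements if pl.scaffold == scaffold]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.marker_id, p.lg, p.cm, p.scaffold, p.pos) for p in self.placements],
            columns=["marker_id", "lg", "cm", "scaffold", "pos"],
        )


MAP_COLUMNS = ["marker_id", "lg", "cm", "scaffold", "pos"]


def read_genetic_map(path: str | Path, name: str, weight: float) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "scaffold": str})
    missing = set(MAP_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing map columns {sorted(missing)}")
    placements = [
        MapPlacement(str(r.marker_id), int(r.lg), float(r.cm), str(r.scaffold), int(r.pos))
        for r in df.itertuples(index=False)
    ]
    return GeneticMap(name=name, weight=weight, placements=placements)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotype matrices


@dataclass
class GenotypeMatrix:
    """Offspring genotype calls with per-call read depths.

    calls/depths: DataFrames indexed by marker_id with one column per
    offspring; classes: Series marker_id -> segregation class; positions:
    optional frame (scaffold, pos) per marker for redundancy reduction.
    """

    calls: pd.DataFrame
    depths: pd.DataFrame
    classes: pd.Series
    positions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.calls.index.equals(self.depths.index):
            raise FormatError("calls and depths marker indices differ")
        if not self.calls.columns.equals(self.depths.columns):
            raise FormatError("calls and depths offspring columns differ")
        if not self.calls.index.equals(self.classes.index):
            raise FormatError("classes index does not match calls")
        bad_class = set(self.classes) - set(SEG_CLASSES)
        if bad_class:
            raise FormatError(f"unknown segregation classes {sorted(bad_class)}")
        if (self.depths.to_numpy() < 0).any():
            raise FormatError("negative depths")

    @property
    def n_offspring(self) -> int:
        return self.calls.shape[1]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls.copy(),
            self.depths.copy(),
            self.classes.copy(),
            None if self.positions is None else self.positions.copy(),
        )


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Genotype TSV: marker_id, seg_class, [scaffold, pos,] then per-offspring
    paired columns <name> (call) and <name>_dp (depth)."""
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("marker_id")
    classes = df.pop("seg_class")
    positions = None
    if "scaffold" in df.columns and "pos" in df.columns:
        positions = pd.DataFrame(
            {"scaffold": df.pop("scaffold"), "pos": df.pop("pos").astype(int)}
        )
    dp_cols = [c for c in df.columns if c.endswith("_dp")]
    call_cols = [c for c in df.columns if not c.endswith("_dp")]
    expected_dp = [c + "_dp" for c in call_cols]
    if dp_cols != expected_dp:
        raise FormatError("depth columns do not pair 1:1 with call columns")
    calls = df[call_cols]
    depths = df[dp_cols].astype(int)
    depths.columns = call_cols
    return GenotypeMatrix(calls, depths, classes, positions)


def write_genotypes(matrix: GenotypeMatrix, path: str | Path) -> None:
    columns = {"seg_class": matrix.classes}
    if matrix.positions is not None:
        columns["scaffold"] = matrix.positions["scaffold"]
        columns["pos"] = matrix.positions["pos"]
    for col in matrix.calls.columns:
        columns[col] = matrix.calls[col]
        columns[col + "_dp"] = matrix.depths[col]
    out = pd.concat(columns, axis=1)
    out.index.name = "marker_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# AGP v2.1


@dataclass
class AgpRow:
    object_id: str
    object_beg: int
    object_end: int
    part_number: int
    component_type: str  # "W" scaffold, "N" gap
    component_id: str | None = None  # W rows
    component_beg: int | None = None
    component_end: int | None = None
    orientation: str | None = None  # +, -, ?
    gap_length: int | None = None  # N rows

    def span(self) -> int:
        return self.object_end - self.object_beg + 1


def validate_agp(rows: Sequence[AgpRow]) -> None:
    """Per object: parts tile 1..L with no holes/overlaps; spans consistent."""
    by_object: dict[str, list[AgpRow]] = {}
    for row in rows:
        by_object.setdefault(row.object_id, []).append(row)
    for obj, obj_rows in by_object.items():
        obj_rows = sorted(obj_rows, key=lambda r: r.part_number)
        expect = 1
        for row in obj_rows:
            if row.object_beg != expect:
                raise FormatError(
                    f"AGP object {obj}: part {row.part_number} begins at "
                    f"{row.object_beg}, expected {expect} (hole or overlap)"
                )
            if row.object_end < row.object_beg:
                raise FormatError(f"AGP object {obj}: inverted span at part {row.part_number}")
            if row.component_type == "W":
                comp_span = row.component_end - row.component_beg + 1
                if comp_span != row.span():
                    raise FormatError(
                        f"AGP object {obj}: component span != object span at "
                        f"part {row.part_number}"
                    )
            elif row.component_type == "N":
                if row.gap_length != row.span():
                    raise FormatError(
                        f"AGP object {obj}: gap length != object span at "
                        f"part {row.part_number}"
                    )
            else:
                raise FormatError(f"AGP object {obj}: component type {row.component_type!r}")
            expect = row.object_end + 1


def write_agp(rows: Sequence[AgpRow], path: str | Path) -> None:
    validate_agp(rows)
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for row in rows:
            if row.component_type == "W":
                fields = [
                    row.object_id, row.object_beg, row.object_end, row.part_number,
                    "W", row.component_id, row.component_beg, row.component_end,
                    row.orientation or "?",
                ]
            else:
                fields = [
                    row.object_id, row.object_beg, row.object_end, row.part_number,
                    "N", row.gap_length, "scaffold", "yes", "map",
                ]
            fh.write("\t".join(str(f) for f in fields) + "\n")


def read_agp(path: str | Path) -> list[AgpRow]:
    rows: list[AgpRow] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"AGP line with {len(parts)} fields: {line!r}")
            obj, beg, end, part, ctype = parts[0], int(parts[1]), int(parts[2]), int(parts[3]), parts[4]
            if ctype == "N" or ctype == "U":
                rows.append(AgpRow(obj, beg, end, part, "N", gap_length=int(parts[5])))
            else:
                rows.append(
                    AgpRow(
                        obj, beg, end, part, "W",
                        component_id=parts[5],
                        component_beg=int(parts[6]),
                        component_end=int(parts[7]),
                        orientation=parts[8],
                    )
                )
    validate_agp(rows)
    return rows


# ---------------------------------------------------------------------------
# pool depth tables (two-bulk allele depths)

POOL_COLUMNS = ["chrom", "pos", "ref1", "alt1", "ref2", "alt2"]


@dataclass
class PoolDepthTable:
    """Per-SNP ref/alt depths for two phenotype-contrasted bulks."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(POOL_COLUMNS) - set(self.frame.columns)
        if missing:
            raise FormatError(f"pool depth table missing columns {sorted(missing)}")
        depths = self.frame[["ref1", "alt1", "ref2", "alt2"]].to_numpy()
        if (depths < 0).any():
            raise FormatError("negative pool depths")
        self.frame = (
            self.frame[POOL_COLUMNS]
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.frame)


def read_pool_depths(path: str | Path) -> PoolDepthTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return PoolDepthTable(df)


def write_pool_depths(table: PoolDepthTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# tabular alignment hits (12-column outfmt-6 style) and gene positions


HIT_COLUMNS = [
    "query", "subject", "identity", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS,
                     dtype={"query": str, "subject": str})
    if (df["bitscore"] < 0).any():
        raise FormatError("negative bit scores")
    return df


def write_hits(df: pd.DataFrame, path: str | Path) -> None:
    df[HIT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_gene_positions(path: str | Path) -> pd.DataFrame:
    """BED-like TSV: gene, chrom, start, end (1-based inclusive). Returns
    a frame with a midpoint column."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    for col in ("gene", "chrom", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"gene position table missing column {col!r}")
    df["midpoint"] = (df["start"] + df["end"]) / 2.0
    return df
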