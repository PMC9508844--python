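"""Readers, writers and in-memory containers for the on-disk formats the
pipeline touches.

One coordinate convention is used everywhere: 0-based, half-open
(BED-native). Any 1-based display is formatting only. All tab-separated
readers skip ``#`` comment lines.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GenomeSequence",
    "LabeledIntervalTrack",
    "ValuedIntervalTrack",
    "Gene",
    "GeneModelSet",
    "CountMatrix",
    "read_fasta",
    "write_fasta",
    "read_interval_track",
    "write_interval_track",
    "read_gene_models",
    "write_gene_models",
    "read_count_table",
    "write_count_table",
    "read_guide_table",
    "write_guide_table",
]

_VALID_BASES = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# genome sequence


@dataclass
class GenomeSequence:
    """Named chromosome sequences over the alphabet {A, C, G, T, N}."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FormatError("genome contains no sequences")
        for name, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"chromosome {name!r} has an empty sequence")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains invalid characters {sorted(bad)}"
                )

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA file; sequences are upper-cased on the way in."""
    sequences: dict[str, list[str]] = {}
    current: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                if name in sequences:
                    raise FormatError(
                        f"{path}: duplicate chromosome {name!r} at line {lineno}"
                    )
                sequences[name] = []
                current = name
            else:
                if current is None:
                    raise FormatError(
                        f"{path}: sequence before any header at line {lineno}"
                    )
                sequences[current].append(line.strip().upper())
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    joined = {name: "".join(parts) for name, parts in sequences.items()}
    for name, seq in joined.items():
        if not seq:
            raise FormatError(f"{path}: record {name!r} has no sequence")
    return GenomeSequence(joined)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# interval tracks


@dataclass(frozen=True)
class _ChromIntervals:
    starts: np.ndarray
    ends: np.ndarray
    payload: np.ndarray  # labels (object) or values (float)


def _index_intervals(
    records: Sequence[tuple], what: str
) -> dict[str, _ChromIntervals]:
    by_chrom: dict[str, list[tuple]] = {}
    for rec in records:
        chrom, start, end, payload = rec
        start, end = int(start), int(end)
        if start < 0 or start >= end:
            raise FormatError(
                f"{what} interval {chrom}:{start}-{end} violates start < end"
            )
        by_chrom.setdefault(chrom, []).append((start, end, payload))
    index: dict[str, _ChromIntervals] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda t: (t[0], t[1]))
        starts = np.array([t[0] for t in ivs], dtype=np.int64)
        ends = np.array([t[1] for t in ivs], dtype=np.int64)
        if np.any(starts[1:] < ends[:-1]):
            i = int(np.nonzero(starts[1:] < ends[:-1])[0][0])
            raise FormatError(
                f"{what} intervals overlap on {chrom} near position {int(starts[i + 1])}"
            )
        payload = np.array([t[2] for t in ivs], dtype=object)
        index[chrom] = _ChromIntervals(starts, ends, payload)
    return index


class _IntervalTrackBase:
    """Sorted, non-overlapping genomic intervals per chromosome.

    ``chromosomes`` declares the namespace the track was computed on; when
    given, queries outside it raise ``KeyError`` while chromosomes inside
    the namespace with no intervals simply return nothing.
    """

    def __init__(
        self,
        records: Sequence[tuple],
        chromosomes: Iterable[str] | None = None,
        name: str = "track",
    ) -> None:
        self.name = name
        self._index = _index_intervals(records, name)
        self.chromosomes = (
            frozenset(chromosomes) if chromosomes is not None else None
        )
        if self.chromosomes is not None:
            extra = set(self._index) - self.chromosomes
            if extra:
                raise FormatError(
                    f"{name}: intervals on undeclared chromosomes {sorted(extra)}"
                )

    def _check_chrom(self, chrom: str) -> None:
        if self.chromosomes is not None and chrom not in self.chromosomes:
            raise KeyError(
                f"chromosome {chrom!r} absent from {self.name} track namespace"
            )

    def overlaps(
        self, chrom: str, start: int, end: int
    ) -> list[tuple[int, int, object]]:
        """All intervals intersecting [start, end), uncut."""
        self._check_chrom(chrom)
        idx = self._index.get(chrom)
        if idx is None:
            return []
        lo = int(np.searchsorted(idx.ends, start, side="right"))
        hi = int(np.searchsorted(idx.starts, end, side="left"))
        return [
            (int(idx.starts[i]), int(idx.ends[i]), idx.payload[i])
            for i in range(lo, hi)
        ]

    def to_records(self) -> list[tuple]:
        out = []
        for chrom, idx in self._index.items():
            for s, e, p in zip(idx.starts, idx.ends, idx.payload):
                out.append((chrom, int(s), int(e), p))
        return out

    def __len__(self) -> int:
        return sum(len(idx.starts) for idx in self._index.values())


class LabeledIntervalTrack(_IntervalTrackBase):
    """Interval segmentation with string labels (chromatin states, LAD/iLAD)."""

    def __init__(
        self,
        records: Sequence[tuple],
        vocabulary: Iterable[str] | None = None,
        chromosomes: Iterable[str] | None = None,
        name: str = "labeled",
    ) -> None:
        super().__init__(records, chromosomes=chromosomes, name=name)
        self.vocabulary = frozenset(vocabulary) if vocabulary is not None else None
        if self.vocabulary is not None:
            for chrom, idx in self._index.items():
                bad = set(idx.payload) - self.vocabulary
                if bad:
                    raise FormatError(
                        f"{name}: labels {sorted(bad)} on {chrom} outside the "
                        f"declared vocabulary"
                    )

    def label_at(self, chrom: str, pos: int) -> str | None:
        """Label of the interval containing ``pos``, or None."""
        hits = self.overlaps(chrom, pos, pos + 1)
        return hits[0][2] if hits else None


class ValuedIntervalTrack(_IntervalTrackBase):
    """Non-negative real-valued signal intervals (bedGraph semantics)."""

    def __init__(
        self,
        records: Sequence[tuple],
        chromosomes: Iterable[str] | None = None,
        name: str = "valued",
    ) -> None:
        coerced = []
        for chrom, start, end, value in records:
            v = float(value)
            if not math.isfinite(v) or v < 0:
                raise FormatError(
                    f"{name}: value {value!r} at {chrom}:{start}-{end} is not a "
                    f"non-negative real"
                )
            coerced.append((chrom, start, end, v))
        super().__init__(coerced, chromosomes=chromosomes, name=name)


def read_interval_track(
    path: str | Path,
    mode: str = "labeled",
    vocabulary: Iterable[str] | None = None,
    chromosomes: Iterable[str] | None = None,
    name: str | None = None,
) -> LabeledIntervalTrack | ValuedIntervalTrack:
    """Read a BED4 (labeled) or bedGraph (valued) file.

    Column 4 is the label in labeled mode and a non-negative real in
    valued mode.
    """
    if mode not in ("labeled", "valued"):
        raise ValueError(f"mode must be 'labeled' or 'valued', got {mode!r}")
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "payload"],
            dtype={"chrom": str, "payload": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: not a 4-column tab-separated file: {exc}") from exc
    if not (
        pd.api.types.is_integer_dtype(df["start"])
        and pd.api.types.is_integer_dtype(df["end"])
    ):
        raise FormatError(f"{path}: start/end columns are not integers")
    track_name = name if name is not None else str(path)
    records = list(
        zip(df["chrom"], df["start"].astype(int), df["end"].astype(int), df["payload"])
    )
    if mode == "labeled":
        return LabeledIntervalTrack(
            records, vocabulary=vocabulary, chromosomes=chromosomes, name=track_name
        )
    valued = []
    for chrom, start, end, raw in records:
        try:
            value = float(raw)
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"{path}: non-numeric value {raw!r} at {chrom}:{start}-{end}"
            ) from exc
        valued.append((chrom, start, end, value))
    return ValuedIntervalTrack(valued, chromosomes=chromosomes, name=track_name)


def write_interval_track(
    track: _IntervalTrackBase, path: str | Path
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, payload in sorted(
            track.to_records(), key=lambda r: (r[0], r[1])
        ):
            if isinstance(payload, float):
                payload = format(payload, "g")
            fh.write(f"{chrom}\t{start}\t{end}\t{payload}\n")


# ---------------------------------------------------------------------------
# gene models


@dataclass(frozen=True)
class Gene:
    """One gene model with exon structure and a normalized expression value."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    expression: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.id}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise FormatError(f"gene {self.id}: invalid span {self.start}-{self.end}")
        if not self.exons:
            raise FormatError(f"gene {self.id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise FormatError(f"gene {self.id}: exon {s}-{e} violates start < end")
            if s < self.start or e > self.end:
                raise FormatError(
                    f"gene {self.id}: exon {s}-{e} outside gene span "
                    f"{self.start}-{self.end}"
                )
            if prev_end is not None and s < prev_end:
                raise FormatError(f"gene {self.id}: exons overlap or are unsorted")
            prev_end = e
        if not math.isfinite(self.expression) or self.expression < 0:
            raise FormatError(
                f"gene {self.id}: negative or non-finite expression "
                f"{self.expression!r}"
            )

    def introns(self) -> list[tuple[int, int]]:
        gaps = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if e1 < s2:
                gaps.append((e1, s2))
        return gaps


class GeneModelSet:
    """A collection of gene models indexed per chromosome."""

    def __init__(self, genes: Sequence[Gene]) -> None:
        ids = [g.id for g in genes]
        if len(ids) != len(set(ids)):
            raise FormatError("duplicate gene ids in gene model set")
        self.genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.id))
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def genes_at(self, chrom: str, pos: int) -> list[Gene]:
        """Genes whose span contains ``pos`` (may be several)."""
        return [
            g for g in self._by_chrom.get(chrom, []) if g.start <= pos < g.end
        ]


def read_gene_models(
    path: str | Path, expression_path: str | Path | None = None
) -> GeneModelSet:
    """Read BED12-style gene models, joining a gene → expression TSV.

    Genes missing from the expression table get expression 0.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: cannot parse BED12: {exc}") from exc
    if df.shape[1] < 12:
        raise FormatError(f"{path}: BED12 requires 12 columns, found {df.shape[1]}")
    expression: dict[str, float] = {}
    if expression_path is not None:
        expr = pd.read_csv(
            expression_path, sep="\t", comment="#", header=None,
            names=["gene", "value"], dtype={"gene": str},
        )
        for gene_id, value in zip(expr["gene"], expr["value"]):
            v = float(value)
            if v < 0:
                raise FormatError(
                    f"{expression_path}: negative expression {v} for gene {gene_id!r}"
                )
            expression[gene_id] = v
    genes = []
    for row in df.itertuples(index=False):
        chrom, start, end = row[0], int(row[1]), int(row[2])
        gene_id, strand = str(row[3]), str(row[5])
        n_blocks = int(row[9])
        sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row[11]).rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise FormatError(
                f"{path}: gene {gene_id}: blockCount {n_blocks} does not match "
                f"blockSizes/blockStarts"
            )
        exons = tuple(
            (start + off, start + off + size) for off, size in zip(offsets, sizes)
        )
        genes.append(
            Gene(
                id=gene_id, chrom=chrom, strand=strand, start=start, end=end,
                exons=exons, expression=expression.get(gene_id, 0.0),
            )
        )
    return GeneModelSet(genes)


def write_gene_models(
    genes: GeneModelSet, path: str | Path, expression_path: str | Path | None = None
) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.start) for s, _ in g.exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{offsets}\n"
            )
    if expression_path is not None:
        with open(expression_path, "w") as fh:
            for g in genes:
                fh.write(f"{g.id}\t{format(g.expression, 'g')}\n")


# ---------------------------------------------------------------------------
# count matrices


@dataclass
class CountMatrix:
    """Guides × samples integer read counts with sample metadata.

    ``counts`` rows are guide ids, columns sample ids. ``sample_info``,
    when present, is indexed by sample id with at least ``timepoint``
    (days) and ``replicate`` columns. ``is_control`` flags non-targeting
    control guides.
    """

    counts: pd.DataFrame
    is_control: pd.Series
    sample_info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate guide id {dup!r} in count matrix")
        if self.counts.columns.duplicated().any():
            raise FormatError("duplicate sample ids in count matrix")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise FormatError("counts must be non-negative")
        self.is_control = self.is_control.reindex(self.counts.index)
        if self.is_control.isna().any():
            raise FormatError("control flags do not cover all guide ids")
        self.is_control = self.is_control.astype(bool)
        if self.sample_info is not None:
            missing = set(self.counts.columns) - set(self.sample_info.index)
            if missing:
                raise FormatError(f"sample metadata missing for {sorted(missing)}")

    @property
    def guide_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def control_ids(self) -> list[str]:
        return list(self.counts.index[self.is_control])


def read_count_table(path: str | Path, control_prefix: str = "CTRL") -> CountMatrix:
    """Read a guides × samples TSV; ids starting with ``control_prefix``
    are flagged as non-targeting controls."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        values = df[col]
        if not pd.api.types.is_numeric_dtype(values):
            raise FormatError(f"{path}: non-numeric counts in sample {col!r}")
        if not np.allclose(values, np.round(values)):
            raise FormatError(f"{path}: non-integer counts in sample {col!r}")
        if (values < 0).any():
            raise FormatError(f"{path}: negative counts in sample {col!r}")
    counts = df.round().astype(np.int64)
    is_control = pd.Series(
        [gid.startswith(control_prefix) for gid in counts.index],
        index=counts.index,
    )
    return CountMatrix(counts=counts, is_control=is_control)


def write_count_table(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="guide")


# ---------------------------------------------------------------------------
# guide manifests

GUIDE_TABLE_COLUMNS = [
    "id", "protospacer", "pam", "expression_sequence",
    "chrom", "start", "strand", "cut_pos", "is_control",
]


def write_guide_table(rows: Iterable[Mapping], path: str | Path) -> None:
    df = pd.DataFrame(list(rows))
    missing = [c for c in GUIDE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"guide table missing columns {missing}")
    df[GUIDE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_guide_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"id": str, "protospacer": str, "chrom": str, "strand": str},
    )
    missing = [c for c in GUIDE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: guide table missing columns {missing}")
    if df["id"].duplicated().any():
        raise FormatError(f"{path}: duplicate guide ids")
    return df
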