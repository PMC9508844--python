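"""Windowed chromatin-context annotation of guide cut sites.

For every guide a fixed window (default 4 kb) centered on the cut site is
intersected with the chromatin-state segmentation, the LAD/iLAD
segmentation, DNaseI and H3K9me3 signal tracks, and gene models. All
fractions are over the *nominal* window length, so windows clipped at a
chromosome end keep comparable denominators (the missing bp count as
unannotated) and carry a ``clipped`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .guide_design import GuideCandidate
from .io_tracks import (
    GeneModelSet,
    GenomeSequence,
    LabeledIntervalTrack,
    ValuedIntervalTrack,
)

__all__ = [
    "Window",
    "AnnotationRecord",
    "AnnotationError",
    "guide_window",
    "state_fractions",
    "lamina_fractions",
    "window_signal",
    "gene_context",
    "annotate_guides",
    "records_to_frame",
]

LAMINA_LABELS = frozenset({"LAD", "iLAD"})
UNANNOTATED = "unannotated"


class AnnotationError(ValueError):
    """Raised when a guide cannot be annotated against the given tracks."""


@dataclass(frozen=True)
class Window:
    """A genomic window anchored on a cut site.

    ``nominal_size`` is the requested window length; when the window is
    clipped at a chromosome boundary ``end - start`` may be smaller.
    """

    chrom: str
    start: int
    end: int
    cut_pos: int
    nominal_size: int
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("window start must be < end")


@dataclass
class AnnotationRecord:
    """Per-guide chromatin features over the annotation window."""

    guide_id: str
    chrom: str
    window_start: int
    window_end: int
    cut_pos: int
    clipped: bool
    state_fraction: dict[str, float]
    breaksite_state: str
    lad_fraction: float
    ilad_fraction: float
    dnase_max: float
    h3k9me3_wmean: float
    genic: bool
    intronic: bool
    exonic: bool
    expressed: bool


def guide_window(
    guide: GuideCandidate, chrom_length: int, window_size: int = 4000
) -> Window:
    """The window [cut - size/2, cut + size/2), clipped at chromosome bounds."""
    if window_size < 2 or window_size % 2:
        raise ValueError("window_size must be even and >= 2")
    cut = guide.cut_pos
    if not 0 <= cut <= chrom_length:
        raise AnnotationError(
            f"guide {guide.id}: cut position {cut} outside chromosome of "
            f"length {chrom_length}"
        )
    half = window_size // 2
    start, end = cut - half, cut + half
    clipped = start < 0 or end > chrom_length
    return Window(
        chrom=guide.chrom,
        start=max(start, 0),
        end=min(end, chrom_length),
        cut_pos=cut,
        nominal_size=window_size,
        clipped=clipped,
    )


def _overlap_bp(window: Window, start: int, end: int) -> int:
    return max(0, min(end, window.end) - max(start, window.start))


def state_fractions(
    window: Window, states: LabeledIntervalTrack
) -> tuple[dict[str, float], str]:
    """Per-label fraction of the window plus the label at the breaksite.

    Fractions use the nominal window length; uncovered bp (including any
    clipped-off bp) accrue to "unannotated".
    """
    fractions: dict[str, float] = {}
    covered = 0
    for s, e, label in states.overlaps(window.chrom, window.start, window.end):
        bp = _overlap_bp(window, s, e)
        fractions[label] = fractions.get(label, 0.0) + bp / window.nominal_size
        covered += bp
    fractions[UNANNOTATED] = (window.nominal_size - covered) / window.nominal_size
    breaksite = states.label_at(window.chrom, window.cut_pos)
    return fractions, breaksite if breaksite is not None else UNANNOTATED


def lamina_fractions(
    window: Window, lads: LabeledIntervalTrack
) -> tuple[float, float]:
    """(LAD, iLAD) fractions of the window; labels must be LAD/iLAD."""
    lad = ilad = 0.0
    for s, e, label in lads.overlaps(window.chrom, window.start, window.end):
        if label not in LAMINA_LABELS:
            raise AnnotationError(f"unknown lamina label {label!r}")
        bp = _overlap_bp(window, s, e)
        if label == "LAD":
            lad += bp / window.nominal_size
        else:
            ilad += bp / window.nominal_size
    return lad, ilad


def window_signal(
    window: Window, track: ValuedIntervalTrack
) -> tuple[float, float]:
    """(max value, coverage-weighted mean) of a signal track over the window.

    The maximum is over interval values overlapping the window (0 when
    none overlap); the weighted mean spreads each value over its
    overlapping bp with uncovered bp contributing 0 signal.
    """
    max_value = 0.0
    weighted = 0.0
    for s, e, value in track.overlaps(window.chrom, window.start, window.end):
        bp = _overlap_bp(window, s, e)
        if bp <= 0:
            continue
        max_value = max(max_value, float(value))
        weighted += float(value) * bp
    return max_value, weighted / window.nominal_size


def gene_context(
    chrom: str,
    cut_pos: int,
    genes: GeneModelSet,
    expression_threshold: float = 1.0,
) -> tuple[bool, bool, bool, bool]:
    """(genic, intronic, exonic, expressed) flags for a cut position.

    A cut is genic when inside any gene span, exonic when inside an exon
    of an overlapping gene, intronic when genic but not exonic, and
    expressed when any overlapping gene exceeds the expression threshold.
    """
    overlapping = genes.genes_at(chrom, cut_pos)
    genic = bool(overlapping)
    exonic = any(
        s <= cut_pos < e for g in overlapping for s, e in g.exons
    )
    intronic = genic and not exonic
    expressed = any(g.expression > expression_threshold for g in overlapping)
    return genic, intronic, exonic, expressed


def annotate_guides(
    guides: list[GuideCandidate],
    genome: GenomeSequence,
    states: LabeledIntervalTrack,
    lads: LabeledIntervalTrack,
    dnase: ValuedIntervalTrack,
    h3k9me3: ValuedIntervalTrack,
    genes: GeneModelSet,
    window_size: int = 4000,
    expression_threshold: float = 1.0,
) -> list[AnnotationRecord]:
    """One AnnotationRecord per guide; deterministic in guide order."""
    records = []
    tracks = [("states", states), ("lads", lads), ("dnase", dnase),
              ("h3k9me3", h3k9me3)]
    for guide in guides:
        if guide.chrom not in genome:
            raise AnnotationError(
                f"guide {guide.id}: chromosome {guide.chrom!r} absent from genome"
            )
        for track_name, track in tracks:
            if (
                track.chromosomes is not None
                and guide.chrom not in track.chromosomes
            ):
                raise AnnotationError(
                    f"guide {guide.id}: chromosome {guide.chrom!r} absent from "
                    f"the {track_name} track namespace"
                )
        window = guide_window(guide, len(genome[guide.chrom]), window_size)
        frac, breaksite = state_fractions(window, states)
        lad, ilad = lamina_fractions(window, lads)
        dnase_max, _ = window_signal(window, dnase)
        _, k9_wmean = window_signal(window, h3k9me3)
        genic, intronic, exonic, expressed = gene_context(
            guide.chrom, guide.cut_pos, genes, expression_threshold
        )
        records.append(
            AnnotationRecord(
                guide_id=guide.id, chrom=guide.chrom,
                window_start=window.start, window_end=window.end,
                cut_pos=guide.cut_pos, clipped=window.clipped,
                state_fraction=frac, breaksite_state=breaksite,
                lad_fraction=lad, ilad_fraction=ilad,
                dnase_max=dnase_max, h3k9me3_wmean=k9_wmean,
                genic=genic, intronic=intronic, exonic=exonic,
                expressed=expressed,
            )
        )
    return records


def records_to_frame(records: list[AnnotationRecord]) -> pd.DataFrame:
    """Flatten annotation records to a table (state fractions as
    state<label>_frac columns, unannotated as unannotated_frac)."""
    labels = sorted(
        {lab for r in records for lab in r.state_fraction if lab != UNANNOTATED}
    )
    rows = []
    for r in records:
        row = {
            "guide_id": r.guide_id, "chrom": r.chrom,
            "window_start": r.window_start, "window_end": r.window_end,
            "cut_pos": r.cut_pos, "clipped": r.clipped,
            "breaksite_state": r.breaksite_state,
            "lad_fraction": r.lad_fraction, "ilad_fraction": r.ilad_fraction,
            "dnase_max": r.dnase_max, "h3k9me3_wmean": r.h3k9me3_wmean,
            "genic": r.genic, "intronic": r.intronic, "exonic": r.exonic,
            "expressed": r.expressed,
        }
        for lab in labels:
            row[f"state{lab}_frac"] = r.state_fraction.get(lab, 0.0)
        row["unannotated_frac"] = r.state_fraction.get(UNANNOTATED, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
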