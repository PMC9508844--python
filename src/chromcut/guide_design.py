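"""Single-cutter sgRNA library design for SpCas9.

Candidate 20-nt protospacers (random, or exhaustively enumerated next to
NGG PAMs) are matched against the genome on both strands by exact Hamming
distance. A guide is retained only when it has exactly one perfect
NGG-adjacent target and no secondary site within the mismatch tolerance
(default 3), so that Cas9 induces a double-strand break at a single,
known location.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_tracks import GenomeSequence

__all__ = [
    "GuideCandidate",
    "OffTargetHit",
    "LibraryManifest",
    "ControlGuide",
    "scan_pam_sites",
    "random_candidates",
    "find_matches",
    "design_single_cutters",
    "assemble_library",
    "reverse_complement",
    "cut_position",
]

PROTOSPACER_LEN = 20
# blunt SpCas9 cut between protospacer bases 17 and 18, 3 bp 5' of the PAM
_CUT_OFFSET_PLUS = 17
_CUT_OFFSET_MINUS = 3

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte-level base codes; N gets a code that never equals a real base
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
_G_CODE = 2


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def cut_position(start: int, strand: str) -> int:
    """Reference coordinate of the blunt cut for a protospacer at ``start``.

    On '+' the PAM sits at [start+20, start+23) and the cut falls between
    bases 17 and 18 of the protospacer; on '-' the PAM occupies
    [start-3, start) on the reference and the cut is mirrored.
    """
    if strand == "+":
        return start + _CUT_OFFSET_PLUS
    if strand == "-":
        return start + _CUT_OFFSET_MINUS
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


@dataclass(frozen=True)
class GuideCandidate:
    """A placed 20-nt protospacer with its PAM and cut site."""

    id: str
    protospacer: str
    pam: str
    chrom: str
    strand: str
    protospacer_start: int
    cut_pos: int

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError(
                f"protospacer must be {PROTOSPACER_LEN} nt, got "
                f"{len(self.protospacer)}"
            )
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise ValueError(f"PAM {self.pam!r} does not match NGG")
        if self.cut_pos != cut_position(self.protospacer_start, self.strand):
            raise ValueError("cut_pos inconsistent with placement")

    @property
    def expression_sequence(self) -> str:
        """Protospacer with one extra 5' G for U6-driven expression (21 nt)."""
        return "G" + self.protospacer


@dataclass(frozen=True)
class OffTargetHit:
    """A genomic placement of a protospacer with its mismatch count."""

    chrom: str
    start: int
    strand: str
    mismatches: int
    pam_ok: bool


@dataclass(frozen=True)
class ControlGuide:
    """A non-targeting control entry: sequence only, no genomic placement."""

    id: str
    protospacer: str

    @property
    def expression_sequence(self) -> str:
        return "G" + self.protospacer


@dataclass
class LibraryManifest:
    """Targeting single-cutter guides plus non-targeting controls."""

    guides: list[GuideCandidate]
    controls: list[ControlGuide]

    def __len__(self) -> int:
        return len(self.guides) + len(self.controls)

    def to_rows(self) -> list[dict]:
        rows = []
        for g in self.guides:
            rows.append(
                {
                    "id": g.id, "protospacer": g.protospacer, "pam": g.pam,
                    "expression_sequence": g.expression_sequence,
                    "chrom": g.chrom, "start": g.protospacer_start,
                    "strand": g.strand, "cut_pos": g.cut_pos,
                    "is_control": False,
                }
            )
        for c in self.controls:
            rows.append(
                {
                    "id": c.id, "protospacer": c.protospacer, "pam": "",
                    "expression_sequence": c.expression_sequence,
                    "chrom": "", "start": -1, "strand": "", "cut_pos": -1,
                    "is_control": True,
                }
            )
        return rows


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def random_candidates(n: int, seed: int) -> list[str]:
    """Draw ``n`` i.i.d. uniform 20-nt sequences over {A, C, G, T}."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, 4, size=(n, PROTOSPACER_LEN))
    bases = np.array(list("ACGT"))
    return ["".join(row) for row in bases[draws]]


def scan_pam_sites(genome: GenomeSequence) -> list[GuideCandidate]:
    """Enumerate every 20-mer adjacent to an NGG PAM on either strand.

    20-mers containing N are skipped. Output is sorted by
    (chrom, start, strand); ids encode the placement.
    """
    out: list[GuideCandidate] = []
    for chrom in genome.chromosomes:
        seq = genome[chrom]
        L = len(seq)
        if L < PROTOSPACER_LEN + 3:
            continue
        arr = _encode(seq)
        placements: list[tuple[int, str]] = []
        # plus strand: protospacer [s, s+20), PAM [s+20, s+23) with GG at +21,+22
        gg = (arr[:-1] == _G_CODE) & (arr[1:] == _G_CODE)
        for p in np.nonzero(gg)[0]:
            s = int(p) - PROTOSPACER_LEN - 1
            if s >= 0 and s + PROTOSPACER_LEN + 3 <= L:
                placements.append((s, "+"))
        # minus strand: CCN on the reference at [s-3, s), protospacer [s, s+20)
        cc = (arr[:-1] == 1) & (arr[1:] == 1)  # C has code 1
        for p in np.nonzero(cc)[0]:
            s = int(p) + 3
            if s + PROTOSPACER_LEN <= L:
                placements.append((s, "-"))
        placements.sort(key=lambda t: (t[0], t[1]))
        for s, strand in placements:
            if strand == "+":
                proto = seq[s : s + PROTOSPACER_LEN]
                pam = seq[s + PROTOSPACER_LEN : s + PROTOSPACER_LEN + 3]
            else:
                proto = reverse_complement(seq[s : s + PROTOSPACER_LEN])
                pam = reverse_complement(seq[s - 3 : s])
            if "N" in proto or "N" in pam[1:]:
                continue
            out.append(
                GuideCandidate(
                    id=f"{chrom}:{s}:{strand}",
                    protospacer=proto, pam=pam, chrom=chrom, strand=strand,
                    protospacer_start=s, cut_pos=cut_position(s, strand),
                )
            )
    return out


def _strand_hits(
    arr: np.ndarray, proto: np.ndarray, max_mismatches: int
) -> tuple[np.ndarray, np.ndarray]:
    """Start positions and mismatch counts of all windows within tolerance."""
    if len(arr) < PROTOSPACER_LEN:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(arr, PROTOSPACER_LEN)
    mm = (windows != proto).sum(axis=1)
    keep = np.nonzero(mm <= max_mismatches)[0]
    return keep.astype(np.int64), mm[keep].astype(np.int64)


def find_matches(
    genome: GenomeSequence,
    protospacer: str,
    max_mismatches: int = 3,
    require_pam: bool = True,
) -> list[OffTargetHit]:
    """All genomic placements of ``protospacer`` within the Hamming tolerance.

    Both strands are scanned exhaustively (no indels, no seed heuristic).
    With ``require_pam`` only placements followed 3' (strand-aware) by an
    NGG PAM are reported; otherwise all placements are reported with
    their ``pam_ok`` flag. Hits are sorted by (chrom, start, strand).
    """
    protospacer = protospacer.upper()
    if len(protospacer) != PROTOSPACER_LEN:
        raise ValueError(f"protospacer must be {PROTOSPACER_LEN} nt")
    if set(protospacer) - set("ACGT"):
        raise ValueError(f"protospacer contains invalid bases: {protospacer!r}")
    if not 1 <= max_mismatches <= 5:
        raise ValueError("max_mismatches must be between 1 and 5")
    proto_fwd = _encode(protospacer)
    proto_rev = _encode(reverse_complement(protospacer))
    hits: list[OffTargetHit] = []
    for chrom in genome.chromosomes:
        seq = genome[chrom]
        arr = _encode(seq)
        L = len(seq)
        # plus strand: the protospacer read directly off the reference
        starts, mms = _strand_hits(arr, proto_fwd, max_mismatches)
        for s, mm in zip(starts, mms):
            s = int(s)
            pam_ok = (
                s + PROTOSPACER_LEN + 3 <= L
                and arr[s + PROTOSPACER_LEN + 1] == _G_CODE
                and arr[s + PROTOSPACER_LEN + 2] == _G_CODE
            )
            hits.append(OffTargetHit(chrom, s, "+", int(mm), bool(pam_ok)))
        # minus strand: reference carries the reverse complement, PAM is a
        # CCN immediately 5' of the match on the reference
        starts, mms = _strand_hits(arr, proto_rev, max_mismatches)
        for s, mm in zip(starts, mms):
            s = int(s)
            pam_ok = s - 3 >= 0 and arr[s - 3] == 1 and arr[s - 2] == 1
            hits.append(OffTargetHit(chrom, s, "-", int(mm), bool(pam_ok)))
    if require_pam:
        hits = [h for h in hits if h.pam_ok]
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def design_single_cutters(
    genome: GenomeSequence,
    candidates: Iterable[str | GuideCandidate],
    max_mismatches: int = 3,
    require_pam: bool = True,
) -> list[GuideCandidate]:
    """Retain candidates with exactly one perfect NGG-adjacent target and
    no secondary site within ``max_mismatches`` mismatches.

    Candidates may be raw 20-nt sequences or pre-placed candidates; each
    retained guide is (re)placed at its unique perfect site. Duplicated
    candidate sequences are considered once.
    """
    seen: set[str] = set()
    retained: list[GuideCandidate] = []
    for cand in candidates:
        seq = cand.protospacer if isinstance(cand, GuideCandidate) else str(cand)
        seq = seq.upper()
        if seq in seen:
            continue
        seen.add(seq)
        if "N" in seq:
            continue
        hits = find_matches(genome, seq, max_mismatches, require_pam)
        perfect = [h for h in hits if h.mismatches == 0 and h.pam_ok]
        if len(perfect) != 1 or len(hits) != 1:
            continue
        hit = perfect[0]
        L = len(genome[hit.chrom])
        if hit.strand == "+":
            if hit.start + PROTOSPACER_LEN + 3 > L:
                continue
            pam = genome[hit.chrom][
                hit.start + PROTOSPACER_LEN : hit.start + PROTOSPACER_LEN + 3
            ]
        else:
            if hit.start - 3 < 0:
                continue
            pam = reverse_complement(genome[hit.chrom][hit.start - 3 : hit.start])
        retained.append(
            GuideCandidate(
                id=f"{hit.chrom}:{hit.start}:{hit.strand}",
                protospacer=seq, pam=pam, chrom=hit.chrom, strand=hit.strand,
                protospacer_start=hit.start,
                cut_pos=cut_position(hit.start, hit.strand),
            )
        )
    return retained


def assemble_library(
    genome: GenomeSequence,
    guides: Sequence[GuideCandidate],
    n_controls: int = 100,
    control_seed: int = 0,
    max_mismatches: int = 3,
    control_prefix: str = "CTRL",
    max_attempts_per_control: int = 1000,
) -> LibraryManifest:
    """Add rejection-sampled non-targeting controls to a guide set.

    Control sequences are random 20-mers verified (PAM-agnostic, so the
    stronger condition) to have no genomic placement within
    ``max_mismatches`` mismatches on either strand.
    """
    rng = np.random.default_rng(control_seed)
    bases = np.array(list("ACGT"))
    controls: list[ControlGuide] = []
    attempts = 0
    budget = n_controls * max_attempts_per_control
    taken = {g.protospacer for g in guides}
    while len(controls) < n_controls:
        if attempts >= budget:
            raise RuntimeError(
                f"could not find {n_controls} non-targeting controls in "
                f"{budget} attempts"
            )
        attempts += 1
        seq = "".join(bases[rng.integers(0, 4, size=PROTOSPACER_LEN)])
        if seq in taken:
            continue
        if find_matches(genome, seq, max_mismatches, require_pam=False):
            continue
        taken.add(seq)
        controls.append(
            ControlGuide(id=f"{control_prefix}_{len(controls) + 1:03d}", protospacer=seq)
        )
    renamed = [
        GuideCandidate(
            id=f"SCC_{i + 1:05d}", protospacer=g.protospacer, pam=g.pam,
            chrom=g.chrom, strand=g.strand,
            protospacer_start=g.protospacer_start, cut_pos=g.cut_pos,
        )
        for i, g in enumerate(guides)
    ]
    return LibraryManifest(guides=renamed, controls=controls)
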