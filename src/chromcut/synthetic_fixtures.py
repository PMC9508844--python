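"""Synthetic genomes, chromatin tracks, gene models, planted
pool-qualifying guide sites and simulated dropout screens.

The generator emulates the shape of the real inputs — a multi-chromosome
genome, a 10-state chromatin segmentation tiling every chromosome,
binary LAD/iLAD lamina tiling, peaked DNaseI signal preferring state-2
(promoter) segments, H3K9me3 plateaus in state-9 (heterochromatin)
segments, intron/exon gene models with expression values — at a scale
where every pipeline stage runs in seconds. ``plant_pool_sites`` writes
unique protospacer+PAM sequences into regions engineered to satisfy
exactly one built-in pool's rule set, giving the design → annotate →
filter chain a known ground truth to recover.

The screen simulator couples toxicity and editing efficiency
multiplicatively: a guide's population is a mixture of edited cells
depleting exponentially (half-life set by the per-day depletion rate)
and unedited cells that stay neutral, sequenced with negative-binomial
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .guide_design import (
    PROTOSPACER_LEN,
    GuideCandidate,
    cut_position,
    find_matches,
)
from .io_tracks import (
    CountMatrix,
    Gene,
    GeneModelSet,
    GenomeSequence,
    LabeledIntervalTrack,
    ValuedIntervalTrack,
)

__all__ = [
    "FixtureSpec",
    "FixtureTracks",
    "ScreenSimSpec",
    "make_genome",
    "make_tracks",
    "plant_pool_sites",
    "simulate_screen",
    "truth_to_guides",
]

STATE_LABELS = tuple(str(i) for i in range(1, 11))

_BASES = np.array(list("ACGT"))


@dataclass
class FixtureSpec:
    """Parameters of the synthetic genome and its tracks."""

    n_chromosomes: int = 6
    chrom_length: int = 120_000
    state_mean_segment: int = 4_000    # bp; exponential dwell length
    lad_mean_segment: int = 25_000     # bp
    min_segment: int = 200             # bp floor so tracks stay well-formed
    dnase_height_range: tuple[float, float] = (0.3, 3.0)
    dnase_peak_width: int = 300
    dnase_peak_prob: float = 0.8       # per state-2 segment
    h3k9_height_range: tuple[float, float] = (6.0, 10.0)
    genes_per_chromosome: int = 4
    gene_length: int = 6_000
    exons_per_gene: int = 3
    exon_length: int = 300
    expressed_gene_value: float = 10.0
    planted_per_pool: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 10_000:
            raise ValueError("need >= 1 chromosome of >= 10 kb")
        if self.planted_per_pool < 0:
            raise ValueError("planted_per_pool must be >= 0")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class FixtureTracks:
    """All annotation inputs for one synthetic genome."""

    states: LabeledIntervalTrack
    lads: LabeledIntervalTrack
    dnase: ValuedIntervalTrack
    h3k9me3: ValuedIntervalTrack
    genes: GeneModelSet


def make_genome(spec: FixtureSpec) -> GenomeSequence:
    """I.i.d. uniform A/C/G/T sequence per chromosome, reproducible."""
    rng = np.random.default_rng(spec.seed)
    sequences = {}
    for name in spec.chrom_names:
        draws = rng.integers(0, 4, size=spec.chrom_length)
        sequences[name] = "".join(_BASES[draws])
    return GenomeSequence(sequences)


def _tile_segments(
    rng: np.random.Generator, length: int, mean_len: int, min_len: int,
    labels: tuple[str, ...],
) -> list[tuple[int, int, str]]:
    """Tile [0, length) with exponential-length labeled segments."""
    out = []
    pos = 0
    prev = None
    while pos < length:
        seg = int(max(min_len, rng.exponential(mean_len)))
        end = min(pos + seg, length)
        label = labels[rng.integers(0, len(labels))]
        # avoid trivially merged neighbours so segment count is meaningful
        if label == prev and len(labels) > 1:
            label = labels[(labels.index(label) + 1) % len(labels)]
        out.append((pos, end, label))
        prev = label
        pos = end
    return out


def make_tracks(genome: GenomeSequence, spec: FixtureSpec) -> FixtureTracks:
    """State, lamina, signal and gene tracks over a synthetic genome.

    States tile every chromosome completely (no unannotated gaps), the
    lamina track alternates LAD/iLAD, DNaseI peaks sit preferentially in
    state-2 segments and H3K9me3 plateaus cover state-9 segments.
    """
    rng = np.random.default_rng(spec.seed + 1)
    chroms = genome.chromosomes
    state_records: list[tuple] = []
    lad_records: list[tuple] = []
    dnase_records: list[tuple] = []
    k9_records: list[tuple] = []
    for chrom in chroms:
        length = len(genome[chrom])
        segments = _tile_segments(
            rng, length, spec.state_mean_segment, spec.min_segment, STATE_LABELS
        )
        state_records.extend((chrom, s, e, lab) for s, e, lab in segments)
        lamina = _tile_segments(
            rng, length, spec.lad_mean_segment, spec.min_segment, ("LAD", "iLAD")
        )
        lad_records.extend((chrom, s, e, lab) for s, e, lab in lamina)
        for s, e, lab in segments:
            if lab == "2" and rng.random() < spec.dnase_peak_prob:
                width = min(spec.dnase_peak_width, e - s)
                lo = int(rng.integers(s, e - width + 1))
                height = rng.uniform(*spec.dnase_height_range)
                dnase_records.append((chrom, lo, lo + width, height))
            elif lab == "9":
                height = rng.uniform(*spec.h3k9_height_range)
                k9_records.append((chrom, s, e, height))
    genes = _make_genes(genome, spec, rng)
    return FixtureTracks(
        states=LabeledIntervalTrack(
            state_records, vocabulary=STATE_LABELS, chromosomes=chroms,
            name="states",
        ),
        lads=LabeledIntervalTrack(
            lad_records, vocabulary=("LAD", "iLAD"), chromosomes=chroms,
            name="lads",
        ),
        dnase=ValuedIntervalTrack(dnase_records, chromosomes=chroms, name="dnase"),
        h3k9me3=ValuedIntervalTrack(k9_records, chromosomes=chroms, name="h3k9me3"),
        genes=genes,
    )


def _make_genes(
    genome: GenomeSequence, spec: FixtureSpec, rng: np.random.Generator
) -> GeneModelSet:
    genes = []
    gid = 0
    for chrom in genome.chromosomes:
        length = len(genome[chrom])
        occupied: list[tuple[int, int]] = []
        attempts = 0
        while (
            len([g for g in genes if g.chrom == chrom]) < spec.genes_per_chromosome
            and attempts < 50 * spec.genes_per_chromosome
        ):
            attempts += 1
            start = int(rng.integers(0, max(1, length - spec.gene_length)))
            end = start + spec.gene_length
            if any(s < end and start < e for s, e in occupied):
                continue
            occupied.append((start, end))
            gid += 1
            n_ex = spec.exons_per_gene
            # exons evenly spread across the span, introns in between
            span = end - start
            exons = []
            for k in range(n_ex):
                ex_start = start + int(k * (span - spec.exon_length) / max(1, n_ex - 1))
                exons.append((ex_start, ex_start + spec.exon_length))
            expression = spec.expressed_gene_value if rng.random() < 0.5 else 0.0
            genes.append(
                Gene(
                    id=f"gene_{gid:03d}", chrom=chrom,
                    strand="+" if rng.random() < 0.5 else "-",
                    start=start, end=end, exons=tuple(exons),
                    expression=expression,
                )
            )
    return GeneModelSet(genes)


# ---------------------------------------------------------------------------
# planting

# how each built-in pool's window is engineered
_PLANT_RULES = {
    "pool2": {"state": "2", "lamina": "iLAD", "dnase": 1.0, "h3k9": None,
              "gene": "intronic_expressed"},
    "pool4": {"state": "4", "lamina": "iLAD", "dnase": None, "h3k9": None,
              "gene": "none"},
    "pool7": {"state": "7", "lamina": "iLAD", "dnase": 0.03, "h3k9": None,
              "gene": "intronic_expressed"},
    "pool8a": {"state": "8", "lamina": "iLAD", "dnase": None, "h3k9": None,
               "gene": "none"},
    "pool8b": {"state": "8", "lamina": "LAD", "dnase": None, "h3k9": None,
               "gene": "none"},
    "pool9": {"state": "9", "lamina": "LAD", "dnase": None, "h3k9": 8.0,
              "gene": "none"},
}
_WINDOW = 4000  # planted sites are engineered for the default 4 kb window


def _clear_region(records: list[tuple], chrom: str, a: int, b: int) -> list[tuple]:
    """Remove/clip intervals overlapping [a, b) on one chromosome."""
    out = []
    for rec in records:
        c, s, e, payload = rec
        if c != chrom or e <= a or s >= b:
            out.append(rec)
            continue
        if s < a:
            out.append((c, s, a, payload))
        if e > b:
            out.append((c, b, e, payload))
    return out


def _override_region(
    records: list[tuple], chrom: str, a: int, b: int, payload
) -> list[tuple]:
    out = _clear_region(records, chrom, a, b)
    out.append((chrom, a, b, payload))
    return out


def plant_pool_sites(
    genome: GenomeSequence,
    tracks: FixtureTracks,
    spec: FixtureSpec,
) -> tuple[GenomeSequence, FixtureTracks, pd.DataFrame]:
    """Write pool-qualifying single-cutter sites into genome and tracks.

    For each built-in pool, ``spec.planted_per_pool`` windows are carved
    out (states, lamina, signal and gene context rewritten to satisfy
    exactly that pool's clauses) and a unique random protospacer + TGG
    PAM is written at the window center on the plus strand. Sites are
    spread round-robin over chromosomes. Each planted protospacer is
    verified to be a single-cutter at <= 3 mismatches and re-randomized
    if not. Returns the edited genome/tracks plus a ground-truth table.
    """
    rng = np.random.default_rng(spec.seed + 2)
    chroms = genome.chromosomes
    pools = list(_PLANT_RULES)
    if spec.planted_per_pool == 0:
        return genome, tracks, pd.DataFrame(
            columns=["guide_id", "pool", "chrom", "strand",
                     "protospacer_start", "cut_pos", "protospacer"]
        )
    needed_spread = -(-10 // 2)  # ceil(k / cap) for the default selection
    if spec.n_chromosomes < min(needed_spread, spec.planted_per_pool):
        raise ValueError(
            f"cannot spread planted sites over {spec.n_chromosomes} chromosomes"
        )
    half = _WINDOW // 2
    seqs = {c: list(genome[c]) for c in chroms}
    state_recs = tracks.states.to_records()
    lad_recs = tracks.lads.to_records()
    dnase_recs = tracks.dnase.to_records()
    k9_recs = tracks.h3k9me3.to_records()
    genes = list(tracks.genes)
    cursors = {c: 3000 for c in chroms}
    rows = []
    site_counter = 0
    for pool in pools:
        rules = _PLANT_RULES[pool]
        for i in range(spec.planted_per_pool):
            chrom = chroms[i % len(chroms)]
            length = len(genome[chrom])
            cursor = cursors[chrom]
            cut = cursor + half
            window = (cursor, cursor + _WINDOW)
            cursors[chrom] = cursor + _WINDOW + 1000 + int(rng.integers(0, 500))
            if window[1] + 3000 > length:
                raise ValueError(
                    f"chromosome {chrom} too short for the requested number "
                    f"of planted sites"
                )
            state_recs = _override_region(state_recs, chrom, *window, rules["state"])
            lad_recs = _override_region(lad_recs, chrom, *window, rules["lamina"])
            dnase_recs = _clear_region(dnase_recs, chrom, *window)
            if rules["dnase"] is not None:
                dnase_recs.append((chrom, cut - 150, cut + 150, rules["dnase"]))
            k9_recs = _clear_region(k9_recs, chrom, *window)
            if rules["h3k9"] is not None:
                k9_recs.append((chrom, window[0], window[1], rules["h3k9"]))
            # clear background genes near the window; planted genes never
            # overhang into a neighbouring window (spacing >= 1000 bp > the
            # 500 bp gene overhang) so they are kept
            margin = (window[0] - 3000, window[1] + 3000)
            genes = [
                g for g in genes
                if g.id.startswith("planted_gene_")
                or g.chrom != chrom or g.end <= margin[0] or g.start >= margin[1]
            ]
            if rules["gene"] == "intronic_expressed":
                g_start, g_end = cut - 2500, cut + 2500
                genes.append(
                    Gene(
                        id=f"planted_gene_{site_counter:03d}", chrom=chrom,
                        strand="+", start=g_start, end=g_end,
                        exons=((g_start, g_start + 200), (g_end - 200, g_end)),
                        expression=spec.expressed_gene_value,
                    )
                )
            proto_start = cut - 17  # plus-strand cut falls between bases 17/18
            proto = "".join(_BASES[rng.integers(0, 4, size=PROTOSPACER_LEN)])
            seqs[chrom][proto_start : proto_start + PROTOSPACER_LEN] = list(proto)
            seqs[chrom][
                proto_start + PROTOSPACER_LEN : proto_start + PROTOSPACER_LEN + 3
            ] = list("TGG")
            rows.append(
                {
                    "guide_id": f"{chrom}:{proto_start}:+", "pool": pool,
                    "chrom": chrom, "strand": "+",
                    "protospacer_start": proto_start, "cut_pos": cut,
                    "protospacer": proto,
                }
            )
            site_counter += 1
    truth = pd.DataFrame(rows)
    edited_genome = GenomeSequence({c: "".join(seqs[c]) for c in chroms})
    # verify planted guides are single-cutters; re-randomize rare collisions
    for _ in range(5):
        dirty = False
        for idx, row in truth.iterrows():
            hits = find_matches(
                edited_genome, row["protospacer"], max_mismatches=3,
                require_pam=True,
            )
            perfect = [h for h in hits if h.mismatches == 0]
            on_target = [
                h for h in perfect
                if h.chrom == row["chrom"] and h.start == row["protospacer_start"]
                and h.strand == "+"
            ]
            if len(hits) == 1 and len(on_target) == 1:
                continue
            dirty = True
            proto = "".join(_BASES[rng.integers(0, 4, size=PROTOSPACER_LEN)])
            s = int(row["protospacer_start"])
            seqs[row["chrom"]][s : s + PROTOSPACER_LEN] = list(proto)
            truth.loc[idx, "protospacer"] = proto
            edited_genome = GenomeSequence({c: "".join(seqs[c]) for c in chroms})
        if not dirty:
            break
    else:
        raise RuntimeError("could not make all planted sites single-cutters")
    edited_tracks = FixtureTracks(
        states=LabeledIntervalTrack(
            state_recs, vocabulary=STATE_LABELS, chromosomes=chroms, name="states"
        ),
        lads=LabeledIntervalTrack(
            lad_recs, vocabulary=("LAD", "iLAD"), chromosomes=chroms, name="lads"
        ),
        dnase=ValuedIntervalTrack(dnase_recs, chromosomes=chroms, name="dnase"),
        h3k9me3=ValuedIntervalTrack(k9_recs, chromosomes=chroms, name="h3k9me3"),
        genes=GeneModelSet(genes),
    )
    return edited_genome, edited_tracks, truth


def truth_to_guides(truth: pd.DataFrame) -> list[GuideCandidate]:
    """Placed GuideCandidates for every planted ground-truth site."""
    guides = []
    for row in truth.itertuples(index=False):
        guides.append(
            GuideCandidate(
                id=row.guide_id, protospacer=row.protospacer, pam="TGG",
                chrom=row.chrom, strand=row.strand,
                protospacer_start=int(row.protospacer_start),
                cut_pos=cut_position(int(row.protospacer_start), row.strand),
            )
        )
    return guides


# ---------------------------------------------------------------------------
# screen simulation


@dataclass
class ScreenSimSpec:
    """Parameters of a simulated pooled dropout screen.

    ``depletion`` is a per-guide exponential depletion rate in units of
    halvings per day for fully edited cells; ``efficiency`` is the
    fraction of cells that actually acquire the cut. Controls must have
    depletion 0. Timepoints follow the day-4 reference / day-8 and
    day-16 readout design.
    """

    guide_ids: list[str]
    is_control: np.ndarray       # bool per guide
    depletion: np.ndarray        # per day, >= 0
    efficiency: np.ndarray       # in [0, 1]
    timepoints: tuple[int, ...] = (4, 8, 16)
    replicates: int = 3
    depth: int = 1_000_000
    overdispersion: float = 0.01
    initial_concentration: float = 1.0
    replicate_jitter_sd: float = 0.1  # log2 sd of per-replicate bottleneck
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.guide_ids)
        self.is_control = np.asarray(self.is_control, dtype=bool)
        self.depletion = np.asarray(self.depletion, dtype=float)
        self.efficiency = np.asarray(self.efficiency, dtype=float)
        if not (len(self.is_control) == len(self.depletion)
                == len(self.efficiency) == n):
            raise ValueError("per-guide arrays must match guide_ids length")
        if len(set(self.guide_ids)) != n:
            raise ValueError("duplicate guide ids")
        if (self.depletion < 0).any():
            raise ValueError("depletion rates must be >= 0")
        if ((self.efficiency < 0) | (self.efficiency > 1)).any():
            raise ValueError("efficiency must be in [0, 1]")
        if self.depletion[self.is_control].any():
            raise ValueError("control guides must have depletion 0")
        if self.depth < 10_000:
            raise ValueError("depth must be >= 10^4")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")


def expected_relative_abundance(
    sim: ScreenSimSpec, initial: np.ndarray, day: float
) -> np.ndarray:
    """Closed-form expected relative abundance at ``day``.

    Each guide's population is a mixture of unedited (neutral) cells
    with weight 1 − efficiency and edited cells depleting as
    2^(−depletion·day).
    """
    weight = initial * (
        (1.0 - sim.efficiency)
        + sim.efficiency * np.exp2(-sim.depletion * day)
    )
    return weight / weight.sum()


def simulate_screen(sim: ScreenSimSpec) -> CountMatrix:
    """Draw a guides × samples count matrix for the simulated screen.

    One library composition is drawn from a Dirichlet with the stated
    concentration; replicates are independent infections of that same
    library, so each gets a small lognormal bottleneck jitter on top.
    Per timepoint counts are negative binomial around depth × relative
    abundance with the stated overdispersion (Poisson when 0).
    """
    rng = np.random.default_rng(sim.seed)
    n = len(sim.guide_ids)
    library = rng.dirichlet(np.full(n, sim.initial_concentration))
    columns = {}
    meta_rows = []
    for rep in range(1, sim.replicates + 1):
        jitter = np.exp2(rng.normal(0.0, sim.replicate_jitter_sd, size=n))
        initial = library * jitter
        initial = initial / initial.sum()
        for day in sim.timepoints:
            rel = expected_relative_abundance(sim, initial, day)
            mu = sim.depth * rel
            if sim.overdispersion > 0:
                size = 1.0 / sim.overdispersion
                p = size / (size + mu)
                counts = rng.negative_binomial(size, p)
            else:
                counts = rng.poisson(mu)
            sample = f"d{day}_r{rep}"
            columns[sample] = counts.astype(np.int64)
            meta_rows.append({"sample": sample, "timepoint": day, "replicate": rep})
    counts_df = pd.DataFrame(columns, index=pd.Index(sim.guide_ids, name="guide"))
    sample_info = pd.DataFrame(meta_rows).set_index("sample")
    return CountMatrix(
        counts=counts_df,
        is_control=pd.Series(sim.is_control, index=counts_df.index),
        sample_info=sample_info,
    )
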