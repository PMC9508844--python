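"""Shared fixtures: a planted synthetic genome and its annotations.

Session-scoped because planting and single-cutter verification dominate
suite runtime; every test treats them as read-only.
"""

from __future__ import annotations

import pytest

from chromcut import (
    FixtureSpec,
    annotate_guides,
    make_genome,
    make_tracks,
    plant_pool_sites,
    truth_to_guides,
)


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=11, planted_per_pool=15)


@pytest.fixture(scope="session")
def planted(fixture_spec):
    """(genome, tracks, truth) with 15 planted sites per built-in pool."""
    genome = make_genome(fixture_spec)
    tracks = make_tracks(genome, fixture_spec)
    return plant_pool_sites(genome, tracks, fixture_spec)


@pytest.fixture(scope="session")
def planted_records(planted):
    """Annotation records for every planted ground-truth guide."""
    genome, tracks, truth = planted
    guides = truth_to_guides(truth)
    records = annotate_guides(
        guides, genome, tracks.states, tracks.lads, tracks.dnase,
        tracks.h3k9me3, tracks.genes,
    )
    return records, truth


def naive_hamming_hits(genome, protospacer, max_mismatches, require_pam):
    """Independent sliding-window Hamming oracle over both strands.

    Pure-python character comparison; deliberately shares no code with
    the package's matcher.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[b] for b in reversed(protospacer))
    hits = []
    for chrom in genome.chromosomes:
        seq = genome[chrom]
        L = len(seq)
        for start in range(L - len(protospacer) + 1):
            window = seq[start : start + len(protospacer)]
            mm_fwd = sum(a != b for a, b in zip(window, protospacer))
            if mm_fwd <= max_mismatches:
                pam = seq[start + 20 : start + 23]
                pam_ok = len(pam) == 3 and pam[1] == "G" and pam[2] == "G"
                if pam_ok or not require_pam:
                    hits.append((chrom, start, "+", mm_fwd, pam_ok))
            mm_rev = sum(a != b for a, b in zip(window, rc))
            if mm_rev <= max_mismatches:
                pam_ok = start >= 3 and seq[start - 3] == "C" and seq[start - 2] == "C"
                if pam_ok or not require_pam:
                    hits.append((chrom, start, "-", mm_rev, pam_ok))
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    return hits
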