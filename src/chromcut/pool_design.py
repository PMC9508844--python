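"""Chromatin-state guide pool filtering and constrained selection.

Each pool is a rule set of thresholds over annotation features: a
required chromatin state over the window, lamina compartment fractions,
accessibility (DNaseI maximum) bounds, H3K9me3 weighted-mean levels and
gene context. Passing guides are then sampled down to ``k`` per pool
under a per-chromosome cap, so a pool spreads its double-strand breaks
over the genome rather than concentrating them.

Threshold inclusivity follows the published wording: "at least" bounds
are inclusive, bounds written with ">" / "<" / "exceed" are strict.
"""

from __future__ import annotations

import random
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .annotate import AnnotationRecord

__all__ = [
    "Bound",
    "PoolDefinition",
    "RuleEvaluation",
    "PoolResult",
    "InsufficientCandidates",
    "builtin_pools",
    "load_pool_definitions",
    "evaluate_rule",
    "select_pool",
    "design_pools",
]


@dataclass(frozen=True)
class Bound:
    """A one-sided threshold with declared inclusivity."""

    value: float
    inclusive: bool = False

    def passes_lower(self, x: float) -> bool:
        return x >= self.value if self.inclusive else x > self.value

    def passes_upper(self, x: float) -> bool:
        return x <= self.value if self.inclusive else x < self.value


GeneRequirement = Literal["genic_intronic", "non_genic", "mixed"]
ExpressionRequirement = Literal["expressed", "non_expressed", "any"]


@dataclass(frozen=True)
class PoolDefinition:
    """A named rule set selecting guides in one chromatin environment."""

    name: str
    required_state: str | None = None
    state_min_fraction: Bound | None = None
    require_breaksite_state: bool = False
    dnase_max_min: Bound | None = None
    dnase_max_max: Bound | None = None
    lamina_compartment: Literal["LAD", "iLAD"] | None = None
    lamina_min_fraction: Bound | None = None
    h3k9me3_wmean_min: Bound | None = None
    gene_requirement: GeneRequirement = "mixed"
    expression_requirement: ExpressionRequirement = "any"

    def __post_init__(self) -> None:
        for bound in (self.state_min_fraction, self.lamina_min_fraction):
            if bound is not None and not 0.0 <= bound.value <= 1.0:
                raise ValueError(f"pool {self.name}: fraction bound outside [0, 1]")
        if self.dnase_max_min is not None and self.dnase_max_max is not None:
            raise ValueError(
                f"pool {self.name}: at most one DNaseI bound may be set"
            )
        if self.lamina_min_fraction is not None and self.lamina_compartment is None:
            raise ValueError(f"pool {self.name}: lamina bound without compartment")


@dataclass
class RuleEvaluation:
    """Pass/fail verdict with the names of every failed clause."""

    passed: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class PoolResult:
    """Selection outcome for one pool plus the full pass/fail ledger."""

    name: str
    selected: list[str]
    ledger: pd.DataFrame  # guide_id, passed, reasons, selected
    error: str | None = None


class InsufficientCandidates(RuntimeError):
    """No k-subset of the passing guides satisfies the chromosome cap."""

    def __init__(self, pool: str, requested: int, max_feasible: int) -> None:
        super().__init__(
            f"pool {pool}: requested {requested} guides but at most "
            f"{max_feasible} satisfy the per-chromosome cap"
        )
        self.pool = pool
        self.requested = requested
        self.max_feasible = max_feasible


def builtin_pools() -> list[PoolDefinition]:
    """The six built-in chromatin-environment pools.

    Pool 2 — promoters: >=65% state 2 (inclusive), breaksite in state 2,
    DNaseI max > 0.2, iLAD > 90%, intronic in an expressed gene.
    Pool 4 — enhancers: >50% state 4, iLAD > 99%, no gene filter.
    Pool 7 — gene bodies: >99% state 7, DNaseI max < 0.06, iLAD > 90%,
    intronic in an expressed gene.
    Pool 8a/8b — polycomb-repressed: >99% state 8, non-genic; 8a in
    iLAD > 99%, 8b in LAD > 99%.
    Pool 9 — H3K9me3 heterochromatin: weighted mean > 5.5, LAD > 99%,
    non-genic, breaksite confirmed state 9.
    """
    return [
        PoolDefinition(
            name="pool2", required_state="2",
            state_min_fraction=Bound(0.65, inclusive=True),
            require_breaksite_state=True,
            dnase_max_min=Bound(0.2),
            lamina_compartment="iLAD", lamina_min_fraction=Bound(0.90),
            gene_requirement="genic_intronic", expression_requirement="expressed",
        ),
        PoolDefinition(
            name="pool4", required_state="4",
            state_min_fraction=Bound(0.50),
            lamina_compartment="iLAD", lamina_min_fraction=Bound(0.99),
            gene_requirement="mixed",
        ),
        PoolDefinition(
            name="pool7", required_state="7",
            state_min_fraction=Bound(0.99),
            dnase_max_max=Bound(0.06),
            lamina_compartment="iLAD", lamina_min_fraction=Bound(0.90),
            gene_requirement="genic_intronic", expression_requirement="expressed",
        ),
        PoolDefinition(
            name="pool8a", required_state="8",
            state_min_fraction=Bound(0.99),
            lamina_compartment="iLAD", lamina_min_fraction=Bound(0.99),
            gene_requirement="non_genic",
        ),
        PoolDefinition(
            name="pool8b", required_state="8",
            state_min_fraction=Bound(0.99),
            lamina_compartment="LAD", lamina_min_fraction=Bound(0.99),
            gene_requirement="non_genic",
        ),
        PoolDefinition(
            name="pool9", required_state="9",
            require_breaksite_state=True,
            h3k9me3_wmean_min=Bound(5.5),
            lamina_compartment="LAD", lamina_min_fraction=Bound(0.99),
            gene_requirement="non_genic",
        ),
    ]


def evaluate_rule(record: AnnotationRecord, pool: PoolDefinition) -> RuleEvaluation:
    """Apply every configured clause; failures are named in ``reasons``."""
    reasons: list[str] = []
    if pool.state_min_fraction is not None:
        if pool.required_state is None:
            raise ValueError(f"pool {pool.name}: state bound without a state")
        frac = record.state_fraction.get(pool.required_state, 0.0)
        if not pool.state_min_fraction.passes_lower(frac):
            reasons.append("state_fraction")
    if pool.require_breaksite_state:
        if pool.required_state is None:
            raise ValueError(f"pool {pool.name}: breaksite clause without a state")
        if record.breaksite_state != pool.required_state:
            reasons.append("breaksite_state")
    if pool.dnase_max_min is not None:
        if not pool.dnase_max_min.passes_lower(record.dnase_max):
            reasons.append("dnase_max")
    if pool.dnase_max_max is not None:
        if not pool.dnase_max_max.passes_upper(record.dnase_max):
            reasons.append("dnase_max")
    if pool.lamina_min_fraction is not None:
        frac = (
            record.lad_fraction
            if pool.lamina_compartment == "LAD"
            else record.ilad_fraction
        )
        if not pool.lamina_min_fraction.passes_lower(frac):
            reasons.append("lamina_fraction")
    if pool.h3k9me3_wmean_min is not None:
        if not pool.h3k9me3_wmean_min.passes_lower(record.h3k9me3_wmean):
            reasons.append("h3k9me3_wmean")
    if pool.gene_requirement == "genic_intronic":
        if not (record.genic and record.intronic):
            reasons.append("gene_context")
    elif pool.gene_requirement == "non_genic":
        if record.genic:
            reasons.append("gene_context")
    if pool.expression_requirement == "expressed" and not record.expressed:
        reasons.append("expression")
    elif pool.expression_requirement == "non_expressed" and record.expressed:
        reasons.append("expression")
    return RuleEvaluation(passed=not reasons, reasons=reasons)


def _max_feasible(chrom_counts: dict[str, int], cap: int) -> int:
    return sum(min(n, cap) for n in chrom_counts.values())


def select_pool(
    passing: Sequence[AnnotationRecord],
    k: int = 10,
    max_per_chrom: int = 2,
    seed: int = 0,
) -> list[str]:
    """Pick ``k`` guide ids from the passing set under the chromosome cap.

    A seeded uniform shuffle followed by a greedy cap-respecting scan;
    greedy is optimal here (the cap is a partition-matroid constraint),
    so infeasibility is detected exactly.
    """
    if not passing:
        raise InsufficientCandidates("<unnamed>", k, 0)
    chrom_counts: dict[str, int] = {}
    for r in passing:
        chrom_counts[r.chrom] = chrom_counts.get(r.chrom, 0) + 1
    feasible = _max_feasible(chrom_counts, max_per_chrom)
    if feasible < k:
        raise InsufficientCandidates("<unnamed>", k, feasible)
    order = list(passing)
    random.Random(seed).shuffle(order)
    selected: list[str] = []
    taken: dict[str, int] = {}
    for r in order:
        if taken.get(r.chrom, 0) >= max_per_chrom:
            continue
        selected.append(r.guide_id)
        taken[r.chrom] = taken.get(r.chrom, 0) + 1
        if len(selected) == k:
            break
    return selected


def design_pools(
    records: Sequence[AnnotationRecord],
    pools: Sequence[PoolDefinition] | None = None,
    k: int = 10,
    max_per_chrom: int = 2,
    seed: int = 0,
    exclusive: bool = True,
) -> list[PoolResult]:
    """Filter and select one pool per definition.

    With ``exclusive`` (default) a guide selected by an earlier pool is
    not offered to later ones (first-claim by pool order). Selection
    errors are collected per pool, not raised.
    """
    if pools is None:
        pools = builtin_pools()
    claimed: set[str] = set()
    results: list[PoolResult] = []
    for i, pool in enumerate(pools):
        rows = []
        passing: list[AnnotationRecord] = []
        for r in records:
            ev = evaluate_rule(r, pool)
            available = r.guide_id not in claimed
            rows.append(
                {
                    "guide_id": r.guide_id, "passed": ev.passed,
                    "reasons": ";".join(ev.reasons), "selected": False,
                }
            )
            if ev.passed and (available or not exclusive):
                passing.append(r)
        ledger = pd.DataFrame(rows)
        try:
            # pool-specific sub-seed keeps selections independent per pool
            selected = select_pool(passing, k, max_per_chrom, seed=seed * 1000 + i)
            error = None
        except InsufficientCandidates as exc:
            selected = []
            error = str(exc).replace("<unnamed>", pool.name)
        if selected:
            ledger.loc[ledger["guide_id"].isin(selected), "selected"] = True
        if exclusive:
            claimed.update(selected)
        results.append(
            PoolResult(name=pool.name, selected=selected, ledger=ledger, error=error)
        )
    return results


def load_pool_definitions(path: str | Path) -> list[PoolDefinition]:
    """Load pool rule sets from a TOML file: one section per pool, clause
    keys matching PoolDefinition fields; bounds are tables with ``value``
    and optional ``inclusive``."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    pools = []
    bound_keys = {
        "state_min_fraction", "dnase_max_min", "dnase_max_max",
        "lamina_min_fraction", "h3k9me3_wmean_min",
    }
    for name, section in data.items():
        kwargs: dict = {"name": name}
        for key, raw in section.items():
            if key in bound_keys:
                if isinstance(raw, dict):
                    kwargs[key] = Bound(
                        float(raw["value"]), bool(raw.get("inclusive", False))
                    )
                else:
                    kwargs[key] = Bound(float(raw))
            else:
                kwargs[key] = raw
        pools.append(PoolDefinition(**kwargs))
    return pools
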