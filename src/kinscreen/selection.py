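"""Kinome target-panel selection with auditable stage accounting.

The workflow mirrors how a representative kinase panel is assembled from a
full kinome annotation: (1) keep genes expressed above an FPKM-like threshold
in any of the RNA-Seq libraries, (2) prioritise trait-associated candidates
by propagating seed scores over a weighted gene network and taking the top
``k``, (3) add one gene from every kinase family still unrepresented so each
family has at least one member, (4) union in a short curated list of
well-studied kinases, (5) drop genes lacking a complete kinase domain, and
(6) drop genes whose DNA synthesis failed.  Every stage records its in/out
counts and the ids added or removed, so the final panel is fully auditable.

The network scoring used by published probabilistic gene networks is not
reproducible from their descriptions; the label-propagation here (retention
weight ``alpha``, a fixed number of rounds, weight-normalised neighbour
averaging) is a deterministic, pluggable stand-in with the same interface.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from ._util import percentage
from .errors import LedgerInconsistencyError, MalformedInputError

logger = logging.getLogger(__name__)

KINASE_GROUPS = ("AGC", "CAMK", "CK1", "CMGC", "STE", "TKL")


@dataclass(frozen=True)
class KinaseGene:
    """One kinase-encoding gene with family label and expression vector."""

    locus_id: str
    family: str
    group: str
    expression: np.ndarray
    has_full_domain: bool = True
    curated: bool = False

    def __post_init__(self):
        expr = np.asarray(self.expression, dtype=float)
        object.__setattr__(self, "expression", expr)
        if not self.family:
            raise MalformedInputError(f"{self.locus_id}: empty family")
        if expr.size == 0:
            raise MalformedInputError(f"{self.locus_id}: empty expression vector")
        if np.any(expr < 0) or not np.all(np.isfinite(expr)):
            raise MalformedInputError(f"{self.locus_id}: expression must be finite and >= 0")

    def aggregated_expression(self, aggregation: str = "max") -> float:
        if aggregation == "max":
            return float(np.max(self.expression))
        if aggregation == "mean":
            return float(np.mean(self.expression))
        raise MalformedInputError(f"unknown aggregation {aggregation!r}")


class GeneNetwork:
    """Undirected weighted gene network (thin wrapper over ``networkx``)."""

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "GeneNetwork":
        g = nx.Graph()
        for a, b, w in edges:
            w = float(w)
            if a == b:
                raise MalformedInputError(f"self-loop on {a}")
            if not np.isfinite(w) or w < 0:
                raise MalformedInputError(f"edge ({a},{b}) has invalid weight {w}")
            g.add_edge(a, b, weight=w)
        return cls(g)

    def neighbors(self, node: str) -> list[tuple[str, float]]:
        if node not in self.graph:
            return []
        return [(nbr, data.get("weight", 1.0)) for nbr, data in self.graph[node].items()]


# --- ledger -----------------------------------------------------------------


@dataclass(frozen=True)
class Stage:
    name: str
    in_count: int
    out_count: int
    removed: tuple[str, ...] = ()
    added: tuple[str, ...] = ()


@dataclass
class SelectionLedger:
    """Ordered record of selection stages with additive consistency checks."""

    stages: list[Stage] = field(default_factory=list)

    def record(
        self,
        name: str,
        in_count: int,
        out_count: int,
        removed: Sequence[str] = (),
        added: Sequence[str] = (),
    ) -> Stage:
        stage = Stage(name, int(in_count), int(out_count), tuple(sorted(removed)), tuple(sorted(added)))
        if stage.out_count != stage.in_count - len(stage.removed) + len(stage.added):
            raise LedgerInconsistencyError(
                f"stage {name!r}: {stage.in_count} - {len(stage.removed)} + {len(stage.added)} "
                f"!= {stage.out_count}"
            )
        if self.stages and stage.in_count != self.stages[-1].out_count:
            raise LedgerInconsistencyError(
                f"stage {name!r}: in_count {stage.in_count} != previous out_count "
                f"{self.stages[-1].out_count}"
            )
        self.stages.append(stage)
        return stage

    @property
    def final_count(self) -> int:
        if not self.stages:
            raise LedgerInconsistencyError("empty ledger")
        return self.stages[-1].out_count

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "in_count": s.in_count,
                    "out_count": s.out_count,
                    "removed": list(s.removed),
                    "added": list(s.added),
                }
                for s in self.stages
            ],
            "final_count": self.final_count,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def run_accounting(
    ledger: SelectionLedger,
    ratios: Mapping[str, tuple[float, float, int]] | None = None,
) -> dict:
    """Validate stage arithmetic and compute requested percentages.

    ``ratios`` maps a label to ``(numerator, denominator, decimals)``;
    percentages are rounded half-up.  Inconsistent stage counts raise
    :class:`LedgerInconsistencyError` naming the offending stage.
    """
    previous: Stage | None = None
    for stage in ledger.stages:
        if stage.out_count != stage.in_count - len(stage.removed) + len(stage.added):
            raise LedgerInconsistencyError(f"stage {stage.name!r}: counts do not add up")
        if previous is not None and stage.in_count != previous.out_count:
            raise LedgerInconsistencyError(
                f"stage {stage.name!r}: in_count does not chain from {previous.name!r}"
            )
        previous = stage
    summary = {
        "final_count": ledger.final_count,
        "stages": [
            {"name": s.name, "in_count": s.in_count, "out_count": s.out_count,
             "delta": s.out_count - s.in_count}
            for s in ledger.stages
        ],
        "percentages": {},
    }
    if ratios:
        for label, (num, den, decimals) in ratios.items():
            summary["percentages"][label] = percentage(num, den, ndigits=decimals)
    return summary


# --- stage operations -------------------------------------------------------


def filter_expression(
    genes: Sequence[KinaseGene],
    threshold: float = 2.0,
    aggregation: str = "max",
) -> list[KinaseGene]:
    """Keep genes whose aggregated expression is >= threshold (inclusive)."""
    return [g for g in genes if g.aggregated_expression(aggregation) >= threshold]


def propagate_scores(
    network: GeneNetwork,
    genes: Sequence[KinaseGene],
    seed_scores: Mapping[str, float],
    rounds: int = 2,
    alpha: float = 0.5,
) -> dict[str, float]:
    """Seeded label propagation restricted to the given gene subset.

    Each round: ``score' = alpha * score + (1 - alpha) * weighted mean of
    neighbour scores`` (neighbours outside the subset are ignored; an
    isolated gene simply decays by ``alpha``).  Deterministic given inputs.
    """
    if not 0.0 <= alpha <= 1.0:
        raise MalformedInputError("alpha must lie in [0, 1]")
    if rounds < 0:
        raise MalformedInputError("rounds must be >= 0")
    ids = [g.locus_id for g in genes]
    member = set(ids)
    scores = {i: float(seed_scores.get(i, 0.0)) for i in ids}
    neighbours = {
        i: [(n, w) for n, w in network.neighbors(i) if n in member] for i in ids
    }
    for _ in range(rounds):
        new = {}
        for i in ids:
            nbrs = neighbours[i]
            total_w = sum(w for _, w in nbrs)
            if total_w > 0:
                nbr_mean = sum(w * scores[n] for n, w in nbrs) / total_w
                new[i] = alpha * scores[i] + (1.0 - alpha) * nbr_mean
            else:
                new[i] = alpha * scores[i]
        scores = new
    return scores


def _rank_key(scores: Mapping[str, float], aggregation: str) -> Callable[[KinaseGene], tuple]:
    def key(g: KinaseGene) -> tuple:
        return (-scores.get(g.locus_id, 0.0), -g.aggregated_expression(aggregation), g.locus_id)

    return key


def select_representatives(
    genes: Sequence[KinaseGene],
    scores: Mapping[str, float],
    k: int,
    aggregation: str = "max",
) -> list[KinaseGene]:
    """Top-``k`` genes by propagated score.

    Ties break by higher aggregated expression, then lexicographic locus id,
    so the selection is deterministic.  ``k`` larger than the population
    returns everything with a warning.
    """
    if k > len(genes):
        logger.warning("k=%d exceeds population %d; returning all genes", k, len(genes))
        k = len(genes)
    return sorted(genes, key=_rank_key(scores, aggregation))[:k]


def complete_family_coverage(
    selected: Sequence[KinaseGene],
    candidates: Sequence[KinaseGene],
    aggregation: str = "max",
) -> tuple[list[KinaseGene], list[KinaseGene]]:
    """Add one gene for every family with candidates but no selected member.

    The highest-expressing candidate wins (ties: lexicographic locus id).
    Families with no candidates at all are reported uncovered via a log line.
    Returns ``(augmented selection, additions)``.
    """
    covered = {g.family for g in selected}
    by_family: dict[str, list[KinaseGene]] = {}
    for g in candidates:
        by_family.setdefault(g.family, []).append(g)
    selected_ids = {g.locus_id for g in selected}
    additions: list[KinaseGene] = []
    for family in sorted(set(by_family) - covered):
        pool = [g for g in by_family[family] if g.locus_id not in selected_ids]
        if not pool:
            logger.warning("family %s has no available candidate; left uncovered", family)
            continue
        best = min(pool, key=lambda g: (-g.aggregated_expression(aggregation), g.locus_id))
        additions.append(best)
    return list(selected) + additions, additions


def add_curated(
    selected: Sequence[KinaseGene],
    curated_ids: Sequence[str],
    pool: Sequence[KinaseGene],
) -> tuple[list[KinaseGene], list[KinaseGene]]:
    """Union in curated genes by id; unknown ids are logged and skipped."""
    by_id = {g.locus_id: g for g in pool}
    selected_ids = {g.locus_id for g in selected}
    additions = []
    for cid in curated_ids:
        if cid in selected_ids:
            continue
        gene = by_id.get(cid)
        if gene is None:
            logger.warning("curated id %s not found in the gene pool; skipped", cid)
            continue
        additions.append(gene)
        selected_ids.add(cid)
    return list(selected) + additions, additions


def filter_domain(selected: Sequence[KinaseGene]) -> tuple[list[KinaseGene], list[str]]:
    """Drop genes whose product lacks a predicted full kinase domain."""
    kept = [g for g in selected if g.has_full_domain]
    removed = [g.locus_id for g in selected if not g.has_full_domain]
    return kept, removed


@dataclass(frozen=True)
class SelectionResult:
    selected: tuple[KinaseGene, ...]
    ledger: SelectionLedger
    scores: dict[str, float]

    @property
    def selected_ids(self) -> list[str]:
        return [g.locus_id for g in self.selected]


def run_selection(
    genes: Sequence[KinaseGene],
    network: GeneNetwork,
    seed_ids: Sequence[str],
    curated_ids: Sequence[str] = (),
    failed_ids: Sequence[str] = (),
    *,
    threshold: float = 2.0,
    aggregation: str = "max",
    alpha: float = 0.5,
    rounds: int = 2,
    k: int = 141,
) -> SelectionResult:
    """Run the full selection workflow and return the panel plus its ledger.

    ``seed_ids`` are trait-associated genes given a unit seed score for the
    network propagation; ``failed_ids`` model DNA-synthesis failures (an
    input list, not a prediction).
    """
    ledger = SelectionLedger()
    ids = [g.locus_id for g in genes]
    if len(set(ids)) != len(ids):
        raise MalformedInputError("duplicate locus ids in the gene table")

    expressed = filter_expression(genes, threshold, aggregation)
    expressed_ids = {g.locus_id for g in expressed}
    ledger.record(
        "expression_filter",
        len(genes),
        len(expressed),
        removed=[i for i in ids if i not in expressed_ids],
    )

    scores = propagate_scores(
        network, expressed, {i: 1.0 for i in seed_ids}, rounds=rounds, alpha=alpha
    )
    reps = select_representatives(expressed, scores, k, aggregation)
    rep_ids = {g.locus_id for g in reps}
    ledger.record(
        "network_prioritization",
        len(expressed),
        len(reps),
        removed=[g.locus_id for g in expressed if g.locus_id not in rep_ids],
    )

    covered, family_added = complete_family_coverage(reps, expressed, aggregation)
    ledger.record(
        "family_coverage",
        len(reps),
        len(covered),
        added=[g.locus_id for g in family_added],
    )

    with_curated, curated_added = add_curated(covered, curated_ids, genes)
    ledger.record(
        "curated_additions",
        len(covered),
        len(with_curated),
        added=[g.locus_id for g in curated_added],
    )

    domain_ok, domain_removed = filter_domain(with_curated)
    ledger.record("domain_filter", len(with_curated), len(domain_ok), removed=domain_removed)

    failed = set(failed_ids)
    final = [g for g in domain_ok if g.locus_id not in failed]
    ledger.record(
        "synthesis_failure",
        len(domain_ok),
        len(final),
        removed=[g.locus_id for g in domain_ok if g.locus_id in failed],
    )

    final_sorted = tuple(sorted(final, key=lambda g: g.locus_id))
    return SelectionResult(selected=final_sorted, ledger=ledger, scores=scores)
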