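"""Greedy pathway-coverage refinement of a sentinel panel.

A pathway is *covered* once the panel contains at least ``q`` of its
genes — capped at the number of its genes present in the scoring universe,
otherwise pathways smaller than q could never be satisfied. Refinement
repeatedly swaps the least valuable selected gene (fewest pathway
memberships, then smallest OIS) for the unselected gene appearing in the
most still-uncovered pathways, until no uncovered pathway remains.

Two determinism/safety rules beyond the basic procedure:

* every tie is broken by (primary criterion, OIS, ascending gene id), so
  refinement is fully deterministic;
* a selected gene whose removal would drop any pathway below its
  attainable coverage is ineligible for exclusion, which makes the total
  coverage deficit strictly decrease each iteration and guarantees
  termination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GeneSetCollection, ImportanceScores, SentinelSelection
from .errors import CoverageInfeasibleError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class CoverageReport:
    """Set-coverage summary of a selection against a pathway collection."""

    per_pathway: pd.DataFrame  # columns: covered_count, pathway_size, fraction
    per_gene_multiplicity: pd.Series  # selected gene -> #pathways containing it
    summary: dict

    def to_frame(self) -> pd.DataFrame:
        return self.per_pathway


def _multiplicity(gene: str, pathways: GeneSetCollection) -> int:
    return sum(1 for _, members in pathways.items() if gene in members)


def coverage_report(
    selection: SentinelSelection,
    pathways: GeneSetCollection,
    q: int = 3,
) -> CoverageReport:
    """Exact intersection counts and coverage fractions per pathway."""
    sel = set(selection.genes)
    rows = []
    for name, members in pathways.items():
        covered = len(members & sel)
        rows.append(
            {
                "pathway": name,
                "covered_count": covered,
                "pathway_size": len(members),
                "fraction": covered / len(members),
            }
        )
    per_pathway = pd.DataFrame(
        rows, columns=["pathway", "covered_count", "pathway_size", "fraction"]
    ).set_index("pathway")
    mult = pd.Series(
        {g: _multiplicity(g, pathways) for g in selection.genes}, dtype=float
    )
    n_pathways = len(pathways)
    summary = {
        "n_pathways": n_pathways,
        "pathways_covered_at_q": int((per_pathway["covered_count"] >= q).sum()),
        "mean_coverage": float(per_pathway["fraction"].mean()) if n_pathways else 0.0,
        "median_coverage": float(per_pathway["fraction"].median()) if n_pathways else 0.0,
        "mean_multiplicity": float(mult.mean()) if len(mult) else 0.0,
    }
    return CoverageReport(per_pathway, mult, summary)


def _attainable(pathways: GeneSetCollection, universe: set[str], q: int) -> dict[str, int]:
    """Coverage target per pathway: min(q, members present in the universe)."""
    return {name: min(q, len(members & universe))
            for name, members in pathways.items()}


def uncovered_pathways(
    selection: SentinelSelection,
    pathways: GeneSetCollection,
    q: int = 3,
    universe: set[str] | None = None,
) -> set[str]:
    """Pathways represented by fewer than their attainable q selected genes.

    ``universe`` is the scoring universe (defaults to all genes appearing
    in any pathway plus the selection); a pathway with fewer than q
    universe members counts as covered once all attainable members are
    selected.
    """
    if q < 0:
        raise ParameterError("q must be >= 0")
    if q == 0:
        return set()
    if universe is None:
        universe = set(selection.genes)
        for _, members in pathways.items():
            universe |= members
    sel = set(selection.genes)
    attain = _attainable(pathways, universe, q)
    return {
        name
        for name, members in pathways.items()
        if len(members & sel) < attain[name]
    }


def _tie_sort_key(gene: str, ois: pd.Series):
    return (float(ois.get(gene, 0.0)), gene)


def _inclusion_candidates(
    selection: SentinelSelection,
    pathways: GeneSetCollection,
    q: int,
    scores: ImportanceScores,
    uncovered: set[str] | None = None,
) -> list[str]:
    """Unselected universe genes in >=1 uncovered pathway, best first:
    most uncovered memberships, then higher OIS, then smaller id."""
    universe = set(scores.gene_ids)
    if uncovered is None:
        uncovered = uncovered_pathways(selection, pathways, q, universe)
    sel = set(selection.genes)
    counts: dict[str, int] = {}
    for name in uncovered:
        for g in pathways[name] & universe:
            if g not in sel:
                counts[g] = counts.get(g, 0) + 1
    ois = scores.ois
    return sorted(counts,
                  key=lambda g: (-counts[g], -float(ois.get(g, 0.0)), g))


def best_inclusion_candidate(
    selection: SentinelSelection,
    pathways: GeneSetCollection,
    q: int,
    scores: ImportanceScores,
    uncovered: set[str] | None = None,
) -> str:
    """Unselected universe gene in the most uncovered pathways.

    Ties go to the higher OIS, then the lexicographically smaller id.
    """
    ranked = _inclusion_candidates(selection, pathways, q, scores, uncovered)
    if not ranked:
        raise CoverageInfeasibleError(
            "no unselected universe gene is a member of any uncovered pathway"
        )
    return ranked[0]


def best_exclusion_candidate(
    selection: SentinelSelection,
    pathways: GeneSetCollection,
    scores: ImportanceScores,
    q: int = 3,
    protected: set[str] | None = None,
    extra_member: str | None = None,
) -> str:
    """Selected gene with the fewest pathway memberships and smallest OIS.

    Genes whose removal would drop a pathway below its attainable coverage
    are ineligible (this keeps refinement monotone). ``extra_member``
    lets the caller count a pending inclusion toward coverage;
    ``protected`` genes (e.g. the pending inclusion) are never returned.
    """
    if not selection.genes:
        raise CoverageInfeasibleError("selection is empty")
    universe = set(scores.gene_ids) | set(selection.genes)
    attain = _attainable(pathways, universe, q)
    effective = set(selection.genes)
    if extra_member is not None:
        effective = effective | {extra_member}
    counts = {name: len(members & effective) for name, members in pathways.items()}
    protected = protected or set()
    ois = scores.ois

    def removable(g: str) -> bool:
        for name, members in pathways.items():
            if g in members and counts[name] - 1 < attain[name]:
                return False
        return True

    candidates = [g for g in selection.genes if g not in protected and removable(g)]
    if not candidates:
        raise CoverageInfeasibleError("no selected gene can be removed without "
                                      "uncovering a pathway")
    return min(
        candidates,
        key=lambda g: (_multiplicity(g, pathways), float(ois.get(g, 0.0)), g),
    )


@dataclass
class RefinementResult:
    """Outcome of coverage refinement: the panel, the swap log, leftovers."""

    selection: SentinelSelection
    swaps: list[tuple[str, str, int]] = field(default_factory=list)
    residual_uncovered: list[str] = field(default_factory=list)
    exact_rescue: bool = False


_EXACT_SEARCH_CAP = 200_000  # max subsets enumerated by the stall rescue


def _exact_cover_rescue(
    initial: SentinelSelection,
    stalled: SentinelSelection,
    pathways: GeneSetCollection,
    q: int,
    scores: ImportanceScores,
) -> SentinelSelection | None:
    """Exhaustive fixed-size search used when greedy refinement stalls.

    Single-swap refinement has local minima: escaping them can require a
    swap that temporarily uncovers a pathway. On small universes the
    optimum is cheap to enumerate, so the stalled panel is replaced by the
    equal-size subset maximizing (pathways covered, total OIS), ties
    broken lexicographically. Returns None when the enumeration would
    exceed the work cap (always the case at realistic problem sizes).
    """
    import itertools
    import math

    universe = sorted(set(scores.gene_ids))
    size = len(stalled)
    if size > len(universe) or math.comb(len(universe), size) > _EXACT_SEARCH_CAP:
        return None
    attain = _attainable(pathways, set(universe), q)
    ois = scores.ois
    best = None
    best_key = None
    for combo in itertools.combinations(universe, size):
        s = set(combo)
        covered = sum(
            1 for name, members in pathways.items()
            if len(members & s) >= attain[name]
        )
        key = (covered, float(sum(ois.get(g, 0.0) for g in combo)))
        if best_key is None or key > best_key:
            best, best_key = combo, key
    if best is None:
        return None
    initial_set = set(initial.genes)
    genes = [g for g in initial.genes if g in set(best)]
    genes += [g for g in best if g not in initial_set]
    prov = {g: (initial.provenance.get(g, "data_driven")
                if g in initial_set else "coverage_replacement")
            for g in genes}
    return SentinelSelection(genes, prov, dict(initial.parameters, q=q))


def refine_selection(
    initial: SentinelSelection,
    pathways: GeneSetCollection,
    q: int,
    scores: ImportanceScores,
    max_iter: int | None = None,
) -> RefinementResult:
    """Swap genes until every attainably-coverable pathway holds >= q genes.

    Each iteration replaces the best exclusion candidate with the best
    inclusion candidate; swapped-in genes carry provenance
    ``coverage_replacement``. On infeasibility (or ``max_iter``) a partial
    result is returned with the residual uncovered pathways listed.
    """
    if len(initial) < 1:
        raise ParameterError("initial selection must be non-empty")
    universe = set(scores.gene_ids)
    genes = list(initial.genes)
    provenance = dict(initial.provenance)
    swaps: list[tuple[str, str, int]] = []
    if max_iter is None:
        first_unc = uncovered_pathways(initial, pathways, q, universe)
        max_iter = max(1, len(first_unc)) * max(1, len(universe))
    selection = SentinelSelection(genes, provenance,
                                  dict(initial.parameters, q=q))
    for _ in range(max_iter):
        unc = uncovered_pathways(selection, pathways, q, universe)
        if not unc:
            return RefinementResult(selection, swaps, [])
        ranked = _inclusion_candidates(selection, pathways, q, scores,
                                       uncovered=unc)
        if not ranked:
            logger.warning("refinement stalled: %d pathway(s) have no "
                           "eligible inclusion candidate", len(unc))
            return _stall_result(initial, selection, pathways, q, scores,
                                 swaps, unc)
        # the top inclusion candidate can pin every selected gene (each
        # protecting a pathway at its attainable minimum); fall through to
        # the next-ranked candidate before declaring the step infeasible
        inc = exc = None
        for cand in ranked:
            try:
                exc = best_exclusion_candidate(
                    selection, pathways, scores, q=q,
                    protected={cand}, extra_member=cand,
                )
                inc = cand
                break
            except CoverageInfeasibleError:
                continue
        if inc is None:
            logger.warning("refinement stalled: no removable gene while %d "
                           "pathway(s) remain uncovered", len(unc))
            return _stall_result(initial, selection, pathways, q, scores,
                                 swaps, unc)
        new_genes = [g for g in selection.genes if g != exc] + [inc]
        new_prov = {g: p for g, p in selection.provenance.items() if g != exc}
        new_prov[inc] = "coverage_replacement"
        selection = SentinelSelection(new_genes, new_prov, selection.parameters)
        swaps.append((exc, inc, len(unc)))
    unc = uncovered_pathways(selection, pathways, q, universe)
    if unc:
        logger.warning("refinement hit max_iter with %d uncovered", len(unc))
        return _stall_result(initial, selection, pathways, q, scores,
                             swaps, unc)
    return RefinementResult(selection, swaps, sorted(unc))


def _stall_result(
    initial: SentinelSelection,
    stalled: SentinelSelection,
    pathways: GeneSetCollection,
    q: int,
    scores: ImportanceScores,
    swaps: list[tuple[str, str, int]],
    unc: set[str],
) -> RefinementResult:
    """Attempt the exact rescue; fall back to the stalled partial result."""
    rescued = _exact_cover_rescue(initial, stalled, pathways, q, scores)
    if rescued is not None:
        rescued_unc = uncovered_pathways(rescued, pathways, q,
                                         set(scores.gene_ids))
        if len(rescued_unc) < len(unc):
            logger.info("exact cover search resolved a greedy stall "
                        "(%d -> %d uncovered)", len(unc), len(rescued_unc))
            return RefinementResult(rescued, swaps, sorted(rescued_unc),
                                    exact_rescue=True)
    return RefinementResult(stalled, swaps, sorted(unc))


def merge_nominations(
    selection: SentinelSelection, nominated: list[str]
) -> SentinelSelection:
    """Union the panel with a nominated gene list.

    Nominated genes already present keep their original provenance; new
    ones are appended in nomination order flagged ``nominated``.
    """
    genes = list(selection.genes)
    provenance = dict(selection.provenance)
    present = set(genes)
    for g in nominated:
        if g in present:
            continue
        genes.append(g)
        provenance[g] = "nominated"
        present.add(g)
    return SentinelSelection(genes, provenance, dict(selection.parameters))
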