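"""Selection of strain consortia that maximise ANF-elimination capacity.

Given the binary presence/absence matrix, a consortium of k genomes is
evaluated by the union of its rows: how many ANF categories the mixture
covers and how many distinct gene features it contributes.  Two objectives
are offered:

* ``lex`` (default) — maximise categories covered, then distinct genes;
* ``genes`` — maximise distinct genes only.

``select_exhaustive`` enumerates every size-k subset (up to a configurable
cap) and is provably optimal, reporting all ties; ``select_greedy`` adds the
genome with the largest marginal gain at each step and carries the classic
(1 − 1/e) max-coverage guarantee on the coverage component.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .pangenome import PresenceMatrix

__all__ = [
    "ConsortiumSolution",
    "union_profile",
    "select_exhaustive",
    "select_greedy",
    "DEFAULT_ENUMERATION_CAP",
]

logger = logging.getLogger(__name__)

DEFAULT_ENUMERATION_CAP = 2_000_000

_OBJECTIVES = ("lex", "genes")


@dataclass(frozen=True)
class ConsortiumSolution:
    """A selected strain subset and its union profile.

    ``objective_value`` is the tuple actually maximised —
    ``(categories_covered, union_gene_count)`` for ``lex``,
    ``(union_gene_count,)`` for ``genes``.  ``ties`` lists every other
    genome-id set achieving the same objective (exhaustive mode only); the
    reported set is the lexicographically smallest among them.
    """

    genome_ids: tuple[str, ...]
    categories_covered: int
    category_set: frozenset[str]
    union_gene_count: int
    objective: str
    objective_value: tuple[int, ...]
    is_optimal: bool
    ties: tuple[tuple[str, ...], ...] = ()


def union_profile(
    matrix: PresenceMatrix, subset
) -> tuple[frozenset[str], int]:
    """Union of the selected genomes' rows: (category set, distinct genes).

    Order-independent and idempotent in *subset*; unknown genome ids raise
    ``KeyError``.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("union_profile requires a non-empty subset")
    index = {g: i for i, g in enumerate(matrix.genome_ids)}
    try:
        rows = [index[g] for g in subset]
    except KeyError as exc:
        raise KeyError(f"unknown genome id {exc.args[0]!r}") from exc
    if not len(matrix.feature_ids):
        return frozenset(), 0
    union = matrix.cells[rows].any(axis=0)
    cats = frozenset(
        matrix.feature_category[f]
        for f, present in zip(matrix.feature_ids, union)
        if present
    )
    return cats, int(union.sum())


def _objective_value(
    cats: frozenset[str], genes: int, objective: str
) -> tuple[int, ...]:
    if objective == "lex":
        return (len(cats), genes)
    if objective == "genes":
        return (genes,)
    raise ValueError(f"objective must be one of {_OBJECTIVES}")


def _solution(matrix, subset, objective, is_optimal, ties=()):
    cats, genes = union_profile(matrix, subset)
    return ConsortiumSolution(
        genome_ids=tuple(subset),
        categories_covered=len(cats),
        category_set=cats,
        union_gene_count=genes,
        objective=objective,
        objective_value=_objective_value(cats, genes, objective),
        is_optimal=is_optimal,
        ties=tuple(ties),
    )


def select_exhaustive(
    matrix: PresenceMatrix,
    k: int,
    objective: str = "lex",
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP,
) -> ConsortiumSolution:
    """Globally optimal size-k consortium by full enumeration.

    Subsets are enumerated in lexicographic genome-id order, so the
    returned optimum is the lexicographically smallest among ties; all
    co-optimal subsets are reported in ``ties``.  Raises when C(n, k)
    exceeds *enumeration_cap* (use :func:`select_greedy` instead).
    """
    n = len(matrix.genome_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    n_subsets = _comb(n, k)
    if n_subsets > enumeration_cap:
        raise ValueError(
            f"C({n},{k}) = {n_subsets} exceeds the enumeration cap "
            f"({enumeration_cap}); use select_greedy"
        )
    ordered = sorted(matrix.genome_ids)
    best_value: tuple[int, ...] | None = None
    best_subsets: list[tuple[str, ...]] = []
    for subset in itertools.combinations(ordered, k):
        cats, genes = union_profile(matrix, subset)
        value = _objective_value(cats, genes, objective)
        if best_value is None or value > best_value:
            best_value = value
            best_subsets = [subset]
        elif value == best_value:
            best_subsets.append(subset)
    winner = best_subsets[0]
    return _solution(
        matrix, winner, objective, is_optimal=True, ties=best_subsets[1:]
    )


def select_greedy(
    matrix: PresenceMatrix, k: int, objective: str = "lex"
) -> ConsortiumSolution:
    """Greedy size-k consortium by largest marginal gain.

    The gain of adding genome g is lexicographic (new categories, then new
    genes) for ``lex``, or just new genes for ``genes``; ties fall to the
    lexicographically smaller genome id.  Stops early (logged) when all
    marginal gains are zero.  ``is_optimal`` is always False.
    """
    n = len(matrix.genome_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    chosen: list[str] = []
    remaining = sorted(matrix.genome_ids)
    current_cats: frozenset[str] = frozenset()
    current_genes = 0
    for _ in range(k):
        best_gain = None
        best_genome = None
        for g in remaining:
            cats, genes = union_profile(matrix, chosen + [g])
            if objective == "lex":
                gain = (len(cats) - len(current_cats), genes - current_genes)
            else:
                gain = (genes - current_genes,)
            if best_gain is None or gain > best_gain:
                best_gain = gain
                best_genome = g
        if all(v == 0 for v in best_gain):
            logger.info(
                "greedy selection stopped early at %d genomes: no marginal gain",
                len(chosen),
            )
            break
        chosen.append(best_genome)
        remaining.remove(best_genome)
        current_cats, current_genes = union_profile(matrix, chosen)
    return _solution(matrix, tuple(chosen), objective, is_optimal=False)


def _comb(n: int, k: int) -> int:
    import math

    return math.comb(n, k)
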