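"""Fragment frequencies, hypergeometric enrichment and FDR control.

A fragment's frequency is the number of molecules containing it at
least once -- repeated occurrences inside one molecule count once.  To
ask whether a fragment (or a cluster of similar fragments) is
over-represented in a foreground set of molecules relative to a
background set, the upper tail of the hypergeometric distribution gives
the probability of seeing at least the observed count by chance, in
direct analogy with Gene Ontology over-representation analysis.  Raw
p-values are always accompanied by Benjamini-Hochberg FDRs.

Two sampling universes are supported.  In the default ``occurrences``
universe the population is the multiset of fragment occurrences (one per
molecule-fragment pair): N is the total background occurrence count and
n the total foreground occurrence count.  In the ``molecules`` universe
the population is the molecules themselves: N and n are the background
and foreground library sizes, and K and k count molecules containing
the unit.  The background must contain the foreground's fragments for
either to be meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Sequence

from .chem_io import FragmentTable, InputError
from .similarity import FragmentCluster

logger = logging.getLogger(__name__)

UNIVERSES = ("occurrences", "molecules")


@dataclass
class FrequencyTable:
    """Per-fragment molecule counts for one fragment table."""

    counts: dict[str, int]
    n_molecules: int


@dataclass
class EnrichmentResult:
    """One tested unit (fragment or cluster) with its contingency counts."""

    unit: str
    cluster_id: int | None
    k: int  # foreground occurrences of the unit
    n: int  # foreground total
    K: int  # background occurrences of the unit
    N: int  # background total
    p_value: float
    fdr: float = float("nan")


def count_frequencies(table: FragmentTable) -> FrequencyTable:
    """Number of molecules containing each fragment.

    Rows are sets, so a molecule contributes at most one to any count;
    empty rows still count toward ``n_molecules``.
    """
    counts: dict[str, int] = {}
    for row in table:
        for frag in row.fragments:
            counts[frag] = counts.get(frag, 0) + 1
    return FrequencyTable(counts=counts, n_molecules=len(table))


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Computed with exact integer binomials and a single rational division,
    then rounded once to float, so the result is correct to full double
    precision for any population size met in practice.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(
            f"inconsistent hypergeometric counts: k={k}, K={K}, n={n}, N={N}"
        )
    if k <= max(0, n + K - N):
        return 1.0
    numerator = sum(
        comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1)
    )
    return float(Fraction(numerator, comb(N, n)))


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Step-up Benjamini-Hochberg adjustment, input order preserved.

    adjusted[i] = min over j with p_j >= p_i of m * p_j / rank_j, capped
    at 1.  Inputs outside (0, 1] are rejected.
    """
    m = len(p_values)
    for p in p_values:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-value out of (0, 1]: {p}")
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, m * p_values[i] / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def _unit_counts(
    table: FragmentTable,
    clusters: list[FragmentCluster] | None,
) -> dict[str, int]:
    """Molecule counts per unit: fragments, or clusters when given.

    A molecule counts once toward a cluster if it contains at least one
    member fragment, regardless of how many members it holds.
    """
    if clusters is None:
        return count_frequencies(table).counts
    counts: dict[str, int] = {}
    membership = {f: c for c in clusters for f in c.members}
    for row in table:
        hit = {f"cluster{membership[f].cluster_id}"
               for f in row.fragments if f in membership}
        for unit in hit:
            counts[unit] = counts.get(unit, 0) + 1
    return counts


def enrich(
    foreground: FragmentTable,
    background: FragmentTable,
    clusters: list[FragmentCluster] | None = None,
    universe: str = "occurrences",
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of foreground units against a background.

    Only units present in the foreground are tested (absent units would
    contribute p = 1 hypotheses and inflate the correction); BH runs
    across all tested units; the result list is sorted by ascending
    p-value, ties by unit name.  A foreground fragment missing from the
    background is fatal.  If ``clusters`` is given they must cover every
    background fragment and the test runs at cluster level.
    """
    if universe not in UNIVERSES:
        raise ValueError(f"universe must be one of {UNIVERSES}")
    bg_universe = background.fragment_universe()
    missing = sorted(foreground.fragment_universe() - bg_universe)
    if missing:
        raise InputError(
            "foreground fragment(s) absent from background: "
            + ", ".join(missing[:5])
            + ("..." if len(missing) > 5 else "")
        )
    if clusters is not None:
        covered = set().union(*(c.members for c in clusters)) if clusters else set()
        uncovered = sorted(bg_universe - covered)
        if uncovered:
            raise InputError(
                "cluster partition does not cover background fragment(s): "
                + ", ".join(uncovered[:5])
            )

    fg_counts = _unit_counts(foreground, clusters)
    bg_counts = _unit_counts(background, clusters)

    if universe == "occurrences":
        N = sum(bg_counts.values())
        n = sum(fg_counts.values())
    else:
        N = len(background)
        n = len(foreground)

    cluster_of = (
        {f"cluster{c.cluster_id}": c for c in clusters} if clusters else {}
    )
    results: list[EnrichmentResult] = []
    for unit, k in fg_counts.items():
        K = bg_counts.get(unit, 0)
        cluster = cluster_of.get(unit)
        results.append(
            EnrichmentResult(
                unit=cluster.representative if cluster else unit,
                cluster_id=cluster.cluster_id if cluster else None,
                k=k, n=n, K=K, N=N,
                p_value=hypergeometric_upper_tail(k, K, n, N),
            )
        )
    fdrs = benjamini_hochberg([r.p_value for r in results])
    for r, fdr in zip(results, fdrs):
        r.fdr = fdr
    results.sort(key=lambda r: (r.p_value, r.unit))
    logger.info(
        "tested %d unit(s) in the %s universe (n=%d of N=%d)",
        len(results), universe, n, N,
    )
    return results


def molecule_universe_enrich(
    foreground: FragmentTable,
    background: FragmentTable,
    clusters: list[FragmentCluster] | None = None,
) -> list[EnrichmentResult]:
    """Enrichment with molecules as the sampled population (GO-style)."""
    return enrich(foreground, background, clusters, universe="molecules")
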