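"""Over-representation analysis with annotation clustering.

Per-term significance is the upper-tail hypergeometric probability of the
query/term overlap within a gene universe, Benjamini-Hochberg adjusted across
terms.  Related terms are grouped into annotation clusters by linking any two
terms whose gene-membership indicator vectors over the universe agree with
Cohen's kappa at or above a threshold; a cluster's enrichment score is
-log10 of the geometric mean of its members' raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

__all__ = ["AnnotationCluster", "hypergeom_p", "enrich", "cluster_terms",
           "membership_kappa"]

DEFAULT_KAPPA_THRESHOLD = 0.5


def hypergeom_p(overlap: int, query_size: int, term_size: int, universe_size: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap)."""
    if not 0 <= overlap <= min(query_size, term_size):
        raise ValueError("overlap must be <= min(query_size, term_size) and >= 0")
    if term_size > universe_size or query_size > universe_size:
        raise ValueError("term and query must fit in the universe")
    if overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe_size, term_size, query_size))


def enrich(
    query: set[str], gmt: GeneSetCollection, universe: set[str]
) -> pd.DataFrame:
    """Hypergeometric over-representation of every term against a query.

    Terms are intersected with the universe first; terms disjoint from the
    universe are omitted.  Results carry the overlapping member genes and are
    sorted by raw p (term ID breaking ties), with Benjamini-Hochberg adjusted
    p-values across the tested terms.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")

    rows = []
    for term in gmt.term_ids:
        members = gmt.members[term] & universe
        if not members:
            continue
        hits = members & query
        p = hypergeom_p(len(hits), len(query), len(members), len(universe))
        rows.append(
            {
                "term_id": term,
                "term_name": gmt.term_names[term],
                "query_size": len(query),
                "universe_size": len(universe),
                "term_size": len(members),
                "overlap": len(hits),
                "p_value": p,
                "members": frozenset(members),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term_id", "term_name", "query_size", "universe_size",
                "term_size", "overlap", "p_value", "p_adjusted", "members",
            ]
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df = df.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    return df[
        ["term_id", "term_name", "query_size", "universe_size", "term_size",
         "overlap", "p_value", "p_adjusted", "members"]
    ]


def membership_kappa(
    a: frozenset[str] | set[str], b: frozenset[str] | set[str], universe_size: int
) -> float:
    """Cohen's kappa between two gene-membership indicators over the universe."""
    if universe_size < 1:
        raise ValueError("universe_size must be >= 1")
    both = len(a & b)
    only_a = len(a) - both
    only_b = len(b) - both
    neither = universe_size - both - only_a - only_b
    if neither < 0:
        raise ValueError("sets exceed the universe")
    po = (both + neither) / universe_size
    pe = (
        (both + only_a) * (both + only_b) + (only_b + neither) * (only_a + neither)
    ) / universe_size**2
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


@dataclass(frozen=True)
class AnnotationCluster:
    """Terms grouped by shared gene membership, with a summary score.

    ``enrichment_score`` is -log10 of the geometric mean of the member terms'
    raw p-values (equivalently the mean of their -log10 p).
    """

    term_ids: tuple[str, ...]
    enrichment_score: float


def cluster_terms(
    results: pd.DataFrame, kappa_threshold: float = DEFAULT_KAPPA_THRESHOLD
) -> list[AnnotationCluster]:
    """Group enriched terms into annotation clusters by membership agreement.

    Terms are linked when the Cohen's kappa of their member-gene indicator
    vectors over the universe reaches ``kappa_threshold``; clusters are the
    connected components of the link graph, scored by -log10 geometric-mean p
    and returned in decreasing score order (ties by first term ID).  The
    result is invariant to the input order of terms.
    """
    if results.empty:
        return []
    terms = sorted(results["term_id"])
    row = results.set_index("term_id")
    universe_size = int(row["universe_size"].iloc[0])

    parent = {t: t for t in terms}

    def find(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for i, t1 in enumerate(terms):
        for t2 in terms[i + 1 :]:
            k = membership_kappa(row.loc[t1, "members"], row.loc[t2, "members"],
                                 universe_size)
            if k >= kappa_threshold:
                parent[find(t1)] = find(t2)

    groups: dict[str, list[str]] = {}
    for t in terms:
        groups.setdefault(find(t), []).append(t)

    clusters = []
    for members in groups.values():
        members = sorted(members)
        logs = -np.log10(row.loc[members, "p_value"].astype(float).to_numpy())
        clusters.append(AnnotationCluster(tuple(members), float(logs.mean())))
    clusters.sort(key=lambda c: (-c.enrichment_score, c.term_ids[0]))
    return clusters
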