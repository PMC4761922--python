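"""Hypergeometric over-representation of annotation terms per cluster and the
dominant-term call reported as "k of n"."""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_test(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric p-value, summed in log space.

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n) — the chance of
    drawing at least k annotated genes in a size-n draw from a universe of N
    genes of which K carry the term.
    """
    if not (0 <= k <= min(K, n) <= N) or n > N or K > N or min(N, K, n, k) < 0:
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def enrich_cluster(
    cluster_members: Iterable[str],
    annotations: pd.DataFrame,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Test every term with >= 1 universe gene against one cluster.

    Returns one row per term with the hypergeometric p, BH-adjusted p across
    the cluster's tested terms, and a ``dominant`` flag on the single best
    term (smallest adjusted p; ties broken by larger overlap k, then
    lexicographic term_id).  Clusters with no annotated members yield no
    dominant term.
    """
    members = {str(m).upper() for m in cluster_members}
    if not members:
        raise ValueError("empty cluster")
    universe_set = {str(u).upper() for u in universe}
    if not members <= universe_set:
        raise ValueError(f"cluster members outside universe: {sorted(members - universe_set)[:5]}")

    N = len(universe_set)
    n = len(members)
    rows = []
    for (term_id, term_name, namespace), sub in annotations.groupby(
        ["term_id", "term_name", "namespace"], sort=True
    ):
        term_genes = set(sub["gene_symbol"]) & universe_set
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & members)
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "namespace": namespace,
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "p_value": hypergeom_test(N, K, n, k),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "namespace", "N", "K", "n", "k", "p_value"],
    )
    if out.empty:
        logger.info("no terms with universe genes; nothing to test")
        out["adjusted_p"] = pd.Series(dtype=float)
        out["dominant"] = pd.Series(dtype=bool)
        return out
    out["adjusted_p"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    out["dominant"] = False
    testable = out[out["k"] >= 1]
    if testable.empty:
        logger.info("cluster has no annotated members; no dominant term called")
    else:
        best = testable.sort_values(
            ["adjusted_p", "k", "term_id"], ascending=[True, False, True]
        ).index[0]
        out.loc[best, "dominant"] = True
    return out.reset_index(drop=True)


def dominant_call(enrichment: pd.DataFrame) -> dict | None:
    """The figure-style summary of a cluster's dominant term: 'k of n'."""
    dom = enrichment[enrichment["dominant"]]
    if dom.empty:
        return None
    row = dom.iloc[0]
    return {
        "term_id": row["term_id"],
        "term_name": row["term_name"],
        "k": int(row["k"]),
        "n": int(row["n"]),
        "adjusted_p": float(row["adjusted_p"]),
        "label": f"{row['term_name']} ({int(row['k'])} of {int(row['n'])})",
    }


def enrich_clusters(
    clusters: list[list[str]],
    annotations: pd.DataFrame,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Per-cluster enrichment over a ranked cluster list (1-based ranks)."""
    frames = []
    universe_set = {str(u).upper() for u in universe}
    for rank, members in enumerate(clusters, start=1):
        res = enrich_cluster(members, annotations, universe_set)
        res.insert(0, "cluster_rank", rank)
        frames.append(res)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
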