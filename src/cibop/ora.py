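"""Over-representation analysis of a hit list against gene sets.

For a hit list of size *n* drawn from a background of *N* symbols and a term
covering *K* background symbols with *k* hits in the overlap, reports

* the exact one-sided hypergeometric tail ``p = P(X >= k)`` (identical to a
  one-sided Fisher exact test on the 2x2 table), and
* the normal-approximation Z-score with finite-population correction::

      z = (k - n*K/N) / sqrt(n * (K/N) * (1 - K/N) * (N - n)/(N - 1))

A term is called enriched when ``z > z_threshold`` (default 1.96, the
two-sided 5% normal quantile).  The exact p is reported alongside; the two
criteria differ for small terms, so a strict-Fisher mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigurationError, TermCollection, fold_symbol

log = logging.getLogger(__name__)


@dataclass
class ORAResult:
    term_id: str
    k: int          # overlap of hits with the term (within background)
    n: int          # hit-list size within background
    K: int          # term size within background
    N: int          # background size
    p_one_sided: float
    z_score: float  # NaN when undefined (K == 0 or K == N or n == N)
    enriched: bool


def _fold_set(symbols) -> set[str]:
    return {fold_symbol(s) for s in symbols if str(s).strip()}


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact ``P(X >= k)`` for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def z_score(k: int, N: int, K: int, n: int) -> float:
    """Finite-population-corrected normal Z for the overlap count."""
    if N <= 1:
        return float("nan")
    var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1)
    if var <= 0:
        return float("nan")
    return (k - n * K / N) / np.sqrt(var)


def ora_test(hits, background, term_symbols, z_threshold: float = 1.96) -> ORAResult:
    """Test one term.  Hits outside the background are dropped (with a
    logged count); the term is intersected with the background before
    counting."""
    bg = _fold_set(background)
    if not bg:
        raise ConfigurationError("empty background")
    hit_set = _fold_set(hits)
    outside = hit_set - bg
    if outside:
        log.info("ora_test: %d hit symbols outside background dropped", len(outside))
    hit_set &= bg
    if not hit_set:
        raise ConfigurationError("no hits remain within the background")
    term = _fold_set(term_symbols) & bg
    k = len(hit_set & term)
    n, K, N = len(hit_set), len(term), len(bg)
    p = hypergeom_upper_tail(k, N, K, n)
    z = z_score(k, N, K, n)
    return ORAResult(
        term_id="", k=k, n=n, K=K, N=N, p_one_sided=p, z_score=z,
        enriched=bool(np.isfinite(z) and z > z_threshold),
    )


def run_ora(
    hits,
    background,
    terms: TermCollection,
    z_threshold: float = 1.96,
    strict_fisher: bool = False,
    add_fdr: bool = False,
) -> pd.DataFrame:
    """Test every term in a collection; returns a table sorted by Z
    descending.

    The ``enriched`` flag follows the Z rule by default (``z > z_threshold``)
    or, with ``strict_fisher``, the exact tail (``p <= 0.05``).  Terms whose
    Z is undefined (term covers none or all of the background) are excluded
    with ``z_defined = False``.  ``add_fdr`` appends Benjamini-Hochberg
    q-values over the defined terms.
    """
    if len(terms) == 0:
        log.warning("run_ora: empty term collection")
        return pd.DataFrame(
            columns=["k", "n", "K", "N", "p_one_sided", "z_score", "z_defined", "enriched"]
        )
    rows = []
    for term_id, symbols in terms.items():
        res = ora_test(hits, background, symbols, z_threshold)
        rows.append(
            {
                "term_id": term_id,
                "k": res.k,
                "n": res.n,
                "K": res.K,
                "N": res.N,
                "p_one_sided": res.p_one_sided,
                "z_score": res.z_score,
                "z_defined": np.isfinite(res.z_score),
                "enriched": (
                    res.p_one_sided <= 0.05 if strict_fisher else res.enriched
                ),
            }
        )
    table = pd.DataFrame(rows).set_index("term_id")
    table.loc[~table["z_defined"], "enriched"] = False
    if add_fdr:
        defined = table["z_defined"]
        q = np.full(len(table), np.nan)
        q[defined.to_numpy()] = stats.false_discovery_control(
            table.loc[defined, "p_one_sided"], method="bh"
        )
        table["q_value"] = q
    return table.sort_values("z_score", ascending=False, na_position="last")


def z_matrix(ora_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-list ORA results into a terms x lists Z-score matrix, the
    heatmap statistic for comparing enrichment across protein lists."""
    cols = {name: tab["z_score"] for name, tab in ora_tables.items()}
    return pd.DataFrame(cols)
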