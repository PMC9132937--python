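"""Two-group differential enrichment: the volcano-plot computation.

Per protein, an unpaired two-sided t-test (Student pooled-variance by
default, matching Perseus; Welch available) between two sample groups on
log2 intensities, with ``log2_fc = mean(A) - mean(B)``.  Proteins are
classified as enriched when they pass a fold-change threshold (default
2-fold) together with an unadjusted p threshold (default 0.05), boundary
inclusive.  No multiple-testing correction by default; Benjamini-Hochberg
q-values are an opt-in column.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigurationError, FormatError, IntensityMatrix

log = logging.getLogger(__name__)

#: p-value substituted when group variances are zero but means differ; the
#: evidence is formally infinite, so the statistic is capped and flagged
P_DEGENERATE = float(np.finfo(float).tiny)


def select_samples(design: pd.DataFrame, selector) -> list[str]:
    """Resolve a group selector to sample ids.

    ``selector`` may be a list of sample ids, a boolean Series over the
    design index, or a dict of design-column -> value (all must match,
    e.g. ``{"genotype": "labeled"}``).
    """
    if isinstance(selector, dict):
        mask = pd.Series(True, index=design.index)
        for col, val in selector.items():
            vals = (val,) if isinstance(val, str) else tuple(val)
            mask &= design[col].isin(vals)
        ids = list(design.index[mask])
    elif isinstance(selector, pd.Series):
        ids = list(design.index[selector.reindex(design.index, fill_value=False)])
    else:
        ids = list(selector)
    if not ids:
        raise ConfigurationError(f"selector {selector!r} matches no samples")
    return ids


def two_group_test(
    matrix: IntensityMatrix,
    design: pd.DataFrame,
    group_a,
    group_b,
    variant: str = "student",
) -> pd.DataFrame:
    """Per-protein two-sided unpaired t-test between groups A and B.

    Returns a DataFrame indexed by protein with columns ``log2_fc`` (A - B),
    ``t_stat``, ``p_value``, ``n_A``, ``n_B``, ``degenerate`` (zero-variance
    flag).  Requires a fully observed (post-imputation) matrix.
    """
    if variant not in ("student", "welch"):
        raise ConfigurationError(f"unknown t-test variant {variant!r}")
    a_ids = select_samples(design, group_a)
    b_ids = select_samples(design, group_b)
    overlap = set(a_ids) & set(b_ids)
    if overlap:
        raise ConfigurationError(f"groups overlap in samples {sorted(overlap)}")
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ConfigurationError(
            f"both groups need >=2 samples (got {len(a_ids)}, {len(b_ids)})"
        )
    A = matrix.values[a_ids].to_numpy(float)
    B = matrix.values[b_ids].to_numpy(float)
    if np.isnan(A).any() or np.isnan(B).any():
        raise FormatError("matrix has missing values; impute before testing")

    nA, nB = A.shape[1], B.shape[1]
    mA, mB = A.mean(axis=1), B.mean(axis=1)
    vA = A.var(axis=1, ddof=1)
    vB = B.var(axis=1, ddof=1)
    diff = mA - mB

    if variant == "student":
        sp2 = ((nA - 1) * vA + (nB - 1) * vB) / (nA + nB - 2)
        se = np.sqrt(sp2 * (1.0 / nA + 1.0 / nB))
        df = np.full_like(se, nA + nB - 2)
    else:
        se = np.sqrt(vA / nA + vB / nB)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (vA / nA + vB / nB) ** 2 / (
                (vA / nA) ** 2 / (nA - 1) + (vB / nB) ** 2 / (nB - 1)
            )

    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero variance, equal means: no evidence either way -> t=0, p=1;
    # zero variance, unequal means: capped at machine tiny and flagged
    zero_eq = degenerate & (diff == 0)
    zero_ne = degenerate & (diff != 0)
    t[zero_eq], p[zero_eq] = 0.0, 1.0
    t[zero_ne] = np.sign(diff[zero_ne]) * np.inf
    p[zero_ne] = P_DEGENERATE
    if zero_ne.any():
        log.warning("%d proteins with zero variance and unequal means", zero_ne.sum())

    return pd.DataFrame(
        {
            "log2_fc": diff,
            "t_stat": t,
            "p_value": p,
            "n_A": nA,
            "n_B": nB,
            "degenerate": degenerate,
        },
        index=matrix.protein_ids,
    )


def classify(
    table: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    add_fdr: bool = False,
) -> pd.DataFrame:
    """Assign enrichment classes by the inclusive fold-change + p rule.

    ``enriched_A`` iff ``log2_fc >= log2(fc_threshold)`` and
    ``p <= p_threshold``; symmetric for ``enriched_B``; otherwise ``ns``.
    With ``add_fdr`` a Benjamini-Hochberg ``q_value`` column is appended
    (informational; classification still uses the unadjusted p).
    """
    if fc_threshold <= 1:
        raise ConfigurationError("fc_threshold must be > 1")
    if not 0 < p_threshold <= 1:
        raise ConfigurationError("p_threshold must be in (0, 1]")
    lfc = np.log2(fc_threshold)
    out = table.copy()
    sig = out["p_value"] <= p_threshold
    cls = np.where(
        sig & (out["log2_fc"] >= lfc),
        "enriched_A",
        np.where(sig & (out["log2_fc"] <= -lfc), "enriched_B", "ns"),
    )
    out["class"] = cls
    if add_fdr:
        out["q_value"] = stats.false_discovery_control(out["p_value"], method="bh")
    return out


#: cap applied to -log10 p for plotting when p underflows
NEGLOG10_CAP = 320.0


def volcano_export(
    table: pd.DataFrame,
    tsv_path=None,
    plot_path=None,
    labels: dict[str, str] | None = None,
    title: str = "",
) -> pd.DataFrame:
    """Export a classified table sorted by p, optionally with a volcano plot.

    ``labels`` maps protein ids to display names (e.g., marker proteins).
    Returns the sorted table (with a ``neg_log10_p`` column, capped at
    ``NEGLOG10_CAP`` for degenerate p-values; caps are logged).
    """
    if "class" not in table.columns:
        raise ConfigurationError("classify() the table before exporting")
    out = table.sort_values("p_value", kind="stable").copy()
    with np.errstate(divide="ignore"):
        neglog = -np.log10(out["p_value"].to_numpy())
    capped = neglog > NEGLOG10_CAP
    if capped.any():
        log.info("volcano_export: capped -log10 p for %d proteins", capped.sum())
    out["neg_log10_p"] = np.minimum(neglog, NEGLOG10_CAP)
    if tsv_path is not None:
        out.to_csv(tsv_path, sep="\t", index_label="protein_group_id")
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        colors = {"enriched_A": "tab:orange", "enriched_B": "tab:blue", "ns": "0.7"}
        fig, ax = plt.subplots(figsize=(5, 4))
        for cls, sub in out.groupby("class"):
            ax.scatter(sub["log2_fc"], sub["neg_log10_p"], s=8,
                       c=colors.get(cls, "k"), label=cls, alpha=0.7, lw=0)
        for pid, name in (labels or {}).items():
            if pid in out.index:
                row = out.loc[pid]
                ax.annotate(name, (row["log2_fc"], row["neg_log10_p"]), fontsize=7)
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 p")
        ax.set_title(title)
        ax.legend(fontsize=7, frameon=False)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return out
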