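"""Regional signature detection and multivariate structure.

One-vs-rest core signatures: a protein belongs to a region's core signature
when its mean log2 abundance in that region exceeds the pooled remaining
regions by at least log2(fc_core) (default 4-fold) at p <= 0.05.  Region
groups are configurable (e.g., cortex and hippocampus merged, since those
samples cluster together in principal-component space).  A protein that
qualifies in several regions is assigned to the region of maximal fold
change and flagged.

Also here: K-means regional expression profiles (on row-standardized
matrices), enriched-vs-background core-marker overlap, PCA over samples,
average-linkage hierarchical clustering on one-minus-Pearson distance,
annotation-list intersection (e.g., druggable targets), and the joint
MS + immunoassay feature x region matrix that feeds a 2-D embedding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import ConfigurationError, FormatError, IntensityMatrix, fold_symbol
from .enrichment import classify, two_group_test

log = logging.getLogger(__name__)


@dataclass
class RegionalSignatureSet:
    """Per-region core-signature tables plus the thresholds that built them.

    ``tables`` maps region-group label -> DataFrame (indexed by protein)
    with the one-vs-rest ``log2_fc`` and ``p_value``.  ``multi_assigned``
    records proteins that passed thresholds in more than one region (kept
    only under their max-fold region).
    """

    tables: dict[str, pd.DataFrame]
    fc_core: float
    p_threshold: float
    multi_assigned: dict[str, list[str]] = field(default_factory=dict)

    @property
    def regions(self) -> list[str]:
        return list(self.tables)

    def proteins(self, region: str) -> list[str]:
        return list(self.tables[region].index)

    def symbols(self, region: str, meta: pd.DataFrame | None = None) -> set[str]:
        ids = self.proteins(region)
        if meta is None:
            return {fold_symbol(i) for i in ids}
        return {fold_symbol(s) for s in meta.loc[ids, "gene_symbol"] if str(s).strip()}

    def total_size(self) -> int:
        return sum(len(t) for t in self.tables.values())


def _region_groups(design: pd.DataFrame, sample_ids, region_groups=None) -> dict[str, list[str]]:
    """Resolve region grouping to {group label: sample ids}."""
    regions = design.loc[sample_ids, "region"]
    if region_groups is None:
        region_groups = {r: [r] for r in pd.unique(regions)}
    out = {}
    for label, members in region_groups.items():
        ids = [s for s in sample_ids if regions[s] in members]
        out[label] = ids
    covered = {s for ids in out.values() for s in ids}
    uncovered = [s for s in sample_ids if s not in covered]
    if uncovered:
        raise ConfigurationError(f"samples not covered by region groups: {uncovered}")
    return out


def core_signatures(
    matrix: IntensityMatrix,
    design: pd.DataFrame,
    region_groups: dict[str, list[str]] | None = None,
    fc_core: float = 4.0,
    p_threshold: float = 0.05,
    variant: str = "student",
) -> RegionalSignatureSet:
    """One-vs-rest core regional signatures on a bait-normalized matrix.

    For each region group, runs the two-group test of that group's samples
    against all remaining samples pooled, and keeps proteins with
    ``log2_fc >= log2(fc_core)`` and ``p <= p_threshold``.
    """
    groups = _region_groups(design, list(matrix.sample_ids), region_groups)
    if len(groups) < 2:
        raise ConfigurationError("need >=2 region groups")
    small = [g for g, ids in groups.items() if len(ids) < 2]
    if small:
        raise ConfigurationError(f"region groups with <2 samples: {small}")

    lfc = np.log2(fc_core)
    candidate: dict[str, pd.DataFrame] = {}
    for label, ids in groups.items():
        rest = [s for s in matrix.sample_ids if s not in ids]
        tab = two_group_test(matrix, design, ids, rest, variant=variant)
        hit = tab[(tab["log2_fc"] >= lfc) & (tab["p_value"] <= p_threshold)]
        candidate[label] = hit[["log2_fc", "t_stat", "p_value"]].copy()

    # a protein qualifying in >1 region goes to its max-fold region
    owner: dict[str, str] = {}
    best: dict[str, float] = {}
    multi: dict[str, list[str]] = {}
    for label, tab in candidate.items():
        for pid, fc in tab["log2_fc"].items():
            if pid not in owner or fc > best[pid]:
                owner[pid], best[pid] = label, fc
            multi.setdefault(pid, []).append(label)
    multi = {pid: labs for pid, labs in multi.items() if len(labs) > 1}
    if multi:
        log.warning("%d proteins qualified in multiple regions; assigned to max fold", len(multi))
    tables = {
        label: tab.loc[[p for p in tab.index if owner[p] == label]]
        for label, tab in candidate.items()
    }
    return RegionalSignatureSet(tables, fc_core, p_threshold, multi)


def zscore_rows(values: pd.DataFrame, on_constant: str = "zero") -> pd.DataFrame:
    """Standardize each row to mean 0, sd 1 across columns.

    Constant rows have undefined z-scores; ``on_constant`` chooses ``"zero"``
    (set to 0 with a warning), ``"drop"``, or ``"error"``.
    """
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0)
    const = sd == 0
    if const.any():
        names = list(values.index[const])
        if on_constant == "error":
            raise FormatError(f"constant rows have undefined z-scores: {names[:10]}")
        if on_constant == "drop":
            log.warning("dropping %d constant rows", const.sum())
            values, mu, sd = values[~const], mu[~const], sd[~const]
        else:
            log.warning("%d constant rows z-scored to 0", const.sum())
            sd = sd.mask(const, 1.0)
    return values.sub(mu, axis=0).div(sd, axis=0)


def kmeans_profiles(
    matrix: IntensityMatrix,
    k: int = 5,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[pd.Series, pd.DataFrame]:
    """K-means clustering of row-standardized protein profiles.

    Returns ``(assignments, centroids)``: per-protein cluster labels (0..k-1)
    and the k x samples centroid matrix.  Deterministic for a fixed seed;
    the best of ``n_restarts`` initialisations (lowest within-cluster sum of
    squares) is kept.  Empty or duplicated centroids (degenerate inputs such
    as all-identical rows) are flagged in the log.
    """
    from sklearn.cluster import KMeans

    if k > matrix.n_proteins:
        raise ConfigurationError(f"k={k} exceeds {matrix.n_proteins} proteins")
    Z = zscore_rows(matrix.values, on_constant="zero")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(Z.to_numpy())
    n_eff = len(np.unique(labels))
    if n_eff < k:
        log.warning("only %d of %d clusters populated", n_eff, k)
    cent = np.round(km.cluster_centers_, 12)
    if len(np.unique(cent, axis=0)) < k:
        log.warning("duplicated centroids detected (degenerate structure)")
    assignments = pd.Series(labels, index=matrix.protein_ids, name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_, columns=matrix.sample_ids)
    return assignments, centroids


def overlap_with_background(
    enriched_sig: RegionalSignatureSet,
    background_sig: RegionalSignatureSet,
    enriched_meta: pd.DataFrame | None = None,
    background_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-region overlap of cell-type-enriched core markers with the bulk
    (background) proteome's core markers.

    Returns one row per region with ``n_enriched_core``, ``n_background_core``,
    ``n_intersection``, ``percent_overlap`` (100 * intersection / enriched),
    and the symbols exclusive to the enriched proteome.
    """
    if set(enriched_sig.regions) != set(background_sig.regions):
        raise ConfigurationError(
            f"region sets differ: {sorted(enriched_sig.regions)} vs "
            f"{sorted(background_sig.regions)}"
        )
    rows = []
    for region in enriched_sig.regions:
        e = enriched_sig.symbols(region, enriched_meta)
        b = background_sig.symbols(region, background_meta)
        inter = e & b
        pct = 100.0 * len(inter) / len(e) if e else float("nan")
        rows.append(
            {
                "region": region,
                "n_enriched_core": len(e),
                "n_background_core": len(b),
                "n_intersection": len(inter),
                "percent_overlap": pct,
                "exclusive_to_enriched": ";".join(sorted(e - b)),
            }
        )
    return pd.DataFrame(rows).set_index("region")


def pca(matrix: IntensityMatrix) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Principal components of samples (observations) over proteins
    (features, centered).

    Returns ``(scores, loadings, variance_fractions)`` where scores are
    samples x components, loadings proteins x components, and the fractions
    sum to 1 over all retained components (eigenvalue order, hence
    non-increasing).  Sign convention: each component's largest-magnitude
    loading is positive.
    """
    if matrix.n_samples < 2:
        raise ConfigurationError("PCA needs >=2 samples")
    if matrix.values.isna().any().any():
        raise FormatError("PCA needs a fully observed matrix")
    X = matrix.values.to_numpy(float).T  # samples x proteins
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    keep = S > S.max() * 1e-12 if S.max() > 0 else S > -1
    U, S, Vt = U[:, keep], S[keep], Vt[keep]
    # fix signs so the largest-|loading| of each component is positive
    flip = np.sign(Vt[np.arange(len(S)), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    frac = S**2 / (S**2).sum()
    comp = [f"PC{i+1}" for i in range(len(S))]
    scores = pd.DataFrame(U * S, index=matrix.sample_ids, columns=comp)
    loadings = pd.DataFrame(Vt.T, index=matrix.protein_ids, columns=comp)
    return scores, loadings, frac


def correlation_distance(values: pd.DataFrame, axis: str = "columns") -> pd.DataFrame:
    """One-minus-Pearson distance matrix between columns (samples) or rows.

    d(x, y) = 1 - r(x, y), in [0, 2].  Items with zero variance have an
    undefined correlation and are an error.
    """
    data = values if axis == "columns" else values.T
    sd = data.std(axis=0, ddof=0)
    bad = list(sd.index[sd == 0])
    if bad:
        raise FormatError(f"constant items have undefined correlation: {bad[:10]}")
    r = data.corr(method="pearson")
    d = (1.0 - r).clip(lower=0.0, upper=2.0)
    np.fill_diagonal(d.to_numpy(), 0.0)
    return d


def hca(
    values: pd.DataFrame,
    axis: str = "columns",
    linkage_method: str = "average",
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage (UPGMA) hierarchical clustering on one-minus-Pearson
    distance.

    Returns the scipy linkage matrix and the dendrogram leaf order (item
    labels).  UPGMA merge heights are non-decreasing by construction.
    """
    d = correlation_distance(values, axis=axis)
    if d.shape[0] < 2:
        raise ConfigurationError("need >=2 items to cluster")
    Z = hierarchy.linkage(squareform(d.to_numpy(), checks=False), method=linkage_method)
    order = [d.index[i] for i in hierarchy.leaves_list(Z)]
    return Z, order


def annotate_with_list(
    proteins,
    reference_list,
    list_name: str = "reference",
    meta: pd.DataFrame | None = None,
    region_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Intersect protein symbols with an annotation list (e.g., druggable
    targets), case-folded; optional per-region breakdown."""
    ref = {fold_symbol(s) for s in reference_list if str(s).strip()}
    if not ref:
        raise ConfigurationError("empty reference list")
    ids = list(proteins)
    if meta is not None:
        symbol_of = {i: fold_symbol(meta.loc[i, "gene_symbol"]) for i in ids}
    else:
        symbol_of = {i: fold_symbol(i) for i in ids}
    rows = [
        {
            "protein_group_id": i,
            "symbol": symbol_of[i],
            "list_name": list_name,
            "region": (region_of or {}).get(i, ""),
        }
        for i in ids
        if symbol_of[i] in ref
    ]
    return pd.DataFrame(rows, columns=["protein_group_id", "symbol", "list_name", "region"])


def joint_signature_matrix(
    regional_means: pd.DataFrame,
    luminex_normalized: pd.DataFrame,
    embedder=None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Stack per-region protein-signature means with normalized immunoassay
    analytes into one z-scored feature x region matrix.

    Both inputs are features x regions over the same region labels.  Each
    feature is z-scored across regions; features constant across regions are
    dropped with a warning.  ``embedder``, if given, is a callable mapping
    the (features x regions) array to 2-D coordinates per feature (e.g., a
    t-SNE adapter); its output is returned as-is and only its shape is part
    of the contract.
    """
    if list(regional_means.columns) != list(luminex_normalized.columns):
        if set(regional_means.columns) == set(luminex_normalized.columns):
            luminex_normalized = luminex_normalized[regional_means.columns]
        else:
            raise ConfigurationError(
                f"region labels differ: {list(regional_means.columns)} vs "
                f"{list(luminex_normalized.columns)}"
            )
    if regional_means.shape[1] < 2:
        raise ConfigurationError("z-scores need >=2 regions")
    stacked = pd.concat([regional_means, luminex_normalized], axis=0)
    if not stacked.index.is_unique:
        raise FormatError("feature labels collide between proteins and analytes")
    Z = zscore_rows(stacked, on_constant="drop")
    coords = None
    if embedder is not None:
        xy = np.asarray(embedder(Z.to_numpy()))
        if xy.shape != (Z.shape[0], 2):
            raise FormatError(f"embedder returned shape {xy.shape}, expected ({Z.shape[0]}, 2)")
        coords = pd.DataFrame(xy, index=Z.index, columns=["dim1", "dim2"])
    return Z, coords


def tsne_embedder(seed: int = 0, perplexity: float = 5.0):
    """Seeded t-SNE adapter for :func:`joint_signature_matrix` (visualization
    only; coordinates are not a tested quantity beyond shape)."""
    def _embed(X: np.ndarray) -> np.ndarray:
        from sklearn.manifold import TSNE

        eff = min(perplexity, max(1.0, (X.shape[0] - 1) / 3.0))
        return TSNE(
            n_components=2, random_state=seed, perplexity=eff, init="pca"
        ).fit_transform(X)

    return _embed
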