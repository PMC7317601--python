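"""Weighted gene co-expression network analysis.

The construction follows the classic unsigned WGCNA recipe:

* similarity  S_XY = |cor(X, Y)|  (absolute Pearson correlation),
* adjacency   a_XY = S_XY ** beta, with beta chosen so the weighted degree
  distribution approximates a power law (scale-free topology fit),
* topological overlap
      w_XY = (l_XY + a_XY) / (min(k_X, k_Y) + 1 - a_XY),
      l_XY = sum_u a_Xu a_uY,   k_X = sum_u a_Xu,
* dissimilarity d_XY = 1 - w_XY, clustered by average linkage; modules are
  branches below a static cut height subject to a minimum size, with an
  optional hybrid step reattaching unassigned genes by eigengene correlation,
* module eigengenes (first principal component of the standardized module
  expression), eigengene-similarity merging, module-trait correlation, and
  per-gene module membership (MM) / gene significance (GS) screening.

Diagonal conventions: a_XX = 0 inside the k and l sums, w_XX is reported as 1
and the dissimilarity diagonal as 0, making dissTOM a valid dissimilarity.
Unassigned genes carry the label 0 ("grey").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress
from scipy.stats import t as t_dist


# ---------------------------------------------------------------------------
# helpers


def _as_matrix(x) -> tuple[np.ndarray, list | None]:
    """Return (values, labels) from a DataFrame or array."""
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), list(x.index)
    return np.asarray(x, dtype=float), None


def _wrap(values: np.ndarray, labels: list | None):
    if labels is None:
        return values
    return pd.DataFrame(values, index=labels, columns=labels)


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    return (values - mu) / sd


# ---------------------------------------------------------------------------
# network construction


def similarity(expr: pd.DataFrame) -> pd.DataFrame:
    """Absolute-Pearson-correlation similarity matrix of the gene rows.

    Raises if there are fewer than 3 samples or any gene has zero variance
    (the error names the offending gene).
    """
    values, genes = _as_matrix(expr)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples to compute correlations")
    sd = values.std(axis=1, ddof=1)
    if np.any(sd == 0):
        idx = int(np.argmax(sd == 0))
        name = genes[idx] if genes else str(idx)
        raise ValueError(f"gene {name!r} has zero variance")
    s = np.abs(np.corrcoef(values))
    np.clip(s, 0.0, 1.0, out=s)
    np.fill_diagonal(s, 1.0)
    return _wrap(s, genes)


def adjacency(sim, beta: int):
    """Soft-thresholded adjacency a_XY = S_XY ** beta, diagonal zeroed."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    values, genes = _as_matrix(sim)
    a = values**beta
    np.fill_diagonal(a, 0.0)
    return _wrap(a, genes)


def connectivity(adj) -> np.ndarray:
    """Weighted degree k_X = sum_u a_Xu of each gene."""
    values, _ = _as_matrix(adj)
    return values.sum(axis=1)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit of a connectivity vector.

    Bins the connectivity into ``n_bins`` equal-width bins, regresses
    log10 of the bin frequency p(k) on log10 of the bin's mean connectivity,
    and returns (signed R^2, slope) where the sign is the sign of the
    *negative* slope — a decaying degree distribution scores positively.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 3 or np.allclose(k, k[0]):
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            xs.append(k[mask].mean())
            ys.append(mask.mean())
    if len(xs) < 3:
        return 0.0, 0.0
    fit = linregress(np.log10(xs), np.log10(ys))
    signed_r2 = fit.rvalue**2 * np.sign(-fit.slope)
    return float(signed_r2), float(fit.slope)


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidates: list[int] | None = None,
    r2_cut: float = 0.8,
    n_bins: int = 10,
    sim: pd.DataFrame | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold exponent by scale-free topology fit.

    For each candidate beta the weighted connectivity is computed and its
    distribution scored by :func:`scale_free_fit`. Selection considers only
    candidates whose mean connectivity stays at or above 1 — beyond that
    point the network is essentially empty, the topological overlap saturates
    and the fit index is meaningless — and returns the smallest such
    candidate whose signed R^2 reaches ``r2_cut``, or the best-fitting one if
    none does, together with the fit table (beta, signed_R2, slope, mean_k).
    """
    if candidates is None:
        candidates = list(range(1, 21))
    if not candidates:
        raise ValueError("candidate list is empty")
    if sim is None:
        sim = similarity(expr)
    s, _ = _as_matrix(sim)
    rows = []
    for beta in candidates:
        a = s**beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        if np.all(k == 0):
            raise ValueError("all connectivities are zero")
        r2, slope = scale_free_fit(k, n_bins=n_bins)
        rows.append({"beta": beta, "signed_R2": r2, "slope": slope, "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    feasible = table[table["mean_k"] >= 1.0]
    if feasible.empty:
        feasible = table
    passing = feasible[feasible["signed_R2"] >= r2_cut]
    if len(passing):
        beta = int(passing["beta"].iloc[0])
    else:
        beta = int(feasible.loc[feasible["signed_R2"].idxmax(), "beta"])
    return beta, table


def topological_overlap(adj):
    """Topological overlap matrix of a soft-thresholded adjacency.

    w_XY = (l_XY + a_XY) / (min(k_X, k_Y) + 1 - a_XY) off the diagonal, with
    l_XY the shared-neighbor sum and k the weighted degree; diagonal set to 1.
    """
    a, genes = _as_matrix(adj)
    if a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must be in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # a_XX = 0, so u ranges over genes other than X and Y
    min_k = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore"):
        w = (l + a) / (min_k + 1.0 - a)
    np.fill_diagonal(w, 1.0)
    return _wrap(w, genes)


def dissimilarity(tom):
    """dissTOM = 1 - TOM with a zero diagonal."""
    w, genes = _as_matrix(tom)
    d = 1.0 - w
    np.fill_diagonal(d, 0.0)
    return _wrap(d, genes)


# ---------------------------------------------------------------------------
# module detection


def cluster_cut(
    diss,
    min_module_size: int = 10,
    cut_height: float | None = None,
    expr: pd.DataFrame | None = None,
    reattach: bool = False,
    reattach_floor: float = 0.3,
) -> np.ndarray:
    """Detect modules by static branch cutting of the average-linkage tree.

    Builds an average-linkage hierarchical tree on the dissimilarity, cuts it
    at a static height, discards branches smaller than ``min_module_size``
    (their genes get label 0), and renumbers modules by decreasing size. With
    ``cut_height=None`` the height is placed in the middle of the largest gap
    of the sorted merge heights, which separates the dense low-height regime
    where modules assemble from the near-ceiling regime where unrelated genes
    join — a choice that adapts to the soft-threshold exponent (the whole
    dissTOM scale compresses toward 1 as beta grows). With ``reattach=True``
    (the hybrid step) each unassigned gene is attached to the module whose
    eigengene it correlates with most strongly, provided that correlation
    reaches ``reattach_floor``; this needs ``expr``.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    d, _ = _as_matrix(diss)
    z = linkage(squareform(d, checks=False), method="average")
    if cut_height is None:
        heights = np.sort(z[:, 2])
        if len(heights) > 1:
            gaps = np.diff(heights)
            # a module of min_module_size genes needs min_module_size - 1
            # merges below the cut, so earlier gaps cannot yield a module
            lo = min(min_module_size - 1, len(gaps) - 1)
            i = lo + int(np.argmax(gaps[lo:]))
            cut_height = float((heights[i] + heights[i + 1]) / 2.0)
        else:
            cut_height = float(heights[0]) / 2.0
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = np.zeros(len(raw), dtype=int)
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_module_size]
    # renumber by decreasing size, ties by first occurrence in the gene order
    order = sorted(
        keep.index, key=lambda c: (-keep[c], int(np.argmax(raw == c)))
    )
    for new, old in enumerate(order, start=1):
        labels[raw == old] = new
    if reattach:
        if expr is None:
            raise ValueError("reattachment requires the expression matrix")
        labels = _reattach_grey(expr, labels, reattach_floor)
    return labels


def _reattach_grey(expr: pd.DataFrame, labels: np.ndarray, floor: float) -> np.ndarray:
    if labels.max() == 0:
        return labels
    me = module_eigengene(expr, labels)
    values, _ = _as_matrix(expr)
    zs = _standardize_rows(values)
    me_z = _standardize_rows(me.to_numpy())
    n = values.shape[1]
    cors = zs @ me_z.T / (n - 1)  # genes x modules
    out = labels.copy()
    module_ids = [int(name[2:]) for name in me.index]
    for i in np.flatnonzero(labels == 0):
        j = int(np.argmax(np.abs(cors[i])))
        if abs(cors[i, j]) >= floor:
            out[i] = module_ids[j]
    return out


def module_eigengene(expr: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """First-principal-component eigengene of each module (modules x samples).

    Member genes are standardized across samples; the ME is the first right
    singular vector rescaled to unit variance, signed so that it correlates
    positively with the module's mean standardized expression.
    """
    values, _ = _as_matrix(expr)
    labels = np.asarray(labels)
    modules = sorted(set(labels) - {0})
    if not modules:
        raise ValueError("no modules to summarize")
    rows = []
    for m in modules:
        member = values[labels == m]
        if member.shape[0] < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")
        zs = _standardize_rows(member)
        _, _, vt = np.linalg.svd(zs, full_matrices=False)
        me = vt[0]
        me = me / me.std(ddof=1)
        if np.corrcoef(me, zs.mean(axis=0))[0, 1] < 0:
            me = -me
        rows.append(me)
    cols = list(expr.columns) if isinstance(expr, pd.DataFrame) else None
    return pd.DataFrame(rows, index=[f"ME{m}" for m in modules], columns=cols)


def merge_modules(
    expr: pd.DataFrame,
    labels: np.ndarray,
    cut_height: float = 0.25,
    max_iter: int = 20,
) -> np.ndarray:
    """Merge modules whose eigengenes are similar.

    Eigengenes are clustered by average linkage on 1 - cor(ME_i, ME_j);
    clusters joined below ``cut_height`` are merged, eigengenes recomputed,
    and the procedure iterated to a fixed point. Labels are renumbered by
    decreasing module size.
    """
    if not (0.0 < cut_height < 1.0):
        raise ValueError("cut_height must be in (0, 1)")
    labels = np.asarray(labels).copy()
    for _ in range(max_iter):
        modules = sorted(set(labels) - {0})
        if len(modules) < 2:
            break
        me = module_eigengene(expr, labels).to_numpy()
        d = 1.0 - np.corrcoef(me)
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, None)
        z = linkage(squareform(d, checks=False), method="average")
        groups = fcluster(z, t=cut_height, criterion="distance")
        if len(set(groups)) == len(modules):
            break
        new_labels = np.zeros_like(labels)
        for gid in set(groups):
            members = [modules[i] for i in np.flatnonzero(groups == gid)]
            mask = np.isin(labels, members)
            new_labels[mask] = min(members)
        labels = new_labels
    return _renumber_by_size(labels)


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    out = np.zeros_like(labels)
    sizes = pd.Series(labels[labels > 0]).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], int(np.argmax(labels == c))))
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


# ---------------------------------------------------------------------------
# module-trait relationships


def _cor_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of a Pearson correlation via the t transform."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    return 2.0 * t_dist.sf(np.abs(t), df=n - 2)


def module_trait(me: pd.DataFrame, traits: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Correlate each module eigengene with each sample trait.

    Returns a long-form table (module, trait, r, p, significant) with the
    two-sided p from t = r * sqrt((n - 2) / (1 - r^2)).
    """
    missing = [s for s in me.columns if s not in traits.index]
    extra = [s for s in traits.index if s not in me.columns]
    if missing or extra:
        raise ValueError(
            f"sample mismatch between eigengenes and traits: missing={missing[:5]}, extra={extra[:5]}"
        )
    tr = traits.loc[list(me.columns)]
    n = me.shape[1]
    rows = []
    me_z = _standardize_rows(me.to_numpy())
    for col in tr.columns:
        tvec = tr[col].to_numpy(dtype=float)
        tz = (tvec - tvec.mean()) / tvec.std(ddof=1)
        r = me_z @ tz / (n - 1)
        p = _cor_pvalue(r, n)
        for module, ri, pi in zip(me.index, r, p):
            rows.append(
                {
                    "module": module,
                    "trait": col,
                    "r": float(ri),
                    "p": float(pi),
                    "significant": bool(pi < alpha),
                }
            )
    return pd.DataFrame(rows)


def gene_scores(
    expr: pd.DataFrame,
    me: pd.DataFrame,
    trait: pd.Series,
    labels: np.ndarray,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Module membership and gene significance of each assigned gene.

    MM is the correlation of a gene's expression with its own module's
    eigengene; GS its correlation with the trait. By default only assigned
    genes are scored; explicitly requesting an unassigned gene raises.
    """
    labels = np.asarray(labels)
    all_genes = list(expr.index)
    label_of = dict(zip(all_genes, labels))
    if genes is None:
        genes = [g for g, lab in zip(all_genes, labels) if lab != 0]
    else:
        grey = [g for g in genes if label_of.get(g, 0) == 0]
        if grey:
            raise ValueError(f"unassigned genes have no module membership: {grey[:5]}")
    values = expr.loc[genes].to_numpy(dtype=float)
    zs = _standardize_rows(values)
    n = values.shape[1]
    tvec = trait.loc[list(expr.columns)].to_numpy(dtype=float)
    tz = (tvec - tvec.mean()) / tvec.std(ddof=1)
    gs = zs @ tz / (n - 1)
    me_z = _standardize_rows(me.to_numpy())
    me_row = {int(name[2:]): i for i, name in enumerate(me.index)}
    mm = np.array(
        [
            float(zs[i] @ me_z[me_row[label_of[g]]] / (n - 1))
            for i, g in enumerate(genes)
        ]
    )
    return pd.DataFrame(
        {"gene": genes, "module": [label_of[g] for g in genes], "MM": mm, "GS": gs}
    )


def screen_key_genes(
    scores: pd.DataFrame,
    mm_thresh: float = 0.8,
    gs_thresh: float = 0.2,
    module: int | None = None,
) -> list[str]:
    """Key genes with |MM| > mm_thresh and |GS| > gs_thresh (strict).

    Optionally restricted to one designated module.
    """
    if not (0.0 <= mm_thresh <= 1.0 and 0.0 <= gs_thresh <= 1.0):
        raise ValueError("thresholds must be in [0, 1]")
    mask = (scores["MM"].abs() > mm_thresh) & (scores["GS"].abs() > gs_thresh)
    if module is not None:
        mask &= scores["module"] == module
    return sorted(scores.loc[mask, "gene"].astype(str))


# ---------------------------------------------------------------------------
# sample QC and the end-to-end run


def flag_outlier_samples(expr: pd.DataFrame, z_cut: float = -2.5) -> list[str]:
    """Samples whose average inter-sample correlation z-score falls below ``z_cut``."""
    c = np.corrcoef(expr.to_numpy(dtype=float).T)
    np.fill_diagonal(c, np.nan)
    avg = np.nanmean(c, axis=1)
    z = (avg - avg.mean()) / avg.std(ddof=1)
    return [s for s, zi in zip(expr.columns, z) if zi < z_cut]


@dataclass
class WGCNAResult:
    """Bundle of an end-to-end co-expression analysis."""

    beta: int
    fit_table: pd.DataFrame
    labels: pd.Series  # gene -> module label (0 = unassigned)
    eigengenes: pd.DataFrame  # modules x samples
    module_trait: pd.DataFrame
    scores: pd.DataFrame  # gene, module, MM, GS
    trait_module: int | None
    key_genes: list[str]


def run_wgcna(
    expr: pd.DataFrame,
    traits: pd.DataFrame,
    trait_column: str | None = None,
    beta: int | None = None,
    candidates: list[int] | None = None,
    r2_cut: float = 0.8,
    min_module_size: int = 10,
    cut_height: float | None = None,
    merge_cut_height: float = 0.25,
    mm_thresh: float = 0.8,
    gs_thresh: float = 0.2,
    reattach: bool = False,
    drop_outliers: bool = False,
) -> WGCNAResult:
    """Full co-expression analysis: network, modules, trait screen, key genes.

    The trait-linked module is the one attaining the largest |module-trait
    correlation| for ``trait_column`` (default: first trait column); key genes
    are screened within it.
    """
    if drop_outliers:
        bad = flag_outlier_samples(expr)
        if bad:
            expr = expr.drop(columns=bad)
            traits = traits.drop(index=[s for s in bad if s in traits.index])
    sim = similarity(expr)
    if beta is None:
        beta, fit_table = pick_soft_threshold(expr, candidates=candidates, r2_cut=r2_cut, sim=sim)
    else:
        _, fit_table = pick_soft_threshold(expr, candidates=[beta], r2_cut=r2_cut, sim=sim)
    adj = adjacency(sim, beta)
    tom = topological_overlap(adj)
    diss = dissimilarity(tom)
    labels = cluster_cut(
        diss, min_module_size=min_module_size, cut_height=cut_height,
        expr=expr, reattach=reattach,
    )
    if labels.max() >= 2:
        labels = merge_modules(expr, labels, cut_height=merge_cut_height)
    if labels.max() == 0:
        empty = pd.DataFrame(columns=["gene", "module", "MM", "GS"])
        return WGCNAResult(
            beta=beta, fit_table=fit_table,
            labels=pd.Series(labels, index=expr.index, name="module"),
            eigengenes=pd.DataFrame(columns=expr.columns),
            module_trait=pd.DataFrame(columns=["module", "trait", "r", "p", "significant"]),
            scores=empty, trait_module=None, key_genes=[],
        )
    me = module_eigengene(expr, labels)
    mt = module_trait(me, traits)
    if trait_column is None:
        trait_column = traits.columns[0]
    sub = mt[mt["trait"] == trait_column]
    best = sub.loc[sub["r"].abs().idxmax(), "module"]
    trait_module = int(str(best)[2:])
    scores = gene_scores(expr, me, traits[trait_column], labels)
    key = screen_key_genes(scores, mm_thresh=mm_thresh, gs_thresh=gs_thresh, module=trait_module)
    return WGCNAResult(
        beta=beta,
        fit_table=fit_table,
        labels=pd.Series(labels, index=expr.index, name="module"),
        eigengenes=me,
        module_trait=mt,
        scores=scores,
        trait_module=trait_module,
        key_genes=key,
    )
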