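"""Genome-wide gene-feature correlation screening and conditional-independence
analysis.

The screen computes Pearson correlations r(g, f) between log2(1+E) gene
expression and slide-level visual feature values over the held-out test
slides, selects pairs passing a correlation threshold R_T among genes passing
a log2 expression threshold E_T (maximum per-tissue median >= E_T), assesses
significance by permutation (N = 1000, with the +1 small-sample correction),
and probes whether a correlation is mediated by tissue identity using partial
correlations r(g, f | t):

* g-t-f indirect: g and f independent given tissue (partial-correlation
  t-test fails to reject at level alpha);
* f-g-t indirect: feature and tissue independent given the gene — tested by
  a block F-test of the tissue indicator columns after removing g;
* g-f-t indirect: gene and tissue independent given the feature (same form).

Reproducibility between datasets is summarized by the Pearson correlation of
the (Fisher-transformed) correlation vectors. Benjamini-Hochberg q-values
over permutation p-values are reported as a clearly supplementary extension;
the primary selection uses the fixed thresholds only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class Thresholds:
    r_t: float = 0.8            # correlation threshold
    e_t: float = 10.0           # log2 expression threshold on the max median
    alpha_ci: float = 0.01      # conditional-independence significance level
    n_perm: int = 1000

    def __post_init__(self):
        if not 0 < self.r_t < 1:
            raise ValueError("r_t must lie in (0, 1)")


def log2p1(expr: pd.DataFrame) -> pd.DataFrame:
    """The expression transform x = log2(1 + E)."""
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression must be non-negative")
    return np.log2(1.0 + expr)


def resolve_duplicates(expr: pd.DataFrame, sample_to_slide: pd.Series,
                       mode: str = "mean_log") -> pd.DataFrame:
    """Collapse duplicate expression samples to one column per slide.

    Duplicates are averaged on the log2(1+E) scale; the result is returned on
    that log scale (genes x slides), which is what every downstream step
    consumes.
    """
    if mode != "mean_log":
        raise ValueError(f"unknown duplicate-resolution mode {mode!r}")
    x = log2p1(expr)
    slides = sample_to_slide.reindex(x.columns)
    if slides.isna().any():
        missing = list(x.columns[slides.isna()])
        raise ValueError(f"samples without a slide mapping: {missing}")
    out = x.T.groupby(slides.to_numpy(), sort=False).mean().T
    out.columns.name = "slide_id"
    return out


# ---------------------------------------------------------------------------
# gene metadata and filtering
# ---------------------------------------------------------------------------

def gene_meta(expr_log: pd.DataFrame, slide_tissue: pd.Series) -> pd.DataFrame:
    """Per-gene tissue medians of log2(1+E): tissue_of_max and max_median."""
    tissues = slide_tissue.reindex(expr_log.columns)
    med = expr_log.T.groupby(tissues.to_numpy()).median().T
    return pd.DataFrame({
        "tissue_of_max": med.idxmax(axis=1),
        "max_median": med.max(axis=1),
    })


def gene_filter(meta: pd.DataFrame, e_t: float) -> pd.Index:
    """Genes expressed somewhere: maximum per-tissue median >= E_T.

    Genes whose expression is low in every tissue are excluded from the
    screen; a gene at exactly the threshold is kept.
    """
    return meta.index[meta["max_median"] >= e_t]


# ---------------------------------------------------------------------------
# correlation screening
# ---------------------------------------------------------------------------

def _standardize(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize; returns (z, constant-column mask)."""
    mu = a.mean(axis=0)
    sd = a.std(axis=0)
    const = sd == 0
    z = (a - mu) / np.where(const, 1.0, sd)
    z[:, const] = 0.0
    return z, const


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Plain two-variable Pearson correlation (NaN if either is constant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def correlate(expr_log: pd.DataFrame, feature_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson r(g, f) for every gene-feature pair over shared slides.

    ``expr_log`` is genes x slides (log scale, duplicates resolved);
    ``feature_matrix`` is slides x features. Pairs involving a constant gene
    or feature get NaN (excluded from all downstream counts).
    """
    shared = expr_log.columns.intersection(feature_matrix.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, have {len(shared)}")
    g = expr_log[shared].to_numpy(dtype=float).T       # n x genes
    f = feature_matrix.loc[shared].to_numpy(dtype=float)
    zg, cg = _standardize(g)
    zf, cf = _standardize(f)
    r = zg.T @ zf / len(shared)
    r[cg, :] = np.nan
    r[:, cf] = np.nan
    return pd.DataFrame(r, index=expr_log.index, columns=feature_matrix.columns)


def select_significant(r: pd.DataFrame, thresholds: Thresholds,
                       meta: pd.DataFrame, use_abs: bool = True
                       ) -> tuple[pd.DataFrame, dict]:
    """Pairs passing |r| >= R_T (or signed r >= R_T) among E_T-passing genes.

    Returns the pair table (gene, feature, r, tissue_of_max, max_median) and
    summary counts: pairs, unique genes, unique features, unique tissues
    (tissues counted through each gene's tissue of maximal expression).
    """
    genes = gene_filter(meta, thresholds.e_t).intersection(r.index)
    sub = r.loc[genes]
    score = sub.abs() if use_abs else sub
    gi, fi = np.nonzero((score >= thresholds.r_t).to_numpy() & sub.notna().to_numpy())
    pairs = pd.DataFrame({
        "gene": sub.index[gi],
        "feature": sub.columns[fi],
        "r": sub.to_numpy()[gi, fi],
    })
    pairs = pairs.join(meta.loc[pairs["gene"], ["tissue_of_max", "max_median"]]
                       .set_index(pairs.index))
    counts = {
        "pairs": len(pairs),
        "unique_genes": pairs["gene"].nunique(),
        "unique_features": pairs["feature"].nunique(),
        "unique_tissues": pairs["tissue_of_max"].nunique(),
    }
    return pairs, counts


def permutation_test(g: np.ndarray, f: np.ndarray, n_perm: int = 1000,
                     seed: int | np.random.Generator = 0) -> float:
    """Permutation p-value for |r(g, f)| with the +1 correction.

    Sample labels of g are permuted; p = (1 + #{|r_perm| >= |r_obs|}) /
    (n_perm + 1), so the smallest attainable p at N = 1000 is 1/1001.
    Degenerate (constant) inputs give p = 1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r_obs = pearson(g, f)
    if np.isnan(r_obs):
        return 1.0
    g = np.asarray(g, dtype=float)
    f = np.asarray(f, dtype=float)
    zg = (g - g.mean()) / g.std()
    zf = (f - f.mean()) / f.std()
    perms = np.stack([rng.permutation(zg) for _ in range(n_perm)])
    r_perm = perms @ zf / len(g)
    hits = int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12))
    return (1 + hits) / (n_perm + 1)


def add_permutation_p(pairs: pd.DataFrame, expr_log: pd.DataFrame,
                      feature_matrix: pd.DataFrame, n_perm: int = 1000,
                      seed: int = 0) -> pd.DataFrame:
    """Permutation p per selected pair plus supplementary BH q-values."""
    shared = expr_log.columns.intersection(feature_matrix.index)
    rng = np.random.default_rng(seed)
    ps = [permutation_test(expr_log.loc[row.gene, shared].to_numpy(),
                           feature_matrix.loc[shared, row.feature].to_numpy(),
                           n_perm, rng)
          for row in pairs.itertuples()]
    out = pairs.copy()
    out["perm_p"] = ps
    if len(out):
        out["q_bh"] = multipletests(out["perm_p"], method="fdr_bh")[1]
    else:
        out["q_bh"] = pd.Series(dtype=float)
    return out


# ---------------------------------------------------------------------------
# reproducibility across datasets
# ---------------------------------------------------------------------------

def fisher_z(r):
    """Variance-stabilizing Fisher transform z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("Fisher transform requires |r| < 1")
    return np.arctanh(r)


def reproducibility(r_a, r_b) -> dict[str, float]:
    """Agreement of two correlation vectors over the same (g, f) pairs, on
    the raw r scale and on the Fisher z scale."""
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    ok = np.isfinite(r_a) & np.isfinite(r_b)
    return {
        "r_scale": pearson(r_a[ok], r_b[ok]),
        "z_scale": pearson(fisher_z(r_a[ok]), fisher_z(r_b[ok])),
    }


# ---------------------------------------------------------------------------
# conditional independence given tissue
# ---------------------------------------------------------------------------

def _tissue_design(tissues: np.ndarray) -> np.ndarray:
    """Intercept + (k-1) tissue indicator columns."""
    levels = pd.unique(tissues)
    cols = [np.ones(len(tissues))]
    cols += [(tissues == lv).astype(float) for lv in levels[1:]]
    return np.column_stack(cols)


def partial_correlation(g: np.ndarray, f: np.ndarray,
                        tissues: np.ndarray) -> tuple[float, float]:
    """Partial correlation r(g, f | tissue) and its two-sided p-value.

    Both variables are residualized on the tissue indicator design by least
    squares (algebraically identical to centering within tissue groups); the
    test statistic is t = r sqrt((n - 2 - k) / (1 - r^2)) with k = #tissues-1
    conditioning covariates. With a single tissue level this reduces to the
    plain correlation and test.
    """
    g = np.asarray(g, dtype=float)
    f = np.asarray(f, dtype=float)
    tissues = np.asarray(tissues)
    n = len(g)
    d = _tissue_design(tissues)
    k = d.shape[1] - 1
    rg = g - d @ np.linalg.lstsq(d, g, rcond=None)[0]
    rf = f - d @ np.linalg.lstsq(d, f, rcond=None)[0]
    r = pearson(rg, rf)
    if np.isnan(r):
        return float("nan"), 1.0
    dof = n - 2 - k
    if dof <= 0:
        return r, 1.0
    r_c = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r_c * np.sqrt(dof / (1 - r_c ** 2))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(r), float(p)


def block_f_test(y: np.ndarray, covariate: np.ndarray,
                 tissues: np.ndarray) -> float:
    """p-value of the tissue indicator block in y ~ covariate + tissue.

    Used when the conditioned-on variable is scalar but the tested variable
    is the categorical tissue label: the (k-1) indicator columns are tested
    jointly with an F-statistic after removing the covariate.
    """
    y = np.asarray(y, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    n = len(y)
    d0 = np.column_stack([np.ones(n), covariate])
    d1 = np.column_stack([d0, _tissue_design(tissues)[:, 1:]])
    k = d1.shape[1] - d0.shape[1]
    if k == 0:
        return 1.0
    rss0 = float(np.sum((y - d0 @ np.linalg.lstsq(d0, y, rcond=None)[0]) ** 2))
    rss1 = float(np.sum((y - d1 @ np.linalg.lstsq(d1, y, rcond=None)[0]) ** 2))
    dof2 = n - d1.shape[1]
    if dof2 <= 0 or rss1 <= 0:
        return 1.0
    f_stat = ((rss0 - rss1) / k) / (rss1 / dof2)
    return float(stats.f.sf(f_stat, k, dof2))


def dependency_patterns(pairs: pd.DataFrame, expr_log: pd.DataFrame,
                        feature_matrix: pd.DataFrame, slide_tissue: pd.Series,
                        alpha: float = 0.01) -> tuple[pd.DataFrame, dict]:
    """Flag indirect dependency patterns for each significant pair.

    * ``gtf_indirect``: the g-f partial-correlation test given tissue does
      NOT reject (p >= alpha) — the gene-feature correlation is mediated by
      tissue identity;
    * ``fgt_indirect``: the f-t block test given g does not reject — the gene
      mediates the feature-tissue association;
    * ``gft_indirect``: the g-t block test given f does not reject.

    Returns the annotated pair table and pattern counts.
    """
    shared = expr_log.columns.intersection(feature_matrix.index)
    tissues = slide_tissue.reindex(shared).to_numpy()
    rows = []
    for row in pairs.itertuples():
        g = expr_log.loc[row.gene, shared].to_numpy()
        f = feature_matrix.loc[shared, row.feature].to_numpy()
        pr, p_gf = partial_correlation(g, f, tissues)
        p_ft = block_f_test(f, g, tissues)
        p_gt = block_f_test(g, f, tissues)
        # alpha = 0 is the degenerate level-zero test: nothing is flagged
        rows.append({"partial_r_given_tissue": pr, "ci_p": p_gf,
                     "gtf_indirect": alpha > 0 and p_gf >= alpha,
                     "fgt_indirect": alpha > 0 and p_ft >= alpha,
                     "gft_indirect": alpha > 0 and p_gt >= alpha})
    flags = pd.DataFrame(rows, index=pairs.index)
    out = pd.concat([pairs, flags], axis=1)
    counts = {
        "pairs": len(out),
        "gtf": int(out["gtf_indirect"].sum()) if len(out) else 0,
        "fgt": int(out["fgt_indirect"].sum()) if len(out) else 0,
        "gft": int(out["gft_indirect"].sum()) if len(out) else 0,
    }
    return out, counts


# ---------------------------------------------------------------------------
# reporting breakdowns
# ---------------------------------------------------------------------------

def layer_tissue_breakdown(pairs: pd.DataFrame) -> pd.DataFrame:
    """Unique correlated genes per network layer, stacked by each gene's
    tissue of maximal expression (layers x tissues count table)."""
    if pairs.empty:
        return pd.DataFrame()
    t = pairs.copy()
    t["layer"] = t["feature"].str.split("_").str[0].astype(int)
    out = (t.drop_duplicates(["layer", "gene"])
            .groupby(["layer", "tissue_of_max"])["gene"].nunique()
            .unstack(fill_value=0).sort_index())
    return out


def genes_per_layer(pairs: pd.DataFrame) -> pd.Series:
    """Unique correlated genes aggregated over all channels of each layer."""
    if pairs.empty:
        return pd.Series(dtype=int)
    t = pairs.copy()
    t["layer"] = t["feature"].str.split("_").str[0].astype(int)
    return t.groupby("layer")["gene"].nunique()


def annotation_subset(pairs: pd.DataFrame, annotations: pd.DataFrame,
                      flags: list[str] | None = None) -> pd.DataFrame:
    """Report the best-correlated feature per annotated gene.

    ``annotations`` is a precomputed gene -> flag flat table (columns
    ``gene`` and ``flag``); genes carrying any of ``flags`` (default: all
    flags present) are kept. One row per gene with its best feature by r,
    grouped by tissue of maximal expression and sorted by r descending.
    """
    if pairs.empty:
        return pairs.iloc[0:0]
    wanted = set(flags) if flags is not None else set(annotations["flag"])
    genes = set(annotations.loc[annotations["flag"].isin(wanted), "gene"])
    sub = pairs[pairs["gene"].isin(genes)]
    if sub.empty:
        return sub
    best = sub.loc[sub.groupby("gene")["r"].idxmax()]
    return (best.sort_values(["tissue_of_max", "r"], ascending=[True, False])
                .reset_index(drop=True))
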