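"""Quantitative histology-tractography comparison layer.

Per-region counts, the two-tier proportional regression (free intercept, then
through the origin when the 95% CI of the intercept covers zero), Pearson and
Spearman correlations with two-sided p-values, the strongest-connection
(top-k) Spearman, voxelwise Pearson within single regions, false-positive /
false-negative classification, streamline sensitivity, and the connectivity
backbone graph.

Correlation coefficients are computed from their definitions (product-moment
on raw values, product-moment on average ranks for Spearman); scipy supplies
only distribution functions for the p-values.  No multiple-testing
correction is applied.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .tracking import StreamlineSet

__all__ = [
    "ProportionalFit",
    "regional_counts",
    "build_connectivity_table",
    "fit_proportional",
    "correlate",
    "topk_spearman",
    "voxelwise_pearson",
    "classify_fp_fn",
    "streamline_sensitivity",
    "export_backbone",
    "anova_across_depths",
]

log = logging.getLogger(__name__)


def regional_counts(surface_ddm, roi_interface_ids: np.ndarray) -> pd.Series:
    """Per-region totals of an interface density.

    ``roi_interface_ids`` assigns each interface voxel to at most one region
    (0 = outside all regions; that mass is logged, not silently dropped).
    """
    ids = np.asarray(roi_interface_ids)
    dens = surface_ddm.density
    if ids.shape != dens.shape:
        raise ValueError("roi id array must align with the interface density")
    outside = float(dens[ids == 0].sum())
    if outside:
        log.info("regional_counts: %.4g density outside all ROIs (%s)", outside, surface_ddm.provenance)
    rois = sorted(int(k) for k in np.unique(ids) if k > 0)
    return pd.Series({r: float(dens[ids == r].sum()) for r in rois}, name=surface_ddm.provenance)


def build_connectivity_table(n_b=None, n_d=None, n_s=None, n_t=None) -> pd.DataFrame:
    """Assemble per-region count columns (N_B, N_D, N_S, N_T) into one table."""
    cols = {"N_B": n_b, "N_D": n_d, "N_S": n_s, "N_T": n_t}
    frame = pd.DataFrame({k: v for k, v in cols.items() if v is not None})
    frame.index.name = "roi"
    if (frame.fillna(0) < 0).any().any():
        raise ValueError("connectivity counts must be nonnegative")
    return frame


@dataclass
class ProportionalFit:
    a: float  # intercept (0.0 when the through-origin model is selected)
    b: float  # slope
    ci_a: tuple  # 95% CI of the intercept from the free-intercept fit
    residuals: np.ndarray
    r: float  # Pearson r of the raw pairs
    p: float
    model_used: int  # 1 = free intercept, 2 = through origin


def fit_proportional(n_b: np.ndarray, n_d: np.ndarray) -> ProportionalFit:
    """Two-tier proportionality fit of streamline counts on fiber counts.

    Ordinary least squares of ``n_d`` on ``n_b`` with an intercept; if zero
    lies inside the t-based 95% confidence interval of the intercept the data
    are refit through the origin and the constrained slope is reported.
    Pearson r (and p) are always those of the raw pairs.
    """
    x = np.asarray(n_b, dtype=float)
    y = np.asarray(n_d, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 aligned (N_B, N_D) pairs")
    if np.ptp(x) == 0:
        raise ValueError("N_B has zero variance; the regression is undefined")
    model1 = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model1.conf_int(alpha=0.05)
    ci_a = (float(ci[0][0]), float(ci[0][1]))
    r, p = correlate(x, y, method="pearson")
    if ci_a[0] <= 0.0 <= ci_a[1]:
        model2 = sm.OLS(y, x[:, None]).fit()
        b = float(model2.params[0])
        return ProportionalFit(0.0, b, ci_a, y - b * x, r, p, model_used=2)
    a, b = float(model1.params[0]), float(model1.params[1])
    return ProportionalFit(a, b, ci_a, y - (a + b * x), r, p, model_used=1)


def _rank_average(x: np.ndarray) -> np.ndarray:
    """Average ranks (ties share the mean of the ranks they occupy)."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j + 1 < len(sx) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _pearson_from_def(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    return float(np.sum(xc * yc) / den)


def _t_pvalue(r: float, n: int) -> float:
    if n < 3:
        return 1.0
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * sps.t.sf(abs(t), df=n - 2))


def correlate(x, y, method: str = "pearson", pvalue: str = "t", rng_seed: int = 0):
    """Correlation coefficient with a two-sided p-value.

    ``method`` is "pearson" (product-moment) or "spearman" (product-moment on
    average ranks).  ``pvalue`` is "t" (t-distribution transform) or
    "permutation" (exact enumeration for n <= 7, otherwise 10000 seeded
    resamples; intended for small samples, n <= 10).  Zero variance in either
    vector leaves the coefficient undefined: (nan, 1.0) is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), 1.0
    if method == "spearman":
        x, y = _rank_average(x), _rank_average(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    r = _pearson_from_def(x, y)
    n = x.size
    if pvalue == "t":
        return r, _t_pvalue(r, n)
    if pvalue == "permutation":
        if n <= 7:
            perms = np.array(list(itertools.permutations(range(n))))
        else:
            rng = np.random.default_rng(rng_seed)
            perms = np.array([rng.permutation(n) for _ in range(10000)])
        null = np.array([_pearson_from_def(x, y[p]) for p in perms])
        return r, float(np.mean(np.abs(null) >= abs(r) - 1e-12))
    raise ValueError(f"unknown pvalue method {pvalue!r}")


def topk_spearman(n_b, n_d, rule: str = "threshold", threshold: float = 100.0, k: int = 10):
    """Spearman correlation restricted to the strongest connections.

    ``rule="threshold"`` keeps regions with ``N_B > threshold`` (default 100);
    ``rule="largest"`` keeps the ``k`` regions with the largest ``N_B``.
    Returns ``(r_s, p, n_selected)``; fewer than 3 surviving regions is an
    error.
    """
    x = np.asarray(n_b, dtype=float)
    y = np.asarray(n_d, dtype=float)
    if rule == "threshold":
        sel = x > threshold
    elif rule == "largest":
        sel = np.zeros(x.size, dtype=bool)
        sel[np.argsort(x, kind="stable")[::-1][:k]] = True
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if sel.sum() < 3:
        raise ValueError(f"top-k selection leaves {int(sel.sum())} regions (< 3)")
    r, p = correlate(x[sel], y[sel], method="spearman")
    return r, p, int(sel.sum())


def voxelwise_pearson(b, d):
    """Pearson correlation of two aligned per-voxel densities within one region.

    Returns ``(r_p, p, n)``; a constant vector leaves r_p undefined (nan,
    flagged with p = 1), mirroring degenerate single-region comparisons.
    """
    b = np.asarray(b, dtype=float)
    d = np.asarray(d, dtype=float)
    if b.size != d.size or b.size < 2:
        raise ValueError("need aligned vectors with n >= 2")
    n = b.size
    if np.ptp(b) == 0 or np.ptp(d) == 0:
        return float("nan"), 1.0, n
    r = _pearson_from_def(b, d)
    return r, _t_pvalue(r, n), n


def classify_fp_fn(table: pd.DataFrame, tol: float = 1e-12):
    """False negatives (N_B > 0, N_D = 0) and false positives (N_B = 0, N_D > 0)."""
    nb = table["N_B"].to_numpy(dtype=float)
    nd = table["N_D"].to_numpy(dtype=float)
    fn = list(table.index[(nb > tol) & (nd <= tol)])
    fp = list(table.index[(nb <= tol) & (nd > tol)])
    return fn, fp


def streamline_sensitivity(
    streamlines: StreamlineSet, true_positive_rois, roi_map: np.ndarray
) -> float:
    """Fraction of region-reaching streamlines that reach a true-positive region."""
    tp = set(int(r) for r in true_positive_rois)
    if not tp:
        raise ValueError("true-positive region set is empty")
    roi_flat = np.asarray(roi_map).ravel()
    from .tracking import visited_pairs

    sid, vox = visited_pairs(streamlines)
    rois = roi_flat[vox]
    n = len(streamlines)
    hit_any = np.zeros(n, dtype=bool)
    hit_tp = np.zeros(n, dtype=bool)
    np.logical_or.at(hit_any, sid, rois > 0)
    is_tp = np.isin(rois, sorted(tp))
    np.logical_or.at(hit_tp, sid, is_tp)
    n_any = int(hit_any.sum())
    n_tp = int((hit_any & hit_tp).sum())
    if n_any == 0:
        warnings.warn("no streamline reaches any region; sensitivity undefined")
        return float("nan")
    return n_tp / n_any


def export_backbone(table: pd.DataFrame, roi_geometry: dict, strength_col: str = "N_D") -> nx.Graph:
    """Connectivity backbone: injection hub plus region nodes.

    Node attribute ``size`` scales with the square root of the region volume;
    each nonzero connection gets an edge with ``weight`` = log10 strength and
    ``connection_weight`` = strength / region volume.  Zero-strength edges are
    omitted.
    """
    def _centre_attrs(geo):
        cx, cy, cz = (float(c) for c in geo.get("centre", (0.0, 0.0, 0.0)))
        return {"centre_x": cx, "centre_y": cy, "centre_z": cz}

    g = nx.Graph()
    inj = roi_geometry.get("injection", {})
    g.add_node("injection", size=float(np.sqrt(inj.get("volume", 1.0))), **_centre_attrs(inj))
    for roi, row in table.iterrows():
        geo = roi_geometry.get(roi, {})
        vol = float(geo.get("volume", 1.0))
        g.add_node(roi, size=float(np.sqrt(vol)), **_centre_attrs(geo))
        strength = float(row[strength_col])
        if strength > 0:
            g.add_edge("injection", roi, strength=strength,
                       weight=float(np.log10(strength)),
                       connection_weight=strength / vol)
    return g


def anova_across_depths(rp_by_depth: dict):
    """One-way F-test of per-region voxelwise correlations across seed depths."""
    groups = [np.asarray(v, dtype=float) for v in rp_by_depth.values()]
    groups = [g[np.isfinite(g)] for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 depth groups with >= 2 finite values each")
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)
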