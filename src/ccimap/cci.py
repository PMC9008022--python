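"""Signature scoring, ternary projection and CCI quantification.

A cell's identity relative to three reference lineages is summarized by the
triple of signature scores (a, b, c).  The angle between the score vector
and each axis has cosine ``coord / ||(a,b,c)||``; a cell equally similar to
all three lineages sits on the simplex centroid, where the three cosines
coincide and their standard deviation vanishes.  The CCI score is
``f / sd(cos1, cos2, cos3)``, so it diverges toward the centroid and is
smallest at the corners.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ccimap.io_qc import ExpressionMatrix, SignatureSet, match_signature_genes
from ccimap.markers import _group_stats

logger = logging.getLogger(__name__)

SQRT3_2 = np.sqrt(3.0) / 2.0


class DegenerateObservationError(ValueError):
    """All three signature scores are zero after clipping."""


class CutpointError(RuntimeError):
    """The ECDF never crosses its fitted logistic curve on the interior grid."""


@dataclass
class TernaryScores:
    """Per-observation signature-score triple plus barycentric coordinates."""

    obs_id: str
    a: float
    b: float
    c: float
    bary: tuple[float, float, float]


@dataclass
class CCIResult:
    """Per-observation CCI quantities; ``cutpoint`` is cohort-level."""

    obs_id: str
    cos1: float
    cos2: float
    cos3: float
    sd_cos: float
    cci: float
    positive: bool
    cutpoint: float


def signature_score(m: ExpressionMatrix, s: SignatureSet) -> np.ndarray:
    """Mean normalized expression of the matched signature genes, per observation.

    SS_i = (sum over matched genes of the normalized value in observation i)
    divided by the number of matched genes.
    """
    if m.layer == "raw_counts":
        raise ValueError("signature_score expects normalized data (lognorm or external_normalized)")
    rows = match_signature_genes(m, s)
    return m.values[rows].mean(axis=0)


def ternary_project(a: float, b: float, c: float) -> tuple[float, float, float]:
    """Clip negatives to zero and normalize (a, b, c) to barycentric coordinates."""
    v = np.clip(np.asarray([a, b, c], float), 0.0, None)
    total = v.sum()
    if total <= 0:
        raise DegenerateObservationError(f"all-zero score triple after clipping: {(a, b, c)}")
    v = v / total
    return (float(v[0]), float(v[1]), float(v[2]))


def ternary_project_many(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized projection of an (n, 3) score array.

    Returns (bary, ok) where rows with an all-zero clipped triple are flagged
    ``ok = False`` and get NaN coordinates instead of raising.
    """
    v = np.clip(np.asarray(scores, float), 0.0, None)
    totals = v.sum(axis=1)
    ok = totals > 0
    bary = np.full_like(v, np.nan)
    bary[ok] = v[ok] / totals[ok, None]
    return bary, ok


def _sd(x: np.ndarray, mode: Literal["sample", "population"], axis: int = -1) -> np.ndarray:
    return x.std(axis=axis, ddof=1 if mode == "sample" else 0)


def cci_score(
    a,
    b,
    c,
    f: float = 10.0,
    epsilon: float = 1e-6,
    sd_mode: Literal["sample", "population"] = "sample",
):
    """Axis cosines, their standard deviation, and the CCI score.

    ``cos_k = coord_k / sqrt(a^2 + b^2 + c^2)`` (the law-of-cosines
    expression for the angle between the score vector and axis k reduces to
    this).  ``sd_cos`` uses the n-1 denominator by default.
    ``cci = f / max(sd_cos, epsilon)``.  Accepts scalars or equal-length
    arrays; scalar input returns scalars.
    """
    arr = np.stack(np.broadcast_arrays(np.asarray(a, float), np.asarray(b, float), np.asarray(c, float)), axis=-1)
    scalar = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if (arr < 0).any():
        raise ValueError("cci_score requires nonnegative scores; clip before calling")
    norms = np.sqrt((arr**2).sum(axis=-1))
    if (norms == 0).any():
        raise DegenerateObservationError("all-zero score triple")
    cosines = arr / norms[..., None]
    sd_cos = _sd(cosines, sd_mode)
    cci = f / np.maximum(sd_cos, epsilon)
    if scalar:
        c1, c2, c3 = (float(x) for x in cosines[0])
        return c1, c2, c3, float(sd_cos[0]), float(cci[0])
    return cosines[..., 0], cosines[..., 1], cosines[..., 2], sd_cos, cci


def cci_cutpoint(
    scores: Sequence[float],
    boundary_tol: float = 1e-3,
) -> tuple[float, pd.DataFrame]:
    """CCI-positivity cut-point from the ECDF vs a fitted logistic curve.

    The empirical CDF of the scores is evaluated on the sorted unique
    values, a two-parameter logistic curve is fitted to (score -> ECDF) by
    binomial-family maximum likelihood (GLM with logit link), and the
    cut-point is the smallest interior score at which the empirical curve
    falls below the fitted curve (a descending sign change of
    ECDF - fitted; ascending changes occur inside the rising bulk of the
    majority mode and do not separate the modes).  Sign changes where
    neither side deviates from the fit by more than ``boundary_tol`` are
    ignored as boundary artifacts.  Scores strictly above the cut-point are
    called positive.

    Returns (cutpoint, grid) where grid has columns score/ecdf/fitted.

    Raises
    ------
    CutpointError
        If no robust interior sign change exists; inspect the score
        distribution before proceeding.
    """
    scores = np.asarray(list(scores), float)
    if len(scores) < 50:
        raise ValueError(f"need >= 50 scores, got {len(scores)}")
    grid = np.unique(scores)
    if len(grid) < 2:
        raise ValueError("need >= 2 distinct score values")
    ecdf = np.searchsorted(np.sort(scores), grid, side="right") / len(scores)

    x = sm.add_constant(grid)
    model = sm.GLM(ecdf, x, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitted = model.fit().predict(x)

    d = ecdf - fitted
    crossings = []
    for i in range(1, len(grid) - 1):
        if d[i - 1] > 0.0 and d[i] <= 0.0 and max(abs(d[i - 1]), abs(d[i])) > boundary_tol:
            crossings.append(i)
    frame = pd.DataFrame({"score": grid, "ecdf": ecdf, "fitted": fitted})
    if not crossings:
        raise CutpointError(
            "ECDF does not robustly cross the fitted logistic curve on the interior grid; "
            "the score distribution may already be logistic-shaped — inspect it before thresholding"
        )
    return float(grid[crossings[0]]), frame


def cci_positive(scores: np.ndarray, cutpoint: float) -> np.ndarray:
    """Boolean mask of scores strictly above the cut-point."""
    return np.asarray(scores, float) > cutpoint


def compute_cci_table(
    m: ExpressionMatrix,
    signatures: Sequence[SignatureSet],
    f: float = 10.0,
    epsilon: float = 1e-6,
    sd_mode: Literal["sample", "population"] = "sample",
    cutpoint: float | None = None,
) -> pd.DataFrame:
    """Full per-observation CCI table for a matrix and the (BS, BK, DK) triple.

    Axis order is fixed as the order of ``signatures``.  When ``cutpoint``
    is None it is estimated from this cohort's scores via
    :func:`cci_cutpoint`.  Degenerate observations (all-zero clipped score
    triple) get NaN coordinates and are excluded from the cut-point fit.
    """
    if len(signatures) != 3:
        raise ValueError("exactly three signatures (BS, BK, DK order) are required")
    abc = np.column_stack([signature_score(m, s) for s in signatures])
    abc = np.clip(abc, 0.0, None)
    bary, ok = ternary_project_many(abc)
    if (~ok).any():
        logger.warning("%d degenerate observations excluded from the ternary map", int((~ok).sum()))
    n = len(m.obs_ids)
    cos = np.full((n, 3), np.nan)
    sd_cos = np.full(n, np.nan)
    cci = np.full(n, np.nan)
    if ok.any():
        c1, c2, c3, sd_ok, cci_ok = cci_score(
            abc[ok, 0], abc[ok, 1], abc[ok, 2], f=f, epsilon=epsilon, sd_mode=sd_mode
        )
        cos[ok] = np.column_stack([c1, c2, c3])
        sd_cos[ok] = sd_ok
        cci[ok] = cci_ok
    if cutpoint is None:
        cutpoint, _ = cci_cutpoint(cci[ok])
    positive = np.zeros(n, bool)
    positive[ok] = cci[ok] > cutpoint
    return pd.DataFrame(
        {
            "obs_id": m.obs_ids,
            "a": abc[:, 0],
            "b": abc[:, 1],
            "c": abc[:, 2],
            "bary_a": bary[:, 0],
            "bary_b": bary[:, 1],
            "bary_c": bary[:, 2],
            "cos1": cos[:, 0],
            "cos2": cos[:, 1],
            "cos3": cos[:, 2],
            "sd_cos": sd_cos,
            "cci": cci,
            "positive": positive,
            "cutpoint": cutpoint,
        }
    )


def cci_signature_genes(
    m: ExpressionMatrix,
    cci_positive_ids: set[str],
    background_ids: set[str],
    min_logfc: float = 0.25,
    min_basemean: float = 0.8,
    min_pct1: float = 0.8,
) -> SignatureSet | None:
    """Genes exclusively upregulated in CCI-positive cells.

    A gene qualifies when all three hold strictly: log fold change
    (positive vs background, same expm1-scale formula as marker calling)
    > ``min_logfc``; mean normalized expression across the union of both
    cell sets > ``min_basemean``; and detection fraction among the
    CCI-positive cells > ``min_pct1``.  Returns None with a warning when no
    gene passes.
    """
    if m.layer != "lognorm":
        raise ValueError("cci_signature_genes expects a lognorm matrix")
    if not cci_positive_ids or not background_ids:
        raise ValueError("both cell sets must be non-empty")
    if cci_positive_ids & background_ids:
        raise ValueError("CCI-positive and background sets overlap")
    pos_mask = np.array([o in cci_positive_ids for o in m.obs_ids])
    bg_mask = np.array([o in background_ids for o in m.obs_ids])
    if pos_mask.sum() != len(cci_positive_ids) or bg_mask.sum() != len(background_ids):
        raise ValueError("some requested obs_ids are absent from the matrix")
    union = pos_mask | bg_mask
    sub = m.values[:, union]
    in_sub = pos_mask[union]
    log_fc, pct1, _ = _group_stats(sub, in_sub)
    base_mean = sub.mean(axis=1)
    keep = (log_fc > min_logfc) & (base_mean > min_basemean) & (pct1 > min_pct1)
    if not keep.any():
        warnings.warn("no gene passes the CCI-signature thresholds", stacklevel=2)
        return None
    order = np.argsort(-log_fc[keep], kind="mergesort")
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    return SignatureSet(name="CCI", genes=[genes[i] for i in order])


def export_ternary_density(
    bary: np.ndarray,
    bins: int = 500,
) -> pd.DataFrame:
    """Gaussian kernel density of barycentric points on a simplex grid.

    The simplex is embedded in the plane (x = b + c/2, y = c * sqrt(3)/2),
    a 2-D Gaussian KDE (Scott's bandwidth) is fitted to the embedded
    points, and the density is evaluated on a ``bins x bins`` lattice
    restricted to the simplex interior.  Columns: bary_a, bary_b, bary_c,
    x, y, density.
    """
    bary = np.asarray(bary, float)
    if bary.ndim != 2 or bary.shape[1] != 3:
        raise ValueError("bary must be an (n, 3) array")
    bary = bary[~np.isnan(bary).any(axis=1)]
    if len(bary) < 10:
        raise ValueError(f"need >= 10 points, got {len(bary)}")
    xy = np.column_stack([bary[:, 1] + bary[:, 2] / 2.0, bary[:, 2] * SQRT3_2])
    kde = stats.gaussian_kde(xy.T)

    ticks = np.linspace(0.0, 1.0, bins)
    gx, gy = np.meshgrid(ticks, ticks * SQRT3_2)
    gx, gy = gx.ravel(), gy.ravel()
    # invert the embedding: c = y / (sqrt(3)/2), b = x - c/2, a = 1 - b - c
    gc = gy / SQRT3_2
    gb = gx - gc / 2.0
    ga = 1.0 - gb - gc
    inside = (ga >= 0) & (gb >= 0) & (gc >= 0)
    gx, gy, ga, gb, gc = gx[inside], gy[inside], ga[inside], gb[inside], gc[inside]
    density = np.empty(len(gx))
    chunk = 200_000
    pts = np.vstack([gx, gy])
    for start in range(0, len(gx), chunk):
        density[start : start + chunk] = kde(pts[:, start : start + chunk])
    return pd.DataFrame(
        {"bary_a": ga, "bary_b": gb, "bary_c": gc, "x": gx, "y": gy, "density": density}
    )
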