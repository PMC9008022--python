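"""Threshold-based marker-gene calling and lineage-signature selection.

One-vs-rest differential expression on the lognorm layer with the
conventional trio of filters: natural-log fold change on the expm1 scale,
detection fractions inside/outside the group (pct1/pct2), and a two-sided
Wilcoxon rank-sum test with BH correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ccimap.io_qc import ExpressionMatrix, SignatureSet

logger = logging.getLogger(__name__)


@dataclass
class MarkerRecord:
    """One gene's one-vs-rest statistics for one group."""

    gene_id: str
    group: str
    log_fc: float
    pct1: float
    pct2: float
    p_value: float
    p_adj: float

    def __post_init__(self) -> None:
        for name in ("pct1", "pct2", "p_value", "p_adj"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg, matching statsmodels' fdr_bh."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _ranksum_pvalues(x_in: np.ndarray, x_out: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p per gene (rows = genes).

    Normal approximation with tie correction when both groups have >= 20
    observations; exact Mann-Whitney enumeration (no ties) below that,
    falling back to the tie-corrected approximation when ties are present.
    """
    n1, n2 = x_in.shape[1], x_out.shape[1]
    data = np.hstack([x_in, x_out])
    ranks = stats.rankdata(data, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0

    use_exact = min(n1, n2) < 20
    n = n1 + n2
    mu = n1 * n2 / 2.0
    # tie correction per gene
    tie_term = np.zeros(data.shape[0])
    has_ties = np.zeros(data.shape[0], bool)
    for i in range(data.shape[0]):
        _, counts = np.unique(data[i], return_counts=True)
        tie_term[i] = (counts**3 - counts).sum()
        has_ties[i] = (counts > 1).any()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    p = np.ones(data.shape[0])
    nz = sigma2 > 0
    z = np.zeros_like(p)
    z[nz] = (u1[nz] - mu) / np.sqrt(sigma2[nz])
    p[nz] = 2.0 * stats.norm.sf(np.abs(z[nz]))
    if use_exact:
        exact_rows = np.where(~has_ties)[0]
        for i in exact_rows:
            res = stats.mannwhitneyu(x_in[i], x_out[i], alternative="two-sided", method="exact")
            p[i] = res.pvalue
    return np.minimum(p, 1.0)


def _group_stats(values: np.ndarray, in_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(log_fc, pct1, pct2) for every gene, group vs rest.

    log_fc = ln((mean(expm1(x_in)) + 1) / (mean(expm1(x_out)) + 1)).
    """
    x_in = values[:, in_mask]
    x_out = values[:, ~in_mask]
    mean_in = np.expm1(x_in).mean(axis=1)
    mean_out = np.expm1(x_out).mean(axis=1)
    log_fc = np.log(mean_in + 1.0) - np.log(mean_out + 1.0)
    pct1 = (x_in > 0).mean(axis=1)
    pct2 = (x_out > 0).mean(axis=1)
    return log_fc, pct1, pct2


def find_markers(
    m: ExpressionMatrix,
    labels: pd.Series | dict[str, str],
    min_logfc: float = 0.25,
    min_pct: float = 0.25,
    max_padj: float = 0.05,
) -> list[MarkerRecord]:
    """One-vs-rest marker detection for every group.

    Parameters
    ----------
    m
        Lognorm-layer matrix.
    labels
        obs_id -> group label (Series indexed by obs_id, or a dict).
        Every observation of ``m`` must be labeled; >= 2 groups with >= 3
        observations each are required.

    For each group, genes detected in at least ``min_pct`` of either side
    are tested with a two-sided rank-sum test; BH adjustment is applied
    within the group's tested genes; only genes with
    ``log_fc >= min_logfc`` and ``p_adj < max_padj`` are returned, sorted
    by group then descending log_fc.
    """
    if m.layer not in ("lognorm", "external_normalized"):
        raise ValueError(f"find_markers expects normalized data, got layer={m.layer!r}")
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    labels = labels.reindex(m.obs_ids)
    if labels.isna().any():
        missing = [o for o, v in zip(m.obs_ids, labels.isna()) if v]
        raise ValueError(f"observations without a group label: {missing[:5]}")
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("find_markers requires >= 2 groups")
    counts = labels.value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(f"groups with < 3 observations: {dict(small)}")

    records: list[MarkerRecord] = []
    label_arr = labels.to_numpy()
    for group in groups:
        in_mask = label_arr == group
        log_fc, pct1, pct2 = _group_stats(m.values, in_mask)
        tested = (pct1 >= min_pct) | (pct2 >= min_pct)
        if not tested.any():
            raise ValueError(f"group {group!r}: no gene passes the min_pct pre-filter")
        idx = np.where(tested)[0]
        p = _ranksum_pvalues(m.values[idx][:, in_mask], m.values[idx][:, ~in_mask])
        p_adj = _bh_adjust(p)
        keep = (log_fc[idx] >= min_logfc) & (p_adj < max_padj)
        for j, k in enumerate(idx):
            if keep[j]:
                records.append(
                    MarkerRecord(
                        gene_id=m.gene_ids[k],
                        group=str(group),
                        log_fc=float(log_fc[k]),
                        pct1=float(pct1[k]),
                        pct2=float(pct2[k]),
                        p_value=float(p[j]),
                        p_adj=float(p_adj[j]),
                    )
                )
    records.sort(key=lambda r: (r.group, -r.log_fc, r.gene_id))
    return records


def select_lineage_signature(
    markers: list[MarkerRecord], group: str, max_pct2: float = 0.4
) -> SignatureSet:
    """Group markers with ``pct2 < max_pct2`` (strict), by descending log_fc."""
    if not markers:
        raise ValueError("empty marker list")
    chosen = [r for r in markers if r.group == group and r.pct2 < max_pct2]
    if not chosen:
        raise ValueError(f"no marker of group {group!r} has pct2 < {max_pct2}")
    chosen.sort(key=lambda r: (-r.log_fc, r.gene_id))
    return SignatureSet(name=group, genes=[r.gene_id for r in chosen])


def progression_signature(
    markers_by_cohort: list[tuple[str, list[MarkerRecord]]],
    max_padj: float = 0.05,
) -> SignatureSet | None:
    """Genes commonly upregulated across cohorts (log_fc > 0, p_adj < 0.05).

    Marker lists are expected to come from a late-vs-early stage contrast
    with the late group under test.  Returns None (with a warning) when the
    intersection is empty.
    """
    if not markers_by_cohort:
        raise ValueError("at least one cohort is required")
    per_cohort: list[set[str]] = []
    for _, markers in markers_by_cohort:
        per_cohort.append({r.gene_id for r in markers if r.log_fc > 0 and r.p_adj < max_padj})
    common = set.intersection(*per_cohort)
    if not common:
        warnings.warn("progression signature: no gene shared across cohorts", stacklevel=2)
        return None
    return SignatureSet(name="progression", genes=sorted(common))


def markers_to_frame(markers: list[MarkerRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene_id,
                "group": r.group,
                "log_fc": r.log_fc,
                "pct1": r.pct1,
                "pct2": r.pct2,
                "p": r.p_value,
                "p_adj": r.p_adj,
            }
            for r in markers
        ]
    )
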