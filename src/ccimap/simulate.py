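"""Synthetic cohort generator with planted lineage and malignant structure.

Three transcriptionally distinct pure populations sit at the corners of the
ternary identity map; a fourth "confused" malignant population co-expresses
all three lineage signatures at a tunable fraction of the pure effect and
additionally expresses a set of malignant-only genes.  Counts are
gamma-Poisson (negative binomial, variance = mu + mu^2 * dispersion) with
lognormal library-size variation and independent Bernoulli dropout.
Everything is deterministic for a fixed seed.

All planted structure scales with ``effect``: at effect = 0 the cohort has
no population structure at all.  Lineage signature genes are expressed at
``exp(effect)`` times baseline in their own population, suppressed by
``exp(-off_suppression * effect)`` in the other two pure populations
(lineage specificity), and lifted by ``exp(confusion * effect)`` in
confused cells.  Each confused cell additionally receives a small zero-sum
asymmetry across the three signatures whose magnitude shrinks as the
cell's confusion grows, so more-confused cells sit closer to the ternary
centroid (higher identity-confusion score) without ever being exactly
central.  Malignant-only genes get ``exp(effect)`` in confused cells and
``exp(-cci_suppression * effect)`` elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ccimap.io_qc import ExpressionMatrix, SignatureSet, validate_metadata
from ccimap.stats import SurvivalRecord

POPULATIONS = ("BS", "BK", "DK")


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``confusion`` is the fraction of each lineage effect expressed by
    confused cells (their per-cell draw is jittered by
    ``confusion_jitter``); ``asym``/``asym_coupling``/``asym_floor``
    control the per-cell zero-sum asymmetry pattern (in units of
    ``effect``) that keeps confused cells off the exact centroid;
    ``stage_fraction`` of confused cells — the most-confused ones — are
    labeled stage II_III, building in a confusion-stage association.
    """

    n_bs: int = 200
    n_bk: int = 200
    n_dk: int = 200
    n_confused: int = 300
    n_genes: int = 2000
    sig_size: int = 25
    n_cci_genes: int = 40
    effect: float = 1.5
    confusion: float = 0.6
    confusion_jitter: float = 0.05
    off_suppression: float = 2.0
    cci_suppression: float = 2.0
    asym: float = 1.7
    asym_coupling: float = 0.75
    asym_floor: float = 0.1
    nb_dispersion: float = 0.3
    dropout: float = 0.05
    libsize_sigma: float = 0.25
    stage_fraction: float = 0.5
    base_mean_sig: float = 1.5
    base_mean_cci: float = 1.2
    base_mean_background: float = 0.15
    seed: int = 1

    def validate(self) -> None:
        sizes = (self.n_bs, self.n_bk, self.n_dk, self.n_confused, self.n_genes, self.sig_size)
        if any(s < 1 for s in sizes):
            raise ValueError("all population/gene sizes must be >= 1")
        if self.sig_size * 3 + self.n_cci_genes > self.n_genes:
            raise ValueError("planted gene sets exceed n_genes")
        if not (0 < self.confusion <= 1):
            raise ValueError("confusion must lie in (0, 1]")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if self.effect < 0 or self.nb_dispersion <= 0:
            raise ValueError("effect must be >= 0 and nb_dispersion > 0")
        if not (0 < self.stage_fraction <= 1):
            raise ValueError("stage_fraction must lie in (0, 1]")


@dataclass
class SyntheticCohort:
    """Generated counts, metadata and the planted ground truth."""

    matrix: ExpressionMatrix
    meta: pd.DataFrame
    truth_signatures: dict[str, SignatureSet]
    truth_population: pd.Series  # obs_id -> BS/BK/DK/confused
    truth_confusion: pd.Series  # obs_id -> per-cell confusion draw (NaN for pure)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with variance mean + mean^2 * dispersion."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam).astype(float)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort according to ``spec``; bitwise-deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_cells = spec.n_bs + spec.n_bk + spec.n_dk + spec.n_confused
    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    obs_ids = [f"cell{i:05d}" for i in range(n_cells)]

    # planted gene blocks are disjoint by construction
    blocks: dict[str, np.ndarray] = {}
    cursor = 0
    for pop in POPULATIONS:
        blocks[pop] = np.arange(cursor, cursor + spec.sig_size)
        cursor += spec.sig_size
    cci_block = np.arange(cursor, cursor + spec.n_cci_genes)

    base = rng.lognormal(np.log(spec.base_mean_background), 0.8, size=spec.n_genes)
    for pop in POPULATIONS:
        base[blocks[pop]] = spec.base_mean_sig * rng.lognormal(0.0, 0.2, size=spec.sig_size)
    base[cci_block] = spec.base_mean_cci * rng.lognormal(0.0, 0.2, size=spec.n_cci_genes)

    population = np.array(
        ["BS"] * spec.n_bs + ["BK"] * spec.n_bk + ["DK"] * spec.n_dk + ["confused"] * spec.n_confused
    )
    confused_mask = population == "confused"

    confusion_draw = np.full(n_cells, np.nan)
    confusion_draw[confused_mask] = np.clip(
        rng.normal(spec.confusion, spec.confusion_jitter, size=spec.n_confused), 0.05, 1.0
    )

    # zero-sum per-cell asymmetry across the three signatures, shrinking
    # with the cell's confusion so high-confusion cells sit nearer the
    # centroid (but never exactly on it)
    delta_cell = spec.effect * spec.asym * np.clip(
        1.0 - spec.asym_coupling * confusion_draw[confused_mask], spec.asym_floor, None
    )
    pattern = np.stack([rng.permutation([-1.0, 0.0, 1.0]) for _ in range(spec.n_confused)], axis=1)
    asym_lift = pattern * delta_cell[None, :]

    lift = np.zeros((spec.n_genes, n_cells))
    for k, pop in enumerate(POPULATIONS):
        own = population == pop
        other_pure = ~own & ~confused_mask
        lift[np.ix_(blocks[pop], own)] = spec.effect
        lift[np.ix_(blocks[pop], other_pure)] = -spec.off_suppression * spec.effect
        lift[np.ix_(blocks[pop], confused_mask)] = (
            confusion_draw[confused_mask] * spec.effect + asym_lift[k]
        )
    lift[np.ix_(cci_block, confused_mask)] = spec.effect
    lift[np.ix_(cci_block, ~confused_mask)] = -spec.cci_suppression * spec.effect

    mean = base[:, None] * np.exp(lift)
    libsize = rng.lognormal(0.0, spec.libsize_sigma, size=n_cells)
    mean = mean * libsize[None, :]

    counts = _nb_counts(rng, mean, spec.nb_dispersion)
    if spec.dropout > 0:
        keep = rng.random(counts.shape) >= spec.dropout
        counts = counts * keep

    matrix = ExpressionMatrix(counts, gene_ids, obs_ids, layer="raw_counts")

    # stage labels: the most-confused fraction of malignant cells is II/III
    stage = np.full(n_cells, None, dtype=object)
    conf_vals = confusion_draw[confused_mask]
    threshold = np.quantile(conf_vals, 1.0 - spec.stage_fraction)
    stage[confused_mask] = np.where(conf_vals >= threshold, "II_III", "I")

    meta = pd.DataFrame(
        {
            "obs_id": obs_ids,
            "sample_id": "synthetic",
            "group": np.where(confused_mask, "malignant_SE", "normal_SE"),
            "subtype": np.where(confused_mask, None, population),
            "stage": stage,
        }
    )
    meta = validate_metadata(meta)

    truth_signatures = {
        pop: SignatureSet(name=pop, genes=[gene_ids[i] for i in blocks[pop]]) for pop in POPULATIONS
    }
    truth_signatures["CCI"] = SignatureSet(name="CCI", genes=[gene_ids[i] for i in cci_block])

    return SyntheticCohort(
        matrix=matrix,
        meta=meta,
        truth_signatures=truth_signatures,
        truth_population=pd.Series(population, index=obs_ids, name="population"),
        truth_confusion=pd.Series(confusion_draw, index=obs_ids, name="confusion"),
    )


def generate_survival(
    n: int,
    cutpoint: float = 0.5,
    hazard_ratio: float = 3.0,
    censor_rate: float = 0.3,
    seed: int = 1,
    base_rate: float = 0.1,
) -> list[SurvivalRecord]:
    """Survival cohort with a planted score threshold.

    Scores are uniform(0, 1); event times are exponential with rate
    ``base_rate`` below the cut-point and ``base_rate * hazard_ratio``
    above.  Censoring times are independent exponentials calibrated so the
    baseline group is censored at roughly ``censor_rate``; ``censor_rate=0``
    disables censoring.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    scores = rng.uniform(0.0, 1.0, size=n)
    rates = np.where(scores > cutpoint, base_rate * hazard_ratio, base_rate)
    event_times = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        censor_lambda = base_rate * censor_rate / (1.0 - censor_rate)
        censor_times = rng.exponential(1.0 / censor_lambda, size=n)
    else:
        censor_times = np.full(n, np.inf)
    observed = event_times <= censor_times
    times = np.minimum(event_times, censor_times)
    return [
        SurvivalRecord(f"subj{i:04d}", float(max(times[i], 1e-9)), bool(observed[i]), float(scores[i]))
        for i in range(n)
    ]
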