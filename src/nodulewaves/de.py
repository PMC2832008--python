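"""Stage assignment, pairwise stage t-tests, differential-gene selection and
the digital-genes integer transform.

Arrays from the wild-type time course fall into three developmental stages:
roots (0-6 dpi, before nodules are visible), incipient nodules (7-10 dpi,
white, pre-fixation) and mature nodules (>=13 dpi, pink, nitrogen-fixing).
Differential genes are those whose log2 ratio differs (Welch t, p < alpha,
no multiple-testing correction) in at least one of the three pairwise stage
comparisons.  The digital transform maps each gene's three stage means to
integers 1-3 encoding statistically supported expression tiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .arrays import ExpressionMatrix

STAGES = ("roots", "incipient", "nodules")
STAGE_PAIRS = (("roots", "incipient"), ("roots", "nodules"), ("incipient", "nodules"))
#: dpi intervals per stage: roots 0-6, incipient 7-10, nodules >=13 (11-12 never sampled)
STAGE_CUTPOINTS = {"roots": (0.0, 6.0), "incipient": (7.0, 10.0), "nodules": (13.0, np.inf)}


class StageError(ValueError):
    """Unassignable dpi or an unusable stage grouping."""


@dataclass
class StageGrouping:
    """Map array_id -> stage, with the dpi cutpoints that produced it."""

    stages: dict[str, str]
    cutpoints: Mapping[str, tuple[float, float]]

    def arrays_in(self, stage: str) -> list[str]:
        return [a for a, s in self.stages.items() if s == stage]


@dataclass
class DeResult:
    """Per-gene p-values for the three stage comparisons plus stage means.

    ``pvalues`` columns are "roots_vs_incipient", "roots_vs_nodules",
    "incipient_vs_nodules"; ``stage_means`` columns follow ``STAGES``.
    """

    pvalues: pd.DataFrame
    stage_means: pd.DataFrame
    alpha: float

    @property
    def selected(self) -> pd.Series:
        return self.pvalues.min(axis=1) < self.alpha


def stage_for_dpi(dpi: float) -> str:
    for stage, (lo, hi) in STAGE_CUTPOINTS.items():
        if lo <= dpi <= hi:
            return stage
    raise StageError(f"dpi {dpi} falls outside the defined stage ranges")


def assign_stages(metadata: pd.DataFrame) -> StageGrouping:
    """Assign every array to a stage from its dpi.

    ``metadata`` is indexed by array_id with a ``dpi`` column; an array with a
    missing dpi or one outside the defined ranges raises, naming the array.
    """
    stages: dict[str, str] = {}
    for array_id, row in metadata.iterrows():
        dpi = row.get("dpi")
        if dpi is None or (isinstance(dpi, float) and np.isnan(dpi)):
            raise StageError(f"array {array_id!r} has no dpi")
        try:
            stages[array_id] = stage_for_dpi(float(dpi))
        except StageError:
            raise StageError(
                f"array {array_id!r}: dpi {dpi} outside the defined stage ranges"
            ) from None
    return StageGrouping(stages=stages, cutpoints=dict(STAGE_CUTPOINTS))


#: Relative tolerance below which a group is treated as constant: values
#: produced by exact arithmetic differ only by float rounding (~1e-16), far
#: below any biological signal on the log2 scale.
_VAR_RTOL = 1e-9


def _welch_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Welch t-test per row, with the degenerate zero-variance
    convention: equal means -> p = 1, unequal means -> p = 0.

    Variances below (1e-9 x the value scale)^2 count as zero so that
    rounding noise from exactly reproducible (zero-noise) data does not
    masquerade as signal.
    """
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    scale = np.maximum.reduce([np.abs(ma), np.abs(mb), np.ones_like(ma)])
    tol = (_VAR_RTOL * scale) ** 2
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    degenerate = (va <= tol) & (vb <= tol)
    if degenerate.any():
        equal = np.abs(ma - mb) <= _VAR_RTOL * scale
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    p = np.where(np.isnan(p), 1.0, p)
    return p


def pairwise_stage_tests(
    expr: ExpressionMatrix, groups: StageGrouping, alpha: float = 0.01
) -> DeResult:
    """Welch two-sided t-tests on log2 values for each of the three stage pairs."""
    by_stage: dict[str, np.ndarray] = {}
    for stage in STAGES:
        arrays = groups.arrays_in(stage)
        arrays = [a for a in arrays if a in expr.values.columns]
        if len(arrays) < 2:
            raise StageError(f"stage {stage!r} has {len(arrays)} arrays; need >= 2")
        by_stage[stage] = expr.values[arrays].to_numpy(dtype=float)
    pvals = {}
    for sa, sb in STAGE_PAIRS:
        pvals[f"{sa}_vs_{sb}"] = _welch_pvalues(by_stage[sa], by_stage[sb])
    pvalues = pd.DataFrame(pvals, index=expr.values.index)
    stage_means = pd.DataFrame(
        {stage: by_stage[stage].mean(axis=1) for stage in STAGES},
        index=expr.values.index,
    )
    return DeResult(pvalues=pvalues, stage_means=stage_means, alpha=alpha)


def select_de_genes(res: DeResult, alpha: float | None = None) -> list[str]:
    """Genes with p < alpha in at least one of the three comparisons (raw p,
    no multiple-testing correction)."""
    alpha = res.alpha if alpha is None else alpha
    mask = res.pvalues.min(axis=1) < alpha
    return list(res.pvalues.index[mask])


def _pair_pvalue(res: DeResult, stage_a: str, stage_b: str, gene: str) -> float:
    for sa, sb in STAGE_PAIRS:
        if {sa, sb} == {stage_a, stage_b}:
            return float(res.pvalues.loc[gene, f"{sa}_vs_{sb}"])
    raise KeyError((stage_a, stage_b))


def digital_transform(res: DeResult, alpha: float | None = None) -> pd.DataFrame:
    """Integer tiers 1-3 per gene and stage.

    The three stage means are ordered ascending (ties broken by the fixed
    stage order roots < incipient < nodules); the lowest stage gets tier 1 and
    walking up, the tier increments only when the pairwise p-value against the
    representative stage of the current tier is below alpha; otherwise the
    stage joins the current tier.
    """
    alpha = res.alpha if alpha is None else alpha
    out = pd.DataFrame(0, index=res.stage_means.index, columns=list(STAGES), dtype=int)
    stage_rank = {s: i for i, s in enumerate(STAGES)}
    for gene in res.stage_means.index:
        means = res.stage_means.loc[gene]
        order = sorted(STAGES, key=lambda s: (means[s], stage_rank[s]))
        tier = 1
        representative = order[0]
        tiers = {order[0]: 1}
        for stage in order[1:]:
            if _pair_pvalue(res, representative, stage, gene) < alpha:
                tier += 1
                representative = stage
            tiers[stage] = tier
        out.loc[gene] = [tiers[s] for s in STAGES]
    return out
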