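"""Rule-based classification of Fix- mutants into the four developmental
categories, wave/marker consistency checking, and detection of genes induced
across all mutants.

The four categories follow where nodule development is blocked:

* cat1 -- nodules with differentiated symbiotic cells and differentiated
  bacteroids that nevertheless do not fix nitrogen (senescence-prone
  mutants); both transcriptome waves passed.
* cat2 -- differentiated, infected plant cells whose bacteroids fail to
  differentiate (bacA-like); wave 1 passed, wave 2 not.
* cat3 -- infected nodules with an infection-thread network but no
  differentiated symbiotic cells (TR3/TE7-like); root-like transcriptome.
* cat4 -- empty, uninfected nodules (V1/exoY-like); root-like transcriptome.

Differentiation markers (ploidy/EI and bacteroid morphology) define the
category; the transcriptome wave calls corroborate it via a consistency
flag rather than entering the decision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .arrays import ExpressionMatrix
from .differentiation import DIFFERENTIATED, INDETERMINATE, UNDIFFERENTIATED

CAT1 = "cat1_fix_minus_fully_differentiated"
CAT2 = "cat2_bacteroid_undifferentiated"
CAT3 = "cat3_infected_no_symbiotic_cells"
CAT4 = "cat4_empty_uninfected"
WILD_TYPE_LIKE = "wild_type_like"
MUTANT_CATEGORIES = (CAT1, CAT2, CAT3, CAT4)

#: Expected (wave1, wave2) pattern per category.
EXPECTED_WAVES = {
    CAT1: (True, True),
    WILD_TYPE_LIKE: (True, True),
    CAT2: (True, False),
    CAT3: (False, False),
    CAT4: (False, False),
}


class ClassificationError(ValueError):
    pass


@dataclass
class MutantObservation:
    """Fused evidence record for one genotype.

    ``bacteroid_diff`` must be None exactly when the nodule is uninfected
    (no bacteria to assess).  ``nitrogen_fixing`` separates the wild type
    from category-1 mutants, which share every differentiation marker.
    """

    genotype: str
    infected: bool
    infection_thread_network: bool
    cell_diff: str  # differentiated / undifferentiated / indeterminate
    bacteroid_diff: bool | None
    wave1_active: bool
    wave2_active: bool
    nitrogen_fixing: bool = False

    def validate(self) -> None:
        if (self.bacteroid_diff is None) != (not self.infected):
            raise ClassificationError(
                f"{self.genotype}: bacteroid_diff must be not-applicable (None) "
                "exactly when the nodule is uninfected"
            )
        if self.cell_diff not in (DIFFERENTIATED, UNDIFFERENTIATED, INDETERMINATE):
            raise ClassificationError(
                f"{self.genotype}: unknown cell_diff value {self.cell_diff!r}"
            )


@dataclass
class MutantCategory:
    genotype: str
    category: str
    consistent: bool
    expected_waves: tuple[bool, bool]
    observed_waves: tuple[bool, bool]


def classify_mutant(obs: MutantObservation) -> MutantCategory:
    """Apply the marker rule table and flag wave consistency.

    Raises for indeterminate cell differentiation (more data needed) and for
    the marker combination differentiated-but-uninfected, which the study
    system cannot produce.
    """
    obs.validate()
    if obs.cell_diff == INDETERMINATE:
        raise ClassificationError(
            f"{obs.genotype}: endoreduplication index in the indeterminate band; "
            "more ploidy data needed before classification"
        )
    if obs.cell_diff == UNDIFFERENTIATED:
        if not obs.infected:
            category = CAT4
        elif obs.infection_thread_network:
            category = CAT3
        else:
            raise ClassificationError(
                f"{obs.genotype}: infected without an infection-thread network "
                "yet undifferentiated; inconsistent evidence"
            )
    else:  # differentiated symbiotic cells
        if not obs.infected:
            raise ClassificationError(
                f"{obs.genotype}: differentiated symbiotic cells without "
                "infection; inconsistent evidence"
            )
        if obs.bacteroid_diff:
            category = WILD_TYPE_LIKE if obs.nitrogen_fixing else CAT1
        else:
            category = CAT2
    expected = EXPECTED_WAVES[category]
    observed = (obs.wave1_active, obs.wave2_active)
    return MutantCategory(
        genotype=obs.genotype,
        category=category,
        consistent=expected == observed,
        expected_waves=expected,
        observed_waves=observed,
    )


def classify_panel(
    observations: Iterable[MutantObservation],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every genotype; returns the category table and summary counts
    (plus the number of distinct mutant categories present)."""
    observations = list(observations)
    if not observations:
        raise ClassificationError("empty observation panel")
    rows = []
    for obs in sorted(observations, key=lambda o: o.genotype):
        result = classify_mutant(obs)
        rows.append(
            {
                "genotype": result.genotype,
                "category": result.category,
                "consistent": result.consistent,
                "wave1_active": result.observed_waves[0],
                "wave2_active": result.observed_waves[1],
            }
        )
    table = pd.DataFrame(rows).set_index("genotype")
    counts = table["category"].value_counts().to_dict()
    counts["n_distinct_mutant_categories"] = int(
        table["category"].isin(MUTANT_CATEGORIES).groupby(table["category"]).any().sum()
    )
    return table, counts


def common_induced_genes(
    expr: ExpressionMatrix,
    mutant_arrays: Mapping[str, Sequence[str]],
    root_arrays: Sequence[str],
    alpha: float = 0.01,
) -> list[str]:
    """Genes induced over roots in every queried mutant.

    Per mutant, a one-sided (greater) Welch t-test of its arrays against the
    root arrays is run per gene; genes with p < alpha in every mutant are
    returned (intersection).
    """
    if not mutant_arrays:
        raise ClassificationError("empty mutant list")
    root_arrays = [a for a in root_arrays if a in expr.values.columns]
    if len(root_arrays) < 2:
        raise ClassificationError("need at least 2 root arrays")
    roots = expr.values[root_arrays].to_numpy(dtype=float)
    keep = np.ones(len(expr.values), dtype=bool)
    for genotype, arrays in mutant_arrays.items():
        arrays = [a for a in arrays if a in expr.values.columns]
        if len(arrays) < 2:
            raise ClassificationError(f"mutant {genotype!r} has fewer than 2 arrays")
        x = expr.values[arrays].to_numpy(dtype=float)
        res = stats.ttest_ind(x, roots, axis=1, equal_var=False, alternative="greater")
        p = np.asarray(res.pvalue, dtype=float)
        # degenerate (near-)zero-variance rows: decide by the mean direction
        mx, mr = x.mean(axis=1), roots.mean(axis=1)
        scale = np.maximum.reduce([np.abs(mx), np.abs(mr), np.ones_like(mx)])
        tol = (1e-9 * scale) ** 2
        vx = x.var(axis=1, ddof=1)
        vr = roots.var(axis=1, ddof=1)
        degenerate = (vx <= tol) & (vr <= tol)
        if degenerate.any():
            greater = mx > mr + 1e-9 * scale
            p[degenerate & greater] = 0.0
            p[degenerate & ~greater] = 1.0
        p = np.where(np.isnan(p), 1.0, p)
        keep &= p < alpha
    return list(expr.values.index[keep])


# ---------------------------------------------------------------------------
# Evidence-table I/O
# ---------------------------------------------------------------------------

EVIDENCE_COLUMNS = (
    "genotype",
    "infected",
    "infection_thread_network",
    "cell_diff",
    "bacteroid_diff",
    "wave1_active",
    "wave2_active",
    "nitrogen_fixing",
)


def read_evidence_table(path: str | Path) -> list[MutantObservation]:
    """Tab-delimited evidence table -> observations.

    ``bacteroid_diff`` accepts true/false/NA (NA = no bacteria to assess).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("NA")
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ClassificationError(f"evidence table missing columns {sorted(missing)}")

    def to_bool(v: str) -> bool:
        return str(v).strip().lower() in ("true", "1", "yes")

    out = []
    for row in df.itertuples(index=False):
        bd = str(row.bacteroid_diff).strip().lower()
        out.append(
            MutantObservation(
                genotype=row.genotype,
                infected=to_bool(row.infected),
                infection_thread_network=to_bool(row.infection_thread_network),
                cell_diff=str(row.cell_diff).strip(),
                bacteroid_diff=None if bd in ("na", "none", "") else bd in ("true", "1", "yes"),
                wave1_active=to_bool(row.wave1_active),
                wave2_active=to_bool(row.wave2_active),
                nitrogen_fixing=to_bool(row.nitrogen_fixing),
            )
        )
    return out


def write_category_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")
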