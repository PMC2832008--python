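"""Secretome categorization and Fisher's exact enrichment testing.

Each gene is assigned to one of four mutually exclusive secretory-pathway
categories from predictor-derived annotation flags (signal peptide,
transmembrane domain count, curated secretory-system membership, protein
length).  A gene set (e.g. the activation-wave profiles) is then tested for
enrichment or depletion of each category against the full probe-set
background with a two-sided Fisher's exact test.  The hypergeometric tail is
summed in log space so that p-values far below double underflow territory
(the study's headline enrichments are of order 1e-52) keep a meaningful
log10(p).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

SECRETORY_SYSTEM = "secretory_system"
MEMBRANE_PROTEIN = "membrane_protein"
SECRETORY_PROTEIN = "secretory_protein"
NON_SECRETORY = "non_secretory"
CATEGORIES = (SECRETORY_SYSTEM, MEMBRANE_PROTEIN, SECRETORY_PROTEIN, NON_SECRETORY)

#: Combined "protein secretion" super-category (everything except non-secretory).
PROTEIN_SECRETION = "protein_secretion"

#: Secreted peptides: secretory proteins shorter than 220 aa (signal peptide included).
PEPTIDE_LENGTH_CUTOFF = 220


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    signal_peptide: bool
    tm_domain_count: int
    secretory_system: bool
    protein_length_aa: int


@dataclass(frozen=True)
class SecretomeCategory:
    category: str
    peptide: bool = False


def categorize_gene(a: GeneAnnotation) -> SecretomeCategory:
    """Assign the single category of a gene.

    Precedence: curated secretory-system membership beats everything; a
    transmembrane domain (including signal-anchor ambiguity, sp=true with
    tm>=1) makes a membrane protein; a signal peptide without transmembrane
    domains makes a secretory protein, sub-classed as peptide when shorter
    than 220 aa; otherwise non-secretory.
    """
    if a.secretory_system:
        return SecretomeCategory(SECRETORY_SYSTEM)
    if a.tm_domain_count >= 1:
        return SecretomeCategory(MEMBRANE_PROTEIN)
    if a.signal_peptide:
        return SecretomeCategory(
            SECRETORY_PROTEIN, peptide=a.protein_length_aa < PEPTIDE_LENGTH_CUTOFF
        )
    return SecretomeCategory(NON_SECRETORY)


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Tab-delimited annotation: gene_id, signal_peptide, tm_domain_count,
    secretory_system, length_aa."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "signal_peptide", "tm_domain_count", "secretory_system", "length_aa"}
    missing = required - set(df.columns)
    if missing:
        raise EnrichmentError(f"annotation table missing columns {sorted(missing)}")
    for col in ("signal_peptide", "secretory_system"):
        df[col] = df[col].astype(bool)
    return df


def categorize_table(annotations: pd.DataFrame) -> pd.DataFrame:
    """Add category/peptide columns to an annotation table."""
    cats, peps = [], []
    for row in annotations.itertuples(index=False):
        c = categorize_gene(
            GeneAnnotation(
                gene_id=row.gene_id,
                signal_peptide=bool(row.signal_peptide),
                tm_domain_count=int(row.tm_domain_count),
                secretory_system=bool(row.secretory_system),
                protein_length_aa=int(row.length_aa),
            )
        )
        cats.append(c.category)
        peps.append(c.peptide)
    out = annotations.copy()
    out["category"] = cats
    out["peptide"] = peps
    return out


# ---------------------------------------------------------------------------
# Fisher's exact test in log space
# ---------------------------------------------------------------------------


def _log_hypergeom_pmf(k: np.ndarray, row1: int, row2: int, col1: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeom drawing col1 items from row1 marked /
    row2 unmarked."""

    def logc(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    return logc(row1, k) + logc(row2, col1 - k) - logc(row1 + row2, col1)


def fisher_exact_log(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the table [[a, b], [c, d]].

    Returns (p, log10 p).  The two-sided p sums, over the support of the
    hypergeometric distribution with the table's margins, the probabilities
    of all tables at most as probable as the observed one (with a 1e-7
    relative tie tolerance); the summation runs in log space and remains
    accurate far below double underflow.
    """
    if min(a, b, c, d) < 0:
        raise EnrichmentError("negative cell count")
    row1, row2, col1 = a + b, c + d, a + c
    lo, hi = max(0, col1 - row2), min(col1, row1)
    k = np.arange(lo, hi + 1)
    logpmf = _log_hypergeom_pmf(k, row1, row2, col1)
    log_obs = logpmf[a - lo]
    include = logpmf <= log_obs + np.log1p(1e-7)
    logp = float(logsumexp(logpmf[include]))
    logp = min(logp, 0.0)
    return float(np.exp(logp)), logp / np.log(10.0)


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5  # Haldane-Anscombe
    return (a * d) / (b * c)


def fisher_enrichment(
    set_genes: Iterable[str],
    background_genes: Iterable[str],
    annotations: pd.DataFrame,
    categories: Sequence[str] = CATEGORIES + (PROTEIN_SECRETION,),
) -> pd.DataFrame:
    """Category enrichment of ``set_genes`` against ``background_genes``.

    The set must be a subset of the background.  For every category a 2x2
    table (in-set vs rest-of-background, category vs not) is tested two-sided;
    the odds ratio uses the Haldane-Anscombe correction when a cell is zero.
    """
    set_genes = set(set_genes)
    background = set(background_genes)
    if not set_genes:
        raise EnrichmentError("empty gene set")
    if not set_genes <= background:
        raise EnrichmentError("gene set is not a subset of the background")
    cat = categorize_table(annotations).set_index("gene_id")["category"]
    cat = cat[cat.index.isin(background)]
    if cat.nunique() < 2:
        raise EnrichmentError("background must contain at least 2 categories")
    in_set = cat.index.isin(set_genes)
    rows = []
    for category in categories:
        if category == PROTEIN_SECRETION:
            has = cat != NON_SECRETORY
        else:
            has = cat == category
        a = int((has & in_set).sum())
        b = int((~has & in_set).sum())
        c = int((has & ~in_set).sum())
        d = int((~has & ~in_set).sum())
        p, log10p = fisher_exact_log(a, b, c, d)
        odds = _odds_ratio(a, b, c, d)
        set_frac = a / max(a + b, 1)
        bg_frac = (a + c) / max(a + b + c + d, 1)
        rows.append(
            {
                "category": category,
                "set_with": a,
                "set_without": b,
                "rest_with": c,
                "rest_without": d,
                "odds_ratio": odds,
                "p_value": p,
                "log10_p": log10p,
                "direction": "enriched" if set_frac > bg_frac else (
                    "depleted" if set_frac < bg_frac else "equal"
                ),
            }
        )
    return pd.DataFrame(rows).set_index("category")


def write_enrichment(result: pd.DataFrame, path: str | Path) -> None:
    result.to_csv(path, sep="\t")
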