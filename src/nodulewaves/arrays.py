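"""Two-channel spot tables, replicate collapse, invariant-gene selection and
median normalization.

The arrays are two-colour hybridizations of a Cy5-labelled sample against a
common Cy3-labelled reference, so each spot yields a sample/reference intensity
ratio.  Global intensity differences between arrays (the Cy5 channel of root
samples is systematically dimmer than that of nodule samples on a nodule-cDNA
probe set) are removed by scaling every array by the median ratio of a set of
invariant genes.  Invariance is scored relative to a constitutive anchor gene
spotted many times across the slide: the genes whose log-ratio to the anchor is
most stable across all arrays are taken as the invariant set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SPOT_COLUMNS = (
    "spot_id",
    "gene_id",
    "replicate_index",
    "sample_intensity",
    "reference_intensity",
)


class SpotTableError(ValueError):
    """Malformed or invalid spot-table content."""


class ParseError(SpotTableError):
    """Unparseable row; carries the 1-based line number."""


class NormalizationError(ValueError):
    """Invariant-set or scale problems during normalization."""


@dataclass
class SpotTable:
    """One array's spot-level intensities.

    ``data`` has columns spot_id, gene_id, replicate_index, sample_intensity,
    reference_intensity.  ``genotype``/``dpi`` are optional array metadata
    (parsed from the file name by :func:`read_spot_table` when it follows the
    ``<genotype>__<dpi>dpi__r<rep>`` convention).
    """

    array_id: str
    data: pd.DataFrame
    genotype: str | None = None
    dpi: float | None = None

    def replicate_counts(self) -> pd.Series:
        return self.data.groupby("gene_id").size()


@dataclass
class RatioMatrix:
    """Per-gene sample/reference ratios (genes x arrays) with array metadata."""

    ratios: pd.DataFrame
    metadata: pd.DataFrame  # index: array_id; columns: genotype, dpi

    @property
    def array_ids(self) -> list[str]:
        return list(self.ratios.columns)


@dataclass
class ExpressionMatrix:
    """Normalized log2 sample/reference ratios (genes x arrays).

    ``scales`` records the per-array normalization factor (the median raw
    ratio over the invariant genes); ``invariant_genes`` the set used.
    """

    values: pd.DataFrame
    scales: pd.Series
    invariant_genes: list[str]
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def linear(self) -> pd.DataFrame:
        return np.exp2(self.values)


def _parse_array_filename(stem: str) -> tuple[str | None, float | None]:
    parts = stem.split("__")
    genotype = parts[0] if parts else None
    dpi = None
    for part in parts[1:]:
        if part.endswith("dpi"):
            try:
                dpi = float(part[:-3])
            except ValueError:
                pass
    return genotype, dpi


def read_spot_table(path: str | Path) -> SpotTable:
    """Read a tab-delimited spot table, validating row by row.

    Raises :class:`ParseError` naming the offending line for non-numeric
    intensities and :class:`SpotTableError` for negative intensities or a
    wrong header.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if tuple(raw.columns) != SPOT_COLUMNS:
        raise SpotTableError(
            f"{path}: expected columns {SPOT_COLUMNS}, found {tuple(raw.columns)}"
        )
    out = raw.copy()
    for col in ("sample_intensity", "reference_intensity"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna()
        if bad.any():
            # +2: header line plus 1-based indexing
            line = int(bad.idxmax()) + 2
            raise ParseError(
                f"{path}: line {line}: cannot parse {col} value {raw[col][bad.idxmax()]!r}"
            )
        if (vals < 0).any():
            line = int((vals < 0).idxmax()) + 2
            raise SpotTableError(f"{path}: line {line}: negative {col}")
        out[col] = vals
    out["replicate_index"] = pd.to_numeric(out["replicate_index"]).astype(int)
    if (out["gene_id"].astype(str).str.len() == 0).any() or out["gene_id"].isna().any():
        raise SpotTableError(f"{path}: empty gene_id")
    genotype, dpi = _parse_array_filename(path.stem)
    return SpotTable(array_id=path.stem, data=out, genotype=genotype, dpi=dpi)


def write_spot_table(table: SpotTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def collapse_replicates(table: SpotTable) -> tuple[pd.Series, list[str]]:
    """Median per-gene sample/reference ratio over replicate spots.

    Spots with a non-positive intensity in either channel are dropped before
    taking the median; genes with no usable spot are excluded and returned in
    the second element.
    """
    d = table.data
    usable = (d["sample_intensity"] > 0) & (d["reference_intensity"] > 0)
    good = d[usable]
    ratios = (
        (good["sample_intensity"] / good["reference_intensity"])
        .groupby(good["gene_id"])
        .median()
    )
    excluded = sorted(set(d["gene_id"]) - set(ratios.index))
    return ratios, excluded


def build_ratio_matrix(tables: Iterable[SpotTable]) -> RatioMatrix:
    """Collapse each array and assemble the genes x arrays ratio matrix."""
    cols: dict[str, pd.Series] = {}
    meta: list[dict] = []
    for t in tables:
        ratios, _ = collapse_replicates(t)
        cols[t.array_id] = ratios
        meta.append({"array_id": t.array_id, "genotype": t.genotype, "dpi": t.dpi})
    ratios = pd.DataFrame(cols).sort_index()
    metadata = pd.DataFrame(meta).set_index("array_id")
    return RatioMatrix(ratios=ratios, metadata=metadata)


def select_invariant_genes(raw: RatioMatrix, anchor_id: str, n: int) -> list[str]:
    """The ``n`` genes whose expression is most stable relative to the anchor.

    Score per gene: standard deviation across arrays of
    log2(gene ratio / anchor ratio); the n lowest-scoring genes are returned,
    ties broken by gene_id lexicographic order.  The anchor itself is the
    scoring reference and is not eligible; neither are genes with a missing
    or non-positive ratio on any array.
    """
    if anchor_id not in raw.ratios.index:
        raise NormalizationError(f"anchor gene {anchor_id!r} absent from the matrix")
    anchor = raw.ratios.loc[anchor_id]
    if anchor.isna().any() or (anchor <= 0).any():
        raise NormalizationError(f"anchor gene {anchor_id!r} missing on some array")
    ok = raw.ratios.notna().all(axis=1) & (raw.ratios > 0).all(axis=1)
    ok[anchor_id] = False
    candidates = raw.ratios[ok]
    if n > len(candidates):
        raise NormalizationError(
            f"requested {n} invariant genes but only {len(candidates)} are scorable"
        )
    rel = np.log2(candidates.divide(anchor, axis=1))
    score = rel.std(axis=1, ddof=0)
    order = (
        pd.DataFrame({"score": score, "gene": score.index.astype(str)})
        .reset_index(drop=True)
        .sort_values(["score", "gene"], kind="mergesort")
    )
    return list(order["gene"].iloc[:n])


def normalize_arrays(raw: RatioMatrix, invariant: Sequence[str]) -> ExpressionMatrix:
    """Scale every array by the median raw ratio over the invariant genes.

    The normalized matrix is stored as log2 ratios; by construction the median
    of the normalized linear ratio over the invariant set is 1 on every array.
    """
    invariant = list(invariant)
    if not invariant:
        raise NormalizationError("empty invariant gene set")
    missing = set(invariant) - set(raw.ratios.index)
    if missing:
        raise NormalizationError(f"invariant genes absent from matrix: {sorted(missing)[:5]}")
    scales = raw.ratios.loc[invariant].median(axis=0)
    if not np.isfinite(scales).all() or (scales <= 0).any():
        bad = scales.index[~np.isfinite(scales) | (scales <= 0)].tolist()
        raise NormalizationError(f"non-positive or non-finite scale for arrays {bad}")
    normalized = raw.ratios.divide(scales, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.log2(normalized)
    values[normalized <= 0] = np.nan
    return ExpressionMatrix(
        values=values,
        scales=scales,
        invariant_genes=invariant,
        metadata=raw.metadata.copy(),
    )


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    """Tab-delimited matrix (first column gene_id) plus a JSON sidecar with
    scales, invariant set and array metadata."""
    path = Path(path)
    expr.values.rename_axis("gene_id").to_csv(path, sep="\t")
    sidecar = {
        "scales": {k: float(v) for k, v in expr.scales.items()},
        "invariant_genes": list(expr.invariant_genes),
        "metadata": json.loads(expr.metadata.reset_index().to_json(orient="records")),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col="gene_id")
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    metadata = pd.DataFrame(sidecar["metadata"])
    if not metadata.empty:
        metadata = metadata.set_index("array_id")
    return ExpressionMatrix(
        values=values,
        scales=pd.Series(sidecar["scales"]),
        invariant_genes=list(sidecar["invariant_genes"]),
        metadata=metadata,
    )
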