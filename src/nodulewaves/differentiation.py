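"""Ploidy quantification, endoreduplication index and bacteroid differentiation.

Flow-cytometry DAPI histograms carry peaks at geometric positions
anchor x 2^j for the ploidy classes 2C..64C.  Each bin's mass is assigned to
the nearest expected peak in log2 fluorescence, giving per-class percentages;
replicate measurements are averaged after per-replicate quantification.  The
endoreduplication index EI = %16C*3 + %32C*4 + %64C*5 summarises high-ploidy
content: roots and nodules without symbiotic-cell differentiation stay below
2 while differentiated nodules exceed 15.  Bacteroid differentiation is
called from the fold ratio of mean cell length between nodule-derived
bacteria and cultured rods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .profiles import linkage_to_newick

PLOIDY_CLASSES = (2, 4, 8, 16, 32, 64)
#: EI weights for the high-ploidy classes.
EI_WEIGHTS = {16: 3.0, 32: 4.0, 64: 5.0}
#: EI decision bounds: below the first -> undifferentiated, above the second
#: -> differentiated symbiotic cells.
EI_LOW, EI_HIGH = 2.0, 15.0

DIFFERENTIATED = "differentiated"
UNDIFFERENTIATED = "undifferentiated"
INDETERMINATE = "indeterminate"


class PloidyError(ValueError):
    pass


@dataclass
class PloidyHistogram:
    """One replicate's binned DAPI fluorescence (linear a.u.)."""

    bin_centers: np.ndarray
    counts: np.ndarray
    sample_id: str = ""
    replicate: int = 0

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.bin_centers) != len(self.counts):
            raise PloidyError("bin_centers and counts differ in length")
        if (self.counts < 0).any():
            raise PloidyError("negative counts")
        if (np.diff(self.bin_centers) <= 0).any():
            raise PloidyError("bin centers must be strictly increasing")


@dataclass
class PloidyProfile:
    """Percent of nuclei per ploidy class (sums to 100)."""

    percentages: dict[int, float]
    n_nuclei: float
    sample_id: str = ""
    replicate_averaged: bool = False

    def as_vector(self) -> np.ndarray:
        return np.array([self.percentages[c] for c in PLOIDY_CLASSES])


@dataclass
class BacteroidCall:
    mean_nodule: float
    mean_cultured: float
    fold: float
    differentiated: bool
    threshold: float


def _fractions_single(h: PloidyHistogram, anchor_2c: float) -> tuple[np.ndarray, float]:
    total = h.counts.sum()
    if total <= 0:
        raise PloidyError(f"histogram {h.sample_id!r} is empty")
    centers = np.log2(np.maximum(h.bin_centers, 1e-300) / anchor_2c)
    # nearest expected peak in log2 space; peaks sit at j = 0..5
    j = np.clip(np.rint(centers), 0, len(PLOIDY_CLASSES) - 1).astype(int)
    percents = np.zeros(len(PLOIDY_CLASSES))
    for cls_idx in range(len(PLOIDY_CLASSES)):
        percents[cls_idx] = h.counts[j == cls_idx].sum()
    return percents / total * 100.0, float(total)


def call_ploidy_fractions(
    histograms: PloidyHistogram | Sequence[PloidyHistogram], anchor_2c: float
) -> PloidyProfile:
    """Per-class percentages from one histogram or several replicates.

    Expected class centers sit at anchor_2c x 2^j (j = 0..5); every bin's
    mass goes to the nearest center in log2 fluorescence.  With replicates,
    percentages are computed per replicate and then averaged.
    """
    if anchor_2c is None or not np.isfinite(anchor_2c) or anchor_2c <= 0:
        raise PloidyError("anchor_2c must be a positive fluorescence position")
    if isinstance(histograms, PloidyHistogram):
        histograms = [histograms]
    histograms = list(histograms)
    if not histograms:
        raise PloidyError("no histograms given")
    per_rep = []
    total = 0.0
    for h in histograms:
        percents, n = _fractions_single(h, anchor_2c)
        per_rep.append(percents)
        total += n
    mean = np.mean(per_rep, axis=0)
    return PloidyProfile(
        percentages={c: float(v) for c, v in zip(PLOIDY_CLASSES, mean)},
        n_nuclei=total,
        sample_id=histograms[0].sample_id,
        replicate_averaged=len(histograms) > 1,
    )


def estimate_anchor_2c(h: PloidyHistogram, min_fraction: float = 0.02) -> float:
    """Estimate the 2C peak position as the lowest prominent local maximum.

    Optional calibration mode for runs without an instrument anchor: the
    histogram is scanned from low fluorescence and the first bin that is a
    local maximum carrying at least ``min_fraction`` of the total mass within
    its half-octave neighbourhood is returned.
    """
    total = h.counts.sum()
    if total <= 0:
        raise PloidyError("empty histogram")
    order = np.argsort(h.bin_centers)
    centers, counts = h.bin_centers[order], h.counts[order]
    for i in range(len(centers)):
        lo, hi = centers[i] / 2 ** 0.5, centers[i] * 2 ** 0.5
        window = (centers >= lo) & (centers <= hi)
        if counts[window].sum() < min_fraction * total:
            continue
        if counts[i] == counts[window].max():
            return float(centers[i])
    raise PloidyError("no prominent peak found")


def endoreduplication_index(p: PloidyProfile) -> float:
    """EI = %16C*3 + %32C*4 + %64C*5."""
    return float(sum(p.percentages.get(c, 0.0) * w for c, w in EI_WEIGHTS.items()))


def classify_symbiotic_cell_differentiation(
    ei: float, low: float = EI_LOW, high: float = EI_HIGH
) -> str:
    """EI < low -> undifferentiated; EI > high -> differentiated; otherwise
    indeterminate (the study's samples never fall in the gap)."""
    if ei < low:
        return UNDIFFERENTIATED
    if ei > high:
        return DIFFERENTIATED
    return INDETERMINATE


def max_occupied_class(p: PloidyProfile, floor_percent: float = 0.5) -> int:
    """Largest ploidy class whose fraction exceeds the occupancy floor."""
    occupied = [c for c in PLOIDY_CLASSES if p.percentages.get(c, 0.0) > floor_percent]
    if not occupied:
        raise PloidyError("no ploidy class above the occupancy floor")
    return max(occupied)


def profiles_to_frame(profiles: Sequence[PloidyProfile]) -> pd.DataFrame:
    rows = {p.sample_id: p.as_vector() for p in profiles}
    return pd.DataFrame.from_dict(rows, orient="index", columns=[f"{c}C" for c in PLOIDY_CLASSES])


def cluster_ploidy_profiles(
    profiles: Sequence[PloidyProfile] | pd.DataFrame, k: int = 2
) -> tuple[pd.Series, np.ndarray, str]:
    """Hierarchical clustering (Euclidean, average linkage) of the
    6-dimensional percentage vectors; returns (labels at k, linkage, newick).

    At k=2 this reproduces the root-like vs nodule-like split of the study's
    archetypal ploidy profiles.
    """
    frame = profiles if isinstance(profiles, pd.DataFrame) else profiles_to_frame(profiles)
    if len(frame) < 2:
        raise PloidyError("need at least 2 profiles to cluster")
    linkage = hierarchy.linkage(pdist(frame.to_numpy(), metric="euclidean"), method="average")
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=frame.index, name="cluster")
    return labels, linkage, linkage_to_newick(linkage, list(frame.index))


def classify_bacteroid_differentiation(
    nodule_lengths: Sequence[float],
    cultured_lengths: Sequence[float],
    threshold: float = 2.5,
) -> BacteroidCall:
    """Call terminal bacteroid differentiation from cell-length samples.

    The fold ratio of mean lengths (nodule-derived over cultured) reaches
    4-5x for fully differentiated bacteroids and about 1x for
    undifferentiated rhizobia; the call is differentiated when
    fold >= threshold (boundary inclusive).
    """
    nodule = np.asarray(nodule_lengths, dtype=float)
    cultured = np.asarray(cultured_lengths, dtype=float)
    if len(nodule) < 10 or len(cultured) < 10:
        raise PloidyError("need at least 10 lengths per sample")
    mean_nodule = float(nodule.mean())
    mean_cultured = float(cultured.mean())
    if mean_cultured <= 0:
        raise PloidyError("non-positive cultured mean length")
    fold = mean_nodule / mean_cultured
    return BacteroidCall(
        mean_nodule=mean_nodule,
        mean_cultured=mean_cultured,
        fold=fold,
        differentiated=fold >= threshold,
        threshold=threshold,
    )
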