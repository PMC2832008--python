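"""Efficiency-corrected relative quantification of qPCR crossing points.

The relative expression of a target transcript in a sample, against a
reference (constitutive control) transcript and a calibrator sample, is

    ratio = E_target^(CP_target,cal - CP_target,sample)
          / E_ref^(CP_ref,cal - CP_ref,sample)

with per-primer amplification efficiencies E in (1, 2] (2 = perfect
doubling).  Ratios are computed per biological replicate and averaged; fold
changes are reported relative to the sample with the lowest mean ratio,
which is scaled to exactly 1.  With E_target = E_ref = 2 the method reduces
to the classical 2^(-ddCP) calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class QpcrError(ValueError):
    pass


@dataclass
class QpcrDataset:
    """Crossing points plus per-transcript efficiencies.

    ``cp`` columns: transcript, sample, replicate, cp.  Technical replicates
    may appear as repeated (transcript, sample, replicate) rows; they are
    averaged at the CP level before ratio computation.
    """

    cp: pd.DataFrame
    efficiencies: dict[str, float]
    reference_transcript: str

    def validate(self) -> None:
        required = {"transcript", "sample", "replicate", "cp"}
        missing = required - set(self.cp.columns)
        if missing:
            raise QpcrError(f"CP table missing columns {sorted(missing)}")
        if not np.isfinite(self.cp["cp"].to_numpy(dtype=float)).all():
            raise QpcrError("non-finite CP value")
        for t, e in self.efficiencies.items():
            if not (1.0 < e <= 2.0):
                raise QpcrError(f"efficiency for {t!r} is {e}; must be in (1, 2]")
        samples = set(self.cp["sample"])
        ref = self.cp[self.cp["transcript"] == self.reference_transcript]
        if set(ref["sample"]) != samples:
            raise QpcrError("reference transcript missing from some samples")


@dataclass
class RelativeExpression:
    """Per-sample fold change (min sample = 1) with replicate mean and sd."""

    target: str
    table: pd.DataFrame  # index: sample; columns: mean_fold, sd_fold, n_replicates
    calibrator: str

    @property
    def folds(self) -> pd.Series:
        return self.table["mean_fold"]


def efficiency_from_percent(percent: float) -> float:
    """Convert a percent amplification efficiency (100 = perfect) to base E."""
    return 1.0 + percent / 100.0


def pfaffl_relative_expression(
    ds: QpcrDataset, target: str, samples: Sequence[str] | None = None
) -> RelativeExpression:
    """Efficiency-corrected fold changes of ``target`` across samples.

    The calibrator is the sample with the lowest mean ratio; replicate
    ratios are averaged per sample and the minimum mean is scaled to
    exactly 1.
    """
    ds.validate()
    if target == ds.reference_transcript:
        raise QpcrError("target must differ from the reference transcript")
    for t in (target, ds.reference_transcript):
        if t not in ds.efficiencies:
            raise QpcrError(f"missing efficiency for {t!r}")
    e_t = ds.efficiencies[target]
    e_r = ds.efficiencies[ds.reference_transcript]

    # collapse technical replicates, then build (sample, replicate) CP tables
    cp = (
        ds.cp.groupby(["transcript", "sample", "replicate"])["cp"].mean().reset_index()
    )
    t_cp = cp[cp["transcript"] == target].pivot(index="replicate", columns="sample", values="cp")
    r_cp = cp[cp["transcript"] == ds.reference_transcript].pivot(
        index="replicate", columns="sample", values="cp"
    )
    if samples is not None:
        t_cp, r_cp = t_cp[list(samples)], r_cp[list(samples)]
    if t_cp.isna().all().any():
        raise QpcrError("target CP missing for some sample")

    def ratios_vs(cal_t: float, cal_r: float) -> pd.DataFrame:
        return e_t ** (cal_t - t_cp) / e_r ** (cal_r - r_cp)

    # provisional calibrator: first sample's mean CPs, then re-anchor on the
    # sample with the lowest mean ratio
    provisional = ratios_vs(t_cp.iloc[:, 0].mean(), r_cp.iloc[:, 0].mean())
    calibrator = provisional.mean(axis=0).idxmin()
    ratios = ratios_vs(t_cp[calibrator].mean(), r_cp[calibrator].mean())
    means = ratios.mean(axis=0)
    sds = ratios.std(axis=0, ddof=1).fillna(0.0)
    scale = means.min()
    table = pd.DataFrame(
        {
            "mean_fold": means / scale,
            "sd_fold": sds / scale,
            "n_replicates": ratios.notna().sum(axis=0),
        }
    )
    table.index.name = "sample"
    return RelativeExpression(target=target, table=table, calibrator=str(calibrator))


def read_cp_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_efficiencies(path: str | Path) -> dict[str, float]:
    """Two-column table (transcript, efficiency); values above 2 are treated
    as percent efficiencies and converted to base E."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        e = float(row[1])
        out[str(row[0])] = efficiency_from_percent(e) if e > 2.0 else e
    return out


def write_relative_expression(rel: RelativeExpression, path: str | Path) -> None:
    rel.table.to_csv(path, sep="\t")
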