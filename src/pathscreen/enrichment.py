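"""Fractional representation, replicate averaging, and vehicle normalization.

The deconvolution statistic is deliberately simple: a construct's fractional
representation in a sample is its read count divided by the sample's total
assigned reads; fractions are averaged over technical then biological
replicates; and each drug arm's fractions are divided by the (averaged)
vehicle-arm fractions to give a per-dose enrichment ratio.  A small symmetric
pseudocount keeps ratios finite when a construct drops out of one arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, SchemaError
from .demux_count import CountTable
from .screen_sim import ARM_DRUG, ARM_T0, ARM_VEHICLE, SampleSheet

#: Default pseudocount added symmetrically to drug and vehicle fractions.
DEFAULT_PSEUDOCOUNT = 1e-6


@dataclass
class FractionTable:
    """Fractional representations (constructs x samples), summing to 1 per sample."""

    fractions: pd.DataFrame
    excluded: list[str]  # samples dropped for having zero assigned reads

    def column(self, sample_id) -> pd.Series:
        return self.fractions[sample_id]


@dataclass
class EnrichmentTable:
    """Vehicle-normalized enrichment ratios (constructs x dose labels)."""

    enrichment: pd.DataFrame
    pseudocount: float


def fractional_representation(counts: CountTable) -> FractionTable:
    """Divide each sample's counts by its total assigned reads.

    Samples with zero assigned reads are excluded (with a warning) rather
    than producing NaN columns.
    """
    df = counts.counts.astype(float)
    totals = df.sum(axis=0)
    excluded = [s for s in df.columns if totals[s] == 0]
    if excluded:
        warnings.warn(
            f"excluding samples with zero assigned reads: {excluded}",
            stacklevel=2,
        )
    kept = df.drop(columns=excluded)
    return FractionTable(fractions=kept / kept.sum(axis=0), excluded=excluded)


def average_replicates(
    ft: FractionTable, samplesheet: SampleSheet, geometric: bool = False
) -> FractionTable:
    """Average fractions over technical, then biological, replicates.

    Output columns are ``(arm, dose_label)`` pairs.  The order (technical
    within biological, then across biological) is fixed; both levels use
    the arithmetic mean by default, or the geometric mean with
    ``geometric=True`` (a sensitivity option; zeros propagate to zero).
    """

    def _mean(df: pd.DataFrame) -> pd.Series:
        if geometric:
            return np.exp(np.log(df.where(df > 0)).mean(axis=1)).fillna(0.0)
        return df.mean(axis=1)

    frame = ft.fractions
    meta = {r.sample_id: r for r in samplesheet}
    missing = [s for s in frame.columns if s not in meta]
    if missing:
        raise ConfigurationError(f"samples missing from sample sheet: {missing}")

    bio_means: dict[tuple[str, str, int], pd.Series] = {}
    for s in frame.columns:
        r = meta[s]
        bio_means.setdefault((r.arm, r.dose_label, r.bio_rep), []).append(s)
    if not bio_means:
        raise ConfigurationError("no replicate groups found")

    level1 = {
        key: _mean(frame[cols]) for key, cols in bio_means.items()
    }
    arm_groups: dict[tuple[str, str], list[pd.Series]] = {}
    for (arm, dose, _bio), series in level1.items():
        arm_groups.setdefault((arm, dose), []).append(series)
    averaged = pd.DataFrame(
        {key: _mean(pd.concat(vals, axis=1)) for key, vals in arm_groups.items()}
    )
    averaged.columns = pd.MultiIndex.from_tuples(
        averaged.columns, names=["arm", "dose_label"]
    )
    return FractionTable(fractions=averaged, excluded=list(ft.excluded))


def vehicle_reference(averaged: FractionTable) -> pd.Series:
    """Single vehicle reference: mean of the averaged vehicle-well fractions."""
    frame = averaged.fractions
    if "arm" not in (frame.columns.names or []):
        raise ConfigurationError("expected replicate-averaged (arm, dose) columns")
    vehicle = frame.loc[:, frame.columns.get_level_values("arm") == ARM_VEHICLE]
    if vehicle.shape[1] == 0:
        raise ConfigurationError("no vehicle samples present")
    return vehicle.mean(axis=1)


def normalize_to_vehicle(
    f_drug: pd.DataFrame,
    f_vehicle: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> EnrichmentTable:
    """Per-dose enrichment: (drug fraction + a) / (vehicle fraction + a).

    The pseudocount ``a`` is applied symmetrically and recorded in the
    output.  Both inputs must cover the same construct set.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if set(f_drug.index) != set(f_vehicle.index):
        only_d = sorted(set(f_drug.index) - set(f_vehicle.index))
        only_v = sorted(set(f_vehicle.index) - set(f_drug.index))
        raise SchemaError(
            f"construct sets differ: only in drug {only_d}, only in vehicle {only_v}"
        )
    ref = f_vehicle.reindex(f_drug.index)
    enr = f_drug.add(pseudocount).div(ref + pseudocount, axis=0)
    return EnrichmentTable(enrichment=enr, pseudocount=pseudocount)


def replicate_concordance(fa: pd.Series, fb: pd.Series) -> float:
    """Squared Pearson correlation of paired fractions; NaN if degenerate."""
    if set(fa.index) != set(fb.index):
        raise SchemaError("replicate columns cover different construct sets")
    if len(fa) < 3:
        raise ValueError("need at least 3 constructs")
    b = fb.reindex(fa.index)
    if np.std(fa.to_numpy()) == 0 or np.std(b.to_numpy()) == 0:
        warnings.warn("zero variance in a replicate; r^2 undefined", stacklevel=2)
        return float("nan")
    r = stats.pearsonr(fa.to_numpy(), b.to_numpy()).statistic
    return float(r**2)


def enrichment_from_counts(
    counts: CountTable,
    samplesheet: SampleSheet,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    geometric: bool = False,
) -> tuple[FractionTable, FractionTable, EnrichmentTable]:
    """Chain fractions -> replicate averaging -> vehicle normalization.

    Returns the per-sample fractions, the replicate-averaged fractions, and
    the per-dose enrichment table.  t0 samples, if present, inform neither
    the drug columns nor the vehicle reference.
    """
    ft = fractional_representation(counts)
    averaged = average_replicates(ft, samplesheet, geometric=geometric)
    frame = averaged.fractions
    arms = frame.columns.get_level_values("arm")
    drug = frame.loc[:, arms == ARM_DRUG]
    if drug.shape[1] == 0:
        raise ConfigurationError("no drug samples present; nothing to normalize")
    drug = drug.droplevel("arm", axis=1)
    ref = vehicle_reference(averaged)
    et = normalize_to_vehicle(drug, ref, pseudocount)
    return ft, averaged, et
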