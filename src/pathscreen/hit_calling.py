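"""Pathway-level hit calling against a negative-control baseline.

A pathway scores as a resistance hit when at least one of its activating
constructs shows relative enrichment — vehicle-normalized enrichment divided
by the mean enrichment of the negative-control constructs at that dose —
strictly greater than 1.5 (i.e. >50% above controls) at two or more drug
concentrations.  The two-dose requirement applies per construct: the same
construct must clear the threshold at both doses.  Control constructs never
support a hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .enrichment import EnrichmentTable
from .manifest import LibraryManifest

DEFAULT_THRESHOLD = 1.5
DEFAULT_MIN_DOSES = 2


def control_baseline(
    table: EnrichmentTable | pd.DataFrame,
    manifest: LibraryManifest,
    control_ids: list[str] | None = None,
) -> pd.Series:
    """Per-dose baseline: mean enrichment of the negative-control constructs.

    Defaults to the manifest's negative controls (HcRed and luciferase in
    the packaged library); positive controls such as MEK1-DD are excluded.
    """
    enr = table.enrichment if isinstance(table, EnrichmentTable) else table
    if control_ids is None:
        control_ids = [r.construct_id for r in manifest.negative_controls]
    if not control_ids:
        raise ConfigurationError("no negative-control constructs available")
    missing = [c for c in control_ids if c not in enr.index]
    if missing:
        raise ConfigurationError(f"controls absent from enrichment table: {missing}")
    baseline = enr.loc[control_ids].mean(axis=0)
    if (baseline <= 0).any():
        raise ConfigurationError("control baseline must be strictly positive")
    return baseline


def relative_enrichment(
    table: EnrichmentTable | pd.DataFrame, baseline: pd.Series
) -> pd.DataFrame:
    """Elementwise enrichment relative to the per-dose control baseline."""
    enr = table.enrichment if isinstance(table, EnrichmentTable) else table
    if (baseline <= 0).any():
        raise ValueError("baseline must be strictly positive")
    return enr.div(baseline, axis=1)


@dataclass
class PathwayCall:
    pathway: str
    called: bool
    supporting_constructs: list[str]
    passing_doses: dict[str, list[str]]  # construct -> doses above threshold
    max_relative_enrichment: float


@dataclass
class HitReport:
    """Pathway-level calls plus the relative-enrichment table behind them."""

    calls: list[PathwayCall]
    relative: pd.DataFrame
    threshold: float
    min_doses: int

    @property
    def hits(self) -> list[str]:
        return [c.pathway for c in self.calls if c.called]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pathway": c.pathway,
                    "called": c.called,
                    "supporting_constructs": ";".join(c.supporting_constructs),
                    "passing_doses": ";".join(
                        f"{cid}:{','.join(d)}"
                        for cid, d in c.passing_doses.items()
                        if d
                    ),
                    "max_relative_enrichment": c.max_relative_enrichment,
                }
                for c in self.calls
            ]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_text(self) -> str:
        lines = [
            f"Pathway hit report (relative enrichment > {self.threshold} at "
            f">= {self.min_doses} doses)",
            "",
        ]
        for c in sorted(self.calls, key=lambda x: (not x.called, x.pathway)):
            mark = "HIT " if c.called else "    "
            supp = ", ".join(c.supporting_constructs) if c.called else "-"
            lines.append(
                f"{mark}{c.pathway:<28} max rel. enrichment "
                f"{c.max_relative_enrichment:7.2f}  supporting: {supp}"
            )
        return "\n".join(lines) + "\n"


def call_hits(
    relative: pd.DataFrame,
    manifest: LibraryManifest,
    threshold: float = DEFAULT_THRESHOLD,
    min_doses: int = DEFAULT_MIN_DOSES,
    per_construct: bool = True,
    enrichment: pd.DataFrame | None = None,
) -> HitReport:
    """Apply the pathway hit rule to a relative-enrichment table.

    A construct passes a dose when its relative enrichment is strictly
    greater than ``threshold``; missing (NaN) values fail.  When the
    vehicle-normalized ``enrichment`` table is supplied, a dose additionally
    requires enrichment > 1: hits are sought among constructs enriched in
    drug versus vehicle, so a construct depleted in the drug arm can never
    pass, however its pseudocount-dominated ratio compares to equally
    depleted controls.  With ``per_construct=True`` (default) a pathway is
    called when one construct passes at >= ``min_doses`` doses; the pooled
    alternative (``per_construct=False``) calls a pathway when >=
    ``min_doses`` doses each have some member construct passing, and exists
    for sensitivity analysis only.
    """
    n_doses = relative.shape[1]
    if min_doses > n_doses:
        raise ConfigurationError(
            f"min_doses={min_doses} exceeds the {n_doses} doses available"
        )
    if min_doses < 1 or threshold < 0:
        raise ConfigurationError("min_doses must be >= 1 and threshold >= 0")

    passing = relative.gt(threshold) & relative.notna()
    if enrichment is not None:
        if not enrichment.index.equals(relative.index) or not (
            enrichment.columns.equals(relative.columns)
        ):
            raise ConfigurationError(
                "enrichment table must share the relative table's schema"
            )
        passing &= enrichment.gt(1.0)
    calls: list[PathwayCall] = []
    for pathway in manifest.pathways:
        members = [
            r.construct_id
            for r in manifest.activators
            if r.pathway == pathway and r.construct_id in relative.index
        ]
        sub = passing.loc[members] if members else passing.iloc[0:0]
        passing_doses = {
            cid: [str(d) for d, ok in sub.loc[cid].items() if ok] for cid in members
        }
        if per_construct:
            supporting = [
                cid for cid in members if len(passing_doses[cid]) >= min_doses
            ]
            called = bool(supporting)
        else:
            doses_hit = sub.any(axis=0)
            called = int(doses_hit.sum()) >= min_doses
            supporting = [cid for cid in members if passing_doses[cid]] if called else []
        max_rel = (
            float(np.nanmax(relative.loc[members].to_numpy()))
            if members and relative.loc[members].notna().to_numpy().any()
            else float("nan")
        )
        calls.append(
            PathwayCall(
                pathway=pathway,
                called=called,
                supporting_constructs=supporting,
                passing_doses=passing_doses,
                max_relative_enrichment=max_rel,
            )
        )
    return HitReport(
        calls=calls, relative=relative, threshold=threshold, min_doses=min_doses
    )
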