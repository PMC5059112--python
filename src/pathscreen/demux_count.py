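"""Demultiplex fixed-layout 27-nt reads into a per-sample construct count table.

Each read is sliced by position (0-based, half-open): construct barcode
``[0, 4)``, common linker ``[4, 21)``, sample index ``[21, 27)``.  The sample
index is matched against the sample sheet (exactly by default, optionally
within a mismatch budget with unique-best-match semantics), the linker is
accepted within a small mismatch budget, and the construct barcode must match
the manifest exactly — the 4-nt barcodes sit at pairwise Hamming distance 2,
so correcting single-substitution neighbors would be ambiguous.

Rejections are data, not errors: every read is tallied either to a
(sample, construct) cell or to a rejection reason, and the totals are
conserved per input file.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import DemuxError
from .manifest import LibraryManifest, hamming
from .screen_sim import DEFAULT_LAYOUT, ReadLayout, SampleSheet

UNKNOWN_INDEX = "unknown_index"

REJECT_BAD_LENGTH = "bad_length"
REJECT_BAD_INDEX = "bad_index"
REJECT_BAD_LINKER = "bad_linker"
REJECT_BAD_BARCODE = "bad_barcode"
REJECT_REASONS = (
    REJECT_BAD_LENGTH,
    REJECT_BAD_INDEX,
    REJECT_BAD_LINKER,
    REJECT_BAD_BARCODE,
)

DEFAULT_MAX_LINKER_MM = 2
DEFAULT_MAX_INDEX_MM = 0

_UNASSIGNED_PREFIX = "unassigned:"


@dataclass(frozen=True)
class ReadCall:
    """Outcome of parsing one read: an assignment or a rejection."""

    sample_id: str | None
    construct_id: str | None
    reason: str | None  # None iff assigned

    @property
    def assigned(self) -> bool:
        return self.reason is None


def _make_parser(
    layout: ReadLayout,
    samplesheet: SampleSheet,
    manifest: LibraryManifest,
    max_linker_mm: int,
    max_index_mm: int,
) -> Callable[[str], ReadCall]:
    """Close over precomputed lookup tables; the returned callable is the
    hot path shared by :func:`parse_read` and :func:`count_barcodes`."""
    layout.validate()
    index_map = samplesheet.index_map()
    barcode_map = manifest.barcode_map()
    linker = layout.linker_seq
    total = layout.total_len
    b_end = layout.barcode_len
    l_end = b_end + len(linker)
    indices = list(index_map)

    def parse(seq: str) -> ReadCall:
        if len(seq) < total:
            return ReadCall(None, None, REJECT_BAD_LENGTH)
        seq = seq[:total].upper()  # longer reads: sequencer padding, truncate
        idx = seq[l_end:total]
        sample = index_map.get(idx)
        if sample is None and max_index_mm > 0:
            best, best_d, tied = None, max_index_mm + 1, False
            for known in indices:
                d = hamming(idx, known)
                if d < best_d:
                    best, best_d, tied = known, d, False
                elif d == best_d:
                    tied = True
            if best is not None and not tied:
                sample = index_map[best]
        if sample is None:
            return ReadCall(None, None, REJECT_BAD_INDEX)
        lnk = seq[b_end:l_end]
        if lnk != linker and hamming(lnk, linker) > max_linker_mm:
            return ReadCall(sample, None, REJECT_BAD_LINKER)
        construct = barcode_map.get(seq[:b_end])
        if construct is None:
            return ReadCall(sample, None, REJECT_BAD_BARCODE)
        return ReadCall(sample, construct, None)

    return parse


def parse_read(
    seq: str,
    layout: ReadLayout = DEFAULT_LAYOUT,
    samplesheet: SampleSheet | None = None,
    manifest: LibraryManifest | None = None,
    max_linker_mm: int = DEFAULT_MAX_LINKER_MM,
    max_index_mm: int = DEFAULT_MAX_INDEX_MM,
) -> ReadCall:
    """Assign a single read sequence, or return its rejection reason.

    Convenience wrapper that rebuilds the lookup tables per call; use
    :func:`count_barcodes` for whole files.
    """
    if samplesheet is None or manifest is None:
        raise ValueError("samplesheet and manifest are required")
    return _make_parser(layout, samplesheet, manifest, max_linker_mm, max_index_mm)(
        seq
    )


@dataclass
class CountTable:
    """Per-sample, per-construct read counts plus rejection tallies.

    ``counts`` is a constructs x samples integer frame; ``unassigned`` maps a
    sample id (or ``"unknown_index"`` when the read could not be assigned to
    a sample at all) to tallies by rejection reason.  The conservation
    invariant — assigned + rejected == reads in — is checked by
    :meth:`conservation_ok`.
    """

    counts: pd.DataFrame
    unassigned: dict[str, dict[str, int]]
    total_reads: int

    def assigned_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def rejected_total(self) -> int:
        return sum(sum(v.values()) for v in self.unassigned.values())

    def conservation_ok(self) -> bool:
        return self.assigned_total() + self.rejected_total() == self.total_reads

    def unassigned_frame(self) -> pd.DataFrame:
        keys = list(self.counts.columns) + [UNKNOWN_INDEX]
        return pd.DataFrame(
            {
                k: {r: self.unassigned.get(k, {}).get(r, 0) for r in REJECT_REASONS}
                for k in keys
            }
        ).T[list(REJECT_REASONS)]

    def write_tsv(self, path: str | Path) -> None:
        """Counts TSV: construct rows then an ``unassigned:<reason>`` block."""
        out = self.counts.copy()
        out[UNKNOWN_INDEX] = 0
        un = self.unassigned_frame()
        for reason in REJECT_REASONS:
            out.loc[_UNASSIGNED_PREFIX + reason] = un[reason]
        out.to_csv(path, sep="\t", index_label="construct_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="construct_id")
        is_un = df.index.str.startswith(_UNASSIGNED_PREFIX)
        counts = df.loc[~is_un].drop(columns=[UNKNOWN_INDEX]).astype(int)
        un_block = df.loc[is_un]
        unassigned: dict[str, dict[str, int]] = {}
        for row_name, row in un_block.iterrows():
            reason = row_name[len(_UNASSIGNED_PREFIX) :]
            for sample, v in row.items():
                if v:
                    unassigned.setdefault(sample, {})[reason] = int(v)
        total = int(counts.to_numpy().sum()) + int(un_block.to_numpy().sum())
        return cls(counts=counts, unassigned=unassigned, total_reads=total)

    def qc_dict(self) -> dict:
        per_sample = {
            s: {
                "assigned": int(self.counts[s].sum()),
                "rejected": {
                    r: int(v)
                    for r, v in self.unassigned.get(s, {}).items()
                },
            }
            for s in self.counts.columns
        }
        return {
            "total_reads": self.total_reads,
            "assigned": self.assigned_total(),
            "rejected": self.rejected_total(),
            "unknown_index": {
                r: int(v) for r, v in self.unassigned.get(UNKNOWN_INDEX, {}).items()
            },
            "per_sample": per_sample,
        }

    def write_qc_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.qc_dict(), fh, indent=2)


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, encoding="ascii")


def count_barcodes(
    fastq_paths: str | Path | Sequence[str | Path],
    layout: ReadLayout = DEFAULT_LAYOUT,
    samplesheet: SampleSheet | None = None,
    manifest: LibraryManifest | None = None,
    max_linker_mm: int = DEFAULT_MAX_LINKER_MM,
    max_index_mm: int = DEFAULT_MAX_INDEX_MM,
) -> CountTable:
    """Stream FASTQ files (plain or gzip) into a :class:`CountTable`.

    Memory use is independent of file size; read order never affects the
    result.  A malformed FASTQ record raises :class:`DemuxError` naming the
    file and the approximate record number.
    """
    if samplesheet is None or manifest is None:
        raise ValueError("samplesheet and manifest are required")
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    parse = _make_parser(layout, samplesheet, manifest, max_linker_mm, max_index_mm)

    sample_ids = samplesheet.sample_ids()
    construct_ids = manifest.construct_ids
    tallies: dict[str, dict[str, int]] = {s: {} for s in sample_ids}
    unassigned: dict[str, dict[str, int]] = {}
    total_reads = 0

    for path in fastq_paths:
        path = Path(path)
        n_rec = 0
        try:
            with _open_maybe_gzip(path) as fh:
                for _title, seq, _qual in FastqGeneralIterator(fh):
                    n_rec += 1
                    call = parse(seq)
                    if call.reason is None:
                        d = tallies[call.sample_id]
                        d[call.construct_id] = d.get(call.construct_id, 0) + 1
                    else:
                        key = call.sample_id or UNKNOWN_INDEX
                        d = unassigned.setdefault(key, {})
                        d[call.reason] = d.get(call.reason, 0) + 1
        except (ValueError, OSError) as exc:
            raise DemuxError(
                f"{path}: bad FASTQ near record {n_rec + 1}: {exc}"
            ) from exc
        total_reads += n_rec

    counts = pd.DataFrame(
        {s: [tallies[s].get(c, 0) for c in construct_ids] for s in sample_ids},
        index=pd.Index(construct_ids, name="construct_id"),
        dtype="int64",
    )
    return CountTable(counts=counts, unassigned=unassigned, total_reads=total_reads)
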