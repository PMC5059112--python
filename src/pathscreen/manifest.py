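"""Pathway-activation library manifests.

A manifest maps each construct in a pooled gain-of-function library to the
signaling pathway it activates and to the 4-nt DNA barcode by which it is
identified in sequencing reads.  The packaged default manifest describes a
library of 36 pathway-activating cDNAs spanning 17 major oncogenic signaling
pathways, plus three control constructs: two inert negative controls (HcRed,
luciferase) that define the enrichment baseline, and constitutively active
MEK1 (MEK1-DD) carried as a positive control for MAPK-pathway drug screens.

The real libraries' barcode sequences are not public, so the packaged
manifest carries synthetic barcodes produced by :func:`assign_barcodes`
with a pairwise Hamming distance of at least 2, which guarantees that no
single substitution can convert one valid barcode into another.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import (
    CapacityError,
    ManifestParseError,
    ManifestValidationError,
)

NUCLEOTIDES = "ACGT"
BARCODE_LENGTH = 4
MIN_BARCODE_DISTANCE = 2

ROLE_ACTIVATOR = "pathway_activator"
ROLE_NEGATIVE = "negative_control"
ROLE_POSITIVE = "positive_control"
ROLES = (ROLE_ACTIVATOR, ROLE_NEGATIVE, ROLE_POSITIVE)

MANIFEST_COLUMNS = (
    "construct_id",
    "pathway",
    "protein",
    "activation_strategy",
    "variant_note",
    "validation_assay",
    "barcode",
    "role",
)

#: Canonical names of the 17 signaling pathways covered by the default library.
CANONICAL_PATHWAYS = (
    "Ras-MAPK",
    "PI3K-AKT-mTOR",
    "NF-κB",
    "JAK-STAT",
    "Wnt/β-catenin",
    "JNK",
    "ERK5",
    "Notch",
    "p38",
    "Hedgehog",
    "TGF-β",
    "Apoptosis (BCL-2 family)",
    "Estrogen receptor",
    "Androgen receptor",
    "Hippo",
    "p53",
    "Ral",
)

_DEFAULT_MANIFEST_RESOURCE = "data/library_manifest.tsv"


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class ConstructRecord:
    """One library member: a barcoded construct and its annotations."""

    construct_id: str
    pathway: str
    protein: str
    activation_strategy: str = ""
    variant_note: str = ""
    validation_assay: str = ""
    barcode: str = ""
    role: str = ROLE_ACTIVATOR

    def validate(self, require_barcode: bool = True) -> None:
        if not self.construct_id:
            raise ManifestValidationError("construct_id must be non-empty")
        if self.role not in ROLES:
            raise ManifestValidationError(
                f"{self.construct_id}: unknown role {self.role!r}"
            )
        if self.role == ROLE_ACTIVATOR and not self.pathway:
            raise ManifestValidationError(
                f"{self.construct_id}: pathway_activator records need a pathway"
            )
        if self.barcode or require_barcode:
            if len(self.barcode) != BARCODE_LENGTH or any(
                c not in NUCLEOTIDES for c in self.barcode
            ):
                raise ManifestValidationError(
                    f"{self.construct_id}: barcode {self.barcode!r} is not a "
                    f"{BARCODE_LENGTH}-nt A/C/G/T string"
                )


@dataclass
class LibraryManifest:
    """An ordered collection of :class:`ConstructRecord` with shared invariants.

    Invariants enforced by :meth:`validate`: unique construct ids, unique
    barcodes at pairwise Hamming distance >= 2, and a non-empty pathway on
    every activating record.
    """

    constructs: list[ConstructRecord]
    version: str = "1"

    def __iter__(self) -> Iterator[ConstructRecord]:
        return iter(self.constructs)

    def __len__(self) -> int:
        return len(self.constructs)

    @property
    def construct_ids(self) -> list[str]:
        return [r.construct_id for r in self.constructs]

    @property
    def activators(self) -> list[ConstructRecord]:
        return [r for r in self.constructs if r.role == ROLE_ACTIVATOR]

    @property
    def controls(self) -> list[ConstructRecord]:
        return [r for r in self.constructs if r.role != ROLE_ACTIVATOR]

    @property
    def negative_controls(self) -> list[ConstructRecord]:
        return [r for r in self.constructs if r.role == ROLE_NEGATIVE]

    @property
    def pathways(self) -> list[str]:
        """Distinct pathway names among activating records, in first-seen order."""
        seen: dict[str, None] = {}
        for r in self.activators:
            seen.setdefault(r.pathway)
        return list(seen)

    def record(self, construct_id: str) -> ConstructRecord:
        for r in self.constructs:
            if r.construct_id == construct_id:
                return r
        raise KeyError(construct_id)

    def pathway_of(self, construct_id: str) -> str:
        return self.record(construct_id).pathway

    def barcode_map(self) -> dict[str, str]:
        """barcode -> construct_id (exact matching only; distance-2 code)."""
        return {r.barcode: r.construct_id for r in self.constructs}

    def validate(self, require_barcodes: bool = True) -> "LibraryManifest":
        seen_ids: set[str] = set()
        for r in self.constructs:
            r.validate(require_barcode=require_barcodes)
            if r.construct_id in seen_ids:
                raise ManifestValidationError(
                    f"duplicate construct_id {r.construct_id!r}"
                )
            seen_ids.add(r.construct_id)
        if require_barcodes:
            barcoded = [r for r in self.constructs if r.barcode]
            for a, b in itertools.combinations(barcoded, 2):
                d = hamming(a.barcode, b.barcode)
                if d == 0:
                    raise ManifestValidationError(
                        f"duplicate barcode {a.barcode!r} shared by "
                        f"{a.construct_id!r} and {b.construct_id!r}"
                    )
                if d < MIN_BARCODE_DISTANCE:
                    raise ManifestValidationError(
                        f"barcodes {a.barcode!r} ({a.construct_id}) and "
                        f"{b.barcode!r} ({b.construct_id}) are at Hamming "
                        f"distance {d} < {MIN_BARCODE_DISTANCE}"
                    )
        return self


@dataclass(frozen=True)
class ManifestSummary:
    """Exact tallies over a manifest's records."""

    n_records: int
    n_activating: int
    n_pathways: int
    n_validated: int
    n_controls: int


def _parse_lines(lines: Iterable[str], source: str) -> LibraryManifest:
    records: list[ConstructRecord] = []
    header: Sequence[str] | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            if tuple(fields) != MANIFEST_COLUMNS:
                raise ManifestParseError(
                    f"{source}, line {lineno}: expected header "
                    f"{list(MANIFEST_COLUMNS)}, got {fields}"
                )
            header = fields
            continue
        if len(fields) != len(MANIFEST_COLUMNS):
            raise ManifestParseError(
                f"{source}, line {lineno}: expected "
                f"{len(MANIFEST_COLUMNS)} tab-separated fields, got {len(fields)}"
            )
        rec = ConstructRecord(**dict(zip(MANIFEST_COLUMNS, fields)))
        try:
            rec.validate(require_barcode=False)
        except ManifestValidationError as exc:
            raise ManifestParseError(f"{source}, line {lineno}: {exc}") from exc
        records.append(rec)
    manifest = LibraryManifest(records)
    manifest.validate(require_barcodes=any(r.barcode for r in records))
    return manifest


def load_manifest(path: str | Path) -> LibraryManifest:
    """Load a manifest from a tab-separated file.

    The file must carry the documented header row; ``#`` comment lines and
    blank lines are ignored.  All manifest invariants are checked; a manifest
    whose records all lack barcodes is accepted (for later barcode
    assignment), but a partially barcoded one is not re-checked leniently.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        return _parse_lines(fh, str(path))


def write_manifest(manifest: LibraryManifest, path: str | Path) -> None:
    """Write a manifest as the documented TSV (UTF-8, header row)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for r in manifest.constructs:
            fh.write(
                "\t".join(getattr(r, col) for col in MANIFEST_COLUMNS) + "\n"
            )


def default_manifest() -> LibraryManifest:
    """The packaged default library: 36 activators over 17 pathways + 3 controls."""
    text = (
        resources.files(__package__)
        .joinpath(_DEFAULT_MANIFEST_RESOURCE)
        .read_text(encoding="utf-8")
    )
    return _parse_lines(text.splitlines(), _DEFAULT_MANIFEST_RESOURCE)


def summarize_manifest(manifest: LibraryManifest) -> ManifestSummary:
    """Exact tallies: records, activators, pathways, validated records, controls."""
    return ManifestSummary(
        n_records=len(manifest),
        n_activating=len(manifest.activators),
        n_pathways=len(manifest.pathways),
        n_validated=sum(1 for r in manifest if r.validation_assay.strip()),
        n_controls=len(manifest.controls),
    )


def _all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=k)]


def _candidate_pool(min_hamming: int, rng: np.random.Generator) -> list[str]:
    """A shuffled pool of 4-mers with guaranteed pairwise distance.

    For ``min_hamming <= 1`` any 4-mers do; for ``min_hamming == 2`` the
    quaternary parity-check code (digit sum == 0 mod 4; 64 words, minimum
    distance 2) gives the largest possible code; for larger distances a
    greedy sieve over a shuffled enumeration is used.
    """
    kmers = _all_kmers(BARCODE_LENGTH)
    order = rng.permutation(len(kmers))
    shuffled = [kmers[i] for i in order]
    if min_hamming <= 1:
        return shuffled
    if min_hamming == 2:
        digit = {c: i for i, c in enumerate(NUCLEOTIDES)}
        return [
            w for w in shuffled if sum(digit[c] for c in w) % len(NUCLEOTIDES) == 0
        ]
    pool: list[str] = []
    for w in shuffled:
        if all(hamming(w, p) >= min_hamming for p in pool):
            pool.append(w)
    return pool


def assign_barcodes(
    manifest: LibraryManifest,
    min_hamming: int = MIN_BARCODE_DISTANCE,
    seed: int = 0,
) -> LibraryManifest:
    """Assign synthetic 4-nt barcodes at pairwise Hamming distance >= ``min_hamming``.

    Deterministic for a fixed seed.  Raises :class:`CapacityError` when the
    manifest holds more records than a 4-mer code at the requested distance
    can accommodate.  ``min_hamming`` below 2 is rejected: distance 2 is a
    manifest invariant (it rules out single-substitution barcode collisions).
    """
    if min_hamming < MIN_BARCODE_DISTANCE:
        raise ValueError(
            f"min_hamming must be >= {MIN_BARCODE_DISTANCE} "
            "(manifest barcode-distance invariant)"
        )
    rng = np.random.default_rng(seed)
    pool = _candidate_pool(min_hamming, rng)
    n = len(manifest)
    if n > len(pool):
        raise CapacityError(
            f"{n} records requested but only {len(pool)} 4-nt barcodes are "
            f"available at pairwise Hamming distance >= {min_hamming}"
        )
    records = [
        replace(rec, barcode=pool[i]) for i, rec in enumerate(manifest.constructs)
    ]
    out = LibraryManifest(records, version=manifest.version)
    out.validate(require_barcodes=True)
    return out
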