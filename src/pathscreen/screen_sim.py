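"""Synthetic pooled pathway-activation screens with a known truth table.

The simulator emulates a positive-selection drug-resistance screen:

1. a pooled lentiviral library is titered for approximately equal construct
   representation (modeled as a lognormal spread around uniform);
2. cells are infected at low multiplicity of infection (MOI), so per-cell
   integration counts are Poisson and uninfected cells are removed by
   puromycin selection;
3. the infected pool is split into seven equal populations: a frozen t = 0
   pool plus a drug arm and a paired vehicle arm at each of three doses
   spanning roughly 20-80% growth inhibition (GI20-GI80);
4. each arm grows for a few weeks with 1:10 passages at confluence, where a
   construct's planted resistance factor rho scales down the growth
   inhibition it experiences (rho = 1: fully sensitive, rho = 0: fully
   resistant);
5. construct barcodes are PCR-amplified and sequenced as fixed-layout 27-nt
   reads (4-nt construct barcode, 17-nt linker ending in the ORF's ATG,
   6-nt sample index) with i.i.d. substitution errors.

All randomness flows from a single scenario seed through per-operation
sub-seeds, so individual arms and samples are independently reproducible.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import CapacityError, ConfigurationError, LayoutError
from .manifest import (
    NUCLEOTIDES,
    LibraryManifest,
    default_manifest,
    hamming,
    write_manifest,
)

ARM_T0 = "t0"
ARM_VEHICLE = "vehicle"
ARM_DRUG = "drug"

#: 17-nt common linker: a Kozak consensus ending in the ORF's ATG start codon.
DEFAULT_LINKER = "CTAGCGCCGCCACCATG"

SAMPLESHEET_COLUMNS = ("sample_id", "index_seq", "arm", "dose_label", "tech_rep", "bio_rep")

_NT_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i


def subseed(seed: int, tag: str) -> int:
    """Derive a stable 31-bit sub-seed for a named operation."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(tag.encode())])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class ReadLayout:
    """Fixed layout of the 27-nt sequencing read.

    Positions (0-based, half-open): barcode ``[0, 4)``, linker ``[4, 21)``,
    sample index ``[21, 27)``.
    """

    barcode_len: int = 4
    linker_seq: str = DEFAULT_LINKER
    index_len: int = 6

    @property
    def total_len(self) -> int:
        return self.barcode_len + len(self.linker_seq) + self.index_len

    def validate(self) -> "ReadLayout":
        if any(c not in NUCLEOTIDES for c in self.linker_seq):
            raise LayoutError("linker_seq must be an A/C/G/T string")
        if not self.linker_seq.endswith("ATG"):
            raise LayoutError("linker_seq must end in the ATG start codon")
        if self.barcode_len <= 0 or self.index_len <= 0:
            raise LayoutError("barcode_len and index_len must be positive")
        return self


DEFAULT_LAYOUT = ReadLayout()


@dataclass(frozen=True)
class Dose:
    """A drug dose label with its nominal growth-inhibition fraction."""

    label: str
    gi: float  # population growth inhibition in [0, 1]


# Dose ladder of the melanoma MEK-inhibitor screen design: three doses
# spanning GI20 to GI80.
DEFAULT_DOSES = (Dose("150nM", 0.2), Dose("750nM", 0.5), Dose("1.5uM", 0.8))


@dataclass
class ScreenScenario:
    """Full parameterization of one simulated screen.

    Parameters
    ----------
    n_cells : cells exposed to virus (the assay seeds 5e5 cells per well).
    moi : mean lentiviral integrations per cell (Poisson rate).
    doses : ordered dose labels with nominal growth-inhibition fractions.
    days : treatment duration in days.
    split_fraction : carry-over fraction at each passage (1:10 split = 0.1).
    capacity : cell count that triggers a passage.
    effects : construct_id -> dose label -> resistance factor rho in [0, 1];
        rho multiplies the growth inhibition the construct experiences
        (1 = no resistance, 0 = full resistance). Missing entries mean 1.
    baseline_growth : net cell divisions per day for uninhibited cells.
    read_depth : sequencing reads per sample.
    error_rate : per-base substitution probability in reads.
    library_cv : coefficient of variation of construct representation in the
        pooled virus (titering is only approximately equal).
    tech_reps : technical (sequencing) replicates per population.
    seed : master seed; every stochastic step derives a sub-seed from it.
    """

    n_cells: int = 500_000
    moi: float = 0.3
    doses: tuple[Dose, ...] = DEFAULT_DOSES
    days: int = 21
    split_fraction: float = 0.1
    capacity: int = 1_000_000
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    baseline_growth: float = 1.0
    read_depth: int = 100_000
    error_rate: float = 0.001
    library_cv: float = 0.3
    tech_reps: int = 2
    seed: int = 0

    @property
    def n_arms(self) -> int:
        """Populations: t0 plus one drug and one vehicle well per dose."""
        return 1 + 2 * len(self.doses)

    def rho(self, construct_id: str, dose_label: str) -> float:
        return self.effects.get(construct_id, {}).get(dose_label, 1.0)

    def dose(self, label: str) -> Dose:
        for d in self.doses:
            if d.label == label:
                return d
        raise ValueError(f"unknown dose label {label!r}")

    def validate(self) -> "ScreenScenario":
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.moi <= 0:
            raise ValueError("moi must be positive")
        if not 0 < self.split_fraction <= 1:
            raise ValueError("split_fraction must be in (0, 1]")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.days < 0 or self.tech_reps < 1 or self.capacity <= 0:
            raise ValueError("days, tech_reps and capacity must be sensible")
        labels = [d.label for d in self.doses]
        if len(set(labels)) != len(labels):
            raise ValueError("dose labels must be distinct")
        for d in self.doses:
            if not 0 <= d.gi <= 1:
                raise ValueError(f"dose {d.label}: gi must be in [0, 1]")
        for cid, per_dose in self.effects.items():
            for lab, r in per_dose.items():
                if not 0 <= r <= 1:
                    raise ValueError(f"effects[{cid}][{lab}]: rho must be in [0, 1]")
        return self

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "n_cells": self.n_cells,
            "moi": self.moi,
            "doses": [{"label": x.label, "gi": x.gi} for x in self.doses],
            "days": self.days,
            "split_fraction": self.split_fraction,
            "capacity": self.capacity,
            "effects": {k: dict(v) for k, v in self.effects.items()},
            "baseline_growth": self.baseline_growth,
            "read_depth": self.read_depth,
            "error_rate": self.error_rate,
            "library_cv": self.library_cv,
            "tech_reps": self.tech_reps,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenScenario":
        d = dict(d)
        if "doses" in d:
            d["doses"] = tuple(Dose(x["label"], float(x["gi"])) for x in d["doses"])
        return cls(**d).validate()

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenScenario":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class SampleRow:
    sample_id: str
    index_seq: str
    arm: str  # t0 | vehicle | drug
    dose_label: str
    tech_rep: int = 1
    bio_rep: int = 1


@dataclass
class SampleSheet:
    """Sample -> index mapping with the replicate and arm structure."""

    rows: list[SampleRow]

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)

    def validate(self, index_len: int = 6) -> "SampleSheet":
        ids = [r.sample_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("sample_id values must be unique")
        idxs = [r.index_seq for r in self.rows]
        if len(set(idxs)) != len(idxs):
            raise ConfigurationError("index_seq values must be pairwise distinct")
        for r in self.rows:
            if len(r.index_seq) != index_len or any(
                c not in NUCLEOTIDES for c in r.index_seq
            ):
                raise ConfigurationError(
                    f"{r.sample_id}: index {r.index_seq!r} is not a "
                    f"{index_len}-nt A/C/G/T string"
                )
            if r.arm not in (ARM_T0, ARM_VEHICLE, ARM_DRUG):
                raise ConfigurationError(f"{r.sample_id}: unknown arm {r.arm!r}")
        drug_doses = {r.dose_label for r in self.rows if r.arm == ARM_DRUG}
        vehicle_doses = {r.dose_label for r in self.rows if r.arm == ARM_VEHICLE}
        if drug_doses and not vehicle_doses:
            raise ConfigurationError("drug samples present but no vehicle arm")
        return self

    def index_map(self) -> dict[str, str]:
        return {r.index_seq: r.sample_id for r in self.rows}

    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows], columns=SAMPLESHEET_COLUMNS)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        rows = [
            SampleRow(
                sample_id=r.sample_id,
                index_seq=r.index_seq,
                arm=r.arm,
                dose_label=r.dose_label,
                tech_rep=int(r.tech_rep),
                bio_rep=int(r.bio_rep),
            )
            for r in df.itertuples()
        ]
        return cls(rows).validate()


def make_index_set(
    n: int, seed: int, length: int = 6, min_hamming: int = 3
) -> list[str]:
    """n sample indices at pairwise Hamming distance >= ``min_hamming``.

    Distance 3 lets a single sequencing substitution in the index be
    corrected unambiguously when mismatch-tolerant index matching is on.
    """
    rng = np.random.default_rng(seed)
    kmers = ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=length)]
    order = rng.permutation(len(kmers))
    chosen: list[str] = []
    for i in order:
        w = kmers[i]
        if all(hamming(w, c) >= min_hamming for c in chosen):
            chosen.append(w)
            if len(chosen) == n:
                return chosen
    raise CapacityError(
        f"cannot find {n} length-{length} indices at distance >= {min_hamming}"
    )


@dataclass
class CellPopulation:
    """Cell counts keyed by genotype (tuple of carried construct ids).

    Most genotypes are singletons; the Poisson tail of the MOI distribution
    yields a minority of multi-integration cells, stored as sorted tuples
    (with repeats, since independent integrations can hit one construct
    twice — each integration contributes one sequencing template).
    """

    abundance: dict[tuple[str, ...], int]

    def total_cells(self) -> int:
        return sum(self.abundance.values())

    def copy(self) -> "CellPopulation":
        return CellPopulation(dict(self.abundance))

    def template_counts(self, construct_ids: Sequence[str]) -> np.ndarray:
        """Sequencing templates per construct: one per integration per cell."""
        tallies = {c: 0 for c in construct_ids}
        for genotype, n in self.abundance.items():
            for cid in genotype:
                tallies[cid] += n
        return np.array([tallies[c] for c in construct_ids], dtype=np.int64)

    def construct_cell_counts(self, construct_ids: Sequence[str]) -> np.ndarray:
        """Cells carrying each construct at least once."""
        tallies = {c: 0 for c in construct_ids}
        for genotype, n in self.abundance.items():
            for cid in set(genotype):
                tallies[cid] += n
        return np.array([tallies[c] for c in construct_ids], dtype=np.int64)

    def subdivide(self, n_parts: int, seed: int) -> list["CellPopulation"]:
        """Randomly split cells into ``n_parts`` equal-probability pools."""
        rng = np.random.default_rng(seed)
        parts: list[dict[tuple[str, ...], int]] = [dict() for _ in range(n_parts)]
        p = np.full(n_parts, 1.0 / n_parts)
        for genotype, n in self.abundance.items():
            alloc = rng.multinomial(n, p)
            for i, a in enumerate(alloc):
                if a:
                    parts[i][genotype] = int(a)
        return [CellPopulation(d) for d in parts]


def simulate_infection(
    n_cells: int,
    moi: float,
    manifest: LibraryManifest,
    seed: int,
    weights: np.ndarray | None = None,
) -> CellPopulation:
    """Infect ``n_cells`` at Poisson MOI and drop uninfected cells.

    Each cell receives ``k ~ Poisson(moi)`` independent integrations; cells
    with ``k = 0`` are removed (puromycin selection).  Each integration draws
    a construct from the pooled library — uniformly unless per-construct
    ``weights`` model imperfect titering.  At MOI 0.3 the surviving pool is
    ~86% single-construct cells.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if moi <= 0:
        raise ValueError("moi must be positive")
    manifest.validate()
    ids = manifest.construct_ids
    nc = len(ids)
    if nc == 0:
        raise ValueError("manifest has no constructs")
    p = np.full(nc, 1.0 / nc) if weights is None else np.asarray(weights, float)
    p = p / p.sum()

    rng = np.random.default_rng(seed)
    k = rng.poisson(moi, size=n_cells)
    abundance: dict[tuple[str, ...], int] = {}

    n_single = int((k == 1).sum())
    if n_single:
        counts1 = rng.multinomial(n_single, p)
        for i, c in enumerate(counts1):
            if c:
                abundance[(ids[i],)] = int(c)

    for kk in np.unique(k[k >= 2]):
        m = int((k == kk).sum())
        draws = rng.choice(nc, size=(m, int(kk)), p=p)
        draws.sort(axis=1)
        uniq, cnt = np.unique(draws, axis=0, return_counts=True)
        for row, c in zip(uniq, cnt):
            genotype = tuple(ids[j] for j in row)
            abundance[genotype] = abundance.get(genotype, 0) + int(c)

    return CellPopulation(abundance)


def simulate_arm(
    pop: CellPopulation,
    scenario: ScreenScenario,
    arm: str,
    seed: int,
) -> CellPopulation:
    """Grow one population for ``scenario.days`` under drug or vehicle.

    The net daily growth exponent of genotype *g* at dose *d* is
    ``baseline_growth * (1 - GI(d) * min_c rho(c, d))`` over the constructs
    *c* carried by *g* (dominant-effect assumption for multi-integration
    cells); a vehicle arm has GI = 0.  Counts are advanced by stochastic
    rounding of the expected multiplicative growth, and a multinomial-thinning
    1:10 passage fires whenever the arm exceeds its capacity.
    """
    if not pop.abundance:
        raise ValueError("population is empty")
    if arm == ARM_VEHICLE:
        gi = 0.0
        label = None
    else:
        gi = scenario.dose(arm).gi  # raises ValueError for unknown labels
        label = arm

    genotypes = list(pop.abundance.keys())
    counts = np.array([pop.abundance[g] for g in genotypes], dtype=np.int64)
    if label is None:
        eff_gi = np.zeros(len(genotypes))
    else:
        eff_gi = np.array(
            [gi * min(scenario.rho(c, label) for c in g) for g in genotypes]
        )
    factor = 2.0 ** (scenario.baseline_growth * (1.0 - eff_gi))

    rng = np.random.default_rng(seed)
    for _ in range(scenario.days):
        mu = counts * factor
        base = np.floor(mu)
        counts = (base + (rng.random(len(mu)) < (mu - base))).astype(np.int64)
        if counts.sum() > scenario.capacity:
            counts = rng.binomial(counts, scenario.split_fraction)
    return CellPopulation(
        {g: int(c) for g, c in zip(genotypes, counts) if c > 0}
    )


@dataclass
class SequencedSample:
    """Reads generated for one sample, plus the underlying template draw."""

    sample_id: str
    reads: list[str]
    template_draw: pd.Series  # construct_id -> templates drawn (pre-error)
    quality_char: str = "I"

    def write_fastq(self, handle) -> None:
        q = self.quality_char * (len(self.reads[0]) if self.reads else 0)
        sid = self.sample_id
        write = handle.write
        for i, seq in enumerate(self.reads):
            write(f"@{sid}.{i}\n{seq}\n+\n{q}\n")


def simulate_sequencing(
    pop: CellPopulation,
    sample: SampleRow,
    layout: ReadLayout,
    manifest: LibraryManifest,
    depth: int,
    error_rate: float,
    seed: int,
) -> SequencedSample:
    """Draw ``depth`` reads from a population's barcode templates.

    A cell with *k* integrations contributes *k* PCR templates; reads are a
    multinomial draw over templates.  Each read is barcode + linker + sample
    index with i.i.d. substitutions at ``error_rate`` (an erroneous base is
    replaced by one of the three other bases uniformly).
    """
    layout.validate()
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    if len(sample.index_seq) != layout.index_len:
        raise LayoutError(
            f"sample {sample.sample_id}: index {sample.index_seq!r} has length "
            f"{len(sample.index_seq)}, layout expects {layout.index_len}"
        )
    ids = manifest.construct_ids
    templates = pop.template_counts(ids)
    total = templates.sum()
    if total == 0:
        raise ValueError("population holds no templates")

    rng = np.random.default_rng(seed)
    draw = rng.multinomial(depth, templates / total)

    base_reads = np.empty((len(ids), layout.total_len), dtype=np.uint8)
    for i, rec in enumerate(manifest.constructs):
        read = rec.barcode + layout.linker_seq + sample.index_seq
        base_reads[i] = np.frombuffer(read.encode(), dtype=np.uint8)

    rows = np.repeat(np.arange(len(ids)), draw)
    matrix = base_reads[rows]
    if error_rate > 0 and matrix.size:
        mask = rng.random(matrix.shape) < error_rate
        n_err = int(mask.sum())
        if n_err:
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            matrix[mask] = _NT_BYTES[(_CODE_OF[matrix[mask]] + shift) % 4]

    blob = matrix.tobytes()
    w = layout.total_len
    reads = [blob[i * w : (i + 1) * w].decode() for i in range(matrix.shape[0])]
    return SequencedSample(
        sample_id=sample.sample_id,
        reads=reads,
        template_draw=pd.Series(draw, index=ids, name=sample.sample_id),
    )


@dataclass
class ScreenOutputs:
    """Everything :func:`generate_screen` produces, in memory and on disk."""

    out_dir: Path
    fastq_path: Path
    samplesheet: SampleSheet
    samplesheet_path: Path
    truth: pd.DataFrame  # columns: construct_id, dose_label, rho
    truth_path: Path
    scenario_path: Path
    manifest_path: Path
    populations: dict[str, CellPopulation]
    template_draws: pd.DataFrame  # constructs x samples, pre-error truth


def _build_samplesheet(scenario: ScreenScenario, seed: int) -> SampleSheet:
    labels: list[tuple[str, str]] = [(ARM_T0, "")]
    for d in scenario.doses:
        labels.append((ARM_DRUG, d.label))
        labels.append((ARM_VEHICLE, d.label))
    n_samples = len(labels) * scenario.tech_reps
    indices = make_index_set(n_samples, seed=subseed(seed, "indices"))
    rows: list[SampleRow] = []
    i = 0
    for arm, dose_label in labels:
        for rep in range(1, scenario.tech_reps + 1):
            tag = f"{arm}_{dose_label}" if dose_label else arm
            rows.append(
                SampleRow(
                    sample_id=f"{tag}_t{rep}",
                    index_seq=indices[i],
                    arm=arm,
                    dose_label=dose_label,
                    tech_rep=rep,
                    bio_rep=1,
                )
            )
            i += 1
    return SampleSheet(rows).validate()


def generate_screen(
    scenario: ScreenScenario,
    manifest: LibraryManifest | None = None,
    out_dir: str | Path = ".",
    layout: ReadLayout = DEFAULT_LAYOUT,
) -> ScreenOutputs:
    """Run a full synthetic screen and write FASTQ, sample sheet and truth.

    Produces the seven-population design (t0 + drug/vehicle pair per dose):
    infection, equal subdivision, per-arm growth, and pooled multiplexed
    sequencing of every sample into a single FASTQ.  Deterministic for a
    fixed ``scenario.seed`` (byte-identical output files).
    """
    scenario.validate()
    layout.validate()
    if manifest is None:
        manifest = default_manifest()
    manifest.validate()
    seed = scenario.seed
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    nc = len(manifest)
    if scenario.library_cv > 0:
        sigma = float(np.sqrt(np.log1p(scenario.library_cv**2)))
        w = np.random.default_rng(subseed(seed, "library")).lognormal(0.0, sigma, nc)
        weights = w / w.sum()
    else:
        weights = None

    pool = simulate_infection(
        scenario.n_cells, scenario.moi, manifest, subseed(seed, "infection"), weights
    )
    parts = pool.subdivide(scenario.n_arms, subseed(seed, "split"))

    populations: dict[str, CellPopulation] = {ARM_T0: parts[0]}
    i = 1
    for d in scenario.doses:
        populations[f"drug_{d.label}"] = simulate_arm(
            parts[i], scenario, d.label, subseed(seed, f"arm:drug:{d.label}")
        )
        populations[f"vehicle_{d.label}"] = simulate_arm(
            parts[i + 1], scenario, ARM_VEHICLE, subseed(seed, f"arm:vehicle:{d.label}")
        )
        i += 2

    samplesheet = _build_samplesheet(scenario, seed)

    fastq_path = out_dir / "reads.fastq"
    draws: dict[str, pd.Series] = {}
    with open(fastq_path, "w", encoding="ascii") as fh:
        for row in samplesheet:
            tag = f"{row.arm}_{row.dose_label}" if row.dose_label else row.arm
            sample = simulate_sequencing(
                populations[tag],
                row,
                layout,
                manifest,
                scenario.read_depth,
                scenario.error_rate,
                subseed(seed, f"seq:{row.sample_id}"),
            )
            sample.write_fastq(fh)
            draws[row.sample_id] = sample.template_draw

    samplesheet_path = out_dir / "samplesheet.tsv"
    samplesheet.write_tsv(samplesheet_path)

    truth = pd.DataFrame(
        [
            {"construct_id": c, "dose_label": d.label, "rho": scenario.rho(c, d.label)}
            for c in manifest.construct_ids
            for d in scenario.doses
        ]
    )
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    scenario_path = out_dir / "scenario.yaml"
    scenario.to_yaml(scenario_path)
    manifest_path = out_dir / "manifest.tsv"
    write_manifest(manifest, manifest_path)

    return ScreenOutputs(
        out_dir=out_dir,
        fastq_path=fastq_path,
        samplesheet=samplesheet,
        samplesheet_path=samplesheet_path,
        truth=truth,
        truth_path=truth_path,
        scenario_path=scenario_path,
        manifest_path=manifest_path,
        populations=populations,
        template_draws=pd.DataFrame(draws),
    )


# -- Presets -----------------------------------------------------------------

#: Constructs planted as resistant (rho = 0.1 at every dose) in the
#: parameter-recovery preset: one activator in each of five pathways,
#: mirroring a MAPK-inhibitor resistance screen's finding structure.
PLANTED_RESISTANT = (
    "KRAS_G12V",       # Ras-MAPK
    "AKT1_myr",        # PI3K-AKT-mTOR
    "IKKB_S177E_S181E",  # NF-κB
    "NOTCH1_ICD",      # Notch
    "ESR1_Y537S",      # Estrogen receptor
)


def preset_scenario(name: str, seed: int = 0) -> ScreenScenario:
    """Bundled scenarios.

    ``uacc62-mek``
        The melanoma MEK-inhibitor screen design (MOI 0.3, doses 150 nM /
        750 nM / 1.5 uM at GI 0.2/0.5/0.8, 21 days, 1:10 splits) with no
        planted resistance — a null screen.
    ``uacc62-mek-planted``
        Same design with rho = 0.1 planted at all doses for one construct
        in each of five pathways (parameter-recovery scenario).
    """
    if name == "uacc62-mek":
        return ScreenScenario(seed=seed).validate()
    if name == "uacc62-mek-planted":
        effects = {
            cid: {d.label: 0.1 for d in DEFAULT_DOSES} for cid in PLANTED_RESISTANT
        }
        return ScreenScenario(effects=effects, seed=seed).validate()
    raise ConfigurationError(
        f"unknown preset {name!r}; available: uacc62-mek, uacc62-mek-planted"
    )
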