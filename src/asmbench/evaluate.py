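"""Factorial benchmarking of assembly performance.

The study design crosses, per genome, the available library categories
(insert sizes) with read lengths and sequencing depths, in replicate.
Each sub-library is assembled (here: by a pluggable contig provider), the
optimal assembly per parameter sweep is selected by largest N50 (ties:
fewest contigs, then largest average contig), replicate metrics are
averaged into validation entries, and relative assembly scores

    S = manifestation mean / max manifestation mean,  0 < S <= 1

are computed per factor — genome-wise for the assembler factor, per
genome and assembler for insert size, read length and depth. A
top-fraction summary reports, per read length, the fraction of scores at
or above a threshold (default 0.95) across all genomes and assemblers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import TOOL_VERSION, config_hash, derive_seed, provenance_header
from .metrics import AssemblyMetrics, compute_metrics, n50
from .reads import (
    QualityFilterSpec,
    ReadLibrary,
    SubsampleSpec,
    TrimSpec,
    pairs_for_depth,
)
from .simulate import (
    INSERT_PRESETS,
    QualityModel,
    ReadPairRecord,
    RepeatSpec,
    SyntheticGenome,
    TruthBlock,
    simulate_genome,
    simulate_read_pairs,
)

__all__ = [
    "GenomeDesign",
    "FactorDesign",
    "SubLibraryKey",
    "EntryKey",
    "AssemblyCandidate",
    "ValidationEntry",
    "RelativeScoreTable",
    "GenomeSpec",
    "StudyConfig",
    "StudyReport",
    "TruthContigProvider",
    "PrecomputedContigProvider",
    "ExternalAssemblerAdapter",
    "default_design",
    "default_study_config",
    "enumerate_design",
    "select_optimal",
    "aggregate_triplicate",
    "relative_scores",
    "top_fraction",
    "run_factor_study",
]

DEFAULT_READ_LENGTHS = (100, 125, 150, 175, 189)


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeDesign:
    """Factor levels available for one genome."""

    categories: tuple[str, ...]
    depths: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.categories or not self.depths:
            raise ValueError("categories and depths must be non-empty")


@dataclass(frozen=True)
class FactorDesign:
    """Per-genome factor sets, shared read lengths and replicate count."""

    genomes: Mapping[str, GenomeDesign]
    read_lengths: tuple[int, ...] = DEFAULT_READ_LENGTHS
    replicates: int = 3

    def __post_init__(self) -> None:
        if not self.genomes or not self.read_lengths or self.replicates < 1:
            raise ValueError("design factor sets must be non-empty")


def default_design() -> FactorDesign:
    """The four-genome benchmark design: 100 factor cells in triplicate.

    Bce, Efa and Pst carry three library categories at two depths; Sen two
    categories at a single depth (3*5*2 + 3*5*2 + 2*5*1 + 3*5*2 = 100).
    """
    return FactorDesign(
        genomes={
            "Bce": GenomeDesign(("TS", "IS1", "IS3"), (45.0, 90.0)),
            "Efa": GenomeDesign(("TS", "IS1", "IS2"), (45.0, 90.0)),
            "Sen": GenomeDesign(("IS1", "IS2"), (45.0,)),
            "Pst": GenomeDesign(("TS", "IS1", "IS3"), (45.0, 90.0)),
        }
    )


@dataclass(frozen=True)
class SubLibraryKey:
    """One sub-library: a factor cell plus its replicate index (1-based)."""

    genome: str
    category: str
    read_length: int
    depth: float
    replicate: int


@dataclass(frozen=True)
class EntryKey:
    """Identity of a validation entry: factor cell plus assembler."""

    genome: str
    assembler: str
    category: str
    read_length: int
    depth: float


def enumerate_design(design: FactorDesign) -> list[SubLibraryKey]:
    """Cartesian product of each genome's factor sets with replicate indices."""
    keys: list[SubLibraryKey] = []
    for gname, gd in design.genomes.items():
        for category in gd.categories:
            for rl in design.read_lengths:
                for depth in gd.depths:
                    for rep in range(1, design.replicates + 1):
                        keys.append(SubLibraryKey(gname, category, rl, depth, rep))
    return keys


def design_counts(design: FactorDesign) -> dict[str, int]:
    """Sub-library counts per genome and in total."""
    counts: dict[str, int] = {}
    for gname, gd in design.genomes.items():
        counts[gname] = (
            len(gd.categories) * len(design.read_lengths) * len(gd.depths) * design.replicates
        )
    counts["total"] = sum(counts.values())
    return counts


# ---------------------------------------------------------------------------
# Optimal-assembly selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssemblyCandidate:
    """One assembly from a parameter sweep (k-mer / overlap cutoff)."""

    label: object  # sweep parameter, e.g. k-mer size
    n50: int
    n_contigs: int
    avg_contig: float
    contigs: tuple[tuple[str, str], ...] | None = None
    truth_blocks: Mapping[str, Sequence[TruthBlock]] | None = None
    metrics: AssemblyMetrics | None = None


def select_optimal(candidates: Sequence[AssemblyCandidate]) -> AssemblyCandidate:
    """Pick the optimal assembly: largest N50, then fewest contigs, then
    largest average contig size; residual ties go to the smallest label."""
    if not candidates:
        raise ValueError("no assembly candidates to select from")
    return min(
        candidates,
        key=lambda c: (-c.n50, c.n_contigs, -c.avg_contig, str(c.label)),
    )


# ---------------------------------------------------------------------------
# Validation entries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationEntry:
    """Replicate-averaged corrected NG50 / NGA50 for one factor cell."""

    genome: str
    assembler: str
    category: str
    read_length: int
    depth: float
    mean_corrected_ng50: float | None
    mean_nga50: float | None
    n_replicates: int
    n_defined_corrected: int
    n_defined_nga: int
    flagged: bool


def aggregate_triplicate(
    records: Sequence[tuple[EntryKey, AssemblyMetrics]], expected_replicates: int = 3
) -> ValidationEntry:
    """Average replicate metrics of one factor cell into a validation entry.

    Undefined (None) metrics are excluded from the mean with counts noted
    and the entry flagged; all records must share one key and match the
    design's replicate count.
    """
    if len(records) != expected_replicates:
        raise ValueError(
            f"expected {expected_replicates} replicates, got {len(records)}"
        )
    keys = {k for k, _ in records}
    if len(keys) != 1:
        raise ValueError(f"replicate key mismatch: {sorted(map(str, keys))}")
    key = records[0][0]
    corr = [m.corrected_ng50 for _, m in records if m.corrected_ng50 is not None]
    nga = [m.nga50 for _, m in records if m.nga50 is not None]
    return ValidationEntry(
        genome=key.genome,
        assembler=key.assembler,
        category=key.category,
        read_length=key.read_length,
        depth=key.depth,
        mean_corrected_ng50=float(np.mean(corr)) if corr else None,
        mean_nga50=float(np.mean(nga)) if nga else None,
        n_replicates=len(records),
        n_defined_corrected=len(corr),
        n_defined_nga=len(nga),
        flagged=(len(corr) != len(records) or len(nga) != len(records)),
    )


# ---------------------------------------------------------------------------
# Relative assembly scores
# ---------------------------------------------------------------------------

_FACTORS = ("assembler", "category", "read_length", "depth")


@dataclass(frozen=True)
class RelativeScoreTable:
    """Per-group manifestation means and scores for one factor.

    ``data`` columns: group columns, ``manifestation``, the two metric
    means, ``s_corrected`` / ``s_nga`` and per-group ``max_abs_*`` (the
    absolute value in bp of the maximal score's mean).
    """

    factor: str
    grouping: str
    data: pd.DataFrame

    def to_wide(self, metric: str = "corrected") -> pd.DataFrame:
        """Manifestation rows x group columns of scores, max_abs footer row."""
        col = f"s_{metric}"
        df = self.data.copy()
        group_cols = ["genome"] if self.grouping == "by_genome" else ["genome", "assembler"]
        df["group"] = df[group_cols].astype(str).agg("/".join, axis=1)
        wide = df.pivot(index="manifestation", columns="group", values=col)
        footer = df.pivot(index="manifestation", columns="group", values=f"max_abs_{metric}")
        wide.loc["max_abs"] = footer.iloc[0]
        return wide


def relative_scores(
    entries: Sequence[ValidationEntry],
    factor: str,
    grouping: str = "by_genome_and_assembler",
) -> RelativeScoreTable:
    """Score each factor manifestation by its mean metric over entries.

    Within each group (genome, or genome x assembler) the manifestation's
    mean corrected NG50 and mean NGA50 are divided by the group maximum, so
    the best manifestation scores exactly 1 (ties all score 1).
    """
    if factor not in _FACTORS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {_FACTORS}")
    if grouping not in ("by_genome", "by_genome_and_assembler"):
        raise ValueError(f"unknown grouping {grouping!r}")
    group_cols = ["genome"] if grouping == "by_genome" else ["genome", "assembler"]
    if factor in group_cols:
        raise ValueError(f"factor {factor!r} cannot also be a grouping column")

    df = pd.DataFrame([asdict(e) for e in entries])
    if df.empty:
        raise ValueError("no validation entries")
    if df[factor].nunique() < 2:
        raise ValueError(f"need >= 2 manifestations of {factor!r}, found fewer")

    rows = []
    for gvals, gdf in df.groupby(group_cols, sort=True):
        if not isinstance(gvals, tuple):
            gvals = (gvals,)
        means = (
            gdf.groupby(factor, sort=True)[["mean_corrected_ng50", "mean_nga50"]]
            .mean()  # skips NaN/None per pandas semantics
        )
        if means["mean_corrected_ng50"].isna().any() or means["mean_nga50"].isna().any():
            bad = means.index[means.isna().any(axis=1)].tolist()
            raise ValueError(
                f"manifestation(s) {bad} of factor {factor!r} have no defined entries "
                f"in group {gvals}"
            )
        max_corr = means["mean_corrected_ng50"].max()
        max_nga = means["mean_nga50"].max()
        for manifestation, m in means.iterrows():
            rows.append(
                dict(zip(group_cols, gvals))
                | {
                    "manifestation": manifestation,
                    "mean_corrected_ng50": m["mean_corrected_ng50"],
                    "mean_nga50": m["mean_nga50"],
                    "s_corrected": m["mean_corrected_ng50"] / max_corr,
                    "s_nga": m["mean_nga50"] / max_nga,
                    "max_abs_corrected": max_corr,
                    "max_abs_nga": max_nga,
                }
            )
    return RelativeScoreTable(factor=factor, grouping=grouping, data=pd.DataFrame(rows))


def top_fraction(
    table: RelativeScoreTable, threshold: float = 0.95
) -> pd.DataFrame:
    """Fraction of scores in [threshold, 1] per manifestation, per metric.

    Pools every group in the score table (e.g. all genomes and assemblers
    for a read-length table).
    """
    df = table.data
    out = (
        df.groupby("manifestation")[["s_corrected", "s_nga"]]
        .agg(lambda s: float((s >= threshold).mean()))
        .rename(
            columns={
                "s_corrected": "frac_top_corrected_ng50",
                "s_nga": "frac_top_nga50",
            }
        )
    )
    out.index.name = table.factor
    return out


# ---------------------------------------------------------------------------
# Contig providers
# ---------------------------------------------------------------------------

DEFAULT_SPAN_FACTORS: Mapping[str, float] = {
    # fraction of the mean insert each assembler exploits for repeat
    # bridging in the truth-based emulation; velvet is run without
    # scaffolding, edena is an OLC assembler with limited pair usage
    "spades": 1.0,
    "abyss": 0.85,
    "velvet": 0.0,
    "edena": 0.3,
}


@dataclass
class TruthContigProvider:
    """Reference-derived contigs: the genome split at unresolvable repeats.

    Emulates an ideal assembler whose only failure mode is repeat
    collapse: a planted repeat copy is resolved when reads span it
    (repeat < read_length - read_margin) or when pairs bridge it
    (repeat + 2*mate_anchor <= span_factor * mean insert of the
    library category); every unresolved copy cuts the reference, with the
    repeat interval dropped. Contigs are exact reference substrings with
    recorded truth blocks, so metrics can bypass alignment.
    """

    span_factors: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPAN_FACTORS)
    )
    mate_anchor: int = 30
    read_margin: int = 20
    min_contig: int = 500

    def resolved(self, repeat_len: int, read_length: int, assembler: str, mean_insert: float) -> bool:
        if repeat_len < read_length - self.read_margin:
            return True
        span = self.span_factors[assembler] * mean_insert
        return repeat_len + 2 * self.mate_anchor <= span

    def provide(
        self,
        key: SubLibraryKey,
        assembler: str,
        pairs: Sequence[ReadPairRecord],
        genome: SyntheticGenome,
    ) -> list[AssemblyCandidate]:
        mean_insert = INSERT_PRESETS[key.category].mean_insert
        cuts: dict[str, list[tuple[int, int]]] = {n: [] for n, _ in genome.replicons}
        for copy in genome.repeat_copies:
            rlen = copy.end - copy.start
            if not self.resolved(rlen, key.read_length, assembler, mean_insert):
                cuts[copy.replicon].append((copy.start, copy.end))

        contigs: list[tuple[str, str]] = []
        blocks: dict[str, list[TruthBlock]] = {}
        i = 0
        for rname, seq in genome.replicons:
            prev = 0
            segments = sorted(cuts[rname]) + [(len(seq), len(seq))]
            for s, e in segments:
                if s - prev >= self.min_contig:
                    i += 1
                    cname = f"{assembler}_contig_{i}"
                    contigs.append((cname, seq[prev:s]))
                    blocks[cname] = [TruthBlock(cname, 0, s - prev, rname, prev, s, "+")]
                prev = e

        lengths = [len(s) for _, s in contigs]
        return [
            AssemblyCandidate(
                label=21,
                n50=n50(lengths) or 0,
                n_contigs=len(contigs),
                avg_contig=(sum(lengths) / len(lengths)) if lengths else 0.0,
                contigs=tuple(contigs),
                truth_blocks={k: tuple(v) for k, v in blocks.items()},
            )
        ]


@dataclass
class PrecomputedContigProvider:
    """Serves externally produced contig sets keyed by (sub-library, assembler)."""

    contig_sets: Mapping[tuple[SubLibraryKey, str], Sequence[AssemblyCandidate]]

    def provide(self, key, assembler, pairs, genome):
        try:
            return list(self.contig_sets[(key, assembler)])
        except KeyError:
            missing = [
                (k, a)
                for (k, a) in [(key, assembler)]
                if (k, a) not in self.contig_sets
            ]
            raise ValueError(f"no contig sets for sub-libraries: {missing}") from None


@dataclass(frozen=True)
class ExternalAssemblerAdapter:
    """Builds shell commands for an external assembler; never runs in tests.

    ``command_template`` may use the placeholders {assembler}, {r1}, {r2},
    {out_dir}, {read_length}, {genome}, {category}, {depth}, {replicate}.
    """

    command_template: str

    def command_for(
        self, key: SubLibraryKey, assembler: str, r1: str, r2: str, out_dir: str
    ) -> str:
        return self.command_template.format(
            assembler=assembler,
            r1=r1,
            r2=r2,
            out_dir=out_dir,
            read_length=key.read_length,
            genome=key.genome,
            category=key.category,
            depth=key.depth,
            replicate=key.replicate,
        )

    def provide(self, key, assembler, pairs, genome):
        raise RuntimeError(
            "the external adapter only builds commands; run them outside the "
            "pipeline and feed results back via PrecomputedContigProvider"
        )


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------


@dataclass
class GenomeSpec:
    """Simulator spec plus factor levels for one study genome."""

    name: str
    gc: float
    length: int = 30_000
    categories: tuple[str, ...] = ("TS", "IS1")
    depths: tuple[float, ...] = (45.0,)
    repeats: tuple[RepeatSpec, ...] = ()
    n_replicons: int = 1


#: Repeat structure planted into every default study genome: one long
#: family only pairs can bridge, two short families reads can span.
DEFAULT_REPEATS = (
    RepeatSpec(length=800, copies=3),
    RepeatSpec(length=160, copies=3),
    RepeatSpec(length=120, copies=3),
)


@dataclass
class StudyConfig:
    """Everything a factor study needs; round-trips through YAML."""

    genomes: list[GenomeSpec]
    read_lengths: tuple[int, ...] = DEFAULT_READ_LENGTHS
    replicates: int = 3
    assemblers: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPAN_FACTORS))
    trim: TrimSpec = field(default_factory=lambda: TrimSpec(10, 1))
    qfilter: QualityFilterSpec = field(default_factory=QualityFilterSpec)
    quality_model: QualityModel = field(default_factory=QualityModel)
    library_read_length: int = 200
    library_margin: float = 5.0
    relocation_threshold: int = 1000
    min_contig: int = 500
    top_threshold: float = 0.95
    master_seed: int = 0

    def design(self) -> FactorDesign:
        return FactorDesign(
            genomes={
                g.name: GenomeDesign(tuple(g.categories), tuple(g.depths))
                for g in self.genomes
            },
            read_lengths=tuple(self.read_lengths),
            replicates=self.replicates,
        )

    def to_dict(self) -> dict:
        return {
            "genomes": [
                {
                    "name": g.name,
                    "gc": g.gc,
                    "length": g.length,
                    "categories": list(g.categories),
                    "depths": list(g.depths),
                    "repeats": [
                        {"length": r.length, "copies": r.copies,
                         "positions": list(r.positions) if r.positions else None}
                        for r in g.repeats
                    ],
                    "n_replicons": g.n_replicons,
                }
                for g in self.genomes
            ],
            "read_lengths": list(self.read_lengths),
            "replicates": self.replicates,
            "assemblers": dict(self.assemblers),
            "trim": {"n5": self.trim.n5, "n3": self.trim.n3},
            "filter": {
                "min_fraction": self.qfilter.min_fraction,
                "min_phred": self.qfilter.min_phred,
            },
            "quality_model": {
                "q_start": self.quality_model.q_start,
                "decay_per_cycle": self.quality_model.decay_per_cycle,
                "gc_penalty": self.quality_model.gc_penalty,
                "insert_penalty": self.quality_model.insert_penalty,
                "noise_sd": self.quality_model.noise_sd,
                "read_noise_sd": self.quality_model.read_noise_sd,
            },
            "library_read_length": self.library_read_length,
            "library_margin": self.library_margin,
            "relocation_threshold": self.relocation_threshold,
            "min_contig": self.min_contig,
            "top_threshold": self.top_threshold,
            "master_seed": self.master_seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        genomes = [
            GenomeSpec(
                name=g["name"],
                gc=g["gc"],
                length=g.get("length", 30_000),
                categories=tuple(g.get("categories", ("TS", "IS1"))),
                depths=tuple(g.get("depths", (45.0,))),
                repeats=tuple(
                    RepeatSpec(
                        r["length"],
                        r.get("copies", 2),
                        tuple(r["positions"]) if r.get("positions") else None,
                    )
                    for r in g.get("repeats", [])
                ),
                n_replicons=g.get("n_replicons", 1),
            )
            for g in d["genomes"]
        ]
        t = d.get("trim", {})
        f = d.get("filter", {})
        q = d.get("quality_model", {})
        return cls(
            genomes=genomes,
            read_lengths=tuple(d.get("read_lengths", DEFAULT_READ_LENGTHS)),
            replicates=d.get("replicates", 3),
            assemblers=dict(d.get("assemblers", DEFAULT_SPAN_FACTORS)),
            trim=TrimSpec(t.get("n5", 10), t.get("n3", 1)),
            qfilter=QualityFilterSpec(f.get("min_fraction", 0.8), f.get("min_phred", 20)),
            quality_model=QualityModel(
                q_start=q.get("q_start", QualityModel.q_start),
                decay_per_cycle=q.get("decay_per_cycle", QualityModel.decay_per_cycle),
                gc_penalty=q.get("gc_penalty", QualityModel.gc_penalty),
                insert_penalty=q.get("insert_penalty", QualityModel.insert_penalty),
                noise_sd=q.get("noise_sd", QualityModel.noise_sd),
                read_noise_sd=q.get("read_noise_sd", QualityModel.read_noise_sd),
            ),
            library_read_length=d.get("library_read_length", 200),
            library_margin=d.get("library_margin", 5.0),
            relocation_threshold=d.get("relocation_threshold", 1000),
            min_contig=d.get("min_contig", 500),
            top_threshold=d.get("top_threshold", 0.95),
            master_seed=d.get("master_seed", 0),
        )


def default_study_config(master_seed: int = 0, genome_length: int = 30_000) -> StudyConfig:
    """The default four-genome study on scaled-down synthetic genomes.

    GC contents follow the four benchmark genomes (Bce 35.4 %, Efa 37.8 %,
    Sen 52.2 %, Pst 63.9 %); genome sizes are scaled down so the full
    factorial runs at desk scale.
    """
    design = default_design()
    genomes = [
        GenomeSpec(
            name=n,
            gc=gc,
            length=genome_length,
            categories=design.genomes[n].categories,
            depths=design.genomes[n].depths,
            repeats=DEFAULT_REPEATS,
        )
        for n, gc in (("Bce", 0.354), ("Efa", 0.378), ("Sen", 0.522), ("Pst", 0.639))
    ]
    return StudyConfig(genomes=genomes, master_seed=master_seed)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass
class StudyReport:
    """All outputs of one factor study run."""

    entries: list[ValidationEntry]
    scores: dict[str, RelativeScoreTable]
    top: pd.DataFrame
    counts: dict[str, int]
    log: list[str]
    cfg_hash: str
    master_seed: int

    def entries_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(e) for e in self.entries])
        return df.sort_values(
            ["genome", "assembler", "category", "read_length", "depth"]
        ).reset_index(drop=True)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = provenance_header(self.cfg_hash, self.master_seed)

        def _write(df: pd.DataFrame, name: str, index: bool = False) -> None:
            path = out / name
            with open(path, "w") as fh:
                fh.write("\n".join(header) + "\n")
                df.to_csv(fh, sep="\t", index=index, na_rep="NA")

        _write(self.entries_frame(), "validation_entries.tsv")
        for factor, table in sorted(self.scores.items()):
            _write(
                table.data.sort_values(list(table.data.columns[:2]) + ["manifestation"]),
                f"scores_{factor}.tsv",
            )
        _write(self.top, "top_fraction.tsv", index=True)
        with open(out / "run_log.txt", "w") as fh:
            fh.write("\n".join(header) + "\n")
            fh.write("\n".join(self.log) + "\n")


def run_factor_study(
    config: StudyConfig,
    seed: int | None = None,
    provider=None,
) -> StudyReport:
    """Execute the full factorial pipeline on synthetic data.

    Stages per genome x category library: simulate reads at the library
    read length, trim (5'/3'), then per read length truncate, quality
    filter, and draw the replicate sub-libraries at each target depth;
    assemble via the contig provider, select the optimal candidate,
    compute metrics, aggregate replicates, and score every factor.
    """
    master = config.master_seed if seed is None else seed
    design = config.design()
    provider = provider or TruthContigProvider(
        span_factors=dict(config.assemblers), min_contig=config.min_contig
    )
    cfg_hash = config_hash(config)
    assemblers = sorted(config.assemblers)
    log: list[str] = [f"master_seed={master}", f"config_hash={cfg_hash}"]

    results: dict[EntryKey, list[tuple[EntryKey, AssemblyMetrics]]] = {}
    n_sublibraries = 0
    n_assemblies = 0

    for gspec in config.genomes:
        genome = simulate_genome(
            gspec.length,
            gspec.gc,
            gspec.repeats,
            seed=derive_seed(master, "genome", gspec.name),
            n_replicons=gspec.n_replicons,
        )
        log.append(
            f"genome {gspec.name}: {genome.length} bp, GC={genome.gc:.3f}, "
            f"{len(genome.repeat_copies)} repeat copies"
        )
        gdesign = design.genomes[gspec.name]
        min_rl = min(design.read_lengths)
        max_depth = max(gdesign.depths)
        n_library = math.ceil(
            config.library_margin * max_depth * genome.length / (2 * min_rl)
        )
        for category in gdesign.categories:
            lib_seed = derive_seed(master, "library", gspec.name, category)
            raw = ReadLibrary(
                simulate_read_pairs(
                    genome,
                    n_library,
                    config.library_read_length,
                    INSERT_PRESETS[category],
                    config.quality_model,
                    seed=lib_seed,
                )
            )
            trimmed = raw.trim(config.trim)
            log.append(
                f"library {gspec.name}/{category}: {n_library} pairs simulated "
                f"(seed={lib_seed}), trimmed to {len(trimmed.pairs[0].mate1_seq)} bp"
            )
            for rl in design.read_lengths:
                truncated = trimmed.trim(TrimSpec(target_length=rl))
                filtered = truncated.quality_filter(config.qfilter)
                log.append(
                    f"  L={rl}: pass_fraction={filtered.pass_fraction:.4f} "
                    f"({len(filtered)} pairs retained)"
                )
                for depth in gdesign.depths:
                    n_needed = pairs_for_depth(
                        SubsampleSpec(depth, genome.length, rl)
                    )
                    for rep in range(1, design.replicates + 1):
                        key = SubLibraryKey(gspec.name, category, rl, depth, rep)
                        sub_seed = derive_seed(
                            master, "subsample", key.genome, key.category,
                            key.read_length, key.depth, key.replicate,
                        )
                        sub = filtered.subsample(n_needed, sub_seed)
                        n_sublibraries += 1
                        for asm in assemblers:
                            candidates = provider.provide(key, asm, sub.pairs, genome)
                            best = select_optimal(candidates)
                            n_assemblies += 1
                            if best.metrics is not None:
                                m = best.metrics
                            else:
                                m = compute_metrics(
                                    best.contigs,
                                    genome,
                                    genome_size=genome.length,
                                    relocation_threshold=config.relocation_threshold,
                                    truth_blocks=best.truth_blocks,
                                    min_len=config.min_contig,
                                )
                            ekey = EntryKey(gspec.name, asm, category, rl, depth)
                            results.setdefault(ekey, []).append((ekey, m))

    entries = [
        aggregate_triplicate(recs, design.replicates)
        for _, recs in sorted(
            results.items(),
            key=lambda kv: (
                kv[0].genome,
                kv[0].assembler,
                kv[0].category,
                kv[0].read_length,
                kv[0].depth,
            ),
        )
    ]
    counts = design_counts(design)
    counts = {f"sublibraries_{k}": v for k, v in counts.items()}
    counts["sublibraries_processed"] = n_sublibraries
    counts["assemblies"] = n_assemblies
    counts["validation_entries"] = len(entries)
    log.append(f"counts: {counts}")

    scores: dict[str, RelativeScoreTable] = {}
    for factor, grouping in (
        ("assembler", "by_genome"),
        ("category", "by_genome_and_assembler"),
        ("read_length", "by_genome_and_assembler"),
        ("depth", "by_genome_and_assembler"),
    ):
        values = {getattr(e, factor) for e in entries}
        if len(values) < 2:
            log.append(f"factor {factor}: single manifestation {values}, no score table")
            continue
        scores[factor] = relative_scores(entries, factor, grouping)
    if "read_length" in scores:
        top = top_fraction(scores["read_length"], config.top_threshold)
    else:
        top = pd.DataFrame(
            columns=["frac_top_corrected_ng50", "frac_top_nga50"]
        ).rename_axis("read_length")
    return StudyReport(
        entries=entries,
        scores=scores,
        top=top,
        counts=counts,
        log=log,
        cfg_hash=cfg_hash,
        master_seed=master,
    )
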