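"""Read trimming, (p;q) quality filtering, depth subsampling and insert sizes.

The processing order of a library is fixed: trim (5'/3' cut or 3'
truncation to a target read length), then pair-integrity quality
filtering, then random subsampling to a target sequencing depth.
:class:`ReadLibrary` enforces that order; the stage functions below can
also be used directly on pair lists.

A read passes a (p;q) filter when at least ``p * 100`` % of its bases have
Phred >= q (both comparisons inclusive). A pair is retained only when both
mates pass. Sequencing depth is ``2 L N / G`` for read length L, pair
count N and genome size G.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .simulate import ReadPairRecord

__all__ = [
    "QualityFilterSpec",
    "TrimSpec",
    "SubsampleSpec",
    "InsertSizeSummary",
    "PipelineOrderError",
    "ReadLibrary",
    "trim_pairs",
    "passes_filter",
    "filter_pairs",
    "pairs_for_depth",
    "subsample_pairs",
    "estimate_insert_sizes",
    "insert_sizes_from_sam",
    "insert_shift",
]


@dataclass(frozen=True)
class QualityFilterSpec:
    """(p;q) rule: at least ``min_fraction`` of bases at Phred >= ``min_phred``."""

    min_fraction: float = 0.8
    min_phred: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.min_fraction <= 1.0:
            raise ValueError(f"min_fraction must be in (0, 1], got {self.min_fraction}")
        if not 0 <= self.min_phred <= 41:
            raise ValueError(f"min_phred must be in [0, 41], got {self.min_phred}")


@dataclass(frozen=True)
class TrimSpec:
    """Fixed 5'/3' trimming, or 3'-only truncation to ``target_length``."""

    n5: int = 0
    n3: int = 0
    target_length: int | None = None

    def __post_init__(self) -> None:
        if self.n5 < 0 or self.n3 < 0:
            raise ValueError("trim amounts must be non-negative")
        if self.target_length is not None and self.target_length < 1:
            raise ValueError("target_length must be >= 1")


@dataclass(frozen=True)
class SubsampleSpec:
    """Target fold-coverage for a genome of size G at read length L."""

    target_depth: float
    G: int
    L: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_depth <= 0:
            raise ValueError("target_depth must be positive")
        if self.G <= 0 or self.L <= 0:
            raise ValueError("G and L must be positive")


@dataclass(frozen=True)
class InsertSizeSummary:
    """Empirical insert-size distribution of usable (proper FR) pairs."""

    n_pairs: int
    mean: float
    sd: float
    histogram: Mapping[int, int]
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs > 0:
            sizes = list(self.histogram)
            if not min(sizes) <= self.mean <= max(sizes):
                raise ValueError("mean outside histogram support")
            if sum(self.histogram.values()) != self.n_pairs:
                raise ValueError("histogram counts do not sum to n_pairs")

    @classmethod
    def from_inserts(cls, inserts: Sequence[int], n_excluded: int = 0) -> "InsertSizeSummary":
        if len(inserts) == 0:
            raise ValueError("no usable pairs to summarize")
        arr = np.asarray(inserts, dtype=float)
        return cls(
            n_pairs=len(inserts),
            mean=float(arr.mean()),
            sd=float(arr.std(ddof=1)) if len(inserts) > 1 else 0.0,
            histogram=dict(sorted(Counter(int(i) for i in inserts).items())),
            n_excluded=n_excluded,
        )


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------


def _trim_read(seq: str, quals: np.ndarray, spec: TrimSpec) -> tuple[str, np.ndarray]:
    if spec.target_length is not None:
        if len(seq) < spec.target_length:
            raise ValueError(f"read of {len(seq)} bp shorter than target {spec.target_length}")
        return seq[: spec.target_length], quals[: spec.target_length]
    if len(seq) <= spec.n5 + spec.n3:
        raise ValueError(f"read of {len(seq)} bp too short for trim ({spec.n5}, {spec.n3})")
    end = len(seq) - spec.n3
    return seq[spec.n5 : end], quals[spec.n5 : end]


def trim_pairs(pairs: Iterable[ReadPairRecord], spec: TrimSpec) -> list[ReadPairRecord]:
    """Trim both mates of every pair; qualities are cut in lockstep."""
    out = []
    for p in pairs:
        try:
            s1, q1 = _trim_read(p.mate1_seq, p.mate1_quals, spec)
            s2, q2 = _trim_read(p.mate2_seq, p.mate2_quals, spec)
        except ValueError as exc:
            raise ValueError(f"pair {p.pair_id}: {exc}") from None
        out.append(
            ReadPairRecord(p.pair_id, s1, q1, s2, q2, truth=p.truth)
        )
    return out


def passes_filter(quals: Sequence[int] | np.ndarray, spec: QualityFilterSpec) -> bool:
    """True iff count(quals >= q) / len(quals) >= p (inclusive on both sides)."""
    arr = np.asarray(quals)
    if arr.size == 0:
        raise ValueError("empty quality sequence")
    return bool(np.count_nonzero(arr >= spec.min_phred) / arr.size >= spec.min_fraction)


def filter_pairs(
    pairs: Sequence[ReadPairRecord], spec: QualityFilterSpec
) -> tuple[list[ReadPairRecord], float | None]:
    """Keep pairs where BOTH mates pass; also return the pass fraction.

    Reads losing their counterpart are discarded with the pair; the pass
    fraction is retained pairs / input pairs, or ``None`` on empty input.
    """
    retained = [
        p
        for p in pairs
        if passes_filter(p.mate1_quals, spec) and passes_filter(p.mate2_quals, spec)
    ]
    frac = len(retained) / len(pairs) if len(pairs) else None
    return retained, frac


def pairs_for_depth(spec: SubsampleSpec) -> int:
    """Smallest pair count N with achieved depth 2LN/G >= target_depth."""
    return math.ceil(spec.target_depth * spec.G / (2 * spec.L))


def subsample_pairs(
    pairs: Sequence[ReadPairRecord], n: int, seed: int
) -> list[ReadPairRecord]:
    """Simple random sample of ``n`` pairs without replacement (mates together)."""
    if n > len(pairs):
        raise ValueError(
            f"requested {n} pairs but only {len(pairs)} available (shortfall {n - len(pairs)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=n, replace=False)
    return [pairs[i] for i in np.sort(idx)]


# ---------------------------------------------------------------------------
# Insert-size estimation
# ---------------------------------------------------------------------------


def estimate_insert_sizes(pairs: Iterable[ReadPairRecord]) -> InsertSizeSummary:
    """Insert-size summary from per-pair fragment truth coordinates.

    Insert = rightmost end - leftmost start (0-based half-open). Pairs
    without truth are excluded and counted; a usable pair must sit on one
    replicon in FR orientation, which truth records guarantee.
    """
    inserts: list[int] = []
    excluded = 0
    for p in pairs:
        if p.truth is None:
            excluded += 1
            continue
        inserts.append(p.truth.end - p.truth.start)
    if not inserts:
        raise ValueError("no usable pairs: no truth coordinates present")
    return InsertSizeSummary.from_inserts(inserts, n_excluded=excluded)


def insert_sizes_from_sam(path: str) -> InsertSizeSummary:
    """Insert-size summary from mapped coordinates in a SAM file.

    Uses the leftmost mate of each properly-oriented FR pair on a single
    reference; cross-replicon and same-strand pairs are excluded and
    counted. Mapping itself is external to this package.
    """
    import pysam

    inserts: list[int] = []
    excluded = 0
    with pysam.AlignmentFile(path, "r") as sam:
        for rec in sam:
            if rec.is_unmapped or rec.mate_is_unmapped or not rec.is_paired:
                continue
            if not rec.is_read1:
                continue
            if rec.reference_id != rec.next_reference_id or rec.is_reverse == rec.mate_is_reverse:
                excluded += 1
                continue
            tlen = rec.template_length
            if tlen > 0:
                inserts.append(int(tlen))
            elif tlen == 0:
                excluded += 1
    if not inserts:
        raise ValueError(f"no usable FR pairs in {path}")
    return InsertSizeSummary.from_inserts(inserts, n_excluded=excluded)


def insert_shift(raw: InsertSizeSummary, filtered: InsertSizeSummary) -> float:
    """Percent decrease of the mean insert from raw to filtered library."""
    if raw.n_pairs == 0 or filtered.n_pairs == 0:
        raise ValueError("both summaries must be non-empty")
    return 100.0 * (raw.mean - filtered.mean) / raw.mean


# ---------------------------------------------------------------------------
# Ordered pipeline
# ---------------------------------------------------------------------------

_STAGES = ("raw", "trimmed", "filtered", "subsampled")


class PipelineOrderError(RuntimeError):
    """Raised when library stages are applied out of order."""


@dataclass
class ReadLibrary:
    """A paired-read library that enforces the trim -> filter -> subsample order.

    Sub-libraries at a given depth are drawn from trimmed libraries after
    quality filtering; any other stage order is refused.
    """

    pairs: list[ReadPairRecord]
    stage: str = "raw"
    pass_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    def trim(self, spec: TrimSpec) -> "ReadLibrary":
        if self.stage not in ("raw", "trimmed"):
            raise PipelineOrderError(f"cannot trim a {self.stage} library: trim precedes filtering")
        return ReadLibrary(trim_pairs(self.pairs, spec), stage="trimmed")

    def quality_filter(self, spec: QualityFilterSpec) -> "ReadLibrary":
        if self.stage not in ("raw", "trimmed"):
            raise PipelineOrderError(
                f"cannot filter a {self.stage} library: filtering precedes subsampling"
            )
        kept, frac = filter_pairs(self.pairs, spec)
        return ReadLibrary(kept, stage="filtered", pass_fraction=frac)

    def subsample(self, n: int, seed: int) -> "ReadLibrary":
        if self.stage != "filtered":
            raise PipelineOrderError(
                f"cannot subsample a {self.stage} library: subsampling follows quality filtering"
            )
        return ReadLibrary(
            subsample_pairs(self.pairs, n, seed), stage="subsampled",
            pass_fraction=self.pass_fraction,
        )

    def insert_summary(self) -> InsertSizeSummary:
        return estimate_insert_sizes(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)
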