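"""Synthetic genomes, paired-end read libraries and contig sets.

Every downstream stage of the benchmarking pipeline (quality filtering,
depth subsampling, contiguity metrics, factorial scoring) is exercised on
data produced here, so the simulators reproduce the statistical structure
the analysis assumes rather than the full biology of a sequencing run:

* genomes are i.i.d. base sequences with an exact target GC composition
  plus planted exact repeats (repeats are the only genome feature the
  assembly analysis interrogates);
* paired reads are drawn FR-oriented from a parametric fragment-length
  distribution (Gaussian, or reflected skew-normal for the left-tailed
  standard-protocol libraries), with Phred qualities from a linear model
  that decays 5'->3' and is penalised by genomic GC content and by
  fragment length;
* contig sets are exact reference substrings optionally stitched across
  misassembly junctions (translocation / inversion / relocation with a
  declared reference gap), with full ground truth recorded.

Coordinates are 0-based half-open throughout; fragment length = end - start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PHRED_MIN",
    "PHRED_MAX",
    "RepeatSpec",
    "RepeatCopy",
    "SyntheticGenome",
    "FragmentModel",
    "QualityModel",
    "FragmentTruth",
    "ReadPairRecord",
    "ContigEvent",
    "TruthBlock",
    "SimulatedContigSet",
    "INSERT_PRESETS",
    "revcomp",
    "gc_fraction",
    "simulate_genome",
    "simulate_read_pairs",
    "simulate_contigs",
]

PHRED_MIN = 2
PHRED_MAX = 40

_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTacgtN", b"TGCATGCAN"):
    _COMPLEMENT[_a] = _b


def _to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return _to_str(_COMPLEMENT[_to_arr(seq)][::-1])


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases in ``seq``."""
    arr = _to_arr(seq)
    return float(np.count_nonzero((arr == ord("G")) | (arr == ord("C"))) / arr.size)


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepeatSpec:
    """A planted repeat family: ``copies`` exact duplicates of one template.

    ``positions`` may fix the insertion start coordinates (all on the first
    replicon); when ``None`` non-overlapping positions are drawn at random.
    """

    length: int
    copies: int = 2
    positions: tuple[int, ...] | None = None


@dataclass(frozen=True)
class RepeatCopy:
    """Realized location of one planted repeat copy."""

    replicon: str
    start: int
    end: int
    family: int  # index into the repeat plan


@dataclass(frozen=True)
class SyntheticGenome:
    """A synthetic multi-replicon genome with known GC and repeat truth."""

    replicons: tuple[tuple[str, str], ...]
    target_gc: float
    repeat_plan: tuple[RepeatSpec, ...]
    repeat_copies: tuple[RepeatCopy, ...]
    seed: int

    @property
    def length(self) -> int:
        return sum(len(s) for _, s in self.replicons)

    @property
    def gc(self) -> float:
        arrs = [_to_arr(s) for _, s in self.replicons]
        gc = sum(int(np.count_nonzero((a == ord("G")) | (a == ord("C")))) for a in arrs)
        return gc / self.length

    def sequence(self, name: str) -> str:
        for n, s in self.replicons:
            if n == name:
                return s
        raise KeyError(f"no replicon named {name!r}")


def _random_bases(n: int, target_gc: float, rng: np.random.Generator) -> np.ndarray:
    """Sequence of length n with exact-count GC composition, shuffled."""
    n_gc = int(round(n * target_gc))
    n_at = n - n_gc
    pool = np.empty(n, dtype=np.uint8)
    pool[: n_gc // 2] = ord("G")
    pool[n_gc // 2 : n_gc] = ord("C")
    pool[n_gc : n_gc + n_at // 2] = ord("A")
    pool[n_gc + n_at // 2 :] = ord("T")
    rng.shuffle(pool)
    return pool


def simulate_genome(
    length: int,
    target_gc: float,
    repeat_plan: Sequence[RepeatSpec] = (),
    seed: int = 0,
    n_replicons: int = 1,
    names: Sequence[str] | None = None,
) -> SyntheticGenome:
    """Generate a genome of ``length`` bp at ``target_gc`` with planted repeats.

    The base sequence is an exact-composition shuffle, so the realized GC
    fraction is within rounding of the target before repeat planting and
    within +/-0.02 after (repeats reuse genome sequence as template).
    Repeats are planted on the first replicon, non-overlapping.
    """
    if length < 10_000:
        raise ValueError(f"genome length must be >= 10 kbp, got {length}")
    if not 0.25 <= target_gc <= 0.80:
        raise ValueError(f"target_gc must be in [0.25, 0.80], got {target_gc}")
    if n_replicons < 1:
        raise ValueError("n_replicons must be >= 1")

    rng = np.random.default_rng(seed)
    base = length // n_replicons
    rep_lengths = [base + (1 if i < length % n_replicons else 0) for i in range(n_replicons)]
    if names is None:
        names = [f"replicon_{i + 1}" for i in range(n_replicons)]
    arrs = [_random_bases(n, target_gc, rng) for n in rep_lengths]

    total_repeat = sum(r.length * r.copies for r in repeat_plan)
    if total_repeat > rep_lengths[0] // 2:
        raise ValueError(
            f"repeat plan needs {total_repeat} bp but replicon 1 has only "
            f"{rep_lengths[0]} bp; repeats must fit comfortably"
        )

    copies: list[RepeatCopy] = []
    host = arrs[0]
    occupied: list[tuple[int, int]] = []
    for fam, spec in enumerate(repeat_plan):
        if spec.length < 1 or spec.copies < 1:
            raise ValueError("repeat length and copy count must be positive")
        if spec.positions is not None:
            if len(spec.positions) != spec.copies:
                raise ValueError("positions must match copy count")
            positions = list(spec.positions)
            for p in positions:
                if p < 0 or p + spec.length > len(host):
                    raise ValueError(f"repeat at {p} exceeds replicon bounds")
        else:
            positions = []
            for _ in range(spec.copies):
                for _attempt in range(1000):
                    p = int(rng.integers(0, len(host) - spec.length + 1))
                    span = (p, p + spec.length)
                    if all(span[1] <= a or span[0] >= b for a, b in occupied + [
                        (q, q + spec.length) for q in positions
                    ]):
                        positions.append(p)
                        break
                else:
                    raise ValueError("could not place repeat copies without overlap")
        template = host[positions[0] : positions[0] + spec.length].copy()
        for p in positions:
            host[p : p + spec.length] = template
            occupied.append((p, p + spec.length))
            copies.append(RepeatCopy(names[0], p, p + spec.length, fam))

    genome = SyntheticGenome(
        replicons=tuple((n, _to_str(a)) for n, a in zip(names, arrs)),
        target_gc=target_gc,
        repeat_plan=tuple(repeat_plan),
        repeat_copies=tuple(copies),
        seed=seed,
    )
    if abs(genome.gc - target_gc) > 0.02:
        raise RuntimeError("realized GC drifted beyond tolerance")  # pragma: no cover
    return genome


# ---------------------------------------------------------------------------
# Fragment and quality models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FragmentModel:
    """Parametric insert-length distribution of a sequencing library.

    ``sd_insert`` defaults to 8 % of the mean: the per-category spreads
    quoted for the library categories describe between-library variation,
    not the within-library fragment spread, which is a tunable simulator
    choice. ``left_tailed`` libraries (the unmodified protocol) use a
    negatively skewed skew-normal; ``symmetric`` ones a Gaussian.
    """

    mean_insert: float
    sd_insert: float | None = None
    shape: str = "symmetric"  # or "left_tailed"
    category_label: str | None = None
    skew: float = -5.0

    @property
    def sd(self) -> float:
        return self.sd_insert if self.sd_insert is not None else 0.08 * self.mean_insert

    def frozen_dist(self):
        """The frozen scipy distribution of fragment lengths."""
        if self.shape == "symmetric":
            return stats.norm(loc=self.mean_insert, scale=self.sd)
        if self.shape == "left_tailed":
            a = self.skew
            delta = a / math.sqrt(1.0 + a * a)
            scale = self.sd / math.sqrt(1.0 - 2.0 * delta * delta / math.pi)
            loc = self.mean_insert - scale * delta * math.sqrt(2.0 / math.pi)
            return stats.skewnorm(a, loc=loc, scale=scale)
        raise ValueError(f"unknown fragment shape {self.shape!r}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.asarray(self.frozen_dist().rvs(size=n, random_state=rng))


#: Library-category presets. Means are the raw-data average insert sizes of
#: the five library preparation categories (TS = unmodified protocol,
#: IS1-IS4 = modified protocols with increasing insert size); TS libraries
#: have the left-tailed shape characteristic of the standard size selection.
INSERT_PRESETS: Mapping[str, FragmentModel] = {
    "TS": FragmentModel(641.0, shape="left_tailed", category_label="TS"),
    "IS1": FragmentModel(686.0, category_label="IS1"),
    "IS2": FragmentModel(990.0, category_label="IS2"),
    "IS3": FragmentModel(1211.0, category_label="IS3"),
    "IS4": FragmentModel(1297.0, category_label="IS4"),
}


@dataclass(frozen=True)
class QualityModel:
    """Linear Phred quality model with 5'->3' decay and GC/insert penalties.

    Expected quality at cycle c (0-based) for a read from a fragment of
    ``insert_bp`` in a genome of GC fraction ``gc``::

        q(c) = q_start - decay_per_cycle * c
               - gc_penalty * max(0, gc - 0.5)
               - insert_penalty * insert_bp / 1000

    Gaussian noise is added at two levels — ``read_noise_sd`` as one offset
    per read (cluster/tile-level quality variation) and ``noise_sd`` per
    base — and the result is clamped to [2, 40]. Defaults are simulator
    choices tuned once so the qualitative trends of real libraries emerge:
    pass fractions under a (p;q) filter decrease smoothly with genomic GC
    and with mean insert size, and filtering preferentially removes long
    fragments.
    """

    q_start: float = 37.0
    decay_per_cycle: float = 0.08
    gc_penalty: float = 8.0
    insert_penalty: float = 3.0
    noise_sd: float = 4.0
    read_noise_sd: float = 2.5

    def expected_quality(self, cycle: int, gc: float = 0.5, insert_bp: float = 0.0) -> float:
        return (
            self.q_start
            - self.decay_per_cycle * cycle
            - self.gc_penalty * max(0.0, gc - 0.5)
            - self.insert_penalty * insert_bp / 1000.0
        )


DEGENERATE_QUALITY = QualityModel(
    q_start=30.0, decay_per_cycle=0.0, gc_penalty=0.0, insert_penalty=0.0, noise_sd=0.0
)


# ---------------------------------------------------------------------------
# Read pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FragmentTruth:
    """True origin of a simulated fragment (0-based half-open)."""

    replicon: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReadPairRecord:
    """One FR-oriented read pair; qualities are integer Phred arrays."""

    pair_id: str
    mate1_seq: str
    mate1_quals: np.ndarray
    mate2_seq: str
    mate2_quals: np.ndarray
    truth: FragmentTruth | None = None

    def __post_init__(self) -> None:
        if len(self.mate1_seq) != len(self.mate1_quals) or len(self.mate2_seq) != len(
            self.mate2_quals
        ):
            raise ValueError("quality length must equal sequence length")
        if len(self.mate1_seq) != len(self.mate2_seq):
            raise ValueError("mate lengths must be equal")


def simulate_read_pairs(
    genome: SyntheticGenome,
    n_pairs: int,
    read_length: int,
    fragment_model: FragmentModel,
    quality_model: QualityModel | None = None,
    seed: int = 0,
) -> list[ReadPairRecord]:
    """Draw ``n_pairs`` FR-oriented read pairs from ``genome``.

    Mate 1 is the fragment's 5' end on the forward strand; mate 2 the
    reverse complement of its 3' end. Fragment lengths come from
    ``fragment_model`` truncated to [read_length, replicon length]
    (out-of-range draws are resampled). Qualities follow ``quality_model``
    with the per-pair fragment-length penalty, clamped to [2, 40].
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    qm = quality_model or QualityModel()
    rng = np.random.default_rng(seed)

    names = [n for n, _ in genome.replicons]
    arrs = [_to_arr(s) for _, s in genome.replicons]
    rep_lens = np.array([a.size for a in arrs])
    if int(rep_lens.min()) < read_length:
        raise ValueError("replicon shorter than the minimum fragment length")
    probs = rep_lens / rep_lens.sum()

    rep_idx = rng.choice(len(arrs), size=n_pairs, p=probs)
    flens = np.rint(fragment_model.sample(n_pairs, rng)).astype(np.int64)
    lo, hi = read_length, rep_lens[rep_idx]
    bad = (flens < lo) | (flens > hi)
    for _ in range(100):
        if not bad.any():
            break
        flens[bad] = np.rint(fragment_model.sample(int(bad.sum()), rng)).astype(np.int64)
        bad = (flens < lo) | (flens > hi)
    np.clip(flens, lo, hi, out=flens)

    starts = np.floor(rng.random(n_pairs) * (rep_lens[rep_idx] - flens + 1)).astype(np.int64)
    ends = starts + flens

    gc = genome.gc
    cyc = np.arange(read_length, dtype=np.float64)
    base_mean = qm.q_start - qm.decay_per_cycle * cyc
    penalty = qm.gc_penalty * max(0.0, gc - 0.5) + qm.insert_penalty * flens / 1000.0
    mean_q = base_mean[None, :] - penalty[:, None]

    def _draw_quals() -> np.ndarray:
        q = mean_q
        if qm.read_noise_sd > 0:
            q = q + rng.normal(0.0, qm.read_noise_sd, size=(n_pairs, 1))
        if qm.noise_sd > 0:
            q = q + rng.normal(0.0, qm.noise_sd, size=(n_pairs, read_length))
        return np.clip(np.rint(q), PHRED_MIN, PHRED_MAX).astype(np.int16)

    q1 = _draw_quals()
    q2 = _draw_quals()

    pairs: list[ReadPairRecord] = []
    for i in range(n_pairs):
        arr = arrs[rep_idx[i]]
        s, e = int(starts[i]), int(ends[i])
        m1 = _to_str(arr[s : s + read_length])
        m2 = _to_str(_COMPLEMENT[arr[e - read_length : e]][::-1])
        pairs.append(
            ReadPairRecord(
                pair_id=f"pair_{i:07d}",
                mate1_seq=m1,
                mate1_quals=q1[i],
                mate2_seq=m2,
                mate2_quals=q2[i],
                truth=FragmentTruth(names[rep_idx[i]], s, e),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Contig sets with injected misassemblies
# ---------------------------------------------------------------------------

EVENT_KINDS = ("translocation", "inversion", "relocation_gap")


@dataclass(frozen=True)
class ContigEvent:
    """A misassembly junction to inject into one simulated contig."""

    contig_index: int
    kind: str  # translocation | inversion | relocation_gap
    gap: int = 5000  # reference gap for relocation_gap events
    replicon: str | None = None  # target replicon for translocations

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class TruthBlock:
    """True alignment of one contig block (all coords 0-based half-open)."""

    contig: str
    c_start: int
    c_end: int
    replicon: str
    r_start: int
    r_end: int
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class SimulatedContigSet:
    """Contigs with per-block ground truth and the injected junction list."""

    contigs: tuple[tuple[str, str], ...]
    truth_blocks: Mapping[str, tuple[TruthBlock, ...]]
    injected_events: tuple[tuple[str, int, str], ...]  # (contig, junction, kind)


def _block_segment(
    arrs: Mapping[str, np.ndarray],
    replicon: str,
    start: int,
    length: int,
    strand: str,
) -> str:
    seg = arrs[replicon][start : start + length]
    if strand == "-":
        seg = _COMPLEMENT[seg][::-1]
    return _to_str(seg)


def simulate_contigs(
    genome: SyntheticGenome,
    n_contigs: int,
    events: Sequence[ContigEvent] = (),
    min_len: int = 1000,
    seed: int = 0,
) -> SimulatedContigSet:
    """Build ``n_contigs`` contigs; contig i receives the events addressed to it.

    Event-free contigs are exact substrings of one replicon. Each injected
    event stitches an additional block after a junction: translocations take
    the next block from a different replicon, inversions flip strand on the
    same replicon, relocations displace the next block by ``gap`` bp on the
    same replicon and strand. Every block is at least ``min_len`` bp, so all
    junctions leave ``min_len`` on each side.
    """
    rng = np.random.default_rng(seed)
    names = [n for n, _ in genome.replicons]
    arrs = {n: _to_arr(s) for n, s in genome.replicons}
    lens = {n: a.size for n, a in arrs.items()}

    by_contig: dict[int, list[ContigEvent]] = {i: [] for i in range(n_contigs)}
    for ev in events:
        if ev.contig_index not in by_contig:
            raise ValueError(f"event addresses contig {ev.contig_index} of {n_contigs}")
        if ev.replicon is not None and ev.replicon not in arrs:
            raise ValueError(f"event references absent replicon {ev.replicon!r}")
        if ev.kind == "translocation" and len(names) < 2 and ev.replicon is None:
            raise ValueError("translocation events need at least two replicons")
        by_contig[ev.contig_index].append(ev)

    def _rand_block_len() -> int:
        return int(rng.integers(min_len, 2 * min_len + 1))

    contigs: list[tuple[str, str]] = []
    truth: dict[str, tuple[TruthBlock, ...]] = {}
    injected: list[tuple[str, int, str]] = []

    for i in range(n_contigs):
        cname = f"contig_{i + 1}"
        evs = by_contig[i]
        for _attempt in range(200):
            try:
                blocks, seqs = _build_contig(
                    cname, evs, names, arrs, lens, _rand_block_len, rng
                )
                break
            except _Retry:
                continue
        else:
            raise ValueError(f"could not place blocks for {cname}; genome too small")
        contigs.append((cname, "".join(seqs)))
        truth[cname] = tuple(blocks)
        for ev, blk in zip(evs, blocks[1:]):
            injected.append((cname, blk.c_start, ev.kind))

    return SimulatedContigSet(tuple(contigs), truth, tuple(injected))


class _Retry(Exception):
    pass


def _build_contig(
    cname: str,
    evs: Sequence[ContigEvent],
    names: Sequence[str],
    arrs: Mapping[str, np.ndarray],
    lens: Mapping[str, int],
    rand_len,
    rng: np.random.Generator,
) -> tuple[list[TruthBlock], list[str]]:
    blocks: list[TruthBlock] = []
    seqs: list[str] = []
    c_pos = 0

    # first block
    blen = rand_len()
    rep = names[int(rng.integers(0, len(names)))]
    if lens[rep] <= blen:
        raise _Retry
    r_start = int(rng.integers(0, lens[rep] - blen + 1))
    strand = "+"
    blocks.append(TruthBlock(cname, 0, blen, rep, r_start, r_start + blen, strand))
    seqs.append(_block_segment(arrs, rep, r_start, blen, strand))
    c_pos = blen

    for ev in evs:
        prev = blocks[-1]
        blen = rand_len()
        if ev.kind == "translocation":
            choices = [n for n in names if n != prev.replicon]
            rep = ev.replicon or choices[int(rng.integers(0, len(choices)))]
            if rep == prev.replicon:
                raise ValueError("translocation target equals current replicon")
            if lens[rep] <= blen:
                raise _Retry
            r_start = int(rng.integers(0, lens[rep] - blen + 1))
            strand = prev.strand
        elif ev.kind == "inversion":
            rep = prev.replicon
            if lens[rep] <= blen:
                raise _Retry
            r_start = int(rng.integers(0, lens[rep] - blen + 1))
            strand = "-" if prev.strand == "+" else "+"
        else:  # relocation_gap
            rep = prev.replicon
            strand = prev.strand
            if strand == "+":
                r_start = prev.r_end + ev.gap
                if r_start + blen > lens[rep]:
                    raise _Retry
            else:
                r_start = prev.r_start - ev.gap - blen
                if r_start < 0:
                    raise _Retry
        blocks.append(TruthBlock(cname, c_pos, c_pos + blen, rep, r_start, r_start + blen, strand))
        seqs.append(_block_segment(arrs, rep, r_start, blen, strand))
        c_pos += blen
    return blocks, seqs
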