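"""Assembly contiguity metrics against a reference.

N50 is the length of the contig at which the longest-first cumulative sum
reaches half the assembly size; NG50 uses half the reference genome size
instead and is undefined when the assembly never reaches it. Two
reference-aware corrections are computed:

* corrected NG50 — contigs are aligned to the reference, broken at
  detected misassembly junctions (translocation / inversion / relocation
  beyond a threshold), and NG50 is recomputed over the broken pieces
  (the GAGE-style correction);
* NGA50 — NG50 over the aligned-block lengths themselves (the QUAST
  convention); unaligned contig portions contribute nothing.

Contigs shorter than 500 bp are discarded before any metric. Alignment is
exact-match anchoring on unique k-mers extended to maximal exact blocks:
suitable for mutation-free contigs; externally assembled contigs carrying
SNVs need an external aligner (documented limitation). Simulated contig
sets can bypass alignment entirely by passing their truth blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .simulate import SyntheticGenome, TruthBlock, _COMPLEMENT, _to_arr

__all__ = [
    "MIN_CONTIG_LEN",
    "RELOCATION_THRESHOLD",
    "AlignedBlock",
    "BreakEvent",
    "AssemblyMetrics",
    "filter_min_length",
    "n50",
    "ng50",
    "align_contigs",
    "detect_breakpoints",
    "break_contigs",
    "compute_metrics",
]

#: Assembled contigs below this length are discarded, metrics included.
MIN_CONTIG_LEN = 500
#: Reference-coordinate gap/overlap beyond which a junction is a relocation.
RELOCATION_THRESHOLD = 1000


@dataclass(frozen=True)
class AlignedBlock:
    """One maximal exact-match block of a contig on the reference."""

    contig: str
    c_start: int
    c_end: int
    replicon: str
    r_start: int
    r_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.c_end - self.c_start != self.r_end - self.r_start:
            raise ValueError("contig and reference intervals must have equal length")

    @property
    def length(self) -> int:
        return self.c_end - self.c_start


@dataclass(frozen=True)
class BreakEvent:
    """A misassembly junction between two adjacent aligned blocks."""

    contig: str
    junction: int  # position on the contig, strictly inside it
    kind: str  # translocation | inversion | relocation
    evidence: str


@dataclass(frozen=True)
class AssemblyMetrics:
    """Contiguity metrics of one contig set against one reference.

    NG-family values are ``None`` (serialized as "NA") when the assembly
    never reaches half the genome size.
    """

    n_contigs: int
    total_len: int
    avg_contig: float
    n50: int | None
    ng50: int | None
    corrected_ng50: int | None
    nga50: int | None
    n_breaks: int

    def as_row(self) -> dict[str, object]:
        def na(v):
            return "NA" if v is None else v

        return {
            "n_contigs": self.n_contigs,
            "total_len": self.total_len,
            "avg_contig": round(self.avg_contig, 1),
            "n50": na(self.n50),
            "ng50": na(self.ng50),
            "corrected_ng50": na(self.corrected_ng50),
            "nga50": na(self.nga50),
            "n_breaks": self.n_breaks,
        }


# ---------------------------------------------------------------------------
# Length-based metrics
# ---------------------------------------------------------------------------


def filter_min_length(
    contigs: Sequence[tuple[str, str]], min_len: int = MIN_CONTIG_LEN
) -> list[tuple[str, str]]:
    """Retain contigs of at least ``min_len`` bp (inclusive)."""
    return [(n, s) for n, s in contigs if len(s) >= min_len]


def _ng_scan(lengths: Sequence[int], half: float) -> int | None:
    # longest first; ties broken stably (caller pre-sorts names for reports)
    acc = 0
    for ln in sorted(lengths, reverse=True):
        acc += ln
        if acc >= half:
            return int(ln)
    return None


def n50(lengths: Sequence[int]) -> int | None:
    """Length at which the longest-first cumulative sum reaches half the total."""
    if not lengths:
        return None
    return _ng_scan(lengths, sum(lengths) / 2)


def ng50(lengths: Sequence[int], genome_size: int) -> int | None:
    """As N50 but against half the reference genome size; None if unreached."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if not lengths:
        return None
    return _ng_scan(lengths, genome_size / 2)


# ---------------------------------------------------------------------------
# Contig-to-reference alignment (unique k-mer anchoring, exact extension)
# ---------------------------------------------------------------------------


def _as_replicons(
    reference: SyntheticGenome | Sequence[tuple[str, str]] | Mapping[str, str],
) -> list[tuple[str, str]]:
    if isinstance(reference, SyntheticGenome):
        return list(reference.replicons)
    if isinstance(reference, Mapping):
        return list(reference.items())
    return list(reference)


def _index_reference(replicons: Sequence[tuple[str, str]], k: int):
    index: dict[bytes, tuple[int, int]] = {}
    dups: set[bytes] = set()
    arrs = []
    for ri, (_, seq) in enumerate(replicons):
        arr = _to_arr(seq)
        arrs.append(arr)
        data = arr.tobytes()
        for p in range(len(data) - k + 1):
            km = data[p : p + k]
            if km in dups:
                continue
            if km in index:
                del index[km]
                dups.add(km)
            else:
                index[km] = (ri, p)
    return index, dups, arrs


def _extend_block(
    carr: np.ndarray,
    rarr: np.ndarray,
    c_start: int,
    c_end: int,
    r_start: int,
    r_end: int,
    strand: str,
) -> tuple[int, int, int, int]:
    """Extend an anchored match to a maximal exact-match block."""
    if strand == "+":
        while c_start > 0 and r_start > 0 and carr[c_start - 1] == rarr[r_start - 1]:
            c_start -= 1
            r_start -= 1
        while c_end < carr.size and r_end < rarr.size and carr[c_end] == rarr[r_end]:
            c_end += 1
            r_end += 1
    else:
        # contig left edge corresponds to reference right edge
        while c_start > 0 and r_end < rarr.size and carr[c_start - 1] == _COMPLEMENT[rarr[r_end]]:
            c_start -= 1
            r_end += 1
        while c_end < carr.size and r_start > 0 and carr[c_end] == _COMPLEMENT[rarr[r_start - 1]]:
            c_end += 1
            r_start -= 1
    return c_start, c_end, r_start, r_end


def _contig_blocks(
    cname: str,
    seq: str,
    index,
    dups,
    rarrs,
    rnames: Sequence[str],
    k: int,
    stride: int,
) -> list[AlignedBlock]:
    carr = _to_arr(seq)
    data = carr.tobytes()
    rc = _COMPLEMENT[carr][::-1].tobytes()
    n = len(data)
    if n < k:
        return []

    # anchors grouped by (replicon, strand, diagonal)
    groups: dict[tuple[int, str, int], list[tuple[int, int]]] = {}
    positions = list(range(0, n - k + 1, stride))
    if positions[-1] != n - k:
        positions.append(n - k)
    for i in positions:
        km = data[i : i + k]
        hit = index.get(km)
        if hit is not None:
            ri, p = hit
            groups.setdefault((ri, "+", p - i), []).append((i, p))
            continue
        km_rc = rc[n - k - i : n - i]
        hit = index.get(km_rc)
        if hit is not None:
            ri, p = hit
            # contig kmer at i == revcomp(ref[p:p+k]); anti-diagonal p + i
            groups.setdefault((ri, "-", p + i), []).append((i, p))

    blocks: list[AlignedBlock] = []
    for (ri, strand, _diag), anchors in groups.items():
        cs = min(a[0] for a in anchors)
        ce = max(a[0] for a in anchors) + k
        if strand == "+":
            rs = min(a[1] for a in anchors)
            re_ = max(a[1] for a in anchors) + k
        else:
            rs = min(a[1] for a in anchors)
            re_ = max(a[1] for a in anchors) + k
        cs, ce, rs, re_ = _extend_block(carr, rarrs[ri], cs, ce, rs, re_, strand)
        blocks.append(AlignedBlock(cname, cs, ce, rnames[ri], rs, re_, strand))

    # drop blocks contained in another, sort, trim residual contig overlaps
    blocks.sort(key=lambda b: (b.c_start, -(b.c_end)))
    kept: list[AlignedBlock] = []
    for b in blocks:
        if kept and b.c_end <= kept[-1].c_end:
            continue
        kept.append(b)
    out: list[AlignedBlock] = []
    for b in kept:
        if out and b.c_start < out[-1].c_end:
            delta = out[-1].c_end - b.c_start
            if b.length <= delta:
                continue
            if b.strand == "+":
                b = replace(b, c_start=b.c_start + delta, r_start=b.r_start + delta)
            else:
                b = replace(b, c_start=b.c_start + delta, r_end=b.r_end - delta)
        out.append(b)
    return out


def align_contigs(
    contigs: Sequence[tuple[str, str]],
    reference: SyntheticGenome | Sequence[tuple[str, str]] | Mapping[str, str],
    anchor_k: int = 31,
) -> dict[str, list[AlignedBlock]]:
    """Anchor each contig on the reference and return blocks per contig.

    Anchors are k-mers unique in the reference (both strands searched via
    the contig's reverse complement); colinear anchors are merged and
    extended to maximal exact-match blocks, sorted by contig coordinate.
    Contigs with no anchors contribute no blocks.
    """
    replicons = _as_replicons(reference)
    if not replicons or all(len(s) == 0 for _, s in replicons):
        raise ValueError("empty reference")
    index, dups, rarrs = _index_reference(replicons, anchor_k)
    rnames = [n for n, _ in replicons]
    stride = max(1, anchor_k // 2)
    out: dict[str, list[AlignedBlock]] = {}
    for cname, seq in contigs:
        blocks = _contig_blocks(cname, seq, index, dups, rarrs, rnames, anchor_k, stride)
        if not blocks:
            # dense retry for short/awkward contigs before declaring unaligned
            blocks = _contig_blocks(cname, seq, index, dups, rarrs, rnames, anchor_k, 1)
        out[cname] = blocks
    return out


# ---------------------------------------------------------------------------
# Misassembly detection and contig breaking
# ---------------------------------------------------------------------------


def detect_breakpoints(
    blocks_by_contig: Mapping[str, Sequence[AlignedBlock | TruthBlock]],
    relocation_threshold: int = RELOCATION_THRESHOLD,
) -> list[BreakEvent]:
    """Classify junctions between adjacent blocks of each contig.

    Different replicons -> translocation; opposite strands -> inversion;
    same replicon and strand with a reference gap/overlap whose size
    discrepancy exceeds ``relocation_threshold`` -> relocation. Smaller
    discrepancies are tolerated without breaking.
    """
    events: list[BreakEvent] = []
    for cname in sorted(blocks_by_contig):
        blocks = sorted(blocks_by_contig[cname], key=lambda b: b.c_start)
        for prev, nxt in zip(blocks, blocks[1:]):
            junction = prev.c_end
            if prev.replicon != nxt.replicon:
                events.append(
                    BreakEvent(cname, junction, "translocation", f"{prev.replicon}|{nxt.replicon}")
                )
            elif prev.strand != nxt.strand:
                events.append(
                    BreakEvent(cname, junction, "inversion", f"{prev.strand}->{nxt.strand}")
                )
            else:
                c_gap = nxt.c_start - prev.c_end
                if prev.strand == "+":
                    r_gap = nxt.r_start - prev.r_end
                else:
                    r_gap = prev.r_start - nxt.r_end
                disc = r_gap - c_gap
                if abs(disc) > relocation_threshold:
                    events.append(
                        BreakEvent(cname, junction, "relocation", f"ref_gap={disc}")
                    )
    return events


def break_contigs(
    contigs: Sequence[tuple[str, str]], events: Sequence[BreakEvent]
) -> list[int]:
    """Lengths of the pieces after breaking each contig at its junctions.

    A contig with m junctions yields m+1 pieces partitioning it exactly.
    """
    lengths_by_name = {n: len(s) for n, s in contigs}
    junctions: dict[str, list[int]] = {}
    for ev in events:
        if ev.contig not in lengths_by_name:
            raise ValueError(f"event references absent contig {ev.contig!r}")
        total = lengths_by_name[ev.contig]
        if not 0 < ev.junction < total:
            raise ValueError(f"junction {ev.junction} not strictly inside {ev.contig}")
        junctions.setdefault(ev.contig, []).append(ev.junction)

    pieces: list[int] = []
    for name, _seq in contigs:
        total = lengths_by_name[name]
        cuts = sorted(set(junctions.get(name, [])))
        prev = 0
        for c in cuts:
            pieces.append(c - prev)
            prev = c
        pieces.append(total - prev)
    return pieces


# ---------------------------------------------------------------------------
# Combined metric computation
# ---------------------------------------------------------------------------


def compute_metrics(
    contigs: Sequence[tuple[str, str]],
    reference: SyntheticGenome | Sequence[tuple[str, str]] | Mapping[str, str],
    genome_size: int | None = None,
    relocation_threshold: int = RELOCATION_THRESHOLD,
    truth_blocks: Mapping[str, Sequence[TruthBlock]] | None = None,
    min_len: int = MIN_CONTIG_LEN,
    anchor_k: int = 31,
    filter_pieces: bool = False,
) -> AssemblyMetrics:
    """All contiguity metrics of ``contigs`` against ``reference``.

    The >=500 bp filter is applied to input contigs before anything else;
    broken pieces are kept regardless of length unless ``filter_pieces``.
    When ``truth_blocks`` is given, alignment is bypassed and junctions are
    detected directly on the recorded truth.
    """
    replicons = _as_replicons(reference)
    if not replicons or all(len(s) == 0 for _, s in replicons):
        raise ValueError("empty reference")
    if genome_size is None:
        genome_size = sum(len(s) for _, s in replicons)

    kept = filter_min_length(contigs, min_len)
    lengths = [len(s) for _, s in kept]
    total = sum(lengths)
    base = dict(
        n_contigs=len(kept),
        total_len=total,
        avg_contig=(total / len(kept)) if kept else 0.0,
        n50=n50(lengths),
        ng50=ng50(lengths, genome_size) if kept else None,
    )
    if not kept:
        return AssemblyMetrics(**base, corrected_ng50=None, nga50=None, n_breaks=0)

    if truth_blocks is not None:
        blocks_by_contig = {n: list(truth_blocks.get(n, [])) for n, _ in kept}
    else:
        blocks_by_contig = align_contigs(kept, replicons, anchor_k)

    events = detect_breakpoints(blocks_by_contig, relocation_threshold)
    piece_lengths = break_contigs(kept, events)
    if filter_pieces:
        piece_lengths = [p for p in piece_lengths if p >= min_len]
    block_lengths = [b.c_end - b.c_start for bl in blocks_by_contig.values() for b in bl]

    return AssemblyMetrics(
        **base,
        corrected_ng50=ng50(piece_lengths, genome_size) if piece_lengths else None,
        nga50=ng50(block_lengths, genome_size) if block_lengths else None,
        n_breaks=len(events),
    )
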