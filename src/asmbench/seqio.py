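"""FASTA / FASTQ / TSV input-output.

FASTQ is Sanger Phred+33 only. Paired reads live in two mate files with
matching ids in matching order (``_1`` / ``_2`` suffix convention). Files
ending in ``.gz`` are transparently (de)compressed.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
from Bio import SeqIO

from .simulate import ReadPairRecord, TruthBlock

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_paired_fastq",
    "write_paired_fastq",
    "write_truth_blocks",
    "read_truth_blocks",
    "phred_to_string",
    "string_to_phred",
]

PHRED_OFFSET = 33


def _open_text(path: str | Path, mode: str) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def phred_to_string(quals: Sequence[int] | np.ndarray) -> str:
    return "".join(chr(int(q) + PHRED_OFFSET) for q in quals)


def string_to_phred(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8).astype(np.int16) - PHRED_OFFSET


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    with _open_text(path, "r") as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    """Write (name, sequence) records as FASTA wrapped at ``width`` columns."""
    with _open_text(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_paired_fastq(
    pairs: Iterable[ReadPairRecord], path1: str | Path, path2: str | Path
) -> None:
    with _open_text(path1, "w") as f1, _open_text(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.pair_id}/1\n{p.mate1_seq}\n+\n{phred_to_string(p.mate1_quals)}\n")
            f2.write(f"@{p.pair_id}/2\n{p.mate2_seq}\n+\n{phred_to_string(p.mate2_quals)}\n")


def _strip_mate(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


def read_paired_fastq(path1: str | Path, path2: str | Path) -> list[ReadPairRecord]:
    """Read two mate FASTQ files into pair records; ids must correspond."""
    pairs: list[ReadPairRecord] = []
    with _open_text(path1, "r") as f1, _open_text(path2, "r") as f2:
        it1 = SeqIO.parse(f1, "fastq")
        it2 = SeqIO.parse(f2, "fastq")
        for r1, r2 in zip(it1, it2, strict=False):
            id1, id2 = _strip_mate(r1.id), _strip_mate(r2.id)
            if id1 != id2:
                raise ValueError(f"orphan mate: {r1.id!r} paired against {r2.id!r}")
            pairs.append(
                ReadPairRecord(
                    pair_id=id1,
                    mate1_seq=str(r1.seq).upper(),
                    mate1_quals=np.asarray(
                        r1.letter_annotations["phred_quality"], dtype=np.int16
                    ),
                    mate2_seq=str(r2.seq).upper(),
                    mate2_quals=np.asarray(
                        r2.letter_annotations["phred_quality"], dtype=np.int16
                    ),
                )
            )
        if next(it1, None) is not None or next(it2, None) is not None:
            raise ValueError("mate files differ in record count: orphan mates present")
    return pairs


_TRUTH_COLS = (
    "contig\tblock\tcontig_start\tcontig_end\treplicon\tref_start\tref_end\tstrand"
)


def write_truth_blocks(
    truth: dict[str, tuple[TruthBlock, ...]] | dict[str, list[TruthBlock]],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    with _open_text(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(_TRUTH_COLS + "\n")
        for cname in sorted(truth):
            for i, b in enumerate(truth[cname]):
                fh.write(
                    f"{b.contig}\t{i}\t{b.c_start}\t{b.c_end}\t{b.replicon}\t"
                    f"{b.r_start}\t{b.r_end}\t{b.strand}\n"
                )


def read_truth_blocks(path: str | Path) -> dict[str, tuple[TruthBlock, ...]]:
    out: dict[str, list[TruthBlock]] = {}
    with _open_text(path, "r") as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("contig\t"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 8:
                raise ValueError(f"malformed truth-block row: {line!r}")
            blk = TruthBlock(f[0], int(f[2]), int(f[3]), f[4], int(f[5]), int(f[6]), f[7])
            out.setdefault(f[0], []).append(blk)
    return {k: tuple(v) for k, v in out.items()}
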