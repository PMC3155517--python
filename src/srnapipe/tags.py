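"""Unique small-RNA tags: per-library counts, alignments, TSV round trip."""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True, order=True)
class Alignment:
    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int = 0

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class TagRecord:
    """A unique insert consensus with per-library counts and alignments."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)
    alignments: list[Alignment] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def libraries(self) -> list[str]:
        return [lib for lib, c in self.counts.items() if c > 0]

    def key(self) -> tuple:
        a = min(self.alignments) if self.alignments else Alignment("~", -1, -1, "+")
        return (a.chrom, a.start, self.sequence)


def write_tag_table(
    tags: list[TagRecord], path: str | os.PathLike, libraries: list[str] | None = None
) -> None:
    """Write tags as TSV, one row per alignment (or one row if unaligned).

    Rows are ordered by (chrom, start, sequence) of the first alignment so
    repeated writes of the same tag set are byte-identical.
    """
    if libraries is None:
        seen: list[str] = []
        for t in tags:
            for lib in t.counts:
                if lib not in seen:
                    seen.append(lib)
        libraries = sorted(seen)
    rows = []
    for t in sorted(tags, key=TagRecord.key):
        base = {
            "sequence": t.sequence,
            "length": t.length,
            **{f"count:{lib}": t.counts.get(lib, 0) for lib in libraries},
            "flags": ",".join(sorted(t.flags)) if t.flags else ".",
        }
        alns = sorted(t.alignments) or [None]
        for a in alns:
            row = dict(base)
            if a is None:
                row.update(chrom=".", start=-1, end=-1, strand=".", mismatches=-1)
            else:
                row.update(
                    chrom=a.chrom,
                    start=a.start,
                    end=a.end,
                    strand=a.strand,
                    mismatches=a.mismatches,
                )
            rows.append(row)
    cols = (
        ["sequence", "length"]
        + [f"count:{lib}" for lib in libraries]
        + ["chrom", "start", "end", "strand", "mismatches", "flags"]
    )
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False)


def read_tag_table(path: str | os.PathLike) -> list[TagRecord]:
    """Inverse of :func:`write_tag_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "flags": str})
    libs = [c.split(":", 1)[1] for c in df.columns if c.startswith("count:")]
    tags: dict[str, TagRecord] = {}
    for _, row in df.iterrows():
        seq = row["sequence"]
        if seq not in tags:
            counts = {
                lib: int(row[f"count:{lib}"])
                for lib in libs
                if int(row[f"count:{lib}"]) > 0
            }
            flags = set() if row["flags"] in (".", "", None) else set(
                str(row["flags"]).split(",")
            )
            tags[seq] = TagRecord(sequence=seq, counts=counts, flags=flags)
        if row["chrom"] != ".":
            tags[seq].alignments.append(
                Alignment(
                    chrom=str(row["chrom"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=str(row["strand"]),
                    mismatches=int(row["mismatches"]),
                )
            )
    return sorted(tags.values(), key=TagRecord.key)
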