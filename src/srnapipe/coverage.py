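"""Strand-aware chromosome coverage in fixed-width bins.

Every alignment occurrence of a tag increments the bin containing its
start coordinate on its strand, weighted by the tag's read count in the
library (multi-mapped occurrences each count).  Profiles are normalized
by the total number of reads in the library, so bin values are
comparable across libraries of different depth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBundle
from .tags import TagRecord

DEFAULT_BIN_SIZE = 10000


from .errors import ConfigurationError  # noqa: F401  (re-exported)


@dataclass
class BinProfile:
    library: str
    bin_size: int
    total: float  # normalization denominator (library read total)
    plus: dict[str, np.ndarray] = field(default_factory=dict)  # raw counts
    minus: dict[str, np.ndarray] = field(default_factory=dict)

    def normalized(self, chrom: str, strand: str) -> np.ndarray:
        raw = (self.plus if strand == "+" else self.minus)[chrom]
        return raw / self.total if self.total > 0 else raw * 0.0


def bin_alignments(
    tags: list[TagRecord],
    genome: GenomeBundle,
    bin_size: int = DEFAULT_BIN_SIZE,
    weighting: str = "reads",
    libraries: list[str] | None = None,
) -> dict[str, BinProfile]:
    """Per-library strand-split bin profiles.

    ``weighting`` is "reads" (each alignment weighted by the library read
    count of the tag) or "unique" (each alignment counts 1).
    """
    if bin_size <= 0:
        raise ConfigurationError("bin-size must be >= 1")
    if weighting not in ("reads", "unique"):
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    if libraries is None:
        libraries = sorted({lib for t in tags for lib in t.libraries()})
    nbins = {
        chrom: max(1, -(-len(seq) // bin_size))
        for chrom, seq in genome.chromosomes.items()
    }
    profiles = {}
    for lib in libraries:
        total = sum(t.counts.get(lib, 0) for t in tags)
        prof = BinProfile(
            library=lib,
            bin_size=bin_size,
            total=float(total),
            plus={c: np.zeros(n) for c, n in nbins.items()},
            minus={c: np.zeros(n) for c, n in nbins.items()},
        )
        for t in tags:
            count = t.counts.get(lib, 0)
            if count == 0:
                continue
            w = float(count) if weighting == "reads" else 1.0
            for a in t.alignments:
                vec = prof.plus if a.strand == "+" else prof.minus
                vec[a.chrom][a.start // bin_size] += w
        profiles[lib] = prof
    return profiles


def export_profiles(
    profiles: dict[str, BinProfile],
    out_dir: str | os.PathLike,
    plot: bool = False,
) -> None:
    """Write per-chromosome histogram TSVs and a heatmap matrix TSV.

    Histogram values are signed: plus-strand coverage above zero,
    minus-strand below.  Heatmap rows are libraries in input order,
    columns are bins concatenated over chromosomes (both strands summed).
    """
    sizes = {p.bin_size for p in profiles.values()}
    if len(sizes) > 1:
        raise ConfigurationError("profiles have mixed bin sizes")
    os.makedirs(out_dir, exist_ok=True)
    libs = list(profiles)
    any_prof = profiles[libs[0]]
    chroms = sorted(any_prof.plus)
    for chrom in chroms:
        data = {"bin_start": np.arange(len(any_prof.plus[chrom])) * any_prof.bin_size}
        for lib in libs:
            data[f"{lib}:plus"] = profiles[lib].normalized(chrom, "+")
            data[f"{lib}:minus"] = -profiles[lib].normalized(chrom, "-")
        pd.DataFrame(data).to_csv(
            os.path.join(out_dir, f"histogram_{chrom}.tsv"), sep="\t", index=False
        )
    cols, mat = [], []
    for lib in libs:
        row = np.concatenate(
            [
                profiles[lib].normalized(c, "+") + profiles[lib].normalized(c, "-")
                for c in chroms
            ]
        )
        mat.append(row)
    for c in chroms:
        cols += [f"{c}:{i * any_prof.bin_size}" for i in range(len(any_prof.plus[c]))]
    pd.DataFrame(mat, index=pd.Index(libs, name="library"), columns=cols).to_csv(
        os.path.join(out_dir, "heatmap_matrix.tsv"), sep="\t"
    )
    if plot:
        _plot_heatmap(profiles, out_dir, chroms)


def export_bedgraph(profile: BinProfile, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(profile.plus):
            for strand, sign in (("+", 1.0), ("-", -1.0)):
                vals = profile.normalized(chrom, strand)
                for i, v in enumerate(vals):
                    if v != 0:
                        s = i * profile.bin_size
                        fh.write(f"{chrom}\t{s}\t{s + profile.bin_size}\t{sign * v:.6g}\n")


def _plot_heatmap(profiles, out_dir, chroms) -> None:  # pragma: no cover
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    libs = list(profiles)
    for chrom in chroms:
        fig, axes = plt.subplots(2, 1, figsize=(10, 4), height_ratios=[1, 2])
        mat = np.vstack(
            [
                profiles[lib].normalized(chrom, "+") + profiles[lib].normalized(chrom, "-")
                for lib in libs
            ]
        )
        axes[0].imshow(mat, aspect="auto", cmap="Greys")
        axes[0].set_yticks(range(len(libs)), libs)
        for lib in libs:
            x = np.arange(mat.shape[1])
            axes[1].bar(x, profiles[lib].normalized(chrom, "+"), alpha=0.5, label=lib)
            axes[1].bar(x, -profiles[lib].normalized(chrom, "-"), alpha=0.5)
        axes[1].legend(fontsize=6)
        fig.suptitle(chrom)
        fig.savefig(os.path.join(out_dir, f"coverage_{chrom}.png"), dpi=120)
        plt.close(fig)
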