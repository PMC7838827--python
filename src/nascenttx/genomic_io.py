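"""Genomic containers and format IO.

Coordinates are 0-based half-open everywhere in memory.  BED and bedGraph
files are read/written in their native 0-based dialect, GTF in its native
1-based closed dialect.  Coverage is stored as per-chromosome vectors of
fragment(-midpoint) counts in fixed-width bins.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome sizes plus the fixed bin width of the coverage grid."""

    chromosomes: tuple[tuple[str, int], ...]
    bin_width: int = 200

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            if length % self.bin_width != 0:
                raise ValueError(
                    f"chromosome {name} length {length} is not a multiple of "
                    f"bin_width {self.bin_width}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def n_bins(self, chrom: str) -> int:
        return -(-self.lengths[chrom] // self.bin_width)

    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c, _ in self.chromosomes)


@dataclass
class BinnedCoverage:
    """Strand-specific fragment-midpoint counts in consecutive fixed bins."""

    sample_id: str
    strand: str
    bin_width: int
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        for chrom, vec in self.data.items():
            vec = np.asarray(vec)
            if vec.ndim != 1:
                raise ValueError(f"coverage for {chrom} must be 1-D")
            if np.any(vec < 0):
                raise ValueError(f"negative counts on {chrom}")
            self.data[chrom] = vec

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def concat(self) -> np.ndarray:
        """All chromosomes concatenated in layout order."""
        return np.concatenate([self.data[c] for c in sorted(self.data)])


def empty_coverage(layout: GenomeLayout, sample_id: str, strand: str) -> BinnedCoverage:
    data = {
        chrom: np.zeros(layout.n_bins(chrom), dtype=np.int64)
        for chrom, _ in layout.chromosomes
    }
    return BinnedCoverage(sample_id, strand, layout.bin_width, data)


# ---------------------------------------------------------------------------
# interval <-> bin arithmetic
# ---------------------------------------------------------------------------

def bin_index_range(start: int, end: int, bin_width: int) -> tuple[int, int]:
    """Half-open range of bin indices whose midpoints fall in [start, end).

    The midpoint of bin i is ``i * w + w // 2``; a bin belongs to an interval
    iff its midpoint does, mirroring the fragment-midpoint counting rule.
    """
    w = bin_width
    half = w // 2
    lo = -(-(start - half) // w)  # ceil((start - half) / w)
    hi = -(-(end - half) // w)
    return max(lo, 0), max(hi, 0)


def bin_midpoints(fragments: pd.DataFrame, layout: GenomeLayout,
                  sample_id: str = "sample") -> dict[str, BinnedCoverage]:
    """Reduce a fragment table (chrom, start, end, strand) to binned coverage.

    Each fragment increments exactly the bin containing floor((start+end)/2).
    Returns one :class:`BinnedCoverage` per strand.
    """
    out = {s: empty_coverage(layout, sample_id, s) for s in "+-"}
    lengths = layout.lengths
    for strand, sub in fragments.groupby("strand"):
        if strand not in out:
            raise ValueError(f"unexpected strand {strand!r}")
        for chrom, chrom_sub in sub.groupby("chrom"):
            if chrom not in lengths:
                raise ValueError(f"unknown chromosome {chrom!r}")
            starts = chrom_sub["start"].to_numpy()
            ends = chrom_sub["end"].to_numpy()
            if np.any(starts < 0) or np.any(ends > lengths[chrom]):
                raise ValueError(f"fragment outside chromosome {chrom}")
            mids = (starts + ends) // 2
            idx = mids // layout.bin_width
            np.add.at(out[strand].data[chrom], idx, 1)
    return out


def count_fragments(intervals: pd.DataFrame,
                    coverage: dict[str, BinnedCoverage],
                    strand_rule: str = "sense") -> np.ndarray:
    """Count binned fragments per interval.

    An interval's count is the sum over bins whose midpoint lies inside it,
    taken on the strand selected by ``strand_rule`` relative to the interval's
    strand ('sense', 'antisense', or 'both').  Unstranded intervals ('.')
    treat '+' as sense.
    """
    if strand_rule not in ("sense", "antisense", "both"):
        raise ValueError(f"unknown strand_rule {strand_rule!r}")
    bw = coverage["+"].bin_width
    csum = {
        s: {c: np.concatenate([[0], np.cumsum(v)]) for c, v in cov.data.items()}
        for s, cov in coverage.items()
    }

    def one(chrom, start, end, strand):
        lo, hi = bin_index_range(int(start), int(end), bw)
        total = 0.0
        flip = {"+": "-", "-": "+", ".": "-"}
        sense = strand if strand in "+-" else "+"
        if strand_rule == "sense":
            use = [sense]
        elif strand_rule == "antisense":
            use = [flip[sense]]
        else:
            use = ["+", "-"]
        for s in use:
            cs = csum[s][chrom]
            hi_c = min(hi, len(cs) - 1)
            lo_c = min(lo, hi_c)
            total += cs[hi_c] - cs[lo_c]
        return total

    strands = intervals["strand"] if "strand" in intervals else pd.Series(
        ["."] * len(intervals), index=intervals.index)
    return np.array([
        one(c, s, e, st)
        for c, s, e, st in zip(intervals["chrom"], intervals["start"],
                               intervals["end"], strands)
    ])


# ---------------------------------------------------------------------------
# annotation IO
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Gene models: one row per gene plus an exon table, 0-based half-open."""

    genes: pd.DataFrame   # gene_id, chrom, start, end, strand, biotype
    exons: pd.DataFrame   # gene_id, chrom, start, end, strand

    def tss(self) -> pd.Series:
        """Strand-aware transcription start site per gene."""
        g = self.genes
        return pd.Series(
            np.where(g["strand"] == "+", g["start"], g["end"]),
            index=g["gene_id"], name="tss",
        )


def read_annotation(path: str, dialect: str) -> "GeneAnnotation | pd.DataFrame":
    """Read a GTF (genes + exons) or BED file into internal coordinates."""
    if dialect == "gtf":
        return _read_gtf(path)
    if dialect == "bed":
        return read_bed(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_gtf(path: str) -> GeneAnnotation:
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes, exons = [], []
    for feat in db.all_features():
        rec = {
            "gene_id": feat.attributes.get("gene_id", [feat.id])[0],
            "chrom": feat.seqid,
            "start": feat.start - 1,  # GTF is 1-based closed
            "end": feat.end,
            "strand": feat.strand,
        }
        if feat.featuretype == "gene":
            rec["biotype"] = feat.attributes.get("gene_biotype", ["protein_coding"])[0]
            genes.append(rec)
        elif feat.featuretype == "exon":
            exons.append(rec)
    gcols = ["gene_id", "chrom", "start", "end", "strand", "biotype"]
    ecols = ["gene_id", "chrom", "start", "end", "strand"]
    return GeneAnnotation(
        pd.DataFrame(genes, columns=gcols),
        pd.DataFrame(exons, columns=ecols),
    )


def write_gtf(annotation: GeneAnnotation, path: str, source: str = "nascenttx"):
    with open(path, "w") as fh:
        for _, g in annotation.genes.iterrows():
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            sub = annotation.exons[annotation.exons["gene_id"] == g.gene_id]
            for _, e in sub.iterrows():
                fh.write(
                    f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )


def read_bed(path: str) -> pd.DataFrame:
    """Read BED3/BED6(+) into a DataFrame; extra columns are preserved."""
    if os.path.getsize(path) == 0:
        return pd.DataFrame(columns=BED_COLUMNS)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    df.columns = BED_COLUMNS[:ncol] + [f"extra_{i}" for i in range(ncol - 6)]
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df:
            df[col] = default
    if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
        bad = int(np.argmax((df["start"] < 0) | (df["start"] >= df["end"])))
        raise ValueError(f"malformed BED interval at line {bad + 1} of {path}")
    return df


def write_bed(df: pd.DataFrame, path: str, extra: list[str] | None = None):
    cols = BED_COLUMNS + (extra or [])
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in out:
            out[col] = default
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(coverage: BinnedCoverage, path: str):
    """Write binned coverage as a run-length-collapsed bedGraph."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{coverage.sample_id}{coverage.strand}"\n')
        bw = coverage.bin_width
        for chrom in sorted(coverage.data):
            vec = coverage.data[chrom]
            if len(vec) == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(vec)]])
            for s, e in zip(starts, ends):
                if vec[s] != 0:
                    fh.write(f"{chrom}\t{s * bw}\t{e * bw}\t{int(vec[s])}\n")


def read_bedgraph(path: str, layout: GenomeLayout, sample_id: str,
                  strand: str) -> BinnedCoverage:
    cov = empty_coverage(layout, sample_id, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"malformed bedGraph line {lineno} in {path}")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if chrom not in cov.data:
                raise ValueError(f"unknown chromosome {chrom!r} at line {lineno}")
            bw = layout.bin_width
            if start % bw or end % bw:
                raise ValueError(f"bedGraph segment not bin-aligned at line {lineno}")
            cov.data[chrom][start // bw:end // bw] = int(float(value))
    return cov


def write_track(obj, path: str, dialect: str):
    """Polymorphic writer: binned coverage -> bedGraph, interval table -> BED."""
    if dialect == "bedgraph":
        write_bedgraph(obj, path)
    elif dialect == "bed":
        write_bed(obj, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def merge_intervals(df: pd.DataFrame, keep_sources: bool = False) -> pd.DataFrame:
    """Collapse overlapping (or touching) intervals into their union.

    With ``keep_sources`` the merged record lists the contributing ``source``
    values (comma-joined, deduplicated, order of first appearance).
    """
    if df.empty:
        out = df.loc[:, ["chrom", "start", "end"]].copy()
        if keep_sources:
            out["sources"] = pd.Series(dtype=str)
        return out
    rows = []
    for chrom, sub in df.sort_values(["chrom", "start", "end"]).groupby("chrom"):
        cur_start = cur_end = None
        cur_sources: list[str] = []
        for _, r in sub.iterrows():
            if cur_start is None or r["start"] > cur_end:
                if cur_start is not None:
                    rows.append((chrom, cur_start, cur_end, cur_sources))
                cur_start, cur_end = int(r["start"]), int(r["end"])
                cur_sources = []
            else:
                cur_end = max(cur_end, int(r["end"]))
            if keep_sources and "source" in sub:
                src = str(r["source"])
                if src not in cur_sources:
                    cur_sources.append(src)
        rows.append((chrom, cur_start, cur_end, cur_sources))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "_sources"])
    if keep_sources:
        out["sources"] = [",".join(s) for s in out["_sources"]]
    return out.drop(columns="_sources").reset_index(drop=True)
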