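"""Genomic text-format IO and exon-space coordinate plumbing.

All coordinates are 0-based half-open (BED convention), declared here once and
enforced by every parser in the package. Gene models come from BED12, candidate
m6A sites and site panels from BED6, and per-base coverage from 4-column
bedGraph. Coverage is unstranded by default; a stranded mode accepting a
plus/minus bedGraph pair is available for users with stranded tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

UNSTRANDED = "."


class FormatError(ValueError):
    """A file could not be parsed as the declared format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A transcript's exon structure; defines the exonic space for coverage.

    ``exons`` are half-open genomic intervals, sorted ascending and
    non-overlapping. The gene-body median used by the POM score is taken over
    the union of these intervals.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id!r}: no exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValidationError(
                    f"gene {self.gene_id!r}: empty exon [{start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"gene {self.gene_id!r}: exons overlap or are unsorted at {start}"
                )
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exonic_positions(self) -> np.ndarray:
        """All exonic genomic base positions, ascending."""
        return np.concatenate([np.arange(s, e) for s, e in self.exons])


@dataclass(frozen=True)
class Site:
    """A candidate m6A site (the peak region), assigned to an owner gene."""

    site_id: str
    chrom: str
    start: int
    end: int
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"site {self.site_id!r}: empty interval [{self.start}, {self.end})"
            )


def project_to_exons(site: Site, gene: GeneModel) -> np.ndarray:
    """Genomic base positions in ``site ∩ exons(gene)``, sorted ascending.

    Raises ValidationError when the intersection is empty (a site must overlap
    at least one exonic base of its owner gene).
    """
    parts = []
    for s, e in gene.exons:
        a, b = max(s, site.start), min(e, site.end)
        if a < b:
            parts.append(np.arange(a, b))
    if not parts:
        raise ValidationError(
            f"site {site.site_id!r} has no exonic overlap with gene {gene.gene_id!r}"
        )
    return np.concatenate(parts)


def exonic_union(genes: Iterable[GeneModel]) -> dict[str, np.ndarray]:
    """Merged exonic intervals per chromosome, as an (n, 2) array each."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).extend(g.exons)
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.asarray(merged, dtype=np.int64)
    return out


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------


def _dense_to_runs(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if arr.size == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z, np.zeros(0)
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], change)).astype(np.int64)
    ends = np.concatenate((change, [arr.size])).astype(np.int64)
    return starts, ends, np.asarray(arr, dtype=np.float64)[starts]


class CoverageTrack:
    """Per-base read depth for one sample.

    Depth is stored either densely (one array per chromosome, used by the
    simulator) or as sorted non-overlapping runs (used when reading bedGraph);
    both representations return identical depths by contract. ``lib_total`` is
    the summed depth over the union of exonic bases of the loaded genes and
    drives the depth-per-million normalization used by the scores.
    """

    def __init__(self, sample_id: str, lib_total: float = 0.0, stranded: bool = False):
        self.sample_id = sample_id
        self.lib_total = float(lib_total)
        self.stranded = stranded
        self._dense: dict[tuple[str, str], np.ndarray] = {}
        self._runs: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    # -- construction -------------------------------------------------------

    def add_dense(self, chrom: str, depths: np.ndarray, strand: str = UNSTRANDED) -> None:
        if np.any(depths < 0):
            raise ValidationError(f"track {self.sample_id!r}: negative depth on {chrom}")
        self._dense[(chrom, strand)] = depths

    def add_runs(
        self,
        chrom: str,
        starts: np.ndarray,
        ends: np.ndarray,
        values: np.ndarray,
        strand: str = UNSTRANDED,
    ) -> None:
        if np.any(values < 0):
            raise ValidationError(f"track {self.sample_id!r}: negative depth on {chrom}")
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if np.any(starts[1:] < ends[:-1]):
            raise ValidationError(
                f"track {self.sample_id!r}: overlapping bedGraph records on {chrom}"
            )
        self._runs[(chrom, strand)] = (
            starts.astype(np.int64),
            ends.astype(np.int64),
            values.astype(np.float64),
        )

    @classmethod
    def from_dense(
        cls,
        sample_id: str,
        dense: dict[str, np.ndarray],
        genes: Sequence[GeneModel] | None = None,
        lib_total: float | None = None,
    ) -> "CoverageTrack":
        track = cls(sample_id)
        for chrom, arr in dense.items():
            track.add_dense(chrom, arr)
        if lib_total is not None:
            track.lib_total = float(lib_total)
        elif genes is not None:
            track.lib_total = track.recompute_lib_total(genes)
        return track

    # -- queries -------------------------------------------------------------

    def _key(self, chrom: str, strand: str | None) -> tuple[str, str]:
        if self.stranded and strand in ("+", "-"):
            return (chrom, strand)
        return (chrom, UNSTRANDED)

    def depth(
        self, chrom: str, positions: np.ndarray, strand: str | None = None
    ) -> np.ndarray:
        """Raw depth at each genomic base position (0 outside any record)."""
        positions = np.asarray(positions, dtype=np.int64)
        key = self._key(chrom, strand)
        if key in self._dense:
            arr = self._dense[key]
            out = np.zeros(positions.size, dtype=np.float64)
            ok = (positions >= 0) & (positions < arr.size)
            out[ok] = arr[positions[ok]]
            return out
        if key in self._runs:
            starts, ends, values = self._runs[key]
            out = np.zeros(positions.size, dtype=np.float64)
            if starts.size == 0:
                return out
            idx = np.searchsorted(starts, positions, side="right") - 1
            ok = idx >= 0
            idx_c = np.clip(idx, 0, starts.size - 1)
            ok &= positions < ends[idx_c]
            out[ok] = values[idx_c[ok]]
            return out
        return np.zeros(positions.size, dtype=np.float64)

    def runs(
        self, chrom: str, strand: str = UNSTRANDED
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Run-length view (starts, ends, values) including zero runs."""
        key = (chrom, strand)
        if key in self._runs:
            return self._runs[key]
        if key in self._dense:
            return _dense_to_runs(self._dense[key])
        z = np.zeros(0, dtype=np.int64)
        return z, z, np.zeros(0)

    @property
    def chroms(self) -> list[str]:
        return sorted({c for c, _ in list(self._dense) + list(self._runs)})

    @property
    def norm_factor(self) -> float:
        """Depth-per-million scale factor; 0 when the library is empty."""
        return 1e6 / self.lib_total if self.lib_total > 0 else 0.0

    def recompute_lib_total(self, genes: Sequence[GeneModel]) -> float:
        """Sum of depth over the union of exonic bases of ``genes``."""
        total = 0.0
        union = exonic_union(genes)
        for chrom, ivs in union.items():
            for strand in ("+", "-", UNSTRANDED):
                key = (chrom, strand)
                if key not in self._dense and key not in self._runs:
                    continue
                starts, ends, values = self.runs(chrom, strand)
                for a, b in ivs:
                    i = np.searchsorted(ends, a, side="right")
                    j = np.searchsorted(starts, b, side="left")
                    if i >= j:
                        continue
                    s = np.clip(starts[i:j], a, None)
                    e = np.clip(ends[i:j], None, b)
                    total += float(((e - s) * values[i:j]).sum())
        return total

    def to_bedgraph(self, path: str | Path) -> None:
        """Write non-zero runs as a 4-column bedGraph (deterministic bytes)."""
        with open(path, "w") as fh:
            for chrom in self.chroms:
                starts, ends, values = self.runs(chrom)
                for s, e, v in zip(starts, ends, values):
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Sample design
# ---------------------------------------------------------------------------

FRACTIONS = ("IP", "INPUT")


@dataclass
class SampleDesign:
    """The sample sheet: one IP and one INPUT row per (condition, replicate)."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "fraction", "condition", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"design table missing columns: {missing}")
        t = self.table.copy()
        t["fraction"] = t["fraction"].astype(str).str.upper()
        t["condition"] = t["condition"].astype(str)
        t["replicate"] = t["replicate"].astype(int)
        bad = ~t["fraction"].isin(FRACTIONS)
        if bad.any():
            raise ValidationError(
                f"design: fraction must be IP or INPUT, got {sorted(t.loc[bad, 'fraction'])}"
            )
        if (t["replicate"] < 1).any():
            raise ValidationError("design: replicate numbers must be positive")
        if t["sample_id"].duplicated().any():
            dups = sorted(t.loc[t["sample_id"].duplicated(), "sample_id"])
            raise ValidationError(f"design: duplicate sample ids {dups}")
        counts = t.groupby(["condition", "replicate"])["fraction"].value_counts()
        for (cond, rep), sub in t.groupby(["condition", "replicate"]):
            fr = sorted(sub["fraction"])
            if fr != ["INPUT", "IP"]:
                raise ValidationError(
                    f"design: ({cond}, replicate {rep}) must have exactly one IP and "
                    f"one INPUT row, got {fr}"
                )
        _ = counts  # grouping above is the actual check
        self.table = t.sort_values(["condition", "replicate", "fraction"]).reset_index(
            drop=True
        )

    @classmethod
    def read(cls, path: str | Path) -> "SampleDesign":
        return cls(pd.read_csv(path, sep="\t"))

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())

    def replicates(self, condition: str) -> list[int]:
        sub = self.table[self.table["condition"] == condition]
        return sorted(sub["replicate"].unique())

    def pairs(self) -> list[tuple[str, int, str, str]]:
        """(condition, replicate, ip_sample_id, input_sample_id) tuples."""
        out = []
        for (cond, rep), sub in self.table.groupby(["condition", "replicate"]):
            ip = sub.loc[sub["fraction"] == "IP", "sample_id"].iloc[0]
            inp = sub.loc[sub["fraction"] == "INPUT", "sample_id"].iloc[0]
            out.append((cond, int(rep), ip, inp))
        return sorted(out)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse a BED12 file into GeneModels, reconstructing exons from blocks."""
    genes = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 12:
            raise FormatError(f"{path}:{lineno}: expected 12 BED fields, got {len(f)}")
        try:
            chrom_start = int(f[1])
            chrom_end = int(f[2])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",") if x != ""]
            offsets = [int(x) for x in f[11].rstrip(",").split(",") if x != ""]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric BED12 field ({exc})") from exc
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise FormatError(
                f"{path}:{lineno}: blockCount={n_blocks} but {len(sizes)} sizes / "
                f"{len(offsets)} starts listed"
            )
        if chrom_end <= chrom_start:
            raise FormatError(f"{path}:{lineno}: chromEnd <= chromStart")
        exons = tuple(
            (chrom_start + off, chrom_start + off + size)
            for off, size in zip(offsets, sizes)
        )
        try:
            genes.append(GeneModel(f[3], f[0], f[5], exons))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            start, end = g.start, g.end
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offs = ",".join(str(s - start) for s, e in g.exons)
            fh.write(
                f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{start}\t{end}\t0\t{len(g.exons)}\t{sizes}\t{offs}\n"
            )


def read_sites(path: str | Path, genes: Sequence[GeneModel]) -> list[Site]:
    """Parse BED sites and assign each to the gene with maximal exonic overlap.

    Ties are broken by lexicographically smallest gene_id (logged);
    unassignable sites are dropped with a logged count.
    """
    trees: dict[str, IntervalTree] = {}
    gene_by_id = {g.gene_id: g for g in genes}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.exons:
            tree[s:e] = g.gene_id

    sites: list[Site] = []
    dropped = 0
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 4:
            raise FormatError(
                f"{path}:{lineno}: expected >= 4 BED fields (chrom,start,end,name)"
            )
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric coordinates") from exc
        if end <= start:
            raise ValidationError(f"{path}:{lineno}: zero-length site interval")
        site_id, chrom = f[3], f[0]
        overlap: dict[str, int] = {}
        for iv in trees.get(chrom, IntervalTree()).overlap(start, end):
            bp = min(end, iv.end) - max(start, iv.begin)
            overlap[iv.data] = overlap.get(iv.data, 0) + bp
        if not overlap:
            dropped += 1
            continue
        best = max(overlap.values())
        winners = sorted(gid for gid, bp in overlap.items() if bp == best)
        if len(winners) > 1:
            log.info(
                "site %s: exonic-overlap tie between %s; assigned to %s",
                site_id, winners, winners[0],
            )
        sites.append(Site(site_id, chrom, start, end, winners[0]))
    if dropped:
        log.info("read_sites(%s): dropped %d sites with no exonic gene overlap", path, dropped)
    _ = gene_by_id
    return sites


def write_sites(sites: Sequence[Site], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.site_id}\t0\t.\n")


def _read_bedgraph_records(path: str | Path):
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 4:
            raise FormatError(f"{path}:{lineno}: expected 4 bedGraph fields")
        try:
            start, end, value = int(f[1]), int(f[2]), float(f[3])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric bedGraph field") from exc
        if value < 0:
            raise ValidationError(f"{path}:{lineno}: negative depth {value}")
        if end <= start:
            raise ValidationError(f"{path}:{lineno}: empty interval")
        by_chrom.setdefault(f[0], []).append((start, end, value))
    return by_chrom


def read_bedgraph(
    path: str | Path,
    genes: Sequence[GeneModel],
    sample_id: str | None = None,
) -> CoverageTrack:
    """Load a 4-column bedGraph as an unstranded CoverageTrack.

    Records within a chromosome must not overlap. ``lib_total`` is computed
    over the exonic union of the supplied genes.
    """
    sample_id = sample_id or Path(path).stem
    track = CoverageTrack(sample_id)
    for chrom, recs in _read_bedgraph_records(path).items():
        arr = np.asarray(recs, dtype=np.float64)
        try:
            track.add_runs(chrom, arr[:, 0], arr[:, 1], arr[:, 2])
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    track.lib_total = track.recompute_lib_total(genes)
    return track


def read_bedgraph_stranded(
    plus_path: str | Path,
    minus_path: str | Path,
    genes: Sequence[GeneModel],
    sample_id: str,
) -> CoverageTrack:
    """Load a per-strand bedGraph pair into a stranded CoverageTrack."""
    track = CoverageTrack(sample_id, stranded=True)
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        for chrom, recs in _read_bedgraph_records(path).items():
            arr = np.asarray(recs, dtype=np.float64)
            try:
                track.add_runs(chrom, arr[:, 0], arr[:, 1], arr[:, 2], strand=strand)
            except ValidationError as exc:
                raise ValidationError(f"{path}: {exc}") from exc
    track.lib_total = track.recompute_lib_total(genes)
    return track
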