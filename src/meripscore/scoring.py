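"""POI and POM enrichment scores for candidate m6A sites.

Each candidate site gets, per replicate and condition, a peak-over-input (POI)
score — mean normalized IP depth over the site's exonic bases relative to the
matched input fraction — and a peak-over-median (POM) score — the same peak
depth relative to the median normalized depth across all exonic bases of the
host gene. Depths are normalized per track to depth-per-million exonic
coverage (1e6 / lib_total) so that libraries of different size are comparable,
and a pseudocount ``eps`` (normalized-depth units) is added to numerator and
denominator so both scores are strictly positive; QC flags record when the
pseudocount dominated a denominator.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    CoverageTrack,
    GeneModel,
    SampleDesign,
    Site,
    ValidationError,
    project_to_exons,
)

log = logging.getLogger(__name__)

DEFAULT_EPS = 0.5

LOW_INPUT = "LOW_INPUT"
LOW_GENE = "LOW_GENE"
ZERO_IP = "ZERO_IP"

SCORE_COLUMNS = ["site_id", "gene_id", "condition", "replicate", "poi", "pom", "qc_flags"]


def normalized_mean_depth(
    track: CoverageTrack,
    chrom: str,
    positions: np.ndarray,
    strand: str | None = None,
) -> float:
    """Mean raw depth over ``positions`` scaled by 1e6 / lib_total.

    Returns 0 (with a warning) when the track's library is empty.
    """
    positions = np.asarray(positions)
    if positions.size == 0:
        raise ValidationError("normalized_mean_depth: positions must be non-empty")
    if track.lib_total <= 0:
        log.warning("track %s has empty library (lib_total=0)", track.sample_id)
        return 0.0
    return float(track.depth(chrom, positions, strand).mean()) * track.norm_factor


def gene_median_depth(track: CoverageTrack, gene: GeneModel) -> float:
    """Median normalized depth over all exonic bases of the gene.

    Zero-depth exonic bases are included (excluding them would act as a hidden
    expression filter); the median is the 50th percentile with linear
    interpolation.
    """
    pos = gene.exonic_positions()
    if track.lib_total <= 0:
        log.warning("track %s has empty library (lib_total=0)", track.sample_id)
        return 0.0
    return float(np.median(track.depth(gene.chrom, pos, gene.strand))) * track.norm_factor


def _poi_from_depths(d_ip: float, d_in: float, eps: float) -> tuple[float, set[str]]:
    flags: set[str] = set()
    if d_in < eps:
        flags.add(LOW_INPUT)
    if d_ip == 0:
        flags.add(ZERO_IP)
    return (d_ip + eps) / (d_in + eps), flags


def _pom_from_depths(d_ip: float, m_gene: float, eps: float) -> tuple[float, set[str]]:
    flags: set[str] = set()
    if m_gene < eps:
        flags.add(LOW_GENE)
    if d_ip == 0:
        flags.add(ZERO_IP)
    return (d_ip + eps) / (m_gene + eps), flags


def poi(
    site: Site,
    gene: GeneModel,
    ip: CoverageTrack,
    input_: CoverageTrack,
    eps: float = DEFAULT_EPS,
) -> tuple[float, set[str]]:
    """Peak-over-input score for one site in one matched IP/input pair."""
    pos = project_to_exons(site, gene)
    d_ip = normalized_mean_depth(ip, site.chrom, pos, gene.strand)
    d_in = normalized_mean_depth(input_, site.chrom, pos, gene.strand)
    return _poi_from_depths(d_ip, d_in, eps)


def pom(
    site: Site,
    gene: GeneModel,
    ip: CoverageTrack,
    eps: float = DEFAULT_EPS,
    denominator_track: CoverageTrack | None = None,
) -> tuple[float, set[str]]:
    """Peak-over-median score: peak IP depth over the host gene's median depth.

    The gene median is taken on the IP track by default; pass
    ``denominator_track`` to use a different track (e.g. the input fraction).
    """
    pos = project_to_exons(site, gene)
    d_ip = normalized_mean_depth(ip, site.chrom, pos, gene.strand)
    m_gene = gene_median_depth(denominator_track or ip, gene)
    return _pom_from_depths(d_ip, m_gene, eps)


def score_all(
    sites: Sequence[Site],
    genes: Sequence[GeneModel],
    tracks: Mapping[str, CoverageTrack],
    design: SampleDesign,
    eps: float = DEFAULT_EPS,
    pom_denominator: str = "ip",
) -> pd.DataFrame:
    """Score every site in every replicate of every condition.

    Returns a table with one row per (site, condition, replicate), complete
    over the design and deterministically sorted. ``qc_flags`` is a
    comma-joined sorted string (empty when clean).
    """
    if pom_denominator not in ("ip", "input"):
        raise ValidationError(
            f"pom_denominator must be 'ip' or 'input', got {pom_denominator!r}"
        )
    missing = [s for s in design.sample_ids if s not in tracks]
    if missing:
        raise ValidationError(f"no coverage track for designed samples: {missing}")

    gene_by_id = {g.gene_id: g for g in genes}
    sites_by_gene: dict[str, list[Site]] = {}
    for site in sites:
        if site.gene_id is None or site.gene_id not in gene_by_id:
            raise ValidationError(
                f"site {site.site_id!r} is not assigned to a loaded gene "
                f"(gene_id={site.gene_id!r})"
            )
        sites_by_gene.setdefault(site.gene_id, []).append(site)

    pairs = design.pairs()
    rows = []
    for gene_id in sorted(sites_by_gene):
        gene = gene_by_id[gene_id]
        pos = gene.exonic_positions()
        gene_sites = sorted(sites_by_gene[gene_id], key=lambda s: s.site_id)
        # per-site slices into the sorted exonic position vector
        slices = []
        for site in gene_sites:
            lo = int(np.searchsorted(pos, site.start, side="left"))
            hi = int(np.searchsorted(pos, site.end, side="left"))
            if lo == hi:
                raise ValidationError(
                    f"site {site.site_id!r} has no exonic overlap with gene {gene_id!r}"
                )
            slices.append((lo, hi))
        for cond, rep, ip_id, in_id in pairs:
            ip_t, in_t = tracks[ip_id], tracks[in_id]
            ip_vec = ip_t.depth(gene.chrom, pos, gene.strand) * ip_t.norm_factor
            in_vec = in_t.depth(gene.chrom, pos, gene.strand) * in_t.norm_factor
            if ip_t.lib_total <= 0 or in_t.lib_total <= 0:
                log.warning("empty library among (%s, %s)", ip_id, in_id)
            med_vec = ip_vec if pom_denominator == "ip" else in_vec
            m_gene = float(np.median(med_vec))
            for site, (lo, hi) in zip(gene_sites, slices):
                d_ip = float(ip_vec[lo:hi].mean())
                d_in = float(in_vec[lo:hi].mean())
                poi_val, poi_flags = _poi_from_depths(d_ip, d_in, eps)
                pom_val, pom_flags = _pom_from_depths(d_ip, m_gene, eps)
                rows.append(
                    (
                        site.site_id,
                        gene_id,
                        cond,
                        rep,
                        poi_val,
                        pom_val,
                        ",".join(sorted(poi_flags | pom_flags)),
                    )
                )
    table = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    table = table.sort_values(["site_id", "condition", "replicate"]).reset_index(drop=True)
    table.attrs["eps"] = eps
    table.attrs["pom_denominator"] = pom_denominator
    return table


def write_scores(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scores(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    table["replicate"] = table["replicate"].astype(int)
    table["poi"] = table["poi"].astype(float)
    table["pom"] = table["pom"].astype(float)
    return table
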