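"""Bench-assay quantifications: qPCR ddCt, isoform ratios, RIP enrichment,
and imaging-based GFP-high classification.

All qPCR arithmetic assumes a per-cycle amplification efficiency of 2
(perfect doubling) unless overridden, so a Ct difference of d corresponds to
a 2**d fold difference in template.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import ValidationError

DEFAULT_EFFICIENCY = 2.0
GFP_HIGH_THRESHOLD = 26.0  # arbitrary units above background


def _check_ct(ct: float, what: str) -> float:
    ct = float(ct)
    if not math.isfinite(ct) or ct <= 0:
        raise ValidationError(f"{what}: Ct must be finite and positive, got {ct}")
    return ct


def relative_expression(
    ct_target: float, ct_reference: float, efficiency: float = DEFAULT_EFFICIENCY
) -> float:
    """Expression of a target relative to a reference gene: eff**(ct_ref - ct_target)."""
    ct_t = _check_ct(ct_target, "target")
    ct_r = _check_ct(ct_reference, "reference")
    return float(efficiency ** (ct_r - ct_t))


def relative_expression_table(
    ct_table: pd.DataFrame,
    reference: str,
    efficiency: float = DEFAULT_EFFICIENCY,
) -> pd.DataFrame:
    """Per-sample, per-target relative expression from a Ct table.

    ``ct_table`` needs columns sample_id, target, primer_pair, ct. The
    reference Ct per sample is the mean over the reference gene's primer
    pairs; each target primer pair yields one relative-expression value and
    primer pairs are averaged on the linear scale.
    """
    required = {"sample_id", "target", "primer_pair", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValidationError(f"Ct table missing columns: {sorted(missing)}")
    ct_table = ct_table.copy()
    ct_table["ct"].map(lambda v: _check_ct(v, "ct"))
    rows = []
    for sample_id, sub in ct_table.groupby("sample_id", sort=True):
        ref_rows = sub[sub["target"] == reference]
        if ref_rows.empty:
            raise ValidationError(
                f"sample {sample_id!r}: no Ct rows for reference gene {reference!r}"
            )
        ct_ref = float(ref_rows["ct"].mean())
        for target, tsub in sub[sub["target"] != reference].groupby("target", sort=True):
            per_pair = [
                relative_expression(ct, ct_ref, efficiency) for ct in tsub["ct"]
            ]
            rows.append((sample_id, target, float(np.mean(per_pair)), len(per_pair)))
    return pd.DataFrame(
        rows, columns=["sample_id", "target", "relative_expression", "n_primer_pairs"]
    )


def isoform_ratio(rel_sigm: float, rel_migm: float) -> float:
    """Secreted-over-membrane IgM isoform ratio from relative expressions."""
    if rel_migm == 0:
        raise ValidationError("isoform_ratio: membrane-isoform expression is zero")
    if rel_sigm < 0 or rel_migm < 0:
        raise ValidationError("isoform_ratio: relative expressions must be positive")
    return float(rel_sigm) / float(rel_migm)


def rip_fold_enrichment(
    ct_table: pd.DataFrame,
    target: str,
    reference: str = "Gapdh",
    efficiency: float = DEFAULT_EFFICIENCY,
) -> float:
    """RIP-qPCR fold enrichment, normalized to an unmethylated reference RNA
    and an isotype-control antibody.

    For each (gene, antibody) cell, pull-down recovery is
    E = eff**(ct_INPUT - ct_IP); the result is
    [E(target, HA) / E(reference, HA)] / [E(target, ISOTYPE) / E(reference, ISOTYPE)].
    ``ct_table`` needs columns target, fraction (IP/INPUT), antibody
    (HA/ISOTYPE), ct; replicate rows for a cell are averaged on the Ct scale.
    """
    required = {"target", "fraction", "antibody", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValidationError(f"Ct table missing columns: {sorted(missing)}")
    t = ct_table.copy()
    t["fraction"] = t["fraction"].astype(str).str.upper()
    t["antibody"] = t["antibody"].astype(str).str.upper()

    def cell(gene: str, fraction: str, antibody: str) -> float:
        sub = t[
            (t["target"] == gene) & (t["fraction"] == fraction) & (t["antibody"] == antibody)
        ]
        if sub.empty:
            raise ValidationError(
                f"rip_fold_enrichment: missing Ct for ({gene}, {fraction}, {antibody})"
            )
        return _check_ct(float(sub["ct"].mean()), f"({gene}, {fraction}, {antibody})")

    def recovery(gene: str, antibody: str) -> float:
        return float(efficiency ** (cell(gene, "INPUT", antibody) - cell(gene, "IP", antibody)))

    return (recovery(target, "HA") / recovery(reference, "HA")) / (
        recovery(target, "ISOTYPE") / recovery(reference, "ISOTYPE")
    )


def classify_gfp_high(
    intensities: Sequence[float] | pd.DataFrame,
    threshold: float = GFP_HIGH_THRESHOLD,
) -> tuple[float, np.ndarray]:
    """Label cells GFP-high by mean fluorescence strictly above ``threshold``.

    The default threshold of 26 arbitrary units is the background cutoff used
    for YTHDF2-GFP imaging (low-cell median 2 a.u.). Accepts a sequence of
    mean intensities or a table with a ``mean_gfp`` column; returns the
    high fraction and the per-cell boolean labels.
    """
    if isinstance(intensities, pd.DataFrame):
        if "mean_gfp" not in intensities.columns:
            raise ValidationError("cell table must have a 'mean_gfp' column")
        values = intensities["mean_gfp"].to_numpy(dtype=float)
    else:
        values = np.asarray(list(intensities), dtype=float)
    if values.size == 0:
        raise ValidationError("classify_gfp_high: need at least one cell")
    if np.any(values < 0):
        raise ValidationError("classify_gfp_high: negative intensity")
    labels = values > threshold
    return float(labels.mean()), labels
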