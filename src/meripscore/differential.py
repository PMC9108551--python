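"""Differential methylation calling: the METTL3-specificity decision rule.

A candidate site is called methylation-machinery-specific when (i) the mean
POI and the mean POM across replicates are both strictly higher in the
reference (wild-type) condition than in the perturbed (methyltransferase-
deleted) condition, and (ii) at least one of the two Welch t-tests comparing
the replicate-level scores between conditions is significant at ``alpha``
(default 0.05, two-sided). Scores are log2-transformed before testing by
default, since POI and POM are fold-change ratios.

The caller is exposed statsmodels-style: build a :class:`DifferentialMethylation`
model from a replicate-level score table, call :meth:`~DifferentialMethylation.fit`,
and inspect the returned :class:`DifferentialMethylationResults`.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import Site, ValidationError

DEFAULT_ALPHA = 0.05

CALL_COLUMNS = [
    "site_id",
    "gene_id",
    "mean_log2_poi_ref",
    "mean_log2_poi_pert",
    "mean_log2_pom_ref",
    "mean_log2_pom_pert",
    "p_poi",
    "p_pom",
    "specific",
]


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance two-sided t-test.

    Returns ``(t, p)`` with Welch-Satterthwaite degrees of freedom. Both
    groups constant and equal returns ``(0, 1)``; both constant but unequal
    returns ``(±inf, 0)``. Requires at least two observations per group.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValidationError(
            "welch_t requires >= 2 replicates per group "
            f"(got {nx} and {ny})"
        )
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if mx == my:
            return 0.0, 1.0
        return math.copysign(math.inf, mx - my), 0.0
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), min(p, 1.0)


def _site_ids(sites: Iterable) -> list[str]:
    out = []
    for s in sites:
        out.append(s.site_id if isinstance(s, Site) else str(s))
    return out


class DifferentialMethylation:
    """Two-condition differential methylation model over a score table.

    Parameters
    ----------
    scores
        Replicate-level score table with columns ``site_id``, ``condition``,
        ``replicate``, ``poi``, ``pom`` (``gene_id`` carried through if
        present), e.g. the output of :func:`meripscore.scoring.score_all`.
    ref, perturbed
        Condition labels for the wild-type-like and machinery-depleted arms.
    log_scores
        Test and compare group means on the log2 scale (default). With
        ``False``, raw scores are used and the mean columns are named
        ``mean_poi_*`` / ``mean_pom_*``.
    """

    def __init__(
        self,
        scores: pd.DataFrame,
        ref: str = "REF",
        perturbed: str = "PERTURBED",
        log_scores: bool = True,
    ):
        required = {"site_id", "condition", "replicate", "poi", "pom"}
        missing = required - set(scores.columns)
        if missing:
            raise ValidationError(f"score table missing columns: {sorted(missing)}")
        present = set(scores["condition"].unique())
        absent = {ref, perturbed} - present
        if absent:
            raise ValidationError(
                f"score table lacks condition(s) {sorted(absent)}; "
                f"present: {sorted(present)} — differential calling needs both arms"
            )
        for cond in (ref, perturbed):
            n = scores.loc[scores["condition"] == cond, "replicate"].nunique()
            if n < 2:
                raise ValidationError(
                    f"condition {cond!r} has {n} replicate(s); >= 2 required"
                )
        counts = (
            scores[scores["condition"].isin([ref, perturbed])]
            .groupby(["site_id", "condition"])["replicate"]
            .nunique()
        )
        if counts.groupby("site_id").size().ne(2).any() or counts.groupby(
            "condition"
        ).nunique().ne(1).any():
            raise ValidationError(
                "score table is not complete over the design: every site needs "
                "scores for every replicate of both conditions"
            )
        self.scores = scores
        self.ref = ref
        self.perturbed = perturbed
        self.log_scores = log_scores

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "DifferentialMethylation":
        from .scoring import read_scores

        return cls(read_scores(path), **kwargs)

    def fit(self, alpha: float = DEFAULT_ALPHA, bh: bool = False
            ) -> "DifferentialMethylationResults":
        """Run both Welch t-tests per site and apply the specificity rule."""
        if not (0.0 < alpha < 1.0):
            raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
        tf = (lambda v: np.log2(v)) if self.log_scores else (lambda v: np.asarray(v, float))
        sub = self.scores[self.scores["condition"].isin([self.ref, self.perturbed])]
        sub = sub.sort_values(["site_id", "condition", "replicate"])
        has_gene = "gene_id" in sub.columns
        rows = []
        for site_id, grp in sub.groupby("site_id", sort=True):
            r = grp[grp["condition"] == self.ref]
            p = grp[grp["condition"] == self.perturbed]
            poi_r, poi_p = tf(r["poi"].to_numpy()), tf(p["poi"].to_numpy())
            pom_r, pom_p = tf(r["pom"].to_numpy()), tf(p["pom"].to_numpy())
            _, p_poi = welch_t(poi_r, poi_p)
            _, p_pom = welch_t(pom_r, pom_p)
            m_poi_r, m_poi_p = float(poi_r.mean()), float(poi_p.mean())
            m_pom_r, m_pom_p = float(pom_r.mean()), float(pom_p.mean())
            specific = (
                (m_poi_r > m_poi_p)
                and (m_pom_r > m_pom_p)
                and (p_poi < alpha or p_pom < alpha)
            )
            rows.append(
                (
                    site_id,
                    r["gene_id"].iloc[0] if has_gene else "",
                    m_poi_r,
                    m_poi_p,
                    m_pom_r,
                    m_pom_p,
                    p_poi,
                    p_pom,
                    specific,
                )
            )
        cols = list(CALL_COLUMNS)
        if not self.log_scores:
            cols = [c.replace("_log2_", "_") for c in cols]
        calls = pd.DataFrame(rows, columns=cols)
        if bh:
            calls["q_poi"] = stats.false_discovery_control(calls["p_poi"])
            calls["q_pom"] = stats.false_discovery_control(calls["p_pom"])
        calls["alpha"] = alpha
        return DifferentialMethylationResults(self, calls, alpha)


class DifferentialMethylationResults:
    """Fitted per-site calls with diagnostics.

    Attributes
    ----------
    calls : pandas.DataFrame
        One row per site: group means, the two p-values, the ``specific``
        verdict, and the alpha used (q-values when BH mode was requested).
    """

    def __init__(self, model: DifferentialMethylation, calls: pd.DataFrame, alpha: float):
        self.model = model
        self.calls = calls
        self.alpha = alpha

    @property
    def n_sites(self) -> int:
        return len(self.calls)

    @property
    def n_specific(self) -> int:
        return int(self.calls["specific"].sum())

    def to_tsv(self, path) -> None:
        self.calls.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def recovery(self, truth: pd.DataFrame) -> dict[str, float]:
        """Confusion metrics of ``specific`` calls against planted truth.

        ``truth`` needs columns ``site_id`` and ``dependent`` (True for sites
        whose enrichment is reduced in the perturbed arm). Sensitivity is NaN
        when the truth has no dependent sites; FDR is NaN without positives.
        """
        merged = self.calls.merge(truth[["site_id", "dependent"]], on="site_id", how="left")
        if merged["dependent"].isna().any():
            bad = merged.loc[merged["dependent"].isna(), "site_id"].head(5).tolist()
            raise ValidationError(f"truth table missing sites, e.g. {bad}")
        called = merged["specific"].to_numpy(bool)
        dep = merged["dependent"].to_numpy(bool)
        tp = int((called & dep).sum())
        fp = int((called & ~dep).sum())
        fn = int((~called & dep).sum())
        tn = int((~called & ~dep).sum())
        sens = tp / (tp + fn) if (tp + fn) else float("nan")
        fdr = fp / (tp + fp) if (tp + fp) else float("nan")
        fpr = fp / (fp + tn) if (fp + tn) else float("nan")
        return {
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "sensitivity": sens, "fdr": fdr, "fpr": fpr,
        }

    def summary(self) -> str:
        m = self.model
        scale = "log2" if m.log_scores else "raw"
        lines = [
            "Differential methylation calling (two Welch t-tests + mean ordering)",
            "=" * 68,
            f"conditions:        {m.ref} (reference) vs {m.perturbed} (perturbed)",
            f"score scale:       {scale}",
            f"alpha:             {self.alpha:g} (two-sided, per test, uncorrected)",
            f"sites tested:      {self.n_sites}",
            f"sites specific:    {self.n_specific} "
            f"({100.0 * self.n_specific / max(self.n_sites, 1):.1f}%)",
            f"median p (POI):    {self.calls['p_poi'].median():.3g}",
            f"median p (POM):    {self.calls['p_pom'].median():.3g}",
        ]
        return "\n".join(lines)

    def plot_scores(self, ax=None):
        """Histogram of per-site mean score differences (ref - perturbed)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        prefix = "mean_log2" if self.model.log_scores else "mean"
        diff_poi = self.calls[f"{prefix}_poi_ref"] - self.calls[f"{prefix}_poi_pert"]
        diff_pom = self.calls[f"{prefix}_pom_ref"] - self.calls[f"{prefix}_pom_pert"]
        ax.hist(diff_poi, bins=50, alpha=0.6, label="POI")
        ax.hist(diff_pom, bins=50, alpha=0.6, label="POM")
        ax.set_xlabel(f"{prefix} score difference (ref - perturbed)")
        ax.set_ylabel("sites")
        ax.legend()
        return ax


def call_sites(
    scores: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    ref: str = "REF",
    perturbed: str = "PERTURBED",
    log_scores: bool = True,
    bh: bool = False,
) -> pd.DataFrame:
    """One-shot functional interface: fit the model and return the call table."""
    model = DifferentialMethylation(scores, ref=ref, perturbed=perturbed, log_scores=log_scores)
    return model.fit(alpha=alpha, bh=bh).calls


def panel_summary(
    scores: pd.DataFrame,
    panel: Iterable,
    control: Iterable,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Global methylation summary over a site panel versus control sites.

    For each condition (optionally each replicate), reports the median POI and
    POM over the m6A-site panel and over the control set, plus a two-sided
    Mann-Whitney p-value comparing the panel and control POI distributions.
    Panel/control entries may be Site objects or site-id strings.
    """
    panel_ids = set(_site_ids(panel))
    control_ids = set(_site_ids(control))
    if not panel_ids or not control_ids:
        raise ValidationError("panel and control site sets must be non-empty")
    have = set(scores["site_id"].unique())
    missing = sorted((panel_ids | control_ids) - have)
    if missing:
        raise ValidationError(
            f"scores missing for {len(missing)} panel/control sites, e.g. {missing[:5]}"
        )
    keys = ["condition", "replicate"] if per_replicate else ["condition"]
    rows = []
    for key_vals, grp in scores.groupby(keys, sort=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        pg = grp[grp["site_id"].isin(panel_ids)]
        cg = grp[grp["site_id"].isin(control_ids)]
        p_poi_vals = pg["poi"].to_numpy(float)
        c_poi_vals = cg["poi"].to_numpy(float)
        pooled = np.concatenate([p_poi_vals, c_poi_vals])
        if np.all(pooled == pooled[0]):
            p_val = 1.0
        else:
            p_val = float(
                stats.mannwhitneyu(p_poi_vals, c_poi_vals, alternative="two-sided").pvalue
            )
        rows.append(
            (*key_vals,
             float(np.median(p_poi_vals)), float(np.median(pg["pom"])),
             float(np.median(c_poi_vals)), float(np.median(cg["pom"])),
             p_val)
        )
    cols = keys + [
        "panel_median_poi", "panel_median_pom",
        "control_median_poi", "control_median_pom",
        "panel_vs_control_p",
    ]
    return pd.DataFrame(rows, columns=cols)
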