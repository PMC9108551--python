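"""End-to-end orchestration: score -> call -> summarize, with a manifest.

All outputs are written atomically (temp file + rename) and a JSON manifest
records the configuration hash, seed, input checksums and package version, so
a rerun with identical inputs is byte-identical and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .differential import DifferentialMethylation, panel_summary
from .genome_io import (
    SampleDesign,
    ValidationError,
    read_bedgraph,
    read_gene_models,
    read_sites,
)
from .scoring import score_all


@dataclass
class RunConfig:
    """Paths and analysis keys for a score-and-call run."""

    genes: str
    sites: str
    design: str
    tracks_dir: str
    out_dir: str
    panel: str | None = None
    control: str | None = None
    eps: float = 0.5
    pom_denominator: str = "ip"
    alpha: float = 0.05
    log_scores: bool = True
    bh: bool = False
    ref: str = "REF"
    perturbed: str = "PERTURBED"
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_df(df: pd.DataFrame, path: Path) -> None:
    atomic_write_text(path, df.to_csv(sep="\t", index=False, float_format="%.10g"))


def run_score_and_call(cfg: RunConfig) -> dict[str, Path]:
    """Read inputs, score all sites, call differential sites, summarize panels.

    Returns the mapping of output names to paths (scores.tsv, calls.tsv,
    optional panel.tsv, manifest.json). Any stage error is re-raised with the
    stage name and offending file.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, Path] = {
        "genes": Path(cfg.genes),
        "sites": Path(cfg.sites),
        "design": Path(cfg.design),
    }
    if cfg.panel:
        inputs["panel"] = Path(cfg.panel)
    if cfg.control:
        inputs["control"] = Path(cfg.control)
    for name, path in inputs.items():
        if not path.exists():
            raise ValidationError(f"[stage read] missing {name} file: {path}")

    def stage(name: str, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    genes = stage("read_genes", read_gene_models, inputs["genes"])
    sites = stage("read_sites", read_sites, inputs["sites"], genes)
    design = stage("read_design", SampleDesign.read, inputs["design"])

    tracks = {}
    tracks_dir = Path(cfg.tracks_dir)
    for sid in design.sample_ids:
        p = tracks_dir / f"{sid}.bedgraph"
        if not p.exists():
            raise ValidationError(f"[stage read_tracks] missing coverage track: {p}")
        tracks[sid] = stage("read_tracks", read_bedgraph, p, genes, sid)
        inputs[f"track:{sid}"] = p

    scores = stage(
        "score", score_all, sites, genes, tracks, design,
        eps=cfg.eps, pom_denominator=cfg.pom_denominator,
    )
    model = stage(
        "call", DifferentialMethylation, scores,
        ref=cfg.ref, perturbed=cfg.perturbed, log_scores=cfg.log_scores,
    )
    results = stage("call", model.fit, alpha=cfg.alpha, bh=cfg.bh)

    outputs: dict[str, Path] = {}
    outputs["scores"] = out_dir / "scores.tsv"
    _atomic_df(scores, outputs["scores"])
    outputs["calls"] = out_dir / "calls.tsv"
    _atomic_df(results.calls, outputs["calls"])

    if cfg.panel and cfg.control:
        panel_ids = [s.site_id for s in stage("panel", read_sites, inputs["panel"], genes)]
        control_ids = [s.site_id for s in stage("panel", read_sites, inputs["control"], genes)]
        summary = stage("panel", panel_summary, scores, panel_ids, control_ids)
        outputs["panel"] = out_dir / "panel.tsv"
        _atomic_df(summary, outputs["panel"])

    # analysis keys only: file identity is captured by the input checksums,
    # so reruns from a different directory stay byte-identical
    path_keys = {"genes", "sites", "design", "tracks_dir", "out_dir", "panel", "control"}
    config_dict = {k: v for k, v in cfg.to_dict().items() if k not in path_keys}
    manifest = {
        "tool": "meripscore",
        "version": __version__,
        "seed": cfg.seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {name: _sha256(p) for name, p in sorted(inputs.items())},
        "outputs": {name: _sha256(p) for name, p in sorted(outputs.items())},
        "n_sites": int(results.n_sites),
        "n_specific": int(results.n_specific),
    }
    outputs["manifest"] = out_dir / "manifest.json"
    atomic_write_text(outputs["manifest"], json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outputs


def run_recovery_benchmark(calls: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Confusion counts and derived metrics of ``specific`` calls vs truth.

    ``truth`` needs site_id plus either a boolean ``dependent`` column or the
    per-condition enrichment columns from the simulator's truth table.
    Undefined ratios (no dependent sites, no positive calls) are NaN.
    """
    if "dependent" not in truth.columns:
        if {"enrichment_ref", "enrichment_pert"} <= set(truth.columns):
            truth = truth.assign(dependent=truth["enrichment_ref"] > truth["enrichment_pert"])
        else:
            raise ValidationError("truth table needs 'dependent' or enrichment columns")
    merged = calls.merge(truth[["site_id", "dependent"]], on="site_id", how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        bad = merged.loc[merged["_merge"] != "both", "site_id"].head(5).tolist()
        raise ValidationError(f"calls and truth site ids do not match, e.g. {bad}")
    called = merged["specific"].astype(bool).to_numpy()
    dep = merged["dependent"].astype(bool).to_numpy()
    tp = int((called & dep).sum())
    fp = int((called & ~dep).sum())
    fn = int((~called & dep).sum())
    tn = int((~called & ~dep).sum())
    metrics = {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "fdr": fp / (tp + fp) if (tp + fp) else float("nan"),
        "fpr": fp / (fp + tn) if (fp + tn) else float("nan"),
    }
    return pd.DataFrame([metrics])
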