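"""One-shot orchestration of the network stage.

Reads the network and the two seed lists, expands each seed set by
random walk with restart, cuts at the running-sum peak, intersects the
expansions and scores every network gene for key-driver enrichment.
All outputs are TSV/plain text plus a YAML run manifest that suffices to
rerun the pipeline identically.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import __version__
from .expansion import ExpansionResult, common_genes, expand_seed_set
from .keydriver import identify_key_drivers
from .network import read_edge_list

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "read_seed_list", "run_full_pipeline"]


@dataclass
class PipelineConfig:
    network: str
    seeds_a: str
    seeds_b: str
    out_dir: str
    score_threshold: float = 0.9
    score_scale: str = "unit"
    strip_taxon_prefix: bool = False
    restart: float = 0.7
    tol: float = 1e-6
    max_iter: int = 10000
    positives_mode: str = "cross"
    include_seeds: bool = True
    driver_alpha: float = 1e-8
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must be in [0, 1]")
        if not 0.0 < self.restart <= 1.0:
            raise ValueError("restart must be in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.positives_mode not in ("cross", "self"):
            raise ValueError("positives_mode must be 'cross' or 'self'")
        if not 0.0 < self.driver_alpha <= 1.0:
            raise ValueError("driver_alpha must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def read_seed_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    seeds = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip()
            if sym:
                seeds.append(sym)
    if not seeds:
        raise ValueError(f"seed list {path} contains no symbols")
    return seeds


def _write_curve(res: ExpansionResult, path: Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("rank\tsymbol\tis_positive\tincrement\tcumulative\n")
        c = res.curve
        for i, sym in enumerate(c.symbols):
            fh.write(
                f"{i + 1}\t{sym}\t{int(c.is_positive[i])}\t"
                f"{c.increments[i]:.6f}\t{c.cumulative[i]:.6f}\n"
            )


def run_full_pipeline(cfg: PipelineConfig) -> dict:
    """Execute read -> expand(A) -> expand(B) -> overlap -> key drivers.

    Writes the two expansion curves and predicted lists, the common-gene
    list, the full driver table and a run manifest into ``cfg.out_dir``;
    returns the manifest as a dict.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    net = read_edge_list(
        cfg.network,
        score_threshold=cfg.score_threshold,
        score_scale=cfg.score_scale,
        strip_taxon_prefix=cfg.strip_taxon_prefix,
    )
    seeds_a = read_seed_list(cfg.seeds_a)
    seeds_b = read_seed_list(cfg.seeds_b)
    logger.info("network: %d genes, %d edges; %d/%d seed symbols read",
                net.n, net.graph.number_of_edges(), len(seeds_a), len(seeds_b))

    res_a = expand_seed_set(net, seeds_a, seeds_b, restart=cfg.restart,
                            tol=cfg.tol, max_iter=cfg.max_iter,
                            positives_mode=cfg.positives_mode)
    res_b = expand_seed_set(net, seeds_b, seeds_a, restart=cfg.restart,
                            tol=cfg.tol, max_iter=cfg.max_iter,
                            positives_mode=cfg.positives_mode)
    logger.info("expansion A: %d seeds -> %d predicted (cutoff rank %d)",
                len(res_a.seeds), len(res_a.predicted), res_a.cutoff_rank)
    logger.info("expansion B: %d seeds -> %d predicted (cutoff rank %d)",
                len(res_b.seeds), len(res_b.predicted), res_b.cutoff_rank)

    common = common_genes(res_a, res_b, include_seeds=cfg.include_seeds)
    logger.info("common genes: %d", len(common))
    records = identify_key_drivers(net, common, driver_alpha=cfg.driver_alpha)
    n_drivers = sum(r.is_driver for r in records)
    logger.info("key drivers at FDR < %g: %d", cfg.driver_alpha, n_drivers)

    files = {
        "curve_a": "expansion_a.curve.tsv",
        "predicted_a": "expansion_a.predicted.txt",
        "curve_b": "expansion_b.curve.tsv",
        "predicted_b": "expansion_b.predicted.txt",
        "common": "common_genes.txt",
        "drivers": "key_drivers.tsv",
    }
    _write_curve(res_a, out / files["curve_a"])
    _write_curve(res_b, out / files["curve_b"])
    (out / files["predicted_a"]).write_text(
        "".join(f"{g}\n" for g in res_a.predicted), encoding="utf-8")
    (out / files["predicted_b"]).write_text(
        "".join(f"{g}\n" for g in res_b.predicted), encoding="utf-8")
    (out / files["common"]).write_text(
        "".join(f"{g}\n" for g in sorted(common)), encoding="utf-8")
    with open(out / files["drivers"], "wt", encoding="utf-8") as fh:
        fh.write("gene\tn_neighbors\tm_common\tp_raw\tp_fdr\tis_driver\n")
        for r in records:
            fh.write(f"{r.gene}\t{r.n_neighbors}\t{r.m_common}\t"
                     f"{r.p_raw:.6e}\t{r.p_fdr:.6e}\t{int(r.is_driver)}\n")

    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "files": files,
        "counts": {
            "network_genes": net.n,
            "network_edges": net.graph.number_of_edges(),
            "mapped_seeds_a": len(res_a.seeds),
            "mapped_seeds_b": len(res_b.seeds),
            "predicted_a": len(res_a.predicted),
            "predicted_b": len(res_b.predicted),
            "common": len(common),
            "drivers": n_drivers,
        },
    }
    with open(out / "manifest.yaml", "wt", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
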