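"""End-to-end run configuration and orchestration.

A run is described by a :class:`RunConfig` (YAML-serializable; every
screening parameter, input path and the seed). ``run_pipeline`` executes
discretize -> screen -> network assembly (+ optional bait extension,
functional enrichment, DE intersection) -> export, stamping every output
bundle with a digest of the configuration so results are traceable to
their exact parameters. Identical config + seed gives byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .coexpression import ScreenParams, screen_baits
from .discretize import DiscretizationParams, discretize_matrix, write_discretized_matrix
from .enrichment import fisher_enrichment
from .io import (
    ValidationError,
    read_annotations,
    read_bait_set,
    read_bin_map,
    read_de_list,
    read_expression_matrix,
)
from .network import build_network, export_network, extend_network, family_distribution, intersect_with_de

logger = logging.getLogger("qcoexp")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a screen."""

    matrix: str = ""
    baits: str = ""
    out_prefix: str = "qcoexp_run"
    extension_baits: str | None = None
    annotations: str | None = None
    bins: str | None = None
    de_lists: tuple[str, ...] = ()
    de_bait: str | None = None
    q: float = 0.06
    r: int = 1
    sign_mode: str = "same-sign-only"
    min_bf: int = 0
    alpha: float = 0.01
    n_permutations: int = 1000
    tie_break: str = "randomized"
    consistency: float = 0.95
    fdr_threshold: float = 0.1
    tf_only: bool = False
    missing_token: str = "NA"
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["de_lists"] = list(self.de_lists)
        return d

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "de_lists" in doc:
            doc["de_lists"] = tuple(doc["de_lists"])
        return cls(**doc)

    def discretization_params(self) -> DiscretizationParams:
        return DiscretizationParams(q=self.q, r=self.r)

    def screen_params(self) -> ScreenParams:
        return ScreenParams(
            sign_mode=self.sign_mode,  # type: ignore[arg-type]
            min_bf=self.min_bf,
            alpha=self.alpha,
            n_permutations=self.n_permutations,
            rng_seed=self.seed,
            tie_break=self.tie_break,  # type: ignore[arg-type]
            consistency=self.consistency,
        )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full screen; returns a summary dict (also written as JSON).

    Outputs (under ``<out_prefix>.*``): the discretized matrix, the called
    edge table, SIF + attribute exports, the family distribution, optional
    enrichment and DE-intersection tables, and ``summary.json`` carrying
    the config digest.
    """
    for fld in ("matrix", "baits"):
        if not getattr(config, fld):
            raise PipelineError(f"stage 'configure' failed: config field {fld!r} is required")
    out_prefix = Path(config.out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    matrix = _stage("read-matrix")(read_expression_matrix)(config.matrix, config.missing_token)
    baits = _stage("read-baits")(read_bait_set)(config.baits, "baits")
    annotations = (
        _stage("read-annotations")(read_annotations)(config.annotations)
        if config.annotations
        else {}
    )

    dparams = config.discretization_params()
    d = _stage("discretize")(discretize_matrix)(matrix, dparams)
    disc_path = out_prefix.with_suffix(".levels.tsv")
    write_discretized_matrix(d, disc_path)

    sparams = config.screen_params()
    edges = _stage("screen")(screen_baits)(d, baits, sparams)

    provenance = {
        "qcoexp_version": __version__,
        "config_digest": config.digest(),
        "q": config.q,
        "r": config.r,
        "min_bf": config.min_bf,
        "alpha": config.alpha,
        "n_permutations": config.n_permutations,
        "sign_mode": config.sign_mode,
        "tie_break": config.tie_break,
        "seed": config.seed,
        "matrix": str(config.matrix),
        "baits": str(config.baits),
    }
    net = _stage("network")(build_network)(edges, annotations, config.tf_only, provenance)

    if config.extension_baits:
        ext = _stage("read-extension-baits")(read_bait_set)(config.extension_baits, "extension")
        net = _stage("extend")(extend_network)(net, ext, d, sparams, annotations, config.tf_only)

    written: list[str] = [str(disc_path)]
    if net.n_edges() > 0:
        for fmt in ("edge-tsv", "sif"):
            paths = _stage("export")(export_network)(net, fmt, out_prefix)
            written += [str(p) for p in paths]
    else:
        logger.warning("no edge called; skipping network export")

    summary: dict = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "n_genes": matrix.n_genes,
        "n_conditions": matrix.n_conditions,
        "n_baits_found": len([b for b in baits if b in matrix.values.index]),
        "n_edges": net.n_edges(),
        "n_nodes": net.n_nodes(),
        "family_distribution": family_distribution(net),
    }

    if config.bins and net.n_edges() > 0:
        bins = _stage("read-bins")(read_bin_map)(config.bins)
        partner_set = {n for n in net.graph.nodes if n not in net.baits}
        background = set(matrix.gene_ids)
        results = _stage("enrich")(fisher_enrichment)(
            partner_set & background, background, bins, config.fdr_threshold
        )
        enr_path = out_prefix.with_suffix(".enrichment.tsv")
        with open(enr_path, "w") as fh:
            fh.write("bin\tk\tK\tn\tN\todds_ratio\tp\tq\tsignificant\n")
            for res in results:
                fh.write(
                    f"{res.bin_label}\t{res.k}\t{res.K}\t{res.n}\t{res.N}\t"
                    f"{res.odds_ratio:.6g}\t{res.p:.6g}\t{res.q:.6g}\t{int(res.significant)}\n"
                )
        written.append(str(enr_path))
        summary["n_bins_tested"] = len(results)
        summary["n_bins_significant"] = sum(r.significant for r in results)

    if config.de_lists:
        if not config.de_bait:
            raise PipelineError("stage 'de-intersect' failed: de_bait is required with de_lists")
        de = [_stage("read-de")(read_de_list)(p) for p in config.de_lists]
        genes, report = _stage("de-intersect")(intersect_with_de)(net, config.de_bait, de)
        de_path = out_prefix.with_suffix(".de_intersection.tsv")
        report.to_csv(de_path, sep="\t")
        written.append(str(de_path))
        summary["n_de_intersection"] = len(genes)

    summary["outputs"] = written
    summary_path = out_prefix.with_suffix(".summary.json")
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
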