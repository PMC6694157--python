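"""End-to-end orchestration with resumable stage artifacts.

Stage order: read + intersect cohort -> per-phenotype feature blocks ->
weighted networks -> pathway extension -> DE + ORA + GSEA on the extended
gene lists.  Every stage writes its artifact under the run directory with a
fixed name; ``manifest.json`` records a content hash per artifact so a
rerun with identical config and inputs can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import enrichment, features, io, kwalks, scca
from .errors import ConfigError

log = logging.getLogger(__name__)

ARTIFACTS = (
    "networks/case.tsv",
    "networks/control.tsv",
    "extended.gmt",
    "extension_report.tsv",
    "de.tsv",
    "ora.tsv",
    "gsea.tsv",
)


@dataclass
class PipelineConfig:
    expression: str
    methylation: str
    probe_map: str
    phenotypes: str
    edges: str
    pathways: str
    outdir: str
    transform: str = "none"  # or log2_plus1
    variance_target: float = features.DEFAULT_VARIANCE_TARGET
    c1: float = scca.DEFAULT_C1
    c2: float = scca.DEFAULT_C2
    scca_tol: float = scca.DEFAULT_TOL
    scca_max_iter: int = scca.DEFAULT_MAX_ITER
    L: int = kwalks.DEFAULT_WALK_LIMIT
    selection: dict = field(default_factory=dict)  # SelectionRule overrides
    de_alpha: float = enrichment.DEFAULT_DE_ALPHA
    n_perm: int = enrichment.DEFAULT_N_PERM
    weight_exponent: float = enrichment.DEFAULT_WEIGHT_EXPONENT
    seed: int = 0
    max_missing_fraction: float = 0.2

    def validate(self, check_paths: bool = True) -> None:
        for par in ("c1", "c2"):
            v = getattr(self, par)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{par}={v} outside (0, 1)")
        if not (0.0 < self.variance_target <= 1.0):
            raise ConfigError(f"variance_target={self.variance_target} outside (0, 1]")
        if self.L < 1:
            raise ConfigError(f"L={self.L} must be >= 1")
        if self.n_perm < 1:
            raise ConfigError(f"n_perm={self.n_perm} must be >= 1")
        if self.transform not in ("none", "log2_plus1"):
            raise ConfigError(f"unknown transform {self.transform!r}")
        self.selection_rule()  # raises on bad rule fields
        if check_paths:
            for par in ("expression", "methylation", "probe_map", "phenotypes", "edges", "pathways"):
                path = Path(getattr(self, par))
                if not path.exists():
                    raise ConfigError(f"{par} file not found: {path}")

    def selection_rule(self) -> kwalks.SelectionRule:
        try:
            return kwalks.SelectionRule(**self.selection)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad selection rule: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_cohort(config: PipelineConfig):
    expr = io.read_expression(config.expression, transform=config.transform)
    meth = io.read_methylation(config.methylation)
    labels = io.read_phenotypes(config.phenotypes)
    expr, meth, labels = io.intersect_cohort(expr, meth, labels)
    meth = io.impute_missing(meth, labels, config.max_missing_fraction)
    log.info("cohort: %d genes, %d probes, %d samples",
             len(expr.gene_ids), len(meth.probe_ids), len(labels.sample_ids))
    return expr, meth, labels


def stage_networks(config: PipelineConfig) -> dict[str, scca.WeightedNetwork]:
    """Build and write the two phenotype-specific weighted networks."""
    expr, meth, labels = _load_cohort(config)
    pmap = io.read_probe_map(config.probe_map)
    edges = io.read_edges(config.edges)
    outdir = Path(config.outdir) / "networks"
    outdir.mkdir(parents=True, exist_ok=True)
    nets = {}
    for phenotype in io.PHENOTYPES:
        blocks = features.build_feature_blocks(
            expr, meth, pmap, labels.samples_of(phenotype), config.variance_target
        )
        net = scca.build_weighted_network(
            blocks, edges, phenotype,
            c1=config.c1, c2=config.c2, tol=config.scca_tol, max_iter=config.scca_max_iter,
        )
        scca.write_network(net, outdir / f"{phenotype}.tsv")
        log.info("%s network: %d nodes, %d edges", phenotype, len(net.nodes), len(net))
        nets[phenotype] = net
    return nets


def stage_extend(config: PipelineConfig, nets: dict[str, scca.WeightedNetwork] | None = None):
    """Extend every pathway in both networks; write GMT + report."""
    outdir = Path(config.outdir)
    if nets is None:
        nets = {
            ph: scca.read_network(outdir / "networks" / f"{ph}.tsv")
            for ph in io.PHENOTYPES
        }
    collection = io.read_gmt(config.pathways)
    extended = kwalks.extend_collection(
        collection, nets[io.CASE], nets[io.CONTROL],
        L=config.L, rule=config.selection_rule(),
    )
    io.write_gmt(kwalks.extended_collection(extended), outdir / "extended.gmt")
    kwalks.extension_report(extended).to_csv(outdir / "extension_report.tsv", sep="\t", index=False)
    n_skipped = sum(1 for e in extended if len(e.mapped_genes) < 2)
    log.info("extended %d pathways (%d with <2 mapped genes left unextended)",
             len(extended), n_skipped)
    return extended


def stage_enrich(config: PipelineConfig, nets=None):
    """DE calling, then ORA and GSEA over the extended pathway lists."""
    outdir = Path(config.outdir)
    expr, _, labels = _load_cohort(config)
    extended = io.read_gmt(outdir / "extended.gmt")
    if nets is None:
        nets = {
            ph: scca.read_network(outdir / "networks" / f"{ph}.tsv")
            for ph in io.PHENOTYPES
        }
    network_genes = nets[io.CASE].nodes | nets[io.CONTROL].nodes
    background = set(expr.gene_ids) & network_genes

    de = enrichment.call_de(expr, labels, alpha=config.de_alpha)
    de.table.to_csv(outdir / "de.tsv", sep="\t", index_label="gene")
    log.info("DE: %d of %d genes at BH<=%.3g", len(de.de_set), len(expr.gene_ids), config.de_alpha)

    ora = enrichment.run_ora(extended, de, background)
    enrichment.ora_table(ora).to_csv(outdir / "ora.tsv", sep="\t", index=False)

    gsea = enrichment.gsea_significance(
        expr, labels, extended,
        n_perm=config.n_perm, seed=config.seed, weight_exponent=config.weight_exponent,
    )
    enrichment.gsea_table(gsea).to_csv(outdir / "gsea.tsv", sep="\t", index=False)
    return ora, gsea


def write_manifest(config: PipelineConfig) -> dict:
    outdir = Path(config.outdir)
    manifest = {
        "config": config.to_dict(),
        "artifacts": {
            name: _sha256(outdir / name) for name in ARTIFACTS if (outdir / name).exists()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and return the artifact manifest."""
    config.validate()
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    nets = stage_networks(config)
    stage_extend(config, nets)
    stage_enrich(config, nets)
    return write_manifest(config)
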