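"""End-to-end orchestration: staged runs, manifests, and the robustness grid.

Stages read the plain-text formats the generator writes (MAF-like TSV,
GISTIC TSV, expression TSV, STRING-style edge list, GMT modules, gene-role
TSV) and leave their outputs plus a run manifest — effective parameters,
input digests, seeds, timestamps — in the run directory, so a rerun with an
identical manifest reproduces identical outputs.

The robustness grid reruns the propagation/nomination stage over the
cartesian product of FDR thresholds {0.01, 0.05, 0.10}, restart
probabilities {0.5, 0.75, 0.9} and combined-score cutoffs {0.4, 0.7},
summarizing stability as the fraction of top-k nominations shared with the
primary setting (alpha 0.75, cutoff 0.7).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import pandas as pd

from . import activity as _activity
from . import exclusivity as _exclusivity
from . import landscape as _landscape
from . import propagation as _propagation
from . import simulate as _simulate

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "PipelineConfig", "run_stage", "run_all", "robustness_grid",
            "GENE_ALIASES", "harmonize_gene"]

# Static alias map applied at load time (no live identifier service).
GENE_ALIASES = {
    "PRAS40": "AKT1S1",
    "PDK1": "PDPK1",
    "S6K1": "RPS6KB1",
    "4EBP1": "EIF4EBP1",
    "P70S6K": "RPS6KB1",
}


def harmonize_gene(symbol: str) -> str:
    return GENE_ALIASES.get(symbol, symbol)


@dataclass
class PipelineConfig:
    """Flat, typed run configuration; CLI flags override file values."""

    seed: int = 0
    alpha: float = 0.75
    kernel: str = "symmetric"
    combined_min: float = 0.7
    nonmutated_cutoff_pct: float = 3.0
    shared_min_pct: float = 5.0
    shared_min_studies: int = 5
    specific_diff_pp: float = 10.0
    textmining_weight: float = 1.0
    neighborhood_hops: Optional[int] = None
    n_null_permutations: int = 100
    encoding: str = "role"

    @classmethod
    def from_file(cls, path: Path | str) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)


@dataclass
class RunManifest:
    """Provenance record written once per run directory."""

    tool_version: str
    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    stages: dict[str, dict] = field(default_factory=dict)
    started: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, rundir: Path) -> None:
        (Path(rundir) / "manifest.json").write_text(
            json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _load_roles(path: Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return {harmonize_gene(r.gene): r.role for r in df.itertuples(index=False)}


def _load_hotspots(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t")
    return [harmonize_gene(r.gene) for r in df.itertuples(index=False)
            if getattr(r, "hotspot", 0)]


def run_stage(
    stage: str,
    indir: Path | str,
    rundir: Path | str,
    config: Optional[PipelineConfig] = None,
) -> RunManifest:
    """Execute one named stage and update the run manifest.

    Stages: ``simulate`` (writes the fixture set into ``indir``),
    ``landscape``, ``activity``, ``propagate``, ``exclusivity``.
    Validation failures raise ValueError naming the first offending input.
    """
    from importlib.metadata import version as _pkg_version
    config = config or PipelineConfig()
    indir, rundir = Path(indir), Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    manifest_path = rundir / "manifest.json"
    if manifest_path.exists():
        manifest = RunManifest(**json.loads(manifest_path.read_text()))
    else:
        try:
            ver = _pkg_version("mtoraxis")
        except Exception:
            ver = "0.0.0+local"
        manifest = RunManifest(tool_version=ver, config=asdict(config))

    t0 = time.time()
    if stage == "simulate":
        paths = _simulate.write_fixture_set(
            indir, _simulate.default_config(rng_seed=config.seed))
        manifest.input_digests = {k: _digest(p) for k, p in paths.items()}
    elif stage == "landscape":
        alt = _require_alterations(indir)
        roles = _load_roles(indir / "gene_roles.tsv")
        cutoffs = _landscape.ClassificationCutoffs(
            config.shared_min_pct, config.shared_min_studies, config.specific_diff_pp)
        _landscape.landscape_table(alt, roles, cutoffs, outdir=rundir)
    elif stage == "activity":
        alt = _require_alterations(indir)
        expr_path = indir / "expression.tsv"
        if not expr_path.exists():
            raise ValueError(f"missing expression matrix: {expr_path}")
        expr = pd.read_csv(expr_path, sep="\t", index_col=0)
        z = _activity.pooled_zscores(expr)
        modules = _activity.read_gmt(indir / "modules.gmt")
        _activity.association_tests(z, alt, modules, outdir=rundir)
    elif stage == "propagate":
        _run_propagation(indir, rundir, config)
    elif stage == "exclusivity":
        alt = _require_alterations(indir)
        roles = _load_roles(indir / "gene_roles.tsv")
        panel = [g for g in _simulate.PANEL_GENES if g in alt.genes]
        binary, provenance = _exclusivity.binarize_alterations(
            alt, roles, encoding=config.encoding)
        records = _exclusivity.pairwise_association(binary, genes=panel)
        _exclusivity.write_exclusivity_outputs(records, rundir)
        (rundir / "exclusivity_meta.json").write_text(json.dumps(
            {"encoding": config.encoding, "provenance": provenance,
             "bh_family_size": int(len(records))}, indent=1) + "\n")
    else:
        raise ValueError(f"unknown stage {stage!r}")

    manifest.stages[stage] = {
        "seconds": round(time.time() - t0, 3),
        "parameters": asdict(config),
    }
    manifest.write(rundir)
    return manifest


def _require_alterations(indir: Path) -> _simulate.CohortAlterationTable:
    for name in ("mutations.maf.tsv", "cna_gistic.tsv", "cohorts.tsv"):
        if not (indir / name).exists():
            raise ValueError(f"missing required input file: {indir / name}")
    return _landscape.read_alteration_inputs(
        indir / "mutations.maf.tsv", indir / "cna_gistic.tsv", indir / "cohorts.tsv")


def _run_propagation(
    indir: Path, rundir: Path, config: PipelineConfig,
) -> pd.DataFrame:
    seeds = [harmonize_gene(s) for s in
             (indir / "seeds.txt").read_text().split()]
    pconf = _propagation.PropagationConfig(
        alpha=config.alpha, kernel=config.kernel, combined_min=config.combined_min,
        textmining_weight=config.textmining_weight, seeds=seeds,
        neighborhood_hops=config.neighborhood_hops,
    )
    graph = _propagation.load_interaction_graph(indir / "network_string.tsv", pconf)
    scores, diagnostics = _propagation.propagate(graph, pconf)
    alt = _require_alterations(indir)
    alt_pct = _pan_alteration_pct(alt)
    hotspots = _load_hotspots(indir / "gene_roles.tsv")
    filtered, _full = _propagation.filter_nonmutated(
        scores, alt_pct, graph, seeds=seeds, hotspot_genes=hotspots,
        cutoff_pct=config.nonmutated_cutoff_pct, outdir=rundir,
    )
    if config.n_null_permutations > 0:
        null = _propagation.degree_matched_null(
            graph, pconf, n_perm=config.n_null_permutations, rng_seed=config.seed)
        null.to_csv(rundir / "null_pvalues.tsv", sep="\t", index_label="gene")
    (rundir / "propagation_diagnostics.json").write_text(
        json.dumps(diagnostics, indent=1) + "\n")
    return filtered


def _pan_alteration_pct(alt: _simulate.CohortAlterationTable) -> pd.Series:
    """Pooled % of samples with non-synonymous mutation or amplification."""
    altered = alt.mutations | (alt.cna > 0)
    return altered.mean(axis=0) * 100.0


def run_all(
    indir: Path | str, rundir: Path | str,
    config: Optional[PipelineConfig] = None, simulate_first: bool = True,
) -> RunManifest:
    """Run every stage in order, simulating inputs first when requested."""
    stages = (["simulate"] if simulate_first else []) + [
        "landscape", "activity", "propagate", "exclusivity"]
    manifest = None
    for stage in stages:
        manifest = run_stage(stage, indir, rundir, config)
    return manifest


ROBUSTNESS_FDR = [0.01, 0.05, 0.10]
ROBUSTNESS_ALPHA = [0.5, 0.75, 0.9]
ROBUSTNESS_COMBINED = [0.4, 0.7]


def robustness_grid(
    indir: Path | str,
    rundir: Path | str,
    config: Optional[PipelineConfig] = None,
    top_k: int = 10,
) -> pd.DataFrame:
    """Rerun nomination over the sensitivity grid and summarize stability.

    Emits one long-format row per (fdr, alpha, combined_min) setting with
    the top-k filtered nominations and their overlap fraction with the
    primary setting.  The FDR threshold annotates which propagation-null
    nominations would be called significant at that level; it does not
    change the ranking itself.
    """
    config = config or PipelineConfig()
    indir, rundir = Path(indir), Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)

    def nominations(alpha: float, combined_min: float) -> list[str]:
        c = replace(config, alpha=alpha, combined_min=combined_min,
                    n_null_permutations=0)
        sub = rundir / f"grid_a{alpha}_c{combined_min}"
        sub.mkdir(exist_ok=True)
        filtered = _run_propagation(indir, sub, c)
        return list(filtered["gene"].head(top_k))

    cache: dict[tuple[float, float], list[str]] = {}
    for alpha in ROBUSTNESS_ALPHA:
        for cm in ROBUSTNESS_COMBINED:
            cache[(alpha, cm)] = nominations(alpha, cm)
    primary = cache[(0.75, 0.7)]

    rows = []
    for fdr in ROBUSTNESS_FDR:
        for alpha in ROBUSTNESS_ALPHA:
            for cm in ROBUSTNESS_COMBINED:
                top = cache[(alpha, cm)]
                overlap = len(set(top) & set(primary)) / max(len(primary), 1)
                rows.append({
                    "fdr_threshold": fdr, "alpha": alpha, "combined_min": cm,
                    "top_k": top_k, "top_genes": ",".join(top),
                    "overlap_with_primary": round(overlap, 4),
                    "is_primary": alpha == 0.75 and cm == 0.7,
                })
    out = pd.DataFrame(rows)
    out.to_csv(rundir / "robustness_grid.tsv", sep="\t", index=False)
    return out
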