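"""End-to-end orchestration: community -> differential -> networks -> association.

One configured run mirrors the full analysis of a two-condition
mucosal-microbiome study: per-group alpha-diversity summaries (median
and IQR with a Mann-Whitney p), Bray-Curtis PCoA and PERMANOVA,
differential-feature screening, per-group co-occurrence network
inference with topology classification and strict-Q3 hub detection, and
rank association of the flagged and hub taxa with host phenotypes.
Networks are inferred per group on that group's samples only;
differential analysis uses all samples.

Every random stage derives its seed deterministically from the master
seed, so a rerun with the same config produces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc_mod
from . import community, differential, netinfer, tabio
from .synthetic_data import SyntheticConfig, generate_study
from .tabio import AbundanceTable, StudyMetadata

__all__ = ["RunConfig", "RunReport", "run", "summarize_groups"]

logger = logging.getLogger("mucohub")


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(outdir / "run.log")):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


@dataclass
class RunConfig:
    """Inputs, thresholds and seeds for one pipeline run."""

    output_dir: str = "mucohub_out"
    table_path: str | None = None
    metadata_path: str | None = None
    group_col: str = "group"
    covariate_cols: list[str] = field(default_factory=list)
    synthetic: SyntheticConfig | None = None
    r_threshold: float = 0.4
    p_threshold: float = 0.05
    lda_threshold: float = 1.5
    alpha: float = 0.05
    n_perm_network: int = 100
    n_perm_permanova: int = 999
    n_draws: int = 20
    covariate: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.r_threshold < 1) or not (0 < self.p_threshold < 1):
            raise ValueError("correlation/p thresholds must lie in (0, 1)")
        if self.lda_threshold <= 0 or not (0 < self.alpha < 1):
            raise ValueError("invalid screening thresholds")


@dataclass
class RunReport:
    """Paths and headline results of a completed run."""

    output_dir: str
    diversity_summary: dict
    permanova: dict
    n_flagged: int
    networks: dict
    hubs: dict
    files: dict


def summarize_groups(values_by_group: dict[str, np.ndarray]) -> dict:
    """Median and IQR per group (type-7 quantiles) plus the Mann-Whitney p."""
    if len(values_by_group) != 2 or any(len(v) == 0 for v in values_by_group.values()):
        raise ValueError("need two non-empty groups")
    out = {}
    for label, vals in values_by_group.items():
        v = np.asarray(vals, dtype=float)
        out[label] = {
            "median": float(np.median(v)),
            "q1": float(np.quantile(v, 0.25)),
            "q3": float(np.quantile(v, 0.75)),
        }
    (a, b) = values_by_group.values()
    _, p = differential.mann_whitney(a, b)
    out["mann_whitney_p"] = p
    return out


def _load_inputs(config: RunConfig) -> tuple[AbundanceTable, StudyMetadata, dict]:
    if config.synthetic is not None:
        study = generate_study(config.synthetic)
        truth = {
            "differential_taxa": study.differential_taxa,
            "planted_hubs": {g: sorted(h.hubs) for g, h in study.planted_hubs.items()},
        }
        return study.table, study.metadata, truth
    if config.table_path is None or config.metadata_path is None:
        raise ValueError("provide either a synthetic config or table+metadata paths")
    table = tabio.read_abundance_table(config.table_path)
    metadata = tabio.read_metadata(
        config.metadata_path, group_col=config.group_col, covariate_cols=config.covariate_cols
    )
    return table, metadata, {}


def _stage(name: str, outdir: Path):
    class _StageTimer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                (outdir / "FAILED").write_text(f"stage {name} failed: {exc}\n")
                logger.error("stage %s: FAILED (%s)", name, exc)
                return False
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)
            return False

    return _StageTimer()


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write all artifacts to the output dir."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    seeds = {
        name: int(np.random.default_rng(config.seed + offset).integers(2**31 - 1))
        for offset, name in enumerate(
            ["synthetic", "permanova", "differential", "network_a", "network_b", "association"]
        )
    }
    logger.info("run seeds: %s", seeds)
    files: dict[str, str] = {}

    with _stage("load", outdir):
        table, metadata, truth = _load_inputs(config)
        table, metadata = tabio.align(table, metadata)
        tabio.write_abundance_table(table, outdir / "abundance.tsv")
        tabio.write_metadata(metadata, outdir / "metadata.tsv")
        files["abundance"] = "abundance.tsv"
        files["metadata"] = "metadata.tsv"
        if truth:
            (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
            files["ground_truth"] = "ground_truth.json"

    levels = metadata.group_levels
    with _stage("community", outdir):
        div = community.alpha_diversity(table)
        div.to_csv(outdir / "diversity.tsv", sep="\t")
        files["diversity"] = "diversity.tsv"
        div_summary = {
            index: summarize_groups(
                {lv: div.loc[metadata.samples_in_group(lv), index].to_numpy() for lv in levels}
            )
            for index in ("shannon", "simpson")
        }
        dist = community.bray_curtis(table)
        ordination = community.pcoa(dist)
        ordination.coordinates.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")
        files["pcoa"] = "pcoa_coordinates.tsv"
        perma = community.permanova(
            dist, metadata, n_perm=config.n_perm_permanova, seed=seeds["permanova"]
        )
        perma_dict = {
            "pseudo_f": perma.pseudo_f,
            "p_value": perma.p_value,
            "n_permutations": perma.n_permutations,
        }
        (outdir / "permanova.json").write_text(json.dumps(perma_dict, indent=2))
        files["permanova"] = "permanova.json"

    with _stage("differential", outdir):
        diff = differential.differential_features(
            table,
            metadata,
            alpha=config.alpha,
            threshold=config.lda_threshold,
            covariate=config.covariate,
            seed=seeds["differential"],
        )
        diff.table.to_csv(outdir / "differential.tsv", sep="\t", index=False)
        files["differential"] = "differential.tsv"

    networks_summary, hubs_summary = {}, {}
    hub_taxa: set[str] = set()
    for label, seed_key in zip(levels, ("network_a", "network_b")):
        with _stage(f"network_{label}", outdir):
            sub = table.subset_samples(metadata.samples_in_group(label))
            rho = netinfer.sparcc(sub, n_draws=config.n_draws, seed=seeds[seed_key])
            pvals = netinfer.permutation_pvalues(
                sub, rho, n_perm=config.n_perm_network, seed=seeds[seed_key] + 1
            )
            net = netinfer.build_network(
                rho,
                pvals,
                taxa=list(sub.feature_ids),
                r_threshold=config.r_threshold,
                p_threshold=config.p_threshold,
            )
            tabio.write_network(net, outdir / f"network_{label}.tsv", format="edgelist")
            tabio.write_network(net, outdir / f"network_{label}.gml", format="gml")
            files[f"network_{label}"] = f"network_{label}.tsv"
            topo = netinfer.topology_metrics(net)
            networks_summary[label] = topo.to_dict()
            if len(net.nodes) >= 4:
                hubset = netinfer.identify_hubs(net)
                hubs_summary[label] = {"q3": hubset.q3, "hubs": sorted(hubset.hubs)}
                hub_taxa |= set(hubset.hubs)
            else:
                hubs_summary[label] = {"q3": None, "hubs": []}
            (outdir / f"topology_{label}.json").write_text(
                json.dumps({"topology": networks_summary[label], "hubs": hubs_summary[label]}, indent=2)
            )
            files[f"topology_{label}"] = f"topology_{label}.json"

    with _stage("association", outdir):
        taxa_of_interest = sorted(set(diff.flagged) | hub_taxa)
        if taxa_of_interest and not metadata.phenotypes.empty:
            assoc = assoc_mod.associate(table, metadata, taxa_subset=taxa_of_interest)
        else:
            assoc = pd.DataFrame(columns=["taxon", "variable", "rho", "p", "q", "significant"])
        assoc.to_csv(outdir / "associations.tsv", sep="\t", index=False)
        files["associations"] = "associations.tsv"

    report = RunReport(
        output_dir=str(outdir),
        diversity_summary=div_summary,
        permanova=perma_dict,
        n_flagged=len(diff.flagged),
        networks=networks_summary,
        hubs=hubs_summary,
        files=files,
    )
    with _stage("report", outdir):
        import mucohub

        payload = asdict(report)
        payload["provenance"] = {
            "seeds": seeds,
            "version": getattr(mucohub, "__version__", "unknown"),
            "config": json.loads(json.dumps(asdict(config), default=str)),
        }
        (outdir / "report.json").write_text(json.dumps(payload, indent=2))
    return report
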