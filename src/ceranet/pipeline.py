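"""End-to-end orchestration of the stepwise screen.

Stage order mirrors the study design: per-sample DE calling against the
blank reference, specificity set algebra (intersection of the two knockdown
contrasts, union of the two controls, overlap removal), antisense/proximity
pairing of the surviving lncRNAs and mRNAs, first-neighbor PPI extension,
PageRank dominance with gene-set enrichment filtering (with the control
track's dominant genes removed), and the dual expression/sequence ceRNA
screen.  A run writes per-stage tables, the networks, and a JSON report of
every stage cardinality; identical configs and seeds give identical reports.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from . import io as cio
from .cerna import (
    dual_screen,
    expression_triads,
    mirna_target_matches,
    assemble_cerna_network,
    sequence_candidates,
    triads_of,
)
from .diffexp import DEThresholds, ExpressionMatrix, call_de
from .networks import TypedNetwork, build_lnc_mrna_network, first_neighbor_extension
from .ranking import PRConfig, filter_enriched, hypergeom_enrich, pagerank, select_dominant
from .simulate import (
    CTRL_SAMPLES,
    KD_SAMPLES,
    SimulationConfig,
    SyntheticDataset,
    simulate_all,
)
from .specificity import (
    FeatureSet,
    intersect_consistent,
    subtract_overlap,
    union_profiles,
    venn_summary,
)

logger = logging.getLogger(__name__)

REFERENCE_SAMPLE = "S0"


class PipelineError(RuntimeError):
    """A stage failed; the stage name is part of the message."""


@dataclass
class PipelineConfig:
    """Everything a run needs: inputs (files or a simulation), thresholds."""

    thresholds: DEThresholds = field(default_factory=DEThresholds)
    pr: PRConfig = field(default_factory=PRConfig)
    proximity_window: int = 10_000
    fdr_cut: float = 0.05
    target_lncrna: Optional[str] = None
    validated_mrnas: Dict[str, str] = field(default_factory=dict)
    seed: int = 42
    simulate: Optional[SimulationConfig] = field(default_factory=SimulationConfig)
    inputs: Dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "thresholds" in raw:
            kwargs["thresholds"] = DEThresholds(**raw["thresholds"])
        if "pr" in raw:
            kwargs["pr"] = PRConfig(**raw["pr"])
        for key in ("proximity_window", "fdr_cut", "target_lncrna", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "validated_mrnas" in raw:
            kwargs["validated_mrnas"] = dict(raw["validated_mrnas"])
        if "inputs" in raw and raw["inputs"]:
            kwargs["inputs"] = dict(raw["inputs"])
            kwargs["simulate"] = None
            for name, p in kwargs["inputs"].items():
                if not Path(p).exists():
                    raise PipelineError(f"config input {name}: file not found: {p}")
        elif "simulate" in raw:
            sim = dict(raw["simulate"] or {})
            sim.setdefault("seed", raw.get("seed", 42))
            kwargs["simulate"] = SimulationConfig(**sim)
        return cls(**kwargs)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> Dict[str, str]:
    """Write a synthetic dataset as standard files; returns the path map."""
    outdir = Path(outdir)
    paths = {
        "gtf": outdir / "annotation.gtf",
        "counts": outdir / "counts_genes.tsv",
        "counts_mirna": outdir / "counts_mirna.tsv",
        "ppi": outdir / "ppi.tsv",
        "ppi_sif": outdir / "ppi.sif",
        "mirna_fasta": outdir / "mirna.fa",
        "utr_fasta": outdir / "utr3.fa",
        "lncrna_fasta": outdir / "lncrna.fa",
        "gmt": outdir / "gene_sets.gmt",
        "truth": outdir / "ground_truth.json",
    }
    cio.write_gtf(dataset.annotation, paths["gtf"])
    genes = ExpressionMatrix(
        counts=dataset.counts.counts.loc[dataset.counts.biotype != "miRNA"],
        biotype=dataset.counts.biotype[dataset.counts.biotype != "miRNA"],
    )
    mirna = dataset.counts.subset("miRNA")
    cio.write_counts(genes, paths["counts"])
    cio.write_counts(mirna, paths["counts_mirna"])
    cio.write_ppi(dataset.ppi, paths["ppi"])
    cio.write_ppi(dataset.ppi, paths["ppi_sif"], fmt="sif")
    cio.write_fasta(dataset.mirna_sequences, paths["mirna_fasta"])
    cio.write_fasta(dataset.utr_sequences, paths["utr_fasta"])
    cio.write_fasta(dataset.lncrna_sequences, paths["lncrna_fasta"])
    cio.write_gmt(dataset.gene_sets, paths["gmt"])
    truth = dataset.truth
    cio.write_json(
        {
            "target_lncrna": truth.target_lncrna,
            "validated_mrnas": truth.validated_mrnas,
            "de_features": sorted(map(list, truth.de_features)),
            "antisense_pairs": sorted(map(list, truth.antisense_pairs)),
            "triads": sorted(map(list, truth.triads)),
            "dominant_genes": sorted(truth.dominant_genes),
            "planted_sites": {
                f"{m}|{t}": pos for (m, t), pos in sorted(truth.planted_sites.items())
            },
        },
        paths["truth"],
    )
    return {k: str(v) for k, v in paths.items()}


def _load_inputs(config: PipelineConfig):
    inputs = config.inputs
    for key in ("gtf", "counts", "ppi", "mirna_fasta", "utr_fasta", "gmt"):
        if key not in inputs:
            raise PipelineError(f"stage load: missing input {key!r}")
    annotation = cio.read_gtf(inputs["gtf"])
    biotype_map = {g.gene_id: g.biotype for g in annotation}
    counts = cio.read_counts(inputs["counts"], biotype=biotype_map)
    if "counts_mirna" in inputs:
        mirna = cio.read_counts(inputs["counts_mirna"], biotype=biotype_map)
    else:
        mirna = counts.subset("miRNA")
    ppi = cio.read_ppi(inputs["ppi"])
    mirna_fa = cio.read_fasta(inputs["mirna_fasta"])
    utr_fa = cio.read_fasta(inputs["utr_fasta"])
    lnc_fa = cio.read_fasta(inputs["lncrna_fasta"]) if "lncrna_fasta" in inputs else {}
    gene_sets, descs = cio.read_gmt(inputs["gmt"])
    return annotation, counts, mirna, ppi, mirna_fa, utr_fa, lnc_fa, gene_sets, descs


def _stage(name: str):
    """Wrap a stage so failures abort with the stage name."""

    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - deliberate re-raise with context
                raise PipelineError(f"stage {name}: {exc}") from exc

        return wrapper

    return decorate


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full screen and write tables, networks, and the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "thresholds": {}}
    thresholds = config.thresholds
    report["thresholds"] = {
        "fc_threshold": thresholds.fc_threshold,
        "p_threshold": thresholds.p_threshold,
        "dispersion": thresholds.dispersion,
        "damping": config.pr.damping,
        "proximity_window": config.proximity_window,
        "fdr_cut": config.fdr_cut,
        "seed": config.seed,
    }

    # ---------------- stage: inputs
    truth = None
    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
        dataset = simulate_all(sim_cfg)
        write_dataset(dataset, outdir / "inputs")
        annotation = dataset.annotation
        gene_matrix = ExpressionMatrix(
            counts=dataset.counts.counts.loc[dataset.counts.biotype != "miRNA"],
            biotype=dataset.counts.biotype[dataset.counts.biotype != "miRNA"],
        )
        mirna_matrix = dataset.counts.subset("miRNA")
        ppi = dataset.ppi
        mirna_fa = dataset.mirna_sequences
        utr_fa = dataset.utr_sequences
        lnc_fa = dataset.lncrna_sequences
        gene_sets = dataset.gene_sets
        descs = {}
        truth = dataset.truth
        target_lnc = config.target_lncrna or truth.target_lncrna
        validated = dict(config.validated_mrnas) or dict(truth.validated_mrnas)
    else:
        (annotation, gene_matrix, mirna_matrix, ppi, mirna_fa, utr_fa, lnc_fa,
         gene_sets, descs) = _load_inputs(config)
        target_lnc = config.target_lncrna
        validated = dict(config.validated_mrnas)
        if not target_lnc:
            raise PipelineError("stage config: target_lncrna is required with file inputs")

    logger.info(
        "thresholds: FC>%g, p<=%g, phi=%g, damping=%g, window=%d, fdr<=%g",
        thresholds.fc_threshold, thresholds.p_threshold, thresholds.dispersion,
        config.pr.damping, config.proximity_window, config.fdr_cut,
    )

    # ---------------- stage: differential expression (4 contrasts)
    de = _stage("diffexp")(call_de)
    gene_profiles = {
        s: de(gene_matrix, s, REFERENCE_SAMPLE, thresholds)
        for s in (*KD_SAMPLES, *CTRL_SAMPLES)
    }
    mirna_profiles = {
        s: de(mirna_matrix, s, REFERENCE_SAMPLE, thresholds)
        for s in (*KD_SAMPLES, *CTRL_SAMPLES)
    }
    for s, prof in gene_profiles.items():
        cio.write_de_profile(prof, outdir / f"de_genes_{s}.tsv")
    for s, prof in mirna_profiles.items():
        cio.write_de_profile(prof, outdir / f"de_mirna_{s}.tsv")
    report["stages"]["de"] = {
        **{f"genes_{s}": len(p) for s, p in gene_profiles.items()},
        **{f"mirna_{s}": len(p) for s, p in mirna_profiles.items()},
    }

    # ---------------- stage: specificity set algebra, per biotype
    kd_sets: Dict[str, FeatureSet] = {}
    ctl_sets: Dict[str, FeatureSet] = {}
    final_sets: Dict[str, FeatureSet] = {}
    for biotype, profiles in (
        ("mRNA", gene_profiles),
        ("lncRNA", gene_profiles),
        ("miRNA", mirna_profiles),
    ):
        kd = intersect_consistent(profiles["S1"], profiles["S2"], biotype)
        ctl = union_profiles(profiles["S3"], profiles["S4"], biotype)
        kd_sets[biotype] = kd
        ctl_sets[biotype] = ctl
        final_sets[biotype] = subtract_overlap(kd, ctl)
        report["stages"][f"specificity_{biotype}"] = {
            "knockdown_intersection": len(kd),
            "control_union": len(ctl),
            "final": len(final_sets[biotype]),
            **venn_summary(kd, ctl),
        }

    # ---------------- stage: lncRNA-mRNA network + PPI extension (study)
    build = _stage("interaction_net")(build_lnc_mrna_network)
    extend = _stage("interaction_net")(first_neighbor_extension)
    study_net = build(
        final_sets["lncRNA"], final_sets["mRNA"], annotation, config.proximity_window
    )
    study_lmp = extend(study_net, ppi)
    ctl_net = build(
        ctl_sets["lncRNA"], ctl_sets["mRNA"], annotation, config.proximity_window
    )
    ctl_lmp = extend(ctl_net, ppi)
    cio.write_network(study_lmp, outdir / "lmp_network.graphml")
    cio.write_network(study_lmp, outdir / "lmp_network.sif", fmt="sif")
    report["stages"]["network"] = {
        "lnc_mrna_nodes": study_net.n_nodes,
        "lnc_mrna_edges": study_net.n_edges,
        "lmp_nodes": study_lmp.n_nodes,
        "lmp_edges": study_lmp.n_edges,
        "control_lmp_nodes": ctl_lmp.n_nodes,
        "control_lmp_edges": ctl_lmp.n_edges,
    }

    # ---------------- stage: PageRank dominance + enrichment filter
    universe = sorted(
        set(annotation.ids("mRNA"))
        | {n for e in ppi for n in e}
        | {g for members in gene_sets.values() for g in members}
    )
    if study_lmp.n_nodes:
        scores = _stage("pagerank")(pagerank)(study_lmp, config.pr)
        dominant = select_dominant(scores, study_lmp, config.pr)
        results = hypergeom_enrich(dominant, gene_sets, universe, descs)
        enriched = filter_enriched(dominant, results, config.fdr_cut)
        pr_mass = sum(scores.values())
    else:
        scores, dominant, results, enriched = {}, [], [], []
        pr_mass = 0.0
    if ctl_lmp.n_nodes:
        ctl_scores = _stage("pagerank")(pagerank)(ctl_lmp, config.pr)
        ctl_dominant = select_dominant(ctl_scores, ctl_lmp, config.pr)
    else:
        ctl_dominant = []
    final_mrnas = [g for g in enriched if g not in set(ctl_dominant)]
    with cio.atomic_write(outdir / "pagerank_scores.tsv") as fh:
        fh.write("node\ttype\tscore\tdominant\n")
        for node in sorted(scores):
            fh.write(
                f"{node}\t{study_lmp.node_type(node)}\t{scores[node]:.10g}"
                f"\t{int(node in set(dominant))}\n"
            )
    with cio.atomic_write(outdir / "enrichment.tsv") as fh:
        fh.write("term_id\toverlap\tset_size\tquery_size\tuniverse_size\tp\tfdr\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.overlap}\t{r.set_size}\t{r.query_size}"
                f"\t{r.universe_size}\t{r.p:.6g}\t{r.fdr:.6g}\n"
            )
    report["stages"]["ranking"] = {
        "pagerank_mass": pr_mass,
        "dominant_mrnas": len(dominant),
        "enriched_mrnas": len(enriched),
        "control_dominant_mrnas": len(ctl_dominant),
        "final_mrnas": len(final_mrnas),
        "final_mrna_ids": final_mrnas,
    }

    # ---------------- stage: dual ceRNA screen
    cern = _stage("cerna")
    if validated:
        expr_set = cern(expression_triads)(
            final_sets["lncRNA"], kd_sets["miRNA"], validated, target_lnc
        )
        seq_set = cern(sequence_candidates)(
            sorted(validated), mirna_fa, utr_fa
        )
    else:
        expr_set, seq_set = set(), set()
    control_up = {
        m for m, d in ctl_sets["miRNA"].members.items() if d in ("up", "conflict")
    }
    final_mirnas = dual_screen(expr_set, seq_set, control_up)
    down_validated = sorted(g for g, d in validated.items() if d == "down")
    matches = mirna_target_matches(
        {m: mirna_fa[m] for m in final_mirnas}, utr_fa, down_validated
    ) if final_mirnas else {}
    per_mirna: Dict[str, List[str]] = {m: [] for m in final_mirnas}
    for gene, hits in matches.items():
        for h in hits:
            if gene not in per_mirna[h.mirna_id]:
                per_mirna[h.mirna_id].append(gene)
    lnc_matches = set()
    if target_lnc and target_lnc in lnc_fa:
        for m in final_mirnas:
            if seq_match_any(mirna_fa[m], lnc_fa[target_lnc]):
                lnc_matches.add(m)
    cerna_net = assemble_cerna_network(
        final_mirnas, target_lnc or "", per_mirna, lnc_matches
    )
    cio.write_network(cerna_net, outdir / "cerna_network.graphml")
    cio.write_network(cerna_net, outdir / "cerna_network.sif", fmt="sif")
    triads = sorted(triads_of(cerna_net, target_lnc or ""))
    report["stages"]["cerna"] = {
        "expression_candidates": len(expr_set),
        "sequence_candidates": len(seq_set),
        "dual_candidates": len(expr_set & seq_set),
        "control_up_removed": len((expr_set & seq_set) & control_up),
        "final_mirnas": sorted(final_mirnas),
        "sponge_site_mirnas": sorted(lnc_matches),
        "triads": [list(t) for t in triads],
    }

    if truth is not None:
        recovered_kd = {
            (f, d)
            for f, d in truth.knockdown_de()
            for bt in ("mRNA", "lncRNA", "miRNA")
            if kd_sets[bt].members.get(f) == d
        }
        planted = truth.knockdown_de()
        report["ground_truth"] = {
            "planted_de": len(planted),
            "recovered_de": len(recovered_kd),
            "de_recovery_percent": (
                100.0 * len(recovered_kd) / len(planted) if planted else 100.0
            ),
            "planted_triads": sorted(map(list, truth.triads)),
            "recovered_triads": [list(t) for t in triads],
            "triads_recovered": len(set(triads) & truth.triads),
            "false_triads": len(set(triads) - truth.triads),
        }

    cio.write_json(report, outdir / "report.json")
    return report


def seq_match_any(mirna_seq: str, target_seq: str) -> bool:
    from .cerna import seed_match

    return bool(seed_match(mirna_seq, target_seq))
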