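"""End-to-end orchestration: simulate -> QC -> modules -> GWAS -> epistasis -> network.

Stages communicate through files in the run directory so any stage can
be rerun from its persisted inputs. Every output table carries the run
seed and thresholds in the report; result tables are written
deterministically, so two runs with the same config and seed produce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import io as qio
from .containers import GenotypeMatrix, PhenotypeTable
from .epistasis import scan_anchors
from .gwas import assoc_scan, manhattan_table, significant_hits, top_main_snps
from .modules import (
    cluster_modules,
    fit_normalization,
    group_summary,
    module_traits,
    normalize,
    structure_correlation,
)
from .network import build_network, select_interactive
from .qc import QcThresholds, run_qc
from .simulate import (
    TruthSpec,
    null_truth,
    simulate_genotypes,
    simulate_phenotypes,
    strong_signal_truth,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run.

    Either point ``geno_prefix``/``pheno_path`` at existing inputs or
    set ``simulate=True`` to generate them (preset ``"strong"`` plants
    recoverable effects, ``"null"`` plants none). Thresholds default to
    the standard values: sample/variant call rate 0.90, HWE alpha 5e-7,
    MAF 0.10, PI_HAT 0.2, pruning 50/5/0.8, k=5 modules, GWAS alpha
    1e-4, interaction alpha 5e-4, top-5 main and top-3 interactive SNPs.
    """

    out_dir: str = "qtmod_run"
    seed: int = 0
    # inputs
    simulate: bool = True
    preset: str = "strong"
    n_samples: int = 500
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_ld_blocks: int = 4
    geno_prefix: str | None = None
    pheno_path: str | None = None
    # thresholds
    qc: QcThresholds = field(default_factory=QcThresholds)
    k_modules: int = 5
    distance: str = "abs-corr"
    gwas_alpha: float = 1e-4
    epi_alpha: float = 5e-4
    top_main: int = 5
    top_interactive: int = 3

    def __post_init__(self) -> None:
        if self.preset not in ("strong", "null"):
            raise ValueError("preset must be 'strong' or 'null'")
        for a in (self.gwas_alpha, self.epi_alpha):
            if not (0.0 < a < 1.0):
                raise ValueError("significance thresholds must be in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["qc"] = self.qc.to_dict()
        return d


def _simulate_inputs(cfg: RunConfig, out: Path):
    seeds = np.random.SeedSequence(cfg.seed).generate_state(3) % (2**31)
    G = simulate_genotypes(
        cfg.n_samples,
        cfg.n_snps,
        cfg.maf_range,
        n_ld_blocks=cfg.n_ld_blocks,
        seed=int(seeds[0]),
    )
    if cfg.preset == "strong":
        spec = strong_signal_truth(G, seed=int(seeds[1]))
    else:
        spec = null_truth(seed=int(seeds[1]))
    P, truth = simulate_phenotypes(G, spec)
    qio.write_ped_map(G, out / "genotypes")
    qio.write_phenotypes(P, out / "phenotypes.tsv")
    qio.write_json(truth, out / "truth.json")
    return G, P, truth


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the machine-readable report.

    Stage outputs land in ``cfg.out_dir``: genotype/phenotype inputs
    (when simulated), QC report, normalized volumes, correlation
    matrix, partition, module traits, per-module association tables,
    Manhattan tables, interaction edges and the selection of main- and
    interactive-effect SNPs. ``report.json`` aggregates everything,
    including truth-recovery metrics when a truth record is present.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg.to_dict(), "stages": []}

    try:
        # ---- inputs
        if cfg.simulate:
            G, P, truth = _simulate_inputs(cfg, out)
        else:
            if not cfg.geno_prefix or not cfg.pheno_path:
                raise ValueError("geno_prefix and pheno_path required when simulate=False")
            G = qio.read_ped_map(cfg.geno_prefix)
            P = qio.read_phenotypes(cfg.pheno_path)
            truth_path = Path(cfg.pheno_path).parent / "truth.json"
            truth = qio.read_json(truth_path) if truth_path.exists() else None
        report["stages"].append("inputs")

        # ---- QC
        G_qc, qc_report = run_qc(G, cfg.qc)
        qio.write_json(qc_report.to_dict(), out / "qc_report.json")
        qc_report.removed_samples.to_csv(out / "qc_removed_samples.tsv", sep="\t", index=False)
        qc_report.removed_variants.to_csv(out / "qc_removed_variants.tsv", sep="\t", index=False)
        # phenotype rows restricted to QC-passed samples
        kept = [s for s in G_qc.sample_ids if s in P.data.index]
        G_qc = G_qc.subset(samples=[i for i, s in enumerate(G_qc.sample_ids) if s in set(kept)])
        P_qc = PhenotypeTable(P.data.loc[list(G_qc.sample_ids)], P.roi_columns)
        report["qc"] = {
            "n_samples_in": G.n_samples,
            "n_variants_in": G.n_variants,
            "n_samples_kept": G_qc.n_samples,
            "n_variants_kept": G_qc.n_variants,
            "removed_samples": len(qc_report.removed_samples),
            "removed_variants": len(qc_report.removed_variants),
        }
        report["stages"].append("qc")

        # ---- demographics
        demo = group_summary(P_qc)
        demo.to_csv(out / "group_summary.tsv", sep="\t", index=False)
        report["stages"].append("demographics")

        # ---- normalization + modules
        model = fit_normalization(P_qc)
        qio.write_json(model.to_dict(), out / "normalization.json")
        normed = normalize(P_qc, model)
        normed.to_csv(out / "normalized_volumes.tsv", sep="\t")
        C = structure_correlation(normed)
        C.to_csv(out / "structure_correlation.tsv", sep="\t")
        partition = cluster_modules(C, k=cfg.k_modules, distance=cfg.distance)
        qio.write_json(
            {"assignment": partition.assignment, "k": partition.k},
            out / "module_partition.json",
        )
        traits = module_traits(partition, normed)
        traits.to_csv(out / "module_traits.tsv", sep="\t")
        report["modules"] = {"sizes": partition.sizes()}
        report["stages"].append("modules")

        # ---- GWAS + epistasis + network per module
        covars = P_qc.covariates()
        autosomal = np.flatnonzero(~G_qc.variant_meta["is_x"].to_numpy())
        G_scan = G_qc.subset(variants=autosomal)
        per_module: dict[str, dict] = {}
        for m in range(1, cfg.k_modules + 1):
            trait = traits[m]
            res = assoc_scan(trait, G_scan, covars)
            res.to_csv(out / f"gwas_module{m}.tsv", sep="\t", index=False)
            manhattan_table(res).to_csv(
                out / f"manhattan_module{m}.tsv", sep="\t", index=False
            )
            hits = significant_hits(res, cfg.gwas_alpha)
            main = top_main_snps(res, cfg.top_main)
            anchors = list(main["snp"])
            edges = scan_anchors(trait, anchors, G_scan, covars, cfg.epi_alpha)
            edges.to_csv(out / f"interactions_module{m}.tsv", sep="\t", index=False)
            net = build_network(edges) if len(edges) else build_network(
                pd.DataFrame(columns=["anchor", "partner", "p"])
            )
            sel = select_interactive(net, cfg.top_interactive) if len(net.edges) else (
                pd.DataFrame(columns=["partner", "degree", "min_p", "anchors"])
            )
            sel.to_csv(out / f"interactive_snps_module{m}.tsv", sep="\t", index=False)
            per_module[str(m)] = {
                "n_significant": int(len(hits)),
                "main_effect_snps": anchors,
                "main_effect_p": [float(x) for x in main["p"]],
                "n_interaction_edges": int(len(edges)),
                "interactive_snps": list(sel["partner"]),
                "interactive_degrees": [int(d) for d in sel["degree"]],
            }
        report["per_module"] = per_module
        report["stages"].append("gwas+epistasis+network")

        # ---- truth recovery
        if truth:
            assignment_true = truth["module_assignment_true"]
            phenos = list(normed.columns)
            ari = adjusted_rand_score(
                [assignment_true[p] for p in phenos],
                [partition.assignment[p] for p in phenos],
            )
            # map true module ids to discovered ids by best overlap
            mapping: dict[int, int] = {}
            for tm in sorted(set(assignment_true.values())):
                mem = [p for p in phenos if assignment_true[p] == tm]
                found = pd.Series([partition.assignment[p] for p in mem])
                mapping[tm] = int(found.mode().iloc[0])
            planted_main = {}
            for snp, tm, _beta in truth.get("main_effects", []):
                dm = mapping[int(tm)]
                ranked = per_module[str(dm)]["main_effect_snps"]
                planted_main[snp] = ranked.index(snp) + 1 if snp in ranked else None
            planted_partners = {}
            for _a, partner, tm, _beta in truth.get("interaction_effects", []):
                dm = mapping[int(tm)]
                planted_partners[partner] = (
                    partner in per_module[str(dm)]["interactive_snps"]
                )
            in_top = [r for r in planted_main.values() if r is not None]
            report["recovery"] = {
                "module_ari": float(ari),
                "main_effect_rank": planted_main,
                "main_effect_in_top": len(in_top),
                "n_planted_main": len(planted_main),
                "interactive_partner_selected": planted_partners,
            }
        report["stages"].append("report")
        qio.write_json(report, out / "report.json")
        return report
    except Exception as err:  # annotate the failed stage, then re-raise
        done = report.get("stages", [])
        stage = done[-1] if done else "start"
        raise RuntimeError(f"pipeline failed after stage '{stage}': {err}") from err
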