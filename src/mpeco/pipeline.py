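"""End-to-end orchestration: simulate -> QC -> CNV -> per-sample cNMF ->
meta-programs -> scoring -> ligand-receptor -> ecosystem statistics.

A single :class:`PipelineConfig` drives every stage; the global seed
deterministically derives a per-stage seed, so two runs with an identical
config produce bit-identical artifacts.  Every run writes a manifest with the
full parameter set and SHA-256 hashes of all outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv as cnv_mod
from . import ecosystem as eco_mod
from . import lr as lr_mod
from . import metaprograms as mp_mod
from . import scoring as sc_mod
from . import synthetic as syn_mod
from .cnmf import NMFConfig, ProgramSet, consensus_factorize, fit_sample, preprocess_for_nmf, usage_gene_scores
from .io_qc import (
    ExpressionMatrix,
    GeneAnnotation,
    filter_samples_min_cells,
    normalize_log_cpm,
    normalize_log_median,
    qc_filter,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "qc", "cnv", "nmf", "metaprograms", "scoring", "lr", "ecosystem"]


class DependencyError(RuntimeError):
    """A stage is missing its upstream artifact."""


@dataclass
class PipelineConfig:
    sim: syn_mod.SimulationConfig = field(default_factory=syn_mod.SimulationConfig)
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    seed: int = 0
    out_dir: str | None = None

    # QC (boundary semantics follow the droplet-QC conventions)
    min_genes: int = 500
    umi_min: int = 500
    umi_max: int = 10000
    mito_max: float = 0.20
    hb_max: float = 0.01
    min_cells_per_sample: int = 100

    # CNV (window sized for the synthetic ~90-gene chromosomes)
    cnv_window: int = 51
    cnv_clip: float = 3.0
    cnv_score_k: float = 2.0
    cnv_corr_min: float = 0.3

    # cNMF (desk-scale profile: short scan, full final consensus)
    nmf: NMFConfig = field(default_factory=lambda: NMFConfig(
        k_range=(4, 10), n_restarts=20, max_iter=200, tol=1e-4, k_scan_restarts=8, k_scan_tol=3e-4
    ))

    # meta-programs
    overlap_min: float = 0.5
    share_min: float = 0.2
    min_samples_abs: int = 3
    cut_corr: float = 0.3
    n_signature: int = 50

    # scoring
    rank_cap: int = 1500
    min_score: float = 0.2

    # ligand-receptor
    lr_n_perm: int = 1000
    lr_min_frac: float = 0.1
    lr_n_decoys: int = 20

    # ecosystem
    n_bulk: int = 50
    bulk_noise_sd: float = 0.1
    survival_baseline_hazard: float = 0.1
    survival_censor_rate: float = 0.2

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["sim"].get("usage_correlation") is not None:
            d["sim"]["usage_correlation"] = np.asarray(d["sim"]["usage_correlation"]).tolist()
        return d


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed (always < 2**31)."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineResult:
    config: PipelineConfig
    em: ExpressionMatrix | None = None
    annot: GeneAnnotation | None = None
    truth: syn_mod.SyntheticTruth | None = None
    qc_report: object | None = None
    cnv_profile: cnv_mod.CNVProfile | None = None
    malignant_cells: pd.Index | None = None
    program_sets: dict[str, ProgramSet] = field(default_factory=dict)
    chosen_k: dict[str, int] = field(default_factory=dict)
    metaprograms: list[mp_mod.MetaProgram] = field(default_factory=list)
    recurrent_programs: list[mp_mod.Program] = field(default_factory=list)
    mp_scores: pd.DataFrame | None = None
    mp_assignment: pd.Series | None = None
    score_correlation: pd.DataFrame | None = None
    lr_results: pd.DataFrame | None = None
    lr_top: pd.DataFrame | None = None
    bulk: pd.DataFrame | None = None
    deconvolution: eco_mod.DeconvolutionResult | None = None
    survival: dict | None = None
    report: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _require(result: PipelineResult, attr: str, needed_by: str, produced_by: str):
    value = getattr(result, attr)
    if value is None or (isinstance(value, (dict, list)) and not value):
        raise DependencyError(
            f"stage '{needed_by}' needs '{attr}' from stage '{produced_by}'; run '{produced_by}' first"
        )
    return value


def run_pipeline(config: PipelineConfig, resume: PipelineResult | None = None) -> PipelineResult:
    """Execute the enabled stages in dependency order.

    ``resume`` carries state from earlier stages when only a suffix of the
    pipeline is being (re)run.
    """
    result = resume if resume is not None else PipelineResult(config=config)
    result.config = config
    stages = [s for s in STAGE_ORDER if s in config.stages]
    report: dict = {"stages": stages}

    if "simulate" in stages:
        sim_cfg = replace(config.sim, seed=stage_seed(config.seed, "simulate"))
        result.em, result.annot, result.truth = syn_mod.generate_dataset(sim_cfg)
        report["n_cells_simulated"] = result.em.n_cells

    if "qc" in stages:
        em = _require(result, "em", "qc", "simulate")
        em, qc_rep = qc_filter(
            em, min_genes=config.min_genes, umi_min=config.umi_min, umi_max=config.umi_max,
            mito_max=config.mito_max, hb_max=config.hb_max,
        )
        em = filter_samples_min_cells(em, min_cells=config.min_cells_per_sample)
        result.em = em
        result.qc_report = qc_rep
        report["qc"] = {"retained": qc_rep.n_retained, "removed_by": qc_rep.removed_by,
                        "cells_after_sample_filter": em.n_cells}

    if "cnv" in stages:
        em = _require(result, "em", "cnv", "qc")
        annot = _require(result, "annot", "cnv", "simulate")
        if "compartment" not in em.cell_meta.columns or em.cell_meta["compartment"].isna().all():
            raise DependencyError("cnv stage needs compartment labels on the cells (epithelial vs reference)")
        comp = em.cell_meta["compartment"]
        reference_ids = list(em.cell_meta.index[comp.isin(["stromal", "immune"])])
        expr_log = normalize_log_median(em)
        profile = cnv_mod.smooth_cnv_profile(
            expr_log, annot, em.cell_ids, reference_ids,
            window=config.cnv_window, clip=config.cnv_clip,
        )
        cnv_mod.cnv_score(profile)
        cnv_mod.cnv_correlation(profile)
        cnv_mod.malignancy_statistic(profile)
        calls = cnv_mod.classify_malignant(
            profile, score_k=config.cnv_score_k, corr_min=config.cnv_corr_min,
            method="mixture", seed=stage_seed(config.seed, "cnv"),
        )
        is_epi = (comp == "epithelial").to_numpy()
        result.cnv_profile = profile
        result.malignant_cells = em.cell_meta.index[is_epi & calls]
        report["cnv"] = {
            "n_epithelial": int(is_epi.sum()),
            "n_malignant_called": int(len(result.malignant_cells)),
            "score_threshold": profile.flags.get("score_threshold"),
        }

    if "nmf" in stages:
        em = _require(result, "em", "nmf", "qc")
        malignant = _require(result, "malignant_cells", "nmf", "cnv")
        seed0 = stage_seed(config.seed, "nmf")
        mal_em = em.subset_cells(np.asarray(em.cell_meta.index.isin(malignant)))
        mal_em = filter_samples_min_cells(mal_em, min_cells=config.min_cells_per_sample)
        expr_log = normalize_log_cpm(mal_em)
        samples = sorted(mal_em.cell_meta["sample_id"].unique())
        for i, s in enumerate(samples):
            mask = (mal_em.cell_meta["sample_id"] == s).to_numpy()
            L = expr_log[mask]
            X = preprocess_for_nmf(L)
            cell_ids = list(mal_em.cell_meta.index[mask])
            cfg = replace(config.nmf, seed=(seed0 + 7919 * i) % (2**31))
            ps = fit_sample(X, s, cell_ids, mal_em.gene_ids, cfg, expr_log=L)
            result.program_sets[s] = ps
            result.chosen_k[s] = ps.k
            # an independent consensus at the same K supports the recurrence filter
            cfg_b = replace(cfg, seed=(cfg.seed + 104729) % (2**31))
            _, usages_b, _ = consensus_factorize(X, ps.k, cfg_b, n_restarts=max(3, cfg.n_restarts // 2))
            ps.flags["replicate_gene_scores"] = pd.DataFrame(
                usage_gene_scores(L, usages_b),
                index=[f"{s}_p{j + 1}_rep" for j in range(ps.k)], columns=mal_em.gene_ids,
            )
        report["nmf"] = {"chosen_k": dict(result.chosen_k),
                         "stability": {s: ps.stability for s, ps in result.program_sets.items()}}

    if "metaprograms" in stages:
        program_sets = _require(result, "program_sets", "metaprograms", "nmf")
        collections = {}
        for s, ps in program_sets.items():
            coll_a = mp_mod.programs_from_programset(ps, n_top=config.n_signature)
            rep = ps.flags["replicate_gene_scores"]
            coll_b = [
                mp_mod.Program.from_spectra_row(pid, s, rep.loc[pid], n_top=config.n_signature)
                for pid in rep.index
            ]
            collections[s] = [coll_a, coll_b]
        recurrent = mp_mod.filter_recurrent_programs(collections, overlap_min=config.overlap_min)
        result.recurrent_programs = recurrent
        result.metaprograms = mp_mod.cluster_programs(
            recurrent,
            share_min=config.share_min,
            min_samples_abs=config.min_samples_abs,
            cut_corr=config.cut_corr,
            n_signature=config.n_signature,
        )
        report["metaprograms"] = {
            mp.mp_id: {"n_samples": mp.n_samples_represented, "n_members": len(mp.member_programs)}
            for mp in result.metaprograms
        }

    if "scoring" in stages:
        em = _require(result, "em", "scoring", "qc")
        mps = _require(result, "metaprograms", "scoring", "metaprograms")
        malignant = _require(result, "malignant_cells", "scoring", "cnv")
        mal_em = em.subset_cells(np.asarray(em.cell_meta.index.isin(malignant)))
        expr_log = pd.DataFrame(normalize_log_cpm(mal_em), index=mal_em.cell_meta.index, columns=mal_em.gene_ids)
        sigs = {mp.mp_id: mp.signature for mp in mps}
        scores = sc_mod.ucell_scores_matrix(expr_log, sigs, rank_cap=config.rank_cap)
        sm = sc_mod.ScoreMatrix(scores=scores, rank_cap=config.rank_cap)
        result.mp_assignment = sc_mod.assign_state(sm, min_score=config.min_score)
        result.mp_scores = scores
        if scores.shape[1] >= 2:
            R, _ = eco_mod.correlation_matrix(scores)
            result.score_correlation = R
        report["scoring"] = {
            "assigned": result.mp_assignment.value_counts().to_dict(),
        }

    if "lr" in stages:
        em = _require(result, "em", "lr", "qc")
        seed = stage_seed(config.seed, "lr")
        db = build_lr_database(config, result, seed)
        labels = em.cell_meta["compartment"]
        expr_log = pd.DataFrame(normalize_log_cpm(em), index=em.cell_meta.index, columns=em.gene_ids)
        genes = [g for g in db.genes() if g in expr_log.columns]
        result.lr_results = lr_mod.permutation_test(
            expr_log, labels, db, n_perm=config.lr_n_perm, seed=seed, min_frac=config.lr_min_frac,
        )
        result.lr_top = lr_mod.select_top_pairs(result.lr_results)
        report["lr"] = {"n_tests": len(result.lr_results), "n_db_genes_present": len(genes),
                        "n_selected": len(result.lr_top)}

    if "ecosystem" in stages:
        truth = _require(result, "truth", "ecosystem", "simulate")
        seed = stage_seed(config.seed, "ecosystem")
        # bulk is simulated on the log2-CPM scale of the pure state profiles
        profiles = np.log2(1.0 + 1e4 * truth.state_profiles)
        result.bulk = syn_mod.generate_bulk(
            truth, profiles, n_bulk=config.n_bulk, noise_sd=config.bulk_noise_sd, seed=seed,
        )
        result.deconvolution = eco_mod.nnls_deconvolve(result.bulk, profiles.T)
        shared = [p for p in profiles.index if p.startswith("MP")]
        target = shared[0] if shared else profiles.index[0]
        score = truth.bulk_proportions[target]
        surv = syn_mod.generate_survival(
            score, effect=config.sim.survival_effect,
            baseline_hazard=config.survival_baseline_hazard,
            censor_rate=config.survival_censor_rate, seed=seed + 1,
        )
        truth.survival_table = surv
        cut = eco_mod.optimal_cutpoint(score.to_numpy(), surv["time"].to_numpy(), surv["event"].to_numpy())
        mae = float(np.abs(result.deconvolution.proportions.to_numpy() - truth.bulk_proportions.to_numpy()).mean())
        result.survival = {
            "target_state": target,
            "optimal": cut["optimal"],
            "median": cut["median"],
        }
        report["ecosystem"] = {
            "deconvolution_mae": mae,
            "optimal_cut_p": cut["optimal"].p,
            "median_cut_p": cut["median"].p,
        }

    result.report = report
    result.manifest = _build_manifest(config, result)
    if config.out_dir:
        _write_outputs(Path(config.out_dir), result)
    return result


def build_lr_database(config: PipelineConfig, result: PipelineResult, seed: int) -> lr_mod.LRDatabase:
    """Planted pairs from the simulation config plus seeded decoy pairs."""
    pairs = [
        (f"planted_{lig}_{rec}", [lig], [rec])
        for lig, rec, _, _, _ in config.sim.lr_pairs_true
    ]
    used = {g for p in pairs for g in p[1] + p[2]}
    gene_ids = result.em.gene_ids if result.em is not None else []
    pool = [g for g in gene_ids if g not in used]
    rng = np.random.default_rng(seed + 13)
    pick = rng.choice(len(pool), size=min(2 * config.lr_n_decoys, len(pool)), replace=False)
    for i in range(config.lr_n_decoys):
        lig, rec = pool[pick[2 * i]], pool[pick[2 * i + 1]]
        pairs.append((f"decoy_{i + 1}", [lig], [rec]))
    return lr_mod.LRDatabase(pairs)


# ---------------------------------------------------------------------------
# manifest and artifact writing
# ---------------------------------------------------------------------------

def _hash_obj(obj) -> str:
    if isinstance(obj, pd.DataFrame):
        payload = obj.to_csv().encode()
    elif isinstance(obj, pd.Series):
        payload = obj.to_csv().encode()
    elif isinstance(obj, np.ndarray):
        payload = obj.tobytes()
    else:
        payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


def _build_manifest(config: PipelineConfig, result: PipelineResult) -> dict:
    artifacts = {}
    if result.mp_scores is not None:
        artifacts["mp_scores"] = _hash_obj(result.mp_scores)
    if result.lr_results is not None:
        artifacts["lr_results"] = _hash_obj(result.lr_results)
    for mp in result.metaprograms:
        artifacts[f"signature_{mp.mp_id}"] = _hash_obj(pd.Series(mp.signature))
    for s, ps in result.program_sets.items():
        artifacts[f"spectra_{s}"] = _hash_obj(ps.spectra)
    if result.deconvolution is not None:
        artifacts["deconvolution"] = _hash_obj(result.deconvolution.proportions)
    cfg_dict = config.to_dict()
    cfg_dict.pop("out_dir", None)  # where outputs land does not affect results
    manifest = {
        "config": cfg_dict,
        "seed": config.seed,
        "artifacts": artifacts,
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()
    return manifest


def _write_outputs(out: Path, result: PipelineResult) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, default=str)
    if result.em is not None and result.annot is not None:
        from .io_qc import write_counts
        write_counts(out / "counts", result.em, result.annot)
    if result.cnv_profile is not None:
        result.cnv_profile.to_frame().to_csv(out / "cnv_calls.tsv", sep="\t")
    for s, ps in result.program_sets.items():
        ps.spectra.to_csv(out / f"spectra_{s}.tsv", sep="\t")
        ps.usages.to_csv(out / f"usages_{s}.tsv", sep="\t")
        if ps.diagnostics is not None:
            ps.diagnostics.to_csv(out / f"k_diagnostics_{s}.tsv", sep="\t", index=False)
    if result.metaprograms:
        mp_mod.write_gmt(out / "mp_signatures.gmt", result.metaprograms)
        if len(result.recurrent_programs) >= 2:
            (out / "program_dendrogram.nwk").write_text(
                mp_mod.program_dendrogram_newick(result.recurrent_programs)
            )
        pd.DataFrame(
            {
                "mp_id": mp.mp_id,
                "member": member,
                "n_samples": mp.n_samples_represented,
            }
            for mp in result.metaprograms
            for member in mp.member_programs
        ).to_csv(out / "mp_members.tsv", sep="\t", index=False)
    if result.mp_scores is not None:
        result.mp_scores.to_csv(out / "mp_scores.tsv", sep="\t")
    if result.score_correlation is not None:
        result.score_correlation.to_csv(out / "mp_score_correlation.tsv", sep="\t")
    if result.lr_results is not None:
        result.lr_results.to_csv(out / "lr_results.tsv", sep="\t", index=False)
    if result.lr_top is not None:
        result.lr_top.to_csv(out / "lr_top_pairs.tsv", sep="\t", index=False)
    if result.deconvolution is not None:
        result.deconvolution.proportions.to_csv(out / "deconvolution.tsv", sep="\t")
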