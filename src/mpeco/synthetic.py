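"""Synthetic multi-sample scRNA-seq generator with planted ground truth.

Emulates the structure of a multi-patient tumour atlas at desk scale: several
samples, three cellular compartments (epithelial / stromal / immune),
epithelial cells expressing mixtures of shared and sample-private expression
programs, malignant cells carrying chromosome-arm dosage shifts, planted
ligand-receptor channels between compartments, and bulk mixtures whose
composition drives survival.  Every downstream stage of the pipeline can be
validated against the stored truth without any external download.

Count model
-----------
Counts are Negative Binomial via a Gamma-Poisson mixture with a dispersion
shared across genes:

    mu_cg = libsize_c * sum_k usage_ck * spectra_kg * dosage_cg
    count_cg ~ Poisson(Gamma(shape=1/phi, scale=mu_cg * phi))

where spectra rows are unit-L1 relative expression profiles, usages are
Dirichlet rows on the simplex (optionally sign-correlated through a Gaussian
copula on the Gamma marginals), and dosage is 1 everywhere except on the
configured chromosome arms of malignant cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .io_qc import ExpressionMatrix, GeneAnnotation, compute_qc_covariates

COMPARTMENTS = ("epithelial", "stromal", "immune")

N_MITO_GENES = 10
N_HB_GENES = 3
MITO_MASS_FRACTION = 0.05   # share of baseline expression carried by mito genes
HB_MASS_FRACTION = 0.002
MARKER_GENES_PER_COMPARTMENT = 50
MARKER_FOLD = 4.0


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Knobs of the generative model; ``seed`` fully determines the output."""

    n_samples: int = 8
    cells_per_sample: int | tuple[int, int] = 300
    n_genes: int = 2000
    n_shared_programs: int = 3
    n_private_programs_per_sample: int = 1
    program_gene_size: int = 100
    loading_strength: float = 5.0
    dirichlet_alpha: float | np.ndarray = 0.5
    usage_correlation: np.ndarray | None = None   # n_shared x n_shared sign structure
    compartment_proportions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    libsize_log_mean: float = 8.0                  # natural-log scale, exp(8) ~ 3000 UMI
    libsize_log_sd: float = 0.3
    nb_dispersion: float = 0.3
    malignant_fraction: float = 0.85
    cnv_arms: list[tuple[str, float]] = field(default_factory=lambda: [("chr3q", 1.5), ("chr7p", 1.5)])
    lr_pairs_true: list[tuple[str, str, str, str, float]] = field(default_factory=list)
    survival_effect: float = -1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_genes", "n_shared_programs", "program_gene_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_private_programs_per_sample < 0:
            raise ConfigurationError("n_private_programs_per_sample must be >= 0")
        alpha = np.atleast_1d(np.asarray(self.dirichlet_alpha, dtype=float))
        if np.any(alpha <= 0):
            raise ConfigurationError("dirichlet_alpha must be strictly positive")
        if not 0 <= self.malignant_fraction <= 1:
            raise ConfigurationError("malignant_fraction must lie in [0, 1]")
        for arm, mult in self.cnv_arms:
            if mult <= 0:
                raise ConfigurationError(f"dosage multiplier for {arm} must be positive")
        n_program_genes = self.program_gene_size * (
            self.n_shared_programs + self.n_samples * self.n_private_programs_per_sample
        )
        reserved = N_MITO_GENES + N_HB_GENES + 2 * MARKER_GENES_PER_COMPARTMENT
        if n_program_genes + reserved > self.n_genes:
            raise ConfigurationError(
                f"disjoint programs need {n_program_genes} genes plus {reserved} reserved; "
                f"only {self.n_genes} available"
            )


@dataclass
class SyntheticTruth:
    """Planted ground truth stored alongside a generated dataset."""

    program_gene_lists: dict[str, list[str]]
    usage_matrix: pd.DataFrame            # cell x state, rows on the simplex
    malignant_labels: pd.Series           # cell -> bool
    arm_dosage: pd.DataFrame              # cell x configured arm multipliers
    state_profiles: pd.DataFrame          # state x gene unit-L1 spectra used for generation
    libsize: pd.Series                    # cell -> expected library size
    bulk_proportions: pd.DataFrame | None = None
    survival_table: pd.DataFrame | None = None

    def expected_mean(self, annot: GeneAnnotation) -> np.ndarray:
        """Analytic NB mean mu_cg recomputed from the stored truth components."""
        usage = self.usage_matrix[self.state_profiles.index].to_numpy()
        mu = usage @ self.state_profiles.to_numpy()
        mu *= self.libsize.to_numpy()[:, None]
        dosage = np.ones_like(mu)
        arms = annot.table["chromosome"].astype(str) + annot.table["arm"].astype(str)
        for arm in self.arm_dosage.columns:
            cols = (arms == arm).to_numpy()
            dosage[:, cols] *= self.arm_dosage[arm].to_numpy()[:, None]
        return mu * dosage


def make_gene_annotation(n_genes: int) -> GeneAnnotation:
    """Synthetic genome: chromosomes 1..22 in contiguous equal blocks, two arms each.

    The trailing genes are flagged as mitochondrial and haemoglobin stand-ins
    (they still live on the synthetic autosomes).
    """
    width = len(str(n_genes - 1))
    gene_ids = [f"G{i:0{width}d}" for i in range(n_genes)]
    chrom_of = np.minimum(np.arange(n_genes) * 22 // n_genes, 21)
    rows = []
    for chrom in range(22):
        idx = np.flatnonzero(chrom_of == chrom)
        half = len(idx) // 2
        for j, g in enumerate(idx):
            rows.append(
                {
                    "gene": gene_ids[g],
                    "chromosome": f"chr{chrom + 1}",
                    "arm": "p" if j < half else "q",
                    "start": j * 1000,
                    "end": j * 1000 + 500,
                }
            )
    table = pd.DataFrame(rows).set_index("gene")
    table["genomic_order"] = np.arange(n_genes)
    table["is_mito"] = False
    table["is_hb"] = False
    table.iloc[-N_MITO_GENES:, table.columns.get_loc("is_mito")] = True
    table.iloc[-(N_MITO_GENES + N_HB_GENES):-N_MITO_GENES, table.columns.get_loc("is_hb")] = True
    return GeneAnnotation(table)


def _baseline_profile(rng: np.random.Generator, annot: GeneAnnotation) -> np.ndarray:
    """Unit-L1 baseline propensity with fixed mass on the mito/hb flag genes."""
    n = len(annot.table)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    is_mito = annot.table["is_mito"].to_numpy()
    is_hb = annot.table["is_hb"].to_numpy()
    body = ~(is_mito | is_hb)
    base[body] *= (1.0 - MITO_MASS_FRACTION - HB_MASS_FRACTION) / base[body].sum()
    base[is_mito] = MITO_MASS_FRACTION / is_mito.sum()
    base[is_hb] = HB_MASS_FRACTION / is_hb.sum()
    return base


def _correlated_gamma(rng: np.random.Generator, alpha: np.ndarray, corr: np.ndarray, n: int) -> np.ndarray:
    """Gamma marginals with a Gaussian-copula correlation structure.

    With ``corr`` = identity this reduces exactly to independent Gamma draws,
    i.e. plain Dirichlet usages after row normalization.
    """
    k = len(alpha)
    if np.allclose(corr, np.eye(k)):
        return rng.gamma(shape=alpha, scale=1.0, size=(n, k))
    # small jitter keeps the Cholesky factor defined for near-singular targets
    L = np.linalg.cholesky(corr + 1e-9 * np.eye(k))
    z = rng.standard_normal((n, k)) @ L.T
    u = scipy.stats.norm.cdf(z)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return scipy.stats.gamma.ppf(u, a=alpha[None, :])


def generate_dataset(config: SimulationConfig) -> tuple[ExpressionMatrix, GeneAnnotation, SyntheticTruth]:
    """Draw a full multi-sample dataset plus its ground truth.

    Deterministic given ``config.seed``: regeneration is bit-identical.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    annot = make_gene_annotation(config.n_genes)
    gene_ids = annot.gene_ids
    n_genes = config.n_genes

    # --- assign gene roles (programs, compartment markers) -----------------
    flagged = (annot.table["is_mito"] | annot.table["is_hb"]).to_numpy()
    lr_genes: set[str] = set()
    for lig, rec, _, _, _ in config.lr_pairs_true:
        for g in (lig, rec):
            if g not in annot.table.index:
                raise ConfigurationError(f"planted ligand/receptor gene {g!r} not in the synthetic genome")
            lr_genes.add(g)
    reserved = flagged | np.isin(gene_ids, sorted(lr_genes))
    pool = rng.permutation(np.flatnonzero(~reserved))
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        out = pool[cursor:cursor + n]
        cursor += n
        return np.sort(out)

    program_names = [f"MP{i + 1}" for i in range(config.n_shared_programs)]
    sample_ids = [f"S{i + 1}" for i in range(config.n_samples)]
    private_names = {
        s: [f"{s}_priv{j + 1}" for j in range(config.n_private_programs_per_sample)]
        for s in sample_ids
    }
    program_genes: dict[str, np.ndarray] = {}
    for name in program_names:
        program_genes[name] = take(config.program_gene_size)
    for s in sample_ids:
        for name in private_names[s]:
            program_genes[name] = take(config.program_gene_size)
    marker_genes = {
        "stromal": take(MARKER_GENES_PER_COMPARTMENT),
        "immune": take(MARKER_GENES_PER_COMPARTMENT),
    }

    # --- state expression profiles -----------------------------------------
    baseline = _baseline_profile(rng, annot)

    def elevated(idx: np.ndarray, fold: float) -> np.ndarray:
        prof = baseline.copy()
        prof[idx] *= fold
        return prof / prof.sum()

    profiles: dict[str, np.ndarray] = {}
    for name, idx in program_genes.items():
        profiles[name] = elevated(idx, config.loading_strength)
    for comp in ("stromal", "immune"):
        profiles[comp] = elevated(marker_genes[comp], MARKER_FOLD)

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    epithelial_states = set(program_names) | {p for s in sample_ids for p in private_names[s]}
    for lig, rec, sender, receiver, strength in config.lr_pairs_true:
        for gene, state in ((lig, sender), (rec, receiver)):
            targets = sorted(epithelial_states) if state == "epithelial" else [state]
            for t in targets:
                prof = profiles[t]
                prof[gene_pos[gene]] = strength * baseline.max()
                profiles[t] = prof / prof.sum()

    state_names = program_names + [p for s in sample_ids for p in private_names[s]] + ["stromal", "immune"]
    state_profiles = pd.DataFrame(
        np.vstack([profiles[s] for s in state_names]), index=state_names, columns=gene_ids
    )

    arm_labels = (annot.table["chromosome"].astype(str) + annot.table["arm"].astype(str)).to_numpy()
    for arm, _ in config.cnv_arms:
        if arm not in arm_labels:
            raise ConfigurationError(f"unknown chromosome arm {arm!r}")

    # --- per-sample cells ----------------------------------------------------
    usage_rows, cell_ids, sample_col, compartment_col = [], [], [], []
    malignant, libsizes, dosage_rows, count_blocks = [], [], [], []
    arms_cfg = [a for a, _ in config.cnv_arms]
    P = state_profiles.to_numpy()

    for s in sample_ids:
        if isinstance(config.cells_per_sample, tuple):
            lo, hi = config.cells_per_sample
            n_cells = int(rng.integers(lo, hi + 1))
        else:
            n_cells = int(config.cells_per_sample)
        comp_idx = rng.choice(3, size=n_cells, p=np.asarray(config.compartment_proportions))
        comps = [COMPARTMENTS[i] for i in comp_idx]
        epi = comp_idx == 0
        n_epi = int(epi.sum())

        sample_programs = program_names + private_names[s]
        k = len(sample_programs)
        alpha = np.broadcast_to(np.atleast_1d(np.asarray(config.dirichlet_alpha, dtype=float)), (k,)).copy()
        corr = np.eye(k)
        if config.usage_correlation is not None:
            ns = config.n_shared_programs
            corr[:ns, :ns] = np.asarray(config.usage_correlation, dtype=float)
            np.fill_diagonal(corr, 1.0)
        gam = _correlated_gamma(rng, alpha, corr, n_epi)
        epi_usage = gam / gam.sum(axis=1, keepdims=True)

        usage = np.zeros((n_cells, len(state_names)))
        cols = [state_names.index(p) for p in sample_programs]
        usage[np.flatnonzero(epi)[:, None], np.array(cols)[None, :]] = epi_usage
        usage[comp_idx == 1, state_names.index("stromal")] = 1.0
        usage[comp_idx == 2, state_names.index("immune")] = 1.0

        is_mal = np.zeros(n_cells, dtype=bool)
        n_mal = int(round(config.malignant_fraction * n_epi))
        mal_pick = rng.permutation(n_epi)[:n_mal]
        is_mal[np.flatnonzero(epi)[mal_pick]] = True

        dosage_cells = np.ones((n_cells, len(arms_cfg)))
        dosage_gene = np.ones((n_cells, n_genes))
        for j, (arm, mult) in enumerate(config.cnv_arms):
            dosage_cells[is_mal, j] = mult
            dosage_gene[np.ix_(is_mal, arm_labels == arm)] = mult

        lib = rng.lognormal(mean=config.libsize_log_mean, sigma=config.libsize_log_sd, size=n_cells)
        mu = (usage @ P) * lib[:, None] * dosage_gene
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape=shape, scale=mu * config.nb_dispersion)
        counts = rng.poisson(lam)

        usage_rows.append(usage)
        cell_ids.extend(f"{s}_c{i:04d}" for i in range(n_cells))
        sample_col.extend([s] * n_cells)
        compartment_col.extend(comps)
        malignant.append(is_mal)
        libsizes.append(lib)
        dosage_rows.append(dosage_cells)
        count_blocks.append(sp.csr_matrix(counts.astype(np.int64)))

    counts = sp.vstack(count_blocks, format="csr")
    meta = compute_qc_covariates(counts, annot=annot)
    meta.index = pd.Index(cell_ids, name="cell_id")
    meta.insert(0, "sample_id", sample_col)
    meta.insert(1, "compartment", compartment_col)
    meta["malignant_true"] = np.concatenate(malignant)
    em = ExpressionMatrix(counts=counts, cell_meta=meta, gene_ids=gene_ids)

    truth = SyntheticTruth(
        program_gene_lists={k: [gene_ids[i] for i in v] for k, v in program_genes.items()},
        usage_matrix=pd.DataFrame(np.vstack(usage_rows), index=meta.index, columns=state_names),
        malignant_labels=pd.Series(np.concatenate(malignant), index=meta.index, name="malignant"),
        arm_dosage=pd.DataFrame(np.vstack(dosage_rows), index=meta.index, columns=arms_cfg),
        state_profiles=state_profiles,
        libsize=pd.Series(np.concatenate(libsizes), index=meta.index, name="libsize"),
    )
    return em, annot, truth


def planted_top_genes(truth: SyntheticTruth, program: str, n: int = 50) -> list[str]:
    """Top-n planted program genes ranked by their weight in the planted profile."""
    genes = truth.program_gene_lists[program]
    w = truth.state_profiles.loc[program, genes]
    return list(w.sort_values(ascending=False, kind="stable").index[:n])


# ---------------------------------------------------------------------------
# bulk mixtures and survival outcomes
# ---------------------------------------------------------------------------

def generate_bulk(
    truth: SyntheticTruth,
    state_profiles: pd.DataFrame,
    n_bulk: int,
    noise_sd: float,
    seed: int,
    proportions: np.ndarray | None = None,
    dirichlet_alpha: float = 2.0,
) -> pd.DataFrame:
    """Bulk mixtures: proportions @ profiles + truncated Gaussian noise.

    Proportions are drawn Dirichlet(``dirichlet_alpha``) unless given
    explicitly; they are stored in ``truth.bulk_proportions``.
    """
    if n_bulk < 1:
        raise ValueError("n_bulk must be >= 1")
    rng = np.random.default_rng(seed)
    states = list(state_profiles.index)
    if proportions is None:
        proportions = rng.dirichlet(np.full(len(states), dirichlet_alpha), size=n_bulk)
    proportions = np.asarray(proportions, dtype=float)
    if proportions.shape != (n_bulk, len(states)):
        raise ValueError("proportions shape must be (n_bulk, n_states)")
    bulk = proportions @ state_profiles.to_numpy()
    if noise_sd > 0:
        bulk = bulk + rng.normal(0.0, noise_sd, size=bulk.shape)
    bulk = np.maximum(bulk, 0.0)
    index = pd.Index([f"B{i + 1}" for i in range(n_bulk)], name="bulk_sample")
    truth.bulk_proportions = pd.DataFrame(proportions, index=index, columns=states)
    return pd.DataFrame(bulk, index=index, columns=state_profiles.columns)


def generate_survival(
    bulk_scores: pd.Series | np.ndarray,
    effect: float,
    baseline_hazard: float = 0.1,
    censor_rate: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival with a log-hazard proportional to the z-scored score.

    time_i ~ Exp(baseline_hazard * exp(effect * z_i)); censoring is an
    independent Exponential competing time calibrated so that roughly
    ``censor_rate`` of subjects are censored when ``effect`` is 0.  Stage is
    an ordinal 1-4 derived from a noisy latent copy of the score.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    rng = np.random.default_rng(seed)
    scores = np.asarray(bulk_scores, dtype=float)
    sd = scores.std()
    z = (scores - scores.mean()) / (sd if sd > 0 else 1.0)
    rate = baseline_hazard * np.exp(effect * z)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        c_rate = baseline_hazard * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=len(scores))
    else:
        t_cens = np.full(len(scores), np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    latent = z + rng.standard_normal(len(scores))
    cuts = np.quantile(latent, [0.25, 0.5, 0.75])
    stage = 1 + np.digitize(latent, cuts)
    index = (
        bulk_scores.index
        if isinstance(bulk_scores, pd.Series)
        else pd.Index([f"B{i + 1}" for i in range(len(scores))], name="bulk_sample")
    )
    return pd.DataFrame({"time": time, "event": event, "stage": stage}, index=index)


def write_dataset(out_dir: str | Path, em: ExpressionMatrix, annot: GeneAnnotation, truth: SyntheticTruth) -> None:
    """Write counts (Matrix Market + TSVs) and truth tables under ``out_dir``."""
    from .io_qc import write_counts

    out = Path(out_dir)
    write_counts(out, em, annot)
    truth.usage_matrix.to_csv(out / "truth_usage.tsv", sep="\t")
    truth.state_profiles.to_csv(out / "truth_state_profiles.tsv", sep="\t")
    truth.arm_dosage.to_csv(out / "truth_arm_dosage.tsv", sep="\t")
    pd.DataFrame(
        {"program": k, "gene": g} for k, genes in truth.program_gene_lists.items() for g in genes
    ).to_csv(out / "truth_program_genes.tsv", sep="\t", index=False)
    if truth.bulk_proportions is not None:
        truth.bulk_proportions.to_csv(out / "truth_bulk_proportions.tsv", sep="\t")
    if truth.survival_table is not None:
        truth.survival_table.to_csv(out / "truth_survival.tsv", sep="\t")
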