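"""Cross-sample aggregation of per-sample NMF programs into meta-programs.

Programs from individual samples are the statistical units: programs that do
not recur within their own sample (shared top-50 genes with a program from an
independent decomposition of the same sample) are dropped, survivors are
hierarchically clustered on 1 - Pearson correlation of their weight vectors,
and clusters represented in enough distinct samples become meta-programs
(MP1, MP2, ...) with a 50-gene consensus signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cnmf import ProgramSet, top_genes

logger = logging.getLogger(__name__)


@dataclass
class Program:
    """A single per-sample expression program with its top-gene signature."""

    id: str
    sample_id: str
    weight_vector: pd.Series      # gene -> weight, unit-L1
    top_gene_set: list[str]

    @classmethod
    def from_spectra_row(cls, program_id: str, sample_id: str, row: pd.Series, n_top: int = 50) -> "Program":
        """Build from a spectra row or gene-score row.

        Negative entries (possible for covariance-based gene scores) carry
        no signature weight and are clipped to zero before L1 normalization.
        """
        w = row.clip(lower=0.0)
        total = w.sum()
        if total > 0:
            w = w / total
        return cls(id=program_id, sample_id=sample_id, weight_vector=w, top_gene_set=top_genes(w, n=n_top))


@dataclass
class MetaProgram:
    mp_id: str
    member_programs: list[str]
    n_samples_represented: int
    signature: list[str]
    mean_weight_vector: pd.Series
    flags: dict = field(default_factory=dict)


def programs_from_programset(ps: ProgramSet, collection: str = "", n_top: int = 50) -> list[Program]:
    """Wrap each program of a ProgramSet as a Program.

    Uses the expression-scale gene scores when available (the scale
    signatures are defined on), falling back to the factorization spectra.
    """
    suffix = f"_{collection}" if collection else ""
    source = ps.gene_scores if ps.gene_scores is not None else ps.spectra
    return [
        Program.from_spectra_row(f"{pid}{suffix}", ps.sample_id, source.loc[pid], n_top=n_top)
        for pid in source.index
    ]


def filter_recurrent_programs(
    programs_per_sample: dict[str, list[list[Program]]],
    overlap_min: float = 0.5,
) -> list[Program]:
    """Keep programs that recur across independent decompositions of a sample.

    ``programs_per_sample`` maps sample -> list of program collections (e.g.
    from different restarts or K settings).  A program is recurrent when some
    program from *another* collection of the same sample shares strictly more
    than ``overlap_min`` of its top-gene set (overlap = |A n B| / |A|).
    Samples contributing a single collection pass through with a warning.
    """
    retained: list[Program] = []
    for sample, collections in programs_per_sample.items():
        if len(collections) < 2:
            logger.warning("sample %s has a single program collection; passing through", sample)
            retained.extend(collections[0])
            continue
        kept = dropped = 0
        for i, coll in enumerate(collections):
            for prog in coll:
                top = set(prog.top_gene_set)
                recurrent = False
                for j, other_coll in enumerate(collections):
                    if i == j:
                        continue
                    for other in other_coll:
                        overlap = len(top & set(other.top_gene_set)) / len(prog.top_gene_set)
                        if overlap > overlap_min:
                            recurrent = True
                            break
                    if recurrent:
                        break
                if recurrent:
                    retained.append(prog)
                    kept += 1
                else:
                    dropped += 1
        logger.info("sample %s: %d recurrent programs kept, %d dropped", sample, kept, dropped)
    return retained


def _weight_matrix(programs: list[Program]) -> pd.DataFrame:
    """Programs x genes, restricted to the union of top-gene sets, unit-L1 rows."""
    union = sorted({g for p in programs for g in p.top_gene_set})
    mat = pd.DataFrame(0.0, index=[p.id for p in programs], columns=union)
    for p in programs:
        common = p.weight_vector.index.intersection(union)
        mat.loc[p.id, common] = p.weight_vector[common]
    sums = mat.sum(axis=1)
    sums[sums == 0] = 1.0
    return mat.div(sums, axis=0)


def cluster_programs(
    programs: list[Program],
    share_min: float = 0.2,
    min_samples_abs: int = 3,
    cut_corr: float = 0.3,
    method: str = "average",
    n_signature: int = 50,
) -> list[MetaProgram]:
    """Average-linkage clustering of programs into meta-programs.

    The distance is 1 - Pearson correlation of unit-L1 weight vectors
    restricted to the union of top-gene sets; the dendrogram is cut at
    correlation ``cut_corr`` (distance 1 - cut_corr).  A cluster becomes a
    meta-program iff the number of distinct samples represented reaches
    max(ceil(share_min * n_samples), min_samples_abs).  Member programs from
    the same sample are allowed.  Output is sorted by cluster size
    (descending) and labelled MP1, MP2, ...
    """
    if len(programs) < 2:
        raise ValueError("need at least 2 programs to cluster")
    mat = _weight_matrix(programs)
    x = mat.to_numpy()
    centered = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=1))
    norm[norm == 0] = 1.0
    corr = np.clip((centered / norm[:, None]) @ (centered / norm[:, None]).T, -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    # order-invariant: sort leaves by program id before linkage
    order = np.argsort(mat.index.to_numpy(), kind="stable")
    dist = dist[np.ix_(order, order)]
    ordered = [programs[i] for i in order]
    Z = linkage(squareform(dist, checks=False), method=method)
    labels = fcluster(Z, t=1.0 - cut_corr, criterion="distance")

    n_samples = len({p.sample_id for p in programs})
    floor = max(int(np.ceil(share_min * n_samples)), min_samples_abs)
    clusters: dict[int, list[Program]] = {}
    for lab, prog in zip(labels, ordered):
        clusters.setdefault(lab, []).append(prog)
    kept = [
        members for members in clusters.values()
        if len({p.sample_id for p in members}) >= floor
    ]
    if not kept:
        logger.warning(
            "no program cluster reaches the sharing floor of %d samples (clusters: %s)",
            floor, {lab: len(v) for lab, v in clusters.items()},
        )
        return []
    kept.sort(key=lambda ms: (-len({p.sample_id for p in ms}), -len(ms), min(p.id for p in ms)))
    out = []
    for i, members in enumerate(kept):
        out.append(_build_metaprogram(f"MP{i + 1}", members, n_signature=n_signature))
    return out


def _build_metaprogram(mp_id: str, members: list[Program], n_signature: int = 50) -> MetaProgram:
    mean_w = mp_signature_weights(members)
    sig = top_genes(mean_w, n=min(n_signature, (mean_w > 0).sum() if (mean_w > 0).any() else n_signature))
    return MetaProgram(
        mp_id=mp_id,
        member_programs=[p.id for p in members],
        n_samples_represented=len({p.sample_id for p in members}),
        signature=sig,
        mean_weight_vector=mean_w,
    )


def mp_signature_weights(members: list[Program]) -> pd.Series:
    """Equal-weight average of unit-L1 member weight vectors over all genes."""
    genes = members[0].weight_vector.index
    acc = np.zeros(len(genes))
    for p in members:
        w = p.weight_vector.reindex(genes).fillna(0.0).to_numpy()
        s = w.sum()
        acc += w / s if s > 0 else w
    return pd.Series(acc / len(members), index=genes)


def mp_signature(mp: MetaProgram, n: int = 50) -> list[str]:
    """Top-n genes of the averaged member weight vector, ties by identifier."""
    return top_genes(mp.mean_weight_vector, n=n)


def program_dendrogram_newick(programs: list[Program], method: str = "average") -> str:
    """Newick rendering of the program clustering tree, for inspection.

    Uses the same 1 - Pearson distance (restricted to the union of top-gene
    sets) as :func:`cluster_programs`; branch lengths are cophenetic
    distances.
    """
    if len(programs) < 2:
        raise ValueError("need at least 2 programs")
    mat = _weight_matrix(programs)
    x = mat.to_numpy()
    centered = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=1))
    norm[norm == 0] = 1.0
    corr = np.clip((centered / norm[:, None]) @ (centered / norm[:, None]).T, -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method=method)
    from scipy.cluster.hierarchy import to_tree

    labels = [p.id for p in programs]
    root = to_tree(Z)

    # branch length of a child = parent height - child height
    def emit(node, parent_dist=None):
        if node.is_leaf():
            bl = parent_dist if parent_dist is not None else 0.0
            return f"{labels[node.id]}:{bl:.6f}"
        inner = ",".join(emit(c, node.dist) for c in (node.left, node.right))
        bl = (parent_dist - node.dist) if parent_dist is not None else 0.0
        return f"({inner}):{max(bl, 0.0):.6f}"

    return emit(root) + ";"


def write_gmt(path, metaprograms: list[MetaProgram], description: str = "mpeco") -> None:
    with open(path, "w") as fh:
        for mp in metaprograms:
            fh.write("\t".join([mp.mp_id, description] + list(mp.signature)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return sets
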