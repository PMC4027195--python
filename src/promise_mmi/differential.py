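"""Paired tumor/normal differential analysis of signatures and expression.

Matched sample pairs are compared feature-by-feature with a paired t-test,
p-values are adjusted by the Benjamini-Hochberg step-up, and a three-rule
coherence filter retains only interaction changes that make mechanistic
sense: a shift in the interaction probability must be significant at the
interaction, gene and miRNA level, co-directional with the miRNA expression
change and counter-directional to the gene expression change (a more
engaged miRNA degrades its target harder, and vice versa). Filtered edges
and gene-level average signatures are exported in formats that Cytoscape
and GSEA consume directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

from . import core as _core
from . import preprocess as _pp
from .core import ProMISeSignature
from .preprocess import ExpressionPair
from .seedmatch import SeedMatchMatrix

__all__ = [
    "paired_t_test",
    "bh_fdr",
    "differential_table",
    "coherent_filter",
    "average_signature_per_gene",
    "export_edge_table",
    "read_edge_table",
    "export_rnk",
    "paired_signature_analysis",
]


def paired_t_test(values_normal: np.ndarray,
                  values_tumor: np.ndarray) -> tuple[float, float, int]:
    """Two-sided paired t-test of tumor minus normal.

    Returns (t, p, df) with t = mean(d) / (sd(d)/sqrt(n)), df = n - 1.
    Zero-variance differences make the statistic undefined: (nan, nan, df)
    is returned and the caller is expected to exclude the feature from FDR
    adjustment.
    """
    a = np.asarray(values_normal, dtype=float)
    b = np.asarray(values_tumor, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = b - a
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        return float("nan"), float("nan"), df
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * _st.t.sf(abs(t), df)
    return float(t), float(p), df


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    NaN entries (e.g. zero-variance features) are passed through as NaN and
    do not count toward the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if valid.any():
        out[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return out


def differential_table(normal: pd.DataFrame, tumor: pd.DataFrame,
                       log2fc_pseudocount: float | None = 1.0) -> pd.DataFrame:
    """Per-feature paired differential statistics.

    ``normal`` and ``tumor`` are features x pairs frames with matching
    indices and pair-aligned columns. Returns a frame indexed by feature
    with t_statistic, p_value, fdr, log2_fold_change, mean_normal and
    mean_tumor. With ``log2fc_pseudocount=None`` (appropriate for
    probability-valued features) the difference of means is reported in the
    log2_fold_change column instead of a ratio.
    """
    if not normal.index.equals(tumor.index):
        raise ValueError("normal and tumor tables must share the feature index")
    if normal.shape[1] != tumor.shape[1]:
        raise ValueError("normal and tumor tables must have equally many pairs")
    rows = []
    for feat in normal.index:
        a = normal.loc[feat].to_numpy(float)
        b = tumor.loc[feat].to_numpy(float)
        t, p, _ = paired_t_test(a, b)
        if log2fc_pseudocount is None:
            fc = b.mean() - a.mean()
        else:
            fc = np.log2((b.mean() + log2fc_pseudocount)
                         / (a.mean() + log2fc_pseudocount))
        rows.append((t, p, fc, a.mean(), b.mean()))
    out = pd.DataFrame(
        rows, index=normal.index,
        columns=["t_statistic", "p_value", "log2_fold_change",
                 "mean_normal", "mean_tumor"],
    )
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    return out


def coherent_filter(diff_interactions: pd.DataFrame,
                    diff_genes: pd.DataFrame,
                    diff_mirnas: pd.DataFrame,
                    fdr_interaction: float = 0.05,
                    fdr_gene: float = 0.05,
                    fdr_mirna: float = 0.05) -> pd.DataFrame:
    """Retain interaction changes coherent with expression changes.

    ``diff_interactions`` is indexed by (gene, mirna) tuples or a
    MultiIndex; the other two by gene / miRNA id. An interaction (i, k) is
    kept iff

    1. all three features are significant at their FDR cutoffs,
    2. sign(t_interaction) == sign(t_miRNA), and
    3. sign(t_interaction) == -sign(t_gene).

    Signs are taken from the t statistics; NaN statistics never pass.
    """
    kept = []
    for key, row in diff_interactions.iterrows():
        gene, mirna = key
        if gene not in diff_genes.index or mirna not in diff_mirnas.index:
            continue
        g = diff_genes.loc[gene]
        m = diff_mirnas.loc[mirna]
        vals = (row["fdr"], g["fdr"], m["fdr"],
                row["t_statistic"], g["t_statistic"], m["t_statistic"])
        if any(np.isnan(v) for v in vals):
            continue
        if not (row["fdr"] <= fdr_interaction and g["fdr"] <= fdr_gene
                and m["fdr"] <= fdr_mirna):
            continue
        s_int = np.sign(row["t_statistic"])
        if s_int == 0:
            continue
        if s_int != np.sign(m["t_statistic"]):
            continue
        if s_int != -np.sign(g["t_statistic"]):
            continue
        kept.append(key)
    return diff_interactions.loc[kept]


def average_signature_per_gene(sig: ProMISeSignature,
                               model: str = "mrna") -> pd.Series:
    """Mean signature of each gene over all M miRNAs (zeros included)."""
    mat = sig.matrix(model)
    return pd.Series(mat.mean(axis=1), index=sig.gene_ids, name="mean_signature")


def export_edge_table(filtered: pd.DataFrame, diff_genes: pd.DataFrame,
                      diff_mirnas: pd.DataFrame, path) -> None:
    """Write kept interactions as a Cytoscape-loadable edge-attribute TSV."""
    if filtered.empty:
        raise ValueError("no interactions to export")
    with open(path, "w") as fh:
        fh.write("gene\tmirna\tt_interaction\tfdr_interaction\tt_gene\tt_mirna\n")
        for (gene, mirna), row in filtered.iterrows():
            fh.write(
                f"{gene}\t{mirna}\t{row['t_statistic']:.10g}\t"
                f"{row['fdr']:.10g}\t"
                f"{diff_genes.loc[gene, 't_statistic']:.10g}\t"
                f"{diff_mirnas.loc[mirna, 't_statistic']:.10g}\n"
            )


def read_edge_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment=None,
                     dtype={"gene": str, "mirna": str})
    return df.set_index(["gene", "mirna"])


def paired_signature_analysis(
    matched: list[tuple[str, ExpressionPair, ExpressionPair]],
    C: SeedMatchMatrix,
    model_cfg: "_core.ModelConfig | None" = None,
    quantile_normalize: bool = True,
    model: str = "mrna",
    fdr_interaction: float = 0.05,
    fdr_gene: float = 0.05,
    fdr_mirna: float = 0.05,
) -> dict:
    """Full paired tumor/normal pipeline over matched expression pairs.

    ``matched`` holds (pair_id, normal, tumor) expression pairs aligned to
    ``C``. The cohort is optionally quantile-normalized (mRNA and miRNA
    separately, normals and tumors together, as samples of one cohort), a
    signature is fitted per sample, and paired differential tables are
    computed for interactions (the chosen signature matrix over
    seed-matched entries), gene expression and miRNA expression, followed
    by the three-rule coherence filter.

    Returns a dict with keys ``interactions``, ``genes``, ``mirnas``
    (differential tables) and ``coherent`` (the filtered interaction
    table).
    """
    if len(matched) < 2:
        raise ValueError("need at least 2 matched pairs")
    model_cfg = model_cfg or _core.ModelConfig(expression_rescale="mean_one")

    samples: list[tuple[str, ExpressionPair]] = []
    for pid, normal, tumor in matched:
        samples.append((normal.sample_id or f"{pid}_normal", normal))
        samples.append((tumor.sample_id or f"{pid}_tumor", tumor))
    genes = matched[0][1].gene_ids
    mirnas = matched[0][1].mirna_ids

    if quantile_normalize:
        mrna = _pp.ExpressionMatrix(
            list(genes), [sid for sid, _ in samples],
            np.column_stack([ep.x_obs for _, ep in samples]))
        mirna = _pp.ExpressionMatrix(
            list(mirnas), [sid for sid, _ in samples],
            np.column_stack([ep.z for _, ep in samples]))
        mrna = _pp.quantile_normalize(mrna)
        mirna = _pp.quantile_normalize(mirna)
        norm = {
            sid: ExpressionPair(list(genes), list(mirnas),
                                mrna.values[:, j], mirna.values[:, j],
                                sample_id=sid)
            for j, (sid, _) in enumerate(samples)
        }
    else:
        norm = {sid: ep for sid, ep in samples}

    mask = C.counts > 0
    rows, cols = np.nonzero(mask)
    idx = pd.MultiIndex.from_tuples(
        [(genes[i], mirnas[k]) for i, k in zip(rows, cols)],
        names=["gene", "mirna"])

    def sig_values(ep: ExpressionPair) -> np.ndarray:
        return _core.fit(ep, C, model_cfg).matrix(model)[rows, cols]

    pids = [pid for pid, _, _ in matched]
    nids = [n.sample_id or f"{pid}_normal" for pid, n, _ in matched]
    tids = [t.sample_id or f"{pid}_tumor" for pid, _, t in matched]
    sig_n = pd.DataFrame({pid: sig_values(norm[s]) for pid, s in zip(pids, nids)},
                         index=idx)
    sig_t = pd.DataFrame({pid: sig_values(norm[s]) for pid, s in zip(pids, tids)},
                         index=idx)
    expr_g_n = pd.DataFrame({pid: norm[s].x_obs for pid, s in zip(pids, nids)},
                            index=genes)
    expr_g_t = pd.DataFrame({pid: norm[s].x_obs for pid, s in zip(pids, tids)},
                            index=genes)
    expr_m_n = pd.DataFrame({pid: norm[s].z for pid, s in zip(pids, nids)},
                            index=mirnas)
    expr_m_t = pd.DataFrame({pid: norm[s].z for pid, s in zip(pids, tids)},
                            index=mirnas)

    diff_int = differential_table(sig_n, sig_t, log2fc_pseudocount=None)
    diff_g = differential_table(expr_g_n, expr_g_t)
    diff_m = differential_table(expr_m_n, expr_m_t)
    kept = coherent_filter(diff_int, diff_g, diff_m,
                           fdr_interaction, fdr_gene, fdr_mirna)
    return {"interactions": diff_int, "genes": diff_g, "mirnas": diff_m,
            "coherent": kept}


def export_rnk(gene_scores: pd.Series, path) -> None:
    """Write a two-column GSEA ``.rnk`` file, descending score, ties by id."""
    df = gene_scores.rename("score").rename_axis("gene").reset_index()
    df = df.sort_values(["score", "gene"], ascending=[False, True])
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            fh.write(f"{row['gene']}\t{row['score']:.10g}\n")
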