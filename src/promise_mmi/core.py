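"""The ProMISe competition model.

Given one sample's observed mRNA vector x (length N), miRNA vector z
(length M) and the seed-match count matrix C (N x M), the model infers
three N x M probability matrices for whether miRNA k targets mRNA i:

* mRNA competition  P(x):  p[i,k] = 1 - [ sum_{j!=i} c[j,k] x_j / sum_j c[j,k] x_j ]^{z_k}
  — one minus the probability that miRNA k is attracted away by every
  competing transcript, amplified by the miRNA's abundance;
* miRNA competition P(z):  p[i,k] = 1 - [ sum_{l!=k} c[i,l] z_l / sum_l c[i,l] z_l ]^{x_i}
  — the mirror image, with miRNAs competing for sites on one transcript;
* joint competition P(j) = P(x) * P(z) element-wise, treating the two
  competitions as independent.

Because miRNA binding degrades its target, the observed mRNA level is an
equilibrium below the total transcribed amount. The hidden total x(t) is
recovered by a fixed-point alternation: starting from x(t) = x(obs), each
iteration (i) evaluates P(x), (ii) adds back the expected reduction
delta[i,k] = eta * p[i,k] * x_i(t) and renormalizes so the total equals the
transcriptional capacity T = capacity_factor * sum(x_obs), and (iii)
evaluates P(z) with the fresh x(t); it stops when neither probability
matrix changed by more than ``tol`` anywhere.

Probabilities are deliberately not normalized across rows or columns: one
miRNA may target many transcripts with high probability and vice versa.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .preprocess import ExpressionPair
from .seedmatch import SeedMatchMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "ProMISeSignature",
    "prob_mrna_competition",
    "prob_mirna_competition",
    "expected_reduction",
    "update_total_mrna",
    "fit",
    "fuse_with_sequence_score",
    "write_signature",
    "read_signature_triplets",
]

#: entries closer to 1 than this are considered saturated
_SATURATION_EPS = 1e-12


@dataclass(frozen=True)
class ModelConfig:
    """Tunable parameters of the fixed-point alternation.

    eta
        Learning rate scaling the per-iteration expected reduction
        (default 0.001).
    capacity_factor
        Transcriptional capacity multiplier: T = capacity_factor * sum(x_obs),
        the assumed total transcribed mRNA before miRNA-mediated degradation
        (default 1.3, i.e. 30% above the observed total).
    tol
        Convergence threshold on the maximum absolute element-wise change of
        both probability matrices (default 1e-5).
    max_iter
        Iteration cap guarding against non-convergence (default 200).
    expression_rescale
        "none" feeds expression values into the exponents as given;
        "mean_one" divides x and z by their respective means first, keeping
        exponents O(1) so probabilities do not saturate at 1 for
        RPKM/RPM-scale inputs. Competition fractions are scale-invariant, so
        this only affects the exponents.
    """

    eta: float = 0.001
    capacity_factor: float = 1.3
    tol: float = 1e-5
    max_iter: int = 200
    expression_rescale: str = "none"

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.capacity_factor < 1:
            raise ValueError("capacity_factor must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.expression_rescale not in ("none", "mean_one"):
            raise ValueError("expression_rescale must be 'none' or 'mean_one'")


@dataclass
class ProMISeSignature:
    """Per-sample interaction signature: the three probability matrices."""

    gene_ids: list[str]
    mirna_ids: list[str]
    p_mrna: np.ndarray = field(repr=False)
    p_mirna: np.ndarray = field(repr=False)
    p_joint: np.ndarray = field(repr=False)
    x_total_final: np.ndarray = field(repr=False)
    converged: bool = True
    n_iter: int = 0
    max_last_change: float = 0.0
    sample_id: str = ""
    config: ModelConfig = field(default_factory=ModelConfig)

    def matrix(self, model: str = "mrna") -> np.ndarray:
        try:
            return {"mrna": self.p_mrna, "mirna": self.p_mirna,
                    "joint": self.p_joint}[model]
        except KeyError:
            raise ValueError(f"unknown model {model!r}; "
                             "expected 'mrna', 'mirna' or 'joint'") from None

    def to_frame(self, model: str = "mrna") -> pd.DataFrame:
        return pd.DataFrame(self.matrix(model), index=self.gene_ids,
                            columns=self.mirna_ids)


def _check_inputs(x: np.ndarray, z: np.ndarray, C: SeedMatchMatrix) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != (C.n_genes,) or z.shape != (C.n_mirnas,):
        raise ValueError(
            f"dimension mismatch: x {x.shape}, z {z.shape}, "
            f"C {C.n_genes}x{C.n_mirnas}"
        )
    if np.any(x < 0) or np.any(z < 0):
        raise ValueError("expression vectors must be nonnegative")
    return x, z


def prob_mrna_competition(x_total: np.ndarray, z: np.ndarray,
                          C: SeedMatchMatrix) -> np.ndarray:
    """mRNA-competition probabilities: transcripts dilute a shared miRNA.

    p[i,k] = 1 - (competing site mass / total site mass)^{z_k}, where site
    mass for miRNA k is sum_j c[j,k] x_j. Computed as exp(z_k * log f) with
    the fraction f clamped to [0, 1]. p[i,k] = 0 whenever c[i,k] = 0,
    z_k = 0, or no expressed transcript carries a site for miRNA k.
    """
    x, z = _check_inputs(x_total, z, C)
    c = C.counts.astype(float)
    site_mass = c * x[:, None]                      # c[i,k] * x_i
    total = site_mass.sum(axis=0)                   # per-miRNA denominator
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (total[None, :] - site_mass) / total[None, :]
        frac = np.clip(frac, 0.0, 1.0)
        # fraction^z in log space; 0^0 := 1 so z=0 gives p=0
        p = 1.0 - np.exp(z[None, :] * np.log(frac))
    p[:, z == 0] = 0.0
    p[:, total == 0] = 0.0
    p[c == 0] = 0.0
    return np.clip(p, 0.0, 1.0)


def prob_mirna_competition(x_total: np.ndarray, z: np.ndarray,
                           C: SeedMatchMatrix) -> np.ndarray:
    """miRNA-competition probabilities: miRNAs compete for one transcript.

    Mirror of :func:`prob_mrna_competition` with the roles of x and z
    swapped: the fraction is over miRNA site mass sum_l c[i,l] z_l on
    transcript i and the exponent is x_i. p[i,k] = 0 whenever c[i,k] = 0,
    x_i = 0, or no expressed miRNA has a site on transcript i.
    """
    x, z = _check_inputs(x_total, z, C)
    c = C.counts.astype(float)
    site_mass = c * z[None, :]                      # c[i,l] * z_l
    total = site_mass.sum(axis=1)                   # per-gene denominator
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (total[:, None] - site_mass) / total[:, None]
        frac = np.clip(frac, 0.0, 1.0)
        p = 1.0 - np.exp(x[:, None] * np.log(frac))
    p[x == 0, :] = 0.0
    p[total == 0, :] = 0.0
    p[c == 0] = 0.0
    return np.clip(p, 0.0, 1.0)


def expected_reduction(p_mrna: np.ndarray, x_total: np.ndarray,
                       eta: float) -> np.ndarray:
    """Expected per-pair mRNA reduction delta[i,k] = eta * p[i,k] * x_i."""
    if eta <= 0:
        raise ValueError("eta must be > 0")
    return eta * np.asarray(p_mrna) * np.asarray(x_total, dtype=float)[:, None]


def update_total_mrna(x_total: np.ndarray, delta: np.ndarray,
                      T: float) -> np.ndarray:
    """Add back the expected reductions and renormalize the total to T."""
    if T <= 0:
        raise ValueError("T must be > 0")
    x = np.asarray(x_total, dtype=float)
    if np.any(x < 0):
        raise ValueError("x_total must be nonnegative")
    x_star = x + np.asarray(delta).sum(axis=1)
    s = x_star.sum()
    if s == 0:
        raise ValueError("degenerate profile: total expression is zero")
    return x_star * (T / s)


def fit(pair: ExpressionPair, C: SeedMatchMatrix,
        cfg: ModelConfig | None = None) -> ProMISeSignature:
    """Run the fixed-point alternation to convergence for one sample.

    Deterministic: identical inputs give bit-identical signatures. On
    failure to converge within ``cfg.max_iter`` a warning is issued and the
    last iterate is returned with ``converged=False``.
    """
    cfg = cfg or ModelConfig()
    x_obs, z = _check_inputs(pair.x_obs, pair.z, C)
    if C.n_mirnas == 0:
        raise ValueError("no miRNAs left after filtering; nothing to fit")
    if not np.any(x_obs > 0) or not np.any(z > 0):
        raise ValueError("need at least one positive mRNA and one positive miRNA value")

    if cfg.expression_rescale == "mean_one":
        x_obs = x_obs / x_obs.mean()
        z = z / z.mean()

    T = cfg.capacity_factor * x_obs.sum()
    x_t = x_obs.copy()

    p_x_prev = np.zeros((C.n_genes, C.n_mirnas))
    p_z_prev = np.zeros((C.n_genes, C.n_mirnas))
    converged = False
    n_iter = 0
    max_change = np.inf
    for n_iter in range(1, cfg.max_iter + 1):
        p_x = prob_mrna_competition(x_t, z, C)
        delta = expected_reduction(p_x, x_t, cfg.eta)
        # the total is re-estimated each iteration as observed + expected
        # reduction (then renormalized to T): the observed level anchors the
        # fixed point, making the alternation a contraction that settles in
        # a handful of iterations
        x_t = update_total_mrna(x_obs, delta, T)
        p_z = prob_mirna_competition(x_t, z, C)
        max_change = max(
            np.max(np.abs(p_x - p_x_prev), initial=0.0),
            np.max(np.abs(p_z - p_z_prev), initial=0.0),
        )
        p_x_prev, p_z_prev = p_x, p_z
        if max_change <= cfg.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"fixed-point alternation did not converge in {cfg.max_iter} "
            f"iterations (last max change {max_change:.3g})"
        )

    nonzero = C.counts > 0
    if nonzero.any():
        saturated = np.sum(p_x_prev[nonzero] > 1 - _SATURATION_EPS)
        if saturated > 0.5 * nonzero.sum():
            logger.warning(
                "%d/%d seed-matched entries saturate at probability 1; "
                "consider expression_rescale='mean_one'",
                saturated, int(nonzero.sum()),
            )

    return ProMISeSignature(
        gene_ids=list(pair.gene_ids),
        mirna_ids=list(pair.mirna_ids),
        p_mrna=p_x_prev,
        p_mirna=p_z_prev,
        p_joint=p_x_prev * p_z_prev,
        x_total_final=x_t,
        converged=converged,
        n_iter=n_iter,
        max_last_change=float(max_change),
        sample_id=pair.sample_id,
        config=cfg,
    )


def fuse_with_sequence_score(sig: ProMISeSignature, pct: np.ndarray | pd.DataFrame,
                             model: str = "mrna") -> np.ndarray:
    """Multiply a signature matrix by aligned sequence-based scores (e.g. PCT).

    Missing score entries (NaN) are treated as 0, removing the pair. The
    mRNA-competition matrix is the default carrier, being the model's
    representative variant.
    """
    if isinstance(pct, pd.DataFrame):
        pct = pct.reindex(index=sig.gene_ids, columns=sig.mirna_ids).to_numpy(float)
    pct = np.nan_to_num(np.asarray(pct, dtype=float), nan=0.0)
    if pct.shape != (len(sig.gene_ids), len(sig.mirna_ids)):
        raise ValueError("sequence-score matrix is not aligned with the signature")
    if np.any((pct < 0) | (pct > 1)):
        raise ValueError("sequence scores must lie in [0, 1]")
    return sig.matrix(model) * pct


def write_signature(sig: ProMISeSignature, prefix, dense: bool = True) -> None:
    """Write a signature as TSV files plus a JSON sidecar.

    ``<prefix>.p_mrna.tsv`` etc. hold the dense matrices (if requested);
    ``<prefix>.triplets.tsv`` lists seed-matched pairs with all three
    probabilities; ``<prefix>.json`` records config and convergence.
    """
    prefix = str(prefix)
    if dense:
        for name in ("p_mrna", "p_mirna", "p_joint"):
            sig.to_frame(name.split("_")[1]).to_csv(
                f"{prefix}.{name}.tsv", sep="\t", index_label="gene"
            )
    mask = (sig.p_mrna > 0) | (sig.p_mirna > 0)
    rows, cols = np.nonzero(mask)
    with open(f"{prefix}.triplets.tsv", "w") as fh:
        fh.write("gene\tmirna\tp_mrna\tp_mirna\tp_joint\n")
        for i, k in zip(rows, cols):
            fh.write(
                f"{sig.gene_ids[i]}\t{sig.mirna_ids[k]}\t"
                f"{sig.p_mrna[i, k]:.10g}\t{sig.p_mirna[i, k]:.10g}\t"
                f"{sig.p_joint[i, k]:.10g}\n"
            )
    sidecar = {
        "sample_id": sig.sample_id,
        "config": asdict(sig.config),
        "T": float(np.sum(sig.x_total_final)),
        "n_iter": sig.n_iter,
        "converged": sig.converged,
        "max_last_change": sig.max_last_change,
        "n_genes": len(sig.gene_ids),
        "n_mirnas": len(sig.mirna_ids),
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_signature_triplets(path) -> pd.DataFrame:
    """Read a ``.triplets.tsv`` signature file into a DataFrame."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"gene": str, "mirna": str})
    required = {"gene", "mirna", "p_mrna", "p_mirna", "p_joint"}
    if not required.issubset(df.columns):
        raise ValueError(f"signature triplet file must have columns {sorted(required)}")
    return df
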