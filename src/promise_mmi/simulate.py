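"""Synthetic data: seed matrices, expression pairs, cohorts, planted truth.

Every pipeline stage can be exercised without external downloads. The
generator emulates the shape of the real inputs — sparse small-integer seed
counts, long-tailed nonnegative expression, miRNA-mediated repression of
the observed mRNA of true targets, and matched tumor/normal cohorts with
planted differential interactions — while recording ground truth for
benchmarking.

A "true" interaction requires both partners to be present: the higher the
miRNA and mRNA abundance, the more likely the pair actually interacts, so
truth pairs are sampled among seed-matched pairs with probability
proportional to w(z_k) * w(x_i), where w(v) = v / (v + median(v)) is a
saturating abundance weight (x taken at its latent, pre-repression level).
The same miRNA weight w(z_k) scales the repression each true target
experiences: a barely-expressed miRNA represses nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import ExpressionPair
from .seedmatch import SeedMatchMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "CohortPair",
    "PRESETS",
    "preset",
    "make_toy",
    "generate",
    "generate_cohort",
    "write_dataset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults give a mixed-competition regime.

    n_genes, n_mirnas
        System size (default 300 x 20, a desk-scale stand-in for the
        ~13000 x 710 real matrices).
    seed_density
        Probability that a (gene, miRNA) pair carries at least one site
        (default 0.15, matching the sparsity of conserved-site tables).
    site_geom_p
        Success probability of the geometric site-count distribution for
        seed-matched pairs; the default 2/3 gives mean count 1.5 on
        support {1, 2, ...}, mimicking the dominance of single sites.
    expression_log_mean, expression_log_sigma
        Parameters of the log-normal expression distribution (applied to
        both mRNA and miRNA); the defaults (0.5, 1.0) give a long-tailed
        nonnegative distribution with median ~1.6 and occasional values
        an order of magnitude higher.
    target_fraction
        Fraction of seed-matched pairs planted as true interactions
        (default 0.1).
    repression_strength
        Maximum multiplicative decrease of a true target's observed mRNA
        per interaction, scaled by the miRNA abundance weight (default
        0.5; must be < 1 so observed expression stays positive).
    rng_seed
        Seed of the generator; identical configs give identical datasets.
    """

    n_genes: int = 300
    n_mirnas: int = 20
    seed_density: float = 0.15
    site_geom_p: float = 2.0 / 3.0
    expression_log_mean: float = 0.5
    expression_log_sigma: float = 1.0
    target_fraction: float = 0.1
    repression_strength: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_mirnas < 1:
            raise ValueError("need at least one gene and one miRNA")
        for name in ("seed_density", "site_geom_p", "target_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.repression_strength < 1:
            raise ValueError("repression_strength must lie in [0, 1)")


#: named generation regimes; parameters of the stress scenarios differ from
#: the mixed default only in the competition structure they emphasize
PRESETS: dict[str, dict] = {
    "mixed": {},
    "no_competition": {"seed_density": 0.02, "n_mirnas": 20},
    "mrna_competition": {"n_genes": 400, "n_mirnas": 5, "seed_density": 0.3},
    "mirna_competition": {"n_genes": 50, "n_mirnas": 40, "seed_density": 0.3},
}


def preset(name: str, **overrides) -> SyntheticConfig:
    """A named :class:`SyntheticConfig` regime, optionally overridden."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return SyntheticConfig(**params)


@dataclass
class CohortPair:
    """One matched normal/tumor sample pair."""

    pair_id: str
    normal: ExpressionPair
    tumor: ExpressionPair


@dataclass
class SyntheticDataset:
    """Generated inputs plus the ground truth they were built from."""

    C: SeedMatchMatrix
    x_obs: np.ndarray
    z: np.ndarray
    latent: np.ndarray = field(repr=False)
    truth: set = field(default_factory=set)
    cohort: list[CohortPair] | None = None
    planted: list[tuple[str, str, str]] | None = None

    @property
    def pair(self) -> ExpressionPair:
        return ExpressionPair(
            gene_ids=list(self.C.genes),
            mirna_ids=list(self.C.mirnas),
            x_obs=self.x_obs,
            z=self.z,
            sample_id="s1",
        )


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _abundance_weight(z: np.ndarray) -> np.ndarray:
    """Saturating weight in [0, 1): w(z) = z / (z + median of positive z)."""
    zp = z[z > 0]
    scale = np.median(zp) if zp.size else 1.0
    return z / (z + scale)


def make_toy() -> SyntheticDataset:
    """Fixed 10-gene x 4-miRNA dataset illustrating the model's structure.

    Gene g01 carries no site for miRNA m2 (its interaction probability must
    be zero); gene g02's only site is for miRNA m4 (its miRNA-competition
    probability must be one, since no other miRNA recognizes it); miRNA m4
    has sites on most genes, exercising mRNA competition. Every call
    returns identical data.
    """
    genes = _ids("g", 10)
    mirnas = _ids("m", 4)
    counts = np.array(
        [
            [2, 0, 1, 2],   # g01: no site for m2
            [0, 0, 0, 1],   # g02: only m4
            [1, 0, 2, 2],
            [0, 1, 0, 1],
            [1, 2, 1, 0],
            [0, 1, 1, 0],
            [2, 1, 0, 1],
            [1, 0, 1, 0],
            [0, 2, 0, 1],
            [1, 3, 0, 0],
        ],
        dtype=np.int64,
    )
    x = np.array([5.0, 1.5, 4.0, 2.0, 3.0, 1.0, 2.5, 1.8, 2.2, 6.0])
    z = np.array([2.0, 3.0, 1.5, 2.5])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        C = SeedMatchMatrix(genes, mirnas, counts)
    truth = {(genes[1], mirnas[3]), (genes[0], mirnas[3]), (genes[4], mirnas[1])}
    return SyntheticDataset(C=C, x_obs=x.copy(), z=z, latent=x.copy(), truth=truth)


def generate(cfg: SyntheticConfig) -> SyntheticDataset:
    """Draw one paired profile with planted true targets.

    Latent mRNA and miRNA abundances are log-normal; each seed-matched pair
    is labeled true with probability proportional to the product of its
    miRNA's and its gene's (latent) abundance weights until
    ``target_fraction`` of pairs are chosen; the observed mRNA of a true
    target is its latent value shrunk by
    ``1 - repression_strength * w(z_k)`` per true interaction.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    genes = _ids("g", cfg.n_genes)
    mirnas = _ids("mir", cfg.n_mirnas)

    mask = rng.random((cfg.n_genes, cfg.n_mirnas)) < cfg.seed_density
    if not mask.any():
        raise ValueError("seed_density too low: no seed-matched pair was generated")
    counts = np.zeros_like(mask, dtype=np.int64)
    counts[mask] = rng.geometric(cfg.site_geom_p, size=int(mask.sum()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        C = SeedMatchMatrix(genes, mirnas, counts)

    latent = rng.lognormal(cfg.expression_log_mean, cfg.expression_log_sigma,
                           cfg.n_genes)
    z = rng.lognormal(cfg.expression_log_mean, cfg.expression_log_sigma,
                      cfg.n_mirnas)
    w = _abundance_weight(z)
    u = _abundance_weight(latent)

    rows, cols = np.nonzero(counts > 0)
    n_pairs = len(rows)
    n_true = int(round(cfg.target_fraction * n_pairs))
    truth: set = set()
    if n_true > 0:
        probs = w[cols] * u[rows]
        if probs.sum() == 0:
            probs = np.ones(n_pairs)
        probs = probs / probs.sum()
        chosen = rng.choice(n_pairs, size=n_true, replace=False, p=probs)
        truth = {(genes[rows[j]], mirnas[cols[j]]) for j in chosen}

    x_obs = latent.copy()
    gi = {g: i for i, g in enumerate(genes)}
    ki = {m: k for k, m in enumerate(mirnas)}
    for g, m in truth:
        x_obs[gi[g]] *= 1.0 - cfg.repression_strength * w[ki[m]]

    return SyntheticDataset(C=C, x_obs=x_obs, z=z, latent=latent, truth=truth)


def generate_cohort(
    cfg: SyntheticConfig,
    n_pairs: int,
    planted: list[tuple[str, str, str]] | None = None,
    n_planted: int = 5,
    mirna_shift: float = 4.0,
    gene_shift: float = 0.7,
    noise_sigma: float = 0.15,
) -> SyntheticDataset:
    """Matched normal/tumor cohort with planted differential interactions.

    Each pair draws its own baseline profile (log-normal biological
    variation around the dataset's latent profile); the tumor sample adds
    independent log-normal measurement noise (``noise_sigma``) and the
    planted shifts. A planted entry is ``(gene, mirna, direction)`` with
    direction

    * ``"up"``: miRNA expression multiplied by ``mirna_shift`` and gene
      expression by ``gene_shift`` (< 1) in tumor — the coherent
      "interaction gained" pattern;
    * ``"down"``: the reciprocal shifts — coherent "interaction lost";
    * ``"incoherent"``: miRNA and gene both shifted up, violating the
      sign rules and serving as a negative control.

    If ``planted`` is None, ``n_planted`` seed-matched pairs with distinct
    genes and distinct miRNAs are chosen with direction "up", emulating
    oncomir gain: the miRNA is drawn from those lowly expressed in normal
    (below the median, so the tumor upregulation is a real gain rather
    than saturation of an already-dominant miRNA) and the target gene from
    those above the median, so its downregulation remains visible.
    """
    if n_pairs < 2:
        raise ValueError("need at least 2 matched pairs")
    base = generate(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, n_pairs]))
    genes, mirnas = base.C.genes, base.C.mirnas
    gi = {g: i for i, g in enumerate(genes)}
    ki = {m: k for k, m in enumerate(mirnas)}

    if planted is None:
        rows, cols = np.nonzero(base.C.counts > 0)
        # mid-band miRNAs: low enough that the gain is real, high enough
        # that a few-fold shift crosses expression ranks in the cohort
        z_lo, z_hi = np.quantile(base.z, [0.25, 0.6])
        x_med = np.median(base.x_obs)
        eligible = [j for j in range(len(rows))
                    if z_lo <= base.z[cols[j]] <= z_hi
                    and base.x_obs[rows[j]] > x_med]
        order = rng.permutation(eligible if eligible else len(rows))
        used_g: set = set()
        used_m: set = set()
        planted = []
        for j in order:
            g, m = genes[rows[j]], mirnas[cols[j]]
            if g in used_g or m in used_m:
                continue
            planted.append((g, m, "up"))
            used_g.add(g)
            used_m.add(m)
            if len(planted) == n_planted:
                break

    gene_factor = np.ones(len(genes))
    mirna_factor = np.ones(len(mirnas))
    for g, m, direction in planted:
        if direction == "up":
            mirna_factor[ki[m]] *= mirna_shift
            gene_factor[gi[g]] *= gene_shift
        elif direction == "down":
            mirna_factor[ki[m]] /= mirna_shift
            gene_factor[gi[g]] /= gene_shift
        elif direction == "incoherent":
            mirna_factor[ki[m]] *= mirna_shift
            gene_factor[gi[g]] /= gene_shift
        else:
            raise ValueError(f"unknown planted direction {direction!r}")

    cohort: list[CohortPair] = []
    for p in range(n_pairs):
        pid = f"p{p + 1:02d}"
        x_base = base.x_obs * rng.lognormal(0.0, noise_sigma, len(genes))
        z_base = base.z * rng.lognormal(0.0, noise_sigma, len(mirnas))
        x_tum = x_base * gene_factor * rng.lognormal(0.0, noise_sigma, len(genes))
        z_tum = z_base * mirna_factor * rng.lognormal(0.0, noise_sigma, len(mirnas))
        cohort.append(CohortPair(
            pair_id=pid,
            normal=ExpressionPair(list(genes), list(mirnas), x_base, z_base,
                                  sample_id=f"{pid}_normal"),
            tumor=ExpressionPair(list(genes), list(mirnas), x_tum, z_tum,
                                 sample_id=f"{pid}_tumor"),
        ))
    return replace_dataset(base, cohort=cohort, planted=planted)


def replace_dataset(ds: SyntheticDataset, **kwargs) -> SyntheticDataset:
    return SyntheticDataset(
        C=ds.C, x_obs=ds.x_obs, z=ds.z, latent=ds.latent, truth=ds.truth,
        cohort=kwargs.get("cohort", ds.cohort),
        planted=kwargs.get("planted", ds.planted),
    )


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write a dataset as the TSV files the CLI pipeline consumes.

    Produces ``seeds.tsv`` (dense), ``mrna.tsv``/``mirna.tsv`` expression
    matrices (cohort samples if present, otherwise the single sample
    ``s1``), ``truth.tsv`` and, for cohorts, ``manifest.tsv`` and
    ``planted.tsv``.
    """
    from pathlib import Path

    from .seedmatch import write_seed_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_seed_matrix(ds.C, outdir / "seeds.tsv", dialect="dense_tsv")

    if ds.cohort:
        samples = []
        xcols, zcols = {}, {}
        manifest = []
        for cp in ds.cohort:
            for cond, ep in (("normal", cp.normal), ("tumor", cp.tumor)):
                samples.append(ep.sample_id)
                xcols[ep.sample_id] = ep.x_obs
                zcols[ep.sample_id] = ep.z
                manifest.append((ep.sample_id, cond, cp.pair_id))
        pd.DataFrame(xcols, index=ds.C.genes).to_csv(
            outdir / "mrna.tsv", sep="\t", index_label="feature")
        pd.DataFrame(zcols, index=ds.C.mirnas).to_csv(
            outdir / "mirna.tsv", sep="\t", index_label="feature")
        pd.DataFrame(manifest, columns=["sample_id", "condition", "pair_id"]).to_csv(
            outdir / "manifest.tsv", sep="\t", index=False)
        if ds.planted:
            pd.DataFrame(ds.planted, columns=["gene", "mirna", "direction"]).to_csv(
                outdir / "planted.tsv", sep="\t", index=False)
    else:
        pd.DataFrame({"s1": ds.x_obs}, index=ds.C.genes).to_csv(
            outdir / "mrna.tsv", sep="\t", index_label="feature")
        pd.DataFrame({"s1": ds.z}, index=ds.C.mirnas).to_csv(
            outdir / "mirna.tsv", sep="\t", index_label="feature")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("gene\tmirna\n")
        for g, m in sorted(ds.truth):
            fh.write(f"{g}\t{m}\n")
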