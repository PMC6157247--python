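"""Synthetic family-study generator.

Emulates the structure of a treatment-response family study: multi-member
pedigrees, gene-dropped genotypes, a pair of correlated log-scale phenotypes
(pre- and post-treatment levels) generated under the bivariate polygenic
model, causal SNPs at stated fractions of variance explained, an optional
four-visit expansion (two visits per treatment period with visit-level
noise calibrated to target correlations), and MCAR missingness.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from famimpute.panels import PhenotypePanel
from famimpute.pedigree_io import Individual, Pedigree, RelationshipMatrix
from famimpute.variance_components import VarianceComponents, build_joint_covariance
from famimpute.mvn_imputation import carryover_fill  # noqa: F401  (re-export convenience)

FAMILY_TEMPLATES = ("sib_pair", "nuclear_4", "three_gen_8")

#: default variance-explained ladder for the five causal SNPs
DEFAULT_CAUSAL_LADDER = (0.125, 0.10, 0.075, 0.05, 0.025)
DEFAULT_CAUSAL_MAF = 0.3

#: visit-level correlation targets: corr(visit1, visit2) within the
#: pre-treatment period, and corr between visits across periods
DEFAULT_VISIT_CORR_PRE = 0.9
DEFAULT_VISIT_CORR_CROSS = 0.8

#: post-treatment sample-level missingness emulating an incomplete study arm
#: of 563 complete samples out of 680
DEFAULT_MISSING_FRACTION = 117.0 / 680.0


def _default_causal_spec() -> list[tuple[float, float]]:
    return [(DEFAULT_CAUSAL_MAF, v) for v in DEFAULT_CAUSAL_LADDER]


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    Defaults reproduce the evaluation conditions used throughout the
    package: 170 nuclear families of 4 (680 samples), latent pre/post
    phenotype correlation 8/9 so the four-visit expansion hits visit
    correlations 0.9 (within pre-treatment) and 0.8 (across periods),
    heritability 0.5 per phenotype, five causal SNPs explaining 12.5%
    down to 2.5% of outcome variance, and ~17% post-treatment missingness.
    """

    n_families: int = 170
    family_template: str = "nuclear_4"
    n_null_snps: int = 100
    causal_spec: list[tuple[float, float]] = field(default_factory=_default_causal_spec)
    vc_true: VarianceComponents | None = None
    pheno_correlation_target: float = DEFAULT_VISIT_CORR_CROSS / DEFAULT_VISIT_CORR_PRE
    heritability: float = 0.5
    visit_corr_pre: float = DEFAULT_VISIT_CORR_PRE
    visit_corr_cross: float = DEFAULT_VISIT_CORR_CROSS
    missing_fraction: float = DEFAULT_MISSING_FRACTION
    missing_mechanism: str = "MCAR"
    n_missing_visit1: int = 4
    n_missing_visit2: int = 1
    n_replicates: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family_template not in FAMILY_TEMPLATES:
            raise ValueError(f"unknown family template {self.family_template!r}")
        if self.missing_mechanism != "MCAR":
            raise ValueError("only MCAR missingness is supported")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        total_v = sum(v for _, v in self.causal_spec)
        if total_v >= 1.0:
            raise ValueError("total causal variance explained must be < 1")
        for maf, _ in self.causal_spec:
            if not 0.0 < maf <= 0.5:
                raise ValueError("causal MAFs must be in (0, 0.5]")
        if not -1.0 < self.pheno_correlation_target < 1.0:
            raise ValueError("pheno_correlation_target must be in (-1, 1)")
        if self.vc_true is None:
            h2, rho = self.heritability, self.pheno_correlation_target
            R = np.array([[1.0, rho], [rho, 1.0]])
            self.vc_true = VarianceComponents(h2 * R, (1.0 - h2) * R)

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _template_members(fid: str, template: str) -> tuple[list[Individual], list[str]]:
    """Members of one family plus the ids of the phenotyped (sampled) subset."""
    p = lambda role: f"{fid}_{role}"  # noqa: E731
    if template == "sib_pair":
        inds = [
            Individual(p("f"), fid, sex="1"),
            Individual(p("m"), fid, sex="2"),
            Individual(p("s1"), fid, p("f"), p("m")),
            Individual(p("s2"), fid, p("f"), p("m")),
        ]
        sampled = [p("s1"), p("s2")]  # parents are pedigree scaffolding only
    elif template == "nuclear_4":
        inds = [
            Individual(p("f"), fid, sex="1"),
            Individual(p("m"), fid, sex="2"),
            Individual(p("c1"), fid, p("f"), p("m")),
            Individual(p("c2"), fid, p("f"), p("m")),
        ]
        sampled = [i.iid for i in inds]
    elif template == "three_gen_8":
        inds = [
            Individual(p("gf"), fid, sex="1"),
            Individual(p("gm"), fid, sex="2"),
            Individual(p("f"), fid, p("gf"), p("gm"), sex="1"),
            Individual(p("u"), fid, p("gf"), p("gm"), sex="1"),
            Individual(p("m"), fid, sex="2"),
            Individual(p("k1"), fid, p("f"), p("m")),
            Individual(p("k2"), fid, p("f"), p("m")),
            Individual(p("k3"), fid, p("f"), p("m")),
        ]
        sampled = [i.iid for i in inds]
    else:  # pragma: no cover
        raise ValueError(template)
    return inds, sampled


def simulate_pedigrees(config: SimulationConfig) -> Pedigree:
    """``n_families`` disjoint copies of the family template."""
    individuals: list[Individual] = []
    for k in range(config.n_families):
        inds, _ = _template_members(f"fam{k + 1:04d}", config.family_template)
        individuals.extend(inds)
    return Pedigree(individuals)


def sampled_ids(config: SimulationConfig) -> list[str]:
    """Ids of the phenotyped study sample (a subset of the pedigree for
    templates whose parents are scaffolding, e.g. ``sib_pair``)."""
    out: list[str] = []
    for k in range(config.n_families):
        _, sampled = _template_members(f"fam{k + 1:04d}", config.family_template)
        out.extend(sampled)
    return out


def gene_drop(
    ped: Pedigree,
    maf: float | np.ndarray,
    seed: int | np.random.Generator,
    n_snps: int | None = None,
) -> np.ndarray:
    """Gene-drop unlinked variants down the pedigree.

    Founder alleles are iid Bernoulli(maf); each child inherits one randomly
    chosen allele from each parent.  ``maf`` may be a scalar (with
    ``n_snps`` copies simulated) or a per-SNP array.  Returns additive
    dosages of shape (n_snps, len(ped)) in pedigree id order.
    """
    maf_arr = np.atleast_1d(np.asarray(maf, dtype=float))
    if n_snps is None:
        n_snps = len(maf_arr)
    if len(maf_arr) == 1:
        maf_arr = np.full(n_snps, maf_arr[0])
    if len(maf_arr) != n_snps:
        raise ValueError("maf array length must equal n_snps")
    if np.any(maf_arr <= 0.0) or np.any(maf_arr > 0.5):
        raise ValueError("maf must be in (0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    snp_ix = np.arange(n_snps)
    alleles: dict[str, np.ndarray] = {}
    for iid in ped.topological_order():
        ind = ped[iid]
        a = np.empty((n_snps, 2), dtype=np.int8)
        for slot, pid in enumerate((ind.father, ind.mother)):
            if pid is None:
                a[:, slot] = rng.random(n_snps) < maf_arr
            else:
                pick = rng.integers(0, 2, size=n_snps)
                a[:, slot] = alleles[pid][snp_ix, pick]
        alleles[iid] = a
    return np.stack([alleles[iid].sum(axis=1) for iid in ped.ids], axis=1).astype(float)


def _component_blocks(phi: RelationshipMatrix) -> list[np.ndarray]:
    from famimpute.variance_components import _phi_components

    return _phi_components(phi)


def _draw_mvn_blocked(
    vc: VarianceComponents, phi: RelationshipMatrix, rng: np.random.Generator
) -> np.ndarray:
    """Draw Y ~ MVN(0, Sigma_A (x) phi + Sigma_E (x) I), shape (2, n).

    Sampling is per family (connected component of phi), with the Cholesky
    factor cached across identical family blocks.
    """
    n = phi.n
    y = np.empty(2 * n)
    chol_cache: dict[bytes, np.ndarray] = {}
    for idx in _component_blocks(phi):
        m = len(idx)
        block = np.ascontiguousarray(phi.values[np.ix_(idx, idx)])
        key = block.tobytes()
        L = chol_cache.get(key)
        if L is None:
            sig = np.kron(vc.sigma_a, block) + np.kron(vc.sigma_e, np.eye(m))
            L = np.linalg.cholesky(sig + 1e-12 * np.trace(sig) / (2 * m) * np.eye(2 * m))
            chol_cache[key] = L
        z = L @ rng.standard_normal(2 * m)
        y[idx] = z[:m]
        y[idx + n] = z[m:]
    return y.reshape(2, n)


def outcome_variance(config: SimulationConfig, visits: bool) -> float:
    """Model-implied variance of the average-difference outcome, without
    causal-SNP contributions.

    For the bivariate (latent) mode this is Var(y1 - y2); the four-visit mode
    adds the averaged visit noise of each period.
    """
    t = config.vc_true.total
    v = t[0, 0] + t[1, 1] - 2.0 * t[0, 1]
    if visits:
        w_pre2, w_post2 = _visit_noise_variances(config)
        v += 0.5 * (w_pre2 + w_post2)
    return float(v)


def _visit_noise_variances(config: SimulationConfig) -> tuple[float, float]:
    """Visit-noise variances hitting the configured visit correlations.

    With latent variances s1^2, s2^2 and covariance s12, noise w_pre on each
    pre-treatment visit gives corr(v1, v2) = s1^2 / (s1^2 + w_pre^2); the
    cross-period visit correlation then pins w_post.  Raises on targets no
    noise level can reach.
    """
    t = config.vc_true.total
    s1, s2, s12 = t[0, 0], t[1, 1], t[0, 1]
    c_pre, c_cross = config.visit_corr_pre, config.visit_corr_cross
    if not 0.0 < c_pre <= 1.0 or not 0.0 < abs(c_cross) <= 1.0:
        raise ValueError("visit correlation targets must be in (0, 1]")
    w_pre2 = s1 * (1.0 / c_pre - 1.0)
    denom = c_cross**2 * (s1 + w_pre2)
    w_post2 = s12**2 / denom - s2
    if w_post2 < -1e-12:
        raise ValueError(
            f"infeasible correlation targets: cross-period visit correlation "
            f"{c_cross} exceeds what the latent covariance supports"
        )
    return float(w_pre2), float(max(w_post2, 0.0))


def causal_effect_sizes(config: SimulationConfig, visits: bool) -> np.ndarray:
    """Per-SNP allelic effects beta_j = sqrt(v_j * V / (2 maf_j (1 - maf_j))).

    ``V`` is the total outcome variance including all causal contributions,
    so each SNP's marginal variance explained is its configured v_j.
    """
    if not config.causal_spec:
        return np.empty(0)
    total_v = sum(v for _, v in config.causal_spec)
    v_total = outcome_variance(config, visits) / (1.0 - total_v)
    return np.array(
        [np.sqrt(v * v_total / (2.0 * maf * (1.0 - maf))) for maf, v in config.causal_spec]
    )


def simulate_phenotypes(
    phi: RelationshipMatrix,
    config: SimulationConfig,
    seed: int | np.random.Generator,
    causal_dosages: np.ndarray | None = None,
    visits: bool = False,
) -> PhenotypePanel | tuple[PhenotypePanel, pd.DataFrame]:
    """Draw the bivariate phenotype panel (and optionally a four-visit table).

    Phenotype 1 is the pre-treatment level, phenotype 2 the post-treatment
    level; both share the polygenic covariance Sigma_A (x) phi and
    environmental covariance Sigma_E (x) I.  Causal SNPs (rows of
    ``causal_dosages``, aligned with ``config.causal_spec``) lower the
    post-treatment level, so the difference outcome carries the effect.

    With ``visits=True`` also returns a table of four visits: two noisy
    replicates of each period calibrated so corr(visit1, visit2) and the
    cross-period visit correlation hit the configured targets.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = phi.n
    y = _draw_mvn_blocked(config.vc_true, phi, rng)
    if causal_dosages is not None and len(config.causal_spec) > 0:
        G = np.atleast_2d(np.asarray(causal_dosages, dtype=float))
        if G.shape != (len(config.causal_spec), n):
            raise ValueError("causal_dosages must be (n_causal, n) matching causal_spec")
        betas = causal_effect_sizes(config, visits)
        centered = G - 2.0 * np.array([maf for maf, _ in config.causal_spec])[:, None]
        y[1] -= betas @ centered
    panel = PhenotypePanel(list(phi.ids), y)
    if not visits:
        return panel
    w_pre2, w_post2 = _visit_noise_variances(config)
    noise = rng.standard_normal((4, n))
    table = pd.DataFrame(
        {
            "visit1": y[0] + np.sqrt(w_pre2) * noise[0],
            "visit2": y[0] + np.sqrt(w_pre2) * noise[1],
            "visit3": y[1] + np.sqrt(w_post2) * noise[2],
            "visit4": y[1] + np.sqrt(w_post2) * noise[3],
        },
        index=pd.Index(phi.ids, name="id"),
    )
    return panel, table


def apply_missingness(
    panel: PhenotypePanel,
    fraction: float,
    seed: int | np.random.Generator,
    phenotype: int = 2,
) -> PhenotypePanel:
    """Mask exactly round(fraction * n) entries of one phenotype, MCAR.

    Rounding is half-up (0.5 * 675 -> 338 masked).  Deterministic given the
    seed; already-missing entries may be re-selected (idempotent).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = panel.copy()
    k = int(np.floor(fraction * panel.n + 0.5))
    chosen = rng.choice(panel.n, size=k, replace=False)
    row = phenotype - 1
    out.values[row, chosen] = np.nan
    out.mask[row, chosen] = True
    return out


def pedigree_to_fam(ped: Pedigree, path) -> None:
    """Write the pedigree in PLINK .fam layout (missing parent/sex/pheno = 0/-9)."""
    with open(path, "w") as fh:
        for ind in ped.individuals:
            fh.write(
                f"{ind.fid}\t{ind.iid}\t{ind.father or '0'}\t{ind.mother or '0'}"
                f"\t{ind.sex or '0'}\t-9\n"
            )
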