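"""Bivariate polygenic variance components by maximum likelihood.

The model: the stacked phenotype vector Y (length 2n, phenotype-major) is
multivariate normal with mean mu and covariance

    Sigma = Sigma_A (x) phi + Sigma_E (x) I,

where Sigma_A and Sigma_E are the 2 x 2 additive-genetic and environmental
covariance matrices of the two phenotypes, phi is the genetic relationship
matrix, and (x) is the Kronecker product.  Missing phenotype entries enter
through the observed-data likelihood: the multivariate-normal density of the
observed sub-vector under the corresponding restriction of Sigma.

Estimation is ML (not REML) with the mean fixed at the per-phenotype observed
means, and the two covariance matrices parameterized by their Cholesky
factors with log-transformed diagonals so the search space is unconstrained
while every candidate is positive definite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from famimpute.panels import PhenotypePanel
from famimpute.pedigree_io import RelationshipMatrix

logger = logging.getLogger(__name__)

LOG2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """Raised when the likelihood optimization fails on every start."""


@dataclass
class VarianceComponents:
    """Additive-genetic (Sigma_A) and environmental (Sigma_E) 2 x 2 covariances.

    Both matrices are symmetric positive semidefinite; diagonals are the
    per-phenotype polygenic / environmental variances (squared phenotype
    units) and off-diagonals the corresponding covariances between the two
    phenotypes.
    """

    sigma_a: np.ndarray
    sigma_e: np.ndarray

    def __post_init__(self) -> None:
        self.sigma_a = np.asarray(self.sigma_a, dtype=float)
        self.sigma_e = np.asarray(self.sigma_e, dtype=float)
        for name, m in (("sigma_a", self.sigma_a), ("sigma_e", self.sigma_e)):
            if m.shape != (2, 2):
                raise ValueError(f"{name} must be 2 x 2, got {m.shape}")
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            scale = 1.0 + float(np.trace(m))
            if np.linalg.eigvalsh(m).min() < -1e-8 * scale:
                raise ValueError(f"{name} must be positive semidefinite")

    @property
    def total(self) -> np.ndarray:
        """Total phenotypic covariance Sigma_A + Sigma_E."""
        return self.sigma_a + self.sigma_e

    def heritability(self, k: int) -> float:
        """Narrow-sense heritability of phenotype k (1-based)."""
        i = k - 1
        tot = self.sigma_a[i, i] + self.sigma_e[i, i]
        return float(self.sigma_a[i, i] / tot) if tot > 0 else np.nan

    @property
    def phenotypic_correlation(self) -> float:
        t = self.total
        return float(t[0, 1] / np.sqrt(t[0, 0] * t[1, 1]))

    def to_flat_text(self, path, extra: dict | None = None) -> None:
        keys = {
            "sigmaA.11": self.sigma_a[0, 0],
            "sigmaA.12": self.sigma_a[0, 1],
            "sigmaA.22": self.sigma_a[1, 1],
            "sigmaE.11": self.sigma_e[0, 0],
            "sigmaE.12": self.sigma_e[0, 1],
            "sigmaE.22": self.sigma_e[1, 1],
        }
        if extra:
            keys.update(extra)
        with open(path, "w") as fh:
            for k, v in keys.items():
                fh.write(f"{k}\t{float(v)!r}\n")

    @classmethod
    def from_flat_text(cls, path) -> "VarianceComponents":
        kv: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    k, v = line.split("\t")
                    kv[k] = float(v)
        sa = np.array(
            [[kv["sigmaA.11"], kv["sigmaA.12"]], [kv["sigmaA.12"], kv["sigmaA.22"]]]
        )
        se = np.array(
            [[kv["sigmaE.11"], kv["sigmaE.12"]], [kv["sigmaE.12"], kv["sigmaE.22"]]]
        )
        return cls(sa, se)


@dataclass
class FittedVarianceComponents(VarianceComponents):
    """Variance components plus the converged log-likelihood and fit metadata."""

    loglik: float = np.nan
    n_obs: int = 0
    converged: bool = False
    n_starts: int = 0


@dataclass
class MeanVector:
    """Stacked mean vector: constant mu_k within each phenotype block."""

    mu_k: np.ndarray  # length 2: per-phenotype scalar means
    n: int

    def __post_init__(self) -> None:
        self.mu_k = np.asarray(self.mu_k, dtype=float)
        if self.mu_k.shape != (2,):
            raise ValueError("mu_k must have length 2")

    @property
    def mu(self) -> np.ndarray:
        """Length-2n phenotype-major vector (mu_1 block then mu_2 block)."""
        return np.repeat(self.mu_k, self.n)


@dataclass
class JointCovariance:
    """The 2n x 2n covariance Sigma = Sigma_A (x) phi + Sigma_E (x) I."""

    sigma: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != (2 * self.n, 2 * self.n):
            raise ValueError("sigma must be 2n x 2n")

    def block(self, k: int, l: int) -> np.ndarray:
        """Phenotype block (k, l), 1-based, each n x n."""
        n = self.n
        return self.sigma[(k - 1) * n : k * n, (l - 1) * n : l * n]


def build_joint_covariance(vc: VarianceComponents, phi: RelationshipMatrix) -> JointCovariance:
    """Assemble Sigma = Sigma_A (x) phi + Sigma_E (x) I (phenotype-major)."""
    n = phi.n
    sigma = np.kron(vc.sigma_a, phi.values) + np.kron(vc.sigma_e, np.eye(n))
    return JointCovariance(sigma, n)


def observed_means(panel: PhenotypePanel) -> MeanVector:
    """Per-phenotype arithmetic means over observed entries only."""
    mu_k = np.empty(2)
    for k in range(2):
        obs = ~panel.mask[k]
        if not obs.any():
            raise ValueError(f"phenotype {k + 1} has no observed values")
        mu_k[k] = panel.values[k, obs].mean()
    return MeanVector(mu_k, panel.n)


def _phi_components(phi: RelationshipMatrix) -> list[np.ndarray]:
    """Index sets of the connected components of phi's sparsity graph.

    Individuals in different components are unrelated (phi = 0 between them),
    so the likelihood factorizes over components — for pedigree-derived phi
    these are exactly the families.
    """
    adj = csr_matrix(np.abs(phi.values) > 1e-14)
    n_comp, labels = connected_components(adj, directed=False)
    return [np.flatnonzero(labels == c) for c in range(n_comp)]


def loglik(
    vc: VarianceComponents,
    mu: MeanVector,
    panel: PhenotypePanel,
    phi: RelationshipMatrix,
) -> float:
    """Observed-data Gaussian log-likelihood log N(Y_o; mu_o, Sigma_oo).

    Computed family by family (connected components of phi), which is exactly
    the dense restricted-covariance density because unrelated blocks
    contribute additively.  Returns -inf for a covariance that is not
    positive definite on the observed entries.
    """
    if phi.n != panel.n:
        raise ValueError("phi and panel have different numbers of individuals")
    n = panel.n
    resid_full = panel.y_stacked - mu.mu
    obs_full = ~panel.mask_stacked
    total = 0.0
    for idx in _phi_components(phi):
        stacked = np.concatenate([idx, idx + n])
        obs = obs_full[stacked]
        if not obs.any():
            continue
        phi_cc = phi.values[np.ix_(idx, idx)]
        m = len(idx)
        sig = np.kron(vc.sigma_a, phi_cc) + np.kron(vc.sigma_e, np.eye(m))
        sig_oo = sig[np.ix_(np.flatnonzero(obs), np.flatnonzero(obs))]
        r = resid_full[stacked][obs]
        try:
            L = np.linalg.cholesky(sig_oo)
        except np.linalg.LinAlgError:
            logger.debug("non-PSD observed covariance block; rejecting point")
            return -np.inf
        z = np.linalg.solve(L, r)
        total += -0.5 * (len(r) * LOG2PI + 2.0 * np.log(np.diag(L)).sum() + z @ z)
    return float(total)


class _LikelihoodMachine:
    """Precomputed structures for fast repeated observed-data likelihoods.

    Families (components of phi) are grouped by size and evaluated with
    batched Cholesky factorizations.  Missing entries are handled by zeroing
    their rows/columns and placing a unit on the diagonal with a zero
    residual, which leaves the observed-block determinant and quadratic form
    unchanged while keeping every family block the same shape.
    """

    def __init__(self, panel: PhenotypePanel, phi: RelationshipMatrix, mu: MeanVector):
        n = panel.n
        resid = np.nan_to_num(panel.y_stacked - mu.mu)
        obs_full = ~panel.mask_stacked
        groups: dict[int, list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}
        for idx in _phi_components(phi):
            stacked = np.concatenate([idx, idx + n])
            obs = obs_full[stacked]
            if not obs.any():
                continue
            groups.setdefault(len(idx), []).append(
                (phi.values[np.ix_(idx, idx)], obs, resid[stacked])
            )
        self.batches: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        for m, items in groups.items():
            phi_b = np.stack([t[0] for t in items])  # (g, m, m)
            obs_b = np.stack([t[1] for t in items])  # (g, 2m)
            r_b = np.stack([t[2] for t in items]) * obs_b  # zero residual at missing
            self.batches.append((phi_b, obs_b, r_b))
        self.n_obs = int(obs_full.sum())

    def loglik(self, sigma_a: np.ndarray, sigma_e: np.ndarray) -> float:
        total = -0.5 * self.n_obs * LOG2PI
        for phi_b, obs_b, r_b in self.batches:
            g, m, _ = phi_b.shape
            eye = np.eye(m)
            sig = np.empty((g, 2 * m, 2 * m))
            for k in range(2):
                for l in range(2):
                    sig[:, k * m : (k + 1) * m, l * m : (l + 1) * m] = (
                        sigma_a[k, l] * phi_b + sigma_e[k, l] * eye
                    )
            obs_outer = obs_b[:, :, None] & obs_b[:, None, :]
            sig = np.where(obs_outer, sig, 0.0)
            diag = np.einsum("gii->gi", sig)
            diag[~obs_b] = 1.0
            try:
                L = np.linalg.cholesky(sig)
            except np.linalg.LinAlgError:
                return -np.inf
            z = np.linalg.solve(L, r_b[:, :, None])[:, :, 0]
            ld = np.log(np.einsum("gii->gi", L)).sum()
            total += -0.5 * (2.0 * ld + float((z * z).sum()))
        return float(total)


def _theta_to_matrices(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log-Cholesky parameter vector -> (Sigma_A, Sigma_E)."""
    la = np.array([[np.exp(theta[0]), 0.0], [theta[1], np.exp(theta[2])]])
    le = np.array([[np.exp(theta[3]), 0.0], [theta[4], np.exp(theta[5])]])
    return la @ la.T, le @ le.T


def _matrices_to_theta(sigma_a: np.ndarray, sigma_e: np.ndarray) -> np.ndarray:
    theta = np.empty(6)
    for base, m in ((0, sigma_a), (3, sigma_e)):
        scale = 1.0 + float(np.trace(m))
        L = np.linalg.cholesky(m + 1e-8 * scale * np.eye(2))
        theta[base] = np.log(L[0, 0])
        theta[base + 1] = L[1, 0]
        theta[base + 2] = np.log(L[1, 1])
    return theta


def _moment_start(panel: PhenotypePanel, phi: RelationshipMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Split the complete-pairs sample covariance half-and-half as a start."""
    both = ~panel.mask[0] & ~panel.mask[1]
    if both.sum() >= 3:
        S = np.cov(panel.values[:, both])
    else:
        v = np.array(
            [
                np.nanvar(panel.values[0][~panel.mask[0]]) if (~panel.mask[0]).sum() > 1 else 1.0,
                np.nanvar(panel.values[1][~panel.mask[1]]) if (~panel.mask[1]).sum() > 1 else 1.0,
            ]
        )
        S = np.diag(np.maximum(v, 1e-6))
    S = np.asarray(S, dtype=float)
    # guard against degenerate / near-singular starts
    scale = max(float(np.trace(S)) / 2.0, 1e-6)
    if np.linalg.eigvalsh(S).min() < 1e-6 * scale:
        S = S + 0.05 * scale * np.eye(2)
    return 0.5 * S, 0.5 * S


def fit_bivariate_polygenic(
    panel: PhenotypePanel,
    phi: RelationshipMatrix,
    mu: MeanVector | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    gtol: float = 1e-6,
    maxiter: int = 500,
) -> FittedVarianceComponents:
    """ML fit of (Sigma_A, Sigma_E) from a possibly incomplete panel.

    Maximizes the observed-data likelihood over the log-Cholesky
    parameterization (6 free parameters) with a moment-based start plus
    ``n_restarts`` random restarts, using quasi-Newton (L-BFGS-B) steps.
    The mean is fixed at the per-phenotype observed means throughout.

    Raises :class:`ConvergenceError` if every start fails.  Warns when phi
    carries no relatedness information (phi = I), in which case only the sum
    Sigma_A + Sigma_E is identified.
    """
    if mu is None:
        mu = observed_means(panel)
    off = phi.values - np.diag(np.diag(phi.values))
    if np.abs(off).max(initial=0.0) < 1e-12:
        warnings.warn(
            "phi has no off-diagonal relatedness: only Sigma_A + Sigma_E is "
            "identified; the polygenic/environmental split is arbitrary",
            stacklevel=2,
        )
    machine = _LikelihoodMachine(panel, phi, mu)

    def objective(theta: np.ndarray) -> float:
        sa, se = _theta_to_matrices(theta)
        ll = machine.loglik(sa, se)
        return np.inf if not np.isfinite(ll) else -ll

    sa0, se0 = _moment_start(panel, phi)
    theta0 = _matrices_to_theta(sa0, se0)
    sd = np.sqrt(max(np.trace(sa0 + se0) / 2.0, 1e-8))
    lo, hi = np.log(sd) - 12.0, np.log(sd) + 6.0
    bounds = [(lo, hi), (-20.0 * sd, 20.0 * sd), (lo, hi)] * 2

    rng = np.random.default_rng(seed)
    starts = [theta0]
    for _ in range(n_restarts):
        starts.append(theta0 + rng.normal(scale=0.5, size=6))

    best: optimize.OptimizeResult | None = None
    n_ok = 0
    for t0 in starts:
        try:
            res = optimize.minimize(
                objective,
                np.clip(t0, [b[0] for b in bounds], [b[1] for b in bounds]),
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
            )
        except (np.linalg.LinAlgError, FloatingPointError):  # pragma: no cover
            continue
        if np.isfinite(res.fun):
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise ConvergenceError(
            f"variance-component optimization failed on all {len(starts)} starts "
            f"(n={panel.n}, n_obs={machine.n_obs})"
        )
    sa, se = _theta_to_matrices(best.x)
    return FittedVarianceComponents(
        sigma_a=0.5 * (sa + sa.T),
        sigma_e=0.5 * (se + se.T),
        loglik=float(-best.fun),
        n_obs=machine.n_obs,
        converged=bool(best.success),
        n_starts=n_ok,
    )
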