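"""Outcome construction and mixed-model score tests for SNP association.

The outcome is a treatment-response contrast of log-scale measurements:
``average_difference`` is mean(visit1, visit2) - mean(visit3, visit4) and
``single_difference`` is visit1 - visit3.  Association uses the linear mixed
model

    y = 1 * b0 + g * b + u + e,   u ~ N(0, tau * phi),  e ~ N(0, s2 * I),

fit by ML under the null (b = 0) once per outcome, then a 1-df chi-square
score test per SNP — the standard score-test economy where the null fit is
reused across all SNPs.  An eigendecomposition of phi makes each likelihood
evaluation O(n) after an O(n^3) setup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from famimpute.pedigree_io import RelationshipMatrix

OUTCOME_DEFINITIONS = ("average_difference", "single_difference")


@dataclass
class OutcomeVector:
    """Per-individual outcome values under a named contrast definition."""

    ids: list[str]
    values: np.ndarray
    definition: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids),):
            raise ValueError("values must be a vector matching ids")
        if self.definition not in OUTCOME_DEFINITIONS:
            raise ValueError(f"unknown outcome definition {self.definition!r}")


@dataclass
class AssociationResult:
    """Per-SNP score-test result.

    ``beta`` is the score-based effect estimate U/V (outcome units per
    allele) with standard error 1/sqrt(V); ``stat`` is the 1-df chi-square
    score statistic U^2/V and ``p`` its upper-tail probability.  Monomorphic
    SNPs yield ``p = nan`` with ``monomorphic = True`` rather than an error.
    """

    snp_id: str
    beta: float
    se: float
    stat: float
    p: float
    n_used: int
    monomorphic: bool = False


@dataclass
class NullModel:
    """ML null fit of y ~ N(1*b0, tau*phi + s2*I), reusable across SNPs."""

    ids: list[str]
    beta0: float
    tau: float
    sigma2: float
    loglik: float
    # rotated quantities: U'y etc. with phi = U diag(d) U'
    U: np.ndarray = field(repr=False)
    d: np.ndarray = field(repr=False)
    w: np.ndarray = field(repr=False)  # 1 / (tau*d + sigma2)
    resid_rot: np.ndarray = field(repr=False)  # U'(y - 1*b0)
    x_rot: np.ndarray = field(repr=False)  # U'1
    xtvx: float = field(repr=False)  # 1'V^-1 1

    @property
    def n(self) -> int:
        return len(self.ids)


def compute_outcome(visits: pd.DataFrame, definition: str) -> OutcomeVector:
    """Build the analysis outcome from a four-visit (log-scale) table.

    ``average_difference`` needs all four visits present (run imputation
    first); ``single_difference`` needs visits 1 and 3.
    """
    if definition == "average_difference":
        needed = ["visit1", "visit2", "visit3", "visit4"]
    elif definition == "single_difference":
        needed = ["visit1", "visit3"]
    else:
        raise ValueError(f"unknown outcome definition {definition!r}")
    for col in needed:
        if col not in visits.columns:
            raise ValueError(f"visits table lacks column {col!r}")
        if visits[col].isna().any():
            raise ValueError(
                f"column {col!r} has missing values; impute or drop before "
                "computing outcomes"
            )
    if definition == "average_difference":
        vals = (visits["visit1"] + visits["visit2"]) / 2.0 - (
            visits["visit3"] + visits["visit4"]
        ) / 2.0
    else:
        vals = visits["visit1"] - visits["visit3"]
    return OutcomeVector([str(i) for i in visits.index], vals.to_numpy(float), definition)


class PhiBasis:
    """Cached eigendecomposition of a relationship matrix.

    Building the basis is O(n^3); reuse it when fitting several outcomes on
    the same sample (e.g. across simulation replicates).
    """

    def __init__(self, phi: RelationshipMatrix):
        self.ids = list(phi.ids)
        d, U = np.linalg.eigh(phi.values)
        self.d = np.clip(d, 0.0, None)
        self.U = U


def fit_null_model(
    outcome: OutcomeVector,
    phi: RelationshipMatrix | None = None,
    basis: PhiBasis | None = None,
) -> NullModel:
    """ML fit of the intercept-only mixed model with a pedigree random effect.

    Profiles the intercept and total scale out of the likelihood and
    maximizes over the single variance ratio lam = tau / s2 on a log grid
    refined by Brent's method.  When phi = I the ratio is unidentified and
    is pinned at lam = 0 (all variance residual).
    """
    if basis is None:
        if phi is None:
            raise ValueError("provide phi or a precomputed basis")
        basis = PhiBasis(phi)
    if list(basis.ids) != list(outcome.ids):
        raise ValueError("outcome and phi id orderings differ")
    y = outcome.values
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 individuals")
    if np.var(y) <= 0:
        raise ValueError("outcome is constant; variance components are degenerate")
    d, U = basis.d, basis.U
    y_rot = U.T @ y
    x_rot = U.T @ np.ones(n)

    def profile_negll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        v = lam * d + 1.0
        w = 1.0 / v
        xtwx = (x_rot * w) @ x_rot
        beta = (x_rot * w) @ y_rot / xtwx
        r = y_rot - beta * x_rot
        s2 = (r * w) @ r / n
        return 0.5 * (n * (np.log(2 * np.pi * s2) + 1.0) + np.log(v).sum())

    if d.max() - d.min() < 1e-12:
        # phi proportional to I: flat in lam; pin at 0
        log_lam_hat = -np.inf
        lam = 0.0
    else:
        grid = np.linspace(-8.0, 8.0, 17)
        vals = [profile_negll(g) for g in grid]
        k = int(np.argmin(vals))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            profile_negll, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        # allow the boundary lam -> 0 to win if it is as good
        if profile_negll(-30.0) <= res.fun + 1e-10:
            log_lam_hat = -np.inf
            lam = 0.0
        else:
            log_lam_hat = float(res.x)
            lam = float(np.exp(log_lam_hat))
    v = lam * d + 1.0
    w_unit = 1.0 / v
    xtwx = (x_rot * w_unit) @ x_rot
    beta0 = float((x_rot * w_unit) @ y_rot / xtwx)
    r = y_rot - beta0 * x_rot
    s2 = float((r * w_unit) @ r / n)
    tau = lam * s2
    ll = -0.5 * (n * np.log(2 * np.pi * s2) + np.log(v).sum() + n)
    return NullModel(
        ids=list(outcome.ids),
        beta0=beta0,
        tau=tau,
        sigma2=s2,
        loglik=float(ll),
        U=U,
        d=d,
        w=w_unit / s2,  # 1 / (tau d + s2)
        resid_rot=r,
        x_rot=x_rot,
        xtvx=xtwx / s2,
    )


def _score_from_rot(null: NullModel, g_rot: np.ndarray) -> tuple[float, float]:
    """Score U and its null variance V for a rotated genotype vector."""
    wg = null.w * g_rot
    u = float(wg @ null.resid_rot)
    gvg = float(wg @ g_rot)
    gvx = float(wg @ null.x_rot)
    v = gvg - gvx * gvx / null.xtvx
    return u, v


def score_test(null: NullModel, dosage: np.ndarray, snp_id: str = "snp") -> AssociationResult:
    """1-df chi-square score test of a single SNP against the null fit."""
    g = np.asarray(dosage, dtype=float)
    if g.shape != (null.n,):
        raise ValueError("dosage length must match the null-model sample")
    if np.nanmin(g) < -1e-9 or np.nanmax(g) > 2.0 + 1e-9:
        raise ValueError("dosages must lie in [0, 2]")
    if np.var(g) <= 0:
        return AssociationResult(snp_id, np.nan, np.nan, np.nan, np.nan, null.n, True)
    u, v = _score_from_rot(null, null.U.T @ g)
    stat = u * u / v
    p = float(chi2.sf(stat, df=1))
    p = max(p, np.finfo(float).tiny)  # p in (0, 1]
    return AssociationResult(
        snp_id, beta=u / v, se=1.0 / np.sqrt(v), stat=float(stat), p=p, n_used=null.n
    )


def score_test_batch(
    null: NullModel, dosages: np.ndarray, snp_ids: list[str] | None = None
) -> pd.DataFrame:
    """Vectorized score tests for a (n_snps, n) dosage matrix.

    Returns a DataFrame with columns snp, beta, se, stat, p, n (the TSV
    layout the CLI writes).  Monomorphic SNPs get p = NaN.
    """
    G = np.asarray(dosages, dtype=float)
    if G.ndim != 2 or G.shape[1] != null.n:
        raise ValueError("dosages must be (n_snps, n)")
    if snp_ids is None:
        snp_ids = [f"snp{i + 1}" for i in range(G.shape[0])]
    G_rot = G @ null.U  # rows: U'g
    WG = G_rot * null.w
    u = WG @ null.resid_rot
    gvg = np.einsum("ij,ij->i", WG, G_rot)
    gvx = WG @ null.x_rot
    v = gvg - gvx * gvx / null.xtvx
    poly = G.var(axis=1) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(poly, u * u / v, np.nan)
        beta = np.where(poly, u / v, np.nan)
        se = np.where(poly, 1.0 / np.sqrt(v), np.nan)
    p = np.where(poly, np.maximum(chi2.sf(stat, df=1), np.finfo(float).tiny), np.nan)
    return pd.DataFrame(
        {"snp": snp_ids, "beta": beta, "se": se, "stat": stat, "p": p, "n": null.n}
    )
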