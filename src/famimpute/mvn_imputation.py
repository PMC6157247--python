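"""Conditional-mean imputation of missing phenotype entries.

The stacked phenotype vector is partitioned into missing and observed blocks,

    (Y_m, Y_o) ~ MVN((mu_m, mu_o), [[S_mm, S_mo], [S_om, S_oo]]),

and each missing entry is replaced by its conditional expectation

    E(Y_m | Y_o) = mu_m + S_mo S_oo^{-1} (Y_o - mu_o).

This is deterministic single imputation: downstream analyses see point
values, not draws, and the conditional variance is exposed as a diagnostic
only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from famimpute.panels import MISSING_CODE, PhenotypePanel
from famimpute.pedigree_io import RelationshipMatrix
from famimpute.variance_components import (
    JointCovariance,
    MeanVector,
    VarianceComponents,
    build_joint_covariance,
    observed_means,
)

__all__ = [
    "PhenotypePanel",
    "ImputedPanel",
    "Blocks",
    "partition_blocks",
    "conditional_mean",
    "conditional_variance",
    "impute_panel",
    "carryover_fill",
]

PROVENANCE_OBSERVED = "observed"
PROVENANCE_MVN = "mvn_imputed"
PROVENANCE_CARRYOVER = "carryover_filled"


class SingularCovarianceError(np.linalg.LinAlgError):
    """Observed-block covariance not invertible even after jitter escalation."""


@dataclass
class ImputedPanel:
    """A completed 2 x n phenotype table with per-entry provenance.

    ``provenance`` entries are one of ``observed``, ``mvn_imputed`` or
    ``carryover_filled``; observed entries are bit-identical to the input.
    ``conditional_sd`` holds the conditional standard deviation of each
    imputed entry (NaN where observed) as an accuracy diagnostic.
    """

    ids: list[str]
    values: np.ndarray
    provenance: np.ndarray
    conditional_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.isnan(self.values).any():
            raise ValueError("imputed panel must not contain missing values")

    def to_panel(self) -> PhenotypePanel:
        return PhenotypePanel(list(self.ids), self.values.copy())

    def to_tsv(self, path, pheno_names: tuple[str, str] = ("pheno1", "pheno2")) -> None:
        """Write values; provenance goes to a sibling ``<path>.provenance.tsv``."""
        self.to_panel().to_tsv(path, pheno_names)
        prov = pd.DataFrame(
            {
                "id": self.ids,
                pheno_names[0]: self.provenance[0],
                pheno_names[1]: self.provenance[1],
            }
        )
        prov.to_csv(f"{path}.provenance.tsv", sep="\t", index=False)


class Blocks(NamedTuple):
    mu_m: np.ndarray
    mu_o: np.ndarray
    sigma_mm: np.ndarray
    sigma_mo: np.ndarray
    sigma_oo: np.ndarray
    y_o: np.ndarray
    idx_m: np.ndarray  # positions of missing entries in the stacked vector
    idx_o: np.ndarray


def partition_blocks(panel: PhenotypePanel, mu: MeanVector, cov: JointCovariance) -> Blocks:
    """Extract the missing/observed partition of (mu, Sigma, Y).

    Within each block the original stacked-Y ordering is preserved, so
    reassembling the blocks reproduces the inputs exactly.
    """
    if cov.n != panel.n or mu.n != panel.n:
        raise ValueError("panel, mean vector and covariance must share n")
    miss = panel.mask_stacked
    if miss.all():
        raise ValueError("no observed entries to condition on")
    idx_m = np.flatnonzero(miss)
    idx_o = np.flatnonzero(~miss)
    mu_full = mu.mu
    return Blocks(
        mu_m=mu_full[idx_m],
        mu_o=mu_full[idx_o],
        sigma_mm=cov.sigma[np.ix_(idx_m, idx_m)],
        sigma_mo=cov.sigma[np.ix_(idx_m, idx_o)],
        sigma_oo=cov.sigma[np.ix_(idx_o, idx_o)],
        y_o=panel.y_stacked[idx_o],
        idx_m=idx_m,
        idx_o=idx_o,
    )


def _factor_with_jitter(sigma_oo: np.ndarray, max_steps: int = 3):
    """Cholesky of S_oo with escalating diagonal jitter if singular.

    Starts at 1e-8 * mean(diag) and multiplies by 10 for at most
    ``max_steps`` escalations before giving up.
    """
    try:
        return cho_factor(sigma_oo, lower=True)
    except np.linalg.LinAlgError:
        pass
    base = 1e-8 * float(np.mean(np.diag(sigma_oo)))
    if base <= 0:
        base = 1e-12
    for step in range(max_steps):
        jitter = base * 10.0**step
        try:
            return cho_factor(sigma_oo + jitter * np.eye(len(sigma_oo)), lower=True)
        except np.linalg.LinAlgError:
            continue
    raise SingularCovarianceError(
        "observed-block covariance is numerically singular after jitter escalation"
    )


def conditional_mean(
    mu_m: np.ndarray,
    mu_o: np.ndarray,
    sigma_mo: np.ndarray,
    sigma_oo: np.ndarray,
    y_o: np.ndarray,
) -> np.ndarray:
    """E(Y_m | Y_o) = mu_m + S_mo S_oo^{-1} (Y_o - mu_o).

    S_oo is handled through a symmetric (Cholesky) factorization rather than
    an explicit inverse, with a small escalating diagonal jitter if the
    factorization fails.
    """
    if len(mu_m) == 0:
        return np.empty(0)
    factor = _factor_with_jitter(np.asarray(sigma_oo, dtype=float))
    w = cho_solve(factor, np.asarray(y_o, dtype=float) - np.asarray(mu_o, dtype=float))
    return np.asarray(mu_m, dtype=float) + np.asarray(sigma_mo, dtype=float) @ w


def conditional_variance(
    sigma_mm: np.ndarray, sigma_mo: np.ndarray, sigma_oo: np.ndarray
) -> np.ndarray:
    """Conditional covariance S_mm - S_mo S_oo^{-1} S_om (diagnostic)."""
    if len(sigma_mm) == 0:
        return np.empty((0, 0))
    factor = _factor_with_jitter(np.asarray(sigma_oo, dtype=float))
    return sigma_mm - sigma_mo @ cho_solve(factor, np.asarray(sigma_mo, dtype=float).T)


def impute_panel(
    panel: PhenotypePanel,
    vc: VarianceComponents,
    phi: RelationshipMatrix,
    mu: MeanVector | None = None,
) -> ImputedPanel:
    """Complete a panel by conditional-mean imputation of every missing entry.

    Observed entries pass through untouched; each missing entry receives its
    conditional expectation given all observed phenotypes of the individual
    and of every relative, under Sigma = Sigma_A (x) phi + Sigma_E (x) I.
    """
    if phi.n != panel.n:
        raise ValueError("phi and panel have different numbers of individuals")
    if list(phi.ids) != list(panel.ids):
        raise ValueError("phi and panel id orderings differ")
    if mu is None:
        mu = observed_means(panel)
    n = panel.n
    values = panel.values.copy()
    provenance = np.full((2, n), PROVENANCE_OBSERVED, dtype=object)
    cond_sd = np.full((2, n), np.nan)
    if not panel.mask.any():
        return ImputedPanel(list(panel.ids), values, provenance, cond_sd)
    cov = build_joint_covariance(vc, phi)
    blocks = partition_blocks(panel, mu, cov)
    try:
        imputed = conditional_mean(
            blocks.mu_m, blocks.mu_o, blocks.sigma_mo, blocks.sigma_oo, blocks.y_o
        )
        cvar = conditional_variance(blocks.sigma_mm, blocks.sigma_mo, blocks.sigma_oo)
    except SingularCovarianceError as e:
        offenders = sorted({panel.ids[i % n] for i in blocks.idx_m})
        raise SingularCovarianceError(
            f"{e} (individuals with missing data: {offenders[:10]}...)"
        ) from None
    flat = values.reshape(-1)
    flat[blocks.idx_m] = imputed
    prov_flat = provenance.reshape(-1)
    prov_flat[blocks.idx_m] = PROVENANCE_MVN
    sd_flat = cond_sd.reshape(-1)
    sd_flat[blocks.idx_m] = np.sqrt(np.clip(np.diag(cvar), 0.0, None))
    return ImputedPanel(list(panel.ids), values, provenance, cond_sd)


def carryover_fill(visits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing visit-1 values from visit 2 and vice versa.

    For near-complete early visits this deterministic carry-over is the
    stated pre-processing step before model-based imputation of the late
    visits.  ``visits`` must carry columns ``visit1`` and ``visit2`` (other
    columns pass through untouched).  A sample missing both visit 1 and
    visit 2 violates the method's precondition and raises ``ValueError``.

    Returns the filled table and a same-shaped provenance table.
    """
    for col in ("visit1", "visit2"):
        if col not in visits.columns:
            raise ValueError(f"visits table must have a {col!r} column")
    out = visits.copy()
    prov = pd.DataFrame(
        PROVENANCE_OBSERVED, index=visits.index, columns=visits.columns, dtype=object
    )
    v1_na = out["visit1"].isna()
    v2_na = out["visit2"].isna()
    both = v1_na & v2_na
    if both.any():
        raise ValueError(
            f"samples missing both visit 1 and visit 2: {list(visits.index[both])[:10]}"
        )
    out.loc[v1_na, "visit1"] = out.loc[v1_na, "visit2"]
    prov.loc[v1_na, "visit1"] = PROVENANCE_CARRYOVER
    out.loc[v2_na, "visit2"] = out.loc[v2_na, "visit1"]
    prov.loc[v2_na, "visit2"] = PROVENANCE_CARRYOVER
    return out, prov


def read_visits_tsv(path) -> pd.DataFrame:
    """Read a four-visit phenotype table (columns id, visit1..visit4, NA code)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str}, na_values=[MISSING_CODE])
    if "id" not in df.columns:
        raise ValueError(f"{path}: expected an 'id' column")
    return df.set_index("id")


def write_visits_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep=MISSING_CODE, index_label="id")
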