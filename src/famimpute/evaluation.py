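"""Simulation-based evaluation drivers: type-I error, power, imputation MSE.

Each driver runs the honest end-to-end pipeline on synthetic family data —
simulate, (carry-over fill), re-estimate variance components, impute, test —
and compares the "incomplete" analysis (drop samples with missing
post-treatment data) against the "imputed" analysis (complete the panel by
conditional-mean imputation) over replicated datasets.  Every reported rate
carries a Monte-Carlo standard error, and summaries are deterministic given
(config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from famimpute.association import (
    PhiBasis,
    compute_outcome,
    fit_null_model,
    score_test_batch,
)
from famimpute.mvn_imputation import carryover_fill, impute_panel
from famimpute.panels import PhenotypePanel
from famimpute.pedigree_io import RelationshipMatrix, compute_phi
from famimpute.synthetic_data import (
    SimulationConfig,
    apply_missingness,
    gene_drop,
    sampled_ids,
    simulate_pedigrees,
    simulate_phenotypes,
)
from famimpute.variance_components import VarianceComponents, fit_bivariate_polygenic

ARMS = ("incomplete", "imputed")
OUTCOMES = ("average_difference", "single_difference")

DEFAULT_TYPE1_ALPHAS = (0.05, 1e-3, 1e-4)
DEFAULT_POWER_ALPHAS = (0.01, 1e-4)


@dataclass
class EvaluationSummary:
    """Result of one evaluation design.

    ``estimates`` is a tidy table (one row per design cell) whose ``rate`` /
    ``mse`` column carries the Monte-Carlo estimate and ``mc_se`` its
    standard error; ``per_replicate`` holds per-replicate diagnostics.
    """

    design: str
    grid: dict
    estimates: pd.DataFrame
    n_replicates: int
    per_replicate: pd.DataFrame | None = None

    def to_tsv(self, path) -> None:
        self.estimates.to_csv(path, sep="\t", index=False)


def _binomial_se(p_hat: float, n: int) -> float:
    return float(np.sqrt(max(p_hat * (1.0 - p_hat), 0.0) / n))


def _mask_visits(
    visits: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Apply the study's missingness pattern to a four-visit table.

    A sample-level MCAR fraction loses both post-treatment visits; a handful
    of early-visit values (disjoint samples for visits 1 and 2, so the
    carry-over precondition holds) go missing as well.
    """
    out = visits.copy()
    n = len(out)
    k = int(np.floor(config.missing_fraction * n + 0.5))
    miss_post = rng.choice(n, size=k, replace=False)
    out.iloc[miss_post, out.columns.get_loc("visit3")] = np.nan
    out.iloc[miss_post, out.columns.get_loc("visit4")] = np.nan
    n_early = config.n_missing_visit1 + config.n_missing_visit2
    if n_early > 0:
        early = rng.choice(n, size=min(n_early, n), replace=False)
        out.iloc[early[: config.n_missing_visit1], out.columns.get_loc("visit1")] = np.nan
        out.iloc[early[config.n_missing_visit1 :], out.columns.get_loc("visit2")] = np.nan
    return out


def _panel_for_outcome(visits: pd.DataFrame, outcome: str) -> PhenotypePanel:
    """Two-phenotype panel feeding imputation for a given outcome definition.

    ``average_difference`` pairs the period means ((v1+v2)/2, (v3+v4)/2);
    ``single_difference`` pairs (v1, v3).  Post-treatment entries are missing
    wherever any contributing visit is.
    """
    ids = [str(i) for i in visits.index]
    if outcome == "average_difference":
        ph1 = ((visits["visit1"] + visits["visit2"]) / 2.0).to_numpy(float)
        ph2 = ((visits["visit3"] + visits["visit4"]) / 2.0).to_numpy(float)
    elif outcome == "single_difference":
        ph1 = visits["visit1"].to_numpy(float)
        ph2 = visits["visit3"].to_numpy(float)
    else:
        raise ValueError(outcome)
    return PhenotypePanel(ids, np.vstack([ph1, ph2]))


def _completed_visits(visits_imp: pd.DataFrame, outcome: str, completed: np.ndarray) -> pd.DataFrame:
    """Rebuild a complete four-visit table from the imputed panel values."""
    out = visits_imp.copy()
    if outcome == "average_difference":
        # distribute the imputed period mean to both missing visits
        miss = out["visit3"].isna() | out["visit4"].isna()
        out.loc[miss, "visit3"] = completed[1][miss.to_numpy()]
        out.loc[miss, "visit4"] = completed[1][miss.to_numpy()]
    else:
        miss = out["visit3"].isna()
        out.loc[miss, "visit3"] = completed[1][miss.to_numpy()]
    return out


def _rejection_pipeline(
    visits_masked: pd.DataFrame,
    phi: RelationshipMatrix,
    basis_full: PhiBasis,
    G: np.ndarray,
    outcome: str,
    arm: str,
    fit_seed: int,
    fit_restarts: int,
) -> np.ndarray:
    """p-values for all SNP columns of G under one (arm, outcome) analysis."""
    visits_filled, _ = carryover_fill(visits_masked)
    if arm == "incomplete":
        keep = (~visits_filled[["visit3", "visit4"]].isna().any(axis=1)).to_numpy()
        sub = visits_filled.loc[keep]
        phi_sub = phi.subset([str(i) for i in sub.index])
        out_vec = compute_outcome(sub, outcome)
        null = fit_null_model(out_vec, phi_sub)
        return score_test_batch(null, G[:, keep])["p"].to_numpy()
    panel = _panel_for_outcome(visits_filled, outcome)
    vc = fit_bivariate_polygenic(panel, phi, n_restarts=fit_restarts, seed=fit_seed)
    imputed = impute_panel(panel, vc, phi)
    completed = _completed_visits(visits_filled, outcome, imputed.values)
    out_vec = compute_outcome(completed, outcome)
    null = fit_null_model(out_vec, basis=basis_full)
    return score_test_batch(null, G)["p"].to_numpy()


def _run_rejections(
    config: SimulationConfig,
    seed: int,
    n_replicates: int,
    alphas: tuple[float, ...],
    causal: bool,
    n_null_snps: int,
    fit_restarts: int,
    outcomes: tuple[str, ...] = OUTCOMES,
    arms: tuple[str, ...] = ARMS,
) -> EvaluationSummary:
    """Shared engine behind :func:`run_type1` and :func:`run_power`."""
    ped = simulate_pedigrees(config)
    ids = sampled_ids(config)
    pos = {iid: k for k, iid in enumerate(ped.ids)}
    sample_idx = np.array([pos[i] for i in ids])
    phi = compute_phi(ped).subset(ids)
    basis_full = PhiBasis(phi)

    if causal:
        snp_ids = [f"causal{j + 1}_v{v}" for j, (_, v) in enumerate(config.causal_spec)]
    else:
        snp_ids = [f"null{j + 1}" for j in range(n_null_snps)]

    pvals: dict[tuple[str, str], list[np.ndarray]] = {
        (arm, oc): [] for arm in arms for oc in outcomes
    }
    rep_rows = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        if causal:
            G_ped = gene_drop(ped, np.array([maf for maf, _ in config.causal_spec]), rng)
            G = G_ped[:, sample_idx]
            _, visits = simulate_phenotypes(
                phi, config, rng, causal_dosages=G, visits=True
            )
        else:
            mafs = rng.uniform(0.05, 0.5, size=n_null_snps)
            G_ped = gene_drop(ped, mafs, rng)
            G = G_ped[:, sample_idx]
            cfg_null = config.with_(causal_spec=[])
            _, visits = simulate_phenotypes(phi, cfg_null, rng, visits=True)
        visits_masked = _mask_visits(visits, config, rng)
        for arm in arms:
            for oc in outcomes:
                p = _rejection_pipeline(
                    visits_masked,
                    phi,
                    basis_full,
                    G,
                    oc,
                    arm,
                    fit_seed=rep,
                    fit_restarts=fit_restarts,
                )
                pvals[(arm, oc)].append(p)
                for alpha in alphas:
                    rep_rows.append(
                        {
                            "replicate": rep,
                            "arm": arm,
                            "outcome": oc,
                            "alpha": alpha,
                            "rate": float(np.mean(p < alpha)),
                        }
                    )

    rows = []
    for (arm, oc), plist in pvals.items():
        P = np.stack(plist)  # (reps, n_snps)
        for alpha in alphas:
            if causal:
                for j, sid in enumerate(snp_ids):
                    r = float(np.mean(P[:, j] < alpha))
                    rows.append(
                        {
                            "snp": sid,
                            "variance_explained": config.causal_spec[j][1],
                            "arm": arm,
                            "outcome": oc,
                            "alpha": alpha,
                            "rate": r,
                            "mc_se": _binomial_se(r, n_replicates),
                            "n_tests": n_replicates,
                        }
                    )
            else:
                r = float(np.mean(P < alpha))
                rows.append(
                    {
                        "arm": arm,
                        "outcome": oc,
                        "alpha": alpha,
                        "rate": r,
                        "mc_se": _binomial_se(r, P.size),
                        "n_tests": P.size,
                    }
                )
    return EvaluationSummary(
        design="power" if causal else "type1",
        grid={
            "alphas": list(alphas),
            "arms": list(arms),
            "outcomes": list(outcomes),
            "ladder": [v for _, v in config.causal_spec] if causal else [],
        },
        estimates=pd.DataFrame(rows),
        n_replicates=n_replicates,
        per_replicate=pd.DataFrame(rep_rows),
    )


def run_type1(
    config: SimulationConfig,
    seed: int = 0,
    n_replicates: int | None = None,
    n_null_snps: int | None = None,
    alphas: tuple[float, ...] = DEFAULT_TYPE1_ALPHAS,
    fit_restarts: int = 2,
    outcomes: tuple[str, ...] = OUTCOMES,
    arms: tuple[str, ...] = ARMS,
) -> EvaluationSummary:
    """Empirical type-I error of the incomplete and imputed analyses.

    Null SNPs are gene-dropped independently of the phenotypes; rejection
    fractions are pooled over replicates per (arm, outcome, alpha) cell,
    with per-replicate rates kept as diagnostics.
    """
    if n_replicates is None:
        n_replicates = config.n_replicates
    if n_null_snps is None:
        n_null_snps = config.n_null_snps
    if n_replicates * n_null_snps == 0:
        raise ValueError("need at least one replicate and one null SNP")
    return _run_rejections(
        config,
        seed,
        n_replicates,
        alphas,
        causal=False,
        n_null_snps=n_null_snps,
        fit_restarts=fit_restarts,
        outcomes=outcomes,
        arms=arms,
    )


def run_power(
    config: SimulationConfig,
    seed: int = 0,
    n_replicates: int | None = None,
    alphas: tuple[float, ...] = DEFAULT_POWER_ALPHAS,
    fit_restarts: int = 2,
    outcomes: tuple[str, ...] = OUTCOMES,
    arms: tuple[str, ...] = ARMS,
) -> EvaluationSummary:
    """Power across the causal variance-explained ladder, per arm and outcome."""
    if not config.causal_spec:
        raise ValueError("config.causal_spec is empty; nothing to evaluate")
    if n_replicates is None:
        n_replicates = config.n_replicates
    return _run_rejections(
        config,
        seed,
        n_replicates,
        alphas,
        causal=True,
        n_null_snps=0,
        fit_restarts=fit_restarts,
        outcomes=outcomes,
        arms=arms,
    )


def run_mse(
    config: SimulationConfig | None = None,
    seed: int = 0,
    n_samples: int = 675,
    missing_fractions: tuple[float, ...] = (0.2, 0.5, 0.8),
    correlations: tuple[float, ...] = (0.9, 0.8),
    n_replicates: int | None = None,
    fit_restarts: int = 1,
) -> EvaluationSummary:
    """Masked-entry imputation accuracy on unrelated samples.

    For each (correlation, missing fraction) cell: draw a bivariate panel
    with the given between-phenotype correlation and unit variances, hide
    the stated fraction of phenotype-2 values, re-estimate the covariance
    from the masked data, impute, and average (truth - imputed)^2 over the
    hidden entries.  With unrelated individuals and unit variances the
    population benchmark is MSE = 1 - rho^2.
    """
    if config is None:
        config = SimulationConfig()
    if n_replicates is None:
        n_replicates = config.n_replicates
    for f in missing_fractions:
        if not 0.0 < f < 1.0:
            raise ValueError("missing fractions must be in (0, 1)")
    ids = [f"s{i + 1}" for i in range(n_samples)]
    phi = RelationshipMatrix(ids, np.eye(n_samples))
    rows = []
    rep_rows = []
    for rho in correlations:
        vc_rho = VarianceComponents(
            np.zeros((2, 2)), np.array([[1.0, rho], [rho, 1.0]])
        )
        cfg = config.with_(vc_true=vc_rho, causal_spec=[])
        for frac in missing_fractions:
            errs = []
            for rep in range(n_replicates):
                rng = np.random.default_rng([seed, int(round(rho * 100)), int(round(frac * 100)), rep])
                panel = simulate_phenotypes(phi, cfg, rng)
                masked = apply_missingness(panel, frac, rng, phenotype=2)
                hidden = masked.mask[1] & ~panel.mask[1]
                if not hidden.any():
                    raise ValueError("empty mask: no entries were hidden")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # phi = I identifiability note
                    vc_hat = fit_bivariate_polygenic(
                        masked, phi, n_restarts=fit_restarts, seed=rep
                    )
                imputed = impute_panel(masked, vc_hat, phi)
                err = float(
                    np.mean((imputed.values[1, hidden] - panel.values[1, hidden]) ** 2)
                )
                errs.append(err)
                rep_rows.append(
                    {"replicate": rep, "correlation": rho, "missing_fraction": frac, "mse": err}
                )
            errs_arr = np.asarray(errs)
            rows.append(
                {
                    "correlation": rho,
                    "missing_fraction": frac,
                    "mse": float(errs_arr.mean()),
                    "mc_se": float(errs_arr.std(ddof=1) / np.sqrt(len(errs_arr)))
                    if len(errs_arr) > 1
                    else np.nan,
                    "n_replicates": len(errs_arr),
                }
            )
    return EvaluationSummary(
        design="mse",
        grid={"correlations": list(correlations), "missing_fractions": list(missing_fractions)},
        estimates=pd.DataFrame(rows),
        n_replicates=n_replicates,
        per_replicate=pd.DataFrame(rep_rows),
    )
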