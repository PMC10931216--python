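"""End-to-end pipeline: prune → diversity → climate join → screening →
RCCA (+ permutation inference) → regularization tuning → report bundle.

The bundle mirrors the tables a canonical-correlation study reports:
descriptive statistics, within- and between-set Pearson correlations, the
four multivariate criteria with F approximations, canonical correlations
with redundancy coefficients, the per-root Wilks sequence, univariate
OLS F-tests of each diversity variable on the climate block, and the
eigenvalue / explained-variability breakdown.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import climate, diversity, rcca, screening, tuning
from .pedigree import Pedigree, load_pedigree, prune_study_set

logger = logging.getLogger(__name__)

#: diversity variables entering the analysis matrix (before screening)
DIVERSITY_VARS = [
    "F", "AR", "meanC", "alpha", "GCI",
    "max_gen", "complete_gen", "equiv_gen", "delta_F", "offspring",
]


@dataclass
class RunConfig:
    pedigree_path: str | Path
    weather_path: str | Path
    out_dir: str | Path | None = None
    home_country: str | None = "ES"
    join_policy: str = "exact"
    vif_threshold: float = 5.0
    rout_q: float = 0.01
    grid_size: int = 10
    k_folds: int = 10
    permutations: int = 499
    seed: int = 0
    run_tuning: bool = True
    alpha_reference: str = "cohort"


@dataclass
class ReportBundle:
    """Everything the pipeline computes, machine-readable."""

    prune_report: object
    study_ids: list[str]
    diversity: pd.DataFrame
    climate_matrix: pd.DataFrame
    screening_genetic: object
    screening_climate: object
    descriptives: pd.DataFrame
    corr_genetic: pd.DataFrame
    corr_climate: pd.DataFrame
    corr_between: pd.DataFrame
    cca: rcca.CcaResult
    significance: rcca.SignificanceTable
    permutation_p: np.ndarray
    univariate: pd.DataFrame
    eigen_table: pd.DataFrame
    tuning_result: object = None
    seed: int = 0
    tables: dict = field(default_factory=dict)


def _fmt_p(p: float) -> float:
    """Three decimals, floored at 0.001 (reporting convention)."""
    return max(round(p, 3), 0.001)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis on a pedigree file and a weather file."""
    rng = np.random.default_rng(config.seed)
    sub = {name: int(s) for name, s in zip(
        ("folds", "perm"), rng.integers(0, 2**31 - 1, 2))}

    stage = "load"
    try:
        ped = load_pedigree(config.pedigree_path)
        store = climate.load_weather(config.weather_path)
        store, scrub_counts = climate.sentinel_scrub(store)

        stage = "prune"
        study_ids, prune_report = prune_study_set(
            ped, climate_coverage=store.coverage(),
            home_country=config.home_country,
        )
        logger.info("prune: %d -> %d (%s)", prune_report.n_initial,
                    prune_report.n_final, prune_report.per_category)

        stage = "diversity"
        div = diversity.diversity_table(ped, alpha_reference=config.alpha_reference)
        div = div.set_index("id").loc[study_ids].reset_index()

        stage = "join"
        clim, missing = climate.assign_birth_climate(
            ped, store, study_ids=study_ids, policy=config.join_policy
        )
        if missing:
            logger.info("join: %d individuals had no climate record", len(missing))
            div = div[~div["id"].isin(missing)].reset_index(drop=True)
        clim = clim.set_index("id").loc[div["id"]].reset_index()

        # complete-case rule: drop rows with any missing climate field
        complete = clim.drop(columns="id").notna().all(axis=1)
        clim = clim[complete.to_numpy()].reset_index(drop=True)
        div = div[complete.to_numpy()].reset_index(drop=True)

        stage = "screen"
        X_full = div[DIVERSITY_VARS].astype(float)
        Y_full = clim.drop(columns="id").astype(float)
        X_kept, rep_gen = screening.screen_matrix(
            X_full, vif_threshold=config.vif_threshold, rout_q=config.rout_q
        )
        Y_kept, rep_cli = screening.screen_matrix(
            Y_full, vif_threshold=config.vif_threshold, rout_q=config.rout_q
        )
        logger.info("screen: genetic kept %s, climate kept %s",
                    list(X_kept.columns), list(Y_kept.columns))

        stage = "rcca"
        Zx, *_ = rcca.standardize(X_kept.to_numpy())
        Zy, *_ = rcca.standardize(Y_kept.to_numpy())
        n, p = Zx.shape
        q = Zy.shape[1]
        fit = rcca.fit_rcca(Zx, Zy)
        sig = rcca.multivariate_tests(fit.r, n, p, q)
        perm_p = rcca.permutation_test(
            Zx, Zy, B=config.permutations,
            seed=np.random.default_rng(sub["perm"]),
        )

        stage = "univariate"
        uni = _univariate_tests(X_kept, Y_kept)

        stage = "tune"
        tune_res = None
        if config.run_tuning:
            grid = tuning.default_grid(config.grid_size)
            tune_res = tuning.tune_rcc(
                Zx, Zy, grid, grid, k=config.k_folds, seed=sub["folds"]
            )

        stage = "report"
        bundle = _assemble(
            config, ped, prune_report, study_ids, div, clim,
            rep_gen, rep_cli, X_kept, Y_kept, fit, sig, perm_p, uni, tune_res,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    if config.out_dir is not None:
        _write_bundle(bundle, Path(config.out_dir))
    return bundle


def _univariate_tests(X: pd.DataFrame, Y: pd.DataFrame) -> pd.DataFrame:
    """OLS of each diversity variable on the full climate block.

    Reports R² (the multivariate generalization of R² for that response),
    adjusted R², hypothesis and error mean squares, F and p with
    (q, n − q − 1) degrees of freedom.
    """
    n, q = Y.shape
    design = np.column_stack([np.ones(n), Y.to_numpy(dtype=float)])
    rows = []
    for name in X.columns:
        y = X[name].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        fitted = design @ coef
        ssr = float(np.sum((fitted - y.mean()) ** 2))
        sse = float(np.sum((y - fitted) ** 2))
        sst = ssr + sse
        r2 = ssr / sst if sst > 0 else 0.0
        df_h, df_e = q, n - q - 1
        msh, mse = ssr / df_h, sse / df_e
        F = msh / mse if mse > 0 else np.inf
        rows.append({
            "variable": name, "R2": r2,
            "adj_R2": 1.0 - (1.0 - r2) * (n - 1) / df_e,
            "hyp_MS": msh, "err_MS": mse, "F": F,
            "df_hyp": df_h, "df_err": df_e,
            "p": _fmt_p(float(stats.f.sf(F, df_h, df_e))),
        })
    return pd.DataFrame(rows)


def _assemble(config, ped, prune_report, study_ids, div, clim,
              rep_gen, rep_cli, X_kept, Y_kept, fit, sig, perm_p, uni,
              tune_res) -> ReportBundle:
    x_names = list(X_kept.columns)
    y_names = list(Y_kept.columns)
    s = fit.r.size
    variates = [f"F{i+1}" for i in range(s)]

    desc_rows = []
    for setname, frame in (("genetic", div[X_kept.columns]),
                           ("climate", clim.drop(columns="id"))):
        for col in frame.columns:
            v = frame[col].astype(float)
            desc_rows.append({
                "set": setname, "variable": col, "mean": v.mean(),
                "sd": v.std(ddof=1), "min": v.min(), "max": v.max(),
                "median": v.median(),
            })
    descriptives = pd.DataFrame(desc_rows)

    Rxx, Ryy, Rxy = rcca.pearson_matrix(X_kept.to_numpy(), Y_kept.to_numpy())
    corr_gen = pd.DataFrame(Rxx, index=x_names, columns=x_names)
    corr_cli = pd.DataFrame(Ryy, index=y_names, columns=y_names)
    corr_btw = pd.DataFrame(Rxy, index=x_names, columns=y_names)

    crit = pd.DataFrame([
        {"criterion": "Pillai's trace", "value": sig.pillai,
         "approx_F": sig.approx_F["pillai"], "df_hyp": sig.df_hyp["pillai"],
         "df_err": sig.df_err["pillai"], "p": _fmt_p(sig.p["pillai"])},
        {"criterion": "Hotelling-Lawley trace", "value": sig.hotelling,
         "approx_F": sig.approx_F["hotelling"], "df_hyp": sig.df_hyp["hotelling"],
         "df_err": sig.df_err["hotelling"], "p": _fmt_p(sig.p["hotelling"])},
        {"criterion": "Wilks' lambda", "value": sig.wilks,
         "approx_F": sig.approx_F["wilks"], "df_hyp": sig.df_hyp["wilks"],
         "df_err": sig.df_err["wilks"], "p": _fmt_p(sig.p["wilks"])},
        {"criterion": "Roy's greatest root", "value": sig.roy,
         "approx_F": np.nan, "df_hyp": np.nan, "df_err": np.nan, "p": np.nan},
    ])

    rd = rcca.redundancy(fit)
    canon = pd.DataFrame(
        {
            "canonical_r": fit.r, "r_squared": fit.r2,
            "redundancy_Y1": rd["X"], "redundancy_Y2": rd["Y"],
            "permutation_p": perm_p, "meaningful": fit.meaningful,
        },
        index=variates,
    )
    roots = pd.DataFrame(sig.roots_table)
    eigen = pd.DataFrame({
        "eigenvalue": fit.eigenvalues,
        "variance_pct": fit.variance_share,
        "cumulative_pct": np.cumsum(fit.variance_share),
    }, index=variates)

    tables = {
        "descriptives": descriptives,
        "corr_genetic": corr_gen,
        "corr_climate": corr_cli,
        "corr_between": corr_btw,
        "criteria": crit,
        "canonical": canon,
        "roots": roots,
        "univariate": uni,
        "eigen": eigen,
        "std_coef_X": pd.DataFrame(fit.coef_X, index=x_names, columns=variates),
        "std_coef_Y": pd.DataFrame(fit.coef_Y, index=y_names, columns=variates),
    }
    return ReportBundle(
        prune_report=prune_report, study_ids=study_ids,
        diversity=div, climate_matrix=clim,
        screening_genetic=rep_gen, screening_climate=rep_cli,
        descriptives=descriptives, corr_genetic=corr_gen,
        corr_climate=corr_cli, corr_between=corr_btw,
        cca=fit, significance=sig, permutation_p=perm_p,
        univariate=uni, eigen_table=eigen, tuning_result=tune_res,
        seed=config.seed, tables=tables,
    )


def _write_bundle(bundle: ReportBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, tab in bundle.tables.items():
        tab.to_csv(out_dir / f"{name}.csv")
    summary = {
        "seed": bundle.seed,
        "prune": {
            "n_initial": bundle.prune_report.n_initial,
            "n_discarded": bundle.prune_report.n_discarded,
            "n_final": bundle.prune_report.n_final,
            "per_category": bundle.prune_report.per_category,
        },
        "n_analysed": int(len(bundle.diversity)),
        "excluded_genetic": bundle.screening_genetic.excluded,
        "excluded_climate": bundle.screening_climate.excluded,
        "canonical_r": bundle.cca.r.tolist(),
        "permutation_p": bundle.permutation_p.tolist(),
        "criteria": {
            "pillai": bundle.significance.pillai,
            "hotelling": bundle.significance.hotelling,
            "wilks": bundle.significance.wilks,
            "roy": bundle.significance.roy,
        },
        "lambda": (
            None if bundle.tuning_result is None else
            {"lambda1": bundle.tuning_result.best_lambda1,
             "lambda2": bundle.tuning_result.best_lambda2,
             "cv_score": bundle.tuning_result.best_score}
        ),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
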