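"""Monte-Carlo validation experiments: null calibration and planted-effect
recovery, run through the same pipeline stages as a real analysis.

These experiments back the package's statistical claims:

* on cohorts simulated with no planted effects, the differential-
  expression test, the pair-selection rule and the log-rank screen reject
  at their nominal rates;
* planted effects of the magnitudes the screens are meant to detect are
  recovered.

Calibration cohorts use 25 samples per group: large enough that the
asymptotic log-rank chi-square operates in its validity regime (at a
24-sample cohort with ~50% censoring the log-rank test is measurably
anticonservative -- a property of the test, not of this implementation).
The t- and correlation-based screens are exact under normality at any n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import AnalysisConfig
from .pipeline import quantify
from .quant import fold_change_between_groups
from .simulate import Coupling, SimulationConfig, simulate_cohort
from .pairs import screen_pairs
from .surv import cox_ph_fit, dichotomize_by_median, logrank_test

__all__ = [
    "CalibrationResult",
    "null_calibration",
    "de_recovery",
    "pair_recovery",
    "cox_coverage",
]


@dataclass
class CalibrationResult:
    """Null rejection fractions with Monte-Carlo uncertainty.

    ``fractions`` holds one per-simulation rejection fraction per
    experiment; ``n_tests`` the total number of tests pooled.
    """

    name: str
    nominal: float
    fractions: np.ndarray
    n_tests: int

    @property
    def fraction(self) -> float:
        return float(np.mean(self.fractions))

    def se(self) -> float:
        """Standard error of the mean fraction.

        The larger of the cluster (per-simulation) estimate and the
        pooled binomial one; tests within a simulation share reference-
        gene and sample noise, so the cluster estimate is the honest one.
        """
        cluster = float(np.std(self.fractions, ddof=1) / np.sqrt(len(self.fractions)))
        binom = float(
            np.sqrt(self.nominal * (1 - self.nominal) / self.n_tests)
        )
        return max(cluster, binom)

    def within_band(self, z: float = 2.576) -> bool:
        return abs(self.fraction - self.nominal) <= z * self.se()


def _null_config(seed: int, n_per_group: int) -> SimulationConfig:
    return SimulationConfig(
        n_per_group=n_per_group,
        n_mirnas=2,
        n_genes=6,
        n_endogenous_mrna=3,
        n_endogenous_mirna=2,
        censor_rate=0.3,
        seed=seed,
    )


def null_calibration(
    n_sims: int = 2000,
    seed: int = 0,
    n_per_group: int = 25,
    de_alpha: float = 0.05,
    pair_alpha: float = 0.10,
    logrank_alpha: float = 0.05,
) -> dict[str, CalibrationResult]:
    """Null rejection rates of the DE, pair-selection and log-rank screens.

    Each simulation draws a cohort with no planted effects, quantifies it
    through the full replicate-aggregation / filtering / normalisation
    chain, and records per-target DE rejections (p < de_alpha), per-pair
    selections in each group and combined (min of the two group p-values
    <= pair_alpha; nominal combined rate 1-(1-alpha)^2 because two
    independent looks are taken), and the log-rank rejection for a
    median-split null marker.
    """
    rng = np.random.default_rng(seed)
    config = AnalysisConfig()
    de_fr, pg_fr, pc_fr, lr_fr = [], [], [], []
    n_de = n_pair = n_lr = 0
    for _ in range(n_sims):
        sim_seed = int(rng.integers(0, 2**31 - 1))
        ct, ann, _ = simulate_cohort(_null_config(sim_seed, n_per_group))
        mrna, mirna, _, _ = quantify(ct, ann, config)

        # differential expression: two-sample t per target
        from .de import differential_expression

        de = differential_expression(mrna, ann, alpha=de_alpha)
        tested = de[~de["untestable"]]
        de_fr.append(float((tested["p_value"] < de_alpha).mean()))
        n_de += len(tested)

        # pair screen selection
        from .pairs import pairwise_group_correlations, select_candidate_pairs

        pairs = select_candidate_pairs(
            pairwise_group_correlations(mrna, mirna, ann), alpha=pair_alpha
        )
        per_group = np.concatenate(
            [pairs["p_localized"].to_numpy(), pairs["p_metastatic"].to_numpy()]
        )
        pg_fr.append(float((per_group <= pair_alpha).mean()))
        pc_fr.append(float(pairs["selected"].mean()))
        n_pair += len(pairs)

        # log-rank on a median-split marker with no survival effect
        labels, degenerate = dichotomize_by_median(mrna.values.iloc[:, 0])
        if not degenerate:
            mask = labels.notna()
            sub = ann.data.reindex(labels.index)[mask]
            lr = logrank_test(
                sub["os_time"].to_numpy(),
                sub["os_event"].to_numpy(),
                labels[mask].to_numpy(),
            )
            lr_fr.append(float(lr.p_value < logrank_alpha))
            n_lr += 1

    combined_nominal = 1.0 - (1.0 - pair_alpha) ** 2
    return {
        "de": CalibrationResult("de", de_alpha, np.array(de_fr), n_de),
        "pair_per_group": CalibrationResult(
            "pair_per_group", pair_alpha, np.array(pg_fr), 2 * n_pair
        ),
        "pair_combined": CalibrationResult(
            "pair_combined", combined_nominal, np.array(pc_fr), n_pair
        ),
        "logrank": CalibrationResult(
            "logrank", logrank_alpha, np.array(lr_fr), n_lr
        ),
    }


def de_recovery(
    n_runs: int = 200,
    seed: int = 0,
    n_per_group: int = 50,
    log2fc: float = 1.0,
    band: tuple[float, float] = (1.8, 2.2),
) -> dict:
    """Fraction of runs recovering a planted log2 fold change within a band."""
    rng = np.random.default_rng(seed)
    hits, fcs = 0, []
    for _ in range(n_runs):
        cfg = SimulationConfig(
            n_per_group=n_per_group, n_mirnas=2, n_genes=4,
            n_endogenous_mrna=3, n_endogenous_mirna=2,
            de_targets={"CCND1": log2fc},
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        ct, ann, _ = simulate_cohort(cfg)
        mrna, _, _, _ = quantify(ct, ann, AnalysisConfig())
        fc = fold_change_between_groups(mrna, ann, "CCND1")
        fcs.append(fc)
        hits += band[0] <= fc <= band[1]
    return {
        "fraction_in_band": hits / n_runs,
        "median_fc": float(np.median(fcs)),
        "n_runs": n_runs,
        "n_per_group": n_per_group,
    }


def pair_recovery(
    n_runs: int = 100,
    seed: int = 0,
    n_per_group: int = 50,
    auc_cutoff: float = 0.8,
) -> dict:
    """Recovery of a planted repression-gain coupling.

    Each run plants an up-regulated miRNA (log2FC 1.2) whose coupling to
    a gene switches from none (localized) to slope -1 (metastatic), and
    counts the run as recovered when the pair screen flags the pair as
    disrupted, repression-gain, and discriminating (orientation-corrected
    AUC strictly above the cutoff).
    """
    rng = np.random.default_rng(seed)
    hits, aucs = 0, []
    for _ in range(n_runs):
        cfg = SimulationConfig(
            n_per_group=n_per_group, n_mirnas=2, n_genes=4,
            n_endogenous_mrna=3, n_endogenous_mirna=2,
            de_targets={"miR-421": 1.2},
            coupling=[Coupling("BCL2", "miR-421", 0.0, -1.0)],
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        ct, ann, _ = simulate_cohort(cfg)
        mrna, mirna, _, _ = quantify(ct, ann, AnalysisConfig())
        table = screen_pairs(mrna, mirna, ann, auc_cutoff=auc_cutoff)
        row = table.set_index(["gene", "mirna"]).loc[("BCL2", "miR-421")]
        aucs.append(float(row["pair_score_auc_oriented"]))
        hits += bool(
            row["disrupted"] and row["repression_gain"] and row["top_pair"]
        )
    return {
        "fraction_recovered": hits / n_runs,
        "median_oriented_auc": float(np.median(aucs)),
        "n_runs": n_runs,
        "n_per_group": n_per_group,
    }


def cox_coverage(
    n_sims: int = 200,
    seed: int = 0,
    n_per_group: int = 50,
    beta: float = float(np.log(2.0)),
) -> dict:
    """Wald 95% CI coverage for a planted log-hazard coefficient.

    The Cox model is fitted on the latent expression of the planted
    marker (the covariate that actually drives the hazard); fits on the
    noisy measured -dCT estimate an attenuated coefficient and are not a
    coverage experiment.
    """
    rng = np.random.default_rng(seed)
    covered, n_used = 0, 0
    for _ in range(n_sims):
        cfg = SimulationConfig(
            n_per_group=n_per_group, n_mirnas=2, n_genes=4,
            n_endogenous_mrna=3, n_endogenous_mirna=2,
            survival_betas={"BCL2": beta}, censor_rate=0.3,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        _, ann, truth = simulate_cohort(cfg)
        x = truth.latent_expression["BCL2"]
        x = (x - x.mean()).to_numpy()[:, None]
        t = ann.data["os_time"].to_numpy()
        e = ann.data["os_event"].to_numpy()
        fit = cox_ph_fit(t, e, x)
        if fit.convergence != "converged":
            continue
        lo, hi = fit.ci()
        covered += bool(np.log(lo[0]) <= beta <= np.log(hi[0]))
        n_used += 1
    return {
        "coverage": covered / n_used,
        "n_sims": n_used,
        "nominal": 0.95,
        "n_per_group": n_per_group,
    }
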