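"""Mechanism diagnostics: spousal correlations, PC-adjustment comparison,
parental-covariate heritability, and the negative-control harness.

Each diagnostic mirrors a standard epidemiological probe:

* spousal phenotypic/genotypic correlations detect assortative mating;
* comparing heritability with and without principal-component adjustment
  probes population stratification;
* heritability after conditioning on parental phenotypes probes dynastic
  and assortment pathways jointly;
* running everything on a negative-control trait (a CRP-like biomarker
  untouched by any mechanism) validates the machinery itself.

Verdict strings always carry the statistic, its SE, and the threshold
used, and are phrased as indicators — never as causal conclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError
from .varcomp import GRMatrix, VarianceFit, reml_univariate

__all__ = [
    "DiagnosticReport",
    "spousal_correlation",
    "stratification_check",
    "parental_covariate_h2",
    "negative_control_run",
]


@dataclass
class DiagnosticReport:
    spousal: pd.DataFrame | None = None
    strat: pd.DataFrame | None = None
    parental_adjusted: pd.DataFrame | None = None
    verdicts: dict[str, str] = field(default_factory=dict)

    def to_markdown(self) -> str:
        parts = []
        if self.spousal is not None:
            parts.append("## Spousal correlations\n\n" + self.spousal.to_markdown(index=False))
        if self.strat is not None:
            parts.append(
                "## Heritability before/after PC adjustment\n\n"
                + self.strat.to_markdown(index=False)
            )
        if self.parental_adjusted is not None:
            parts.append(
                "## Heritability with parental-phenotype covariates\n\n"
                + self.parental_adjusted.to_markdown(index=False)
            )
        if self.verdicts:
            parts.append(
                "## Verdicts\n\n"
                + "\n".join(f"- **{k}**: {v}" for k, v in self.verdicts.items())
            )
        return "\n\n".join(parts) + "\n"


def spousal_correlation(values: pd.Series | dict, pairs: list[tuple[str, str]]):
    """Product-moment correlation of a per-individual variable across spouse
    pairs; SE by the normal-theory formula sqrt((1 - r^2) / (n - 2)).

    ``values`` maps individual id -> value; pairs with a missing member are
    skipped.  Returns (r, se, n_pairs).
    """
    if isinstance(values, pd.Series):
        values = values.to_dict()
    a, b = [], []
    for x, y in pairs:
        if x in values and y in values:
            va, vb = values[x], values[y]
            if not (np.isnan(va) or np.isnan(vb)):
                a.append(va)
                b.append(vb)
    n = len(a)
    if n < 3:
        raise DataError("spousal correlation needs at least 3 complete pairs")
    a = np.asarray(a)
    b = np.asarray(b)
    if a.std() == 0 or b.std() == 0:
        raise DataError("zero variance in one margin of the spousal pairs")
    r = float(np.corrcoef(a, b)[0, 1])
    se = float(np.sqrt((1.0 - r**2) / (n - 2)))
    return r, se, n


def stratification_check(
    y, X_base, grm: GRMatrix, pcs: np.ndarray, **reml_kw
) -> tuple[VarianceFit, VarianceFit, str]:
    """Heritability without and with principal-component covariates.

    Attenuation after PC adjustment is evidence of population
    stratification; the verdict reports the paired estimates and their
    joint uncertainty.
    """
    fit_raw = reml_univariate(y, X_base, grm, **reml_kw)
    pcs = np.asarray(pcs, dtype=float)
    if pcs.ndim == 1:
        pcs = pcs[:, None]
    if X_base is None:
        X_adj = pcs
    else:
        Xb = np.asarray(X_base, dtype=float)
        if Xb.ndim == 1:
            Xb = Xb[:, None]
        # adjusting twice for the same components must be a no-op, so drop
        # PC columns that duplicate existing covariates
        fresh = [
            j for j in range(pcs.shape[1])
            if not any(
                np.allclose(pcs[:, j], Xb[:, i], atol=1e-12) for i in range(Xb.shape[1])
            )
        ]
        X_adj = np.column_stack([Xb, pcs[:, fresh]]) if fresh else Xb
    fit_adj = reml_univariate(y, X_adj, grm, **reml_kw)
    diff = fit_raw.h2 - fit_adj.h2
    joint_se = float(np.hypot(fit_raw.se_h2, fit_adj.se_h2))
    if diff > 2 * joint_se:
        verdict = (
            f"attenuation after PC adjustment: h2 {fit_raw.h2:.3f} (SE {fit_raw.se_h2:.3f}) "
            f"-> {fit_adj.h2:.3f} (SE {fit_adj.se_h2:.3f}), difference {diff:.3f} exceeds "
            f"2 x joint SE {joint_se:.3f}; indicator of possible population stratification"
        )
    else:
        verdict = (
            f"h2 {fit_raw.h2:.3f} (SE {fit_raw.se_h2:.3f}) vs PC-adjusted {fit_adj.h2:.3f} "
            f"(SE {fit_adj.se_h2:.3f}); difference {diff:.3f} within 2 x joint SE "
            f"{joint_se:.3f}; no indicator of stratification from this comparison"
        )
    return fit_raw, fit_adj, verdict


def parental_covariate_h2(
    y_child, parental_covars, grm: GRMatrix, X_base=None, **reml_kw
) -> tuple[VarianceFit, VarianceFit]:
    """Heritability before and after conditioning on parental phenotypes.

    Rows with missing parental data fall to the complete-case filter inside
    REML.  Returns (base fit, parental-adjusted fit).
    """
    P = np.asarray(parental_covars, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    fit_base = reml_univariate(y_child, X_base, grm, **reml_kw)
    if X_base is None:
        X_full = P
    else:
        Xb = np.asarray(X_base, dtype=float)
        if Xb.ndim == 1:
            Xb = Xb[:, None]
        X_full = np.column_stack([Xb, P])
    fit_adj = reml_univariate(y_child, X_full, grm, **reml_kw)
    return fit_base, fit_adj


def negative_control_run(
    cohort,
    grm: GRMatrix,
    pcs: np.ndarray,
    analysis_rows: np.ndarray,
    trio_frame: pd.DataFrame,
    nt_scores: pd.DataFrame | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> DiagnosticReport:
    """Run every mechanism probe on the negative-control trait.

    Executes spousal correlation, trio attenuation and the stratification
    check on the control phenotype; each verdict asserts whether the
    mechanism reads null within sampling error.  ``analysis_rows`` selects
    the generation analysed by REML; ``trio_frame`` must come from
    :func:`popdynh2.pgs.trio_design` on the control trait.
    """
    from .pgs import bootstrap_attenuation_se, sur_difference_test, trio_regression

    if len(trio_frame) < 10:
        raise DataError("negative-control trio analysis needs at least 10 trios")
    report = DiagnosticReport()

    ids = cohort.individuals["id"]
    control = pd.Series(cohort.phenos["control"].to_numpy(), index=ids)
    r, se, n = spousal_correlation(control, cohort.spouse_pairs)
    report.spousal = pd.DataFrame(
        [{"variable": "control", "r": r, "se": se, "n": n}]
    )
    null_sp = abs(r) <= 2 * se
    report.verdicts["spousal_control"] = (
        f"spousal r = {r:.3f} (SE {se:.3f}), threshold 2 x SE: "
        + ("null, as expected for the control trait" if null_sp
           else "NON-NULL — control trait shows assortment; investigate the harness")
    )

    tr = trio_regression(
        trio_frame["y"], trio_frame["score_child"],
        trio_frame["score_mother"], trio_frame["score_father"],
    )
    tr.se_attenuation, tr.n_boot_dropped = bootstrap_attenuation_se(
        trio_frame["y"], trio_frame["score_child"], trio_frame["score_mother"],
        trio_frame["score_father"], n_reps=n_boot, seed=seed,
    )
    tr.n_boot = n_boot
    tr.p_diff = sur_difference_test(
        trio_frame["y"], trio_frame["score_child"], trio_frame["score_mother"],
        trio_frame["score_father"],
    )["p"]
    null_att = abs(tr.attenuation_pct) <= 2 * tr.se_attenuation
    report.verdicts["attenuation_control"] = (
        f"attenuation {tr.attenuation_pct:.1f}% (bootstrap SE {tr.se_attenuation:.1f}), "
        f"threshold 2 x SE: "
        + ("null, as expected for the control trait" if null_att
           else "NON-NULL — control trait shows parental-score attenuation")
    )

    y = cohort.phenos["control"].to_numpy()[analysis_rows]
    fit_raw, fit_adj, verdict = stratification_check(y, None, grm, pcs)
    report.strat = pd.DataFrame(
        [
            {"trait": "control", "h2_unadjusted": fit_raw.h2, "se_unadjusted": fit_raw.se_h2,
             "h2_pc_adjusted": fit_adj.h2, "se_pc_adjusted": fit_adj.se_h2}
        ]
    )
    report.verdicts["stratification_control"] = verdict
    return report
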