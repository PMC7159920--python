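"""Polygenic scores, nontransmitted-allele scores, and the trio attenuation analysis.

A polygenic score is a weighted sum of effect-allele counts over a retained
variant set: weights below a discovery p-value threshold survive, and LD is
thinned by clumping — the smallest-p variant in each window is kept and
nearby variants correlated with it beyond an r-squared cap are removed.
Scores are standardized to unit SD in the scoring sample.

The trio analysis regresses the child phenotype on the child score alone
and then co-adjusted for both parental scores.  Attenuation of the child
coefficient, parental coefficients that survive adjustment, and association
of a score built from the *nontransmitted* parental alleles are all
signatures of dynastic effects and/or assortative mating: nontransmitted
alleles cannot act through the child's own genome, so any association they
show with the child phenotype is environmental in origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError

__all__ = [
    "TrioResult",
    "weights_from_effects",
    "harmonize_weights",
    "select_variants",
    "build_pgs",
    "nontransmitted_score",
    "trio_design",
    "trio_regression",
    "attenuation",
    "bootstrap_attenuation_se",
    "sur_difference_test",
    "variance_explained",
]

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
#: bootstrap replicates with |independent-model coefficient| below this are dropped
B_IND_EPS = 1e-8


@dataclass
class TrioResult:
    b_child_ind: float
    se_child_ind: float
    b_child_adj: float
    se_child_adj: float
    b_mother_ind: float
    se_mother_ind: float
    b_father_ind: float
    se_father_ind: float
    b_mother_adj: float
    se_mother_adj: float
    b_father_adj: float
    se_father_adj: float
    n_trios: int
    attenuation_pct: float = np.nan
    se_attenuation: float = np.nan
    p_diff: float = np.nan
    n_boot: int = 0
    n_boot_dropped: int = 0


def weights_from_effects(cohort, trait: str = "a") -> pd.DataFrame:
    """Weight table (variant, effect_allele, weight, p) from simulator truth."""
    if cohort.effects is None:
        raise DataError("cohort carries no effect set")
    wf = cohort.effects.weights_frame(cohort.variants)
    col = {"a": "beta_a", "b": "beta_b"}[trait]
    return pd.DataFrame(
        {
            "variant": wf["variant"],
            "effect_allele": wf["effect_allele"],
            "weight": wf[col],
            "p": wf["p"],
        }
    )


def harmonize_weights(variants: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Align weight effect alleles with the dosage coding.

    Weights whose effect allele is the dosage's other allele are
    sign-flipped; strand-ambiguous (A/T, C/G) variants and variants absent
    from the genotype data are dropped.  Duplicate variant ids are an error.
    """
    if weights["variant"].duplicated().any():
        dup = weights.loc[weights["variant"].duplicated(), "variant"].iloc[0]
        raise DataError(f"duplicate variant id in weights: {dup}")
    merged = weights.merge(
        variants[["id", "effect_allele", "other_allele", "pos", "chrom"]].rename(
            columns={"id": "variant", "effect_allele": "geno_effect", "other_allele": "geno_other"}
        ),
        on="variant",
        how="inner",
    )
    status = np.full(len(merged), "", dtype=object)
    w = merged["weight"].to_numpy(dtype=float).copy()
    for i, row in enumerate(merged.itertuples()):
        pair = (row.geno_effect, row.geno_other)
        if pair in _AMBIGUOUS:
            status[i] = "ambiguous"
        elif row.effect_allele == row.geno_effect:
            status[i] = "kept"
        elif row.effect_allele == row.geno_other:
            status[i] = "flipped"
            w[i] = -w[i]
        else:
            status[i] = "allele_mismatch"
    merged["weight"] = w
    merged["status"] = status
    return merged[merged["status"].isin(["kept", "flipped"])].reset_index(drop=True), merged


def select_variants(
    dosages: np.ndarray,
    variants: pd.DataFrame,
    weights: pd.DataFrame,
    p_threshold: float = 5e-8,
    window_kb: float = 250.0,
    r2_max: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Threshold + clump; returns (retained weight rows, retention log).

    Clumping keeps the smallest-p variant in each ``window_kb`` window and
    removes all other variants in that window whose r-squared with it
    exceeds ``r2_max``.
    """
    harmon, log = harmonize_weights(variants, weights)
    cand = harmon[harmon["p"] < p_threshold].copy()
    if cand.empty:
        raise DataError("no variants pass the p-value threshold")
    vidx = pd.Index(variants["id"])
    cand["col"] = vidx.get_indexer(cand["variant"])
    cand = cand.sort_values(["p", "pos"], kind="stable").reset_index(drop=True)
    removed = np.zeros(len(cand), dtype=bool)
    kept_rows = []
    pos = cand["pos"].to_numpy(dtype=float)
    chrom = cand["chrom"].to_numpy()
    X = dosages.astype(float)
    for i in range(len(cand)):
        if removed[i]:
            continue
        kept_rows.append(i)
        near = np.flatnonzero(
            (~removed)
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window_kb * 1000.0)
        )
        near = near[near != i]
        if near.size:
            xi = X[:, cand["col"].iloc[i]]
            for j in near:
                xj = X[:, cand["col"].iloc[j]]
                if xi.std() == 0 or xj.std() == 0:
                    continue
                r = np.corrcoef(xi, xj)[0, 1]
                if r * r > r2_max:
                    removed[j] = True
    retained = cand.iloc[kept_rows].reset_index(drop=True)
    log = log.copy()
    log["retained"] = log["variant"].isin(retained["variant"])
    return retained, log


def build_pgs(
    dosages: np.ndarray,
    variants: pd.DataFrame,
    weights: pd.DataFrame,
    p_threshold: float = 5e-8,
    window_kb: float = 250.0,
    r2_max: float = 0.1,
    standardize: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-individual polygenic score over the retained variant set."""
    retained, log = select_variants(
        dosages, variants, weights, p_threshold, window_kb, r2_max
    )
    score = dosages[:, retained["col"].to_numpy()].astype(float) @ retained[
        "weight"
    ].to_numpy()
    if standardize:
        sd = score.std()
        if sd == 0:
            raise DataError("polygenic score has zero variance; cannot standardize")
        score = (score - score.mean()) / sd
    return score, log


def nontransmitted_score(
    cohort,
    weights: pd.DataFrame,
    p_threshold: float = 5e-8,
    window_kb: float = 250.0,
    r2_max: float = 0.1,
    standardize: bool = True,
) -> pd.DataFrame:
    """Nontransmitted-allele scores for every complete trio.

    Uses the same retained variant set as :func:`build_pgs`.  Returns a
    frame indexed like ``trios()`` with maternal, paternal and combined
    nontransmitted scores.
    """
    trios = cohort.trios()
    if trios.empty:
        raise DataError("no complete trios in cohort")
    retained, _ = select_variants(
        cohort.dosages, cohort.variants, weights, p_threshold, window_kb, r2_max
    )
    cols = retained["col"].to_numpy()
    w = retained["weight"].to_numpy()
    child_rows = cohort.row_of(trios["child"].to_numpy())
    nt_m = cohort.nontransmitted(child_rows, "m")[:, cols].astype(float)
    nt_f = cohort.nontransmitted(child_rows, "f")[:, cols].astype(float)
    s_m = nt_m @ w
    s_f = nt_f @ w
    comb = s_m + s_f
    if standardize:
        for arr in (s_m, s_f, comb):
            sd = arr.std()
            if sd == 0:
                raise DataError("nontransmitted score has zero variance")
            arr -= arr.mean()
            arr /= sd
    return pd.DataFrame(
        {"child": trios["child"], "score_nt_m": s_m, "score_nt_f": s_f, "score_nt": comb}
    )


def trio_design(
    cohort,
    weights: pd.DataFrame | None = None,
    trait: str = "trait_a",
    p_threshold: float = 1.0,
    window_kb: float = 0.0,
    r2_max: float = 1.1,
) -> pd.DataFrame:
    """Assemble the trio analysis frame: child phenotype plus standardized
    child/mother/father polygenic scores.

    With the defaults the score uses every weighted variant (no threshold,
    no clumping) — appropriate for simulator truth weights.
    """
    trios = cohort.trios()
    if trios.empty:
        raise DataError("no complete trios in cohort")
    if weights is None:
        weights = weights_from_effects(cohort, "a" if trait != "control" else "a")
    score, _ = build_pgs(
        cohort.dosages, cohort.variants, weights, p_threshold, window_kb, r2_max
    )
    rows_c = cohort.row_of(trios["child"].to_numpy())
    rows_m = cohort.row_of(trios["mother"].to_numpy())
    rows_f = cohort.row_of(trios["father"].to_numpy())
    y = cohort.phenos[trait].to_numpy()[rows_c]
    return pd.DataFrame(
        {
            "child": trios["child"],
            "y": y,
            "score_child": score[rows_c],
            "score_mother": score[rows_m],
            "score_father": score[rows_f],
        }
    )


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS via least squares: (beta, se, residuals)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n, p = X.shape
    sigma2 = resid @ resid / (n - p)
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    return beta, se, resid


def _design(covars, n, *cols):
    parts = [np.ones(n)]
    if covars is not None:
        C = np.asarray(covars, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        parts.append(C)
    parts.extend(cols)
    return np.column_stack(parts)


def _standardize(v, name):
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0:
        raise DataError(f"{name} has zero variance")
    return (v - v.mean()) / sd


def trio_regression(
    y, score_child, score_mother, score_father, covars=None
) -> TrioResult:
    """Independent and co-adjusted trio regressions.

    Fits the child-only model, the two single-parent models, and the
    three-score model by least squares.  Scores are standardized to unit
    SD; a pair of scores correlated above 0.99 is an error.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    sc = _standardize(score_child, "child score")
    sm = _standardize(score_mother, "mother score")
    sf = _standardize(score_father, "father score")
    names = ["child", "mother", "father"]
    scores = [sc, sm, sf]
    for i in range(3):
        for j in range(i + 1, 3):
            r = np.corrcoef(scores[i], scores[j])[0, 1]
            if abs(r) > 0.99:
                raise DataError(
                    f"collinear polygenic scores: {names[i]} vs {names[j]} (r = {r:.3f})"
                )
    pos = 1 + (0 if covars is None else np.atleast_2d(np.asarray(covars).T).shape[0])

    b_ci, se_ci, _ = _ols(y, _design(covars, n, sc))
    b_mi, se_mi, _ = _ols(y, _design(covars, n, sm))
    b_fi, se_fi, _ = _ols(y, _design(covars, n, sf))
    b_adj, se_adj, _ = _ols(y, _design(covars, n, sc, sm, sf))

    res = TrioResult(
        b_child_ind=float(b_ci[pos]), se_child_ind=float(se_ci[pos]),
        b_mother_ind=float(b_mi[pos]), se_mother_ind=float(se_mi[pos]),
        b_father_ind=float(b_fi[pos]), se_father_ind=float(se_fi[pos]),
        b_child_adj=float(b_adj[pos]), se_child_adj=float(se_adj[pos]),
        b_mother_adj=float(b_adj[pos + 1]), se_mother_adj=float(se_adj[pos + 1]),
        b_father_adj=float(b_adj[pos + 2]), se_father_adj=float(se_adj[pos + 2]),
        n_trios=n,
    )
    if res.b_child_ind != 0:
        res.attenuation_pct = attenuation(res.b_child_ind, res.b_child_adj)
    return res


def attenuation(b_ind: float, b_adj: float) -> float:
    """Percent attenuation ``100 * (b_ind - b_adj) / b_ind``."""
    if b_ind == 0:
        raise DataError("attenuation undefined when the independent coefficient is 0")
    return 100.0 * (b_ind - b_adj) / b_ind


def bootstrap_attenuation_se(
    y, score_child, score_mother, score_father, covars=None,
    n_reps: int = 1000, seed: int = 0,
) -> tuple[float, int]:
    """Bootstrap SE of the attenuation percentage, resampling whole trios.

    Replicates with an independent-model coefficient below ``B_IND_EPS``
    in magnitude are dropped; the dropped count is returned.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    sc = _standardize(score_child, "child score")
    sm = _standardize(score_mother, "mother score")
    sf = _standardize(score_father, "father score")
    C = None if covars is None else np.asarray(covars, dtype=float)
    if C is not None and C.ndim == 1:
        C = C[:, None]
    pos = 1 + (0 if C is None else C.shape[1])
    rng = np.random.default_rng(seed)
    vals = []
    dropped = 0
    for _ in range(n_reps):
        idx = rng.integers(0, n, n)
        cov_b = None if C is None else C[idx]
        b1, *_ = _ols(y[idx], _design(cov_b, n, sc[idx]))
        b2, *_ = _ols(y[idx], _design(cov_b, n, sc[idx], sm[idx], sf[idx]))
        if abs(b1[pos]) < B_IND_EPS:
            dropped += 1
            continue
        vals.append(100.0 * (b1[pos] - b2[pos]) / b1[pos])
    if len(vals) < 2:
        raise DataError("too few valid bootstrap replicates")
    return float(np.std(vals, ddof=1)), dropped


def _sur_stacked(y, X1, X2, pos1, pos2) -> tuple[float, float]:
    """Stacked-estimating-equation SUR: difference between coefficient
    ``pos1`` of the model with design X1 and ``pos2`` of the model with X2,
    with its robust (sandwich) variance."""
    n = len(y)
    b1, _, e1 = _ols(y, X1)
    b2, _, e2 = _ols(y, X2)
    p1, p2 = X1.shape[1], X2.shape[1]
    Ginv = np.zeros((p1 + p2, p1 + p2))
    Ginv[:p1, :p1] = np.linalg.inv(X1.T @ X1 / n)
    Ginv[p1:, p1:] = np.linalg.inv(X2.T @ X2 / n)
    moments = np.hstack([X1 * e1[:, None], X2 * e2[:, None]])
    B = moments.T @ moments / n
    V = Ginv @ B @ Ginv.T / n
    sel = np.zeros(p1 + p2)
    sel[pos1] = 1.0
    sel[p1 + pos2] = -1.0
    return float(b1[pos1] - b2[pos2]), float(sel @ V @ sel)


def sur_difference_test(
    y, score_child, score_mother, score_father, covars=None,
    method: str = "stacked",
    n_reps: int = 1000, seed: int = 0,
) -> dict:
    """Test whether the child-score coefficient differs between the
    child-only and the co-adjusted model (seemingly-unrelated regressions).

    ``stacked``: both models' estimating equations are stacked and a robust
    joint (sandwich) covariance gives the variance of the coefficient
    difference; Wald test against the standard normal.  ``bootstrap``:
    paired resampling of trios, normal p from the bootstrap SD of the
    difference.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise DataError("models must be fit on identical complete trios")
    n = len(y)
    sc = _standardize(score_child, "child score")
    sm = _standardize(score_mother, "mother score")
    sf = _standardize(score_father, "father score")
    C = None if covars is None else np.asarray(covars, dtype=float)
    if C is not None and C.ndim == 1:
        C = C[:, None]
    pos = 1 + (0 if C is None else C.shape[1])

    X1 = _design(C, n, sc)
    X2 = _design(C, n, sc, sm, sf)
    b1, _, e1 = _ols(y, X1)
    b2, _, e2 = _ols(y, X2)
    diff = float(b1[pos] - b2[pos])

    if method == "stacked":
        diff, var_diff = _sur_stacked(y, X1, X2, pos, pos)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        diffs = []
        for _ in range(n_reps):
            idx = rng.integers(0, n, n)
            cb = None if C is None else C[idx]
            bb1, *_ = _ols(y[idx], _design(cb, n, sc[idx]))
            bb2, *_ = _ols(y[idx], _design(cb, n, sc[idx], sm[idx], sf[idx]))
            diffs.append(bb1[pos] - bb2[pos])
        var_diff = float(np.var(diffs, ddof=1))
    else:
        raise DataError(f"unknown SUR method {method!r}")

    if var_diff <= 0:
        p = 1.0 if diff == 0 else 0.0
        z = 0.0 if diff == 0 else np.inf
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return {"diff": diff, "se_diff": float(np.sqrt(max(var_diff, 0.0))), "z": float(z), "p": p}


def variance_explained(
    score, y, covars=None, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Incremental R-squared of the score over the covariates, with a
    bootstrap SE over individuals."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    s = _standardize(score, "score")
    C = None if covars is None else np.asarray(covars, dtype=float)
    if C is not None and C.ndim == 1:
        C = C[:, None]

    def r2(yv, Xv):
        _, _, resid = _ols(yv, Xv)
        return 1.0 - resid @ resid / np.sum((yv - yv.mean()) ** 2)

    def inc(idx):
        yb = y[idx]
        cb = None if C is None else C[idx]
        base = r2(yb, _design(cb, len(idx))) if cb is not None else 0.0
        full = r2(yb, _design(cb, len(idx), s[idx]))
        return full - base

    point = inc(np.arange(n))
    rng = np.random.default_rng(seed)
    boots = [inc(rng.integers(0, n, n)) for _ in range(n_boot)]
    return float(point), float(np.std(boots, ddof=1))
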