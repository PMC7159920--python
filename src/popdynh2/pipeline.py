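"""End-to-end orchestration: simulate -> estimate -> diagnose -> report.

``run_pipeline`` executes the full study design in dependency order:
univariate heritability (with and without PC adjustment), genetic
correlation, bivariate heritability with its Monte-Carlo SE, then the
three mechanism probes (spousal correlations, trio attenuation,
negative control).  Every stage's outputs are digested into a manifest so
a rerun with the same seed reproduces the report exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bivar import flag_inflation, mc_standard_error
from .cohort import SimConfig, preset_config, simulate_scenario
from .diagnostics import spousal_correlation, stratification_check
from .exceptions import ConfigError, PopdynError
from .io import write_phen, write_pedigree, write_raw, write_spouses, write_weights
from .pgs import (
    bootstrap_attenuation_se,
    build_pgs,
    nontransmitted_score,
    sur_difference_test,
    trio_design,
    trio_regression,
    weights_from_effects,
)
from .varcomp import compute_grm, compute_pcs, inverse_normal_transform, reml_bivariate

__all__ = ["PROFILES", "load_config", "run_pipeline", "make_report", "fmt_pct", "fmt_est"]

PROFILES = {
    "test": dict(n_boot=200, mc_draws=100_000),
    "paper": dict(n_boot=1000, mc_draws=1_000_000),
}


class StageError(PopdynError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path: str | Path) -> SimConfig:
    """Load a YAML scenario file mirroring :class:`SimConfig` field-for-field.

    An optional ``preset`` key selects a named preset; remaining keys
    override its fields.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("scenario file must be a YAML mapping")
    preset = raw.pop("preset", None)
    for key in ("maf_range", "subpop_shift"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    try:
        if preset:
            return preset_config(preset, **raw)
        return SimConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def fmt_est(x: float, se: float, digits: int = 3) -> str:
    return f"{x:.{digits}f} ({se:.{digits}f})"


def fmt_pct(x: float, se: float) -> str:
    """Paper-style percentage cell, e.g. ``34.4% (9.3)``."""
    return f"{x:.1f}% ({se:.1f})"


def run_pipeline(
    config: SimConfig,
    out_dir: str | Path,
    profile: str = "test",
    n_pcs: int = 20,
) -> dict:
    """Execute the whole analysis; returns the manifest dictionary.

    Stages: simulate, relatedness (GRM + PCs), variance components
    (univariate pair + bivariate + bivariate h2), trio (if trios exist),
    spousal, report.  A failing stage raises :class:`StageError` naming
    itself; outputs of earlier stages are preserved.
    """
    if profile not in PROFILES:
        raise ConfigError(f"unknown profile {profile!r}")
    prof = PROFILES[profile]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "version": __version__,
        "profile": profile,
        "stages": {},
    }
    results: dict = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                files = fn() or []
            except PopdynError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(name, exc) from exc
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "outputs": {str(f.name): _digest(f) for f in files},
            }
        return deco

    state: dict = {}

    @stage("simulate")
    def _sim():
        cohort = simulate_scenario(config)
        state["cohort"] = cohort
        files = []
        for writer, fname in [
            (write_raw, "genotypes.raw"),
            (write_phen, "phenotypes.phen"),
            (write_pedigree, "pedigree.tsv"),
            (write_spouses, "spouses.tsv"),
            (write_weights, "weights.tsv"),
        ]:
            path = out / fname
            writer(cohort, path)
            files.append(path)
        return files

    @stage("relatedness")
    def _grm():
        cohort = state["cohort"]
        rows = np.flatnonzero(cohort.generation_mask(cohort.last_generation))
        state["rows"] = rows
        grm = compute_grm(cohort.dosages[rows], ids=list(cohort.ids[rows]))
        k = min(n_pcs, len(rows) - 1)
        state["grm"] = grm
        state["pcs"] = compute_pcs(grm, k)

    @stage("varcomp")
    def _vc():
        cohort, rows, grm, pcs = state["cohort"], state["rows"], state["grm"], state["pcs"]
        yA = inverse_normal_transform(cohort.phenos["trait_a"].to_numpy()[rows])
        yB = inverse_normal_transform(cohort.phenos["trait_b"].to_numpy()[rows])
        raw_fit, adj_fit, verdict = stratification_check(yA, None, grm, pcs)
        results["h2_unadjusted"] = raw_fit
        results["h2_adjusted"] = adj_fit
        results["strat_verdict"] = verdict
        bfit = reml_bivariate(yA, yB, pcs, grm)
        results["bivariate_fit"] = bfit
        if np.isfinite(bfit.rg) and bfit.r_p != 0:
            est = mc_standard_error(
                bfit.rg, bfit.se_rg, bfit.h2_A, bfit.se_h2_A,
                bfit.h2_B, bfit.se_h2_B, bfit.r_p, bfit.se_rp,
                n_draws=prof["mc_draws"], seed=config.seed,
            )
            results["bivariate_h2"] = est
            results["bivariate_verdict"] = flag_inflation(est)

    @stage("trio")
    def _trio():
        cohort = state["cohort"]
        if cohort.trios().empty:
            results["trio"] = None
            return
        frame = trio_design(cohort)
        tr = trio_regression(
            frame["y"], frame["score_child"], frame["score_mother"], frame["score_father"]
        )
        tr.se_attenuation, tr.n_boot_dropped = bootstrap_attenuation_se(
            frame["y"], frame["score_child"], frame["score_mother"],
            frame["score_father"], n_reps=prof["n_boot"], seed=config.seed,
        )
        tr.n_boot = prof["n_boot"]
        tr.p_diff = sur_difference_test(
            frame["y"], frame["score_child"], frame["score_mother"], frame["score_father"]
        )["p"]
        results["trio"] = tr
        weights = weights_from_effects(cohort, "a")
        nt = nontransmitted_score(cohort, weights, p_threshold=1.0, window_kb=0.0)
        child_rows = cohort.row_of(nt["child"].to_numpy())
        yc = cohort.phenos["trait_a"].to_numpy()[child_rows]
        r = float(np.corrcoef(nt["score_nt"], yc)[0, 1])
        results["nontransmitted_corr"] = r

    @stage("spousal")
    def _spouse():
        cohort = state["cohort"]
        pairs = cohort.spouse_pairs
        rows_out = []
        if pairs:
            ids = cohort.individuals["id"]
            for trait in ("trait_a", "control"):
                vals = pd.Series(cohort.phenos[trait].to_numpy(), index=ids)
                r, se, n = spousal_correlation(vals, pairs)
                rows_out.append({"variable": trait, "r": r, "se": se, "n": n})
            weights = weights_from_effects(cohort, "a")
            score, _ = build_pgs(
                cohort.dosages, cohort.variants, weights,
                p_threshold=1.0, window_kb=0.0, r2_max=1.1,
            )
            vals = pd.Series(score, index=ids)
            r, se, n = spousal_correlation(vals, pairs)
            rows_out.append({"variable": "pgs_trait_a", "r": r, "se": se, "n": n})
        results["spousal"] = pd.DataFrame(rows_out)

    @stage("report")
    def _report():
        return make_report(results, out)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    manifest["results"] = results
    return manifest


def make_report(results: dict, out_dir: str | Path) -> list[Path]:
    """Render the paper-shaped TSV tables and a markdown summary.

    Numeric cells carry SEs in parentheses.  Missing sections are omitted
    with a logged warning line in the markdown.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    md: list[str] = ["# Scenario report\n"]

    raw_fit = results.get("h2_unadjusted")
    adj_fit = results.get("h2_adjusted")
    if raw_fit is not None and adj_fit is not None:
        t1 = pd.DataFrame(
            [
                {
                    "trait": "trait_a",
                    "unadjusted": fmt_est(raw_fit.h2, raw_fit.se_h2),
                    "pc_adjusted": fmt_est(adj_fit.h2, adj_fit.se_h2),
                }
            ]
        )
        p = out / "table_stratification.tsv"
        t1.to_csv(p, sep="\t", index=False)
        files.append(p)
        md.append("## Stratification (h2 before/after PC adjustment)\n")
        md.append(t1.to_markdown(index=False))
        md.append(f"\n{results.get('strat_verdict', '')}\n")
    else:
        md.append("_warning: stratification section missing_\n")

    tr = results.get("trio")
    if tr is not None:
        t2 = pd.DataFrame(
            [
                {"term": "Child PGS",
                 "independent": fmt_est(tr.b_child_ind, tr.se_child_ind),
                 "adjusted": fmt_est(tr.b_child_adj, tr.se_child_adj),
                 "p_difference": f"{tr.p_diff:.3g}",
                 "attenuation": fmt_pct(tr.attenuation_pct, tr.se_attenuation)},
                {"term": "Mother PGS",
                 "independent": fmt_est(tr.b_mother_ind, tr.se_mother_ind),
                 "adjusted": fmt_est(tr.b_mother_adj, tr.se_mother_adj),
                 "p_difference": "", "attenuation": ""},
                {"term": "Father PGS",
                 "independent": fmt_est(tr.b_father_ind, tr.se_father_ind),
                 "adjusted": fmt_est(tr.b_father_adj, tr.se_father_adj),
                 "p_difference": "", "attenuation": ""},
            ]
        )
        p = out / "table_trio.tsv"
        t2.to_csv(p, sep="\t", index=False)
        files.append(p)
        md.append("## Dynastic effects (trio polygenic-score attenuation)\n")
        md.append(t2.to_markdown(index=False))
        if "nontransmitted_corr" in results:
            md.append(
                f"\nNontransmitted-score / child-phenotype correlation: "
                f"{results['nontransmitted_corr']:.3f}\n"
            )
    else:
        md.append("_warning: trio section missing_\n")

    sp = results.get("spousal")
    if sp is not None and len(sp):
        t3 = sp.copy()
        t3["r (SE)"] = [fmt_est(r, s) for r, s in zip(t3["r"], t3["se"])]
        t3 = t3[["variable", "r (SE)", "n"]]
        p = out / "table_spousal.tsv"
        t3.to_csv(p, sep="\t", index=False)
        files.append(p)
        md.append("## Assortative mating (spousal correlations)\n")
        md.append(t3.to_markdown(index=False))
    else:
        md.append("_warning: spousal section missing_\n")

    best = results.get("bivariate_h2")
    bfit = results.get("bivariate_fit")
    if best is not None and bfit is not None:
        md.append("## Bivariate heritability\n")
        md.append(
            f"rg = {fmt_est(bfit.rg, bfit.se_rg)}, h2_A = {fmt_est(bfit.h2_A, bfit.se_h2_A)}, "
            f"h2_B = {fmt_est(bfit.h2_B, bfit.se_h2_B)}, r_p = {fmt_est(bfit.r_p, bfit.se_rp)}\n"
        )
        md.append(f"h2_AB = {fmt_est(best.h2_ab, best.se_h2_ab)}\n")
        md.append(results.get("bivariate_verdict", "") + "\n")

    p = out / "report.md"
    p.write_text("\n".join(md))
    files.append(p)
    return files
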