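"""Simulator: founder draws, effects, phenotypes, mating, transmission."""

import numpy as np
import pandas as pd
import pytest

import popdynh2 as p
from popdynh2.cohort import draw_effects, genetic_values, make_phenotypes


def hudson_fst(dosages, labels):
    """Independent ratio-of-averages Hudson estimator, used as the oracle."""
    num = den = 0.0
    for k1, k2 in [(0, 1)]:
        d1 = dosages[labels == k1]
        d2 = dosages[labels == k2]
        p1 = d1.mean(axis=0) / 2
        p2 = d2.mean(axis=0) / 2
        n1, n2 = len(d1), len(d2)
        num += np.sum(
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n1 - 1)
            - p2 * (1 - p2) / (n2 - 1)
        )
        den += np.sum(p1 * (1 - p2) + p2 * (1 - p1))
    return num / den


@pytest.mark.parametrize(
    "kw",
    [
        dict(maf_range=(0.0, 0.5)),
        dict(maf_range=(0.5, 0.1)),
        dict(n_causal=100, n_snps=50),
        dict(h2_target=1.2),
        dict(rg_true=1.5),
        dict(env_corr=-2.0),
        dict(spousal_corr_target=1.0),
        dict(fst=1.0),
        dict(subpop_shift=(0.0, 0.0)),  # length mismatch with n_subpops=1
        dict(n_subpops=50, n_founder_couples=10, subpop_shift=tuple([0.0] * 50)),
    ],
)
def test_config_validation(kw):
    with pytest.raises(p.ConfigError):
        p.SimConfig(**kw)


def test_zero_fst_gives_ancestral_frequencies():
    cfg = p.SimConfig(n_founder_couples=50, n_snps=100, n_causal=10, n_subpops=2,
                      fst=0.0, subpop_shift=(0.0, 0.0), seed=1)
    c = p.simulate_founders(cfg)
    assert np.allclose(c.variants["freq_pop0"], c.variants["founder_freq"])
    assert np.allclose(c.variants["freq_pop1"], c.variants["founder_freq"])


def test_fst_calibration_hudson():
    cfg = p.SimConfig(n_founder_couples=1000, n_snps=5000, n_causal=10, n_subpops=2,
                      fst=0.1, subpop_shift=(0.0, 0.0), seed=2)
    c = p.simulate_founders(cfg)
    labels = c.individuals["subpop"].to_numpy()
    est = hudson_fst(c.dosages, labels)
    assert abs(est - 0.1) < 0.01


def test_founder_determinism():
    cfg = p.SimConfig(n_founder_couples=40, n_snps=80, n_causal=20, seed=7)
    a = p.simulate_scenario(cfg)
    b = p.simulate_scenario(cfg)
    assert np.array_equal(a.dosages, b.dosages)
    assert a.phenos.equals(b.phenos)
    assert a.individuals.equals(b.individuals)


def test_effects_perfect_correlation_proportional():
    cfg = p.SimConfig(n_founder_couples=50, n_snps=200, n_causal=100, rg_true=1.0,
                      h2_target=0.5, h2_target_B=0.5, seed=3)
    eff = draw_effects(cfg)
    assert np.allclose(eff.beta_a, eff.beta_b)


def test_effects_correlation_recovered():
    cfg = p.SimConfig(n_founder_couples=50, n_snps=1500, n_causal=1000, rg_true=0.7,
                      h2_target=0.5, h2_target_B=0.5, seed=4)
    eff = draw_effects(cfg)
    r = np.corrcoef(eff.beta_a[eff.causal], eff.beta_b[eff.causal])[0, 1]
    assert abs(r - 0.7) < 0.05


def test_null_heritability_zero_effects():
    cfg = p.SimConfig(n_founder_couples=50, n_snps=100, n_causal=10, h2_target=0.0, seed=5)
    eff = draw_effects(cfg)
    assert np.all(eff.beta_a == 0.0)
    c = p.simulate_founders(cfg)
    assert np.var(genetic_values(c, eff)["g_a"]) == 0.0


def test_noncausal_variants_have_zero_effect():
    cfg = p.SimConfig(n_founder_couples=50, n_snps=300, n_causal=100, seed=6)
    eff = draw_effects(cfg)
    assert np.all(eff.beta_a[~eff.causal] == 0.0)
    assert np.isclose(np.sum(eff.beta_a**2), cfg.h2_target)


def test_founder_phenotype_unit_variance():
    cfg = p.SimConfig(n_founder_couples=2000, n_snps=400, n_causal=200,
                      h2_target=0.6, seed=8)
    c = p.simulate_scenario(cfg)
    v = np.var(c.phenos["trait_a"])
    assert abs(v - 1.0) < 0.03


def test_subpop_shift_mean_difference():
    # fst = 0 isolates the configured mean shift from genetic drift
    cfg = p.SimConfig(n_founder_couples=2000, n_snps=400, n_causal=200, h2_target=0.4,
                      n_subpops=2, fst=0.0, subpop_shift=(0.5, -0.5), seed=9)
    c = p.simulate_scenario(cfg)
    lab = c.individuals["subpop"].to_numpy()
    y = c.phenos["trait_a"].to_numpy()
    assert abs((y[lab == 0].mean() - y[lab == 1].mean()) - 1.0) < 0.1


def test_pure_noise_phenotype():
    cfg = p.SimConfig(n_founder_couples=500, n_snps=100, n_causal=10,
                      h2_target=0.0, seed=10)
    c = p.simulate_scenario(cfg)
    assert np.allclose(c.phenos["trait_a"], c.phenos["e_a"])


def test_random_mating_null_correlation():
    cfg = p.SimConfig(n_founder_couples=1000, n_snps=200, n_causal=100,
                      spousal_corr_target=0.0, n_generations=2, seed=14)
    c = p.simulate_scenario(cfg)
    ids = c.individuals["id"]
    vals = pd.Series(c.phenos["trait_a"].to_numpy(), index=ids)
    r, se, n = p.spousal_correlation(vals, c.spouse_pairs_by_gen[0])
    assert abs(r) < 2.0 / np.sqrt(n)


def test_assortment_calibrated_to_spousal_target():
    cfg = p.SimConfig(n_founder_couples=2000, n_snps=300, n_causal=150, h2_target=0.6,
                      spousal_corr_target=0.56, n_generations=2, seed=15)
    c = p.simulate_scenario(cfg)
    ids = c.individuals["id"]
    vals = pd.Series(c.phenos["trait_a"].to_numpy(), index=ids)
    r, _, _ = p.spousal_correlation(vals, c.spouse_pairs_by_gen[0])
    assert 0.52 <= r <= 0.60
    # phenotypic assortment must induce a positive genetic-value correlation
    gvals = pd.Series(c.phenos["g_a"].to_numpy(), index=ids)
    rg, seg, _ = p.spousal_correlation(gvals, c.spouse_pairs_by_gen[0])
    assert rg > 2 * seg


def test_mendelian_transmission(sib_cohort):
    c = sib_cohort
    kids = np.flatnonzero(c.generation_mask(1))
    moms = c.row_of(c.individuals["mother_id"].to_numpy()[kids])
    dads = c.row_of(c.individuals["father_id"].to_numpy()[kids])
    # bookkeeping identity: child dosage = transmitted_m + transmitted_f
    assert np.array_equal(
        c.dosages[kids], c.transmitted_m[kids] + c.transmitted_f[kids]
    )
    # homozygous parents transmit deterministically
    hom = c.dosages[dads] == 2
    assert np.all(c.transmitted_f[kids][hom] == 1)
    # heterozygous parents transmit each allele with probability 1/2
    het = c.dosages[dads] == 1
    n_het = het.sum()
    assert n_het > 10_000
    frac = c.transmitted_f[kids][het].mean()
    assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / n_het)
    # child dosage distribution for het x het parents is (1/4, 1/2, 1/4)
    both = (c.dosages[dads] == 1) & (c.dosages[moms] == 1)
    d = c.dosages[kids][both]
    probs = np.bincount(d, minlength=3) / d.size
    assert np.allclose(probs, [0.25, 0.5, 0.25], atol=4 * np.sqrt(0.25 / d.size))


def test_nontransmitted_complements_transmitted(sib_cohort):
    c = sib_cohort
    kids = np.flatnonzero(c.generation_mask(1))
    moms = c.row_of(c.individuals["mother_id"].to_numpy()[kids])
    nt = c.nontransmitted(kids, "m")
    assert np.array_equal(nt + c.transmitted_m[kids], c.dosages[moms])


def test_single_generation_has_no_trios():
    cfg = p.SimConfig(n_founder_couples=30, n_snps=50, n_causal=10, n_generations=1, seed=16)
    c = p.simulate_scenario(cfg)
    assert c.trios().empty
    from popdynh2.pgs import weights_from_effects

    with pytest.raises(p.DataError):
        p.nontransmitted_score(c, weights_from_effects(c, "a"))


def test_reproduce_requires_pairs():
    cfg = p.SimConfig(n_founder_couples=30, n_snps=50, n_causal=10, seed=17)
    c = p.simulate_founders(cfg)
    with pytest.raises(p.StateError):
        p.reproduce(c, cfg)


def test_allele_frequency_conservation(null_cohort):
    c = null_cohort
    g0 = np.flatnonzero(c.generation_mask(0))
    g1 = np.flatnonzero(c.generation_mask(1))
    p0 = c.dosages[g0].mean(axis=0) / 2
    p1 = c.dosages[g1].mean(axis=0) / 2
    tol = 4 * np.sqrt(p0 * (1 - p0) / (2 * len(g1)))
    assert np.mean(np.abs(p1 - p0) <= tol) > 0.99


def test_assortment_raises_offspring_genetic_variance():
    cfg = p.preset_config("assortment", seed=18, n_founder_couples=1000,
                          n_snps=600, n_causal=300)
    c = p.simulate_scenario(cfg)
    v0 = np.var(c.phenos["g_a"][c.generation_mask(0)])
    v2 = np.var(c.phenos["g_a"][c.generation_mask(2)])
    assert v2 > v0


def test_dynastic_component_zero_for_founders():
    cfg = p.preset_config("dynastic", seed=19, n_founder_couples=100,
                          n_snps=200, n_causal=100)
    c = p.simulate_scenario(cfg)
    assert np.all(c.phenos["dynastic"][c.generation_mask(0)] == 0.0)
    assert np.std(c.phenos["dynastic"][c.generation_mask(1)]) > 0.0


def test_negative_control_untouched_by_mechanisms():
    cfg = p.preset_config("dynastic", seed=20, n_founder_couples=300,
                          n_snps=300, n_causal=150,
                          n_subpops=1, subpop_shift=(0.7,))
    c = p.simulate_scenario(cfg)
    # control = own genetic value + own residual: no shift, no dynastic term
    assert np.allclose(
        c.phenos["control"], c.phenos["g_control"] + c.phenos["e_control"]
    )
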