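import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy import stats

from lumoscall import cnmodel
from lumoscall.cnmodel import (CloneModel, assign_segment_clone,
                               assign_variant_clone, betabinomial_pmf,
                               cbs_segment, copy_state_for_clone,
                               exon_depth_loglik, expected_exon_depth,
                               expected_het_af, expected_somatic_af,
                               expected_somatic_af_piecewise, f_prior_density,
                               f_prior_logpdf, fit_clone_model,
                               het_af_loglik, round_half_away,
                               segment_depth_ratio, somatic_af_loglik)
from lumoscall.formats_io import Config


# ---------------------------------------------------------------------------
# closed-form allele-fraction algebra
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("f,n,m,expected", [
    (0.5, 2, 1, 0.25),
    (1.0, 2, 1, 0.5),
    (0.2, 2, 1, 0.10),
    (0.0, 3, 1, 0.0),       # no tumor cells -> no somatic signal
])
def test_expected_somatic_af(f, n, m, expected):
    assert expected_somatic_af(f, n, m) == pytest.approx(expected)


@pytest.mark.parametrize("f,n,m,expected", [
    (1.0, 2, 1, 0.5),
    (0.6, 3, 1, 0.4),
    (0.0, 2, 1, 0.5),        # pure normal: hets sit at 1/2
])
def test_expected_het_af(f, n, m, expected):
    assert expected_het_af(f, n, m) == pytest.approx(expected)


def test_somatic_af_degenerate_denominator():
    assert expected_somatic_af(1.0, 0, 0) == 0.0


def test_piecewise_somatic_af_cases():
    f = np.array([0.5, 0.2])
    assert expected_somatic_af_piecewise(0, f, 0, 2, 1) == pytest.approx(0.25)
    # other clone in an altered segment occupies one copy
    assert expected_somatic_af_piecewise(1, f, 0, 3, 1) == pytest.approx(
        0.2 / (0.5 * 3 + 2 * 0.5))
    # homozygous deletion in the altered clone: variant survives only in
    # non-deleted cells
    f2 = np.array([0.6, 0.5])
    assert expected_somatic_af_piecewise(1, f2, 0, 0, 0) == pytest.approx(0.2)


@pytest.mark.parametrize("f,n,c,r_cn,expected", [
    (1.0, 2, 2.0, 100.0, 100.0),
    (0.5, 4, 2.0, 100.0, 150.0),
    (1.0, 0, 2.0, 100.0, 0.0),
])
def test_expected_exon_depth(f, n, c, r_cn, expected):
    assert expected_exon_depth(f, n, c, r_cn) == pytest.approx(expected)


@pytest.mark.parametrize("f,c,ratio,phi,expected", [
    (1.0, 2.0, 1.0, 0.5, (2, 1)),
    (0.5, 2.0, 1.5, None, (4, 2)),   # (3 - 1) / 0.5
    (1.0, 2.0, 1.0, 0.5, (2, 1)),
])
def test_copy_state_inversion(f, c, ratio, phi, expected):
    assert copy_state_for_clone(f, c, ratio, phi) == expected


def test_copy_state_m_from_het_fraction():
    # f=1, N=2, het fraction 0.5 -> M = 2 * 0.5 / 1 = 1
    assert copy_state_for_clone(1.0, 2.0, 1.0, 0.5) == (2, 1)
    # zero ratio -> homozygous deletion
    assert copy_state_for_clone(0.5, 2.0, 0.0, 0.5) == (0, 0)


def test_copy_state_round_trips_generative_states():
    """The depth/het inversion recovers every (f, N, M) condition exactly
    from its own noise-free expectations."""
    for f in (0.3, 0.6, 0.9):
        for n, m in ((1, 0), (2, 0), (2, 1), (3, 1), (4, 1), (4, 2)):
            ratio = (f * n + 2 * (1 - f)) / 2.0
            phi = expected_het_af(f, n, m)
            assert copy_state_for_clone(f, 2.0, ratio, phi) == (n, m), (f, n, m)


def test_round_half_away_from_zero():
    assert round_half_away([0.5, 1.5, -0.5, 2.4]).tolist() == [1.0, 2.0, -1.0, 2.0]


# ---------------------------------------------------------------------------
# likelihood primitives against independent oracles
# ---------------------------------------------------------------------------

def bb_pmf_lgamma(k, n, a, b):
    """Beta-binomial pmf via explicit log-gamma algebra (oracle)."""
    return math.exp(
        math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
        + math.lgamma(k + a) + math.lgamma(n - k + b) - math.lgamma(n + a + b)
        + math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b))


def test_betabinomial_uniform_beta_closed_form():
    # Beta(1,1) mixing -> discrete uniform: pmf = 1/(n+1)
    assert betabinomial_pmf(1, 2, 1.0, 1.0) == pytest.approx(1 / 3, rel=1e-12)
    for n in (5, 30):
        for k in range(n + 1):
            assert betabinomial_pmf(k, n, 1.0, 1.0) == pytest.approx(
                1 / (n + 1), rel=1e-12)


def test_betabinomial_degenerate_and_normalized():
    assert betabinomial_pmf(0, 0, 2.0, 3.0) == 1.0
    k = np.arange(31)
    assert betabinomial_pmf(k, 30, 7.5, 7.5).sum() == pytest.approx(1.0, rel=1e-12)


def test_betabinomial_rejects_bad_shapes():
    with pytest.raises(ValueError):
        betabinomial_pmf(1, 2, 0.0, 1.0)
    with pytest.raises(ValueError):
        betabinomial_pmf(1, 2, 1.0, -2.0)


def test_betabinomial_matches_integral_oracle():
    """pmf(k; n, a, b) equals the binomial pmf integrated against the Beta
    mixing density (brute-force quadrature)."""
    for (k, n, a, b) in [(3, 10, 2.0, 5.0), (0, 12, 7.5, 7.5), (20, 40, 50.0, 30.0)]:
        integrand = lambda p: stats.binom.pmf(k, n, p) * stats.beta.pdf(p, a, b)
        val, _ = integrate.quad(integrand, 0.0, 1.0, epsabs=1e-13, epsrel=1e-12)
        assert betabinomial_pmf(k, n, a, b) == pytest.approx(val, rel=1e-8)


def test_pmf_oracle_grid_binomial_poisson_betabinomial(rng):
    """1000-case equivalence grid against log-gamma oracles (1e-10 relative)."""
    cases = 0
    while cases < 1000:
        n = int(rng.integers(1, 5000))
        k = int(rng.integers(0, n + 1))
        p = float(rng.uniform(0.01, 0.99))
        a = float(rng.uniform(0.1, 300.0))
        b = float(rng.uniform(0.1, 300.0))
        lam = float(rng.uniform(0.1, 2000.0))

        binom_oracle = math.exp(
            math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
            + k * math.log(p) + (n - k) * math.log(1 - p))
        assert stats.binom.pmf(k, n, p) == pytest.approx(binom_oracle, rel=1e-10)

        pois_oracle = math.exp(k * math.log(lam) - lam - math.lgamma(k + 1))
        assert stats.poisson.pmf(k, lam) == pytest.approx(pois_oracle, rel=1e-10)

        assert betabinomial_pmf(k, n, a, b) == pytest.approx(
            bb_pmf_lgamma(k, n, a, b), rel=1e-10)
        cases += 1


def test_poisson_depth_likelihood_examples():
    assert math.exp(exon_depth_loglik(100, 100)) == pytest.approx(0.039861, abs=1e-5)
    assert math.exp(exon_depth_loglik(0, 0)) == pytest.approx(1.0, abs=1e-3)
    # unimodality: likelihood decreases as |observed - expected| grows
    lls = [float(exon_depth_loglik(100 + d, 100)) for d in (0, 5, 10, 20, 40)]
    assert all(x > y for x, y in zip(lls, lls[1:]))


def test_het_likelihood_parameter_plumbing_and_symmetry():
    assert float(het_af_loglik(15, 30, 30.0, 0.5)) == pytest.approx(
        math.log(bb_pmf_lgamma(15, 30, 15.0, 15.0)), rel=1e-10)
    assert float(het_af_loglik(10, 30, 30.0, 0.5)) == pytest.approx(
        float(het_af_loglik(20, 30, 30.0, 0.5)), rel=1e-12)


def test_het_likelihood_mean_approaches_phi_at_large_w(rng):
    w, phi, n = 1e5, 0.3, 500
    p = rng.beta(w * phi, w * (1 - phi), 20000)
    k = rng.binomial(n, p)
    assert k.mean() == pytest.approx(phi * n, rel=0.01)


def test_somatic_likelihood_folding():
    # phi = 0.25, W = 40 -> shapes (10, 30); phi = 0.75 folds to the same
    assert float(somatic_af_loglik(12, 60, 40.0, 0.25)) == pytest.approx(
        math.log(bb_pmf_lgamma(12, 60, 10.0, 30.0)), rel=1e-10)
    assert float(somatic_af_loglik(12, 60, 40.0, 0.75)) == pytest.approx(
        float(somatic_af_loglik(12, 60, 40.0, 0.25)), rel=1e-12)
    # unfolded mode keeps phi as is
    assert float(somatic_af_loglik(12, 60, 40.0, 0.75, folded=False)) == \
        pytest.approx(math.log(bb_pmf_lgamma(12, 60, 30.0, 10.0)), rel=1e-10)


def test_f_prior_mode_density_and_normalization():
    # f_pi = 0.5, alpha = 1.5 -> Beta(1.5, 1.5); density at the mode is 4/pi
    assert f_prior_density(0.5, 0.5, 1.5) == pytest.approx(4 / math.pi, rel=1e-12)
    grid = np.linspace(1e-4, 1 - 1e-4, 10_001)
    for f_pi in (0.3, 0.5, 0.7):
        dens = f_prior_density(grid, f_pi, 1.5)
        assert grid[np.argmax(dens)] == pytest.approx(f_pi, abs=2e-4)
    val, _ = integrate.quad(lambda x: f_prior_density(x, 0.3, 1.5), 0, 1)
    assert val == pytest.approx(1.0, rel=1e-8)
    with pytest.raises(ValueError):
        f_prior_logpdf(0.5, 0.5, 1.0)


def test_allele_fraction_limits():
    assert expected_somatic_af(1e-12, 2, 1) == pytest.approx(0.0, abs=1e-11)
    assert expected_somatic_af(1.0, 2, 1) == 0.5
    assert expected_het_af(1e-12, 2, 1) == pytest.approx(0.5, abs=1e-12)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def test_cbs_flat_profile_single_segment(rng):
    x = rng.normal(0.0, 0.05, 500)
    assert cbs_segment(x, alpha=1e-5) == [(0, 500)]


def test_cbs_recovers_step_boundary(rng):
    x = np.concatenate([rng.normal(0.0, 0.05, 250),
                        rng.normal(-1.0, 0.05, 250)])
    segs = cbs_segment(x, alpha=1e-5)
    assert len(segs) == 2
    assert abs(segs[0][1] - 250) <= 2


def test_cbs_up_down_three_segments(rng):
    x = np.concatenate([rng.normal(0.0, 0.05, 150),
                        rng.normal(0.58, 0.05, 100),
                        rng.normal(0.0, 0.05, 150)])
    segs = cbs_segment(x, alpha=1e-5)
    assert len(segs) == 3
    assert abs(segs[0][1] - 150) <= 2 and abs(segs[1][1] - 250) <= 2


def test_cbs_short_profile_single_segment(caplog):
    with caplog.at_level("WARNING", logger="lumoscall"):
        assert cbs_segment(np.zeros(7)) == [(0, 7)]


def test_segment_depth_ratio_per_chromosome(rng):
    exons = pd.DataFrame({
        "chrom": ["1"] * 100 + ["2"] * 100,
        "tumor_depth": np.concatenate([np.full(50, 100.0), np.full(50, 50.0),
                                       np.full(100, 100.0)])
        + rng.normal(0, 2.0, 200),
        "control_depth": np.full(200, 100.0),
    })
    seg_id = segment_depth_ratio(exons, 1e-5)
    assert len(np.unique(seg_id[:50])) == 1
    assert len(np.unique(seg_id[50:100])) == 1
    assert seg_id[0] != seg_id[60]
    assert len(np.unique(seg_id[100:])) == 1   # chromosomes never merge


# ---------------------------------------------------------------------------
# clone assignment and the EM fit
# ---------------------------------------------------------------------------

def test_assign_segment_clone_recovers_generating_clone(rng):
    """A segment generated under clone 2's (f, N, M) is assigned clone 2."""
    model = CloneModel(f=np.array([0.6, 0.3]), W=np.array([200.0, 200.0]), C=2.0)
    f2, n2, m2 = 0.3, 3, 1
    n_exons, n_hets = 200, 50
    rc = np.full(n_exons, 400.0)
    rt = rng.poisson((f2 * n2 + 2 * (1 - f2)) * rc / 2.0).astype(float)
    phi = expected_het_af(f2, n2, m2)
    het_n = rng.poisson(rt.mean(), n_hets)
    band = np.where(rng.random(n_hets) < 0.5, phi, 1 - phi)
    het_k = rng.binomial(het_n, band)
    seg = cnmodel.Segment(chrom="1", start=0, end=1, exon_lo=0, exon_hi=n_exons,
                          mean_ratio=float(rt.mean() / rc.mean()),
                          het_minor_fraction=float(np.minimum(het_k, het_n - het_k).sum()
                                                   / het_n.sum()))
    seg.per_clone_states = [
        copy_state_for_clone(model.f[i], model.C, seg.mean_ratio,
                             seg.het_minor_fraction)
        for i in range(model.K)]
    assert assign_segment_clone(model, seg, rt, rc, het_k, het_n) == 1
    assert seg.per_clone_states[1] == (n2, m2)


def test_assign_segment_clone_k1_and_tie_break():
    model = CloneModel(f=np.array([0.5]), W=np.array([100.0]), C=2.0)
    seg = cnmodel.Segment(chrom="1", start=0, end=1, exon_lo=0, exon_hi=10,
                          mean_ratio=1.0, het_minor_fraction=0.5)
    seg.per_clone_states = [(2, 1)]
    rc = np.full(10, 100.0)
    assert assign_segment_clone(model, seg, rc, rc, np.array([50]),
                                np.array([100])) == 0
    # diploid segment: every clone implies (2, 1); tie goes to the larger f
    model2 = CloneModel(f=np.array([0.6, 0.3]), W=np.array([100.0, 100.0]), C=2.0)
    seg.per_clone_states = [(2, 1), (2, 1)]
    assert assign_segment_clone(model2, seg, rc, rc, np.array([50]),
                                np.array([100])) == 0


def test_assign_variant_clone_by_allele_fraction():
    model = CloneModel(f=np.array([0.5, 0.2]), W=np.array([100.0, 100.0]), C=2.0)
    seg = cnmodel.Segment(chrom="1", start=0, end=1, exon_lo=0, exon_hi=10,
                          mean_ratio=1.0, het_minor_fraction=0.5,
                          clone=1, n_total=2, m_minor=1)
    # BAF 0.25 matches clone 1 (phi = 0.25); BAF 0.10 matches clone 2 (0.10)
    clone, phi = assign_variant_clone(model, seg, r_b=100, r_t=400)
    assert clone == 0 and phi == pytest.approx(0.25)
    clone, phi = assign_variant_clone(model, seg, r_b=40, r_t=400)
    assert clone == 1 and phi == pytest.approx(0.10)


def test_assign_variant_clone_recovery_rate(rng):
    """>90% of synthetic variants at 500x are assigned their true clone."""
    f = np.array([0.6, 0.3, 0.1])
    model = CloneModel(f=f, W=np.full(3, 200.0), C=2.0)
    seg = cnmodel.Segment(chrom="1", start=0, end=1, exon_lo=0, exon_hi=10,
                          mean_ratio=1.0, het_minor_fraction=0.5,
                          clone=1, n_total=2, m_minor=1)
    correct = total = 0
    for true_clone in range(3):
        phi = expected_somatic_af_piecewise(true_clone, f, 0, 2, 1)
        for _ in range(100):
            r_t = int(rng.poisson(500))
            r_b = int(rng.binomial(r_t, phi))
            clone, _ = assign_variant_clone(model, seg, r_b, r_t)
            correct += clone == true_clone
            total += 1
    assert correct / total > 0.9


def test_fit_requires_hets(cohort_k1):
    exons, hets, soms = cohort_k1.fit_inputs()
    with pytest.raises(ValueError, match="heterozygous"):
        fit_clone_model(exons, hets.iloc[:0], soms, Config(K=1))


def test_fit_clone_model_k1_recovery(cohort_k1):
    """Truth f=0.7, diploid + one-copy-loss: f recovered within 0.05 and
    the loss segment state identified."""
    exons, hets, soms = cohort_k1.fit_inputs()
    model, segments, assignments, trace = fit_clone_model(
        exons, hets, soms, Config(K=1))
    assert model.f[0] == pytest.approx(0.7, abs=0.05)
    states = sorted((s.n_total, s.m_minor) for s in segments)
    assert states == [(1, 0), (2, 1)]
    assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))


def test_fit_clone_model_k2_recovery(cohort_k2):
    """Truth f={0.6, 0.3} with loss and gain events: both fractions
    recovered within 0.05, objective non-decreasing."""
    exons, hets, soms = cohort_k2.fit_inputs()
    model, segments, assignments, trace = fit_clone_model(
        exons, hets, soms, Config(K=2))
    assert model.f[0] == pytest.approx(0.6, abs=0.05)
    assert model.f[1] == pytest.approx(0.3, abs=0.05)
    assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))
    # identifiability: fractions sorted descending
    assert list(model.f) == sorted(model.f, reverse=True)


def test_copy_state_recovery_suite():
    """(N, M) recovered for >= 90% of segments across the 15-condition
    grid (f x copy state) at 400x."""
    from lumoscall.simulate import SegmentSpec, synthesize_cohort
    hits = total = 0
    for f in (0.3, 0.6, 0.9):
        for n, m in ((1, 0), (2, 0), (2, 1), (3, 1), (4, 1)):
            co = synthesize_cohort([f], [SegmentSpec(60), SegmentSpec(60, 0, n, m)],
                                   n_hets=80, n_somatics=0, mean_coverage=400,
                                   seed=100 + n * 10 + m + int(f * 100))
            exons, hets, _ = co.fit_inputs()
            model = CloneModel(f=np.array([f]), W=np.array([co.w_truth]), C=2.0)
            data = cnmodel._EMData(exons, hets, hets.iloc[:0], co.seg_id)
            segs = cnmodel._build_segments(exons, data, co.seg_id)
            cnmodel._e_step(model, data, segs, True)
            hits += (segs[1].n_total, segs[1].m_minor) == (n, m)
            total += 1
    assert total == 15 and hits / total >= 0.9


def test_dilution_linearity(cohort_k1):
    """Mixing tumor with matched-normal reads scales the fitted sample
    fraction linearly (|f_hat - d*f| < 0.08)."""
    from lumoscall.simulate import dilute_cohort
    cfg = Config(K=1)
    for d in (1.0, 0.75, 0.5):
        exons, hets, soms = dilute_cohort(cohort_k1, d, seed=11)
        model, *_ = fit_clone_model(exons, hets, soms, cfg)
        assert model.f[0] == pytest.approx(0.7 * d, abs=0.08), d
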