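"""Mendelian randomization: 2SLS, instruments, harmonization, Wald/IVW."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twasmr import (
    DEFAULT_PRS_SNPS_WEIGHTS,
    PrsWeights,
    bidirectional_mr,
    build_prs,
    f_statistic,
    harmonize,
    ivw,
    select_instrument,
    tsls,
    two_sample_mr,
    wald_ratio,
)
from twasmr.mr import _classify


def _iv_data(seed=0, n=50, theta=0.7):
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, 0.3, n).astype(float)
    x = 0.5 * g + rng.standard_normal(n)
    y = theta * x + rng.standard_normal(n)
    return g, x, y


# ---------------------------------------------------------------------------
# instrument selection / strength


def test_select_single_record_returned():
    df = pd.DataFrame([{"gene": "g1", "snp_id": "rs1", "beta": 0.5,
                        "se": 0.1, "p": 1e-6, "n": 100}])
    out = select_instrument(df)
    assert out.iloc[0]["snp_id"] == "rs1"
    assert out.iloc[0]["f_stat"] == pytest.approx(25.0)


def test_select_minimum_p_wins():
    df = pd.DataFrame(
        [
            {"gene": "g1", "snp_id": "rsA", "beta": 0.2, "se": 0.05,
             "p": 1e-8, "n": 100},
            {"gene": "g1", "snp_id": "rsB", "beta": 0.9, "se": 0.05,
             "p": 1e-4, "n": 100},
        ]
    )
    assert select_instrument(df).iloc[0]["snp_id"] == "rsA"


def test_select_tiebreaks_exhaustively():
    """p ties -> larger |beta|; |beta| ties -> lexicographic snp_id,
    over every ordering of three records."""
    records = [
        {"gene": "g", "snp_id": "rsC", "beta": 0.3, "se": 0.1, "p": 1e-5, "n": 50},
        {"gene": "g", "snp_id": "rsA", "beta": -0.2, "se": 0.1, "p": 1e-5, "n": 50},
        {"gene": "g", "snp_id": "rsB", "beta": 0.3, "se": 0.1, "p": 1e-5, "n": 50},
    ]
    for perm in itertools.permutations(records):
        chosen = select_instrument(pd.DataFrame(list(perm))).iloc[0]
        assert chosen["snp_id"] == "rsB"  # |0.3| beats |0.2|; rsB < rsC


def test_f_statistic_algebra():
    # construct x = g exactly: r2 = 1 -> F infinite
    g = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
    f, r2 = f_statistic(g, g)
    assert np.isinf(f) and r2 == 1.0
    # independent noise: F = (n-2) r2/(1-r2)
    rng = np.random.default_rng(1)
    g = rng.binomial(2, 0.4, 102).astype(float)
    x = rng.standard_normal(102)
    f, r2 = f_statistic(g, x)
    assert f == pytest.approx(100 * r2 / (1 - r2), rel=1e-10)


def test_f_statistic_constant_instrument_rejected():
    with pytest.raises(ValueError, match="constant"):
        f_statistic(np.ones(10), np.arange(10.0))


def test_f_exactly_ten_is_retained():
    """Exclusion is strictly F < 10; F = 10 keeps the instrument."""
    # craft g, x with r2 = 0.5 at n = 12 -> F = 10
    g = np.array([-1.0, 1.0] * 6)
    rng = np.random.default_rng(3)
    e = rng.standard_normal(12)
    e -= e.mean() + g * (g @ e) / (g @ g)      # orthogonalise to g
    e *= np.sqrt((g @ g) / (e @ e))            # equal variance -> r2 = 0.5
    x = g + e
    f, r2 = f_statistic(g, x)
    assert f == pytest.approx(10.0, abs=1e-8)
    # exclusion is strictly F < threshold: F equal to the cutoff is kept
    res = tsls(g, x, g + x, min_f=f)
    assert res.classification != "weak_instrument"


# ---------------------------------------------------------------------------
# 2SLS


def test_tsls_degenerate_instrument_equals_ols():
    _, x, y = _iv_data(seed=2)
    res = tsls(x, x, y, min_f=0, allow_weak=True)
    slope = np.polyfit(x, y, 1)[0]
    assert res.beta == pytest.approx(slope, rel=1e-10)


def test_tsls_single_iv_equals_ratio_of_slopes():
    g, x, y = _iv_data(seed=7)
    res = tsls(g, x, y, allow_weak=True)  # algebraic identity regardless of F
    num = np.polyfit(g, y, 1)[0]
    den = np.polyfit(g, x, 1)[0]
    assert res.beta == pytest.approx(num / den, abs=1e-10)
    # also the covariance-ratio identity
    cov_ratio = np.cov(g, y)[0, 1] / np.cov(g, x)[0, 1]
    assert res.beta == pytest.approx(cov_ratio, abs=1e-10)


def test_tsls_se_uses_original_exposure_residuals():
    g, x, y = _iv_data(seed=8, n=200)
    res = tsls(g, x, y)
    beta_iv = np.cov(g, y)[0, 1] / np.cov(g, x)[0, 1]
    a = y.mean() - beta_iv * x.mean()
    u = y - a - beta_iv * x
    sigma2 = (u @ u) / (len(y) - 2)
    gq = np.column_stack([np.ones_like(g), g])
    W = np.column_stack([x, np.ones_like(x)])
    P = gq @ np.linalg.solve(gq.T @ gq, gq.T)
    What = P @ W
    se = np.sqrt(sigma2 * np.linalg.inv(What.T @ What)[0, 0])
    assert res.se == pytest.approx(se, rel=1e-8)


def test_tsls_weak_instrument_flagged():
    rng = np.random.default_rng(9)
    g = rng.binomial(2, 0.3, 100).astype(float)
    x = rng.standard_normal(100)          # no instrument effect at all
    y = rng.standard_normal(100)
    res = tsls(g, x, y)
    assert res.classification == "weak_instrument"
    assert np.isnan(res.beta)
    forced = tsls(g, x, y, allow_weak=True)
    assert np.isfinite(forced.beta)


def test_tsls_with_covariates_removes_confounding():
    rng = np.random.default_rng(10)
    n = 2000
    g = rng.binomial(2, 0.3, n).astype(float)
    c = rng.standard_normal(n)
    x = 0.6 * g + c + rng.standard_normal(n)
    y = 0.5 * x + 2.0 * c + rng.standard_normal(n)
    res = tsls(g, x, y, covariates=c)
    assert res.beta == pytest.approx(0.5, abs=3 * res.se)


# ---------------------------------------------------------------------------
# PRS


def test_prs_single_snp():
    dos = pd.DataFrame({"rs1": [0.0, 1.0, 2.0]}, index=["a", "b", "c"])
    w = PrsWeights(("rs1",), ("A",), (0.5,))
    np.testing.assert_allclose(build_prs(dos, w), [0.0, 0.5, 1.0])


def test_prs_zero_weights():
    dos = pd.DataFrame({"rs1": [0.0, 2.0], "rs2": [1.0, 1.0]})
    w = PrsWeights(("rs1", "rs2"), ("A", "C"), (0.0, 0.0))
    assert build_prs(dos, w).abs().sum() == 0.0


def test_prs_allele_flip_recomputed_by_hand():
    dos = pd.DataFrame({"rs1": [0.0, 1.0, 2.0, 0.5, 1.5],
                        "rs2": [2.0, 0.0, 1.0, 1.0, 2.0]})
    w = PrsWeights(("rs1", "rs2"), ("A", "G"), (0.4, -0.3))
    counted = pd.Series({"rs1": "A", "rs2": "C"})  # rs2 counted allele differs
    score = build_prs(dos, w, counted_alleles=counted)
    manual = 0.4 * dos["rs1"] + (-0.3) * (2.0 - dos["rs2"])
    np.testing.assert_allclose(score, manual)


def test_prs_missing_snp_rejected():
    dos = pd.DataFrame({"rs1": [0.0, 1.0]})
    w = PrsWeights(("rs1", "rs9"), ("A", "C"), (1.0, 1.0))
    with pytest.raises(KeyError, match="rs9"):
        build_prs(dos, w)


def test_prs_weights_validated():
    with pytest.raises(ValueError, match="duplicate"):
        PrsWeights(("rs1", "rs1"), ("A", "C"), (1.0, 1.0))
    with pytest.raises(ValueError, match="finite"):
        PrsWeights(("rs1",), ("A",), (float("nan"),))


# ---------------------------------------------------------------------------
# classification rule


@pytest.mark.parametrize(
    "p_fwd, p_rev, expected",
    [
        (0.01, 0.5, "putative_causal"),
        (0.5, 0.01, "reverse"),
        (0.04, 0.04, "bidirectional"),
        (0.5, 0.5, "none"),
        (0.05, 0.5, "none"),           # strict < at alpha
        (0.01, 0.05, "putative_causal"),  # >= alpha counts as null
    ],
)
def test_classification_rule(p_fwd, p_rev, expected):
    assert _classify(p_fwd, p_rev, 0.05) == expected


def test_bidirectional_mr_recovers_forward_truth(small_cohort):
    from twasmr.pipeline import eqtl_scan
    eqtl = eqtl_scan(small_cohort.expression, small_cohort.dosages)
    inst = select_instrument(eqtl)
    prs = build_prs(small_cohort.dosages, DEFAULT_PRS_SNPS_WEIGHTS)
    res = bidirectional_mr(
        small_cohort.expression, small_cohort.phenotype,
        small_cohort.dosages, inst, prs,
    )
    causal = set(small_cohort.truth.loc[small_cohort.truth.theta != 0, "gene"])
    found = set(res.loc[res.classification == "putative_causal", "feature_id"])
    assert len(found & causal) >= 3  # power at n=400 is partial but real


# ---------------------------------------------------------------------------
# harmonization


def _stats_row(snp, ea, oa, beta, se=0.1):
    return {"snp_id": snp, "effect_allele": ea, "other_allele": oa,
            "beta": beta, "se": se}


def test_harmonize_flips_swapped_alleles():
    exp = pd.DataFrame([_stats_row("rs1", "A", "G", 0.3)])
    out = pd.DataFrame([_stats_row("rs1", "G", "A", -0.2)])
    h = harmonize(exp, out)
    assert h.iloc[0]["beta_outcome"] == pytest.approx(0.2)
    assert h.iloc[0]["flipped"] and not h.iloc[0]["dropped"]


def test_harmonize_drops_mismatched_alleles():
    exp = pd.DataFrame([_stats_row("rs1", "A", "G", 0.3)])
    out = pd.DataFrame([_stats_row("rs1", "A", "C", 0.2)])
    h = harmonize(exp, out)
    assert h.iloc[0]["dropped"]
    assert h.iloc[0]["drop_reason"] == "allele_mismatch"


def test_harmonize_palindromic_flag_and_strict_drop():
    exp = pd.DataFrame([_stats_row("rs1", "A", "T", 0.3)])
    out = pd.DataFrame([_stats_row("rs1", "A", "T", 0.2)])
    kept = harmonize(exp, out)
    assert kept.iloc[0]["palindromic"] and not kept.iloc[0]["dropped"]
    dropped = harmonize(exp, out, drop_palindromic=True)
    assert dropped.iloc[0]["dropped"]
    assert dropped.iloc[0]["drop_reason"] == "palindromic"


def test_harmonize_idempotent():
    exp = pd.DataFrame([
        _stats_row("rs1", "A", "G", 0.3), _stats_row("rs2", "C", "T", -0.1),
    ])
    out = pd.DataFrame([
        _stats_row("rs1", "G", "A", -0.2), _stats_row("rs2", "C", "T", 0.4),
    ])
    once = harmonize(exp, out)
    again = harmonize(
        exp,
        once.rename(columns={"beta_outcome": "beta", "se_outcome": "se"})[
            ["snp_id", "effect_allele", "other_allele", "beta", "se"]
        ],
    )
    np.testing.assert_allclose(once["beta_outcome"], again["beta_outcome"])
    assert not again["flipped"].any()


def test_harmonize_empty_intersection_rejected():
    exp = pd.DataFrame([_stats_row("rs1", "A", "G", 0.3)])
    out = pd.DataFrame([_stats_row("rs2", "A", "G", 0.3)])
    with pytest.raises(ValueError, match="shared"):
        harmonize(exp, out)


# ---------------------------------------------------------------------------
# Wald ratio / IVW


def test_wald_ratio_algebra():
    res = wald_ratio(0.5, 0.05, 1.0, 0.2)
    assert res.beta == pytest.approx(2.0)
    assert res.se == pytest.approx(0.4)
    neg = wald_ratio(-0.5, 0.05, 1.0, 0.1)
    assert neg.beta == pytest.approx(-2.0)
    assert neg.se == pytest.approx(0.2)
    assert neg.p == pytest.approx(
        2 * stats.norm.sf(abs(neg.beta / neg.se)), rel=1e-10
    )


def test_wald_ratio_zero_outcome():
    res = wald_ratio(1.0, 0.1, 0.0, 0.1)
    assert res.beta == 0.0 and res.p == 1.0


def test_wald_ratio_zero_exposure_rejected():
    with pytest.raises(ValueError):
        wald_ratio(0.0, 0.1, 1.0, 0.1)


def test_ivw_hand_weighted_mean():
    res = ivw([2.0, 4.0], [1.0, 1.0])
    assert res.beta == pytest.approx(3.0)
    assert res.se == pytest.approx(1 / np.sqrt(2))


def test_ivw_dominance_limit():
    res = ivw([1.0, 1.0], [0.1, 10.0])
    assert res.beta == pytest.approx(1.0, abs=1e-4)
    assert res.se == pytest.approx(0.1, abs=1e-4)


def test_ivw_single_snp_equals_wald_ratio():
    w = wald_ratio(0.4, 0.05, 0.8, 0.12)
    i = ivw([w.beta], [w.se])
    assert i.beta == pytest.approx(w.beta)
    assert i.se == pytest.approx(w.se)
    assert i.p == pytest.approx(w.p)


def test_ivw_identical_estimates_shrink_se():
    k = 4
    res = ivw([1.5] * k, [0.3] * k)
    assert res.beta == pytest.approx(1.5)
    assert res.se == pytest.approx(0.3 / np.sqrt(k))


def test_ivw_rejects_bad_se():
    with pytest.raises(ValueError):
        ivw([1.0, 2.0], [0.1, 0.0])


# ---------------------------------------------------------------------------
# two-sample dispatch


def test_two_sample_method_dispatch():
    exposure = pd.DataFrame(
        [
            dict(gene="g1", **_stats_row("rs1", "A", "G", 0.5)),
            dict(gene="g2", **_stats_row("rs2", "C", "T", 0.4)),
            dict(gene="g2", **_stats_row("rs3", "A", "C", 0.6)),
        ]
    )
    outcome = pd.DataFrame(
        [
            _stats_row("rs1", "A", "G", 1.0, 0.2),
            _stats_row("rs2", "C", "T", 0.8, 0.2),
            _stats_row("rs3", "A", "C", 1.2, 0.2),
        ]
    )
    res = two_sample_mr(exposure, outcome).set_index("feature_id")
    assert res.loc["g1", "method"] == "Wald ratio"
    assert res.loc["g1", "nsnp"] == 1
    assert res.loc["g2", "method"] == "Inverse variance weighted"
    assert res.loc["g2", "nsnp"] == 2
    assert res.loc["g1", "beta"] == pytest.approx(2.0)


def test_two_sample_omits_gene_without_shared_snps():
    exposure = pd.DataFrame(
        [
            dict(gene="g1", **_stats_row("rs1", "A", "G", 0.5)),
            dict(gene="g2", **_stats_row("rs9", "C", "T", 0.4)),
        ]
    )
    outcome = pd.DataFrame([_stats_row("rs1", "A", "G", 1.0, 0.2)])
    res = two_sample_mr(exposure, outcome)
    assert list(res.feature_id) == ["g1"]
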