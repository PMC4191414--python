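"""Replicate aggregation, z-scores, one-tailed t-test and the joint hit rule."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as hs

from gemscreen import (
    Call,
    DEFAULT_THRESHOLDS,
    GeneScore,
    Thresholds,
    aggregate_gene,
    call_hits,
    classify_gene,
    compute_zscores,
    one_tailed_p,
)
from gemscreen.hit_calling import (
    DegenerateScreenError,
    HitCallingError,
    InsufficientReplicatesError,
)
from gemscreen.normalization import GeneViabilityRatio


def _ratio(gene, rep, value, toxic=False):
    return GeneViabilityRatio(gene, rep, math.nan if toxic else value, 1.0, toxic)


def _score(gene="G1", ratio=1.0, z=0.0, p=0.5, call=Call.NONE):
    return GeneScore(
        gene_symbol=gene,
        n_replicates=3,
        mean_ratio=ratio,
        log2_ratio=math.log2(ratio) if ratio > 0 else math.nan,
        zscore=z,
        p_one_tailed=p,
        neg_log10_p=-math.log10(p),
        call=call,
    )


# --- aggregation ------------------------------------------------------------

def test_aggregate_mean_and_sample_sd():
    mean, sd, n = aggregate_gene([_ratio("G1", i, v) for i, v in enumerate((0.6, 0.7, 0.8), 1)])
    assert (mean, n) == (pytest.approx(0.70), 3)
    assert sd == pytest.approx(0.10)


def test_aggregate_constant_replicates():
    mean, sd, n = aggregate_gene([_ratio("G1", i, 1.0) for i in (1, 2, 3)])
    assert (mean, sd, n) == (1.0, 0.0, 3)


def test_aggregate_skips_toxic_replicates():
    ratios = [_ratio("G1", 1, 0.6), _ratio("G1", 2, 0.8), _ratio("G1", 3, 0.0, toxic=True)]
    mean, sd, n = aggregate_gene(ratios)
    assert (mean, n) == (pytest.approx(0.70), 2)


def test_single_usable_replicate_is_excluded():
    with pytest.raises(InsufficientReplicatesError):
        aggregate_gene([_ratio("G1", 1, 0.6), _ratio("G1", 2, 0.0, toxic=True)])


# --- z-scores ---------------------------------------------------------------

def test_two_gene_population_forces_plus_minus_inv_sqrt2():
    a = 0.4  # log2 ratios +-a: mean 0, sample sd a*sqrt(2) -> z = +-1/sqrt(2)
    out = {
        s.gene_symbol: s.zscore
        for s in compute_zscores([_score("G1", 2**a), _score("G2", 2**-a)])
    }
    assert out["G1"] == pytest.approx(1 / math.sqrt(2))
    assert out["G2"] == pytest.approx(-1 / math.sqrt(2))


def test_three_gene_symmetric_population_closed_form():
    # log2 ratios {+a, -a, 0}: mean 0, sample sd a -> z = {+1, -1, 0}
    a = 0.4
    scores = [_score("G1", 2**a), _score("G2", 2**-a), _score("G3", 1.0)]
    out = {s.gene_symbol: s.zscore for s in compute_zscores(scores)}
    assert out["G1"] == pytest.approx(1.0)
    assert out["G2"] == pytest.approx(-1.0)
    assert out["G3"] == pytest.approx(0.0, abs=1e-12)


def test_zscores_location_invariant_and_standardized():
    rng = np.random.default_rng(5)
    ratios = 2 ** rng.normal(0, 0.2, 50)
    scores = [_score(f"G{i:02d}", r) for i, r in enumerate(ratios)]
    shifted = [_score(f"G{i:02d}", r * 4.0) for i, r in enumerate(ratios)]  # +2 in log2
    z1 = np.array([s.zscore for s in compute_zscores(scores)])
    z2 = np.array([s.zscore for s in compute_zscores(shifted)])
    np.testing.assert_allclose(z1, z2, rtol=1e-9)
    assert z1.mean() == pytest.approx(0.0, abs=1e-9)
    assert z1.std(ddof=1) == pytest.approx(1.0, rel=1e-9)


def test_controls_excluded_from_z_population_but_scored():
    scores = [_score(f"G{i}", r) for i, r in enumerate((0.9, 1.0, 1.1))]
    atr = GeneScore("ATR", 3, 0.7, math.log2(0.7), math.nan, 0.01, 2.0, Call.NONE, is_control=True)
    out = compute_zscores(scores + [atr])
    z_lib = [s.zscore for s in out if not s.is_control]
    assert np.mean(z_lib) == pytest.approx(0.0, abs=1e-9)
    z_atr = next(s.zscore for s in out if s.is_control)
    assert z_atr < -1.5  # far below a null library of spread ~0.1 in log2


def test_robust_zscores_ignore_a_heavy_hit_tail():
    """Median/MAD standardization is unmoved by a few extreme sensitizers."""
    rng = np.random.default_rng(6)
    base = [_score(f"G{i:02d}", r) for i, r in enumerate(2 ** rng.normal(0, 0.1, 40))]
    spiked = base + [_score(f"S{i}", 0.25) for i in range(3)]
    z_base = {s.gene_symbol: s.zscore for s in compute_zscores(base, robust=True)}
    z_spiked = {s.gene_symbol: s.zscore for s in compute_zscores(spiked, robust=True)}
    for g in z_base:
        assert z_spiked[g] == pytest.approx(z_base[g], abs=0.25)
    # whereas the classical z population is visibly deflated by the spikes
    z_cls = {s.gene_symbol: s.zscore for s in compute_zscores(spiked)}
    spread_ratio = np.std([z_cls[g] for g in z_base]) / np.std([z_spiked[g] for g in z_base])
    assert spread_ratio < 0.8


def test_log2_of_mean_close_to_mean_of_log2_at_screen_noise():
    """The two aggregation orders differ only at second order in the CV."""
    rng = np.random.default_rng(14)
    for _ in range(100):
        reps = rng.normal(1.0, 0.15, 3)  # CV 15%
        if (reps <= 0).any():
            continue
        assert math.log2(np.mean(reps)) == pytest.approx(
            float(np.mean(np.log2(reps))), abs=0.1
        )


def test_bh_column_is_informational_only():
    """call_hits emits BH-adjusted q's that never feed the calls."""
    rng = np.random.default_rng(23)
    ratios = []
    for i in range(30):
        for rep in (1, 2, 3):
            ratios.append(_ratio(f"G{i:02d}", rep, float(2 ** rng.normal(0, 0.15))))
    nt = list(2 ** rng.normal(0, 0.15, 24))
    scores = call_hits(ratios, nt)
    for s in scores:
        assert s.bh_q >= s.p_one_tailed  # BH only adjusts upward
        assert 0 < s.bh_q <= 1
        assert classify_gene(s) is s.call  # calls derive from raw p alone


def test_degenerate_screen_rejected():
    scores = [_score(f"G{i}", 1.0) for i in range(5)]
    with pytest.raises(DegenerateScreenError):
        compute_zscores(scores)


# --- one-tailed t-test ------------------------------------------------------

NT_SIX = [1.0, 0.98, 1.02, 0.99, 1.01, 1.0]


def test_identical_groups_give_half():
    assert one_tailed_p([1.0, 0.9, 1.1], [1.0, 0.9, 1.1]) == pytest.approx(0.5)


def test_p_matches_independent_t_cdf_recomputation():
    """Pooled-variance t mapped through the incomplete-beta tail, independently."""
    from scipy import special

    g = [0.5, 0.6, 0.55]
    n1, n2 = len(g), len(NT_SIX)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * np.var(g, ddof=1) + (n2 - 1) * np.var(NT_SIX, ddof=1)) / df
    t = (np.mean(g) - np.mean(NT_SIX)) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    expected = 0.5 * special.betainc(df / 2, 0.5, df / (df + t * t))
    assert one_tailed_p(g, NT_SIX) == pytest.approx(expected, abs=1e-10)


def test_p_symmetric_under_group_swap():
    g = [0.5, 0.6, 0.55]
    assert one_tailed_p(g, NT_SIX) == pytest.approx(one_tailed_p(NT_SIX, g), abs=1e-15)


def test_zero_variance_conventions():
    assert one_tailed_p([1.0, 1.0], [1.0, 1.0]) == 1.0
    assert one_tailed_p([0.5, 0.5], [1.0, 1.0]) == 1e-300
    assert one_tailed_p([0.5, 0.5, 0.5], [1.0, 1.0, 1.0], alternative="less") == 1e-300


def test_fixed_tail_alternatives():
    g = [1.2, 1.3, 1.25]
    p_auto = one_tailed_p(g, NT_SIX)
    assert one_tailed_p(g, NT_SIX, alternative="greater") == pytest.approx(p_auto)
    assert one_tailed_p(g, NT_SIX, alternative="less") == pytest.approx(1 - p_auto)


def test_too_few_values_rejected():
    with pytest.raises(HitCallingError):
        one_tailed_p([1.0], NT_SIX)


# --- classification ---------------------------------------------------------

BRUTE_THR = DEFAULT_THRESHOLDS


def _brute_force_call(ratio, z, neg_log_p):
    """Literal evaluation of the three printed inequalities."""
    if ratio < 0.7 and z < -1.5 and neg_log_p > 1:
        return Call.SENSITIZATION
    if ratio > 1.3 and z > 1.5 and neg_log_p > 1:
        return Call.RESISTANCE
    return Call.NONE


@pytest.mark.parametrize(
    "ratio,z,p,expected",
    [
        (0.65, -1.8, 0.05, Call.SENSITIZATION),
        (0.65, -1.2, 0.01, Call.NONE),  # z criterion fails
        (0.70, -2.0, 0.01, Call.NONE),  # boundary: strict < 0.7
        (1.35, 1.6, 0.08, Call.RESISTANCE),
        (1.30, 1.6, 0.08, Call.NONE),  # boundary: strict > 1.3
        (0.65, -1.8, 0.1, Call.NONE),  # -log10 p = 1 exactly, strict >
    ],
)
def test_three_criteria_rule(ratio, z, p, expected):
    assert classify_gene(_score(ratio=ratio, z=z, p=p)) is expected


def test_classifier_agrees_with_brute_force_on_random_scores():
    rng = np.random.default_rng(99)
    for _ in range(200):
        ratio = float(rng.uniform(0.3, 1.7))
        z = float(rng.uniform(-4, 4))
        p = float(rng.uniform(1e-4, 1.0))
        s = _score(ratio=ratio, z=z, p=p)
        assert classify_gene(s) is _brute_force_call(ratio, z, -math.log10(p))


def test_toxic_scores_stay_excluded():
    s = GeneScore("G1", 1, math.nan, math.nan, math.nan, math.nan, math.nan, Call.TOXIC_EXCLUDED)
    assert classify_gene(s) is Call.TOXIC_EXCLUDED


@given(
    hs.lists(
        hs.tuples(
            hs.floats(0.2, 2.0), hs.floats(-4, 4), hs.floats(1e-6, 1.0)
        ),
        min_size=10,
        max_size=60,
    )
)
def test_joint_rule_never_exceeds_marginal_rates(rows):
    """AND of three criteria flags at most as many genes as any single one."""
    scores = [_score(f"G{i:03d}", r, z, p) for i, (r, z, p) in enumerate(rows)]
    calls = [classify_gene(s) for s in scores]
    n_hits = sum(c is not Call.NONE for c in calls)
    n_ratio = sum(s.mean_ratio < 0.7 or s.mean_ratio > 1.3 for s in scores)
    n_z = sum(s.zscore < -1.5 or s.zscore > 1.5 for s in scores)
    n_p = sum(s.neg_log10_p > 1 for s in scores)
    assert n_hits <= min(n_ratio, n_z, n_p)


def test_threshold_invariants_enforced():
    with pytest.raises(HitCallingError):
        Thresholds(sens_ratio_max=1.1)
    with pytest.raises(HitCallingError):
        Thresholds(z_low=0.5)


# --- call_hits composition --------------------------------------------------

def test_call_hits_scores_every_gene_and_is_order_invariant():
    rng = np.random.default_rng(21)
    ratios = []
    for i in range(12):
        for rep in (1, 2, 3):
            ratios.append(_ratio(f"G{i:02d}", rep, float(2 ** rng.normal(0, 0.15))))
    nt = list(2 ** rng.normal(0, 0.15, 24))
    a = call_hits(ratios, nt)
    b = call_hits(list(reversed(ratios)), nt)
    assert a == b
    assert [s.gene_symbol for s in a] == sorted(f"G{i:02d}" for i in range(12))


def test_call_hits_marks_insufficient_genes_toxic():
    ratios = [_ratio("G0", 1, 0.9), _ratio("G0", 2, 1.0), _ratio("G0", 3, 1.1)]
    ratios += [_ratio("G1", 1, 1.05), _ratio("G1", 2, 0.95), _ratio("G1", 3, 1.0)]
    ratios += [_ratio("G2", 1, 1.1), _ratio("G2", 2, 1.0), _ratio("G2", 3, 0.92)]
    ratios += [_ratio("GTOX", 1, 0.0, toxic=True), _ratio("GTOX", 2, 0.0, toxic=True)]
    out = call_hits(ratios, [1.0, 0.95, 1.05, 1.02, 0.98])
    by_gene = {s.gene_symbol: s for s in out}
    assert by_gene["GTOX"].call is Call.TOXIC_EXCLUDED
    assert all(by_gene[g].call is not Call.TOXIC_EXCLUDED for g in ("G0", "G1", "G2"))
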