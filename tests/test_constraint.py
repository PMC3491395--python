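import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from psidr.constraint import (
    bh_select,
    conservation_pipeline,
    daf_spectra,
    poisson_conservation_p,
    preservation_rate,
    variant_density,
)


# ---------------------------------------------------------- Poisson tail


def _poisson_cdf_oracle(k, lam):
    """Direct log-space pmf summation, independent of scipy."""
    total = 0.0
    for i in range(k + 1):
        log_pmf = -lam + i * math.log(lam) - math.lgamma(i + 1) if lam > 0 else (0.0 if i == 0 else -math.inf)
        total += math.exp(log_pmf)
    return min(total, 1.0)


def test_poisson_p_matches_direct_summation_over_grid():
    for lam in (0.3, 1.5, 5.0, 15.0, 30.0, 50.0):
        length = 1000
        rate = lam / length
        for k in range(0, 101, 1):
            p = poisson_conservation_p(k, length, rate)
            assert p == pytest.approx(_poisson_cdf_oracle(k, lam), abs=1e-12)


def test_poisson_p_worked_examples():
    # lambda = 15: few substitutions -> small tail, many -> tail near 1
    assert poisson_conservation_p(5, 1000, 0.015) == pytest.approx(2.792e-3, rel=5e-3)
    assert 0.9 < poisson_conservation_p(20, 1000, 0.015) < 1.0
    assert poisson_conservation_p(0, 2000, 0.015) == pytest.approx(math.exp(-30))


def test_poisson_p_degenerate_and_monotone():
    assert poisson_conservation_p(7, 1000, 0.0) == 1.0
    grid = [poisson_conservation_p(k, 1000, 0.015) for k in range(60)]
    assert all(a <= b for a, b in zip(grid, grid[1:]))  # nondecreasing in k
    rates = [poisson_conservation_p(10, 1000, r) for r in (0.005, 0.01, 0.02, 0.05)]
    assert all(a >= b for a, b in zip(rates, rates[1:]))  # nonincreasing in r*L


def test_poisson_p_rejects_bad_input():
    with pytest.raises(ValueError):
        poisson_conservation_p(-1, 100, 0.01)
    with pytest.raises(ValueError):
        poisson_conservation_p(1, 0, 0.01)


# ------------------------------------------------------------------- BH


def _bh_oracle(p, fdr):
    """Exhaustive evaluation of the step-up definition."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if p[i] <= fdr * rank / n:
            k_star = rank
    selected = [False] * n
    for rank, i in enumerate(order, start=1):
        if rank <= k_star:
            selected[i] = True
    return selected


def test_bh_worked_examples():
    sel = bh_select([0.001, 0.01, 0.03, 0.04, 0.2], fdr=0.05)
    assert list(sel) == [True, True, True, True, False]
    assert not bh_select([1.0, 1.0, 1.0]).any()
    assert bh_select([0.04], fdr=0.05).all()  # 0.04 <= 0.05 * 1/1


def test_bh_matches_exhaustive_step_up_on_random_lists():
    rng = np.random.default_rng(17)
    for _ in range(1000):
        n = int(rng.integers(1, 51))
        p = rng.uniform(0, 1, size=n)
        if rng.random() < 0.3:  # inject ties and near-threshold values
            p = np.round(p, 2)
        assert list(bh_select(p, 0.05)) == _bh_oracle(list(p), 0.05)


def test_bh_agrees_with_statsmodels():
    statsmodels = pytest.importorskip("statsmodels.stats.multitest")
    rng = np.random.default_rng(4)
    for _ in range(50):
        p = rng.uniform(0, 1, size=int(rng.integers(2, 80)))
        ours = bh_select(p, 0.05)
        ref = statsmodels.multipletests(p, alpha=0.05, method="fdr_bh")[0]
        assert (ours == ref).all()


def test_bh_selection_grows_with_fdr():
    rng = np.random.default_rng(2)
    p = rng.uniform(0, 1, 60)
    prev = np.zeros(60, dtype=bool)
    for fdr in (0.01, 0.05, 0.1, 0.3, 0.6):
        cur = bh_select(p, fdr)
        assert (prev <= cur).all()
        prev = cur


def test_bh_rejects_bad_input():
    with pytest.raises(ValueError):
        bh_select([0.5], fdr=1.5)
    with pytest.raises(ValueError):
        bh_select([1.2])


# ------------------------------------------------------------ preservation


def test_preservation_rate():
    df = pd.DataFrame(
        {
            "pseudogene_id": ["a", "b", "a", "b"],
            "species": ["chimp", "chimp", "mouse", "mouse"],
            "aligned_bp": [800, 0, 200, 100],
            "substitutions": [1, 0, 1, 1],
            "length": [1000, 500, 1000, 500],
        }
    )
    out = preservation_rate(df).set_index("species")
    assert out.loc["chimp", "preservation_pct"] == pytest.approx(100 * 800 / 1500)
    assert out.loc["mouse", "preservation_pct"] == pytest.approx(100 * 300 / 1500)


def test_preservation_matches_planted_decay(corpus, surveyed_truth):
    out = preservation_rate(corpus.divergence).set_index("species")
    assert out.loc["chimp", "preservation_pct"] == pytest.approx(95.0, abs=2.0)
    assert out.loc["mouse", "preservation_pct"] == pytest.approx(55.0, abs=2.0)


# ------------------------------------------------------ pipeline + spectra


def test_conservation_pipeline_single_strong_case():
    df = pd.DataFrame(
        {
            "pseudogene_id": ["p"],
            "species": ["chimp"],
            "aligned_bp": [1900],
            "substitutions": [0],
            "length": [2000],
        }
    )
    results, combined = conservation_pipeline(df, rates={"chimp": 0.015}, fdr=0.05)
    assert results[0].p_value == pytest.approx(math.exp(-30))
    assert combined == {"p": True}


def test_conservation_combine_rules():
    df = pd.DataFrame(
        {
            "pseudogene_id": ["p", "p"],
            "species": ["chimp", "mouse"],
            "aligned_bp": [1000, 1000],
            "substitutions": [0, 50],
            "length": [1000, 1000],
        }
    )
    _, union = conservation_pipeline(df, fdr=0.05, combine="union")
    _, inter = conservation_pipeline(df, fdr=0.05, combine="intersection")
    _, chimp = conservation_pipeline(df, fdr=0.05, combine="chimp")
    assert union["p"] and chimp["p"] and not inter["p"]


def test_corpus_conserved_recovery(decoration, surveyed_truth):
    planted = set(surveyed_truth[surveyed_truth.conserved].index)
    called = {pid for pid, v in decoration.conservation.items() if v}
    # strong planted signal (0.1x background): full power
    assert planted <= called
    # false discoveries stay near the FDR level
    assert len(called - planted) <= max(5, 0.15 * len(called))


def test_daf_spectra_identical_samples():
    daf = np.linspace(0.01, 0.99, 200)
    spectra, comps = daf_spectra({"a": daf, "b": daf.copy()})
    assert comps[("a", "b")] == pytest.approx(1.0)
    assert spectra["a"].sum() == 200


def test_daf_spectra_detects_frequency_shift():
    rng = np.random.default_rng(23)
    low = rng.beta(0.5, 3.0, size=500)
    high = rng.beta(3.0, 0.5, size=500)
    _, comps = daf_spectra({"lo": low, "hi": high})
    assert comps[("hi", "lo")] < 1e-6


def test_daf_spectra_skips_empty_class():
    _, comps = daf_spectra({"a": np.array([0.1, 0.2]), "b": np.array([])})
    assert comps == {}


def test_variant_density():
    out = variant_density({"t": 30}, {"t": 15_000})
    assert out["t"] == pytest.approx(2.0)
    with pytest.raises(ValueError):
        variant_density({"t": 1}, {"t": 0})


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
def test_bh_property_never_selects_above_fdr_threshold_rank(p):
    sel = bh_select(np.array(p), 0.05)
    n = len(p)
    if sel.any():
        k_star = sel.sum()
        assert sorted(np.asarray(p)[sel])[-1] <= 0.05 * k_star / n + 1e-12
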