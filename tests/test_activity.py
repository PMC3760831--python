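"""ANOVA components, studentized-range quantiles and Duncan's MRT.

The quantile function is validated against the sqrt(2)*t identity for p=2,
published table values to three decimals, and an independent Gauss-Legendre
double-integral evaluation of the studentized-range CDF. Duncan's letter
assignment is validated against an independent recursive range-splitting
implementation on toy and randomised data.
"""

from math import lgamma

import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss
from scipy.stats import norm

from bmy1type.activity import (
    anova_components,
    duncan_mrt,
    rank_group_count,
    studentized_range_q,
)
from bmy1type.panel import simulate_activity


def test_anova_components():
    groups = {f"g{i}": [1.0, 2.0, 3.0] for i in range(8)}
    mse, df = anova_components(groups)
    assert df == 16 and mse == pytest.approx(1.0)
    same = {"a": [5.0, 5.0], "b": [5.0, 5.0]}
    assert anova_components(same)[0] == 0.0
    two = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]}
    assert anova_components(two) == (pytest.approx(1.0), 4)
    with pytest.raises(ValueError):
        anova_components({"a": [1.0], "b": [2.0]})
    with pytest.raises(ValueError):
        anova_components({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})


def _cdf_oracle(q, k, df):
    """Independent studentized-range CDF by Gauss-Legendre double integral."""
    zn, zw = leggauss(240)
    z = zn * 9.0
    zw = zw * 9.0
    def inner(qs):
        vals = k * norm.pdf(z) * np.maximum(norm.cdf(z) - norm.cdf(z - qs), 0) ** (k - 1)
        return float(np.sum(vals * zw))
    sn, sw = leggauss(240)
    s = (sn * (4.0 - 1e-6) + (4.0 + 1e-6)) / 2
    ws = sw * (4.0 - 1e-6) / 2
    logc = (df / 2) * np.log(df) + (1 - df / 2) * np.log(2) - lgamma(df / 2)
    fs = np.exp(logc + (df - 1) * np.log(s) - df * s * s / 2)
    return float(np.sum(fs * np.array([inner(q * si) for si in s]) * ws))


def test_quantiles_match_published_table_values():
    assert round(studentized_range_q(2, 16, 0.05), 3) == 2.998
    assert round(studentized_range_q(3, 16, 0.05), 3) == 3.649
    assert round(studentized_range_q(4, 16, 0.05), 3) == 4.046
    # sqrt(2) * two-sample t analogue at large df approximates 2.772
    assert studentized_range_q(2, 10000, 0.05) == pytest.approx(2.772, abs=1e-3)


@pytest.mark.parametrize("k,df", [(2, 16), (3, 16), (8, 16), (3, 12)])
def test_quantiles_agree_with_integration_oracle(k, df):
    q = studentized_range_q(k, df, 0.05)
    assert _cdf_oracle(q, k, df) == pytest.approx(0.95, abs=1e-4)


def test_quantile_monotone_in_alpha():
    qs = [studentized_range_q(3, 16, a) for a in (0.01, 0.05, 0.25, 0.75, 0.999)]
    assert all(x > y for x, y in zip(qs, qs[1:]))
    assert qs[-1] < 0.25  # alpha -> 1 drives q toward 0


def test_quantile_rejects_bad_parameters():
    for args in [(1, 16, 0.05), (2, 0, 0.05), (2, 16, 0.0), (2, 16, 1.0)]:
        with pytest.raises(ValueError):
            studentized_range_q(*args)


def _duncan_letters_recursive(groups, alpha=0.05):
    """Independent Duncan implementation: recursive range splitting.

    The full range is tested first; a non-significant range makes all its
    members one homogeneous group; otherwise the two (k-1)-spans are examined
    recursively. Letters are then assigned to maximal homogeneous intervals.
    """
    mse, df = anova_components(groups)
    n = len(next(iter(groups.values())))
    means = {g: float(np.mean(v)) for g, v in groups.items()}
    order = sorted(means, key=lambda g: (means[g], g))
    m = [means[g] for g in order]
    sem = np.sqrt(mse / n)
    intervals = set()

    def examine(i, j):
        if i >= j:
            return
        span = j - i + 1
        alpha_p = 1 - (1 - alpha) ** (span - 1)
        rp = studentized_range_q(span, df, alpha_p) * sem if sem > 0 else 0.0
        if m[j] - m[i] <= rp:
            intervals.add((i, j))
        else:
            examine(i, j - 1)
            examine(i + 1, j)

    examine(0, len(m) - 1)
    for i in range(len(m)):
        if not any(a <= i <= b for a, b in intervals):
            intervals.add((i, i))
    maximal = sorted(
        iv for iv in intervals
        if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in intervals)
    )
    letters = {g: "" for g in order}
    for idx, (i, j) in enumerate(maximal):
        for t in range(i, j + 1):
            letters[order[t]] += chr(ord("a") + idx)
    return letters


def test_all_identical_groups_share_one_letter():
    groups = {f"g{i}": [10.0, 10.0, 10.0] for i in range(5)}
    res = duncan_mrt(groups)
    assert set(res.letters.values()) == {"a"}
    assert rank_group_count(res) == 1


def test_widely_separated_groups_get_distinct_letters():
    groups = {f"g{i}": [100.0 * i + d for d in (-1, 0, 1)] for i in range(8)}
    res = duncan_mrt(groups)
    assert rank_group_count(res) == 8
    assert all(len(v) == 1 for v in res.letters.values())


def test_duncan_agrees_with_recursive_brute_force():
    """Span-sweep letters equal the independent recursive implementation on
    fixed 4-group toy data and on randomised layouts."""
    toy = {
        "a": [10.0, 11.0, 9.0],
        "b": [12.0, 13.0, 11.5],
        "c": [20.0, 21.0, 19.0],
        "d": [20.5, 21.5, 19.5],
    }
    assert duncan_mrt(toy).letters == _duncan_letters_recursive(toy)
    rng = np.random.default_rng(5)
    for trial in range(20):
        k = int(rng.integers(3, 7))
        groups = {
            f"g{i}": list(rng.normal(rng.uniform(0, 30), 3.0, 3))
            for i in range(k)
        }
        assert duncan_mrt(groups).letters == _duncan_letters_recursive(groups), trial


def test_letters_are_contiguous_and_monotone():
    rng = np.random.default_rng(17)
    for _ in range(10):
        groups = {
            f"g{i}": list(rng.normal(rng.uniform(0, 50), 5.0, 3)) for i in range(6)
        }
        res = duncan_mrt(groups)
        # each letter marks one contiguous run in mean order
        for letter in set("".join(res.letters.values())):
            idx = [i for i, g in enumerate(res.order) if letter in res.letters[g]]
            assert idx == list(range(idx[0], idx[-1] + 1))
        # every group carries at least one letter
        assert all(res.letters[g] for g in res.order)


def test_alpha_limits():
    groups = {
        "a": [9.5, 10.0, 10.5],
        "b": [10.5, 11.0, 11.5],
        "c": [11.5, 12.0, 12.5],
        "d": [12.5, 13.0, 13.5],
    }
    tiny = duncan_mrt(groups, alpha=1e-6)
    assert rank_group_count(tiny) == 1
    loose = duncan_mrt(groups, alpha=0.5)
    assert rank_group_count(loose) == 4
    with pytest.raises(ValueError):
        duncan_mrt(groups, alpha=0.0)


def test_simulated_table_extremes_rank_correctly(tables):
    """Across seeds, W127 is alone in the top rank and z043 sits in the
    bottom rank in a clear majority of simulations."""
    top_alone = bottom = 0
    n_seeds = 40
    for seed in range(n_seeds):
        groups = {
            a: list(v) for a, v in simulate_activity(tables.activity, seed).items()
        }
        res = duncan_mrt(groups)
        top = res.order[-1]
        if top == "W127" and all(
            res.letters[top][-1] not in res.letters[g]
            for g in res.order[:-1]
        ):
            top_alone += 1
        if res.order[0] == "z043" and "a" in res.letters["z043"]:
            bottom += 1
    assert top_alone > n_seeds / 2
    assert bottom > n_seeds / 2
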