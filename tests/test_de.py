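"""RPM quantification, exact rate test, screening filters, ΔΔCt."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circorf import (
    SimDesign,
    ddct,
    de_filter,
    differential_table,
    make_toy_genome,
    rate_test,
    rpm,
    simulate_junction_counts,
    sustained_down,
)
from circorf.simulate import TruthTable, null_circle_truth


@pytest.mark.parametrize(
    "reads, total, expected",
    [(5, 1_000_000, 5.0), (0, 2_000_000, 0.0), (250, 50_000_000, 5.0)],
)
def test_rpm_formula(reads, total, expected):
    assert rpm(reads, total) == pytest.approx(expected)


def test_rpm_rejects_bad_inputs():
    with pytest.raises(ValueError):
        rpm(5, 0)
    with pytest.raises(ValueError):
        rpm(-1, 100)


def test_rate_test_symmetric_null():
    lfc, p = rate_test([10], [10], [1e6], [1e6])
    assert lfc == pytest.approx(0.0)
    assert p == 1.0


def test_rate_test_extreme_example_exact_tail():
    """kA=0 over 3 samples vs kB=24: p = 2×0.5²⁴ by direct tail summation,
    log2fc = log2(24.5/0.5)."""
    lfc, p = rate_test([0, 0, 0], [8, 8, 8], [1e6] * 3, [1e6] * 3)
    # independent tail: P(X<=0 | n=24, p=1/2) summed directly
    tail = sum(math.comb(24, k) * 0.5**24 for k in range(0, 1))
    assert p == pytest.approx(2 * tail, rel=1e-12)
    assert p == pytest.approx(1.1920928955078125e-07)
    assert lfc == pytest.approx(math.log2(24.5 / 0.5), abs=1e-9)
    assert lfc == pytest.approx(5.615, abs=5e-4)


def test_rate_test_all_zero_is_defined():
    assert rate_test([0, 0], [0, 0], [1e6] * 2, [1e6] * 2) == (0.0, 1.0)


@given(
    st.integers(min_value=0, max_value=200),
    st.integers(min_value=0, max_value=200),
    st.integers(min_value=10_000, max_value=1_000_000),
    st.integers(min_value=10_000, max_value=1_000_000),
)
@settings(max_examples=150, derandomize=True)
def test_rate_test_antisymmetry(kA, kB, LA, LB):
    """Swapping the groups negates the fold change and preserves p."""
    lfc1, p1 = rate_test([kA], [kB], [LA], [LB])
    lfc2, p2 = rate_test([kB], [kA], [LB], [LA])
    assert lfc1 == pytest.approx(-lfc2, abs=1e-12)
    assert p1 == pytest.approx(p2, rel=1e-9)


def test_rate_test_monotone_in_imbalance():
    """For fixed totals and equal libraries, p is non-increasing as the
    pooled counts grow more imbalanced."""
    n = 60
    last = None
    for kA in range(n // 2, -1, -1):  # kA·LB − kB·LA grows as kA shrinks
        _, p = rate_test([kA], [n - kA], [1e6], [1e6])
        if last is not None:
            assert p <= last + 1e-12
        last = p


@pytest.mark.parametrize(
    "p, lfc, expected",
    [(0.01, -1.5, "down"), (0.2, -2.0, "none"), (0.01, -0.5, "none"), (0.01, 1.5, "up")],
)
def test_de_filter_thresholds(p, lfc, expected):
    assert de_filter(lfc, p) == expected


def test_sustained_down_requires_both_timepoints():
    assert sustained_down("down", "down") is True
    assert sustained_down("down", "none") is False
    assert sustained_down("up", "down") is False
    with pytest.raises(ValueError):
        sustained_down("down", None)


@pytest.mark.parametrize(
    "args, expected",
    [((20, 15, 18, 15), 0.25), ((18, 15, 18, 15), 1.0), ((17, 15, 18, 15), 2.0)],
)
def test_ddct_relative_quantity(args, expected):
    assert ddct(*args) == pytest.approx(expected)


def test_ddct_rejects_nonfinite():
    with pytest.raises(ValueError):
        ddct(float("nan"), 15, 18, 15)


def _matrix(planted_lfc):
    genome, genes = make_toy_genome(1, 8000, 4, 3, seed=0)
    truth = TruthTable()
    for g in genes:
        truth.add(null_circle_truth(g, genome))
    target = sorted(truth)[0]
    design = SimDesign(
        baseline_mean=50.0,
        dispersion=0.0,
        planted_log2fc={target: {"d10": planted_lfc, "d20": planted_lfc}},
        seed=123,
    )
    return target, simulate_junction_counts(truth, design)


def test_differential_table_flags_planted_suppression():
    target, matrix = _matrix(-2.0)
    table, results = differential_table(matrix)
    assert results[target].sustained_down is True
    for tp in ("d10", "d20"):
        assert results[target].call[tp] == "down"
        assert results[target].log2fc[tp] < -1
    others = [r for cid, r in results.items() if cid != target]
    assert not any(r.sustained_down for r in others)
    assert set(table.columns) >= {"circ_id", "timepoint", "kA", "kB", "log2fc", "p", "p_bh", "call"}


def test_differential_table_requires_both_groups():
    _, matrix = _matrix(0.0)
    matrix.conditions[:] = "vehicle"
    with pytest.raises(ValueError, match="missing"):
        differential_table(matrix)


def test_rpm_matrix_matches_scalar_formula():
    _, matrix = _matrix(0.0)
    r = matrix.rpm_matrix()
    cid, sid = matrix.circ_ids[0], matrix.sample_ids[0]
    assert r.loc[cid, sid] == pytest.approx(
        rpm(int(matrix.counts.loc[cid, sid]), int(matrix.library_sizes[sid]))
    )
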