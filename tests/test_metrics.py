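"""Node-dynamics and allegiance metric formulas against hand-enumerated
values, plus their invariance properties."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from commdyn import metrics as m
from commdyn.errors import (
    ConfigError,
    DegenerateInputError,
    UndefinedMetricError,
)

label_matrices = arrays(
    np.int64,
    st.tuples(st.integers(2, 6), st.integers(2, 6)),
    elements=st.integers(1, 4),
)


# ----------------------------------------------------------------------
# hand-enumerated cases
# ----------------------------------------------------------------------

@pytest.mark.parametrize(
    "columns, expected",
    [
        ([[1], [1], [1], [1]], [0.0]),  # never changes
        ([[1], [2], [1], [2]], [1.0]),  # changes every step
        ([[1], [1], [2], [2], [2], [3]], [2 / 5]),  # two changes in five steps
    ],
)
def test_flexibility_hand_cases(columns, expected):
    assert m.flexibility(np.array(columns)) == pytest.approx(expected)


def test_flexibility_undefined_for_single_layer():
    with pytest.raises(UndefinedMetricError):
        m.flexibility(np.array([[1, 2, 3]]))


def test_cohesion_single_joint_move():
    # nodes i and j move together once (step 2 of 2); k never moves
    labels = np.array([[1, 1, 1], [1, 1, 1], [2, 2, 1]])
    M, omega = m.cohesion(labels)
    assert M[0, 1] == pytest.approx(0.5)
    assert M[0, 2] == 0 and M[1, 2] == 0
    assert omega[0] == pytest.approx(0.5)


def test_cohesion_static_partition_is_zero():
    labels = np.tile([1, 2, 1, 2], (5, 1))
    M, omega = m.cohesion(labels)
    assert np.all(M == 0) and np.all(omega == 0)


def test_lone_mover_has_flexibility_but_no_cohesion():
    # node 0 changes at every step, always alone
    labels = np.array([[1, 3, 3], [2, 3, 3], [1, 3, 3], [2, 3, 3]])
    assert m.flexibility(labels)[0] == 1.0
    _, omega = m.cohesion(labels)
    assert omega[0] == 0.0


def test_promiscuity_hand_cases():
    # 4 communities present; node 0 visits {1,2}, node 1 visits all 4, node 2 static
    labels = np.array([[1, 1, 3], [2, 2, 3], [1, 3, 3], [2, 4, 3]])
    p = m.promiscuity(labels)
    assert p[0] == pytest.approx(0.5)
    assert p[1] == pytest.approx(1.0)
    assert p[2] == pytest.approx(1 / 4)


def test_allegiance_hand_cases():
    labels = np.array([[1, 1, 2], [1, 1, 2], [1, 2, 2], [1, 2, 2]])
    P = m.allegiance(labels)
    assert P[0, 1] == pytest.approx(0.5)  # co-assigned 2 of 4 layers
    assert np.all(np.diag(P) == 1.0)
    assert P == pytest.approx(P.T)
    always = np.tile([1, 1, 2], (4, 1))
    assert m.allegiance(always)[0, 1] == 1.0
    assert m.allegiance(always)[0, 2] == 0.0


def test_allegiance_changes_denominator_variant():
    labels = np.tile([1, 1], (4, 1))
    P = m.allegiance(labels, denominator="changes")
    assert P[0, 1] == pytest.approx(4 / 3)  # literal L-1 variant exceeds 1
    with pytest.raises(ConfigError):
        m.allegiance(labels, denominator="bogus")


def test_recruitment_integration_hand_case():
    # ref = {A: {0,1}, B: {2,3}}; P(0,1)=0.5, P(0,2)=P(0,3)=0.25
    ref = np.array([1, 1, 2, 2])
    P = np.eye(4)
    P[0, 1] = P[1, 0] = 0.5
    P[0, 2] = P[2, 0] = 0.25
    P[0, 3] = P[3, 0] = 0.25
    P[2, 3] = P[3, 2] = 0.7
    P[1, 2] = P[2, 1] = 0.1
    P[1, 3] = P[3, 1] = 0.1
    recr, integ = m.recruitment_integration(P, ref)
    assert recr[0] == pytest.approx(0.5)
    assert integ[0] == pytest.approx(0.25)


def test_recruitment_perfect_match_and_one_block():
    ref = np.array([1, 1, 2, 2])
    labels = np.tile(ref, (5, 1))
    P = m.allegiance(labels)
    recr, integ = m.recruitment_integration(P, ref)
    assert recr == pytest.approx(np.ones(4))
    assert integ == pytest.approx(np.zeros(4))
    # all nodes actually in ONE community but ref has two groups
    P1 = m.allegiance(np.tile([7, 7, 7, 7], (5, 1)))
    recr, integ = m.recruitment_integration(P1, ref)
    assert recr == pytest.approx(np.ones(4))
    assert integ == pytest.approx(np.ones(4))


def test_recruitment_singleton_reference_community_is_missing():
    ref = np.array([1, 2, 2])
    P = m.allegiance(np.tile([1, 2, 2], (3, 1)))
    recr, _ = m.recruitment_integration(P, ref)
    assert np.isnan(recr[0])


def test_recruitment_requires_full_reference():
    with pytest.raises(ConfigError):
        m.recruitment_integration(np.eye(3), np.array([1, 2]))


# ----------------------------------------------------------------------
# z-Rand and consensus
# ----------------------------------------------------------------------

def test_zrand_self_similarity_positive_and_symmetric():
    p1 = np.array([1, 1, 1, 2, 2, 2])
    p2 = np.array([1, 1, 2, 2, 3, 3])
    assert m.zrand(p1, p1) > 0
    assert m.zrand(p1, p2) == pytest.approx(m.zrand(p2, p1))


def test_zrand_undefined_cases():
    with pytest.raises(UndefinedMetricError):
        m.zrand(np.array([1]), np.array([1]))
    with pytest.raises(UndefinedMetricError):
        # all singletons: no co-assigned pairs anywhere, zero variance
        m.zrand(np.arange(6), np.array([1, 1, 2, 2, 3, 3]))


def test_consensus_unanimity_and_majority():
    x = np.array([1, 1, 2, 2, 3, 3])
    y = np.array([1, 2, 1, 2, 1, 2])
    ref, idx = m.consensus_partition([x, x, x])
    assert np.array_equal(ref, x) and idx == 0
    ref, idx = m.consensus_partition([x] * 9 + [y])
    assert np.array_equal(ref, x)


def test_consensus_tie_breaks_to_lowest_index():
    x = np.array([1, 1, 2, 2, 3, 3])
    y = np.array([1, 2, 1, 2, 1, 2])
    # two of each: scores are symmetric, tie -> index 0
    _, idx = m.consensus_partition([y, y, x, x])
    assert idx == 0


def test_consensus_degenerate_input():
    with pytest.raises(DegenerateInputError):
        m.consensus_partition([np.array([1, 1])])


# ----------------------------------------------------------------------
# static role metrics
# ----------------------------------------------------------------------

def test_within_module_degree_hand_case():
    # one 4-node community with within-strengths [0.6, 0.6, 0.2, 0.2]
    C = np.zeros((4, 4))
    vals = {(0, 1): 1.0, (0, 2): 0.4, (0, 3): 0.4, (1, 2): 0.4, (1, 3): 0.4,
            (2, 3): -0.2}
    for (i, j), v in vals.items():
        C[i, j] = C[j, i] = v
    ref = np.ones(4, dtype=int)
    z = m.within_module_degree(C, ref)
    assert z == pytest.approx([1.0, 1.0, -1.0, -1.0])


def test_within_module_degree_uniform_and_singleton():
    C = np.full((4, 4), 0.5)
    np.fill_diagonal(C, 0.0)
    assert m.within_module_degree(C, np.ones(4, int)) == pytest.approx(np.zeros(4))
    z = m.within_module_degree(C, np.array([1, 1, 1, 2]))
    assert np.isnan(z[3])


def test_participation_coefficient_closed_forms():
    # block-diagonal: all strength within own community -> 0
    C = np.zeros((4, 4))
    C[0, 1] = C[1, 0] = 1.0
    C[2, 3] = C[3, 2] = 1.0
    ref = np.array([1, 1, 2, 2])
    assert m.participation_coefficient(C, ref) == pytest.approx(np.zeros(4))
    # equal strength to each of K=3 communities -> 1 - 1/3
    C = np.full((6, 6), 1.0)
    np.fill_diagonal(C, 0.0)
    ref = np.array([1, 1, 2, 2, 3, 3])
    # node 0: strength 1 to own community (node 1) and 2 to each other community
    # use explicit construction: connect node 0 with weight 2 to its community
    C[0, 1] = C[1, 0] = 2.0
    pc = m.participation_coefficient(C, ref)
    assert pc[0] == pytest.approx(1 - 1 / 3)


def test_participation_zero_strength_is_missing():
    C = np.zeros((3, 3))
    pc = m.participation_coefficient(C, np.array([1, 1, 2]))
    assert np.all(np.isnan(pc))


def test_hub_integrator_classification_conventions():
    rng = np.random.default_rng(0)
    wmd = rng.permutation(148).astype(float)  # 148 distinct values
    pc = rng.permutation(148).astype(float)
    hubs, integrators = m.classify_hubs_integrators(wmd, pc, percentile=95)
    assert hubs.sum() == 8  # ceil(0.05 * 148)
    assert integrators.sum() == 8
    const = np.full(10, 3.3)
    h, _ = m.classify_hubs_integrators(const, const)
    assert h.sum() == 0
    h, i = m.classify_hubs_integrators(const, const, percentile=0)
    assert h.all() and i.all()


# ----------------------------------------------------------------------
# properties
# ----------------------------------------------------------------------

@given(label_matrices)
def test_bounded_metrics_and_cohesion_flexibility_bound(labels):
    flex = m.flexibility(labels)
    prom = m.promiscuity(labels)
    P = m.allegiance(labels)
    _, omega = m.cohesion(labels)
    assert np.all((flex >= 0) & (flex <= 1))
    assert np.all((prom > 0) & (prom <= 1))
    assert np.all((P >= 0) & (P <= 1))
    assert np.all(omega >= 0)
    # a node that moves jointly with someone must itself move
    assert np.all(flex[omega > 0] > 0)


@given(label_matrices, st.permutations(list(range(1, 5))))
def test_metrics_invariant_under_label_relabeling(labels, perm):
    lut = np.array([0] + list(perm))
    relabeled = lut[labels]
    assert m.flexibility(labels) == pytest.approx(m.flexibility(relabeled))
    assert m.promiscuity(labels) == pytest.approx(m.promiscuity(relabeled))
    assert m.allegiance(labels) == pytest.approx(m.allegiance(relabeled))
    assert m.cohesion(labels)[1] == pytest.approx(m.cohesion(relabeled)[1])


@given(label_matrices)
def test_recruitment_bounds_with_realized_reference(labels):
    P = m.allegiance(labels)
    ref = labels[0]
    recr, integ = m.recruitment_integration(P, ref)
    ok = ~np.isnan(recr)
    assert np.all((recr[ok] >= 0) & (recr[ok] <= 1))
    ok = ~np.isnan(integ)
    assert np.all((integ[ok] >= 0) & (integ[ok] <= 1))


def test_static_partition_recruitment_dominates_integration():
    ref = np.array([1, 1, 2, 2, 3, 3])
    P = m.allegiance(np.tile(ref, (4, 1)))
    recr, integ = m.recruitment_integration(P, ref)
    assert np.all(recr >= integ)
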