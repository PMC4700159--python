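import numpy as np
import pytest
from scipy.optimize import brentq

from conftest import dual_matrices, oracle_box_qp, random_tsvm_problem
from pptsvm.kernel import KernelSpec, gram
from pptsvm.tsvm import (
    TSVMBinaryModel,
    TSVMTrainingProblem,
    _coupled_distances,
    continuous_output,
    dual_objective,
    perpendicular_distances,
    predict_label,
    train_tsvm,
)


def test_separable_blobs_perfectly_classified(separable_binary):
    problem, model = separable_binary
    X = np.vstack([problem.A, problem.B])
    y = np.r_[np.ones(10), -np.ones(10)]
    assert np.all(predict_label(model, X) == y)


def test_dual_feasibility(separable_binary):
    problem, model = separable_binary
    assert np.all(model.alpha >= -1e-8) and np.all(model.alpha <= problem.c1 + 1e-8)
    assert np.all(model.beta >= -1e-8) and np.all(model.beta <= problem.c2 + 1e-8)


@pytest.mark.parametrize("seed", [0, 3, 11, 42])
def test_dual_matches_independent_qp_oracle(seed):
    """Dual objective and recovered surfaces agree with a generic QP solve."""
    rng = np.random.default_rng(seed)
    p = random_tsvm_problem(rng)
    model = train_tsvm(p)
    (M1, P1, c1), (M2, P2, c2) = dual_matrices(p)
    a_ref = oracle_box_qp(M1, np.ones(M1.shape[0]), c1)
    b_ref = oracle_box_qp(M2, np.ones(M2.shape[0]), c2)
    e1, e2 = np.ones(M2.shape[0]), np.ones(M1.shape[0])
    assert dual_objective(M1, e2, model.alpha) == pytest.approx(
        dual_objective(M1, e2, a_ref), abs=1e-6)
    assert dual_objective(M2, e1, model.beta) == pytest.approx(
        dual_objective(M2, e1, b_ref), abs=1e-6)
    np.testing.assert_allclose(np.r_[model.u1, model.b1], -P1 @ a_ref, atol=1e-6)
    np.testing.assert_allclose(np.r_[model.u2, model.b2], P2 @ b_ref, atol=1e-6)


def test_swapping_classes_flips_labels(separable_binary):
    problem, model = separable_binary
    swapped = TSVMTrainingProblem(
        A=problem.B, B=problem.A, c1=problem.c2, c2=problem.c1, kernel=problem.kernel
    )
    model_sw = train_tsvm(swapped)
    X = np.vstack([problem.A, problem.B])
    assert np.all(predict_label(model_sw, X) == -predict_label(model, X))


def test_perpendicular_distances_hand_toy():
    """Two reference points, hand-fixed surfaces: s1, s2 by scalar arithmetic."""
    g = 1.0
    C = np.array([[0.0], [1.0]])
    u1, b1 = np.array([1.0, 0.0]), 0.5
    u2, b2 = np.array([0.3, -0.4]), -0.2
    m = TSVMBinaryModel(C=C, u1=u1, b1=b1, u2=u2, b2=b2, kernel=KernelSpec(g=g))
    x = np.array([0.3])
    k0, k1 = np.exp(-g * 0.3**2), np.exp(-g * 0.7**2)
    kcc = np.exp(-g * 1.0)
    # u^T K u written out entry by entry
    n1 = np.sqrt(1.0 * 1.0)  # u1 = e1: picks K[0,0] = 1
    n2 = np.sqrt(0.3 * 0.3 + (-0.4) ** 2 + 2 * 0.3 * (-0.4) * kcc)
    s1_expect = abs(k0 * 1.0 + 0.5) / n1
    s2_expect = abs(k0 * 0.3 + k1 * (-0.4) - 0.2) / n2
    s1, s2 = perpendicular_distances(m, x)
    assert s1 == pytest.approx(s1_expect, abs=1e-12)
    assert s2 == pytest.approx(s2_expect, abs=1e-12)


def test_distance_scale_invariance(separable_binary):
    _, model = separable_binary
    x = np.array([1.0, -2.0])
    s1, _ = perpendicular_distances(model, x)
    scaled = TSVMBinaryModel(
        C=model.C, u1=2.0 * model.u1, b1=2.0 * model.b1,
        u2=model.u2, b2=model.b2, kernel=model.kernel,
    )
    s1_scaled, _ = perpendicular_distances(scaled, x)
    assert s1_scaled == pytest.approx(s1, rel=1e-12)


def test_point_on_surface_has_zero_distance(separable_binary):
    problem, model = separable_binary
    Kcc = model.Kcc

    def resp1(t):
        x = (1 - t) * problem.A[0] + t * problem.B[0]
        return (gram(x[None, :], model.C, model.kernel) @ model.u1 + model.b1).item()

    # the response is ~0 near class +1 points; scan for a sign-change bracket
    ts = np.linspace(-1.0, 1.5, 251)
    vals = [resp1(t) for t in ts]
    k = next(i for i in range(len(ts) - 1) if vals[i] * vals[i + 1] < 0)
    t_star = brentq(resp1, ts[k], ts[k + 1], xtol=1e-15)
    x_star = (1 - t_star) * problem.A[0] + t_star * problem.B[0]
    s1, _ = perpendicular_distances(model, x_star)
    assert s1 <= 1e-8
    assert Kcc is model.Kcc  # Gram over C cached, not recomputed


def test_tie_breaks_to_plus_one():
    # identical surfaces: every point is a tie, and the ranking output is 0
    C = np.array([[0.0], [1.0]])
    u = np.array([0.5, -0.5])
    m = TSVMBinaryModel(C=C, u1=u, b1=0.1, u2=u.copy(), b2=0.1, kernel=KernelSpec(g=1.0))
    x = np.array([0.4])
    assert predict_label(m, x) == 1
    assert continuous_output(m, x) == 0.0


def test_continuous_output_bound_and_sign(separable_binary):
    problem, model = separable_binary
    rng = np.random.default_rng(5)
    # sample around the training distribution, where the score is meaningful
    X = np.vstack([problem.A, problem.B]) + rng.normal(0, 1.5, (20, 2))
    f = continuous_output(model, X)
    d_plus, d_minus = _coupled_distances(model, X)
    d_min = np.minimum(d_plus, d_minus)
    assert np.all(np.abs(f) <= d_min + 1e-12)
    s1, s2 = perpendicular_distances(model, X)
    # where the clamped magnitude is nonzero, the sign follows the
    # nearer-surface label
    live = (np.abs(s1 - s2) > 1e-12) & (f != 0)
    assert live.sum() >= 10
    assert np.all(np.sign(f[live]) == np.where(s1[live] < s2[live], 1, -1))


def test_continuous_output_ranks_classes(separable_binary):
    problem, model = separable_binary
    f_pos = continuous_output(model, problem.A)
    f_neg = continuous_output(model, problem.B)
    assert f_pos.min() > f_neg.max()


def test_training_accuracy_monotone_in_separation():
    accs = []
    for sep in [1.0, 2.0, 3.0, 4.0, 6.0]:
        rng = np.random.default_rng(17)
        A = rng.normal(0, 1, (15, 2)) + [sep / 2, 0.0]
        B = rng.normal(0, 1, (15, 2)) + [-sep / 2, 0.0]
        p = TSVMTrainingProblem(A=A, B=B, c1=0.25, c2=0.25, kernel=KernelSpec(g=0.25))
        m = train_tsvm(p)
        X = np.vstack([A, B])
        y = np.r_[np.ones(15), -np.ones(15)]
        accs.append(np.mean(predict_label(m, X) == y))
    assert all(b >= a for a, b in zip(accs, accs[1:]))


def test_serialization_round_trip_exact(separable_binary):
    _, model = separable_binary
    restored = TSVMBinaryModel.from_dict(model.to_dict())
    np.testing.assert_array_equal(restored.C, model.C)
    np.testing.assert_array_equal(restored.u1, model.u1)
    np.testing.assert_array_equal(restored.u2, model.u2)
    np.testing.assert_array_equal(restored.alpha, model.alpha)
    assert restored.b1 == model.b1 and restored.b2 == model.b2
    assert restored.kernel == model.kernel and restored.gamma == model.gamma


def test_degenerate_single_class_rejected():
    with pytest.raises(ValueError, match="at least one sample"):
        TSVMTrainingProblem(
            A=np.empty((0, 2)), B=np.ones((3, 2)),
            c1=0.25, c2=0.25, kernel=KernelSpec(g=1.0),
        )
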