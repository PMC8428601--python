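import numpy as np
import pytest

import spotdiff as sd
from spotdiff.diffusion import dense_ranks
from spotdiff.errors import (
    InvalidInputError,
    TopologyMismatchError,
    UndefinedEntropyError,
)

BOUNDARY_MODES = ("zero-flux", "nearest-inner")


# ---------------------------------------------------------------------------
# Laplacian stencils
# ---------------------------------------------------------------------------

def test_rectilinear_stencil_annihilates_constants_and_linears(lattice_5x5):
    g = lattice_5x5
    np.testing.assert_allclose(sd.laplacian_rectilinear(np.full(25, 5.0), g), 0)
    np.testing.assert_allclose(sd.laplacian_rectilinear(g.coords[:, 0], g), 0, atol=1e-12)


def test_rectilinear_stencil_exact_on_quadratics(lattice_5x5):
    """Lap(x^2 + y^2) = 4 exactly on a unit lattice."""
    u = (lattice_5x5.coords ** 2).sum(axis=1)
    np.testing.assert_allclose(sd.laplacian_rectilinear(u, lattice_5x5), 4.0)


def test_hexagonal_stencil_exact_on_quadratics(hex_lattice_5x5):
    """The 7-point hex stencil with coefficient 2/(3h^2) gives Lap = 4 for
    x^2+y^2; linear fields vanish by the symmetry of the six offsets."""
    g = hex_lattice_5x5
    u = (g.coords ** 2).sum(axis=1)
    np.testing.assert_allclose(sd.laplacian_hexagonal(u, g), 4.0, atol=1e-10)
    np.testing.assert_allclose(sd.laplacian_hexagonal(g.coords[:, 0], g), 0, atol=1e-10)


def test_unstructured_agrees_with_rectilinear_on_perfect_lattice(lattice_5x5):
    """Cross-operator oracle: the graph Laplacian with k=4 on an exact unit
    lattice reproduces the 5-point stencil at every inner point."""
    coords = sd.rectilinear_lattice(5, 5)
    gu = sd.build_grid(coords, "unstructured", k=4)
    rng = np.random.default_rng(1)
    u = rng.uniform(0, 1, 25)
    inner_u = np.flatnonzero(gu.inner_mask)
    inner_r = np.flatnonzero(lattice_5x5.inner_mask)
    np.testing.assert_array_equal(inner_u, inner_r)
    np.testing.assert_allclose(
        sd.laplacian_unstructured(u, gu), sd.laplacian_rectilinear(u, lattice_5x5),
        atol=1e-12,
    )


def test_topology_mismatch_raises(lattice_5x5):
    with pytest.raises(TopologyMismatchError):
        sd.laplacian_hexagonal(np.ones(25), lattice_5x5)


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("boundary", BOUNDARY_MODES)
def test_constant_field_is_fixed_point(lattice_5x5, boundary):
    params = sd.DiffusionParams(boundary=boundary)
    u = np.full(25, 0.7)
    np.testing.assert_array_equal(sd.propagate(u, lattice_5x5, params), u)


def test_hot_spot_spreads_to_neighbors(lattice_5x5):
    u = np.full(25, 0.1)
    center = 12
    u[center] = 1.0
    out = sd.propagate(u, lattice_5x5)
    assert out[center] < u[center]
    for q in lattice_5x5.neighbor_index[center]:
        assert out[q] > u[q]


def test_zero_diffusivity_is_identity(lattice_5x5):
    rng = np.random.default_rng(2)
    u = rng.uniform(0, 1, 25)
    np.testing.assert_array_equal(
        sd.propagate(u, lattice_5x5, sd.DiffusionParams(D=0.0)), u
    )


def test_unstable_timestep_raises(lattice_9x9):
    """A dt far beyond the stability bound blows up and is reported."""
    from spotdiff.errors import NumericalInstabilityError

    rng = np.random.default_rng(30)
    pm = sd.ProfileMatrix.from_raw(rng.integers(0, 40, size=(2, 81)).astype(float))
    with pytest.raises(NumericalInstabilityError, match="dt"):
        sd.rank_by_diffusion(pm, lattice_9x9, sd.DiffusionParams(dt=50.0))


@pytest.mark.parametrize("boundary", BOUNDARY_MODES)
def test_engine_matches_naive_reimplementation(boundary):
    """Oracle equivalence: the sparse-operator engine reproduces a
    straightforward loop implementation of the stencil + forward-Euler
    update (with either boundary rule) on a 4x4 lattice to 1e-12."""
    coords = sd.rectilinear_lattice(4, 4)
    g = sd.build_grid(coords, "rectilinear", spacing=1.0)
    params = sd.DiffusionParams(dt=0.02, boundary=boundary)
    rng = np.random.default_rng(4)
    u_engine = rng.uniform(0.2, 1.0, 16)
    u_naive = u_engine.copy()
    D, dt, h = params.D, 0.02, 1.0

    for _ in range(50):
        lap = np.zeros(16)
        for s in range(16):
            neigh = g.neighbor_index[s]
            if boundary == "zero-flux" or g.inner_mask[s]:
                lap[s] = (u_naive[neigh].sum() - len(neigh) * u_naive[s]) / h**2
        if boundary == "nearest-inner":
            for s in np.flatnonzero(g.boundary_mask):
                lap[s] = lap[g.nearest_inner[s]]
        u_naive = np.maximum(u_naive + D * dt * lap, 0.0)
        u_engine = sd.propagate(u_engine, g, params)
        np.testing.assert_allclose(u_engine, u_naive, atol=1e-12)


# ---------------------------------------------------------------------------
# Entropy
# ---------------------------------------------------------------------------

def test_entropy_uniform_is_log_n():
    assert sd.entropy(np.ones(8)) == pytest.approx(np.log(8))


def test_entropy_point_mass_is_zero():
    assert sd.entropy(np.array([0.0, 5.0, 0.0])) == 0.0


def test_entropy_hand_computed():
    """u=(1,1,2): u_hat=(.25,.25,.5), H = -(2*.25 ln .25 + .5 ln .5)."""
    expected = -(2 * 0.25 * np.log(0.25) + 0.5 * np.log(0.5))
    assert sd.entropy(np.array([1.0, 1.0, 2.0])) == pytest.approx(expected)


def test_entropy_zero_mass_errors():
    with pytest.raises(UndefinedEntropyError):
        sd.entropy(np.zeros(4))


def test_entropy_subset_argument(lattice_3x3):
    u = np.arange(9, dtype=float)
    sub = lattice_3x3.inner_indices
    assert sd.entropy(u, sub) == 0.0  # single inner point -> point mass


# ---------------------------------------------------------------------------
# Diffusion time
# ---------------------------------------------------------------------------

def test_constant_profile_converges_in_one_step(lattice_5x5):
    params = sd.DiffusionParams()
    t, steps, conv = sd.diffusion_time(np.full(25, 0.5), lattice_5x5, params)
    assert steps == 1 and conv
    assert t == pytest.approx(params.resolve_dt(lattice_5x5))


def test_hot_spot_takes_longer_than_one_step(lattice_9x9):
    u0 = np.full(81, 0.1)
    u0[40] = 1.0
    t, steps, conv = sd.diffusion_time(u0, lattice_9x9)
    assert conv and steps > 1


def test_structured_profile_outlasts_shuffles(lattice_9x9):
    """A coherent half-field profile homogenizes more slowly than random
    rearrangements of the same values (the core ranking premise)."""
    raw = np.where(lattice_9x9.coords[:, 0] < 4, 40, 0).astype(float)
    u0 = sd.normalize_profiles(raw[None, :])[0]
    t_struct, _, _ = sd.diffusion_time(u0, lattice_9x9)
    rng = np.random.default_rng(8)
    t_shuf = []
    for _ in range(20):
        t, _, _ = sd.diffusion_time(u0[rng.permutation(81)], lattice_9x9)
        t_shuf.append(t)
    assert t_struct > np.median(t_shuf)


def test_diffusion_time_invariant_under_location_relabeling(lattice_9x9):
    raw = np.where(lattice_9x9.coords[:, 1] > 5, 30, 2).astype(float)
    u0 = sd.normalize_profiles(raw[None, :])[0]
    t_ref, s_ref, _ = sd.diffusion_time(u0, lattice_9x9)
    rng = np.random.default_rng(9)
    perm = rng.permutation(81)
    gp = sd.build_grid(lattice_9x9.coords[perm], "rectilinear", spacing=1.0)
    t_perm, s_perm, _ = sd.diffusion_time(u0[perm], gp)
    assert s_perm == s_ref
    assert t_perm == pytest.approx(t_ref)


def test_rescaling_log_values_leaves_diffusion_time_unchanged(lattice_9x9):
    """Max-division removes any constant factor on the log-transformed
    values, so the diffusion input — and hence t_d — is identical."""
    raw = np.where(lattice_9x9.coords[:, 0] < 4, 25, 1).astype(float)
    y_hat = np.log2(raw + 2)
    u_a = y_hat / y_hat.max()
    scaled = 3.7 * y_hat
    u_b = scaled / scaled.max()
    np.testing.assert_allclose(u_a, u_b)
    assert sd.diffusion_time(u_a, lattice_9x9) == sd.diffusion_time(u_b, lattice_9x9)


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def test_minmax_and_dense_ranks():
    """t_d=(10,30,20) must normalize to (0,1,0.5) and rank as (3,1,2)."""
    np.testing.assert_allclose(sd.minmax_normalize(np.array([10.0, 30.0, 20.0])), [0, 1, 0.5])
    np.testing.assert_array_equal(dense_ranks(np.array([10.0, 30.0, 20.0])), [3, 1, 2])
    np.testing.assert_array_equal(dense_ranks(np.array([5.0, 5.0, 1.0])), [1, 1, 2])


def test_minmax_degenerate_range_warns():
    with pytest.warns(UserWarning):
        np.testing.assert_array_equal(sd.minmax_normalize(np.array([2.0, 2.0])), [0, 0])


def test_rank_by_diffusion_single_gene(lattice_5x5):
    raw = np.arange(25, dtype=float)[None, :]
    pm = sd.ProfileMatrix.from_raw(raw, ["only"])
    with pytest.warns(UserWarning):
        res = sd.rank_by_diffusion(pm, lattice_5x5)
    assert res.t_d_normalized[0] == 0.0
    assert res.rank[0] == 1


def test_rank_by_diffusion_worker_invariance(lattice_9x9):
    rng = np.random.default_rng(12)
    raw = rng.integers(0, 40, size=(8, 81)).astype(float)
    pm = sd.ProfileMatrix.from_raw(raw)
    r1 = sd.rank_by_diffusion(pm, lattice_9x9, n_workers=1)
    r2 = sd.rank_by_diffusion(pm, lattice_9x9, n_workers=2)
    np.testing.assert_array_equal(r1.t_d, r2.t_d)
    np.testing.assert_array_equal(r1.steps, r2.steps)


def test_rank_by_diffusion_rejects_degenerate_genes(lattice_5x5):
    with pytest.warns(UserWarning):
        pm = sd.ProfileMatrix.from_raw(np.zeros((2, 25)), ["a", "b"], c=1)
    with pytest.raises(InvalidInputError):
        sd.rank_by_diffusion(pm, lattice_5x5)


def test_max_steps_cap_marks_nonconverged(lattice_9x9):
    rng = np.random.default_rng(13)
    raw = rng.integers(0, 40, size=(3, 81)).astype(float)
    pm = sd.ProfileMatrix.from_raw(raw)
    params = sd.DiffusionParams(max_steps=1, eps=1e-300)
    res = sd.rank_by_diffusion(pm, lattice_9x9, params)
    assert not res.converged.any()
    np.testing.assert_allclose(res.t_d, params.resolve_dt(lattice_9x9))


# ---------------------------------------------------------------------------
# Top-profile selection
# ---------------------------------------------------------------------------

def _make_result(values):
    values = np.asarray(values, dtype=float)
    n = len(values)
    return sd.DiffusionResult(
        gene_names=np.array([f"g{i:03d}" for i in range(n)], dtype=object),
        t_d=values,
        t_d_normalized=sd.minmax_normalize(values) if np.ptp(values) else values * 0,
        rank=dense_ranks(values),
        converged=np.ones(n, dtype=bool),
        steps=np.ones(n, dtype=int),
    )


def test_select_top_finds_high_plateau():
    """Three genes on a high plateau before a sharp drop are selected; the
    knee index is verified against a brute-force chord-distance oracle."""
    values = np.array([1.0, 0.98, 0.96] + list(np.linspace(0.1, 0.0, 27)))
    res = _make_result(values)
    picked = sd.select_top(res)
    assert picked == ["g000", "g001", "g002"]

    # brute-force oracle over all indices
    n = len(values)
    x = np.linspace(0, 1, n)
    y = (values - values[-1]) / (values[0] - values[-1])
    best, best_d = 0, -1.0
    for i in range(n):
        num = abs((y[-1] - y[0]) * x[i] - (x[-1] - x[0]) * y[i] + x[-1] * y[0] - y[-1] * x[0])
        den = np.hypot(y[-1] - y[0], x[-1] - x[0])
        if num / den > best_d:
            best, best_d = i, num / den
    assert len(picked) == best


def test_select_top_flat_and_linear_curves_select_nothing():
    assert sd.select_top(_make_result(np.full(10, 3.0))) == []
    assert sd.select_top(_make_result(np.linspace(1, 0, 10))) == []


def test_select_top_needs_three_genes():
    with pytest.raises(InvalidInputError):
        sd.select_top(_make_result([1.0, 0.5]))
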