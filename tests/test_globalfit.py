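"""Global ODE fitting and SSR-ratio confidence contours."""

import numpy as np
import pytest

from dnphkin import (
    GlobalFitProblem,
    RateConstantSet,
    ReactionConditions,
    SamplingSpec,
    Trace,
    build_scheme,
    contour_from_residual,
    fitspace_contour,
    generate_stopped_flow_set,
    global_fit,
)
from dnphkin.globalfit import _make_residual_fn, ssr_ratio_threshold

TRUE = RateConstantSet(k1=1.0, k2=2.36)


def _binding_traces(wavelengths, noise, seed, *, enzymes=(22.0, 88.0), n_points=200, t_end=3.0):
    scheme = build_scheme("binding_only")
    conds = [ReactionConditions(enzyme_total=e, substrate_total=10.0) for e in enzymes]
    sampling = SamplingSpec(mode="logarithmic", n_points=n_points, t_end=t_end)
    return tuple(
        generate_stopped_flow_set(scheme, TRUE, conds, wavelengths, sampling, noise, seed=seed)
    )


def test_noiseless_binding_recovery():
    """Two-wavelength noiseless binding data pin k1 and k2 to the generator."""
    traces = _binding_traces([251, 286], 0.0, seed=0)
    problem = GlobalFitProblem(
        scheme=build_scheme("binding_only"),
        traces=traces,
        free=("k1", "k2"),
        init=RateConstantSet(k1=0.4, k2=0.8),
    )
    fit = global_fit(problem, seed=5, n_starts=3)
    assert fit.converged
    assert fit.estimates["k1"] == pytest.approx(1.0, rel=1e-5)
    assert fit.estimates["k2"] == pytest.approx(2.36, rel=1e-5)
    assert fit.diagnostics["kd_app"] == pytest.approx(2.36, rel=1e-5)
    assert not fit.diagnostics["unidentifiable"]


def test_optimum_never_worse_than_generator():
    """Fitted SSR is bounded by the SSR at the generating parameters."""
    traces = _binding_traces([286], 0.002, seed=21, n_points=120)
    problem = GlobalFitProblem(
        scheme=build_scheme("binding_only"),
        traces=traces,
        free=("k1", "k2"),
        init=RateConstantSet(k1=0.5, k2=1.0),
    )
    fit = global_fit(problem, seed=1, n_starts=2)
    residual = _make_residual_fn(problem)
    r_true = residual({"k1": 1.0, "k2": 2.36})
    assert fit.ssr <= float(r_true @ r_true) + 1e-12


def test_blind_wavelength_flags_unidentifiable():
    """At 275 nm a binding-only signal is flat, so neither rate is constrained."""
    traces = _binding_traces([275], 0.002, seed=3, enzymes=(30.0,), n_points=80, t_end=1.0)
    problem = GlobalFitProblem(
        scheme=build_scheme("binding_only"),
        traces=traces,
        free=("k1", "k2"),
        init=RateConstantSet(k1=0.5, k2=1.0),
    )
    fit = global_fit(problem, seed=2, n_starts=2)
    assert set(fit.diagnostics["unidentifiable"]) == {"k1", "k2"}


def test_parameterisation_invariance():
    """Fitting (k1, k2) and (k1, KD) reaches the same SSR minimum."""
    traces = _binding_traces([286], 0.002, seed=11, enzymes=(30.0,), n_points=80, t_end=1.0)
    scheme = build_scheme("binding_only")
    init = RateConstantSet(k1=0.5, k2=1.0)
    fit_rates = global_fit(
        GlobalFitProblem(scheme=scheme, traces=traces, free=("k1", "k2"), init=init),
        seed=2, n_starts=3,
    )
    fit_kd = global_fit(
        GlobalFitProblem(
            scheme=scheme, traces=traces, free=("k1", "kd_app"), init=init,
            parameterisation="k1_kd",
        ),
        seed=2, n_starts=3,
    )
    assert fit_kd.ssr == pytest.approx(fit_rates.ssr, rel=1e-9)
    kd_direct = fit_rates.estimates["k2"] / fit_rates.estimates["k1"]
    assert fit_kd.estimates["kd_app"] == pytest.approx(kd_direct, rel=1e-4)


def test_contour_matches_analytic_ellipse_on_linear_model():
    """For a linear least-squares problem the SSR-ratio region is exactly the
    F-distribution confidence ellipse of the parameter pair."""
    rng = np.random.default_rng(3)
    design = rng.normal(size=(40, 3))
    x_true = np.array([1.0, -0.5, 2.0])
    y = design @ x_true + rng.normal(0, 0.1, 40)
    x_hat, *_ = np.linalg.lstsq(design, y, rcond=None)

    def residual(x):
        return design @ x - y

    grid_x = x_hat[0] + np.linspace(-0.2, 0.2, 21)
    grid_y = x_hat[1] + np.linspace(-0.2, 0.2, 21)
    region = contour_from_residual(
        residual, x_hat, (0, 1), grid_x, grid_y,
        confidence=0.95, n_obs=40, n_params=3,
    )
    assert region.valid.all()
    # closed-form ellipse from the covariance of the pair
    cov = np.linalg.inv(design.T @ design)
    quad = np.linalg.inv(cov[:2, :2])
    r0 = residual(x_hat)
    ssr_min = float(r0 @ r0)
    analytic = np.zeros_like(region.contained)
    for i, gy in enumerate(grid_y):
        for j, gx in enumerate(grid_x):
            dx = np.array([gx - x_hat[0], gy - x_hat[1]])
            analytic[i, j] = 1.0 + (dx @ quad @ dx) / ssr_min <= region.threshold
    assert np.array_equal(region.contained, analytic)
    # the best-fit node sits at ratio exactly 1
    assert region.ssr_ratio[10, 10] == pytest.approx(1.0, abs=1e-9)


def test_equilibrium_dominated_contour_elongates_along_kd_line():
    """When sampling sees mostly the binding equilibrium, only KD = k2/k1 is
    constrained: the SSR ratio stays below threshold along the k2/k1 = const
    line over a 3-fold range, while off-line nodes are excluded."""
    scheme = build_scheme("binding_only")
    conds = [ReactionConditions(enzyme_total=e, substrate_total=10.0) for e in (22.0, 44.0, 88.0)]
    sampling = SamplingSpec(mode="uniform", n_points=50, t_end=2.0)
    raw = generate_stopped_flow_set(scheme, TRUE, conds, [286], sampling, 0.001, seed=7)
    traces = []
    for tr in raw:  # discard the relaxation: keep the equilibrium plateau only
        keep = tr.time >= 0.3
        traces.append(
            Trace(time=tr.time[keep], signal=tr.signal[keep], wavelength=tr.wavelength,
                  conditions=tr.conditions, noise_sigma=tr.noise_sigma)
        )
    problem = GlobalFitProblem(
        scheme=scheme, traces=tuple(traces), free=("k1", "k2"),
        init=TRUE, fit_offsets=False,
    )
    fit = global_fit(problem, seed=1, n_starts=2)
    k1_hat, k2_hat = fit.estimates["k1"], fit.estimates["k2"]
    scale = np.array([1.0, 1.7, 3.0])
    region = fitspace_contour(
        problem, fit, ("k1", "k2"), {"k1": k1_hat * scale, "k2": k2_hat * scale}
    )
    diagonal = [bool(region.contained[i, i]) for i in range(3)]
    assert all(diagonal), "constant-KD line must stay inside the region"
    assert not region.contained[0, 2], "3-fold k1 at fixed k2 must be excluded"
    assert not region.contained[2, 0], "3-fold k2 at fixed k1 must be excluded"


def test_fitspace_region_covers_generator():
    """Over 50 seeded noisy replicates the 95% region contains the generating
    (k1, k2) in at least 85% of cases."""
    scheme = build_scheme("binding_only")
    cond = ReactionConditions(enzyme_total=30.0, substrate_total=10.0)
    sampling = SamplingSpec(mode="logarithmic", n_points=60, t_end=1.0)
    n_reps, contained = 50, 0
    for rep in range(n_reps):
        traces = tuple(
            generate_stopped_flow_set(scheme, TRUE, [cond], [286], sampling, 0.002, seed=1000 + rep)
        )
        problem = GlobalFitProblem(
            scheme=scheme, traces=traces, free=("k1", "k2"),
            init=RateConstantSet(k1=0.7, k2=1.5),
        )
        fit = global_fit(problem, seed=rep, n_starts=1)
        residual = _make_residual_fn(problem)
        r = residual({"k1": TRUE.k1, "k2": TRUE.k2})
        ratio = float(r @ r) / fit.ssr
        threshold = ssr_ratio_threshold(0.95, fit.n_points, 3)  # k1, k2 + offset
        contained += ratio <= threshold
    assert contained / n_reps >= 0.85


def test_problem_validation():
    traces = _binding_traces([286], 0.0, seed=0, enzymes=(30.0,), n_points=30, t_end=1.0)
    scheme = build_scheme("binding_only")
    with pytest.raises(ValueError, match="at least one trace"):
        GlobalFitProblem(scheme=scheme, traces=(), free=("k1",), init=TRUE)
    with pytest.raises(ValueError, match="unknown free parameter"):
        GlobalFitProblem(scheme=scheme, traces=traces, free=("k9",), init=TRUE)
    with pytest.raises(ValueError, match="kd_app"):
        GlobalFitProblem(
            scheme=scheme, traces=traces, free=("k1", "k2"), init=TRUE,
            parameterisation="k1_kd",
        )
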