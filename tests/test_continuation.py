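import numpy as np
import pytest

from mepdsim import CouplingParams, KNDyParams, MePDParams, update
from mepdsim.models import mepd_jacobian, mepd_rhs
from mepdsim.continuation import (
    ContinuationError,
    continue_codim1_locus,
    continue_equilibria,
    continue_limit_cycle,
    detect_codim1,
    detect_codim2,
    find_equilibrium,
    locate_torus_bifurcation,
)
from mepdsim.continuation.equilibria import sn_test


# --- equilibrium location -------------------------------------------------

def test_origin_found_without_drive():
    x = find_equilibrium(MePDParams(), (0.05, 0.05, 0.05))
    np.testing.assert_allclose(x, 0.0, atol=1e-12)


def test_equilibrium_residual_contract():
    p = update(MePDParams(), Kp=1.0)
    x = find_equilibrium(p, (0.1, 0.1, 0.1))
    assert np.linalg.norm(mepd_rhs(0.0, x, p)) < 1e-12


def test_unstable_focus_inside_cycle():
    # the equilibrium continued past the Hopf point is an unstable focus
    p = update(MePDParams(), Kp=2.3)
    x = find_equilibrium(p, (0.2, 0.2, 0.2))
    ev = np.linalg.eigvals(mepd_jacobian(x, p))
    pair = ev[np.abs(ev.imag) > 1e-6]
    assert pair.size == 2 and np.all(pair.real > 0)


def test_newton_failure_reports_residual():
    p = update(MePDParams(), Kp=2.0)
    with pytest.raises(ContinuationError, match="residual|converge"):
        find_equilibrium(p, (1e6, 1e6, 1e6), max_iter=3)


# --- one-parameter branches ----------------------------------------------

def test_branch_residuals_below_contract(kp_branch):
    p = kp_branch.base
    for i in range(len(kp_branch)):
        r = mepd_rhs(0.0, kp_branch.states[i], kp_branch.param_at(i))
        assert np.linalg.norm(r) < 1e-10


def test_branch_covers_range(kp_branch):
    assert kp_branch.params[0] == pytest.approx(0.0)
    assert kp_branch.params.max() >= 3.0 - 1e-6
    assert kp_branch.status == "ok"


def test_hopf_detected_near_published_value(hopf_point):
    assert hopf_point.params["Kp"] == pytest.approx(1.4, abs=0.05)
    assert hopf_point.info["hopf_frequency"] > 1e-6
    pair = hopf_point.eigenvalues[np.abs(hopf_point.eigenvalues.imag) > 1e-6]
    assert np.max(np.abs(pair.real)) < 1e-8


def test_branch_step_halving_invariance(mepd_defaults):
    a = continue_equilibria(mepd_defaults, "Kp", (0.0, 3.0), ds0=0.01)
    b = continue_equilibria(mepd_defaults, "Kp", (0.0, 3.0), ds0=0.005)
    hb_a = [x for x in detect_codim1(a) if x.kind == "HB"][0]
    hb_b = [x for x in detect_codim1(b) if x.kind == "HB"][0]
    assert hb_a.params["Kp"] == pytest.approx(hb_b.params["Kp"], abs=1e-6)


def test_low_and_high_activity_segments(mepd_defaults):
    # low activity at small Kp; constant high-activity state at large Kp
    br = continue_equilibria(mepd_defaults, "Kp", (0.0, 25.0))
    i_lo = int(np.argmin(np.abs(br.params - 0.5)))
    assert br.states[i_lo, 0] < 0.1 and bool(br.stable[i_lo])
    mask_hi = br.params > 20.0
    assert mask_hi.any()
    hi_states = br.states[mask_hi]
    hi_stable = br.stable[mask_hi]
    assert hi_states[:, 0].max() > 0.4
    assert hi_stable[hi_states[:, 0] > 0.4].any()


def test_saddle_node_pair_bounds_bistable_window(mepd_defaults):
    br = continue_equilibria(mepd_defaults, "Kp", (0.0, 25.0))
    sns = [b for b in detect_codim1(br) if b.kind == "SN"]
    assert len(sns) == 2
    kp1, kp2 = sorted(b.params["Kp"] for b in sns)
    assert kp1 > 10.0 and kp2 > kp1
    for b in sns:
        assert np.min(np.abs(b.eigenvalues)) < 1e-8


def test_fold_count_matches_det_sign_changes(mepd_defaults):
    br = continue_equilibria(mepd_defaults, "Kp", (0.0, 25.0))
    dets = np.array(
        [sn_test(mepd_jacobian(br.states[i], br.param_at(i))) for i in range(len(br))]
    )
    sign_changes = int(np.sum(dets[:-1] * dets[1:] < 0))
    n_folds = len([b for b in detect_codim1(br) if b.kind == "SN"])
    assert n_folds == sign_changes


def test_full_gaba_suppression_removes_hopf():
    p = update(MePDParams(), beta1=1.0)
    br = continue_equilibria(p, "Kp", (0.0, 14.0))
    assert not any(b.kind == "HB" for b in detect_codim1(br))


def test_malformed_range_rejected(mepd_defaults):
    with pytest.raises(ValueError):
        continue_equilibria(mepd_defaults, "Kp", (3.0, 0.0))


# --- limit cycles ---------------------------------------------------------

@pytest.fixture(scope="module")
def cycle_branch(hopf_point, mepd_defaults):
    return continue_limit_cycle(
        hopf_point, mepd_defaults, "Kp", (hopf_point.params["Kp"], 2.55), dp0=0.02
    )


def test_cycle_period_near_onset_matches_hopf_frequency(cycle_branch, hopf_point):
    T_pred = 2 * np.pi / hopf_point.info["hopf_frequency"]
    assert cycle_branch.periods[0] == pytest.approx(T_pred, rel=0.05)


def test_cycle_period_monotone_decreasing(cycle_branch):
    mask = (cycle_branch.params >= 1.5) & (cycle_branch.params <= 2.5)
    assert mask.sum() >= 5
    assert np.all(np.diff(cycle_branch.periods[mask]) < 0)


def test_cycle_extrema_ordering(cycle_branch):
    assert np.all(cycle_branch.maxima >= cycle_branch.minima)
    assert np.all(cycle_branch.periods > 0)


def test_cycle_amplitude_shrinks_towards_hopf(cycle_branch):
    amp = cycle_branch.maxima[:, 0] - cycle_branch.minima[:, 0]
    assert amp[0] < amp[-1]
    assert amp[0] < 0.1  # small near onset


def test_cycle_stable_supercritical(cycle_branch):
    assert bool(cycle_branch.stable[len(cycle_branch) // 2])


def test_cycle_requires_hopf_kind(hopf_point, mepd_defaults):
    from mepdsim.continuation import BifurcationPoint

    fake = BifurcationPoint(kind="SN", params={"Kp": 2.0}, state=np.zeros(3))
    with pytest.raises(ValueError):
        continue_limit_cycle(fake, mepd_defaults, "Kp", (2.0, 3.0))


# --- two-parameter loci ---------------------------------------------------

@pytest.fixture(scope="module")
def hb_locus(hopf_point, mepd_defaults):
    return continue_codim1_locus(
        hopf_point, mepd_defaults, ("Kp", "alpha"), ((0.0, 30.0), (0.0, 1.0)),
        ds0=0.02, ds_max=0.1,
    )


def test_hb_locus_points_satisfy_test_functions(hb_locus):
    from mepdsim.continuation.equilibria import hopf_test
    from mepdsim.params import unchecked_replace

    for i in range(0, len(hb_locus), 10):
        pe = unchecked_replace(
            hb_locus.base,
            Kp=hb_locus.params[i, 0],
            alpha=hb_locus.params[i, 1],
        )
        assert np.linalg.norm(mepd_rhs(0.0, hb_locus.states[i], pe)) < 1e-10
        assert abs(hopf_test(mepd_jacobian(hb_locus.states[i], pe))) < 1e-8


def test_oscillation_needs_majority_excitation_to_glut(hb_locus):
    # the HB locus never descends to low alpha: oscillations exist only
    # when most of the drive goes to the glutamatergic population
    assert hb_locus.params[:, 1].min() > 0.5


def test_bt_point_on_hb_locus(hb_locus):
    pts = detect_codim2([hb_locus])
    bts = [b for b in pts if b.kind == "BT"]
    assert bts, "expected a Bogdanov-Takens point where omega -> 0"
    bt = bts[0]
    mods = np.sort(np.abs(bt.eigenvalues))
    assert mods[0] < 0.05 and mods[1] < 0.05  # double-degenerate pair shrinking


# --- torus ----------------------------------------------------------------

def test_tr_aligns_with_subsystem_hopf(hopf_point):
    tr = locate_torus_bifurcation(
        MePDParams(), KNDyParams(), CouplingParams(1.5, 0.5), "Kp", (0.0, 3.0)
    )
    assert tr is not None and tr.kind == "TR"
    assert tr.params["Kp"] == pytest.approx(hopf_point.params["Kp"], abs=1e-6)


def test_no_tr_without_coupling():
    tr = locate_torus_bifurcation(
        MePDParams(), KNDyParams(), CouplingParams(0.0, 0.0), "Kp", (0.0, 3.0)
    )
    assert tr is None


def test_no_tr_without_hopf_in_range():
    tr = locate_torus_bifurcation(
        MePDParams(), KNDyParams(), CouplingParams(1.0, 1.0), "Kp", (0.0, 1.0)
    )
    assert tr is None


# --- connectivity-plane loci and cusp -------------------------------------

@pytest.fixture(scope="module")
def cil_branch():
    p = update(MePDParams(), Kp=2.3)
    return p, continue_equilibria(p, "c_il", (0.0, 80.0), guess=(0.1, 0.1, 0.1))


def test_connectivity_branch_has_hb_sn_hb_structure(cil_branch):
    _, br = cil_branch
    kinds = [b.kind for b in detect_codim1(br)]
    assert "SN" in kinds and "HB" in kinds


def test_cusp_where_sn_branches_meet(cil_branch):
    p, br = cil_branch
    sn = [b for b in detect_codim1(br) if b.kind == "SN"][0]
    curve = continue_codim1_locus(
        sn, p, ("c_il", "c_li"), ((0.0, 80.0), (0.0, 40.0)), ds0=0.05, ds_max=0.5
    )
    assert curve.status == "ok" and len(curve) > 50
    cps = [b for b in detect_codim2([curve]) if b.kind == "CP"]
    assert len(cps) == 1
    cp = cps[0]
    # the cusp sits where the locus turns in its second parameter
    assert cp.params["c_li"] == pytest.approx(curve.params[:, 1].min(), abs=1.0)


def test_homoclinic_proxy_locus():
    """Large-period proxy points lie in the oscillation-death window."""
    from mepdsim.continuation import approximate_homoclinic

    hc = approximate_homoclinic(
        MePDParams(), ("Kp", "alpha"), ((0.0, 20.0), (0.9, 0.9)),
        n_grid=1,
        # the cycle period dips ~4x below onset before the homoclinic rise
        # and the primary branch folds shortly after it climbs back, so the
        # attainable proxy threshold is relative to onset but below it.
        # coarse threshold: crossed during the steep period rise towards
        # the homoclinic, well before the first cycle fold stalls the march
        period_ratio=0.3,
        lc_kwargs={"dp0": 0.05, "dp_max": 0.5, "compute_floquet": False},
    )
    assert hc.kind == "HC"
    assert len(hc) >= 1
    assert np.all(hc.params[:, 0] > 14.0) and np.all(hc.params[:, 0] < 20.0)
    # threshold reached: recorded periods at or above the proxy level
    assert hc.aux is not None and np.all(hc.aux > 0)


def test_quasiperiodic_spectrum_above_tr():
    """Just above the torus transition the v trace carries two
    incommensurate frequencies (KNDy pulse rhythm + MePD forcing)."""
    from fractions import Fraction

    from mepdsim import integrate
    from mepdsim.continuation import spectral_peaks

    tr = locate_torus_bifurcation(
        MePDParams(), KNDyParams(), CouplingParams(1.5, 0.5), "Kp", (0.0, 3.0)
    )
    traj = integrate(
        "coupled",
        mepd=update(MePDParams(), Kp=tr.params["Kp"] + 0.2),
        coupling=CouplingParams(1.5, 0.5),
        t_span=(0.0, 500.0),
    )
    freqs = spectral_peaks(traj.post_times, traj.post_component("v"), n_peaks=12)
    assert len(freqs) >= 2

    def incommensurate(f1: float, f2: float) -> bool:
        ratio = max(f1, f2) / min(f1, f2)
        return all(
            abs(ratio - Fraction(p, q)) > 1e-3
            for p in range(1, 9)
            for q in range(1, 9)
        )

    # the slow pulse rhythm contributes harmonically related peaks; the
    # fast circuit forcing contributes a line incommensurate with them
    pairs = [
        (freqs[i], freqs[j])
        for i in range(len(freqs))
        for j in range(i + 1, len(freqs))
    ]
    assert any(incommensurate(a, b) for a, b in pairs), f"peaks {freqs}"
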