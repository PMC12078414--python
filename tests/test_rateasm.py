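import numpy as np
import pytest

from ccrama import physmodel as pm
from ccrama import rateasm as ra
from ccrama import synthgen as sg
from ccrama.gridmetrics import DihedralSeries
from ccrama.rateasm import (KnownAmplitudes, ResidueRateSet, normalize_rates,
                            proxy_diagnostic, proxy_tau_ccca, proxy_tau_nnh,
                            proxy_tau_opt)


def make_rate_set(residue=0, gamma=1.0, tau=2e-9, amps=None):
    amps = amps or {rid: float(i + 1) * 1e8
                    for i, rid in enumerate(pm.RATE_REGISTRY)}
    rates = {rid: amps[rid] * tau for rid in pm.RATE_REGISTRY}
    return ResidueRateSet(residue, rates, tau_nnh=tau, tau_ccca=tau,
                          tau_opt=tau, true_tau={r: tau for r in rates},
                          true_amp=amps)


class TestProxies:
    def test_equal_plane_rates_recover_tau(self):
        tau, _ = proxy_tau_nnh(3.0, 3.0, a_nnh=1.5e9)
        assert np.isclose(tau, 3.0 / 1.5e9)

    def test_arithmetic_mean_of_planes(self):
        tau, flagged = proxy_tau_ccca(2.0, 4.0, a_ccca=1.0)
        assert tau == 3.0 and not flagged

    def test_single_plane_fallback_flagged(self):
        tau, flagged = proxy_tau_nnh(2.0, None, a_nnh=1.0)
        assert tau == 2.0 and flagged
        with pytest.raises(ValueError):
            proxy_tau_nnh(None, None, a_nnh=1.0)

    def test_opt_blend_weights(self):
        assert proxy_tau_opt(1.0, 0.0) == pytest.approx(0.7)
        assert proxy_tau_opt(0.0, 1.0) == pytest.approx(0.3)
        assert proxy_tau_opt(2.0, 2.0) == pytest.approx(2.0)

    def test_opt_blend_linearity(self):
        a = proxy_tau_opt(1.0, 2.0)
        b = proxy_tau_opt(3.0, 5.0)
        assert proxy_tau_opt(1 + 3, 2 + 5) == pytest.approx(a + b)

    def test_opt_applies_only_to_amide_proton_rates(self):
        rs = make_rate_set()
        rs.tau_ccca, rs.tau_nnh = 2e-9, 4e-9
        rs.tau_opt = proxy_tau_opt(rs.tau_ccca, rs.tau_nnh)
        assert ra.proxy_tau(rs, "opt", "NHN_CAHA") == pytest.approx(
            0.7 * 2e-9 + 0.3 * 4e-9)
        assert ra.proxy_tau(rs, "opt", "CAHA_C") == pytest.approx(2e-9)


class TestNormalization:
    def test_exact_recovery_when_proxy_equals_true_tau(self):
        rs = make_rate_set(tau=3e-9)
        approx = normalize_rates(rs, "ccca")
        for rid in pm.REMOTE_RATE_IDS:
            assert np.isclose(approx[rid], rs.true_amp[rid], rtol=1e-12)

    def test_uniform_proxy_scaling_inverts_slope(self):
        c = 2.0
        rs = make_rate_set(tau=3e-9)
        rs.tau_ccca = 3e-9 * c
        r2, slope = proxy_diagnostic([rs], "ccca")
        assert np.isclose(slope, 1.0 / c, rtol=1e-12)
        assert np.isclose(r2, 1.0, atol=1e-12)

    def test_nonpositive_proxy_rejected(self):
        rs = make_rate_set()
        with pytest.raises(ValueError):
            ResidueRateSet(0, rs.rates, tau_ccca=-1e-9)


class TestProxyDiagnostic:
    def test_identity_cloud(self):
        sets = [make_rate_set(i, tau=2e-9) for i in range(3)]
        r2, slope = proxy_diagnostic(sets, "ccca")
        assert slope == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_doubled_cloud(self):
        rs = make_rate_set(tau=2e-9)
        rs.tau_ccca = 1e-9  # y = Gamma / tau_ccca = 2 x
        r2, slope = proxy_diagnostic([rs], "ccca")
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_noisy_cloud_matches_closed_form(self, rng):
        x = rng.uniform(-5e9, 5e9, 40)
        noise = rng.standard_normal(40) * 2e8
        y = 1.3 * x + noise
        # build synthetic rate sets carrying the cloud (5 sets x 8 rates)
        sets = []
        k = 0
        for i in range(5):
            amps = {}
            rates = {}
            for rid in pm.RATE_REGISTRY:
                if rid in pm.REMOTE_RATE_IDS:
                    amps[rid] = x[k]
                    rates[rid] = y[k] * 1e-9
                    k += 1
                else:
                    amps[rid] = 1.0
                    rates[rid] = 1e-9
            sets.append(ResidueRateSet(i, rates, tau_nnh=1e-9, tau_ccca=1e-9,
                                       tau_opt=1e-9, true_amp=amps,
                                       true_tau={r: 1e-9 for r in rates}))
        r2, slope = proxy_diagnostic(sets, "ccca")
        assert slope == pytest.approx(float(np.sum(x * y) / np.sum(x * x)),
                                      rel=1e-12)
        assert r2 == pytest.approx(float(np.corrcoef(x, y)[0, 1] ** 2),
                                   rel=1e-12)

    def test_requires_truth(self):
        rs = make_rate_set()
        rs.true_amp = None
        with pytest.raises(ValueError, match="truth"):
            proxy_diagnostic([rs], "ccca")


@pytest.fixture(scope="module")
def static_chain():
    """Frozen conformer without tumbling: amplitudes are exact."""
    n = 64
    phi, psi = -25.0, 165.0
    series = [DihedralSeries(np.full(n, phi), np.full(n, psi), 1e-12)
              for _ in range(3)]
    return sg.chain_coordinates(series), (phi, psi)


@pytest.fixture(scope="module")
def tumbler_sets():
    return sg.rigid_ensemble_rate_sets([(-25.0, 165.0)] * 3, 150_000,
                                       1e-12, 2e-9, 1, 10e-9)


class TestComputeRate:
    def test_static_amplitude_matches_forward_model(self, static_chain):
        chain, (phi, psi) = static_chain
        bound = 32e-12
        for rid in ("NHN_CAHA", "NHN_C", "Cm1_C", "HAHN1_C", "C_CCA"):
            kind = pm.RATE_REGISTRY[rid]
            gamma, tau, amp, _ = ra.compute_rate(chain, 1, kind, 1e-12, bound)
            want = float(pm.structural_amplitude(kind, phi, psi))
            assert np.isclose(amp, want, rtol=1e-8), rid

    def test_field_scaling_of_mechanism_classes(self, static_chain):
        chain, _ = static_chain
        bound = 32e-12
        c1 = pm.PhysicalConstants.at_proton_mhz(800.0)
        c2 = pm.PhysicalConstants.at_proton_mhz(1600.0)
        g_dc1, *_ = ra.compute_rate(chain, 1, pm.RATE_REGISTRY["NHN_C"],
                                    1e-12, bound, constants=c1)
        g_dc2, *_ = ra.compute_rate(chain, 1, pm.RATE_REGISTRY["NHN_C"],
                                    1e-12, bound, constants=c2)
        assert np.isclose(g_dc2 / g_dc1, 2.0, rtol=1e-10)
        g_cc1, *_ = ra.compute_rate(chain, 1, pm.RATE_REGISTRY["Cm1_C"],
                                    1e-12, bound, constants=c1)
        g_cc2, *_ = ra.compute_rate(chain, 1, pm.RATE_REGISTRY["Cm1_C"],
                                    1e-12, bound, constants=c2)
        assert np.isclose(g_cc2 / g_cc1, 4.0, rtol=1e-10)
        g_dd1, *_ = ra.compute_rate(chain, 1, pm.RATE_REGISTRY["NHN_CAHA"],
                                    1e-12, bound, constants=c1)
        g_dd2, *_ = ra.compute_rate(chain, 1, pm.RATE_REGISTRY["NHN_CAHA"],
                                    1e-12, bound, constants=c2)
        assert np.isclose(g_dd2 / g_dd1, 1.0, rtol=1e-10)

    def test_zero_anisotropy_csa_rate_vanishes(self, static_chain):
        chain, _ = static_chain
        iso = {"C": pm.CsaTensor(100.0, 100.0, 100.0, 37.0, "C'N/C'O"),
               "N": pm.N_CSA}
        gamma, tau, amp, conv = ra.compute_rate(
            chain, 1, pm.RATE_REGISTRY["NHN_C"], 1e-12, 32e-12, csa_map=iso)
        assert gamma == 0.0 and amp == 0.0

    def test_missing_atoms_reported(self, static_chain):
        chain, _ = static_chain
        broken = {k: v for k, v in chain.items() if k[1] != "HA"}
        with pytest.raises(KeyError, match="HA"):
            ra.compute_rate(broken, 1, pm.RATE_REGISTRY["NHN_CAHA"],
                            1e-12, 32e-12)


class TestRigidTumbler:
    """Structure/dynamics separation on a tumbling rigid conformer."""

    def test_proxy_times_agree_with_each_other(self, tumbler_sets):
        rs = tumbler_sets[1]
        # both proxies estimate the same tumbling time; MC error at
        # T / tau ~ 75 is the limiting factor
        assert rs.tau_nnh == pytest.approx(rs.tau_ccca, rel=0.25)

    def test_amplitude_recovery_is_exact_under_own_tau(self, tumbler_sets):
        rs = tumbler_sets[1]
        approx = normalize_rates(rs, "true")
        for rid in pm.REMOTE_RATE_IDS:
            want = float(pm.structural_amplitude(pm.RATE_REGISTRY[rid],
                                                 -25.0, 165.0))
            assert np.isclose(approx[rid], want, rtol=1e-6), rid

    def test_scaling_invariance_of_separation(self, tumbler_sets):
        # scaling every rate and the proxy by c leaves amplitudes unchanged
        rs = tumbler_sets[1]
        c = 3.7
        scaled = ResidueRateSet(
            rs.residue, {k: c * v for k, v in rs.rates.items()},
            tau_nnh=c * rs.tau_nnh, tau_ccca=c * rs.tau_ccca,
            tau_opt=c * rs.tau_opt)
        a0 = normalize_rates(rs, "ccca")
        a1 = normalize_rates(scaled, "ccca")
        for rid in a0:
            assert np.isclose(a0[rid], a1[rid], rtol=1e-12)


def test_rate_table_round_trip(tmp_path):
    sets = {i: make_rate_set(i, tau=2e-9) for i in (1, 2)}
    path = tmp_path / "rates.csv"
    ra.save_rate_table(path, sets, "ccca")
    back = ra.load_rate_table(path)
    assert set(back) == {1, 2}
    for rid in pm.RATE_REGISTRY:
        assert np.isclose(back[1]["rates"][rid], sets[1].rates[rid],
                          rtol=1e-12)
    for rid in pm.REMOTE_RATE_IDS:
        assert np.isclose(back[2]["tau_proxy_s"][rid], 2e-9, rtol=1e-9)


def test_known_amplitudes_match_printed_tensor_geometry():
    ka = KnownAmplitudes.from_model()
    c = pm.PhysicalConstants()
    # independent evaluation of the amide-plane amplitude
    want = (4.0 / 15.0 * (c.mu0 * c.hbar / (4 * np.pi)) * c.gamma_N ** 2
            * c.gamma_H * c.B0 * 170e-6 / (1.01e-10) ** 3
            * pm.p2(np.cos(np.radians(20.0))))
    assert np.isclose(ka.a_nnh, want, rtol=1e-10)
    assert ka.a_nnh > 0 and ka.a_ccca > 0
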