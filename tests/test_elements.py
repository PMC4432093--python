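"""J-refocusing elements, CTP wrapping, real-time loop and HSQC skeletons."""

import numpy as np
import pytest

from pureshift import (
    AcquisitionPlan,
    CtpGradients,
    ElementSpec,
    EnsembleConfig,
    HsqcPlan,
    Simulator,
    WaterModel,
    minimal_pair,
)
from pureshift.elements import (
    bashd_element,
    bird_element,
    build_element,
    contract_fidelity,
    ctp_wrap,
    element_duration,
    element_phase_tables,
    hsqc_sequence,
    realtime_acquisition,
    run_pure_shift_1d,
)
from pureshift.processing import concatenate_chunks, ft_2d, zero_fill_and_ft
from pureshift.analysis import peak_pick, peak_pick_2d


class TestBird:
    def test_core_duration_is_one_over_j(self):
        ev = bird_element(ElementSpec(kind="bird", J_NH_nominal=90.0))
        core = sum(e.duration for e in ev if "core" in e.tags)
        assert core == pytest.approx(1.0 / 90.0)          # 11.11 ms
        assert core == pytest.approx(11.1e-3, abs=0.02e-3)

    def test_invalid_j_rejected(self):
        with pytest.raises(ValueError):
            bird_element(ElementSpec(kind="bird", J_NH_nominal=-5.0))

    def test_wrong_kind_rejected(self):
        with pytest.raises(ValueError):
            bird_element(ElementSpec(kind="bashd"))

    def test_contract_inverts_remote_only(self, amide_triplet_nj):
        sim = Simulator(amide_triplet_nj, relaxation=False)
        ev = bird_element(ElementSpec(kind="bird"))
        assert contract_fidelity(sim, ev) >= 0.999

    def test_j_mismatch_degrades_contract(self, amide_triplet_nj):
        """Actual J = 80 Hz against a 90 Hz nominal element: the active
        proton inversion error becomes measurable."""
        import dataclasses
        ss80 = dataclasses.replace(amide_triplet_nj)
        J = ss80.J.copy()
        J[0, 1] = J[1, 0] = 80.0
        ss80 = dataclasses.replace(ss80, J=J)
        sim90 = Simulator(amide_triplet_nj, relaxation=False)
        sim80 = Simulator(ss80, relaxation=False)
        ev = bird_element(ElementSpec(kind="bird", J_NH_nominal=90.0))
        f_match = contract_fidelity(sim90, ev)
        f_mismatch = contract_fidelity(sim80, ev)
        assert f_mismatch < f_match
        assert f_mismatch < 0.999

    def test_duration_accounting_exact(self):
        ev = bird_element(ElementSpec(kind="bird"))
        assert element_duration(ev) == sum(e.duration for e in ev)


class TestBashd:
    def test_contract_with_distant_passive(self, amide_triplet_nj):
        """Active at band centre, passive ~1975 Hz away: fidelity >= 0.99."""
        sim = Simulator(amide_triplet_nj, relaxation=False)
        spec = ElementSpec(kind="bashd", shape_duration=2.44e-3)
        assert contract_fidelity(sim, bashd_element(spec)) >= 0.99

    def test_passive_inside_band_recouples(self):
        """A passive proton inside the refocused band is re-inverted with
        the amide, so its coupling is NOT suppressed (recoupling)."""
        ss = minimal_pair(J_hh=8.0, T2=0.060, ha_ppm=8.1)  # -75 Hz, in band
        sim = Simulator(ss, relaxation=False)
        spec = ElementSpec(kind="bashd", shape_duration=2.44e-3)
        assert contract_fidelity(sim, bashd_element(spec)) < 0.5

    def test_band_edge_less_effective_than_centre(self):
        centre = minimal_pair(J_hh=0.0, T2=0.060, h_ppm=8.25)
        edge = minimal_pair(J_hh=0.0, T2=0.060, h_ppm=8.25 + 1000 / 500.0)
        spec = ElementSpec(kind="bashd", shape_duration=2.44e-3)
        f_c = contract_fidelity(Simulator(centre, relaxation=False), bashd_element(spec))
        f_e = contract_fidelity(Simulator(edge, relaxation=False), bashd_element(spec))
        assert f_e < f_c

    def test_bashd_shorter_than_bird(self):
        b = element_duration(bird_element(ElementSpec(kind="bird")))
        s = element_duration(bashd_element(ElementSpec(kind="bashd",
                                                       shape_duration=2.44e-3)))
        assert s < b

    def test_missing_shape_kind_rejected(self):
        with pytest.raises(ValueError):
            bashd_element(ElementSpec(kind="bird"))


class TestCtpWrap:
    def test_solute_signal_retained_with_gradients(self, amide_triplet_nj):
        ens = EnsembleConfig(n_slices=64)
        sim = Simulator(amide_triplet_nj, ensemble=ens, relaxation=False)
        rho = sim.state_from_operator(amide_triplet_nj.operator("HN", "x"))
        tables, rec, steps = element_phase_tables(ElementSpec(kind="gbird"))
        D = sim._detect_op("H1")

        def sig(r):
            return abs(np.einsum("sij,ji->", r, D) / r.shape[0] * 4.0 / sim.system.dim)

        for kind in ("gbird", "gbashd"):
            ev = build_element(ElementSpec(kind=kind))
            _, out = sim.run_events(ev, rho.copy(), tables, 0)
            assert sig(out) >= 0.999

    def test_water_dephased_by_wrapped_element(self):
        """One wrapped element leaves <= 2 % of transverse water coherent
        at the reference gradient strengths (16.6/13.6 G/cm, 0.5 ms)."""
        w = WaterModel(offset_hz=0.0, M0=1.0, tau_rd=1e9, T1=1e9, T2=1e9, n_slices=64)
        w.reset(tip_deg=90.0)
        for e in build_element(ElementSpec(kind="gbashd")):
            if e.kind == "hard_pulse":
                w.rotate(e.flip_deg, e.phase_deg)
            elif e.kind == "gradient":
                w.gradient_phase(e.amplitude, e.duration)
        assert abs(w.transverse()) <= 0.02

    def test_single_crusher_on_fine_grid(self):
        """A lone 16.6 G/cm, 0.5 ms gradient leaves <= 1 % water coherence."""
        w = WaterModel(offset_hz=0.0, M0=1.0, tau_rd=1e9, T1=1e9, T2=1e9, n_slices=513)
        w.reset(tip_deg=90.0)
        w.gradient_phase(16.6, 0.5e-3)
        assert abs(w.transverse()) <= 0.01

    @pytest.mark.parametrize("axis", ["x", "z"])
    def test_axis_choice_preserves_both_properties(self, axis, amide_triplet_nj):
        ens = EnsembleConfig(n_slices=64)
        sim = Simulator(amide_triplet_nj, ensemble=ens, relaxation=False)
        rho = sim.state_from_operator(amide_triplet_nj.operator("HN", "x"))
        spec = ElementSpec(kind="gbashd", ctp=CtpGradients(axis=axis))
        tables, rec, steps = element_phase_tables(spec)
        ev = build_element(spec)
        D = sim._detect_op("H1")
        _, out = sim.run_events(ev, rho.copy(), tables, 0)
        assert abs(np.einsum("sij,ji->", out, D) / 64 * 4.0 / sim.system.dim) >= 0.999

    def test_wrap_without_gradients_rejected(self):
        spec = ElementSpec(kind="gbird", ctp=CtpGradients(g1=0.0, g2=0.0))
        with pytest.raises(ValueError, match="gradients"):
            ctp_wrap(bird_element(spec), spec)


class TestAcquisitionPlan:
    @pytest.mark.parametrize("n,chunk_ms,sw_ps", [
        (2, 102.4, 9.77), (4, 51.2, 19.53), (8, 25.6, 39.06),
    ])
    def test_chunk_arithmetic_1024_at_5k(self, n, chunk_ms, sw_ps):
        plan = AcquisitionPlan(sw=5000.0, total_points=1024, n_chunks=n)
        assert plan.chunk_duration * 1e3 == pytest.approx(chunk_ms, abs=0.01)
        assert plan.sw_ps == pytest.approx(sw_ps, abs=0.01)

    def test_non_divisible_chunking_rejected(self):
        with pytest.raises(ValueError, match="submultiple"):
            AcquisitionPlan(sw=5000.0, total_points=1024, n_chunks=3)

    def test_single_chunk_is_plain_acquisition(self, amide_triplet):
        sim = Simulator(amide_triplet)
        plan = AcquisitionPlan(sw=5000.0, total_points=256, n_chunks=1,
                               element=ElementSpec(kind="bird"))
        cf = run_pure_shift_1d(amide_triplet, plan, sim=sim)
        rho = sim.state_from_operator(amide_triplet.operator("HN", "x"))
        direct, _ = sim.acquire_chunk(rho, 256, plan.dwell)
        assert np.abs(cf.stream() - direct).max() <= 1e-12

    def test_sw_ps_invariant(self):
        plan = AcquisitionPlan(sw=5000.0, total_points=960, n_chunks=6)
        assert plan.sw_ps == 1.0 / (plan.chunk_points * plan.dwell)


class TestOracleEquivalence:
    def test_ideal_element_equals_jhh_free_fid(self, amide_triplet):
        """Real-time pure shift with the ideal element reproduces the FID of
        the same system with active-passive J_HH removed (no relaxation)."""
        sim = Simulator(amide_triplet, relaxation=False)
        plan = AcquisitionPlan(sw=5000.0, total_points=512, n_chunks=4,
                               element=ElementSpec(kind="ideal"))
        ps = run_pure_shift_1d(amide_triplet, plan, sim=sim)
        ss0 = amide_triplet.zero_homonuclear_j()
        sim0 = Simulator(ss0, relaxation=False)
        plan0 = AcquisitionPlan(sw=5000.0, total_points=512, n_chunks=1,
                                element=ElementSpec(kind="ideal"))
        ref = run_pure_shift_1d(ss0, plan0, sim=sim0)
        assert np.abs(ps.stream() - ref.stream()).max() <= 1e-8

    def test_two_step_cycle_equals_single_step_with_perfect_pulses(self, amide_triplet_nj):
        sim = Simulator(amide_triplet_nj, relaxation=False)
        ev = realtime_acquisition(AcquisitionPlan(
            sw=5000.0, total_points=256, n_chunks=2, element=ElementSpec(kind="bird")))
        spec1 = ElementSpec(kind="bird", exorcycle_steps=1)
        spec2 = ElementSpec(kind="bird", exorcycle_steps=2)
        out = {}
        for spec in (spec1, spec2):
            tables, rec, steps = element_phase_tables(spec)
            rho0 = sim.state_from_operator(amide_triplet_nj.operator("HN", "x"))
            out[spec.exorcycle_steps] = sim.run_sequence(
                ev, rho0=rho0, phase_tables=tables, receiver_table=rec, n_steps=steps)
        assert np.abs(out[1] - out[2]).max() <= 1e-8


@pytest.fixture(scope="module")
def spectra(amide_triplet):
    """Coupled reference plus BIRD spectra at several chunk counts."""
    out = {}
    for n in (1, 2, 4, 8):
        plan = AcquisitionPlan(sw=5000.0, total_points=1024, n_chunks=n,
                               element=ElementSpec(kind="bird"))
        cf = run_pure_shift_1d(amide_triplet, plan, sim=Simulator(amide_triplet))
        out[n] = (plan, zero_fill_and_ft(concatenate_chunks(cf), 16384))
    return out


class TestPureShiftSpectra:
    def test_multiplet_collapses_to_singlet(self, spectra):
        _, coupled = spectra[1]
        _, dec = spectra[4]
        thr_c = 0.4 * np.real(coupled.data).max()
        thr_d = 0.4 * np.real(dec.data).max()
        n_coupled = len(peak_pick(coupled, thr_c, min_separation_hz=2.0))
        n_dec = len(peak_pick(dec, thr_d, min_separation_hz=2.0))
        assert n_coupled == 2 and n_dec == 1

    def test_singlet_at_active_shift_within_one_point(self, spectra):
        for n in (2, 4, 8):
            _, spec = spectra[n]
            pk = peak_pick(spec, 0.5 * np.real(spec.data).max(), min_separation_hz=2.0)
            assert pk[0].position_hz == pytest.approx(-5.0, abs=5000.0 / 16384 + 0.15)

    def test_linewidth_grows_with_element_duration(self, amide_triplet):
        """Longer J-refocusing elements cost more T2 signal, broadening the
        decoupled line: BIRD (11 ms) vs BASHD (2.7 ms) vs ideal (0 ms)."""
        widths = {}
        for kind in ("ideal", "bashd", "bird"):
            plan = AcquisitionPlan(sw=5000.0, total_points=1024, n_chunks=4,
                                   element=ElementSpec(kind=kind))
            cf = run_pure_shift_1d(amide_triplet, plan, sim=Simulator(amide_triplet))
            spec = zero_fill_and_ft(concatenate_chunks(cf), 16384)
            pk = peak_pick(spec, 0.5 * np.real(spec.data).max(), min_separation_hz=2.0)
            widths[kind] = pk[0].fwhm_hz
        assert widths["ideal"] < widths["bashd"] < widths["bird"]

    def test_ideal_element_line_has_natural_width(self, amide_triplet):
        """With a zero-duration element and an acquisition long enough to
        avoid truncation, the decoupled FWHM is 1/(pi T2) within 3 %."""
        plan = AcquisitionPlan(sw=5000.0, total_points=4096, n_chunks=4,
                               element=ElementSpec(kind="ideal"))
        cf = run_pure_shift_1d(amide_triplet, plan, sim=Simulator(amide_triplet))
        spec = zero_fill_and_ft(concatenate_chunks(cf), 32768)
        pk = peak_pick(spec, 0.5 * np.real(spec.data).max(), min_separation_hz=2.0)
        assert pk[0].fwhm_hz >= 1.0 / (np.pi * 0.060) - 1e-6
        assert pk[0].fwhm_hz == pytest.approx(1.0 / (np.pi * 0.060), rel=0.03)


class TestHsqc:
    def test_single_pair_peak_position(self, amide_triplet):
        acq = AcquisitionPlan(sw=5000.0, total_points=256, n_chunks=4,
                              element=ElementSpec(kind="bird"))
        hp = HsqcPlan(n_increments=64, sw1=1500.0, mode="ideal_start")
        spec = ft_2d(hsqc_sequence(amide_triplet, hp, acq), zf2=8192, zf1=512,
                     window1="sine_squared")
        pk = peak_pick_2d(spec.data, 0.5 * spec.data.max())
        assert len(pk) >= 1
        i, j, _ = max(pk, key=lambda t: t[2])
        assert spec.axis1_hz[i] == pytest.approx(0.0, abs=1500.0 / 512 + 0.01)
        assert spec.axis2_hz[j] == pytest.approx(-5.0, abs=5000.0 / 8192 + 0.7)

    def test_explicit_and_ideal_start_agree_on_position(self):
        ss = minimal_pair(J_hh=8.0, T2=0.060, n_ppm=118.0)
        acq = AcquisitionPlan(sw=5000.0, total_points=256, n_chunks=4,
                              element=ElementSpec(kind="bird"))
        pos = {}
        amp = {}
        for mode, ninc in (("ideal_start", 32), ("explicit", 32)):
            hp = HsqcPlan(n_increments=ninc, sw1=1500.0, mode=mode)
            spec = ft_2d(hsqc_sequence(ss, hp, acq), zf2=4096, zf1=256,
                         window1="sine_squared")
            pk = max(peak_pick_2d(spec.data, 0.5 * spec.data.max()), key=lambda t: t[2])
            pos[mode] = (spec.axis1_hz[pk[0]], spec.axis2_hz[pk[1]])
            amp[mode] = pk[2]
        assert pos["explicit"][0] == pytest.approx(pos["ideal_start"][0], abs=1500.0 / 256)
        assert pos["explicit"][1] == pytest.approx(pos["ideal_start"][1], abs=5000.0 / 4096)
        assert 0.05 <= amp["explicit"] / amp["ideal_start"] <= 1.5

    def test_f2_doublet_without_element_singlet_with(self, amide_triplet):
        hp = HsqcPlan(n_increments=8, sw1=1500.0, mode="ideal_start")
        n_pk = {}
        for kind, n in (("bird", 1), ("bird", 4)):
            acq = AcquisitionPlan(sw=5000.0, total_points=1024, n_chunks=n,
                                  element=ElementSpec(kind=kind))
            spec = ft_2d(hsqc_sequence(amide_triplet, hp, acq), zf2=16384, zf1=64,
                         window1="sine_squared")
            row = spec.data[spec.index_of(0.0, -5.0)[0]]
            from pureshift.processing import Spectrum1D
            s1 = Spectrum1D(row, spec.axis2_hz, 8.25, 500.0)
            n_pk[n] = len(peak_pick(s1, 0.4 * row.max(), min_separation_hz=2.0))
        assert n_pk[1] == 2 and n_pk[4] == 1

    def test_se_pair_gives_pure_absorption_peak(self):
        """Echo/antiecho combination yields one absorption peak without a
        quadrature image (BASHD element, short enough that relaxation
        anisotropy inside the element is negligible)."""
        ss = minimal_pair(J_hh=8.0, T2=0.060, n_ppm=118.0)
        acq = AcquisitionPlan(sw=5000.0, total_points=256, n_chunks=4,
                              element=ElementSpec(kind="bashd"))
        hp = HsqcPlan(n_increments=64, sw1=1500.0, mode="ideal_start",
                      echo_antiecho=True)
        spec = ft_2d(hsqc_sequence(ss, hp, acq), zf2=4096, zf1=256,
                     window1="sine_squared")
        i_pk, j_pk = spec.index_of(50.68, -5.0)
        i_im, _ = spec.index_of(-50.68, -5.0)
        assert abs(spec.data[i_im, j_pk]) <= 0.01 * spec.data[i_pk, j_pk]

    def test_se_processing_requires_both_records(self):
        ss = minimal_pair()
        acq = AcquisitionPlan(sw=5000.0, total_points=128, n_chunks=2,
                              element=ElementSpec(kind="ideal"))
        hp = HsqcPlan(n_increments=4, sw1=1500.0, mode="ideal_start", echo_antiecho=True)
        res = hsqc_sequence(ss, hp, acq)
        del res["records"]["anti"]
        with pytest.raises(ValueError, match="echo/antiecho"):
            ft_2d(res)
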