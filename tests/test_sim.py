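"""Virtual instrument and sample: elution, AGC, reporters, attribution."""

import numpy as np
import pytest

from targetms import sim
from targetms.sim import (
    Analyte,
    SampleScenario,
    ScanRequest,
    VirtualInstrument,
    elution_intensity,
    make_adh1_scenario,
    make_proteome_scenario,
)


def toy_analyte(key="AAAAAAGK/2", abundance=(1.0,) * 11, apex=100.0, sigma=8.0,
                coeff=1e4, frag_mz=(300.0, 400.0, 500.0), frag_rel=(0.5, 0.3, 0.2),
                prec=600.0, role="background"):
    return Analyte(
        key=key, sequence=key.split("/")[0], charge=int(key.split("/")[1]),
        protein="P1", channel_abundance=tuple(abundance), apex_s=apex,
        sigma_s=sigma, flux_coeff=coeff, frag_mz=frag_mz, frag_rel=frag_rel,
        precursor_mz=prec, role=role,
    )


def toy_scenario(analytes, **kw):
    defaults = dict(label_scheme="TMT11", gradient_s=600.0, counting_noise=False,
                    mass_jitter=False, seed=0)
    defaults.update(kw)
    return SampleScenario(analytes=analytes, **defaults)


class TestElutionModel:
    def test_apex_is_maximum(self):
        a = toy_analyte()
        assert elution_intensity(a, a.apex_s) == pytest.approx(
            a.flux_coeff * a.total_abundance
        )

    def test_one_sigma_point(self):
        a = toy_analyte()
        assert elution_intensity(a, a.apex_s + a.sigma_s) == pytest.approx(
            elution_intensity(a, a.apex_s) * np.exp(-0.5)
        )

    def test_beyond_six_sigma_is_zero(self):
        a = toy_analyte()
        assert elution_intensity(a, a.apex_s + 6.5 * a.sigma_s) == 0.0


class TestScenarioGenerators:
    def test_same_seed_identical(self):
        a = make_adh1_scenario(seed=5)
        b = make_adh1_scenario(seed=5)
        assert a.to_json() == b.to_json()

    def test_empty_proteome(self):
        sc = make_proteome_scenario(n_proteins=0)
        assert sc.analytes == []

    def test_negative_size_rejected(self):
        with pytest.raises(ValueError):
            make_proteome_scenario(n_proteins=-1)

    def test_spike_design_ratios_in_ground_truth(self):
        sc = make_adh1_scenario(seed=0)
        spikes = [a for a in sc.analytes if a.role == "spike"]
        assert len(spikes) == 12
        for a in spikes:
            v = np.array(a.channel_abundance)
            assert v[0] == 0.0 and v[-1] == 0.0  # blank channels
            groups = v[1:4], v[4:7], v[7:10]
            means = [g.mean() for g in groups]
            assert means[1] / means[0] == pytest.approx(2.0)
            assert means[2] / means[0] == pytest.approx(4.0)

    def test_background_channels_are_1_to_1(self):
        sc = make_adh1_scenario(seed=0)
        bg = [a for a in sc.analytes if a.role == "background"]
        for a in bg[:10]:
            v = np.array(a.channel_abundance)
            assert v.max() / v.min() == pytest.approx(1.0)

    def test_dilution_scales_spike_only(self):
        a = make_adh1_scenario(seed=0, dilution_factor=1.0)
        b = make_adh1_scenario(seed=0, dilution_factor=1000.0)
        sa = [x for x in a.analytes if x.role == "spike"][0]
        sb = [x for x in b.analytes if x.role == "spike"][0]
        assert sb.total_abundance == pytest.approx(sa.total_abundance / 1000.0)

    def test_design_longer_than_plex_rejected(self):
        with pytest.raises(ValueError, match="design"):
            make_adh1_scenario(design_ratios=(1, 2, 4, 8), replicates=3)

    def test_proteome_abundance_spread_matches_configured_sigma(self):
        # distribution oracle at n=2000: empirical log10 sd within 10%
        sc = make_proteome_scenario(
            n_proteins=2000, peptides_per_protein=1, abundance_log10_sigma=1.2,
            seed=3,
        )
        per_protein = {}
        for a in sc.analytes:
            per_protein[a.protein] = a.total_abundance
        sd = np.std(np.log10(list(per_protein.values())))
        assert sd == pytest.approx(1.2, rel=0.1)


class TestInstrument:
    def test_injection_never_exceeds_cap(self):
        sc = toy_scenario([toy_analyte()])
        inst = VirtualInstrument(sc)
        rec = inst.execute(
            ScanRequest(type="SPS_MS3", time=0.0, center_mz=600.0, width_mz=0.7,
                        notches=((300.0, 1.0),), max_it_ms=2000.0)
        )
        assert rec.realized_it_ms <= 2000.0

    def test_reporter_linearity_below_agc(self):
        a = toy_analyte(abundance=(1, 0, 2, 0, 0, 0, 0, 0, 0, 0, 1), apex=100.0)
        sc = toy_scenario([a])
        # weak enough that AGC never caps: use tiny fill times
        r1 = VirtualInstrument(sc).execute(
            ScanRequest(type="SPS_MS3", time=100.0, center_mz=600.0, width_mz=0.7,
                        notches=((300.0, 1.0),), max_it_ms=1.0)
        )
        r2 = VirtualInstrument(sc).execute(
            ScanRequest(type="SPS_MS3", time=100.0, center_mz=600.0, width_mz=0.7,
                        notches=((300.0, 1.0),), max_it_ms=2.0)
        )
        assert np.allclose(r2.reporters, 2.0 * r1.reporters)

    def test_reporters_proportional_to_channel_abundance_without_interference(self):
        a = toy_analyte(abundance=(0, 1, 2, 4, 0, 0, 0, 0, 0, 0, 0), apex=100.0)
        sc = toy_scenario([a])
        rec = VirtualInstrument(sc).execute(
            ScanRequest(type="SPS_MS3", time=100.0, center_mz=600.0, width_mz=0.7,
                        notches=((300.0, 1.0), (400.0, 1.0)), max_it_ms=100.0)
        )
        rep = rec.reporters
        assert rep[2] / rep[1] == pytest.approx(2.0)
        assert rep[3] / rep[1] == pytest.approx(4.0)
        assert rep[0] == 0.0

    def test_ms3_attribution_sums_to_one_and_interference_monotone(self):
        target = toy_analyte(apex=100.0)
        clean = toy_scenario([target])
        rec = VirtualInstrument(clean).execute(
            ScanRequest(type="SPS_MS3", time=100.0, center_mz=600.0, width_mz=0.7,
                        notches=((300.0, 1.0),), max_it_ms=10.0)
        )
        assert sum(rec.attribution.values()) == pytest.approx(1.0)
        assert rec.attribution[target.key] == pytest.approx(1.0)
        # an interferer with a fragment inside the notch lowers the share
        interferer = toy_analyte(
            key="WWWWWWGK/2", prec=600.2, frag_mz=(300.4,), frag_rel=(1.0,),
            apex=100.0, role="interferer",
        )
        dirty = toy_scenario([target, interferer])
        rec2 = VirtualInstrument(dirty).execute(
            ScanRequest(type="SPS_MS3", time=100.0, center_mz=600.0, width_mz=0.7,
                        notches=((300.0, 1.0),), max_it_ms=10.0)
        )
        assert sum(rec2.attribution.values()) == pytest.approx(1.0)
        assert rec2.attribution[target.key] < rec.attribution[target.key]

    def test_ms2_empty_window_empty_peaks(self):
        sc = toy_scenario([toy_analyte()])
        rec = VirtualInstrument(sc).execute(
            ScanRequest(type="IT_PRM", time=100.0, center_mz=900.0, width_mz=0.7,
                        max_it_ms=100.0)
        )
        assert len(rec.peaks_mz) == 0

    def test_request_in_past_rejected(self):
        sc = toy_scenario([toy_analyte()])
        inst = VirtualInstrument(sc)
        inst.execute(ScanRequest(type="MS1", time=100.0, max_it_ms=50.0))
        with pytest.raises(ValueError, match="past"):
            inst.execute(ScanRequest(type="MS1", time=50.0, max_it_ms=50.0))

    def test_empty_notch_list_rejected(self):
        sc = toy_scenario([toy_analyte()])
        with pytest.raises(ValueError, match="notch"):
            VirtualInstrument(sc).execute(
                ScanRequest(type="SPS_MS3", time=0.0, center_mz=600.0,
                            width_mz=0.7, max_it_ms=10.0)
            )

    def test_unknown_scan_type_rejected(self):
        sc = toy_scenario([toy_analyte()])
        with pytest.raises(ValueError, match="scan type"):
            VirtualInstrument(sc).execute(
                ScanRequest(type="MS9", time=0.0, max_it_ms=10.0)
            )

    def test_seeded_determinism_with_noise(self):
        sc = make_adh1_scenario(seed=2, counting_noise=True)
        reqs = [
            ScanRequest(type="MS1", time=10.0 * i, max_it_ms=50.0) for i in range(5)
        ]
        out = []
        for _ in range(2):
            inst = VirtualInstrument(sc, seed=42)
            out.append(
                [
                    (r.peaks_mz.tolist(), r.peaks_int.tolist())
                    for r in (inst.execute(q) for q in reqs)
                ]
            )
        assert out[0] == out[1]


def test_scenario_json_roundtrip():
    sc = make_adh1_scenario(seed=4, background_size=5)
    again = SampleScenario.from_json(sc.to_json())
    assert again.to_json() == sc.to_json()


def test_warp_preserves_elution_order():
    sc = make_proteome_scenario(n_proteins=50, peptides_per_protein=1, seed=1)
    warped = sim.warp_gradient(sc, 1.15)
    orig = np.array([a.apex_s for a in sc.analytes])
    new = np.array([a.apex_s for a in warped.analytes])
    assert (np.argsort(orig) == np.argsort(new)).all()
    # inverse maps warped times back
    t = 1234.5
    assert sim.unwarp_time(
        sc.gradient_s * (t / sc.gradient_s) ** 1.15, sc.gradient_s, 1.15
    ) == pytest.approx(t)
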