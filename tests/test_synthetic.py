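import numpy as np
import pytest

from ramscreen.errors import ValidationError
from ramscreen.preprocess import snv
from ramscreen.synthetic import (DEFAULT_AGENTS, NOISELESS_INSTRUMENT,
                                 Composition, InstrumentModel,
                                 builtin_compound_library, derive_seed,
                                 generate_binary_panel,
                                 generate_case_like_set, simulate_spectrum)


class TestLibrary:
    REQUIRED = {"cocaine_hcl", "cocaine_base", "levamisole", "procaine",
                "paracetamol", "phenacetin", "caffeine", "lactose",
                "mannitol", "inositol"}

    def test_required_compounds_present(self, library):
        assert self.REQUIRED <= set(library)

    def test_cocaine_diagnostic_peaks(self, library):
        hcl = {p.center for p in library["cocaine_hcl"].peaks}
        base = {p.center for p in library["cocaine_base"].peaks}
        assert 1716 in hcl and 1599 in hcl
        assert 1712 in base and 1603 in base
        # shared aromatic ring-breathing mode near 1,000 /cm
        assert any(abs(p.center - 1000) < 10 for p in library["cocaine_hcl"].peaks)
        assert any(abs(p.center - 1000) < 10 for p in library["levamisole"].peaks)

    def test_carbonyl_window_selective_for_cocaine(self, library):
        """No non-cocaine compound has a band centered in (1700, 1728]."""
        for name, prof in library.items():
            if name.startswith("cocaine"):
                continue
            for p in prof.peaks:
                assert not (1700.0 < p.center <= 1728.0), \
                    f"{name} has a band at {p.center}"

    def test_procaine_shoulder_below_roi(self, library):
        assert any(1680.0 <= p.center <= 1700.0
                   for p in library["procaine"].peaks)

    def test_paracetamol_fluorescent(self, library):
        assert library["paracetamol"].fluorescence_amp > 0

    def test_mannitol_bands_below_1560(self, library):
        assert all(p.center < 1560.0 for p in library["mannitol"].peaks)


class TestSimulateSpectrum:
    def test_pure_cocaine_peak_position(self, library, grid):
        sp = simulate_spectrum(Composition({"cocaine_hcl": 1.0}), library,
                               NOISELESS_INSTRUMENT, grid, seed=3)
        mask = (grid.values >= 1560) & (grid.values <= 1756)
        w = grid.values[mask][np.argmax(sp.intensities[mask])]
        assert abs(w - 1716.0) <= grid.spacing

    def test_invalid_compositions_rejected(self, library, grid):
        with pytest.raises(ValidationError):
            Composition({"cocaine_hcl": 0.5, "lactose": 0.4})
        with pytest.raises(ValidationError):
            Composition({"cocaine_hcl": 1.5, "lactose": -0.5})
        with pytest.raises(KeyError):
            simulate_spectrum(Composition({"unobtainium": 1.0}), library,
                              NOISELESS_INSTRUMENT, grid, seed=0)

    def test_seed_determinism(self, library, grid):
        inst = InstrumentModel(seed=0)
        comp = Composition({"cocaine_hcl": 0.4, "procaine": 0.6})
        a = simulate_spectrum(comp, library, inst, grid, seed=123)
        b = simulate_spectrum(comp, library, inst, grid, seed=123)
        np.testing.assert_array_equal(a.intensities, b.intensities)
        c = simulate_spectrum(comp, library, inst, grid, seed=124)
        assert np.any(c.intensities != a.intensities)

    def test_mixture_additivity(self, library, grid):
        """Noise/gain/baseline off: mixture = weighted sum of scaled pure
        spectra, pointwise."""
        a = simulate_spectrum(Composition({"cocaine_hcl": 1.0}), library,
                              NOISELESS_INSTRUMENT, grid, seed=1)
        b = simulate_spectrum(Composition({"mannitol": 1.0}), library,
                              NOISELESS_INSTRUMENT, grid, seed=2)
        mix = simulate_spectrum(
            Composition({"cocaine_hcl": 0.5, "mannitol": 0.5}), library,
            NOISELESS_INSTRUMENT, grid, seed=3)
        expected = 0.5 * a.intensities + 0.5 * b.intensities
        assert np.max(np.abs(mix.intensities - expected)) <= 1e-9

    def test_intensities_nonnegative(self, library, grid):
        inst = InstrumentModel(noise_sd=500.0)  # extreme noise forces clipping
        sp = simulate_spectrum(Composition({"lactose": 1.0}), library, inst,
                               grid, seed=9)
        assert sp.intensities.min() >= 0.0

    def test_snv_height_increases_with_concentration(self, library, grid):
        """The 1,716 /cm SNV peak height grows strictly with cocaine
        content in mannitol mixtures (concentration dependence survives
        full-spectrum SNV through the diluent's own bands)."""
        idx = int(np.argmin(np.abs(grid.values - 1716.0)))
        heights = []
        for wt in range(10, 101, 10):
            w = wt / 100.0
            comp = Composition({"cocaine_hcl": w, "mannitol": 1.0 - w}
                               if wt < 100 else {"cocaine_hcl": 1.0})
            sp = simulate_spectrum(comp, library, NOISELESS_INSTRUMENT, grid,
                                   seed=1)
            heights.append(snv(sp.intensities)[idx])
        assert np.all(np.diff(heights) > 0)


class TestBinaryPanel:
    def test_default_design_counts(self, library, grid):
        panel = generate_binary_panel(library=library, replicates=10,
                                      instrument=NOISELESS_INSTRUMENT,
                                      grid=grid, seed=5)
        ids = {m.sample_id for m in panel.metas}
        assert len(ids) == 88
        assert len(panel) == 880
        wt = np.array([m.cocaine_wt_pct for m in panel.metas])
        uniq_mix = {m.sample_id for m in panel.metas
                    if 0 < m.cocaine_wt_pct < 100}
        assert len(uniq_mix) == 72
        assert len({m.sample_id for m in panel.metas
                    if m.cocaine_wt_pct == 0}) == 8
        assert len({m.sample_id for m in panel.metas
                    if m.cocaine_wt_pct == 100}) == 8
        # labels carry the true wt% and agent tag
        assert set(np.unique(wt)) == {0.0, 10.0, 20.0, 30.0, 40.0, 50.0,
                                      60.0, 70.0, 80.0, 90.0, 100.0}
        assert {m.source_tag for m in panel.metas} == set(DEFAULT_AGENTS)

    def test_minimal_design(self, library, grid):
        panel = generate_binary_panel(library=library,
                                      agents=("levamisole",), levels=(50,),
                                      replicates=1,
                                      instrument=NOISELESS_INSTRUMENT,
                                      grid=grid, seed=5)
        assert len(panel) == 3
        assert len({m.sample_id for m in panel.metas}) == 3

    def test_invalid_designs_rejected(self, library, grid):
        with pytest.raises(ValidationError):
            generate_binary_panel(library=library, agents=(), grid=grid)
        with pytest.raises(ValidationError):
            generate_binary_panel(library=library, levels=(0.0, 50.0),
                                  grid=grid)
        with pytest.raises(KeyError):
            generate_binary_panel(library=library, agents=("unknown",),
                                  grid=grid)

    def test_seed_determinism(self, library, grid):
        kw = dict(library=library, agents=("procaine",), levels=(30.0,),
                  replicates=2, grid=grid, seed=17)
        a = generate_binary_panel(**kw)
        b = generate_binary_panel(**kw)
        np.testing.assert_array_equal(a.matrix, b.matrix)


class TestCaseLikeSet:
    def test_purity_distribution(self, library, grid):
        sset = generate_case_like_set(n_hcl=58, n_base=0, n_negative=0,
                                      replicates=1, library=library,
                                      instrument=NOISELESS_INSTRUMENT,
                                      grid=grid, seed=21)
        wt = np.array([m.cocaine_wt_pct for m in sset.metas])
        assert len(wt) == 58
        assert wt.min() >= 19.1 and wt.max() <= 85.5
        # sample mean within 3 sd of the mean of the target distribution
        assert abs(wt.mean() - 64.4) <= 3 * 15.0 / np.sqrt(58)

    def test_negative_only_set(self, library, grid):
        sset = generate_case_like_set(n_hcl=0, n_base=0, n_negative=12,
                                      replicates=1, library=library,
                                      instrument=NOISELESS_INSTRUMENT,
                                      grid=grid, seed=4)
        assert all(m.cocaine_form == "none" for m in sset.metas)
        assert all(m.cocaine_wt_pct == 0 for m in sset.metas)

    def test_empty_pool_rejected(self, library, grid):
        with pytest.raises(ValidationError):
            generate_case_like_set(n_hcl=1, n_base=0, n_negative=0,
                                   adulterant_pool=(), library=library,
                                   grid=grid, seed=0)

    def test_seed_determinism(self, library, grid):
        kw = dict(n_hcl=3, n_base=2, n_negative=2, replicates=2,
                  library=library, grid=grid, seed=33)
        a = generate_case_like_set(**kw)
        b = generate_case_like_set(**kw)
        np.testing.assert_array_equal(a.matrix, b.matrix)
        assert [m.sample_id for m in a.metas] == [m.sample_id for m in b.metas]


def test_library_yaml_round_trip(tmp_path, library):
    from ramscreen.synthetic import library_from_yaml, library_to_yaml
    path = tmp_path / "library.yaml"
    library_to_yaml(library, path)
    back = library_from_yaml(path)
    assert set(back) == set(library)
    for name in library:
        assert back[name] == library[name]


def test_derive_seed_stable_and_bounded():
    s1 = derive_seed(7, "panel", 1)
    assert s1 == derive_seed(7, "panel", 1)
    assert s1 != derive_seed(7, "panel", 2)
    assert 0 <= s1 < 2**31
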