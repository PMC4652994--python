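"""Generator-level checks: closed forms, conservation, determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from screenkit import (
    CohortConfig,
    GeneSet,
    ScreenLibrary,
    SimConfig,
    activity_correlation,
    count_barcodes,
    enrichment,
    generate_cohort,
    generate_ct_table,
    generate_lda_wells,
    make_library,
    metagene_score,
    simulate_infection,
    simulate_screen,
    write_barcode_fastq,
)
from screenkit.errors import InvalidParameterError, SimulationError


class TestInfection:
    def test_poisson_closed_forms_at_moi_one(self):
        res = simulate_infection(200_000, moi=1.0, seed=1)
        assert res["infected_fraction"] == pytest.approx(1 - np.exp(-1), abs=0.01)
        expected_single = np.exp(-1) / (1 - np.exp(-1))
        assert res["single_integration_fraction"] == pytest.approx(expected_single, abs=0.01)
        # summary consistent with raw counts
        k = res["integrations"]
        assert res["infected_fraction"] == (k > 0).mean()
        assert (res["removed_by_selection"] == (k == 0)).all()

    def test_low_moi_limit_single_integration(self):
        res = simulate_infection(500_000, moi=0.01, seed=2)
        assert res["single_integration_fraction"] == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("n_cells,moi", [(0, 1.0), (10, 0.0), (10, -1.0)])
    def test_invalid_parameters(self, n_cells, moi):
        with pytest.raises(InvalidParameterError):
            simulate_infection(n_cells, moi)


class TestScreenSimulator:
    def test_read_conservation_and_determinism(self, tiny_library):
        cfg = SimConfig(doublings=3, reads_per_sample=50_000, bottleneck_cells=10_000,
                        post_selection_cells=50_000, n_lines=2, tumors_per_line=2, seed=7)
        control, tumors = simulate_screen(tiny_library, cfg)
        assert control.counts.sum() == cfg.reads_per_sample
        for t in tumors:
            assert t.counts.sum() == cfg.reads_per_sample
            assert (t.counts >= 0).all()
        assert len(tumors) == cfg.n_lines * cfg.tumors_per_line
        control2, tumors2 = simulate_screen(tiny_library, cfg)
        pd.testing.assert_series_equal(control.counts, control2.counts)
        for a, b in zip(tumors, tumors2):
            pd.testing.assert_series_equal(a.counts, b.counts)
        control3, _ = simulate_screen(tiny_library, dataclasses.replace(cfg, seed=8))
        assert not control.counts.equals(control3.counts)

    def test_expectation_mode_matches_growth_closed_form(self):
        lib = make_library(n_genes=10, driver_effects={"DRV": 0.25}, seed=3)
        cfg = SimConfig(doublings=12, seed=0)
        _, tumors = simulate_screen(lib, cfg, expectation=True)
        w = lib.fitness
        p0 = np.full(len(lib), 1.0 / len(lib))
        expected = p0 * w**cfg.doublings
        expected /= expected.sum()
        got = tumors[0].counts.to_numpy() / cfg.reads_per_sample
        assert np.max(np.abs(got - expected) / expected) < 1e-6

    def test_single_fit_shrna_exponential_enrichment(self):
        # one hairpin at w = 1.2 for 10 doublings, drift disabled
        lib = make_library(n_genes=5, driver_effects={"DRV": 0.2}, driver_efficacy=1.0, seed=4)
        lib = ScreenLibrary(
            lib.table.assign(
                gene_effect=np.where(lib.table["shrna_id"] == "DRV.sh1", 0.2, 0.0)
            )
        )
        control, tumors = simulate_screen(lib, SimConfig(doublings=10), expectation=True)
        p0 = 1.0 / len(lib)
        growth = 1.2**10
        norm = p0 * growth + (1 - p0)
        idx = lib.table["shrna_id"] == "DRV.sh1"
        got = (tumors[0].counts[idx.to_numpy()] / control.counts[idx.to_numpy()]).iloc[0]
        assert got == pytest.approx(growth / norm, rel=1e-9)

    def test_neutral_null_log2fc_centered(self):
        # all effects zero: log2 fold changes centered at 0 at large reads/bottleneck
        lib = make_library(n_genes=24, seed=5)
        cfg = SimConfig(doublings=0, bottleneck_cells=1_000_000,
                        reads_per_sample=1_000_000, n_lines=1, tumors_per_line=1, seed=5)
        control, tumors = simulate_screen(lib, cfg)
        table = enrichment(control, tumors)
        assert np.abs(table["log2fc"]).mean() < 0.05

    def test_bottleneck_representation(self):
        # 200 shRNAs at a 100,000-cell bottleneck: ~500 cells each, no dropout
        lib = make_library(n_genes=30, shrnas_per_gene=(6, 7), seed=6)
        cfg = SimConfig(doublings=0, reads_per_sample=100_000, n_lines=1,
                        tumors_per_line=1, seed=6)
        _, tumors = simulate_screen(lib, cfg)
        assert (tumors[0].counts > 0).all()

    def test_extinction_raises(self, tiny_library):
        dead = ScreenLibrary(
            tiny_library.table.assign(knockdown_efficacy=1.0, gene_effect=-1.0)
        )
        with pytest.raises(SimulationError):
            simulate_screen(dead, SimConfig(doublings=1, n_lines=1, tumors_per_line=1))

    def test_empty_library_rejected(self, tiny_library):
        with pytest.raises(InvalidParameterError):
            simulate_screen(
                ScreenLibrary(tiny_library.table.iloc[:0]), SimConfig()
            )


class TestFastq:
    def test_error_free_round_trip(self, tiny_library, tmp_path):
        counts = pd.Series(
            [100, 300, 50, 250, 200, 100], index=tiny_library.table["shrna_id"]
        )
        path = tmp_path / "reads.fastq"
        sampled = write_barcode_fastq(counts, tiny_library, path, reads=1000, seed=9)
        got = count_barcodes(path, tiny_library.barcode_map(), max_mismatch=0)
        assert got.unassigned_reads == 0
        assert (got.counts == sampled).all()

    def test_substitution_error_fraction(self, tiny_library, tmp_path):
        lib = make_library(n_genes=4, barcode_length=21, seed=10)
        counts = pd.Series(1.0, index=lib.table["shrna_id"])
        path = tmp_path / "noisy.fastq"
        write_barcode_fastq(counts, lib, path, reads=20_000, error_rate=0.01, seed=11)
        barcodes = set(lib.table["barcode"])
        clean = 0
        with open(path) as fh:
            lines = fh.read().splitlines()
        seqs = lines[1::4]
        clean = sum(s in barcodes for s in seqs)
        frac_err = 1 - clean / len(seqs)
        assert frac_err == pytest.approx(1 - 0.99**21, abs=0.02)

    def test_degenerate_inputs(self, tiny_library, tmp_path):
        empty = pd.Series(0.0, index=tiny_library.table["shrna_id"])
        with pytest.raises(InvalidParameterError):
            write_barcode_fastq(empty, tiny_library, tmp_path / "x.fastq", reads=10)
        ok = pd.Series(1.0, index=tiny_library.table["shrna_id"])
        with pytest.raises(InvalidParameterError):
            write_barcode_fastq(ok, tiny_library, tmp_path / "x.fastq", reads=0)
        with pytest.raises(InvalidParameterError):
            write_barcode_fastq(ok, tiny_library, tmp_path / "x.fastq", reads=10,
                                error_rate=0.5)


class TestLdaWells:
    def test_negative_fraction_matches_single_hit_poisson(self):
        exp = generate_lda_wells(0.1, doses=(10,), wells_per_dose=100_000, seed=12)
        p = np.exp(-1.0)
        frac = exp.data["negative_wells"].iloc[0] / 100_000
        z = (frac - p) / np.sqrt(p * (1 - p) / 100_000)
        assert abs(z) < 4  # binomial sampling error

    def test_saturation_at_high_frequency(self):
        exp = generate_lda_wells(1.0, doses=(50,), wells_per_dose=1000, seed=13)
        assert exp.data["negative_wells"].iloc[0] == 0

    @pytest.mark.parametrize("freq", [0.0, -0.1, 1.5])
    def test_invalid_frequency(self, freq):
        with pytest.raises(InvalidParameterError):
            generate_lda_wells(freq)


class TestCohort:
    def test_activity_coupling_limits(self):
        base = dict(n_samples=165, gene_noise_sd=1e-9, mesenchymal_shift=0.0)
        syn0 = generate_cohort(CohortConfig(activity_coupling=0.0, seed=14, **base))
        r0, _ = activity_correlation(
            metagene_score(syn0.expression, GeneSet("w", syn0.gene_sets["WNT_ACTIVITY"])),
            metagene_score(syn0.expression, GeneSet("m", syn0.gene_sets["MESENCHYMAL"])),
        )
        assert abs(r0) < 0.2
        syn1 = generate_cohort(CohortConfig(activity_coupling=1.0, seed=14, **base))
        r1, _ = activity_correlation(
            metagene_score(syn1.expression, GeneSet("w", syn1.gene_sets["WNT_ACTIVITY"])),
            metagene_score(syn1.expression, GeneSet("m", syn1.gene_sets["MESENCHYMAL"])),
        )
        assert r1 > 0.999

    def test_structure_and_determinism(self):
        cfg = CohortConfig(seed=15, deleted_genes={"NLK": 0.4})
        syn = generate_cohort(cfg)
        assert syn.expression.shape[1] == cfg.n_samples
        assert syn.copy_number.shape == syn.expression.shape
        assert set(syn.subtypes.unique()) <= {
            "Proneural", "Neural", "Classical", "Mesenchymal"
        }
        assert (syn.survival["time_days"] > 0).all()
        assert syn.survival["event"].isin([0, 1]).all()
        # deleted gene shows focal loss in roughly the configured fraction
        frac_deleted = (syn.copy_number.loc["NLK"] < 1.6).mean()
        assert 0.2 < frac_deleted < 0.6
        syn2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(syn.expression, syn2.expression)
        pd.testing.assert_frame_equal(syn.survival, syn2.survival)

    def test_zero_probability_subtype_warns(self):
        props = {"Proneural": 0.5, "Neural": 0.5, "Classical": 0.0, "Mesenchymal": 0.0}
        with pytest.warns(UserWarning):
            generate_cohort(CohortConfig(subtype_proportions=props, seed=16))

    def test_bad_proportions_rejected(self):
        with pytest.raises(InvalidParameterError):
            CohortConfig(subtype_proportions={"Proneural": 0.5, "Neural": 0.2,
                                              "Classical": 0.2, "Mesenchymal": 0.2})


class TestCtTable:
    @pytest.mark.parametrize("fold,expected_ddct", [(1.0, 0.0), (0.5, 1.0), (4.0, -2.0)])
    def test_noise_free_ddct_arithmetic(self, fold, expected_ddct):
        table = generate_ct_table({"TARGET": fold}, ct_noise_sd=0.0, seed=17)
        mean_ct = table.groupby(["sample", "gene"])["ct"].mean().unstack()
        dct = mean_ct["TARGET"] - mean_ct["ACTB"]
        ddct = dct["treated"] - dct["control"]
        assert ddct == pytest.approx(expected_ddct, abs=1e-12)

    def test_invalid_fold_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_ct_table({"TARGET": -1.0})
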