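"""Synthetic-data generators: determinism, constraint satisfaction, and
noiseless/noisy parameter recovery against the analysis modules."""

import io

import numpy as np
import pytest

from rrnthermo import (
    DEFAULT_PRIMERS,
    GrowthSimConfig,
    QpcrSimConfig,
    RrnFamilyConfig,
    extract_thermometer_region,
    expression_ratio,
    fit_cell_factor,
    fit_standard_curve,
    gc_content,
    generate_growth_curves,
    generate_od_count_pairs,
    generate_qpcr_experiment,
    generate_rrn_family,
    interval_growth_rates,
    mu_max_by_temperature,
    write_fasta,
)
from rrnthermo.errors import GenerationError
from rrnthermo.simulate import DEFAULT_GROWTH_SPECS, ParalogSpec, TemperatureGrowthSpec


def _fasta_bytes(records):
    buf = io.StringIO()
    write_fasta(records, buf)
    return buf.getvalue()


class TestRrnFamily:
    def test_regions_extract_at_795_with_target_gc(self, family):
        targets = {"rrsA": 58.9, "rrsB": 56.5, "rrsC": 56.4}
        for rec in family:
            region = extract_thermometer_region(
                rec, DEFAULT_PRIMERS["109aF"], DEFAULT_PRIMERS["915aR"]
            )
            assert len(region) == 795
            assert gc_content(region) == pytest.approx(targets[rec.id], abs=0.2)

    def test_same_seed_reproduces_byte_identical_fasta(self):
        cfg = RrnFamilyConfig(seed=123)
        a = _fasta_bytes(generate_rrn_family(cfg))
        b = _fasta_bytes(generate_rrn_family(RrnFamilyConfig(seed=123)))
        assert a == b
        c = _fasta_bytes(generate_rrn_family(RrnFamilyConfig(seed=124)))
        assert a != c

    def test_gc_targeting_over_config_grid(self):
        for seed in range(5):
            for target in (45.0, 52.5, 60.0, 66.0):
                cfg = RrnFamilyConfig(
                    paralogs=(ParalogSpec("x", target, 0.01), ParalogSpec("y", 50.0, 0.0)),
                    seed=seed,
                )
                rec = generate_rrn_family(cfg)[0]
                region = extract_thermometer_region(
                    rec, DEFAULT_PRIMERS["109aF"], DEFAULT_PRIMERS["915aR"]
                )
                assert gc_content(region) == pytest.approx(target, abs=0.2)

    def test_unreachable_gc_raises(self):
        cfg = RrnFamilyConfig(
            paralogs=(ParalogSpec("x", 99.5, 0.0),), seed=0
        )
        with pytest.raises(GenerationError):
            generate_rrn_family(cfg)

    def test_invalid_paralog_spec_rejected(self):
        with pytest.raises(GenerationError):
            ParalogSpec("x", 58.9, 0.5)
        with pytest.raises(GenerationError):
            ParalogSpec("x", 0.0, 0.01)


class TestQpcrSim:
    def test_noiseless_standards_recover_curve_exactly(self):
        # with a unit standard stock, the fitted curve is the generative one
        cfg = QpcrSimConfig(ct_sd=0.0, standard_stock_copies=1.0, seed=0)
        plate = generate_qpcr_experiment(cfg)
        for target in plate.targets:
            curve = fit_standard_curve(plate.standards(target))
            assert curve.slope == pytest.approx(cfg.slope, rel=1e-12)
            assert curve.intercept == pytest.approx(cfg.intercept, rel=1e-12)
            assert curve.r_squared == pytest.approx(1.0)

    def test_noiseless_ratio_is_exact_quotient(self):
        cfg = QpcrSimConfig(
            true_copies={"rrsA": 5.6e5, "rrsBC": 1.0e6}, ct_sd=0.0,
            temperature=30.0, seed=0,
        )
        plate = generate_qpcr_experiment(cfg)
        curves = {t: fit_standard_curve(plate.standards(t)) for t in plate.targets}
        assert expression_ratio(plate, curves, 30.0).mean == pytest.approx(
            0.56, rel=1e-9
        )

    def test_plate_determinism_and_design_shape(self):
        cfg = QpcrSimConfig(seed=9, temperature=40.0)
        p1 = generate_qpcr_experiment(cfg)
        p2 = generate_qpcr_experiment(QpcrSimConfig(seed=9, temperature=40.0))
        assert p1.to_frame().equals(p2.to_frame())
        # 2 targets x (4 dilutions x 3 tech) standards + (4 bio x 3 tech) unknowns
        assert len(p1.standards("rrsA")) == 12
        assert len(p1.unknowns("rrsA", 40.0)) == 12
        assert len(p1.wells) == 48

    def test_monte_carlo_sd_matches_delta_method_within_factor_1_5(self):
        """Empirical sd of the recovered mean ratio vs analytic propagation.

        Per target, the log10 quantity error combines unknown-well Ct noise
        (averaged over technical and biological replicates) and the
        standard-curve prediction error at the unknown's log-concentration
        (intercept variance sigma^2/m plus slope variance sigma^2/Sxx times
        the squared lever arm), all divided by the slope.
        """
        cfg = QpcrSimConfig(temperature=25.0, seed=0)
        means = []
        for seed in range(120):
            plate = generate_qpcr_experiment(
                QpcrSimConfig(temperature=25.0, seed=seed)
            )
            curves = {t: fit_standard_curve(plate.standards(t)) for t in plate.targets}
            means.append(expression_ratio(plate, curves, 25.0).mean)
        means = np.asarray(means)

        s, sd = abs(cfg.slope), cfg.ct_sd
        sigma_mean = sd / np.sqrt(cfg.tech_reps)  # per-dilution / per-bio-rep mean Ct
        x = np.log10(np.asarray(cfg.dilutions) * cfg.standard_stock_copies)
        sxx = ((x - x.mean()) ** 2).sum()
        var_log10 = 0.0
        for target, copies in cfg.true_copies.items():
            lever = (np.log10(copies) - x.mean()) ** 2
            var_curve = (sigma_mean**2) * (1 / len(x) + lever / sxx) / s**2
            var_ct = (sigma_mean**2) / s**2 / cfg.bio_reps
            var_log10 += var_curve + var_ct
        predicted_sd = 0.56 * np.log(10) * np.sqrt(var_log10)

        empirical_sd = means.std(ddof=1)
        assert empirical_sd < 1.5 * predicted_sd
        assert empirical_sd > predicted_sd / 1.5

    def test_ratio_estimator_scale_invariant_across_copy_scales(self):
        for scale in (1.0, 50.0):
            cfg = QpcrSimConfig(
                true_copies={"rrsA": 5.6e5 * scale, "rrsBC": 1.0e6 * scale},
                standard_stock_copies=1e7 * scale,
                temperature=25.0,
                seed=77,
            )
            plate = generate_qpcr_experiment(cfg)
            curves = {t: fit_standard_curve(plate.standards(t)) for t in plate.targets}
            ratio = expression_ratio(plate, curves, 25.0)
            if scale == 1.0:
                first = ratio.ratios
            else:
                assert np.allclose(ratio.ratios, first)


class TestGrowthSim:
    def test_noiseless_exponential_phase_recovers_mu_exactly(self):
        cfg = GrowthSimConfig(
            specs=(TemperatureGrowthSpec(45.0, 0.16),),
            od_noise_sd=0.0,
            replicates=1,
            seed=0,
        )
        profile = interval_growth_rates(generate_growth_curves(cfg)[0])
        assert profile.mu_max == pytest.approx(0.16, rel=1e-9)

    def test_zero_mu_gives_flat_curve(self):
        cfg = GrowthSimConfig(
            specs=(TemperatureGrowthSpec(25.0, 0.0),),
            od_noise_sd=0.0,
            replicates=1,
            seed=0,
        )
        profile = interval_growth_rates(generate_growth_curves(cfg)[0])
        assert profile.mu_max == pytest.approx(0.0, abs=1e-12)

    def test_sampling_frequency_does_not_change_noiseless_mu(self):
        mus = []
        for interval in (4.0, 2.0):
            cfg = GrowthSimConfig(
                specs=(TemperatureGrowthSpec(40.0, 0.13),),
                sampling_interval=interval,
                od_noise_sd=0.0,
                replicates=1,
                seed=0,
            )
            mus.append(interval_growth_rates(generate_growth_curves(cfg)[0]).mu_max)
        assert mus[0] == pytest.approx(mus[1], rel=1e-9)

    def test_noisy_mu_max_recovery_within_0_02(self):
        for seed in range(10):
            cfg = GrowthSimConfig(
                specs=(TemperatureGrowthSpec(45.0, 0.16),),
                od_noise_sd=0.01,
                replicates=4,
                seed=seed,
            )
            profiles = [interval_growth_rates(c) for c in generate_growth_curves(cfg)]
            for p in profiles:
                assert p.mu_max == pytest.approx(0.16, abs=0.02)

    def test_curve_determinism(self):
        a = generate_growth_curves(GrowthSimConfig(seed=5))
        b = generate_growth_curves(GrowthSimConfig(seed=5))
        assert a == b

    def test_default_grid_yields_study_cardinals(self):
        curves = generate_growth_curves(GrowthSimConfig(seed=2))
        assert sorted({c.temperature for c in curves}) == [25, 30, 35, 40, 45, 50]
        profiles = [interval_growth_rates(c) for c in curves]
        summary = mu_max_by_temperature(profiles)
        by_temp = dict(zip(summary["temperature"], summary["mean_mu_max"]))
        assert max(by_temp, key=by_temp.get) == 45.0

    def test_default_specs_peak_at_0_16(self):
        by_temp = {s.temperature: s.mu for s in DEFAULT_GROWTH_SPECS}
        assert by_temp[45.0] == 0.16


class TestOdCountPairs:
    def test_noiseless_pairs_fit_exactly(self):
        pairs = generate_od_count_pairs(factor=2.1e9, noise_cv=0.0, seed=4)
        cf = fit_cell_factor(pairs)
        assert cf.factor == pytest.approx(2.1e9, rel=1e-12)
        assert cf.fit_r_squared == pytest.approx(1.0)

    def test_noisy_recovery_within_5_percent(self):
        for seed in range(20):
            pairs = generate_od_count_pairs(factor=2.1e9, noise_cv=0.05, seed=seed)
            assert fit_cell_factor(pairs).factor == pytest.approx(2.1e9, rel=0.05)

    def test_determinism(self):
        assert generate_od_count_pairs(seed=8) == generate_od_count_pairs(seed=8)
        assert generate_od_count_pairs(seed=8) != generate_od_count_pairs(seed=9)
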