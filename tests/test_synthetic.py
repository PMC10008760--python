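"""The generative machinery: parameter-level and TAC-level simulation."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from pumba import (
    GenerativeConfig,
    generate_parameter_dataset,
    generate_tac_dataset,
    get_profile,
    make_study,
)


def zero_noise_profile():
    prof = get_profile("synthetic-srtm")
    return dataclasses.replace(prof, sd_subject=(0.0,) * 3, sd_resid=(0.0,) * 3)


class TestParameterGeneration:
    def test_degenerate_noise_reproduces_means_exactly(self):
        prof = zero_noise_profile()
        cfg = GenerativeConfig(profile=prof, delta=0.2, n_per_group=3, seed=0)
        table = generate_parameter_dataset(cfg)
        for _, row in table.iterrows():
            k = prof.regions.index(row["region"])
            for i, p in enumerate(prof.parameters):
                expected = prof.log_central[p] + prof.region_offsets[p][k]
                if p == "logBPND" and row["group"] == "Patient":
                    expected += 0.2
                assert row[p] == pytest.approx(expected, abs=1e-12)

    def test_group_difference_concentrates_on_delta(self):
        """Across replicates the empirical patient-control difference in the
        log binding parameter converges to the configured shift."""
        prof = get_profile("synthetic-srtm")
        cfg = GenerativeConfig(profile=prof, delta=0.1, n_per_group=50, seed=2)
        diffs = []
        for rep in range(60):
            t = generate_parameter_dataset(cfg, seed=300 + rep)
            diffs.append(
                t.loc[t.group == "Patient", "logBPND"].mean()
                - t.loc[t.group == "Control", "logBPND"].mean()
            )
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean() - 0.1) < 3 * se

    def test_diagonal_covariances_give_uncorrelated_subject_effects(self):
        prof = get_profile("synthetic-2tc").diagonalized()
        cfg = GenerativeConfig(profile=prof, delta=0.0, n_per_group=150, seed=3)
        t = generate_parameter_dataset(cfg)
        # subject means across regions isolate the subject-level deviations
        sm = t.groupby("subject")[list(prof.parameters)].mean()
        corr = sm.corr().to_numpy()
        off = corr[np.tril_indices(4, k=-1)]
        assert np.all(np.abs(off) < 0.12)

    def test_marginal_distribution_matches_configuration(self):
        """Kolmogorov-Smirnov sanity check of one region's binding values
        against the configured normal law."""
        prof = get_profile("synthetic-1tc")
        cfg = GenerativeConfig(profile=prof, delta=0.0, n_per_group=600, seed=4)
        t = generate_parameter_dataset(cfg)
        region = prof.regions[3]
        vals = t.loc[t.region == region, "logVT"].to_numpy()
        i = prof.parameters.index("logVT")
        mu = prof.log_central["logVT"] + prof.region_offsets["logVT"][3]
        sd = np.hypot(prof.sd_subject[i], prof.sd_resid[i])
        assert stats.kstest(vals, "norm", args=(mu, sd)).pvalue > 0.001

    def test_validation(self):
        prof = get_profile("synthetic-srtm")
        with pytest.raises(ValueError):
            GenerativeConfig(profile=prof, n_per_group=1)
        with pytest.raises(ValueError):
            GenerativeConfig(profile=prof, mode="tac")  # needs the 2TC
        with pytest.raises(ValueError):
            GenerativeConfig(profile=prof, error_multiplier=-1.0)


class TestTACGeneration:
    def test_zero_multiplier_reproduces_noiseless_curves(self):
        from pumba import make_default_schedule, make_synthetic_aif, simulate_tac_2tc
        from pumba.kinetics import PK2TC

        prof = get_profile("synthetic-2tc")
        cfg = GenerativeConfig(profile=prof, delta=0.1, n_per_group=2, mode="tac",
                               error_multiplier=0.0, seed=5)
        tacs, truth = generate_tac_dataset(cfg)
        aif, sched = make_synthetic_aif(), make_default_schedule()
        row = truth.iloc[7]
        tac = next(t for t in tacs if t.subject == row.subject and t.region == row.region)
        params = PK2TC(K1=np.exp(row.logK1), VND=np.exp(row.logVND),
                       BPP=np.exp(row.logBPP), k4=np.exp(row.logk4))
        clean = simulate_tac_2tc(params, aif, sched)
        np.testing.assert_allclose(tac.values, clean.values, rtol=1e-12)

    def test_noise_scales_exactly_with_multiplier_at_fixed_seed(self):
        prof = get_profile("synthetic-2tc")
        base = dict(profile=prof, delta=0.1, n_per_group=2, mode="tac", seed=6)
        t0, _ = generate_tac_dataset(GenerativeConfig(**base, error_multiplier=0.0))
        t1, _ = generate_tac_dataset(GenerativeConfig(**base, error_multiplier=1.0))
        t4, _ = generate_tac_dataset(GenerativeConfig(**base, error_multiplier=4.0))
        r1 = t1[0].values - t0[0].values
        r4 = t4[0].values - t0[0].values
        np.testing.assert_allclose(r4, 4.0 * r1, rtol=1e-9)

    def test_truth_table_shares_parameter_generator_schema(self):
        prof = get_profile("synthetic-2tc")
        cfg = GenerativeConfig(profile=prof, delta=0.1, n_per_group=3, mode="tac", seed=7)
        tacs, truth = generate_tac_dataset(cfg)
        assert set(truth.columns) >= {"subject", "region", "group", *prof.parameters}
        assert len(truth) == 2 * 3 * 9
        assert len(tacs) == len(truth)
        assert all(t.weights is not None for t in tacs)


class TestStudyPlanning:
    def test_ledger_is_reproducible(self):
        prof = get_profile("synthetic-1tc")
        cfg = GenerativeConfig(profile=prof, seed=42)
        a = make_study(cfg, 3)
        b = make_study(cfg, 3)
        assert a.seed_ledger == b.seed_ledger

    def test_distinct_master_seeds_give_disjoint_replicate_seeds(self):
        prof = get_profile("synthetic-1tc")
        a = make_study(GenerativeConfig(profile=prof, seed=1), 10)
        b = make_study(GenerativeConfig(profile=prof, seed=2), 10)
        assert set(a.seeds).isdisjoint(b.seeds)

    def test_replicate_regenerates_from_ledger_seed(self):
        prof = get_profile("synthetic-1tc")
        study = make_study(GenerativeConfig(profile=prof, seed=9), 3)
        datasets = {i: d for i, _, d in study}
        again = study.dataset(1)
        assert again.equals(datasets[1])

    def test_paper_scale_study_is_constructible(self):
        # the full-size design: 500 replicates per condition, lazily generated
        prof = get_profile("synthetic-2tc")
        study = make_study(GenerativeConfig(profile=prof, mode="tac", seed=0), 500)
        assert study.replicates == 500
        assert len(set(study.seeds)) == 500
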