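import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dmharmonize import (
    ConnectivityTable,
    SubjectMetadata,
    apply_harmonization,
    dm_transform,
    fit_harmonization,
    fit_zig,
    load_model,
    residualize_covariate,
    save_model,
)


def _meta_for(tables_sites, sex=None):
    rows = []
    for table, site in tables_sites:
        for k, sid in enumerate(table.subject_ids):
            rows.append(
                {
                    "subject_id": sid,
                    "site": site,
                    "sex": sex[site][k] if sex else "M",
                }
            )
    return SubjectMetadata(pd.DataFrame(rows))


def _zig_table(rng, n_subjects, n_regions, lam, shape, scale, prefix):
    n_conn = n_regions * (n_regions - 1) // 2
    vals = rng.gamma(shape, scale, size=(n_subjects, n_conn))
    vals[rng.random((n_subjects, n_conn)) < lam] = 0.0
    return ConnectivityTable(
        np.expm1(vals), [f"{prefix}{k}" for k in range(n_subjects)], n_regions
    )


class TestFit:
    def test_self_harmonization_fits_identical_params(self, paired_study):
        ref, _, meta = paired_study
        clone = ConnectivityTable(
            ref.values.copy(),
            [f"c-{s}" for s in ref.subject_ids],
            ref.n_regions,
        )
        meta2 = SubjectMetadata(
            pd.concat(
                [
                    meta.frame,
                    meta.frame.loc[ref.subject_ids]
                    .reset_index()
                    .assign(subject_id=clone.subject_ids)
                    .set_index("subject_id"),
                ]
            ).reset_index()
        )
        model = fit_harmonization(ref, clone, meta2)
        for tr in model.per_connection["all"]:
            assert tr.ref_params.lam == tr.new_params.lam
            if not tr.ref_params.degenerate:
                assert tr.ref_params.beta == pytest.approx(tr.new_params.beta)
                assert tr.ref_params.gamma_shape == pytest.approx(
                    tr.new_params.gamma_shape
                )

    def test_sex_stratification_fits_groups_independently(self):
        rng = np.random.default_rng(2)
        ref = _zig_table(rng, 120, 3, 0.1, 2.0, 1.0, "r")
        new = _zig_table(rng, 120, 3, 0.1, 3.0, 0.5, "n")
        sex = {"R": ["M"] * 60 + ["F"] * 60, "N": ["M"] * 60 + ["F"] * 60}
        meta = _meta_for([(ref, "R"), (new, "N")], sex=sex)
        model = fit_harmonization(ref, new, meta, stratify_by_sex=True)
        assert model.strata == ["F", "M"]
        male = model.per_connection["M"][0]
        female = model.per_connection["F"][0]
        assert male.ref_params.beta != female.ref_params.beta

    def test_stratum_missing_from_reference_is_an_error(self):
        rng = np.random.default_rng(3)
        ref = _zig_table(rng, 40, 3, 0.0, 2.0, 1.0, "r")
        new = _zig_table(rng, 40, 3, 0.0, 2.0, 1.0, "n")
        sex = {"R": ["M"] * 40, "N": ["M"] * 20 + ["F"] * 20}
        meta = _meta_for([(ref, "R"), (new, "N")], sex=sex)
        with pytest.raises(ValueError, match="absent in reference"):
            fit_harmonization(ref, new, meta, stratify_by_sex=True)

    def test_pair_index_mismatch_rejected(self, paired_study):
        ref, new, meta = paired_study
        smaller = ConnectivityTable(
            new.values[:, :3], new.subject_ids, 3
        )
        with pytest.raises(ValueError):
            fit_harmonization(ref, smaller, meta)

    def test_model_json_round_trip(self, tmp_path, paired_study):
        ref, new, meta = paired_study
        model = fit_harmonization(ref, new, meta)
        path = save_model(model, tmp_path / "model.json")
        back = load_model(path)
        assert back.reference_site == model.reference_site
        assert back.per_connection["all"] == model.per_connection["all"]
        harmonized = apply_harmonization(back, new, meta)
        expected = apply_harmonization(model, new, meta)
        np.testing.assert_array_equal(harmonized.values, expected.values)


class TestApply:
    def test_zeros_always_map_to_zero(self, paired_study):
        ref, new, meta = paired_study
        model = fit_harmonization(ref, new, meta)
        harmonized = apply_harmonization(model, new, meta)
        assert (harmonized.values[new.values == 0] == 0).all()
        assert (harmonized.values >= 0).all()

    def test_all_zero_new_connection_maps_to_zero(self):
        rng = np.random.default_rng(4)
        ref = _zig_table(rng, 60, 3, 0.1, 2.0, 1.0, "r")
        new = _zig_table(rng, 60, 3, 0.1, 2.0, 1.0, "n")
        new.values[:, 1] = 0.0
        meta = _meta_for([(ref, "R"), (new, "N")])
        model = fit_harmonization(ref, new, meta)
        assert model.per_connection["all"][1].new_params.lam == 1.0
        harmonized = apply_harmonization(model, new, meta)
        assert (harmonized.values[:, 1] == 0).all()

    def test_self_harmonization_is_identity_on_nonzeros(self, paired_study):
        ref, _, meta = paired_study
        model = fit_harmonization(ref, ref, meta)
        harmonized = apply_harmonization(model, ref, meta)
        nz = ref.values > 0
        np.testing.assert_allclose(
            harmonized.values[nz], ref.values[nz], rtol=1e-8
        )

    def test_rank_preservation_within_connection(self, paired_study):
        ref, new, meta = paired_study
        model = fit_harmonization(ref, new, meta)
        harmonized = apply_harmonization(model, new, meta)
        for k in range(0, new.n_connections, 17):
            order = np.argsort(new.values[:, k], kind="stable")
            mapped = harmonized.values[order, k]
            assert (np.diff(mapped) >= -1e-12).all()

    def test_sparser_reference_sends_small_nonzeros_to_zero(self):
        rng = np.random.default_rng(5)
        new_vals = rng.gamma(2.0, 1.0, 3000)  # no zeros: lam_new = 0
        ref_vals = rng.gamma(3.0, 2.0, 3000)
        ref_vals[rng.random(3000) < 0.4] = 0.0
        pn, pr = fit_zig(new_vals), fit_zig(ref_vals)
        mapped = dm_transform(new_vals, pn, pr)
        frac_zeroed = (mapped == 0).mean()
        assert 0.3 < frac_zeroed < 0.5
        # the zeroed inputs are exactly the smallest ones
        threshold = new_vals[mapped > 0].min()
        assert (new_vals[mapped == 0] <= threshold).all()

    def test_distribution_alignment_against_empirical_qm_oracle(self):
        rng = np.random.default_rng(12)
        n = 2000
        new_vals = np.where(rng.random(n) < 0.2, 0.0, rng.gamma(2.0, 1.0, n))
        ref_vals = np.where(rng.random(n) < 0.4, 0.0, rng.gamma(3.0, 2.0, n))
        mapped = dm_transform(new_vals, fit_zig(new_vals), fit_zig(ref_vals))

        assert (mapped == 0).mean() == pytest.approx(0.4, abs=0.03)
        ks = stats.ks_2samp(mapped[mapped > 0], ref_vals[ref_vals > 0])
        crit = 1.358 * np.sqrt(
            1 / (mapped > 0).sum() + 1 / (ref_vals > 0).sum()
        )
        assert ks.statistic < crit

        # empirical quantile-mapping oracle at n=10^6: the fitted parametric
        # transform and the fully nonparametric map through the empirical
        # CDFs must agree in every decile of the mapped distribution
        big = 10**6
        big_new = np.where(rng.random(big) < 0.2, 0.0, rng.gamma(2.0, 1.0, big))
        big_ref = np.where(rng.random(big) < 0.4, 0.0, rng.gamma(3.0, 2.0, big))
        parametric = dm_transform(big_new, fit_zig(big_new), fit_zig(big_ref))
        order = np.argsort(big_new, kind="stable")
        ranks = np.empty(big)
        ranks[order] = np.arange(1, big + 1)
        sorted_ref = np.sort(big_ref)
        empirical = sorted_ref[np.minimum((ranks / (big + 1) * big).astype(int),
                                          big - 1)]
        deciles = np.arange(0.5, 1.0, 0.1)  # deciles above the zero mass
        got = np.quantile(parametric, deciles)
        want = np.quantile(empirical, deciles)
        np.testing.assert_allclose(got, want, rtol=0.02)

    def test_double_harmonization_is_nearly_idempotent(self, paired_study):
        ref, new, meta = paired_study
        model = fit_harmonization(ref, new, meta)
        once = apply_harmonization(model, new, meta)
        model2 = fit_harmonization(ref, once, meta)
        twice = apply_harmonization(model2, once, meta)
        nz = once.values > 0
        # second pass only re-estimates on already-aligned data
        rel = np.abs(twice.values[nz] - once.values[nz]) / once.values[nz]
        assert np.median(rel) < 0.1

    def test_non_zero_preserving_variant_can_move_zeros(self):
        rng = np.random.default_rng(6)
        ref = _zig_table(rng, 200, 3, 0.05, 2.0, 1.0, "r")
        new = _zig_table(rng, 200, 3, 0.5, 2.0, 1.0, "n")
        meta = _meta_for([(ref, "R"), (new, "N")])
        model = fit_harmonization(ref, new, meta, preserve_zeros=False)
        harmonized = apply_harmonization(model, new, meta)
        moved = (new.values == 0) & (harmonized.values > 0)
        assert moved.any()


class TestResidualize:
    def _study(self, slope, seed=8, n=200):
        rng = np.random.default_rng(seed)
        x = rng.normal(70, 5, n)
        n_conn = 3
        vals = 5.0 + slope * (x - x.mean())[:, None] + rng.normal(0, 0.5, (n, n_conn))
        vals = np.clip(vals, 0, None)
        table = ConnectivityTable(vals, [f"s{k}" for k in range(n)], 3)
        meta = SubjectMetadata(
            pd.DataFrame(
                {"subject_id": table.subject_ids, "site": "A", "age": x}
            )
        )
        return table, meta, x

    def test_recovers_generating_slope(self):
        table, meta, x = self._study(slope=0.3)
        _, slopes = residualize_covariate(table, meta, "age")
        xc = x - x.mean()
        se = 0.5 / np.sqrt(float(xc @ xc))
        assert slopes.loc["A"].to_numpy() == pytest.approx(0.3, abs=3 * se)

    def test_null_slope_leaves_values_unchanged(self):
        table, meta, x = self._study(slope=0.0)
        resid, slopes = residualize_covariate(table, meta, "age")
        assert np.abs(slopes.to_numpy()).max() < 0.02
        np.testing.assert_allclose(resid.values, table.values, atol=0.5)

    def test_residuals_orthogonal_to_covariate(self):
        table, meta, x = self._study(slope=0.3)
        resid, _ = residualize_covariate(table, meta, "age")
        xc = x - x.mean()
        corr = xc @ (resid.values - resid.values.mean(axis=0))
        np.testing.assert_allclose(corr, 0.0, atol=1e-8)

    def test_constant_covariate_rejected(self):
        table, meta, _ = self._study(slope=0.0)
        meta.frame["age"] = 50.0
        with pytest.raises(ValueError, match="constant"):
            residualize_covariate(table, meta, "age")

    def test_missing_covariate_rejected(self):
        table, meta, _ = self._study(slope=0.0)
        meta.frame.iloc[0, meta.frame.columns.get_loc("age")] = np.nan
        with pytest.raises(ValueError, match="missing"):
            residualize_covariate(table, meta, "age")
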