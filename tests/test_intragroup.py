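"""Within-group summaries and the ethnicity × gender ANOVA."""

import numpy as np
import pandas as pd
import pytest

from skinoverlap.dataset import SkinDataset
from skinoverlap.intragroup import anova_two_way, summarize_groups

from conftest import make_dataset


def balanced_2x2(cell_means: dict[tuple[str, str], float], n_per_cell: int,
                 noise: np.ndarray | None = None) -> SkinDataset:
    """Balanced 2-group × 2-gender layout with given L* cell means."""
    rows = []
    k = 0
    for (group, gender), mu in cell_means.items():
        for i in range(n_per_cell):
            eps = 0.0 if noise is None else float(noise[k])
            rows.append(
                {"subject_id": f"{group}{gender}{i}", "group": group, "gender": gender,
                 "age": 30.0, "body_site": "cheek", "L": mu + eps, "a": 10.0, "b": 15.0}
            )
            k += 1
    return SkinDataset(pd.DataFrame(rows))


class TestSummarizeGroups:
    def test_identical_samples_zero_dispersion(self):
        ds = make_dataset({"CA": np.tile((50.0, 10.0, 15.0), (5, 1))})
        s = summarize_groups(ds)
        assert s.loc["CA", ["L_sd", "a_sd", "b_sd", "C_sd", "dE_mean", "dE_sd"]].eq(0).all()

    def test_symmetric_pair(self):
        ds = make_dataset({"CA": np.array([[50.0, 10, 15], [54.0, 10, 15]])})
        s = summarize_groups(ds)
        assert s.loc["CA", "L_mean"] == pytest.approx(52.0)
        assert s.loc["CA", "dE_mean"] == pytest.approx(2.0)
        assert s.loc["CA", "dE_sd"] == pytest.approx(0.0)

    def test_chroma_summarized_per_sample(self):
        ds = make_dataset({"CA": np.array([[50.0, 3, 4], [50.0, -3, -4]])})
        s = summarize_groups(ds)
        # mean chroma of per-sample chromas (5, 5), not chroma of the mean (0)
        assert s.loc["CA", "C_mean"] == pytest.approx(5.0)

    def test_single_sample_group_rejected(self):
        ds = make_dataset({"CA": np.zeros((3, 3)), "CN": np.zeros((1, 3))})
        with pytest.raises(ValueError, match="CN"):
            summarize_groups(ds)

    def test_permutation_invariance(self, two_cloud_dataset):
        shuffled = SkinDataset(
            two_cloud_dataset.frame.sample(frac=1.0, random_state=7).reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(
            summarize_groups(two_cloud_dataset), summarize_groups(shuffled)
        )

    def test_mean_de_positive_unless_degenerate(self, two_cloud_dataset):
        s = summarize_groups(two_cloud_dataset)
        assert (s["dE_mean"] > 0).all()


class TestAnova:
    def test_hand_worked_balanced_decomposition(self):
        # cell means: CA/f 50, CA/m 54, CN/f 60, CN/m 62, n=4 per cell.
        # grand mean 56.5; group means 52, 61; gender means 55, 58.
        # SS_group = 16 * (52-56.5)^2 * 2 ... computed by hand below.
        means = {("CA", "female"): 50.0, ("CA", "male"): 54.0,
                 ("CN", "female"): 60.0, ("CN", "male"): 62.0}
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 1e-9, 16)  # effectively zero residual
        ds = balanced_2x2(means, n_per_cell=4, noise=noise)
        tbl = anova_two_way(ds, attribute="L")
        n = 4
        ss_group = 2 * n * ((52 - 56.5) ** 2 + (61 - 56.5) ** 2)
        ss_gender = 2 * n * ((55 - 56.5) ** 2 + (58 - 56.5) ** 2)
        ss_total_model = n * sum((m - 56.5) ** 2 for m in means.values())
        ss_inter = ss_total_model - ss_group - ss_gender
        assert tbl.loc["ethnicity", "sum_sq"] == pytest.approx(ss_group, rel=1e-6)
        assert tbl.loc["gender", "sum_sq"] == pytest.approx(ss_gender, rel=1e-6)
        assert tbl.loc["ethnicity:gender", "sum_sq"] == pytest.approx(ss_inter, rel=1e-4)

    def test_components_sum_to_total_when_balanced(self, rng):
        means = {("CA", "female"): 50.0, ("CA", "male"): 52.0,
                 ("CN", "female"): 55.0, ("CN", "male"): 56.0}
        ds = balanced_2x2(means, n_per_cell=30, noise=rng.normal(0, 2.0, 120))
        tbl = anova_two_way(ds, attribute="L")
        y = ds.frame["L"].to_numpy()
        ss_total = ((y - y.mean()) ** 2).sum()
        assert tbl["sum_sq"].sum() == pytest.approx(ss_total, rel=1e-9)

    def test_residual_free_effect_has_eta_one(self):
        means = {("CA", "female"): 50.0, ("CA", "male"): 50.0,
                 ("CN", "female"): 60.0, ("CN", "male"): 60.0}
        rng = np.random.default_rng(1)
        ds = balanced_2x2(means, n_per_cell=5, noise=rng.normal(0, 1e-9, 20))
        tbl = anova_two_way(ds, attribute="L")
        assert tbl.loc["ethnicity", "partial_eta_sq"] > 0.999999

    def test_null_simulation_f_near_one_p_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(12)
        fs, ps = [], []
        for _ in range(200):
            noise = rng.normal(0, 3.0, 800)
            means = {("CA", "female"): 55.0, ("CA", "male"): 55.0,
                     ("CN", "female"): 55.0, ("CN", "male"): 55.0}
            ds = balanced_2x2(means, n_per_cell=200, noise=noise)
            tbl = anova_two_way(ds, attribute="L")
            fs.append(tbl.loc["ethnicity", "F"])
            ps.append(tbl.loc["ethnicity", "p"])
        assert np.mean(fs) == pytest.approx(1.0, abs=0.35)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_power_ethnicity_shift_detected(self, rng):
        means = {("CA", "female"): 55.0, ("CA", "male"): 55.0,
                 ("CN", "female"): 60.0, ("CN", "male"): 60.0}
        ds = balanced_2x2(means, n_per_cell=200, noise=rng.normal(0, 3.0, 800))
        tbl = anova_two_way(ds, attribute="L")
        assert tbl.loc["ethnicity", "p"] < 1e-3
        assert tbl.loc["ethnicity", "partial_eta_sq"] > tbl.loc["gender", "partial_eta_sq"]

    def test_missing_gender_cell_rejected(self):
        rows = []
        for g, sex in (("CA", "female"), ("CN", "female"), ("CN", "male")):
            for i in range(3):
                rows.append({"subject_id": f"{g}{sex}{i}", "group": g, "gender": sex,
                             "age": 30.0, "body_site": "cheek",
                             "L": 50.0 + i, "a": 10.0, "b": 15.0})
        ds = SkinDataset(pd.DataFrame(rows))
        with pytest.raises(ValueError, match="both genders"):
            anova_two_way(ds, attribute="L")

    def test_type_three_available(self, rng):
        means = {("CA", "female"): 50.0, ("CA", "male"): 52.0,
                 ("CN", "female"): 55.0, ("CN", "male"): 56.0}
        ds = balanced_2x2(means, n_per_cell=20, noise=rng.normal(0, 2.0, 80))
        t2 = anova_two_way(ds, attribute="L", ss_type=2)
        t3 = anova_two_way(ds, attribute="L", ss_type=3)
        # balanced design: Type II and III agree
        np.testing.assert_allclose(
            t2["sum_sq"].to_numpy(), t3["sum_sq"].to_numpy(), rtol=1e-8
        )

    def test_unknown_attribute_rejected(self, two_cloud_dataset):
        with pytest.raises(ValueError, match="attribute"):
            anova_two_way(two_cloud_dataset, attribute="C")
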