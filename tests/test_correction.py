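import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import methbatch as mb


def make_m(values, samples):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return mb.MMatrix(
        pd.DataFrame(
            values,
            index=[f"cg{i}" for i in range(values.shape[0])],
            columns=samples,
        )
    )


def two_batch_study(n_probes=200, n_per=20, shift=1.0, seed=0, gender_effect=0.0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per
    sheet = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "slide": ["A"] * n_per + ["B"] * n_per,
            "gender": np.tile(["F", "M"], n // 2),
        }
    )
    male = (sheet["gender"] == "M").to_numpy()
    vals = rng.normal(0.0, 0.3, (n_probes, n))
    vals[:, n_per:] += shift
    vals[:, male] += gender_effect
    return make_m(vals, sheet["sample_id"].tolist()), sheet


class TestFitApplyContracts:
    def test_single_batch_is_identity(self, rng):
        m = make_m(rng.normal(size=(30, 10)), [f"s{i}" for i in range(10)])
        sheet = pd.DataFrame(
            {"sample_id": m.sample_ids, "slide": ["A"] * 10}
        )
        for method in ("eb_location_scale", "mean_center"):
            model = mb.fit_correction(m, sheet, "slide", (), method)
            out = mb.apply_correction(m, model)
            np.testing.assert_allclose(out.values, m.values, atol=1e-10)

    def test_mean_center_zeroes_batch_residual_means(self):
        m, sheet = two_batch_study(shift=0.7)
        model = mb.fit_correction(m, sheet, "slide", (), "mean_center")
        out = mb.apply_correction(m, model)
        in_a = (sheet["slide"] == "A").to_numpy()
        mean_a = out.values[:, in_a].mean(axis=1)
        mean_b = out.values[:, ~in_a].mean(axis=1)
        np.testing.assert_allclose(mean_a, mean_b, atol=1e-8)

    def test_mean_center_idempotent(self):
        m, sheet = two_batch_study(shift=0.5)
        model = mb.fit_correction(m, sheet, "slide", (), "mean_center")
        once = mb.apply_correction(m, model)
        model2 = mb.fit_correction(once, sheet, "slide", (), "mean_center")
        twice = mb.apply_correction(once, model2)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_eb_recovers_additive_shift(self):
        m, sheet = two_batch_study(n_probes=400, shift=1.0, seed=3)
        model = mb.fit_correction(m, sheet, "slide", ())
        # raw per-batch locations differ by the simulated shift (M units)
        gap = (model.gamma_hat[1] - model.gamma_hat[0]) * np.sqrt(model.var_pooled)
        se = 3 * np.std(gap) / np.sqrt(gap.size)
        assert gap.mean() == pytest.approx(1.0, abs=se)
        out = mb.apply_correction(m, model)
        batch_means = [
            out.values[:, (sheet["slide"] == b).to_numpy()].mean() for b in ("A", "B")
        ]
        assert abs(batch_means[0] - batch_means[1]) < 0.05

    def test_declared_gender_effect_retained(self):
        m, sheet = two_batch_study(n_probes=500, shift=1.0, seed=5, gender_effect=2.0)
        model = mb.fit_correction(m, sheet, "slide", ("gender",))
        out = mb.apply_correction(m, model)
        male = (sheet["gender"] == "M").to_numpy()
        fitted = (out.values[:, male].mean(axis=1) - out.values[:, ~male].mean(axis=1)).mean()
        assert fitted == pytest.approx(2.0, rel=0.05)

    def test_eb_shrinkage_moves_less_than_mean_center_under_null(self):
        m, sheet = two_batch_study(n_probes=2000, shift=0.0, seed=8)
        eb = mb.apply_correction(m, mb.fit_correction(m, sheet, "slide", ()))
        mc = mb.apply_correction(
            m, mb.fit_correction(m, sheet, "slide", (), "mean_center")
        )
        d_eb = np.abs(mb.ilogit2(eb.values) - mb.ilogit2(m.values)).mean()
        d_mc = np.abs(mb.ilogit2(mc.values) - mb.ilogit2(m.values)).mean()
        assert d_eb < d_mc

    def test_output_finite(self):
        m, sheet = two_batch_study(n_probes=50, seed=2)
        out = mb.apply_correction(m, mb.fit_correction(m, sheet, "slide", ()))
        assert np.isfinite(out.values).all()


class TestValidation:
    def test_confounded_design_rejected(self):
        m, sheet = two_batch_study(n_probes=20)
        sheet = sheet.assign(group=np.where(sheet["slide"] == "A", "x", "y"))
        with pytest.raises(ValueError, match="confounded"):
            mb.fit_correction(m, sheet, "slide", ("group",))

    def test_zero_variance_probe_rejected(self):
        m, sheet = two_batch_study(n_probes=5)
        vals = m.values.copy()
        vals[2] = 0.0
        flat = make_m(vals, list(m.sample_ids))
        with pytest.raises(ValueError, match="shift_betas"):
            mb.fit_correction(flat, sheet, "slide", ())

    def test_tiny_batch_rejected(self):
        m, _ = two_batch_study(n_probes=5, n_per=2)
        sheet = pd.DataFrame(
            {"sample_id": m.sample_ids, "slide": ["A", "A", "A", "B"]}
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            mb.fit_correction(m, sheet, "slide", ())

    def test_sample_mismatch_rejected(self):
        m, sheet = two_batch_study(n_probes=5)
        model = mb.fit_correction(m, sheet, "slide", ())
        other = make_m(m.values, [f"x{i}" for i in range(m.shape[1])])
        with pytest.raises(ValueError, match="samples"):
            mb.apply_correction(other, model)


class TestSequential:
    def test_superbatch_then_slide(self):
        m, sheet = two_batch_study(n_probes=60, shift=0.5, seed=9)
        sheet = sheet.assign(superbatch=np.where(sheet["slide"] == "A", "S1", "S2"))
        out = mb.sequential_correction(m, sheet, ["superbatch", "slide"])
        assert out.shape == m.shape
        assert np.isfinite(out.values).all()


class TestAgainstBioconductorComBat:
    """Independent oracle: sva::ComBat on a small fixture."""

    def test_matches_sva_combat(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; oracle cannot run")
        rng = np.random.default_rng(42)
        n_per, n_probes = 8, 30
        n = 2 * n_per
        sheet = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "slide": ["A"] * n_per + ["B"] * n_per,
                "gender": np.tile(["F", "M"], n // 2),
                "cell_fraction": rng.uniform(0.0, 0.3, n),
            }
        )
        vals = rng.normal(0.0, 0.5, (n_probes, n))
        vals[:, n_per:] += rng.normal(0.5, 0.3, (n_probes, 1))
        m = make_m(vals, sheet["sample_id"].tolist())

        mat_path = tmp_path / "m.tsv"
        sheet_path = tmp_path / "sheet.tsv"
        out_path = tmp_path / "combat.tsv"
        mb.write_matrix_tsv(m.frame, mat_path)
        sheet.to_csv(sheet_path, sep="\t", index=False)
        script = tmp_path / "combat.R"
        script.write_text(
            f"""
            suppressMessages(library(sva))
            dat <- as.matrix(read.delim("{mat_path}", row.names = 1))
            sheet <- read.delim("{sheet_path}")
            mod <- model.matrix(~ gender + cell_fraction, data = sheet)
            out <- ComBat(dat = dat, batch = sheet$slide, mod = mod,
                          par.prior = TRUE, prior.plots = FALSE)
            write.table(out, "{out_path}", sep = "\t", quote = FALSE)
            """
        )
        subprocess.run(
            ["Rscript", "--vanilla", str(script)], check=True, capture_output=True
        )
        expected = pd.read_csv(out_path, sep="\t", index_col=0).to_numpy()

        model = mb.fit_correction(m, sheet, "slide", ("gender", "cell_fraction"))
        ours = mb.apply_correction(m, model).values
        np.testing.assert_allclose(ours, expected, atol=1e-4)
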