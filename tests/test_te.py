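"""ΔTE arithmetic, jackknife spread, Z-score conventions and group shifts."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from ribodelta._errors import InsufficientDataError, ValidationError
from ribodelta.simulate import SimulationConfig, simulate_count_matrices, simulate_gene_truth
from ribodelta.te import (
    TranslationEfficiency,
    ecdf_table,
    group_shift_test,
    jackknife_resamples,
    jackknife_scale_factor,
    jackknife_sd,
    te_zscore,
    z_to_p,
)

from conftest import brute_force_jackknife_values


def make_te(rna_ctl, rna_mut, trap_ctl, trap_mut, genes=1, **kw):
    """One-gene (or broadcast) TE model from per-group count tuples."""
    def cols(prefix, genotype, assay, values):
        return {
            f"{assay}_{genotype}_{i+1}": [v] * genes for i, v in enumerate(values)
        }

    rna = pd.DataFrame(
        {**cols("r", "control", "RNA", rna_ctl), **cols("r", "mutant", "RNA", rna_mut)},
        index=[f"g{i}" for i in range(genes)],
    )
    trap = pd.DataFrame(
        {**cols("t", "control", "TRAP", trap_ctl), **cols("t", "mutant", "TRAP", trap_mut)},
        index=[f"g{i}" for i in range(genes)],
    )
    rows = []
    for c in rna.columns:
        rows.append({"sample_id": c, "genotype": c.split("_")[1], "assay": "RNA",
                     "animal_id": c})
    for c in trap.columns:
        rows.append({"sample_id": c, "genotype": c.split("_")[1], "assay": "TRAP",
                     "animal_id": c})
    kw.setdefault("library_scale", False)
    return TranslationEfficiency(rna, trap, pd.DataFrame(rows), **kw)


class TestDeltaTE:
    def test_all_groups_identical(self):
        m = make_te((7, 7), (7, 7), (7, 7), (7, 7))
        assert m.delta_te().iloc[0] == 0.0

    def test_trap_doubling(self):
        """TRAP mutant 15, TRAP control 7, RNA both 7 → ΔTE = (4−3) − 0 = 1."""
        m = make_te((7, 7), (7, 7), (7, 7), (15, 15))
        assert m.delta_te().iloc[0] == 1.0

    def test_rna_doubling_antisymmetric(self):
        m = make_te((7, 7), (15, 15), (7, 7), (7, 7))
        assert m.delta_te().iloc[0] == -1.0

    def test_genotype_swap_negates(self, rng):
        cfg = SimulationConfig(seed=21, n_genes=300)
        truth = simulate_gene_truth(cfg)
        rna, trap, sheet = simulate_count_matrices(truth, cfg)
        fwd = TranslationEfficiency(rna, trap, sheet).delta_te()
        swapped = sheet.copy()
        swapped["genotype"] = swapped["genotype"].map(
            {"control": "mutant", "mutant": "control"}
        )
        rev = TranslationEfficiency(rna, trap, swapped).delta_te()
        assert np.allclose(fwd.to_numpy(), -rev.to_numpy())

    def test_gene_absent_from_one_assay_dropped(self):
        m = make_te((7, 7), (7, 7), (7, 7), (7, 7), genes=3)
        m2 = TranslationEfficiency(m.rna.iloc[:2], m.trap, m.sheet, library_scale=False)
        assert list(m2.delta_te().index) == ["g0", "g1"]

    def test_group_of_one_rejected(self):
        with pytest.raises(InsufficientDataError):
            make_te((7,), (7, 7), (7, 7), (7, 7))


class TestJackknife:
    def test_identical_replicates_zero_sd(self):
        groups = {
            "trap_mutant": np.array([3.0, 3.0]),
            "trap_control": np.array([2.0, 2.0]),
            "rna_mutant": np.array([1.0, 1.0]),
            "rna_control": np.array([1.0, 1.0]),
        }
        assert jackknife_sd(groups)[0] == 0.0

    def test_2222_equals_exhaustive_enumeration(self, rng):
        """Groups of (2,2,2,2): 16 combinations, scale factor 1 — the sd must
        equal the brute-force enumeration exactly."""
        for _ in range(10):
            groups = {
                g: rng.normal(size=2)
                for g in ("trap_mutant", "trap_control", "rna_mutant", "rna_control")
            }
            oracle = brute_force_jackknife_values(groups).std(ddof=1)
            assert abs(jackknife_scale_factor([2, 2, 2, 2]) - 1.0) < 1e-15
            assert abs(jackknife_sd(groups)[0] - oracle) < 1e-12

    def test_4433_subsample_close_to_exhaustive(self, rng):
        """(4,4,3,3) → 144 combinations subsampled to 100: within 10%."""
        sizes = {"trap_mutant": 4, "trap_control": 4, "rna_mutant": 3, "rna_control": 3}
        for trial in range(10):
            groups = {g: rng.normal(size=n) for g, n in sizes.items()}
            exhaustive = jackknife_sd(groups, max_resamples=144, seed=0)[0]
            sub = jackknife_sd(groups, max_resamples=100, seed=trial)[0]
            assert abs(sub - exhaustive) / exhaustive < 0.10

    def test_resample_count_capped(self, rng):
        sizes = {"trap_mutant": 4, "trap_control": 4, "rna_mutant": 3, "rna_control": 3}
        groups = {g: rng.normal(size=(5, n)) for g, n in sizes.items()}
        vals = jackknife_resamples(groups, max_resamples=100, seed=1)
        assert vals.shape == (5, 100)

    def test_seeded_subsample_reproducible(self, rng):
        sizes = {"trap_mutant": 4, "trap_control": 4, "rna_mutant": 3, "rna_control": 3}
        groups = {g: rng.normal(size=n) for g, n in sizes.items()}
        a = jackknife_sd(groups, seed=7)
        b = jackknife_sd(groups, seed=7)
        assert a == b

    def test_sd_estimates_true_spread_under_null(self):
        """Calibration of the rescaled jackknife: across many null genes the
        mean jackknife sd matches the empirical sd of ΔTE estimates."""
        cfg = SimulationConfig(
            seed=17,
            n_genes=1000,
            proportions={"fmrp_like": 0, "top_like": 0, "down_both": 0, "null": 1},
        )
        truth = simulate_gene_truth(cfg)
        rna, trap, sheet = simulate_count_matrices(truth, cfg)
        model = TranslationEfficiency(rna, trap, sheet, library_scale=False)
        res = model.fit(seed=3)
        # stratify by baseline so per-gene variances are comparable within the
        # stratum; compare in root-mean-square terms (ŝd² is the unbiased scale)
        mid = truth["baseline"].between(40, 80)
        emp = res.frame.loc[mid.values, "delta_te"].std(ddof=1)
        est = np.sqrt((res.frame.loc[mid.values, "jackknife_sd"] ** 2).mean())
        assert abs(est - emp) / emp < 0.10


class TestZScore:
    def test_ratio(self):
        z, unstable = te_zscore(np.array([2.0]), np.array([0.5]))
        assert z[0] == 4.0 and not unstable[0]

    def test_degenerate_zero_zero(self):
        z, unstable = te_zscore(np.array([0.0]), np.array([0.0]))
        assert z[0] == 0.0 and not unstable[0]

    def test_degenerate_nonzero_delta(self):
        z, unstable = te_zscore(np.array([1.0]), np.array([0.0]))
        assert np.isnan(z[0]) and unstable[0]

    def test_negative_sd_rejected(self):
        with pytest.raises(ValidationError):
            te_zscore(np.array([1.0]), np.array([-0.1]))


class TestZToP:
    def test_z4_matches_printed_bound(self):
        p = float(z_to_p(4.0))
        assert 3.0e-5 <= p <= 3.2e-5

    def test_z0(self):
        assert float(z_to_p(0.0)) == 0.5

    def test_agrees_with_quadrature_oracle(self):
        for z in np.linspace(-6, 6, 25):
            oracle, _ = integrate.quad(
                lambda x: np.exp(-x * x / 2) / np.sqrt(2 * np.pi), z, np.inf
            )
            assert abs(float(z_to_p(z)) - oracle) < 1e-10

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            z_to_p(np.nan)


class TestClassify:
    def test_strict_threshold(self):
        cfg = SimulationConfig(seed=1, n_genes=10)
        truth = simulate_gene_truth(cfg)
        rna, trap, sheet = simulate_count_matrices(truth, cfg)
        res = TranslationEfficiency(rna, trap, sheet).fit()
        res.frame["z"] = [4.0, 5.0, -6.0, 0.0, 3.9, -4.0, 4.01, -4.01, 1.0, -1.0]
        inc, dec = res.classify()
        assert inc == ["g01", "g06"]
        assert dec == ["g02", "g07"]


class TestGroupShift:
    def test_welch_hand_toy(self):
        """Set (1,2,3) vs rest (2,4,6): t = −2/√(1/3 + 4/3)."""
        s = pd.Series([1.0, 2.0, 3.0, 2.0, 4.0, 6.0],
                      index=["a", "b", "c", "d", "e", "f"])
        res = group_shift_test(s, {"a", "b", "c"})
        assert abs(res.t - (-2.0 / np.sqrt(5.0 / 3.0))) < 1e-12

    def test_power_on_shifted_set(self, rng):
        vals = np.concatenate([rng.normal(1.0, 0.2, 50), rng.normal(0.0, 0.2, 50)])
        idx = [f"g{i}" for i in range(100)]
        res = group_shift_test(pd.Series(vals, index=idx), set(idx[:50]))
        assert res.p < 1e-6 and res.t > 0

    def test_null_t_centered(self, rng):
        ts = []
        for _ in range(200):
            vals = rng.normal(0, 1, 60)
            idx = [f"g{i}" for i in range(60)]
            res = group_shift_test(pd.Series(vals, index=idx), set(idx[:20]))
            ts.append(res.t)
        assert abs(np.mean(ts)) < 0.2

    def test_small_group_rejected(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(InsufficientDataError):
            group_shift_test(s, {"a"})

    def test_ecdf_table(self):
        t = ecdf_table([3.0, 1.0, 2.0])
        assert list(t["value"]) == [1.0, 2.0, 3.0]
        assert list(t["cumulative_fraction"]) == [1 / 3, 2 / 3, 1.0]
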