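"""Signature refitting: loader dialects, annealer vs exact grid oracle."""

import numpy as np
import pandas as pd
import pytest

from adenosig import (
    AnnealingParams,
    Catalogue96,
    ConfigurationError,
    RefitError,
    SignatureMatrix,
    bootstrap_exposures,
    catalogue_to_vector,
    combined_exposure,
    load_signature_matrix,
    refit_catalogue,
    refit_exposures,
    refit_oracle_grid,
)
from adenosig.catalogue import CLASSES_96
from adenosig.refit import write_signature_tsv

FAST = AnnealingParams(steps=2000, restarts=2, seed=99)


def make_catalogue(counts_by_class, sample_id="s"):
    counts = {c: 0 for c in CLASSES_96}
    counts.update(counts_by_class)
    return Catalogue96(sample_id, counts)


class TestSignatureMatrix:
    def test_uniform_single_column(self):
        m = SignatureMatrix(("flat",), np.full((96, 1), 1 / 96))
        assert m.k == 1

    def test_column_sum_enforced(self):
        bad = np.full((96, 1), 1 / 96)
        bad[0] += 0.01
        with pytest.raises(ValueError, match="sum to 1"):
            SignatureMatrix(("x",), bad)

    def test_subset_preserves_order(self, signatures):
        sub = signatures.subset(["SBS36", "SBS18"])
        assert sub.names == ("SBS36", "SBS18")
        np.testing.assert_array_equal(sub.probs[:, 0], signatures.column("SBS36"))

    def test_subset_unknown_name(self, signatures):
        with pytest.raises(KeyError):
            signatures.subset(["SBS999"])


class TestLoader:
    def test_bracket_roundtrip(self, tmp_path, signatures):
        path = tmp_path / "sig.tsv"
        write_signature_tsv(signatures, path)
        loaded = load_signature_matrix(path)
        assert loaded.names == signatures.names
        np.testing.assert_allclose(loaded.probs, signatures.probs, atol=1e-12)

    def test_subset_on_load(self, tmp_path, signatures):
        path = tmp_path / "sig.tsv"
        write_signature_tsv(signatures, path)
        m = load_signature_matrix(path, subset=["SBS18", "SBS36"])
        assert m.names == ("SBS18", "SBS36")
        assert m.k == 2

    def test_type_subtype_dialect(self, tmp_path, signatures):
        rows = []
        for i, cls in enumerate(CLASSES_96):
            rows.append({
                "Type": cls[2:5],
                "Subtype": cls[0] + cls[2] + cls[6],
                "SBS18": signatures.column("SBS18")[i],
            })
        # shuffled row order must not matter
        df = pd.DataFrame(rows).sample(frac=1, random_state=0)
        path = tmp_path / "cosmic.tsv"
        df.to_csv(path, sep="\t", index=False)
        m = load_signature_matrix(path)
        np.testing.assert_allclose(m.column("SBS18"), signatures.column("SBS18"))

    def test_bad_column_sum_rejected(self, tmp_path):
        df = pd.DataFrame({"class": list(CLASSES_96), "X": [0.9 / 96] * 96})
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="sum to 1"):
            load_signature_matrix(path)

    def test_missing_rows_rejected(self, tmp_path):
        df = pd.DataFrame({"class": list(CLASSES_96[:90]), "X": [1 / 90] * 90})
        path = tmp_path / "short.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing"):
            load_signature_matrix(path)


class TestCatalogueToVector:
    def test_single_class(self):
        cat = make_catalogue({CLASSES_96[3]: 5})
        v = catalogue_to_vector(cat)
        assert v[3] == 1.0 and v.sum() == 1.0

    def test_zero_snvs_raises(self):
        with pytest.raises(RefitError):
            catalogue_to_vector(make_catalogue({}))

    def test_normalisation(self, rng):
        counts = dict(zip(CLASSES_96, (int(x) for x in rng.integers(0, 20, 96))))
        v = catalogue_to_vector(make_catalogue(counts))
        assert v.sum() == pytest.approx(1.0)


class TestRefit:
    def test_pure_signature_recovered(self, signatures):
        v = signatures.column("SBS18")
        fit = refit_exposures(v, signatures, FAST)
        assert fit["SBS18"] == pytest.approx(1.0, abs=1e-3)
        assert fit.reconstruction_error <= 1e-3

    def test_two_component_mixture_matches_grid_oracle(self, signatures):
        sub = signatures.subset(["SBS18", "SBS1"])
        v = 0.7 * sub.column("SBS18") + 0.3 * sub.column("SBS1")
        fit = refit_exposures(v, sub, FAST)
        oracle = refit_oracle_grid(v, sub, step=0.01)
        assert fit["SBS18"] == pytest.approx(0.7, abs=1e-2)
        assert fit["SBS1"] == pytest.approx(0.3, abs=1e-2)
        assert fit.reconstruction_error <= oracle.reconstruction_error + 1e-3

    def test_reproducible_for_fixed_seed(self, signatures, rng):
        v = rng.dirichlet(np.ones(96))
        a = refit_exposures(v, signatures, FAST)
        b = refit_exposures(v, signatures, FAST)
        np.testing.assert_array_equal(a.exposures, b.exposures)

    def test_scale_invariance(self, signatures, rng):
        counts = dict(zip(CLASSES_96, (int(x) for x in rng.integers(0, 30, 96))))
        cat1 = make_catalogue(counts)
        cat10 = make_catalogue({c: 10 * n for c, n in counts.items()})
        f1 = refit_catalogue(cat1, signatures, FAST)
        f10 = refit_catalogue(cat10, signatures, FAST)
        np.testing.assert_array_equal(f1.exposures, f10.exposures)

    def test_simplex_invariant(self, signatures, rng):
        for _ in range(5):
            v = rng.dirichlet(np.ones(96) * 0.5)
            fit = refit_exposures(v, signatures, FAST)
            assert np.all(fit.exposures >= 0)
            assert fit.exposures.sum() == pytest.approx(1.0, abs=1e-6)

    def test_nonfinite_rejected(self, signatures):
        v = np.full(96, 1 / 96)
        v[0] = np.nan
        with pytest.raises(ValueError):
            refit_exposures(v, signatures, FAST)

    def test_cosine_objective_runs(self, signatures):
        v = signatures.column("SBS30")
        fit = refit_exposures(v, signatures, AnnealingParams(steps=500, restarts=1, seed=1),
                              objective="cosine")
        assert fit["SBS30"] > 0.5

    def test_low_confidence_flag(self, signatures):
        small = make_catalogue({CLASSES_96[0]: 10})
        big = make_catalogue({CLASSES_96[0]: 100})
        assert refit_catalogue(small, signatures, FAST).low_confidence
        assert not refit_catalogue(big, signatures, FAST).low_confidence


class TestGridOracle:
    def test_single_signature(self, signatures, rng):
        sub = signatures.subset(["SBS5"])
        v = rng.dirichlet(np.ones(96))
        oracle = refit_oracle_grid(v, sub, step=0.01)
        assert oracle.exposures[0] == 1.0

    def test_twin_columns_lexicographic_tie(self):
        col = np.full((96, 1), 1 / 96)
        m = SignatureMatrix(("a", "b"), np.hstack([col, col]))
        oracle = refit_oracle_grid(np.full(96, 1 / 96), m, step=0.5)
        # lattice enumerated lexicographically; first optimum is (0, 1)
        np.testing.assert_array_equal(oracle.exposures, [0.0, 1.0])

    def test_k_guard(self, signatures):
        with pytest.raises(ConfigurationError):
            refit_oracle_grid(np.full(96, 1 / 96), signatures.subset(
                ["SBS1", "SBS2", "SBS3", "SBS5", "SBS13"]), step=0.1)

    def test_noise_free_three_component(self, signatures):
        sub = signatures.subset(["SBS18", "SBS30", "SBS5"])
        truth = np.array([0.5, 0.3, 0.2])
        v = sub.probs @ truth
        fit = refit_exposures(v, sub, FAST)
        oracle = refit_oracle_grid(v, sub, step=0.01)
        assert fit.reconstruction_error <= oracle.reconstruction_error + 1e-3
        np.testing.assert_allclose(fit.exposures, truth, atol=0.01)


class TestCombinedExposure:
    def test_addition(self, signatures):
        v = (0.5 * signatures.column("SBS18") + 0.3 * signatures.column("SBS36")
             + 0.2 * signatures.column("SBS1"))
        fit = refit_exposures(v, signatures, FAST)
        assert combined_exposure(fit, ["SBS18", "SBS36"]) == pytest.approx(0.8, abs=0.02)

    def test_all_names_sum_to_one(self, signatures):
        v = signatures.column("SBS1")
        fit = refit_exposures(v, signatures, FAST)
        assert combined_exposure(fit, list(signatures.names)) == pytest.approx(1.0, abs=1e-6)

    def test_unknown_name(self, signatures):
        fit = refit_exposures(signatures.column("SBS1"), signatures, FAST)
        with pytest.raises(KeyError):
            combined_exposure(fit, ["SBS999"])


class TestBootstrap:
    def test_degenerate_single_class(self, signatures):
        cat = make_catalogue({CLASSES_96[0]: 200})
        out = bootstrap_exposures(cat, signatures, FAST, n_boot=3)
        assert np.allclose(out["q025"], out["q975"], atol=1e-9)

    def test_interval_shrinks_with_burden(self, signatures, rng):
        truth = np.zeros(16)
        truth[signatures.names.index("SBS18")] = 0.7
        truth[signatures.names.index("SBS1")] = 0.3
        probs = signatures.probs @ truth
        widths = {}
        for n in (50, 1000):
            counts = rng.multinomial(n, probs)
            cat = make_catalogue(dict(zip(CLASSES_96, (int(x) for x in counts))))
            out = bootstrap_exposures(cat, signatures, FAST, n_boot=20)
            widths[n] = (out["q975"] - out["q025"]).mean()
        assert widths[1000] < widths[50]

    def test_n_boot_validated(self, signatures):
        cat = make_catalogue({CLASSES_96[0]: 10})
        with pytest.raises(ConfigurationError):
            bootstrap_exposures(cat, signatures, FAST, n_boot=0)
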