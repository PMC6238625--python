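"""Ensemble aggregation and the hand-rolled statistics against oracles."""

import numpy as np
import pytest

from clockloops.clamping import FAMILIES, LoopReport
from clockloops.config import RhythmCriterion
from clockloops.ensemble import (
    Ensemble,
    circular_mean,
    invert_repressor_phases,
    lda_project,
    loop_frequency_table,
    oscillator_venn,
    pca_project,
    ranksum,
    score_loop_association,
)
from clockloops.network import ParameterSet
from clockloops.pso import FitResult
from clockloops.scoring import Score


def _fit(topo, rng, tissue, seed, score_total, shift=0.0):
    lo = 0.1
    v = rng.uniform(lo, 2.0, topo.n_parameters) + shift
    return FitResult(
        params=ParameterSet(topo, v),
        score=Score(total=score_total),
        trace=np.array([score_total]),
        tissue=tissue,
        seed=seed,
        fit_id=f"{tissue}-{seed}",
    )


def _report(fit_id, essential, oscillators, score=None):
    return LoopReport(
        fit_id=fit_id,
        essential_families=sorted(essential),
        essential_members=[f"{f}:x" for f in essential],
        minimal_oscillators=[tuple(f"{f}:x" for f in o) for o in oscillators],
        minimal_oscillator_families=[tuple(sorted(o)) for o in oscillators],
        synergy={},
        edge_clamp_rhythmic={},
        clamp_constants={},
        criterion=RhythmCriterion(),
        score=score,
    )


@pytest.fixture
def ensemble(topo, rng):
    fits, reports = [], []
    spec = [
        ("liver", 0, 2.0, ["Repressilator"], [("Repressilator",)], 0.0),
        ("liver", 1, 4.0, ["Repressilator", "Per2_loop"],
         [("Repressilator",), ("Per2_loop",)], 0.0),
        ("liver", 2, 15.0, [], [("Bmal1_RevErbA", "Per2_loop")], 0.0),
        ("SCN", 0, 3.0, ["Bmal1_RevErbA"], [("Bmal1_RevErbA",)], 1.5),
        ("SCN", 1, 6.0, ["Bmal1_RevErbA", "Cry1_loop"],
         [("Bmal1_RevErbA",)], 1.5),
        ("SCN", 2, 30.0, ["Cry1_loop"], [("Cry1_loop",)], 1.5),
    ]
    for tissue, seed, s, ess, osc, shift in spec:
        f = _fit(topo, rng, tissue, seed, s, shift)
        fits.append(f)
        reports.append(_report(f.fit_id, ess, osc, s))
    return Ensemble(fits=fits, reports=reports)


class TestEnsembleContainer:
    def test_alignment_enforced(self, ensemble):
        with pytest.raises(ValueError):
            Ensemble(fits=ensemble.fits, reports=ensemble.reports[:-1])

    def test_unique_ids_enforced(self, ensemble):
        fits = ensemble.fits[:1] * 2
        with pytest.raises(ValueError):
            Ensemble(fits=fits, reports=ensemble.reports[:2])


class TestFrequencyTable:
    def test_good_fits_only(self, ensemble):
        tab = loop_frequency_table(ensemble, threshold=10.0)
        assert set(tab.index) == set(FAMILIES)
        # liver: 2 good fits, both with Repressilator essential
        assert tab.loc["Repressilator", "liver"] == 1.0
        assert tab.loc["Per2_loop", "liver"] == 0.5
        # SCN: 2 good fits, both Bmal1_RevErbA
        assert tab.loc["Bmal1_RevErbA", "SCN"] == 1.0
        assert tab.loc["Cry1_loop", "SCN"] == 0.5

    def test_values_are_fractions(self, ensemble):
        tab = loop_frequency_table(ensemble)
        assert ((tab >= 0) & (tab <= 1)).all().all()


class TestVenn:
    def test_partition(self, ensemble):
        venn = oscillator_venn(ensemble, "liver")
        assert sum(venn.values()) == 3
        assert venn[("Repressilator",)] == 1
        assert venn[("Per2_loop", "Repressilator")] == 1
        assert venn[("Bmal1_RevErbA", "Per2_loop")] == 1


class TestPCA:
    def test_matches_sklearn(self, ensemble):
        sklearn = pytest.importorskip("sklearn.decomposition")
        X = ensemble.parameter_matrix()
        Z = (X - X.mean(0)) / np.where(X.std(0) == 0, 1, X.std(0))
        proj = pca_project(ensemble)
        ref = sklearn.PCA(n_components=2).fit(Z)
        ours = proj.coordinates
        theirs = ref.transform(Z)
        for k in range(2):  # sign of each axis is arbitrary
            assert np.allclose(ours[:, k], theirs[:, k], atol=1e-8) or np.allclose(
                ours[:, k], -theirs[:, k], atol=1e-8
            )
        assert np.allclose(proj.explained, ref.explained_variance_ratio_, atol=1e-8)

    def test_needs_three_fits(self, ensemble):
        small = Ensemble(fits=ensemble.fits[:2], reports=ensemble.reports[:2])
        with pytest.raises(ValueError):
            pca_project(small)


class TestLDA:
    def test_separates_shifted_classes(self, ensemble):
        proj = lda_project(ensemble)
        labels = [f.tissue for f in ensemble.fits]
        c1 = proj.coordinates[[i for i, l in enumerate(labels) if l == "liver"], 0]
        c2 = proj.coordinates[[i for i, l in enumerate(labels) if l == "SCN"], 0]
        # classes were generated with a mean shift: the first discriminant
        # must separate them completely
        assert max(c1) < min(c2) or max(c2) < min(c1)

    def test_generalized_eigen_oracle(self, ensemble):
        """The discriminant satisfies S_b w = lambda (S_w + ridge I) w."""
        import scipy.linalg

        X = ensemble.parameter_matrix()
        Z = (X - X.mean(0)) / np.where(X.std(0) == 0, 1, X.std(0))
        labels = np.array([f.tissue for f in ensemble.fits])
        Sw = np.zeros((Z.shape[1],) * 2)
        Sb = np.zeros_like(Sw)
        for c in np.unique(labels):
            Zc = Z[labels == c]
            D = Zc - Zc.mean(0)
            Sw += D.T @ D
            dm = (Zc.mean(0) - Z.mean(0))[:, None]
            Sb += len(Zc) * dm @ dm.T
        ridge = 1e-6
        evals = scipy.linalg.eigh(Sb, Sw + ridge * np.eye(Z.shape[1]),
                                  eigvals_only=True)
        lam = np.sort(evals)[::-1][0]
        proj = lda_project(ensemble, ridge=ridge)
        w = proj.loadings[:, 0]
        lhs = Sb @ w
        rhs = lam * (Sw + ridge * np.eye(Z.shape[1])) @ w
        assert np.allclose(lhs, rhs, atol=1e-6 * max(1.0, np.abs(lhs).max()))

    def test_needs_two_tissues(self, ensemble):
        liver = [i for i, f in enumerate(ensemble.fits) if f.tissue == "liver"]
        sub = Ensemble(fits=[ensemble.fits[i] for i in liver],
                       reports=[ensemble.reports[i] for i in liver])
        with pytest.raises(ValueError):
            lda_project(sub)


class TestRanksum:
    def test_exact_small_case(self):
        """{1,2} vs {3,4}: W = 3 is the most extreme of C(4,2)=6 assignments,
        two-sided p = 2 * 1/6 = 1/3."""
        w, p = ranksum([1.0, 2.0], [3.0, 4.0])
        assert w == 3.0
        assert p == pytest.approx(1.0 / 3.0)

    def test_symmetry(self):
        _, p1 = ranksum([1, 2, 3], [4, 5, 6])
        _, p2 = ranksum([4, 5, 6], [1, 2, 3])
        assert p1 == pytest.approx(p2)

    def test_identical_samples_p_one(self):
        _, p = ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_matches_scipy_large_samples(self, rng):
        from scipy.stats import ranksums

        x = rng.normal(0.0, 1.0, 25)
        y = rng.normal(0.6, 1.0, 30)
        w, p = ranksum(x, y)
        ref = ranksums(x, y)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ranksum([], [1.0])

    def test_one_sided_exact(self):
        """{1,2} vs {3,4}: P(W <= 3) = 1/6 for 'less'; 'greater' gives 1."""
        _, p_less = ranksum([1.0, 2.0], [3.0, 4.0], alternative="less")
        _, p_greater = ranksum([1.0, 2.0], [3.0, 4.0], alternative="greater")
        assert p_less == pytest.approx(1.0 / 6.0)
        assert p_greater == pytest.approx(1.0)

    def test_one_sided_matches_scipy_large(self, rng):
        from scipy.stats import ranksums

        x = rng.normal(-0.4, 1.0, 30)
        y = rng.normal(0.0, 1.0, 28)
        _, p = ranksum(x, y, alternative="less")
        ref = ranksums(x, y, alternative="less")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_unknown_alternative_rejected(self):
        with pytest.raises(ValueError):
            ranksum([1.0], [2.0], alternative="sideways")


class TestCircular:
    def test_wraparound_mean(self):
        m, R = circular_mean([23.0, 1.0])
        assert m == pytest.approx(0.0, abs=1e-9)
        assert R == pytest.approx(np.cos(np.pi / 12), abs=1e-9)

    def test_concentrated(self):
        m, R = circular_mean([6.0, 6.0, 6.0])
        assert m == pytest.approx(6.0)
        assert R == pytest.approx(1.0)

    def test_antipodal_undefined(self):
        m, R = circular_mean([0.0, 12.0])
        assert np.isnan(m)
        assert R == 0.0

    def test_invert_repressors(self):
        phases = {"Bmal1": 2.0, "Per2": 20.0}
        roles = {"Bmal1": "activator", "Per2": "repressor"}
        out = invert_repressor_phases(phases, roles)
        assert out["Bmal1"] == 2.0
        assert out["Per2"] == 8.0


class TestAssociation:
    def test_structure(self, ensemble):
        out = score_loop_association(ensemble)
        assert out["n_low"] + out["n_high"] == 6
        assert 0.0 <= out["ranksum_p"] <= 1.0
        assert set(out["by_family"]) == set(FAMILIES)

    def test_needs_four_fits(self, ensemble):
        small = Ensemble(fits=ensemble.fits[:3], reports=ensemble.reports[:3])
        with pytest.raises(ValueError):
            score_loop_association(small)
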