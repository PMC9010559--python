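"""The synthetic-data generator: noise laws, truth labels, determinism, IO."""

import numpy as np
import pandas as pd
import pytest

from splitreg.kinetics import PerturbationSpec, PoolKinetics, steady_state
from splitreg.simulate import (
    DEFAULT_ISOFORMS,
    GroupModel,
    StudyBundle,
    StudyDesign,
    default_isoform_kinetics,
    default_probe_annotation,
    generate_count_matrix,
    generate_densitometry,
    generate_peptide_table,
    scenario_suite,
    simulate_study,
    toy_isoform_proteome,
    truth_labels,
    _nb_draw,
)
from splitreg.proteomics import DigestionRule


class TestCountingNoise:
    def test_negative_binomial_moments(self):
        rng = np.random.default_rng(0)
        mu, phi, n = 500.0, 0.05, 100_000
        draws = _nb_draw(rng, np.full(n, mu), phi)
        assert draws.mean() == pytest.approx(mu, rel=0.01)
        assert draws.var() == pytest.approx(mu + phi * mu * mu, rel=0.05)

    def test_poisson_limit_variance_equals_mean(self):
        rng = np.random.default_rng(1)
        draws = _nb_draw(rng, np.full(100_000, 500.0), 0.0)
        assert draws.var() / draws.mean() == pytest.approx(1.0, rel=0.05)

    def test_noise_free_probe_means(self, default_kins, default_pool):
        """With all stochastic layers off, empirical probe means converge to
        lane * efficiency * signal (law of large numbers)."""
        state = steady_state(default_kins, default_pool)
        design = StudyDesign(groups={"Ctrl": 2, "T": 2}, lane_sigma=0.0,
                             dispersion=0.0, background_mean=0.0, biological_cv=0.0)
        probes = default_probe_annotation()
        rng = np.random.default_rng(2)
        n_rep = 3000
        states = {f"s{i}": state for i in range(n_rep)}
        groups = {f"s{i}": "Ctrl" for i in range(n_rep)}
        cm = generate_count_matrix(states, probes, design, groups, rng,
                                   lane_factors={s: 1.0 for s in states})
        iso = DEFAULT_ISOFORMS[0]
        k = list(state.isoform_ids).index(iso)
        expected_exon = 6.0 * (state.M[k] + state.P[k])
        expected_intron = 20.0 * state.P[k]
        assert cm.counts.loc[f"{iso}_exon"].mean() == pytest.approx(expected_exon, rel=0.01)
        assert cm.counts.loc[f"{iso}_intron"].mean() == pytest.approx(expected_intron, rel=0.01)

    def test_missing_control_probes_rejected(self, default_kins, default_pool):
        state = steady_state(default_kins, default_pool)
        probes = default_probe_annotation()
        endo_only = probes[probes["class"] == "endogenous"]
        with pytest.raises(ValueError, match="positive"):
            generate_count_matrix({"s1": state}, endo_only, StudyDesign(),
                                  {"s1": "Ctrl"}, np.random.default_rng(0))


class TestDeterminism:
    def test_identical_seeds_identical_bundles(self):
        b1 = scenario_suite("colchicine-6h", seed=42)
        b2 = scenario_suite("colchicine-6h", seed=42)
        assert np.array_equal(b1.counts.counts.to_numpy(), b2.counts.counts.to_numpy())
        pd.testing.assert_frame_equal(b1.truth, b2.truth)

    def test_different_seeds_differ(self):
        b1 = scenario_suite("null", seed=1)
        b2 = scenario_suite("null", seed=2)
        assert not np.array_equal(b1.counts.counts.to_numpy(), b2.counts.counts.to_numpy())

    def test_peptide_table_deterministic(self):
        seqs = toy_isoform_proteome(3, rng=0)
        ab = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [2.0, 2.0, 2.0]},
                          index=list(seqs))
        t1 = generate_peptide_table(seqs, ab, missing_rate=0.2, rng=7)
        t2 = generate_peptide_table(seqs, ab, missing_rate=0.2, rng=7)
        pd.testing.assert_frame_equal(t1, t2)


class TestTruthLabels:
    def _models(self, **kw):
        kins = tuple(default_isoform_kinetics(**kw))
        pool = PoolKinetics()
        return kins, pool

    def test_shared_parameters_mean_unchanged(self):
        kins, pool = self._models()
        models = {"Ctrl": GroupModel(kins, pool), "T": GroupModel(kins, pool)}
        truth = truth_labels(models, "Ctrl")
        assert set(truth["mode"]) == {"unchanged"}

    def test_drug_on_feedback_competent_isoforms(self):
        kins, pool = self._models()
        colch = PerturbationSpec("colchicine", 10.0)
        models = {"Ctrl": GroupModel(kins, pool), "C": GroupModel(kins, pool, colch)}
        assert set(truth_labels(models, "Ctrl")["mode"]) == {"autoinhibition"}

    def test_drug_without_feedback_is_unchanged(self):
        kins, pool = self._models(alpha=0.0)
        colch = PerturbationSpec("colchicine", 10.0)
        models = {"Ctrl": GroupModel(kins, pool), "C": GroupModel(kins, pool, colch)}
        assert set(truth_labels(models, "Ctrl")["mode"]) == {"unchanged"}

    def test_transcription_plus_drug_is_mixed(self):
        bundle = scenario_suite("pe-4day", seed=0)
        truth = bundle.truth.set_index("isoform")["mode"]
        assert truth["Tubb6"] == "mixed"
        assert truth["Tubb2a"] == "mixed"
        assert truth["Tuba1a"] == "autoactivation"

    def test_transcriptional_scenarios(self):
        up = scenario_suite("pe-transcriptional", seed=0)
        down = scenario_suite("transcriptional-down", seed=0)
        assert set(up.truth["mode"]) == {"transcriptional-up"}
        assert set(down.truth["mode"]) == {"transcriptional-down"}


class TestDensitometryGenerator:
    def test_noise_free_intensity_equals_amount_times_equivalents(self, default_kins, default_pool):
        state = steady_state(default_kins, default_pool)
        samples = pd.DataFrame({"group": ["Ctrl"]}, index=["s1"])
        table = generate_densitometry({"s1": state}, samples, rng=0, noise_sigma=0.0)
        free = table[(table["fraction"] == "free") & (table["target"] == "alpha-tub")]
        assert free["intensity"].unique() == pytest.approx(state.F * 5.0)  # 10 uL / 2x dilution

    def test_duplicates_share_amount_differ_by_noise(self, default_kins, default_pool):
        state = steady_state(default_kins, default_pool)
        samples = pd.DataFrame({"group": ["Ctrl"]}, index=["s1"])
        table = generate_densitometry({"s1": state}, samples, rng=0, noise_sigma=0.2)
        poly = table[(table["fraction"] == "poly") & (table["target"] == "alpha-tub")]
        assert len(poly) == 2
        assert poly["intensity"].iloc[0] != poly["intensity"].iloc[1]

    def test_blot_without_control_rejected(self, default_kins, default_pool):
        state = steady_state(default_kins, default_pool)
        samples = pd.DataFrame({"group": ["PE"]}, index=["s1"])
        with pytest.raises(ValueError, match="no 'Ctrl' sample"):
            generate_densitometry({"s1": state}, samples, rng=0)


class TestPeptideGenerator:
    def test_noise_free_single_isoform(self):
        ab = pd.DataFrame({"s1": {"iso": 7.0}})
        t = generate_peptide_table({"iso": "AAAKCCCK"}, ab, DigestionRule("trypsin", 0),
                                   missing_rate=0.0, noise_sigma=0.0, rng=0)
        assert (t["intensity"] == 7.0).all()

    def test_shared_peptides_sum_parent_abundances(self):
        ab = pd.DataFrame({"s1": {"A": 2.0, "B": 3.0}})
        seqs = {"A": "GGGKAAAK", "B": "GGGKCCCK"}  # GGGK shared
        t = generate_peptide_table(seqs, ab, DigestionRule("trypsin", 0),
                                   missing_rate=0.0, noise_sigma=0.0, rng=0)
        t = t.set_index("peptide")["intensity"]
        assert t["GGGK"] == pytest.approx(5.0)
        assert t["AAAK"] == pytest.approx(2.0)

    def test_missingness_rate_roughly_respected(self):
        ab = pd.DataFrame({f"s{i}": {"iso": 5.0} for i in range(50)})
        t = generate_peptide_table({"iso": "AAAKCCCKDDDKFFFK"}, ab,
                                   DigestionRule("trypsin", 0), missing_rate=0.3, rng=3)
        assert t["intensity"].isna().mean() == pytest.approx(0.3, abs=0.07)


class TestBundleIO:
    def test_round_trip(self, tmp_path):
        bundle = scenario_suite("pe-4day", seed=9, with_proteomics=True)
        bundle.write(tmp_path / "b")
        back = StudyBundle.read(tmp_path / "b")
        assert np.array_equal(back.counts.counts.to_numpy().astype(int),
                              bundle.counts.counts.to_numpy().astype(int))
        assert list(back.counts.counts.columns) == list(bundle.counts.counts.columns)
        pd.testing.assert_frame_equal(back.truth, bundle.truth)
        assert back.config == bundle.config
        assert back.proteome == bundle.proteome
        assert np.allclose(back.densitometry["intensity"], bundle.densitometry["intensity"])

    def test_unknown_scenario_lists_catalogue(self):
        with pytest.raises(ValueError, match="catalogue"):
            scenario_suite("warp-drive")


class TestStudyDesignValidation:
    def test_group_size_minimum(self):
        with pytest.raises(ValueError, match=">= 2"):
            StudyDesign(groups={"Ctrl": 1, "T": 6})

    def test_control_must_be_a_group(self):
        with pytest.raises(ValueError, match="control"):
            StudyDesign(groups={"A": 3, "B": 3}, control="Ctrl")

    def test_simulate_study_honours_group_sizes(self, default_kins, default_pool):
        models = {"Ctrl": GroupModel(tuple(default_kins), default_pool),
                  "T": GroupModel(tuple(default_kins), default_pool)}
        design = StudyDesign(groups={"Ctrl": 3, "T": 4})
        cm, states = simulate_study(models, design, rng=0)
        assert (cm.samples["group"] == "Ctrl").sum() == 3
        assert (cm.samples["group"] == "T").sum() == 4
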