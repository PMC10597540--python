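import json

import numpy as np
import pytest
from scipy import stats as sps

from episub import (
    SimParams,
    simulate_cohort,
    simulate_regulator_network,
    write_fixture_bundle,
)
from episub import io as eio
from episub.containers import MODALITIES, ParameterError


class TestSimParams:
    def test_invalid_probability_named(self):
        with pytest.raises(ParameterError, match="recurrence_rate_subtype"):
            SimParams(recurrence_rate_subtype=1.4)

    def test_tiny_subtype_rejected(self):
        with pytest.raises(ParameterError, match="subtype_fraction"):
            SimParams(subtype_fraction=0.02)

    def test_signal_cannot_exceed_features(self):
        with pytest.raises(ParameterError, match="n_signal_features"):
            SimParams(n_signal_features={m: 10_000 for m in MODALITIES})


class TestSimulateCohort:
    def test_deterministic_under_seed(self):
        a = simulate_cohort(SimParams(seed=7))
        b = simulate_cohort(SimParams(seed=7))
        for m in MODALITIES:
            np.testing.assert_array_equal(a[0][m].values.to_numpy(), b[0][m].values.to_numpy())
        assert a[1].table.equals(b[1].table)
        assert a[2].subtype_members == b[2].subtype_members

    def test_availability_is_nested_with_complete_core(self):
        mats, meta, _ = simulate_cohort(SimParams(seed=1))
        sizes = {m: len(mats[m].sample_ids) for m in MODALITIES}
        assert sizes == {"blood_mirna": 40, "blood_mrna": 35,
                         "brain_mirna": 32, "brain_mrna": 32}
        complete = set.intersection(*(set(mats[m].sample_ids) for m in MODALITIES))
        assert len(complete) == 30

    def test_null_effect_leaves_group_means_equal(self):
        params = SimParams(seed=3, effect_size=0.0, n_subjects=200,
                           modality_missingness={m: 0 for m in MODALITIES},
                           n_complete=200)
        mats, _, truth = simulate_cohort(params)
        mat = mats["blood_mirna"].values
        members = [s for s in mat.columns if s in set(truth.subtype_members)]
        rest = [s for s in mat.columns if s not in set(truth.subtype_members)]
        sig = truth.signal_features["blood_mirna"]
        diff = mat.loc[sig, members].mean(axis=1) - mat.loc[sig, rest].mean(axis=1)
        # per-feature SE ~ sqrt(1/115 + 1/85); mean over 100 signal features
        assert abs(diff.mean()) < 0.05
        assert np.abs(diff).max() < 0.65

    def test_signal_shift_directions(self):
        params = SimParams(seed=5, effect_size=3.0)
        mats, _, truth = simulate_cohort(params)
        members = set(truth.subtype_members)
        for modality, sign in (("blood_mirna", -1), ("blood_mrna", +1)):
            mat = mats[modality].values
            inside = [s for s in mat.columns if s in members]
            outside = [s for s in mat.columns if s not in members]
            sig = truth.signal_features[modality]
            diff = (mat.loc[sig, inside].mean(axis=1) - mat.loc[sig, outside].mean(axis=1)).mean()
            assert np.sign(diff) == sign and abs(diff) > 2.0

    def test_recurrence_counts_match_binomial_oracle(self):
        """With both rates 0.5 every cohort is Binomial(40, 0.5); the total
        over 100 seeds must sit inside the exact 99% band of Binomial(4000, 0.5)."""
        total = 0
        for seed in range(100):
            _, meta, _ = simulate_cohort(
                SimParams(seed=seed, recurrence_rate_subtype=0.5,
                          recurrence_rate_background=0.5)
            )
            total += int(meta.table["outcome"].sum())
        lo = sps.binom.ppf(0.005, 4000, 0.5)
        hi = sps.binom.ppf(0.995, 4000, 0.5)
        assert lo <= total <= hi

    def test_truth_membership_size(self):
        _, _, truth = simulate_cohort(SimParams(seed=9))
        assert len(truth.subtype_members) == round(0.575 * 40)


class TestSimulateRegulatorNetwork:
    def test_planted_edges_all_repression_within_signal(self):
        _, _, truth = simulate_cohort(SimParams(seed=2))
        net = truth.planted_network
        sig_mir = set(truth.signal_features["blood_mirna"])
        sig_gene = set(truth.signal_features["blood_mrna"])
        planted = net[net["regulator"].isin(sig_mir)]
        assert (planted["sign"] == "repression").all()
        assert planted["target"].isin(sig_gene).all()

    def test_zero_decoy_density_leaves_only_planted_edges(self):
        params = SimParams(seed=4, decoy_density=0.0)
        _, _, truth = simulate_cohort(params)
        net = truth.planted_network
        sig_mir = set(truth.signal_features["blood_mirna"])
        assert net["regulator"].isin(sig_mir).all()

    def test_planted_edge_count_follows_poisson_density(self):
        """10 signal miRNAs at density 5 give ~Poisson(50) planted edges
        (clipped below at 1 per regulator); the mean over seeds must sit
        within the exact 99.9% band of the summed distribution."""
        counts = []
        for seed in range(30):
            params = SimParams(
                seed=seed,
                n_signal_features={"blood_mirna": 10, "blood_mrna": 500,
                                   "brain_mirna": 10, "brain_mrna": 500},
            )
            _, _, truth = simulate_cohort(params)
            net = truth.planted_network
            sig = set(truth.signal_features["blood_mirna"])
            counts.append(int(net["regulator"].isin(sig).sum()))
        lo = sps.poisson.ppf(0.0005, 50 * 30) / 30
        hi = sps.poisson.ppf(0.9995, 50 * 30) / 30
        assert lo - 0.2 <= np.mean(counts) <= hi + 0.2  # small clip bias allowance

    def test_no_duplicate_edges(self):
        _, _, truth = simulate_cohort(SimParams(seed=6))
        assert not truth.planted_network.duplicated(["regulator", "target"]).any()


class TestFixtureBundle:
    def test_round_trip_and_rewrite_identical(self, tmp_path):
        params = SimParams(seed=12, n_features={"blood_mirna": 50, "blood_mrna": 80,
                                                "brain_mirna": 50, "brain_mrna": 80},
                           n_signal_features={"blood_mirna": 12, "blood_mrna": 20,
                                              "brain_mirna": 12, "brain_mrna": 20})
        paths = write_fixture_bundle(params, tmp_path / "bundle")
        mats, meta, truth = (lambda t: t)(  # regenerate for comparison
            __import__("episub").simulate_cohort(params)
        )
        again = eio.read_matrix(paths["blood_mirna"], "blood_mirna")
        np.testing.assert_allclose(
            again.values.to_numpy(), mats["blood_mirna"].values.to_numpy(), rtol=1e-9
        )
        meta_again = eio.read_metadata(paths["metadata"])
        assert list(meta_again.table.index) == list(meta.table.index)
        content1 = {k: open(p, "rb").read() for k, p in paths.items()}
        paths2 = write_fixture_bundle(params, tmp_path / "bundle")
        content2 = {k: open(p, "rb").read() for k, p in paths2.items()}
        assert content1 == content2

    def test_truth_json_member_count(self, tmp_path):
        params = SimParams(seed=1)
        paths = write_fixture_bundle(params, tmp_path / "b")
        truth = json.load(open(paths["truth"]))
        assert len(truth["subtype_members"]) == round(0.575 * 40)
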