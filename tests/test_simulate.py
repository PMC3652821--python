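import numpy as np
import pandas as pd
import pytest

from endosig.preprocess import collapse_probes
from endosig.simulate import (
    SimulationConfig,
    generate_multicondition,
    generate_multistudy,
    generate_pathway_db,
)

TABLE4_GROUPS = [("air", 6), ("lps", 5), ("smoke", 6), ("lps_smoke", 5)]


class TestMultistudy:
    def test_reproducible_given_seed(self):
        cfg = SimulationConfig(genes_master=300, signature_size=20,
                               private_de_per_study=20, n_per_group=4, seed=5)
        studies_a, truth_a = generate_multistudy(cfg)
        studies_b, truth_b = generate_multistudy(cfg)
        for sa, sb in zip(studies_a, studies_b):
            pd.testing.assert_frame_equal(sa.matrix, sb.matrix)
            assert sa.probe_map == sb.probe_map
        assert truth_a.signature_genes == truth_b.signature_genes

    def test_signature_forced_into_every_universe(self):
        cfg = SimulationConfig(n_studies=3, genes_master=2000, universe_frac=0.7,
                               signature_size=100, seed=7)
        studies, truth = generate_multistudy(cfg)
        universes = [st.gene_universe() for st in studies]
        inter = set.intersection(*universes)
        assert len(inter) >= 100
        assert truth.signature_genes <= inter
        for st, uni in zip(studies, universes):
            assert truth.per_study_universe[st.study_id] == uni

    def test_private_de_disjoint_from_signature_and_each_other(self):
        cfg = SimulationConfig(genes_master=800, signature_size=40,
                               private_de_per_study=60, n_per_group=3, seed=2)
        _, truth = generate_multistudy(cfg)
        seen: set[str] = set()
        for sid, private in truth.per_study_private_de.items():
            assert not (private & truth.signature_genes)
            assert not (private & seen)
            assert private <= truth.per_study_universe[sid]
            seen |= private

    def test_infeasible_signature_raises_named_bound(self):
        cfg = SimulationConfig(genes_master=100, universe_frac=0.5, signature_size=80,
                               private_de_per_study=1)
        with pytest.raises(ValueError, match="universe size"):
            generate_multistudy(cfg)
        cfg2 = SimulationConfig(genes_master=1000, universe_frac=0.4, signature_size=100,
                                n_studies=3, private_de_per_study=1)
        # 100 <= round(0.4*1000)=400 but 100 > 1000*0.4^3 = 64
        with pytest.raises(ValueError, match="expected universe intersection"):
            generate_multistudy(cfg2)

    def test_group_sizes_and_labels_in_metadata_not_sample_ids(self):
        cfg = SimulationConfig(genes_master=300, signature_size=20,
                               private_de_per_study=10, n_per_group=(8, 6, 4), seed=1)
        studies, _ = generate_multistudy(cfg)
        for st, n in zip(studies, (8, 6, 4)):
            labels = st.group_labels()
            assert labels.count("control") == n and labels.count("exposed") == n
            assert not any("control" in s or "exposed" in s for s in st.samples)

    def test_planted_mean_shift_matches_effect_size(self):
        cfg = SimulationConfig(n_studies=1, genes_master=600, universe_frac=1.0,
                               signature_size=150, private_de_per_study=0,
                               n_per_group=8, effect_size=3.0, noise_sd=0.5, seed=9)
        studies, truth = generate_multistudy(cfg)
        gm = collapse_probes(studies[0])
        labels = np.array([studies[0].groups[s] for s in gm.columns])
        diff = (gm.loc[:, labels == "exposed"].mean(axis=1)
                - gm.loc[:, labels == "control"].mean(axis=1))
        sig_diff = np.abs(diff.loc[sorted(truth.signature_genes)].to_numpy())
        planted = cfg.effect_size * cfg.noise_sd
        se = sig_diff.std(ddof=1) / np.sqrt(sig_diff.size)
        assert abs(sig_diff.mean() - planted) < 3 * se


class TestMulticondition:
    def test_table4_design_emits_22_samples(self):
        st = generate_multicondition(["a", "b", "c", "d", "e"], TABLE4_GROUPS,
                                     {"lps": 1.0}, seed=0)
        assert len(st.samples) == 22
        labels = st.group_labels()
        assert {g: labels.count(g) for g in set(labels)} == dict(TABLE4_GROUPS)

    def test_duplicate_group_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            generate_multicondition(["a"] * 5, [("air", 3), ("air", 3)], {}, seed=0)

    def test_zero_effects_leave_no_group_structure(self):
        out: dict = {}
        st = generate_multicondition([f"g{i}" for i in range(10)], TABLE4_GROUPS,
                                     {}, seed=4, effects_out=out)
        assert all(v == 0.0 for shifts in out.values() for v in shifts.values())
        labels = np.array(st.group_labels())
        X = st.matrix.to_numpy()
        gaps = [abs(X[:, labels == "lps"].mean() - X[:, labels == "air"].mean())]
        assert max(gaps) < 0.5  # noise-scale only

    def test_fixed_sign_mode_plants_uniform_shift(self):
        out: dict = {}
        generate_multicondition(["g1", "g2"], [("air", 3), ("lps", 3)],
                                {"lps": 2.0}, seed=1, sign_mode="fixed", effects_out=out)
        assert out["g1"]["lps"] == 2.0 and out["g2"]["lps"] == 2.0

    def test_random_signs_make_equal_magnitudes_distinct(self):
        out: dict = {}
        generate_multicondition([f"g{i}" for i in range(50)], TABLE4_GROUPS,
                                {"lps": 2.0, "lps_smoke": 2.0}, seed=1, effects_out=out)
        lps = np.array([out[g]["lps"] for g in out])
        mix = np.array([out[g]["lps_smoke"] for g in out])
        assert (lps != mix).any()
        assert set(np.abs(lps)) == {2.0}


class TestPathwayDB:
    def test_forced_sizes_and_empty_collection(self):
        uni = {f"g{i}" for i in range(40)}
        db = generate_pathway_db(uni, n_pathways=5, size_range=(10, 10), seed=0)
        assert len(db) == 5 and all(len(v) == 10 for v in db.values())
        assert generate_pathway_db(uni, 0, (5, 5), seed=0) == {}

    def test_planted_overlap_fraction_exact(self):
        uni = {f"g{i}" for i in range(100)}
        source = {f"g{i}" for i in range(20)}
        db = generate_pathway_db(uni, 0, (5, 5),
                                 planted=[("P", source, 0.75)], seed=3)
        members = set(db["P"])
        assert len(members) == len(source)
        assert len(members & source) == 15

    def test_invalid_overlap_frac_rejected(self):
        uni = {f"g{i}" for i in range(30)}
        with pytest.raises(ValueError, match="overlap_frac"):
            generate_pathway_db(uni, 0, (5, 5), planted=[("P", {"g1"}, 1.5)], seed=0)

    def test_reproducible_given_seed(self):
        uni = {f"g{i}" for i in range(60)}
        assert generate_pathway_db(uni, 8, (5, 15), seed=7) == generate_pathway_db(
            uni, 8, (5, 15), seed=7
        )
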