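"""Screen statistics: percent change, Blom scores, clustering, hit rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from nichescreen import (
    EffectModel,
    FieldSpec,
    HitRules,
    blom_normalize,
    cluster_compounds,
    cut_clusters,
    generate_plate,
    normalize_matrix,
    percent_change,
    select_hits,
    summarize_screen,
    tree_to_newick,
)
from nichescreen.screen import PARAMETERS, DegenerateControlError, hits_to_frame
from oracles import brute_centroid_linkage


class TestPercentChange:
    @pytest.mark.parametrize("drug,control,expected", [
        (100.0, 100.0, 0.0),
        (50.0, 100.0, -0.5),
        (120.0, 80.0, 0.5),
    ])
    def test_printed_formula(self, drug, control, expected):
        assert percent_change(drug, control) == pytest.approx(expected)

    def test_zero_control_names_parameter(self):
        with pytest.raises(DegenerateControlError, match="total_cscs"):
            percent_change(5.0, 0.0, parameter="total_cscs")

    @given(st.floats(0.1, 100), st.floats(0.1, 100), st.floats(0.01, 50))
    def test_scale_invariance(self, drug, control, k):
        assert percent_change(k * drug, k * control) == pytest.approx(
            percent_change(drug, control), rel=1e-9
        )


class TestBlom:
    def test_single_observation_scores_zero(self):
        assert blom_normalize([3.7]) == pytest.approx([0.0])

    def test_three_distinct_values_closed_form(self):
        got = np.sort(blom_normalize([10.0, -2.0, 5.0]))
        want = norm.ppf((np.array([1, 2, 3]) - 0.375) / 3.25)
        assert np.allclose(got, want, atol=1e-12)
        assert got[1] == pytest.approx(0.0, abs=1e-12)
        assert got[2] == pytest.approx(0.8694, abs=5e-5)

    def test_ties_use_average_rank(self):
        # two tied minima among n=4: both get the score at rank 1.5
        got = blom_normalize([1.0, 1.0, 2.0, 3.0])
        want = norm.ppf((1.5 - 0.375) / 4.25)
        assert got[0] == got[1] == pytest.approx(want, abs=1e-12)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            blom_normalize([1.0, np.nan])

    @given(st.lists(st.integers(-10**6, 10**6), min_size=2, max_size=30, unique=True))
    def test_strictly_monotone_and_rank_only(self, values):
        x = np.asarray(values, dtype=float)
        s = blom_normalize(x)
        order = np.argsort(x)
        assert np.all(np.diff(s[order]) > 0)
        # any strictly increasing transform leaves the scores unchanged
        assert np.allclose(blom_normalize(np.exp(x / 1e6)), s, atol=1e-12)


class TestClustering:
    def test_identical_rows_merge_first_at_height_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [5.0, 5.0], [1.0, 2.0]],
                         index=["a", "b", "c"])
        tree = cluster_compounds(m)
        assert {int(tree.linkage[0, 0]), int(tree.linkage[0, 1])} == {0, 2}
        assert tree.linkage[0, 2] == 0.0

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 9))
            X = rng.normal(size=(n, 6))
            m = pd.DataFrame(X, index=[f"c{i}" for i in range(n)])
            tree = cluster_compounds(m)
            for row, (pair, height, size) in zip(tree.linkage, brute_centroid_linkage(X)):
                assert {int(row[0]), int(row[1])} == pair
                assert row[2] == pytest.approx(height, abs=1e-9)
                assert int(row[3]) == size

    def test_permutation_invariance_up_to_relabeling(self, rng):
        X = rng.normal(size=(7, 6))
        m = pd.DataFrame(X, index=[f"c{i}" for i in range(7)])
        perm = rng.permutation(7)
        mp = m.iloc[perm]
        t1, t2 = cluster_compounds(m), cluster_compounds(mp)
        # same multiset of merge heights and same leaf partition per merge
        assert np.allclose(np.sort(t1.heights), np.sort(t2.heights))
        a1 = cut_clusters(t1, n_clusters=3)
        a2 = cut_clusters(t2, n_clusters=3).reindex(a1.index)
        # partitions agree up to label renaming
        mapping = {}
        for lbl1, lbl2 in zip(a1, a2):
            assert mapping.setdefault(lbl1, lbl2) == lbl2

    def test_missing_values_rejected(self):
        m = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]], index=["a", "b"])
        with pytest.raises(ValueError, match="missing"):
            cluster_compounds(m)

    def test_newick_roundtrip_parses(self):
        m = pd.DataFrame(np.eye(4), index=list("abcd"))
        nwk = tree_to_newick(cluster_compounds(m))
        assert nwk.endswith(";") and nwk.count("(") == 3
        import io as _io

        from Bio import Phylo

        tree = Phylo.read(_io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == list("abcd")


def _mk_pct(**cols):
    base = {p: [0.0] for p in PARAMETERS}
    base.update({k: [v] for k, v in cols.items()})
    return pd.DataFrame(base, index=["x"])


class TestHitRules:
    """The selection rules on cluster-mean percent changes."""

    def _classify(self, pct_row, rules=None):
        from nichescreen.screen import _classify

        return _classify(pct_row.iloc[0], rules or HitRules())[0]

    def test_pan_cytotoxic_cluster_excluded(self):
        row = _mk_pct(total_cafs=-0.40, total_cscs=-0.85,
                      colony_count=-0.85, total_colony_cells=-0.85)
        assert self._classify(row) == "excluded"

    def test_anti_csc_cluster_selected(self):
        row = _mk_pct(total_cscs=-0.70, colony_count=-0.50,
                      total_colony_cells=-0.60, colony_density=-0.30,
                      total_cafs=-0.10)
        assert self._classify(row) == "anti_CSC"

    def test_anti_csc_requires_caf_sparing(self):
        row = _mk_pct(total_cscs=-0.70, colony_count=-0.50,
                      total_colony_cells=-0.60, colony_density=-0.30,
                      total_cafs=-0.40)
        assert self._classify(row) == "anti_CAF"  # CAF loss 40%: not CSC-selective

    def test_all_zero_cluster_neutral(self):
        assert self._classify(_mk_pct()) == "neutral"

    def test_custom_minimum_effect_threshold(self):
        row = _mk_pct(total_cscs=-0.18)
        assert self._classify(row) == "neutral"
        assert self._classify(row, HitRules(min_effect=0.10)) == "anti_CSC"


class TestScreenPipeline:
    def test_control_identical_profiles_have_zero_change(self):
        phen = pd.DataFrame({
            "well": ["w1", "w2", "w3"],
            **{p: [10.0, 10.0, 10.0] for p in PARAMETERS},
        })
        ann = pd.DataFrame({
            "well": ["w1", "w2", "w3"],
            "compound": ["control", "a", "a"],
            "replicate": [1, 1, 2],
            "role": ["control", "treated", "treated"],
        })
        pct = summarize_screen(phen, ann)
        assert np.allclose(pct.loc["a"].to_numpy(dtype=float), 0.0)

    def test_no_controls_rejected(self):
        phen = pd.DataFrame({"well": ["w1"], **{p: [1.0] for p in PARAMETERS}})
        ann = pd.DataFrame({"well": ["w1"], "compound": ["a"],
                            "replicate": [1], "role": ["treated"]})
        with pytest.raises(ValueError, match="control"):
            summarize_screen(phen, ann)

    def test_planted_effects_recovered_end_to_end(self):
        base = FieldSpec(width_px=300, height_px=300, n_caf=150, n_cancer=60,
                         n_colonies=1, colony_radius_um=140.0,
                         noise_sd=(0, 0, 0), seed=13)
        effects = {f"null_{i}": EffectModel() for i in range(12)}
        effects["anticsc"] = EffectModel(csc_fraction=0.2)
        effects["anticaf"] = EffectModel(caf_survival=0.3)
        plate = generate_plate(effects, base, n_control_wells=3)
        pct = summarize_screen(plate.phenotypes, plate.annotation)
        tree = cluster_compounds(normalize_matrix(pct))
        hits = select_hits(tree, pct)
        cls = {c: h.classification for h in hits for c in h.compounds}
        assert cls["anticsc"] == "anti_CSC"
        assert cls["anticaf"] == "anti_CAF"
        nulls = [cls[f"null_{i}"] for i in range(12)]
        assert nulls.count("neutral") >= 0.9 * len(nulls)

    def test_hit_report_lists_triggering_rule(self):
        m = pd.concat(
            [_mk_pct(total_cafs=-0.5).rename(index={"x": "hit"})]
            + [_mk_pct().rename(index={"x": f"n{i}"}) for i in range(5)]
        )
        tree = cluster_compounds(normalize_matrix(m))
        df = hits_to_frame(select_hits(tree, m))
        rule = df.set_index("compound").loc["hit", "rule"]
        assert df.set_index("compound").loc["hit", "classification"] == "anti_CAF"
        assert "CAF" in rule
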