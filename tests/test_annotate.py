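import numpy as np
import pandas as pd
import pytest

from repeatscape import annotate, preprocess
from repeatscape.annotate import ClusterAnnotation, UNANNOTATED, UNCLUSTERED
from repeatscape.cluster_engine import ClusterSet
from repeatscape.seqio import RepeatLibraryEntry, SequenceRecord

import oracles
from conftest import random_seq


def _library(rng, n=2):
    names = ["RLG_x", "RLC_y", "RIL_z"][:n]
    sfs = ["Gypsy", "Copia", "L1"][:n]
    return [
        RepeatLibraryEntry(nm, sf, nm, "Class I LTR", random_seq(rng, 1000))
        for nm, sf in zip(names, sfs)
    ]


class TestAnnotateCluster:
    def test_all_reads_from_one_family(self, rng):
        lib = _library(rng)
        reads = [
            SequenceRecord(f"r{i}", lib[0].sequence[j:j + 100])
            for i, j in enumerate(range(0, 1000, 100))
        ]
        ann = annotate.annotate_cluster("CL0", reads, lib)
        assert ann.family == "RLG_x"
        assert ann.superfamily == "Gypsy"
        assert ann.hit_fraction == 1.0

    def test_plurality_rule(self, rng):
        lib = _library(rng)
        reads = [SequenceRecord(f"a{i}", lib[0].sequence[i * 50:i * 50 + 100])
                 for i in range(6)]
        reads += [SequenceRecord(f"b{i}", lib[1].sequence[i * 50:i * 50 + 100])
                  for i in range(4)]
        ann = annotate.annotate_cluster("CL0", reads, lib)
        assert ann.family == "RLG_x"
        assert ann.hit_fraction == pytest.approx(0.6)
        assert ann.vote_breakdown == {"RLC_y": 4, "RLG_x": 6}

    def test_random_reads_unannotated(self, rng):
        lib = _library(rng)
        reads = [SequenceRecord(f"r{i}", random_seq(rng, 100)) for i in range(5)]
        ann = annotate.annotate_cluster("CL0", reads, lib)
        assert ann.family == UNANNOTATED
        assert ann.hit_fraction == 0.0
        # oracle: no read has a qualifying alignment to any library entry
        for r in reads[:2]:
            for entry in lib:
                assert oracles.sw_score_strands(r.sequence, entry.sequence) < 50


def _comp_inputs(sizes, hit_fractions, families, total):
    clusters = {}
    anns = {}
    used = 0
    for i, (size, hf, fam) in enumerate(zip(sizes, hit_fractions, families)):
        members = [f"c{i}_{j}" for j in range(size)]
        clusters[f"CL{i}"] = members
        used += size
        anns[f"CL{i}"] = ClusterAnnotation(
            f"CL{i}", fam, "Gypsy" if fam != UNANNOTATED else UNANNOTATED,
            "Class I LTR" if fam != UNANNOTATED else UNANNOTATED, hf, {})
    cs = ClusterSet(clusters=clusters, modularity=0.0,
                    unclustered=[f"u{j}" for j in range(total - used)])
    return cs, anns


class TestComposition:
    def test_single_cluster_full_support(self):
        cs, anns = _comp_inputs([200], [1.0], ["X"], total=1000)
        comp = annotate.composition(cs, anns, 1000)
        assert comp.loc["X", "fraction"] == pytest.approx(0.20)

    def test_partial_support_splits_to_unannotated(self):
        cs, anns = _comp_inputs([200], [0.5], ["X"], total=1000)
        comp = annotate.composition(cs, anns, 1000)
        assert comp.loc["X", "fraction"] == pytest.approx(0.10)
        assert comp.loc[UNANNOTATED, "fraction"] == pytest.approx(0.10)

    def test_additivity_across_clusters(self):
        cs, anns = _comp_inputs([100, 50], [1.0, 1.0], ["Y", "Y"], total=1000)
        comp = annotate.composition(cs, anns, 1000)
        assert comp.loc["Y", "fraction"] == pytest.approx(0.15)

    def test_fractions_sum_to_one(self, rng):
        sizes = list(rng.integers(10, 80, size=5))
        hfs = list(rng.uniform(0, 1, size=5))
        fams = ["A", "B", "A", UNANNOTATED, "C"]
        cs, anns = _comp_inputs(sizes, hfs, fams, total=1000)
        comp = annotate.composition(cs, anns, 1000)
        assert comp["fraction"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_cluster_relabeling(self):
        cs, anns = _comp_inputs([100, 50], [0.8, 0.6], ["A", "B"], total=500)
        comp1 = annotate.composition(cs, anns, 500)
        relabeled = ClusterSet(
            clusters={"ZZ" + k: v for k, v in cs.clusters.items()},
            modularity=0.0, unclustered=cs.unclustered)
        anns2 = {
            "ZZ" + k: ClusterAnnotation("ZZ" + k, a.family, a.superfamily,
                                        a.te_class, a.hit_fraction, {})
            for k, a in anns.items()
        }
        comp2 = annotate.composition(relabeled, anns2, 500)
        pd.testing.assert_frame_equal(comp1, comp2)

    def test_inconsistent_totals_rejected(self):
        cs, anns = _comp_inputs([200], [1.0], ["X"], total=1000)
        with pytest.raises(ValueError, match="total"):
            annotate.composition(cs, anns, 900)


@pytest.fixture(scope="module")
def planted_pool(rng):
    from repeatscape import synthetic

    spec = synthetic.GenomeSpec(
        genome_length=60_000,
        families=(synthetic.FamilySpec("RLG_x", "Gypsy", 800, 15, 0.01),
                  synthetic.FamilySpec("RLC_y", "Copia", 800, 8, 0.01)),
        seed=4,
    )
    genome, ledger, lib = synthetic.make_genome(spec)
    pairs, _ = synthetic.simulate_reads(genome, coverage=2.0, seed=4)
    return pairs, lib, ledger


class TestReplicateComposition:
    def test_identical_seeds_give_zero_sd(self, planted_pool):
        pairs, lib, _ = planted_pool
        table = annotate.replicate_composition(
            pairs, lib, k=200, replicates=3, seeds=[7, 7, 7]
        )
        assert (table["sd"] == 0).all()

    def test_distinct_seeds_give_finite_sd(self, planted_pool):
        pairs, lib, _ = planted_pool
        table = annotate.replicate_composition(
            pairs, lib, k=200, replicates=3, seeds=[1, 2, 3]
        )
        assert np.isfinite(table["sd"]).all()
        repcols = [c for c in table.columns if c.startswith("rep")]
        assert len(repcols) == 3
        np.testing.assert_allclose(
            table["mean"], table[repcols].mean(axis=1), atol=1e-15
        )

    def test_single_replicate_sd_not_available(self, planted_pool):
        pairs, lib, _ = planted_pool
        table = annotate.replicate_composition(
            pairs, lib, k=200, replicates=1, seeds=[5]
        )
        assert table["sd"].isna().all()

    def test_planted_fraction_recovered(self, planted_pool):
        pairs, lib, ledger = planted_pool
        table = annotate.replicate_composition(
            pairs, lib, k=len(pairs), replicates=2, seeds=[1, 2]
        )
        for fam, truth in ledger.family_fractions.items():
            assert table.loc[fam, "mean"] == pytest.approx(truth, abs=0.05)


class TestCoverageTitration:
    def test_cv_hand_arithmetic(self, monkeypatch, planted_pool):
        pairs, lib, _ = planted_pool
        reps = iter([0.1, 0.2, 0.3] * 10)

        def fake_run(pairs_, lib_, k, seed, **kw):
            f = next(reps)
            return pd.DataFrame(
                {"superfamily": ["Gypsy"], "te_class": ["Class I LTR"],
                 "fraction": [f]}, index=pd.Index(["famA"], name="family"))

        monkeypatch.setattr(annotate, "run_replicate", fake_run)
        out = annotate.coverage_titration(pairs, lib, [0.5], replicates=3)
        row = out[out["family"] == "famA"].iloc[0]
        assert row["cv"] == pytest.approx(0.5)  # sd 0.1 / mean 0.2
        summary = out[out["family"] == "__summary__"].iloc[0]
        assert summary["cv"] == pytest.approx(0.5)

    def test_identical_replicates_cv_zero(self, monkeypatch, planted_pool):
        pairs, lib, _ = planted_pool

        def fake_run(pairs_, lib_, k, seed, **kw):
            return pd.DataFrame(
                {"superfamily": ["Gypsy"], "te_class": ["Class I LTR"],
                 "fraction": [0.25]}, index=pd.Index(["famA"], name="family"))

        monkeypatch.setattr(annotate, "run_replicate", fake_run)
        out = annotate.coverage_titration(pairs, lib, [0.5], replicates=3)
        assert out[out["family"] == "famA"]["cv"].iloc[0] == pytest.approx(0.0)

    def test_zero_mean_family_excluded(self, monkeypatch, planted_pool):
        pairs, lib, _ = planted_pool

        def fake_run(pairs_, lib_, k, seed, **kw):
            return pd.DataFrame(
                {"superfamily": ["Gypsy", UNANNOTATED],
                 "te_class": ["Class I LTR", UNANNOTATED],
                 "fraction": [0.0, 1.0]},
                index=pd.Index(["famA", UNANNOTATED], name="family"))

        monkeypatch.setattr(annotate, "run_replicate", fake_run)
        out = annotate.coverage_titration(pairs, lib, [0.5], replicates=3)
        assert "famA" not in set(out["family"])
        assert np.isnan(out[out["family"] == "__summary__"]["cv"].iloc[0])
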