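import math

import numpy as np
import pandas as pd
import pytest

from barseq_noise import noise_decomposition as nd
from barseq_noise import synthetic_data as sd
from barseq_noise.demux import BarcodeCountTable


class TestBoxStats:
    def test_five_point_example(self):
        box = nd.summarize_box([1, 2, 3, 4, 5])
        assert box.median == 3
        assert box.lower_hinge == 2 and box.upper_hinge == 4
        assert box.iqr == 2
        assert box.notch_halfwidth == pytest.approx(1.58 * 2 / math.sqrt(5))
        assert box.whisker_low == 1 and box.whisker_high == 5

    def test_single_value(self):
        box = nd.summarize_box([7.0])
        assert box.median == box.lower_hinge == box.upper_hinge == 7.0
        assert box.iqr == 0 and box.notch_halfwidth == 0

    def test_outlier_excluded_from_whisker(self):
        box = nd.summarize_box([0, 0, 0, 100])
        # brute-force whisker rule: max value within Q3 + 1.5 IQR
        vals = np.array([0, 0, 0, 100])
        q1, q3 = np.percentile(vals, [25, 75])
        fence = q3 + 1.5 * (q3 - q1)
        assert box.whisker_high == vals[vals <= fence].max() == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            nd.summarize_box([])


class TestReplicateR2:
    def _table(self, counts, sample="s1"):
        df = pd.DataFrame({"sample_id": sample,
                           "barcode_id": list(counts.keys()),
                           "count": list(counts.values())})
        return BarcodeCountTable(df)

    def test_identical_tables_give_unity(self):
        counts = {f"b{i}": 100 + i for i in range(20)}
        cmp = nd.replicate_r2(self._table(counts), self._table(counts))
        assert cmp.r_squared == pytest.approx(1.0)

    def test_too_few_barcodes_rejected(self):
        with pytest.raises(ValueError, match="3"):
            nd.replicate_r2(self._table({"a": 1}), self._table({"a": 2}))

    def test_independent_vectors_have_near_zero_r2(self):
        rng = np.random.default_rng(0)
        passed = 0
        for _ in range(20):
            a = pd.Series(rng.multinomial(50_000, rng.dirichlet(np.ones(500))),
                          index=[f"b{i}" for i in range(500)])
            b = pd.Series(rng.multinomial(50_000, rng.dirichlet(np.ones(500))),
                          index=[f"b{i}" for i in range(500)])
            cmp = nd.replicate_r2(a, b)
            passed += cmp.r_squared < 0.05
        assert passed >= 19

    def test_split_pairs_at_high_coverage_reproduce(self):
        # technical replicates by symmetric splitting at > 600 reads/barcode
        rng = np.random.default_rng(1)
        high = 0
        n_pairs = 20
        for seed in range(n_pairs):
            counts = rng.multinomial(800_000, rng.dirichlet(np.full(500, 20.0)))
            a, b = sd.split_sample(counts, 2, seed=seed)
            sa = pd.Series(a, index=[f"b{i}" for i in range(500)])
            sb = pd.Series(b, index=[f"b{i}" for i in range(500)])
            cmp = nd.replicate_r2(sa, sb)
            high += cmp.r_squared > 0.9
        assert high >= 0.95 * n_pairs

    def test_r2_decreases_with_depth(self):
        rng = np.random.default_rng(2)
        p = rng.dirichlet(np.full(500, 20.0))
        means = []
        for depth in (10_000, 1_000, 100):
            vals = []
            for seed in range(15):
                local = np.random.default_rng(seed)
                a = pd.Series(local.multinomial(depth, p),
                              index=[f"b{i}" for i in range(500)])
                b = pd.Series(local.multinomial(depth, p),
                              index=[f"b{i}" for i in range(500)])
                vals.append(nd.replicate_r2(a, b).r_squared)
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


def study_fitness_table(rng=None, sigma_batch=0.0, sigma_rep=0.0, noise=0.0):
    """Fitness table mirroring the study layout: 28 replicates in 9 batches,
    21 IRA1 + 13 GPB2 barcodes everywhere, engineered sets (6 IRA1non,
    8 IRA1mis) only in the first, four-replicate batch."""
    rng = rng or np.random.default_rng(0)
    batches = [4, 4, 3, 3, 3, 3, 3, 3, 2]
    barcodes = (
        [(f"ira1_{i}", "IRA1", 0.7) for i in range(21)]
        + [(f"gpb2_{i}", "GPB2", 0.35) for i in range(13)]
    )
    engineered = (
        [(f"non_{i}", "IRA1non", 0.71) for i in range(6)]
        + [(f"mis_{i}", "IRA1mis", 0.69) for i in range(8)]
    )
    rows = []
    rep = 0
    for b, k in enumerate(batches, start=1):
        delta = rng.normal(0, sigma_batch) if sigma_batch else 0.0
        for _ in range(k):
            rep += 1
            eps = rng.normal(0, sigma_rep) if sigma_rep else 0.0
            members = barcodes + (engineered if b == 1 else [])
            for bc, geno, s in members:
                rows.append({
                    "barcode_id": bc, "replicate_id": f"rep_{rep:02d}",
                    "batch_id": f"batch_{b}",
                    "s_hat": s + delta + eps + (rng.normal(0, noise) if noise else 0.0),
                })
    genotype_map = pd.Series({bc: g for bc, g, _ in barcodes + engineered})
    return pd.DataFrame(rows), genotype_map


class TestVarianceDecomposition:
    def test_equal_values_give_zero_sds(self):
        fitness, gmap = study_fitness_table()
        fitness["s_hat"] = 1.0
        decomp = nd.variance_decomposition(fitness, gmap)
        for df in (decomp.within_experiment, decomp.across_replicate,
                   decomp.across_batch):
            assert (df["sd"] == 0).all()

    def test_study_design_observation_bookkeeping(self):
        # 28 GPB2 + 4 IRA1non + 4 IRA1mis within-experiment observations;
        # 34 barcodes x 9 batches across replicates; 34 across batches
        fitness, gmap = study_fitness_table(noise=0.01)
        decomp = nd.variance_decomposition(
            fitness, gmap,
            within_groups=["GPB2", "IRA1non", "IRA1mis"],
            across_groups=["IRA1", "GPB2"],
        )
        assert decomp.counts() == {
            "within_experiment": 36,
            "across_replicate": 306,
            "across_batch": 34,
        }

    def test_sd_ordering_under_batch_gt_rep_noise(self):
        # sigma_batch > sigma_rep > 0 orders the three category medians
        ordered = 0
        for seed in range(10):
            fitness, gmap = study_fitness_table(
                rng=np.random.default_rng(seed),
                sigma_batch=0.10, sigma_rep=0.03, noise=0.01,
            )
            decomp = nd.variance_decomposition(
                fitness, gmap,
                within_groups=["GPB2", "IRA1non", "IRA1mis"],
                across_groups=["IRA1", "GPB2"],
            )
            m = [decomp.within_experiment["sd"].median(),
                 decomp.across_replicate["sd"].median(),
                 decomp.across_batch["sd"].median()]
            ordered += m[0] < m[1] < m[2]
        assert ordered >= 9

    def test_zero_env_noise_makes_categories_comparable(self):
        fitness, gmap = study_fitness_table(
            rng=np.random.default_rng(3), sigma_batch=0.0, sigma_rep=0.0, noise=0.02,
        )
        # use engineered sets only: identical true fitness within group
        decomp = nd.variance_decomposition(
            fitness, gmap,
            within_groups=["IRA1non", "IRA1mis"],
            across_groups=["IRA1", "GPB2"],
        )
        meds = [decomp.within_experiment["sd"].median(),
                decomp.across_replicate["sd"].median(),
                decomp.across_batch["sd"].median()]
        assert max(meds) / min(meds) < 2.0

    def test_small_groups_skipped_and_logged(self):
        fitness = pd.DataFrame({
            "barcode_id": ["a", "b"], "replicate_id": ["r1", "r1"],
            "batch_id": ["b1", "b1"], "s_hat": [0.1, 0.2],
        })
        gmap = pd.Series({"a": "X", "b": "Y"})
        decomp = nd.variance_decomposition(fitness, gmap)
        assert decomp.within_experiment.empty
        assert decomp.skipped


class TestGenotypeContrast:
    def test_identical_groups_give_zero(self):
        fitness, gmap = study_fitness_table()
        fitness["s_hat"] = 0.5
        diffs, sd_ = nd.genotype_contrast(fitness, gmap, "IRA1", "GPB2")
        assert (diffs["difference"] == 0).all() and sd_ == 0

    def test_two_replicate_arithmetic(self):
        fitness = pd.DataFrame({
            "barcode_id": ["a1", "a2", "b1", "a1", "a2", "b1"],
            "replicate_id": ["r1"] * 3 + ["r2"] * 3,
            "batch_id": "b1",
            "s_hat": [1.0, 1.0, 0.5, 1.0, 1.0, 0.7],
        })
        gmap = pd.Series({"a1": "A", "a2": "A", "b1": "B"})
        diffs, _ = nd.genotype_contrast(fitness, gmap, "A", "B")
        assert diffs["difference"].tolist() == [0.5, pytest.approx(0.3)]

    def test_contrast_cancels_shared_deviates(self):
        # shared batch/replicate shifts move both genotypes together, so the
        # contrast SD falls below the SD of per-genotype replicate medians
        wins = 0
        for seed in range(20):
            fitness, gmap = study_fitness_table(
                rng=np.random.default_rng(100 + seed),
                sigma_batch=0.10, sigma_rep=0.03, noise=0.01,
            )
            _, contrast_sd = nd.genotype_contrast(fitness, gmap, "IRA1", "GPB2")
            fitness["genotype"] = gmap.reindex(fitness.barcode_id).to_numpy()
            med = (fitness[fitness.genotype.isin(["IRA1", "GPB2"])]
                   .groupby(["replicate_id", "genotype"])["s_hat"].median().unstack())
            median_sd = med.std(ddof=1).mean()
            wins += contrast_sd < median_sd
        assert wins >= 19

    def test_contrast_invariant_to_per_replicate_shift(self):
        fitness, gmap = study_fitness_table(rng=np.random.default_rng(4), noise=0.02)
        _, sd_before = nd.genotype_contrast(fitness, gmap, "IRA1", "GPB2")
        shifts = {r: i * 0.37 for i, r in enumerate(fitness["replicate_id"].unique())}
        fitness["s_hat"] = fitness["s_hat"] + fitness["replicate_id"].map(shifts)
        _, sd_after = nd.genotype_contrast(fitness, gmap, "IRA1", "GPB2")
        assert sd_after == pytest.approx(sd_before, abs=1e-12)

    def test_replicate_missing_genotype_excluded(self):
        fitness = pd.DataFrame({
            "barcode_id": ["a1", "b1", "a1"],
            "replicate_id": ["r1", "r1", "r2"],
            "batch_id": "b1", "s_hat": [1.0, 0.5, 1.0],
        })
        gmap = pd.Series({"a1": "A", "b1": "B"})
        diffs, _ = nd.genotype_contrast(fitness, gmap, "A", "B")
        assert diffs["replicate_id"].tolist() == ["r1"]


class TestConditionEffect:
    def _measurements(self, rng, effect, sigma_batch, confounded):
        # confounded: drug only in batch 1, control only in batch 2;
        # balanced: both conditions in every batch
        rows = []
        n_batches = 2 if confounded else 4
        for b in range(1, n_batches + 1):
            delta = rng.normal(0, sigma_batch)
            for cond in ("control", "drug"):
                if confounded and ((cond == "drug") != (b == 1)):
                    continue
                for _ in range(3):
                    mu = effect if cond == "drug" else 0.0
                    rows.append({"condition": cond, "batch_id": f"b{b}",
                                 "s_hat": mu + delta + rng.normal(0, 0.01)})
        return pd.DataFrame(rows)

    def test_balanced_design_recovers_effect(self):
        rng = np.random.default_rng(5)
        m = self._measurements(rng, effect=0.3, sigma_batch=0.0, confounded=False)
        eff = nd.estimate_condition_effect(m)
        assert not eff.confounded
        assert abs(eff.estimate) == pytest.approx(0.3, abs=0.02)

    def test_confounded_design_flagged_and_misleading(self):
        # condition nested in batch with sigma_batch >= effect: the naive SE
        # drastically understates the error in at least half the seeds
        bad = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            m = self._measurements(rng, effect=0.1, sigma_batch=0.15, confounded=True)
            eff = nd.estimate_condition_effect(m)
            assert eff.confounded
            bad += abs(abs(eff.estimate) - 0.1) > 2 * eff.naive_se
        assert bad >= 20

    def test_single_replicate_per_condition_rejected(self):
        m = pd.DataFrame({"condition": ["a", "b"], "batch_id": ["b1", "b2"],
                          "s_hat": [0.1, 0.2]})
        with pytest.raises(ValueError, match="fewer than 2"):
            nd.estimate_condition_effect(m)

    def test_single_condition_rejected(self):
        m = pd.DataFrame({"condition": ["a"] * 4, "batch_id": ["b1"] * 4,
                          "s_hat": [0.1, 0.2, 0.1, 0.3]})
        with pytest.raises(ValueError, match="two conditions"):
            nd.estimate_condition_effect(m)
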