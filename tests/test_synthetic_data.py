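import numpy as np
import pandas as pd
import pytest
from scipy import stats

from barseq_noise import synthetic_data as sd
from barseq_noise.index_design import build_scheme

from conftest import make_readset


def deterministic_design(**kw):
    base = dict(timepoints=(0.0, 1.0, 2.0, 3.0), bottleneck_size=0,
                reads_per_sample=1000, n_replicates=1)
    base.update(kw)
    return sd.CompetitionDesign(**base)


class TestCompetition:
    def test_neutral_pool_has_constant_frequencies(self, two_lineage_pool):
        res = sd.simulate_competition(two_lineage_pool, deterministic_design())
        wide = res.wide("batch_1", "rep_01")
        assert np.allclose(wide.to_numpy(), 0.5)

    def test_mutant_ratio_doubles_per_interval(self):
        # closed form: s = ln 2 doubles the mutant/reference ratio each interval
        pool = [
            sd.LineageSpec("A" * 26, "reference", 0.0, 0.0, 1 - 1e-3),
            sd.LineageSpec("C" * 26, "mutant", np.log(2), 1.0, 1e-3),
        ]
        res = sd.simulate_competition(pool, deterministic_design(timepoints=(0.0, 1.0)))
        wide = res.wide("batch_1", "rep_01")
        ratio = wide.loc["C" * 26] / wide.loc["A" * 26]
        assert ratio[1.0] / ratio[0.0] == pytest.approx(2.0, rel=1e-12)

    def test_bottleneck_mean_matches_deterministic_recursion(self):
        # the multinomial bottleneck is unbiased: the mean trajectory over
        # many seeds follows the deterministic recursion
        pool = [
            sd.LineageSpec("A" * 26, "reference", 0.0, 0.0, 0.6),
            sd.LineageSpec("C" * 26, "mut1", 0.3, 1.0, 0.3),
            sd.LineageSpec("G" * 26, "mut2", -0.2, 1.0, 0.1),
        ]
        det = sd.simulate_competition(pool, deterministic_design())
        expected = det.wide("batch_1", "rep_01")
        n_seeds, bottleneck = 400, 2000
        draws = []
        for seed in range(n_seeds):
            res = sd.simulate_competition(
                pool, deterministic_design(bottleneck_size=bottleneck), seed=seed
            )
            draws.append(res.wide("batch_1", "rep_01").to_numpy())
        draws = np.array(draws)
        mean = draws.mean(axis=0)
        mc_se = draws.std(axis=0, ddof=1) / np.sqrt(n_seeds)
        # skip t0 where both are exact
        assert np.all(np.abs(mean - expected.to_numpy())[:, 1:] <= 3 * mc_se[:, 1:] + 1e-12)

    def test_frequencies_sum_to_one_and_deterministic_seeding(self, small_pool):
        design = sd.CompetitionDesign(timepoints=(0, 1, 2), bottleneck_size=5000,
                                      n_replicates=2, n_batches=2)
        model = sd.BatchEffectModel(0.1, 0.05)
        a = sd.simulate_competition(small_pool, design, model, seed=42)
        b = sd.simulate_competition(small_pool, design, model, seed=42)
        pd.testing.assert_frame_equal(a.frequencies, b.frequencies)
        sums = a.frequencies.groupby(["batch_id", "replicate_id", "timepoint"])["frequency"].sum()
        assert np.allclose(sums, 1.0)

    def test_non_increasing_timepoints_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            sd.CompetitionDesign(timepoints=(0.0, 1.0, 1.0))

    def test_batch_deviates_order_seff_spread(self, small_pool):
        # sigma_batch > sigma_rep: a lineage's s_eff varies more across
        # batches than across replicates within a batch
        design = sd.CompetitionDesign(timepoints=(0, 1), bottleneck_size=0,
                                      n_replicates=6, n_batches=12)
        model = sd.BatchEffectModel(sigma_batch=0.2, sigma_rep=0.02)
        res = sd.simulate_competition(small_pool, design, model, seed=7)
        s = res.s_eff
        mutant = s[s.barcode_id == small_pool[-1].barcode_id]
        within = mutant.groupby("batch_id")["s_eff"].std(ddof=1).mean()
        batch_means = mutant.groupby("batch_id")["s_eff"].mean()
        across = batch_means.std(ddof=1)
        assert across > within

    def test_reference_free_pool_flagged(self):
        pool = [
            sd.LineageSpec("A" * 26, "mut", 0.1, 1.0, 0.5),
            sd.LineageSpec("C" * 26, "mut", -0.1, 1.0, 0.5),
        ]
        res = sd.simulate_competition(pool, deterministic_design())
        assert res.metadata["has_reference"] is False


class TestPool:
    def test_default_pool_invariants(self):
        pool = sd.make_pool(seed=3, include_engineered=True)
        assert len(pool) == 500
        assert sum(l.initial_frequency for l in pool) == pytest.approx(1.0, abs=1e-12)
        assert len({l.barcode_id for l in pool}) == 500
        refs = [l for l in pool if l.genotype_label == "reference"]
        assert all(l.base_fitness == 0 and l.env_sensitivity == 0 for l in refs)
        # engineered sets share one true fitness each
        for label in ("IRA1non", "IRA1mis"):
            vals = {l.base_fitness for l in pool if l.genotype_label == label}
            assert len(vals) == 1

    def test_duplicate_barcodes_rejected(self):
        pool = [
            sd.LineageSpec("A" * 26, "reference", 0.0, 0.0, 0.5),
            sd.LineageSpec("A" * 26, "mut", 0.1, 1.0, 0.5),
        ]
        with pytest.raises(ValueError, match="unique"):
            sd.simulate_competition(pool, deterministic_design())


class TestSplitSample:
    def test_totals_conserved_exactly(self):
        splits = sd.split_sample({"bc1": 10, "bc2": 0}, 2, seed=1)
        assert splits[0]["bc1"] + splits[1]["bc1"] == 10
        assert splits[0]["bc2"] == splits[1]["bc2"] == 0

    def test_all_zero_input(self):
        splits = sd.split_sample(np.zeros(5, dtype=int), 3, seed=1)
        assert all((s == 0).all() for s in splits)

    def test_too_few_splits_rejected(self):
        with pytest.raises(ValueError):
            sd.split_sample({"bc1": 5}, 1)

    def test_split_fractions_within_binomial_envelope(self):
        # 10^6 cells over 500 barcodes: each barcode's share of split 1 is
        # Binomial(n_i, 1/2); check against the 99% envelope
        rng = np.random.default_rng(5)
        counts = rng.multinomial(1_000_000, np.full(500, 1 / 500))
        a, b = sd.split_sample(counts, 2, seed=6)
        z = stats.norm.ppf(0.995)
        inside = np.abs(a - counts / 2) <= z * np.sqrt(counts * 0.25)
        assert inside.mean() >= 0.97


class TestSequencing:
    def test_exact_read_depth_per_sample(self, unique8):
        design = sd.CompetitionDesign(timepoints=(0, 1), reads_per_sample=10_000)
        freqs = {s: pd.Series({"AAAA": 0.6, "CCCC": 0.4}) for s in list(unique8.samples)[:2]}
        reads = sd.simulate_sequencing(freqs, design, unique8, seed=0)
        per_sample = reads.df.groupby("origin_sample").size()
        assert (per_sample == 10_000).all()

    def test_no_duplication_gives_distinct_umis(self, unique8):
        # many more molecules than reads: every read is its own molecule
        design = sd.CompetitionDesign(timepoints=(0, 1), reads_per_sample=50,
                                      pcr_molecules_per_sample=500_000, umi_length=12)
        freqs = {list(unique8.samples)[0]: pd.Series({"AAAA": 0.5, "CCCC": 0.5})}
        reads = sd.simulate_sequencing(freqs, design, unique8, seed=1)
        assert reads.df.umi.nunique() == len(reads.df)

    def test_missing_assignment_rejected(self, unique8):
        design = sd.CompetitionDesign(timepoints=(0, 1))
        with pytest.raises(ValueError, match="missing"):
            sd.simulate_sequencing({"ghost": pd.Series({"AAAA": 1.0})},
                                   design, unique8, assignment={}, seed=0)

    def test_read_frequencies_match_input_multinomially(self, unique8):
        # chi-square goodness of fit of read counts vs input frequencies
        rng = np.random.default_rng(2)
        p = rng.dirichlet(np.full(20, 5.0))
        bcs = [f"bc{i}" for i in range(20)]
        design = sd.CompetitionDesign(timepoints=(0, 1), reads_per_sample=20_000,
                                      pcr_molecules_per_sample=400_000)
        sample = list(unique8.samples)[0]
        passed = 0
        n_runs = 20
        for seed in range(n_runs):
            reads = sd.simulate_sequencing({sample: pd.Series(p, index=bcs)},
                                           design, unique8, seed=seed)
            obs = reads.df.barcode_id.value_counts().reindex(bcs, fill_value=0)
            _, pval = stats.chisquare(obs, f_exp=p * 20_000)
            passed += pval > 0.001
        assert passed >= n_runs - 1


class TestMisassignment:
    def test_zero_rates_identity(self, unique8):
        reads = make_readset(unique8, reads_per_sample=200)
        out = sd.apply_misassignment(reads, 0.0, 0.0, seed=0)
        pd.testing.assert_frame_equal(out.df, reads.df)
        assert (out.df.event == "none").all()

    def test_breakpoint_middle_fraction_matches_geometry(self, unique8):
        # uniform breakpoints over 40 + 167 + 40 bp: middle fraction 167/247
        reads = make_readset(unique8, reads_per_sample=12_500)  # 1e5 reads
        out = sd.apply_misassignment(reads, 1.0, 0.0, seed=3)
        assert (out.df.event == "template_switch").all()
        p_mid = 167 / 247
        frac = (out.df.breakpoint_region == "middle").mean()
        mc_se = np.sqrt(p_mid * (1 - p_mid) / len(out.df))
        assert abs(frac - p_mid) <= 3 * mc_se

    def test_hop_presents_as_single_illumina_mismatch(self, unique8):
        reads = make_readset(unique8, reads_per_sample=2000)
        out = sd.apply_misassignment(reads, 0.0, 1.0, seed=4)
        assert (out.df.event == "index_hop").all()
        visible = out.df[~out.df.hidden]
        orig = visible.origin_sample.map(unique8.samples)
        tuples = list(zip(visible.f_idx, visible.n_idx, visible.r_idx, visible.s_idx))
        mismatches = [
            sum(a != b for a, b in zip(t, o)) for t, o in zip(tuples, orig)
        ]
        assert mismatches and set(mismatches) == {1}
        pos_changed = [
            [i for i, (a, b) in enumerate(zip(t, o)) if a != b][0]
            for t, o in zip(tuples, orig)
        ]
        assert set(pos_changed) <= {1, 3}  # N or S only

    def test_truth_bookkeeping_partitions_events(self, unique8):
        reads = make_readset(unique8, reads_per_sample=1000)
        out = sd.apply_misassignment(reads, 0.2, 0.1, seed=5)
        events = out.df[out.df.event != "none"]
        assert len(events) == events.hidden.sum() + (~events.hidden).sum()
        assert set(sd.TRUTH_COLUMNS).isdisjoint(out.reads().columns)

    def test_empty_readset_with_positive_rate_rejected(self, unique8):
        empty = sd.ReadSet(pd.DataFrame(columns=list(sd.READ_COLUMNS) + list(sd.TRUTH_COLUMNS)),
                           scheme=unique8, assignment=dict(unique8.samples))
        with pytest.raises(ValueError, match="empty"):
            sd.apply_misassignment(empty, 0.5, 0.0)

    def test_rate_bounds_enforced(self, unique8):
        reads = make_readset(unique8, reads_per_sample=10)
        with pytest.raises(ValueError):
            sd.apply_misassignment(reads, 0.8, 0.3)

    def test_misassignment_deterministic_under_seed(self, unique8):
        reads = make_readset(unique8, reads_per_sample=500)
        a = sd.apply_misassignment(reads, 0.3, 0.1, seed=9)
        b = sd.apply_misassignment(reads, 0.3, 0.1, seed=9)
        pd.testing.assert_frame_equal(a.df, b.df)


class TestGeometry:
    def test_barcode_must_fit_in_middle(self):
        with pytest.raises(ValueError, match="middle"):
            sd.AmpliconGeometry(middle_len=20, barcode_length=26)

    def test_default_geometry(self):
        g = sd.AmpliconGeometry()
        assert g.total_len == 247
        assert g.barcode_start == (167 - 26) // 2
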