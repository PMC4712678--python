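import numpy as np
import pytest

from editscan.panel import CS1, CS2, make_sample_sheet, random_panel, revcomp
from editscan.simgen import (
    SimulationConfig,
    draw_sample_levels,
    homopolymer_runs,
    htr2c_cluster_probs,
    simulate_run,
    synthesize_read,
)


def _clean_config(**kw):
    base = dict(sub_rate=0.0, indel_rate=0.0, frac_below_q20=0.0)
    base.update(kw)
    return SimulationConfig(**base)


class TestSampleLevels:
    def test_degenerate_concentration_pins_levels_to_mu(self):
        """kappa → ∞ collapses the between-sample beta to a point mass."""
        panel = random_panel(3, seed=1)
        sheet = make_sample_sheet(4, 4, seed=2)
        cfg = _clean_config(seed=5, mu=0.3, delta=0.0, kappa=1e6)
        truth = draw_sample_levels(panel, sheet, cfg)
        assert np.allclose(truth.levels["true_level"], 0.3, atol=1e-2)

    def test_mu_zero_gives_all_zero_levels(self):
        panel = random_panel(2, seed=1)
        sheet = make_sample_sheet(3, 3, seed=2)
        cfg = _clean_config(seed=5, mu=0.0, delta=0.0)
        truth = draw_sample_levels(panel, sheet, cfg)
        assert (truth.levels["true_level"] == 0.0).all()

    def test_group_means_recover_planted_shift(self):
        """Monte-Carlo: AD 21.8% vs NDC 26.8% group means recovered within
        2 SE of the mean over 100 replicates (the study's effect size)."""
        panel = random_panel(1, seed=1)
        sheet = make_sample_sheet(n_ad=28, n_ndc=20, seed=3)
        ad_ids = {r.sample_id for r in sheet if r.group == "AD"}
        mus_ad, mus_ndc = [], []
        for rep in range(100):
            cfg = _clean_config(seed=rep, mu=0.268, delta=-0.05, kappa=200)
            levels = draw_sample_levels(panel, sheet, cfg).levels
            is_ad = levels["sample_id"].isin(ad_ids)
            mus_ad.append(levels[is_ad]["true_level"].mean())
            mus_ndc.append(levels[~is_ad]["true_level"].mean())
        # per-replicate SE of a group mean ~ sd/sqrt(n); mean over 100 reps
        # shrinks it by another factor 10
        se_ad = np.std(mus_ad, ddof=1) / 10
        se_ndc = np.std(mus_ndc, ddof=1) / 10
        assert abs(np.mean(mus_ad) - 0.218) < 2 * se_ad + 1e-3
        assert abs(np.mean(mus_ndc) - 0.268) < 2 * se_ndc + 1e-3

    def test_invalid_mu_rejected(self):
        panel = random_panel(1, seed=1)
        sheet = make_sample_sheet(2, 2, seed=3)
        cfg = _clean_config(mu=1.3)
        with pytest.raises(ValueError, match="outside"):
            draw_sample_levels(panel, sheet, cfg)


class TestSynthesizeRead:
    def test_error_free_read_contains_insert_verbatim(self, rng):
        panel = random_panel(1, seed=4)
        amp = next(iter(panel.amplicons.values()))
        cfg = _clean_config()
        state = {sid: False for sid in amp.site_offsets}
        seq, qual = synthesize_read(amp, "ACGTACGTAC", state, cfg, rng)
        assert seq == "ACGTACGTAC" + CS1 + amp.insert + revcomp(CS2)
        assert len(seq) == len(qual)

    def test_edited_sites_read_g(self, rng):
        panel = random_panel(1, sites_per_amplicon=1, seed=4)
        amp = next(iter(panel.amplicons.values()))
        cfg = _clean_config()
        state = {sid: True for sid in amp.site_offsets}
        seq, _ = synthesize_read(amp, "ACGTACGTAC", state, cfg, rng)
        prefix = 10 + len(CS1)
        for sid, off in amp.site_offsets.items():
            assert seq[prefix + off] == "G"
            assert amp.insert[off] == "A"

    def test_indel_rate_matches_expectation(self, rng):
        """Fraction of length-altered reads matches a direct simulation of
        the per-homopolymer-run indel model."""
        panel = random_panel(1, seed=4)
        amp = next(iter(panel.amplicons.values()))
        cfg = _clean_config(indel_rate=0.01)
        state = {sid: False for sid in amp.site_offsets}
        construct_len = 10 + len(CS1) + len(amp.insert) + len(CS2)
        n_runs = len(homopolymer_runs(
            "ACGTACGTAC" + CS1 + amp.insert + revcomp(CS2)))
        n = 10_000
        changed = 0
        for _ in range(n):
            seq, _ = synthesize_read(amp, "ACGTACGTAC", state, cfg, rng)
            if len(seq) != construct_len:
                changed += 1
        # oracle: P(change) from binomial event counts with +/-1 cancellation
        orng = np.random.default_rng(999)
        events = orng.binomial(n_runs, 0.01, size=200_000)
        signs = np.array([
            np.abs(orng.choice([-1, 1], size=k).sum()) > 0 if k else False
            for k in events
        ])
        p_expect = signs.mean()
        se = np.sqrt(p_expect * (1 - p_expect) / n)
        assert abs(changed / n - p_expect) < 4 * se

    def test_unknown_site_in_state_rejected(self, rng):
        panel = random_panel(1, seed=4)
        amp = next(iter(panel.amplicons.values()))
        with pytest.raises(ValueError, match="unregistered"):
            synthesize_read(amp, "ACGTACGTAC", {"nope": True},
                            _clean_config(), rng)


class TestSimulateRun:
    def test_read_count_conservation(self, tmp_path):
        panel = random_panel(2, seed=6)
        sheet = make_sample_sheet(1, 1, seed=6)
        cfg = _clean_config(seed=1, reads_per_cell=100)
        _, report = simulate_run(panel, sheet, cfg, tmp_path / "r.fastq")
        assert report.n_cells == 4
        assert report.n_reads == 400
        n_records = sum(
            1 for line in open(tmp_path / "r.fastq") if line.startswith("@sim")
        )
        assert n_records == 400

    def test_same_seed_byte_identical(self, tmp_path):
        panel = random_panel(2, seed=6)
        sheet = make_sample_sheet(2, 2, seed=6)
        cfg = SimulationConfig(seed=42, reads_per_cell=30)
        simulate_run(panel, sheet, cfg, tmp_path / "a.fastq")
        simulate_run(panel, sheet, cfg, tmp_path / "b.fastq")
        assert (tmp_path / "a.fastq").read_bytes() == (
            tmp_path / "b.fastq"
        ).read_bytes()

    def test_independent_marginals_match_levels(self, tmp_path):
        """With independent per-site editing, per-read edit frequencies over
        10^4 reads match the planted level within 3 binomial SD."""
        panel = random_panel(1, seed=8)
        sheet = make_sample_sheet(1, 0, seed=8)
        cfg = _clean_config(seed=9, reads_per_cell=10_000, kappa=1e6, mu=0.3)
        truth, _ = simulate_run(panel, sheet, cfg, tmp_path / "m.fastq")
        (site_id,) = panel.sites
        amp = next(iter(panel.amplicons.values()))
        off = 10 + len(CS1) + amp.site_offsets[site_id]
        n_g = n_tot = 0
        with open(tmp_path / "m.fastq") as fh:
            for i, line in enumerate(fh):
                if i % 4 == 1:
                    n_tot += 1
                    n_g += line[off] == "G"
        level = truth.levels["true_level"].iloc[0]
        sd = np.sqrt(level * (1 - level) / n_tot)
        assert abs(n_g / n_tot - level) < 3 * sd

    def test_cluster_joint_model_marginals(self, tmp_path):
        """Cluster-state truth marginals equal the per-site truth levels."""
        from editscan.panel import example_panel

        panel, _ = example_panel()
        sheet = make_sample_sheet(2, 2, seed=10)
        cfg = _clean_config(
            seed=11, cluster_probs={"HTR2C_ABCD": htr2c_cluster_probs()},
            cluster_kappa=0.0,
        )
        truth = draw_sample_levels(panel, sheet, cfg)
        cl = panel.clusters["HTR2C_ABCD"]
        states = truth.cluster_states
        for r in sheet:
            sub = states[states["sample_id"] == r.sample_id]
            assert np.isclose(sub["probability"].sum(), 1.0)
            for idx, sid in enumerate(cl.site_ids):
                marginal = sub[sub["state"].str[idx] == "1"]["probability"].sum()
                lvl = truth.levels.query(
                    "sample_id == @r.sample_id and site_id == @sid"
                )["true_level"].iloc[0]
                assert np.isclose(marginal, lvl)
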