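import itertools

import numpy as np
import pandas as pd
import pytest

from editscan.aligncount import AlignedRead
from editscan.isoform import (
    CodonModel,
    compare_abundance,
    enumerate_variants,
    htr2c_codon_model,
    phase_read,
    single_codon_model,
    variant_abundance,
)
from editscan.panel import SiteCluster

from oracles import anova_two_way_balanced

CLUSTER = SiteCluster("HTR2C_ABCD",
                      ("HTR2C_A", "HTR2C_B", "HTR2C_Cp", "HTR2C_C", "HTR2C_D"),
                      codon_model_id="HTR2C")
MODEL = htr2c_codon_model(CLUSTER)


def _aligned(bases, quals=None, offsets=(61, 63, 67, 68, 73)):
    """Minimal aligned read covering the five cluster sites."""
    seq = list("C" * 100)
    qual = [chr(33 + 40)] * 100
    for off, b, q in zip(offsets, bases, quals or [40] * 5):
        seq[off] = b
        qual[off] = chr(33 + q)
    return AlignedRead(
        read_id="r", amplicon_id="amp_HTR2C", seq="".join(seq),
        qual="".join(qual), score=100, ref_start=0, cigar=[("M", 100)],
        site_read_pos={sid: off for sid, off in zip(CLUSTER.site_ids, offsets)},
    )


class TestEnumeration:
    def test_32_mrna_variants_24_protein_isoforms(self):
        """Five two-state sites give 2^5 = 32 mRNA variants whose three
        affected codons translate to 24 distinct amino-acid triplets."""
        table = enumerate_variants(CLUSTER, MODEL)
        assert len(table) == 32
        assert table["state"].nunique() == 32
        assert table["protein"].nunique() == 24

    def test_unedited_is_ini_fully_edited_is_vgv(self):
        table = enumerate_variants(CLUSTER, MODEL).set_index("state")
        assert table.loc["00000", "protein"] == "INI"
        assert table.loc["11111", "protein"] == "VGV"

    def test_protein_count_matches_bruteforce_translation(self):
        """Distinct-protein count agrees with direct codon substitution and
        translation over all 32 states (independent genetic-code walk)."""
        code = {
            "ATA": "I", "GTA": "V", "ATG": "M", "GTG": "V",
            "AAT": "N", "GAT": "D", "AGT": "S", "GGT": "G",
        }
        pos_map = {"HTR2C_A": (0, 0), "HTR2C_B": (0, 2), "HTR2C_Cp": (1, 0),
                   "HTR2C_C": (1, 1), "HTR2C_D": (2, 0)}
        proteins = set()
        for bits in itertools.product("01", repeat=5):
            codons = [list("ATA"), list("AAT"), list("ATA")]
            for sid, bit in zip(CLUSTER.site_ids, bits):
                if bit == "1":
                    ci, cp = pos_map[sid]
                    codons[ci][cp] = "G"
            proteins.add("".join(code["".join(c)] for c in codons))
        table = enumerate_variants(CLUSTER, MODEL)
        assert table["protein"].nunique() == len(proteins) == 24

    def test_single_site_cluster_two_states(self):
        cl = SiteCluster("c1", ("sX",))
        model = single_codon_model(cl, "ATA", 0)
        table = enumerate_variants(cl, model)
        assert len(table) == 2
        assert set(table["protein"]) == {"I", "V"}

    def test_model_rejects_non_a_codon_position(self):
        with pytest.raises(ValueError, match="not 'A'"):
            CodonModel("c", ("CTA",), (1,), {"s": (0, 0)})


class TestPhasing:
    def test_all_a_gives_ini_state(self):
        assert phase_read(_aligned("AAAAA"), CLUSTER) == "00000"

    def test_all_g_gives_vgv_state(self):
        assert phase_read(_aligned("GGGGG"), CLUSTER) == "11111"

    def test_vdv_state_translation(self):
        state = phase_read(_aligned("GAGAG"), CLUSTER)
        assert state == "10101"
        table = enumerate_variants(CLUSTER, MODEL).set_index("state")
        assert table.loc[state, "protein"] == "VDV"

    def test_ct_base_rejects_read(self):
        assert phase_read(_aligned("AATAA"), CLUSTER) is None

    def test_low_quality_rejects_read(self):
        assert phase_read(_aligned("AAAAA", quals=[40, 40, 15, 40, 40]),
                          CLUSTER) is None

    def test_deleted_site_rejects_read(self):
        ar = _aligned("AAAAA")
        ar.site_read_pos["HTR2C_C"] = -1
        assert phase_read(ar, CLUSTER) is None


class TestAbundance:
    def test_counts_to_abundance(self):
        states = ["00000"] * 58 + ["11111"] * 20 + ["10101"] * 22
        table = variant_abundance(states, CLUSTER, MODEL).set_index("state")
        assert table.loc["00000", "abundance"] == pytest.approx(0.58)
        assert table["abundance"].sum() == pytest.approx(1.0)
        assert len(table) == 32  # unobserved states retained at 0

    def test_single_read(self):
        table = variant_abundance(["01010"], CLUSTER, MODEL).set_index("state")
        assert table.loc["01010", "abundance"] == 1.0

    def test_zero_reads_error(self):
        with pytest.raises(ValueError, match="no phased reads"):
            variant_abundance([], CLUSTER, MODEL)

    def test_multinomial_recovery(self, rng):
        """Planted joint distribution recovered within 3 multinomial SE at
        10^4 phased reads."""
        probs = {"00000": 0.45, "10101": 0.2, "11111": 0.13, "10100": 0.22}
        labels = list(probs)
        n = 10_000
        draws = rng.choice(labels, size=n, p=list(probs.values()))
        table = variant_abundance(list(draws), CLUSTER, MODEL).set_index("state")
        for s, p in probs.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(table.loc[s, "abundance"] - p) < 3 * se


class TestCompareAbundance:
    def _profiles(self, means, n_per_group=3, sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for group, by_state in means.items():
            for i in range(n_per_group):
                for state, m in by_state.items():
                    rows.append({
                        "sample_id": f"{group}{i}", "group": group,
                        "state": state,
                        "abundance": m + rng.normal(0, sd),
                    })
        return pd.DataFrame(rows)

    def test_identical_group_means_interaction_near_one(self):
        means = {"AD": {"00000": 0.6, "11111": 0.4},
                 "NDC": {"00000": 0.6, "11111": 0.4}}
        prof = self._profiles(means, sd=0.01, seed=5)
        res = compare_abundance(prof)
        assert res.interaction_p > 0.3

    def test_balanced_layout_matches_hand_anova(self):
        """F statistics agree with a hand sums-of-squares decomposition to
        6 decimals on a balanced 2 groups × 2 variants × 3 replicates table."""
        table = [
            [[0.61, 0.58, 0.64], [0.39, 0.41, 0.37]],  # AD: INI, VGV
            [[0.45, 0.47, 0.44], [0.55, 0.52, 0.56]],  # NDC
        ]
        rows = []
        for gi, group in enumerate(["AD", "NDC"]):
            for vi, state in enumerate(["00000", "11111"]):
                for ri, val in enumerate(table[gi][vi]):
                    rows.append({"sample_id": f"{group}{ri}", "group": group,
                                 "state": state, "abundance": val})
        res = compare_abundance(pd.DataFrame(rows))
        oracle = anova_two_way_balanced(table)
        assert res.anova.loc["C(group)", "F"] == pytest.approx(
            oracle["A"][0], abs=1e-6)
        assert res.anova.loc["C(state)", "F"] == pytest.approx(
            oracle["B"][0], abs=1e-6)
        assert res.anova.loc["C(group):C(state)", "F"] == pytest.approx(
            oracle["AB"][0], abs=1e-6)

    def test_planted_ini_shift_detected(self):
        means = {"AD": {"00000": 0.58, "10101": 0.2, "11111": 0.22},
                 "NDC": {"00000": 0.45, "10101": 0.33, "11111": 0.22}}
        prof = self._profiles(means, n_per_group=10, sd=0.03, seed=6)
        res = compare_abundance(prof)
        assert res.interaction_p < 0.003
        ini = res.per_variant.set_index("state").loc["00000"]
        assert ini["diff"] > 0 and ini["p_value"] < 0.003

    def test_degenerate_data_flagged(self):
        means = {"AD": {"00000": 0.5, "11111": 0.5},
                 "NDC": {"00000": 0.5, "11111": 0.5}}
        with pytest.raises(ValueError, match="degenerate"):
            compare_abundance(self._profiles(means, sd=0.0))
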