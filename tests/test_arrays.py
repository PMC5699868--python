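"""Tiling, normalization, top-decile selection and enrichment statistics."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

import switchlab as sl
from switchlab.arrays import ArrayDesign, PeptideArrayTable, aa_enrichment, compare_probes
from switchlab.synth import AAWeightModel, client_sequences, gen_array


def make_table(intensities, sequences=None, replicate=1):
    n = len(intensities)
    seqs = sequences or ["ACDEFGHIKLMNPQRSTV"] * n
    return PeptideArrayTable(
        pd.DataFrame(
            {
                "spot_id": [f"s{i}" for i in range(n)],
                "protein_id": "p",
                "start_1based": np.arange(1, n + 1),
                "sequence": seqs,
                "replicate": replicate,
                "intensity": intensities,
            }
        )
    )


class TestTiling:
    @pytest.mark.parametrize(
        "length,expected", [(18, 1), (21, 2), (248, 77), (24, 3)]
    )
    def test_tile_counts(self, length, expected):
        tiles = sl.tile_sequence("A" * length)
        assert len(tiles) == expected

    def test_tile_starts_step_by_three(self):
        tiles = sl.tile_sequence("A" * 21)
        assert [s for s, _ in tiles] == [1, 4]

    def test_short_sequence_errors(self):
        with pytest.raises(ValueError):
            sl.tile_sequence("A" * 17)


class TestNormalize:
    def test_divides_by_replicate_max(self):
        out = sl.normalize_array(make_table([2.0, 4.0, 8.0]))
        assert np.allclose(sorted(out.spots["intensity"]), [0.25, 0.5, 1.0])

    def test_idempotent(self):
        once = sl.normalize_array(make_table([2.0, 4.0, 8.0]))
        twice = sl.normalize_array(once)
        assert np.allclose(once.spots["intensity"], twice.spots["intensity"])

    def test_replicates_normalized_independently(self):
        df = pd.concat(
            [make_table([1.0, 5.0], replicate=1).spots, make_table([2.0, 40.0], replicate=2).spots]
        )
        out = sl.normalize_array(PeptideArrayTable(df))
        for _, sub in out.spots.groupby("replicate"):
            assert sub["intensity"].max() == pytest.approx(1.0)

    def test_all_zero_replicate_errors(self):
        with pytest.raises(ValueError, match="no positive intensity"):
            sl.normalize_array(make_table([0.0, 0.0]))


class TestSelectTop:
    def test_single_top_spot_for_ten_distinct(self):
        table = sl.normalize_array(make_table(list(np.arange(1.0, 11.0))))
        assert sl.select_top(table) == ["s9"]

    def test_ceiling_rule_77_spots(self):
        table = sl.normalize_array(make_table(list(np.arange(1.0, 78.0))))
        assert len(sl.select_top(table)) == 8  # ceil(7.7)

    def test_ties_break_by_spot_id(self):
        table = sl.normalize_array(make_table([3.0] * 10))
        assert sl.select_top(table) == ["s0"]


class TestEnrichment:
    def test_top_matching_array_composition_gives_zero(self):
        # every spot identical ⇒ any top set has the array's composition
        table = make_table([1.0] * 10)
        res = aa_enrichment(table, per_replicate=False)
        assert np.allclose(res.table["log2_enrichment"], 0.0)

    def test_doubled_frequency_gives_one_log2_unit(self):
        # array: W at 5% overall; top spot: W at 10%
        seqs = ["WACDEFGHIKLMNPQRST", "WWACDEFGHIKLMNPQRS"] + ["ACDEFGHIKLMNPQRSTV"] * 18
        counts = Counter("".join(seqs))
        table = make_table([1.0] * 19 + [9.0], sequences=seqs[:-1] + [seqs[1]])
        # construct directly instead: top spot s19 has sequence with 2 W
        res = aa_enrichment(table, ArrayDesign(top_fraction=0.05), per_replicate=False)
        top_seq = seqs[1]
        f_top = top_seq.count("W") / len(top_seq)
        f_all = (
            sum(s.count("W") for s in seqs[:-1] + [seqs[1]])
            / sum(len(s) for s in seqs[:-1] + [seqs[1]])
        )
        row = res.table.set_index("aa").loc["W"]
        assert row["log2_enrichment"] == pytest.approx(math.log2(f_top / f_all))

    def test_brute_force_oracle_small_array(self):
        # literal residue counting on a <=20-spot array must match exactly
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list(sl.arrays.AA_ALPHABET), 18)) for _ in range(12)]
        inten = rng.uniform(0.5, 2.0, 12)
        table = make_table(list(inten), sequences=seqs)
        res = aa_enrichment(table, per_replicate=False)
        top_ids = res.top_ids
        idx = {f"s{i}": s for i, s in enumerate(seqs)}
        top_res = Counter("".join(idx[i] for i in top_ids))
        all_res = Counter("".join(seqs))
        for _, row in res.table.iterrows():
            aa = row["aa"]
            f_all = all_res[aa] / sum(all_res.values())
            if top_res.get(aa, 0) > 0:
                f_top = top_res[aa] / sum(top_res.values())
                assert row["log2_enrichment"] == pytest.approx(math.log2(f_top / f_all))
                assert row["flag"] == ""
            else:
                f_top = 0.5 / sum(top_res.values())  # pseudo-count floor
                assert row["log2_enrichment"] == pytest.approx(math.log2(f_top / f_all))
                assert row["flag"] == "depletion_floor"

    def test_composition_frequencies_sum_to_one(self, preference_array):
        from switchlab.arrays import _composition

        comp = _composition(preference_array.spots["sequence"].unique())
        freqs = np.array(list(comp.values())) / sum(comp.values())
        assert freqs.sum() == pytest.approx(1.0)

    def test_enrichment_invariant_to_uniform_rescaling(self, preference_array):
        res_a = aa_enrichment(preference_array)
        scaled = PeptideArrayTable(
            preference_array.spots.assign(intensity=preference_array.spots.intensity * 37.0)
        )
        res_b = aa_enrichment(scaled)
        pd.testing.assert_frame_equal(res_a.table, res_b.table)

    def test_recovers_injected_preferences(self, preference_array):
        """C/Y/W/R enriched and D/E depleted at p<0.05, as injected."""
        tab = aa_enrichment(preference_array).table.set_index("aa")
        for aa in "CYWR":
            assert tab.loc[aa, "log2_enrichment"] > 0
            assert tab.loc[aa, "p_value"] < 0.05
        for aa in "DE":
            assert tab.loc[aa, "log2_enrichment"] < 0
            assert tab.loc[aa, "p_value"] < 0.05

    def test_null_false_positive_rate_near_alpha(self):
        """Under equal weights the t-test flags ~5% of amino acids."""
        total = significant = 0
        for s in range(200):
            seqs = client_sequences(seed=5000 + s, lengths={"a": 150, "b": 130})
            table = gen_array(seqs, AAWeightModel.uniform(noise_sd=0.2, seed=5000 + s), replicates=3)
            tab = aa_enrichment(table).table
            total += len(tab)
            significant += int((tab["p_value"] < 0.05).sum())
        rate = significant / total
        assert 0.025 <= rate <= 0.085


class TestCompareProbes:
    def test_identical_probes_no_difference(self, preference_array):
        res = aa_enrichment(preference_array)
        cmp = compare_probes(res, res).set_index("aa")
        assert np.allclose(cmp["delta_E"], 0.0)
        assert (cmp["p_value"] > 0.99).all()

    def test_detects_differential_proline_preference(self, clients):
        # probe A tolerates proline, probe B strongly disfavours it
        a = gen_array(clients, AAWeightModel.with_preferences({"P": 0.0}, noise_sd=0.2, seed=2), 3)
        b = gen_array(clients, AAWeightModel.with_preferences({"P": -1.0}, noise_sd=0.2, seed=3), 3)
        cmp = compare_probes(aa_enrichment(a), aa_enrichment(b)).set_index("aa")
        assert cmp.loc["P", "delta_E"] > 0
        assert cmp.loc["P", "p_value"] < 0.05

    def test_requires_per_replicate_values(self, preference_array):
        pooled = aa_enrichment(preference_array, per_replicate=False)
        with pytest.raises(ValueError, match="per-replicate"):
            compare_probes(pooled, pooled)
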