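"""Directional-consistency calls, candidate ranking, recurrent families."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raceqtl import de, eqtl, integrate
from raceqtl.errors import ConfigError
from raceqtl.integrate import (
    ConsistencyCall,
    DirectionVector,
    build_direction_vector,
    check_consistency,
    rank_candidates,
    select_recurrent_families,
    standard_directions,
)
from raceqtl.sim import PlantedDriver, SimConfig, simulate_dataset

COMPS = de.STANDARD_COMPARISONS
WORKED_FREQS = {"AS": 0.0744, "AA": 0.2247, "CA": 0.5149}


def _de_table(rows):
    """rows: {gene: (log2fc, padj, direction)}"""
    return pd.DataFrame(
        {
            "log2fc": [v[0] for v in rows.values()],
            "p": [v[1] for v in rows.values()],
            "padj": [v[1] for v in rows.values()],
            "direction": [v[2] for v in rows.values()],
        },
        index=list(rows),
    )


def _dv(directions) -> DirectionVector:
    return DirectionVector("g", dict(zip(COMPS, directions)))


class TestBuildDirectionVector:
    def test_all_down_pattern(self):
        # a gene down-regulated in every comparison, like the strongest
        # candidates in the all-cancer analysis
        tables = {
            COMPS[0]: _de_table({"XKR9": (-1.6, 3.3e-43, "down")}),
            COMPS[1]: _de_table({"XKR9": (-1.1, 8.1e-11, "down")}),
            COMPS[2]: _de_table({"XKR9": (-0.63, 4.1e-16, "down")}),
        }
        dv = build_direction_vector("XKR9", tables)
        assert standard_directions(dv) == (-1, -1, -1)

    def test_partial_nde_pattern(self):
        tables = {
            COMPS[0]: _de_table({"SIGLEC14": (-1.5, 2.2e-44, "down")}),
            COMPS[1]: _de_table({"SIGLEC14": (-0.97, 3.9e-8, "down")}),
            COMPS[2]: _de_table({"SIGLEC14": (-0.1, 0.5, "nde")}),
        }
        dv = build_direction_vector("SIGLEC14", tables)
        assert standard_directions(dv) == (-1, -1, 0)

    def test_absent_gene_is_all_nde(self):
        tables = {c: _de_table({"other": (0.0, 1.0, "nde")}) for c in COMPS}
        assert standard_directions(build_direction_vector("ghost", tables)) == (0, 0, 0)


class TestCheckConsistency:
    def test_worked_example_all_consistent(self):
        # down in every comparison while the expression-increasing allele is
        # rarest in AS and commonest in CA -> fully consistent
        call = check_consistency(_dv((-1, -1, -1)), WORKED_FREQS, min_gap=0.02)
        assert call.verdict == "consistent"
        assert call.n_evaluated == 3 and call.n_consistent == 3

    def test_orientation_flip_all_inconsistent(self):
        flipped = {p: 1 - f for p, f in WORKED_FREQS.items()}
        call = check_consistency(_dv((-1, -1, -1)), flipped, min_gap=0.02)
        assert call.verdict == "inconsistent"
        assert call.n_consistent == 0 and call.n_evaluated == 3

    def test_nde_comparison_skipped(self):
        call = check_consistency(_dv((-1, -1, 0)), WORKED_FREQS, min_gap=0.02)
        assert call.verdict == "consistent"
        assert call.n_evaluated == 2
        assert call.status[COMPS[2]] == "skipped_nde"

    def test_small_gap_skipped_not_counted(self):
        freqs = {"AS": 0.30, "AA": 0.31, "CA": 0.50}
        call = check_consistency(_dv((-1, -1, -1)), freqs, min_gap=0.02)
        assert call.status[COMPS[1]] == "skipped_small_gap"  # AS vs AA gap 0.01
        assert call.n_evaluated == 2 and call.verdict == "consistent"

    def test_all_nde_unevaluable(self):
        call = check_consistency(_dv((0, 0, 0)), WORKED_FREQS)
        assert call.verdict == "unevaluable" and call.n_evaluated == 0

    def test_missing_population_rejected(self):
        with pytest.raises(ConfigError, match="population"):
            check_consistency(_dv((-1, 0, 0)), {"AS": 0.1})

    @settings(max_examples=60, deadline=None)
    @given(
        f=st.tuples(*[st.floats(min_value=0, max_value=1) for _ in range(3)]),
        d=st.tuples(*[st.sampled_from([-1, 0, 1]) for _ in range(3)]),
        gap_lo=st.floats(min_value=0, max_value=0.2),
        gap_hi=st.floats(min_value=0, max_value=0.3),
    )
    def test_monotone_gap_property(self, f, d, gap_lo, gap_hi):
        """A larger min_gap never creates consistency and never evaluates more."""
        lo, hi = sorted([gap_lo, gap_lo + gap_hi])
        freqs = dict(zip(("AS", "AA", "CA"), f))
        call_lo = check_consistency(_dv(d), freqs, min_gap=lo)
        call_hi = check_consistency(_dv(d), freqs, min_gap=hi)
        assert call_hi.n_evaluated <= call_lo.n_evaluated
        for comp in COMPS:
            if call_hi.status[comp] == "inconsistent":
                assert call_lo.status[comp] == "inconsistent"

    def test_end_to_end_orientation_invariance(self):
        """Complementing stored alt frequencies while negating slopes leaves
        every verdict unchanged."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            f = rng.uniform(0, 1, size=3)
            slope = rng.uniform(0.1, 2) * rng.choice([-1, 1])
            d = rng.choice([-1, 0, 1], size=3)
            freq_frame = pd.DataFrame(
                {"snp_id": "rs1", "population": ["AS", "AA", "CA"], "alt_freq": f}
            )
            rec = eqtl.EqtlRecord("rs1", "g", "A", "G", slope=slope, p=1e-6)
            flipped_frame = freq_frame.assign(alt_freq=1 - freq_frame["alt_freq"])
            rec_flipped = eqtl.EqtlRecord("rs1", "g", "G", "A", slope=-slope, p=1e-6)
            call = check_consistency(
                _dv(d), eqtl.orient_effect_allele(rec, freq_frame)
            )
            call_flipped = check_consistency(
                _dv(d), eqtl.orient_effect_allele(rec_flipped, flipped_frame)
            )
            assert call.verdict == call_flipped.verdict
            assert call.status == call_flipped.status


class TestRankCandidates:
    @staticmethod
    def _surv(genes, p):
        return pd.DataFrame(
            {"logrank_statistic": 5.0, "p": p, "padj": p, "direction_of_effect": -1.0},
            index=pd.Index(genes, name="gene_id"),
        )

    @staticmethod
    def _call(snp, gene, statuses):
        return ConsistencyCall(snp, gene, dict(zip(COMPS, statuses)))

    def test_single_significant_candidate(self):
        calls = [self._call("rs1", "g1", ["consistent"] * 3)]
        tables = {c: _de_table({"g1": (-1.0, 1e-5, "down")}) for c in COMPS}
        out = rank_candidates(calls, self._surv(["g1"], 0.001), tables)
        assert list(out["candidates"]["gene_id"]) == ["g1"]
        assert out["candidates"]["rank"].tolist() == [1]

    def test_survival_null_goes_to_secondary_listing(self):
        calls = [self._call("rs1", "g1", ["consistent"] * 3)]
        tables = {c: _de_table({"g1": (-1.0, 1e-5, "down")}) for c in COMPS}
        out = rank_candidates(calls, self._surv(["g1"], 0.8), tables)
        assert out["candidates"].empty
        assert list(out["consistent_only"]["gene_id"]) == ["g1"]

    def test_inconsistent_pairs_excluded(self):
        calls = [self._call("rs1", "g1", ["consistent", "inconsistent", "consistent"])]
        tables = {c: _de_table({"g1": (-1.0, 1e-5, "down")}) for c in COMPS}
        out = rank_candidates(calls, self._surv(["g1"], 0.001), tables)
        assert out["candidates"].empty and out["consistent_only"].empty

    def test_deterministic_total_order(self):
        calls = [
            self._call("rs1", "gB", ["consistent"] * 3),
            self._call("rs2", "gA", ["consistent"] * 3),
        ]
        tables = {c: _de_table({"gA": (-1.0, 1e-5, "down"), "gB": (-1.0, 1e-5, "down")}) for c in COMPS}
        out = rank_candidates(calls, self._surv(["gA", "gB"], 0.001), tables)
        assert list(out["candidates"]["gene_id"]) == ["gA", "gB"]  # gene id tiebreak


class TestPlantedDriverRecovery:
    def test_sensitivity_and_null_false_consistency(self):
        """Planted drivers are called consistent in >= 95% of 20 seeds; SNPs
        with equal frequencies across races in <= 5%."""
        hits, null_hits, null_total = 0, 0, 0
        for seed in range(20):
            cfg = SimConfig(
                n_per_population={"AS": 100, "AA": 100, "CA": 400},
                n_genes=60,
                n_snps=4,
                planted_drivers=[
                    PlantedDriver(
                        "rs_d", "GENE_D", {"AS": 0.10, "AA": 0.30, "CA": 0.60}, 1.0
                    )
                ],
                seed=5000 + seed,
            )
            ds = simulate_dataset(cfg)
            norm = de.normalize_log2(ds["counts"])
            tables = de.run_standard_comparisons(norm, ds["counts"].sample_meta["race"])
            gm, freqs = ds["genotypes"], ds["freqs"]
            records = eqtl.eqtl_scan(
                gm, norm, [(s, "GENE_D") for s in gm.snp_ids]
            )
            for rec in records:
                if rec.untestable or rec.increasing_allele == "undetermined":
                    continue
                dv = build_direction_vector("GENE_D", tables)
                call = check_consistency(
                    dv, eqtl.orient_effect_allele(rec, freqs), snp_id=rec.snp_id
                )
                significant = rec.padj is not None and rec.padj <= 0.05
                if rec.snp_id == "rs_d":
                    if significant and call.verdict == "consistent":
                        hits += 1
                else:
                    null_total += 1
                    if significant and call.verdict == "consistent":
                        null_hits += 1
        assert hits >= 19  # >= 95% of 20 seeds
        assert null_hits <= max(1, 0.05 * null_total)


class TestRecurrentFamilies:
    def test_two_members_one_cancer_plus_recurrence_selected(self):
        deg_sets = {
            ("X", ("AS", "CA")): {("K1", "down"), ("K2", "down")},
            ("Y", ("AS", "CA")): {("K1", "down")},
        }
        out = select_recurrent_families(deg_sets, {"K1": "KLK", "K2": "KLK"})
        assert out.loc[out["family"] == "KLK", "selected"].item()

    def test_single_cancer_fails_condition_two(self):
        deg_sets = {("X", ("AS", "CA")): {("K1", "down"), ("K2", "down")}}
        out = select_recurrent_families(deg_sets, {"K1": "KLK", "K2": "KLK"})
        row = out.loc[out["family"] == "KLK"].iloc[0]
        assert row["condition1"] and not row["condition2"] and not row["selected"]

    def test_single_members_fail_condition_one(self):
        deg_sets = {
            ("X", ("AS", "CA")): {("K1", "down")},
            ("Y", ("AS", "CA")): {("K2", "down")},
            ("Z", ("AS", "CA")): {("K3", "down")},
        }
        out = select_recurrent_families(deg_sets, {f"K{i}": "KLK" for i in (1, 2, 3)})
        row = out.loc[out["family"] == "KLK"].iloc[0]
        assert not row["condition1"] and not row["selected"]

    def test_opposite_directions_do_not_pair(self):
        deg_sets = {
            ("X", ("AS", "CA")): {("K1", "down"), ("K2", "up")},
            ("Y", ("AS", "CA")): {("K1", "down")},
        }
        out = select_recurrent_families(deg_sets, {"K1": "KLK", "K2": "KLK"})
        assert not out.loc[out["family"] == "KLK", "condition1"].item()
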