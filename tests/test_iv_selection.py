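import numpy as np
import pandas as pd
import pytest

from mrnetwork.iv_selection import (
    FilterConfig,
    build_instrument_set,
    clump,
    cross_trait_banned,
    drop_confounder_associated,
    drop_cross_trait,
    drop_outcome_associated,
    harmonize,
    instrument_strength,
    pval_lookup,
    select_by_pvalue,
)

from conftest import make_record, random_records


class TestPvalueSelection:
    def test_threshold_is_strict(self):
        recs = [make_record(variant_id=f"v{i}", pval=p)
                for i, p in enumerate((1e-7, 1e-5, 1e-3))]
        kept = select_by_pvalue(recs, 5e-6)
        assert [r.variant_id for r in kept] == ["v0"]

    def test_all_above_threshold_gives_empty(self):
        recs = [make_record(variant_id=f"v{i}", pval=0.5) for i in range(3)]
        assert select_by_pvalue(recs, 5e-6) == []

    def test_matches_brute_force_on_random_records(self, rng):
        recs = random_records(rng, n=500)
        kept = select_by_pvalue(recs, 1e-3)
        assert kept == [r for r in recs if r.pval < 1e-3]


class TestClump:
    def test_distance_rule_keeps_best_pvalue(self):
        a = make_record(variant_id="a", chrom="1", pos=1000, pval=1e-9)
        b = make_record(variant_id="b", chrom="1", pos=2000, pval=1e-8)
        assert [r.variant_id for r in clump([a, b])] == ["a"]

    def test_different_chromosomes_both_kept(self):
        a = make_record(variant_id="a", chrom="1", pos=1000, pval=1e-9)
        b = make_record(variant_id="b", chrom="2", pos=1000, pval=1e-8)
        assert len(clump([a, b])) == 2

    def test_missing_position_raises(self):
        a = make_record(variant_id="a", chrom=None, pos=None)
        with pytest.raises(ValueError, match="chrom and pos"):
            clump([a])

    def test_matches_exhaustive_greedy_oracle_with_ld(self, rng):
        n = 50
        recs = [
            make_record(
                variant_id=f"v{i}",
                chrom=str(int(rng.integers(1, 3))),
                pos=int(rng.integers(1, 5_000_000)),
                pval=float(rng.uniform(1e-12, 1e-4)),
            )
            for i in range(n)
        ]
        ld = {}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.uniform() < 0.3:
                    ld[frozenset((f"v{i}", f"v{j}"))] = float(rng.uniform())
        got = {r.variant_id for r in clump(recs, ld=ld, clump_r2=0.1, clump_kb=1000)}

        # independent greedy oracle
        order = sorted(range(n), key=lambda i: (recs[i].pval, i))
        kept = []
        for i in order:
            ok = True
            for j in kept:
                same = recs[i].chrom == recs[j].chrom
                near = abs(recs[i].pos - recs[j].pos) <= 1_000_000
                r2 = ld.get(frozenset((recs[i].variant_id, recs[j].variant_id)), 0.0)
                if same and near and r2 >= 0.1:
                    ok = False
                    break
            if ok:
                kept.append(i)
        assert got == {recs[i].variant_id for i in kept}


class TestCrossTrait:
    def _universe(self, rng, n_traits=10, n_var=60):
        pvals = {
            f"T{t}": {f"v{i}": float(rng.uniform(1e-12, 1.0)) for i in range(n_var)}
            for t in range(n_traits)
        }
        selected = {
            t: [make_record(variant_id=v, pval=p) for v, p in lk.items() if p < 5e-2]
            for t, lk in pvals.items()
        }
        return selected, pvals

    def test_single_trait_instrument_kept(self):
        sel = {"A": [make_record(variant_id="v1", pval=1e-8)]}
        pv = {"A": {"v1": 1e-8}, "B": {"v1": 0.5}}
        filtered, removed = drop_cross_trait(sel, pv, 5e-6)
        assert [r.variant_id for r in filtered["A"]] == ["v1"]
        assert removed["A"] == 0

    def test_shared_instrument_removed_from_both(self):
        sel = {
            "A": [make_record(variant_id="v1", pval=1e-8)],
            "B": [make_record(variant_id="v1", pval=1e-8)],
        }
        pv = {"A": {"v1": 1e-8}, "B": {"v1": 1e-8}}
        filtered, removed = drop_cross_trait(sel, pv, 5e-6)
        assert filtered["A"] == [] and filtered["B"] == []
        assert removed == {"A": 1, "B": 1}

    def test_matches_brute_force_membership_oracle(self, rng):
        selected, pvals = self._universe(rng)
        banned = cross_trait_banned(selected, pvals, p_cross_trait=5e-2)
        cands = {r.variant_id for recs in selected.values() for r in recs}
        oracle = {
            v for v in cands
            if sum(pvals[t][v] < 5e-2 for t in pvals) >= 2
        }
        assert banned == oracle


class TestConfounderAndOutcome:
    def test_empty_confounder_list_is_identity(self):
        recs = [make_record(variant_id=f"v{i}") for i in range(4)]
        assert drop_confounder_associated(recs, (), 1e-5) == recs

    def test_confounder_associated_removed(self):
        recs = [make_record(variant_id="v1"), make_record(variant_id="v2")]
        out = drop_confounder_associated(recs, [{"v1": 1e-9}], 1e-5)
        assert [r.variant_id for r in out] == ["v2"]

    def test_outcome_associated_removed(self):
        recs = [make_record(variant_id="v1"), make_record(variant_id="v2")]
        out = drop_outcome_associated(recs, {"v1": 1e-9, "v2": 0.5}, 5e-8)
        assert [r.variant_id for r in out] == ["v2"]

    def test_matches_brute_force_oracle(self, rng):
        recs = random_records(rng, n=200)
        conf = {r.variant_id: float(rng.uniform(1e-12, 1.0)) for r in recs}
        out = drop_outcome_associated(recs, conf, 1e-3)
        assert out == [r for r in recs if conf[r.variant_id] >= 1e-3]


class TestHarmonize:
    def test_swapped_alleles_negate_outcome_beta(self):
        ex = make_record(effect_allele="A", other_allele="G", beta=0.2, eaf=0.3)
        oc = make_record(effect_allele="G", other_allele="A", beta=0.1, eaf=0.7)
        rows, drops = harmonize([ex], [oc])
        assert rows.loc[0, "b_Y"] == pytest.approx(-0.1)
        assert rows.loc[0, "b_X"] == pytest.approx(0.2)  # exposure untouched
        assert sum(drops.values()) == 0

    def test_strand_flip_aligns(self):
        ex = make_record(effect_allele="A", other_allele="G", beta=0.2)
        oc = make_record(effect_allele="T", other_allele="C", beta=0.1)
        rows, _ = harmonize([ex], [oc])
        assert rows.loc[0, "b_Y"] == pytest.approx(0.1)

    def test_ambiguous_palindrome_dropped(self):
        ex = make_record(effect_allele="A", other_allele="T", eaf=0.50)
        oc = make_record(effect_allele="A", other_allele="T", eaf=0.50)
        rows, drops = harmonize([ex], [oc])
        assert len(rows) == 0 and drops["palindromic_ambiguous"] == 1

    def test_informative_palindrome_oriented_by_frequency(self):
        ex = make_record(effect_allele="A", other_allele="T", eaf=0.10, beta=0.2)
        # outcome reports the complementary strand: frequency on the other side
        oc = make_record(effect_allele="A", other_allele="T", eaf=0.90, beta=0.1)
        rows, _ = harmonize([ex], [oc])
        assert rows.loc[0, "b_Y"] == pytest.approx(-0.1)

    def test_incompatible_alleles_dropped(self):
        ex = make_record(effect_allele="A", other_allele="G")
        oc = make_record(effect_allele="A", other_allele="C")
        rows, drops = harmonize([ex], [oc])
        assert len(rows) == 0 and drops["incompatible_alleles"] == 1

    def test_absent_from_outcome_counted(self):
        ex = make_record(variant_id="v1")
        rows, drops = harmonize([ex], [])
        assert len(rows) == 0 and drops["not_in_outcome"] == 1


class TestInstrumentStrength:
    def test_closed_form(self):
        rows = pd.DataFrame(
            {"variant_id": ["v"], "b_X": [0.1], "se_X": [0.01], "pval_X": [1e-9],
             "b_Y": [0.05], "se_Y": [0.01], "pval_Y": [0.5], "eaf": [0.5],
             "n_X": [10_000], "n_Y": [10_000]}
        )
        out = instrument_strength(rows)
        assert out.loc[0, "R2"] == pytest.approx(0.005)
        assert out.loc[0, "F"] == pytest.approx((10_000 - 2) * 0.005 / 0.995)
        assert out.loc[0, "F"] == pytest.approx(50.24, abs=0.01)

    def test_zero_effect_gives_zero(self):
        rows = pd.DataFrame(
            {"variant_id": ["v"], "b_X": [0.0], "se_X": [0.01], "pval_X": [0.9],
             "b_Y": [0.0], "se_Y": [0.01], "pval_Y": [0.5], "eaf": [0.5],
             "n_X": [10_000], "n_Y": [10_000]}
        )
        out = instrument_strength(rows)
        assert out.loc[0, "R2"] == 0.0 and out.loc[0, "F"] == 0.0

    def test_f_monotone_in_n(self):
        fs = []
        for n in (1_000, 10_000, 100_000):
            rows = pd.DataFrame(
                {"variant_id": ["v"], "b_X": [0.1], "se_X": [0.01], "pval_X": [1e-9],
                 "b_Y": [0.05], "se_Y": [0.01], "pval_Y": [0.5], "eaf": [0.5],
                 "n_X": [n], "n_Y": [n]}
            )
            fs.append(instrument_strength(rows).loc[0, "F"])
        assert fs[0] < fs[1] < fs[2]

    def test_missing_eaf_reported_unavailable(self):
        rows = pd.DataFrame(
            {"variant_id": ["v"], "b_X": [0.1], "se_X": [0.01], "pval_X": [1e-9],
             "b_Y": [0.05], "se_Y": [0.01], "pval_Y": [0.5], "eaf": [None],
             "n_X": [10_000], "n_Y": [10_000]}
        )
        out = instrument_strength(rows)
        assert np.isnan(out.loc[0, "R2"]) and np.isnan(out.loc[0, "F"])


class TestFullFiltration:
    def _records(self, rng, n=40):
        recs = []
        for i in range(n):
            recs.append(
                make_record(
                    variant_id=f"v{i}",
                    chrom=str(i % 5 + 1),
                    pos=1 + (i // 5) * 20_000_000,
                    pval=float(rng.uniform(1e-12, 1e-4)),
                    beta=float(rng.normal(0, 0.1)),
                    eaf=float(rng.uniform(0.1, 0.9)),
                )
            )
        return recs

    def test_provenance_counts_sum(self, rng):
        exp = self._records(rng)
        out = [make_record(variant_id=f"v{i}", beta=0.01, pval=0.5) for i in range(35)]
        iset = build_instrument_set("X", "Y", exp, out)
        assert iset.check_provenance()
        assert iset.provenance["initial"] == len(exp)

    def test_filtration_is_idempotent(self, rng):
        exp = self._records(rng)
        out = [make_record(variant_id=f"v{i}", beta=0.01, pval=0.5) for i in range(40)]
        cfg = FilterConfig()
        first = build_instrument_set("X", "Y", exp, out, cfg)
        survivors = [r for r in exp if r.variant_id in set(first.rows["variant_id"])]
        second = build_instrument_set("X", "Y", survivors, out, cfg)
        assert list(second.rows["variant_id"]) == list(first.rows["variant_id"])
        pd.testing.assert_frame_equal(
            second.rows.reset_index(drop=True), first.rows.reset_index(drop=True)
        )

    def test_filter_config_validation(self):
        with pytest.raises(ValueError):
            FilterConfig(p_instrument=0.0)
        with pytest.raises(ValueError):
            FilterConfig(min_ivs=1)
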