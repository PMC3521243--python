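"""The seed-domain heuristic: filters, seeding, three-case rule, mapping."""

import numpy as np
import pytest

from chempfam import (DomainHit, DomainLigandMapper, FilterConfig, MapType,
                      TargetCategory, TargetRecord, build_seed_set,
                      classify_target, cooccurrence_report, filter_activities,
                      map_activities)
from chempfam.mapping import Provenance, SeedSet
from chempfam.synthetic import SyntheticConfig, generate_activities, generate_proteome

from conftest import make_activity
from oracles import brute_force_mapping, brute_force_pair_counts


class TestFilter:
    def test_toy_table_keeps_exactly_the_three_qualifying_records(self, toy_activities):
        kept = filter_activities(toy_activities)
        assert sorted(a.activity_id for a in kept) == [1, 2, 4]

    @pytest.mark.parametrize("value,unit,expected", [
        (10.0, "nM", True),        # far below threshold
        (50.0, "uM", True),        # inclusive boundary
        (50.0, "µM", True),        # unicode micro sign
        (50.000001, "uM", False),
        (5e-5, "M", True),
        (0.05, "mM", True),
        (60.0, "uM", False),
        (5e7, "pM", True),         # 50 uM expressed in pM
    ])
    def test_concentration_conversion(self, value, unit, expected):
        rec = make_activity(value=value, unit=unit)
        assert bool(filter_activities([rec])) is expected

    @pytest.mark.parametrize("atype,value,expected", [
        ("pKd", 6.0, True),          # -log10(5e-5) = 4.301 <= 6.0
        ("pKd", 4.301, False),       # just below -log10(5e-5) = 4.30103
        ("pKd", 4.30103, True),
        ("-Log Ki", 5.0, True),
        ("pA2", 7.0, True),
        ("pI", 2.0, False),
    ])
    def test_log_scale_types_compared_on_log_molar(self, atype, value, expected):
        rec = make_activity(activity_type=atype, value=value, unit="")
        assert bool(filter_activities([rec])) is expected

    def test_unsupported_unit_rejected_not_crashed(self, caplog):
        rec = make_activity(value=1.0, unit="mg/mL")
        assert filter_activities([rec]) == []

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            FilterConfig(threshold_concentration=0.0)
        with pytest.raises(ValueError):
            FilterConfig(log_types=frozenset({"NotAllowed"}))


class TestSeedSet:
    def test_single_domain_target_with_qualifying_activity_seeds(self, trypsin_target):
        acts = [make_activity(target="P00760")]
        seeds = build_seed_set([trypsin_target], acts)
        assert seeds.families == {"Trypsin"}
        assert seeds.provenance["Trypsin"] is Provenance.DATA_DERIVED

    def test_manual_addition_has_manual_provenance(self, trypsin_target):
        seeds = build_seed_set([trypsin_target], [], manual_additions={"Pkinase_Tyr"})
        assert seeds.provenance["Pkinase_Tyr"] is Provenance.MANUAL

    def test_manual_colliding_with_data_keeps_data_provenance(self, trypsin_target):
        acts = [make_activity(target="P00760")]
        seeds = build_seed_set([trypsin_target], acts, manual_additions={"Trypsin"})
        assert seeds.provenance["Trypsin"] is Provenance.DATA_DERIVED

    def test_two_family_target_contributes_nothing(self, akt3_target):
        acts = [make_activity(target="Q9Y243")]
        assert build_seed_set([akt3_target], acts).families == set()

    def test_excluded_fragment_is_ignored(self):
        frag = TargetRecord("Q864F1", [DomainHit("Q864F1", "GAF", 10, 150)])
        acts = [make_activity(target="Q864F1")]
        assert build_seed_set([frag], acts, excluded_targets={"Q864F1"}).families == set()

    def test_repeat_copies_of_one_family_still_count_single(self):
        t = TargetRecord("A", [DomainHit("A", "fn3", 1, 90),
                               DomainHit("A", "fn3", 100, 190)])
        seeds = build_seed_set([t], [make_activity(target="A")])
        assert seeds.families == {"fn3"}

    def test_seed_monotonicity_adding_activities_never_removes(self):
        targets = [TargetRecord("A", [DomainHit("A", "F1", 1, 90)]),
                   TargetRecord("B", [DomainHit("B", "F2", 1, 90)])]
        base = [make_activity(1, target="A")]
        more = base + [make_activity(2, target="B")]
        s0 = build_seed_set(targets, base).families
        s1 = build_seed_set(targets, more).families
        assert s0 <= s1


def _seeds(*families: str) -> SeedSet:
    return SeedSet({f: Provenance.DATA_DERIVED for f in families})


class TestClassification:
    def test_akt3_maps_to_pkinase(self, akt3_target):
        cls = classify_target(akt3_target, _seeds("Pkinase", "Trypsin"))
        assert cls.category is TargetCategory.ONE_SEED
        assert cls.mapped_family == "Pkinase"

    def test_copies_of_nonseed_family_are_irrelevant(self):
        t = TargetRecord("A", [DomainHit("A", "fn3", 1, 90),
                               DomainHit("A", "fn3", 100, 190),
                               DomainHit("A", "SH2-like", 200, 280)])
        cls = classify_target(t, _seeds("SH2-like"))
        assert cls.category is TargetCategory.ONE_SEED
        assert cls.mapped_family == "SH2-like"

    def test_two_distinct_seed_families_is_conflict(self, akt3_target):
        cls = classify_target(akt3_target, _seeds("Pkinase", "PH"))
        assert cls.category is TargetCategory.MULTI_SEED_CONFLICT
        assert cls.mapped_family is None

    def test_no_seed_family(self, akt3_target):
        assert classify_target(akt3_target, _seeds("Trypsin")).category \
            is TargetCategory.NO_SEED

    def test_zero_domain_target_is_no_seed(self):
        t = TargetRecord("A", [])
        assert classify_target(t, _seeds("F")).category is TargetCategory.NO_SEED

    def test_multiple_copies_of_one_seed_family_still_one_seed(self):
        t = TargetRecord("A", [DomainHit("A", "Pkinase", 1, 250),
                               DomainHit("A", "Pkinase", 300, 550)])
        cls = classify_target(t, _seeds("Pkinase"))
        assert cls.category is TargetCategory.ONE_SEED


class TestMapActivities:
    def test_per_activity_fan_out(self, akt3_target):
        acts = [make_activity(i, i, target="Q9Y243") for i in (1, 2, 3)]
        rows = map_activities([akt3_target], _seeds("Pkinase"), acts)
        assert len(rows) == 3
        assert {r.domain for r in rows} == {"Pkinase"}
        assert {r.maptype for r in rows} == {MapType.MULTI}

    def test_conflict_target_yields_no_rows(self, akt3_target):
        acts = [make_activity(1, target="Q9Y243")]
        assert map_activities([akt3_target], _seeds("Pkinase", "PH"), acts) == []

    def test_single_domain_target_gets_maptype_single(self, trypsin_target):
        rows = map_activities([trypsin_target], _seeds("Trypsin"),
                              [make_activity(target="P00760")])
        assert rows[0].maptype is MapType.SINGLE

    def test_unknown_target_skipped(self, trypsin_target, caplog):
        rows = map_activities([trypsin_target], _seeds("Trypsin"),
                              [make_activity(target="NOPE")])
        assert rows == []

    def test_mapping_soundness_on_random_fixtures(self):
        """Every emitted domain is a seed and occurs in the target architecture."""
        for seed in range(5):
            conf = SyntheticConfig(rng_seed=seed, n_targets=80)
            targets, _, truth = generate_proteome(conf)
            acts = generate_activities(targets, truth, conf)
            m = DomainLigandMapper().fit(targets.values(), acts)
            for row in m.predict(acts):
                assert row.domain in m.seed_set_
                assert row.domain in targets[row.target_accession].families

    def test_heuristic_equals_brute_force_oracle(self):
        for seed in range(10):
            conf = SyntheticConfig(rng_seed=1000 + seed, n_targets=60)
            targets, _, truth = generate_proteome(conf)
            acts = generate_activities(targets, truth, conf)
            m = DomainLigandMapper().fit(targets.values(), acts)
            got = [(r.activity_id, r.domain, r.compound_id, r.target_accession,
                    r.maptype.value) for r in m.predict(acts)]
            oracle_seeds, oracle_map = brute_force_mapping(targets.values(), acts)
            assert m.seed_set_.families == oracle_seeds
            assert got == oracle_map

    def test_determinism_identical_inputs_identical_output(self, tmp_path):
        from chempfam.io import write_mappings
        conf = SyntheticConfig(rng_seed=7, n_targets=50)
        targets, _, truth = generate_proteome(conf)
        acts = generate_activities(targets, truth, conf)
        outs = []
        for i in range(2):
            rows = DomainLigandMapper().fit_predict(targets.values(), acts)
            p = tmp_path / f"m{i}.tsv"
            write_mappings(rows, p)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]


class TestCooccurrence:
    def test_never_alone_family_flagged_at_threshold(self):
        targets = [TargetRecord(f"A{i}", [DomainHit(f"A{i}", "X", 1, 90),
                                          DomainHit(f"A{i}", "Y", 100, 190)])
                   for i in range(150)]
        targets.append(TargetRecord("B", [DomainHit("B", "Y", 1, 90)]))
        _, candidates = cooccurrence_report(targets, _seeds("Y"), min_count=100)
        row = candidates.set_index("family").loc["X"]
        assert row["n_targets"] == 150 and bool(row["flagged"])
        assert "Y" not in candidates["family"].values  # occurs alone once

    def test_all_single_domain_targets_give_empty_candidates(self):
        targets = [TargetRecord(f"T{i}", [DomainHit(f"T{i}", f"F{i}", 1, 50)])
                   for i in range(5)]
        pairs, candidates = cooccurrence_report(targets, _seeds("F0"))
        assert pairs.empty and candidates.empty

    def test_pair_counts_match_brute_force(self):
        conf = SyntheticConfig(rng_seed=3, n_targets=50)
        targets, _, truth = generate_proteome(conf)
        seeds = _seeds(*truth.expected_seed_families)
        pairs, _ = cooccurrence_report(targets.values(), seeds)
        got = {(r.family_a, r.family_b): r.n_targets
               for r in pairs.itertuples(index=False)}
        assert got == brute_force_pair_counts(targets.values(),
                                              truth.expected_seed_families)


class TestEstimatorApi:
    def test_get_set_params_round_trip(self):
        m = DomainLigandMapper(threshold_molar=1e-6)
        params = m.get_params()
        assert params["threshold_molar"] == 1e-6
        m2 = DomainLigandMapper().set_params(**params)
        assert m2.threshold_molar == 1e-6

    def test_predict_before_fit_raises(self):
        with pytest.raises(RuntimeError):
            DomainLigandMapper().predict([])

    def test_manual_seed_survives_without_activity_data(self, akt3_target):
        m = DomainLigandMapper(manual_seeds=("Pkinase_Tyr",))
        m.fit([akt3_target], [])
        assert "Pkinase_Tyr" in m.seed_set_
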