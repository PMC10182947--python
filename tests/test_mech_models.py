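import json

import numpy as np
import pandas as pd
import pytest

from mechtox import (
    MECHANISMS,
    CompoundSpec,
    GeneratorConfig,
    StudyDesign,
    TrainedModels,
    ValidationError,
    assemble_training,
    concordance_summary,
    demo_test_design,
    export_radar,
    generate_study,
    predict_profiles,
    preprocess_study,
    rank_biomarkers,
    train_all,
)
from mechtox.mech_models import ToxicityProfile

from conftest import make_table


@pytest.fixture(scope="module")
def trained_setup(small_design, small_signatures, fast_train_config):
    cfg = GeneratorConfig(n_features=200, seed=42)
    table = generate_study(small_design, small_signatures, cfg)
    prep = preprocess_study(table)
    assembly = assemble_training(prep.table)
    trained = train_all(prep.table, assembly, fast_train_config)
    return prep.table, assembly, trained, cfg


class TestAssembly:
    def test_every_model_partitions_the_usable_samples(self, trained_setup):
        table, assembly, _, _ = trained_setup
        usable = set(
            table.samples.index[table.samples["type"].isin(["control", "treated"])]
        )
        for mid in assembly.positives:
            pos = set(assembly.positives[mid])
            neg = set(assembly.negatives[mid])
            assert pos and neg
            assert not pos & neg
            if mid == "TOX":
                assert pos | neg <= usable
            else:
                assert pos | neg == usable

    def test_tox_negatives_are_nontoxic_and_controls(self, trained_setup):
        table, assembly, _, _ = trained_setup
        s = table.samples
        for sid in assembly.negatives["TOX"]:
            row = s.loc[sid]
            assert row["type"] == "control" or row["mechanism_label"] == "NT"

    def test_missing_chol_compounds_raise(self, small_signatures):
        design = StudyDesign(
            tuple(
                CompoundSpec(f"c{m}", m, ic10=10, ic50=100)
                for m in ("OS", "MI", "APT", "ST")
            ),
            n_batches=1,
        )
        t = generate_study(
            design,
            [s for s in small_signatures if s.mechanism != "CHOL"],
            GeneratorConfig(n_features=200, seed=0),
        )
        with pytest.raises(ValidationError, match="CHOL"):
            assemble_training(t)

    def test_secondary_mechanism_counts_only_with_dual_label(self):
        design = StudyDesign(
            (
                CompoundSpec("a", "OS", ic10=5, ic50=50,
                             mechanism_secondary="APT"),
                CompoundSpec("b", "APT", ic10=5, ic50=50),
                CompoundSpec("c", "MI", ic10=5, ic50=50),
                CompoundSpec("d", "ST", ic10=5, ic50=50),
                CompoundSpec("e", "CHOL", ic10=5, ic50=50),
            ),
            n_batches=1,
        )
        t = generate_study(design, [], GeneratorConfig(n_features=20, seed=0))
        t.samples["mechanism_secondary"] = [
            {"a": "APT"}.get(c) for c in t.samples["compound"]
        ]
        primary_only = assemble_training(t)
        dual = assemble_training(t, dual_label=True)
        a_ids = set(t.samples.index[t.samples["compound"] == "a"])
        assert not a_ids & set(primary_only.positives["APT"])
        assert a_ids <= set(dual.positives["APT"])
        assert a_ids <= set(dual.positives["OS"])


class TestTraining:
    def test_fixed_seed_reproduces_model_artefacts(self, trained_setup,
                                                   fast_train_config):
        table, assembly, trained, _ = trained_setup
        again = train_all(table, assembly, fast_train_config)
        d1 = {m: trained.models[m].to_dict() for m in trained.models}
        d2 = {m: again.models[m].to_dict() for m in again.models}
        assert json.dumps(d1, sort_keys=True, default=str) == json.dumps(
            d2, sort_keys=True, default=str
        )

    def test_threshold_comes_from_the_models_roc(self, trained_setup):
        from mechtox import select_threshold

        _, _, trained, _ = trained_setup
        for mm in trained.models.values():
            assert mm.threshold == select_threshold(mm.roc)

    def test_chol_flagged_non_validated(self, trained_setup):
        _, _, trained, _ = trained_setup
        assert not trained.models["CHOL"].validated
        assert all(trained.models[m].validated for m in trained.models
                   if m != "CHOL")

    def test_serialization_round_trip_preserves_predictions(self, tmp_path,
                                                            trained_setup):
        table, _, trained, _ = trained_setup
        path = tmp_path / "models.json"
        trained.save(path)
        back = TrainedModels.load(path)
        ids = trained.models["TOX"].sample_ids[:10]
        Z = trained.scaler.transform(table.intensities.loc[ids])
        np.testing.assert_array_equal(
            trained.models["TOX"].fit.predict(Z),
            back.models["TOX"].fit.predict(back.scaler.transform(
                table.intensities.loc[ids]
            )),
        )
        assert back.models["OS"].threshold == trained.models["OS"].threshold

    def test_missing_values_rejected_unless_imputed(self, trained_setup,
                                                    fast_train_config):
        table, assembly, _, _ = trained_setup
        broken = table.copy()
        sid = broken.samples.index[broken.samples["type"] == "treated"][0]
        broken.intensities.loc[sid, broken.feature_ids[0]] = np.nan
        with pytest.raises(ValidationError, match="impute"):
            train_all(broken, assembly, fast_train_config)


class TestBiomarkers:
    def test_planted_down_marker_has_negative_direction(self, trained_setup,
                                                        small_signatures):
        table, _, trained, _ = trained_setup
        bio = rank_biomarkers(trained, table, vip_cut=1.5)
        for sig in small_signatures:
            down = {
                f for f, d in zip(sig.marker_features, sig.directions) if d == -1
            }
            hits = bio[(bio["model"] == sig.mechanism)
                       & bio["feature"].isin(down)]
            if len(hits):
                assert (hits["direction"] == -1).all()

    def test_infinite_cut_empties_the_table(self, trained_setup):
        table, _, trained, _ = trained_setup
        assert rank_biomarkers(trained, table, vip_cut=np.inf).empty

    def test_planted_markers_recovered_above_vip_cut(self, trained_setup,
                                                     small_signatures):
        table, _, trained, _ = trained_setup
        bio = rank_biomarkers(trained, table, vip_cut=1.5)
        for sig in small_signatures:
            found = set(bio.loc[bio["model"] == sig.mechanism, "feature"])
            frac = np.mean([m in found for m in sig.marker_features])
            assert frac >= 0.7


class TestPrediction:
    @pytest.fixture(scope="module")
    def profiles(self, trained_setup, small_signatures):
        table, _, trained, cfg = trained_setup
        test_design = demo_test_design(seed=2, n_compounds=10, n_nontoxic=3,
                                       n_batches=2)
        test_cfg = GeneratorConfig(n_features=200, seed=77,
                                   assay_seed=cfg.seed)
        test_raw = generate_study(test_design, small_signatures, test_cfg)
        test_prep = preprocess_study(test_raw, apply_filters=False)
        return (
            predict_profiles(trained, test_prep.table),
            {c.name: c.mechanism_primary for c in test_design.compounds},
        )

    def test_values_clipped_to_unit_interval(self, profiles):
        profs, _ = profiles
        for p in profs:
            for v in p.ypred.values():
                assert 0.0 <= v <= 1.0

    def test_nontoxic_compounds_not_called_toxic(self, profiles):
        profs, truth = profiles
        nt = [p for p in profs if truth[p.compound] == "NT" and not p.excluded]
        assert nt
        frac_negative = np.mean([not p.calls["TOX"] for p in nt])
        assert frac_negative >= 0.8

    def test_tox_index_rises_with_concentration(self, profiles):
        profs, truth = profiles
        by_compound = {}
        for p in profs:
            if truth[p.compound] != "NT" and not p.excluded:
                by_compound.setdefault(p.compound, []).append(p)
        diffs = []
        for plist in by_compound.values():
            plist.sort(key=lambda p: p.concentration)
            diffs.append(plist[-1].ypred["TOX"] - plist[0].ypred["TOX"])
        assert np.median(diffs) > 0

    def test_low_protein_condition_excluded_without_calls(self, trained_setup,
                                                          small_signatures):
        table, _, trained, cfg = trained_setup
        design = StudyDesign(
            (CompoundSpec("hot", "OS", ic10=1.0, ic50=5.0),),
            n_batches=1, design_kind="test_fixed",
            concentrations_fixed=(1e6,),
        )
        gen = GeneratorConfig(n_features=200, seed=5, assay_seed=cfg.seed,
                              protein_cv=0.0, protein_decline=0.9)
        t = generate_study(design, small_signatures[:1], gen)
        profs = predict_profiles(trained, t)
        hot = [p for p in profs if p.compound == "hot"][0]
        assert hot.excluded and hot.exclusion_reason == "LP"
        assert hot.calls == {} and hot.ypred == {}

    def test_feature_mismatch_reported(self, trained_setup):
        table, _, trained, _ = trained_setup
        t = make_table(np.ones((2, 2)), types=["treated", "blank"])
        with pytest.raises(ValidationError, match="lacks training feature"):
            predict_profiles(trained, t)


class TestConcordance:
    def mk_profile(self, compound, conc, calls):
        ypred = {m: (0.9 if calls.get(m) else 0.1)
                 for m in ("TOX",) + MECHANISMS}
        return ToxicityProfile(compound, conc, ypred,
                               {m: bool(calls.get(m)) for m in ypred},
                               n_wells=4)

    def test_perfect_agreement_scores_100(self):
        profs = [self.mk_profile("a", c, {"TOX": True, "OS": True})
                 for c in (1.0, 10.0)]
        out = concordance_summary(profs, {"a": "OS"})
        assert (out["mechanism_concordance_pct"] == 100.0).all()
        assert (out["tox_positive_pct"] == 100.0).all()

    def test_no_calls_scores_zero(self):
        profs = [self.mk_profile("a", 1.0, {}), self.mk_profile("b", 1.0, {})]
        out = concordance_summary(profs, {"a": "OS", "b": "MI"})
        assert (out["mechanism_concordance_pct"] == 0.0).all()

    def test_nontoxic_compounds_ignored(self):
        profs = [self.mk_profile("a", 1.0, {"OS": True}),
                 self.mk_profile("n", 1.0, {})]
        out = concordance_summary(profs, {"a": "OS", "n": "NT"})
        assert out.loc[0, "n"] == 1


class TestRadarExport:
    def test_round_trip_and_polygon_count(self, tmp_path):
        profs = [
            ToxicityProfile("a", c, {m: 0.5 for m in ("TOX",) + MECHANISMS},
                            {m: False for m in ("TOX",) + MECHANISMS},
                            n_wells=4)
            for c in (1.0, 10.0, 100.0, 1000.0)
        ]
        path = tmp_path / "radar.json"
        data = export_radar(profs, path)
        back = json.loads(path.read_text())
        assert len(back["a"]["concentrations"]) == 4
        assert back["a"]["axes"] == ["TOX", "OS", "MI", "APT", "ST"]
        for entry in back["a"]["concentrations"]:
            assert entry["values"] == [0.5] * 5

    def test_all_zero_profile_is_a_degenerate_point(self, tmp_path):
        profs = [
            ToxicityProfile("z", 1.0, {m: 0.0 for m in ("TOX",) + MECHANISMS},
                            {m: False for m in ("TOX",) + MECHANISMS},
                            n_wells=4)
        ]
        data = export_radar(profs, tmp_path / "r.json")
        assert data["z"]["concentrations"][0]["values"] == [0.0] * 5

    def test_empty_profile_list_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            export_radar([], tmp_path / "r.json")
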